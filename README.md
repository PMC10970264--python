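# plastotype

Chloroplast marker-panel design and maternal-lineage genotyping for
maize plastome panels.

Maize chloroplast genomes are haploid, maternally inherited, and
conserved enough that a species-wide panel carries only on the order of
a hundred SNP/InDel loci — yet those loci split cultivars into a
handful of chloroplast groups tied to cytoplasm types, including the
C-, S- and T-type male-sterile (CMS) cytoplasms. A small set of
group-diagnostic markers therefore answers questions nuclear markers
cannot: *which parent was the mother of this hybrid?* *which direction
was this reciprocal cross made?* *which CMS cytoplasm does this line
carry?*

`plastotype` is the desk-side pipeline for building and using such a
panel, aimed at breeders and germplasm curators working from assembled,
aligned plastomes:

* **variant discovery** — SNP calling by alignment column scan, and
  InDel calling that merges adjacent gap columns with identical carrier
  patterns into single events;
* **marker filtering** — strict <1 % minor-allele-frequency
  elimination and a 60 bp conserved-flank eligibility rule;
* **specificity** — one-vs-rest Weir–Cockerham (1984) F_st per locus
  and group, computed on haploid calls encoded as homozygous diploids;
  a locus is group-specific when exactly one group exceeds
  F_st > 0.9;
* **panel selection** — one-locus-per-group, or the provably smallest
  subset whose per-group allele signatures are pairwise distinct;
* **KASP assay design** — allele-specific FAM/HEX primers whose
  3'-terminal base discriminates the alleles, plus a common reverse
  primer, sized to a 58 °C nearest-neighbor Tm target; and an auditor
  for existing marker tables;
* **lineage** — strict-concordance trio verdicts, reciprocal-cross
  resolution and cytoplasm classification;
* **synthetic panels** — a seeded generator of quadripartite plastome
  alignments with planted, fully known variation, so every stage is
  testable end to end without any sequence download.

The package ships the published 59-marker Varietal Chloroplast Panel
(VCP) table as a fixture (`plastotype.io.packaged_marker_table()`).

## Worked example

```python
from plastotype.simulate import SimulationConfig, generate_panel
from plastotype.variants import build_inventory
from plastotype.panel import (assign_specificity, build_signatures,
                              select_core_panel)
from plastotype.lineage import trace_trios

aln, gene_map, truth = generate_panel(SimulationConfig(seed=1))
inv = build_inventory(aln, gene_map)
print(f"{aln.n_samples} samples, {inv.n_snps} SNPs + {inv.n_indels} InDels "
      f"(1 per {inv.bp_per_variant:.0f} bp)")

groups = sorted(aln.groups())
results = assign_specificity(inv.loci, aln.samples, groups, threshold=0.9)
signatures = build_signatures(inv.loci, aln.samples, groups)
panel = select_core_panel(results, signatures, groups, policy="one-per-group")
print("core panel:", ", ".join(panel.locus_ids))

for trio in trace_trios(aln, panel, loci=inv.loci):
    print(trio.hybrid_id, trio.verdict,
          f"({trio.mismatch_father} father mismatches)")
```

prints

```
24 samples, 40 SNPs + 3 InDels (1 per 465 bp)
core panel: CPMSNP25, CPMSNP09, CPMSNP05, CPMIDP01, CPMSNP03
HYB01 maternal=mother (2 father mismatches)
HYB02 maternal=mother (2 father mismatches)
HYB03 maternal=mother (2 father mismatches)
HYB04 maternal=mother (2 father mismatches)
```

The 24 samples are 5 chloroplast groups × 4 cultivars plus 4 hybrids
from two trios and one reciprocal pair. All 43 planted loci are
recovered; the selected panel holds one maximally differentiated locus
per group (here including a group-diagnostic InDel); and every hybrid
matches its true mother at all five panel loci while mismatching the
other parent, so each cross — including both directions of the
reciprocal pair — is resolved to its maternal lineage.

The same stages are available as a CLI:

```sh
plastotype run-all -o run/ --seed 1        # simulate + all stages + manifest
plastotype validate-markers                 # audit the packaged VCP table
plastotype call-variants --aln panel.fa --sheet samples.tsv \
    --genes genes.bed -o out/               # VCF 4.2 + TSV + inventory JSON
```

`run-all` writes a manifest with SHA-256 hashes of every artifact;
identical seed and config reproduce identical hashes.

## Layout

```
src/plastotype/
  io.py         readers/writers: FASTA+sheet, BED/GFF3, VCF 4.2, marker TSV
  simulate.py   seeded synthetic plastome panels with ground truth
  summary.py    quadripartite structure detection, genome summary
  variants.py   SNP/InDel calling, annotation, flanks, density
  panel.py      MAF filter, WC84 F_st, specificity, panel selection
  kasp.py       primer design, Tm estimation, marker-table audit
  lineage.py    panel genotyping, trio verdicts, cytoplasm calls
  cli.py        click CLI wiring the stages together
  data/         packaged VCP marker table (59 markers)
```

See `docs/methods.md` for the statistical model, design decisions and
known limitations.
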