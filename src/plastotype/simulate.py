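"""Synthetic plastome panels with planted, fully known variation.

The generator emulates the statistical structure of a maize plastome
panel: quadripartite genomes (LSC–IRa–SSC–IRb, IRb the exact reverse
complement of IRa), a handful of chloroplast groups, group-diagnostic
SNPs (fixed within their group, fixed for the other allele everywhere
else), shared SNPs that cut across groups, rare singleton alleles,
multi-base InDels planted as alignment gap blocks, invariant flanks
around every locus, and trios whose hybrids inherit the maternal
plastome byte-for-byte.

Plastomes are highly conserved within a species, so the background
mutation model is "none": outside planted loci all samples are
identical to the reference (an optional ``noise_rate`` exists for
robustness experiments and defaults to 0, keeping truth recovery
exact).

Every draw comes from a child stream of one global seed
(``numpy.random.SeedSequence.spawn``), so adding a component never
perturbs earlier draws and a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import CapacityError, ConfigError
from .io import (
    PathLike,
    write_alignment,
    write_gene_map,
)
from .model import (
    DELETION,
    GROUPS,
    GeneInterval,
    GeneMap,
    PlastomeAlignment,
    SampleRecord,
)

_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMP)[::-1].decode("ascii")


@dataclass(frozen=True)
class TrioSpec:
    """One cross to simulate: mother group × father group."""

    mother_group: str
    father_group: str
    n_hybrids: int = 1
    reciprocal: bool = False


#: Default crosses: two straight trios plus one reciprocal pair, echoing
#: a validation design of trios, reciprocal crosses and CMS-line crosses.
DEFAULT_TRIOS = (
    TrioSpec("H", "B", 1, False),
    TrioSpec("C", "B", 1, False),
    TrioSpec("T", "D", 1, True),
)


@dataclass
class SimulationConfig:
    """Desk-scale defaults: a 20 kb genome with the region proportions of
    a real plastome; full scale (140,600 bp, 176 samples) is reachable by
    overriding ``genome_length``/``samples_per_group``."""

    seed: int = 1
    genome_length: int = 20_000
    region_lengths: Optional[tuple[int, int, int]] = None  # (LSC, IR, SSC)
    n_groups: int = 5
    samples_per_group: int = 4
    n_group_diagnostic_snps: int = 5
    n_shared_snps: int = 10
    n_indels: int = 3
    indel_length_range: tuple[int, int] = (1, 85)
    n_rare_alleles: int = 5
    n_genic_snps: int = 5
    flank_width: int = 60
    gc_content: float = 0.384
    gene_counts: tuple[int, int, int] = (8, 4, 2)  # protein_coding, tRNA, rRNA
    gene_length_range: tuple[int, int] = (150, 400)
    trios: tuple[TrioSpec, ...] = DEFAULT_TRIOS
    cms_groups: tuple[str, ...] = ("C", "T")
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_groups < 2 or self.n_groups > len(GROUPS):
            raise ConfigError(f"n_groups must be in [2, {len(GROUPS)}]")
        if self.region_lengths is None:
            # proportions of the printed outgroup genome (82,928 / 22,750 /
            # 12,554 of 140,982)
            lsc = round(self.genome_length * 0.5882)
            ir = round(self.genome_length * 0.1614)
            self.region_lengths = (lsc, ir, self.genome_length - lsc - 2 * ir)
        lsc, ir, ssc = self.region_lengths
        if lsc + 2 * ir + ssc != self.genome_length:
            raise ConfigError(
                f"region lengths {self.region_lengths} do not sum to "
                f"genome_length {self.genome_length}"
            )
        if min(lsc, ir, ssc) <= 2 * self.flank_width:
            raise ConfigError("regions too small for the requested flank width")
        groups = self.group_labels
        for t in self.trios:
            if t.mother_group not in groups or t.father_group not in groups:
                raise ConfigError(
                    f"trio {t} references a group outside {groups}"
                )
        if not 0.0 <= self.noise_rate < 1.0:
            raise ConfigError("noise_rate must be in [0, 1)")

    @property
    def group_labels(self) -> tuple[str, ...]:
        return GROUPS[: self.n_groups]


@dataclass
class PlantedLocus:
    """Ground truth for one planted variant."""

    locus_id: str
    kind: str                      # "SNP" | "InDel"
    cols: tuple[int, int]
    alleles: list[str]
    allele_by_sample: list[str]    # allele string per sample, panel order
    group: Optional[str]           # diagnostic group, or None
    origin: str                    # diagnostic | shared | rare | indel
    genic: bool = False


@dataclass
class TruthSet:
    loci: list[PlantedLocus]
    true_mother: dict[str, str]        # hybrid id -> mother sample id
    group_of: dict[str, str]           # sample id -> group
    reference: str                      # ungapped reference genome
    region_bounds: tuple[int, int, int, int]  # starts of IRa, SSC, IRb, end

    def singleton_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci if l.origin == "rare"]

    def diagnostic_ids(self) -> dict[str, str]:
        return {l.locus_id: l.group for l in self.loci if l.group is not None}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _place_genes(
    cfg: SimulationConfig, rng: np.random.Generator
) -> GeneMap:
    """Non-overlapping gene intervals in the single-copy regions."""
    lsc, ir, ssc = cfg.region_lengths
    ssc_start = lsc + ir
    regions = [("LSC", 0, lsc), ("SSC", ssc_start, ssc_start + ssc)]
    wanted = (
        [("protein_coding", cfg.gene_counts[0]), ("tRNA", cfg.gene_counts[1]),
         ("rRNA", cfg.gene_counts[2])]
    )
    intervals: list[GeneInterval] = []
    occupied: list[tuple[int, int]] = []
    counter = 0
    for category, count in wanted:
        for _ in range(count):
            length = (
                int(rng.integers(*cfg.gene_length_range))
                if category != "tRNA"
                else int(rng.integers(70, 90))
            )
            placed = False
            for _attempt in range(200):
                rname, rstart, rend = regions[int(rng.integers(len(regions)))]
                if rend - rstart < length + 2:
                    continue
                s = int(rng.integers(rstart, rend - length))
                e = s + length
                if all(e <= os or s >= oe for os, oe in occupied):
                    counter += 1
                    prefix = {"protein_coding": "pcg", "tRNA": "trn", "rRNA": "rrn"}
                    intervals.append(
                        GeneInterval(
                            name=f"{prefix[category]}{counter:02d}",
                            start=s,
                            end=e,
                            category=category,
                            region=rname,
                        )
                    )
                    occupied.append((s, e))
                    placed = True
                    break
            if not placed:
                raise CapacityError(
                    f"cannot place a {category} gene of {length} bp; "
                    "reduce gene_counts or enlarge the genome"
                )
    return GeneMap(intervals=intervals)


class _Planner:
    """Sequential random placement of locus intervals with an exclusion
    zone of ``min_gap`` between interval boundaries, tracked as boolean
    masks so every remaining valid start stays reachable."""

    def __init__(self, rng: np.random.Generator, min_gap: int, n: int) -> None:
        self.rng = rng
        self.min_gap = min_gap
        self.n = n
        self.blocked = np.zeros(n, dtype=bool)  # too close to a chosen locus
        self.chosen: list[tuple[int, int]] = []

    def _invalidate(self, start: int, end: int) -> None:
        lo = max(0, start - self.min_gap)
        hi = min(self.n, end + self.min_gap)
        self.blocked[lo:hi] = True
        self.chosen.append((start, end))

    def place(self, allowed: np.ndarray, span: int, what: str) -> int:
        """Pick one start uniformly from positions whose whole block fits."""
        ok = allowed & ~self.blocked
        if span > 1:
            # block must fit inside `allowed`, clear of exclusion zones
            window = np.lib.stride_tricks.sliding_window_view(
                allowed & ~self.blocked, span
            ).all(axis=1)
            candidates = np.flatnonzero(window)
        else:
            candidates = np.flatnonzero(ok)
        if candidates.size == 0:
            raise CapacityError(
                f"cannot place another separated {what} locus: genome too "
                "small for the requested flank separation"
            )
        start = int(candidates[int(self.rng.integers(candidates.size))])
        self._invalidate(start, start + span)
        return start

    def place_many(self, allowed: np.ndarray, spans: Sequence[int],
                   what: str) -> list[int]:
        return [self.place(allowed, s, what) for s in spans]


def generate_panel(
    config: SimulationConfig,
) -> tuple[PlastomeAlignment, GeneMap, TruthSet]:
    """Simulate an aligned plastome panel with fully known ground truth."""
    cfg = config
    rng_genome, rng_genes, rng_pos, rng_alleles, rng_trio, rng_noise = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(6)
    )
    lsc, ir, ssc = cfg.region_lengths
    ira_start, ssc_start, irb_start = lsc, lsc + ir, lsc + ir + ssc
    single = _random_sequence(rng_genome, lsc + ir + ssc, cfg.gc_content)
    ira = single[lsc : lsc + ir]
    reference = single + revcomp(ira)
    assert len(reference) == cfg.genome_length

    gene_map = _place_genes(cfg, rng_genes)

    # --- sample roster -----------------------------------------------------
    groups = cfg.group_labels
    samples: list[SampleRecord] = []
    for g in groups:
        sterile = g in cfg.cms_groups
        for i in range(cfg.samples_per_group):
            samples.append(
                SampleRecord(
                    sample_id=f"{g}{i + 1:02d}",
                    group=g,
                    role="cultivar",
                    fertility="sterile" if sterile else "fertile",
                )
            )
    by_group = {g: [s for s in samples if s.group == g] for g in groups}

    # trio parents chosen first so rare alleles can avoid them
    trio_rows: list[tuple[str, str, str]] = []  # (hybrid, mother, father)
    parent_ids: set[str] = set()
    hybrid_counter = 0
    for spec in cfg.trios:
        mother = by_group[spec.mother_group][
            int(rng_trio.integers(len(by_group[spec.mother_group])))
        ]
        father = by_group[spec.father_group][
            int(rng_trio.integers(len(by_group[spec.father_group])))
        ]
        mother.role = "parent"
        father.role = "parent"
        parent_ids.update((mother.sample_id, father.sample_id))
        for _ in range(spec.n_hybrids):
            hybrid_counter += 1
            trio_rows.append(
                (f"HYB{hybrid_counter:02d}", mother.sample_id, father.sample_id)
            )
            if spec.reciprocal:
                hybrid_counter += 1
                trio_rows.append(
                    (f"HYB{hybrid_counter:02d}", father.sample_id, mother.sample_id)
                )

    # --- choose locus positions -------------------------------------------
    w = cfg.flank_width
    min_gap = 2 * w  # gap between locus intervals must exceed this
    in_gene = np.zeros(cfg.genome_length, dtype=bool)
    for iv in gene_map.intervals:
        in_gene[iv.start : iv.end] = True
    single_copy = np.zeros(cfg.genome_length, dtype=bool)
    single_copy[w : ira_start] = True            # LSC, clear of the genome edge
    single_copy[ssc_start:irb_start] = True      # SSC
    genic_candidates = np.flatnonzero(single_copy & in_gene)
    inter_candidates = np.flatnonzero(single_copy & ~in_gene)

    n_snps = cfg.n_group_diagnostic_snps * cfg.n_groups + cfg.n_shared_snps
    if cfg.n_genic_snps > n_snps:
        raise ConfigError("n_genic_snps exceeds the total SNP count")
    genic_mask = single_copy & in_gene
    inter_mask = single_copy & ~in_gene
    planner = _Planner(rng_pos, min_gap, cfg.genome_length)
    # longest blocks first: InDels, then the point loci
    lo, hi = cfg.indel_length_range
    indel_lengths = sorted(
        (int(rng_pos.integers(lo, hi + 1)) for _ in range(cfg.n_indels)),
        reverse=True,
    )
    indel_starts = planner.place_many(inter_mask, indel_lengths, "InDel")
    genic_pos = planner.place_many(
        genic_mask, [1] * cfg.n_genic_snps, "genic SNP"
    )
    inter_needed = n_snps - cfg.n_genic_snps + cfg.n_rare_alleles
    inter_pos = planner.place_many(
        inter_mask, [1] * inter_needed, "intergenic SNP"
    )

    snp_positions = genic_pos + inter_pos[: n_snps - cfg.n_genic_snps]
    rare_positions = inter_pos[n_snps - cfg.n_genic_snps :]

    # --- allele assignment -------------------------------------------------
    n_core = len(samples)
    seq_arr = np.tile(
        np.frombuffer(reference.encode("ascii"), dtype="S1"), (n_core, 1)
    ).copy()
    sample_index = {s.sample_id: i for i, s in enumerate(samples)}
    group_rows = {
        g: [sample_index[s.sample_id] for s in by_group[g]] for g in groups
    }

    planted: list[dict] = []  # interim records, resolved to ids after sorting

    def _alt_base(pos: int) -> str:
        refb = reference[pos]
        others = [b for b in "ACGT" if b != refb]
        return others[int(rng_alleles.integers(3))]

    snp_iter = iter(snp_positions)
    for g in groups:  # diagnostic SNPs
        for _ in range(cfg.n_group_diagnostic_snps):
            pos = next(snp_iter)
            alt = _alt_base(pos)
            seq_arr[group_rows[g], pos] = alt.encode()
            planted.append(
                dict(kind="SNP", cols=(pos, pos + 1), group=g, origin="diagnostic")
            )
    for _ in range(cfg.n_shared_snps):  # shared SNPs: half of two groups each
        pos = next(snp_iter)
        alt = _alt_base(pos)
        g1, g2 = rng_alleles.choice(len(groups), size=2, replace=False)
        rows = []
        for gi in (g1, g2):
            members = group_rows[groups[gi]]
            k = max(1, len(members) // 2)
            rows.extend(members[:k])
        seq_arr[rows, pos] = alt.encode()
        planted.append(dict(kind="SNP", cols=(pos, pos + 1), group=None,
                            origin="shared"))
    eligible_rare = [
        i for s, i in sample_index.items()
        if samples[i].sample_id not in parent_ids
    ]
    for pos in rare_positions:  # singleton private alleles
        alt = _alt_base(pos)
        row = eligible_rare[int(rng_alleles.integers(len(eligible_rare)))]
        seq_arr[row, pos] = alt.encode()
        planted.append(dict(kind="SNP", cols=(pos, pos + 1), group=None,
                            origin="rare"))
    # InDel carriers come from the non-reference groups only: the first
    # sample defines the ungapped coordinate frame shared with the gene
    # map, so it never carries a gap block.
    indel_groups = groups[1:]
    for s, L in zip(indel_starts, indel_lengths):  # InDels: gap blocks
        # carriers: a whole group (diagnostic-style) or halves of two groups
        if len(indel_groups) < 2 or rng_alleles.random() < 0.6:
            g = indel_groups[int(rng_alleles.integers(len(indel_groups)))]
            rows = group_rows[g]
            group = g
        else:
            g1, g2 = rng_alleles.choice(len(indel_groups), size=2,
                                        replace=False)
            rows = []
            for gi in (g1, g2):
                members = group_rows[indel_groups[gi]]
                rows.extend(members[: max(1, len(members) // 2)])
            group = None
        seq_arr[rows, s : s + L] = b"-"
        planted.append(dict(kind="InDel", cols=(s, s + L), group=group,
                            origin="indel"))

    if cfg.noise_rate > 0:
        mask = rng_noise.random(seq_arr.shape) < cfg.noise_rate
        flips = rng_noise.integers(0, 4, size=int(mask.sum()))
        bases = np.frombuffer(b"ACGT", dtype="S1")
        seq_arr[mask] = bases[flips]

    # --- hybrids: byte-identical maternal plastomes ------------------------
    hybrid_records = []
    hybrid_seqs = []
    true_mother = {}
    for hyb_id, mother_id, father_id in trio_rows:
        m_row = sample_index[mother_id]
        hybrid_records.append(
            SampleRecord(
                sample_id=hyb_id,
                group=samples[m_row].group,
                role="hybrid",
                mother_id=mother_id,
                father_id=father_id,
                fertility="unknown",
            )
        )
        hybrid_seqs.append(seq_arr[m_row].copy())
        true_mother[hyb_id] = mother_id

    all_samples = samples + hybrid_records
    if hybrid_seqs:
        seq_arr = np.vstack([seq_arr] + [s[None, :] for s in hybrid_seqs])
    sequences = [row.tobytes().decode("ascii") for row in seq_arr]
    alignment = PlastomeAlignment(samples=all_samples, sequences=sequences)

    # --- resolve locus ids and truth genotypes -----------------------------
    planted.sort(key=lambda d: d["cols"][0])
    n_snp_id = n_indel_id = 0
    loci: list[PlantedLocus] = []
    for rec in planted:
        s, e = rec["cols"]
        if rec["kind"] == "SNP":
            n_snp_id += 1
            locus_id = f"CPMSNP{n_snp_id:02d}"
            calls = [seq.tobytes().decode() for seq in seq_arr[:, s:e]]
        else:
            n_indel_id += 1
            locus_id = f"CPMIDP{n_indel_id:02d}"
            calls = [
                row.tobytes().decode().replace("-", "") for row in seq_arr[:, s:e]
            ]
        alleles: list[str] = []
        for c in calls:
            if c not in alleles:
                alleles.append(c)
        loci.append(
            PlantedLocus(
                locus_id=locus_id,
                kind=rec["kind"],
                cols=(s, e),
                alleles=alleles,
                allele_by_sample=calls,
                group=rec["group"],
                origin=rec["origin"],
                genic=bool(in_gene[s]) if rec["kind"] == "SNP" else False,
            )
        )

    truth = TruthSet(
        loci=loci,
        true_mother=true_mother,
        group_of={s.sample_id: s.group for s in all_samples if s.group},
        reference=reference,
        region_bounds=(ira_start, ssc_start, irb_start, cfg.genome_length),
    )
    return alignment, gene_map, truth


# ---------------------------------------------------------------------------
# fixture emission + truth round trip
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["locus_id", "kind", "aln_start", "aln_end", "group", "origin",
                 "genic", "alleles"]


def write_truth(truth: TruthSet, aln: PlastomeAlignment, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS + aln.sample_ids) + "\n")
        for l in truth.loci:
            row = [
                l.locus_id, l.kind, str(l.cols[0]), str(l.cols[1]),
                l.group or "", l.origin, str(l.genic).lower(),
                ",".join(a if a else "-" for a in l.alleles),
            ] + [a if a else "-" for a in l.allele_by_sample]
            fh.write("\t".join(row) + "\n")


def read_truth(path: PathLike, aln: PlastomeAlignment) -> TruthSet:
    """Rebuild a TruthSet's locus table from a truth TSV (pedigree and group
    information come from the alignment's sample sheet)."""
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fixed = len(TRUTH_COLUMNS)
        sample_ids = header[n_fixed:]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            alleles = [DELETION if a == "-" else a for a in f[7].split(",")]
            calls = [DELETION if a == "-" else a for a in f[n_fixed:]]
            loci.append(
                PlantedLocus(
                    locus_id=f[0],
                    kind=f[1],
                    cols=(int(f[2]), int(f[3])),
                    alleles=alleles,
                    allele_by_sample=calls,
                    group=f[4] or None,
                    origin=f[5],
                    genic=f[6] == "true",
                )
            )
    if sample_ids != aln.sample_ids:
        raise ConfigError("truth TSV sample order differs from the alignment")
    true_mother = {
        s.sample_id: s.mother_id for s in aln.samples if s.role == "hybrid"
    }
    return TruthSet(
        loci=loci,
        true_mother=true_mother,
        group_of={s.sample_id: s.group for s in aln.samples if s.group},
        reference=aln.sequences[0].replace("-", ""),
        region_bounds=(0, 0, 0, 0),
    )


def emit_fixture(config: SimulationConfig, out_dir: PathLike) -> dict[str, Path]:
    """Write the four pipeline input files: FASTA, sheet, gene BED, truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln, gene_map, truth = generate_panel(config)
    paths = {
        "fasta": out / "panel.fa",
        "sheet": out / "samples.tsv",
        "genes": out / "genes.bed",
        "truth": out / "truth.tsv",
    }
    write_alignment(aln, paths["fasta"], paths["sheet"])
    write_gene_map(gene_map, paths["genes"])
    write_truth(truth, aln, paths["truth"])
    return paths
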