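"""SNP and InDel calling from a plastome multiple alignment.

Because the input is a gap-aware multiple alignment of haploid genomes,
an exhaustive pairwise comparison of samples reduces to a column scan:

* a gap-free column with two or more distinct unambiguous bases is a SNP
  (``N`` is missing data and never creates an allele);
* maximal runs of adjacent gap-containing columns sharing one identical
  per-sample gap pattern are merged into a single InDel event — two
  adjacent gap runs with different carrier sets remain separate loci.

The merging rule matters in practice: a single biological
insertion/deletion spanning several alignment columns must surface as
one marker, not one per column.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .io import reference_coordinates
from .model import (
    Annotation,
    GeneMap,
    PlastomeAlignment,
    VariantInventory,
    VariantLocus,
)

_GAP = b"-"[0]
_N = b"N"[0]


def _allele_codes(column_calls: list[Optional[str]]) -> tuple[list[str], np.ndarray]:
    """Distinct alleles in order of first appearance + genotype indices."""
    alleles: list[str] = []
    geno = np.empty(len(column_calls), dtype=int)
    for i, call in enumerate(column_calls):
        if call is None:
            geno[i] = -1
            continue
        try:
            geno[i] = alleles.index(call)
        except ValueError:
            alleles.append(call)
            geno[i] = len(alleles) - 1
    return alleles, geno


def call_snps(aln: PlastomeAlignment) -> list[VariantLocus]:
    """One locus per gap-free column with >= 2 distinct non-N bases."""
    arr = aln.to_array().view(np.uint8)
    has_gap = (arr == _GAP).any(axis=0)
    loci: list[VariantLocus] = []
    n_id = 0
    is_n = arr == _N
    # quick polymorphic pre-screen: column differs anywhere from row 0
    candidate = ((arr != arr[0]) | is_n).any(axis=0) & ~has_gap
    for col in np.flatnonzero(candidate):
        column = arr[:, int(col)]
        calls = [
            None if c == _N else chr(c) for c in column
        ]
        distinct = {c for c in calls if c is not None}
        if len(distinct) < 2:
            continue
        alleles, geno = _allele_codes(calls)
        n_id += 1
        loci.append(
            VariantLocus(
                locus_id=f"CPMSNP{n_id:02d}",
                kind="SNP",
                cols=(int(col), int(col) + 1),
                alleles=alleles,
                genotypes=geno,
            )
        )
    return loci


def call_indels(aln: PlastomeAlignment) -> list[VariantLocus]:
    """Merge adjacent gap columns with identical per-sample gap patterns
    into single InDel events; alleles are the gap-stripped subsequences."""
    arr = aln.to_array().view(np.uint8)
    gap = arr == _GAP
    gap_cols = np.flatnonzero(gap.any(axis=0))
    loci: list[VariantLocus] = []
    runs: list[tuple[int, int]] = []
    for col in gap_cols:
        col = int(col)
        if runs and runs[-1][1] == col and np.array_equal(
            gap[:, col], gap[:, col - 1]
        ):
            runs[-1] = (runs[-1][0], col + 1)
        else:
            runs.append((col, col + 1))
    n_id = 0
    for start, end in runs:
        block = arr[:, start:end]
        calls: list[Optional[str]] = []
        for row in block:
            s = row.tobytes().decode("ascii")
            if "N" in s:
                calls.append(None)
            else:
                calls.append(s.replace("-", ""))
        distinct = {c for c in calls if c is not None}
        if len(distinct) < 2:
            continue
        alleles, geno = _allele_codes(calls)
        n_id += 1
        loci.append(
            VariantLocus(
                locus_id=f"CPMIDP{n_id:02d}",
                kind="InDel",
                cols=(start, end),
                alleles=alleles,
                genotypes=geno,
            )
        )
    return loci


def call_variants(aln: PlastomeAlignment) -> list[VariantLocus]:
    """All loci, position-sorted; no alignment column contributes twice."""
    return sorted(call_snps(aln) + call_indels(aln), key=lambda l: l.cols)


def annotate(
    loci: Sequence[VariantLocus],
    gene_map: GeneMap,
    aln: PlastomeAlignment,
    reference_sample: Optional[str] = None,
) -> list[VariantLocus]:
    """Attach genic/intergenic annotation in the reference coordinate frame.

    A locus is genic iff its reference-frame interval intersects a gene
    interval; intergenic loci record the bracketing gene pair.  The
    reference sample (default: first) defines the gap-to-ungapped map.
    """
    ref_idx = 0 if reference_sample is None else aln.index_of(reference_sample)
    coords = reference_coordinates(aln.sequences[ref_idx])
    genes = gene_map.sorted()
    for locus in loci:
        start = int(coords[locus.cols[0]])
        end_col = locus.cols[1]
        end = (
            int(coords[end_col]) if end_col < aln.length
            else int(coords[-1]) + (aln.sequences[ref_idx][-1] != "-")
        )
        if end <= start:  # reference gapped across the locus: anchor point
            end = start + 1
        locus.ref_start, locus.ref_end = start, end
        hit = next(
            (g for g in genes if g.start < end and start < g.end), None
        )
        if hit is not None:
            locus.annotation = Annotation(genic=True, gene=hit.name)
        else:
            before = next(
                (g.name for g in reversed(genes) if g.end <= start), None
            )
            after = next((g.name for g in genes if g.start >= end), None)
            locus.annotation = Annotation(
                genic=False, between=(before or "", after or "")
            )
    return list(loci)


def extract_flanks(
    locus: VariantLocus, aln: PlastomeAlignment, width: int = 60
) -> tuple[str, str, bool]:
    """Flanking alignment columns around a locus + conservation verdict.

    ``flanks_conserved`` is True iff both flanks are full-width, identical
    across every sample, and free of gaps and Ns — the eligibility
    condition for designing allele-specific primers on them.  Truncated
    flanks (locus closer than ``width`` to an alignment edge) are flagged
    on the locus and can never be conserved.
    """
    if width < 1:
        raise DataError("flank width must be >= 1")
    start, end = locus.cols
    left_lo = max(0, start - width)
    right_hi = min(aln.length, end + width)
    truncated = (start - left_lo < width) or (right_hi - end < width)
    left = [seq[left_lo:start] for seq in aln.sequences]
    right = [seq[end:right_hi] for seq in aln.sequences]
    conserved = (
        not truncated
        and len(set(left)) == 1
        and len(set(right)) == 1
        and not set(left[0] + right[0]) - set("ACGT")
    )
    locus.flank_left = left[0]
    locus.flank_right = right[0]
    locus.flanks_conserved = conserved
    locus.flank_truncated = truncated
    return left[0], right[0], conserved


def density(n_loci: int, genome_length: float) -> float:
    """Average spacing: one variant per ``genome_length / n_loci`` bp."""
    if n_loci < 1:
        raise DataError("variant density undefined with zero loci")
    return genome_length / n_loci


def build_inventory(
    aln: PlastomeAlignment,
    gene_map: Optional[GeneMap] = None,
    flank_width: int = 60,
    reference_sample: Optional[str] = None,
) -> VariantInventory:
    """Full discovery pass: call, annotate, extract flanks, summarise.

    The density denominator is the mean ungapped genome length across
    samples (not the alignment length).
    """
    loci = call_variants(aln)
    if gene_map is not None:
        annotate(loci, gene_map, aln, reference_sample=reference_sample)
    for locus in loci:
        extract_flanks(locus, aln, width=flank_width)
    mean_len = float(
        np.mean([len(s) - s.count("-") for s in aln.sequences])
    )
    return VariantInventory.from_loci(loci, genome_length=mean_len)
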