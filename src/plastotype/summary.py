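"""Quadripartite structure detection and per-genome structural summary.

A plastome is circular with four segments: LSC and SSC (single copy)
separated by two inverted repeats, IRa and IRb, that are exact reverse
complements of each other.  ``detect_quadripartite`` finds the longest
exact reverse-complement repeat pair of at least ``min_ir`` bases via
k-mer anchoring (k = 31) with maximal exact extension; circularity is
handled by doubling the sequence.  ``summarize`` then produces the
region lengths, GC content and gene counts by category and region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CoordinateError, DataError, StructureNotFoundError
from .model import GeneMap, GenomeSummary
from .simulate import revcomp


@dataclass(frozen=True)
class QuadripartiteStructure:
    """Region intervals, 0-based half-open on the given (linearised) genome.

    ``lsc`` may wrap the origin of the circular genome, in which case
    ``lsc[1] < lsc[0]`` and the region is [lsc0, n) + [0, lsc1).
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    genome_length: int

    @property
    def ir_length(self) -> int:
        return self.ira[1] - self.ira[0]

    def _span(self, iv: tuple[int, int]) -> int:
        s, e = iv
        return e - s if e >= s else self.genome_length - s + e

    @property
    def lsc_length(self) -> int:
        return self._span(self.lsc)

    @property
    def ssc_length(self) -> int:
        return self._span(self.ssc)

    def region_of(self, pos: int) -> str:
        for name, iv in (("IRa", self.ira), ("IRb", self.irb),
                         ("SSC", self.ssc), ("LSC", self.lsc)):
            s, e = iv
            if e >= s:
                if s <= pos < e:
                    return name
            elif pos >= s or pos < e:
                return name
        raise CoordinateError(f"position {pos} outside genome")


def _longest_rc_repeat(seq: str, min_len: int, k: int = 31) -> tuple[int, int, int]:
    """Longest pair (i, j, L) with seq[i:i+L] == revcomp(seq[j:j+L]), i < j,
    non-overlapping.  Seeds k-mers of the sequence against its reverse
    complement and extends each hit to a maximal exact match.
    """
    n = len(seq)
    if n < 2 * k:
        raise StructureNotFoundError("sequence shorter than the anchor size")
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "?"}
    best = (0, 0, 0)
    seen: dict[int, list[tuple[int, int]]] = {}
    for i in range(n - k + 1):
        kmer = revcomp(seq[i : i + k])
        for j in index.get(kmer, ()):
            if j <= i:
                continue
            # anti-diagonal is invariant under extension
            diag = i + j + k
            covered = False
            for a, b in seen.get(diag, ()):
                if a <= i < b:
                    covered = True
                    break
            if covered:
                continue
            a, b, L = i, j, k  # seq[a:a+L] == rc(seq[b:b+L])
            while a > 0 and b + L < n and seq[a - 1] == comp.get(seq[b + L], "?"):
                a -= 1
                L += 1
            while a + L < n and b > 0 and seq[a + L] == comp.get(seq[b - 1], "?"):
                b -= 1
                L += 1
            seen.setdefault(diag, []).append((a, a + L))
            if L > best[2] and a + L <= b:
                best = (a, b, L)
    if best[2] < min_len:
        raise StructureNotFoundError(
            f"no reverse-complement repeat of >= {min_len} bp found "
            f"(longest: {best[2]} bp)"
        )
    return best


def detect_quadripartite(
    genome: str, min_ir: int = 1000, k: int = 31, circular: bool = True
) -> QuadripartiteStructure:
    """Locate LSC / IRa / SSC / IRb on an ungapped plastome sequence.

    The IR pair is the longest exact reverse-complement repeat of at
    least ``min_ir`` bases; the longer single-copy segment between the
    repeats is the LSC, the shorter the SSC.
    """
    genome = genome.upper().replace("-", "")
    n = len(genome)
    if n <= 4 * min_ir:
        raise DataError(f"genome of {n} bp too short for min_ir={min_ir}")
    if circular:
        # double the sequence so repeats spanning the origin are visible,
        # then reduce coordinates mod n
        i, j, L = _longest_rc_repeat(genome + genome, min_ir, k=k)
        if L > n:  # degenerate: repeat longer than the genome itself
            raise StructureNotFoundError("repeat structure inconsistent")
        i, j = i % n, j % n
    else:
        i, j, L = _longest_rc_repeat(genome, min_ir, k=k)
    ira = (i, (i + L) % n or n)
    irb = (j, (j + L) % n or n)
    gap_a = (irb[0] - ira[1]) % n          # segment between IRa end and IRb start
    gap_b = (ira[0] - irb[1]) % n          # segment wrapping the other way
    seg_a = (ira[1] % n, irb[0])
    seg_b = (irb[1] % n, ira[0])
    if gap_a >= gap_b:
        lsc, ssc = seg_a, seg_b
    else:
        lsc, ssc = seg_b, seg_a
    return QuadripartiteStructure(
        lsc=lsc, ira=ira, ssc=ssc, irb=irb, genome_length=n
    )


def gc_fraction(sequence: str) -> float:
    """GC over unambiguous bases (A, C, G, T) only."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise DataError("sequence contains no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def summarize(
    genome: str,
    gene_map: GeneMap,
    structure: QuadripartiteStructure,
) -> GenomeSummary:
    """Per-genome summary: region lengths, GC, gene counts by category
    and by region.  A gene spanning a boundary counts toward the region
    containing its start."""
    genome = genome.upper().replace("-", "")
    n = len(genome)
    if structure.genome_length != n:
        raise CoordinateError(
            f"structure refers to a {structure.genome_length} bp genome, "
            f"got {n} bp"
        )
    by_region: dict[str, dict[str, int]] = {
        r: {"protein_coding": 0, "tRNA": 0, "rRNA": 0}
        for r in ("LSC", "IRa", "IRb", "SSC")
    }
    counts = {"protein_coding": 0, "tRNA": 0, "rRNA": 0}
    for gene in gene_map.intervals:
        if not 0 <= gene.start < n:
            raise CoordinateError(
                f"gene {gene.name} starts at {gene.start}, outside [0, {n})"
            )
        counts[gene.category] += 1
        by_region[structure.region_of(gene.start)][gene.category] += 1
    ir_len = structure.ir_length
    lsc_len = structure.lsc_length
    ssc_len = n - lsc_len - 2 * ir_len
    return GenomeSummary(
        total_length=n,
        lsc_length=lsc_len,
        ir_length=ir_len,
        ssc_length=ssc_len,
        gc_fraction=gc_fraction(genome),
        n_genes=sum(counts.values()),
        n_protein_coding=counts["protein_coding"],
        n_trna=counts["tRNA"],
        n_rrna=counts["rRNA"],
        genes_by_region=by_region,
    )
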