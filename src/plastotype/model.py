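"""Core domain objects.

The pipeline works on a multiple alignment of complete plastomes
(haploid, maternally inherited, one sequence per sample) plus per-sample
metadata.  Variants are called directly from alignment columns; panels,
KASP markers and lineage verdicts are all derived views of those calls.

Coordinate convention: 0-based, half-open everywhere inside the package.
1-based coordinates appear only at the VCF/report boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, CoordinateError, DataError, PanelError

#: Chloroplast group labels used throughout (maize plastome lineages).
GROUPS = ("B", "C", "D", "H", "T")

ROLES = ("cultivar", "wild", "parent", "hybrid", "outgroup")
FERTILITY = ("fertile", "sterile", "unknown")
ALIGNMENT_ALPHABET = frozenset("ACGTN-")
GENE_CATEGORIES = ("protein_coding", "tRNA", "rRNA")
REGIONS = ("LSC", "IRa", "IRb", "SSC")

#: Deletion allele: the empty string (printed as "-" at format boundaries).
DELETION = ""


@dataclass
class SampleRecord:
    """One row of the sample sheet."""

    sample_id: str
    group: Optional[str] = None          # one of GROUPS, or None if unknown
    role: str = "cultivar"
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    fertility: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DataError(f"unknown role {self.role!r} for {self.sample_id}")
        if self.fertility not in FERTILITY:
            raise DataError(
                f"unknown fertility {self.fertility!r} for {self.sample_id}"
            )
        if self.role == "hybrid" and not (self.mother_id and self.father_id):
            raise DataError(
                f"hybrid {self.sample_id} must carry both parent ids"
            )


@dataclass
class PlastomeAlignment:
    """Aligned plastome panel: equal-length sequences + sample metadata."""

    samples: list[SampleRecord]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.sequences):
            raise AlignmentError(
                f"{len(self.samples)} samples but {len(self.sequences)} sequences"
            )
        if len(self.samples) < 2:
            raise AlignmentError("an alignment needs at least 2 samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sample ids in alignment")
        known = {s.sample_id for s in self.samples}
        for s in self.samples:
            for pid in (s.mother_id, s.father_id):
                if pid is not None and pid not in known:
                    raise DataError(
                        f"parent {pid!r} of {s.sample_id} not in sample sheet"
                    )
        length = len(self.sequences[0])
        for rec, seq in zip(self.samples, self.sequences):
            if len(seq) != length:
                raise AlignmentError(
                    f"sequence length mismatch for sample {rec.sample_id!r}: "
                    f"{len(seq)} != {length}"
                )
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise AlignmentError(
                    f"invalid characters {sorted(bad)} in {rec.sample_id!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def index_of(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(sample_id) from None

    def sequence_of(self, sample_id: str) -> str:
        return self.sequences[self.index_of(sample_id)]

    def to_array(self) -> np.ndarray:
        """(n_samples, length) array of single-byte characters."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype="S1"
        ).reshape(self.n_samples, self.length)

    def groups(self) -> dict[str, list[str]]:
        """Map group label -> sample ids (samples with a known group only)."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            if s.group is not None:
                out.setdefault(s.group, []).append(s.sample_id)
        return out


@dataclass(frozen=True)
class GeneInterval:
    name: str
    start: int
    end: int
    category: str
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise CoordinateError(
                f"gene {self.name}: invalid interval [{self.start}, {self.end})"
            )
        if self.category not in GENE_CATEGORIES:
            raise DataError(f"gene {self.name}: unknown category {self.category!r}")


@dataclass
class GeneMap:
    """Annotated gene intervals in ungapped reference coordinates."""

    intervals: list[GeneInterval]

    def __post_init__(self) -> None:
        by_cat: dict[str, list[GeneInterval]] = {}
        for iv in self.intervals:
            by_cat.setdefault(iv.category, []).append(iv)
        for cat, ivs in by_cat.items():
            ivs = sorted(ivs, key=lambda g: g.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise DataError(
                        f"overlapping {cat} genes {a.name} and {b.name}"
                    )

    def sorted(self) -> list[GeneInterval]:
        return sorted(self.intervals, key=lambda g: (g.start, g.end))


@dataclass
class MarkerTableRow:
    """One row of a KASP marker table (the published VCP dialect).

    Sentinels are resolved at parse time: "/" -> None, "-" -> the empty
    string (deletion allele).  ``primer_common`` may be empty only for
    InDel rows that use the two-flank layout; such rows carry a note.
    """

    marker_id: str
    variation_locus_id: str
    allele_fam: str
    allele_hex: str
    specific_type: Optional[str]
    corresponding_allele: Optional[str]
    primer_fam: str
    primer_hex: str
    primer_common: str
    flank1: str = ""
    flank2: str = ""
    notes: list[str] = field(default_factory=list)

    @property
    def is_indel(self) -> bool:
        a, b = self.allele_fam, self.allele_hex
        return len(a) != len(b) or a == DELETION or b == DELETION


@dataclass
class Annotation:
    genic: bool
    gene: Optional[str] = None                 # set when genic
    between: Optional[tuple[str, str]] = None  # bracketing genes when intergenic


@dataclass
class VariantLocus:
    """One SNP or one merged InDel event.

    ``cols`` is the half-open alignment-column range (width 1 for a SNP).
    ``alleles`` are gap-stripped strings; the deletion allele is "".
    ``genotypes[i]`` indexes ``alleles`` for sample i; -1 means missing.
    """

    locus_id: str
    kind: str                      # "SNP" | "InDel"
    cols: tuple[int, int]
    alleles: list[str]
    genotypes: np.ndarray
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None
    annotation: Optional[Annotation] = None
    flank_left: Optional[str] = None
    flank_right: Optional[str] = None
    flanks_conserved: Optional[bool] = None
    flank_truncated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "InDel"):
            raise DataError(f"unknown variant kind {self.kind!r}")
        if len(self.alleles) < 2:
            raise DataError(f"{self.locus_id}: needs >= 2 alleles")
        if self.kind == "SNP" and any(len(a) != 1 for a in self.alleles):
            raise DataError(f"{self.locus_id}: SNP alleles must be single bases")
        if self.kind == "InDel" and len({len(a) for a in self.alleles}) == 1:
            raise DataError(f"{self.locus_id}: InDel alleles must differ in length")
        self.genotypes = np.asarray(self.genotypes, dtype=int)

    @property
    def span(self) -> int:
        return self.cols[1] - self.cols[0]

    def allele_of(self, sample_index: int) -> Optional[str]:
        g = int(self.genotypes[sample_index])
        return None if g < 0 else self.alleles[g]


@dataclass
class VariantInventory:
    loci: list[VariantLocus]
    n_snps: int
    n_indels: int
    n_genic: int
    n_intergenic: int
    bp_per_variant: Optional[float]

    @classmethod
    def from_loci(
        cls, loci: Sequence[VariantLocus], genome_length: Optional[int] = None
    ) -> "VariantInventory":
        n_snps = sum(1 for l in loci if l.kind == "SNP")
        n_indels = len(loci) - n_snps
        annotated = [l for l in loci if l.annotation is not None]
        n_genic = sum(1 for l in annotated if l.annotation.genic)
        dens = None
        if genome_length is not None and loci:
            dens = genome_length / len(loci)
        return cls(
            loci=list(loci),
            n_snps=n_snps,
            n_indels=n_indels,
            n_genic=n_genic,
            n_intergenic=len(annotated) - n_genic,
            bp_per_variant=dens,
        )


@dataclass
class GenomeSummary:
    """Structural summary of one plastome: region lengths, GC, gene counts."""

    total_length: int
    lsc_length: int
    ir_length: int
    ssc_length: int
    gc_fraction: float
    n_genes: int
    n_protein_coding: int
    n_trna: int
    n_rrna: int
    genes_by_region: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        if self.lsc_length + 2 * self.ir_length + self.ssc_length != self.total_length:
            raise DataError(
                "region lengths do not partition the genome: "
                f"{self.lsc_length} + 2*{self.ir_length} + {self.ssc_length} "
                f"!= {self.total_length}"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise DataError(f"gc_fraction {self.gc_fraction} outside [0, 1]")
        if self.n_protein_coding + self.n_trna + self.n_rrna != self.n_genes:
            raise DataError("gene category counts do not sum to the total")


@dataclass
class SpecificityResult:
    """Per-locus one-vs-rest F_st scan outcome."""

    locus_id: str
    fst_by_group: dict[str, float]
    assigned_group: Optional[str]
    group_allele: Optional[str]
    threshold: float


@dataclass
class Panel:
    """An ordered marker set with the per-group allele signature matrix.

    A panel is valid iff its group signature rows are pairwise distinct:
    only then can every candidate group be told apart.
    """

    locus_ids: list[str]
    group_order: list[str]
    signature: dict[str, tuple[str, ...]]
    policy: str
    loci: Optional[list[VariantLocus]] = None

    def __post_init__(self) -> None:
        for g in self.group_order:
            row = self.signature.get(g)
            if row is None or len(row) != len(self.locus_ids):
                raise PanelError(f"signature row for group {g} malformed")
        rows = [self.signature[g] for g in self.group_order]
        if len(set(rows)) != len(rows):
            dup = [
                (a, b)
                for i, a in enumerate(self.group_order)
                for b in self.group_order[i + 1:]
                if self.signature[a] == self.signature[b]
            ]
            raise PanelError(f"indistinguishable group signature rows: {dup}")

    @property
    def size(self) -> int:
        return len(self.locus_ids)


@dataclass
class KaspMarker:
    """A designed KASP assay: two allele-specific primers + common primer."""

    marker_id: str
    locus_id: str
    allele_fam: str
    allele_hex: str
    primer_fam: str
    primer_hex: str
    primer_common: str            # empty for two-flank large-InDel layout
    orientation: str              # "forward" | "reverse"
    tm_fam: float
    tm_hex: float
    tm_common: Optional[float]
    specific_type: Optional[str] = None
    corresponding_allele: Optional[str] = None
    flank1: str = ""
    flank2: str = ""
    notes: list[str] = field(default_factory=list)


@dataclass
class RowAudit:
    """Internal-consistency verdict for one marker-table row."""

    marker_id: str
    orientation_call: str         # "forward" | "reverse" | "inconsistent" | "indel"
    flank_check: str              # "pass" | "fail" | "not-checkable"
    notes: list[str] = field(default_factory=list)


@dataclass
class GenotypeVector:
    sample_id: str
    calls: tuple[Optional[str], ...]   # allele string per panel locus; None = missing


@dataclass
class TrioResult:
    hybrid_id: str
    mother_candidate: str
    father_candidate: str
    match_mother: int
    mismatch_mother: int
    match_father: int
    mismatch_father: int
    verdict: str   # "maternal=mother" | "maternal=father" | "ambiguous" | "inconsistent"


@dataclass
class CytoplasmCall:
    sample_id: str
    group: Optional[str]
    labels: tuple[str, ...]
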