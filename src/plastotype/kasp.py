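"""KASP assay construction and marker-table auditing.

A KASP marker is two allele-specific primers (read on the FAM and HEX
fluorescence channels) plus one common primer on the opposite strand.
Allele discrimination rides on the 3'-terminal base of the
allele-specific primers, so each one is a suffix of (left flank +
allele) ending exactly at the first base that differs between the two
alleles; the common primer is the reverse complement of a window of the
opposite flank.  Primers are designed only on conserved flanks — a
variant too close to another variant has no invariant primer landing
site and is refused.

Primer length is the shortest in the allowed range whose estimated
melting temperature reaches the annealing target (58 °C, the assay's
cycling temperature).  Designs are attempted on the given strand first
("forward": 3' bases equal the alleles) and on the complement strand
("reverse": 3' bases equal the complemented alleles); the reverse
design is used when the forward cannot reach the target Tm or when its
Tm balance between the two allele primers is strictly better.

No universal FAM/HEX tail sequences are prepended: published VCP
tables print tail-less primers, and ``with_tails`` exists for export.
"""

from __future__ import annotations

from typing import Optional, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .errors import DataError, NoDesignError
from .model import DELETION, KaspMarker, MarkerTableRow, RowAudit, VariantLocus
from .simulate import revcomp

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Standard KASP universal tails (FAM, HEX), for export only.
FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"


def estimate_tm(primer: str, method: str = "nn") -> float:
    """Melting temperature in °C.

    ``nn``: nearest-neighbor with the SantaLucia unified parameter set at
    50 mM monovalent salt and 200 nM primer (the package default).
    ``wallace``: the 2 °C(A/T) + 4 °C(G/C) rule.
    Deterministic; invalid bases raise.
    """
    primer = primer.upper()
    if not primer or set(primer) - set("ACGT"):
        raise DataError(f"invalid primer sequence {primer!r}")
    if method == "wallace":
        return float(_mt.Tm_Wallace(primer))
    if method == "nn":
        if len(primer) < 8:
            raise DataError("nearest-neighbor Tm needs >= 8 nt")
        return float(
            _mt.Tm_NN(
                primer, nn_table=_mt.DNA_NN3, Na=50, dnac1=200, dnac2=0
            )
        )
    raise DataError(f"unknown Tm method {method!r}")


def _shortest_meeting_tm(
    context: str,
    tm_target: float,
    len_range: tuple[int, int],
    anchor: str = "suffix",
) -> Optional[tuple[str, float]]:
    """Shortest window of ``context`` (anchored at its 3' end for
    ``suffix``, at its start for ``prefix``) reaching the Tm target."""
    lo, hi = len_range
    for L in range(lo, min(hi, len(context)) + 1):
        window = context[-L:] if anchor == "suffix" else context[:L]
        tm = estimate_tm(window)
        if tm >= tm_target:
            return window, tm
    return None


def _first_difference(a1: str, a2: str, flank_right: str) -> int:
    """Index (from the variant start) of the first discriminating base."""
    s1, s2 = a1 + flank_right, a2 + flank_right
    for d in range(min(len(s1), len(s2))):
        if s1[d] != s2[d]:
            return d
    raise NoDesignError(
        "alleles are indistinguishable within the available flank"
    )


def _design_one_strand(
    a1: str,
    a2: str,
    flank_left: str,
    flank_right: str,
    tm_target: float,
    len_range: tuple[int, int],
) -> Optional[tuple[str, str, str, float, float, float]]:
    d = _first_difference(a1, a2, flank_right)
    out = []
    for a in (a1, a2):
        context = flank_left + (a + flank_right)[: d + 1]
        hit = _shortest_meeting_tm(context, tm_target, len_range, "suffix")
        if hit is None:
            return None
        out.append(hit)
    common_window = _shortest_meeting_tm(
        flank_right[d:], tm_target, len_range, "prefix"
    )
    if common_window is None:
        return None
    (p1, t1), (p2, t2) = out
    common = revcomp(common_window[0])
    return p1, p2, common, t1, t2, estimate_tm(common)


def design_kasp(
    locus: VariantLocus,
    flank_left: Optional[str] = None,
    flank_right: Optional[str] = None,
    tm_target: float = 58.0,
    len_range: tuple[int, int] = (18, 35),
    marker_id: Optional[str] = None,
    large_indel_threshold: int = 50,
) -> KaspMarker:
    """Design a KASP assay for a biallelic locus with conserved flanks."""
    flank_left = flank_left if flank_left is not None else locus.flank_left
    flank_right = flank_right if flank_right is not None else locus.flank_right
    if flank_left is None or flank_right is None:
        raise NoDesignError(f"{locus.locus_id}: flanks not available")
    if locus.flanks_conserved is False:
        raise NoDesignError(
            f"{locus.locus_id}: flanks are not conserved across samples; "
            "marker design refused"
        )
    if len(locus.alleles) != 2:
        raise NoDesignError(f"{locus.locus_id}: KASP design needs a biallelic locus")
    if min(len(flank_left), len(flank_right)) < len_range[0]:
        raise NoDesignError(f"{locus.locus_id}: flanks shorter than minimum "
                            "primer length")
    a_fam, a_hex = locus.alleles
    marker_id = marker_id or locus.locus_id.replace("CPM", "C") + "K"
    notes: list[str] = []

    if max(len(a_fam), len(a_hex)) > large_indel_threshold:
        return _design_two_flank(
            locus, a_fam, a_hex, flank_left, flank_right, tm_target,
            len_range, marker_id,
        )

    fwd = _design_one_strand(
        a_fam, a_hex, flank_left, flank_right, tm_target, len_range
    )
    rev = _design_one_strand(
        revcomp(a_fam), revcomp(a_hex), revcomp(flank_right),
        revcomp(flank_left), tm_target, len_range,
    )
    if fwd is None and rev is None:
        raise NoDesignError(
            f"{locus.locus_id}: no primer reaches {tm_target} °C on either "
            "strand within the length range"
        )
    orientation = "forward"
    design = fwd
    if fwd is None:
        orientation, design = "reverse", rev
    elif rev is not None and abs(rev[3] - rev[4]) < abs(fwd[3] - fwd[4]):
        orientation, design = "reverse", rev
    p_fam, p_hex, p_common, tm_fam, tm_hex, tm_common = design
    return KaspMarker(
        marker_id=marker_id,
        locus_id=locus.locus_id,
        allele_fam=a_fam,
        allele_hex=a_hex,
        primer_fam=p_fam,
        primer_hex=p_hex,
        primer_common=p_common,
        orientation=orientation,
        tm_fam=tm_fam,
        tm_hex=tm_hex,
        tm_common=tm_common,
        flank1=flank_left,
        flank2=flank_right,
        notes=notes,
    )


def _design_two_flank(
    locus: VariantLocus,
    a_fam: str,
    a_hex: str,
    flank_left: str,
    flank_right: str,
    tm_target: float,
    len_range: tuple[int, int],
    marker_id: str,
) -> KaspMarker:
    """Large-insertion layout: no common primer; two flank records anchor
    the assay (one outside the event, one inside the long allele)."""
    d = _first_difference(a_fam, a_hex, flank_right)
    primers = []
    for a in (a_fam, a_hex):
        context = flank_left + (a + flank_right)[: d + 1]
        hit = _shortest_meeting_tm(context, tm_target, len_range, "suffix")
        if hit is None:
            raise NoDesignError(
                f"{locus.locus_id}: allele primer cannot reach "
                f"{tm_target} °C"
            )
        primers.append(hit)
    long_allele = max((a_fam, a_hex), key=len)
    return KaspMarker(
        marker_id=marker_id,
        locus_id=locus.locus_id,
        allele_fam=a_fam,
        allele_hex=a_hex,
        primer_fam=primers[0][0],
        primer_hex=primers[1][0],
        primer_common="",
        orientation="forward",
        tm_fam=primers[0][1],
        tm_hex=primers[1][1],
        tm_common=None,
        flank1=flank_right[:30],
        flank2=long_allele[-25:],
        notes=["two-flank large-InDel layout: no common primer"],
    )


def with_tails(marker: KaspMarker) -> KaspMarker:
    """Copy of a marker with the universal FAM/HEX tails prepended."""
    import dataclasses

    return dataclasses.replace(
        marker,
        primer_fam=FAM_TAIL + marker.primer_fam,
        primer_hex=HEX_TAIL + marker.primer_hex,
        notes=marker.notes + ["universal tails prepended"],
    )


def marker_to_row(marker: KaspMarker) -> MarkerTableRow:
    """Convert a designed marker to the published table dialect."""
    return MarkerTableRow(
        marker_id=marker.marker_id,
        variation_locus_id=marker.locus_id,
        allele_fam=marker.allele_fam,
        allele_hex=marker.allele_hex,
        specific_type=marker.specific_type,
        corresponding_allele=marker.corresponding_allele,
        primer_fam=marker.primer_fam,
        primer_hex=marker.primer_hex,
        primer_common=marker.primer_common,
        flank1=marker.flank1,
        flank2=marker.flank2,
        notes=list(marker.notes),
    )


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------

def _classify_orientation(row: MarkerTableRow) -> str:
    f3, h3 = row.primer_fam[-1], row.primer_hex[-1]
    if (f3, h3) == (row.allele_fam, row.allele_hex):
        return "forward"
    comp = (_COMPLEMENT[row.allele_fam], _COMPLEMENT[row.allele_hex])
    if (f3, h3) == comp:
        return "reverse"
    return "inconsistent"


def _flank_containment(row: MarkerTableRow) -> tuple[str, list[str]]:
    if not (row.flank1 or row.flank2):
        return "not-checkable", []
    contexts = []
    for a in (row.allele_fam, row.allele_hex):
        local = row.flank1 + a + row.flank2
        contexts.extend((local, revcomp(local)))
    primers = [p for p in (row.primer_fam, row.primer_hex, row.primer_common) if p]
    missing = [
        p for p in primers if not any(p in ctx for ctx in contexts)
    ]
    if not missing:
        return "pass", []
    # incomplete flank information: cannot distinguish contradiction from
    # a primer landing outside the printed windows
    return "not-checkable", [f"primer not located in printed flanks: {p[:12]}…"
                             for p in missing]


def audit_marker_table(rows: Sequence[MarkerTableRow]) -> list[RowAudit]:
    """Internal-consistency audit; reports findings, never mutates.

    SNP rows are classified forward/reverse/inconsistent by the
    3'-terminal-base rule; rows with flank data get a primer-in-flank
    containment check; InDel rows are audited for allele length
    difference only.
    """
    audits = []
    for row in rows:
        notes = list(row.notes)
        if row.is_indel:
            orientation = "indel"
            if len(row.allele_fam) == len(row.allele_hex):
                orientation = "inconsistent"
                notes.append("InDel alleles do not differ in length")
        else:
            orientation = _classify_orientation(row)
            if orientation == "inconsistent":
                notes.append(
                    "3' bases (%s, %s) match neither the alleles (%s, %s) "
                    "nor their complements"
                    % (row.primer_fam[-1], row.primer_hex[-1],
                       row.allele_fam, row.allele_hex)
                )
        flank_check, flank_notes = _flank_containment(row)
        audits.append(
            RowAudit(
                marker_id=row.marker_id,
                orientation_call=orientation,
                flank_check=flank_check,
                notes=notes + flank_notes,
            )
        )
    return audits


def audit_designed(marker: KaspMarker) -> RowAudit:
    """Audit a marker designed by this package (round-trip check)."""
    return audit_marker_table([marker_to_row(marker)])[0]
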