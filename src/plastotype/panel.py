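"""Locus filtering, one-vs-rest F_st, specificity calls, panel selection.

The differentiation statistic is the Weir & Cockerham (1984)
ratio-of-averages F_st estimator for two populations: the focal
chloroplast group versus all remaining samples pooled.  Chloroplast
calls are haploid and effectively homozygous, so each haploid call is
encoded as one homozygous diploid individual; every heterozygosity term
of the estimator then vanishes and the estimate reduces to its
between-population components.  A locus is "specific" to a group when
exactly one group's one-vs-rest F_st exceeds the threshold (default
0.9); loci exceeding it for several groups, or none, are assigned no
group.  Multi-allelic loci are collapsed to focal-allele vs pooled
others before estimation.

Panel policies:

* ``one-per-group`` — per group, the specific locus with the highest
  F_st (ties broken by lexicographic locus id); panel size = number of
  groups.
* ``minimal`` — exhaustive search over group-assigned loci, by
  increasing subset size, for the smallest panel whose per-group allele
  signature rows are pairwise distinct.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import (
    ConfigError,
    DataError,
    InsufficientDataError,
    MonomorphicLocusError,
    UncoveredGroupError,
)
from .model import (
    MarkerTableRow,
    Panel,
    SampleRecord,
    SpecificityResult,
    VariantLocus,
)


# ---------------------------------------------------------------------------
# allele frequencies and the MAF filter
# ---------------------------------------------------------------------------

@dataclass
class LocusFrequencies:
    """Per-locus allele counts over non-missing haploid calls."""

    locus_id: str
    counts: dict[str, int]
    counts_by_group: dict[str, dict[str, int]]
    n_nonmissing: int
    maf: float


def allele_frequencies(
    loci: Sequence[VariantLocus], samples: Sequence[SampleRecord]
) -> list[LocusFrequencies]:
    out = []
    for locus in loci:
        counts: dict[str, int] = {}
        by_group: dict[str, dict[str, int]] = {}
        for i, rec in enumerate(samples):
            a = locus.allele_of(i)
            if a is None:
                continue
            counts[a] = counts.get(a, 0) + 1
            if rec.group is not None:
                g = by_group.setdefault(rec.group, {})
                g[a] = g.get(a, 0) + 1
        n = sum(counts.values())
        ranked = sorted(counts.values(), reverse=True)
        maf = ranked[1] / n if len(ranked) > 1 else 0.0
        out.append(
            LocusFrequencies(
                locus_id=locus.locus_id,
                counts=counts,
                counts_by_group=by_group,
                n_nonmissing=n,
                maf=maf,
            )
        )
    return out


def maf_filter(
    freqs: Sequence[LocusFrequencies], threshold: float = 0.01
) -> tuple[list[LocusFrequencies], list[LocusFrequencies]]:
    """Partition into (kept, eliminated); eliminated iff maf < threshold
    (strict, so a locus at exactly the threshold survives)."""
    if not 0.0 < threshold < 0.5:
        raise ConfigError(f"MAF threshold {threshold} outside (0, 0.5)")
    kept = [f for f in freqs if f.maf >= threshold]
    eliminated = [f for f in freqs if f.maf < threshold]
    return kept, eliminated


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984), two populations, homozygous-diploid encoding
# ---------------------------------------------------------------------------

def weir_cockerham_fst(n1: int, p1: float, n2: int, p2: float) -> float:
    """WC84 theta-hat for two populations of homozygous diploids.

    ``n1``/``n2`` are haploid sample counts (one homozygous diploid
    individual each); ``p1``/``p2`` are focal-allele frequencies.  With
    all individuals homozygous the observed heterozygosity is zero, so
    the c component vanishes.  A fixed difference returns exactly 1.0;
    equal frequencies return a value <= 0.  Negative estimates are
    reported as computed, never clamped.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"each population needs >= 2 samples (got {n1} and {n2})"
        )
    if {p1, p2} == {0.0, 1.0}:
        # fixed difference: the b and c components are analytically zero,
        # so the estimate is exactly 1 for any sample sizes
        return 1.0
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = 0.0
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        raise MonomorphicLocusError("F_st undefined: no variation in the data")
    return a / denom


def _pop_frequencies(
    locus: VariantLocus, samples: Sequence[SampleRecord], focal_group: str
) -> tuple[int, dict[str, int], int, dict[str, int]]:
    focal: dict[str, int] = {}
    rest: dict[str, int] = {}
    for i, rec in enumerate(samples):
        a = locus.allele_of(i)
        if a is None:
            continue
        target = focal if rec.group == focal_group else rest
        target[a] = target.get(a, 0) + 1
    return sum(focal.values()), focal, sum(rest.values()), rest


def focal_allele(
    locus: VariantLocus, samples: Sequence[SampleRecord], focal_group: str
) -> str:
    """The allele most enriched in the focal group relative to the rest."""
    n1, focal, n2, rest = _pop_frequencies(locus, samples, focal_group)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError(f"no calls for group {focal_group} contrast")
    alleles = sorted(set(focal) | set(rest))
    return max(
        alleles, key=lambda a: (focal.get(a, 0) / n1 - rest.get(a, 0) / n2, a)
    )


def fst_one_vs_rest(
    locus: VariantLocus, samples: Sequence[SampleRecord], focal_group: str
) -> float:
    """One-vs-rest WC84 F_st for a locus and a focal chloroplast group."""
    n1, focal, n2, rest = _pop_frequencies(locus, samples, focal_group)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"group {focal_group!r} contrast has populations of {n1} and {n2}"
        )
    if len(set(focal) | set(rest)) < 2:
        raise MonomorphicLocusError(f"{locus.locus_id} is monomorphic")
    target = focal_allele(locus, samples, focal_group)
    p1 = focal.get(target, 0) / n1
    p2 = rest.get(target, 0) / n2
    return weir_cockerham_fst(n1, p1, n2, p2)


def assign_specificity(
    loci: Sequence[VariantLocus],
    samples: Sequence[SampleRecord],
    groups: Sequence[str],
    threshold: float = 0.9,
) -> list[SpecificityResult]:
    """Per locus: F_st against every group; assign iff exactly one exceeds
    the threshold."""
    ungrouped = [s.sample_id for s in samples if s.group is None]
    if ungrouped:
        raise DataError(f"samples without group labels: {ungrouped}")
    results = []
    for locus in loci:
        fst_by_group: dict[str, float] = {}
        for g in groups:
            try:
                fst_by_group[g] = fst_one_vs_rest(locus, samples, g)
            except MonomorphicLocusError:
                fst_by_group[g] = math.nan
        hits = [g for g, v in fst_by_group.items() if v > threshold]
        if len(hits) == 1:
            g = hits[0]
            results.append(
                SpecificityResult(
                    locus_id=locus.locus_id,
                    fst_by_group=fst_by_group,
                    assigned_group=g,
                    group_allele=focal_allele(locus, samples, g),
                    threshold=threshold,
                )
            )
        else:
            results.append(
                SpecificityResult(
                    locus_id=locus.locus_id,
                    fst_by_group=fst_by_group,
                    assigned_group=None,
                    group_allele=None,
                    threshold=threshold,
                )
            )
    return results


# ---------------------------------------------------------------------------
# signatures and panel selection
# ---------------------------------------------------------------------------

def build_signatures(
    loci: Sequence[VariantLocus],
    samples: Sequence[SampleRecord],
    groups: Sequence[str],
) -> dict[str, dict[str, str]]:
    """locus_id -> group -> majority allele (ties by lexicographic allele)."""
    out: dict[str, dict[str, str]] = {}
    for locus in loci:
        per_group: dict[str, str] = {}
        for g in groups:
            counts: dict[str, int] = {}
            for i, rec in enumerate(samples):
                if rec.group != g:
                    continue
                a = locus.allele_of(i)
                if a is not None:
                    counts[a] = counts.get(a, 0) + 1
            if not counts:
                raise InsufficientDataError(f"group {g} has no calls at "
                                            f"{locus.locus_id}")
            per_group[g] = max(sorted(counts), key=lambda a: counts[a])
        out[locus.locus_id] = per_group
    return out


def signatures_from_marker_table(
    rows: Sequence[MarkerTableRow], groups: Sequence[str]
) -> tuple[list[SpecificityResult], dict[str, dict[str, str]]]:
    """Derive specificity results and signature rows from a marker table.

    A row specific to group g carries its "corresponding allele" in g and
    the assay's other allele everywhere else.  InDel rows print I/D codes
    for the corresponding allele: I = the insertion (longer) allele,
    D = the deletion (shorter) allele.
    """
    results = []
    signatures: dict[str, dict[str, str]] = {}
    for row in rows:
        if row.specific_type is None:
            results.append(
                SpecificityResult(
                    locus_id=row.variation_locus_id,
                    fst_by_group={},
                    assigned_group=None,
                    group_allele=None,
                    threshold=0.9,
                )
            )
            continue
        alleles = [row.allele_fam, row.allele_hex]
        corr = row.corresponding_allele
        if corr == "I":
            group_allele = max(alleles, key=len)
        elif corr == "D":
            group_allele = min(alleles, key=len)
        else:
            group_allele = corr
        if group_allele not in alleles:
            raise DataError(
                f"{row.marker_id}: corresponding allele {corr!r} is neither "
                "assay allele"
            )
        other = alleles[1 - alleles.index(group_allele)]
        results.append(
            SpecificityResult(
                locus_id=row.variation_locus_id,
                fst_by_group={},
                assigned_group=row.specific_type,
                group_allele=group_allele,
                threshold=0.9,
            )
        )
        signatures[row.variation_locus_id] = {
            g: (group_allele if g == row.specific_type else other)
            for g in groups
        }
    return results, signatures


def _coverage(
    results: Sequence[SpecificityResult], groups: Sequence[str]
) -> dict[str, list[SpecificityResult]]:
    cov = {g: [r for r in results if r.assigned_group == g] for g in groups}
    missing = [g for g, rs in cov.items() if not rs]
    if missing:
        raise UncoveredGroupError(f"no specific locus for groups: {missing}")
    return cov


def _make_panel(
    locus_ids: Sequence[str],
    groups: Sequence[str],
    signatures: dict[str, dict[str, str]],
    policy: str,
) -> Panel:
    signature = {
        g: tuple(signatures[l][g] for l in locus_ids) for g in groups
    }
    return Panel(
        locus_ids=list(locus_ids),
        group_order=list(groups),
        signature=signature,
        policy=policy,
    )


def _rows_distinct(
    locus_ids: Sequence[str],
    groups: Sequence[str],
    signatures: dict[str, dict[str, str]],
) -> bool:
    rows = {tuple(signatures[l][g] for l in locus_ids) for g in groups}
    return len(rows) == len(groups)


def select_core_panel(
    results: Sequence[SpecificityResult],
    signatures: dict[str, dict[str, str]],
    groups: Sequence[str],
    policy: str = "one-per-group",
) -> Panel:
    """Select a discriminating core panel under the given policy."""
    cov = _coverage(results, groups)
    if policy == "one-per-group":
        chosen = []
        for g in groups:
            best = sorted(
                cov[g],
                key=lambda r: (
                    -(r.fst_by_group.get(g) if r.fst_by_group.get(g) is not None
                      and not math.isnan(r.fst_by_group.get(g)) else 0.0),
                    r.locus_id,
                ),
            )[0]
            chosen.append(best.locus_id)
        return _make_panel(chosen, groups, signatures, policy)
    if policy == "minimal":
        pool = sorted(
            {r.locus_id for r in results if r.assigned_group is not None
             and r.locus_id in signatures}
        )
        for size in range(1, len(groups) + 1):
            for combo in itertools.combinations(pool, size):
                if _rows_distinct(combo, groups, signatures):
                    return _make_panel(combo, groups, signatures, policy)
        raise UncoveredGroupError("no discriminating subset exists")
    raise ConfigError(f"unknown panel policy {policy!r}")


def constrained_panel(
    results: Sequence[SpecificityResult],
    signatures: dict[str, dict[str, str]],
    candidate_groups: Sequence[str],
    policy: str = "minimal",
) -> Panel:
    """Panel discriminating only a known candidate subset of groups, e.g.
    the sterile-cytoplasm groups when fertility status is already known."""
    groups = list(candidate_groups)
    if len(groups) < 2:
        raise ConfigError("constrained panel needs >= 2 candidate groups")
    restricted = [
        r for r in results
        if r.assigned_group is None or r.assigned_group in groups
    ]
    return select_core_panel(restricted, signatures, groups, policy=policy)
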