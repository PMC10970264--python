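"""F_st estimator vs direct-formula oracle; filtering; panel selection."""

import itertools

import numpy as np
import pytest

from plastotype.errors import (
    ConfigError,
    InsufficientDataError,
    MonomorphicLocusError,
    UncoveredGroupError,
)
from plastotype.model import (
    Panel,
    PlastomeAlignment,
    SampleRecord,
    SpecificityResult,
    VariantLocus,
)
from plastotype.panel import (
    allele_frequencies,
    assign_specificity,
    build_signatures,
    constrained_panel,
    fst_one_vs_rest,
    maf_filter,
    select_core_panel,
    signatures_from_marker_table,
    weir_cockerham_fst,
)
from plastotype.simulate import SimulationConfig, generate_panel


def wc84_direct(n1, p1, n2, p2):
    """Independent transcription of the Weir & Cockerham (1984) theta-hat
    for two populations of homozygous diploids (h = 0), written directly
    from the published component formulas."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = n1 + n2 - (n1**2 + n2**2) / (n1 + n2)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2)
    return a / (a + b)


def hudson_fst(n1, p1, n2, p2):
    """Hudson-style estimator (cross-check at fixed differences)."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


def _locus_from_groups(group_alleles, samples_per_group=None, counts=None):
    """Build (locus, samples) where group g's members carry given alleles."""
    samples, calls = [], []
    for g, alleles in group_alleles.items():
        for i, a in enumerate(alleles):
            samples.append(SampleRecord(f"{g}{i}", group=g))
            calls.append(a)
    distinct = []
    geno = []
    for c in calls:
        if c is None:
            geno.append(-1)
            continue
        if c not in distinct:
            distinct.append(c)
        geno.append(distinct.index(c))
    locus = VariantLocus("L1", "SNP", (0, 1), distinct, np.array(geno))
    return locus, samples


class TestWeirCockerham:
    def test_fixed_difference_is_exactly_one(self):
        assert weir_cockerham_fst(10, 1.0, 20, 0.0) == 1.0

    def test_equal_frequencies_are_non_positive(self):
        assert weir_cockerham_fst(10, 0.5, 20, 0.5) <= 0.0

    def test_matches_direct_formula_on_random_configurations(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n1, n2 = (int(x) for x in rng.integers(2, 200, size=2))
            p1, p2 = rng.random(2)
            if p1 == p2:
                continue
            got = weir_cockerham_fst(n1, p1, n2, p2)
            assert got == pytest.approx(wc84_direct(n1, p1, n2, p2), abs=1e-10)

    def test_agrees_with_hudson_at_fixed_difference(self):
        for n1, n2 in [(5, 7), (10, 20), (88, 88)]:
            assert weir_cockerham_fst(n1, 1.0, n2, 0.0) == 1.0
            assert hudson_fst(n1, 1.0, n2, 0.0) == 1.0

    def test_small_population_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            weir_cockerham_fst(1, 1.0, 20, 0.0)

    def test_monomorphic_is_undefined(self):
        with pytest.raises(MonomorphicLocusError):
            weir_cockerham_fst(10, 0.0, 20, 0.0)


class TestFstOneVsRest:
    def test_diagnostic_contrast_scores_one(self):
        locus, samples = _locus_from_groups(
            {"B": ["A"] * 10, "C": ["T"] * 10, "D": ["T"] * 10}
        )
        assert fst_one_vs_rest(locus, samples, "B") == 1.0

    def test_uniform_locus_scores_low(self):
        locus, samples = _locus_from_groups(
            {"B": ["A", "T"] * 5, "C": ["A", "T"] * 5}
        )
        assert fst_one_vs_rest(locus, samples, "B") <= 0.0

    def test_oracle_value_for_skewed_frequencies(self):
        # focal 12 samples at 0.75 vs pooled 30 at 0.1
        locus, samples = _locus_from_groups(
            {
                "B": ["A"] * 9 + ["T"] * 3,
                "C": ["A"] * 3 + ["T"] * 12,
                "D": ["T"] * 15,
            }
        )
        want = wc84_direct(12, 9 / 12, 30, 3 / 30)
        assert fst_one_vs_rest(locus, samples, "B") == pytest.approx(
            want, abs=1e-12
        )


class TestMafFilter:
    def _freqs(self, n_minor, n_total):
        locus, samples = _locus_from_groups(
            {"B": ["A"] * (n_total - n_minor) + ["T"] * n_minor}
        )
        return allele_frequencies([locus], samples)

    def test_singleton_among_176_is_eliminated(self):
        freqs = self._freqs(1, 176)
        kept, eliminated = maf_filter(freqs, 0.01)
        assert not kept and len(eliminated) == 1
        assert eliminated[0].maf == pytest.approx(1 / 176)

    def test_exact_threshold_is_kept(self):
        freqs = self._freqs(2, 200)  # maf exactly 0.01
        kept, eliminated = maf_filter(freqs, 0.01)
        assert len(kept) == 1 and not eliminated

    def test_partition_is_exhaustive(self, panel_seed1, inventory_seed1):
        aln, _, _ = panel_seed1
        freqs = allele_frequencies(inventory_seed1.loci, aln.samples)
        kept, eliminated = maf_filter(freqs, 0.10)
        assert len(kept) + len(eliminated) == len(freqs)

    def test_planted_singletons_eliminated_at_study_scale(self):
        # singleton frequency must sit below 1% -> >100 samples, as in a
        # 176-sample panel
        cfg = SimulationConfig(
            seed=6, genome_length=30_000, samples_per_group=21,
            n_rare_alleles=10, trios=(),
        )
        aln, _, truth = generate_panel(cfg)
        from plastotype.variants import call_variants

        loci = call_variants(aln)
        freqs = allele_frequencies(loci, aln.samples)
        _, eliminated = maf_filter(freqs, 0.01)
        assert sorted(f.locus_id for f in eliminated) == sorted(
            truth.singleton_ids()
        )


class TestSpecificity:
    def test_synthetic_recovery_all_loci(self):
        for seed in range(5):
            aln, _, truth = generate_panel(SimulationConfig(seed=seed))
            from plastotype.variants import call_variants

            loci = call_variants(aln)
            groups = sorted(aln.groups())
            results = assign_specificity(loci, aln.samples, groups)
            want = truth.diagnostic_ids()
            for r in results:
                assert r.assigned_group == want.get(r.locus_id), r.locus_id

    def test_two_groups_sharing_contrast_hit_both_and_get_none(self):
        # with exactly two groups the one-vs-rest contrasts coincide: a
        # fixed difference exceeds the threshold for both -> multi-hit, none
        locus, samples = _locus_from_groups(
            {"H": ["A"] * 6, "C": ["T"] * 6}
        )
        (result,) = assign_specificity([locus], samples, ["H", "C"])
        assert result.fst_by_group["H"] == 1.0
        assert result.fst_by_group["C"] == 1.0
        assert result.assigned_group is None

    def test_allele_shared_by_two_groups_stays_subthreshold(self):
        locus, samples = _locus_from_groups(
            {
                "H": ["A"] * 4, "C": ["A"] * 4,
                "B": ["T"] * 4, "D": ["T"] * 4, "T": ["T"] * 4,
            }
        )
        (result,) = assign_specificity(
            [locus], samples, ["B", "C", "D", "H", "T"]
        )
        assert all(v < 0.9 for v in result.fst_by_group.values())
        assert result.assigned_group is None

    def test_ungrouped_sample_is_an_error(self):
        locus, samples = _locus_from_groups({"B": ["A"] * 4, "C": ["T"] * 4})
        samples[0].group = None
        with pytest.raises(Exception, match="group"):
            assign_specificity([locus], samples, ["B", "C"])


def _indicator_setup(groups):
    """One perfectly specific locus per group + signatures."""
    results, signatures = [], {}
    for g in groups:
        lid = f"LOC_{g}"
        results.append(
            SpecificityResult(lid, {h: (1.0 if h == g else -0.1) for h in groups},
                              g, "X", 0.9)
        )
        signatures[lid] = {h: ("X" if h == g else "o") for h in groups}
    return results, signatures


def brute_force_minimum_panel_size(signatures, groups):
    """Exhaustive subset search over all loci for the smallest
    discriminating set (independent of the selection code)."""
    pool = sorted(signatures)
    for size in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, size):
            rows = {tuple(signatures[l][g] for l in combo) for g in groups}
            if len(rows) == len(groups):
                return size
    return None


class TestPanelSelection:
    GROUPS5 = ["B", "C", "D", "H", "T"]

    def test_one_per_group_gives_one_locus_per_group(self):
        results, signatures = _indicator_setup(self.GROUPS5)
        panel = select_core_panel(results, signatures, self.GROUPS5)
        assert panel.size == 5
        rows = [panel.signature[g] for g in self.GROUPS5]
        assert len(set(rows)) == 5

    def test_minimal_policy_drops_one_indicator(self):
        results, signatures = _indicator_setup(self.GROUPS5)
        panel = select_core_panel(results, signatures, self.GROUPS5,
                                  policy="minimal")
        assert panel.size == 4
        assert panel.size == brute_force_minimum_panel_size(
            signatures, self.GROUPS5
        )

    def test_two_groups(self):
        results, signatures = _indicator_setup(["B", "D"])
        assert select_core_panel(results, signatures, ["B", "D"]).size == 2
        assert select_core_panel(
            results, signatures, ["B", "D"], policy="minimal"
        ).size == 1

    def test_uncovered_group_is_named(self):
        results, signatures = _indicator_setup(["B", "C"])
        with pytest.raises(UncoveredGroupError, match="D"):
            select_core_panel(results, signatures, ["B", "C", "D"])

    def test_highest_fst_wins_with_lexicographic_ties(self):
        results, signatures = _indicator_setup(["B", "C"])
        extra = SpecificityResult("LOC_A", {"B": 0.95, "C": -0.1}, "B", "X", 0.9)
        signatures["LOC_A"] = {"B": "X", "C": "o"}
        panel = select_core_panel(results + [extra], signatures, ["B", "C"])
        assert "LOC_B" in panel.locus_ids  # fst 1.0 beats 0.95
        tied = SpecificityResult("LOC_0", {"B": 1.0, "C": -0.1}, "B", "X", 0.9)
        signatures["LOC_0"] = {"B": "X", "C": "o"}
        panel2 = select_core_panel(results + [tied], signatures, ["B", "C"])
        assert "LOC_0" in panel2.locus_ids  # lexicographically first at 1.0

    def test_constrained_panel_for_sterile_candidates(self):
        results, signatures = _indicator_setup(self.GROUPS5)
        sterile = ["C", "H", "T"]
        assert constrained_panel(results, signatures, sterile).size == 2
        assert constrained_panel(
            results, signatures, sterile, policy="one-per-group"
        ).size == 3

    def test_constrained_pair_needs_single_locus(self):
        results, signatures = _indicator_setup(self.GROUPS5)
        assert constrained_panel(results, signatures, ["B", "D"]).size == 1

    def test_single_candidate_group_rejected(self):
        results, signatures = _indicator_setup(self.GROUPS5)
        with pytest.raises(ConfigError):
            constrained_panel(results, signatures, ["C"])

    def test_adding_loci_never_breaks_validity(self):
        results, signatures = _indicator_setup(self.GROUPS5)
        panel = select_core_panel(results, signatures, self.GROUPS5,
                                  policy="minimal")
        ids = list(panel.locus_ids)
        for extra in sorted(set(signatures) - set(ids)):
            ids.append(extra)
            grown = Panel(
                locus_ids=ids,
                group_order=self.GROUPS5,
                signature={
                    g: tuple(signatures[l][g] for l in ids)
                    for g in self.GROUPS5
                },
                policy="manual",
            )
            assert grown.size == len(ids)  # constructor validated distinctness


class TestMarkerTableSignatures:
    def test_published_assignments_cover_all_groups(self, vcp_rows):
        results, signatures = signatures_from_marker_table(
            vcp_rows, ["B", "C", "D", "H", "T"]
        )
        assigned = {r.assigned_group for r in results if r.assigned_group}
        assert assigned == {"B", "C", "D", "H", "T"}
        assert sum(1 for r in results if r.assigned_group is None) == 10

    def test_indel_codes_resolve_to_alleles(self, vcp_rows):
        _, signatures = signatures_from_marker_table(
            vcp_rows, ["B", "C", "D", "H", "T"]
        )
        cidp01 = signatures["CPMIDP01"]
        assert len(cidp01["H"]) == 83          # "I": the insertion allele
        cidp02 = signatures["CPMIDP02"]
        assert cidp02["H"] == ""               # "D": the deletion allele
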