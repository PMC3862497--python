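"""Quality-control filters: thresholds, exact tests, pruning rules."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from straysink.containers import MISSING, CollectionSet
from straysink.qc import (
    LocusPanel,
    QcReport,
    filter_individuals,
    filter_loci,
    hwe_exact_test,
    hwe_locus_screen,
    ld_pair_test,
    microsat_contamination_screen,
    prune_linked_loci,
    replicate_concordance,
    sequential_bonferroni,
)
from straysink.simulate import sample_genotype_matrix
from tests.conftest import make_collection


def _matrix_with_missing(n, L, missing_per_row):
    g = np.ones((n, L), dtype=np.int8)
    for i, k in enumerate(missing_per_row):
        g[i, :k] = MISSING
    return g


class TestIndividualFilter:
    def test_strictly_more_than_twenty_percent_missing_removed(self):
        # 28/135 = 0.207 exceeds the cutoff; 27/135 = 0.200 does not
        coll = make_collection(_matrix_with_missing(3, 135, [28, 27, 0]))
        keep, removed = filter_individuals(coll, 0.20)
        assert list(keep) == [1, 2]
        assert removed["missing"] == ["c_0"]

    def test_otolith_flagged_stray_removed_despite_complete_genotypes(self):
        coll = make_collection(
            np.ones((3, 10), dtype=np.int8), stray=np.array([False, True, False])
        )
        keep, removed = filter_individuals(coll)
        assert removed["stray"] == ["c_1"] and list(keep) == [0, 2]

    def test_idempotent(self):
        coll = make_collection(_matrix_with_missing(5, 20, [10, 0, 5, 0, 0]))
        keep1, _ = filter_individuals(coll, 0.20)
        once = coll.subset_individuals(keep1)
        keep2, removed2 = filter_individuals(once, 0.20)
        assert list(keep2) == list(range(once.n_individuals))
        assert not removed2["missing"] and not removed2["stray"]


class TestLocusFilter:
    def _collections(self, typed_counts):
        # one historical collection of 60 fish; loci typed in the given counts
        g = np.ones((60, len(typed_counts)), dtype=np.int8)
        g[0] = 2  # keep loci polymorphic
        for l, k in enumerate(typed_counts):
            g[k:, l] = MISSING
        hist = make_collection(g, "h", role="sink-historical")
        return CollectionSet([hist], [f"L{i}" for i in range(len(typed_counts))])

    def test_locus_coverage_boundary(self):
        colls = self._collections([54, 55, 60])
        panel = filter_loci(colls, LocusPanel(list(colls.loci)), min_typed=55)
        assert panel.status["L0"] == "removed:low-coverage"
        assert panel.status["L1"] == "retained"
        assert panel.status["L2"] == "retained"

    def test_invariant_locus_removed(self):
        g = np.ones((60, 2), dtype=np.int8)
        g[0, 0] = 2
        # locus L1 is heterozygous everywhere? no: make it fixed hom-ref
        g[:, 1] = 2
        colls = CollectionSet(
            [make_collection(g, "h", role="sink-historical")], ["L0", "L1"]
        )
        panel = filter_loci(colls, LocusPanel(["L0", "L1"]), min_typed=10)
        assert panel.status["L1"] == "removed:invariant"
        assert panel.status["L0"] == "retained"


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact-fraction enumeration of all genotype tables with the observed
    allele counts; two-sided probability-ordering p-value."""
    n = n_hom_ref + n_het + n_hom_alt
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n - n_ref
    weights = {}
    for h in range(n_ref % 2, min(n_ref, n_alt) + 1, 2):
        a, b = (n_ref - h) // 2, (n_alt - h) // 2
        weights[h] = Fraction(factorial(n) * 2**h, factorial(a) * factorial(h) * factorial(b))
    total = sum(weights.values())
    p_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= p_obs) / total


class TestHweExactTest:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((3, 0, 3), Fraction(20, 924)),
            ((0, 6, 0), Fraction(84, 924)),
            ((10, 0, 0), Fraction(1)),
        ],
    )
    def test_enumeration_examples(self, counts, expected):
        assert hwe_exact_test(counts) == pytest.approx(float(expected), abs=1e-12)

    def test_matches_oracle_on_moderate_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = tuple(rng.integers(0, 15, 3))
            if sum(c) == 0:
                continue
            assert hwe_exact_test(c) == pytest.approx(float(hwe_oracle(*c)), abs=1e-10)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test((0, 0, 0))


class TestSequentialBonferroni:
    def test_all_significant_at_five_percent(self):
        assert sequential_bonferroni([0.001, 0.02, 0.03], 0.05).all()

    def test_sequence_stops_at_first_failure(self):
        flags = sequential_bonferroni([0.001, 0.02, 0.03], 0.01)
        assert list(flags) == [True, False, False]

    def test_empty_input(self):
        assert sequential_bonferroni([]).size == 0

    @given(st.lists(st.floats(0, 1), max_size=20), st.floats(1e-4, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_rejections_form_prefix_of_sorted_pvalues(self, pvals, alpha):
        flags = sequential_bonferroni(pvals, alpha)
        rejected = sorted(p for p, f in zip(pvals, flags) if f)
        kept = [p for p, f in zip(pvals, flags) if not f]
        if rejected and kept:
            assert max(rejected) <= min(kept)


class TestHweLocusScreen:
    def _study(self, rng, n_coll=5, n=80, L=12, bad_in=0):
        colls = []
        for i in range(n_coll):
            g = sample_genotype_matrix(np.full(L, 0.5), n, rng)
            if i < bad_in:
                g[:, 0] = 1  # locus 0 all-heterozygous: extreme HWE violation
            colls.append(
                make_collection(g, f"c{i}", role="sink-historical", site=f"s{i}")
            )
        return CollectionSet(colls, [f"L{j}" for j in range(L)])

    def test_majority_rule_removes_locus(self, rng):
        colls = self._study(rng, bad_in=3)
        panel = hwe_locus_screen(colls, LocusPanel(list(colls.loci)), alpha=0.01)
        assert panel.status["L0"] == "removed:HWE"

    def test_minority_deviation_retained(self, rng):
        colls = self._study(rng, bad_in=2)
        panel = hwe_locus_screen(colls, LocusPanel(list(colls.loci)), alpha=0.01)
        assert panel.status["L0"] == "retained"

    def test_null_data_loses_no_loci(self, rng):
        colls = self._study(rng, bad_in=0, L=30)
        panel = hwe_locus_screen(colls, LocusPanel(list(colls.loci)), alpha=0.01)
        assert all(s == "retained" for s in panel.status.values())


class TestLdPairTest:
    def test_identical_columns_maximally_associated(self, rng):
        g = sample_genotype_matrix(np.array([0.5]), 50, rng)[:, 0]
        assert ld_pair_test(g, g.copy(), 999, rng) <= 0.005

    def test_monomorphic_partner_gives_p_one(self, rng):
        a = sample_genotype_matrix(np.array([0.5]), 30, rng)[:, 0]
        assert ld_pair_test(a, np.ones(30, dtype=np.int8), 99, rng) == 1.0

    def test_too_few_individuals_rejected(self, rng):
        with pytest.raises(ValueError):
            ld_pair_test(np.array([1]), np.array([1]), 99, rng)

    def test_null_pvalues_uniform(self, rng):
        from scipy import stats

        ps = []
        for _ in range(400):
            g = sample_genotype_matrix(rng.uniform(0.2, 0.8, 2), 50, rng)
            ps.append(ld_pair_test(g[:, 0], g[:, 1], 199, rng))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPruneLinkedLoci:
    def _panel(self, het, miss=None):
        panel = LocusPanel(list(het))
        panel.heterozygosity.update(het)
        panel.historical_missing.update(miss or {})
        return panel

    def test_lower_heterozygosity_locus_removed(self):
        panel = self._panel({"A": 0.30, "B": 0.40})
        pvals = {("A", "B"): np.array([0.01] * 5 + [0.5] * 4)}  # 5/9 significant
        prune_linked_loci(pvals, panel)
        assert panel.status["A"] == "removed:linked"
        assert panel.status["B"] == "retained"

    def test_known_linked_pair_pruned_despite_minority_significance(self):
        panel = self._panel({"A": 0.30, "B": 0.40})
        pvals = {("A", "B"): np.array([0.01] * 4 + [0.5] * 5)}  # only 4/9
        prune_linked_loci(pvals, panel, known_linked_pairs=[("A", "B")])
        assert panel.status["A"] == "removed:linked"

    def test_missingness_breaks_heterozygosity_tie(self):
        panel = self._panel({"A": 0.30, "B": 0.30}, {"A": 0.10, "B": 0.02})
        pvals = {("A", "B"): np.array([0.01] * 5 + [0.5] * 4)}
        prune_linked_loci(pvals, panel)
        assert panel.status["A"] == "removed:linked"
        assert panel.status["B"] == "retained"

    def test_chain_broken_by_highest_degree_locus(self):
        # A-B and B-C linked: removing B alone resolves the triplet
        panel = self._panel({"A": 0.5, "B": 0.5, "C": 0.5})
        sig = np.array([0.01] * 5 + [0.5] * 4)
        prune_linked_loci({("A", "B"): sig, ("B", "C"): sig}, panel)
        assert panel.status["B"] == "removed:linked"
        assert panel.status["A"] == panel.status["C"] == "retained"


class TestMicrosatScreen:
    def test_three_alleles_at_one_locus_flags_individual(self):
        obs = [[frozenset({120, 124, 128}), frozenset({100})]]
        flags, unscreened = microsat_contamination_screen(obs)
        assert flags[0] and unscreened == 0

    def test_two_alleles_everywhere_not_flagged(self):
        obs = [[frozenset({120, 124})] * 7]
        flags, _ = microsat_contamination_screen(obs)
        assert not flags[0]

    def test_unscored_individual_counted_not_flagged(self):
        flags, unscreened = microsat_contamination_screen([[None, frozenset()]])
        assert not flags[0] and unscreened == 1


class TestReplicateConcordance:
    def test_identical_replicates(self):
        g = np.ones((5, 20), dtype=np.int8)
        _, overall, per_pass = replicate_concordance(g, g.copy())
        assert overall == 0.0 and per_pass == 0.0

    def test_single_disagreement_rate_and_half_attribution(self):
        a = np.ones((10, 10), dtype=np.int8)
        b = a.copy()
        b[0, 0] = 2
        _, overall, per_pass = replicate_concordance(a, b)
        assert overall == pytest.approx(0.01) and per_pass == pytest.approx(0.005)

    def test_empty_overlap_rejected(self):
        a = np.ones((2, 3), dtype=np.int8)
        b = np.full((2, 3), MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            replicate_concordance(a, b)


class TestQcReportAccounting:
    def test_balance_invariant(self):
        report = QcReport()
        report.start("x", 100)
        report.record("x", "stray", 3)
        report.record("x", "missing", 10)
        report.record("x", "microsat", 20)
        report.record("x", "hwe_model", 5)
        assert report.final("x") == 62
        assert report.balanced()
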