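import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methylink.association import (
    AssociationDataset,
    association_sweep,
    bh_adjust,
    binomial_direction_test,
    central_offsets,
    contingency_p,
    ld_prime,
    relative_mod_positions,
    window_contingency,
)
from methylink.expression import build_profiles, category_shifts
from methylink.models import GeneModel, ModifiedBase, SweepConfig
from methylink.synth import SyntheticScenario, generate_linked_dataset


def oracle_ld_norm(a, b, c, d):
    """Independent normalisation: enumerate all tables with the same margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    ld = a / n - (r1 / n) * (c1 / n)
    lds = []
    for a2 in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        lds.append(a2 / n - (r1 / n) * (c1 / n))
    if ld > 0:
        return ld / max(lds)
    if ld < 0:
        return ld / abs(min(lds))
    return 0.0


class TestLdPrime:
    def test_published_table_one(self):
        _, ld_norm = ld_prime(22, 8, 25, 49)
        assert round(ld_norm, 2) == 0.51

    def test_published_table_two(self):
        _, ld_norm = ld_prime(22, 8, 35, 53)
        assert round(ld_norm, 2) == 0.48

    def test_independence(self):
        assert ld_prime(10, 10, 10, 10) == (0.0, 0.0)

    def test_perfect_positive(self):
        _, ld_norm = ld_prime(10, 0, 0, 10)
        assert ld_norm == pytest.approx(1.0)

    def test_perfect_negative(self):
        _, ld_norm = ld_prime(0, 10, 10, 0)
        assert ld_norm == pytest.approx(-1.0)

    def test_zero_margin_undefined(self):
        _, ld_norm = ld_prime(0, 0, 10, 4)
        assert math.isnan(ld_norm)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ld_prime(0, 0, 0, 0)

    def test_exhaustive_oracle_equivalence_small_n(self):
        # every 2x2 table with n <= 30 and no zero margin
        for n in range(1, 31):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        ld_raw, ld_norm = ld_prime(a, b, c, d)
                        assert -1 - 1e-12 <= ld_norm <= 1 + 1e-12
                        assert np.sign(ld_norm) == np.sign(ld_raw)
                        assert ld_norm == pytest.approx(
                            oracle_ld_norm(a, b, c, d), abs=1e-12
                        )

    def test_extreme_iff_boundary_table(self):
        # |ld_norm| = 1 exactly when a is at its margin-compatible extreme
        for (a, b, c, d), expect in [((3, 2, 0, 5), 1.0), ((0, 5, 3, 2), -1.0),
                                     ((2, 3, 1, 4), None)]:
            _, ld_norm = ld_prime(a, b, c, d)
            if expect is None:
                assert abs(ld_norm) < 1
            else:
                assert ld_norm == pytest.approx(expect)


class TestContingencyP:
    def test_zero_statistic(self):
        assert contingency_p(10, 10, 10, 10) == pytest.approx(1.0)

    def test_uncorrected_value(self):
        # chi2 = 104 * (22*49 - 8*25)^2 / (30*74*47*57) = 13.4805
        chi2 = 104 * (22 * 49 - 8 * 25) ** 2 / (30 * 74 * 47 * 57)
        expected = stats.chi2.sf(chi2, 1)
        assert contingency_p(22, 8, 25, 49, correction=False) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(2.4e-4, rel=0.02)

    def test_corrected_value(self):
        n = 104
        chi2 = n * (abs(22 * 49 - 8 * 25) - n / 2) ** 2 / (30 * 74 * 47 * 57)
        expected = stats.chi2.sf(chi2, 1)
        assert contingency_p(22, 8, 25, 49, correction=True) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(5.5e-4, rel=0.02)

    def test_zero_margin_flagged_as_one(self):
        assert contingency_p(0, 0, 10, 4) == 1.0

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_row_and_column_swap_invariance(self, table):
        a, b, c, d = table
        p = contingency_p(a, b, c, d)
        assert contingency_p(d, c, b, a) == pytest.approx(p)

    @given(st.tuples(*[st.integers(0, 40)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_directly(self, table):
        a, b, c, d = table
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        expected = stats.chi2_contingency([[a, b], [c, d]]).pvalue
        assert contingency_p(a, b, c, d) == pytest.approx(float(expected))


class TestBhAdjust:
    def test_worked_example(self):
        adjusted, _ = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        adjusted, reject = bh_adjust([0.2])
        assert adjusted[0] == pytest.approx(0.2)
        assert not reject[0]

    def test_zeros(self):
        adjusted, reject = bh_adjust([0.0, 0.0])
        np.testing.assert_array_equal(adjusted, [0.0, 0.0])
        assert reject.all()

    def test_empty(self):
        adjusted, reject = bh_adjust([])
        assert adjusted.size == 0 and reject.size == 0

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_superset_of_bonferroni(self, ps):
        alpha = 0.05
        adjusted, reject = bh_adjust(ps, alpha)
        bonferroni = np.minimum(np.asarray(ps) * len(ps), 1.0) <= alpha
        assert np.all(reject[bonferroni])
        assert np.all(adjusted <= 1.0 + 1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_order_invariance(self, ps, rnd):
        shuffled = ps[:]
        rnd.shuffle(shuffled)
        a1, _ = bh_adjust(ps)
        a2, _ = bh_adjust(shuffled)
        assert sorted(np.round(a1, 12)) == sorted(np.round(a2, 12))


class TestBinomialDirectionTest:
    def test_all_concordant(self):
        assert binomial_direction_test(10, 10) == pytest.approx(2 * 0.5**10)

    def test_exact_half(self):
        assert binomial_direction_test(5, 10) == pytest.approx(1.0)

    def test_single_trial(self):
        assert binomial_direction_test(0, 1) == pytest.approx(1.0)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_direction_test(0, 0)


class TestRelativeModPositions:
    def test_plus_strand(self):
        gene = GeneModel("g", "c1", 1000, 2000, "+")
        mods = [ModifiedBase("c1", 950, "+", "A", "m6A", 99.0),
                ModifiedBase("c1", 1005, "+", "A", "m6A", 99.0),
                ModifiedBase("c1", 1005, "-", "A", "m6A", 99.0)]  # wrong strand
        rel = relative_mod_positions([gene], mods)["g"]
        assert rel.tolist() == [-50, 5]

    def test_minus_strand(self):
        gene = GeneModel("g", "c1", 1000, 2000, "-")  # tsc = 2000
        mods = [ModifiedBase("c1", 2050, "-", "A", "m6A", 99.0),
                ModifiedBase("c1", 1995, "-", "A", "m6A", 99.0)]
        rel = relative_mod_positions([gene], mods)["g"]
        assert rel.tolist() == [-50, 5]


def tally_oracle(genes, mods_a, mods_b, shifts, offset, window, cutoff):
    """Direct per-gene tally, independent of the windowing implementation."""
    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    for g in genes:
        direction = shifts[g.gene_id].direction
        if direction == "none":
            continue

        def count(mods):
            total = 0
            for m in mods:
                if m.contig_id != g.contig_id or m.strand != g.strand:
                    continue
                if m.nucmod_score < cutoff:
                    continue
                r = m.position - g.tsc_position if g.strand == "+" \
                    else g.tsc_position - m.position
                if offset <= r < offset + window:
                    total += 1
            return total

        na, nb = count(mods_a), count(mods_b)
        if na == nb:
            continue
        key = {("up", True): "a", ("up", False): "b",
               ("down", True): "c", ("down", False): "d"}[(direction, nb > na)]
        cells[key] += 1
    return cells["a"], cells["b"], cells["c"], cells["d"]


class TestWindowContingency:
    def build_shifts(self, dataset, k=3):
        prof_a = build_profiles(dataset.counts_a, dataset.genes, k=k)
        prof_b = build_profiles(dataset.counts_b, dataset.genes, k=k)
        return category_shifts(prof_a, prof_b)

    def test_all_unchanged_flagged(self):
        genes = [GeneModel(f"g{i}", "c1", 1000 * i, 1000 * i + 500, "+")
                 for i in range(1, 5)]
        counts = {g.gene_id: 10.0 for g in genes}
        prof = build_profiles(counts, genes, k=2)
        shifts = category_shifts(prof, prof)
        result = window_contingency(genes, [], [], shifts, -50, 27)
        assert result.n == 0 and result.degenerate

    def test_degenerate_single_cell(self):
        genes = [GeneModel(f"g{i}", "c1", 2000 * i, 2000 * i + 500, "+")
                 for i in range(1, 5)]
        counts_a = {g.gene_id: 1.0 for g in genes}
        counts_b = {g.gene_id: 10_000.0 for g in genes}
        counts_a["anchor1"] = counts_b["anchor1"] = 500.0
        counts_b["anchor2"] = counts_a["anchor2"] = 600.0
        anchor_genes = genes + [
            GeneModel("anchor1", "c1", 20_000, 20_400, "+"),
            GeneModel("anchor2", "c1", 30_000, 30_400, "+"),
        ]
        prof_a = build_profiles(counts_a, anchor_genes, k=3)
        prof_b = build_profiles(counts_b, anchor_genes, k=3)
        shifts = category_shifts(prof_a, prof_b)
        mods_b = [ModifiedBase("c1", g.start - 30, "+", "A", "m6A", 150.0)
                  for g in genes]
        result = window_contingency(anchor_genes, [], mods_b, shifts, -50, 27)
        assert (result.a, result.b, result.c, result.d) == (4, 0, 0, 0)
        assert math.isnan(result.ld_norm)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_tally_oracle_on_random_scenarios(self, seed):
        rng = np.random.default_rng(seed)
        scenario = SyntheticScenario(
            genome_length=60_000, n_genes=40, gene_length_mean=600,
            noncanonical_density=15.0, coupling_strength=float(rng.random()),
            shift_fraction=0.5, seed=seed,
        )
        dataset = generate_linked_dataset(scenario)
        shifts = self.build_shifts(dataset)
        offset = int(rng.integers(-200, 100))
        window = int(rng.integers(20, 80))
        cutoff = float(rng.choice([0, 100, 150]))
        result = window_contingency(
            dataset.genes, dataset.mods_a, dataset.mods_b, shifts,
            offset, window, score_cutoff=cutoff,
        )
        expected = tally_oracle(dataset.genes, dataset.mods_a, dataset.mods_b,
                                shifts, offset, window, cutoff)
        assert (result.a, result.b, result.c, result.d) == expected


class TestCentralOffsets:
    def test_odd_window(self):
        assert list(central_offsets(-50, 27)) == list(range(-40, -33))

    def test_even_window(self):
        # mid = floor(-50 + 35/2) = floor(-32.5) = -33
        assert list(central_offsets(-50, 36)) == list(range(-36, -29))

    def test_width_always_seven(self):
        for offset in (-100, -1, 0, 13):
            for window in (7, 27, 36, 90):
                assert len(list(central_offsets(offset, window))) == 7


class TestAssociationSweep:
    def test_single_grid_point_consistency(self, linked_null):
        ds = linked_null
        dataset = AssociationDataset(ds.genes, ds.mods_a, ds.mods_b,
                                     ds.counts_a, ds.counts_b, ds.genome)
        config = SweepConfig(window_sizes=(27,), category_counts=(3,),
                             score_cutoffs=(100.0,), offset_range=(-60, -60))
        _, rows = association_sweep(dataset, config)
        assert len(rows) == 1
        shifts = self.build_shifts(ds)
        direct = window_contingency(ds.genes, ds.mods_a, ds.mods_b, shifts,
                                    -60, 27, score_cutoff=100.0)
        row = rows[0]
        assert (row.a, row.b, row.c, row.d) == (direct.a, direct.b,
                                                direct.c, direct.d)
        assert row.chi2_p == pytest.approx(direct.chi2_p)

    def build_shifts(self, ds, k=3):
        prof_a = build_profiles(ds.counts_a, ds.genes, k=k)
        prof_b = build_profiles(ds.counts_b, ds.genes, k=k)
        return category_shifts(prof_a, prof_b)

    def test_determinism(self, linked_coupled):
        ds = linked_coupled
        dataset = AssociationDataset(ds.genes, ds.mods_a, ds.mods_b,
                                     ds.counts_a, ds.counts_b, ds.genome)
        config = SweepConfig(window_sizes=(27, 47), category_counts=(3,),
                             score_cutoffs=(100.0,), offset_range=(-150, 0))
        r1, rows1 = association_sweep(dataset, config)
        r2, rows2 = association_sweep(dataset, config)
        assert rows1 == rows2
        assert r1.n_windows_significant == r2.n_windows_significant

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            SweepConfig(window_sizes=())

    def test_window_below_seven_rejected(self):
        with pytest.raises(ValueError):
            SweepConfig(window_sizes=(5,))

    def test_planted_coupling_recovered(self, linked_coupled):
        ds = linked_coupled
        dataset = AssociationDataset(ds.genes, ds.mods_a, ds.mods_b,
                                     ds.counts_a, ds.counts_b, ds.genome)
        config = SweepConfig(window_sizes=(27, 47, 67), category_counts=(3,),
                             score_cutoffs=(100.0,), offset_range=(-350, 100))
        result, rows = association_sweep(dataset, config)
        assert result.n_windows_significant > 0
        peak = max(result.offsets, key=lambda o: o.hit_count)
        assert -80 <= peak.offset <= -20
        inside = [o for o in result.offsets if -80 <= o.offset <= -20]
        assert all(o.mean_ld >= 0.5 for o in inside)

    def test_base_restriction_reduces_calls(self, linked_coupled):
        ds = linked_coupled
        dataset = AssociationDataset(ds.genes, ds.mods_a, ds.mods_b,
                                     ds.counts_a, ds.counts_b, ds.genome)
        a_only, _ = dataset.filtered("A", 0.0)
        c_only, _ = dataset.filtered("C", 0.0)
        assert len(a_only) + len(c_only) == len(ds.mods_a)
        assert all(m.base == "A" for m in a_only)
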