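import numpy as np
import pytest

from clrdiff import (
    ClrEnsemble,
    ConditionDesign,
    CountTable,
    abundance_medians,
    build_ensemble,
    clr_transform,
    difference_distributions,
    effect_size,
    filter_features,
    generate_null,
    SyntheticSpec,
)
from clrdiff.effect_stats import summarize


def _design6():
    return ConditionDesign(
        {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
    )


def _ensemble(clr: np.ndarray) -> ClrEnsemble:
    k, f, s = clr.shape
    assert s == 6
    return ClrEnsemble(
        tuple(f"f{i}" for i in range(f)),
        ("a1", "a2", "a3", "b1", "b2", "b3"),
        clr,
    )


class TestAbundanceMedians:
    def test_constant_feature(self):
        clr = np.full((4, 2, 6), 0.0)
        clr[:, 1, :] = 2.5
        out = abundance_medians(_ensemble(clr), _design6())
        assert np.allclose(out["rab_all"], [0.0, 2.5])
        assert np.allclose(out["rab_condA"], [0.0, 2.5])
        assert np.allclose(out["rab_condB"], [0.0, 2.5])

    def test_single_instance_direct_median(self):
        clr = np.array([[[1.0, 1.0, 3.0, 5.0, 5.0, 7.0]]])
        out = abundance_medians(_ensemble(clr), _design6())
        assert out["rab_condA"][0] == 1.0
        assert out["rab_condB"][0] == 5.0
        assert out["rab_all"][0] == 4.0

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        clr = rng.normal(size=(3, 5, 6))
        ens = _ensemble(clr)
        # keep an A-condition sample first so the A/B roles are unchanged
        perm = [2, 0, 1, 5, 3, 4]
        ens_perm = ClrEnsemble(
            ens.feature_ids,
            tuple(ens.sample_ids[j] for j in perm),
            clr[:, :, perm],
        )
        out = abundance_medians(ens, _design6())
        out_perm = abundance_medians(ens_perm, _design6())
        for col in ("rab_all", "rab_condA", "rab_condB"):
            assert np.allclose(out[col], out_perm[col])


class TestDifferenceDistributions:
    def test_degenerate_no_variation(self):
        clr = np.full((2, 3, 6), 1.7)
        between, within = difference_distributions(_ensemble(clr), _design6(), seed=0)
        assert np.all(between == 0)
        assert np.all(within == 0)
        eff = effect_size(between, within)
        assert np.all(eff["effect"] == 0)  # no-variation convention

    def test_pure_shift_fixture(self):
        clr = np.zeros((4, 2, 6))
        clr[:, 0, 3:] = 2.0  # feature 0 shifted +2 in condition B
        between, within = difference_distributions(_ensemble(clr), _design6(), seed=1)
        assert np.all(between[:, 0, :] == 2.0)
        assert np.all(between[:, 1, :] == 0.0)

    def test_draw_count_is_max_group_size(self):
        clr = np.zeros((3, 2, 6))
        between, _ = difference_distributions(_ensemble(clr), _design6(), seed=0)
        assert between.shape == (3, 2, 3)

    def test_reproducible_under_seed(self, small_table, small_design):
        ens = build_ensemble(filter_features(small_table), n_instances=4, seed=5)
        b1, w1 = difference_distributions(ens, small_design, seed=11)
        b2, w2 = difference_distributions(ens, small_design, seed=11)
        assert np.array_equal(b1, b2)
        assert np.array_equal(w1, w2)

    def test_null_medians_near_zero(self):
        spec = SyntheticSpec(n_features=100, n_per_group=7, depth=1e5, seed=4)
        table, design, _ = generate_null(spec)
        ens = build_ensemble(filter_features(table), n_instances=64, seed=4)
        res = summarize(ens, design, seed=4)
        # sign-symmetry of the null: between-differences centred on zero
        assert abs(np.median(res["diff_btw"])) < 0.05
        assert np.quantile(np.abs(res["diff_btw"]), 0.9) < 0.5


class TestEffectSize:
    def test_constant_draws(self):
        between = np.full((2, 1, 3), 4.0)
        within = np.full((2, 1, 3), 2.0)
        eff = effect_size(between, within)
        assert eff["diff_btw"][0] == 4.0
        assert eff["diff_win"][0] == 2.0
        assert eff["effect"][0] == 2.0

    def test_symmetric_between_gives_zero_effect(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(1, 1, 20001))
        between = np.concatenate([draws, -draws], axis=2)
        within = np.abs(rng.normal(size=(1, 1, 40002))) + 0.5
        eff = effect_size(between, within)
        assert abs(eff["effect"][0]) < 0.05

    def test_known_shift_recovered(self):
        # counts constructed from proportions where one feature's clr is
        # shifted by exactly 6.2 log2 units between conditions
        rng = np.random.default_rng(9)
        n_feat, delta = 100, 6.2
        base = rng.dirichlet(np.full(n_feat, 50.0))
        boosted = base.copy()
        boosted[0] *= 2.0 ** (delta * n_feat / (n_feat - 1))
        boosted /= boosted.sum()
        assert clr_transform(boosted)[0] - clr_transform(base)[0] == pytest.approx(delta)
        depth = 10**6
        counts = np.column_stack(
            [rng.multinomial(depth, base) for _ in range(3)]
            + [rng.multinomial(depth, boosted) for _ in range(3)]
        )
        table = CountTable(
            tuple(f"f{i}" for i in range(n_feat)),
            ("a1", "a2", "a3", "b1", "b2", "b3"),
            counts,
        )
        ens = build_ensemble(filter_features(table), n_instances=64, seed=10)
        res = summarize(ens, _design6(), seed=10)
        assert res["diff_btw"][0] == pytest.approx(delta, abs=0.2)

    def test_diff_win_floor_applied(self):
        between = np.zeros((1, 1, 5))
        within = np.zeros((1, 1, 5))
        eff = effect_size(between, within)
        assert eff["diff_win"][0] == pytest.approx(1e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            effect_size(np.zeros((1, 1, 3)), np.zeros((1, 1, 4)))


class TestInvariants:
    def test_effect_antisymmetric_under_role_swap(self, small_table, small_design):
        # put a Y-condition sample first so the A/B roles exchange exactly
        t = filter_features(small_table)
        ens = build_ensemble(t, n_instances=8, seed=3)
        perm = [3, 4, 5, 0, 1, 2]
        ens_swapped = ClrEnsemble(
            ens.feature_ids,
            tuple(ens.sample_ids[j] for j in perm),
            ens.clr[:, :, perm],
        )
        res = summarize(ens, small_design, seed=6)
        res_sw = summarize(ens_swapped, small_design, seed=6)
        assert np.allclose(res_sw["effect"], -res["effect"])
        assert np.allclose(res_sw["diff_btw"], -res["diff_btw"])
        assert np.allclose(res_sw["diff_win"], res["diff_win"])
        assert np.allclose(res_sw["rab_condA"], res["rab_condB"])
        assert np.allclose(res_sw["rab_condB"], res["rab_condA"])

    def test_sign_consistency(self, small_table, small_design):
        ens = build_ensemble(filter_features(small_table), n_instances=16, seed=1)
        res = summarize(ens, small_design, seed=1)
        strong = np.abs(res["effect"]) > 0.2
        assert np.all(
            np.sign(res["effect"][strong]) == np.sign(res["diff_btw"][strong])
        )
        assert np.all(res["diff_win"] > 0)

    def test_effect_invariant_under_count_scaling(self):
        # deep samples with real between-sample variation: multiplying every
        # count by 10 barely moves the posterior, so effects agree closely
        rng = np.random.default_rng(14)
        base = rng.dirichlet(np.full(30, 20.0))
        cols = []
        for i in range(6):
            p = base * np.exp(rng.normal(0, 0.3, size=30))
            p /= p.sum()
            if i >= 3:
                p[0] *= 4
                p /= p.sum()
            cols.append(rng.multinomial(10**5, p))
        counts = np.column_stack(cols)
        ids = tuple(f"f{i}" for i in range(30))
        samples = ("a1", "a2", "a3", "b1", "b2", "b3")
        t1 = CountTable(ids, samples, counts)
        t2 = CountTable(ids, samples, counts * 10)
        r1 = summarize(build_ensemble(t1, 32, seed=2), _design6(), seed=2)
        r2 = summarize(build_ensemble(t2, 32, seed=2), _design6(), seed=2)
        assert np.corrcoef(r1["effect"], r2["effect"])[0, 1] > 0.98
        assert np.allclose(r1["diff_btw"], r2["diff_btw"], atol=0.15)


class TestSelexVariantFixture:
    """Behavioral check on printed variant count vectors embedded in a
    library where most features drop proportionally after selection."""

    @pytest.fixture(scope="class")
    def selex_results(self):
        rng = np.random.default_rng(35)
        kdie_a = [149, 89, 165, 68, 135, 128, 199]
        kdie_b = [0, 0, 1, 0, 1, 0, 0]
        segd_a = [755, 554, 669, 797, 862, 650, 2170]
        segd_b = [4710, 995, 906, 1716, 784, 804, 641]
        n_bg = 150
        bg_a = rng.poisson(130.0, size=(n_bg, 7))
        bg_b = rng.poisson(0.5, size=(n_bg, 7))
        counts = np.vstack(
            [
                np.concatenate([kdie_a, kdie_b])[None, :],
                np.concatenate([segd_a, segd_b])[None, :],
                np.hstack([bg_a, bg_b]),
            ]
        )
        ids = ("KDIE", "SEGD") + tuple(f"bg{i}" for i in range(n_bg))
        samples = tuple(f"ns{i}" for i in range(7)) + tuple(f"s{i}" for i in range(7))
        table = CountTable(ids, samples, counts)
        design = ConditionDesign(
            {s: ("NS" if s.startswith("ns") else "S") for s in samples}
        )
        from clrdiff import analyze

        return analyze(
            filter_features(table), design, n_instances=64, seed=35, tests=("welch",)
        )

    def test_geometric_mean_tracker_not_significant(self, selex_results):
        row = selex_results.set_index("feature_id").loc["KDIE"]
        assert row["we_eBH"] > 0.3
        assert abs(row["effect"]) < 1.0

    def test_enriched_variant_large_positive_difference(self, selex_results):
        row = selex_results.set_index("feature_id").loc["SEGD"]
        assert row["diff_btw"] > 3.0
        assert row["we_eBH"] < 0.05
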