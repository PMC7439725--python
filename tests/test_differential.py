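"""Differential effect scans, null controls, and empirical-FDR calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cistrans import activity as act
from cistrans import differential as diff
from cistrans import simulate as sim
from cistrans.config import SimulationConfig
from conftest import build_study


class TestBuildNullPairs:
    def _bm(self, n=60):
        return pd.DataFrame(
            {"barcode_id": [f"b{i}" for i in range(n)], "element_id": "pos0"}
        )

    def test_disjoint_subsets_and_unused_remainder(self):
        nulls = diff.build_null_pairs(self._bm(), ["pos0"], 10, seed=0)
        assert len(nulls) == 10
        for np_ in nulls:
            assert len(np_.subset_a) == len(np_.subset_b) == 13
            assert not set(np_.subset_a) & set(np_.subset_b)
            assert 60 - len(set(np_.subset_a) | set(np_.subset_b)) == 34

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            diff.build_null_pairs(self._bm(), ["pos0"], 5, subset_size=31, seed=0)

    def test_deterministic_given_seed(self):
        a = diff.build_null_pairs(self._bm(), ["pos0"], 5, seed=42)
        b = diff.build_null_pairs(self._bm(), ["pos0"], 5, seed=42)
        assert a == b


class TestPairwiseEffect:
    def _obs(self, values, replicate=1):
        return pd.DataFrame({"log_ratio": values, "replicate": replicate})

    def test_mean_difference(self):
        jitter = [0, 1e-6, -1e-6, 2e-6]
        a = self._obs(np.array([1.0, 1.0, 1.0, 1.0]) + jitter)
        b = self._obs(np.array([2.0, 2.0, 2.0, 2.0]) + jitter)
        effect, p = diff.pairwise_effect(a, b)
        assert effect == pytest.approx(1.0, abs=1e-5)
        assert p < 0.01

    def test_identical_groups_give_zero_and_p_one(self):
        a = self._obs([1.0, 2.0, 3.0])
        effect, p = diff.pairwise_effect(a, a.copy())
        assert effect == 0.0
        assert p == 1.0

    def test_degenerate_group_flagged_missing(self):
        effect, p = diff.pairwise_effect(self._obs([1.0]), self._obs([2.0, 3.0]))
        assert np.isnan(p)

    def test_null_pvalues_uniform(self):
        """p-values from null pseudo-pairs pass a KS test against U(0,1).

        The pseudo-pairs are spread over many positive-control pools so the
        1000 draws share few barcodes and the KS reference is valid.
        """
        cfg = SimulationConfig(n_pairs=2, n_negative_controls=5,
                               n_positive_controls=100, seed=13)
        _, truth = sim.simulate_truth(cfg)
        dna, rna = sim.simulate_counts(truth, cfg)
        obs = act.compute_log_ratios(dna, rna)
        positives = sorted(truth.alpha.index[truth.alpha.index.str.startswith("pos")])
        nulls = diff.build_null_pairs(truth.barcode_map, positives, 10, seed=14)
        assert len(nulls) == 1000
        hesc = obs[obs["environment"] == "hESC"]
        by_bc = dict(tuple(hesc.groupby("barcode_id")))
        pvals = []
        for np_ in nulls:
            a = pd.concat([by_bc[b] for b in np_.subset_a])
            b = pd.concat([by_bc[b] for b in np_.subset_b])
            pvals.append(diff.pairwise_effect(a, b)[1])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestCalibration:
    def _fake_results(self, null_qs, null_effects, real_qs=()):
        rows = []
        for i, (q, e) in enumerate(zip(null_qs, null_effects)):
            rows.append(dict(unit_id=f"n{i}", axis="cis_hESC", effect=e, p=q, q=q,
                             is_null=True))
        for i, q in enumerate(real_qs):
            rows.append(dict(unit_id=f"r{i}", axis="cis_hESC", effect=1.0, p=q, q=q,
                             is_null=False))
        return pd.DataFrame(rows)

    def test_order_statistic_rule(self):
        """Cutoff sits at the 10th-smallest null q; at most 9 of 100 nulls pass."""
        rng = np.random.default_rng(0)
        null_qs = np.sort(rng.uniform(0, 1, 100))
        res = self._fake_results(null_qs, rng.normal(0, 1, 100))
        cal = diff.calibrate_empirical_fdr(res)["cis"]
        assert null_qs[8] < cal.q_cutoff <= null_qs[9]
        assert (null_qs < cal.q_cutoff).sum() <= 9
        assert cal.achieved_null_rate < 0.10

    def test_effect_floor_is_min_significant_null_effect(self):
        # 9 nulls sit far below the cutoff (the 10th-smallest q); the floor is
        # the smallest |effect| among exactly those significant nulls
        small = np.linspace(0.001, 0.009, 9)
        null_qs = np.concatenate([small, np.full(91, 0.9)])
        effects = np.concatenate(
            [[0.7, -0.4, 0.5, 0.6, 0.8, 0.9, 1.0, 1.1, 1.2], np.full(91, 0.05)]
        )
        res = self._fake_results(null_qs, effects)
        cal = diff.calibrate_empirical_fdr(res)["cis"]
        assert cal.effect_floor == pytest.approx(0.4)
        assert (null_qs < cal.q_cutoff).sum() == 9

    def test_no_small_null_q_gives_zero_floor(self):
        null_qs = np.full(60, 0.9)  # every null q ties at the cutoff
        res = self._fake_results(null_qs, np.full(60, 0.01), real_qs=[0.001] * 5)
        cal = diff.calibrate_empirical_fdr(res)["cis"]
        assert cal.effect_floor == 0.0
        marked = diff.apply_significance(res, {"cis": cal, "trans": cal, "native": cal})
        assert marked.loc[~marked["is_null"], "significant"].all()

    def test_too_few_nulls_raises(self):
        res = self._fake_results([0.5] * 10, [0.1] * 10)
        with pytest.raises(ValueError, match="null results"):
            diff.calibrate_empirical_fdr(res)

    def test_full_run_controls_null_rate(self, small_study):
        for family, cal in small_study.calibration.items():
            assert cal.achieved_null_rate < 0.10


class TestAssignPairEffect:
    @pytest.mark.parametrize(
        "e1,s1,e2,s2,expected_effect,expected_sig",
        [
            (0.8, True, 0.5, True, 0.8, True),     # both significant: max |.|
            (0.8, False, -0.5, True, -0.5, True),  # only one significant
            (0.3, False, -0.6, False, -0.6, False),  # neither: max |.|, not sig
        ],
    )
    def test_rules(self, e1, s1, e2, s2, expected_effect, expected_sig):
        effect, sig = diff.assign_pair_effect(e1, s1, e2, s2)
        assert effect == expected_effect
        assert sig is expected_sig

    def test_missing_model_falls_back(self):
        effect, sig = diff.assign_pair_effect(np.nan, False, 0.4, True)
        assert (effect, sig) == (0.4, True)
        effect, sig = diff.assign_pair_effect(np.nan, False, np.nan, False)
        assert np.isnan(effect) and sig is False


class TestEffectScans:
    def test_plugin_additivity(self, small_study):
        """native = cis_hESC + trans_mouse_seq exactly, per pair."""
        w = small_study.results[~small_study.results["is_null"]].pivot(
            index="unit_id", columns="axis", values="effect"
        )
        assert np.allclose(
            w["native"], w["cis_hESC"] + w["trans_mouse_seq"], atol=1e-9
        )

    def test_pure_cis_pair_recovery(self, small_study):
        """Pairs with only a cis truth show it on both cis axes and ~0 trans."""
        truth = small_study.truth.pairs.set_index("pair_id")
        pure = truth[truth["has_cis"] & ~truth["has_trans"]]
        w = small_study.results[~small_study.results["is_null"]].pivot(
            index="unit_id", columns="axis", values="effect"
        ).loc[pure.index]
        resid_h = w["cis_hESC"] - pure["cis_true"]
        resid_m = w["cis_mESC"] - pure["cis_true"]
        assert resid_h.abs().median() < 0.25
        assert resid_m.abs().median() < 0.25
        assert w["trans_human_seq"].abs().median() < 0.25

    def test_recovery_correlations(self, small_study):
        truth = small_study.truth.pairs.set_index("pair_id")
        real = small_study.assigned[~small_study.assigned["is_null"]]
        j = real.join(truth)
        assert np.corrcoef(j["cis_effect"], j["cis_true"])[0, 1] >= 0.9
        assert np.corrcoef(j["trans_effect"], j["trans_true"])[0, 1] >= 0.9

    def test_cross_environment_cis_correlation(self, small_study):
        """Environment-independent cis truth shows up in both environments."""
        w = small_study.results[~small_study.results["is_null"]].pivot(
            index="unit_id", columns="axis", values="effect"
        )
        assert np.corrcoef(w["cis_hESC"], w["cis_mESC"])[0, 1] >= 0.9

    def test_sign_symmetry_under_label_swaps(self, small_study):
        """Swapping species negates cis; swapping environments negates trans;
        the native (diagonal) contrast negates under the joint swap."""
        base = small_study.results[~small_study.results["is_null"]]

        def effects(res, axis):
            return res[(res["axis"] == axis) & ~res["is_null"]].set_index("unit_id")[
                "effect"
            ]

        catalog = small_study.catalog.copy()
        swap_sp = {"human": "mouse", "mouse": "human", "": ""}
        catalog["species"] = catalog["species"].map(swap_sp)
        res_sp = diff.run_effect_scans(
            small_study.observations, catalog, small_study.null_pairs[:5]
        )
        for axis in ("cis_hESC", "cis_mESC"):
            a = effects(base, axis)
            assert np.allclose(a, -effects(res_sp, axis).loc[a.index], atol=1e-9)

        obs = small_study.observations.copy()
        obs["environment"] = obs["environment"].map({"hESC": "mESC", "mESC": "hESC"})
        res_env = diff.run_effect_scans(
            obs, small_study.catalog, small_study.null_pairs[:5]
        )
        for axis in ("trans_human_seq", "trans_mouse_seq"):
            a = effects(base, axis)
            assert np.allclose(a, -effects(res_env, axis).loc[a.index], atol=1e-9)

        res_both = diff.run_effect_scans(obs, catalog, small_study.null_pairs[:5])
        a = effects(base, "native")
        assert np.allclose(a, -effects(res_both, "native").loc[a.index], atol=1e-9)


def test_pure_null_false_call_rate_bounded():
    """With no planted effects, few real pairs are called significant."""
    rates = []
    for seed in range(6):
        cfg = SimulationConfig(
            n_pairs=60, n_negative_controls=40, frac_cis=0.0, frac_trans=0.0,
            n_motifs=0, seed=100 + seed,
        )
        study = build_study(cfg)
        real = study.assigned[~study.assigned["is_null"]]
        rates.append(float(real["cis_sig"].mean()))
    assert np.mean(rates) <= 0.15
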