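"""Composition, PWM scanning with exact null, and the three model families."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cistrans import motifs as mot
from cistrans import simulate as sim
from cistrans.config import SimulationConfig


class TestComposition:
    @pytest.mark.parametrize(
        "seq,gc,cpg",
        [
            ("ACGT", 0.5, 1 / 3),
            ("CGCG", 1.0, 2 / 3),
            ("AAAA", 0.0, 0.0),
            ("acgt", 0.5, 1 / 3),
            ("ACNGT", 0.5, 1 / 3),  # N dropped from both counts
        ],
    )
    def test_examples(self, seq, gc, cpg):
        c = mot.sequence_composition(seq)
        assert c.gc_content == pytest.approx(gc)
        assert c.cpg_rate == pytest.approx(cpg)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mot.sequence_composition("")


def _consensus_pwm(word, p=0.97):
    pwm = np.full((len(word), 4), (1 - p) / 3)
    for i, b in enumerate(word):
        pwm[i, "ACGT".index(b)] = p
    return pwm


_RC = str.maketrans("ACGT", "TGCA")


class TestScanner:
    def test_consensus_hit_at_offset(self):
        word = "ACGTACGT"
        seq = "T" * 20 + word + "T" * 20
        hits = mot.scan_motifs(seq, _consensus_pwm(word))
        assert any(h.offset == 20 and h.strand == "+" for h in hits)

    def test_reverse_complement_hits_minus_strand(self):
        word = "AACGTACC"
        rc = word.translate(_RC)[::-1]
        seq = "T" * 10 + rc + "T" * 10
        hits = mot.scan_motifs(seq, _consensus_pwm(word))
        assert any(h.strand == "-" and h.offset == 10 for h in hits)

    def test_malformed_pwm_rejected(self):
        with pytest.raises(ValueError):
            mot.scan_motifs("ACGT" * 10, np.full((4, 4), 0.3))

    def test_exact_null_matches_brute_force_enumeration(self):
        """Lattice survival function equals enumeration over all 4^w words."""
        rng = np.random.default_rng(3)
        for _ in range(3):
            w = 5
            pwm = rng.dirichlet([1.0, 1.0, 1.0, 1.0], size=w)
            int_scores = mot._lattice_scores(pwm)
            sf, lo = mot._score_survival(int_scores)
            totals = [
                int(sum(int_scores[i, b] for i, b in enumerate(word)))
                for word in itertools.product(range(4), repeat=w)
            ]
            totals = np.array(totals)
            for s in np.unique(totals)[::5]:
                exact = (totals >= s).mean()
                assert sf[s - lo] == pytest.approx(exact, abs=1e-12)

    def test_background_hit_rate_matches_threshold(self):
        """On random sequence, per-position hit rate ~ p_threshold x 2 strands."""
        rng = np.random.default_rng(4)
        pwm = rng.dirichlet([0.4, 0.4, 0.4, 0.4], size=8)
        threshold = 1e-3
        # the discrete null cannot hit the threshold exactly; the achievable
        # rate is the survival value at the score cutoff
        int_scores = mot._lattice_scores(pwm)
        sf, lo = mot._score_survival(int_scores)
        cutoff = mot._min_hit_score(pwm, threshold)
        per_strand = sf[cutoff - lo]
        n_seq, L = 800, 144
        n_windows = n_seq * (L - 8 + 1)
        n_hits = 0
        for _ in range(n_seq):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
            n_hits += len(mot.scan_motifs(seq, pwm, threshold))
        rate = n_hits / n_windows
        assert rate == pytest.approx(2 * per_strand, rel=0.25)

    def test_fimo_roundtrip_agrees_with_scanner(self):
        """Hits written in FIMO format and re-ingested match the scanner."""
        rng = np.random.default_rng(5)
        word = "ACCGGTAT"
        seqs = {}
        for i in range(20):
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 144)])
            if i % 2 == 0:
                s = s[:50] + word + s[58:]
            seqs[f"s{i}"] = s
        rows = []
        for name, s in seqs.items():
            for h in mot.scan_motifs(s, _consensus_pwm(word), motif_id="m1"):
                rows.append(
                    {
                        "motif_id": h.motif_id,
                        "motif_alt_id": "",
                        "sequence_name": name,
                        "start": h.offset + 1,
                        "stop": h.offset + 8,
                        "strand": h.strand,
                        "score": h.score,
                        "p-value": h.p_value,
                    }
                )
        table = mot.read_fimo(pd.DataFrame(rows))
        presence_fimo = mot.hits_to_presence(table, list(seqs), ["m1"])
        presence_scan = mot.build_presence_matrix(
            pd.DataFrame({"element_id": list(seqs), "sequence": list(seqs.values())}),
            {"m1": _consensus_pwm(word)},
        )
        pd.testing.assert_frame_equal(presence_fimo, presence_scan)

    def test_unplanted_sequences_scan_near_background(self):
        """Generator sequences without planted motifs give ~background rate."""
        cfg = SimulationConfig(n_pairs=50, n_motifs=0, seed=6)
        _, truth = sim.simulate_truth(cfg)
        seqs = sim.simulate_sequences(truth, cfg)
        pwm = _consensus_pwm("ACGTACGA", p=0.97)
        n_hits = sum(
            len(mot.scan_motifs(s, pwm, 1e-4)) for s in seqs["sequence"]
        )
        n_windows = len(seqs) * (144 - 8 + 1) * 2
        assert n_hits / n_windows < 5e-4


class TestActivityModel:
    def _data(self, n=300, beta=1.0, seed=0):
        rng = np.random.default_rng(seed)
        presence = pd.Series(rng.random(n) < 0.4)
        gc = rng.uniform(0.3, 0.7, n)
        comps = pd.DataFrame({"gc_content": gc, "cpg_rate": gc / 5 + rng.normal(0, 0.01, n)})
        y = pd.Series(1.0 + 2 * gc + beta * presence + rng.normal(0, 0.3, n))
        return presence, y, comps

    def test_planted_activator_recovered(self):
        presence, y, comps = self._data(beta=1.0)
        res = mot.motif_activity_model(presence, y, comps)
        assert res["beta"] == pytest.approx(1.0, abs=0.15)
        assert res["class"] == "activator"
        assert res["p"] < 1e-6

    def test_planted_repressor_recovered(self):
        presence, y, comps = self._data(beta=-0.8, seed=1)
        res = mot.motif_activity_model(presence, y, comps)
        assert res["class"] == "repressor"
        assert res["p"] < 1e-6

    def test_type_one_error_rate_on_permuted_labels(self):
        """Permuted motif labels give ~5% of p below 0.05 and tiny LRT stats."""
        presence, y, comps = self._data(beta=0.0, seed=2)
        rng = np.random.default_rng(3)
        pvals, stats_ = [], []
        for _ in range(1000):
            perm = pd.Series(rng.permutation(presence.to_numpy()))
            res = mot.motif_activity_model(perm, y, comps)
            pvals.append(res["p"])
            stats_.append(res["lr_stat"])
        frac = np.mean(np.array(pvals) < 0.05)
        assert 0.03 <= frac <= 0.07
        assert np.median(stats_) < 1.0

    def test_collinear_motif_attenuated(self):
        """A motif identical to a composition covariate explains nothing extra."""
        n = 200
        rng = np.random.default_rng(4)
        gc = np.repeat([0.3, 0.7], n // 2)
        presence = pd.Series(gc == 0.7)
        comps = pd.DataFrame({"gc_content": gc, "cpg_rate": rng.normal(0.1, 0.01, n)})
        y = pd.Series(2 * gc + rng.normal(0, 0.1, n))
        res = mot.motif_activity_model(presence, y, comps)
        assert res["p"] > 0.05
        assert abs(res["variance_explained"]) < 0.01

    def test_unbalanced_motif_skipped(self):
        presence, y, comps = self._data()
        presence[:] = True
        presence.iloc[:5] = False
        assert mot.motif_activity_model(presence, y, comps) is None


class TestCisModel:
    def _pair_comps(self, n, rng):
        return pd.DataFrame(
            {
                "mean_gc": rng.uniform(0.3, 0.7, n),
                "mean_cpg": rng.uniform(0.0, 0.2, n),
                "abs_dgc": rng.uniform(0, 0.1, n),
                "abs_dcpg": rng.uniform(0, 0.05, n),
            }
        )

    def test_planted_disruption_effect_recovered(self):
        rng = np.random.default_rng(5)
        n = 200
        disrupted = pd.Series(rng.random(n) < 0.3)
        comps = self._pair_comps(n, rng)
        y = pd.Series(0.3 + 0.8 * disrupted + rng.normal(0, 0.2, n))
        res = mot.motif_cis_model(disrupted, y, comps)
        assert res["beta"] == pytest.approx(0.8, abs=0.15)
        assert res["p"] < 1e-6

    def test_all_zero_disruption_skipped(self):
        rng = np.random.default_rng(6)
        n = 50
        res = mot.motif_cis_model(
            pd.Series(np.zeros(n, bool)), pd.Series(rng.random(n)),
            self._pair_comps(n, rng),
        )
        assert res is None

    def test_activator_disruption_shifts_cis_toward_retaining_species(self):
        """With an activator planted, disrupted-in-human pairs have
        mouse-higher (positive) cis effects relative to maintained pairs."""
        cfg = SimulationConfig(n_pairs=400, frac_cis=1.0, n_motifs=12, seed=8)
        _, truth = sim.simulate_truth(cfg)
        activators = truth.motifs[
            (truth.motifs["family"] == "activity") & (truth.motifs["beta"] > 0.3)
        ]
        assert not activators.empty
        motif_id = activators.sort_values("beta").iloc[-1]["motif_id"]
        pl = truth.placements[truth.placements["motif_id"] == motif_id]
        pairs = truth.pairs.set_index("pair_id")
        dis_h = pl[~pl["in_human"] & pl["in_mouse"]]["pair_id"]
        maintained = pl[pl["in_human"] & pl["in_mouse"]]["pair_id"]
        assert (
            pairs.loc[dis_h, "cis_true"].mean()
            > pairs.loc[maintained, "cis_true"].mean()
        )


class TestTransModel:
    def test_planted_trans_shift_recovered(self):
        rng = np.random.default_rng(8)
        n = 300
        presence = pd.Series(rng.random(n) < 0.4)
        gc = rng.uniform(0.3, 0.7, n)
        comps = pd.DataFrame({"gc_content": gc, "cpg_rate": gc / 5})
        y = pd.Series(0.5 * presence + rng.normal(0, 0.2, n))
        res = mot.motif_trans_model(presence, y, comps)
        assert res["beta"] == pytest.approx(0.5, abs=0.1)
        assert res["p"] < 1e-6

    def test_null_significance_rate(self):
        rng = np.random.default_rng(9)
        n = 200
        gc = rng.uniform(0.3, 0.7, n)
        comps = pd.DataFrame({"gc_content": gc, "cpg_rate": gc / 5})
        y = pd.Series(rng.normal(0, 0.3, n))
        pvals = [
            mot.motif_trans_model(pd.Series(rng.random(n) < 0.4), y, comps)["p"]
            for _ in range(400)
        ]
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_identical_presence_gives_identical_results(self):
        rng = np.random.default_rng(10)
        n = 100
        presence = pd.Series(rng.random(n) < 0.5)
        comps = pd.DataFrame(
            {"gc_content": rng.uniform(0.3, 0.7, n), "cpg_rate": rng.uniform(0, 0.2, n)}
        )
        y = pd.Series(rng.normal(0, 1, n))
        r1 = mot.motif_trans_model(presence, y, comps)
        r2 = mot.motif_trans_model(presence.copy(), y, comps)
        assert r1 == r2


class TestSharedMotifs:
    def test_jaccard_examples(self):
        assert mot.shared_motif_fraction({"A", "B", "C"}, {"B", "C", "D"}) == 0.5
        assert mot.shared_motif_fraction({"A"}, {"A"}) == 1.0
        assert np.isnan(mot.shared_motif_fraction(set(), set()))

    def test_disruption_driven_cis_lowers_sharing(self):
        """When cis truth comes from disruption, no-cis pairs share more."""
        cfg = SimulationConfig(n_pairs=200, frac_cis=0.5, seed=11)
        catalog, truth = sim.simulate_truth(cfg)
        # presence straight from planted placements (scanner tested separately)
        elements = catalog.loc[catalog["class"] == "TSS", "element_id"]
        presence = pd.DataFrame(
            False, index=pd.Index(elements, name="element_id"),
            columns=truth.motifs["motif_id"],
        )
        for r in truth.placements.itertuples():
            if r.in_human:
                presence.at[f"{r.pair_id}_human", r.motif_id] = True
            if r.in_mouse:
                presence.at[f"{r.pair_id}_mouse", r.motif_id] = True
        cis_sig = truth.pairs.set_index("pair_id")["has_cis"]
        out = mot.shared_fraction_comparison(presence, catalog, cis_sig)
        assert out["p"] < 0.05
        assert out["median_shared_no_cis"] >= out["median_shared_cis"]


class TestBiotypeEnrichment:
    def test_matches_brute_force_tail_sum(self):
        """Hypergeometric p equals the exact tail sum for universes <= 30."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            M = int(rng.integers(10, 31))
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            elements = [f"e{i}" for i in range(M)]
            in_motif = rng.permutation([True] * K + [False] * (M - K))
            in_bio = rng.permutation([True] * n + [False] * (M - n))
            presence = pd.DataFrame({"m": in_motif}, index=elements)
            biotypes = pd.Series(
                np.where(in_bio, "mRNA", "other"), index=elements
            )
            res = mot.biotype_enrichment(presence, biotypes)
            k = int((in_motif & in_bio).sum())
            brute = sum(
                math.comb(K, j) * math.comb(M - K, n - j) / math.comb(M, n)
                for j in range(k, min(K, n) + 1)
            )
            got = res.loc[res["biotype"] == "mRNA", "p"].iloc[0]
            assert got == pytest.approx(brute, abs=1e-12)

    def test_ubiquitous_motif_never_enriched(self):
        presence = pd.DataFrame({"m": [True] * 30}, index=[f"e{i}" for i in range(30)])
        biotypes = pd.Series(["mRNA"] * 15 + ["eRNA"] * 15, index=presence.index)
        res = mot.biotype_enrichment(presence, biotypes)
        assert (res["p"] == 1.0).all()

    def test_absent_motif_skipped(self):
        presence = pd.DataFrame({"m": [False] * 10}, index=[f"e{i}" for i in range(10)])
        biotypes = pd.Series(["mRNA"] * 10, index=presence.index)
        assert mot.biotype_enrichment(presence, biotypes).empty


class TestDirectionAgreement:
    def _setup(self, beta, lfc, q):
        trans_results = pd.DataFrame(
            {"motif_id": ["m1"], "beta": [beta], "significant": [True]}
        )
        tf_de = pd.DataFrame(
            {"gene": ["TF1"], "log2fc_mESC_vs_hESC": [lfc], "qvalue": [q]}
        )
        motif_tf = pd.DataFrame({"motif_id": ["m1"], "tf": ["TF1"]})
        return mot.direction_agreement(trans_results, tf_de, motif_tf)

    def test_matching_signs_agree(self):
        out = self._setup(0.4, 2.0, 1e-5)
        assert out["n_agree"] == 1 and out["fraction_agree"] == 1.0

    def test_opposite_signs_disagree(self):
        out = self._setup(0.4, -2.0, 1e-5)
        assert out["n_de"] == 1 and out["n_agree"] == 0

    def test_subthreshold_fold_change_excluded(self):
        out = self._setup(0.4, 0.5, 1e-5)
        assert out["n_de"] == 0 and np.isnan(out["fraction_agree"])

    def test_missing_tf_counted_separately(self):
        trans_results = pd.DataFrame(
            {"motif_id": ["m1"], "beta": [0.4], "significant": [True]}
        )
        tf_de = pd.DataFrame({"gene": [], "log2fc_mESC_vs_hESC": [], "qvalue": []})
        motif_tf = pd.DataFrame({"motif_id": ["m1"], "tf": ["TF1"]})
        out = mot.direction_agreement(trans_results, tf_de, motif_tf)
        assert out["n_missing_from_de"] == 1


def test_informative_motif_filter():
    activity_results = pd.DataFrame(
        {"motif_id": ["m1", "m2", "m3"], "q": [0.01, 0.01, 0.5]}
    )
    tf_expression = pd.DataFrame(
        {
            "gene": ["TF1", "TF2", "TF3"],
            "expr_hESC": [5.0, 0.0, 5.0],
            "expr_mESC": [5.0, 5.0, 5.0],
        }
    )
    motif_tf = pd.DataFrame(
        {"motif_id": ["m1", "m2", "m3"], "tf": ["TF1", "TF2", "TF3"]}
    )
    # m2's TF is silent in hESC, m3 is not activity-associated
    assert mot.informative_motifs(activity_results, tf_expression, motif_tf) == ["m1"]
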