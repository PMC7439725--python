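"""Motif scanning and motif-association linear models.

Three nested-model families link TF motifs to the assay's readouts, each
tested with a likelihood-ratio test of the motif term against a reduced model
with sequence-composition covariates only:

* activity family:  mean(activity) ~ GC + CpG + motif_present
* cis family:       |cis effect|   ~ mean(GC) + mean(CpG) + |dGC| + |dCpG| + motif_disrupted
* trans family:     trans effect   ~ GC + CpG + motif_present

A motif is an "activator" when its activity-model coefficient is positive,
a "repressor" when negative.  In the trans family a positive coefficient
associates the motif with higher activity in the mESC environment.

The internal scanner scores position-weight matrices against a uniform 0.25
background on both strands and calls a hit when the score's p-value under the
exact lattice null distribution is at or below the threshold (default 1e-4);
FIMO-style hit tables are accepted as the preferred ingestion path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

SCAN_P_THRESHOLD = 1e-4
_SCALE = 1000  # lattice discretisation for the scanner's exact null
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SequenceComposition:
    gc_content: float
    cpg_rate: float


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    offset: int  # 0-based offset on the forward strand
    strand: str
    score: float
    p_value: float


def sequence_composition(sequence: str) -> SequenceComposition:
    """GC fraction and CpG dinucleotide rate of a sequence.

    Case-insensitive; non-ACGT symbols are excluded from numerator and
    denominator (the sequence is compacted before dinucleotide counting).
    """
    if not sequence:
        raise ValueError("empty sequence")
    clean = [b for b in sequence.upper() if b in "ACGT"]
    if not clean:
        raise ValueError("sequence contains no ACGT symbols")
    gc = sum(b in "GC" for b in clean) / len(clean)
    if len(clean) < 2:
        cpg = 0.0
    else:
        s = "".join(clean)
        cpg = sum(s[i : i + 2] == "CG" for i in range(len(s) - 1)) / (len(s) - 1)
    return SequenceComposition(gc_content=gc, cpg_rate=cpg)


def _validate_pwm(pwm: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4 or len(pwm) == 0:
        raise ValueError("PWM must be a (width, 4) matrix")
    if np.any(pwm < 0) or not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("PWM columns must be probabilities summing to 1")
    return pwm


def _lattice_scores(pwm: np.ndarray, background: float = 0.25) -> np.ndarray:
    """Integer log-odds scores on the discretisation lattice, shape (w, 4)."""
    with np.errstate(divide="ignore"):
        logodds = np.log2(np.maximum(pwm, 1e-10) / background)
    return np.round(logodds * _SCALE).astype(np.int64)


def _score_survival(int_scores: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null survival function of the window score.

    Under the uniform background each position contributes one of its 4
    lattice scores with probability 1/4; the total-score pmf is the
    convolution over positions (dynamic programming on the lattice).
    Returns (sf, offset) with ``P(S >= s) = sf[s - offset]``.
    """
    cur_lo = 0
    cur = np.array([1.0])
    for col in int_scores:
        c_lo = int(col.min())
        width = int(col.max()) - c_lo
        new = np.zeros(len(cur) + width)
        for s in col:
            new[int(s) - c_lo : int(s) - c_lo + len(cur)] += 0.25 * cur
        cur = new
        cur_lo += c_lo
    sf = np.cumsum(cur[::-1])[::-1]
    return sf, cur_lo


def scan_motifs(
    sequence: str,
    pwm: np.ndarray,
    p_threshold: float = SCAN_P_THRESHOLD,
    motif_id: str = "motif",
) -> list[MotifHit]:
    """Scan both strands of a sequence for hits of one PWM.

    A window is a hit iff the exact-null p-value of its log-odds score is
    <= ``p_threshold``.
    """
    pwm = _validate_pwm(pwm)
    w = len(pwm)
    seq = sequence.upper()
    if w > len(seq):
        return []
    int_scores = _lattice_scores(pwm)
    sf, lo = _score_survival(int_scores)

    def pval(total: int) -> float:
        idx = total - lo
        if idx < 0:
            return 1.0
        if idx >= len(sf):
            return 0.0
        return float(sf[idx])

    hits = []
    for strand in ("+", "-"):
        if strand == "+":
            s = seq
        else:
            s = "".join(_COMP.get(b, "N") for b in reversed(seq))
        codes = np.array([("ACGT".index(b) if b in "ACGT" else -1) for b in s])
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        valid = (windows >= 0).all(axis=1)
        totals = int_scores[np.arange(w), np.where(windows < 0, 0, windows)].sum(axis=1)
        for off in np.nonzero(valid)[0]:
            total = int(totals[off])
            p = pval(total)
            if p <= p_threshold:
                fwd_off = int(off) if strand == "+" else len(seq) - w - int(off)
                hits.append(
                    MotifHit(motif_id, fwd_off, strand, total / _SCALE, p)
                )
    return hits


def read_fimo(path_or_df: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Ingest a FIMO-style TSV hit table.

    Expects at least the columns motif_id, sequence_name, start, stop,
    strand, score, p-value (FIMO's 1-based coordinates are kept as-is).
    Comment lines starting with '#' are skipped.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", comment="#")
    required = {"motif_id", "sequence_name", "start", "stop", "strand", "score", "p-value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FIMO table missing columns: {sorted(missing)}")
    return df


def hits_to_presence(
    hits: pd.DataFrame, elements: list[str], motif_ids: list[str] | None = None
) -> pd.DataFrame:
    """Collapse a hit table to a boolean element x motif presence matrix."""
    if motif_ids is None:
        motif_ids = sorted(hits["motif_id"].unique())
    presence = pd.DataFrame(False, index=pd.Index(elements, name="element_id"), columns=motif_ids)
    for _, h in hits.iterrows():
        if h["sequence_name"] in presence.index and h["motif_id"] in presence.columns:
            presence.at[h["sequence_name"], h["motif_id"]] = True
    return presence


def _min_hit_score(pwm: np.ndarray, p_threshold: float) -> int:
    """Smallest lattice window score whose exact-null p-value is <= threshold."""
    int_scores = _lattice_scores(_validate_pwm(pwm))
    sf, lo = _score_survival(int_scores)
    ok = np.nonzero(sf <= p_threshold)[0]
    if len(ok) == 0:
        return int(int_scores.max(axis=1).sum()) + 1  # unreachable: no hit possible
    return int(ok[0]) + lo


def build_presence_matrix(
    sequences: pd.DataFrame,
    pwms: dict[str, np.ndarray],
    p_threshold: float = SCAN_P_THRESHOLD,
) -> pd.DataFrame:
    """Scan every sequence with every PWM; presence = >= 1 hit on either strand.

    Uses the same exact-null score cutoff as :func:`scan_motifs`, computed
    once per motif.
    """
    elements = sequences["element_id"].tolist()
    presence = pd.DataFrame(
        False, index=pd.Index(elements, name="element_id"), columns=sorted(pwms)
    )
    coded = {
        eid: np.array([("ACGT".index(b) if b in "ACGT" else -1) for b in seq.upper()])
        for eid, seq in zip(sequences["element_id"], sequences["sequence"])
    }
    for motif_id in sorted(pwms):
        int_scores = _lattice_scores(_validate_pwm(pwms[motif_id]))
        w = len(int_scores)
        cutoff = _min_hit_score(pwms[motif_id], p_threshold)
        # minus-strand scoring: forward matrix read back-to-front with
        # complemented columns (A<->T, C<->G)
        rc_scores = int_scores[::-1][:, [3, 2, 1, 0]]
        for eid, codes in coded.items():
            if len(codes) < w:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, w)
            valid = (windows >= 0).all(axis=1)
            safe = np.where(windows < 0, 0, windows)
            fwd = int_scores[np.arange(w), safe].sum(axis=1)
            rev = rc_scores[np.arange(w), safe].sum(axis=1)
            best = np.maximum(fwd, rev)[valid]
            if len(best) and best.max() >= cutoff:
                presence.at[eid, motif_id] = True
    return presence


def pair_motif_indicators(
    presence: pd.DataFrame, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Per-pair maintained / disrupted-in-human / disrupted-in-mouse indicators.

    "Disrupted in human" means the motif is present in the mouse member but
    not the human member; the three indicators are mutually exclusive.
    """
    tss = catalog[catalog["class"] == "TSS"]
    rows = []
    for pid, grp in tss.groupby("pair_id"):
        by_sp = dict(zip(grp["species"], grp["element_id"]))
        if "human" not in by_sp or "mouse" not in by_sp:
            continue
        in_h = presence.loc[by_sp["human"]]
        in_m = presence.loc[by_sp["mouse"]]
        for motif_id in presence.columns:
            h, m = bool(in_h[motif_id]), bool(in_m[motif_id])
            rows.append(
                dict(
                    pair_id=pid,
                    motif_id=motif_id,
                    maintained=h and m,
                    disrupted_in_human=(m and not h),
                    disrupted_in_mouse=(h and not m),
                )
            )
    return pd.DataFrame(rows)


def _lrt_ols(y: np.ndarray, X_red: np.ndarray, x_motif: np.ndarray) -> dict:
    X_full = np.column_stack([X_red, x_motif])
    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    lr = 2.0 * (fit_full.llf - fit_red.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), 1))
    return {
        "beta": float(fit_full.params[-1]),
        "p": p,
        "lr_stat": float(lr),
        "variance_explained": float(fit_full.rsquared - fit_red.rsquared),
    }


def motif_activity_model(
    presence: pd.Series,
    mean_activity: pd.Series,
    compositions: pd.DataFrame,
    min_per_group: int = 20,
) -> dict | None:
    """activity ~ GC + CpG + motif_present, LRT on the motif term.

    Returns None (skipped) when fewer than ``min_per_group`` elements carry
    or lack the motif.
    """
    df = pd.DataFrame(
        {
            "y": mean_activity,
            "gc": compositions["gc_content"],
            "cpg": compositions["cpg_rate"],
            "motif": presence.astype(float),
        }
    ).dropna()
    n_with = int(df["motif"].sum())
    if n_with < min_per_group or len(df) - n_with < min_per_group:
        return None
    X_red = sm.add_constant(df[["gc", "cpg"]].to_numpy())
    res = _lrt_ols(df["y"].to_numpy(), X_red, df["motif"].to_numpy())
    res["class"] = "activator" if res["beta"] > 0 else "repressor"
    res["n_with"] = n_with
    res["n_without"] = len(df) - n_with
    return res


def motif_cis_model(
    disruption: pd.Series,
    abs_cis_effect: pd.Series,
    pair_compositions: pd.DataFrame,
) -> dict | None:
    """|cis| ~ mean(GC) + mean(CpG) + |dGC| + |dCpG| + motif_disrupted.

    ``pair_compositions`` needs columns mean_gc, mean_cpg, abs_dgc, abs_dcpg
    indexed by pair.  Skipped (None) when no pair is disrupted for the motif.
    """
    df = pd.DataFrame(
        {
            "y": abs_cis_effect,
            "mean_gc": pair_compositions["mean_gc"],
            "mean_cpg": pair_compositions["mean_cpg"],
            "abs_dgc": pair_compositions["abs_dgc"],
            "abs_dcpg": pair_compositions["abs_dcpg"],
            "disrupted": disruption.astype(float),
        }
    ).dropna()
    if df["disrupted"].sum() == 0 or df["disrupted"].nunique() < 2:
        return None
    X_red = sm.add_constant(df[["mean_gc", "mean_cpg", "abs_dgc", "abs_dcpg"]].to_numpy())
    return _lrt_ols(df["y"].to_numpy(), X_red, df["disrupted"].to_numpy())


def motif_trans_model(
    presence: pd.Series,
    trans_effect: pd.Series,
    compositions: pd.DataFrame,
) -> dict | None:
    """trans effect ~ GC + CpG + motif_present (signed response).

    beta > 0 associates the motif with higher activity in mESCs.  Skipped
    when presence is constant.
    """
    df = pd.DataFrame(
        {
            "y": trans_effect,
            "gc": compositions["gc_content"],
            "cpg": compositions["cpg_rate"],
            "motif": presence.astype(float),
        }
    ).dropna()
    if df["motif"].nunique() < 2:
        return None
    X_red = sm.add_constant(df[["gc", "cpg"]].to_numpy())
    return _lrt_ols(df["y"].to_numpy(), X_red, df["motif"].to_numpy())


def fit_model_family(
    family: str,
    presence_or_indicator: pd.DataFrame,
    response: pd.Series,
    compositions: pd.DataFrame,
    fdr: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Fit one model family for every motif and BH-correct across motifs.

    ``family`` is "activity", "cis" or "trans"; ``presence_or_indicator`` is
    the element x motif presence matrix (activity/trans) or the pair x motif
    disruption matrix (cis), aligned to ``response`` by index.
    """
    fitters = {
        "activity": motif_activity_model,
        "cis": motif_cis_model,
        "trans": motif_trans_model,
    }
    if family not in fitters:
        raise ValueError(f"unknown model family {family!r}")
    rows = []
    for motif_id in presence_or_indicator.columns:
        res = fitters[family](
            presence_or_indicator[motif_id], response, compositions, **kwargs
        )
        if res is None:
            continue
        rows.append({"motif_id": motif_id, "family": family, **res})
    results = pd.DataFrame(rows)
    if not results.empty:
        results["q"] = multipletests(results["p"], method="fdr_bh")[1]
        results["significant"] = results["q"] < fdr
    return results


def informative_motifs(
    activity_results: pd.DataFrame,
    tf_expression: pd.DataFrame,
    motif_tf: pd.DataFrame,
    q_threshold: float = 0.05,
    min_expression: float = 1.0,
) -> list[str]:
    """Motifs significantly tied to activity whose TF is expressed in both environments.

    ``tf_expression`` needs columns gene, expr_hESC, expr_mESC; ``motif_tf``
    maps motif_id to tf.
    """
    expr = tf_expression.set_index("gene")
    expressed = set(
        expr.index[
            (expr["expr_hESC"] >= min_expression) & (expr["expr_mESC"] >= min_expression)
        ]
    )
    tf_of = dict(zip(motif_tf["motif_id"], motif_tf["tf"]))
    sig = activity_results[activity_results["q"] < q_threshold]
    return [m for m in sig["motif_id"] if tf_of.get(m) in expressed]


def shared_motif_fraction(set_a: set[str], set_b: set[str]) -> float:
    """Jaccard fraction of shared motifs between the two members of a pair."""
    union = set_a | set_b
    if not union:
        return np.nan
    return len(set_a & set_b) / len(union)


def shared_fraction_comparison(
    presence: pd.DataFrame, catalog: pd.DataFrame, cis_sig: pd.Series
) -> dict:
    """Do pairs without cis effects share more motifs than pairs with them?

    One-sided Mann-Whitney test (alternative: no-cis pairs share more).
    Pairs whose members both lack motifs are excluded (undefined fraction).
    """
    tss = catalog[catalog["class"] == "TSS"]
    fracs, sigs = [], []
    for pid, grp in tss.groupby("pair_id"):
        by_sp = dict(zip(grp["species"], grp["element_id"]))
        if "human" not in by_sp or "mouse" not in by_sp or pid not in cis_sig.index:
            continue
        sa = set(presence.columns[presence.loc[by_sp["human"]]])
        sb = set(presence.columns[presence.loc[by_sp["mouse"]]])
        f = shared_motif_fraction(sa, sb)
        if np.isnan(f):
            continue
        fracs.append(f)
        sigs.append(bool(cis_sig.loc[pid]))
    fracs = np.array(fracs)
    sigs = np.array(sigs)
    with_cis = fracs[sigs]
    without_cis = fracs[~sigs]
    if len(with_cis) == 0 or len(without_cis) == 0:
        raise ValueError("need pairs both with and without cis effects")
    stat, p = stats.mannwhitneyu(without_cis, with_cis, alternative="greater")
    return {
        "median_shared_no_cis": float(np.median(without_cis)),
        "median_shared_cis": float(np.median(with_cis)),
        "p": float(p),
        "n_cis": int(len(with_cis)),
        "n_no_cis": int(len(without_cis)),
    }


def biotype_enrichment(
    presence: pd.DataFrame, biotypes: pd.Series, fdr: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each motif in each biotype.

    The universe is all tested elements; for a motif present in ``K`` of
    ``M`` elements and a biotype with ``n`` elements, the p-value is the
    upper tail of overlap >= observed.  BH-corrected across motif x biotype.
    """
    biotypes = biotypes.loc[presence.index]
    M = len(presence)
    rows = []
    for motif_id in presence.columns:
        in_motif = presence[motif_id]
        K = int(in_motif.sum())
        if K == 0:
            continue
        for biotype, members in biotypes.groupby(biotypes):
            n = len(members)
            if n == 0:
                continue
            k = int(in_motif.loc[members.index].sum())
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
            rows.append(
                dict(motif_id=motif_id, biotype=biotype, overlap=k, motif_total=K,
                     biotype_total=n, universe=M, p=p)
            )
    results = pd.DataFrame(rows)
    if not results.empty:
        results["q"] = multipletests(results["p"], method="fdr_bh")[1]
        results["significant"] = results["q"] < fdr
    return results


def direction_agreement(
    trans_results: pd.DataFrame,
    tf_de: pd.DataFrame,
    motif_tf: pd.DataFrame,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.01,
) -> dict:
    """Do trans-associated TFs change expression in the matching direction?

    A TF is differentially expressed iff |log2fc_mESC_vs_hESC| >=
    ``lfc_threshold`` and qvalue < ``q_threshold``; it "agrees" when the sign
    of its trans-model coefficient matches the sign of its fold change.
    TFs absent from the DE table are excluded and counted separately.
    """
    tf_of = dict(zip(motif_tf["motif_id"], motif_tf["tf"]))
    de = tf_de.set_index("gene")
    sig = trans_results[trans_results["significant"]]

    per_tf: dict[str, list[float]] = {}
    for _, r in sig.iterrows():
        tf = tf_of.get(r["motif_id"])
        if tf is not None:
            per_tf.setdefault(tf, []).append(r["beta"])

    rows, n_missing = [], 0
    for tf, betas in per_tf.items():
        if tf not in de.index:
            n_missing += 1
            continue
        lfc = float(de.at[tf, "log2fc_mESC_vs_hESC"])
        qv = float(de.at[tf, "qvalue"])
        is_de = abs(lfc) >= lfc_threshold and qv < q_threshold
        beta = float(np.mean(betas))
        rows.append(
            dict(
                tf=tf,
                beta=beta,
                log2fc=lfc,
                qvalue=qv,
                differentially_expressed=is_de,
                agrees=bool(is_de and np.sign(beta) == np.sign(lfc)),
            )
        )
    table = pd.DataFrame(rows)
    de_tfs = table[table["differentially_expressed"]] if not table.empty else table
    n_de = len(de_tfs)
    n_agree = int(de_tfs["agrees"].sum()) if n_de else 0
    return {
        "table": table,
        "n_trans_tfs": len(per_tf),
        "n_missing_from_de": n_missing,
        "n_de": n_de,
        "n_agree": n_agree,
        "fraction_agree": (n_agree / n_de) if n_de else np.nan,
    }
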