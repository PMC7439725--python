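"""Cis, trans, and native differential tests with empirical-FDR calibration.

Five models are fit per library: cis effects in hESC and in mESC (mouse vs
human sequence, environment fixed), trans effects of the human and of the
mouse sequence (mESC vs hESC environment, sequence fixed), and native effects
(mouse sequence in mESC vs human sequence in hESC).  Effects are positive when
the mouse sequence or mESC environment has higher activity.

The null distribution is formed from pseudo-pairs of identical sequences:
each 60-barcode positive-control tile is down-sampled into two disjoint
13-barcode subsets that are pushed through the identical code path as real
pairs.  Significance is calibrated empirically: the q-value cutoff is the
largest threshold at which fewer than 10% of null controls are called
significant, and real effects must additionally exceed the minimum significant
null effect size (the "effect floor").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AXES = ("cis_hESC", "cis_mESC", "trans_human_seq", "trans_mouse_seq", "native")
#: environments sampled for the A (human-side) and B (mouse-side) group per axis
AXIS_ENVIRONMENTS = {
    "cis_hESC": ("hESC", "hESC"),
    "cis_mESC": ("mESC", "mESC"),
    "trans_human_seq": ("hESC", "mESC"),
    "trans_mouse_seq": ("hESC", "mESC"),
    "native": ("hESC", "mESC"),
}
AXIS_FAMILY = {
    "cis_hESC": "cis",
    "cis_mESC": "cis",
    "trans_human_seq": "trans",
    "trans_mouse_seq": "trans",
    "native": "native",
}
EMPIRICAL_FDR_TARGET = 0.10
NULL_SUBSET_SIZE = 13
MIN_NULLS_PER_FAMILY = 50


@dataclass(frozen=True)
class NullPair:
    """Two disjoint barcode subsets of one positive-control tile."""

    null_id: str
    source_element: str
    subset_a: tuple[str, ...]
    subset_b: tuple[str, ...]


@dataclass(frozen=True)
class CalibrationResult:
    family: str
    q_cutoff: float
    effect_floor: float
    achieved_null_rate: float


def build_null_pairs(
    barcode_map: pd.DataFrame,
    positive_elements: list[str],
    n_pairs_per_tile: int = 50,
    subset_size: int = NULL_SUBSET_SIZE,
    seed: int = 0,
) -> list[NullPair]:
    """Down-sample each positive-control tile into disjoint pseudo-pairs.

    Each draw takes two disjoint ``subset_size``-barcode subsets from one
    tile's barcode pool; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_element = barcode_map.groupby("element_id")["barcode_id"].apply(list)
    nulls = []
    for element in positive_elements:
        pool = sorted(by_element.get(element, []))
        if len(pool) < 2 * subset_size:
            raise ValueError(
                f"positive control {element} has {len(pool)} barcodes; "
                f"need >= {2 * subset_size} for disjoint subsets"
            )
        for k in range(n_pairs_per_tile):
            pick = rng.choice(len(pool), size=2 * subset_size, replace=False)
            nulls.append(
                NullPair(
                    null_id=f"null_{element}_{k:04d}",
                    source_element=element,
                    subset_a=tuple(pool[i] for i in pick[:subset_size]),
                    subset_b=tuple(pool[i] for i in pick[subset_size:]),
                )
            )
    return nulls


def pairwise_effect(
    observations_a: pd.DataFrame, observations_b: pd.DataFrame
) -> tuple[float, float]:
    """Signed effect (mean B - mean A) and F-test p-value.

    The test compares an OLS fit of barcode-level log ratios on a group
    indicator plus a categorical replicate covariate against the
    replicate-only model; the null is "no differential transcription".
    Degenerate inputs (a group with < 2 observations) give a NaN p-value.
    """
    ya = observations_a["log_ratio"].to_numpy(float)
    yb = observations_b["log_ratio"].to_numpy(float)
    if len(ya) < 2 or len(yb) < 2:
        return (float(yb.mean() - ya.mean()) if len(ya) and len(yb) else np.nan, np.nan)
    effect = float(yb.mean() - ya.mean())

    y = np.concatenate([ya, yb])
    group = np.concatenate([np.zeros(len(ya)), np.ones(len(yb))])
    reps = np.concatenate(
        [observations_a["replicate"].to_numpy(), observations_b["replicate"].to_numpy()]
    )
    rep_levels = np.unique(reps)
    # intercept + replicate dummies (drop first level)
    X_red = np.column_stack(
        [np.ones(len(y))] + [(reps == lv).astype(float) for lv in rep_levels[1:]]
    )
    X_full = np.column_stack([X_red, group])

    rss_red = _rss(X_red, y)
    rss_full = _rss(X_full, y)
    df_full = len(y) - np.linalg.matrix_rank(X_full)
    if df_full <= 0:
        return effect, np.nan
    if rss_full < 1e-30:
        p = 1.0 if rss_red - rss_full < 1e-30 else 0.0
        return effect, p
    f_stat = (rss_red - rss_full) / (rss_full / df_full)
    p = float(stats.f.sf(max(f_stat, 0.0), 1, df_full))
    return effect, p


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def run_effect_scans(
    observations: pd.DataFrame,
    catalog: pd.DataFrame,
    null_pairs: list[NullPair],
    active_pairs: set[str] | None = None,
) -> pd.DataFrame:
    """Test all five effect axes for real pairs and null pseudo-pairs.

    Parameters
    ----------
    observations
        Barcode-level log ratios (element_id, barcode_id, environment,
        replicate, log_ratio).
    catalog
        Element catalog; pairs are taken from rows with class "TSS".
    null_pairs
        Pseudo-pairs from :func:`build_null_pairs`; they go through the
        identical code path, with subset A playing the human/hESC side.
    active_pairs
        If given, restrict real pairs to this set (the active-pair filter).

    Returns a DataFrame (unit_id, axis, effect, p, q, is_null) with BH
    q-values computed jointly over real and null units per axis.
    """
    tss = catalog[catalog["class"] == "TSS"]
    element_of = {
        (r.pair_id, r.species): r.element_id for r in tss.itertuples()
    }
    pair_ids = sorted({r.pair_id for r in tss.itertuples()})
    if active_pairs is not None:
        pair_ids = [p for p in pair_ids if p in active_pairs]

    by_elem_env = dict(tuple(observations.groupby(["element_id", "environment"])))
    empty = observations.iloc[0:0]

    def elem_obs(element_id: str, env: str) -> pd.DataFrame:
        return by_elem_env.get((element_id, env), empty)

    # pre-slice each null pair's subsets per environment once
    null_obs: dict[tuple[str, str, str], pd.DataFrame] = {}
    for np_ in null_pairs:
        for env in set(e for pair in AXIS_ENVIRONMENTS.values() for e in pair):
            src = elem_obs(np_.source_element, env)
            sel_a = src[src["barcode_id"].isin(np_.subset_a)]
            sel_b = src[src["barcode_id"].isin(np_.subset_b)]
            null_obs[(np_.null_id, "a", env)] = sel_a
            null_obs[(np_.null_id, "b", env)] = sel_b

    rows = []
    for axis in AXES:
        env_a, env_b = AXIS_ENVIRONMENTS[axis]
        for pid in pair_ids:
            if axis in ("cis_hESC", "cis_mESC", "native"):
                eid_a = element_of.get((pid, "human"))
                eid_b = element_of.get((pid, "mouse"))
            elif axis == "trans_human_seq":
                eid_a = eid_b = element_of.get((pid, "human"))
            else:
                eid_a = eid_b = element_of.get((pid, "mouse"))
            if eid_a is None or eid_b is None:
                continue
            obs_a = elem_obs(eid_a, env_a)
            obs_b = elem_obs(eid_b, env_b)
            if obs_a.empty or obs_b.empty:
                rows.append(dict(unit_id=pid, axis=axis, effect=np.nan, p=np.nan, is_null=False))
                continue
            effect, p = pairwise_effect(obs_a, obs_b)
            rows.append(dict(unit_id=pid, axis=axis, effect=effect, p=p, is_null=False))
        for np_ in null_pairs:
            obs_a = null_obs[(np_.null_id, "a", env_a)]
            obs_b = null_obs[(np_.null_id, "b", env_b)]
            if obs_a.empty or obs_b.empty:
                rows.append(dict(unit_id=np_.null_id, axis=axis, effect=np.nan, p=np.nan, is_null=True))
                continue
            effect, p = pairwise_effect(obs_a, obs_b)
            rows.append(dict(unit_id=np_.null_id, axis=axis, effect=effect, p=p, is_null=True))

    results = pd.DataFrame(rows)
    results["q"] = np.nan
    for axis in AXES:
        mask = (results["axis"] == axis) & results["p"].notna()
        if mask.any():
            results.loc[mask, "q"] = multipletests(
                results.loc[mask, "p"], method="fdr_bh"
            )[1]
    return results


def calibrate_empirical_fdr(
    results: pd.DataFrame, target: float = EMPIRICAL_FDR_TARGET
) -> dict[str, CalibrationResult]:
    """Per-family q cutoff and effect floor from null differential controls.

    A null control unit is "called significant" the same way a real pair is:
    through either of the family's two models (so its unit-level q is the
    minimum q over the family's axes).  The cutoff is the largest threshold
    ``c`` with ``#{null units: q < c} / #units < target``; the effect floor
    is the minimum absolute effect among null model results with q < c (0
    when no null is below the cutoff).  Families absent from ``results`` are
    skipped.
    """
    out = {}
    for family in ("cis", "trans", "native"):
        axes = [a for a in AXES if AXIS_FAMILY[a] == family]
        fam = results[results["axis"].isin(axes) & results["q"].notna()]
        if fam.empty:
            continue
        nulls = fam[fam["is_null"]]
        unit_q = nulls.groupby("unit_id")["q"].min()
        n = len(unit_q)
        if n < MIN_NULLS_PER_FAMILY:
            raise ValueError(
                f"need >= {MIN_NULLS_PER_FAMILY} null results for family "
                f"{family!r}, got {n}"
            )
        qs = np.sort(unit_q.to_numpy())
        m_allowed = int(np.ceil(target * n)) - 1
        if m_allowed < 0:
            cutoff = 0.0
        elif m_allowed >= n:
            cutoff = np.inf
        else:
            cutoff = float(qs[m_allowed])
        n_sig = int((qs < cutoff).sum())
        sig_effects = np.abs(
            nulls.loc[nulls["q"] < cutoff, "effect"].to_numpy()
        )
        floor = float(sig_effects.min()) if len(sig_effects) else 0.0
        rate = n_sig / n
        assert rate < target
        out[family] = CalibrationResult(family, cutoff, floor, rate)
    return out


def apply_significance(
    results: pd.DataFrame, calibration: dict[str, CalibrationResult]
) -> pd.DataFrame:
    """Mark each result significant iff q < family cutoff and |effect| > floor."""
    results = results.copy()
    cutoffs = results["axis"].map(lambda a: calibration[AXIS_FAMILY[a]].q_cutoff)
    floors = results["axis"].map(lambda a: calibration[AXIS_FAMILY[a]].effect_floor)
    results["significant"] = (
        results["q"].notna()
        & (results["q"] < cutoffs)
        & (results["effect"].abs() > floors)
    )
    return results


def assign_pair_effect(
    effect_1: float, significant_1: bool, effect_2: float, significant_2: bool
) -> tuple[float, bool]:
    """Collapse the two models of one axis family into one signed effect.

    If exactly one model is significant, its effect is used; otherwise the
    effect with the larger absolute value (ties go to the first model).
    Significance is the OR of the two models.
    """
    miss_1 = effect_1 is None or np.isnan(effect_1)
    miss_2 = effect_2 is None or np.isnan(effect_2)
    if miss_1 and miss_2:
        return np.nan, False
    if miss_1:
        return float(effect_2), bool(significant_2)
    if miss_2:
        return float(effect_1), bool(significant_1)
    if significant_1 != significant_2:
        chosen = effect_1 if significant_1 else effect_2
    else:
        chosen = effect_1 if abs(effect_1) >= abs(effect_2) else effect_2
    return float(chosen), bool(significant_1 or significant_2)


def assign_effects(results: pd.DataFrame) -> pd.DataFrame:
    """Per-pair assigned cis and trans effects (plus native) from scan results.

    Returns a DataFrame indexed by unit_id with columns cis_effect, cis_sig,
    trans_effect, trans_sig, native_effect, native_sig.
    """
    req = {"significant"}
    if not req <= set(results.columns):
        raise ValueError("run apply_significance before assigning pair effects")
    wide_eff = results.pivot_table(
        index="unit_id", columns="axis", values="effect", aggfunc="first"
    )
    wide_sig = (
        results.assign(sig=results["significant"].astype(float))
        .pivot_table(index="unit_id", columns="axis", values="sig", aggfunc="first")
        .fillna(0.0)
        .astype(bool)
    )
    is_null = results.groupby("unit_id")["is_null"].first()

    rows = []
    for uid in wide_eff.index:
        cis, cis_sig = assign_pair_effect(
            wide_eff.at[uid, "cis_hESC"] if "cis_hESC" in wide_eff else np.nan,
            bool(wide_sig.at[uid, "cis_hESC"]) if "cis_hESC" in wide_sig else False,
            wide_eff.at[uid, "cis_mESC"] if "cis_mESC" in wide_eff else np.nan,
            bool(wide_sig.at[uid, "cis_mESC"]) if "cis_mESC" in wide_sig else False,
        )
        trans, trans_sig = assign_pair_effect(
            wide_eff.at[uid, "trans_human_seq"] if "trans_human_seq" in wide_eff else np.nan,
            bool(wide_sig.at[uid, "trans_human_seq"]) if "trans_human_seq" in wide_sig else False,
            wide_eff.at[uid, "trans_mouse_seq"] if "trans_mouse_seq" in wide_eff else np.nan,
            bool(wide_sig.at[uid, "trans_mouse_seq"]) if "trans_mouse_seq" in wide_sig else False,
        )
        native = wide_eff.at[uid, "native"] if "native" in wide_eff else np.nan
        native_sig = bool(wide_sig.at[uid, "native"]) if "native" in wide_sig else False
        rows.append(
            dict(
                unit_id=uid,
                cis_effect=cis,
                cis_sig=cis_sig,
                trans_effect=trans,
                trans_sig=trans_sig,
                native_effect=native,
                native_sig=native_sig,
                is_null=bool(is_null.get(uid, False)),
            )
        )
    return pd.DataFrame(rows).set_index("unit_id")
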