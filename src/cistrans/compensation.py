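"""Cis-trans co-occurrence, compensation classes, and native-effect contrasts.

A pair with both a significant cis and a significant trans effect is
"compensatory" when the two effects have opposite signs (the sequence change
and the environment change pull activity in opposite directions, stabilising
native activity) and "directional" when they share a sign.  Pairs with only
one significant effect are cis_only / trans_only; with neither, "neither".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("compensatory", "directional", "cis_only", "trans_only", "neither")


def cooccurrence_test(flags: pd.DataFrame) -> tuple[float, float]:
    """Fisher's exact test of cis-significance x trans-significance.

    ``flags`` needs boolean columns ``cis_sig`` and ``trans_sig`` over all
    active tested pairs.  Returns (odds ratio, two-sided p).  An empty margin
    leaves the odds undefined (NaN).
    """
    cis = flags["cis_sig"].astype(bool)
    trans = flags["trans_sig"].astype(bool)
    table = np.array(
        [
            [(cis & trans).sum(), (cis & ~trans).sum()],
            [(~cis & trans).sum(), (~cis & ~trans).sum()],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def classify_pair(
    cis_effect: float, cis_sig: bool, trans_effect: float, trans_sig: bool
) -> str:
    """Compensation class of a single pair from its assigned effects."""
    if cis_sig and trans_sig:
        s_c, s_t = np.sign(cis_effect), np.sign(trans_effect)
        if s_c == 0 and s_t == 0:
            return "neither"  # exact double zero: excluded upstream
        # an exact zero with significance inherits the other effect's sign,
        # making the pair directional by convention
        if s_c == 0 or s_t == 0:
            return "directional"
        return "compensatory" if s_c != s_t else "directional"
    if cis_sig:
        return "cis_only"
    if trans_sig:
        return "trans_only"
    return "neither"


def classify_pairs(
    assigned: pd.DataFrame, catalog_pairs: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every pair and summarise fractions per biotype x conservation.

    Parameters
    ----------
    assigned
        Per-pair assigned effects (index unit_id; columns cis_effect, cis_sig,
        trans_effect, trans_sig), e.g. from
        :func:`cistrans.differential.assign_effects`.
    catalog_pairs
        Optional pair annotations (pair_id, biotype, conserved) used for the
        group summary.

    Returns
    -------
    calls : DataFrame (pair_id, cis_effect, trans_effect, class)
    fractions : DataFrame of compensatory/directional fractions per
        biotype x conservation group, computed over pairs with both effects
        significant.  Empty when no annotations are given.
    """
    rows = []
    for uid, r in assigned.iterrows():
        if np.isnan(r["cis_effect"]) and np.isnan(r["trans_effect"]):
            continue
        if (
            r["cis_sig"]
            and r["trans_sig"]
            and r["cis_effect"] == 0
            and r["trans_effect"] == 0
        ):
            continue  # double exact zero carries no direction; log-worthy edge
        rows.append(
            dict(
                pair_id=uid,
                cis_effect=r["cis_effect"],
                trans_effect=r["trans_effect"],
                **{
                    "class": classify_pair(
                        r["cis_effect"], r["cis_sig"], r["trans_effect"], r["trans_sig"]
                    )
                },
            )
        )
    calls = pd.DataFrame(rows)

    if catalog_pairs is None or calls.empty:
        return calls, pd.DataFrame()
    both = calls[calls["class"].isin(["compensatory", "directional"])].merge(
        catalog_pairs[["pair_id", "biotype", "conserved"]], on="pair_id"
    )
    frac_rows = []
    for (biotype, conserved), grp in both.groupby(["biotype", "conserved"]):
        n = len(grp)
        frac_rows.append(
            dict(
                biotype=biotype,
                conserved=conserved,
                n_pairs=n,
                frac_compensatory=(grp["class"] == "compensatory").mean(),
                frac_directional=(grp["class"] == "directional").mean(),
            )
        )
    return calls, pd.DataFrame(frac_rows)


def compare_native_by_class(
    native_effects: pd.Series, classes: pd.Series, min_group: int = 3
) -> dict:
    """One-sided rank-sum test: |native| smaller for compensatory pairs.

    ``native_effects`` and ``classes`` are aligned by index (pair id).
    Returns medians of |native| per class and the Mann-Whitney p-value for
    the alternative that compensatory < directional.
    """
    df = pd.DataFrame({"native": native_effects, "cls": classes}).dropna()
    comp = df.loc[df["cls"] == "compensatory", "native"].abs()
    direc = df.loc[df["cls"] == "directional", "native"].abs()
    if len(comp) < min_group or len(direc) < min_group:
        raise ValueError(
            f"need >= {min_group} pairs per class, got "
            f"{len(comp)} compensatory / {len(direc)} directional"
        )
    stat, p = stats.mannwhitneyu(comp, direc, alternative="less")
    return {
        "median_abs_native_compensatory": float(comp.median()),
        "median_abs_native_directional": float(direc.median()),
        "statistic": float(stat),
        "p": float(p),
        "n_compensatory": int(len(comp)),
        "n_directional": int(len(direc)),
    }
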