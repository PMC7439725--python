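"""Enhancer redundancy inside TADs via Otsu-thresholded expression correlation.

For each assayed element, the transcribed enhancers sharing a TAD with it (a
TAD called in either the hESC or the mESC Hi-C map counts) form its
neighbourhood.  Pearson correlations of log-transformed expression between
the element and each neighbour are thresholded with Otsu's method — the
histogram uses 100 equal bins on [0, 1], negative correlations are clipped to
0 — and the neighbours above the cutoff are the element's "redundant"
enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

N_BINS = 100


@dataclass(frozen=True)
class OtsuResult:
    threshold: float
    degenerate: bool


def assign_tad_and_count(
    element_positions: pd.DataFrame,
    enhancer_positions: pd.DataFrame,
    tads: pd.DataFrame,
) -> dict[str, set[str]]:
    """Enhancers sharing at least one TAD (from either source) with each element.

    ``element_positions`` / ``enhancer_positions`` need columns id, chrom,
    position; ``tads`` needs chrom, start, end (0-based half-open) and
    optionally source.  An element's own id never appears in its set; an
    element covered by no TAD gets an empty set.
    """
    trees: dict[str, IntervalTree] = {}
    for i, t in tads.iterrows():
        if t["start"] >= t["end"]:
            raise ValueError(f"invalid TAD interval [{t['start']}, {t['end']})")
        trees.setdefault(t["chrom"], IntervalTree()).addi(t["start"], t["end"], i)

    def tad_ids(chrom: str, pos: int) -> set[int]:
        tree = trees.get(chrom)
        return {iv.data for iv in tree[pos]} if tree is not None else set()

    enh_tads = {
        r["id"]: tad_ids(r["chrom"], r["position"])
        for _, r in enhancer_positions.iterrows()
    }
    out: dict[str, set[str]] = {}
    for _, r in element_positions.iterrows():
        own = tad_ids(r["chrom"], r["position"])
        out[r["id"]] = {
            enh
            for enh, tset in enh_tads.items()
            if enh != r["id"] and own & tset
        }
    return out


def correlate_expression(
    element_id: str,
    enhancer_ids: set[str] | list[str],
    expression: pd.DataFrame,
) -> pd.Series:
    """Pearson r of log1p expression between an element and its neighbours.

    Neighbours with constant (zero-variance) transformed expression are
    excluded (their r is undefined).  Requires >= 3 samples.
    """
    if expression.shape[1] < 3:
        raise ValueError("need >= 3 expression samples")
    x = np.log1p(expression.loc[element_id].to_numpy(float))
    if np.std(x) == 0:
        return pd.Series(dtype=float)
    vals = {}
    for enh in sorted(enhancer_ids):
        y = np.log1p(expression.loc[enh].to_numpy(float))
        if len(y) != len(x):
            raise ValueError("expression dimension mismatch")
        if np.std(y) == 0:
            continue
        vals[enh] = float(stats.pearsonr(x, y).statistic)
    return pd.Series(vals, dtype=float)


def otsu_threshold(correlations: np.ndarray | pd.Series) -> OtsuResult:
    """Otsu threshold of a correlation histogram (100 bins on [0, 1]).

    Values are clipped to [0, 1] (negative r maps to 0).  The threshold is
    the histogram bin edge maximising the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2``; ties break to the lowest maximising edge.
    All-identical inputs are degenerate: the threshold is that value.
    """
    vals = np.clip(np.asarray(correlations, dtype=float), 0.0, 1.0)
    if len(vals) == 0:
        raise ValueError("no correlation values")
    if np.all(vals == vals[0]):
        return OtsuResult(threshold=float(vals[0]), degenerate=True)

    counts, edges = np.histogram(vals, bins=N_BINS, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    n = counts.sum()

    best_var, best_edge = -np.inf, edges[1]
    for t in range(1, N_BINS):  # internal edges
        c0, c1 = counts[:t], counts[t:]
        n0, n1 = c0.sum(), c1.sum()
        if n0 == 0 or n1 == 0:
            var = 0.0
        else:
            w0, w1 = n0 / n, n1 / n
            mu0 = (c0 * centers[:t]).sum() / n0
            mu1 = (c1 * centers[t:]).sum() / n1
            var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:
            best_var, best_edge = var, edges[t]
    return OtsuResult(threshold=float(best_edge), degenerate=False)


def count_redundant(
    correlations: np.ndarray | pd.Series, threshold: float
) -> int:
    """Number of enhancers strictly above the correlation cutoff."""
    vals = np.clip(np.asarray(correlations, dtype=float), 0.0, 1.0)
    return int((vals > threshold).sum())


def redundancy_table(
    element_positions: pd.DataFrame,
    enhancer_positions: pd.DataFrame,
    tads: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Per-element TAD-enhancer counts and redundant-enhancer counts.

    Applies :func:`assign_tad_and_count`, :func:`correlate_expression`,
    :func:`otsu_threshold` (one histogram per element) and
    :func:`count_redundant` end to end.
    """
    neighbours = assign_tad_and_count(element_positions, enhancer_positions, tads)
    rows = []
    for eid, enh in neighbours.items():
        r = dict(element_id=eid, n_tad_enhancers=len(enh), otsu_threshold=np.nan,
                 n_redundant=0)
        if enh and eid in expression.index:
            cors = correlate_expression(eid, enh, expression)
            if len(cors) >= 2 and cors.nunique() > 1:
                otsu = otsu_threshold(cors)
                r["otsu_threshold"] = otsu.threshold
                r["n_redundant"] = count_redundant(cors, otsu.threshold)
        rows.append(r)
    return pd.DataFrame(rows)


def dedupe_downsample(
    redundancy: pd.DataFrame,
    tad_of_element: dict[str, int | str],
    classes: pd.Series,
    n_resamples: int = 20,
    seed: int = 0,
) -> dict:
    """Robustness of the redundancy-vs-compensation contrast to TAD duplicates.

    One element is retained uniformly at random per TAD; the rank-sum
    comparison of ``n_redundant`` between directional and compensatory
    elements is recomputed over ``n_resamples`` draws.  Reports the fraction
    of resamples preserving the full-data effect direction (directional
    minus compensatory median difference sign).
    """
    rng = np.random.default_rng(seed)
    df = redundancy.set_index("element_id")
    df = df[df.index.isin(classes.index)]
    df = df.join(classes.rename("cls"))
    df = df[df["cls"].isin(["directional", "compensatory"])]
    if df.empty:
        raise ValueError("no classified elements to compare")

    def direction(sub: pd.DataFrame) -> float:
        med_d = sub.loc[sub["cls"] == "directional", "n_redundant"].median()
        med_c = sub.loc[sub["cls"] == "compensatory", "n_redundant"].median()
        return float(med_d - med_c)

    full_dir = np.sign(direction(df))
    by_tad: dict = {}
    for eid in df.index:
        by_tad.setdefault(tad_of_element.get(eid), []).append(eid)

    preserved, skipped = 0, 0
    for _ in range(n_resamples):
        keep = [members[rng.integers(len(members))] for members in by_tad.values()]
        sub = df.loc[df.index.isin(keep)]
        if sub["cls"].nunique() < 2:
            skipped += 1
            continue
        if np.sign(direction(sub)) == full_dir:
            preserved += 1
    n_valid = n_resamples - skipped
    return {
        "full_data_direction": full_dir,
        "n_resamples": n_resamples,
        "n_skipped": skipped,
        "fraction_preserving_direction": preserved / n_valid if n_valid else np.nan,
    }
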