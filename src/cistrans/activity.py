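"""Barcode counts to per-(sequence, environment) activity estimates.

MPRA activity is the log2-scale rate at which a regulatory sequence drives
transcription of its barcodes, read out as the RNA/DNA barcode-count ratio.
Elements are first filtered for adequate representation in the input DNA
library (at least 50% of assigned barcodes at >= 10 DNA counts); per-barcode
log ratios are computed on a counts-per-million scale with a pseudocount of 1;
an element's activity alpha is the mean over replicates of the median over
barcodes of these log ratios.  An element is called active when its alpha is
high relative to the empirical null formed by random negative-control
sequences (Benjamini-Hochberg q < 0.05).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DNA_COUNT_MIN = 10
DNA_FRACTION_MIN = 0.5
ACTIVE_Q_THRESHOLD = 0.05
MIN_NEGATIVE_CONTROLS = 20


def filter_by_dna_representation(
    dna_counts: pd.DataFrame,
    barcode_map: pd.DataFrame,
    min_count: int = DNA_COUNT_MIN,
    min_fraction: float = DNA_FRACTION_MIN,
) -> set[str]:
    """Elements with >= ``min_fraction`` of barcodes at >= ``min_count`` DNA counts.

    The filter is evaluated on the single pooled input DNA library; barcodes
    absent from the DNA table count as zero.  A fraction of exactly 50% is
    kept ("at least 50%").
    """
    counts = dict(zip(dna_counts["barcode_id"], dna_counts["count"]))
    kept = set()
    for element_id, grp in barcode_map.groupby("element_id"):
        assigned = grp["barcode_id"].tolist()
        n_ok = sum(counts.get(bc, 0) >= min_count for bc in assigned)
        if n_ok >= min_fraction * len(assigned):
            kept.add(element_id)
    return kept


def compute_log_ratios(
    dna_counts: pd.DataFrame,
    rna_counts: pd.DataFrame,
    kept_elements: set[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-barcode log2 RNA/DNA ratios on the counts-per-million scale.

    Each sample (the pooled DNA library, and every environment x replicate
    RNA sample) is scaled to CPM; the ratio is
    ``log2((rna_cpm + 1) / (dna_cpm + 1))``.

    Returns a DataFrame with columns element_id, barcode_id, environment,
    replicate, log_ratio.
    """
    dna_total = dna_counts["count"].sum()
    if dna_total <= 0:
        raise ValueError("DNA library size is zero")
    dna_cpm = dict(
        zip(dna_counts["barcode_id"], dna_counts["count"] * 1e6 / dna_total)
    )

    out = []
    for (env, rep), grp in rna_counts.groupby(["environment", "replicate"]):
        total = grp["count"].sum()
        if total <= 0:
            raise ValueError(f"RNA library size is zero for {env} replicate {rep}")
        rna_cpm = grp["count"].to_numpy() * 1e6 / total
        d = np.array([dna_cpm.get(bc, 0.0) for bc in grp["barcode_id"]])
        frame = pd.DataFrame(
            {
                "element_id": grp["element_id"].to_numpy(),
                "barcode_id": grp["barcode_id"].to_numpy(),
                "environment": env,
                "replicate": rep,
                "log_ratio": np.log2((rna_cpm + pseudocount) / (d + pseudocount)),
            }
        )
        out.append(frame)
    obs = pd.concat(out, ignore_index=True)
    if kept_elements is not None:
        obs = obs[obs["element_id"].isin(kept_elements)].reset_index(drop=True)
    return obs


def estimate_activity(observations: pd.DataFrame) -> pd.DataFrame:
    """Mean-over-replicates of median-over-barcodes log ratios.

    Returns a DataFrame with columns element_id, environment, alpha,
    n_barcodes_used.  Elements with no observations are simply absent
    (callers treat missing estimates as flagged).
    """
    if observations.empty:
        return pd.DataFrame(columns=["element_id", "environment", "alpha", "n_barcodes_used"])
    per_rep = (
        observations.groupby(["element_id", "environment", "replicate"])["log_ratio"]
        .median()
        .reset_index()
    )
    alpha = (
        per_rep.groupby(["element_id", "environment"])["log_ratio"]
        .mean()
        .rename("alpha")
        .reset_index()
    )
    n_bc = (
        observations.groupby(["element_id", "environment"])["barcode_id"]
        .nunique()
        .rename("n_barcodes_used")
        .reset_index()
    )
    return alpha.merge(n_bc, on=["element_id", "environment"])


def test_active(
    activities: pd.DataFrame,
    control_elements: set[str],
    q_threshold: float = ACTIVE_Q_THRESHOLD,
) -> pd.DataFrame:
    """Empirical activity test against the negative-control null.

    For each environment, the one-sided empirical p-value of an element is
    ``(1 + #{controls with alpha >= observed}) / (1 + #controls)``; BH
    q-values are computed over all tested (non-control) elements per
    environment, and an element is active iff q < ``q_threshold``.
    """
    out = []
    for env, grp in activities.groupby("environment"):
        is_ctrl = grp["element_id"].isin(control_elements)
        ctrl_alphas = np.sort(grp.loc[is_ctrl, "alpha"].to_numpy())
        if len(ctrl_alphas) < MIN_NEGATIVE_CONTROLS:
            raise ValueError(
                f"need >= {MIN_NEGATIVE_CONTROLS} negative controls in {env}, "
                f"got {len(ctrl_alphas)}"
            )
        tested = grp.loc[~is_ctrl].copy()
        n_ge = len(ctrl_alphas) - np.searchsorted(
            ctrl_alphas, tested["alpha"].to_numpy(), side="left"
        )
        tested["p_active"] = (1 + n_ge) / (1 + len(ctrl_alphas))
        tested["q_active"] = multipletests(tested["p_active"], method="fdr_bh")[1]
        tested["active"] = tested["q_active"] < q_threshold
        out.append(tested)
    return pd.concat(out, ignore_index=True)


def select_representative_tile(
    alpha_tile1_human_native: float,
    alpha_tile2_human_native: float,
    alpha_tile1_mouse_native: float,
    alpha_tile2_mouse_native: float,
) -> str:
    """Pick the tile representing a pair in downstream analyses.

    The TSS-overlapping tile (tile1) is used unless the upstream tile has
    strictly more activity in both native contexts (human sequence in hESC
    and mouse sequence in mESC).  Missing estimates default to tile1 with a
    warning.
    """
    values = (
        alpha_tile1_human_native,
        alpha_tile2_human_native,
        alpha_tile1_mouse_native,
        alpha_tile2_mouse_native,
    )
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in values):
        warnings.warn("missing tile activity estimate; defaulting to tile1")
        return "tile1"
    if (
        alpha_tile2_human_native > alpha_tile1_human_native
        and alpha_tile2_mouse_native > alpha_tile1_mouse_native
    ):
        return "tile2"
    return "tile1"
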