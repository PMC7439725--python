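"""Conserved vs non-conserved TSS calls from mapped coordinates and CAGE coverage.

A reciprocally mapped TSS is conserved when the window of ±50 bp around its
mapped position in the other species contains a maximum CAGE read coverage of
at least 10.  Enhancers carry two TSSs (sense and antisense); the enhancer is
conserved when either TSS window passes.  The coverage input is a
per-position maximum-count track, so "contains >= 10 reads" is a max over the
window, not a sum.  The window is closed: 101 positions.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

WINDOW = 50
MIN_COVERAGE = 10


class CoverageTrack:
    """Sparse per-position coverage on one chromosome (absent positions are 0).

    ``span`` optionally declares the coordinate range the track covers;
    queries outside it raise, matching the contract that classification
    requires the window to lie inside the track.
    """

    def __init__(
        self,
        values: Mapping[int, float],
        span: tuple[int, int] | None = None,
    ) -> None:
        self.values = dict(values)
        if span is None:
            if self.values:
                span = (min(self.values), max(self.values))
            else:
                span = (0, 0)
        self.span = span

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chromosome: str) -> "CoverageTrack":
        sub = df[df["chromosome"] == chromosome]
        return cls(dict(zip(sub["position"], sub["value"])))

    def window_max(self, position: int, window: int = WINDOW) -> float:
        lo, hi = position - window, position + window
        if lo < self.span[0] or hi > self.span[1]:
            raise ValueError(
                f"window [{lo}, {hi}] outside track span {self.span}"
            )
        return max(
            (self.values.get(p, 0.0) for p in range(lo, hi + 1)), default=0.0
        )


def classify_conservation(
    mapped_positions: int | list[int],
    coverage: CoverageTrack,
    reciprocal_ok: bool = True,
    min_coverage: float = MIN_COVERAGE,
    window: int = WINDOW,
) -> str:
    """"conserved" or "non_conserved" for a mapped TSS (or enhancer TSS pair).

    For a gene TSS pass the single mapped position; for an enhancer pass both
    TSS positions — it is conserved when either window has max coverage >=
    ``min_coverage``.  Conservation is only evaluated for reciprocally
    mappable TSSs.
    """
    if not reciprocal_ok:
        raise ValueError("conservation is only defined for reciprocally mapped TSSs")
    positions = (
        [mapped_positions] if np.isscalar(mapped_positions) else list(mapped_positions)
    )
    if not positions:
        raise ValueError("no mapped positions given")
    for pos in positions:
        if coverage.window_max(int(pos), window) >= min_coverage:
            return "conserved"
    return "non_conserved"


def classify_table(
    mapping: pd.DataFrame,
    coverage_by_chrom: Mapping[str, CoverageTrack],
) -> pd.DataFrame:
    """Classify a mapping table (element_id, chromosome, mapped positions).

    ``mapping`` needs columns element_id, chromosome, mapped_position (and
    optionally mapped_position_2 for enhancers, reciprocal_ok).  Rows with
    reciprocal_ok False get class "unmapped".
    """
    rows = []
    for _, r in mapping.iterrows():
        if "reciprocal_ok" in mapping.columns and not r["reciprocal_ok"]:
            rows.append(dict(element_id=r["element_id"], conservation="unmapped"))
            continue
        positions = [int(r["mapped_position"])]
        if "mapped_position_2" in mapping.columns and not pd.isna(
            r.get("mapped_position_2")
        ):
            positions.append(int(r["mapped_position_2"]))
        track = coverage_by_chrom[r["chromosome"]]
        rows.append(
            dict(
                element_id=r["element_id"],
                conservation=classify_conservation(positions, track),
            )
        )
    return pd.DataFrame(rows)
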