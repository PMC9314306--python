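"""Clinical-endpoint layer: change-from-baseline precision comparison.

Given two analyses of the same endpoint — mean (95% CI) change from
baseline (CFB) in the total score per 4-week interval — the fold-increase
in sample size the wider analysis would need to match the narrower one's
precision is

    N = (CI_wide / CI_narrow)^2,

the squared ratio of confidence-interval widths (precision scales with
1/sqrt(n)).  The published comparator table ships with the package; CI
widths are taken from the bounds at their printed precision and summaries
are reported at the conventional precision (cells to 2 decimals, per-arm
medians to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import INTERVAL_LABELS
from .references import load_mmrm_reference

Z95 = 1.959964  # two-sided 95% normal quantile


def ci_width(lo, hi):
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("upper CI bound must exceed the lower bound")
    return hi - lo


def implied_se(ci_lower, ci_upper, ndigits: int = 2):
    """Standard error implied by a normal 95% CI, at reporting precision."""
    se = ci_width(ci_lower, ci_upper) / (2 * Z95)
    return np.round(se, ndigits) if ndigits is not None else se


def relative_sample_size(ci_wide_width, ci_narrow_width):
    """(width ratio)^2: the fold-larger study the wide analysis needs."""
    w = np.asarray(ci_wide_width, dtype=float)
    n = np.asarray(ci_narrow_width, dtype=float)
    if np.any(w <= 0) or np.any(n <= 0):
        raise ValueError("CI widths must be positive")
    return (w / n) ** 2


@dataclass
class RelativeN:
    """Per-cell relative sample sizes with the conventional summaries."""

    cells: pd.DataFrame          # arm, interval, width_mmrm, width_irt, n
    median_by_arm: dict
    minimum: float
    min_cell: tuple

    def summary(self) -> dict:
        return {
            "minimum": round(self.minimum, 2),
            "min_cell": self.min_cell,
            "median_by_arm": {a: round(v, 1) for a, v in self.median_by_arm.items()},
            "cells": {
                (r.arm, r.interval): round(r.n, 2) for r in self.cells.itertuples()
            },
        }


def relative_n_table(irt: pd.DataFrame, mmrm: pd.DataFrame) -> RelativeN:
    """Cell-wise relative sample size from two (arm, interval, lo, hi) grids."""
    key = ["arm", "interval"]
    a = mmrm[key + ["lo", "hi"]].rename(columns={"lo": "lo_m", "hi": "hi_m"})
    b = irt[key + ["lo", "hi"]].rename(columns={"lo": "lo_i", "hi": "hi_i"})
    merged = a.merge(b, on=key, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("IRT and MMRM grids do not match on arm x interval")
    merged["width_mmrm"] = ci_width(merged["lo_m"], merged["hi_m"])
    merged["width_irt"] = ci_width(merged["lo_i"], merged["hi_i"])
    merged["n"] = relative_sample_size(merged["width_mmrm"], merged["width_irt"])
    cells = merged[key + ["width_mmrm", "width_irt", "n"]]
    med = {arm: float(np.median(g["n"])) for arm, g in cells.groupby("arm")}
    imin = cells["n"].idxmin()
    return RelativeN(cells=cells.reset_index(drop=True), median_by_arm=med,
                     minimum=float(cells["n"].min()),
                     min_cell=(cells.loc[imin, "arm"], cells.loc[imin, "interval"]))


def reference_frames(ref: dict | None = None) -> dict:
    """The packaged comparator table as tidy frames, one per method."""
    ref = ref or load_mmrm_reference()
    out = {}
    for method in ("mmrm", "irt"):
        rows = []
        for arm, block in ref["arms"].items():
            vals = block[method]
            for i, label in enumerate(ref["interval_labels"]):
                rows.append({"arm": arm, "interval": label, "mean": vals["mean"][i],
                             "lo": vals["lo"][i], "hi": vals["hi"][i], "se": vals["se"][i]})
        out[method] = pd.DataFrame(rows)
    return out


def reference_relative_n() -> RelativeN:
    """Relative sample sizes computed from the packaged comparator table."""
    frames = reference_frames()
    return relative_n_table(frames["irt"], frames["mmrm"])


def mcid_assessment(cfb_means: pd.DataFrame, mcid: float = 2.0) -> dict:
    """Earliest 4-week interval whose mean CFB reaches the minimal clinically
    important difference (a decrease of at least ``mcid`` points), per arm.

    ``cfb_means`` needs columns arm, interval, mean (interval labels in
    chronological order as in :data:`INTERVAL_LABELS`).  Returns arm ->
    interval label, or None when the MCID is never reached.
    """
    order = {lab: i for i, lab in enumerate(INTERVAL_LABELS)}
    out = {}
    for arm, g in cfb_means.groupby("arm"):
        g = g.sort_values(by="interval", key=lambda s: s.map(order))
        hit = g[g["mean"] <= -mcid]
        out[arm] = None if hit.empty else str(hit["interval"].iloc[0])
    return out
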