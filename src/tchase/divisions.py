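"""In vitro calibration: dye-dilution division counting vs YFP induction.

Activated reporter T cells are tracked with a division dye whose fluorescence
halves at each division, giving peak counts n_0..n_k by division number.
Because a cell in peak i stands for 2**-i founder cells, the
expansion-normalized mean division number of a culture is the
founder-weighted mean

    m = sum_i i * n_i / 2**i  /  sum_i n_i / 2**i.

Regressing the fraction of YFP-induced cells against m across cultures gives
the per-division labeling efficiency line (with its 95% mean-response
envelope), which is what justifies reading average division activity off YFP
frequencies in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DivisionProfile",
    "mean_divisions",
    "yfp_division_regression",
    "read_division_profiles",
]


@dataclass(frozen=True)
class DivisionProfile:
    """Peak counts of one culture: peak_counts[i] cells that divided i times."""

    peak_counts: tuple
    culture_id: str = ""
    condition: str = ""
    frac_yfp: float = np.nan

    def __post_init__(self) -> None:
        counts = np.asarray(self.peak_counts, dtype=float)
        if counts.size == 0 or np.any(counts < 0):
            raise ValueError("peak counts must be a nonempty nonnegative vector")
        if not np.any(counts > 0):
            raise ValueError("division profile needs at least one positive peak")


def mean_divisions(profile: DivisionProfile) -> float:
    """Expansion-normalized mean division number of one culture.

    Each peak-i cell is weighted by 2**-i so cohorts of founders, not their
    expanded progeny, carry the average.  Invariant to uniform rescaling of
    the counts and to appending empty peaks.
    """
    counts = np.asarray(profile.peak_counts, dtype=float)
    i = np.arange(counts.size)
    founders = counts / 2.0**i
    return float(np.sum(i * founders) / np.sum(founders))


def yfp_division_regression(points, eval_at=None):
    """OLS line (with 95% mean-response envelope) of %YFP against divisions.

    Parameters
    ----------
    points : iterable of (mean_divisions, frac_yfp) pairs; >= 3 required.
    eval_at : array-like, optional
        Division numbers at which to evaluate the envelope; defaults to the
        observed ones.

    Returns a dict with slope, intercept, and a DataFrame ``envelope`` with
    columns m, fit, lo, hi.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 (m, frac_yfp) points")
    m, y = pts[:, 0], pts[:, 1]
    if np.allclose(m, m[0]):
        raise ValueError("degenerate design: all mean division numbers equal")
    X = sm.add_constant(m)
    res = sm.OLS(y, X).fit()
    grid = np.asarray(eval_at, dtype=float) if eval_at is not None else np.sort(m)
    pred = res.get_prediction(sm.add_constant(grid))
    band = pred.conf_int(alpha=0.05)
    envelope = pd.DataFrame(
        {"m": grid, "fit": pred.predicted_mean, "lo": band[:, 0], "hi": band[:, 1]}
    )
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "r_squared": float(res.rsquared),
        "envelope": envelope,
        "result": res,
    }


def read_division_profiles(path) -> list:
    """Read culture profiles from a CSV with columns culture_id, condition,
    frac_yfp and peak columns n0..n10 (missing peaks read as zero)."""
    df = pd.read_csv(path)
    peak_cols = [c for c in df.columns if c.startswith("n") and c[1:].isdigit()]
    peak_cols.sort(key=lambda c: int(c[1:]))
    profiles = []
    for _, row in df.iterrows():
        counts = tuple(float(row.get(c, 0.0) or 0.0) for c in peak_cols)
        profiles.append(
            DivisionProfile(
                peak_counts=counts,
                culture_id=str(row.get("culture_id", "")),
                condition=str(row.get("condition", "")),
                frac_yfp=float(row.get("frac_yfp", np.nan)),
            )
        )
    return profiles
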