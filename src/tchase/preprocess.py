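"""From organ-level mouse records to the pooled per-mouse observables.

Naive T cells recirculate freely between spleen and lymph nodes on timescales
of hours, so the two organs are treated as one well-mixed peripheral pool:
counts are summed and fractions combined as count-weighted averages.  From the
pooled naive and the thymic mSP records of each mouse the fitting observables
are derived:

    N   pooled naive count (spleen + LN)
    L   = N * frac_yfp            YFP+ naive count
    l   = frac_yfp                YFP+ naive fraction
    l+  = frac_ki67_in_yfp        Ki67+ fraction within YFP+ naive cells
    k+obs = frac_ki67_total       Ki67+ fraction within all naive cells
    Y   = mSP count * frac_yfp    YFP+ mSP count
    K+  = Y * frac_ki67_in_yfp    YFP+Ki67+ mSP count
    Z   = Y / N                   thymic label normalized by the naive pool
    K+mSP = mSP count * frac_ki67_total   bulk Ki67+ mSP count

l+ is undefined (NaN, excluded from residuals) for mice with no labeled naive
cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["pool_spleen_ln", "derive_observables", "clamp_fractions", "age_classes"]

_FRACTION_COLS = ["frac_yfp", "frac_ki67_in_yfp", "frac_ki67_total"]


def pool_spleen_ln(records: pd.DataFrame) -> pd.Series:
    """Pool the spleen and LN rows of one mouse/lineage/population.

    Counts add; each fraction becomes the count-weighted average.  A single
    present organ passes through unchanged; two zero counts leave the pooled
    fractions undefined (NaN).
    """
    sub = records[records["organ"].isin(["spleen", "LN"])]
    if sub.empty:
        raise ValueError("no spleen or LN records to pool")
    n = float(sub["total_count"].sum())
    out = {"total_count": n}
    for col in _FRACTION_COLS:
        if n > 0:
            out[col] = float((sub["total_count"] * sub[col]).sum() / n)
        else:
            out[col] = np.nan
    return pd.Series(out)


def derive_observables(records: pd.DataFrame) -> pd.DataFrame:
    """Build the per-mouse pooled observable table from a mouse-record table.

    Returns one row per mouse x lineage with the fitting observables; mice
    lacking either the pooled naive or the thymic mSP measurement for a
    lineage are dropped (logged).
    """
    rows = []
    dropped = 0
    for (mid, lin), grp in records.groupby(["mouse_id", "lineage"], sort=True):
        naive = grp[(grp["population"] == "naive")]
        msp = grp[(grp["population"] == "mSP") & (grp["organ"] == "thymus")]
        if naive.empty or msp.empty:
            dropped += 1
            continue
        pooled = pool_spleen_ln(naive)
        N = pooled["total_count"]
        ell = pooled["frac_yfp"]
        L = N * ell
        msp_row = msp.iloc[0]
        M = float(msp_row["total_count"])
        Y = M * float(msp_row["frac_yfp"])
        row = {
            "mouse_id": mid,
            "lineage": lin,
            "age_at_treatment_d": float(grp["age_at_treatment_d"].iloc[0]),
            "t": float(grp["time_d"].iloc[0]),
            "N": N,
            "L": L,
            "l": ell,
            "lplus": float(pooled["frac_ki67_in_yfp"]) if L > 0 else np.nan,
            "kobs": float(pooled["frac_ki67_total"]),
            "Y": Y,
            "Kplus": Y * float(msp_row["frac_ki67_in_yfp"]),
            "kplus_msp_total": M * float(msp_row["frac_ki67_total"]),
            "Z": Y / N if N > 0 else np.nan,
        }
        rows.append(row)
    if dropped:
        logger.info("dropped %d mouse/lineage groups with missing organs", dropped)
    out = pd.DataFrame(rows).sort_values(["lineage", "t", "mouse_id"])
    return out.reset_index(drop=True)


def clamp_fractions(values: np.ndarray, eps: float | None = None) -> np.ndarray:
    """Clamp fractions into [eps, 1 - eps] ahead of logit transforms.

    By default eps is half the smallest nonzero fraction in ``values`` (so
    exact zeros map just below every observed positive value).
    """
    values = np.asarray(values, dtype=float)
    if eps is None:
        pos = values[np.isfinite(values) & (values > 0)]
        eps = 0.5 * pos.min() if pos.size else 1e-6
        eps = min(eps, 0.5)
    return np.clip(values, eps, 1.0 - eps)


def age_classes(ages, n_classes: int = 3) -> pd.Series:
    """Tertiles (by default) of age at treatment start; used only to size
    plot points — the kinetic models themselves ignore host age."""
    return pd.qcut(pd.Series(ages), n_classes, labels=False, duplicates="drop")
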