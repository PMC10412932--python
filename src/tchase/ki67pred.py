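"""Per-mouse validation: does labeled-cell kinetics predict bulk Ki67?

If the fitted dynamics of YFP-labeled cells are representative of the whole
naive population, then each mouse's total naive Ki67+ fraction should be
predictable from its own thymic Ki67+ mSP count and naive pool size via the
quasi-steady-state relation k+_pred = theta*K+_mSP/(beta*N) + 2p/beta.  The
comparison of k+_pred against the observed k+ per mouse — in absolute and
fractional terms — is the model-validation readout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .inference import BootstrapResult, FitResult
from .kinetics import predict_ki67_fraction

logger = logging.getLogger(__name__)

__all__ = ["predict_per_mouse"]


def predict_per_mouse(
    fit: FitResult,
    obs: pd.DataFrame,
    boot: BootstrapResult | None = None,
    use_p: bool = False,
    min_kobs: float = 0.0,
) -> pd.DataFrame:
    """Predict each mouse's total naive Ki67+ fraction from its own thymus.

    Parameters
    ----------
    fit : FitResult
        A converged fit providing theta, beta (and p).
    obs : DataFrame
        Pooled observables with per-mouse ``kplus_msp_total``, ``N``,
        ``kobs`` and ``t``.
    boot : BootstrapResult, optional
        Replicate parameter estimates; when given, each mouse gets a 95%
        percentile interval of the prediction over the replicates.
    use_p : bool
        Include the self-renewal term 2p/beta.  Off by default: the
        statistically favored model has no naive division, and predictions
        with p on differ by exactly 2*p/beta for every mouse.
    min_kobs : float
        Mice with observed fractions at or below this floor get NaN
        fractional differences (they are logged, not dropped).

    Returns a frame ordered by time post-treatment with columns
    kpred, ci_lo, ci_hi, kobs, abs_diff, frac_diff.
    """
    e = fit.estimates
    theta, beta = e["theta"], e.get("beta", np.nan)
    p = e.get("p", 0.0) if use_p else 0.0
    if not np.isfinite(beta) or beta <= 0:
        raise ValueError("fit does not provide a positive Ki67 loss rate beta")

    kmsp = obs["kplus_msp_total"].to_numpy(dtype=float)
    N = obs["N"].to_numpy(dtype=float)
    kpred = predict_ki67_fraction(theta, beta, p, kmsp, N)

    if boot is not None:
        reps = boot.replicates
        th_r = reps["theta"].to_numpy()
        be_r = reps["beta"].to_numpy()
        p_r = reps["p"].to_numpy() if (use_p and "p" in reps) else np.zeros_like(th_r)
        grid = (
            th_r[:, None] * kmsp[None, :] / (be_r[:, None] * N[None, :])
            + 2.0 * p_r[:, None] / be_r[:, None]
        )
        ci_lo, ci_hi = np.percentile(grid, [2.5, 97.5], axis=0)
    else:
        ci_lo = ci_hi = np.full_like(kpred, np.nan)

    kobs = obs["kobs"].to_numpy(dtype=float)
    abs_diff = kpred - kobs
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_diff = np.where(kobs > min_kobs, abs_diff / kobs, np.nan)
    n_excluded = int(np.sum(~(kobs > min_kobs)))
    if n_excluded:
        logger.info(
            "%d mice below the observed-fraction floor excluded from "
            "fractional differences", n_excluded,
        )
    out = pd.DataFrame(
        {
            "mouse_id": obs["mouse_id"].to_numpy(),
            "t": obs["t"].to_numpy(dtype=float),
            "kpred": kpred,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
            "kobs": kobs,
            "abs_diff": abs_diff,
            "frac_diff": frac_diff,
        }
    )
    return out.sort_values("t", kind="stable").reset_index(drop=True)
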