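"""Empirical curves describing labeled-thymocyte kinetics.

After a short tamoxifen pulse, the number of YFP+ mature single-positive (mSP)
thymocytes rises to a unimodal peak as labeled precursors transit the final
stages of thymic development, then relaxes to a low long-run plateau sustained
by heritably labeled upstream progenitors.  Rather than modeling that
developmental chain mechanistically, the pipeline describes the label content
of the source population with two empirical forms:

* a *bump* curve for YFP+ mSP counts,    ``Y(t) = Y0 - a * t**b * exp(-c*t)``
  (a rising-then-falling excursion above/below a plateau ``Y0``; a < 0 gives
  the rise-and-return-to-plateau shape seen in the data), and
* a *generalized-logistic bump* for the normalized counts
  ``Z(t) = k * exp(a*t) * (1 + exp(v*(t - tau)))**(-(a + b)/v)``
  (exponential rise at rate ``a`` switching, with sharpness ``v`` around time
  ``tau``, to exponential decay at rate ``b``).

The same bump form, with its own parameters, describes the YFP+Ki67+ mSP
timecourse K+(t).  Both curves are fitted by least squares on log- (counts) or
logit- (fractions/ratios) transformed observations, with a seeded
Latin-hypercube multi-start followed by local refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

logger = logging.getLogger(__name__)

__all__ = [
    "BumpSourceParams",
    "LogisticSourceParams",
    "bump_curve",
    "logistic_bump",
    "SourceFit",
    "fit_source",
]


@dataclass(frozen=True)
class BumpSourceParams:
    """Parameters of the plateau-plus-bump curve ``Y0 - a * t**b * exp(-c*t)``.

    Attributes
    ----------
    Y0 : float
        Long-run plateau (cells); also the value at t=0 since the bump term
        vanishes there for any b > 0.
    a : float
        Bump amplitude (cells * day**-b).  Sign free: a < 0 places the bump
        above the plateau.
    b : float
        Power controlling the rise (> 0).  The bump extremum sits at t = b/c.
    c : float
        Exponential relaxation rate of the bump (/day, > 0).
    """

    Y0: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"bump power b must be > 0, got {self.b}")
        if self.c <= 0:
            raise ValueError(f"bump decay c must be > 0, got {self.c}")

    @property
    def peak_time(self) -> float:
        return self.b / self.c

    @property
    def peak_height(self) -> float:
        """Signed height of the bump extremum above the plateau."""
        return -self.a * self.peak_time**self.b * np.exp(-self.b)


@dataclass(frozen=True)
class LogisticSourceParams:
    """Parameters of ``k * exp(a*t) * (1 + exp(v*(t - tau)))**(-(a+b)/v)``.

    ``a`` and ``b`` (/day) are the initial rise and final fall rates; ``v``
    (/day, > 0) sets how sharply the curve switches between them around time
    ``tau`` (days); ``k`` is the t -> -inf scale.  These symbols are a distinct
    parameter set from the bump curve's a, b.
    """

    k: float
    a: float
    b: float
    v: float
    tau: float

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError(f"switch sharpness v must be > 0, got {self.v}")
        if self.k <= 0:
            raise ValueError(f"scale k must be > 0, got {self.k}")


def bump_curve(params: BumpSourceParams, t):
    """Evaluate the bump curve at times ``t`` (days, >= 0).

    Vectorized over ``t``; t=0 is handled exactly (the bump term vanishes).
    """
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), -np.inf)
    bump = np.where(t > 0, np.exp(params.b * logt - params.c * t), 0.0)
    return params.Y0 - params.a * bump


def logistic_bump(params: LogisticSourceParams, t):
    """Evaluate the generalized-logistic bump at times ``t``.

    Computed in log space (``logaddexp``) so large ``v*(t - tau)`` never
    overflows.
    """
    t = np.asarray(t, dtype=float)
    expo = (params.a + params.b) / params.v
    logz = (
        np.log(params.k)
        + params.a * t
        - expo * np.logaddexp(0.0, params.v * (t - params.tau))
    )
    return np.exp(logz)


# ---------------------------------------------------------------------------
# fitting


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _transform(values, transform: str):
    if transform == "log":
        return np.log(values)
    if transform == "logit":
        return _logit(values)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class SourceFit:
    """Result of fitting a source curve: parameters, transformed RSS, metadata."""

    params: BumpSourceParams | LogisticSourceParams
    rss: float
    n_obs: int
    n_params: int
    converged: bool
    seed: int


def _bump_from_internal(x, tmax):
    # internal parametrization: log10 Y0, log10 peak height H, b, c
    y0, h = 10.0 ** x[0], 10.0 ** x[1]
    b, c = x[2], x[3]
    a = -h / ((b / c) ** b * np.exp(-b))
    return BumpSourceParams(Y0=y0, a=a, b=b, c=c)


def _logistic_from_internal(x, tmax):
    return LogisticSourceParams(k=10.0 ** x[0], a=x[1], b=x[2], v=x[3], tau=x[4])


def _default_bounds(form: str, values, tmax):
    vmax = float(np.max(values))
    if form == "bump":
        lo = [np.log10(vmax) - 4, np.log10(vmax) - 3, 0.2, 0.01]
        hi = [np.log10(vmax) + 1, np.log10(vmax) + 1.3, 6.0, 2.0]
    elif form == "logistic_bump":
        lo = [np.log10(vmax) - 4, 0.01, 0.002, 0.05, 0.0]
        hi = [np.log10(vmax) + 1, 2.0, 1.0, 10.0, 80.0]
    else:
        raise ValueError(f"unknown source form {form!r}")
    return np.array(lo), np.array(hi)


def fit_source(
    times,
    values,
    form: str = "bump",
    transform: str = "log",
    bounds=None,
    n_starts: int = 100,
    n_refine: int = 3,
    seed: int = 0,
    init=None,
) -> SourceFit:
    """Fit a thymic source curve by multi-start transformed least squares.

    Parameters
    ----------
    times, values : array-like
        Observation days and (positive) observed counts or ratios.
    form : {"bump", "logistic_bump"}
    transform : {"log", "logit"}
        Transform applied to both data and model before the sum of squares;
        log for counts, logit for frequencies/ratios.
    bounds : (lo, hi) in the internal search space, optional.
    n_starts, n_refine : int
        Latin-hypercube start count and number of best starts refined locally.
    seed : int
        Seeds the start-point sampler; fixed seed gives identical fits.
    init : BumpSourceParams | LogisticSourceParams, optional
        Warm start; always refined in addition to the best random starts
        (with n_starts=0, it is the only start).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values) & (values > 0)
    if transform == "logit":
        mask &= values < 1
    times, values = times[mask], values[mask]
    builder = _bump_from_internal if form == "bump" else _logistic_from_internal
    curve = bump_curve if form == "bump" else logistic_bump
    lo, hi = _default_bounds(form, values, times.max()) if bounds is None else bounds
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    if times.size < lo.size:
        raise ValueError("fewer observations than source parameters")

    tobs = _transform(values, transform)

    def residuals(x):
        pred = curve(builder(x, times.max()), times)
        pred = np.clip(pred, 1e-300, 1 - 1e-12 if transform == "logit" else np.inf)
        return _transform(pred, transform) - tobs

    start_list = []
    if n_starts > 0:
        sampler = qmc.LatinHypercube(d=lo.size, seed=seed)
        starts = lo + sampler.random(n_starts) * (hi - lo)
        ssr0 = np.array([float(np.sum(residuals(x) ** 2)) for x in starts])
        order = np.argsort(ssr0)
        start_list = [starts[i] for i in order[:n_refine]]
    if init is not None:
        x_init = (
            np.array([np.log10(init.Y0), np.log10(max(init.peak_height, 1e-12)),
                      init.b, init.c])
            if form == "bump"
            else np.array([np.log10(init.k), init.a, init.b, init.v, init.tau])
        )
        start_list.append(np.clip(x_init, lo, hi))
    if not start_list:
        raise ValueError("no starts: n_starts=0 requires an init")

    best = None
    for x0 in start_list:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), x_scale="jac")
        except Exception:  # pragma: no cover - pathological start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("no source-fit start converged")
    params = builder(best.x, times.max())
    pred = curve(params, times)
    if np.any(pred < 0):
        logger.warning("fitted %s curve is negative somewhere on the data range", form)
    return SourceFit(
        params=params,
        rss=float(2 * best.cost),
        n_obs=int(times.size),
        n_params=int(lo.size),
        converged=bool(best.success),
        seed=seed,
    )
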