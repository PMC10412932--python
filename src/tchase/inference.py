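"""Transformed least-squares inference for the labeled-cell kinetic models.

Counts are fitted on the log scale and fractions/ratios on the logit scale —
both transforms approximately variance-stabilize flow-cytometry-derived
observations, so streams enter the objective with unit weights.  Four model
configurations are supported:

    counts_p0      dL/dt = theta*Y(t) - mu*L           (L stream, log)
    frequency_p0   dl/dt = theta*Z(t) - mu*l           (l stream, logit)
    ki67_p0        Ki67-stratified model with p = 0    (L log + l+ logit)
    ki67_full      Ki67-stratified model with p free   (L log + l+ logit)

under two strategies for the thymic source curves: ``separate`` (sources
pre-fitted to the thymic streams and frozen) or ``simultaneous`` (source
parameters join the free set and the thymic residuals join the objective, so
source uncertainty propagates into the kinetic parameters).

Optimization is a seeded Latin-hypercube pseudorandom search over the kinetic
parameters (sources started from their stream-wise fits) followed by bounded
trust-region least-squares refinement of the best starts.  Model comparison
uses the nested F-test on transformed residual sums of squares; uncertainty
comes from case bootstrap resampling of mice, which preserves the
within-mouse coupling of count and fraction streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import logit
from scipy.stats import f as f_dist
from scipy.stats import qmc

from .kinetics import KineticParams, simulate_labeled_counts, simulate_labeled_frequency, simulate_recast
from .preprocess import clamp_fractions
from .sources import (
    BumpSourceParams,
    LogisticSourceParams,
    _default_bounds,
    bump_curve,
    fit_source,
    logistic_bump,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitSpec",
    "FitResult",
    "BootstrapResult",
    "transformed_ssr",
    "fit_model",
    "fit_nested_pair",
    "f_test_nested",
    "bootstrap",
]

_MODELS = ("counts_p0", "frequency_p0", "ki67_p0", "ki67_full")

# kinetic parameter search ranges (/day); log10 search scale except p, which
# may probe slightly negative values so the p = 0 null is interior
_KINETIC_BOUNDS = {
    "theta": (0.05, 5.0, True),
    "mu": (1 / 500, 0.5, True),
    "beta": (0.02, 5.0, True),
    "p": (-0.05, 0.1, False),
}

_MODEL_KINETIC = {
    "counts_p0": ("theta", "mu"),
    "frequency_p0": ("theta", "mu"),
    "ki67_p0": ("theta", "mu", "beta"),
    "ki67_full": ("theta", "mu", "p", "beta"),
}

_MODEL_SOURCES = {
    "counts_p0": (("y", "bump", "Y", "log"),),
    "frequency_p0": (("z", "logistic_bump", "Z", "logit"),),
    "ki67_p0": (("y", "bump", "Y", "log"), ("kplus", "bump", "Kplus", "log")),
    "ki67_full": (("y", "bump", "Y", "log"), ("kplus", "bump", "Kplus", "log")),
}


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how: model, source strategy, and search settings."""

    model: str
    strategy: str = "separate"
    n_starts: int = 200
    n_refine: int = 5
    seed: int = 0
    h: float = 0.05
    bounds: dict = field(default_factory=dict)  # kinetic overrides, natural scale

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.strategy not in ("separate", "simultaneous"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class FitResult:
    estimates: dict
    rss: float
    n_obs: int
    n_params: int
    stream_rss: dict
    residuals: dict
    converged: bool
    seed: int
    best_start: int
    model: str
    strategy: str
    at_bounds: list
    sources: dict

    def kinetic_params(self) -> KineticParams:
        e = self.estimates
        return KineticParams(
            theta=e["theta"],
            mu=e["mu"],
            p=e.get("p", 0.0),
            beta=e.get("beta", 0.0),
        )


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame
    ci: dict
    n_boot: int
    seed: int
    n_failed: int = 0


# ---------------------------------------------------------------------------


def transformed_ssr(observed, predicted, transform: str) -> float:
    """Sum of squared differences on the log or logit scale.

    Non-finite observations are skipped (and simply do not contribute).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    mask = np.isfinite(observed) & np.isfinite(predicted)
    o, p = observed[mask], predicted[mask]
    if transform == "log":
        r = np.log(o) - np.log(p)
    elif transform == "logit":
        r = logit(o) - logit(p)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return float(np.sum(r**2))


# --- internal parameter-space helpers --------------------------------------


def _bump_internal(p: BumpSourceParams):
    return np.array([np.log10(p.Y0), np.log10(max(p.peak_height, 1e-12)), p.b, p.c])


def _logistic_internal(p: LogisticSourceParams):
    return np.array([np.log10(p.k), p.a, p.b, p.v, p.tau])


def _bump_from_x(x):
    y0, h, b, c = 10.0 ** x[0], 10.0 ** x[1], x[2], x[3]
    return BumpSourceParams(Y0=y0, a=-h / ((b / c) ** b * np.exp(-b)), b=b, c=c)


def _logistic_from_x(x):
    return LogisticSourceParams(k=10.0 ** x[0], a=x[1], b=x[2], v=x[3], tau=x[4])


_SOURCE_CODEC = {
    "bump": (_bump_internal, _bump_from_x, bump_curve, 4),
    "logistic_bump": (_logistic_internal, _logistic_from_x, logistic_bump, 5),
}


class _Space:
    """Bounded internal coordinates: log10 for positive rates, linear else."""

    def __init__(self):
        self.names, self.lo, self.hi, self.log = [], [], [], []

    def add(self, name, lo, hi, log):
        self.names.append(name)
        if log:
            lo, hi = np.log10(lo), np.log10(hi)
        self.lo.append(lo)
        self.hi.append(hi)
        self.log.append(log)

    def finalize(self):
        self.lo = np.asarray(self.lo, float)
        self.hi = np.asarray(self.hi, float)
        return self

    def natural(self, x):
        return {
            n: (10.0 ** v if lg else v)
            for n, v, lg in zip(self.names, x, self.log)
        }


# --- stream assembly --------------------------------------------------------


def _check_single_lineage(obs: pd.DataFrame) -> None:
    lins = obs["lineage"].unique()
    if len(lins) != 1:
        raise ValueError(f"fit_model expects one lineage at a time, got {list(lins)}")


def _prep_stream(times, values, transform):
    """Clamp/mask a data stream; returns (times, transformed obs, n_used)."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    mask = np.isfinite(values)
    if transform == "log":
        mask &= values > 0
        tv = np.log(values[mask])
    else:
        vals = clamp_fractions(values[np.isfinite(values)])
        out = np.full_like(values, np.nan)
        out[np.isfinite(values)] = vals
        tv = logit(out[mask])
    return times[mask], tv, int(mask.sum())


def _clip_pred(pred, transform):
    if transform == "log":
        return np.clip(pred, 1e-12, None)
    return np.clip(pred, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------


def fit_model(
    spec: FitSpec,
    obs: pd.DataFrame,
    sources: dict | None = None,
    extra_starts: list | None = None,
    source_starts: tuple = (60, 2),
    source_init: dict | None = None,
) -> FitResult:
    """Fit a kinetic model to a single-lineage pooled-observable table.

    Parameters
    ----------
    spec : FitSpec
    obs : DataFrame
        Pooled per-mouse observables (one lineage).
    sources : dict, optional
        Pre-fitted source parameters keyed "y"/"z"/"kplus".  Required meaning
        depends on strategy: for ``separate`` they are frozen (fitted
        internally from the thymic streams when omitted); for
        ``simultaneous`` they seed the joint fit.
    extra_starts : list of dict, optional
        Additional start points given as natural-scale estimate dicts (e.g. a
        nested model's solution, or a bootstrap warm start).
    """
    _check_single_lineage(obs)
    t = obs["t"].to_numpy(dtype=float)

    # peripheral streams
    periph = []
    if spec.model == "counts_p0":
        periph.append(("L", "log", *_prep_stream(t, obs["L"], "log")[:2]))
    elif spec.model == "frequency_p0":
        periph.append(("l", "logit", *_prep_stream(t, obs["l"], "logit")[:2]))
    else:
        periph.append(("L", "log", *_prep_stream(t, obs["L"], "log")[:2]))
        periph.append(("lplus", "logit", *_prep_stream(t, obs["lplus"], "logit")[:2]))

    # thymic streams and source definitions
    src_defs = _MODEL_SOURCES[spec.model]
    thymic = {}
    for key, form, col, transform in src_defs:
        tt, tv, _ = _prep_stream(t, obs[col], transform)
        thymic[key] = (form, transform, tt, tv, obs[col].to_numpy(dtype=float))

    # stage 1: per-stream source fits (centers for simultaneous, frozen for
    # separate when not supplied)
    fitted_sources = dict(sources or {})
    for key, (form, transform, tt, tv, raw) in thymic.items():
        if key not in fitted_sources:
            sf = fit_source(
                tt,
                np.exp(tv) if transform == "log" else 1 / (1 + np.exp(-tv)),
                form=form,
                transform=transform,
                n_starts=source_starts[0],
                n_refine=source_starts[1],
                seed=spec.seed + 7919,
                init=(source_init or {}).get(key),
            )
            fitted_sources[key] = sf.params

    # parameter space
    space = _Space()
    kin_names = _MODEL_KINETIC[spec.model]
    for name in kin_names:
        lo, hi, lg = _KINETIC_BOUNDS[name]
        lo, hi = spec.bounds.get(name, (lo, hi))
        space.add(name, lo, hi, lg)
    n_kin = len(kin_names)

    src_slices = {}
    if spec.strategy == "simultaneous":
        pos = n_kin
        for key, (form, transform, tt, tv, raw) in thymic.items():
            to_x, from_x, curve, npar = _SOURCE_CODEC[form]
            vals = raw[np.isfinite(raw) & (raw > 0)]
            lo, hi = _default_bounds(form, vals, tt.max())
            for j in range(npar):
                space.add(f"{key}[{j}]", lo[j], hi[j], False)
            src_slices[key] = slice(pos, pos + npar)
            pos += npar
    space.finalize()

    center = np.empty(len(space.names))
    center[:n_kin] = 0.5 * (space.lo[:n_kin] + space.hi[:n_kin])
    for key, sl in src_slices.items():
        form = thymic[key][0]
        to_x = _SOURCE_CODEC[form][0]
        center[sl] = np.clip(to_x(fitted_sources[key]), space.lo[sl], space.hi[sl])

    def unpack(x):
        kin = {
            n: (10.0 ** v if lg else v)
            for n, v, lg in zip(kin_names, x[:n_kin], space.log[:n_kin])
        }
        srcs = {}
        for key, (form, *_rest) in thymic.items():
            if key in src_slices:
                srcs[key] = _SOURCE_CODEC[form][1](x[src_slices[key]])
            else:
                srcs[key] = fitted_sources[key]
        return kin, srcs

    def src_fn(form, params):
        curve = _SOURCE_CODEC[form][2]
        return lambda tq, p=params: curve(p, tq)

    def predict(kin, srcs):
        """Per-stream model predictions at each stream's own times."""
        kp = KineticParams(
            theta=kin["theta"],
            mu=kin["mu"],
            p=kin.get("p", 0.0),
            beta=kin.get("beta", 0.0),
        )
        preds = {}
        if spec.model == "counts_p0":
            yfn = src_fn(thymic["y"][0], srcs["y"])
            preds["L"] = simulate_labeled_counts(kp, yfn, periph[0][2], h=spec.h)
        elif spec.model == "frequency_p0":
            zfn = src_fn(thymic["z"][0], srcs["z"])
            preds["l"] = simulate_labeled_frequency(kp, zfn, periph[0][2], h=spec.h)
        else:
            yfn = src_fn(thymic["y"][0], srcs["y"])
            kfn = src_fn(thymic["kplus"][0], srcs["kplus"])
            tL = periph[0][2]
            L, _ = simulate_recast(kp, yfn, kfn, tL, h=spec.h)
            preds["L"] = L
            tlp = periph[1][2]
            _, lplus = simulate_recast(kp, yfn, kfn, tlp, h=spec.h)
            preds["lplus"] = lplus
        return preds

    def residuals(x):
        kin, srcs = unpack(x)
        preds = predict(kin, srcs)
        parts = []
        for name, transform, tt, tv in periph:
            pr = _clip_pred(preds[name], transform)
            parts.append((np.log(pr) if transform == "log" else logit(pr)) - tv)
        if spec.strategy == "simultaneous":
            for key, (form, transform, tt, tv, raw) in thymic.items():
                pr = _clip_pred(src_fn(form, srcs[key])(tt), transform)
                parts.append(
                    (np.log(pr) if transform == "log" else logit(pr)) - tv
                )
        return np.concatenate(parts)

    # ki67 models predict L and lplus from one solve; avoid the double solve
    if spec.model in ("ki67_p0", "ki67_full"):
        tL, tlp = periph[0][2], periph[1][2]
        t_all = np.unique(np.concatenate([tL, tlp]))
        iL = np.searchsorted(t_all, tL)
        ilp = np.searchsorted(t_all, tlp)

        def predict(kin, srcs):  # noqa: F811 - optimized override
            kp = KineticParams(
                theta=kin["theta"], mu=kin["mu"],
                p=kin.get("p", 0.0), beta=kin.get("beta", 0.0),
            )
            yfn = src_fn(thymic["y"][0], srcs["y"])
            kfn = src_fn(thymic["kplus"][0], srcs["kplus"])
            L, lplus = simulate_recast(kp, yfn, kfn, t_all, h=spec.h)
            return {"L": L[iL], "lplus": lplus[ilp]}

    # global pseudorandom search over the kinetic block
    sampler = qmc.LatinHypercube(d=n_kin, seed=spec.seed)
    starts = np.tile(center, (spec.n_starts, 1))
    starts[:, :n_kin] = space.lo[:n_kin] + sampler.random(spec.n_starts) * (
        space.hi[:n_kin] - space.lo[:n_kin]
    )
    all_starts = [starts[i] for i in range(spec.n_starts)]
    for est in extra_starts or []:
        x = center.copy()
        for i, (n, lg) in enumerate(zip(kin_names, space.log[:n_kin])):
            if n in est:
                v = est[n]
                x[i] = np.log10(max(v, 10.0 ** space.lo[i])) if lg else v
        x = np.clip(x, space.lo, space.hi)
        all_starts.append(x)

    ssr0 = np.array([float(np.sum(residuals(x) ** 2)) for x in all_starts])
    order = np.argsort(ssr0)
    n_extra = len(all_starts) - spec.n_starts
    refine = list(order[: spec.n_refine])
    # extra starts (warm starts / nested solutions) are always refined
    refine += [i for i in range(spec.n_starts, len(all_starts)) if i not in refine]

    best, best_idx = None, -1
    for idx in refine:
        try:
            sol = least_squares(
                residuals, all_starts[idx], bounds=(space.lo, space.hi),
                x_scale="jac",
            )
        except Exception:  # pragma: no cover
            continue
        if best is None or sol.cost < best.cost:
            best, best_idx = sol, int(idx)
    if best is None:
        raise RuntimeError("no fitting start converged")

    kin, srcs = unpack(best.x)
    preds = predict(kin, srcs)
    stream_rss, res_by_stream, n_obs = {}, {}, 0
    for name, transform, tt, tv in periph:
        pr = _clip_pred(preds[name], transform)
        r = (np.log(pr) if transform == "log" else logit(pr)) - tv
        stream_rss[name] = float(np.sum(r**2))
        res_by_stream[name] = r
        n_obs += r.size
    if spec.strategy == "simultaneous":
        for key, (form, transform, tt, tv, raw) in thymic.items():
            pr = _clip_pred(src_fn(form, srcs[key])(tt), transform)
            r = (np.log(pr) if transform == "log" else logit(pr)) - tv
            stream_rss[key] = float(np.sum(r**2))
            res_by_stream[key] = r
            n_obs += r.size

    estimates = dict(kin)
    for key, params in srcs.items():
        for fname, fval in vars(params).items():
            estimates[f"{key}.{fname}"] = float(fval)

    at_bounds = [
        space.names[i]
        for i in range(len(space.names))
        if np.isclose(best.x[i], space.lo[i]) or np.isclose(best.x[i], space.hi[i])
    ]
    if at_bounds:
        logger.info("parameters at bounds: %s", at_bounds)
    n_params = len(space.names)
    if n_obs <= n_params:
        raise ValueError("fewer observations than free parameters")
    return FitResult(
        estimates=estimates,
        rss=float(2 * best.cost),
        n_obs=n_obs,
        n_params=n_params,
        stream_rss=stream_rss,
        residuals=res_by_stream,
        converged=bool(best.success),
        seed=spec.seed,
        best_start=best_idx,
        model=spec.model,
        strategy=spec.strategy,
        at_bounds=at_bounds,
        sources=srcs,
    )


# ---------------------------------------------------------------------------


def f_test_nested(fit0: FitResult, fit1: FitResult):
    """F-test of a restricted model (fit0) against its nesting model (fit1).

    F = ((RSS0 - RSS1)/(k1 - k0)) / (RSS1/(n - k1)), p from F(k1-k0, n-k1).
    """
    if fit1.n_params <= fit0.n_params:
        raise ValueError("fit1 must have more free parameters than fit0")
    if fit0.n_obs != fit1.n_obs:
        raise ValueError("nested fits must use identical data")
    if fit1.n_obs <= fit1.n_params:
        raise ValueError("not enough observations for the F-test")
    dk = fit1.n_params - fit0.n_params
    df2 = fit1.n_obs - fit1.n_params
    num = max(fit0.rss - fit1.rss, 0.0) / dk
    F = num / (fit1.rss / df2)
    return F, float(f_dist.sf(F, dk, df2))


def fit_nested_pair(
    obs: pd.DataFrame,
    strategy: str = "separate",
    sources: dict | None = None,
    n_starts: int = 50,
    n_refine: int = 3,
    seed: int = 0,
    h: float = 0.05,
):
    """Fit ki67_p0 and ki67_full on the same data and F-test the division rate.

    The full model is warm-started from the restricted solution (with p = 0),
    which guarantees RSS_full <= RSS_p0.  Returns (fit_p0, fit_full, F, p).
    """
    spec0 = FitSpec(model="ki67_p0", strategy=strategy, n_starts=n_starts,
                    n_refine=n_refine, seed=seed, h=h)
    fit0 = fit_model(spec0, obs, sources=sources)
    warm = dict(fit0.estimates)
    warm["p"] = 0.0
    spec1 = FitSpec(model="ki67_full", strategy=strategy, n_starts=n_starts,
                    n_refine=n_refine, seed=seed, h=h)
    src1 = sources
    if strategy == "simultaneous":
        # seed the joint fit's source block from the restricted solution
        src1 = {k: v for k, v in fit0.sources.items()}
    fit1 = fit_model(spec1, obs, sources=src1, extra_starts=[warm])
    F, p = f_test_nested(fit0, fit1)
    return fit0, fit1, F, p


# ---------------------------------------------------------------------------


def bootstrap(
    spec: FitSpec,
    obs: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
    sources: dict | None = None,
    base_fit: FitResult | None = None,
    max_failure_frac: float = 0.2,
) -> BootstrapResult:
    """Case bootstrap over mice: resample rows with replacement and refit.

    Each pooled-observable row carries every stream of one mouse, so row
    resampling preserves the within-mouse coupling between counts and
    fractions.  Replicate fits are warm-started at the base estimates.
    """
    _check_single_lineage(obs)
    base = base_fit or fit_model(spec, obs, sources=sources)
    # NB: sources the caller froze stay frozen across replicates; sources that
    # were fitted from the data are refitted per replicate, so their
    # uncertainty propagates into the intervals.
    rng = np.random.default_rng(seed)
    n = len(obs)
    rows = []
    failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        sample = obs.iloc[idx].reset_index(drop=True)
        try:
            fit = fit_model(
                FitSpec(
                    model=spec.model, strategy=spec.strategy,
                    n_starts=max(spec.n_starts // 10, 5),
                    n_refine=1, seed=spec.seed, h=max(spec.h, 0.25),
                    bounds=spec.bounds,
                ),
                sample,
                sources=sources,
                extra_starts=[base.estimates],
                source_starts=(0, 0),
                source_init=base.sources,
            )
        except Exception:
            failed += 1
            continue
        rows.append({"replicate": b, **{k: v for k, v in fit.estimates.items()}})
    if failed > max_failure_frac * n_boot:
        raise RuntimeError(
            f"bootstrap aborted: {failed}/{n_boot} replicates failed to converge"
        )
    reps = pd.DataFrame(rows)
    ci = {}
    for col in reps.columns:
        if col == "replicate":
            continue
        lo, hi = np.percentile(reps[col].to_numpy(), [2.5, 97.5])
        ci[col] = (float(lo), float(hi))
    return BootstrapResult(replicates=reps, ci=ci, n_boot=n_boot, seed=seed,
                           n_failed=failed)
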