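"""Synthetic mouse cohorts for the pulse-chase division-reporter study design.

The generator emulates the experiment the pipeline analyses: 61 reporter mice
aged 42-110 days receive a 5-day tamoxifen pulse (t = 0 at the first
injection), and single mice are sacrificed at timepoints spanning days 4-66.
Each mouse contributes, per lineage (CD4/CD8): one thymic record of mature
single-positive (mSP) thymocytes, and spleen + lymph-node records of naive
T cells, with total counts and YFP/Ki67 fractions.

Noise structure
---------------
Counts carry multiplicative lognormal error with a stated CV; fractions carry
additive Gaussian error on the logit scale.  Both are centered so that they
are *mean-preserving on the natural scale* (the lognormal gets the usual
-sigma^2/2 shift; the logit noise a second-order mean correction), so the
generator introduces no systematic bias at the default noise levels.  The
spleen and lymph-node records of one mouse derive from a single noisy pooled
count split by a fixed organ fraction, so all derived labeled subset counts
of that mouse share the same count error — mirroring the fact that measured
Ki67+/- labeled counts come from one cell-counter reading multiplied by flow
fractions, and are therefore not independent.

The per-mouse total naive Ki67 fraction is generated from the
quasi-steady-state prediction evaluated at the mouse's own realized mSP Ki67+
count and naive pool size, reflecting the within-mouse pairing of thymic and
peripheral measurements that the validation analysis exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .kinetics import (
    KineticParams,
    predict_ki67_fraction,
    simulate_labeled_frequency,
    simulate_recast,
)
from .sources import (
    BumpSourceParams,
    LogisticSourceParams,
    bump_curve,
    logistic_bump,
)

__all__ = [
    "StudyDesign",
    "NoiseModel",
    "LineageTruth",
    "GroundTruth",
    "generate_cohort",
    "truth_curves",
    "default_design",
    "default_truth",
]

ORGANS = ("thymus", "spleen", "LN")
LINEAGES = ("CD4", "CD8")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the pulse-chase cohort."""

    n_mice: int = 61
    age_at_treatment_range: tuple[float, float] = (42.0, 110.0)
    treatment_duration: float = 5.0
    sampling_times: tuple[float, ...] | None = None  # default: days 4..66 spread
    lineages: tuple[str, ...] = LINEAGES
    naive_pool_mean: dict[str, float] = field(
        default_factory=lambda: {"CD4": 2.0e7, "CD8": 1.0e7}
    )
    msp_pool_mean: dict[str, float] = field(
        default_factory=lambda: {"CD4": 1.0e6, "CD8": 3.0e5}
    )

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        for lin in self.lineages:
            if self.naive_pool_mean[lin] <= 0 or self.msp_pool_mean[lin] <= 0:
                raise ValueError("pool means must be > 0")
        if self.sampling_times is not None:
            if min(self.sampling_times) < self.treatment_duration - 1:
                raise ValueError("sampling before the end of the treatment window")

    def resolved_sampling_times(self) -> np.ndarray:
        """Sacrifice days: one mouse per timepoint, spread over days 4-66."""
        if self.sampling_times is not None:
            times = np.asarray(self.sampling_times, dtype=float)
            if times.size == self.n_mice:
                return times
            return times[np.arange(self.n_mice) % times.size]
        return np.round(np.linspace(4.0, 66.0, self.n_mice))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement/inter-mouse noise: count CV and logit-scale fraction SD.

    ``organ_split_fraction`` is the share of pooled naive cells placed in the
    spleen (the rest in lymph nodes).  Defaults reproduce the qualitative
    observation that frequencies are less noisy than counts.
    """

    count_cv: float = 0.2
    fraction_logit_sd: float = 0.3
    organ_split_fraction: float = 0.45

    def __post_init__(self) -> None:
        if self.count_cv < 0 or self.fraction_logit_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if not 0 < self.organ_split_fraction < 1:
            raise ValueError("organ_split_fraction must be in (0, 1)")


@dataclass(frozen=True)
class LineageTruth:
    """Ground-truth kinetics and thymic label curves for one lineage.

    ``y_source`` may be a bump curve (YFP+ mSP counts) or a logistic bump
    (the count-normalized ratio Z; the count curve is then Z * naive pool).
    ``kplus_source`` is the YFP+Ki67+ mSP bump; if None, K+(t) is a fixed
    fraction ``kplus_ratio`` of Y(t).  ``msp_ki67_frac`` is the bulk Ki67+
    fraction among all mSP thymocytes (held constant, as intrathymic
    proliferation is not modeled dynamically).
    """

    kinetic: KineticParams
    y_source: BumpSourceParams | LogisticSourceParams
    kplus_source: BumpSourceParams | None = None
    kplus_ratio: float = 0.35
    msp_ki67_frac: float = 0.35


@dataclass(frozen=True)
class GroundTruth:
    lineages: dict[str, LineageTruth]
    noise: NoiseModel = field(default_factory=NoiseModel)

    def with_noise(self, noise: NoiseModel) -> "GroundTruth":
        return replace(self, noise=noise)


# ---------------------------------------------------------------------------
# defaults anchored to the simultaneous-fit point estimates

_SOURCE_DEFAULTS = {
    # bump Y(t): peak near day 10 above a nonzero late plateau (residual
    # labeling of self-renewing progenitors keeps feeding labeled mSPs)
    "CD4": dict(
        y=BumpSourceParams(Y0=3000.0, a=-2000.0, b=2.0, c=0.2),
        kplus=BumpSourceParams(Y0=600.0, a=-1600.0, b=2.0, c=0.25),
        z=LogisticSourceParams(k=3.0e-5, a=0.35, b=0.08, v=0.5, tau=12.0),
    ),
    "CD8": dict(
        y=BumpSourceParams(Y0=1000.0, a=-600.0, b=2.0, c=0.2),
        kplus=BumpSourceParams(Y0=200.0, a=-480.0, b=2.0, c=0.25),
        z=LogisticSourceParams(k=2.5e-5, a=0.35, b=0.08, v=0.5, tau=12.0),
    ),
}

# point estimates (rates /day) by fitting strategy, per lineage
_KINETIC_DEFAULTS = {
    ("frequency", "CD4"): KineticParams(theta=0.59, mu=1 / 35),
    ("frequency", "CD8"): KineticParams(theta=0.63, mu=1 / 72),
    ("counts", "CD4"): KineticParams(theta=0.74, mu=1 / 26),
    ("counts", "CD8"): KineticParams(theta=1.00, mu=1 / 35),
    ("ki67", "CD4"): KineticParams(theta=0.84, mu=1 / 21, p=1 / 300, beta=1 / 1.7),
    ("ki67", "CD8"): KineticParams(theta=0.99, mu=1 / 39, p=1 / 4600, beta=1 / 4.3),
}
# Ki67 lifetimes used to complete the no-division truths (the p=0 analyses do
# not constrain beta, but the generator still emits Ki67 observables)
_BETA_DEFAULTS = {"CD4": 1 / 1.7, "CD8": 1 / 4.3}


def default_design(**overrides) -> StudyDesign:
    return StudyDesign(**overrides)


def default_truth(
    flavor: str = "ki67", noise: NoiseModel | None = None
) -> GroundTruth:
    """Ground truth anchored at the simultaneous-fit point estimates.

    flavor : {"ki67", "frequency", "counts"}
        Which fitting strategy's point estimates to take as truth, and which
        source representation to drive the generator with: "frequency" uses
        the logistic ratio curve Z(t); the others use bump count curves.
    """
    if flavor not in {"ki67", "frequency", "counts"}:
        raise ValueError(f"unknown truth flavor {flavor!r}")
    lineages = {}
    for lin in LINEAGES:
        kin = _KINETIC_DEFAULTS[(flavor, lin)]
        if flavor != "ki67":
            kin = replace(kin, beta=_BETA_DEFAULTS[lin])
        src = _SOURCE_DEFAULTS[lin]
        if flavor == "frequency":
            lineages[lin] = LineageTruth(kinetic=kin, y_source=src["z"])
        else:
            lineages[lin] = LineageTruth(
                kinetic=kin, y_source=src["y"], kplus_source=src["kplus"]
            )
    return GroundTruth(lineages=lineages, noise=noise or NoiseModel())


# ---------------------------------------------------------------------------
# truth curve evaluation


def _source_fns(truth: LineageTruth, design: StudyDesign, lineage: str):
    """Return (Y(t) counts, Z(t) ratio, K+(t) counts) callables."""
    n_mean = design.naive_pool_mean[lineage]
    if isinstance(truth.y_source, LogisticSourceParams):
        zfn = lambda t: logistic_bump(truth.y_source, t)
        yfn = lambda t: n_mean * zfn(t)
    else:
        yfn = lambda t: bump_curve(truth.y_source, t)
        zfn = lambda t: yfn(t) / n_mean
    if truth.kplus_source is not None:
        kfn = lambda t: bump_curve(truth.kplus_source, t)
    else:
        kfn = lambda t: truth.kplus_ratio * yfn(t)
    return yfn, zfn, kfn


def truth_curves(truth: GroundTruth, design: StudyDesign, times) -> pd.DataFrame:
    """Noiseless forward-model trajectories, for oracles and plotting.

    Returns a tidy frame with one row per (lineage, time) and columns
    Y, Z, Kplus (thymic curves), L, l, lplus (peripheral labeled cells) and
    kpred (quasi-steady-state total naive Ki67+ fraction).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    frames = []
    for lin, lt in truth.lineages.items():
        yfn, zfn, kfn = _source_fns(lt, design, lin)
        n_mean = design.naive_pool_mean[lin]
        m_mean = design.msp_pool_mean[lin]
        L, lplus = simulate_recast(lt.kinetic, yfn, kfn, times)
        ell = simulate_labeled_frequency(lt.kinetic, zfn, times)
        if lt.kinetic.beta > 0:
            kpred = predict_ki67_fraction(
                lt.kinetic.theta,
                lt.kinetic.beta,
                lt.kinetic.p,
                lt.msp_ki67_frac * m_mean,
                n_mean,
            )
        else:  # the Ki67 turnover prediction needs a finite Ki67 lifetime
            kpred = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "lineage": lin,
                    "time_d": times,
                    "Y": yfn(times),
                    "Z": zfn(times),
                    "Kplus": np.minimum(kfn(times), yfn(times)),
                    "L": L,
                    "l": ell,
                    "lplus": lplus,
                    "kpred": float(kpred),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# noise primitives


def _count_noise(mean, cv, rng, size):
    if cv == 0:
        return np.full(size, float(mean))
    sigma = np.sqrt(np.log1p(cv**2))
    return mean * np.exp(rng.normal(-sigma**2 / 2, sigma, size))


def _fraction_noise(f, sd, rng):
    """Logit-additive Gaussian noise, mean-corrected on the natural scale."""
    f = np.asarray(f, dtype=float)
    if sd == 0:
        return f.copy()
    inner = (f > 0) & (f < 1)
    out = f.copy()
    fi = f[inner]
    shift = -0.5 * sd**2 * (1.0 - 2.0 * fi)  # cancels the O(sd^2) Jensen gap
    out[inner] = expit(logit(fi) + shift + rng.normal(0.0, sd, fi.shape))
    return out


# ---------------------------------------------------------------------------
# cohort generation

_COLUMNS = [
    "mouse_id",
    "age_at_treatment_d",
    "time_d",
    "organ",
    "lineage",
    "population",
    "total_count",
    "frac_yfp",
    "frac_ki67_in_yfp",
    "frac_ki67_total",
]


def generate_cohort(
    truth: GroundTruth, design: StudyDesign, seed: int
) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy mouse-record table.

    One row per mouse x organ x lineage x population (thymus/mSP and
    spleen+LN/naive).  Deterministic for a fixed (truth, design, seed).
    """
    rng = np.random.default_rng(seed)
    times = design.resolved_sampling_times()
    n = design.n_mice
    ages = rng.uniform(*design.age_at_treatment_range, n)
    noise = truth.noise
    s = noise.organ_split_fraction

    rows = []
    for lin in design.lineages:
        lt = truth.lineages[lin]
        kin = lt.kinetic
        yfn, zfn, kfn = _source_fns(lt, design, lin)
        n_mean = design.naive_pool_mean[lin]
        m_mean = design.msp_pool_mean[lin]

        # noiseless peripheral trajectories at the sampling times
        ell_t = simulate_labeled_frequency(kin, zfn, times)
        _, lplus_t = simulate_recast(kin, yfn, kfn, times)
        y_t, kp_t = yfn(times), np.minimum(kfn(times), yfn(times))

        # shared noisy pooled counts
        n_pool = _count_noise(n_mean, noise.count_cv, rng, n)
        m_pool = _count_noise(m_mean, noise.count_cv, rng, n)

        # noisy fractions (applied at the pooled level; spleen and LN records
        # inherit the same values so weighted pooling recovers them exactly)
        ell_obs = _fraction_noise(ell_t, noise.fraction_logit_sd, rng)
        lplus_obs = _fraction_noise(
            np.nan_to_num(lplus_t, nan=0.0), noise.fraction_logit_sd, rng
        )
        yfrac_obs = _fraction_noise(y_t / m_mean, noise.fraction_logit_sd, rng)
        with np.errstate(invalid="ignore", divide="ignore"):
            kp_ratio = np.where(y_t > 0, kp_t / np.maximum(y_t, 1e-300), 0.0)
        kp_frac_obs = _fraction_noise(kp_ratio, noise.fraction_logit_sd, rng)
        msp_k_obs = _fraction_noise(
            np.full(n, lt.msp_ki67_frac), noise.fraction_logit_sd, rng
        )
        # total naive Ki67: QSS prediction at this mouse's realized thymic
        # Ki67+ numbers and naive pool size, plus fraction noise
        if kin.beta > 0:
            k_truth = predict_ki67_fraction(
                kin.theta, kin.beta, kin.p, msp_k_obs * m_pool, n_pool
            )
        else:
            k_truth = np.zeros(n)
        k_obs = _fraction_noise(np.clip(k_truth, 0.0, 1.0), noise.fraction_logit_sd, rng)

        for i in range(n):
            mid = f"m{i + 1:03d}"
            base = dict(
                mouse_id=mid,
                age_at_treatment_d=round(float(ages[i]), 1),
                time_d=float(times[i]),
                lineage=lin,
            )
            rows.append(
                base
                | dict(
                    organ="thymus",
                    population="mSP",
                    total_count=m_pool[i],
                    frac_yfp=yfrac_obs[i],
                    frac_ki67_in_yfp=kp_frac_obs[i],
                    frac_ki67_total=msp_k_obs[i],
                )
            )
            for organ, share in (("spleen", s), ("LN", 1.0 - s)):
                rows.append(
                    base
                    | dict(
                        organ=organ,
                        population="naive",
                        total_count=share * n_pool[i],
                        frac_yfp=ell_obs[i],
                        frac_ki67_in_yfp=lplus_obs[i],
                        frac_ki67_total=k_obs[i],
                    )
                )
    return pd.DataFrame(rows, columns=_COLUMNS)
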