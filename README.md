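# tchase — pulse-chase division-reporter kinetics of naive T cells

`tchase` quantifies the population dynamics of naive CD4 and CD8 T cells from
pulse-chase timecourses in Ki67 division-reporter mice.  In these animals a
short tamoxifen pulse heritably marks dividing cells (and their progeny) with
YFP; because thymocytes divide heavily and resting naive T cells barely at
all, the label enters the periphery almost entirely through thymic export.
Tracking labeled-cell numbers and frequencies in the thymus and periphery
over the following two months, and fitting compartmental ODE models to those
timecourses, yields the rates that govern naive T cell homeostasis.  The
package is aimed at quantitative immunologists and modelers who want a
tested, reusable implementation of this analysis — with a synthetic-cohort
generator standing in for animal data, so every stage is verifiable by
parameter recovery.

## The models

Let Y(t) be the number of YFP+ mature single-positive (mSP) thymocytes,
N the (steady) naive pool size, and Z(t) = Y(t)/N.  Labeled naive T cells L
and their labeled frequency ℓ = L/N obey

    dL/dt = Θ·Y(t) − μ·L                dℓ/dt = Θ·Z(t) − μ·ℓ

where Θ (/day) is the per-capita thymic export rate and μ (/day) the loss
rate; 1/μ is the mean residence time.  Stratifying labeled cells by Ki67 —
expressed for a mean 1/β days after division — and allowing self-renewal at
rate p gives

    dL+/dt = Θ·K+(t) − (μ+β)·L+ + p·(2L− + L+)
    dL−/dt = Θ·K−(t) − (μ+p)·L− + β·L+

with K±(t) the YFP+Ki67± mSP timecourses.  The fitted observables are the
statistically independent pair L = L+ + L− (counts, log scale) and
ℓ+ = L+/L (fraction, logit scale).  Thymic label kinetics are described
empirically: Y(t) = Y0 − a·t^b·e^(−ct) (a unimodal excursion over a late
plateau) and Z(t) = k·e^(at)·(1 + e^(v(t−τ)))^(−(a+b)/v).  Sources are either
pre-fitted and frozen ("separate") or fitted jointly with the kinetics
("simultaneous", which propagates source uncertainty).  Model comparison
(does p > 0 help?) uses nested F-tests; uncertainty comes from case-bootstrap
resampling of mice.  A quasi-steady-state relation
k+_pred = Θ·K+_mSP/(β·N) + 2p/β predicts each mouse's bulk naive Ki67
fraction from its own thymus, validating that labeled cells behave like the
whole population.

## Worked example

Simulate the default study (61 mice, 5-day pulse, sacrifices over days 4–66)
at the frequency-model ground truth (Θ = 0.59/day, 1/μ = 35 days) and refit
it:

```sh
python examples/03_residence_time_fit.py
```

prints

```
fitted per-capita thymic export rate theta = 0.629 /day
fitted loss rate mu = 0.0310 /day  ->  mean residence time 1/mu = 32.2 days
transformed RSS = 11.45 over 122 observations (7 free parameters)
```

One noisy cohort recovers the generating values to within sampling error: the
export rate within ~7% and the residence time within ~8% (medians across 25
replicate cohorts land within a few percent; see below).  The other scripts
in `examples/` walk through cohort simulation, thymic source fitting, the
division-rate F-test, bootstrap intervals, per-mouse Ki67 prediction, and the
in vitro dye-dilution calibration; each prints its numbers with a line on
what they mean.

A thin CLI wraps the same functionality
(`tchase simulate|fit-sources|fit|compare|bootstrap|predict-ki67|recover`),
writing a reproducibility manifest next to every artifact.

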