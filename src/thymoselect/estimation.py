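"""Steady-state rate estimation from cohort cell counts.

The estimation workflow turns a cohort of per-mouse steady-state counts into
model rates using three ingredients:

1. *Residence-time identities.*  The mean dwell time in a compartment is the
   reciprocal of its total per-cell exit rate: ``tau1 = 1/(phi1+mu1)``,
   ``tau2 = 1/(phi2+mu2)``, ``tau4 = 1/(xi4+mu4)``, ``tau8 = 1/(xi8+mu8)``.
2. *Through-origin regressions.*  At steady state the compartment counts are
   proportional across mice (``n2* = a1 n1*`` etc.); the slopes ``a1..a5``
   are estimated by least squares through the origin.
3. *Sweep and filter.*  The SP proliferation rates are not identified by
   steady-state counts alone.  Candidate values are swept on a grid
   (proliferation time capped at 7 days, i.e. ``lam >= 1/7`` per day, and
   bounded by stability), each candidate's trajectory is integrated from an
   empty thymus, and a candidate is accepted when every compartment is within
   one cohort SD of the cohort mean at ``t_acc = 21`` days.  Point estimates
   of swept rates are means over the accepted grid.

The two estimators follow the scikit-learn protocol (``fit`` on a cohort
DataFrame, fitted attributes with a trailing underscore, ``get_params`` /
``set_params``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats
from sklearn.base import BaseEstimator, clone

from . import model
from .cohort import CohortStats, cohort_stats, validate_cohort
from .params import (CompartmentState, DegenerateSpectrumError, LineageRates,
                     PooledRates)


class InconsistentConfigError(ValueError):
    """A residence-time identity forces a negative rate for this cohort."""


class EmptyAcceptedSetError(ValueError):
    """No swept candidate passed the acceptance filter."""


# --------------------------------------------------------------------------
# regression through the origin

@dataclass(frozen=True)
class RegressionResult:
    """Least-squares slope through the origin, ``y ~ slope * x``.

    ``slope = sum(x*y) / sum(x**2)`` (the unique minimizer of the squared
    error ``E(a) = sum((y - a x)**2)``); ``p_value`` is the two-sided t-test
    of the slope with ``n - 1`` degrees of freedom; ``p_pearson`` is the
    Pearson-correlation test, reported alongside because published analyses
    of such cohorts often quote that test instead.
    """

    slope: float
    sse: float
    p_value: float
    p_pearson: float
    residuals: np.ndarray

    @property
    def n(self) -> int:
        return len(self.residuals)


def origin_regression(x, y) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be 1-d vectors of equal length >= 2")
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("regression through the origin needs sum(x**2) > 0")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    sse = float(resid @ resid)
    n = len(x)
    se = np.sqrt(sse / (n - 1) / sxx)
    t = slope / se if se > 0 else np.inf
    p = float(2.0 * sstats.t.sf(abs(t), df=n - 1))
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        p_pearson = float(sstats.pearsonr(x, y).pvalue)
    else:  # constant column (e.g. noise-free synthetic cohorts)
        p_pearson = np.nan
    return RegressionResult(slope=slope, sse=sse, p_value=p,
                            p_pearson=p_pearson, residuals=resid)


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class EstimationConfig:
    """Scalar constants of the estimation workflow.

    Residence times (days): ``tau1`` pre-DP, ``tau2`` post-DP, ``tau3``
    pooled SP, ``tau4``/``tau8`` CD4/CD8 SP.  ``tau2`` defaults to the
    two-decimal convention 0.67 d (so 1/tau2 = 1.4925/d), not 2/3 d.
    ``phi_out`` is the thymic export flux (cells/day); ``mu4``/``mu8`` the
    fixed medullary death rates (1/day); ``lambda_min`` the smallest
    admissible proliferation rate (1/day, the 7-day proliferation-time cap);
    ``n_lambda3``/``n_phi4`` the sweep grid sizes; ``t_acc`` the acceptance
    horizon (days); ``dt`` the RK4 fallback step (days).
    """

    tau1: float = 2.5
    tau2: float = 0.67
    tau3: float = 4.0
    tau4: float = 4.0
    tau8: float = 4.0
    phi_out: float = 2.5e6
    mu4: float = 0.04
    mu8: float = 0.11
    lambda_min: float = 1.0 / 7.0
    n_lambda3: int = 100
    n_phi4: int = 100
    t_acc: float = 21.0
    dt: float = model.DEFAULT_DT

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "tau3", "tau4", "tau8", "phi_out",
                     "t_acc", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.lambda_min < 1.0 / self.tau3:
            raise ValueError("lambda_min must lie in [0, 1/tau3)")
        if self.mu4 >= 1.0 / self.tau4 or self.mu8 >= 1.0 / self.tau8:
            raise ValueError("medullary death rates must satisfy mu < 1/tau")
        if self.n_lambda3 < 1 or self.n_phi4 < 1:
            raise ValueError("sweep grids need at least one point")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EstimationConfig":
        # coerce numerics: YAML 1.1 reads exponent literals like 3.0e6 as str
        kwargs = {f.name: (int(d[f.name]) if f.name.startswith("n_")
                           else float(d[f.name]))
                  for f in dataclasses.fields(cls) if f.name in d}
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "EstimationConfig":
        """Load from YAML or JSON (YAML is a JSON superset)."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# --------------------------------------------------------------------------
# acceptance filter

def acceptance_filter(rates, stats: CohortStats, t_acc: float = 21.0,
                      dt: float = model.DEFAULT_DT) -> bool:
    """One-SD-at-21-days acceptance rule.

    Integrates the model from an empty thymus (all compartments zero) and
    accepts iff every modeled count at ``t_acc`` lies within one cohort SD of
    the cohort mean.  Unstable parameter sets are rejected outright.  The
    integration uses the exact cascade solution, falling back to RK4 for
    (near-)degenerate spectra.
    """
    if not model.stability(rates).stable:
        return False
    if isinstance(rates, PooledRates):
        init = CompartmentState.pooled(0.0, 0.0, 0.0, 0.0)
        cols = ("n1", "n2", "n3")
    else:
        init = CompartmentState.split(0.0, 0.0, 0.0, 0.0, 0.0)
        cols = ("n1", "n2", "n4", "n8")
    try:
        n_t = model.solution_at_times(rates, init, [t_acc])[0]
    except DegenerateSpectrumError:
        traj = model.rk4_simulate(rates, init, t_end=t_acc, dt=dt)
        n_t = traj.iloc[-1][list(cols)].to_numpy(dtype=float)
    mean = np.array([stats.mean_of(c) for c in cols])
    sd = np.array([stats.sd_of(c) for c in cols])
    return bool(np.all(np.abs(n_t - mean) <= sd))


# --------------------------------------------------------------------------
# estimation chains on summary inputs
#
# The chains consume only the summary quantities (residence times, export
# flux, regression slopes, cohort means); the estimators compute those
# summaries from a cohort, while the sensitivity analysis perturbs them
# directly.  The filter reference statistics stay separate so perturbed
# inputs are always judged against the unperturbed cohort.

@dataclass(frozen=True)
class PooledInputs:
    """The summary-input vector of the pooled-model chain."""
    tau1: float
    tau2: float
    tau3: float
    phi_out: float
    a1: float
    a2: float
    nbar3: float
    nbar1: float

    def perturbed(self, factors) -> "PooledInputs":
        vals = np.array([self.tau1, self.tau2, self.tau3, self.phi_out,
                         self.a1, self.a2, self.nbar3, self.nbar1]) * np.asarray(factors)
        return PooledInputs(*vals)


@dataclass(frozen=True)
class LineageInputs:
    """The summary-input vector of the lineage-model chain."""
    tau4: float
    tau8: float
    mu4: float
    mu8: float
    a3: float
    a4: float
    a5: float

    def perturbed(self, factors) -> "LineageInputs":
        vals = np.array([self.tau4, self.tau8, self.mu4, self.mu8,
                         self.a3, self.a4, self.a5]) * np.asarray(factors)
        return LineageInputs(*vals)


@dataclass
class PooledFit:
    phi: float
    phi1: float
    mu1: float
    phi3: float
    mu3: float
    accepted: pd.DataFrame  # columns lam3, phi2, mu2
    n_candidates: int

    def means(self) -> dict[str, float]:
        m = {"phi": self.phi, "phi1": self.phi1, "mu1": self.mu1,
             "phi3": self.phi3, "mu3": self.mu3}
        if len(self.accepted):
            m.update(lam3=float(self.accepted["lam3"].mean()),
                     phi2=float(self.accepted["phi2"].mean()),
                     mu2=float(self.accepted["mu2"].mean()))
        return m


def fit_pooled_chain(inputs: PooledInputs, stats: CohortStats,
                     lambda_min: float = 1.0 / 7.0, n_lambda3: int = 100,
                     t_acc: float = 21.0, dt: float = model.DEFAULT_DT) -> PooledFit:
    """Pooled-model estimation from summary inputs.

    Point rates follow from the export-flux constraint and the residence-time
    identities; ``lam3`` is swept on an equally spaced grid over
    ``[lambda_min, 1/tau3]`` with ``phi2 = a2 (phi3 + mu3 - lam3)`` and
    ``mu2 = 1/tau2 - phi2`` per candidate, filtered by the 21-day rule.
    """
    phi3 = inputs.phi_out / inputs.nbar3
    mu3 = 1.0 / inputs.tau3 - phi3
    if mu3 < 0:
        raise InconsistentConfigError(
            "mu3 = 1/tau3 - phi_out/nbar3 < 0: export flux too large for tau3")
    phi = inputs.nbar1 / inputs.tau1
    phi1 = inputs.a1 / inputs.tau2
    mu1 = 1.0 / inputs.tau1 - phi1
    if mu1 < 0:
        raise InconsistentConfigError(
            "mu1 = 1/tau1 - a1/tau2 < 0: regression slope too steep for tau1, tau2")
    grid = np.linspace(lambda_min, 1.0 / inputs.tau3, n_lambda3)
    rows = []
    for lam3 in grid:
        d3 = phi3 + mu3 - lam3
        phi2 = inputs.a2 * d3
        mu2 = 1.0 / inputs.tau2 - phi2
        if d3 <= 0 or phi2 < 0 or mu2 < 0:
            continue
        cand = PooledRates(phi=phi, phi1=phi1, mu1=mu1, phi2=phi2, mu2=mu2,
                           phi3=phi3, mu3=mu3, lam3=lam3)
        if acceptance_filter(cand, stats, t_acc=t_acc, dt=dt):
            rows.append((lam3, phi2, mu2))
    accepted = pd.DataFrame(rows, columns=["lam3", "phi2", "mu2"])
    return PooledFit(phi=phi, phi1=phi1, mu1=mu1, phi3=phi3, mu3=mu3,
                     accepted=accepted, n_candidates=len(grid))


@dataclass
class LineageFit:
    xi4: float
    xi8: float
    accepted: pd.DataFrame  # columns phi4, phi8, lam4, lam8
    rejections: dict[str, int]
    n_candidates: int

    def means(self) -> dict[str, float]:
        m = {"xi4": self.xi4, "xi8": self.xi8}
        if len(self.accepted):
            for c in ("phi4", "phi8", "lam4", "lam8"):
                m[c] = float(self.accepted[c].mean())
        return m


def fit_lineage_chain(inputs: LineageInputs, m1: dict[str, float],
                      stats: CohortStats, lambda_min: float = 1.0 / 7.0,
                      n_phi4: int = 100, t_acc: float = 21.0,
                      dt: float = model.DEFAULT_DT) -> LineageFit:
    """Lineage-model estimation from summary inputs.

    ``m1`` supplies the pooled-stage means (``phi, phi1, mu1, phi2, mu2,
    lam3``).  ``xi4 = 1/tau4 - mu4`` and ``xi8 = 1/tau8 - mu8`` follow from
    the residence-time identities.  ``phi4`` is swept over the open interval
    ``(0, phi2)``; per candidate ``phi8 = phi2 - phi4``, ``lam4 = 1/tau4 -
    a3 phi4`` (the steady-state relation ``n4* = n2* phi4 / (1/tau4 - lam4)``
    with ``n2*/n4*`` replaced by the regression slope ``a3``) and ``lam8 =
    lam3 a5 - lam4 a4`` (the proliferation-flux balance ``lam4 n4 + lam8 n8 =
    lam3 n3`` divided by ``n8``).  Candidates with a proliferation time above
    7 days (``lam < lambda_min``) or at/beyond the stability boundary
    (``lam >= 1/tau``) in either lineage are rejected before the 21-day
    filter.
    """
    xi4 = 1.0 / inputs.tau4 - inputs.mu4
    xi8 = 1.0 / inputs.tau8 - inputs.mu8
    if xi4 <= 0 or xi8 <= 0:
        raise InconsistentConfigError("xi = 1/tau - mu <= 0: death rate too "
                                      "large for the residence time")
    grid = np.linspace(0.0, m1["phi2"], n_phi4 + 2)[1:-1]
    rejections = {"lam4_window": 0, "lam8_window": 0, "unstable": 0, "filter": 0}
    rows = []
    for phi4 in grid:
        phi8 = m1["phi2"] - phi4
        lam4 = 1.0 / inputs.tau4 - inputs.a3 * phi4
        lam8 = m1["lam3"] * inputs.a5 - lam4 * inputs.a4
        if not lambda_min <= lam4 < 1.0 / inputs.tau4:
            rejections["lam4_window"] += 1
            continue
        if not lambda_min <= lam8 < 1.0 / inputs.tau8:
            rejections["lam8_window"] += 1
            continue
        cand = LineageRates(phi=m1["phi"], phi1=m1["phi1"], mu1=m1["mu1"],
                            phi4=phi4, phi8=phi8, mu2=m1["mu2"],
                            xi4=xi4, mu4=inputs.mu4, lam4=lam4,
                            xi8=xi8, mu8=inputs.mu8, lam8=lam8)
        if not model.stability(cand).stable:
            rejections["unstable"] += 1
            continue
        if not acceptance_filter(cand, stats, t_acc=t_acc, dt=dt):
            rejections["filter"] += 1
            continue
        rows.append((phi4, phi8, lam4, lam8))
    accepted = pd.DataFrame(rows, columns=["phi4", "phi8", "lam4", "lam8"])
    return LineageFit(xi4=xi4, xi8=xi8, accepted=accepted,
                      rejections=rejections, n_candidates=len(grid))


# --------------------------------------------------------------------------
# scikit-learn estimators

class PooledSPEstimator(BaseEstimator):
    """Estimator for the three-compartment (pooled SP) model rates.

    Parameters mirror :class:`EstimationConfig`.  After ``fit`` on a cohort
    DataFrame the point estimates are available as ``phi_``, ``phi1_``,
    ``mu1_``, ``phi3_``, ``mu3_``; the accepted sweep as ``accepted_``
    (columns ``lam3, phi2, mu2``); accepted-mean values as ``lambda3_``,
    ``phi2_``, ``mu2_``; and ``intervals_`` maps each swept rate to its
    accepted ``(min, max)``.
    """

    def __init__(self, tau1: float = 2.5, tau2: float = 0.67, tau3: float = 4.0,
                 phi_out: float = 2.5e6, lambda_min: float = 1.0 / 7.0,
                 n_lambda3: int = 100, t_acc: float = 21.0,
                 dt: float = model.DEFAULT_DT):
        self.tau1 = tau1
        self.tau2 = tau2
        self.tau3 = tau3
        self.phi_out = phi_out
        self.lambda_min = lambda_min
        self.n_lambda3 = n_lambda3
        self.t_acc = t_acc
        self.dt = dt

    @classmethod
    def from_config(cls, cfg: EstimationConfig) -> "PooledSPEstimator":
        return cls(tau1=cfg.tau1, tau2=cfg.tau2, tau3=cfg.tau3,
                   phi_out=cfg.phi_out, lambda_min=cfg.lambda_min,
                   n_lambda3=cfg.n_lambda3, t_acc=cfg.t_acc, dt=cfg.dt)

    def fit(self, X: pd.DataFrame, y=None) -> "PooledSPEstimator":
        X = validate_cohort(X)
        self.stats_ = cohort_stats(X)
        self.regressions_ = {
            "a1": origin_regression(X["n1"], X["n2"]),
            "a2": origin_regression(X["n2"], X["n3"]),
        }
        self.a1_ = self.regressions_["a1"].slope
        self.a2_ = self.regressions_["a2"].slope
        self.inputs_ = PooledInputs(
            tau1=self.tau1, tau2=self.tau2, tau3=self.tau3,
            phi_out=self.phi_out, a1=self.a1_, a2=self.a2_,
            nbar3=self.stats_.mean_of("n3"), nbar1=self.stats_.mean_of("n1"))
        res = fit_pooled_chain(self.inputs_, self.stats_,
                               lambda_min=self.lambda_min,
                               n_lambda3=self.n_lambda3,
                               t_acc=self.t_acc, dt=self.dt)
        if not len(res.accepted):
            raise EmptyAcceptedSetError(
                "no lam3 candidate passed the 21-day one-SD acceptance filter")
        self.fit_ = res
        self.phi_ = res.phi
        self.phi1_ = res.phi1
        self.mu1_ = res.mu1
        self.phi3_ = res.phi3
        self.mu3_ = res.mu3
        self.accepted_ = res.accepted
        self.lambda3_ = float(res.accepted["lam3"].mean())
        self.phi2_ = float(res.accepted["phi2"].mean())
        self.mu2_ = float(res.accepted["mu2"].mean())
        self.intervals_ = {c: (float(res.accepted[c].min()), float(res.accepted[c].max()))
                           for c in ("lam3", "phi2", "mu2")}
        self.n_accepted_ = len(res.accepted)
        return self

    def means_(self) -> dict[str, float]:
        return {"phi": self.phi_, "phi1": self.phi1_, "mu1": self.mu1_,
                "phi3": self.phi3_, "mu3": self.mu3_, "lam3": self.lambda3_,
                "phi2": self.phi2_, "mu2": self.mu2_}

    def to_rates(self) -> PooledRates:
        """Point-estimate rate vector (swept rates at accepted means)."""
        return PooledRates(phi=self.phi_, phi1=self.phi1_, mu1=self.mu1_,
                           phi2=self.phi2_, mu2=self.mu2_, phi3=self.phi3_,
                           mu3=self.mu3_, lam3=self.lambda3_)


class LineageSPEstimator(BaseEstimator):
    """Estimator for the four-compartment (CD4/CD8-resolved) model rates.

    Fits the pooled stage internally (or reuses a supplied ``pooled``
    estimator template) and then estimates the medullary rates.  Fitted
    attributes: ``xi4_``, ``xi8_`` (residence-time determined), the accepted
    sweep ``accepted_`` (columns ``phi4, phi8, lam4, lam8``), accepted means
    ``phi4_``, ``phi8_``, ``lambda4_``, ``lambda8_``, the regression slopes
    ``a3_``, ``a4_``, ``a5_`` and per-cause ``rejection_counts_``.
    """

    def __init__(self, pooled: PooledSPEstimator | None = None,
                 tau4: float = 4.0, tau8: float = 4.0, mu4: float = 0.04,
                 mu8: float = 0.11, lambda_min: float = 1.0 / 7.0,
                 n_phi4: int = 100, t_acc: float = 21.0,
                 dt: float = model.DEFAULT_DT):
        self.pooled = pooled
        self.tau4 = tau4
        self.tau8 = tau8
        self.mu4 = mu4
        self.mu8 = mu8
        self.lambda_min = lambda_min
        self.n_phi4 = n_phi4
        self.t_acc = t_acc
        self.dt = dt

    @classmethod
    def from_config(cls, cfg: EstimationConfig) -> "LineageSPEstimator":
        return cls(pooled=PooledSPEstimator.from_config(cfg), tau4=cfg.tau4,
                   tau8=cfg.tau8, mu4=cfg.mu4, mu8=cfg.mu8,
                   lambda_min=cfg.lambda_min, n_phi4=cfg.n_phi4,
                   t_acc=cfg.t_acc, dt=cfg.dt)

    def fit(self, X: pd.DataFrame, y=None) -> "LineageSPEstimator":
        X = validate_cohort(X)
        self.pooled_ = (clone(self.pooled) if self.pooled is not None
                        else PooledSPEstimator(t_acc=self.t_acc, dt=self.dt))
        self.pooled_.fit(X)
        self.stats_ = cohort_stats(X)
        self.regressions_ = {
            "a3": origin_regression(X["n4"], X["n2"]),
            "a4": origin_regression(X["n8"], X["n4"]),
            "a5": origin_regression(X["n8"], X["n3"]),
        }
        self.a3_ = self.regressions_["a3"].slope
        self.a4_ = self.regressions_["a4"].slope
        self.a5_ = self.regressions_["a5"].slope
        self.inputs_ = LineageInputs(tau4=self.tau4, tau8=self.tau8,
                                     mu4=self.mu4, mu8=self.mu8,
                                     a3=self.a3_, a4=self.a4_, a5=self.a5_)
        res = fit_lineage_chain(self.inputs_, self.pooled_.means_(),
                                self.stats_, lambda_min=self.lambda_min,
                                n_phi4=self.n_phi4, t_acc=self.t_acc,
                                dt=self.dt)
        if not len(res.accepted):
            raise EmptyAcceptedSetError(
                "no phi4 candidate accepted; rejection counts by cause: "
                f"{res.rejections}")
        self.fit_ = res
        self.xi4_ = res.xi4
        self.xi8_ = res.xi8
        self.accepted_ = res.accepted
        self.phi4_ = float(res.accepted["phi4"].mean())
        self.phi8_ = float(res.accepted["phi8"].mean())
        self.lambda4_ = float(res.accepted["lam4"].mean())
        self.lambda8_ = float(res.accepted["lam8"].mean())
        self.intervals_ = {c: (float(res.accepted[c].min()), float(res.accepted[c].max()))
                           for c in ("phi4", "phi8", "lam4", "lam8")}
        self.rejection_counts_ = res.rejections
        self.n_accepted_ = len(res.accepted)
        return self

    def to_rates(self) -> LineageRates:
        """Point-estimate rate vector (swept rates at accepted means)."""
        return LineageRates(phi=self.pooled_.phi_, phi1=self.pooled_.phi1_,
                            mu1=self.pooled_.mu1_, phi4=self.phi4_,
                            phi8=self.phi8_, mu2=self.pooled_.mu2_,
                            xi4=self.xi4_, mu4=self.mu4, lam4=self.lambda4_,
                            xi8=self.xi8_, mu8=self.mu8, lam8=self.lambda8_)


def estimate_pooled(cohort: pd.DataFrame,
                    config: EstimationConfig | None = None) -> PooledSPEstimator:
    """Functional wrapper: fit a :class:`PooledSPEstimator` on a cohort."""
    est = (PooledSPEstimator.from_config(config) if config is not None
           else PooledSPEstimator())
    return est.fit(cohort)


def estimate_lineage(cohort: pd.DataFrame,
                     config: EstimationConfig | None = None) -> LineageSPEstimator:
    """Functional wrapper: fit a :class:`LineageSPEstimator` on a cohort."""
    est = (LineageSPEstimator.from_config(config) if config is not None
           else LineageSPEstimator())
    return est.fit(cohort)
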