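"""Full-factorial perturbation sensitivity analysis.

Every summary input of the estimation chain (residence times, export flux,
regression slopes, cohort means for the pooled model; residence times,
medullary death rates and slopes for the lineage model) is perturbed by
+/- a fixed fraction (10% by default), every sign combination is enumerated
(2^8 corners for the pooled model, 2^7 corners x the phi4 sweep for the
lineage model), the estimation chain is re-run per corner, and each output
rate is summarized over all accepted candidates by mean, central-95%
("trimmed") interval and min-max.  Acceptance uses the same one-SD 21-day
rule, always referenced to the *unperturbed* cohort statistics.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .cohort import cohort_stats
from .estimation import (EstimationConfig, InconsistentConfigError,
                         LineageInputs, PooledInputs, fit_lineage_chain,
                         fit_pooled_chain, origin_regression)

POOLED_THETA = ("tau1", "tau2", "tau3", "phi_out", "a1", "a2", "nbar3", "nbar1")
LINEAGE_THETA = ("tau4", "tau8", "mu4", "mu8", "a3", "a4", "a5")


def perturbation_factors(k: int, fraction: float) -> np.ndarray:
    """All 2^k sign combinations of (1 +/- fraction), one row per corner."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    signs = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    return 1.0 + fraction * signs


def perturbation_grid(theta, fraction: float) -> np.ndarray:
    """All 2^k corner vectors theta_i (1 +/- fraction); baseline excluded."""
    theta = np.asarray(theta, dtype=float)
    return perturbation_factors(len(theta), fraction) * theta[None, :]


def trimmed_interval(values, mass: float = 0.95) -> tuple[float, float]:
    """Empirical central-``mass`` interval (linear-interpolated percentiles)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimmed_interval needs at least one value")
    tail = 100.0 * (1.0 - mass) / 2.0
    lo, hi = np.percentile(values, [tail, 100.0 - tail])
    return float(lo), float(hi)


def _summarize(samples: dict[str, list[float]], mass: float) -> pd.DataFrame:
    rows = {}
    for name, vals in samples.items():
        v = np.asarray(vals, dtype=float)
        lo, hi = trimmed_interval(v, mass)
        rows[name] = {"mean": v.mean(), "trim_lo": lo, "trim_hi": hi,
                      "min": v.min(), "max": v.max(), "n_samples": len(v)}
    return pd.DataFrame(rows).T


def sensitivity_pooled(cohort: pd.DataFrame,
                       config: EstimationConfig | None = None,
                       fraction: float = 0.1,
                       trim_mass: float = 0.95) -> pd.DataFrame:
    """Pooled-model sensitivity summary.

    Returns a DataFrame indexed by parameter (``phi, phi1, mu1, phi2, mu2,
    lam3``) with columns ``mean, trim_lo, trim_hi, min, max, n_samples``.
    Corners whose accepted set is empty contribute no samples; if every
    corner is empty an error is raised.
    """
    cfg = config or EstimationConfig()
    stats = cohort_stats(cohort)
    base = PooledInputs(
        tau1=cfg.tau1, tau2=cfg.tau2, tau3=cfg.tau3, phi_out=cfg.phi_out,
        a1=origin_regression(cohort["n1"], cohort["n2"]).slope,
        a2=origin_regression(cohort["n2"], cohort["n3"]).slope,
        nbar3=stats.mean_of("n3"), nbar1=stats.mean_of("n1"))
    samples: dict[str, list[float]] = {
        k: [] for k in ("phi", "phi1", "mu1", "phi2", "mu2", "lam3",
                        "phi3", "mu3")}
    for factors in perturbation_factors(len(POOLED_THETA), fraction):
        inputs = base.perturbed(factors)
        try:
            res = fit_pooled_chain(inputs, stats, lambda_min=cfg.lambda_min,
                                   n_lambda3=cfg.n_lambda3, t_acc=cfg.t_acc,
                                   dt=cfg.dt)
        except InconsistentConfigError:
            continue
        m = len(res.accepted)
        if m == 0:
            continue
        for k, v in (("phi", res.phi), ("phi1", res.phi1), ("mu1", res.mu1),
                     ("phi3", res.phi3), ("mu3", res.mu3)):
            samples[k].extend([v] * m)
        samples["lam3"].extend(res.accepted["lam3"])
        samples["phi2"].extend(res.accepted["phi2"])
        samples["mu2"].extend(res.accepted["mu2"])
    if not samples["phi"]:
        raise ValueError("sensitivity sweep: every perturbation corner was rejected")
    return _summarize(samples, trim_mass)


def sensitivity_lineage(cohort: pd.DataFrame,
                        m1_means: dict[str, float],
                        config: EstimationConfig | None = None,
                        fraction: float = 0.1,
                        trim_mass: float = 0.95) -> pd.DataFrame:
    """Lineage-model sensitivity summary.

    ``m1_means`` are the baseline pooled-stage means (``phi, phi1, mu1,
    phi2, mu2, lam3``), held fixed across corners; only the lineage summary
    inputs are perturbed.  Summarizes ``xi4, xi8, phi4, phi8, lam4, lam8,
    mu4, mu8``.
    """
    cfg = config or EstimationConfig()
    stats = cohort_stats(cohort)
    base = LineageInputs(
        tau4=cfg.tau4, tau8=cfg.tau8, mu4=cfg.mu4, mu8=cfg.mu8,
        a3=origin_regression(cohort["n4"], cohort["n2"]).slope,
        a4=origin_regression(cohort["n8"], cohort["n4"]).slope,
        a5=origin_regression(cohort["n8"], cohort["n3"]).slope)
    names = ("phi4", "phi8", "lam4", "lam8", "xi4", "xi8", "mu4", "mu8")
    samples: dict[str, list[float]] = {k: [] for k in names}
    for factors in perturbation_factors(len(LINEAGE_THETA), fraction):
        inputs = base.perturbed(factors)
        try:
            res = fit_lineage_chain(inputs, m1_means, stats,
                                    lambda_min=cfg.lambda_min,
                                    n_phi4=cfg.n_phi4, t_acc=cfg.t_acc,
                                    dt=cfg.dt)
        except InconsistentConfigError:
            continue
        m = len(res.accepted)
        if m == 0:
            continue
        for c in ("phi4", "phi8", "lam4", "lam8"):
            samples[c].extend(res.accepted[c])
        for k, v in (("xi4", res.xi4), ("xi8", res.xi8),
                     ("mu4", inputs.mu4), ("mu8", inputs.mu8)):
            samples[k].extend([v] * m)
    if not samples["phi4"]:
        raise ValueError("sensitivity sweep: every perturbation corner was rejected")
    return _summarize(samples, trim_mass)
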