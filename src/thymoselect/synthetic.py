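"""Synthetic cohort generation with known ground truth.

The generator emulates the dominant structure of real steady-state cohorts:
mouse-to-mouse total-cellularity variation that scales all compartments of a
mouse nearly proportionally (a shared lognormal size factor), plus smaller
independent multiplicative measurement noise per compartment, with the pooled
SP count formed as the exact sum of the lineage counts *after* noise so the
``a5 = a4 + 1`` regression identity holds in synthetic data as it does in
real tables.

It does not emulate flow-cytometry gating error structure, lineage-specific
biological covariation beyond the shared size factor, or age effects; see the
methods note for what that implies about parameter-recovery results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import lineage_to_pooled, steady_state, stability
from .params import LineageRates

#: lineage rates matching the published wild-type point estimates
DEFAULT_TRUTH = LineageRates(phi=35.35e6, phi1=0.137, mu1=0.263,
                             phi4=0.070, phi8=0.054, mu2=1.369,
                             xi4=0.21, mu4=0.04, lam4=0.216,
                             xi8=0.14, mu8=0.11, lam8=0.093)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative settings for a synthetic cohort.

    ``size_dispersion`` is the SD of the log mouse-level size factor
    (0.6 by default, matching the log-scale spread of wild-type cohorts);
    ``noise_cv`` the per-compartment multiplicative measurement CV.
    Both lognormal factors are mean-one ("mean-adjusted") so large cohorts
    average to the model steady state.
    """

    truth: LineageRates = DEFAULT_TRUTH
    n_mice: int = 8
    size_dispersion: float = 0.6
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 2:
            raise ValueError("n_mice must be >= 2")
        if self.size_dispersion < 0 or self.noise_cv < 0:
            raise ValueError("size_dispersion and noise_cv must be >= 0")
        if not stability(self.truth).stable:
            raise ValueError("truth rates must satisfy both stability conditions")


def _mean_one_lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a cohort table from the generative model of ``spec``.

    Per mouse ``j``: size factor ``s_j`` (mean-one lognormal with log-SD
    ``size_dispersion``); per compartment ``i`` in (n1, n2, n4, n8):
    ``n_ij = s_j * n_i*(truth) * e_ij`` with ``e_ij`` mean-one lognormal of
    CV ``noise_cv``; then ``n3 = n4 + n8`` exactly.  Deterministic under a
    fixed ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    star = steady_state(spec.truth)
    base = np.array([star.n1, star.n2, star.n4, star.n8])
    s = _mean_one_lognormal(rng, spec.size_dispersion, spec.n_mice)
    noise_sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    eps = _mean_one_lognormal(rng, noise_sigma, (spec.n_mice, 4))
    counts = s[:, None] * base[None, :] * eps
    df = pd.DataFrame(counts, columns=["n1", "n2", "n4", "n8"])
    df.insert(0, "mouse", np.arange(1, spec.n_mice + 1))
    df.insert(3, "n3", df["n4"] + df["n8"])
    return df


def matched_config_kwargs(truth: LineageRates, phi_out: float | None = None) -> dict:
    """Estimation-config values consistent with ``truth`` (for recovery tests).

    Residence times are the reciprocal total exit rates of ``truth``;
    ``phi_out`` defaults to the truth's steady-state export flux
    ``xi4 n4* + xi8 n8*``; the medullary death rates are the truth's own.
    """
    star = steady_state(truth)
    if phi_out is None:
        phi_out = truth.xi4 * star.n4 + truth.xi8 * star.n8
    pooled = lineage_to_pooled(truth, star)
    return {
        "tau1": 1.0 / (truth.phi1 + truth.mu1),
        "tau2": 1.0 / (truth.phi4 + truth.phi8 + truth.mu2),
        "tau3": 1.0 / (pooled.phi3 + pooled.mu3),
        "tau4": 1.0 / (truth.xi4 + truth.mu4),
        "tau8": 1.0 / (truth.xi8 + truth.mu8),
        "phi_out": phi_out,
        "mu4": truth.mu4,
        "mu8": truth.mu8,
    }
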