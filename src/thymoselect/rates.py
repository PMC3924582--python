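"""Biology-facing outputs: fluxes, fate probabilities, stringency, variability.

Fate probabilities are competing-risk ratios: a cell in a compartment with
exit rates ``r_1..r_k`` takes fate ``j`` with probability ``r_j / sum(r)``.
Fluxes are instantaneous ``rate x count`` products; following the source
analysis they are evaluated against the experimental mean counts by default,
with model-consistent steady-state counts available as an alternative.
Variability is first-order (delta-method) worst-case propagation of
parameter half-widths through the probability ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .cohort import CohortStats
from .model import steady_state
from .params import LineageRates, PooledRates

HOURS_PER_DAY = 24.0


def _counts_from(source, split: bool) -> dict[str, float]:
    if isinstance(source, CohortStats):
        cols = ("n1", "n2", "n4", "n8") if split else ("n1", "n2", "n3")
        return {c: source.mean_of(c) for c in cols}
    # a CompartmentState (e.g. the model steady state)
    if split:
        return {"n1": source.n1, "n2": source.n2, "n4": source.n4, "n8": source.n8}
    return {"n1": source.n1, "n2": source.n2, "n3": source.n3}


def flux_report(rates, counts) -> pd.DataFrame:
    """Per-process fluxes, in cells/day and cells/hour.

    ``counts`` is either a :class:`CohortStats` (experimental means, the
    default convention of the published flux lists) or a
    :class:`CompartmentState` such as ``steady_state(rates)``.
    """
    split = isinstance(rates, LineageRates)
    n = _counts_from(counts, split)
    rows: list[tuple[str, str, float, float]] = [
        ("death by neglect", "n1", rates.mu1, n["n1"]),
        ("positive selection", "n1", rates.phi1, n["n1"]),
        ("negative selection death", "n2", rates.mu2, n["n2"]),
    ]
    if split:
        rows += [
            ("CD4 positive selection", "n2", rates.phi4, n["n2"]),
            ("CD8 positive selection", "n2", rates.phi8, n["n2"]),
            ("negative selection death", "n4", rates.mu4, n["n4"]),
            ("negative selection death", "n8", rates.mu8, n["n8"]),
            ("egress to periphery", "n4", rates.xi4, n["n4"]),
            ("egress to periphery", "n8", rates.xi8, n["n8"]),
            ("proliferation", "n4", rates.lam4, n["n4"]),
            ("proliferation", "n8", rates.lam8, n["n8"]),
        ]
    else:
        rows += [
            ("positive selection", "n2", rates.phi2, n["n2"]),
            ("negative selection death", "n3", rates.mu3, n["n3"]),
            ("egress to periphery", "n3", rates.phi3, n["n3"]),
            ("proliferation", "n3", rates.lam3, n["n3"]),
        ]
    df = pd.DataFrame(rows, columns=["process", "compartment", "rate_per_day", "count"])
    df["cells_per_day"] = df["rate_per_day"] * df["count"]
    df["cells_per_hour"] = df["cells_per_day"] / HOURS_PER_DAY
    return df


def flux_of(report: pd.DataFrame, process: str, compartment: str) -> float:
    """Cells/hour of one process row of :func:`flux_report`."""
    m = (report["process"] == process) & (report["compartment"] == compartment)
    if m.sum() != 1:
        raise KeyError(f"no unique flux row for ({process!r}, {compartment!r})")
    return float(report.loc[m, "cells_per_hour"].iloc[0])


# --------------------------------------------------------------------------
# fate probabilities

@dataclass(frozen=True)
class PooledFates:
    """Per-cell fate probabilities of the pooled model (fractions in [0, 1]).

    ``p1``: death by neglect (pre-DP); ``p2``: cortical negative selection
    (post-DP); ``p3``/``q3``: medullary death / proliferation (SP).
    """

    p1: float
    p2: float
    p3: float
    q3: float

    def percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.__dict__.items()}

    def survival_product(self) -> float:
        """(1-p1)(1-p2)(1-p3): probability of not dying in any compartment."""
        return (1 - self.p1) * (1 - self.p2) * (1 - self.p3)


@dataclass(frozen=True)
class LineageFates:
    """Per-cell fate probabilities of the lineage model (fractions).

    ``s4``/``s8``: post-DP cell becomes CD4/CD8 SP; ``p2``: cortical negative
    selection; ``p4``/``q4`` (``p8``/``q8``): medullary death/proliferation;
    ``exit4``/``exit8`` are the complements 1 - p - q (maturation and egress).
    """

    p1: float
    p2: float
    s4: float
    s8: float
    p4: float
    q4: float
    p8: float
    q8: float

    @property
    def exit4(self) -> float:
        return 1.0 - self.p4 - self.q4

    @property
    def exit8(self) -> float:
        return 1.0 - self.p8 - self.q8

    def percent(self) -> dict[str, float]:
        out = {k: 100.0 * v for k, v in self.__dict__.items()}
        out["exit4"] = 100.0 * self.exit4
        out["exit8"] = 100.0 * self.exit8
        return out


def _ratio(num: float, *terms: float) -> float:
    den = sum(terms)
    if den <= 0:
        raise ZeroDivisionError("competing-risk denominator must be positive")
    return num / den


def fate_probabilities(rates) -> PooledFates | LineageFates:
    """Competing-risk fate probabilities of either model."""
    if isinstance(rates, PooledRates):
        return PooledFates(
            p1=_ratio(rates.mu1, rates.mu1, rates.phi1),
            p2=_ratio(rates.mu2, rates.mu2, rates.phi2),
            p3=_ratio(rates.mu3, rates.mu3, rates.phi3, rates.lam3),
            q3=_ratio(rates.lam3, rates.mu3, rates.phi3, rates.lam3),
        )
    den2 = (rates.mu2, rates.phi4, rates.phi8)
    return LineageFates(
        p1=_ratio(rates.mu1, rates.mu1, rates.phi1),
        p2=_ratio(rates.mu2, *den2),
        s4=_ratio(rates.phi4, *den2),
        s8=_ratio(rates.phi8, *den2),
        p4=_ratio(rates.mu4, rates.mu4, rates.xi4, rates.lam4),
        q4=_ratio(rates.lam4, rates.mu4, rates.xi4, rates.lam4),
        p8=_ratio(rates.mu8, rates.mu8, rates.xi8, rates.lam8),
        q8=_ratio(rates.lam8, rates.mu8, rates.xi8, rates.lam8),
    )


# --------------------------------------------------------------------------
# stringency

@dataclass(frozen=True)
class StringencyReport:
    """Selection stringency: thymic output flux over pre-DP input flux.

    ``sigma`` is the fraction of the entering cell flux that leaves the
    thymus; ``survival_product`` (pooled model only) is the probability of
    surviving all three selection stages, (1-p1)(1-p2)(1-p3).  Both are
    fractions; multiply by 100 for percent.
    """

    sigma: float
    survival_product: float | None


def stringency(rates, counts, phi: float | None = None) -> StringencyReport:
    """Egress-flux / influx ratio at the given counts.

    ``counts`` follows the :func:`flux_report` convention (CohortStats or a
    model state); ``phi`` defaults to the model influx ``rates.phi``.
    """
    phi = rates.phi if phi is None else phi
    if phi <= 0:
        raise ValueError("influx phi must be > 0")
    split = isinstance(rates, LineageRates)
    n = _counts_from(counts, split)
    if split:
        sigma = (rates.xi4 * n["n4"] + rates.xi8 * n["n8"]) / phi
        surv = None
    else:
        sigma = rates.phi3 * n["n3"] / phi
        surv = fate_probabilities(rates).survival_product()
    return StringencyReport(sigma=sigma, survival_product=surv)


# --------------------------------------------------------------------------
# first-order variability propagation

@dataclass(frozen=True)
class RateDeltas:
    """Half-widths of the rate parameters (same units as the rates, >= 0).

    Typically the half-widths of min-max or trimmed sensitivity intervals.
    ``dn4bar``, ``dn8bar`` (cells) and ``dphi`` (cells/day) feed only the
    stringency propagation.
    """

    dmu1: float = 0.0
    dphi1: float = 0.0
    dmu2: float = 0.0
    dphi2: float = 0.0
    dmu3: float = 0.0
    dphi3: float = 0.0
    dlam3: float = 0.0
    dphi4: float = 0.0
    dphi8: float = 0.0
    dmu4: float = 0.0
    dxi4: float = 0.0
    dlam4: float = 0.0
    dmu8: float = 0.0
    dxi8: float = 0.0
    dlam8: float = 0.0
    dn4bar: float = 0.0
    dn8bar: float = 0.0
    dphi: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class VariabilityReport:
    """First-order half-widths of the fate probabilities (fractions)."""

    dp1: float
    dp2: float
    dp3: float
    dq3: float
    ds4: float
    ds8: float
    dp4: float
    dq4: float
    dp8: float
    dq8: float
    dsigma: float | None = None

    def percent(self) -> dict[str, float]:
        return {k: (100.0 * v if v is not None else None)
                for k, v in self.__dict__.items()}


def _dp_two_fate(mu, phi, dmu, dphi):
    return (phi * dmu + mu * dphi) / (mu + phi) ** 2


def variability(pooled: PooledRates, lineage: LineageRates, deltas: RateDeltas,
                stats: CohortStats | None = None) -> VariabilityReport:
    """Worst-case first-order propagation of rate half-widths.

    Each output is the sum of absolute sensitivity terms, e.g.
    ``dp1 = (phi1 dmu1 + mu1 dphi1) / (mu1 + phi1)^2``.  When ``stats`` is
    given, the stringency half-width ``dsigma`` is propagated from the egress
    rates, the SP mean counts and the influx.
    """
    d = deltas
    D3 = (pooled.mu3 + pooled.phi3 + pooled.lam3) ** 2
    Ds = (lineage.mu2 + lineage.phi4 + lineage.phi8) ** 2
    D4 = (lineage.mu4 + lineage.xi4 + lineage.lam4) ** 2
    D8 = (lineage.mu8 + lineage.xi8 + lineage.lam8) ** 2
    dsigma = None
    if stats is not None:
        sigma = (lineage.xi4 * stats.mean_of("n4")
                 + lineage.xi8 * stats.mean_of("n8")) / lineage.phi
        dsigma = ((stats.mean_of("n4") * d.dxi4 + lineage.xi4 * d.dn4bar
                   + stats.mean_of("n8") * d.dxi8 + lineage.xi8 * d.dn8bar)
                  / lineage.phi + sigma * d.dphi / lineage.phi)
    return VariabilityReport(
        dp1=_dp_two_fate(pooled.mu1, pooled.phi1, d.dmu1, d.dphi1),
        dp2=_dp_two_fate(pooled.mu2, pooled.phi2, d.dmu2, d.dphi2),
        dp3=((pooled.phi3 + pooled.lam3) * d.dmu3 + pooled.mu3 * d.dphi3
             + pooled.mu3 * d.dlam3) / D3,
        dq3=(pooled.lam3 * d.dmu3 + pooled.lam3 * d.dphi3
             + (pooled.mu3 + pooled.phi3) * d.dlam3) / D3,
        ds4=(lineage.phi4 * d.dmu2 + lineage.phi4 * d.dphi8
             + (lineage.mu2 + lineage.phi8) * d.dphi4) / Ds,
        ds8=(lineage.phi8 * d.dmu2 + lineage.phi8 * d.dphi4
             + (lineage.mu2 + lineage.phi4) * d.dphi8) / Ds,
        dp4=(lineage.mu4 * d.dxi4 + lineage.mu4 * d.dlam4
             + (lineage.xi4 + lineage.lam4) * d.dmu4) / D4,
        dq4=(lineage.lam4 * d.dxi4 + lineage.lam4 * d.dmu4
             + (lineage.xi4 + lineage.mu4) * d.dlam4) / D4,
        dp8=(lineage.mu8 * d.dxi8 + lineage.mu8 * d.dlam8
             + (lineage.xi8 + lineage.lam8) * d.dmu8) / D8,
        dq8=(lineage.lam8 * d.dxi8 + lineage.lam8 * d.dmu8
             + (lineage.xi8 + lineage.mu8) * d.dlam8) / D8,
        dsigma=dsigma,
    )
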