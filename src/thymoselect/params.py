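"""Parameter vectors and state containers for the thymocyte compartment models.

Two deterministic linear ODE models of thymocyte development after the
double-negative (DN) stage are supported:

* the *pooled* model — pre-DP (``n1``) → post-DP (``n2``) → pooled SP (``n3``),
* the *lineage* model — the SP pool resolved into CD4 SP (``n4``) and
  CD8 SP (``n8``) compartments, with ``n3 = n4 + n8``.

All rates are per day; the DN influx ``phi`` is cells/day; counts are cells.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Sequence


class NoSteadyStateError(ValueError):
    """A positive steady state does not exist for the given rates."""


class DegenerateSpectrumError(ValueError):
    """Two decay rates coincide; the cascade closed form is singular.

    Use :func:`thymoselect.model.rk4_simulate` for this (measure-zero) case.
    """


def _check_nonneg(obj) -> None:
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite, got {v!r}")
        if v < 0:
            raise ValueError(f"{type(obj).__name__}.{f.name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class PooledRates:
    """Rates of the three-compartment (pooled SP) model.

    Attributes
    ----------
    phi : float
        DN → pre-DP influx, cells/day.
    phi1, mu1 : float
        Pre-DP differentiation (positive selection) and death-by-neglect
        rates, 1/day.
    phi2, mu2 : float
        Post-DP differentiation and negative-selection death rates, 1/day.
    phi3, mu3, lam3 : float
        SP egress (maturation), death and proliferation rates, 1/day.
    """

    phi: float
    phi1: float
    mu1: float
    phi2: float
    mu2: float
    phi3: float
    mu3: float
    lam3: float

    def __post_init__(self) -> None:
        _check_nonneg(self)

    @property
    def decay_rates(self) -> tuple[float, float, float]:
        """Per-compartment net loss rates (negatives of the Jacobian eigenvalues)."""
        return (self.phi1 + self.mu1, self.phi2 + self.mu2,
                self.phi3 + self.mu3 - self.lam3)

    def to_dict(self) -> dict[str, float]:
        return {"phi": self.phi, "phi1": self.phi1, "mu1": self.mu1,
                "phi2": self.phi2, "mu2": self.mu2, "phi3": self.phi3,
                "mu3": self.mu3, "lambda3": self.lam3}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "PooledRates":
        return cls(phi=d["phi"], phi1=d["phi1"], mu1=d["mu1"], phi2=d["phi2"],
                   mu2=d["mu2"], phi3=d["phi3"], mu3=d["mu3"], lam3=d["lambda3"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "PooledRates":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class LineageRates:
    """Rates of the four-compartment (CD4/CD8-resolved) model.

    ``phi4``/``phi8`` are the post-DP → CD4/CD8 SP differentiation rates;
    ``xi4``/``xi8`` the egress rates; ``mu4``/``mu8`` the medullary death
    rates; ``lam4``/``lam8`` the proliferation rates (all 1/day).
    """

    phi: float
    phi1: float
    mu1: float
    phi4: float
    phi8: float
    mu2: float
    xi4: float
    mu4: float
    lam4: float
    xi8: float
    mu8: float
    lam8: float

    def __post_init__(self) -> None:
        _check_nonneg(self)

    @property
    def phi2(self) -> float:
        """Total post-DP differentiation rate, phi4 + phi8 (1/day)."""
        return self.phi4 + self.phi8

    @property
    def decay_rates(self) -> tuple[float, float, float, float]:
        return (self.phi1 + self.mu1, self.phi4 + self.phi8 + self.mu2,
                self.xi4 + self.mu4 - self.lam4, self.xi8 + self.mu8 - self.lam8)

    def to_dict(self) -> dict[str, float]:
        return {"phi": self.phi, "phi1": self.phi1, "mu1": self.mu1,
                "phi4": self.phi4, "phi8": self.phi8, "mu2": self.mu2,
                "xi4": self.xi4, "mu4": self.mu4, "lambda4": self.lam4,
                "xi8": self.xi8, "mu8": self.mu8, "lambda8": self.lam8}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "LineageRates":
        return cls(phi=d["phi"], phi1=d["phi1"], mu1=d["mu1"], phi4=d["phi4"],
                   phi8=d["phi8"], mu2=d["mu2"], xi4=d["xi4"], mu4=d["mu4"],
                   lam4=d["lambda4"], xi8=d["xi8"], mu8=d["mu8"], lam8=d["lambda8"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "LineageRates":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class CompartmentState:
    """Cell counts of one model state at time ``t`` (days).

    Either ``n3`` is stored directly (pooled model) or the state is
    lineage-resolved, in which case ``n3`` is the exact sum ``n4 + n8``.
    """

    t: float
    n1: float
    n2: float
    _n3: float | None = None
    n4: float | None = None
    n8: float | None = None

    def __post_init__(self) -> None:
        split = self.n4 is not None or self.n8 is not None
        if split and (self.n4 is None or self.n8 is None):
            raise ValueError("n4 and n8 must be given together")
        if split and self._n3 is not None:
            raise ValueError("give either n3 or (n4, n8), not both")
        if not split and self._n3 is None:
            raise ValueError("one of n3 or (n4, n8) is required")
        for name in ("n1", "n2", "_n3", "n4", "n8"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"count {name.lstrip('_')} must be finite and >= 0, got {v!r}")

    @property
    def is_split(self) -> bool:
        return self.n4 is not None

    @property
    def n3(self) -> float:
        return self.n4 + self.n8 if self.is_split else self._n3

    @classmethod
    def pooled(cls, t: float, n1: float, n2: float, n3: float) -> "CompartmentState":
        return cls(t=t, n1=n1, n2=n2, _n3=n3)

    @classmethod
    def split(cls, t: float, n1: float, n2: float, n4: float, n8: float) -> "CompartmentState":
        return cls(t=t, n1=n1, n2=n2, n4=n4, n8=n8)

    def counts(self) -> tuple[float, ...]:
        """Counts in model order: (n1, n2, n3) or (n1, n2, n4, n8)."""
        if self.is_split:
            return (self.n1, self.n2, self.n4, self.n8)
        return (self.n1, self.n2, self.n3)


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalues of the model Jacobian and the resulting stability verdict.

    ``stable`` is true iff every eigenvalue is strictly negative;
    ``slowest_timescale`` is ``-1/max(eigenvalues)`` (days) when stable.
    """

    eigenvalues: tuple[float, ...]
    stable: bool
    slowest_timescale: float | None

    @classmethod
    def from_eigenvalues(cls, eigs: Sequence[float]) -> "StabilityReport":
        eigs = tuple(float(b) for b in eigs)
        stable = all(b < 0 for b in eigs)
        slowest = -1.0 / max(eigs) if stable else None
        return cls(eigenvalues=eigs, stable=stable, slowest_timescale=slowest)
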