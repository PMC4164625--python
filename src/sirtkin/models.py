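"""Closed-form initial-rate models for sirtuin deacetylation kinetics.

Units are fixed package-wide: concentrations in µM, velocities in µM/min,
time in min. Peptide substrate is assumed saturating throughout, so every
model is a function of [NAD+] (the varied substrate) and, where relevant,
the inhibitor concentrations [NAM] and [isoNAM].

The central model is the hyperbolic mixed base-exchange rate law

    v = vmax * S * (1 + I/K1) / [ S*(1 + I/K3) + Km*(1 + I/K2) ],

with S = [NAD+], I = [NAM] and K3 = alpha*K2. The numerator term reflects
turnover from the NAM-bound alkylimidate intermediate (the inhibitor-bound
complex retains activity — "partial" inhibition), so at saturating S and I
the velocity plateaus at vmax*K3/K1 instead of vanishing. K1 is frequently
too large to estimate from data; it is represented internally by its
reciprocal r1 = 1/K1 so that the omitted-term limit is exactly r1 = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "BaseExchangeParams",
    "MixedInhibitionParams",
    "Ic50Params",
    "ConcentrationPoint",
    "rate_base_exchange",
    "rate_base_exchange_with_competitor",
    "rate_mixed",
    "rate_michaelis",
    "ic50_response",
]


def _check_conc(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return value


def _check_pos(name: str, value: float) -> float:
    value = float(value)
    if not (value > 0) or not math.isfinite(value):
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ConcentrationPoint:
    """One assay condition: [NAD+], [NAM], [isoNAM], all in µM."""

    nad: float
    nam: float = 0.0
    isonam: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nad", _check_conc("nad", self.nad))
        object.__setattr__(self, "nam", _check_conc("nam", self.nam))
        object.__setattr__(self, "isonam", _check_conc("isonam", self.isonam))


@dataclass(frozen=True)
class BaseExchangeParams:
    """Macroscopic constants of the hyperbolic mixed base-exchange model.

    Parameters
    ----------
    vmax : maximal velocity, µM/min.
    km : Michaelis constant of NAD+, µM.
    k2 : NAM constant multiplying the Km term of the denominator, µM.
    alpha : dimensionless competitive-character ratio; K3 = alpha*k2.
    r1 : reciprocal of the numerator constant K1, 1/µM. ``r1 = 0`` encodes
        K1 = ∞, i.e. the [NAM]/K1 numerator term omitted — the regime the
        SIRT3 and SIRT1 global fits land in.

    Notes
    -----
    When K1 is finite, net inhibition requires K1 >= K3: otherwise NAM-bound
    turnover exceeds the loss through the denominator and NAM activates.
    Construction flags (but does not forbid) that violation via
    :attr:`net_inhibition`.
    """

    vmax: float
    km: float
    k2: float
    alpha: float
    r1: float = 0.0
    net_inhibition: bool = field(init=False, compare=False)

    def __post_init__(self) -> None:
        _check_pos("vmax", self.vmax)
        _check_pos("km", self.km)
        _check_pos("k2", self.k2)
        _check_pos("alpha", self.alpha)
        if not (self.r1 >= 0) or not math.isfinite(self.r1):
            raise ValueError(f"r1 must be >= 0 and finite, got {self.r1!r}")
        object.__setattr__(
            self, "net_inhibition", self.r1 == 0.0 or self.k1 >= self.k3
        )

    @property
    def k3(self) -> float:
        """K3 = alpha*K2 (µM), the constant multiplying the S term."""
        return self.alpha * self.k2

    @property
    def k1(self) -> float:
        """Numerator constant K1 (µM); ``inf`` when the term is omitted."""
        return math.inf if self.r1 == 0.0 else 1.0 / self.r1

    @classmethod
    def with_k1(
        cls, vmax: float, km: float, k2: float, alpha: float, k1: float = math.inf
    ) -> "BaseExchangeParams":
        """Construct from K1 directly (``k1=inf`` for the omitted term)."""
        r1 = 0.0 if math.isinf(k1) else 1.0 / _check_pos("k1", k1)
        return cls(vmax=vmax, km=km, k2=k2, alpha=alpha, r1=r1)


@dataclass(frozen=True)
class MixedInhibitionParams:
    """Constants of the standard (linear) mixed noncompetitive model.

    v = vmax*S / [ S*(1 + I/(alpha*Ki)) + Km*(1 + I/Ki) ].

    alpha >> 1 is the competitive limit (only the Km term is scaled),
    alpha = 1 is pure noncompetitive, alpha << 1 uncompetitive.
    """

    vmax: float
    km: float
    ki: float
    alpha: float

    def __post_init__(self) -> None:
        _check_pos("vmax", self.vmax)
        _check_pos("km", self.km)
        _check_pos("ki", self.ki)
        _check_pos("alpha", self.alpha)


@dataclass(frozen=True)
class Ic50Params:
    """One-site dose-response parameters: v_i = v0 / (1 + I/ic50)."""

    v0: float
    ic50: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        _check_pos("v0", self.v0)
        _check_pos("ic50", self.ic50)
        _check_pos("hill", self.hill)


def rate_base_exchange(p: BaseExchangeParams, point: ConcentrationPoint) -> float:
    """Velocity (µM/min) of the hyperbolic mixed base-exchange model.

    The point must have ``isonam == 0``; this model carries no isoNAM term
    (see :func:`rate_base_exchange_with_competitor`).
    """
    if point.isonam != 0.0:
        raise ValueError(
            "rate_base_exchange has no isoNAM term; use "
            "rate_base_exchange_with_competitor for isonam > 0"
        )
    s, i = point.nad, point.nam
    num = p.vmax * s * (1.0 + i * p.r1)
    den = s * (1.0 + i / p.k3) + p.km * (1.0 + i / p.k2)
    return num / den


def rate_base_exchange_with_competitor(
    p: BaseExchangeParams, ki_competitor: float, point: ConcentrationPoint
) -> float:
    """Base-exchange model extended with an inert, dead-end competitor.

    isoNAM binds the C pocket in competition with NAD+ but cannot drive the
    reverse (base-exchange) reaction, so it enters only the Km term:

        v = vmax*S*(1 + I/K1) /
            [ S*(1 + I/K3) + Km*(1 + I/K2 + C/Ki_c) ],   C = [isoNAM].

    Reduces exactly to :func:`rate_base_exchange` at C = 0; raising the
    apparent Km it derepresses NAM inhibition (the fraction inhibited by a
    fixed [NAM] falls as C grows).
    """
    _check_pos("ki_competitor", ki_competitor)
    s, i, c = point.nad, point.nam, point.isonam
    num = p.vmax * s * (1.0 + i * p.r1)
    den = s * (1.0 + i / p.k3) + p.km * (1.0 + i / p.k2 + c / ki_competitor)
    return num / den


def rate_mixed(p: MixedInhibitionParams, substrate: float, inhibitor: float) -> float:
    """Velocity (µM/min) of the standard mixed noncompetitive model."""
    s = _check_conc("substrate", substrate)
    i = _check_conc("inhibitor", inhibitor)
    den = s * (1.0 + i / (p.alpha * p.ki)) + p.km * (1.0 + i / p.ki)
    return p.vmax * s / den


def rate_michaelis(vmax: float, km: float, substrate: float) -> float:
    """Michaelis-Menten velocity vmax*S/(S+Km), µM/min."""
    _check_pos("vmax", vmax)
    _check_pos("km", km)
    s = _check_conc("substrate", substrate)
    return vmax * s / (s + km)


def ic50_response(p: Ic50Params, inhibitor: float) -> float:
    """One-site dose-response velocity v0/(1 + (I/IC50)^h), h = 1 by default.

    The Hill exponent is exposed for completeness but the package-wide
    default is the plain one-site curve (h = 1), under which
    ``ic50_response(p, p.ic50) == p.v0/2`` exactly.
    """
    i = _check_conc("inhibitor", inhibitor)
    if p.hill == 1.0:
        return p.v0 / (1.0 + i / p.ic50)
    return p.v0 / (1.0 + (i / p.ic50) ** p.hill)
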