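"""Mechanistic diagnostics computed from fitted rate-law parameters.

These are the quantities a kineticist reads off the fitted constants:
double-reciprocal (Lineweaver-Burk) line geometry and the common
intersection point that classifies the inhibition modality, Dixon-plot
slopes, the model-implied IC50 at a given substrate level, percent
inhibition (with optional derepression by an inert competitor), the
operational base-exchange constant and its upper bound, and the Kd -> ΔG
thermodynamic conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .models import (
    BaseExchangeParams,
    ConcentrationPoint,
    rate_base_exchange,
    rate_base_exchange_with_competitor,
)

__all__ = [
    "LineSpec",
    "ThermoContext",
    "lineweaver_burk_lines",
    "intersection_point",
    "dixon_slope",
    "percent_inhibition",
    "ic50_from_model",
    "kd_to_delta_g",
    "kex_upper_bound",
]

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.9872e-3


@dataclass(frozen=True)
class LineSpec:
    """One double-reciprocal line 1/v = intercept + slope * (1/S).

    intercept in min/µM, slope in min, labelled by its inhibitor level (µM).
    """

    intercept: float
    slope: float
    label: float

    def y_at(self, inv_s: float) -> float:
        return self.intercept + self.slope * inv_s


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic conventions for Kd -> ΔG conversion.

    Defaults: 310.15 K (assays at 37 °C), 1 M standard state.
    """

    temperature_K: float = 310.15
    r_kcal: float = R_KCAL
    standard_state_M: float = 1.0

    def __post_init__(self) -> None:
        if not (self.temperature_K > 0):
            raise ValueError("temperature must be positive")
        if self.standard_state_M != 1.0:
            raise ValueError("standard state is fixed at 1 M")


def lineweaver_burk_lines(
    p: BaseExchangeParams, nam_levels: list[float]
) -> list[LineSpec]:
    """Double-reciprocal lines of the base-exchange model at each [NAM].

    Exact for K1 = ∞, where 1/v is affine in 1/S:
    intercept = (1 + I/K3)/vmax, slope = Km (1 + I/K2)/vmax.
    """
    if p.r1 != 0.0 and not p.net_inhibition:
        raise ValueError("K1 < K3: line geometry undefined for net activation")
    return [
        LineSpec(
            intercept=(1.0 + i / p.k3) / p.vmax,
            slope=p.km * (1.0 + i / p.k2) / p.vmax,
            label=float(i),
        )
        for i in nam_levels
    ]


def intersection_point(p: BaseExchangeParams) -> tuple[float, float, str]:
    """Common intersection of the double-reciprocal lines (K1 = ∞ case).

    Every pair of lines meets at x = -1/(alpha Km), y = (1/vmax)(1 - 1/alpha).
    Returns (x, y, modality), where modality names the limiting signature:
    alpha = 1 puts the point on the x-axis at -1/Km (noncompetitive, the
    SIRT1 picture); alpha -> ∞ pushes it to the y-axis at 1/vmax
    (competitive); intermediate alpha > 1 is mixed with competitive
    character (the SIRT3 picture).
    """
    if p.alpha <= 0:
        raise ValueError("alpha must be positive")
    x = -1.0 / (p.alpha * p.km)
    y = (1.0 - 1.0 / p.alpha) / p.vmax
    if p.alpha == 1.0:
        return (x, 0.0, "noncompetitive")
    return (x, y, "mixed (competitive character)" if p.alpha > 1 else
            "mixed (uncompetitive character)")


def dixon_slope(p: BaseExchangeParams, nad: float) -> float:
    """Slope of the Dixon plot (1/v vs [NAM]) at fixed [NAD+], min·µM⁻².

    Valid in the linear Dixon regime K1 = ∞:
    slope = (1/vmax) (1/K3 + Km/(S K2)); it decreases with S and saturates
    at 1/(vmax K3) — so a more competitive enzyme (larger alpha at fixed
    K2) shows a smaller saturating Dixon slope.
    """
    if not (nad > 0):
        raise ValueError("nad must be positive")
    if p.r1 != 0.0:
        raise ValueError("Dixon slope is defined for the K1 = ∞ (linear) regime")
    return (1.0 / p.k3 + p.km / (nad * p.k2)) / p.vmax


def percent_inhibition(
    p: BaseExchangeParams,
    point: ConcentrationPoint,
    ki_competitor: float | None = None,
    relative_to: str = "uninhibited",
) -> float:
    """Percent inhibition at a point, 100 * (1 - v / v_reference).

    ``relative_to`` selects the reference rate:

    - ``"uninhibited"`` (default): v(S, 0, 0), no NAM and no competitor —
      total inhibition by everything present at the point.
    - ``"matched_isonam"``: v(S, 0, C), no NAM but the point's isoNAM —
      the NAM-specific inhibition measured in a derepression series. This
      is the quantity that *falls* as the inert competitor is raised: the
      competitor crowds NAM's contribution out of the apparent Km while
      being unable to drive base exchange.

    ``ki_competitor`` is required whenever the point carries isoNAM.
    """
    if point.isonam > 0 and ki_competitor is None:
        raise ValueError("ki_competitor required when isonam > 0")
    if relative_to == "uninhibited":
        ref_point = ConcentrationPoint(point.nad, 0.0, 0.0)
    elif relative_to == "matched_isonam":
        ref_point = ConcentrationPoint(point.nad, 0.0, point.isonam)
    else:
        raise ValueError(f"unknown reference {relative_to!r}")
    if ki_competitor is not None:
        v0 = rate_base_exchange_with_competitor(p, ki_competitor, ref_point)
        v = rate_base_exchange_with_competitor(p, ki_competitor, point)
    else:
        v0 = rate_base_exchange(p, ref_point)
        v = rate_base_exchange(p, point)
    if v0 <= 0:
        raise ValueError("reference rate is zero (no substrate?)")
    return 100.0 * (1.0 - v / v0)


def ic50_from_model(p: BaseExchangeParams, nad: float) -> float:
    """[NAM] giving 50% inhibition at the stated [NAD+], µM.

    Closed form for K1 = ∞: IC50 = (S + Km)/(S/K3 + Km/K2), which runs
    from K2 at S -> 0 to K3 at S -> ∞. For finite K1 the root of
    v(I) = v(0)/2 is found numerically; a model whose maximal inhibition
    falls short of 50% (K1 < 2 K3 at saturating S and I) has no IC50.
    """
    if not (nad > 0):
        raise ValueError("nad must be positive")
    if p.r1 == 0.0:
        return (nad + p.km) / (nad / p.k3 + p.km / p.k2)

    v0 = rate_base_exchange(p, ConcentrationPoint(nad, 0.0))

    def f(i: float) -> float:
        return rate_base_exchange(p, ConcentrationPoint(nad, i)) - 0.5 * v0

    hi = max(p.k2, p.k3, p.km, nad)
    for _ in range(60):
        if f(hi) < 0:
            break
        hi *= 4.0
    else:
        raise ValueError("model predicts < 50% maximal inhibition: no IC50")
    return brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12)


def kd_to_delta_g(kd_uM: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Binding free energy ΔG = R T ln(Kd / 1 M) in kcal/mol (Kd in µM)."""
    if not (kd_uM > 0):
        raise ValueError("kd must be positive")
    return ctx.r_kcal * ctx.temperature_K * math.log(kd_uM * 1e-6 / ctx.standard_state_M)


def kex_upper_bound(k1_bound_uM: float, p: BaseExchangeParams) -> float:
    """Upper bound on the base-exchange constant from a bound on K1.

    Uses the chain Kd,NAM <= Kd,competitor ≈ Ki,competitor together with
    K1 ≈ Kd,NAM (slow-catalysis approximation), giving
    Kex <= k1_bound/K3 - 1. Raises if the bound is below K3 (a bound at
    exactly K3 returns 0: no exchange).
    """
    if not (k1_bound_uM >= p.k3):
        raise ValueError("K1 bound must exceed K3 for a meaningful Kex bound")
    return k1_bound_uM / p.k3 - 1.0
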