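"""Synthetic assay-data generator.

Emulates the fluorometric initial-rate assays: velocities on the study's
concentration designs with multiplicative Gaussian noise (constant
coefficient of variation, the usual behaviour of plate-reader initial
rates), truncated at zero. A zero-CV design returns rates exactly on the
model surface, which is how the round-trip identifiability checks and the
acceptance analyses generate their inputs.

Built-in designs (concentrations in µM unless noted):

========================  ====================================================
name                      grid
========================  ====================================================
sirt3_nam                 NAD+ {100, 375, 750, 1500, 3000} x NAM {0, 25, 100, 200}
sirt1_nam                 NAD+ {50, 125, 750, 1500} x NAM {0, 50, 100}
sirt3_isonam              NAD+ {100, 375, 750, 1500, 3000} x isoNAM {0, 2.5, 10, 40} mM
sirt3_derepression        NAD+ 500, NAM 100, isoNAM {0, 50, 500, 700, 900}
ic50_nam                  NAM {0, 1, 5, 10, 50, 100, 200, 500} at NAD+ 100
ic50_isonam               isoNAM {0, 0.05, 0.1, 1, 5, 10} mM at NAD+ 100
========================  ====================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import RATE_COLUMNS, KineticDataset
from .models import (
    BaseExchangeParams,
    ConcentrationPoint,
    Ic50Params,
    MixedInhibitionParams,
    ic50_response,
    rate_base_exchange,
    rate_base_exchange_with_competitor,
    rate_michaelis,
    rate_mixed,
)

__all__ = ["AssayDesign", "builtin_design", "generate_rates", "generate_ic50_curve",
           "DESIGNS"]

#: default multiplicative noise level (coefficient of variation) for
#: simulated assays; chosen as typical fluorometric plate-reader precision.
DEFAULT_CV = 0.05


@dataclass(frozen=True)
class AssayDesign:
    """A concentration grid plus the replication/noise plan."""

    name: str
    nad_levels: tuple[float, ...]
    nam_levels: tuple[float, ...] = (0.0,)
    isonam_levels: tuple[float, ...] = (0.0,)
    replicates: int = 1
    cv: float = DEFAULT_CV
    additive_floor: float = 0.0  # µM/min, optional noise floor
    seed: int = 0
    enzyme: str = ""

    def __post_init__(self) -> None:
        for attr in ("nad_levels", "nam_levels", "isonam_levels"):
            levels = tuple(float(x) for x in getattr(self, attr))
            if any(x < 0 or not math.isfinite(x) for x in levels):
                raise ValueError(f"{attr} must be finite and non-negative")
            if sorted(set(levels)) != list(levels):
                raise ValueError(f"{attr} must be sorted and distinct")
            object.__setattr__(self, attr, levels)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.cv < 0 or self.additive_floor < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def n_cells(self) -> int:
        return len(self.nad_levels) * len(self.nam_levels) * len(self.isonam_levels)

    def grid(self) -> list[ConcentrationPoint]:
        return [
            ConcentrationPoint(s, i, c)
            for s in self.nad_levels
            for i in self.nam_levels
            for c in self.isonam_levels
        ]

    def with_noise(self, cv: float, replicates: int, seed: int) -> "AssayDesign":
        return AssayDesign(
            self.name, self.nad_levels, self.nam_levels, self.isonam_levels,
            replicates=replicates, cv=cv, additive_floor=self.additive_floor,
            seed=seed, enzyme=self.enzyme,
        )


DESIGNS: dict[str, AssayDesign] = {
    "sirt3_nam": AssayDesign(
        "sirt3_nam", (100, 375, 750, 1500, 3000), (0, 25, 100, 200),
        enzyme="SIRT3",
    ),
    "sirt1_nam": AssayDesign(
        "sirt1_nam", (50, 125, 750, 1500), (0, 50, 100), enzyme="SIRT1"
    ),
    "sirt3_isonam": AssayDesign(
        "sirt3_isonam", (100, 375, 750, 1500, 3000),
        isonam_levels=(0, 2500, 10000, 40000), enzyme="SIRT3",
    ),
    "sirt3_derepression": AssayDesign(
        "sirt3_derepression", (500,), (100,), (0, 50, 500, 700, 900),
        enzyme="SIRT3",
    ),
    "ic50_nam": AssayDesign(
        "ic50_nam", (100,), (0, 1, 5, 10, 50, 100, 200, 500), enzyme="SIRT3"
    ),
    "ic50_isonam": AssayDesign(
        "ic50_isonam", (100,), isonam_levels=(0, 50, 100, 1000, 5000, 10000),
        enzyme="SIRT3",
    ),
}


def builtin_design(name: str) -> AssayDesign:
    """Return one of the study's concentration grids by name."""
    try:
        return DESIGNS[name]
    except KeyError:
        raise ValueError(
            f"unknown design {name!r}; available: {sorted(DESIGNS)}"
        ) from None


def _model_velocity(params, point: ConcentrationPoint,
                    ki_competitor: float | None) -> float:
    if isinstance(params, BaseExchangeParams):
        if point.isonam > 0:
            if ki_competitor is None:
                raise ValueError("ki_competitor required for isonam > 0")
            return rate_base_exchange_with_competitor(params, ki_competitor, point)
        return rate_base_exchange(params, point)
    if isinstance(params, MixedInhibitionParams):
        inhib = point.isonam if point.isonam > 0 else point.nam
        return rate_mixed(params, point.nad, inhib)
    if isinstance(params, tuple) and len(params) == 2:  # (vmax, km)
        return rate_michaelis(params[0], params[1], point.nad)
    raise TypeError(f"unsupported parameter object {type(params).__name__}")


def _apply_noise(v: np.ndarray, design: AssayDesign, rng: np.random.Generator
                 ) -> np.ndarray:
    if design.cv == 0 and design.additive_floor == 0:
        return v
    noisy = v * (1.0 + design.cv * rng.standard_normal(v.shape))
    if design.additive_floor > 0:
        noisy = noisy + design.additive_floor * rng.standard_normal(v.shape)
    return np.clip(noisy, 0.0, None)


def generate_rates(
    params,
    design: AssayDesign,
    ki_competitor: float | None = None,
    enzyme: str | None = None,
) -> KineticDataset:
    """Simulate an initial-rate table on a design.

    ``params`` is a BaseExchangeParams, MixedInhibitionParams, or a
    (vmax, km) tuple for plain Michaelis-Menten. Observed rates are
    v_model * (1 + eps), eps ~ N(0, cv^2), truncated at zero; the draw is
    a single seeded stream, so a given (design, seed) is fully
    reproducible and cv = 0 returns the exact model surface.
    """
    rng = np.random.default_rng(design.seed)
    enzyme = enzyme if enzyme is not None else design.enzyme
    rows = []
    truth = np.array(
        [_model_velocity(params, pt, ki_competitor) for pt in design.grid()]
    )
    for rep in range(1, design.replicates + 1):
        v_obs = _apply_noise(truth, design, rng)
        for pt, v in zip(design.grid(), v_obs):
            rows.append((enzyme, pt.nad, pt.nam, pt.isonam, v, rep))
    df = pd.DataFrame(rows, columns=RATE_COLUMNS)
    return KineticDataset(
        df, enzyme=enzyme,
        provenance=f"synthetic:{design.name}:seed={design.seed}:cv={design.cv}",
    )


def generate_ic50_curve(p: Ic50Params, design: AssayDesign) -> pd.DataFrame:
    """Simulate a dose-response curve (inhibitor_uM, v_uM_per_min).

    The varied inhibitor is whichever of the design's NAM / isoNAM axes has
    more than one level.
    """
    if len(design.nam_levels) > 1 and len(design.isonam_levels) > 1:
        raise ValueError("dose-response design must vary a single inhibitor")
    levels = (
        design.nam_levels if len(design.nam_levels) > 1 else design.isonam_levels
    )
    rng = np.random.default_rng(design.seed)
    truth = np.array([ic50_response(p, i) for i in levels])
    rows = []
    for _ in range(design.replicates):
        v_obs = _apply_noise(truth, design, rng)
        rows.extend(zip(levels, v_obs))
    return pd.DataFrame(rows, columns=["inhibitor_uM", "v_uM_per_min"])
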