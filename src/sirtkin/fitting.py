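"""Global nonlinear least-squares fitting of the initial-rate models.

"Global" means one shared parameter set is fit jointly to every point of a
velocity grid (all substrate x inhibitor combinations at once), minimizing
the unweighted sum of squared velocity residuals — the convention of the
standard curve-fitting packages for this kind of plate-reader data.
Positivity is enforced by optimizing log10-parameters; alpha is boxed to
log10(alpha) in [-3, 20] so that an effectively competitive fit (alpha of
order 1e19) remains representable. Each fit runs a deterministic
multi-start: an algebraic linear-least-squares initializer (the rate law
times its denominator is linear in a reparameterized unknown vector) plus
Latin-hypercube starts over data-driven ranges; the best sum of squares
wins, ties broken by start index.

Standard errors come from the Gauss-Newton covariance
SSR/(n-p) * (J'J)^-1 propagated from the log scale to the natural scale.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .models import (
    BaseExchangeParams,
    Ic50Params,
    MixedInhibitionParams,
)

__all__ = [
    "KineticDataset",
    "FitResult",
    "fit_base_exchange",
    "fit_mixed",
    "fit_michaelis",
    "fit_ic50",
    "compare_models",
]

RATE_COLUMNS = ["enzyme", "nad_uM", "nam_uM", "isonam_uM", "v_uM_per_min", "replicate"]

LOG_ALPHA_BOUNDS = (-3.0, 20.0)
N_STARTS = 8


@dataclass
class KineticDataset:
    """Initial rates on a concentration grid.

    ``data`` is a tidy frame with columns enzyme, nad_uM, nam_uM,
    isonam_uM, v_uM_per_min, replicate (units in the names); metadata
    carries enzyme label, assay temperature and a provenance tag.
    """

    data: pd.DataFrame
    enzyme: str = ""
    temperature_K: float = 310.15
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in RATE_COLUMNS if c not in self.data.columns]
        if "isonam_uM" in missing:  # optional column, implied zero
            self.data = self.data.assign(isonam_uM=0.0)
            missing.remove("isonam_uM")
        if missing:
            raise ValueError(f"rate table missing columns: {missing}")
        if (self.data["v_uM_per_min"] < 0).any():
            raise ValueError("velocities must be non-negative")
        for c in ("nad_uM", "nam_uM", "isonam_uM"):
            if (self.data[c] < 0).any() or not np.isfinite(self.data[c]).all():
                raise ValueError(f"{c} must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def nad(self) -> np.ndarray:
        return self.data["nad_uM"].to_numpy(float)

    @property
    def nam(self) -> np.ndarray:
        return self.data["nam_uM"].to_numpy(float)

    @property
    def isonam(self) -> np.ndarray:
        return self.data["isonam_uM"].to_numpy(float)

    @property
    def v(self) -> np.ndarray:
        return self.data["v_uM_per_min"].to_numpy(float)

    def averaged(self) -> "KineticDataset":
        """Replicate-averaged copy (mean velocity per concentration cell)."""
        g = (
            self.data.groupby(["enzyme", "nad_uM", "nam_uM", "isonam_uM"], as_index=False)[
                "v_uM_per_min"
            ]
            .mean()
            .assign(replicate=0)
        )
        return KineticDataset(
            g[RATE_COLUMNS], self.enzyme, self.temperature_K, self.provenance
        )

    def fingerprint(self) -> str:
        """Order-independent digest of the numeric content (for comparisons)."""
        arr = np.column_stack([self.nad, self.nam, self.isonam, self.v])
        arr = arr[np.lexsort(arr.T[::-1])]
        return hashlib.sha256(np.round(arr, 9).tobytes()).hexdigest()[:16]


@dataclass
class FitResult:
    """Estimates, uncertainties and goodness-of-fit for one model fit."""

    model: str
    estimates: dict[str, float]
    stderr: dict[str, float]
    ssr: float
    n: int
    n_params: int
    aicc: float
    success: bool
    message: str = ""
    flags: list[str] = field(default_factory=list)
    residuals: np.ndarray | None = None
    data_fingerprint: str = ""

    def params_base_exchange(self) -> BaseExchangeParams:
        e = self.estimates
        k1 = e.get("k1", math.inf)
        return BaseExchangeParams.with_k1(e["vmax"], e["km"], e["k2"], e["alpha"], k1)

    def params_mixed(self) -> MixedInhibitionParams:
        e = self.estimates
        return MixedInhibitionParams(e["vmax"], e["km"], e["ki"], e["alpha"])

    def params_ic50(self) -> Ic50Params:
        return Ic50Params(self.estimates["v0"], self.estimates["ic50"])

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": self.model,
            "estimates": self.estimates,
            "stderr": self.stderr,
            "ssr": self.ssr,
            "n": self.n,
            "n_params": self.n_params,
            "aicc": self.aicc,
            "success": self.success,
            "message": self.message,
            "flags": self.flags,
            "data_fingerprint": self.data_fingerprint,
        }

    def summary(self) -> str:
        lines = [f"model: {self.model}   n={self.n}  SSR={self.ssr:.6g}  AICc={self.aicc:.4g}"]
        for k, v in self.estimates.items():
            se = self.stderr.get(k, float("nan"))
            lines.append(f"  {k:>8s} = {v:.6g}  (se {se:.3g})")
        for fl in self.flags:
            lines.append(f"  flag: {fl}")
        return "\n".join(lines)


def _aicc(ssr: float, n: int, p: int) -> float:
    k = p + 1  # + residual variance
    if n - k - 1 <= 0:
        return math.inf
    if ssr <= 0:
        ssr = np.finfo(float).tiny
    return n * math.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _multistart(
    resid: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    n_starts: int = N_STARTS,
    seed: int = 0,
):
    """Run least_squares from the supplied start plus LHS starts; best SSR wins."""
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    extra = qmc.scale(sampler.random(n_starts), lo, hi)
    starts = [np.clip(theta0, lo, hi)] + list(extra)
    best = None
    for idx, t0 in enumerate(starts):
        try:
            sol = least_squares(
                resid, t0, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000,
            )
        except Exception:
            continue
        ssr = float(sol.cost * 2)
        if best is None or ssr < best[0] * (1 - 1e-12):
            best = (ssr, idx, sol)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best[2]


def _wald(sol, n: int, names: Sequence[str], values: np.ndarray) -> dict[str, float]:
    """Gauss-Newton SEs on the natural scale from a log10-parameter fit."""
    p = len(names)
    ssr = float(sol.cost * 2)
    if n <= p:
        return {k: math.nan for k in names}
    jac = sol.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * ssr / (n - p)
        se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_log = np.full(p, np.nan)
    return {
        k: float(v * math.log(10) * s) for k, v, s in zip(names, values, se_log)
    }


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------- base exchange


def _linear_init_base_exchange(
    s: np.ndarray, i: np.ndarray, v: np.ndarray, with_k1: bool
) -> np.ndarray | None:
    """Algebraic start: v*denominator = numerator is linear in
    (vmax, vmax/K1, 1/K3, Km, Km/K2)."""
    cols = [s, -v * s * i, -v, -v * i]
    if with_k1:
        cols.insert(1, s * i)
    amat = np.column_stack(cols)
    try:
        coef, *_ = np.linalg.lstsq(amat, v * s, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if with_k1:
        vmax, w1, u3, km, q2 = coef
    else:
        vmax, u3, km, q2 = coef
        w1 = 0.0
    if not (vmax > 0 and u3 > 0 and km > 0 and q2 > 0):
        return None
    k3, k2 = 1.0 / u3, km / q2
    theta = [math.log10(vmax), math.log10(km), math.log10(k2), math.log10(k3 / k2)]
    if with_k1:
        r1 = w1 / vmax
        theta.append(math.log10(r1) if r1 > 0 else -20.0)
    return np.array(theta)


def _weight_vector(v: np.ndarray, weighting: str) -> np.ndarray:
    """Residual weights: 'none' (unweighted, the default convention) or
    'relative' (1/v, the MLE-matched choice under constant-CV noise)."""
    if weighting == "none":
        return np.ones_like(v)
    if weighting == "relative":
        return 1.0 / np.clip(v, 1e-6 * max(v.max(), 1e-300), None)
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_base_exchange(
    data: KineticDataset,
    fix_k1_infinite: bool = True,
    seed: int = 0,
    k1_profile_factor: float = 100.0,
    weighting: str = "none",
) -> FitResult:
    """Global fit of the hyperbolic mixed base-exchange model.

    Estimates vmax, Km, K2, alpha and, unless ``fix_k1_infinite``, K1.
    When K1 is fitted, its estimability is checked by a profile test: the
    model is refit with K1 pinned at ``k1_profile_factor`` times the largest
    tested [NAM]; if the fit is not appreciably worse, the data carry no
    information on K1, the term is omitted (K1 = ∞, the usual outcome for
    SIRT3 and SIRT1 data) and the K1-free fit is returned with a flag.
    """
    _require(np.all(data.isonam == 0), "base-exchange fit requires isonam = 0")
    s, i, v = data.nad, data.nam, data.v
    _require(len(np.unique(s)) >= 2, "need >= 2 distinct NAD+ levels")
    _require(len(np.unique(i)) >= 2, "need >= 2 distinct NAM levels")
    npar = 4 if fix_k1_infinite else 5
    _require(len(v) >= npar + 2, "too few points for a global fit")
    w = _weight_vector(v, weighting)

    def make_resid(with_k1: bool):
        def resid(theta: np.ndarray) -> np.ndarray:
            vmax, km, k2, alpha = 10.0 ** theta[:4]
            r1 = 10.0 ** theta[4] if with_k1 else 0.0
            k3 = alpha * k2
            den = s * (1.0 + i / k3) + km * (1.0 + i / k2)
            return (vmax * s * (1.0 + i * r1) / den - v) * w
        return resid

    vscale = max(v.max(), 1e-12)
    smed = np.median(s[s > 0])
    imax = max(i.max(), 1.0)
    lo = np.array([math.log10(vscale) - 3, math.log10(smed) - 3,
                   math.log10(imax) - 4, LOG_ALPHA_BOUNDS[0]])
    hi = np.array([math.log10(vscale) + 3, math.log10(smed) + 3,
                   math.log10(imax) + 4, LOG_ALPHA_BOUNDS[1]])

    def run(with_k1: bool):
        lo_, hi_ = lo, hi
        if with_k1:
            lo_ = np.append(lo, -math.log10(imax) - 8)
            hi_ = np.append(hi, -math.log10(imax) + 4)
        theta0 = _linear_init_base_exchange(s, i, v, with_k1)
        if theta0 is None:
            theta0 = (lo_ + hi_) / 2
        return _multistart(make_resid(with_k1), theta0, lo_, hi_, seed=seed), with_k1

    flags: list[str] = []
    if fix_k1_infinite:
        sol, with_k1 = run(False)
    else:
        sol, with_k1 = run(True)
        # profile test for K1 estimability at k1 = factor * max tested [NAM]
        ssr_free = float(sol.cost * 2)
        r1_pin = 1.0 / (k1_profile_factor * imax)
        resid4 = make_resid(False)

        def resid_pinned(theta: np.ndarray) -> np.ndarray:
            vmax, km, k2, alpha = 10.0 ** theta[:4]
            k3 = alpha * k2
            den = s * (1.0 + i / k3) + km * (1.0 + i / k2)
            return (vmax * s * (1.0 + i * r1_pin) / den - v) * w

        sol_pin = _multistart(resid_pinned, sol.x[:4], lo, hi, seed=seed)
        ssr_pin = float(sol_pin.cost * 2)
        n = len(v)
        k1_hat = 10.0 ** (-sol.x[4])
        # K1 is dropped when its point estimate lies beyond the
        # identifiability bound, or when the profile-likelihood check shows
        # that pinning K1 far beyond the design barely changes the SSR
        if (
            k1_hat > k1_profile_factor * imax
            or ssr_free <= 0
            or (ssr_pin - ssr_free) / max(ssr_free, 1e-300)
            < 3.84 / max(n - 5, 1)
        ):
            flags.append(
                "k1 not estimable from this design; [NAM]/K1 term omitted"
            )
            sol = _multistart(resid4, sol.x[:4], lo, hi, seed=seed)
            with_k1 = False

    vmax, km, k2, alpha = 10.0 ** sol.x[:4]
    names = ["vmax", "km", "k2", "alpha"]
    values = np.array([vmax, km, k2, alpha])
    est = dict(zip(names, values))
    if with_k1:
        k1 = 10.0 ** (-sol.x[4])
        names = names + ["k1"]
        values = np.append(values, k1)
        est["k1"] = k1
        if k1 < alpha * k2:
            flags.append("fitted K1 < K3: model predicts net activation by NAM")
    est["k3"] = est["alpha"] * est["k2"]
    se = _wald(sol, len(v), names, values)
    ssr = float(sol.cost * 2)
    if math.isclose(alpha, 10.0 ** LOG_ALPHA_BOUNDS[1], rel_tol=0.01):
        flags.append("competitive limit reached (alpha at upper bound)")
    return FitResult(
        model="base_exchange",
        estimates=est,
        stderr=se,
        ssr=ssr,
        n=len(v),
        n_params=len(names),
        aicc=_aicc(ssr, len(v), len(names)),
        success=bool(sol.status > 0),
        message=sol.message,
        flags=flags,
        residuals=sol.fun,
        data_fingerprint=data.fingerprint(),
    )


# ------------------------------------------------------------------- mixed


def fit_mixed(
    data: KineticDataset,
    competitive_limit: bool = False,
    inhibitor: str = "auto",
    seed: int = 0,
    weighting: str = "none",
) -> FitResult:
    """Global fit of the standard mixed noncompetitive model.

    ``inhibitor`` selects the varied inhibitor column ("nam", "isonam", or
    "auto" to pick whichever is nonzero). With ``competitive_limit`` the
    alpha term is removed (pure competitive form) and alpha is reported as
    infinite.
    """
    if inhibitor == "auto":
        inhibitor = "isonam" if np.any(data.isonam > 0) else "nam"
    i = {"nam": data.nam, "isonam": data.isonam}[inhibitor]
    s, v = data.nad, data.v
    _require(len(np.unique(s)) >= 2, "need >= 2 distinct substrate levels")
    _require(
        len(np.unique(i)) >= 2,
        "inhibition constant unidentifiable: need >= 2 inhibitor levels",
    )
    npar = 3 if competitive_limit else 4
    _require(len(v) >= npar + 2, "too few points for a global fit")
    w = _weight_vector(v, weighting)

    def resid(theta: np.ndarray) -> np.ndarray:
        if competitive_limit:
            vmax, km, ki = 10.0 ** theta
            den = s + km * (1.0 + i / ki)
        else:
            vmax, km, ki = 10.0 ** theta[:3]
            alpha = 10.0 ** theta[3]
            den = s * (1.0 + i / (alpha * ki)) + km * (1.0 + i / ki)
        return (vmax * s / den - v) * w

    vscale = max(v.max(), 1e-12)
    smed = np.median(s[s > 0])
    imax = max(i.max(), 1.0)
    lo = [math.log10(vscale) - 3, math.log10(smed) - 3, math.log10(imax) - 4]
    hi = [math.log10(vscale) + 3, math.log10(smed) + 3, math.log10(imax) + 4]
    if not competitive_limit:
        lo.append(LOG_ALPHA_BOUNDS[0])
        hi.append(LOG_ALPHA_BOUNDS[1])
    lo, hi = np.array(lo), np.array(hi)

    # linear start: vmax*S - km*v - (km/ki)*v*i - u*v*s*i = v*s,  u = 1/(alpha*ki)
    cols = [s, -v, -v * i] + ([] if competitive_limit else [-v * s * i])
    try:
        coef, *_ = np.linalg.lstsq(np.column_stack(cols), v * s, rcond=None)
    except np.linalg.LinAlgError:
        coef = None
    theta0 = (lo + hi) / 2
    if coef is not None and coef[0] > 0 and coef[1] > 0 and coef[2] > 0:
        vmax0, km0, q = coef[0], coef[1], coef[2]
        ki0 = km0 / q
        t = [math.log10(vmax0), math.log10(km0), math.log10(ki0)]
        if not competitive_limit:
            u = coef[3]
            alpha0 = 1.0 / (u * ki0) if u > 0 else 10.0 ** LOG_ALPHA_BOUNDS[1]
            t.append(math.log10(max(alpha0, 1e-3)))
        theta0 = np.array(t)

    sol = _multistart(resid, theta0, lo, hi, seed=seed)
    flags: list[str] = []
    if competitive_limit:
        vmax, km, ki = 10.0 ** sol.x
        alpha = math.inf
        names, values = ["vmax", "km", "ki"], np.array([vmax, km, ki])
        flags.append("alpha pinned to competitive limit")
    else:
        vmax, km, ki, alpha = 10.0 ** sol.x
        names = ["vmax", "km", "ki", "alpha"]
        values = np.array([vmax, km, ki, alpha])
        # alpha only enters through I/(alpha*Ki); once that term is
        # negligible over the whole design the fit is in the competitive
        # limit and alpha has no finite estimate
        if i.max() / (alpha * ki) < 1e-6:
            flags.append("competitive limit reached (alpha not identifiable)")
    est = dict(zip(names, values))
    est["alpha"] = float(alpha)
    se = _wald(sol, len(v), names, values)
    ssr = float(sol.cost * 2)
    return FitResult(
        model="mixed_competitive" if competitive_limit else "mixed",
        estimates=est,
        stderr=se,
        ssr=ssr,
        n=len(v),
        n_params=len(names),
        aicc=_aicc(ssr, len(v), len(names)),
        success=bool(sol.status > 0),
        message=sol.message,
        flags=flags,
        residuals=sol.fun,
        data_fingerprint=data.fingerprint(),
    )


# --------------------------------------------------------------- michaelis


def fit_michaelis(
    data: KineticDataset, seed: int = 0, weighting: str = "none"
) -> FitResult:
    """Fit vmax and Km of the Michaelis-Menten equation to v([NAD+])."""
    s, v = data.nad, data.v
    _require(len(np.unique(s)) >= 3, "need >= 3 distinct substrate levels")
    w = _weight_vector(v, weighting)

    def resid(theta: np.ndarray) -> np.ndarray:
        vmax, km = 10.0 ** theta
        return (vmax * s / (s + km) - v) * w

    vscale = max(v.max(), 1e-12)
    smed = np.median(s[s > 0])
    lo = np.array([math.log10(vscale) - 3, math.log10(smed) - 3])
    hi = np.array([math.log10(vscale) + 3, math.log10(smed) + 3])
    coef, *_ = np.linalg.lstsq(np.column_stack([s, -v]), v * s, rcond=None)
    theta0 = (
        np.log10(coef) if coef[0] > 0 and coef[1] > 0 else (lo + hi) / 2
    )
    sol = _multistart(resid, theta0, lo, hi, seed=seed)
    vmax, km = 10.0 ** sol.x
    flags = []
    if km > s.max() or km < s.min() / 2:
        flags.append("Km outside (or at the edge of) the tested substrate range")
    names, values = ["vmax", "km"], np.array([vmax, km])
    se = _wald(sol, len(v), names, values)
    ssr = float(sol.cost * 2)
    return FitResult(
        model="michaelis",
        estimates=dict(zip(names, values)),
        stderr=se,
        ssr=ssr,
        n=len(v),
        n_params=2,
        aicc=_aicc(ssr, len(v), 2),
        success=bool(sol.status > 0),
        message=sol.message,
        flags=flags,
        residuals=sol.fun,
        data_fingerprint=data.fingerprint(),
    )


# -------------------------------------------------------------------- IC50


def fit_ic50(
    curve: Sequence[tuple[float, float]] | pd.DataFrame,
    seed: int = 0,
    weighting: str = "none",
) -> FitResult:
    """Fit v0 and IC50 of the one-site dose-response model to (I, v) pairs."""
    if isinstance(curve, pd.DataFrame):
        arr = curve.to_numpy(float)
    else:
        arr = np.asarray(list(curve), dtype=float)
    _require(arr.ndim == 2 and arr.shape[1] == 2, "curve must be (inhibitor, v) pairs")
    i, v = arr[:, 0], arr[:, 1]
    _require(len(np.unique(i)) >= 4, "need >= 4 inhibitor concentrations")
    _require(i.min() <= np.sort(np.unique(i))[1] / 4 or i.min() == 0,
             "need an uninhibited (I = 0 or low-I) anchor")
    _require((v >= 0).all(), "velocities must be non-negative")

    w = _weight_vector(v, weighting)

    def resid(theta: np.ndarray) -> np.ndarray:
        v0, ic50 = 10.0 ** theta
        return (v0 / (1.0 + i / ic50) - v) * w

    v0_guess = v[np.argmin(i)]
    flags = []
    if v.min() > 0.5 * v0_guess:
        flags.append("curve does not reach 50% inhibition; IC50 extrapolated")
    if np.ptp(v) < 1e-3 * max(v0_guess, 1e-12):
        raise ValueError("flat curve: no inhibition to fit")
    ipos = i[i > 0]
    lo = np.array([math.log10(max(v0_guess, 1e-12)) - 2, math.log10(ipos.min()) - 3])
    hi = np.array([math.log10(max(v0_guess, 1e-12)) + 2, math.log10(ipos.max()) + 3])
    # anchor start at the interpolated half-velocity crossing
    order = np.argsort(i)
    icross = float(np.interp(0.5 * v0_guess, v[order][::-1], i[order][::-1]))
    if not (icross > 0 and math.isfinite(icross)):
        icross = float(np.median(ipos))
    theta0 = np.array([math.log10(max(v0_guess, 1e-12)), math.log10(icross)])
    sol = _multistart(resid, theta0, lo, hi, seed=seed)
    v0, ic50 = 10.0 ** sol.x
    names, values = ["v0", "ic50"], np.array([v0, ic50])
    se = _wald(sol, len(v), names, values)
    ssr = float(sol.cost * 2)
    return FitResult(
        model="ic50",
        estimates=dict(zip(names, values)),
        stderr=se,
        ssr=ssr,
        n=len(v),
        n_params=2,
        aicc=_aicc(ssr, len(v), 2),
        success=bool(sol.status > 0),
        message=sol.message,
        flags=flags,
        residuals=sol.fun,
    )


# --------------------------------------------------------- model comparison


def compare_models(results: Sequence[FitResult]) -> pd.DataFrame:
    """AICc ranking of fits of the same dataset.

    Returns a frame sorted by AICc (ties broken by parameter count, fewer
    first) with the Δ-AICc column relative to the best model. Raises if the
    fits do not share a data fingerprint.
    """
    if len(results) < 2:
        raise ValueError("need at least two fits to compare")
    fps = {r.data_fingerprint for r in results if r.data_fingerprint}
    if len(fps) > 1:
        raise ValueError("fits were made to different datasets")
    rows = [
        {"model": r.model, "n_params": r.n_params, "ssr": r.ssr, "aicc": r.aicc}
        for r in results
    ]
    df = pd.DataFrame(rows).sort_values(
        ["aicc", "n_params"], kind="mergesort", ignore_index=True
    )
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    df["rank"] = np.arange(1, len(df) + 1)
    return df
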