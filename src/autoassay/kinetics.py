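"""Diprotic pH-dependence model of enzyme activity and its estimation.

The enzyme is treated as a weak diprotic acid: three protonation states
(EH2+, EH, E-) with rapid protonation equilibria both free and with bound
substrate,

    K1E = [H+][EH]/[EH2+],   K2E = [H+][E-]/[EH],
    K1ES = [H+][ESH]/[ESH2+], K2ES = [H+][ES-]/[ESH],

substrate affinity of the neutral form KM = [EH][S]/[ESH], and turnover
from all three substrate-bound states (k2 for ESH, k2' = alpha*k2 for
ESH2+, k2'' = beta*k2 for ES-).  Solving the rapid-equilibrium scheme gives
the rate law

    v(S, pH) = Vmax * S * (1 + alpha*cH/K1ES + beta*K2ES/cH)
               / (KM * fE(cH) + S * fES(cH)),

with proton concentration cH = 10**(-pH) and the Michaelis acidity
functions

    fE  = 1 + cH/K1E  + K2E/cH,
    fES = 1 + cH/K1ES + K2ES/cH.

At fixed pH this is exactly Michaelis-Menten in S with apparent constants
Km_app = KM*fE/fES and Vmax_app = Vmax*(1 + alpha*cH/K1ES + beta*K2ES/cH)/fES,
so per-pH MM fits and the 8-parameter global fit describe the same data.

For alpha = beta = 0 the pH of maximum activity at fixed S has the closed
form  cH_opt = sqrt((KM*K2E + S*K2ES) / (KM/K1E + S/K1ES)).

Units follow enzymology convention: substrate and KM in mM, dissociation
constants and cH in M, activity in mU.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (FitFailureError, InsufficientDataError,
                     InvalidArgumentError, UnsupportedModelError)

__all__ = [
    "DiproticParams",
    "RateObservation",
    "MMParams",
    "FitResult",
    "proton_concentration",
    "acidity_functions",
    "diprotic_rate",
    "apparent_mm",
    "optimum_pH",
    "fit_diprotic",
    "fit_michaelis_menten",
]


@dataclass
class DiproticParams:
    """The eight parameters of the diprotic activity model.

    Vmax [mU], KM [mM], dissociation constants [M], and the turnover-number
    ratios alpha = k2'/k2 (acidic form) and beta = k2''/k2 (basic form).
    """

    Vmax: float
    KM: float
    K1E: float
    K2E: float
    K1ES: float
    K2ES: float
    alpha: float = 0.0
    beta: float = 0.0

    _NAMES = ("Vmax", "KM", "K1E", "K2E", "K1ES", "K2ES", "alpha", "beta")

    def __post_init__(self) -> None:
        for name in ("Vmax", "KM", "K1E", "K2E", "K1ES", "K2ES"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise InvalidArgumentError("alpha and beta must be >= 0")
        if self.K2E >= self.K1E or self.K2ES >= self.K1ES:
            warnings.warn(
                "expected the second deprotonation to be weaker "
                "(K2E < K1E and K2ES < K1ES)", stacklevel=2,
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self._NAMES], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "DiproticParams":
        return cls(*[float(v) for v in a])

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in self._NAMES}


@dataclass
class RateObservation:
    """One measured initial rate: substrate S [mM], pH, rate [mU]."""

    S: float
    pH: float
    rate: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.S < 0:
            raise InvalidArgumentError("S must be >= 0")
        if not 0.0 < self.pH < 14.0:
            raise InvalidArgumentError("pH must lie in (0, 14)")
        if self.weight <= 0:
            raise InvalidArgumentError("weight must be > 0")


@dataclass
class MMParams:
    """Michaelis-Menten constants with asymptotic standard errors."""

    Km: float
    Vmax: float
    Km_se: float
    Vmax_se: float
    identifiable: bool


@dataclass
class FitResult:
    """Best multistart fit: parameters, SSR and convergence bookkeeping."""

    params: DiproticParams
    ssr: float
    n_converged: int
    n_starts: int
    seed: int
    ses: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def proton_concentration(pH) -> float:
    """cH [M] = 10**(-pH)."""
    return 10.0 ** (-np.asarray(pH, dtype=float))


def acidity_functions(p: DiproticParams, cH) -> tuple[np.ndarray, np.ndarray]:
    """Michaelis acidity functions (fE, fES) at proton concentration cH [M]."""
    cH = np.asarray(cH, dtype=float)
    if np.any(cH <= 0):
        raise InvalidArgumentError("cH must be > 0")
    fE = 1.0 + cH / p.K1E + p.K2E / cH
    fES = 1.0 + cH / p.K1ES + p.K2ES / cH
    return fE, fES


def diprotic_rate(p: DiproticParams, S, pH) -> np.ndarray:
    """Initial rate [mU] at substrate S [mM] and the given pH."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise InvalidArgumentError("S must be >= 0")
    cH = proton_concentration(pH)
    fE, fES = acidity_functions(p, cH)
    num = p.Vmax * S * (1.0 + p.alpha * cH / p.K1ES + p.beta * p.K2ES / cH)
    return num / (p.KM * fE + S * fES)


def apparent_mm(p: DiproticParams, pH: float) -> tuple[float, float]:
    """Apparent (Km_app [mM], Vmax_app [mU]) of the fixed-pH MM form."""
    cH = proton_concentration(pH)
    fE, fES = acidity_functions(p, cH)
    km_app = p.KM * fE / fES
    vmax_app = p.Vmax * (1.0 + p.alpha * cH / p.K1ES + p.beta * p.K2ES / cH) / fES
    return float(km_app), float(vmax_app)


def optimum_pH(p: DiproticParams, S: float) -> float:
    """pH of maximum activity at fixed substrate S [mM] (alpha = beta = 0).

    Closed form from d(rate)/d(cH) = 0:
    cH_opt = sqrt((KM*K2E + S*K2ES) / (KM/K1E + S/K1ES)).
    """
    if p.alpha != 0 or p.beta != 0:
        raise UnsupportedModelError(
            "closed-form optimum pH requires alpha = beta = 0"
        )
    if S <= 0:
        raise InvalidArgumentError("S must be > 0")
    ch_opt = np.sqrt((p.KM * p.K2E + S * p.K2ES) / (p.KM / p.K1E + S / p.K1ES))
    return float(-np.log10(ch_opt))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOG_IDX = slice(0, 6)  # Vmax, KM, K1E, K2E, K1ES, K2ES optimized in log space


def _pack(p: np.ndarray) -> np.ndarray:
    x = np.empty(8)
    x[_LOG_IDX] = np.log(p[_LOG_IDX])
    x[6:] = p[6:]
    return x


def _unpack(x: np.ndarray) -> np.ndarray:
    p = np.empty(8)
    p[_LOG_IDX] = np.exp(np.clip(x[_LOG_IDX], -80.0, 80.0))
    p[6:] = x[6:]
    return p


def fit_diprotic(data: Sequence[RateObservation],
                 guess: DiproticParams,
                 n_starts: int = 5000,
                 perturbation_range: tuple[float, float] = (1e-3, 1e3),
                 seed: int = 0,
                 max_nfev: int = 1000) -> FitResult:
    """Multistart weighted nonlinear least squares of the diprotic model.

    The first start is the guess itself; the remaining ``n_starts - 1``
    starts multiply each parameter of the guess by an independent
    log-uniform factor in ``perturbation_range``.  Positive parameters are
    optimized in log space, alpha and beta with a linear >= 0 bound.  Among
    converged starts the fit with the lowest sum of squared residuals is
    returned; it is never worse than the fit started at the guess.
    """
    data = list(data)
    if len(data) < 8:
        raise InsufficientDataError("need at least 8 rate observations")
    S = np.array([o.S for o in data])
    pH = np.array([o.pH for o in data])
    rate = np.array([o.rate for o in data])
    w = np.sqrt(np.array([o.weight for o in data]))
    if len(np.unique(pH)) < 2 or len(np.unique(S)) < 2:
        raise InsufficientDataError(
            "observations must span >= 2 pH values and >= 2 substrate levels"
        )
    if n_starts < 1:
        raise InvalidArgumentError("n_starts must be >= 1")
    lo, hi = perturbation_range
    if not (0 < lo < hi):
        raise InvalidArgumentError("perturbation_range must satisfy 0 < lo < hi")

    cH = proton_concentration(pH)

    def residuals(x: np.ndarray) -> np.ndarray:
        Vmax, KM, K1E, K2E, K1ES, K2ES, alpha, beta = _unpack(x)
        fE = 1.0 + cH / K1E + K2E / cH
        fES = 1.0 + cH / K1ES + K2ES / cH
        num = Vmax * S * (1.0 + alpha * cH / K1ES + beta * K2ES / cH)
        return w * (rate - num / (KM * fE + S * fES))

    lb = np.full(8, -np.inf)
    ub = np.full(8, np.inf)
    lb[6:] = 0.0

    rng = np.random.default_rng(seed)
    factors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_starts, 8)))
    factors[0, :] = 1.0  # start 1 = the unperturbed guess
    g = guess.as_array()

    best_res, best_ssr, n_conv = None, np.inf, 0
    for i in range(n_starts):
        p0 = g * factors[i]
        p0[_LOG_IDX] = np.maximum(p0[_LOG_IDX], 1e-300)
        try:
            res = least_squares(residuals, _pack(p0), bounds=(lb, ub),
                                method="trf", max_nfev=max_nfev)
        except (ValueError, FloatingPointError):
            continue
        if not res.success or not np.isfinite(res.cost):
            continue
        n_conv += 1
        ssr = 2.0 * res.cost
        if ssr < best_ssr:
            best_res, best_ssr = res, ssr
    if best_res is None:
        raise FitFailureError(
            f"none of {n_starts} starts converged",
            diagnostics={"n_starts": n_starts},
        )

    p_hat = _unpack(best_res.x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = DiproticParams.from_array(p_hat)

    # asymptotic SEs: transform the log-space Jacobian back to natural units
    J = best_res.jac.copy()
    J[:, _LOG_IDX] = J[:, _LOG_IDX] / p_hat[_LOG_IDX]
    dof = max(1, len(data) - 8)
    s2 = best_ssr / dof
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
        ses = {n: float(np.sqrt(max(0.0, cov[i, i])))
               for i, n in enumerate(DiproticParams._NAMES)}
    except np.linalg.LinAlgError:
        ses = {}

    return FitResult(params=params, ssr=float(best_ssr), n_converged=n_conv,
                     n_starts=n_starts, seed=seed, ses=ses)


def fit_michaelis_menten(data: Sequence[tuple[float, float]],
                         identifiability_threshold: float = 3.0) -> MMParams:
    """Fit v = Vmax*S/(Km+S) with asymptotic standard errors.

    ``identifiable`` is False when Km_se/Km exceeds the threshold — the
    regime where the measured range never approaches substrate saturation
    and the data are effectively first-order in S.
    """
    S = np.array([d[0] for d in data], dtype=float)
    v = np.array([d[1] for d in data], dtype=float)
    if len(np.unique(S)) < 3:
        raise InsufficientDataError("need >= 3 distinct substrate levels")

    vmax0 = max(v.max(), 1e-12) * 1.2
    half = vmax0 / 2.0
    km0 = float(S[np.argmin(np.abs(v - half))])
    km0 = min(max(km0, 1e-6), 1e6)

    def residuals(x: np.ndarray) -> np.ndarray:
        vmax, km = np.exp(x)
        return v - vmax * S / (km + S)

    best = None
    for km_start in (km0, np.median(S), 10.0 * S.max()):
        res = least_squares(residuals, np.log([vmax0, km_start]),
                            bounds=(np.log([1e-12, 1e-9]), np.log([1e12, 1e9])),
                            method="trf", max_nfev=2000)
        if best is None or res.cost < best.cost:
            best = res
    vmax, km = np.exp(best.x)

    # natural-parameter Jacobian of the residuals at the optimum; the exact
    # inverse is required here — a pseudo-inverse would truncate the
    # near-singular (unidentifiable) direction and hide its huge variance
    J = np.column_stack([-S / (km + S), vmax * S / (km + S) ** 2])
    dof = max(1, len(S) - 2)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        vmax_se = float(np.sqrt(max(0.0, cov[0, 0])))
        km_se = float(np.sqrt(max(0.0, cov[1, 1])))
        if not (np.isfinite(vmax_se) and np.isfinite(km_se)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vmax_se = km_se = np.inf
    identifiable = bool(km_se / km <= identifiability_threshold)
    return MMParams(Km=float(km), Vmax=float(vmax), Km_se=km_se,
                    Vmax_se=vmax_se, identifiable=identifiable)
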