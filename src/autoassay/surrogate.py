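"""Kriging (Gaussian-random-process) response surfaces.

Activity measured over assay conditions is modelled as a Gaussian process
on the normalized unit cube with an anisotropic Matern-5/2 covariance,

    k(x, x') = prod-wise scaled distance r = ||(x - x') / l||,
    k(r) = (1 + sqrt(5) r + 5 r^2 / 3) exp(-sqrt(5) r),

a constant mean (the grand mean of the responses) and a ridge/noise
regularizer ``lambda`` ("smoothing").  The smoothing is chosen by
generalized cross validation (GCV),

    GCV(lambda) = n * || (I - A(lambda)) y ||^2 / tr(I - A(lambda))^2,
    A(lambda)   = K (K + lambda I)^{-1},

evaluated cheaply for all candidate lambdas from one eigendecomposition of
K.  Optionally the per-axis length scales are tuned by Nelder-Mead.  The
length-scale objective is the profile negative log marginal likelihood
(with lambda and the signal variance profiled out), not the GCV score:
lambda and the length scale trade off into a single effective smoothing
bandwidth, leaving the GCV surface flat along a ridge in length scale,
whereas the marginal likelihood identifies the length scale of data drawn
from a GP.  The final smoothing at the selected length scales is the GCV
choice.  In the noiseless limit GCV drives lambda toward zero and the
surface interpolates the data; with pure noise it drives lambda up and the
surface shrinks to the grand mean.

The predictive standard error reported is the Kriging standard error of
the *signal* (model uncertainty, not observation noise):

    se^2(x) = sigma^2 (1 - k(x)^T (K + lambda I)^{-1} k(x)),
    sigma^2 = y~^T (K + lambda I)^{-1} y~ / n .

That is the spread the acquisition rule needs for its lower bound.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial.distance import cdist

from .design import Condition, Design, ParameterSpace, normalize_points, validate_condition
from .errors import InsufficientDataError, InvalidArgumentError, OutOfRangeError, SingularDesignError

__all__ = [
    "Prediction",
    "SurfaceModel",
    "fit_surface",
    "predict_with_uncertainty",
    "surface_optimum",
    "slice_grid",
]

_SQRT5 = np.sqrt(5.0)
_JITTER = 1e-10
# log10(lambda) grid searched by GCV before local refinement
_LAM_GRID = np.logspace(-10, 4, 57)


def _matern52(r: np.ndarray) -> np.ndarray:
    return (1.0 + _SQRT5 * r + (5.0 / 3.0) * r * r) * np.exp(-_SQRT5 * r)


def _kernel(A: np.ndarray, B: np.ndarray, lengthscales: np.ndarray) -> np.ndarray:
    return _matern52(cdist(A / lengthscales, B / lengthscales))


def _gcv_curve(w: np.ndarray, z2: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """GCV(lambda) for every lambda at once, given eigenvalues w of K and
    squared eigen-coordinates z2 of the centred responses."""
    n = w.size
    shrink = lams[:, None] / (w[None, :] + lams[:, None])  # rows: lambdas
    rss = shrink**2 @ z2
    denom = shrink.sum(axis=1)
    return n * rss / denom**2


@dataclass
class Prediction:
    """Predictive mean and standard error at one condition."""

    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise InvalidArgumentError("predictive se must be >= 0")


@dataclass
class SurfaceModel:
    """A fitted Kriging surface over a normalized design."""

    space: ParameterSpace
    X: np.ndarray                     # (n, d) normalized training points
    y: np.ndarray                     # (n,) responses, assay units
    lengthscales: np.ndarray          # (d,) per-axis, normalized coords
    smoothing: float                  # GCV-chosen lambda
    kernel: str = "matern52"
    mu: float = 0.0
    sigma2: float = 0.0
    gcv_score: float = np.nan
    _cho: tuple = field(default=None, repr=False, compare=False)
    _alpha: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.y) != len(self.X) or len(self.y) < 2:
            raise InvalidArgumentError("need |y| = rows of X >= 2")
        if self.smoothing <= 0 or np.any(self.lengthscales <= 0):
            raise InvalidArgumentError("smoothing and length scales must be > 0")
        if self._cho is None:
            self._factorize()

    def _factorize(self) -> None:
        n = len(self.y)
        K = _kernel(self.X, self.X, self.lengthscales)
        Kreg = K + (self.smoothing + _JITTER) * np.eye(n)
        self._cho = cho_factor(Kreg, lower=True)
        yt = self.y - self.mu
        self._alpha = cho_solve(self._cho, yt)
        self.sigma2 = max(0.0, float(yt @ self._alpha) / n)

    def predict(self, Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean and signal standard error at normalized query points."""
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        Kq = _kernel(Xq, self.X, self.lengthscales)
        mean = self.mu + Kq @ self._alpha
        v = cho_solve(self._cho, Kq.T)
        var = self.sigma2 * np.clip(1.0 - np.einsum("ij,ji->i", Kq, v), 0.0, None)
        return mean, np.sqrt(var)

    # -- persistence ------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "space": self.space.to_dict(),
            "X": self.X.tolist(),
            "y": self.y.tolist(),
            "lengthscales": self.lengthscales.tolist(),
            "smoothing": self.smoothing,
            "kernel": self.kernel,
            "mu": self.mu,
            "gcv_score": None if np.isnan(self.gcv_score) else self.gcv_score,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SurfaceModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            space=ParameterSpace.from_dict(p["space"]),
            X=np.asarray(p["X"], dtype=float),
            y=np.asarray(p["y"], dtype=float),
            lengthscales=np.asarray(p["lengthscales"], dtype=float),
            smoothing=float(p["smoothing"]),
            kernel=p.get("kernel", "matern52"),
            mu=float(p.get("mu", 0.0)),
            gcv_score=p["gcv_score"] if p.get("gcv_score") is not None else np.nan,
        )


def _eigen(X: np.ndarray, yt: np.ndarray,
           lengthscales: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = _kernel(X, X, lengthscales)
    w, Q = eigh(K)
    w = np.maximum(w, 0.0) + _JITTER
    z2 = (Q.T @ yt) ** 2
    return w, z2


def _nll_at_lengthscales(X: np.ndarray, yt: np.ndarray,
                         lengthscales: np.ndarray) -> float:
    """Profile negative log marginal likelihood, minimized over lambda.

    The signal variance is profiled out analytically:
    nll(lambda) = n/2 log(yt' (K + lambda I)^{-1} yt / n)
                  + 1/2 log det(K + lambda I).
    """
    w, z2 = _eigen(X, yt, lengthscales)
    n = w.size
    denom = w[None, :] + _LAM_GRID[:, None]
    quad = (z2[None, :] / denom).sum(axis=1)
    logdet = np.log(denom).sum(axis=1)
    return float(np.min(0.5 * n * np.log(np.maximum(quad, 1e-300) / n)
                        + 0.5 * logdet))


def _gcv_at_lengthscales(X: np.ndarray, yt: np.ndarray,
                         lengthscales: np.ndarray) -> tuple[float, float]:
    """Best GCV score over the lambda grid for given length scales."""
    w, z2 = _eigen(X, yt, lengthscales)
    scores = _gcv_curve(w, z2, _LAM_GRID)
    i = int(np.argmin(scores))
    # local refinement in log-lambda around the grid minimum
    lo = np.log10(_LAM_GRID[max(0, i - 1)])
    hi = np.log10(_LAM_GRID[min(len(_LAM_GRID) - 1, i + 1)])
    res = minimize_scalar(
        lambda ll: float(_gcv_curve(w, z2, np.array([10.0**ll]))[0]),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-3},
    )
    if res.fun <= scores[i]:
        return float(res.fun), float(10.0**res.x)
    return float(scores[i]), float(_LAM_GRID[i])


def fit_surface(space: ParameterSpace, conditions: Sequence[Condition],
                y: Sequence[float], optimize_lengthscales: bool = True,
                seed: int = 0, nm_maxiter: int | None = None) -> SurfaceModel:
    """Fit a Kriging surface to measured responses.

    Smoothing is chosen by generalized cross validation; if
    ``optimize_lengthscales`` the per-axis length scales are additionally
    tuned by Nelder-Mead on the profile marginal likelihood, starting from
    unit length scales on the normalized cube.  Replicated points are
    handled exactly (the regularizer guarantees invertibility).
    """
    X = normalize_points(space, list(conditions))
    y = np.asarray(list(y), dtype=float)
    d = space.dim
    n_min = max(4, d + 2)
    if len(y) != len(X):
        raise InvalidArgumentError("conditions and y differ in length")
    if len(y) < n_min:
        raise InsufficientDataError(
            f"need at least {n_min} observations for {d} axes, got {len(y)}"
        )
    if np.allclose(X, X[0], atol=1e-12):
        raise SingularDesignError("all design points identical")

    mu = float(np.mean(y))
    yt = y - mu

    def objective(log_ls: np.ndarray) -> float:
        ls = np.exp(np.clip(log_ls, -4.0, 4.0))
        return _nll_at_lengthscales(X, yt, ls)

    log_ls = np.zeros(d)
    if optimize_lengthscales and np.ptp(yt) > 0:
        res = minimize(
            objective, log_ls, method="Nelder-Mead",
            options={"maxiter": nm_maxiter or 60 * d,
                     "xatol": 1e-2, "fatol": 1e-10, "adaptive": d > 2},
        )
        log_ls = np.clip(res.x, -4.0, 4.0)
    ls = np.exp(log_ls)
    score, lam = _gcv_at_lengthscales(X, yt, ls)
    return SurfaceModel(space=space, X=X, y=y, lengthscales=ls,
                        smoothing=max(lam, _JITTER), mu=mu, gcv_score=score)


def predict_with_uncertainty(model: SurfaceModel,
                             points: Sequence[Condition]) -> list[Prediction]:
    """Evaluate the surface at conditions given in natural units."""
    for c in points:
        validate_condition(model.space, c)
    Xq = normalize_points(model.space, list(points))
    mean, se = model.predict(Xq)
    return [Prediction(float(m), float(s)) for m, s in zip(mean, se)]


def surface_optimum(model: SurfaceModel, maximize: bool = True,
                    restarts: int = 20, seed: int = 0
                    ) -> tuple[Condition, Prediction]:
    """Locate the surface optimum by multistart bounded quasi-Newton search.

    Starts at uniform random points of the unit cube plus the best training
    point; returns the best local optimum in natural units together with
    the model's prediction there.  Deterministic for a fixed seed.
    """
    if restarts < 1:
        raise InvalidArgumentError("restarts must be >= 1")
    d = model.space.dim
    rng = np.random.default_rng(seed)
    sign = -1.0 if maximize else 1.0

    def f(x: np.ndarray) -> float:
        m, _ = model.predict(x[None, :])
        return sign * float(m[0])

    starts = rng.uniform(size=(restarts, d))
    i_best = int(np.argmax(model.y) if maximize else np.argmin(model.y))
    starts = np.vstack([starts, model.X[i_best]])
    best_x, best_f = None, np.inf
    bounds = [(0.0, 1.0)] * d
    for x0 in starts:
        res = minimize(f, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, 0.0, 1.0), float(res.fun)
    vals = {ax.name: float(ax.denormalize(t))
            for ax, t in zip(model.space.axes, best_x)}
    cond = Condition(vals, id="optimum", meta={"x_norm": best_x})
    mean, se = model.predict(best_x[None, :])
    return cond, Prediction(float(mean[0]), float(se[0]))


def slice_grid(model: SurfaceModel, axis1: str, axis2: str,
               fixed: Mapping[str, float] | None = None,
               n: int = 50) -> "pd.DataFrame":
    """Mean/se of the surface on an n x n grid of two axes, other axes fixed.

    Returns a long-format table (axis1, axis2, mean, se) suitable for
    plotting interpolated slices through the parameter space.
    """
    import pandas as pd

    fixed = dict(fixed or {})
    names = model.space.names
    for nm in (axis1, axis2):
        if nm not in names:
            raise InvalidArgumentError(f"unknown axis {nm!r}")
    t = np.linspace(0.0, 1.0, n)
    G1, G2 = np.meshgrid(t, t, indexing="ij")
    Xq = np.empty((n * n, model.space.dim))
    for j, ax in enumerate(model.space.axes):
        if ax.name == axis1:
            Xq[:, j] = G1.ravel()
        elif ax.name == axis2:
            Xq[:, j] = G2.ravel()
        else:
            Xq[:, j] = float(ax.normalize(fixed.get(ax.name, ax.denormalize(0.5))))
    mean, se = model.predict(Xq)
    a1 = model.space.axis(axis1).denormalize(G1.ravel())
    a2 = model.space.axis(axis2).denormalize(G2.ravel())
    return pd.DataFrame({axis1: a1, axis2: a2, "mean": mean, "se": se})
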