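"""Iterative response-surface optimization of assay conditions.

The campaign mirrors autonomous buffer-optimization practice: an initial
space-filling round builds a coarse Kriging model of activity over the
allowed condition range; each refinement round proposes a batch of new
conditions by *Boltzmann sampling* on the acquisition energy

    E(x) = mean(x) - k * se(x)          (minimization)
    E(x) = -(mean(x) + k * se(x))       (maximization, sign reversed)

i.e. the lower confidence bound of the model estimate, over a large pool of
uniform random candidates: P(x) proportional to exp(-E(x) / T).  A
minimum normalized distance to all existing measurements is enforced; a
candidate violating it is *repaired* by redrawing from an isotropic normal
centred at it and keeping the feasible draw closest to the original point,
or — if no draw is feasible — the draw farthest from its nearest
neighbour (the fallback rule).  The minimum distance starts at
``min_dist0`` (0.25 in the reference campaign) and shrinks by ``shrink``
(2/3) each round, focusing later batches near the estimated optimum.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .design import (Condition, Design, ParameterSpace, denormalize_points,
                     normalize_points, space_filling_design)
from .errors import CampaignAborted, InvalidArgumentError
from .surrogate import (Prediction, SurfaceModel, fit_surface,
                        predict_with_uncertainty, surface_optimum)

__all__ = [
    "CampaignConfig",
    "Measurement",
    "CampaignState",
    "lower_confidence_bound",
    "boltzmann_weights",
    "boltzmann_select",
    "propose_batch",
    "run_campaign",
    "nearest_k_mean",
]


@dataclass
class CampaignConfig:
    """Schedule and acquisition knobs of an optimization campaign.

    Defaults follow the reference five-round schedule: a 20-point initial
    space-filling design, four refinement batches of 19, minimum distance
    0.25 shrinking by 2/3 per round.
    """

    space: ParameterSpace
    initial_n: int = 20
    batch_n: int = 19
    rounds: int = 5
    min_dist0: float = 0.25
    shrink: float = 2.0 / 3.0
    lcb_k: float = 1.96
    temperature: float | None = None   # None -> adaptive (IQR of pool energies)
    pool_size: int | None = None       # None -> 1000 * d
    repair_sigma: float | None = None  # None -> the round's min_dist
    repair_tries: int = 500
    maximize: bool = True
    optimize_lengthscales: bool = True
    restarts: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        d = self.space.dim
        if self.initial_n < d + 2:
            raise InvalidArgumentError(f"initial_n must be >= d+2 = {d + 2}")
        if self.batch_n < 1 or self.rounds < 1:
            raise InvalidArgumentError("batch_n and rounds must be >= 1")
        if not (0.0 < self.min_dist0 <= np.sqrt(d)):
            raise InvalidArgumentError("min_dist0 must lie in (0, sqrt(d)]")
        if not (0.0 < self.shrink <= 1.0):
            raise InvalidArgumentError("shrink must lie in (0, 1]")
        if self.lcb_k < 0:
            raise InvalidArgumentError("lcb_k must be >= 0")
        if self.temperature is not None and self.temperature <= 0:
            raise InvalidArgumentError("temperature must be > 0")


@dataclass
class Measurement:
    condition: Condition
    response: float
    round: int


@dataclass
class CampaignState:
    """Complete log of a campaign: measurements, model and optimum history."""

    space: ParameterSpace
    measurements: list[Measurement] = field(default_factory=list)
    model: SurfaceModel | None = None
    optimum_history: list[tuple[Condition, Prediction]] = field(default_factory=list)
    round: int = 0

    def conditions(self) -> list[Condition]:
        return [m.condition for m in self.measurements]

    def responses(self) -> np.ndarray:
        return np.asarray([m.response for m in self.measurements], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            row = {"round": m.round, "id": m.condition.id}
            row.update({n: m.condition.values[n] for n in self.space.names})
            row["response"] = m.response
            row["accepted_by"] = m.condition.meta.get("accepted_by", "initial")
            rows.append(row)
        cols = ["round", "id"] + self.space.names + ["response", "accepted_by"]
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def lower_confidence_bound(pred: Prediction, k: float,
                           maximize: bool = False) -> float:
    """Acquisition energy: the lower bound of the model estimate.

    ``mean - k*se`` for minimization; for maximization the sign is simply
    reversed, giving ``-(mean + k*se)``.
    """
    if k < 0:
        raise InvalidArgumentError("k must be >= 0")
    if maximize:
        return -(pred.mean + k * pred.se)
    return pred.mean - k * pred.se


def boltzmann_weights(energies: np.ndarray, temperature: float) -> np.ndarray:
    """Normalized selection probabilities proportional to exp(-E/T)."""
    if temperature <= 0:
        raise InvalidArgumentError("temperature must be > 0")
    e = np.asarray(energies, dtype=float)
    w = np.exp(-(e - e.min()) / temperature)
    return w / w.sum()


def boltzmann_select(energies: np.ndarray, temperature: float,
                     rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw candidate indices (with replacement) from the Boltzmann law."""
    p = boltzmann_weights(energies, temperature)
    return rng.choice(len(p), size=size, p=p)


def _adaptive_temperature(energies: np.ndarray) -> float:
    q1, q3 = np.percentile(energies, [25, 75])
    t = float(q3 - q1)
    if t <= 0:
        t = float(np.std(energies))
    return t if t > 0 else 1.0


def _min_dist_to(x: np.ndarray, pts: np.ndarray) -> float:
    if pts.size == 0:
        return np.inf
    return float(cdist(x[None, :], pts).min())


def propose_batch(model: SurfaceModel, existing: Sequence[Condition],
                  n: int, min_dist: float, config: CampaignConfig,
                  seed: int = 0) -> list[Condition]:
    """Propose ``n`` new conditions by Boltzmann sampling on the LCB energy.

    Each accepted point is added to the exclusion set before the next draw
    (no within-batch duplicates).  Every returned condition carries
    ``meta['accepted_by']`` in {'boltzmann', 'repair', 'fallback'} and
    ``meta['x_norm']`` (its normalized coordinates).
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if min_dist < 0:
        raise InvalidArgumentError("min_dist must be >= 0")
    d = model.space.dim
    rng = np.random.default_rng(seed)
    pool_size = config.pool_size or 1000 * d
    pool = rng.uniform(size=(pool_size, d))
    mean, se = model.predict(pool)
    if config.maximize:
        energies = -(mean + config.lcb_k * se)
    else:
        energies = mean - config.lcb_k * se
    temperature = config.temperature or _adaptive_temperature(energies)
    sigma = config.repair_sigma or (min_dist if min_dist > 0 else 0.05)

    taken = normalize_points(model.space, list(existing)) if existing else \
        np.empty((0, d))
    alive = np.ones(pool_size, dtype=bool)
    out: list[Condition] = []
    for j in range(n):
        idx_alive = np.flatnonzero(alive)
        w = boltzmann_weights(energies[idx_alive], temperature)
        pick = int(rng.choice(idx_alive, p=w))
        alive[pick] = False
        x = pool[pick]
        if _min_dist_to(x, taken) >= min_dist:
            accepted_by, x_new = "boltzmann", x
        else:
            draws = rng.normal(loc=x, scale=sigma,
                               size=(config.repair_tries, d))
            draws = np.clip(draws, 0.0, 1.0)
            dmin = cdist(draws, taken).min(axis=1) if taken.size else \
                np.full(len(draws), np.inf)
            feasible = dmin >= min_dist
            if feasible.any():
                cand = draws[feasible]
                x_new = cand[int(np.argmin(np.linalg.norm(cand - x, axis=1)))]
                accepted_by = "repair"
            else:
                x_new = draws[int(np.argmax(dmin))]
                accepted_by = "fallback"
        taken = np.vstack([taken, x_new])
        vals = {ax.name: float(ax.denormalize(t))
                for ax, t in zip(model.space.axes, x_new)}
        out.append(Condition(vals, id=f"prop:{j}",
                             meta={"accepted_by": accepted_by,
                                   "x_norm": x_new.copy()}))
    return out


def run_campaign(evaluator: Callable[[Condition], float],
                 config: CampaignConfig) -> CampaignState:
    """Run the closed loop: space-filling round, then refinement rounds.

    Round 1 measures ``initial_n`` space-filling conditions; each of the
    remaining ``rounds - 1`` rounds proposes ``batch_n`` conditions with
    minimum distance ``min_dist0 * shrink**(j-1)`` (j = 1-based refinement
    index), measures them, refits the surface and records its optimum.  If
    the evaluator raises, the campaign aborts with the partial log attached
    to the :class:`CampaignAborted` exception.
    """
    space = config.space
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=3 * (config.rounds + 1) + 1)
    state = CampaignState(space=space)

    def measure(conds: Sequence[Condition], rnd: int) -> None:
        for c in conds:
            c.meta["round"] = rnd
            try:
                resp = float(evaluator(c))
            except Exception as exc:  # preserve the partial log
                raise CampaignAborted(
                    f"evaluator failed at round {rnd}, condition {c.id!r}: {exc}",
                    state=state,
                ) from exc
            state.measurements.append(Measurement(c, resp, rnd))

    def refit(rnd: int) -> None:
        state.model = fit_surface(
            space, state.conditions(), state.responses(),
            optimize_lengthscales=config.optimize_lengthscales,
            seed=int(seeds[3 * rnd]),
        )
        opt = surface_optimum(state.model, maximize=config.maximize,
                              restarts=config.restarts,
                              seed=int(seeds[3 * rnd + 1]))
        state.optimum_history.append(opt)

    initial = space_filling_design(space, config.initial_n,
                                   seed=int(seeds[0]))
    for i, c in enumerate(initial.conditions):
        c.id = f"1:{i}"
        c.meta["accepted_by"] = "initial"
    state.round = 1
    measure(initial.conditions, 1)
    refit(1)

    for rnd in range(2, config.rounds + 1):
        j = rnd - 1  # 1-based refinement index
        min_dist = config.min_dist0 * config.shrink ** (j - 1)
        batch = propose_batch(state.model, state.conditions(),
                              config.batch_n, min_dist, config,
                              seed=int(seeds[3 * rnd + 2]))
        for i, c in enumerate(batch):
            c.id = f"{rnd}:{i}"
        state.round = rnd
        measure(batch, rnd)
        refit(rnd)
    return state


def nearest_k_mean(state: CampaignState, k: int,
                   round_index: int | None = None) -> float:
    """Mean response of the k measurements nearest the optimum estimate.

    With ``round_index`` (1-based) the optimum of that round and only the
    measurements available then are used — the per-iteration diagnostic of
    campaign quality.  Ties are broken by measurement order.
    """
    if round_index is None:
        round_index = state.round
    if not 1 <= round_index <= len(state.optimum_history):
        raise InvalidArgumentError(f"no optimum recorded for round {round_index}")
    ms = [m for m in state.measurements if m.round <= round_index]
    if k < 1 or k > len(ms):
        raise InvalidArgumentError(
            f"k must be in [1, {len(ms)}], got {k}"
        )
    opt_cond, _ = state.optimum_history[round_index - 1]
    x_opt = normalize_points(state.space, [opt_cond])[0]
    X = normalize_points(state.space, [m.condition for m in ms])
    dist = np.linalg.norm(X - x_opt, axis=1)
    order = np.argsort(dist, kind="stable")[:k]
    return float(np.mean([ms[i].response for i in order]))
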