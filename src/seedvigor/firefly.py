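"""Firefly algorithm: a bounded population minimizer, plus the (lr, bs) tuner.

Each firefly is a candidate solution in a box; its brightness is the
(negated) objective.  A firefly i moves toward every brighter firefly j::

    x_i <- x_i + beta0 * exp(-gamma * r_ij^2) * (x_j - x_i) + alpha * (u - 1/2)

with r_ij the Euclidean distance and u ~ U[0,1] drawn per dimension.  The
brightest firefly, having no attractor, performs a pure alpha-random step.
Positions are clamped to the box after every move and integer-typed
dimensions are rounded to the nearest in-bounds integer.  The step factor
alpha is held constant over iterations.

The hyperparameter tuner wraps the minimizer over a 2-D box — learning rate
(continuous, searched on a log10 scale) and batch size (integer) — scoring
each candidate by a trainer callback that returns the validation
misclassification rate (1 - accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FAConfig",
    "FireflyState",
    "ObjectiveError",
    "attractiveness",
    "firefly_distance",
    "move_firefly",
    "misclassification_objective",
    "fa_minimize",
    "tune_hyperparams",
]


class ObjectiveError(RuntimeError):
    def __init__(self, position: np.ndarray):
        super().__init__(f"objective returned a non-finite value at {position}")
        self.position = np.asarray(position)


@dataclass
class FAConfig:
    """Population size, step/attraction parameters, bounds and budget."""

    n_pop: int = 10
    bounds: tuple[tuple[float, float], ...] = ((-5.0, 5.0), (-5.0, 5.0))
    alpha: float = 0.2
    beta0: float = 1.0
    gamma: float = 1.0
    n_iter: int = 20
    integer_dims: tuple[int, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop < 2:
            raise ValueError("population size must be >= 2")
        if self.alpha < 0 or self.gamma < 0 or self.beta0 <= 0:
            raise ValueError("require alpha >= 0, gamma >= 0, beta0 > 0")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lower < upper")
        if any(d < 0 or d >= self.dim for d in self.integer_dims):
            raise ValueError("integer dimension index out of range")

    @property
    def dim(self) -> int:
        return len(self.bounds)


@dataclass
class FireflyState:
    positions: np.ndarray  # n_pop x dim
    fitness: np.ndarray  # n_pop
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)  # best-so-far per iteration


def attractiveness(beta0: float, gamma: float, r: float) -> float:
    """Attraction beta = beta0 * exp(-gamma * r^2) at distance r."""
    if r < 0:
        raise ValueError("distance must be >= 0")
    return beta0 * np.exp(-gamma * r * r)


def firefly_distance(xi: np.ndarray, xj: np.ndarray) -> float:
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError("positions must share dimension")
    return float(np.linalg.norm(xi - xj))


def _clamp(x: np.ndarray, cfg: FAConfig) -> np.ndarray:
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    x = np.clip(x, lo, hi)
    for d in cfg.integer_dims:
        x[d] = np.clip(np.round(x[d]), np.ceil(lo[d]), np.floor(hi[d]))
    return x


def move_firefly(
    xi: np.ndarray, xj: np.ndarray, cfg: FAConfig, rng: np.random.Generator
) -> np.ndarray:
    """One attracted move of xi toward a brighter xj, plus the random step."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.shape != (cfg.dim,):
        raise ValueError("position dimension mismatch")
    beta = attractiveness(cfg.beta0, cfg.gamma, firefly_distance(xi, xj))
    u = rng.uniform(0.0, 1.0, size=cfg.dim)
    x_new = xi + beta * (xj - xi) + cfg.alpha * (u - 0.5)
    return _clamp(x_new, cfg)


def _random_step(xi: np.ndarray, cfg: FAConfig, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(0.0, 1.0, size=cfg.dim)
    return _clamp(np.asarray(xi, float) + cfg.alpha * (u - 0.5), cfg)


def misclassification_objective(true_labels, predicted_labels) -> float:
    """1 - (agreements / samples); the quantity the tuner minimizes."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0 or p.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    return float(1.0 - np.mean(t == p))


def _eval(f, x: np.ndarray) -> float:
    v = float(f(x))
    if not np.isfinite(v):
        raise ObjectiveError(x)
    return v


def fa_minimize(f, cfg: FAConfig, initial_positions: np.ndarray | None = None) -> FireflyState:
    """Minimize ``f`` over the box with the firefly algorithm.

    Per iteration every firefly moves toward each brighter one (brightness
    ranking frozen at the start of the iteration, positions updated in
    place); the brightest takes a pure random step; all fitness values are
    then re-evaluated and the best-so-far recorded.  ``initial_positions``
    may override the first rows of the uniform initial population (used to
    plant an incumbent solution).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    X = rng.uniform(lo, hi, size=(cfg.n_pop, cfg.dim))
    if initial_positions is not None:
        init = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        X[: len(init)] = init
    for i in range(cfg.n_pop):
        X[i] = _clamp(X[i], cfg)
    fit = np.array([_eval(f, X[i]) for i in range(cfg.n_pop)])
    ib = int(np.argmin(fit))
    state = FireflyState(X, fit, X[ib].copy(), float(fit[ib]), [float(fit[ib])])
    for _ in range(cfg.n_iter):
        start_fit = fit.copy()
        brightest = int(np.argmin(start_fit))
        for i in range(cfg.n_pop):
            if i == brightest:
                X[i] = _random_step(X[i], cfg, rng)
                continue
            for j in range(cfg.n_pop):
                if start_fit[j] < start_fit[i]:
                    X[i] = move_firefly(X[i], X[j], cfg, rng)
        fit = np.array([_eval(f, X[i]) for i in range(cfg.n_pop)])
        ib = int(np.argmin(fit))
        if fit[ib] < state.best_fitness:
            state.best_fitness = float(fit[ib])
            state.best_position = X[ib].copy()
        state.trace.append(state.best_fitness)
    state.positions = X
    state.fitness = fit
    return state


def tune_hyperparams(
    trainer,
    cfg: FAConfig | None = None,
    lr_bounds: tuple[float, float] = (1e-4, 1e-1),
    bs_bounds: tuple[int, int] = (1, 32),
    include_default: tuple[float, int] | None = None,
) -> dict:
    """Firefly search over (lr, bs) minimizing ``trainer(lr, bs)``.

    ``trainer`` returns the validation misclassification rate for one
    candidate. The learning rate is searched on a log10 scale and batch size
    as an integer; both dimensions are normalized to the unit box for the
    search itself so that the attraction kernel and the alpha-random step
    act on comparable scales, and are mapped back to (lr, bs) for every
    trainer call. When ``include_default`` is given, that incumbent (lr, bs)
    seeds the initial population so the tuned optimum can never be worse
    than the default. Returns the best pair, its objective and a log of
    every evaluation.
    """
    if cfg is None:
        cfg = FAConfig()
    if cfg.dim != 2:
        raise ValueError("hyperparameter search is 2-D: (log10 lr, bs)")
    cfg = FAConfig(
        n_pop=cfg.n_pop,
        bounds=((0.0, 1.0), (0.0, 1.0)),
        alpha=cfg.alpha,
        beta0=cfg.beta0,
        gamma=cfg.gamma,
        n_iter=cfg.n_iter,
        rng_seed=cfg.rng_seed,
    )
    log_lo, log_hi = np.log10(lr_bounds[0]), np.log10(lr_bounds[1])
    bs_lo, bs_hi = int(bs_bounds[0]), int(bs_bounds[1])

    def decode(x: np.ndarray) -> tuple[float, int]:
        lr = float(10.0 ** (log_lo + x[0] * (log_hi - log_lo)))
        bs = int(np.clip(round(bs_lo + x[1] * (bs_hi - bs_lo)), bs_lo, bs_hi))
        return lr, bs

    evaluations: list[dict] = []
    cache: dict[tuple[float, int], float] = {}

    def objective(x: np.ndarray) -> float:
        lr, bs = decode(x)
        key = (round(np.log10(lr), 12), bs)
        if key not in cache:
            cache[key] = float(trainer(lr, bs))
            evaluations.append({"lr": lr, "bs": bs, "f_obj": cache[key]})
        return cache[key]

    seeded_default = None
    if include_default is not None:
        lr0, bs0 = include_default
        seeded_default = np.array(
            [
                (np.log10(lr0) - log_lo) / (log_hi - log_lo),
                (bs0 - bs_lo) / max(1, bs_hi - bs_lo),
            ]
        )

    state = fa_minimize(objective, cfg, initial_positions=seeded_default)
    best_lr, best_bs = decode(state.best_position)
    return {
        "lr": best_lr,
        "bs": best_bs,
        "f_obj": state.best_fitness,
        "trace": state.trace,
        "evaluations": evaluations,
    }
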