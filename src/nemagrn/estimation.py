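"""Ensemble parameter estimation for the gene circuit.

The fit minimizes the root-mean-squared mismatch between simulated and
reference profiles at the target times.  Because in-situ staining intensity
carries no absolute scale, profiles are compared after unit-maximum
normalization per gene per time point; a gene whose reference profile is
identically zero at a time point ("no observed expression") is instead
compared raw against zero, so spurious simulated expression is penalized.

The global optimizer is a scatter-search metaheuristic in the spirit of
enhanced scatter search (eSS): a Latin-hypercube diverse set seeds a small
reference set balancing quality and diversity, which is evolved by pairwise
hyper-rectangle combination, a go-beyond intensification step, and
stagnation-triggered regeneration.  No local search is used.  Repeating the
search from independent seeds yields an ensemble of best-fit parameter sets
whose statistics drive the network inference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from . import gene_circuit as gc

logger = logging.getLogger(__name__)

PER_GENE_TIME = "per_gene_time"
RAW = "raw"


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class FitConfig:
    """Settings for one ensemble of scatter-search fits.

    Bounds: the sigmoid saturates beyond |input| of about 3, so regulatory
    weights outside [-5, 5] add no expressiveness; decay rates in
    [0.01, 1] /hour keep steady-state levels of order 1-100 and dynamics
    resolvable over the 50-hour fitting window.
    """

    t_bounds: tuple[float, float] = (-5.0, 5.0)
    m_bounds: tuple[float, float] = (-5.0, 5.0)
    h_bounds: tuple[float, float] = (-5.0, 5.0)
    lam_bounds: tuple[float, float] = (0.01, 1.0)
    r_bounds: tuple[float, float] = (0.1, 5.0)
    d_bounds: tuple[float, float] = (0.0, 0.5)
    budget: int = 10000
    weights: tuple[float, ...] | None = None  # per-gene objective weights
    normalization: str = PER_GENE_TIME
    model: str = gc.SIMPLIFIED
    seed: int = 0
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-9
    refset_size: int = 10
    diverse_factor: int = 10  # diverse set has diverse_factor * dim points
    stall_limit: int = 10

    def __post_init__(self) -> None:
        for name in ("t_bounds", "m_bounds", "h_bounds", "lam_bounds",
                     "r_bounds", "d_bounds"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise EstimationError(f"{name} must be finite with lower < upper")
        if self.budget < 100:
            raise EstimationError("budget must be at least 100 evaluations")
        if self.normalization not in (PER_GENE_TIME, RAW):
            raise EstimationError("normalization must be 'per_gene_time' or 'raw'")

    def bound_vectors(self, n_genes: int) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper bound vectors in optimization-vector order."""
        lo = [self.t_bounds[0]] * (n_genes * n_genes)
        hi = [self.t_bounds[1]] * (n_genes * n_genes)
        blocks = [self.m_bounds, self.h_bounds, self.lam_bounds]
        if self.model == gc.FULL:
            blocks += [self.r_bounds, self.d_bounds]
        for b in blocks:
            lo += [b[0]] * n_genes
            hi += [b[1]] * n_genes
        return np.asarray(lo, float), np.asarray(hi, float)


def profile_rms(simulated_targets: np.ndarray, reference: gc.ReferenceData,
                weights: Sequence[float] | None = None,
                normalization: str = PER_GENE_TIME) -> float:
    """Weighted RMS mismatch over all (gene, time, segment) triplets.

    ``simulated_targets`` has shape (n_target_times, n_genes, n_points).
    """
    sim = np.asarray(simulated_targets, dtype=float)
    ref = reference.targets
    if sim.shape != ref.shape:
        raise EstimationError(f"simulated targets shape {sim.shape} != {ref.shape}")
    n = reference.n
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if w.shape != (n,) or np.any(w < 0):
        raise EstimationError("weights must be non-negative, one per gene")
    num = 0.0
    den = 0.0
    for k in range(sim.shape[0]):
        for i in range(n):
            r = ref[k, i]
            s = sim[k, i]
            if normalization == PER_GENE_TIME:
                rmax = r.max()
                if rmax > 0:
                    r = r / rmax
                    smax = s.max()
                    s = s / smax if smax > 0 else s
                # identically-zero reference: compare raw simulation to zero
            d = s - r
            num += w[i] * float(d @ d)
            den += w[i] * d.size
    return float(np.sqrt(num / den)) if den > 0 else 0.0


class CircuitObjective:
    """Callable objective: simulate a parameter vector, score against the
    reference.

    Simulation failures return a large finite penalty (10x the worst feasible
    value seen so far, floor 1e3) so the search stays alive and the failed
    region is ranked last.
    """

    def __init__(self, reference: gc.ReferenceData, config: FitConfig):
        self.reference = reference
        self.config = config
        self.worst_feasible = 0.0
        self.n_failures = 0

    @property
    def dim(self) -> int:
        return gc.n_free_parameters(self.reference.n, self.config.model)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.config.bound_vectors(self.reference.n)

    def __call__(self, x: np.ndarray) -> float:
        ref = self.reference
        try:
            params = gc.GeneCircuitParams.from_vector(x, ref.gene_names,
                                                      self.config.model)
            result = gc.simulate(params, ref.initial, ref.maternal_profile,
                                 ref.all_times, rtol=self.config.sim_rtol,
                                 atol=self.config.sim_atol)
            value = profile_rms(result.concentrations[1:], ref,
                                self.config.weights, self.config.normalization)
        except gc.GeneCircuitError as exc:
            self.n_failures += 1
            penalty = max(1e3, 10.0 * self.worst_feasible)
            logger.debug("simulation failed (%s); penalty %.3g", exc, penalty)
            return penalty
        self.worst_feasible = max(self.worst_feasible, value)
        return value


@dataclass
class OptimizationRun:
    """Outcome of one scatter-search run.

    ``trace`` records incumbent improvements as (evaluation index, value)
    pairs; the final entry equals ``best_value``.
    """

    best_x: np.ndarray
    best_value: float
    n_evaluations: int
    seed: int
    trace: list[tuple[int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"best_x": np.asarray(self.best_x).tolist(),
                "best_value": float(self.best_value),
                "n_evaluations": int(self.n_evaluations), "seed": int(self.seed),
                "trace": [[int(k), float(v)] for k, v in self.trace]}

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizationRun":
        return cls(np.asarray(d["best_x"], float), float(d["best_value"]),
                   int(d["n_evaluations"]), int(d["seed"]),
                   [(int(k), float(v)) for k, v in d["trace"]])


class _Budget:
    """Evaluation counter that records the incumbent trace."""

    def __init__(self, fun: Callable, budget: int):
        self.fun = fun
        self.budget = budget
        self.n = 0
        self.best_x: np.ndarray | None = None
        self.best_f = np.inf
        self.trace: list[tuple[int, float]] = []

    @property
    def exhausted(self) -> bool:
        return self.n >= self.budget

    def __call__(self, x: np.ndarray) -> float:
        self.n += 1
        f = float(self.fun(x))
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x, float)
            self.trace.append((self.n, f))
        return f


def _greedy_diverse(pool: np.ndarray, chosen: np.ndarray, k: int,
                    span: np.ndarray) -> list[int]:
    """Indices of k pool rows maximizing min-distance to the chosen set."""
    sel: list[int] = []
    scaled_pool = pool / span
    scaled_chosen = [c / span for c in chosen]
    for _ in range(k):
        dmin = np.full(len(pool), np.inf)
        for c in scaled_chosen:
            dmin = np.minimum(dmin, np.linalg.norm(scaled_pool - c, axis=1))
        dmin[sel] = -np.inf
        best = int(np.argmax(dmin))
        sel.append(best)
        scaled_chosen.append(scaled_pool[best])
    return sel


def scatter_search(fun: Callable[[np.ndarray], float], lower, upper, *,
                   budget: int = 10000, seed: int = 0, refset_size: int = 10,
                   diverse_factor: int = 10,
                   stall_limit: int = 10) -> OptimizationRun:
    """Scatter-search global minimization within box bounds.

    Fully deterministic under ``seed``; stops when the evaluation budget is
    spent.  Returns the incumbent and its improvement trace.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    dim = lower.size
    if upper.shape != lower.shape or np.any(upper <= lower):
        raise EstimationError("invalid bounds")
    if budget < 2 * refset_size:
        raise EstimationError("budget too small for the reference set")
    rng = np.random.default_rng(seed)
    span = upper - lower
    ev = _Budget(fun, budget)

    def lhs(n_pts: int) -> np.ndarray:
        sampler = qmc.LatinHypercube(d=dim, seed=rng)
        return lower + sampler.random(n_pts) * span

    def evaluate_set(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vals = []
        kept = []
        for x in X:
            if ev.exhausted:
                break
            kept.append(x)
            vals.append(ev(x))
        return np.asarray(kept, float), np.asarray(vals, float)

    # --- diversification: Latin hypercube over the box -------------------
    n_div = max(diverse_factor * dim, 2 * refset_size)
    X, F = evaluate_set(lhs(n_div))
    if len(X) == 0:
        raise EstimationError("budget exhausted before any evaluation")

    def build_refset(X: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(F, kind="stable")
        nq = refset_size // 2
        quality = list(order[:nq])
        rest = [i for i in order[nq:]]
        if rest:
            div = _greedy_diverse(X[rest], X[quality], min(refset_size - nq, len(rest)),
                                  span)
            quality += [rest[i] for i in div]
        R, RF = X[quality], F[quality]
        order = np.argsort(RF, kind="stable")
        return R[order], RF[order]

    R, RF = build_refset(X, F)
    b = len(R)
    stall = 0
    while not ev.exhausted:
        prev_best = RF[0]
        children, child_f = [], []
        for i in range(b):
            for j in range(i + 1, b):
                if ev.exhausted:
                    break
                xi, xj = R[i], R[j]
                d = (xj - xi) / 2.0
                alpha = 1.0 if RF[i] <= RF[j] else -1.0
                beta = (j - i - 1) / (b - 2) if b > 2 else 0.0
                c1 = xi - d * (1 + alpha * beta)
                c2 = xi + d * (1 - alpha * beta)
                child = np.clip(c1 + (c2 - c1) * rng.random(dim), lower, upper)
                f_child = ev(child)
                # go-beyond: keep stepping while the direction improves
                parent, pf = xi, RF[i]
                step = child - parent
                factor = 1.0
                while f_child < pf and not ev.exhausted:
                    parent, pf = child, f_child
                    cand = np.clip(child + step * factor * rng.uniform(0.5, 1.0),
                                   lower, upper)
                    f_cand = ev(cand)
                    if f_cand < f_child:
                        child, f_child = cand, f_cand
                        factor *= 2.0
                        step = child - parent
                    else:
                        break
                children.append(child)
                child_f.append(f_child)
        if children:
            pool = np.vstack([R, np.asarray(children)])
            pool_f = np.concatenate([RF, np.asarray(child_f)])
            # quality selection with a minimum-separation guard
            order = np.argsort(pool_f, kind="stable")
            newR, newF = [], []
            for k in order:
                if len(newR) == b:
                    break
                x = pool[k]
                if all(np.linalg.norm((x - y) / span) > 1e-8 for y in newR):
                    newR.append(x)
                    newF.append(pool_f[k])
            R = np.asarray(newR)
            RF = np.asarray(newF)
            b = len(R)
        if RF[0] < prev_best - 1e-15:
            stall = 0
        else:
            stall += 1
        if stall >= stall_limit and not ev.exhausted:
            # regeneration: keep only the incumbent, rebuild the reference
            # set from a fresh diverse sample (an in-run restart)
            Xn, Fn = evaluate_set(lhs(max(diverse_factor * dim, b)))
            if len(Xn):
                pool = np.vstack([R[:1], Xn])
                pool_f = np.concatenate([RF[:1], Fn])
                R, RF = build_refset(pool, pool_f)
                b = len(R)
            stall = 0
    assert ev.best_x is not None
    return OptimizationRun(ev.best_x, ev.best_f, ev.n, seed, ev.trace)


@dataclass
class Ensemble:
    """Best parameter sets from independent optimization runs."""

    runs: list[OptimizationRun]
    gene_names: tuple[str, ...]
    maternal_name: str
    model: str = gc.SIMPLIFIED

    def __post_init__(self) -> None:
        seeds = [r.seed for r in self.runs]
        if len(set(seeds)) != len(seeds):
            raise EstimationError("ensemble runs must have distinct seeds")

    def __len__(self) -> int:
        return len(self.runs)

    def param_sets(self) -> list[gc.GeneCircuitParams]:
        return [gc.GeneCircuitParams.from_vector(r.best_x, self.gene_names, self.model)
                for r in self.runs]

    def parameter_matrix(self) -> np.ndarray:
        """(n_runs, n_parameters) matrix of best vectors."""
        return np.vstack([r.best_x for r in self.runs])

    def best_run(self) -> OptimizationRun:
        return min(self.runs, key=lambda r: r.best_value)

    def to_dict(self) -> dict:
        return {"gene_names": list(self.gene_names), "maternal_name": self.maternal_name,
                "model": self.model, "runs": [r.to_dict() for r in self.runs]}

    @classmethod
    def from_dict(cls, d: dict) -> "Ensemble":
        return cls([OptimizationRun.from_dict(r) for r in d["runs"]],
                   tuple(d["gene_names"]), str(d["maternal_name"]), str(d["model"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "Ensemble":
        return cls.from_dict(json.loads(Path(path).read_text()))


def run_ensemble(reference: gc.ReferenceData, config: FitConfig,
                 n_runs: int = 100) -> Ensemble:
    """Independent scatter-search runs with seeds ``config.seed + 0..n-1``.

    Individual run failures are logged and skipped; the ensemble fails only
    if every run fails.
    """
    if n_runs < 2:
        raise EstimationError("an ensemble needs at least 2 runs")
    runs: list[OptimizationRun] = []
    for k in range(n_runs):
        objective = CircuitObjective(reference, config)
        lo, hi = objective.bounds()
        try:
            run = scatter_search(objective, lo, hi, budget=config.budget,
                                 seed=config.seed + k,
                                 refset_size=config.refset_size,
                                 diverse_factor=config.diverse_factor,
                                 stall_limit=config.stall_limit)
        except EstimationError as exc:
            logger.warning("optimization run %d failed: %s", k, exc)
            continue
        runs.append(run)
    if not runs:
        raise EstimationError("all optimization runs failed")
    return Ensemble(runs, reference.gene_names, reference.maternal_name, config.model)
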