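"""Gene-circuit ODE model on a one-dimensional chain of cell-layer points.

The model is the connectionist gene-circuit formalism: the production rate of
each gene product is a sigmoid of a weighted sum of regulator concentrations,
and each product decays linearly.  For gene ``i`` at spatial point ``a``::

    dP_i^a/dt = R_i * s( sum_j T_ij P_j^a + m_i P_mat^a + h_i )
                + D_i * (P_i^{a-1} - 2 P_i^a + P_i^{a+1})
                - lambda_i * P_i^a

with interaction matrix ``T``, maternal influence ``m`` of a fixed maternal
gradient ``P_mat``, constant influence ``h``, production rate ``R``, diffusion
coefficient ``D``, decay rate ``lambda`` (per hour) and the sigmoid
``s(f) = 1/2 + arctan(f)/pi``.

Two parameterizations are exposed:

* ``"simplified"`` — ``R`` fixed at 1 and ``D`` at 0, leaving ``n*(n+3)``
  free parameters for ``n`` interacting genes (T, m, h, lambda).  This is the
  model actually fitted: with unit-normalized reference profiles the
  production rate is confounded with decay, and on a changing 2-D cell layer
  a meaningful diffusion term would have to be time dependent.
* ``"full"`` — ``R`` and ``D`` free as well, ``n*(n+5)`` parameters.

Spatial points are uncoupled whenever ``D = 0``; diffusion, when enabled,
uses a discrete Laplacian with no-flux (reflecting) boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

SIMPLIFIED = "simplified"
FULL = "full"
_MODELS = (SIMPLIFIED, FULL)


class GeneCircuitError(ValueError):
    """Invalid parameters, reference data or failed simulation."""


def sigmoid(f):
    """Regulation sigmoid ``s(f) = 1/2 + arctan(f)/pi``, strictly in (0, 1)."""
    return 0.5 + np.arctan(f) / np.pi


def sigmoid_deriv(f):
    """Derivative ``s'(f) = 1 / (pi (1 + f^2))`` of the regulation sigmoid."""
    return 1.0 / (np.pi * (1.0 + np.square(f)))


def n_free_parameters(n_genes: int, model: str = SIMPLIFIED) -> int:
    """Number of optimization variables for ``n_genes`` interacting genes.

    ``n (n + 3)`` for the simplified model (T, m, h, lambda) and ``n (n + 5)``
    for the full model (additionally R and D).
    """
    if model == SIMPLIFIED:
        return n_genes * (n_genes + 3)
    if model == FULL:
        return n_genes * (n_genes + 5)
    raise GeneCircuitError(f"unknown model {model!r}; expected one of {_MODELS}")


def _vec(x, n, name) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (n,):
        raise GeneCircuitError(f"{name} must have shape ({n},), got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise GeneCircuitError(f"{name} contains non-finite values")
    return v


@dataclass(frozen=True)
class GeneCircuitParams:
    """Parameters of one gene circuit over ``n`` interacting genes.

    ``T`` is the n-by-n interaction matrix (``T[i, j]`` = effect of gene j on
    gene i), ``m`` the per-gene maternal influence, ``h`` the constant
    influence, ``lam`` the decay rate in 1/hour (strictly positive).  ``R``
    (production rate, default 1) and ``D`` (diffusion coefficient, default 0)
    belong to the full model.
    """

    gene_names: tuple[str, ...]
    T: np.ndarray
    m: np.ndarray
    h: np.ndarray
    lam: np.ndarray
    R: np.ndarray | None = None
    D: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = tuple(str(g) for g in self.gene_names)
        n = len(names)
        if n == 0:
            raise GeneCircuitError("need at least one interacting gene")
        object.__setattr__(self, "gene_names", names)
        T = np.asarray(self.T, dtype=float)
        if T.shape != (n, n) or not np.all(np.isfinite(T)):
            raise GeneCircuitError(f"T must be a finite ({n}, {n}) matrix")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "m", _vec(self.m, n, "m"))
        object.__setattr__(self, "h", _vec(self.h, n, "h"))
        lam = _vec(self.lam, n, "lam")
        if np.any(lam <= 0):
            raise GeneCircuitError("decay rates lambda must be strictly positive")
        object.__setattr__(self, "lam", lam)
        R = np.ones(n) if self.R is None else _vec(self.R, n, "R")
        D = np.zeros(n) if self.D is None else _vec(self.D, n, "D")
        if np.any(D < 0):
            raise GeneCircuitError("diffusion coefficients must be non-negative")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "D", D)

    @property
    def n(self) -> int:
        return len(self.gene_names)

    def to_vector(self, model: str = SIMPLIFIED) -> np.ndarray:
        """Flatten to the optimization vector: T row-major, m, h, lambda
        (then R, D for the full model)."""
        blocks = [self.T.ravel(), self.m, self.h, self.lam]
        if model == FULL:
            blocks += [self.R, self.D]
        elif model != SIMPLIFIED:
            raise GeneCircuitError(f"unknown model {model!r}")
        v = np.concatenate(blocks)
        assert v.size == n_free_parameters(self.n, model)
        return v

    @classmethod
    def from_vector(cls, vector, gene_names: Sequence[str],
                    model: str = SIMPLIFIED) -> "GeneCircuitParams":
        names = tuple(gene_names)
        n = len(names)
        v = np.asarray(vector, dtype=float).ravel()
        if v.size != n_free_parameters(n, model):
            raise GeneCircuitError(
                f"vector length {v.size} != {n_free_parameters(n, model)} for "
                f"{model} model with {n} genes")
        T = v[: n * n].reshape(n, n)
        m, h, lam = (v[n * n + k * n: n * n + (k + 1) * n] for k in range(3))
        R = D = None
        if model == FULL:
            R = v[n * n + 3 * n: n * n + 4 * n]
            D = v[n * n + 4 * n: n * n + 5 * n]
        return cls(names, T, m, h, lam, R, D)

    def replace_scalar(self, param_id: tuple, value: float) -> "GeneCircuitParams":
        """Copy with one scalar parameter replaced (see :func:`parameter_ids`)."""
        block = param_id[0]
        kw = {"gene_names": self.gene_names, "T": self.T.copy(), "m": self.m.copy(),
              "h": self.h.copy(), "lam": self.lam.copy(), "R": self.R.copy(),
              "D": self.D.copy()}
        if block == "T":
            kw["T"][param_id[1], param_id[2]] = value
        elif block in ("m", "h", "lam", "R", "D"):
            kw[block][param_id[1]] = value
        else:
            raise GeneCircuitError(f"unknown parameter block {block!r}")
        return GeneCircuitParams(**kw)

    def scalar(self, param_id: tuple) -> float:
        block = param_id[0]
        if block == "T":
            return float(self.T[param_id[1], param_id[2]])
        return float(getattr(self, block if block != "lam" else "lam")[param_id[1]])

    def to_dict(self) -> dict:
        return {"gene_names": list(self.gene_names), "T": self.T.tolist(),
                "m": self.m.tolist(), "h": self.h.tolist(), "lam": self.lam.tolist(),
                "R": self.R.tolist(), "D": self.D.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GeneCircuitParams":
        return cls(tuple(d["gene_names"]), np.asarray(d["T"], float),
                   np.asarray(d["m"], float), np.asarray(d["h"], float),
                   np.asarray(d["lam"], float),
                   np.asarray(d["R"], float) if "R" in d else None,
                   np.asarray(d["D"], float) if "D" in d else None)


def parameter_ids(n_genes: int, model: str = SIMPLIFIED) -> list[tuple]:
    """Scalar parameter identifiers in optimization-vector order.

    Each id is ``("T", i, j)`` or ``(block, i)`` with block in
    {m, h, lam, R, D}; indices are 0-based gene indices.
    """
    ids: list[tuple] = [("T", i, j) for i in range(n_genes) for j in range(n_genes)]
    blocks = ["m", "h", "lam"] + (["R", "D"] if model == FULL else [])
    for b in blocks:
        ids += [(b, i) for i in range(n_genes)]
    assert len(ids) == n_free_parameters(n_genes, model)
    return ids


def parameter_label(param_id: tuple, gene_names: Sequence[str],
                    maternal_name: str = "maternal") -> str:
    """Human-readable label, e.g. ``T[snail<-foxA]`` or ``m[snail]``."""
    block = param_id[0]
    if block == "T":
        return f"T[{gene_names[param_id[1]]}<-{gene_names[param_id[2]]}]"
    if block == "m":
        return f"m[{gene_names[param_id[1]]}<-{maternal_name}]"
    return f"{block}[{gene_names[param_id[1]]}]"


def rhs(P: np.ndarray, params: GeneCircuitParams,
        maternal: np.ndarray) -> np.ndarray:
    """Time derivative of the concentration matrix ``P`` (genes x points)."""
    P = np.asarray(P, dtype=float)
    maternal = np.asarray(maternal, dtype=float)
    if P.ndim != 2 or P.shape[0] != params.n or P.shape[1] != maternal.size:
        raise GeneCircuitError(
            f"state must have shape ({params.n}, {maternal.size}), got {P.shape}")
    if not np.all(np.isfinite(P)):
        raise GeneCircuitError("non-finite concentrations in state")
    f = params.T @ P + np.outer(params.m, maternal) + params.h[:, None]
    dP = params.R[:, None] * sigmoid(f) - params.lam[:, None] * P
    if np.any(params.D > 0):
        dP += params.D[:, None] * _laplacian_no_flux(P)
    return dP


def _laplacian_no_flux(P: np.ndarray) -> np.ndarray:
    lap = np.empty_like(P)
    lap[:, 1:-1] = P[:, :-2] - 2.0 * P[:, 1:-1] + P[:, 2:]
    lap[:, 0] = P[:, 1] - P[:, 0]
    lap[:, -1] = P[:, -2] - P[:, -1]
    return lap


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories sampled at requested times.

    ``concentrations`` has shape (n_times, n_genes, n_points).
    """

    times: np.ndarray
    concentrations: np.ndarray
    gene_names: tuple[str, ...]

    @property
    def n_points(self) -> int:
        return self.concentrations.shape[2]

    def at_time(self, t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[k] - t) > 1e-9:
            raise GeneCircuitError(f"time {t} was not simulated")
        return self.concentrations[k]


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise GeneCircuitError("times must start at 0 and be strictly increasing")
    return t


def simulate(params: GeneCircuitParams, initial: np.ndarray, maternal: np.ndarray,
             times, rtol: float = 1e-6, atol: float = 1e-9,
             method: str = "RK45") -> SimulationResult:
    """Integrate the circuit from ``initial`` (genes x points), sampling at
    ``times`` (hours, starting at 0).

    Uses an adaptive explicit Runge-Kutta scheme; the vector field is smooth
    and non-stiff over the fitted parameter ranges.  Raises
    :class:`GeneCircuitError` on solver failure or non-finite output.
    """
    t = _check_times(times)
    maternal = np.asarray(maternal, dtype=float).ravel()
    P0 = np.asarray(initial, dtype=float)
    n, A = params.n, maternal.size
    if P0.shape != (n, A):
        raise GeneCircuitError(f"initial state must have shape ({n}, {A})")

    def fun(_t, y):
        P = y.reshape(n, A)
        f = params.T @ P + np.outer(params.m, maternal) + params.h[:, None]
        dP = params.R[:, None] * sigmoid(f) - params.lam[:, None] * P
        if np.any(params.D > 0):
            dP += params.D[:, None] * _laplacian_no_flux(P)
        return dP.ravel()

    sol = solve_ivp(fun, (t[0], t[-1]), P0.ravel(), t_eval=t, method=method,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise GeneCircuitError(f"ODE solver failed: {sol.message}")
    conc = sol.y.T.reshape(len(t), n, A)
    if not np.all(np.isfinite(conc)):
        raise GeneCircuitError("simulation produced non-finite concentrations")
    # trajectories are analytically non-negative from non-negative starts;
    # clip integrator round-off only
    if conc.min() < -1e-6:
        raise GeneCircuitError("simulation produced significantly negative concentrations")
    conc = np.maximum(conc, 0.0)
    return SimulationResult(t, conc, params.gene_names)


@dataclass(frozen=True)
class ReferenceData:
    """Observed (or synthetic) profiles the circuit is fitted against.

    ``initial`` holds the interacting genes' profiles at t = 0 (all zero in
    the gut-formation setup), ``targets`` the fitting targets with shape
    (n_target_times, n_genes, n_points), and ``maternal_profile`` the fixed
    maternal gradient applied at every time.
    """

    gene_names: tuple[str, ...]
    maternal_name: str
    maternal_profile: np.ndarray
    initial: np.ndarray
    target_times: tuple[float, ...]
    targets: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(str(g) for g in self.gene_names)
        object.__setattr__(self, "gene_names", names)
        mat = np.asarray(self.maternal_profile, dtype=float).ravel()
        init = np.asarray(self.initial, dtype=float)
        tt = tuple(float(x) for x in self.target_times)
        targ = np.asarray(self.targets, dtype=float)
        n, A = len(names), mat.size
        if init.shape != (n, A):
            raise GeneCircuitError(f"initial must have shape ({n}, {A})")
        if targ.shape != (len(tt), n, A):
            raise GeneCircuitError(f"targets must have shape ({len(tt)}, {n}, {A})")
        if any(t <= 0 for t in tt) or np.any(np.diff(tt) <= 0):
            raise GeneCircuitError("target times must be positive and increasing")
        if not (np.all(np.isfinite(mat)) and np.all(np.isfinite(init))
                and np.all(np.isfinite(targ))):
            raise GeneCircuitError("reference data contains non-finite values")
        object.__setattr__(self, "maternal_profile", mat)
        object.__setattr__(self, "initial", init)
        object.__setattr__(self, "target_times", tt)
        object.__setattr__(self, "targets", targ)

    @property
    def n(self) -> int:
        return len(self.gene_names)

    @property
    def n_points(self) -> int:
        return self.maternal_profile.size

    @property
    def all_times(self) -> tuple[float, ...]:
        return (0.0,) + self.target_times

    def to_dict(self) -> dict:
        return {"gene_names": list(self.gene_names), "maternal_name": self.maternal_name,
                "maternal_profile": self.maternal_profile.tolist(),
                "initial": self.initial.tolist(),
                "target_times": list(self.target_times),
                "targets": self.targets.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceData":
        return cls(tuple(d["gene_names"]), str(d["maternal_name"]),
                   np.asarray(d["maternal_profile"], float),
                   np.asarray(d["initial"], float), tuple(d["target_times"]),
                   np.asarray(d["targets"], float))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceData":
        return cls.from_dict(json.loads(Path(path).read_text()))
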