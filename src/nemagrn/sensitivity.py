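"""Local parameter sensitivities of fitted gene circuits.

A parameter's sensitivity is defined from the derivatives of all simulated
concentrations with respect to the parameter at an evaluation time: the
absolute derivatives are averaged along the cell layer for each gene, and
the highest of these per-gene averages is the system's sensitivity towards
the parameter.  Absolute values make the quantity comparable across
parameters of either regulatory sign.

Two methods are exposed:

* ``"fd"`` (default): central finite differences with step
  ``max(1e-4, 1e-4 |theta|)``.  Simulations for differencing run at tight
  solver tolerances so the difference quotient is not dominated by
  integration error.
* ``"fsa"``: forward sensitivity analysis, integrating the variational ODE
  ``dS/dt = R s'(f) (T S + df/dtheta) - lambda S - [theta = lambda_i] P``
  jointly with the model.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import gene_circuit as gc
from .estimation import Ensemble

FD_REL_STEP = 1e-4
FD_MIN_STEP = 1e-4
#: Solver tolerances used inside sensitivity computations (tighter than the
#: fitting default so finite differences of trajectories remain meaningful).
SENS_RTOL = 1e-10
SENS_ATOL = 1e-12


class SensitivityError(ValueError):
    pass


def _sim_at(params: gc.GeneCircuitParams, reference: gc.ReferenceData,
            t_eval: float) -> np.ndarray:
    result = gc.simulate(params, reference.initial, reference.maternal_profile,
                         (0.0, t_eval), rtol=SENS_RTOL, atol=SENS_ATOL)
    return result.concentrations[-1]


def _fd_sensitivity(params, reference, param_id, t_eval, step=None) -> float:
    theta = params.scalar(param_id)
    if step is None:
        step = max(FD_MIN_STEP, FD_REL_STEP * abs(theta))
    if param_id[0] == "lam" and theta - step <= 0:
        step = theta / 2.0
    try:
        plus = _sim_at(params.replace_scalar(param_id, theta + step), reference, t_eval)
        minus = _sim_at(params.replace_scalar(param_id, theta - step), reference, t_eval)
    except gc.GeneCircuitError as exc:
        raise SensitivityError(f"simulation failed under perturbation: {exc}") from exc
    deriv = np.abs(plus - minus) / (2.0 * step)  # (n_genes, n_points)
    return float(deriv.mean(axis=1).max())


def _fsa_sensitivity(params, reference, param_id, t_eval) -> float:
    n, A = params.n, reference.n_points
    maternal = reference.maternal_profile
    block = param_id[0]

    def fun(_t, y):
        P = y[: n * A].reshape(n, A)
        S = y[n * A:].reshape(n, A)
        f = params.T @ P + np.outer(params.m, maternal) + params.h[:, None]
        g = gc.sigmoid_deriv(f)
        dP = params.R[:, None] * gc.sigmoid(f) - params.lam[:, None] * P
        # explicit df/dtheta at fixed state, plus non-sigmoid direct terms
        E = np.zeros((n, A))
        extra = np.zeros((n, A))
        if block == "T":
            E[param_id[1]] = P[param_id[2]]
        elif block == "m":
            E[param_id[1]] = maternal
        elif block == "h":
            E[param_id[1]] = 1.0
        elif block == "lam":
            extra[param_id[1]] = -P[param_id[1]]
        elif block == "R":
            extra[param_id[1]] = gc.sigmoid(f[param_id[1]])
        elif block == "D":
            extra[param_id[1]] = gc._laplacian_no_flux(P)[param_id[1]]
        else:
            raise SensitivityError(f"unknown parameter block {block!r}")
        dS = params.R[:, None] * g * (params.T @ S + E) - params.lam[:, None] * S + extra
        if np.any(params.D > 0):
            dP += params.D[:, None] * gc._laplacian_no_flux(P)
            dS += params.D[:, None] * gc._laplacian_no_flux(S)
        return np.concatenate([dP.ravel(), dS.ravel()])

    y0 = np.concatenate([reference.initial.ravel(), np.zeros(n * A)])
    sol = solve_ivp(fun, (0.0, t_eval), y0, t_eval=[t_eval], rtol=SENS_RTOL,
                    atol=SENS_ATOL)
    if not sol.success:
        raise SensitivityError(f"forward sensitivity solve failed: {sol.message}")
    S = np.abs(sol.y[n * A:, -1].reshape(n, A))
    return float(S.mean(axis=1).max())


def parameter_sensitivity(params: gc.GeneCircuitParams,
                          reference: gc.ReferenceData, param_id: tuple,
                          t_eval: float | None = None, method: str = "fd",
                          fd_step: float | None = None) -> float:
    """Sensitivity of the circuit towards one scalar parameter.

    ``t_eval`` defaults to the last fitting target time.  The returned value
    is the maximum over genes of the cell-layer-averaged absolute derivative
    of concentration with respect to the parameter at ``t_eval``.
    """
    if t_eval is None:
        t_eval = reference.target_times[-1]
    if t_eval <= 0:
        raise SensitivityError("t_eval must be positive")
    if method == "fd":
        return _fd_sensitivity(params, reference, param_id, t_eval, fd_step)
    if method == "fsa":
        return _fsa_sensitivity(params, reference, param_id, t_eval)
    raise SensitivityError("method must be 'fd' or 'fsa'")


def sensitivity_report(source, reference: gc.ReferenceData,
                       t_eval: float | None = None,
                       method: str = "fd") -> pd.DataFrame:
    """Per-parameter sensitivities for every run of an ensemble.

    Returns a long-format table with one row per (run, parameter) plus the
    per-parameter ensemble mean and standard deviation.  Per-run failures are
    excluded and counted in the ``n_failed`` column.
    """
    if isinstance(source, Ensemble):
        sets = source.param_sets()
        gene_names, mat = source.gene_names, source.maternal_name
    else:
        sets = list(source)
        if not sets:
            raise SensitivityError("empty ensemble")
        gene_names, mat = sets[0].gene_names, reference.maternal_name
    n = len(gene_names)
    ids = gc.parameter_ids(n, gc.SIMPLIFIED)
    rows = []
    for pid in ids:
        label = gc.parameter_label(pid, gene_names, mat)
        values, failed = [], 0
        for run_idx, params in enumerate(sets):
            try:
                s = parameter_sensitivity(params, reference, pid, t_eval, method)
            except SensitivityError:
                failed += 1
                continue
            values.append(s)
            rows.append({"parameter": label, "block": pid[0], "run": run_idx,
                         "sensitivity": s})
        arr = np.asarray(values)
        rows.append({"parameter": label, "block": pid[0], "run": -1,
                     "sensitivity": float(arr.mean()) if arr.size else np.nan,
                     "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                     "n_failed": failed})
    return pd.DataFrame(rows)
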