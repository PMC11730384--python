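"""Neuron-astrocyte mass model at a single network node.

Each node carries 14 state variables: three second-order postsynaptic
potential pairs (pyramidal cells, excitatory and inhibitory interneurons),
two second-order neurotransmitter release pairs (glutamate, GABA), and four
concentrations (extracellular and astrocytic glutamate and GABA).

The neuronal compartment is a Jansen-Rit-type circuit in which the firing
thresholds of pyramidal cells and inhibitory interneurons are modulated by
the extracellular neurotransmitter concentrations through the sigmoidal
excitability levels v_Glu and v_GABA.  The local field potential (LFP) is
the difference of the excitatory and inhibitory postsynaptic contributions
seen by the pyramidal population, E_ExIn - E_InIn.

All functions are vectorized: scalar arguments give scalars, arrays of node
values give arrays.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .params import ModelParameters

__all__ = [
    "STATE_FIELDS",
    "N_STATE_VARS",
    "ExcitabilityLevels",
    "sigmoid",
    "michaelis_menten",
    "excitability_levels",
    "firing_rates",
    "nodal_drift",
    "lfp",
    "find_node_equilibrium",
]

#: Order of the 14 per-node state variables in every state array.
STATE_FIELDS = (
    "E_Pyr", "dE_Pyr",
    "E_ExIn", "dE_ExIn",
    "E_InIn", "dE_InIn",
    "J_Glu", "dJ_Glu",
    "J_GABA", "dJ_GABA",
    "Glu_e", "Glu_Ast",
    "GABA_e", "GABA_Ast",
)
N_STATE_VARS = len(STATE_FIELDS)
_IDX = {name: i for i, name in enumerate(STATE_FIELDS)}


def sigmoid(x: ArrayLike, nu: float, r: float, theta: float, delta: float = 0.0):
    """Offset logistic function ``nu / (1 + exp(r*(theta - x))) - delta``.

    Strictly increasing in ``x`` with range ``(-delta, nu - delta)``.
    ``nu`` must be non-negative and the slope ``r`` positive.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid: non-finite input x")
    if nu < 0:
        raise ValueError(f"sigmoid: nu must be >= 0, got {nu}")
    if r <= 0:
        raise ValueError(f"sigmoid: slope r must be > 0, got {r}")
    with np.errstate(over="ignore"):
        out = nu / (1.0 + np.exp(r * (theta - x))) - delta
    return out if out.ndim else float(out)


def sigmoid_deriv(x: ArrayLike, nu: float, r: float, theta: float):
    """Derivative of :func:`sigmoid` with respect to ``x`` (offset-free)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(r * (theta - x)))
    out = nu * r * s * (1.0 - s)
    return out if out.ndim else float(out)


def michaelis_menten(x: ArrayLike, V: float, K: float):
    """Michaelis-Menten saturation ``V*x / (K + x)``; range ``[0, V)``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("michaelis_menten: negative concentration")
    if V < 0:
        raise ValueError(f"michaelis_menten: V must be >= 0, got {V}")
    if K <= 0:
        raise ValueError(f"michaelis_menten: K must be > 0, got {K}")
    out = V * x / (K + x)
    return out if out.ndim else float(out)


class ExcitabilityLevels(NamedTuple):
    v_Pyr: ArrayLike
    v_ExIn: ArrayLike
    v_InIn: ArrayLike
    v_Glu: ArrayLike
    v_GABA: ArrayLike


def excitability_levels(Glu_e: ArrayLike, GABA_e: ArrayLike,
                        p: ModelParameters) -> ExcitabilityLevels:
    """Firing-threshold modulation by extracellular neurotransmitters.

    Rising Glu_e lowers the thresholds of pyramidal cells and inhibitory
    interneurons (v_Pyr, v_InIn); rising GABA_e raises the pyramidal
    threshold.  Excitatory interneurons are unaffected (v_ExIn = v0).
    """
    Glu_e = np.asarray(Glu_e, dtype=float)
    GABA_e = np.asarray(GABA_e, dtype=float)
    v_Glu = sigmoid(Glu_e, p.m_Glu_Pyr, p.r_Glu_PyrInIn, p.theta_Glu_PyrInIn,
                    p.delta_Glu_Pyr)
    v_GABA = sigmoid(GABA_e, p.m_GABA_Pyr, p.r_GABA_Pyr, p.theta_GABA_Pyr,
                     p.delta_GABA_Pyr)
    v_Pyr = p.v0 + v_GABA - v_Glu
    v_ExIn = np.broadcast_to(np.float64(p.v0), Glu_e.shape) if Glu_e.ndim else p.v0
    v_InIn = p.v0 - p.mu_Glu_InIn_over_Pyr * np.asarray(v_Glu)
    if Glu_e.ndim == 0:
        return ExcitabilityLevels(float(v_Pyr), float(p.v0), float(v_InIn),
                                  float(v_Glu), float(v_GABA))
    return ExcitabilityLevels(v_Pyr, np.asarray(v_ExIn), v_InIn,
                              np.asarray(v_Glu), np.asarray(v_GABA))


def firing_rates(E_Pyr: ArrayLike, E_ExIn: ArrayLike, E_InIn: ArrayLike,
                 v: ExcitabilityLevels, p: ModelParameters):
    """Population firing rates from membrane potentials; all in [0, nu_max]."""
    E_Pyr = np.asarray(E_Pyr, dtype=float)
    E_ExIn = np.asarray(E_ExIn, dtype=float)
    E_InIn = np.asarray(E_InIn, dtype=float)
    with np.errstate(over="ignore"):
        F_Pyr = p.nu_max / (1.0 + np.exp(p.r * (np.asarray(v.v_Pyr) - (E_ExIn - E_InIn))))
        F_ExIn = p.nu_max / (1.0 + np.exp(p.r * (np.asarray(v.v_ExIn) - p.C_Pyr_to_ExIn * E_Pyr)))
        F_InIn = p.nu_max / (1.0 + np.exp(p.r * (np.asarray(v.v_InIn) - p.C_Pyr_to_InIn * E_Pyr)))
    if E_Pyr.ndim == 0:
        return float(F_Pyr), float(F_ExIn), float(F_InIn)
    return F_Pyr, F_ExIn, F_InIn


def lfp(state: NDArray) -> NDArray:
    """Local field potential E_ExIn - E_InIn (last axis holds the 14 fields)."""
    state = np.asarray(state, dtype=float)
    return state[..., _IDX["E_ExIn"]] - state[..., _IDX["E_InIn"]]


def _check_state(state: NDArray) -> None:
    bad = ~np.isfinite(state)
    if bad.any():
        which = np.argwhere(bad)[0]
        raise FloatingPointError(
            f"non-finite state variable {STATE_FIELDS[which[-1]]!r} "
            f"at index {tuple(which[:-1])}"
        )


def nodal_drift(state: NDArray, Q_Pyr: ArrayLike, Q_Ast_Glu: ArrayLike,
                Q_Ast_GABA: ArrayLike, q: ArrayLike,
                p: ModelParameters) -> NDArray:
    """Deterministic drift of the 14 state variables given feedback inputs.

    ``state`` has shape ``(..., 14)`` with fields ordered as
    :data:`STATE_FIELDS`; the feedback terms and the baseline input ``q``
    broadcast against the leading axes.  Returns an array of the same shape.
    """
    state = np.atleast_2d(np.asarray(state, dtype=float))
    _check_state(state)
    squeeze = state.shape[0] == 1 and np.ndim(Q_Pyr) == 0

    (E_Pyr, dE_Pyr, E_ExIn, dE_ExIn, E_InIn, dE_InIn,
     J_Glu, dJ_Glu, J_GABA, dJ_GABA, Glu_e, Glu_Ast, GABA_e, GABA_Ast) = state.T

    v = excitability_levels(Glu_e, GABA_e, p)
    F_Pyr, F_ExIn, F_InIn = firing_rates(E_Pyr, E_ExIn, E_InIn, v, p)

    out = np.empty_like(state)
    # Postsynaptic potential dynamics (second-order synaptic filters)
    out[:, 0] = dE_Pyr
    out[:, 1] = p.A * p.a * F_Pyr - 2.0 * p.a * dE_Pyr - p.a**2 * E_Pyr
    out[:, 2] = dE_ExIn
    out[:, 3] = (p.A * p.a * (p.C_ExIn_to_Pyr * F_ExIn + Q_Pyr + q)
                 - 2.0 * p.a * dE_ExIn - p.a**2 * E_ExIn)
    out[:, 4] = dE_InIn
    out[:, 5] = (p.B * p.b * p.C_InIn_to_Pyr * F_InIn
                 - 2.0 * p.b * dE_InIn - p.b**2 * E_InIn)
    # Glutamate release and concentrations
    out[:, 6] = dJ_Glu
    out[:, 7] = (p.W * p.w_r * (F_Pyr + Q_Ast_Glu)
                 - (p.w_r + p.w_d) * dJ_Glu - p.w_r * p.w_d * J_Glu)
    uptake_glu_ast = sigmoid(Glu_e, p.V_Glue_Ast, p.r_Glue_AstPyr, p.theta_Glue_AstPyr)
    uptake_glu_pyr = sigmoid(Glu_e, p.V_Glue_Pyr, p.r_Glue_AstPyr, p.theta_Glue_AstPyr)
    out[:, 10] = J_Glu - uptake_glu_ast - uptake_glu_pyr
    out[:, 11] = uptake_glu_ast - Glu_Ast / p.tau_GluAst
    # GABA release and concentrations
    out[:, 8] = dJ_GABA
    out[:, 9] = (p.Z * p.z_r * (F_InIn + Q_Ast_GABA)
                 - (p.z_r + p.z_d) * dJ_GABA - p.z_r * p.z_d * J_GABA)
    # Michaelis-Menten uptake evaluated without the non-negativity guard:
    # transient tiny negatives at coarse dt are diagnosed, not clamped.
    uptake_gaba_ast = p.V_GABAe_Ast * GABA_e / (p.K_GABAe_Ast + GABA_e)
    uptake_gaba_inin = p.V_GABAe_InIn * GABA_e / (p.K_GABAe_InIn + GABA_e)
    out[:, 12] = J_GABA - uptake_gaba_ast - uptake_gaba_inin
    out[:, 13] = uptake_gaba_ast - GABA_Ast / p.tau_GABAAst
    return out[0] if squeeze else out


def find_node_equilibrium(p: ModelParameters, q: float | None = None,
                          Q_Pyr: float = 0.0, Q_Ast_Glu: float = 0.0,
                          Q_Ast_GABA: float = 0.0,
                          tol: float = 1e-12, max_iter: int = 200) -> NDArray:
    """Equilibrium of the isolated 14-dimensional node by damped Newton.

    With constant input ``q`` (default ``q_mean``) and frozen feedback
    terms, solves ``drift(x) = 0``.  The returned root has drift max-norm
    below ``tol`` scaled by the drift magnitude at the starting point.
    """
    if q is None:
        q = p.q_mean

    def drift(x: NDArray) -> NDArray:
        return np.atleast_1d(nodal_drift(x, Q_Pyr, Q_Ast_Glu, Q_Ast_GABA, q, p))

    def neuronal_balance(Glu_e: float, GABA_e: float):
        """Equilibrium potentials/rates at frozen concentrations via a
        scalar scan-and-bisect in u = E_ExIn - E_InIn."""
        v = excitability_levels(Glu_e, GABA_e, p)

        def mismatch(u: float) -> float:
            F_Pyr = sigmoid(u, p.nu_max, p.r, v.v_Pyr)
            E_Pyr = p.A * F_Pyr / p.a
            F_ExIn = sigmoid(p.C_Pyr_to_ExIn * E_Pyr, p.nu_max, p.r, v.v_ExIn)
            F_InIn = sigmoid(p.C_Pyr_to_InIn * E_Pyr, p.nu_max, p.r, v.v_InIn)
            return (p.A * (p.C_ExIn_to_Pyr * F_ExIn + Q_Pyr + q) / p.a
                    - p.B * p.C_InIn_to_Pyr * F_InIn / p.b - u)

        lo = -p.B * p.C_InIn_to_Pyr * p.nu_max / p.b - 1.0
        hi = p.A * (p.C_ExIn_to_Pyr * p.nu_max + Q_Pyr + q) / p.a + 1.0
        us = np.linspace(lo, hi, 801)
        ms = np.array([mismatch(u) for u in us])
        idx = np.flatnonzero(ms[:-1] * ms[1:] <= 0)
        a_, b_ = (us[idx[0]], us[idx[0] + 1]) if idx.size else (lo, hi)
        for _ in range(80):
            m_ = 0.5 * (a_ + b_)
            if mismatch(a_) * mismatch(m_) <= 0:
                b_ = m_
            else:
                a_ = m_
        u = 0.5 * (a_ + b_)
        F_Pyr = sigmoid(u, p.nu_max, p.r, v.v_Pyr)
        E_Pyr = p.A * F_Pyr / p.a
        F_ExIn = sigmoid(p.C_Pyr_to_ExIn * E_Pyr, p.nu_max, p.r, v.v_ExIn)
        F_InIn = sigmoid(p.C_Pyr_to_InIn * E_Pyr, p.nu_max, p.r, v.v_InIn)
        return E_Pyr, F_Pyr, F_ExIn, F_InIn

    def solve_monotone(balance, target: float, hi0: float, what: str) -> float:
        """Root of the increasing uptake curve balance(x) = target."""
        if target <= 0:
            return 0.0
        hi = hi0
        while balance(hi) < target:
            hi *= 2.0
            if hi > 1e9:
                raise RuntimeError(
                    f"{what} release exceeds total uptake capacity; "
                    "no equilibrium concentration exists")
        lo = 0.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if balance(mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # Damped Gauss-Seidel between the fast (neuronal) and slow
    # (neurotransmitter) balances.
    Glu_e, GABA_e = p.theta_Glue_AstPyr, p.K_GABAe_Ast
    for _ in range(max_iter):
        E_Pyr, F_Pyr, F_ExIn, F_InIn = neuronal_balance(Glu_e, GABA_e)
        J_Glu = p.W * (F_Pyr + Q_Ast_Glu) / p.w_d
        J_GABA = p.Z * (F_InIn + Q_Ast_GABA) / p.z_d
        glu_new = solve_monotone(
            lambda c: (sigmoid(c, p.V_Glue_Ast, p.r_Glue_AstPyr, p.theta_Glue_AstPyr)
                       + sigmoid(c, p.V_Glue_Pyr, p.r_Glue_AstPyr, p.theta_Glue_AstPyr)),
            J_Glu, 4.0 * p.theta_Glue_AstPyr, "glutamate")
        gaba_new = solve_monotone(
            lambda c: (michaelis_menten(c, p.V_GABAe_Ast, p.K_GABAe_Ast)
                       + michaelis_menten(c, p.V_GABAe_InIn, p.K_GABAe_InIn)),
            J_GABA, 4.0 * p.K_GABAe_Ast, "GABA")
        delta = max(abs(glu_new - Glu_e), abs(gaba_new - GABA_e))
        Glu_e += 0.5 * (glu_new - Glu_e)
        GABA_e += 0.5 * (gaba_new - GABA_e)
        if delta < 1e-12:
            break
    else:
        raise RuntimeError("concentration fixed point did not converge")

    E_Pyr, F_Pyr, F_ExIn, F_InIn = neuronal_balance(Glu_e, GABA_e)
    x = np.zeros(N_STATE_VARS)
    x[_IDX["E_Pyr"]] = E_Pyr
    x[_IDX["E_ExIn"]] = p.A * (p.C_ExIn_to_Pyr * F_ExIn + Q_Pyr + q) / p.a
    x[_IDX["E_InIn"]] = p.B * p.C_InIn_to_Pyr * F_InIn / p.b
    x[_IDX["J_Glu"]] = p.W * (F_Pyr + Q_Ast_Glu) / p.w_d
    x[_IDX["J_GABA"]] = p.Z * (F_InIn + Q_Ast_GABA) / p.z_d
    x[_IDX["Glu_e"]] = Glu_e
    x[_IDX["Glu_Ast"]] = p.tau_GluAst * sigmoid(
        Glu_e, p.V_Glue_Ast, p.r_Glue_AstPyr, p.theta_Glue_AstPyr)
    x[_IDX["GABA_e"]] = GABA_e
    x[_IDX["GABA_Ast"]] = p.tau_GABAAst * michaelis_menten(
        GABA_e, p.V_GABAe_Ast, p.K_GABAe_Ast)

    # Newton polish on the full 14-dimensional drift.
    for _ in range(50):
        f = drift(x)
        if np.max(np.abs(f)) < tol * max(1.0, np.max(np.abs(x))):
            return x
        # Finite-difference Jacobian (14x14; cheap and robust here).
        J = np.empty((N_STATE_VARS, N_STATE_VARS))
        h = 1e-7 * np.maximum(np.abs(x), 1.0)
        for j in range(N_STATE_VARS):
            xp = x.copy()
            xp[j] += h[j]
            xm = x.copy()
            xm[j] -= h[j]
            J[:, j] = (drift(xp) - drift(xm)) / (2.0 * h[j])
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Jacobian in equilibrium search") from exc
        lam = 1.0
        fnorm = np.linalg.norm(f)
        while lam > 1e-8:
            x_new = x + lam * step
            try:
                f_new = drift(x_new)
            except FloatingPointError:
                lam /= 2.0
                continue
            if np.linalg.norm(f_new) < fnorm:
                x = x_new
                break
            lam /= 2.0
        else:
            raise RuntimeError("equilibrium search stalled (no descent step)")
    raise RuntimeError("equilibrium search did not converge")
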