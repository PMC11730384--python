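"""Bifurcation analysis of the quasi-steady-state neuronal compartment.

Because extracellular glutamate and GABA evolve far more slowly than the
membrane potentials, their influence on the neuronal circuit can be frozen
into the two excitability levels (v_Glu, v_GABA) and treated as bifurcation
parameters of the reduced 6-dimensional system (the three postsynaptic
potential pairs).  Over the (v_Glu, v_GABA) plane this module locates
equilibria, their stability, the loci of supercritical Hopf points, and the
amplitude/frequency landscape of the stable periodic orbits together with
peak-to-peak amplitude isolines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from numpy.typing import NDArray

from .model import sigmoid, sigmoid_deriv
from .params import ModelParameters

__all__ = [
    "ReducedSystem",
    "PeriodicOrbitSummary",
    "reduced_drift",
    "find_equilibrium",
    "reduced_jacobian",
    "stability_eigenvalues",
    "hopf_locus",
    "characterize_orbit",
    "amplitude_isolines",
    "concentration_to_v",
    "v_to_concentration",
]

#: Orbit classification threshold on LFP peak-to-peak amplitude (mV).
PTP_THRESHOLD = 1e-3


@dataclass(frozen=True)
class ReducedSystem:
    """Neuronal compartment with frozen excitability levels.

    State: (E_Pyr, dE_Pyr, E_ExIn, dE_ExIn, E_InIn, dE_InIn).
    """

    params: ModelParameters
    v_Glu: float = 0.0       # mV
    v_GABA: float = 0.0      # mV
    q_const: float | None = None   # input rate; defaults to q_mean
    Q_Pyr_const: float = 0.0

    @property
    def q(self) -> float:
        return self.params.q_mean if self.q_const is None else self.q_const

    @property
    def v_Pyr(self) -> float:
        return self.params.v0 + self.v_GABA - self.v_Glu

    @property
    def v_InIn(self) -> float:
        return self.params.v0 - self.params.mu_Glu_InIn_over_Pyr * self.v_Glu


@dataclass
class PeriodicOrbitSummary:
    """Amplitude extrema and frequency of the attractor at one (v_Glu, v_GABA)."""

    v_Glu: float
    v_GABA: float
    amplitudes: dict = field(default_factory=dict)  # observable -> (min, max, ptp)
    frequency: float = 0.0   # Hz; 0 for non-periodic attractors
    classification: str = "stable_focus"  # stable_focus | periodic | other

    @property
    def ptp_lfp(self) -> float:
        return self.amplitudes["LFP"][2]


def reduced_drift(y: NDArray, sys: ReducedSystem) -> NDArray:
    """Drift of the 6-dimensional frozen-excitability compartment."""
    p = sys.params
    E_Pyr, dE_Pyr, E_ExIn, dE_ExIn, E_InIn, dE_InIn = y
    F_Pyr = sigmoid(E_ExIn - E_InIn, p.nu_max, p.r, sys.v_Pyr)
    F_ExIn = sigmoid(p.C_Pyr_to_ExIn * E_Pyr, p.nu_max, p.r, p.v0)
    F_InIn = sigmoid(p.C_Pyr_to_InIn * E_Pyr, p.nu_max, p.r, sys.v_InIn)
    return np.array([
        dE_Pyr,
        p.A * p.a * F_Pyr - 2 * p.a * dE_Pyr - p.a**2 * E_Pyr,
        dE_ExIn,
        p.A * p.a * (p.C_ExIn_to_Pyr * F_ExIn + sys.Q_Pyr_const + sys.q)
        - 2 * p.a * dE_ExIn - p.a**2 * E_ExIn,
        dE_InIn,
        p.B * p.b * p.C_InIn_to_Pyr * F_InIn - 2 * p.b * dE_InIn - p.b**2 * E_InIn,
    ])


def reduced_jacobian(y: NDArray, sys: ReducedSystem) -> NDArray:
    """Closed-form 6x6 Jacobian of :func:`reduced_drift`."""
    p = sys.params
    E_Pyr, _, E_ExIn, _, E_InIn, _ = y
    dF_Pyr = sigmoid_deriv(E_ExIn - E_InIn, p.nu_max, p.r, sys.v_Pyr)
    dF_ExIn = sigmoid_deriv(p.C_Pyr_to_ExIn * E_Pyr, p.nu_max, p.r, p.v0)
    dF_InIn = sigmoid_deriv(p.C_Pyr_to_InIn * E_Pyr, p.nu_max, p.r, sys.v_InIn)
    J = np.zeros((6, 6))
    J[0, 1] = 1.0
    J[1, 0] = -p.a**2
    J[1, 1] = -2 * p.a
    J[1, 2] = p.A * p.a * dF_Pyr
    J[1, 4] = -p.A * p.a * dF_Pyr
    J[2, 3] = 1.0
    J[3, 0] = p.A * p.a * p.C_ExIn_to_Pyr * dF_ExIn * p.C_Pyr_to_ExIn
    J[3, 2] = -p.a**2
    J[3, 3] = -2 * p.a
    J[4, 5] = 1.0
    J[5, 0] = p.B * p.b * p.C_InIn_to_Pyr * dF_InIn * p.C_Pyr_to_InIn
    J[5, 4] = -p.b**2
    J[5, 5] = -2 * p.b
    return J


def find_equilibrium(sys: ReducedSystem, residual_tol: float = 1e-10) -> list[NDArray]:
    """All equilibria of the reduced system, ordered by E_Pyr.

    The steady state reduces to a scalar fixed-point equation in
    u = E_ExIn - E_InIn (with E_Pyr = A*F_Pyr(u)/a), which is scanned
    densely for sign changes, bracketed by bisection, and polished by
    damped Newton in the full 6-dimensional drift.
    """
    p = sys.params

    def g(u: NDArray) -> NDArray:
        F_Pyr = sigmoid(u, p.nu_max, p.r, sys.v_Pyr)
        E_Pyr = p.A * np.asarray(F_Pyr) / p.a
        F_ExIn = sigmoid(p.C_Pyr_to_ExIn * E_Pyr, p.nu_max, p.r, p.v0)
        F_InIn = sigmoid(p.C_Pyr_to_InIn * E_Pyr, p.nu_max, p.r, sys.v_InIn)
        rhs = (p.A * (p.C_ExIn_to_Pyr * np.asarray(F_ExIn)
                      + sys.Q_Pyr_const + sys.q) / p.a
               - p.B * p.C_InIn_to_Pyr * np.asarray(F_InIn) / p.b)
        return rhs - u

    lo = -p.B * p.C_InIn_to_Pyr * p.nu_max / p.b - 1.0
    hi = p.A * (p.C_ExIn_to_Pyr * p.nu_max + sys.Q_Pyr_const + sys.q) / p.a + 1.0
    us = np.linspace(lo, hi, 4001)
    gs = g(us)
    roots_u = []
    for i in range(len(us) - 1):
        if gs[i] == 0.0:
            roots_u.append(us[i])
        elif gs[i] * gs[i + 1] < 0:
            a_, b_ = us[i], us[i + 1]
            for _ in range(80):
                m = 0.5 * (a_ + b_)
                if g(np.array([a_]))[0] * g(np.array([m]))[0] <= 0:
                    b_ = m
                else:
                    a_ = m
            roots_u.append(0.5 * (a_ + b_))

    equilibria = []
    for u in roots_u:
        F_Pyr = sigmoid(u, p.nu_max, p.r, sys.v_Pyr)
        E_Pyr = p.A * F_Pyr / p.a
        F_ExIn = sigmoid(p.C_Pyr_to_ExIn * E_Pyr, p.nu_max, p.r, p.v0)
        F_InIn = sigmoid(p.C_Pyr_to_InIn * E_Pyr, p.nu_max, p.r, sys.v_InIn)
        y = np.array([
            E_Pyr, 0.0,
            p.A * (p.C_ExIn_to_Pyr * F_ExIn + sys.Q_Pyr_const + sys.q) / p.a, 0.0,
            p.B * p.C_InIn_to_Pyr * F_InIn / p.b, 0.0,
        ])
        # Damped Newton polish on the full drift.
        for _ in range(60):
            f = reduced_drift(y, sys)
            if np.max(np.abs(f)) < residual_tol:
                break
            step = np.linalg.solve(reduced_jacobian(y, sys), -f)
            lam, fn = 1.0, np.linalg.norm(f)
            while lam > 1e-10:
                y_new = y + lam * step
                if np.linalg.norm(reduced_drift(y_new, sys)) < fn:
                    y = y_new
                    break
                lam /= 2.0
            else:
                break
        if np.max(np.abs(reduced_drift(y, sys))) >= residual_tol:
            raise RuntimeError(
                f"Newton polish failed at (v_Glu={sys.v_Glu}, v_GABA={sys.v_GABA}); "
                f"residual {np.max(np.abs(reduced_drift(y, sys))):.2e}")
        if not any(np.allclose(y, e, atol=1e-8) for e in equilibria):
            equilibria.append(y)
    if not equilibria:
        raise RuntimeError("no equilibrium found (scan range exhausted)")
    equilibria.sort(key=lambda e: e[0])
    return equilibria


def stability_eigenvalues(sys: ReducedSystem, eq: NDArray) -> NDArray:
    """Eigenvalues of the analytic Jacobian, sorted by descending real part."""
    lam = np.linalg.eigvals(reduced_jacobian(eq, sys))
    return lam[np.argsort(-lam.real)]


def _leading_complex_real(sys: ReducedSystem) -> float:
    """Real part of the leading complex eigenvalue pair at the upper
    equilibrium (largest E_Pyr)."""
    eq = find_equilibrium(sys)[-1]
    lam = stability_eigenvalues(sys, eq)
    complex_pairs = lam[np.abs(lam.imag) > 1e-9]
    if complex_pairs.size == 0:
        return float(lam[0].real)
    return float(complex_pairs[0].real)


def hopf_locus(p: ModelParameters,
               v_Glu_grid: NDArray, v_GABA_grid: NDArray,
               tol: float = 1e-6, q_const: float | None = None,
               Q_Pyr_const: float = 0.0) -> list[NDArray]:
    """Loci of Hopf points on the (v_Glu, v_GABA) lattice.

    Evaluates the leading complex-pair real part on the lattice, bisects
    every sign-changing edge down to |Re lambda| < tol, and chains the
    crossing points into polylines (arrays of (v_Glu, v_GABA) rows).
    """
    v_Glu_grid = np.asarray(v_Glu_grid, dtype=float)
    v_GABA_grid = np.asarray(v_GABA_grid, dtype=float)

    def alpha(vg: float, vb: float) -> float:
        return _leading_complex_real(ReducedSystem(
            params=p, v_Glu=vg, v_GABA=vb, q_const=q_const,
            Q_Pyr_const=Q_Pyr_const))

    field = np.array([[alpha(vg, vb) for vb in v_GABA_grid] for vg in v_Glu_grid])

    points: list[tuple[float, float]] = []

    def bisect(p0, a0, p1, a1):
        for _ in range(200):
            pm = (0.5 * (p0[0] + p1[0]), 0.5 * (p0[1] + p1[1]))
            am = alpha(*pm)
            if abs(am) < tol:
                return pm
            if a0 * am <= 0:
                p1, a1 = pm, am
            else:
                p0, a0 = pm, am
        return pm

    ni, nj = field.shape
    for i in range(ni):
        for j in range(nj):
            if i + 1 < ni and field[i, j] * field[i + 1, j] < 0:
                points.append(bisect((v_Glu_grid[i], v_GABA_grid[j]), field[i, j],
                                     (v_Glu_grid[i + 1], v_GABA_grid[j]), field[i + 1, j]))
            if j + 1 < nj and field[i, j] * field[i, j + 1] < 0:
                points.append(bisect((v_Glu_grid[i], v_GABA_grid[j]), field[i, j],
                                     (v_Glu_grid[i], v_GABA_grid[j + 1]), field[i, j + 1]))
    if not points:
        import warnings
        warnings.warn("no Hopf crossing found on the supplied grid")
        return []
    # Greedy nearest-neighbour chaining into polylines.
    remaining = [np.array(pt) for pt in points]
    cell = np.hypot(np.ptp(v_Glu_grid) / max(len(v_Glu_grid) - 1, 1),
                    np.ptp(v_GABA_grid) / max(len(v_GABA_grid) - 1, 1))
    polylines = []
    while remaining:
        chain = [remaining.pop(0)]
        extended = True
        while extended and remaining:
            extended = False
            for end in (0, -1):
                if not remaining:
                    break
                d = [np.linalg.norm(chain[end] - q) for q in remaining]
                k = int(np.argmin(d))
                if d[k] < 2.0 * cell:
                    pt = remaining.pop(k)
                    chain.insert(0, pt) if end == 0 else chain.append(pt)
                    extended = True
        polylines.append(np.array(chain))
    return polylines


@njit(cache=True)
def _reduced_heun(y, n_steps, dt, A, a, B, b, C_EP, C_IP, C_PE, C_PI,
                  nu_max, r, v0, v_Pyr, v_InIn, drive,
                  out, stride):  # pragma: no cover - jit
    d1 = np.empty(6)
    d2 = np.empty(6)
    yp = np.empty(6)
    rec = 0
    for k in range(n_steps):
        for rep in range(2):
            src = y if rep == 0 else yp
            F_Pyr = nu_max / (1.0 + np.exp(r * (v_Pyr - (src[2] - src[4]))))
            F_ExIn = nu_max / (1.0 + np.exp(r * (v0 - C_PE * src[0])))
            F_InIn = nu_max / (1.0 + np.exp(r * (v_InIn - C_PI * src[0])))
            d = d1 if rep == 0 else d2
            d[0] = src[1]
            d[1] = A * a * F_Pyr - 2 * a * src[1] - a * a * src[0]
            d[2] = src[3]
            d[3] = A * a * (C_EP * F_ExIn + drive) - 2 * a * src[3] - a * a * src[2]
            d[4] = src[5]
            d[5] = B * b * C_IP * F_InIn - 2 * b * src[5] - b * b * src[4]
            if rep == 0:
                for j in range(6):
                    yp[j] = y[j] + dt * d1[j]
        for j in range(6):
            y[j] = y[j] + 0.5 * dt * (d1[j] + d2[j])
        if (k + 1) % stride == 0 and rec < out.shape[0]:
            for j in range(6):
                out[rec, j] = y[j]
            rec += 1
    return rec


def integrate_reduced(sys: ReducedSystem, y0: NDArray, duration: float,
                      dt: float = 1e-4, record_stride: int = 10) -> tuple[NDArray, NDArray]:
    """Deterministic Heun integration of the reduced system.

    Returns (time, trajectory) with trajectory of shape (T, 6).
    """
    p = sys.params
    n_steps = int(round(duration / dt))
    n_rec = n_steps // record_stride
    out = np.empty((n_rec, 6))
    y = np.array(y0, dtype=np.float64)
    _reduced_heun(y, n_steps, dt, p.A, p.a, p.B, p.b,
                  p.C_ExIn_to_Pyr, p.C_InIn_to_Pyr,
                  p.C_Pyr_to_ExIn, p.C_Pyr_to_InIn,
                  p.nu_max, p.r, p.v0, sys.v_Pyr, sys.v_InIn,
                  sys.Q_Pyr_const + sys.q, out, record_stride)
    time = (np.arange(n_rec) + 1) * (dt * record_stride)
    return time, out


def characterize_orbit(sys: ReducedSystem, settle: float = 20.0,
                       measure: float = 20.0, dt: float = 1e-4,
                       record_stride: int = 10) -> PeriodicOrbitSummary:
    """Classify the attractor and measure its amplitude extrema and frequency.

    The system is integrated deterministically from a small perturbation of
    the upper equilibrium; after the settle window, per-observable min/max
    are recorded and the frequency is the reciprocal of the mean interval
    between upward zero crossings of the mean-removed LFP.
    """
    if settle <= 0 or measure <= 0:
        raise ValueError("settle and measure windows must be positive")
    eq = find_equilibrium(sys)[-1]
    y0 = eq + 1e-2 * np.abs(eq).max() * np.ones(6)
    _, traj_settle = integrate_reduced(sys, y0, settle, dt, record_stride)
    _, traj = integrate_reduced(sys, traj_settle[-1], measure, dt, record_stride)
    obs = {
        "LFP": traj[:, 2] - traj[:, 4],
        "E_Pyr": traj[:, 0],
        "E_InIn": traj[:, 4],
    }
    amplitudes = {k: (float(v.min()), float(v.max()), float(np.ptp(v)))
                  for k, v in obs.items()}
    summary = PeriodicOrbitSummary(v_Glu=sys.v_Glu, v_GABA=sys.v_GABA,
                                   amplitudes=amplitudes)
    x = obs["LFP"]
    ptp = amplitudes["LFP"][2]
    if ptp <= PTP_THRESHOLD:
        return summary
    # Drifting extrema (no convergence to a repeating orbit) -> "other".
    half = len(x) // 2
    ptp1, ptp2 = np.ptp(x[:half]), np.ptp(x[half:])
    if abs(ptp1 - ptp2) > 0.05 * max(ptp1, ptp2):
        summary.classification = "other"
        return summary
    xm = x - x.mean()
    up = np.flatnonzero((xm[:-1] < 0) & (xm[1:] >= 0))
    if len(up) < 2:
        summary.classification = "other"
        return summary
    fs = 1.0 / (dt * record_stride)
    # Linear interpolation of the crossing instants for sub-sample accuracy.
    frac = xm[up] / (xm[up] - xm[up + 1])
    t_cross = (up + frac) / fs
    summary.frequency = float(1.0 / np.mean(np.diff(t_cross)))
    summary.classification = "periodic"
    return summary


def amplitude_isolines(v_Glu_grid: NDArray, v_GABA_grid: NDArray,
                       field: NDArray, levels: Sequence[float]) -> dict[float, list[NDArray]]:
    """Marching-squares contours of a peak-to-peak amplitude lattice.

    ``field`` has shape (len(v_Glu_grid), len(v_GABA_grid)); returned
    polylines are arrays of (v_Glu, v_GABA) rows in parameter coordinates.
    """
    from skimage import measure

    v_Glu_grid = np.asarray(v_Glu_grid, dtype=float)
    v_GABA_grid = np.asarray(v_GABA_grid, dtype=float)
    field = np.asarray(field, dtype=float)
    if field.shape != (len(v_Glu_grid), len(v_GABA_grid)):
        raise ValueError("field shape does not match grids")
    out: dict[float, list[NDArray]] = {}
    for level in levels:
        polys = []
        if field.min() < level < field.max():
            for contour in measure.find_contours(field, level):
                vg = np.interp(contour[:, 0], np.arange(len(v_Glu_grid)), v_Glu_grid)
                vb = np.interp(contour[:, 1], np.arange(len(v_GABA_grid)), v_GABA_grid)
                polys.append(np.column_stack([vg, vb]))
        out[float(level)] = polys
    return out


def concentration_to_v(Glu_e, GABA_e, p: ModelParameters):
    """Map concentrations to excitability levels via the modulation sigmoids."""
    v_Glu = sigmoid(Glu_e, p.m_Glu_Pyr, p.r_Glu_PyrInIn, p.theta_Glu_PyrInIn,
                    p.delta_Glu_Pyr)
    v_GABA = sigmoid(GABA_e, p.m_GABA_Pyr, p.r_GABA_Pyr, p.theta_GABA_Pyr,
                     p.delta_GABA_Pyr)
    return v_Glu, v_GABA


def _inverse_sigmoid(y, nu: float, r: float, theta: float, delta: float):
    y = np.asarray(y, dtype=float)
    if np.any(y <= -delta) or np.any(y >= nu - delta):
        raise ValueError(
            f"value outside the open sigmoid range ({-delta}, {nu - delta})")
    out = theta - np.log(nu / (y + delta) - 1.0) / r
    return out if out.ndim else float(out)


def v_to_concentration(v_Glu, v_GABA, p: ModelParameters):
    """Closed-form inverse of :func:`concentration_to_v`.

    Raises a domain error at or outside the sigmoid asymptotes.
    """
    Glu_e = _inverse_sigmoid(v_Glu, p.m_Glu_Pyr, p.r_Glu_PyrInIn,
                             p.theta_Glu_PyrInIn, p.delta_Glu_Pyr)
    GABA_e = _inverse_sigmoid(v_GABA, p.m_GABA_Pyr, p.r_GABA_Pyr,
                              p.theta_GABA_Pyr, p.delta_GABA_Pyr)
    return Glu_e, GABA_e
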