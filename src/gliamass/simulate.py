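"""Stochastic Heun integration of the coupled neuron-astrocyte network.

The N-node system (14 equations per node) is driven by a baseline input
firing rate q that is redrawn independently per node at every integration
step from Normal(q_mean, q_sd^2) and held constant within the step; with q
frozen, the predictor-corrector scheme reduces to deterministic Heun (RK2)
driven by a piecewise-constant stochastic input.

The production protocol mirrors a calibration-then-batch design: one long
calibration run from the deterministic single-node equilibrium establishes
a statistically stationary state whose end point seeds a set of shorter
batches that differ only in their noise streams.

Randomness is counter-based: one master seed plus (parameter-pair, batch,
node) indices derive an independent Philox stream per node, so removing the
network coupling makes an N-node run bitwise identical to N single-node
runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from numpy.typing import NDArray

from .layers import StructuralLayers, astrocytic_feedback, neuronal_feedback
from .model import (N_STATE_VARS, STATE_FIELDS, excitability_levels,
                    find_node_equilibrium, firing_rates, nodal_drift)
from .params import ModelParameters

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "sample_q",
    "node_streams",
    "heun_step",
    "run_simulation",
    "default_initial_state",
    "calibrate_then_batch",
    "define_parameter_grid",
]

_PARAM_ORDER = (
    "A", "a", "B", "b",
    "C_ExIn_to_Pyr", "C_InIn_to_Pyr", "C_Pyr_to_ExIn", "C_Pyr_to_InIn",
    "nu_max", "r", "v0",
    "W", "w_r", "w_d",
    "V_Glue_Ast", "V_Glue_Pyr", "r_Glue_AstPyr", "theta_Glue_AstPyr", "tau_GluAst",
    "Z", "z_r", "z_d",
    "V_GABAe_Ast", "K_GABAe_Ast", "V_GABAe_InIn", "K_GABAe_InIn", "tau_GABAAst",
    "m_Glu_Pyr", "r_Glu_PyrInIn", "theta_Glu_PyrInIn", "delta_Glu_Pyr",
    "m_GABA_Pyr", "r_GABA_Pyr", "theta_GABA_Pyr", "delta_GABA_Pyr",
    "mu_Glu_InIn_over_Pyr",
    "m_Glu_Ast", "r_Glu_Ast", "theta_Glu_Ast",
    "omega_Pyr", "omega_Glu", "omega_GABA",
)


def _pack(p: ModelParameters) -> NDArray:
    return np.array([getattr(p, name) for name in _PARAM_ORDER], dtype=np.float64)


@dataclass
class SimulationConfig:
    """Settings of one stochastic network integration."""

    duration: float = 120.0          # s
    dt: float = 1e-4                 # s
    calibration_duration: float = 370.0  # s
    batch_duration: float = 120.0    # s
    n_batches: int = 10
    seed: int = 0
    record_stride: int = 10          # steps per stored sample (1 kHz at default dt)
    omega_Glu: float | None = None   # optional parameter override (umol^-1)
    omega_GABA: float | None = None  # optional parameter override (umol^-1)
    q_mode: str = "per_step"         # "per_step" (white-noise reading) or "fixed"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one step")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.q_mode not in ("per_step", "fixed"):
            raise ValueError(f"unknown q_mode {self.q_mode!r}")

    def apply_overrides(self, p: ModelParameters) -> ModelParameters:
        changes = {}
        if self.omega_Glu is not None:
            changes["omega_Glu"] = self.omega_Glu
        if self.omega_GABA is not None:
            changes["omega_GABA"] = self.omega_GABA
        return p.replace(**changes) if changes else p


@dataclass
class SimulationResult:
    """Recorded trajectories of one run plus provenance metadata."""

    time: NDArray                    # (T,) sample times, s
    states: NDArray                  # (T, N, 14) in STATE_FIELDS order
    params: ModelParameters
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]

    @property
    def fs(self) -> float:
        """Stored sampling rate, Hz."""
        return 1.0 / float(self.time[1] - self.time[0])

    def field(self, name: str) -> NDArray:
        """Trajectory (T, N) of one state variable by name."""
        return self.states[:, :, STATE_FIELDS.index(name)]

    @property
    def lfp(self) -> NDArray:
        """Local field potential E_ExIn - E_InIn, shape (T, N)."""
        return self.field("E_ExIn") - self.field("E_InIn")

    def derived(self) -> dict[str, NDArray]:
        """Firing rates and excitability levels recomputed per sample."""
        v = excitability_levels(self.field("Glu_e"), self.field("GABA_e"), self.params)
        F_Pyr, F_ExIn, F_InIn = firing_rates(
            self.field("E_Pyr"), self.field("E_ExIn"), self.field("E_InIn"),
            v, self.params)
        return {
            "LFP": self.lfp, "F_Pyr": F_Pyr, "F_ExIn": F_ExIn, "F_InIn": F_InIn,
            "v_Glu": np.asarray(v.v_Glu), "v_GABA": np.asarray(v.v_GABA),
        }

    def final_state(self) -> NDArray:
        return self.states[-1].copy()

    def save(self, path: str | Path) -> None:
        """Write to HDF5 (.h5) or NPZ (.npz)."""
        path = Path(path)
        meta = {k: v for k, v in self.meta.items() if np.isscalar(v) or isinstance(v, str)}
        if path.suffix in (".h5", ".hdf5"):
            import h5py
            with h5py.File(path, "w") as fh:
                fh.create_dataset("states/time", data=self.time)
                fh.create_dataset("states/values", data=self.states,
                                  compression="gzip", compression_opts=4)
                d = self.derived()
                for k, v in d.items():
                    fh.create_dataset(f"derived/{k}", data=v,
                                      compression="gzip", compression_opts=4)
                g = fh.create_group("meta")
                for k, v in meta.items():
                    g.attrs[k] = v
                for k, v in self.params.as_dict().items():
                    g.attrs[f"param_{k}"] = v
        else:
            np.savez_compressed(
                path, time=self.time, states=self.states,
                param_names=np.array(list(self.params.as_dict())),
                param_values=np.array(list(self.params.as_dict().values())),
                **{f"meta_{k}": v for k, v in meta.items()})

    @classmethod
    def load(cls, path: str | Path) -> "SimulationResult":
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            import h5py
            with h5py.File(path, "r") as fh:
                time = fh["states/time"][:]
                states = fh["states/values"][:]
                attrs = dict(fh["meta"].attrs)
            pdict = {k[6:]: float(v) for k, v in attrs.items() if k.startswith("param_")}
            meta = {k: v for k, v in attrs.items() if not k.startswith("param_")}
            return cls(time=time, states=states,
                       params=ModelParameters(**pdict), meta=meta)
        data = np.load(path, allow_pickle=False)
        pdict = dict(zip(data["param_names"].tolist(),
                         data["param_values"].tolist()))
        meta = {k[5:]: data[k].item() for k in data.files if k.startswith("meta_")}
        return cls(time=data["time"], states=data["states"],
                   params=ModelParameters(**pdict), meta=meta)


def sample_q(N: int, q_mean: float, q_sd: float, rng: np.random.Generator) -> NDArray:
    """Draw N independent baseline input rates from Normal(q_mean, q_sd^2)."""
    if q_sd < 0:
        raise ValueError("q_sd must be >= 0")
    if q_sd == 0:
        return np.full(N, q_mean)
    return rng.normal(q_mean, q_sd, size=N)


def node_streams(master_seed: int, pair_index: int, batch_index: int,
                 N: int) -> list[np.random.Generator]:
    """Independent Philox streams, one per node, from a counter-based key.

    The key packs (master_seed, pair, batch, node) into disjoint bit fields,
    so any (pair, batch, node) substream can be reproduced in isolation.
    """
    if not (0 <= pair_index < 2**20 and 0 <= batch_index < 2**10 and N <= 2**14):
        raise ValueError("pair/batch/node index out of key range")
    return [
        np.random.Generator(np.random.Philox(
            key=(int(master_seed) << 44) | (pair_index << 24)
                | (batch_index << 14) | node))
        for node in range(N)
    ]


# ----------------------------------------------------------------------
# numba kernel
# ----------------------------------------------------------------------

@njit(cache=True)
def _drift_kernel(x, q, pv, Wp, Wa, F_Pyr, bind, dx):  # pragma: no cover - jit
    N = x.shape[0]
    (A, a, B, b, C_EP, C_IP, C_PE, C_PI, nu_max, r, v0,
     W, w_r, w_d, V_ga, V_gp, r_g, th_g, tau_g,
     Z, z_r, z_d, V_ba, K_ba, V_bi, K_bi, tau_b,
     m_gP, r_gP, th_gP, d_gP, m_bP, r_bP, th_bP, d_bP, mu,
     m_gA, r_gA, th_gA, om_P, om_G, om_B) = (
        pv[0], pv[1], pv[2], pv[3], pv[4], pv[5], pv[6], pv[7], pv[8], pv[9],
        pv[10], pv[11], pv[12], pv[13], pv[14], pv[15], pv[16], pv[17], pv[18],
        pv[19], pv[20], pv[21], pv[22], pv[23], pv[24], pv[25], pv[26], pv[27],
        pv[28], pv[29], pv[30], pv[31], pv[32], pv[33], pv[34], pv[35], pv[36],
        pv[37], pv[38], pv[39], pv[40], pv[41])
    for n in range(N):
        Glu_e = x[n, 10]
        GABA_e = x[n, 12]
        v_Glu = m_gP / (1.0 + np.exp(r_gP * (th_gP - Glu_e))) - d_gP
        v_GABA = m_bP / (1.0 + np.exp(r_bP * (th_bP - GABA_e))) - d_bP
        v_Pyr = v0 + v_GABA - v_Glu
        F_Pyr[n] = nu_max / (1.0 + np.exp(r * (v_Pyr - (x[n, 2] - x[n, 4]))))
        bind[n] = m_gA / (1.0 + np.exp(r_gA * (th_gA - Glu_e)))
    for n in range(N):
        Qp = 0.0
        Qmix = 0.0
        for m in range(N):
            Qp += Wp[n, m] * F_Pyr[m]
            Qmix += Wa[n, m] * bind[m]
        Qp *= om_P
        Q_glu = om_G * Qmix
        Q_gaba = om_B * Qmix
        Glu_e = x[n, 10]
        GABA_e = x[n, 12]
        v_Glu = m_gP / (1.0 + np.exp(r_gP * (th_gP - Glu_e))) - d_gP
        v_InIn = v0 - mu * v_Glu
        F_ExIn = nu_max / (1.0 + np.exp(r * (v0 - C_PE * x[n, 0])))
        F_InIn = nu_max / (1.0 + np.exp(r * (v_InIn - C_PI * x[n, 0])))
        dx[n, 0] = x[n, 1]
        dx[n, 1] = A * a * F_Pyr[n] - 2.0 * a * x[n, 1] - a * a * x[n, 0]
        dx[n, 2] = x[n, 3]
        dx[n, 3] = A * a * (C_EP * F_ExIn + Qp + q[n]) - 2.0 * a * x[n, 3] - a * a * x[n, 2]
        dx[n, 4] = x[n, 5]
        dx[n, 5] = B * b * C_IP * F_InIn - 2.0 * b * x[n, 5] - b * b * x[n, 4]
        dx[n, 6] = x[n, 7]
        dx[n, 7] = (W * w_r * (F_Pyr[n] + Q_glu)
                    - (w_r + w_d) * x[n, 7] - w_r * w_d * x[n, 6])
        up_ga = V_ga / (1.0 + np.exp(r_g * (th_g - Glu_e)))
        up_gp = V_gp / (1.0 + np.exp(r_g * (th_g - Glu_e)))
        dx[n, 10] = x[n, 6] - up_ga - up_gp
        dx[n, 11] = up_ga - x[n, 11] / tau_g
        dx[n, 8] = x[n, 9]
        dx[n, 9] = (Z * z_r * (F_InIn + Q_gaba)
                    - (z_r + z_d) * x[n, 9] - z_r * z_d * x[n, 8])
        up_ba = V_ba * GABA_e / (K_ba + GABA_e)
        up_bi = V_bi * GABA_e / (K_bi + GABA_e)
        dx[n, 12] = x[n, 8] - up_ba - up_bi
        dx[n, 13] = up_ba - x[n, 13] / tau_b


@njit(cache=True)
def _heun_chunk(x, qs, dt, pv, Wp, Wa, out, stride,
                step0, rec0):  # pragma: no cover - jit
    """Advance len(qs) steps; record every stride-th global step into out.

    Returns (next_global_step, next_record_index, blowup_step) where
    blowup_step is -1 on success.
    """
    N = x.shape[0]
    d1 = np.empty((N, 14))
    d2 = np.empty((N, 14))
    xp = np.empty((N, 14))
    F_Pyr = np.empty(N)
    bind = np.empty(N)
    step = step0
    rec = rec0
    for k in range(qs.shape[0]):
        q = qs[k]
        _drift_kernel(x, q, pv, Wp, Wa, F_Pyr, bind, d1)
        for n in range(N):
            for j in range(14):
                xp[n, j] = x[n, j] + dt * d1[n, j]
        _drift_kernel(xp, q, pv, Wp, Wa, F_Pyr, bind, d2)
        ok = True
        for n in range(N):
            for j in range(14):
                x[n, j] = x[n, j] + 0.5 * dt * (d1[n, j] + d2[n, j])
                if not np.isfinite(x[n, j]):
                    ok = False
        step += 1
        if not ok:
            return step, rec, step
        if step % stride == 0 and rec < out.shape[0]:
            for n in range(N):
                for j in range(14):
                    out[rec, n, j] = x[n, j]
            rec += 1
    return step, rec, -1


# ----------------------------------------------------------------------
# reference (numpy) single step, used by tests and tiny problems
# ----------------------------------------------------------------------

def heun_step(state: NDArray, dt: float, q_vec: NDArray,
              layers: StructuralLayers, p: ModelParameters) -> NDArray:
    """One deterministic Heun (RK2) step with q frozen within the step."""

    def drift(x: NDArray) -> NDArray:
        F_Pyr, _, _ = firing_rates(
            x[:, 0], x[:, 2], x[:, 4],
            excitability_levels(x[:, 10], x[:, 12], p), p)
        Q_Pyr = neuronal_feedback(np.asarray(F_Pyr), layers, p.omega_Pyr)
        Q_glu, Q_gaba = astrocytic_feedback(x[:, 10], layers, p)
        return nodal_drift(x, Q_Pyr, Q_glu, Q_gaba, q_vec, p)

    state = np.asarray(state, dtype=float)
    d1 = drift(state)
    predictor = state + dt * d1
    d2 = drift(predictor)
    result = state + 0.5 * dt * (d1 + d2)
    if not np.all(np.isfinite(result)):
        node = int(np.argwhere(~np.isfinite(result))[0][0])
        raise FloatingPointError(f"integration blow-up at node {node}")
    return result


def default_initial_state(p: ModelParameters, N: int) -> NDArray:
    """Deterministic single-node equilibrium at q_mean, replicated N times.

    This anchors every run at the stable baseline state close to the Hopf
    branch from which noise-modulated oscillations develop.
    """
    eq = find_node_equilibrium(p, q=p.q_mean)
    return np.tile(eq, (N, 1))


def run_simulation(initial: NDArray, cfg: SimulationConfig,
                   layers: StructuralLayers, p: ModelParameters,
                   pair_index: int = 0, batch_index: int = 0,
                   chunk_steps: int = 20000) -> SimulationResult:
    """Integrate the network for ``cfg.duration`` seconds.

    The baseline input q is redrawn per node at every step (default) from
    per-node Philox substreams keyed by (seed, pair_index, batch_index,
    node).  Samples are stored every ``record_stride`` steps, including the
    initial state at t=0.
    """
    p = cfg.apply_overrides(p)
    initial = np.array(initial, dtype=np.float64)
    if initial.shape != (layers.n_nodes, N_STATE_VARS):
        raise ValueError(
            f"initial state shape {initial.shape} does not match "
            f"({layers.n_nodes}, {N_STATE_VARS})")
    N = layers.n_nodes
    n_steps = int(round(cfg.duration / cfg.dt))
    n_rec = n_steps // cfg.record_stride
    out = np.empty((n_rec + 1, N, N_STATE_VARS))
    out[0] = initial
    pv = _pack(p)
    rngs = node_streams(cfg.seed, pair_index, batch_index, N)
    q_fixed = None
    if cfg.q_mode == "fixed":
        q_fixed = np.array([sample_q(1, p.q_mean, p.q_sd, rng)[0] for rng in rngs])

    x = initial.copy()
    step, rec = 0, 1
    while step < n_steps:
        n_chunk = min(chunk_steps, n_steps - step)
        if q_fixed is not None:
            qs = np.broadcast_to(q_fixed, (n_chunk, N)).copy()
        elif p.q_sd == 0:
            qs = np.full((n_chunk, N), p.q_mean)
        else:
            qs = np.empty((n_chunk, N))
            for n, rng in enumerate(rngs):
                qs[:, n] = rng.normal(p.q_mean, p.q_sd, size=n_chunk)
        step, rec, blow = _heun_chunk(x, qs, cfg.dt, pv, layers.Omega_Pyr,
                                      layers.Omega_Ast, out, cfg.record_stride,
                                      step, rec)
        if blow >= 0:
            bad = np.argwhere(~np.isfinite(x))
            node = int(bad[0][0]) if bad.size else -1
            raise FloatingPointError(
                f"integration blow-up at step {blow} (t={blow * cfg.dt:.4f} s), "
                f"node {node}")
    time = np.arange(n_rec + 1) * (cfg.dt * cfg.record_stride)
    meta = {
        "seed": cfg.seed, "pair_index": pair_index, "batch_index": batch_index,
        "dt": cfg.dt, "record_stride": cfg.record_stride,
        "duration": cfg.duration, "q_mode": cfg.q_mode,
        "layer_checksum": layers.checksum(), "n_nodes": N,
        "n_equations": N * N_STATE_VARS,
    }
    return SimulationResult(time=time, states=out, params=p, meta=meta)


def calibrate_then_batch(cfg: SimulationConfig, layers: StructuralLayers,
                         p: ModelParameters,
                         pair_index: int = 0) -> list[SimulationResult]:
    """Calibration run followed by n_batches noise-independent batches.

    The calibration (batch index 0 in the seeding scheme) starts from the
    deterministic single-node equilibrium replicated across nodes; its end
    state is the common initial condition of every batch.  Batches differ
    only in their noise substreams (batch indices 1..n_batches).
    """
    if cfg.calibration_duration < cfg.batch_duration:
        raise ValueError("calibration must be at least as long as a batch")
    p_eff = cfg.apply_overrides(p)
    initial = default_initial_state(p_eff, layers.n_nodes)
    calib_cfg = dataclasses.replace(cfg, duration=cfg.calibration_duration)
    calibration = run_simulation(initial, calib_cfg, layers, p,
                                 pair_index=pair_index, batch_index=0)
    start = calibration.final_state()
    results = []
    batch_cfg = dataclasses.replace(cfg, duration=cfg.batch_duration)
    for i in range(cfg.n_batches):
        res = run_simulation(start, batch_cfg, layers, p,
                             pair_index=pair_index, batch_index=i + 1)
        res.meta["calibration_duration"] = cfg.calibration_duration
        res.meta["calibration_checksum"] = float(np.sum(start))
        results.append(res)
    return results


def define_parameter_grid(omega_Glu_range: tuple[float, float] = (2.90, 6.47),
                          omega_GABA_range: tuple[float, float] = (0.14, 1.94),
                          n_per_axis: int = 35) -> list[tuple[float, float]]:
    """Rectangular grid of (omega_Glu, omega_GABA) pairs over the explored
    coupling ranges; the default 35 x 35 grid gives 1225 pairs."""
    g0, g1 = omega_Glu_range
    b0, b1 = omega_GABA_range
    if not (g1 >= g0 and b1 >= b0):
        raise ValueError("empty parameter range")
    if n_per_axis < 1:
        raise ValueError("n_per_axis must be >= 1")
    glus = np.linspace(g0, g1, n_per_axis)
    gabas = np.linspace(b0, b1, n_per_axis)
    return [(float(g), float(b)) for g in glus for b in gabas]
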