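"""Model parameter registry.

Every constant of the neuron-astrocyte mass model lives in a single
:class:`ModelParameters` record.  Values are loaded from a strict YAML
registry (one key per field, unknown keys rejected) so that a simulation is
always traceable to an explicit, complete parameter file.

Units convention (applied consistently, never converted implicitly):

* membrane potentials and excitability levels: mV
* rates and rate constants: s^-1 (written "Hz" for firing rates)
* concentrations: umol (treated as umol/L)
* sigmoid slopes acting on potentials: mV^-1; acting on concentrations: umol^-1
* global astrocytic couplings omega_Glu, omega_GABA: umol^-1
* time: s
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelParameters", "load_parameters", "default_parameters"]


@dataclass(frozen=True)
class ModelParameters:
    """Complete constant set of the neuron-astrocyte mass network model.

    The neuronal compartment is a Jansen-Rit-type three-population model
    (pyramidal cells, excitatory and inhibitory interneurons); the
    neurotransmitter compartment adds second-order release kinetics and
    sigmoidal / Michaelis-Menten uptake for extracellular glutamate and GABA.
    """

    # --- synaptic impulse responses -------------------------------------
    A: float        # excitatory synaptic gain (mV)
    a: float        # excitatory rate constant (s^-1)
    B: float        # inhibitory synaptic gain (mV)
    b: float        # inhibitory rate constant (s^-1)

    # --- intra-node connectivity constants (dimensionless) --------------
    C_ExIn_to_Pyr: float
    C_InIn_to_Pyr: float
    C_Pyr_to_ExIn: float
    C_Pyr_to_InIn: float

    # --- firing-rate sigmoid --------------------------------------------
    nu_max: float   # maximal firing rate (s^-1)
    r: float        # sigmoid slope (mV^-1)
    v0: float       # baseline excitability threshold (mV)

    # --- glutamate release / uptake -------------------------------------
    W: float        # glutamate release gain (umol)
    w_r: float      # release rise rate constant (s^-1)
    w_d: float      # release decay rate constant (s^-1)
    V_Glue_Ast: float       # maximal astrocytic Glu_e uptake rate (umol s^-1)
    V_Glue_Pyr: float       # maximal neuronal Glu_e uptake rate (umol s^-1)
    r_Glue_AstPyr: float    # shared uptake sigmoid slope (umol^-1)
    theta_Glue_AstPyr: float  # shared uptake sigmoid threshold (umol)
    tau_GluAst: float       # astrocytic glutamate degradation time constant (s)

    # --- GABA release / uptake ------------------------------------------
    Z: float        # GABA release gain (umol)
    z_r: float      # release rise rate constant (s^-1)
    z_d: float      # release decay rate constant (s^-1)
    V_GABAe_Ast: float      # maximal astrocytic GABA_e uptake rate (umol s^-1)
    K_GABAe_Ast: float      # astrocytic half-saturation constant (umol)
    V_GABAe_InIn: float     # maximal neuronal GABA_e uptake rate (umol s^-1)
    K_GABAe_InIn: float     # neuronal half-saturation constant (umol)
    tau_GABAAst: float      # astrocytic GABA degradation time constant (s)

    # --- excitability modulation sigmoids (Glu_e -> v_Glu, GABA_e -> v_GABA)
    m_Glu_Pyr: float        # v_Glu sigmoid amplitude (mV)
    r_Glu_PyrInIn: float    # v_Glu sigmoid slope (umol^-1)
    theta_Glu_PyrInIn: float  # v_Glu sigmoid threshold (umol)
    delta_Glu_Pyr: float    # v_Glu sigmoid offset (mV)
    m_GABA_Pyr: float       # v_GABA sigmoid amplitude (mV)
    r_GABA_Pyr: float       # v_GABA sigmoid slope (umol^-1)
    theta_GABA_Pyr: float   # v_GABA sigmoid threshold (umol)
    delta_GABA_Pyr: float   # v_GABA sigmoid offset (mV)
    mu_Glu_InIn_over_Pyr: float  # interneuron / pyramidal sensitivity ratio

    # --- astrocytic glutamate binding sigmoid (network feedback kernel) -
    m_Glu_Ast: float        # binding sigmoid amplitude (umol s^-1)
    r_Glu_Ast: float        # binding sigmoid slope (umol^-1)
    theta_Glu_Ast: float    # binding sigmoid threshold (umol)

    # --- global couplings ------------------------------------------------
    omega_Pyr: float        # neuronal network coupling (dimensionless)
    omega_Glu: float        # astrocytic coupling onto Glu release (umol^-1)
    omega_GABA: float       # astrocytic coupling onto GABA release (umol^-1)

    # --- stochastic baseline input ---------------------------------------
    q_mean: float   # mean baseline input firing rate (Hz)
    q_sd: float     # standard deviation of baseline input (Hz)

    def __post_init__(self) -> None:
        positive = (
            "a", "b", "w_r", "w_d", "z_r", "z_d", "tau_GluAst", "tau_GABAAst",
            "nu_max", "r", "K_GABAe_Ast", "K_GABAe_InIn",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be > 0, got {getattr(self, name)}")
        for name in ("omega_Pyr", "omega_Glu", "omega_GABA", "q_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {getattr(self, name)}")
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {f.name!r} is not finite: {value}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


_FIELD_NAMES = [f.name for f in dataclasses.fields(ModelParameters)]


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a complete parameter registry from YAML.

    The schema is strict: every :class:`ModelParameters` field must be
    present exactly once and unknown keys are rejected, so a registry can
    never silently fall back to a substitute value.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"parameter registry {path} is not a YAML mapping")
    unknown = sorted(set(raw) - set(_FIELD_NAMES))
    if unknown:
        raise ValueError(f"unknown parameter keys in {path}: {unknown}")
    missing = sorted(set(_FIELD_NAMES) - set(raw))
    if missing:
        raise ValueError(
            f"parameter registry {path} is incomplete; missing keys: {missing}. "
            "Refusing to run with substituted values."
        )
    values = {}
    for key, val in raw.items():
        if isinstance(val, bool) or not isinstance(val, (int, float)):
            raise ValueError(f"parameter {key!r} must be numeric, got {val!r}")
        values[key] = float(val)
    return ModelParameters(**values)


def default_parameters() -> ModelParameters:
    """The packaged default registry (baseline working point)."""
    ref = resources.files("gliamass").joinpath("data/default_parameters.yaml")
    with resources.as_file(ref) as path:
        return load_parameters(path)
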