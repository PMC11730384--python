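# gliamass

Whole-brain **neuron–astrocyte mass network modelling**: a two-layer
(neuronal + astrocytic) structurally coupled stochastic dynamical system,
with the bifurcation machinery used to parameterize it and the activity /
multiplex-connectivity pipelines used to analyze it.

Most whole-brain models describe only neurons. `gliamass` is for
computational neuroscientists who want astrocytes in the loop: each brain
region is a mass model of four coupled cell populations — pyramidal cells
(Pyr), excitatory and inhibitory interneurons (ExIn, InIn), and astrocytes
(Ast) — interacting through electrical firing and through glutamatergic and
GABAergic transmission. Regions are coupled by two structural layers: a
white-matter layer `Ω_Pyr` linking pyramidal populations, and a
gap-junction syncytium layer `Ω_Ast` linking astrocytic populations of
adjacent regions only.

## The model

Each node carries 14 state variables. The neuronal compartment is a
Jansen–Rit-type circuit of second-order synaptic filters,

```
Ë_Pyr  = A·a·F_Pyr                                − 2a·Ė_Pyr  − a²·E_Pyr
Ë_ExIn = A·a·(C_ExIn→Pyr·F_ExIn + Q_Pyr + q)      − 2a·Ė_ExIn − a²·E_ExIn
Ë_InIn = B·b·C_InIn→Pyr·F_InIn                    − 2b·Ė_InIn − b²·E_InIn
```

with sigmoidal firing rates `F = S(·, ν_max, r, v, 0)` whose thresholds are
modulated by the extracellular neurotransmitter concentrations:
`v_Pyr = v0 + v_GABA − v_Glu`, `v_InIn = v0 − μ·v_Glu`, `v_ExIn = v0`,
where `v_Glu = S(Glu_e, …)` and `v_GABA = S(GABA_e, …)`. Glutamate and GABA
are released through second-order kinetics driven by `F_Pyr` and `F_InIn`,
taken up by sigmoidal (glutamate) and Michaelis–Menten (GABA) transporters,
and degraded in the astrocytic pools. The astrocytic network feedback

```
Q_Glu→Ast[n]  = ω_Glu  · Σ_m Ω_Ast[n,m] · S(Glu_e[m], m_Glu_Ast, r_Glu_Ast, θ_Glu_Ast, 0)
Q_GABA→Ast[n] = ω_GABA · Σ_m Ω_Ast[n,m] · S(Glu_e[m], …)
```

modulates the local release rates (glutamate-driven gliotransmission only),
while `Q_Pyr = ω_Pyr · Ω_Pyr · F_Pyr` carries the long-range excitatory
input. The local field potential is `LFP = E_ExIn − E_InIn`.

The coupled N-node system (14·N equations; 3024 at the 216-region
parcellation) is integrated with a stochastic Heun scheme: the baseline
input `q` is redrawn per node at every step from Normal(240, 10²) Hz and
held constant within the step.

Because the concentrations evolve far more slowly than the potentials, the
neuronal compartment can be analyzed with (v_Glu, v_GABA) frozen as
bifurcation parameters: the `bifurcation` module finds equilibria, Hopf
loci, and the amplitude/frequency landscape of the periodic orbits — the
alpha-band oscillations whose noise-driven amplitude modulation is the
model's central dynamical motif.

## Worked example

```python
import gliamass as gm

p = gm.default_parameters()                # calibrated baseline registry
layers = gm.surrogate_layers(16, seed=7)   # modular Ω_Pyr + ring Ω_Ast

cfg = gm.SimulationConfig(duration=120.0, calibration_duration=370.0,
                          batch_duration=120.0, n_batches=1, seed=2026)
batch = gm.calibrate_then_batch(cfg, layers, p)[0]

from gliamass.activity import summarize_activity
s = summarize_activity(batch)
print(f"LFP peak        {s.peak_frequency:.2f} Hz")
print(f"envelope peak   {s.env_peak_frequency:.3f} Hz")
print(f"Glu_e / GABA_e  {s.whole_brain['glu_mean']:.1f} / "
      f"{s.whole_brain['gaba_mean']:.1f} umol")

from gliamass.connectivity import build_multiplex, summarize_topology
t = summarize_topology(build_multiplex(batch), seed=0)
print(f"clustering {t.clustering_coefficient:.3f}  "
      f"path length {t.path_length:.2f}  "
      f"code length {t.code_length:.2f} bits")
```

prints

```
LFP peak        10.25 Hz
envelope peak   0.025 Hz
Glu_e / GABA_e  11.1 / 16.5 umol
clustering 0.370  path length 3.60  code length 4.81 bits
```

— an alpha-band (8–13 Hz) rhythm whose amplitude waxes and wanes on a
sub-0.1 Hz timescale set by the neurotransmitter homeostasis, with
extracellular levels inside the physiological design windows (Glu_e in
[5, 15], GABA_e in [5, 35] μmol), and the global topology of the four-layer
multiplex functional network (LFP-PLV, LFP-AEC, Glu_e-C, GABA_e-C layers,
each thresholded to its top 25 % strongest connections).

A command line mirrors the library:

```bash
gliamass simulate --nodes 16 --duration 120 --seed 1 --out run.h5
gliamass bifurcate --grid 21 --out landscape.csv
gliamass analyze-activity --results run.h5 --out activity.csv
gliamass analyze-connectivity --results run.h5 --out topology.json
gliamass reduce --results run.h5 --out reducibility.json
gliamass pipeline --config cfg.yaml --seed 1 --out runs/demo
```

## Module map

| module | contents |
| --- | --- |
| `gliamass.params` | strict YAML parameter registry, calibrated defaults |
| `gliamass.model` | nodal equations, sigmoid/Michaelis–Menten, equilibria |
| `gliamass.layers` | Ω_Pyr/Ω_Ast loading, normalization, surrogates, feedback |
| `gliamass.simulate` | stochastic Heun integrator (numba), calibration/batch protocol |
| `gliamass.bifurcation` | reduced-system equilibria, Hopf loci, orbit landscapes |
| `gliamass.activity` | envelopes, spectral peaks, profiles, GMM clustering |
| `gliamass.connectivity` | PLV/AEC/correlation layers, multiplex metrics, map equation, reducibility |
| `gliamass.pipeline`, `gliamass.cli` | orchestration and command line |

See `docs/methods.md` for the modelling assumptions, parameter rationale,
numerical choices, and known limitations.
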