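# Methods

## Model

`gliamass` implements a neural mass network in which every region (node)
couples a Jansen–Rit-type neuronal circuit to a neurotransmitter
compartment mediated by astrocytes. The 14 per-node state variables are
three postsynaptic-potential pairs `(E, Ė)` for pyramidal cells and the
two interneuron populations, two release-rate pairs `(J, J̇)` for glutamate
and GABA, and four concentrations: extracellular and astrocytic glutamate
and GABA.

The compartments talk to each other in both directions. Upward, firing
drives release: `J_Glu` follows `F_Pyr`, `J_GABA` follows `F_InIn`, each
through a second-order linear filter with rise/decay constants
`(w_r, w_d)` and `(z_r, z_d)`. Extracellular levels balance release against
uptake — sigmoidal transporters for glutamate (astrocytic uptake dominant),
Michaelis–Menten transporters for GABA (neuronal uptake dominant) — and the
astrocytic pools degrade with time constants `τ_GluAst`, `τ_GABAAst`.
Downward, concentrations move firing thresholds: rising `Glu_e` lowers the
pyramidal and inhibitory-interneuron thresholds (via the sigmoid `v_Glu`),
rising `GABA_e` raises the pyramidal threshold (via `v_GABA`); excitatory
interneurons are unaffected. Pyramidal excitatory self-feedback is omitted.

Two structural layers couple the nodes. `Ω_Pyr` (white matter) feeds
neighbouring firing rates into the excitatory input of each node with
global gain `ω_Pyr`; `Ω_Ast` (gap-junction syncytium, first-neighbour
lattice with reciprocal-distance weights) feeds neighbouring extracellular
glutamate — passed through the astrocytic binding sigmoid — into the local
release rates with gains `ω_Glu` and `ω_GABA`. Gliotransmission is
glutamate-driven only; there is no GABA-induced gliotransmission and no
astrocytic self-feedback (zero diagonal). Both matrices are row-normalized
(zero diagonal, rows summing to one) so every node receives a convex
combination of its neighbours' activity. Axonal delays are not modelled.

## Parameters

The defaults live in `src/gliamass/data/default_parameters.yaml` and load
through a strict registry: a YAML file must contain every field exactly
once, or the registry refuses to run — there is no silent substitution.

The neuronal compartment uses the standard Jansen–Rit constants
(`A = 3.25 mV`, `a = 100 s⁻¹`, `B = 22 mV`, `b = 50 s⁻¹`, connectivity
135/108/33.75/33.75, `ν_max = 5 s⁻¹`, `r = 0.56 mV⁻¹`, `v0 = 6 mV`), the
circuit this model extends. The baseline input is `q ~ Normal(240, 10²)`
Hz per node and step, and the neuronal coupling is `ω_Pyr = 7.5`; the
astrocytic couplings default to the midpoints of the explored ranges,
`ω_Glu ∈ [2.90, 6.47]`, `ω_GABA ∈ [0.14, 1.94]` μmol⁻¹ (35 × 35 grid,
1225 pairs, via `define_parameter_grid`).

The neurotransmitter-compartment constants were calibrated once, before
the test suite was frozen, to the model's published design constraints and
are not tuned thereafter:

* extracellular levels inside the physiological windows `Glu_e ∈ [5, 15]`
  and `GABA_e ∈ [5, 35]` μmol across the coupling ranges (realized spans on
  the surrogate network: roughly 9.6–14.8 and 11–23 μmol at the rectangle
  corners);
* release/uptake dynamics evolving below 0.5 Hz (the uptake linearization
  gives concentration time constants of a few seconds);
* a baseline working point where the neuronal compartment holds a stable
  alpha-band periodic orbit at 10–11 Hz, near (but inside) the Hopf locus.

Concretely, the thresholds of the excitability sigmoids are frozen so that
the coupled uniform fixed point at the default couplings sits at
`(v_Glu, v_GABA) = (0, +2)` mV — the sigmoid midpoint for glutamate
(maximal sensitivity) and a +2 mV GABAergic shift that places the orbit at
10.77 Hz. Because the structural layers are row-stochastic, this fixed
point is independent of the particular surrogate topology. Increasing
`ω_Glu` pushes nodes toward larger-amplitude, slower (< 8 Hz) spiking-like
orbits; increasing `ω_GABA` pushes toward the stable-focus side — the two
qualitative ends of the orbit landscape.

Units: potentials mV, rates s⁻¹, concentrations μmol (μmol/L), time s;
no implicit conversions anywhere.

## Numerics

**Integration.** Stochastic Heun: with `q` frozen within a step, predictor
`x + dt·f(x)` and corrector `x + dt/2·(f(x) + f(x_pred))`, which is
deterministic RK2 driven by piecewise-constant noise; the deterministic
sub-scheme converges at order 2 (verified against a 100×-finer reference).
Default `dt = 10⁻⁴ s` (~100 steps per synaptic time constant at
`a = 100 s⁻¹`), samples stored every 10 steps (1 kHz). The network feedback
terms are recomputed at the predictor state. The kernel is numba-compiled;
noise is generated in chunks from per-node Philox streams keyed by
`(master seed, parameter-pair, batch, node)`, so an N-node run with
couplings set to zero is bitwise identical to N isolated runs — the
decoupling property the tests exploit.

**Protocol.** Every run starts from the deterministic single-node
equilibrium at `q = q_mean` (found by a damped Gauss–Seidel between the
scalar neuronal balance and the monotone concentration balances, polished
by Newton to max-residual < 10⁻¹⁰·scale), replicated across nodes. A 370 s
calibration run reaches the statistically stationary state; its end state
seeds the batches (default ten of 120 s) which differ only in their noise
streams.

**Interpretation of q.** The baseline input is called both a firing rate
and white noise; the default reading resamples it per node per integration
step and holds it within the step (so its effective strength depends on
`dt`). A `q_mode="fixed"` switch draws it once per run instead.

**Concentration positivity** is diagnosed, not clamped: uptake sigmoids are
nonzero at zero concentration, so coarse steps could push tiny negatives;
the calibrated regime keeps concentrations well inside positive windows.

**Bifurcation analysis.** The quasi-steady-state reduction freezes
`(v_Glu, v_GABA)` and analyzes the 6-dimensional neuronal compartment.
Equilibria come from a dense scan + bisection of the scalar fixed-point
equation in `u = E_ExIn − E_InIn`, polished by damped Newton with the
closed-form Jacobian; stability from its eigenvalues. Hopf loci are grid
sign-changes of the leading complex-pair real part, bisected to
`|Re λ| < 10⁻⁶`; when several equilibria coexist the upper branch (largest
`E_Pyr`) is used. Orbits are characterized by brute-force integration
(default 20 s settle + 20 s measure; near the locus the caller should
settle for hundreds of seconds since transients decay at `|Re λ|`):
classification is `periodic` if the LFP peak-to-peak exceeds 10⁻³ mV and
the two measure-half amplitudes agree within 5 % (otherwise `other`);
frequency is the reciprocal mean interval between upward zero crossings
with sub-sample interpolation. Amplitude isolines use marching squares
with linear edge interpolation. Orbits below 8 Hz are retained, not
discarded.

**Spectra and envelopes.** Welch estimates use 4 s Hann segments, 50 %
overlap, per-segment linear detrend; whole-brain peaks average regional
spectra before peak-picking. Amplitude envelopes are Hilbert magnitudes of
the alpha-band (8–13 Hz, 4th-order Butterworth, forward–backward)
filtered LFP; one second is trimmed at each end before statistics. The
envelope-modulation peak uses 40 s segments with constant (mean-only)
detrend and the DC bin excluded — per-segment linear detrending would
remove the sub-0.1 Hz modulation the estimate is meant to resolve.

**Connectivity.** PLV is the modulus of the time-averaged unit phasor of
analytic-signal phase differences; AEC and the concentration layers are
absolute Pearson correlations of 0.5 Hz-low-passed series. Each layer is
thresholded independently to its top 25 % strongest edges (ties broken
lexicographically; retained edges keep their weights — weighted metrics
reduce to binary behaviour on binary inputs). Batch-averaged layers use
arithmetic means for PLV and back-transformed Fisher-z means for
correlations. The multiplex couples layers by identity blocks of weight 1.
Clustering counts intra-layer triads only (identity interlayer links
connect only replicas and create no triangles in the multiplex block
structure); path lengths run on the supra-network with edge length
1/weight intra-layer and 1 interlayer; versatility is the Perron vector of
the supra-adjacency summed over replicas and max-normalized. The map
equation is the two-level form for an undirected weighted walk (visit
rates ∝ supra-strength), minimized by deterministic greedy node moves plus
exhaustive pairwise module merges — adequate for the desk-scale networks
used here, not tuned for thousands of nodes. Reducibility uses density
matrices `ρ = L/tr L`, quantum Jensen–Shannon distances with average
linkage, and the quality `q = (h_agg − mean layer entropy)/h_agg`; exact
quality ties resolve toward more merges so fully redundant layers
collapse.

**GMM clustering** uses shared-full ("tied") covariance by default for
activity profiles and per-component full covariance for topology features,
k-means initialization, best-of-10 EM replicates by log-likelihood, and
AIC selection preferring the smaller component count within 2 AIC units.
Singular covariances are ridge-regularized (`reg_covar = 10⁻⁶`).

**Scattered heatmaps** use Delaunay piecewise-linear interpolation (exact
at data points, linear precision, convex-combination bounded); the method
is flagged in metadata.

## Surrogate structural layers

Empirical connectomes require restricted MRI data and external toolchains,
so the package loads precomputed matrices (CSV/TSV/MatrixMarket) and ships
surrogate generators for everything downstream, which only needs
row-stochastic matrices of the right topological character:

* `surrogate_neuronal_layer`: planted communities (denser and heavier
  within-community edges, contrast ratio `p_in/p_out`), log-normal weights
  for hub heterogeneity, and a boosted hub community (a precuneus
  analogue); connectivity is enforced by bounded resampling.
* `surrogate_astrocytic_layer`: a ring lattice (the 1-D analogue of the
  cortical-mantle first-neighbour lattice) or a k-nearest-neighbour graph
  on supplied coordinates, weighted by reciprocal Euclidean distance
  (geodesic distances would need the cortical surface mesh).

The surrogates reproduce the structural properties the model's mechanisms
depend on — row-stochastic convex mixing, community structure and hubs in
the neuronal layer, strict first-neighbour locality in the astrocytic
layer — but not the anatomical embedding, hemispheric symmetry, or the
empirical weight spectra of tractography connectomes. Passing tests
therefore validate the dynamical and analytical machinery at desk scale;
they do not certify anatomically realistic spatial patterns.

## Problem sizes

The package's own experiments run at reduced scale by design: 4–16-node
surrogate networks, one 370 s calibration + one 120 s batch for the
spectral checks, 5 noise seeds × 3 grid points per coupling-trend sweep,
and a 216-node instantiation for dimension accounting. The full
1225-pair × 10-batch × 216-node production sweep is supported by the same
code paths (the CLI exposes it) but is a cluster-scale undertaking.

## Known limitations

* Parameter defaults are a calibrated set satisfying the published design
  constraints, not a transcription of an external table; other constant
  sets satisfying the same constraints exist.
* The map-equation optimizer is greedy and deterministic; it finds the
  planted partitions of the test networks but carries no global optimality
  guarantee.
* The exact non-uniform sampling of the coupling plane used to tile the
  `(v_Glu, v_GABA)` grid uniformly is emulated by the rectangular grid
  plus the bifurcation maps, not replicated.
* Hemodynamics, axonal delays, plasticity, and GABA-induced
  gliotransmission are out of scope.
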