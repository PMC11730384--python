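# Default parameter registry: the baseline working point of the
# neuron-astrocyte mass network model.
#
# The neuronal compartment uses the standard Jansen-Rit constant set
# (A, a, B, b, connectivity constants, sigmoid nu_max/r/v0), which places the
# isolated compartment on its alpha-band limit cycle at the baseline input
# q_mean = 240 Hz.  The neurotransmitter compartment constants are calibrated
# so that, at baseline, extracellular glutamate and GABA settle near the
# centers of sensitivity of their excitability sigmoids (v_Glu = v_GABA = 0)
# inside the operating windows Glu_e in [5, 15] umol and GABA_e in [5, 35]
# umol, with release/uptake dynamics evolving below 0.5 Hz.
# See docs/methods.md for the calibration rationale.

# Synaptic impulse responses
A: 3.25          # mV
a: 100.0         # 1/s
B: 22.0          # mV
b: 50.0          # 1/s

# Intra-node connectivity constants (dimensionless)
C_Pyr_to_ExIn: 135.0
C_ExIn_to_Pyr: 108.0
C_Pyr_to_InIn: 33.75
C_InIn_to_Pyr: 33.75

# Firing-rate sigmoid
nu_max: 5.0      # 1/s
r: 0.56          # 1/mV
v0: 6.0          # mV

# Glutamate release / uptake
W: 2.0           # umol
w_r: 10.0        # 1/s
w_d: 5.0         # 1/s
V_Glue_Ast: 3.2      # umol/s
V_Glue_Pyr: 0.8      # umol/s
r_Glue_AstPyr: 0.4   # 1/umol
theta_Glue_AstPyr: 10.0  # umol
tau_GluAst: 2.0      # s

# GABA release / uptake
Z: 2.7           # umol
z_r: 10.0        # 1/s
z_d: 5.0         # 1/s
V_GABAe_Ast: 0.6     # umol/s
K_GABAe_Ast: 30.0    # umol
V_GABAe_InIn: 2.0    # umol/s
K_GABAe_InIn: 30.0   # umol
tau_GABAAst: 2.0     # s

# Excitability modulation sigmoids
m_Glu_Pyr: 4.0       # mV
r_Glu_PyrInIn: 0.25  # 1/umol
theta_Glu_PyrInIn: 10.89  # umol (baseline Glu_e; frozen by calibration)
delta_Glu_Pyr: 2.0   # mV
m_GABA_Pyr: 8.0      # mV
r_GABA_Pyr: 0.2      # 1/umol
theta_GABA_Pyr: 11.09  # umol (frozen by calibration: v_GABA=+2 mV at baseline GABA_e)
delta_GABA_Pyr: 4.0  # mV
mu_Glu_InIn_over_Pyr: 0.5

# Astrocytic glutamate binding sigmoid (shares slope/threshold with uptake)
m_Glu_Ast: 1.0       # umol/s
r_Glu_Ast: 0.4       # 1/umol
theta_Glu_Ast: 10.0  # umol

# Global couplings
omega_Pyr: 7.5       # dimensionless
omega_Glu: 4.5       # 1/umol (midpoint of explored range [2.90, 6.47])
omega_GABA: 1.0      # 1/umol (midpoint of explored range [0.14, 1.94])

# Stochastic baseline input
q_mean: 240.0    # Hz
q_sd: 10.0       # Hz
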