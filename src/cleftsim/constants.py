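"""Physical constants (CODATA 2018 exact values) and package defaults.

Internal computation is always in SI units; the named defaults below are
the physiological operating point of the model: a 20 nm glutamatergic
cleft at body temperature with a -4 mV trans-cleft potential.
"""

#: elementary charge (C)
E_CHARGE = 1.602176634e-19

#: Boltzmann constant (J/K)
K_B = 1.380649e-23

#: physiological temperature (K)
T_BODY_K = 310.0

#: default cleft width (m) — 20 nm
D_CLEFT = 20e-9

#: default diffusion coefficient (m^2/s) — 0.33 um^2/ms
D_DIFF = 0.33e-9

#: default trans-cleft voltage (V) — -4 mV
V_CLEFT = -4e-3

#: soft-wall defaults: peak force (N), region half-width (m), steepness (m)
F_MAX = 9.6e-12
WALL_X0 = 2e-9
WALL_LC = -3e-10

#: numerical protocol defaults: time step (s), run count, censoring horizon (s)
DT = 10e-9
N_RUNS = 50_000
T_MAX = 5e-3
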