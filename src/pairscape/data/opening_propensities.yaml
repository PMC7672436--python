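# Published opening propensities dG_w at delta-Opening = -60 deg
# (kcal/mol, 3-sigma uncertainties) per sequence class and central pair.
# These are transcribed reference inputs for the downstream gap arithmetic;
# the package does not attempt to recompute them from simulation.
delta_sigma: -60.0
propensities:
  I:
    "aA:aT": [8.36, 0.08]
    "aG:aC": [10.21, 0.10]
    "aG/aT": [5.25, 0.11]
  II:
    "aA:aT": [9.76, 0.07]
    "aG:aC": [12.38, 0.13]
    "aG/aT": [6.61, 0.11]
  III:
    "aA:aT": [10.80, 0.07]
    "aG:aC": [12.37, 0.10]
    "aG/aT": [7.40, 0.12]
  C1:
    "aA:aT": [9.56, 0.06]
    "aG:aC": [11.29, 0.08]
    "aG/aT": [6.97, 0.11]
  C2:
    "aA:aT": [10.08, 0.07]
    "aG:aC": [11.32, 0.08]
    "aG/aT": [6.60, 0.11]
  H1:
    "aA:aT": [10.03, 0.07]
    "aG:aC": [12.38, 0.10]
    "aG/aT": [8.08, 0.12]
  H2:
    "aA:aT": [9.51, 0.07]
    "aG:aC": [12.43, 0.08]
    "aG/aT": [7.07, 0.11]
  H3:
    "aA:aT": [9.22, 0.06]
    "aG:aC": [11.44, 0.08]
    "aG/aT": [6.64, 0.08]
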