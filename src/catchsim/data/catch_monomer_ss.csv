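# Mean per-residue secondary-structure occupancies for single CATCH(6K+),
# CATCH(6E-) and CATCH(6D-) peptides at 310 K, from replica-exchange
# simulations with DSSP assignment. "helix" is the combined 3-10/alpha/pi
# helix occupancy. Used as the worked-example input of the
# secondary-structure aggregation analysis.
residue,helix_6K,helix_6E,helix_6D,bend_6K,bend_6E,bend_6D,turn_6K,turn_6E,turn_6D,coil_6K,coil_6E,coil_6D
1,0.23,0.24,0.20,0.00,0.00,0.00,0.29,0.22,0.19,0.48,0.54,0.61
2,0.39,0.47,0.37,0.00,0.00,0.00,0.32,0.27,0.25,0.28,0.27,0.37
3,0.47,0.62,0.54,0.18,0.08,0.10,0.24,0.23,0.24,0.09,0.07,0.12
4,0.50,0.66,0.60,0.19,0.09,0.09,0.23,0.21,0.25,0.08,0.04,0.06
5,0.48,0.69,0.63,0.18,0.07,0.09,0.24,0.18,0.21,0.10,0.07,0.08
6,0.50,0.72,0.64,0.21,0.07,0.09,0.22,0.19,0.22,0.06,0.03,0.05
7,0.55,0.75,0.63,0.13,0.04,0.07,0.27,0.18,0.21,0.05,0.03,0.09
8,0.48,0.74,0.60,0.20,0.04,0.10,0.26,0.19,0.25,0.06,0.02,0.05
9,0.43,0.66,0.50,0.16,0.04,0.09,0.32,0.26,0.30,0.09,0.04,0.12
10,0.27,0.46,0.34,0.00,0.00,0.00,0.31,0.39,0.35,0.41,0.16,0.31
11,0.12,0.28,0.19,0.00,0.00,0.00,0.18,0.34,0.29,0.70,0.39,0.52
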