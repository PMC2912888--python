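# Per-class Lennard-Jones parameters.
# epsilon: well depth (kcal/mol), CHARMM19-style seeds; radius: class radius (Angstrom),
# so that r_min(i,j) = r_i + r_j; polar: 1 for N/O classes (hydrogen-bond capable).
# Radii can be refitted from a corpus with tetrapot.calibration.fit_lj_radii.
# class	epsilon	radius	polar
N_BB	0.2384	1.65	1
C_ALPHA	0.0486	1.85	0
C_CARBONYL_BB	0.1200	1.80	0
O_CARBONYL_BB	0.1591	1.52	1
C_CH3	0.1811	1.90	0
C_CH2	0.1142	1.90	0
C_CH1	0.0486	1.92	0
C_AROMATIC	0.1200	1.85	0
C_RING_N	0.1200	1.82	0
C_AMIDE	0.1200	1.80	0
C_CARBOXYL	0.1200	1.80	0
C_GUANIDINIUM	0.1200	1.80	0
O_AMIDE	0.1591	1.52	1
O_CARBOXYL	0.6469	1.49	1
O_HYDROXYL	0.1591	1.54	1
N_AMIDE	0.2384	1.68	1
N_AMINE	0.2384	1.69	1
N_GUANIDINIUM	0.2384	1.68	1
N_RING	0.2384	1.66	1
S_THIOETHER	0.0430	1.95	0
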