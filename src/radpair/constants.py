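"""Physical constants and default model parameters.

All Hamiltonian terms are carried in angular-frequency units (rad/s).
Magnetic fields and hyperfine coupling constants (HFCCs) are supplied in
microtesla and converted with the electron gyromagnetic ratio.
"""

#: Free-electron gyromagnetic ratio, rad s^-1 T^-1 (g = 2.00231930436).
GAMMA_E = 1.76085963e11

#: Geomagnetic field magnitude used as the control condition, μT.
GMF_UT = 55.26

#: Hypomagnetic (shielded) field magnitude, μT.
HMF_UT = 0.29

#: Isotropic HFCC of the flavin semiquinone H5 proton with electron A, μT.
A1_H5_UT = -802.9

#: Isotropic HFCC of a single ¹⁷O nucleus in superoxide with electron B, μT
#: (DFT-derived input; taken as a constant of the model).
A2_O17_UT = 1886.8

#: Nuclear spin quantum number of ¹⁷O.
SPIN_O17 = 2.5

#: Default spin-selective recombination rate k, s^-1 (1/k = pair lifetime).
K_DEFAULT = 2e6

#: Default phenomenological spin-relaxation rate r, s^-1 (1/r = coherence lifetime).
R_DEFAULT = 2e5

#: BrdU+ proliferating-cell counts after 8 weeks: group mean and SD.
BRDU_GMF_MEAN = 1826.20
BRDU_GMF_SD = 174.55
BRDU_HMF_MEAN = 1363.51
BRDU_HMF_SD = 131.34

#: Experimental GMF/HMF cell-count ratio band (center ± half-width).
BAND_CENTER = 1.34
BAND_HALF_WIDTH = 0.18
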