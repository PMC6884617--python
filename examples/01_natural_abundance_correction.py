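"""Correct a measured isotopologue spectrum for natural abundance.

Builds the theoretical MID of unlabeled citrate, treats it as a
measured spectrum, and shows that correction returns a pure M0
species — the defining property of the correction step.
"""

import numpy as np

from glutrace import build_correction_matrix, correct_mid, natural_mid

formula = "C6H8O7"  # citrate
measured = natural_mid(formula, max_shift=6, metabolite="citrate")
print("measured (unlabeled citrate):", np.round(measured.abundances, 4))
# M1 is ~7% from natural 13C alone: uncorrected spectra overstate labeling.

matrix = build_correction_matrix(formula, tracer_element="C", tracer_positions=6)
corrected = correct_mid(measured, matrix)
print("corrected:                    ", np.round(corrected.abundances, 4))
# After correction all signal collapses onto M0: no tracer-derived label.
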