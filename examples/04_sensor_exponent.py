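"""Estimate the camera's power-law exponent from known intensity steps.

Phone sensors store pixel values P ~ I^n rather than linearly in the
incident intensity I; n < 1 compresses measured absorbances (and
calibration slopes) by the factor n. Given a ladder of known relative
intensities and the pixel values they produce, n is the log-log slope.
"""

import numpy as np

from duobeam import correct_exponent, estimate_exponent

rng = np.random.default_rng(0)
true_n = 0.64

intensities = np.linspace(0.05, 1.0, 12)  # e.g. a neutral-density step ladder
pixels = intensities**true_n * np.exp(rng.normal(0, 0.01, intensities.size))

n_hat = estimate_exponent(np.column_stack([intensities, pixels]))
print(f"true exponent     : {true_n}")
print(f"estimated exponent: {n_hat:.4f}")

A_measured = 0.64  # an absorbance read off the compressed sensor
print(f"measured A {A_measured} linearizes to {correct_exponent(A_measured, n_hat):.4f}")
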