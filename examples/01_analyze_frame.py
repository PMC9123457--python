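"""Measure absorbance from a single dual-beam spectrum photograph.

Renders a synthetic frame (two diffraction stripes of a white LED; the
right stripe passes through a 3 mg/L sample) and runs the full analysis:
orientation check, stripe localization, wavelength calibration from the
LED's red/blue channel peaks, and band absorbance at 535 nm.
"""

from duobeam import RunConfig, analyze
from duobeam.synth import CameraModel, SceneConfig, render

scene = SceneConfig(concentration=3.0)  # mg/L; absorber band at 535 nm
camera = CameraModel(exponent=0.64, noise_sd=0.01)
frame, truth = render(scene, camera=camera, seed=42)

# Anchor wavelengths are a per-LED constant, measured once with a bench
# spectrometer; here the renderer tells us its true values.
config = RunConfig(
    target_wavelength_nm=535.0,
    lambda_red_nm=truth.lambda_red,
    lambda_blue_nm=truth.lambda_blue,
    exponent=camera.exponent,
)

result = analyze(frame, config)
print(f"target wavelength : {result.wavelength_nm:g} nm "
      f"(prominent channel {result.channel})")
print(f"measured A        : {result.A:.4f}   <- compressed by the sensor power law")
print(f"linearized A / n  : {result.A_linear:.4f}")
print(f"ground truth e*c*l: {truth.absorbance_true:.4f}")
# The measured absorbance is ~n*eps*c*l; dividing by the sensor exponent n
# recovers the true Beer-Lambert absorbance.
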