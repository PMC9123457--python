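"""Build a Beer-Lambert calibration curve from a synthetic standard series.

Renders 6 concentration levels x 3 replicates, takes a blank frame first
(as the bench procedure requires), measures every frame's absorbance at
535 nm, and fits absorbance against concentration by ordinary least
squares. With a sensor exponent n < 1 the fitted slope is n*eps*l, not
eps*l — the power-law compression the exponent correction undoes.
"""

from duobeam import RunConfig, analyze, blank_offset, fit_calibration
from duobeam.synth import CameraModel, SceneConfig, make_series, render

scene = SceneConfig()
camera = CameraModel(exponent=0.64, noise_sd=0.01)
_, truth = render(scene, camera=CameraModel(noise_sd=0.0), seed=0)
config = RunConfig(lambda_red_nm=truth.lambda_red, lambda_blue_nm=truth.lambda_blue)

blank_frame, _ = render(scene, camera=camera, seed=1)
offset = blank_offset(blank_frame, config)
print(f"blank offset: {offset:+.4f} (zero up to noise for a balanced device)")

series = make_series(scene, [0, 1, 2, 3, 4, 5], replicates=3, seed=2, camera=camera)
points = [(c, analyze(frame, config, blank=offset).A) for frame, _, c in series]
curve = fit_calibration(points, analyte="nitrate", wavelength_nm=535.0)

ideal = scene.epsilon * scene.path_length_cm
print(f"fitted slope : {curve.slope:.4f} A per mg/L")
print(f"ideal eps*l  : {ideal:.4f}  -> slope/ideal = {curve.slope / ideal:.3f} "
      f"~ sensor exponent {camera.exponent}")
print(f"intercept    : {curve.intercept:+.4f}")
print(f"R^2          : {curve.r_squared:.4f} over {curve.n_points} frames")
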