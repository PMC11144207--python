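"""Extract the functional dose-volume vector V5..V60 for the fLung.

A Gaussian-falloff dose grid centred in the left lung stands in for a
planned dose distribution; Vx is the percentage of fLung volume receiving
at least x Gy. These twelve percentages are the covariates of the
pneumonitis risk models.
"""

from ventidose import jacobian_determinant, segment_high_function
from ventidose.dvh import cumulative_dvh, extract_fv_vector
from ventidose.phantom import PhantomSpec, generate_dose_grid, generate_phantom_pair

spec = PhantomSpec(noise_sd=0.0)
_, _, truth, lung = generate_phantom_pair(spec)
flung = segment_high_function(jacobian_determinant(truth), lung, threshold=1.2)

dose = generate_dose_grid(spec, target_center=spec.lung_geometry[0].center,
                          prescription=60.0, falloff_mm=40.0)

fv = extract_fv_vector(dose, flung)
print(f"fLung: {flung.volume_cc:.0f} cc of {lung.volume_cc:.0f} cc lung")
print("functional dose-volume vector (% of fLung receiving >= x Gy):")
print(fv.as_series().round(1).to_string())

curve = cumulative_dvh(dose, flung, bin_width=0.1)
mean_dose = 0.1 * (curve.cumulative_percent / 100.0).sum()
print(f"mean fLung dose from the DVH integral: {mean_dose:.1f} Gy")

# V5 >= V10 >= ... >= V60 by construction (a cumulative DVH); the vector
# feeds the logistic risk models in the riskmodel module
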