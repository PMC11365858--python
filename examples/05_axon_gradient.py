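"""Quantify a surface-in axon gradient in 750 um distance bins.

Simulates a periventricular field where myelinated-axon density is
reduced, and axon diameter increased, next to the ventricular surface --
the surface-in degeneration pattern -- and recovers both gradients.
"""

from myelotype import bin_gradient, generate_axon_field
from myelotype.axons import fit_bin_slopes

axons = generate_axon_field(density_at_surface_per_mm2=40.0,
                            density_slope_per_mm2_per_um=0.02,
                            diameter_mean_fn=lambda d: 1.2 - 0.0001 * d,
                            field_extent_um=(3000.0, 1000.0), seed=5)
profile = bin_gradient(axons, field_area_per_bin_mm2=0.75, n_bins=4)
print(profile.to_frame().to_string(index=False, float_format="%.2f"))
dens_slope, diam_slope = fit_bin_slopes(profile)
print(f"\ndensity slope: {dens_slope * 1000:+.1f} axons/mm^2 per mm "
      f"(positive: density recovers away from the surface)")
print(f"diameter slope: {diam_slope * 1000:+.3f} um per mm "
      f"(negative: axons are swollen near the surface)")
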