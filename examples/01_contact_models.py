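"""Evaluate the four contact-model force expressions at one pixel.

Shows the force each model predicts for the same indentation, the model
nesting (HS with zero prestress is exactly Hertz), and the hallmark of
compressive prestress: a negative total force at shallow depth that turns
positive once the Hertz term takes over.
"""

from prestressmap import (PixelContext, TipDescriptors,
                          cslc_force, hertz_force, hs_force,
                          negative_force_crossover, sneddon_force,
                          tip_radius_at)

td = TipDescriptors(r=50e-9, a=10e-9, b=30e-9, c=0.02)
ctx = PixelContext(gx=0.2, gy=-0.4)   # local topographic slopes
d = 200e-9                            # 200 nm indentation
R = float(tip_radius_at(td, ctx, d))
print(f"effective tip radius at d=200 nm: R = {R*1e9:.1f} nm "
      "(base radius corrected for local slope and depth)")

E, sigma, theta = 10e3, 20e3, 0.35
print(f"HS      (sigma=20 kPa, E=10 kPa): F = {hs_force(sigma, E, R, d)*1e9:.3f} nN")
print(f"Hertz   (E=10 kPa):               F = {hertz_force(E, R, d)*1e9:.3f} nN")
print(f"Sneddon (theta=20 deg, E=10 kPa): F = {sneddon_force(E, theta, d)*1e9:.3f} nN")
print(f"CSLC    (T=0.2 mN/m, r_cell=8um): F = {cslc_force(2e-4, 8e-6, R, d)*1e9:.3f} nN")
print(f"nesting check: HS(sigma=0) - Hertz = "
      f"{hs_force(0.0, E, R, d) - hertz_force(E, R, d):.2e} N")

# compressive prestress: the element bends away from the tip at shallow depth
dstar = negative_force_crossover(sigma=-5e3, E=10e3, td=td, ctx=ctx, d_max=2e-6)
print(f"\ncompressive pixel (sigma = -5 kPa): total force is negative down to "
      f"d* = {dstar*1e9:.1f} nm, then the elastic term dominates")
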