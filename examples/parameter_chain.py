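"""Physical parameter chain for the crowding benchmark.

Derives every particle parameter of the two-species benchmark from first
principles: Stokes-Einstein diffusion constants at 20 degC in water, the
equal-volume radius of the association product, and the packing formula
that converts an occupied volume fraction into particle numbers.
"""

from rdx import equal_volume_radius, stokes_einstein_D, thermal_energy
from rdx.systems import benchmark_particle_numbers

print(f"thermal energy at 293.15 K: {thermal_energy(293.15):.4f} kJ/mol")
r_a, r_b = 1.5, 3.0
r_c = equal_volume_radius(r_a, r_b)
print(f"product radius (equal volume): {r_c:.2f} nm")
for name, r in (("A", r_a), ("B", r_b), ("C", r_c)):
    print(f"D_{name} (Stokes-Einstein, r = {r:.2f} nm): "
          f"{stokes_einstein_D(r):.2f} nm^2/us")

print("\noccupied volume fraction -> total particles (100 nm box):")
for phi in (0.01, 0.10, 0.20, 0.30, 0.40, 0.50):
    n_a, n_b = benchmark_particle_numbers(phi)
    print(f"  {phi:4.0%}: {n_a + n_b:5d}  (N_A = N_B = {n_a})")

# The diffusion constants set how far a particle moves per 0.1 ns timestep
# (~0.17 nm for A), and the packing numbers reproduce densities from dilute
# (1%) up to strongly crowded (50%, beyond cytosol's ~30%).
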