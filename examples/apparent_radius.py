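"""Soft repulsion admits overlap: the apparent collision radius.

Monte Carlo samples the 50%-occupied benchmark and measures the same-type
radial distribution function of the small species. With the default soft
force constant (k = 10 kJ/mol/nm^2) particles interpenetrate a little, so
the apparent radius from the 50%-area rule falls below the nominal 1.5 nm
collision radius. Takes ~20 s.
"""

from rdx.validation import apparent_radius_study

app, rdf = apparent_radius_study(phi=0.5, box_edge=40.0, seed=3,
                                 relax_sweeps=2000, sample_sweeps=3000)
print(f"first g(r) maximum at {app.first_max_r:.2f} nm "
      f"(contact distance sigma_AA = 3.0 nm)")
print(f"apparent collision radius r_app(A) = {app.r_app:.3f} nm "
      f"(nominal 1.5 nm)")
print(f"overlap interval ({app.quantiles[0]:.1%}-{app.quantiles[1]:.1%} area): "
      f"pair distances {app.interval[0]:.2f}-{app.interval[1]:.2f} nm")
# The gap between r_app and the collision radius measures how much overlap
# the chosen force constant permits; stiffer springs close it.
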