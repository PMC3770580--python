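<simulation>
  <!-- Reversible association A + B <-> C in a crowded 25 nm box (30% occupied
       volume). The forward rate is given macroscopically (nm^3/us) and is
       converted to a per-encounter microscopic rate at parse time. -->
  <global box_origin="0 0 0" box_extent="25 25 25" dt="1e-4" temperature="293.15"
          n_steps="5000" seed="1" output_stride="50"/>
  <particles>
    <type name="A" collision_radius="1.5" reaction_radius="1.5" diffusion_constant="143.1"/>
    <type name="B" collision_radius="3.0" reaction_radius="3.0" diffusion_constant="71.6"/>
    <type name="C" collision_radius="3.12" reaction_radius="3.12" diffusion_constant="68.82"/>
    <place type="A" n="37"/>
    <place type="B" n="37"/>
  </particles>
  <potentials>
    <box_wall force_constant="10"/>
    <pair_repulsion force_constant="10"/>
  </potentials>
  <groups/>
  <reactions>
    <fusion educts="A B" product="C" rate="60" rate_is_macroscopic="true"/>
    <fission educt="C" products="A B" rate="0.071"/>
  </reactions>
</simulation>
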