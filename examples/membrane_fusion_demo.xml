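<simulation>
  <!-- Qualitative vesicle-fusion-style demo: membrane-bound proteins on a
       disk, a calcium channel emitting ions, SNARE-complex formation via
       fusion, complex disassembly via fission, and short-range attraction
       that clusters complexes. Illustrates every reaction kind and the
       geometry potentials; rates and sizes are illustrative only. -->
  <global box_origin="-25 -25 -25" box_extent="25 25 25" dt="1e-4"
          temperature="293.15" n_steps="2000" seed="7" output_stride="100"/>
  <particles>
    <type name="SyxClosed" collision_radius="1.5" reaction_radius="1.5" diffusion_constant="50"/>
    <type name="SyxOpen"   collision_radius="1.5" reaction_radius="1.5" diffusion_constant="50"/>
    <type name="Snap25"    collision_radius="1.5" reaction_radius="1.5" diffusion_constant="50"/>
    <type name="Snare"     collision_radius="2.0" reaction_radius="2.0" diffusion_constant="40"/>
    <type name="Channel"   collision_radius="2.5" reaction_radius="2.5" diffusion_constant="10"/>
    <type name="Ca"        collision_radius="0.3" reaction_radius="0.5" diffusion_constant="500"/>
    <place type="SyxClosed" n="12"/>
    <place type="Snap25" n="12"/>
    <place type="Channel" n="1"/>
  </particles>
  <potentials>
    <box_wall force_constant="10"/>
    <pair_repulsion force_constant="10"/>
    <pair_attraction force_constant_repulsion="10" force_constant_attraction="1"
                     width="2" types_a="Snare" types_b="Snare"/>
    <disk_membrane center="0 0 0" radius="20" force_constant="10"
                   types="SyxClosed SyxOpen Snap25 Snare Channel"/>
    <cylinder_wall center="0 0 0" radius="20" force_constant="10" types="Ca"/>
  </potentials>
  <groups/>
  <reactions>
    <conversion educt="SyxClosed" product="SyxOpen" rate="1.0"/>
    <conversion educt="SyxOpen" product="SyxClosed" rate="0.5"/>
    <fusion educts="SyxOpen Snap25" product="Snare" rate="10"/>
    <fission educt="Snare" products="SyxOpen Snap25" rate="0.01"/>
    <birth source="Channel" product="Ca" rate="5"/>
    <decay educt="Ca" rate="2"/>
  </reactions>
</simulation>
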