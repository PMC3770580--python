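"""Declarative simulation configuration (XML, five sections).

A configuration document has the sections ``global``, ``particles``,
``potentials``, ``groups`` and ``reactions``::

    <simulation>
      <global box_origin="0 0 0" box_extent="100 100 100"
              dt="1e-4" temperature="293.15" n_steps="1000" seed="1"
              output_stride="10"/>
      <particles>
        <type name="A" collision_radius="1.5" reaction_radius="1.5"
              diffusion_constant="143.1"/>
        <place type="A" n="100"/>               <!-- uniform random -->
        <particle type="A" position="1 2 3"/>   <!-- explicit -->
      </particles>
      <potentials>
        <box_wall force_constant="10"/>          <!-- defaults to the box -->
        <pair_repulsion force_constant="10"/>
      </potentials>
      <groups>
        <group name="dimer">
          <member type="A" position="0 0 0"/>
          <member type="A" position="3 0 0"/>
          <bond i="0" j="1" force_constant="10" length="3"/>
        </group>
        <instance group="dimer" n="2"/>
      </groups>
      <reactions>
        <fusion educts="A B" product="C" rate="1e-2"/>
        <fission educt="C" products="A B" rate="1e-3"/>
      </reactions>
    </simulation>

Bimolecular rates may be given macroscopically (``rate_is_macroscopic=
"true"``, nm^3/us); they are converted to microscopic rates with the
Erban-Chapman inversion using the educts' diffusion constants and reaction
radii. Unknown elements produce warnings; missing required attributes raise
errors naming the offending path. Group templates are expanded at build
time into ordinary particles plus harmonic bonds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .model import (
    ParticleTypeSpec,
    SimulationParameters,
    SystemState,
    TypeRegistry,
    make_rng,
)
from .potentials import (
    BoxWall,
    CylinderWall,
    DiskMembrane,
    HarmonicBond,
    PairAttraction,
    PairRepulsion,
    PotentialSet,
    SphereSurface,
)
from .reactions import ReactionRule, invert_erban

__all__ = ["ConfigDocument", "GroupTemplate", "parse_config", "serialize_config"]


class ConfigError(ValueError):
    """A malformed or inconsistent configuration document."""


@dataclass
class GroupTemplate:
    name: str
    member_types: list
    member_positions: np.ndarray  # (M, 3) template coordinates
    bonds: list  # (i, j, force_constant, length)


@dataclass
class ConfigDocument:
    params: SimulationParameters
    box_origin: np.ndarray
    box_extent: np.ndarray
    registry: TypeRegistry
    placements: list  # ("count", type, n) | ("explicit", type, position)
    potentials: PotentialSet
    reactions: list
    groups: dict = field(default_factory=dict)
    group_instances: list = field(default_factory=list)  # (group name, n)

    def build(self, rng=None):
        """Materialize (state, potentials) — groups become particles + bonds."""
        rng = make_rng(self.params.seed if rng is None else rng)
        state = SystemState.empty(self.registry, self.box_origin, self.box_extent)
        for placement in self.placements:
            if placement[0] == "count":
                _, type_name, n = placement
                state.add_particles(
                    type_name, rng.uniform(self.box_origin, self.box_extent, size=(n, 3)))
            else:
                _, type_name, position = placement
                state.add_particles(type_name, np.asarray(position)[None, :])
        potentials = PotentialSet(list(self.potentials))
        for group_name, n in self.group_instances:
            template = self.groups[group_name]
            for _ in range(n):
                anchor = rng.uniform(self.box_origin, self.box_extent)
                ids = []
                for type_name, rel in zip(template.member_types, template.member_positions):
                    new_ids = state.add_particles(type_name, (anchor + rel)[None, :])
                    ids.append(int(new_ids[0]))
                for i, j, k, length in template.bonds:
                    potentials.add(HarmonicBond(id_i=ids[i], id_j=ids[j],
                                                force_constant=k, length=length))
        return state, potentials


def _require(element, attr, path):
    value = element.get(attr)
    if value is None:
        raise ConfigError(f"missing required attribute {path}@{attr}")
    return value


def _vec(text, path):
    parts = text.split()
    if len(parts) != 3:
        raise ConfigError(f"{path}: expected three numbers, got {text!r}")
    try:
        return tuple(float(v) for v in parts)
    except ValueError as exc:
        raise ConfigError(f"{path}: malformed number in {text!r}") from exc


def _num(text, path):
    try:
        return float(text)
    except ValueError as exc:
        raise ConfigError(f"{path}: malformed number {text!r}") from exc


def _names(element, attr):
    value = element.get(attr)
    return tuple(value.split()) if value else None


def parse_config(source) -> ConfigDocument:
    """Parse a configuration document from a path, file object or XML string."""
    if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(source).exists():
        tree = ET.parse(source)
        root = tree.getroot()
    elif hasattr(source, "read"):
        root = ET.parse(source).getroot()
    else:
        root = ET.fromstring(source)
    if root.tag != "simulation":
        raise ConfigError(f"root element must be <simulation>, got <{root.tag}>")

    known = {"global", "particles", "potentials", "groups", "reactions"}
    for child in root:
        if child.tag not in known:
            warnings.warn(f"ignoring unknown section <{child.tag}>", stacklevel=2)

    g = root.find("global")
    if g is None:
        raise ConfigError("missing required section <global>")
    params = SimulationParameters(
        dt=_num(_require(g, "dt", "global"), "global@dt"),
        temperature=_num(g.get("temperature", "293.15"), "global@temperature"),
        seed=int(_require(g, "seed", "global")),
        n_steps=int(_require(g, "n_steps", "global")),
        output_stride=int(g.get("output_stride", "1")),
    )
    box_origin = np.array(_vec(g.get("box_origin", "0 0 0"), "global@box_origin"))
    box_extent = np.array(_vec(_require(g, "box_extent", "global"), "global@box_extent"))

    p = root.find("particles")
    if p is None:
        raise ConfigError("missing required section <particles>")
    registry = TypeRegistry()
    placements = []
    for el in p:
        if el.tag == "type":
            registry.add(ParticleTypeSpec(
                name=_require(el, "name", "particles/type"),
                collision_radius=_num(_require(el, "collision_radius", "particles/type"),
                                      "particles/type@collision_radius"),
                reaction_radius=_num(_require(el, "reaction_radius", "particles/type"),
                                     "particles/type@reaction_radius"),
                diffusion_constant=_num(_require(el, "diffusion_constant", "particles/type"),
                                        "particles/type@diffusion_constant"),
            ))
        elif el.tag == "place":
            placements.append(("count", _require(el, "type", "particles/place"),
                               int(_require(el, "n", "particles/place"))))
        elif el.tag == "particle":
            placements.append(("explicit", _require(el, "type", "particles/particle"),
                               np.array(_vec(_require(el, "position", "particles/particle"),
                                             "particles/particle@position"))))
        else:
            warnings.warn(f"ignoring unknown element <particles>/<{el.tag}>", stacklevel=2)

    def check_types(names, path):
        if names is None:
            return None
        for n in names:
            if n not in registry:
                raise ConfigError(f"{path} references undeclared type {n!r}")
        return names

    potentials = PotentialSet()
    pot = root.find("potentials")
    for el in pot if pot is not None else ():
        path = f"potentials/{el.tag}"
        k = _num(el.get("force_constant", "10"), f"{path}@force_constant")
        if el.tag == "box_wall":
            potentials.add(BoxWall(
                origin=_vec(el.get("origin") or g.get("box_origin", "0 0 0"), path),
                extent=_vec(el.get("extent") or _require(g, "box_extent", "global"), path),
                force_constant=k, types=check_types(_names(el, "types"), path)))
        elif el.tag == "pair_repulsion":
            potentials.add(PairRepulsion(
                force_constant=k,
                types_a=check_types(_names(el, "types_a"), path),
                types_b=check_types(_names(el, "types_b"), path)))
        elif el.tag == "pair_attraction":
            potentials.add(PairAttraction(
                force_constant_repulsion=_num(el.get("force_constant_repulsion", "10"), path),
                force_constant_attraction=_num(el.get("force_constant_attraction", "1"), path),
                width=_num(el.get("width", "2"), path),
                types_a=check_types(_names(el, "types_a"), path),
                types_b=check_types(_names(el, "types_b"), path)))
        elif el.tag in ("sphere_surface", "disk_membrane", "cylinder_wall"):
            cls = {"sphere_surface": SphereSurface, "disk_membrane": DiskMembrane,
                   "cylinder_wall": CylinderWall}[el.tag]
            potentials.add(cls(
                center=_vec(el.get("center", "0 0 0"), path),
                radius=_num(_require(el, "radius", path), f"{path}@radius"),
                force_constant=k, types=check_types(_names(el, "types"), path)))
        elif el.tag == "harmonic_bond":
            potentials.add(HarmonicBond(
                id_i=int(_require(el, "id_i", path)), id_j=int(_require(el, "id_j", path)),
                force_constant=k, length=_num(el.get("length", "0"), path)))
        else:
            warnings.warn(f"ignoring unknown element <potentials>/<{el.tag}>", stacklevel=2)

    groups: dict[str, GroupTemplate] = {}
    group_instances = []
    gr = root.find("groups")
    for el in gr if gr is not None else ():
        if el.tag == "group":
            name = _require(el, "name", "groups/group")
            member_types, member_positions, bonds = [], [], []
            for sub in el:
                if sub.tag == "member":
                    t = _require(sub, "type", f"groups/group[{name}]/member")
                    if t not in registry:
                        raise ConfigError(
                            f"groups/group[{name}]/member references undeclared type {t!r}")
                    member_types.append(t)
                    member_positions.append(_vec(
                        _require(sub, "position", f"groups/group[{name}]/member"),
                        f"groups/group[{name}]/member@position"))
                elif sub.tag == "bond":
                    bonds.append((int(_require(sub, "i", "bond")),
                                  int(_require(sub, "j", "bond")),
                                  _num(sub.get("force_constant", "10"), "bond"),
                                  _num(sub.get("length", "0"), "bond")))
            for i, j, _, _ in bonds:
                if not (0 <= i < len(member_types) and 0 <= j < len(member_types)):
                    raise ConfigError(f"groups/group[{name}]/bond indices out of range")
            groups[name] = GroupTemplate(name=name, member_types=member_types,
                                         member_positions=np.asarray(member_positions),
                                         bonds=bonds)
        elif el.tag == "instance":
            gname = _require(el, "group", "groups/instance")
            group_instances.append((gname, int(el.get("n", "1"))))
        else:
            warnings.warn(f"ignoring unknown element <groups>/<{el.tag}>", stacklevel=2)
    for gname, _ in group_instances:
        if gname not in groups:
            raise ConfigError(f"groups/instance references undeclared group {gname!r}")

    reactions = []
    rx = root.find("reactions")
    for el in rx if rx is not None else ():
        path = f"reactions/{el.tag}"
        if el.tag not in ("conversion", "fusion", "fission", "birth", "decay"):
            warnings.warn(f"ignoring unknown element <reactions>/<{el.tag}>", stacklevel=2)
            continue
        rate = _num(_require(el, "rate", path), f"{path}@rate")
        macroscopic = el.get("rate_is_macroscopic", "false").lower() in ("true", "1", "yes")
        if el.tag == "fusion":
            educts = tuple(_require(el, "educts", path).split())
            products = (_require(el, "product", path),)
        elif el.tag == "fission":
            educts = (_require(el, "educt", path),)
            products = tuple(_require(el, "products", path).split())
        elif el.tag == "decay":
            educts = (_require(el, "educt", path),)
            products = ()
        elif el.tag == "birth":
            educts = (_require(el, "source", path),)
            products = (_require(el, "product", path),)
        else:  # conversion
            educts = (_require(el, "educt", path),)
            products = (_require(el, "product", path),)
        for t in (*educts, *products):
            if t not in registry:
                raise ConfigError(f"{path} references undeclared type {t!r}")
        if macroscopic:
            if el.tag != "fusion":
                raise ConfigError(f"{path}: rate_is_macroscopic applies to fusion rules only")
            spec_a, spec_b = registry[educts[0]], registry[educts[1]]
            rate = invert_erban(
                rate,
                spec_a.diffusion_constant + spec_b.diffusion_constant,
                spec_a.reaction_radius + spec_b.reaction_radius,
            )
        separation = el.get("separation")
        reactions.append(ReactionRule(
            kind=el.tag, educts=educts, products=products, rate=rate,
            separation=float(separation) if separation is not None else None,
            name=el.get("name", "")))

    return ConfigDocument(
        params=params, box_origin=box_origin, box_extent=box_extent,
        registry=registry, placements=placements, potentials=potentials,
        reactions=reactions, groups=groups, group_instances=group_instances,
    )


def serialize_config(doc: ConfigDocument) -> str:
    """Render a ConfigDocument back to its XML form (microscopic rates)."""
    root = ET.Element("simulation")
    g = ET.SubElement(root, "global")
    g.set("box_origin", " ".join(f"{v:g}" for v in doc.box_origin))
    g.set("box_extent", " ".join(f"{v:g}" for v in doc.box_extent))
    g.set("dt", f"{doc.params.dt:g}")
    g.set("temperature", f"{doc.params.temperature:g}")
    g.set("n_steps", str(doc.params.n_steps))
    g.set("seed", str(doc.params.seed))
    g.set("output_stride", str(doc.params.output_stride))

    p = ET.SubElement(root, "particles")
    for spec in doc.registry:
        ET.SubElement(p, "type", name=spec.name,
                      collision_radius=f"{spec.collision_radius:g}",
                      reaction_radius=f"{spec.reaction_radius:g}",
                      diffusion_constant=f"{spec.diffusion_constant:.10g}")
    for placement in doc.placements:
        if placement[0] == "count":
            ET.SubElement(p, "place", type=placement[1], n=str(placement[2]))
        else:
            ET.SubElement(p, "particle", type=placement[1],
                          position=" ".join(f"{v:.7f}" for v in placement[2]))

    pot = ET.SubElement(root, "potentials")
    for term in doc.potentials:
        if isinstance(term, BoxWall):
            el = ET.SubElement(pot, "box_wall",
                               origin=" ".join(f"{v:g}" for v in term.origin),
                               extent=" ".join(f"{v:g}" for v in term.extent),
                               force_constant=f"{term.force_constant:g}")
            if term.types:
                el.set("types", " ".join(term.types))
        elif isinstance(term, PairRepulsion):
            el = ET.SubElement(pot, "pair_repulsion", force_constant=f"{term.force_constant:g}")
            if term.types_a:
                el.set("types_a", " ".join(term.types_a))
            if term.types_b:
                el.set("types_b", " ".join(term.types_b))
        elif isinstance(term, PairAttraction):
            el = ET.SubElement(
                pot, "pair_attraction",
                force_constant_repulsion=f"{term.force_constant_repulsion:g}",
                force_constant_attraction=f"{term.force_constant_attraction:g}",
                width=f"{term.width:g}")
            if term.types_a:
                el.set("types_a", " ".join(term.types_a))
            if term.types_b:
                el.set("types_b", " ".join(term.types_b))
        elif isinstance(term, (SphereSurface, DiskMembrane, CylinderWall)):
            tag = {SphereSurface: "sphere_surface", DiskMembrane: "disk_membrane",
                   CylinderWall: "cylinder_wall"}[type(term)]
            el = ET.SubElement(pot, tag, center=" ".join(f"{v:g}" for v in term.center),
                               radius=f"{term.radius:g}",
                               force_constant=f"{term.force_constant:g}")
            if term.types:
                el.set("types", " ".join(term.types))
        elif isinstance(term, HarmonicBond):
            ET.SubElement(pot, "harmonic_bond", id_i=str(term.id_i), id_j=str(term.id_j),
                          force_constant=f"{term.force_constant:g}",
                          length=f"{term.length:g}")

    gr = ET.SubElement(root, "groups")
    for template in doc.groups.values():
        el = ET.SubElement(gr, "group", name=template.name)
        for t, pos in zip(template.member_types, template.member_positions):
            ET.SubElement(el, "member", type=t,
                          position=" ".join(f"{v:g}" for v in pos))
        for i, j, k, length in template.bonds:
            ET.SubElement(el, "bond", i=str(i), j=str(j),
                          force_constant=f"{k:g}", length=f"{length:g}")
    for gname, n in doc.group_instances:
        ET.SubElement(gr, "instance", group=gname, n=str(n))

    rx = ET.SubElement(root, "reactions")
    for rule in doc.reactions:
        attrs = {"rate": f"{rule.rate:.12g}"}
        if rule.name:
            attrs["name"] = rule.name
        if rule.kind == "fusion":
            attrs.update(educts=" ".join(rule.educts), product=rule.products[0])
        elif rule.kind == "fission":
            attrs.update(educt=rule.educts[0], products=" ".join(rule.products))
            if rule.separation is not None:
                attrs["separation"] = f"{rule.separation:g}"
        elif rule.kind == "decay":
            attrs.update(educt=rule.educts[0])
        elif rule.kind == "birth":
            attrs.update(source=rule.educts[0], product=rule.products[0])
        else:
            attrs.update(educt=rule.educts[0], product=rule.products[0])
        ET.SubElement(rx, rule.kind, **attrs)

    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"
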