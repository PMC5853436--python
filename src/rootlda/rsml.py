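"""Reading and writing Root System Markup Language (RSML) files.

RSML is the XML interchange format for root architecture: a scene holds
plants, each plant holds top-level roots (seminals here), and laterals
nest inside their parent root.  Geometry is a polyline of <point> nodes;
plant metadata (line, NUpE class, nitrate, group code) travels in a
<properties> block.  One file per plant.
"""

from __future__ import annotations

import datetime
from pathlib import Path

from lxml import etree

from .rootgen import PlantMeta, RootCurve, RootSystem

__all__ = ["write_rsml", "read_rsml", "write_cohort", "read_cohort"]

_FLOAT_FMT = "%.6f"


def _root_element(curve: RootCurve, root_id: str) -> etree._Element:
    root = etree.Element("root", ID=root_id, label=curve.order)
    geom = etree.SubElement(root, "geometry")
    poly = etree.SubElement(geom, "polyline")
    for x, y in curve.points:
        etree.SubElement(poly, "point", x=_FLOAT_FMT % x, y=_FLOAT_FMT % y)
    if curve.order == "lateral":
        props = etree.SubElement(root, "properties")
        etree.SubElement(props, "attachment_arclength").text = (
            _FLOAT_FMT % curve.attachment_arclength
        )
    return root


def rsml_tree(system: RootSystem) -> etree._ElementTree:
    """Build the RSML document for one root system."""
    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "mm"
    etree.SubElement(meta, "resolution").text = "1"
    etree.SubElement(meta, "last-modified").text = datetime.date(2000, 1, 1).isoformat()
    etree.SubElement(meta, "software").text = "rootlda"
    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant", ID=system.plant_id, label=system.meta.line)
    props = etree.SubElement(plant, "properties")
    etree.SubElement(props, "line").text = system.meta.line
    etree.SubElement(props, "nupe_class").text = system.meta.nupe_class
    etree.SubElement(props, "nitrate").text = system.meta.nitrate
    etree.SubElement(props, "group_code").text = str(system.meta.group_code)
    etree.SubElement(props, "seed_x").text = _FLOAT_FMT % system.seed_point[0]
    etree.SubElement(props, "seed_y").text = _FLOAT_FMT % system.seed_point[1]

    seminal_elems = []
    for i, c in enumerate(system.seminal_curves):
        el = _root_element(c, f"{system.plant_id}_S{i}")
        plant.append(el)
        seminal_elems.append(el)
    lat_counter = [0] * len(seminal_elems)
    for c in system.lateral_curves:
        j = lat_counter[c.parent_index]
        lat_counter[c.parent_index] += 1
        el = _root_element(c, f"{system.plant_id}_S{c.parent_index}_L{j}")
        seminal_elems[c.parent_index].append(el)
    return etree.ElementTree(rsml)


def write_rsml(system: RootSystem, path: str | Path) -> Path:
    """Write one root system to an RSML file."""
    path = Path(path)
    tree = rsml_tree(system)
    path.write_bytes(
        etree.tostring(tree, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )
    return path


def _parse_polyline(root_el: etree._Element) -> list[list[float]]:
    pts = root_el.findall("./geometry/polyline/point")
    return [[float(p.get("x")), float(p.get("y"))] for p in pts]


def read_rsml(path: str | Path) -> RootSystem:
    """Read a single-plant RSML file back into a RootSystem."""
    tree = etree.parse(str(path))
    plant = tree.find(".//scene/plant")
    if plant is None:
        raise ValueError(f"{path}: no <plant> element")
    props = {el.tag: (el.text or "") for el in plant.findall("./properties/*")}
    meta = PlantMeta(
        line=props.get("line", plant.get("label", "unknown")),
        nupe_class=props.get("nupe_class", "low"),
        nitrate=props.get("nitrate", "low"),
    )
    curves: list[RootCurve] = []
    for i, root_el in enumerate(plant.findall("./root")):
        curves.append(RootCurve(points=_parse_polyline(root_el), order="seminal"))
        for lat_el in root_el.findall("./root"):
            att_el = lat_el.find("./properties/attachment_arclength")
            att = float(att_el.text) if att_el is not None else 0.0
            curves.append(
                RootCurve(points=_parse_polyline(lat_el), order="lateral",
                          parent_index=i, attachment_arclength=att)
            )
    # reorder: seminals first (RootSystem indexes laterals into the seminal list)
    return RootSystem(
        plant_id=plant.get("ID", Path(path).stem),
        seed_point=[float(props.get("seed_x", 0.0)), float(props.get("seed_y", 0.0))],
        curves=tuple(sorted(curves, key=lambda c: c.order != "seminal")),
        meta=meta,
    )


def write_cohort(cohort: list[RootSystem], out_dir: str | Path) -> list[Path]:
    """Write one RSML file per plant into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [write_rsml(sys_, out_dir / f"{sys_.plant_id}.rsml") for sys_ in cohort]


def read_cohort(in_dir: str | Path) -> list[RootSystem]:
    """Read every ``*.rsml`` file in a directory, sorted by filename."""
    paths = sorted(Path(in_dir).glob("*.rsml"))
    if not paths:
        raise FileNotFoundError(f"no .rsml files in {in_dir}")
    return [read_rsml(p) for p in paths]
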