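"""Per-residue backbone validation flags.

Produces the boolean outlier panel the mode classifier consumes:
Ramachandran outliers (with the upper-right signature box and the high-psi
band), omega state, CA-trace geometry outliers, and covalent bond/angle
outliers including the C-N-CA marker that is diagnostic of badly formed
peptide bonds.

The Ramachandran and CA-geometry references are coarse packaged maps,
replaceable via config; authentic external validation results can also be
imported per residue (:func:`apply_external_flags`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .backbone_geometry import BackboneGeometry
from .config import Config
from .structure_io import Structure

TRANS, CIS_PRO, CIS_NONPRO, TWISTED, UNDEFINED = (
    "trans",
    "cis_pro",
    "cis_nonpro",
    "twisted",
    "undefined",
)
OMEGA_OUTLIER_STATES = (CIS_PRO, CIS_NONPRO, TWISTED)


@dataclass
class ValidationFlags:
    rama_outlier: bool = False
    rama_upper_right: bool = False
    high_psi_band: bool = False
    rama_evaluated: bool = False
    omega_state: str = UNDEFINED
    ca_geom_outlier: bool = False
    ca_evaluated: bool = False
    bond_geom_outlier: bool = False
    cnca_outlier: bool = False


def _load_boxes(filename: str, path: str | Path | None, keyed: bool):
    if path is None:
        text = resources.files("barbedwire.data").joinpath(filename).read_text()
    else:
        text = Path(path).read_text()
    if keyed:
        boxes: dict[str, list[tuple[float, ...]]] = {}
    else:
        flat: list[tuple[float, ...]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if keyed:
            boxes.setdefault(parts[0], []).append(tuple(map(float, parts[1:5])))
        else:
            flat.append(tuple(map(float, parts[:4])))
    return boxes if keyed else flat


def load_rama_map(path: str | Path | None = None) -> dict[str, list[tuple]]:
    return _load_boxes("rama_regions.txt", path, keyed=True)


def load_ca_map(path: str | Path | None = None) -> list[tuple]:
    return _load_boxes("ca_regions.txt", path, keyed=False)


def _in_box(x: float, y: float, box: tuple) -> bool:
    x0, x1, y0, y1 = box
    return x0 <= x <= x1 and y0 <= y <= y1


def residue_rama_class(res_name: str, next_res_name: str | None) -> str:
    if res_name == "GLY":
        return "gly"
    if res_name == "PRO":
        return "pro"
    if next_res_name == "PRO":
        return "prepro"
    return "general"


def classify_omega(
    omega: float, next_is_proline: bool, config: Config | None = None
) -> str:
    """Cis (|w| <= 30, split Pro/nonPro by the later residue of the bond),
    twisted (30 < |w| < 150), otherwise trans."""
    config = config or Config()
    if math.isnan(omega):
        return UNDEFINED
    a = abs(omega)
    if a <= config.cis_max:
        return CIS_PRO if next_is_proline else CIS_NONPRO
    if a < config.twisted_max:
        return TWISTED
    return TRANS


def classify_rama(
    phi: float,
    psi: float,
    res_class: str = "general",
    rama_map: dict[str, list[tuple]] | None = None,
    config: Config | None = None,
) -> tuple[bool, bool, bool]:
    """(rama_outlier, rama_upper_right, high_psi_band) for one residue.

    The upper-right flag requires an outlier inside the signature box
    (-15 < phi < 170, 60 < psi < 170); the high-psi band is the same psi
    range regardless of outlier status.
    """
    config = config or Config()
    if math.isnan(phi) or math.isnan(psi):
        return False, False, False
    rama_map = rama_map or load_rama_map(config.rama_table)
    allowed = any(_in_box(phi, psi, box) for box in rama_map.get(res_class, []))
    outlier = not allowed
    high_psi = config.high_psi_min < psi < config.high_psi_max
    upper_right = (
        outlier
        and config.upper_right_phi_min < phi < config.upper_right_phi_max
        and high_psi
    )
    return outlier, upper_right, high_psi


def classify_ca_geometry(
    ca_angle: float,
    d_in: float,
    d_out: float,
    ca_map: list[tuple] | None = None,
    config: Config | None = None,
) -> tuple[bool, bool]:
    """(outlier, evaluated) from the CA pseudo-angle and the incoming/
    outgoing pseudo-dihedral pair tested against the coarse CA-trace map."""
    config = config or Config()
    if math.isnan(ca_angle) or math.isnan(d_in) or math.isnan(d_out):
        return False, False
    if ca_angle < config.ca_angle_min or ca_angle > config.ca_angle_max:
        return True, True
    ca_map = ca_map or load_ca_map(config.ca_table)
    allowed = any(_in_box(d_in, d_out, box) for box in ca_map)
    return (not allowed), True


def compute_flags(
    structure: Structure,
    geometry: dict[str, list[BackboneGeometry]],
    config: Config | None = None,
) -> list[ValidationFlags]:
    """The full validation panel for every residue, in structure order."""
    config = config or Config()
    rama_map = load_rama_map(config.rama_table)
    ca_map = load_ca_map(config.ca_table)
    out: list[ValidationFlags] = []
    for chain_id, residues in structure.chains.items():
        geoms = geometry[chain_id]
        n = len(residues)
        for i, res in enumerate(residues):
            g = geoms[i]
            f = ValidationFlags()
            next_name = (
                residues[i + 1].res_name
                if i + 1 < n and not g.chain_break_after
                else None
            )
            if not (math.isnan(g.phi) or math.isnan(g.psi)):
                f.rama_evaluated = True
                f.rama_outlier, f.rama_upper_right, f.high_psi_band = classify_rama(
                    g.phi,
                    g.psi,
                    residue_rama_class(res.res_name, next_name),
                    rama_map,
                    config,
                )
            f.omega_state = classify_omega(g.omega, res.res_name == "PRO", config)
            f.ca_geom_outlier, f.ca_evaluated = classify_ca_geometry(
                g.ca_angle, g.ca_dihedral_in, g.ca_dihedral_out, ca_map, config
            )
            f.bond_geom_outlier = any(
                abs(z) > config.z_cutoff for z in g.bond_z.values()
            )
            f.cnca_outlier = abs(g.bond_z.get("C-N-CA", 0.0)) > config.z_cutoff
            out.append(f)
    return out


def apply_external_flags(
    structure: Structure,
    flags: list[ValidationFlags],
    external: dict,
) -> list[ValidationFlags]:
    """Override internal flags with external validation results.

    ``external`` maps "chain:seq_num[:icode]" to a dict of
    ValidationFlags field names, enabling substitution of authentic
    Ramachandran/CA-geometry calls from other validation software.
    """
    valid = set(ValidationFlags.__dataclass_fields__)
    by_key = {}
    for res, f in zip(structure.residues(), flags):
        key = f"{res.chain_id}:{res.seq_num}"
        by_key[key] = f
        if res.icode:
            by_key[f"{key}:{res.icode}"] = f
    for key, updates in external.items():
        if key not in by_key:
            raise KeyError(f"external flags reference unknown residue {key!r}")
        for name, value in updates.items():
            if name not in valid:
                raise KeyError(f"unknown flag field {name!r}")
            setattr(by_key[key], name, value)
    return flags
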