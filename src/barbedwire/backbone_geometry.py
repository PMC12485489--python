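"""Backbone internal coordinates and covalent-geometry z-scores.

Forward direction: measure phi/psi/omega, CA-trace pseudo-angles and
pseudo-dihedrals, bond/angle z-scores and chain breaks on a parsed
structure.  Inverse direction: build Cartesian backbones from internal
coordinates (NeRF placement), which is how all synthetic test structures
are generated.

Conventions
-----------
* Dihedrals are signed, IUPAC convention, reported in (-180, 180].
* omega of residue *i* is the CA(i-1)-C(i-1)-N(i)-CA(i) dihedral, i.e.
  the peptide bond PRECEDING residue *i*; junction-spanning covalent
  terms (C-N, CA-C-N, C-N-CA) are likewise stored on the later residue.
* A chain break is declared between residues i-1 and i when the
  C(i-1)-N(i) distance exceeds the break cutoff or either atom is
  missing; no dihedral or z-score spans a break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import Config
from .structure_io import Atom, Residue, Structure

NAN = float("nan")

#: torsion C(i)-N(i)-CA(i)-CB(i) placing CB with L-amino-acid chirality
CB_TORSION = 122.6
CB_BOND = 1.530
N_CA_CB_ANGLE = 110.5

BOND_NAMES = ("N-CA", "CA-C", "C-N", "C-O")
ANGLE_NAMES = ("N-CA-C", "CA-C-N", "C-N-CA", "CA-C-O")
#: terms that span the peptide bond and are stored on the later residue
JUNCTION_NAMES = ("C-N", "CA-C-N", "C-N-CA")


def _norm_angle(deg: float) -> float:
    """Map an angle in degrees to (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, in (-180, 180].

    Returns NaN for collinear/coincident point triples where the
    dihedral is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-10 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        return NAN
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / b2n
    return _norm_angle(math.degrees(math.atan2(y, x)))


def compute_angle(p1, p2, p3) -> float:
    """Bond angle (degrees) at p2."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        return NAN
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return math.degrees(math.acos(c))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF: place atom d bonded to c with angle b-c-d and torsion a-b-c-d."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(dihedral)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


@dataclass(frozen=True)
class GeometryTargets:
    """Ideal values and sigmas for the named backbone bonds and angles."""

    targets: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (ideal, sigma) in self.targets.items():
            if sigma <= 0:
                raise ValueError(f"nonpositive sigma for {name}")

    def ideal(self, name: str) -> float:
        return self.targets[name][0]

    def sigma(self, name: str) -> float:
        return self.targets[name][1]

    def z(self, name: str, observed: float) -> float:
        ideal, sigma = self.targets[name]
        return (observed - ideal) / sigma

    @classmethod
    def load(cls, path: str | Path | None = None) -> "GeometryTargets":
        if path is None:
            text = (
                resources.files("barbedwire.data")
                .joinpath("geometry_targets.txt")
                .read_text()
            )
        else:
            text = Path(path).read_text()
        targets = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, ideal, sigma = line.split()
            targets[name] = (float(ideal), float(sigma))
        return cls(targets)


@dataclass
class BackboneGeometry:
    """Per-residue internal coordinates and validation-relevant geometry."""

    phi: float = NAN
    psi: float = NAN
    omega: float = NAN
    bond_z: dict[str, float] = field(default_factory=dict)
    ca_angle: float = NAN
    ca_dihedral_in: float = NAN
    ca_dihedral_out: float = NAN
    chain_break_before: bool = False
    chain_break_after: bool = False


def _pos(res: Residue, name: str) -> np.ndarray | None:
    atom = res.atom(name)
    return None if atom is None else atom.position


def analyze_backbone(
    structure: Structure,
    targets: GeometryTargets | None = None,
    config: Config | None = None,
) -> dict[str, list[BackboneGeometry]]:
    """Measure phi/psi/omega, bond/angle z-scores, CA virtual geometry and
    chain breaks for every residue; fields stay NaN/absent where atoms are
    missing or a break intervenes."""
    targets = targets or GeometryTargets.load(config.geometry_table if config else None)
    config = config or Config()
    out: dict[str, list[BackboneGeometry]] = {}
    for chain_id, residues in structure.chains.items():
        n = len(residues)
        geoms = [BackboneGeometry() for _ in range(n)]
        N = [_pos(r, "N") for r in residues]
        CA = [_pos(r, "CA") for r in residues]
        C = [_pos(r, "C") for r in residues]
        O = [_pos(r, "O") for r in residues]

        # chain breaks between i-1 and i
        broken_before = [False] * n
        for i in range(1, n):
            c_prev, n_cur = C[i - 1], N[i]
            if c_prev is None or n_cur is None:
                broken_before[i] = True
            elif np.linalg.norm(n_cur - c_prev) > config.chain_break_distance:
                broken_before[i] = True
        for i in range(n):
            geoms[i].chain_break_before = broken_before[i] if i > 0 else False
            geoms[i].chain_break_after = broken_before[i + 1] if i + 1 < n else False

        def linked(i: int, j: int) -> bool:
            """True when residues i..j are contiguous (no break, in range)."""
            if i < 0 or j >= n:
                return False
            return not any(broken_before[k] for k in range(i + 1, j + 1))

        for i in range(n):
            g = geoms[i]
            # dihedrals
            if linked(i - 1, i) and all(
                p is not None for p in (C[i - 1], N[i], CA[i], C[i])
            ):
                g.phi = compute_dihedral(C[i - 1], N[i], CA[i], C[i])
            if linked(i, i + 1) and all(
                p is not None for p in (N[i], CA[i], C[i], N[i + 1])
            ):
                g.psi = compute_dihedral(N[i], CA[i], C[i], N[i + 1])
            if linked(i - 1, i) and all(
                p is not None for p in (CA[i - 1], C[i - 1], N[i], CA[i])
            ):
                g.omega = compute_dihedral(CA[i - 1], C[i - 1], N[i], CA[i])

            # intra-residue covalent terms
            meas: dict[str, float] = {}
            if N[i] is not None and CA[i] is not None:
                meas["N-CA"] = float(np.linalg.norm(CA[i] - N[i]))
            if CA[i] is not None and C[i] is not None:
                meas["CA-C"] = float(np.linalg.norm(C[i] - CA[i]))
            if C[i] is not None and O[i] is not None:
                meas["C-O"] = float(np.linalg.norm(O[i] - C[i]))
            if all(p is not None for p in (N[i], CA[i], C[i])):
                meas["N-CA-C"] = compute_angle(N[i], CA[i], C[i])
            if all(p is not None for p in (CA[i], C[i], O[i])):
                meas["CA-C-O"] = compute_angle(CA[i], C[i], O[i])
            # junction terms, stored on the later residue
            if linked(i - 1, i):
                if C[i - 1] is not None and N[i] is not None:
                    meas["C-N"] = float(np.linalg.norm(N[i] - C[i - 1]))
                if all(p is not None for p in (CA[i - 1], C[i - 1], N[i])):
                    meas["CA-C-N"] = compute_angle(CA[i - 1], C[i - 1], N[i])
                if all(p is not None for p in (C[i - 1], N[i], CA[i])):
                    meas["C-N-CA"] = compute_angle(C[i - 1], N[i], CA[i])
            g.bond_z = {
                name: targets.z(name, value)
                for name, value in meas.items()
                if name in targets.targets
            }

            # CA virtual geometry
            if linked(i - 1, i + 1) and all(
                p is not None for p in (CA[i - 1], CA[i], CA[i + 1])
            ):
                g.ca_angle = compute_angle(CA[i - 1], CA[i], CA[i + 1])
            if linked(i - 2, i + 1) and all(
                p is not None for p in (CA[i - 2], CA[i - 1], CA[i], CA[i + 1])
            ):
                g.ca_dihedral_in = compute_dihedral(
                    CA[i - 2], CA[i - 1], CA[i], CA[i + 1]
                )
            if linked(i - 1, i + 2) and all(
                p is not None for p in (CA[i - 1], CA[i], CA[i + 1], CA[i + 2])
            ):
                g.ca_dihedral_out = compute_dihedral(
                    CA[i - 1], CA[i], CA[i + 1], CA[i + 2]
                )
        out[chain_id] = geoms
    return out


@dataclass
class ResidueSpec:
    """Internal-coordinate recipe for one residue of a built backbone.

    ``overrides`` maps backbone term names (see
    :data:`BOND_NAMES`/:data:`ANGLE_NAMES`) to values; junction terms
    (C-N, CA-C-N, C-N-CA) apply to the peptide bond PRECEDING this
    residue, matching where the analysis stores them.
    """

    res_name: str = "ALA"
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = set(BOND_NAMES) | set(ANGLE_NAMES)
        for name, value in self.overrides.items():
            if name not in valid:
                raise ValueError(f"unknown backbone term: {name}")
            if name in BOND_NAMES and value <= 0:
                raise ValueError(f"nonpositive bond length for {name}: {value}")


def build_backbone(
    spec: Sequence[ResidueSpec | tuple],
    plddt: float | Sequence[float] = 50.0,
    chain_id: str = "A",
    targets: GeometryTargets | None = None,
    start_seq: int = 1,
) -> Structure:
    """Build N/CA/C/O (+CB for non-Gly) coordinates from internal
    coordinates by sequential NeRF placement.

    Geometry defaults to the packaged ideal targets; any term can be
    overridden per residue.  ``analyze_backbone`` on the result recovers
    every specified dihedral and override.
    """
    if not spec:
        raise ValueError("empty backbone spec")
    targets = targets or GeometryTargets.load()
    specs = [
        s if isinstance(s, ResidueSpec) else ResidueSpec(*s) for s in spec
    ]
    n = len(specs)
    if np.isscalar(plddt):
        plddt_values = [float(plddt)] * n
    else:
        plddt_values = [float(p) for p in plddt]
        if len(plddt_values) != n:
            raise ValueError("plddt length does not match spec length")

    def term(i: int, name: str) -> float:
        return specs[i].overrides.get(name, targets.ideal(name))

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))

    # first residue in a canonical frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (term(0, "N-CA"), 0.0, 0.0)
    ang = math.radians(term(0, "N-CA-C"))
    C[0] = CA[0] + term(0, "CA-C") * np.array([-math.cos(ang), math.sin(ang), 0.0])

    for i in range(1, n):
        N[i] = place_atom(
            N[i - 1], CA[i - 1], C[i - 1],
            term(i, "C-N"), term(i, "CA-C-N"), specs[i - 1].psi,
        )
        CA[i] = place_atom(
            CA[i - 1], C[i - 1], N[i],
            term(i, "N-CA"), term(i, "C-N-CA"), specs[i].omega,
        )
        C[i] = place_atom(
            C[i - 1], N[i], CA[i],
            term(i, "CA-C"), term(i, "N-CA-C"), specs[i].phi,
        )

    residues = []
    for i, s in enumerate(specs):
        atoms = [
            Atom("N", "N", N[i]),
            Atom("CA", "C", CA[i]),
            Atom("C", "C", C[i]),
        ]
        # carbonyl O anti to the next amide N across the planar peptide
        o_pos = place_atom(
            N[i], CA[i], C[i],
            term(i, "C-O"), term(i, "CA-C-O"), _norm_angle(s.psi + 180.0),
        )
        atoms.append(Atom("O", "O", o_pos))
        if s.res_name != "GLY":
            cb = place_atom(C[i], N[i], CA[i], CB_BOND, N_CA_CB_ANGLE, CB_TORSION)
            atoms.append(Atom("CB", "C", cb))
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_num=start_seq + i,
                icode="",
                res_name=s.res_name,
                atoms=atoms,
                plddt=plddt_values[i],
            )
        )
    st = Structure(source_format="pdb", title="built backbone")
    st.chains[chain_id] = residues
    return st
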