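"""Synthetic structure generator.

Builds small structures that exercise every classification rule without
any downloads: packed helix bundles, isolated helices and strands,
polyproline-II ribbons, and "barbed coil" conformers that emulate the
distorted geometry seen in unpredicted low-confidence regions (high-psi
Ramachandran band, cis/twisted peptides, systematically compressed
C-N-CA angles near the -4 sigma outlier threshold).

All randomness is seeded through the spec; the same spec always yields
the identical structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .backbone_geometry import GeometryTargets, ResidueSpec, build_backbone
from .structure_io import Structure

KINDS = ("helix_bundle", "lone_helix", "lone_strand", "ppii", "barbed_coil", "mixed")

HELIX = (-57.0, -47.0)
STRAND = (-120.0, 130.0)
PPII = (-75.0, 150.0)

#: bundle placement of the second helix relative to the first (axis
#: separation / axial shift in A, azimuthal spin in degrees); chosen so
#: the interface produces vdW-gap contacts along the whole length and
#: every residue window scores well above the packed cutoff
BUNDLE_SEPARATION = 6.0
BUNDLE_Z_SHIFT = 1.0
BUNDLE_AZIMUTH = 210.0

#: half-width (deg) of the per-residue jitter around the coil's base
#: dihedrals; small enough that the coil stays a wide smooth arc
COIL_JITTER = 15.0

#: default distortion rates of the barbed coil: fraction of peptide bonds
#: given cis/twisted omegas, and fraction of junctions with the C-N-CA
#: angle drawn near the -4 sigma systematic distortion
OMEGA_DISTORTION_FRACTION = 0.25
CNCA_DISTORTION_FRACTION = 0.5
TWISTED_OMEGA = 135.0
CIS_OMEGA = 8.0


@dataclass
class FixtureSpec:
    kind: str
    length: int = 12
    plddt: float | Sequence[float] = 50.0
    distortions: list[tuple[int, str, float]] = field(default_factory=list)
    seed: int = 0
    omega_fraction: float = OMEGA_DISTORTION_FRACTION
    cnca_fraction: float = CNCA_DISTORTION_FRACTION
    res_name: str = "ALA"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.length < 3:
            raise ValueError("fixture length must be >= 3")
        for site, _, _ in self.distortions:
            if not 0 <= site < self.length:
                raise ValueError(f"distortion site {site} out of range")


def transform(structure: Structure, rotation=None, translation=None) -> Structure:
    """Apply a rigid motion in place and return the structure."""
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    for res in structure.residues():
        for atom in res.atoms:
            atom.position = R @ atom.position + t
    return structure


def _canonicalize_axis(structure: Structure) -> Structure:
    """Center on the CA centroid and rotate the principal CA axis onto z."""
    ca = np.array(
        [r.atom("CA").position for r in structure.residues() if r.atom("CA")]
    )
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, z))
    if s < 1e-12:
        R = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return transform(structure, R, -R @ center)


def _apply_distortions(
    specs: list[ResidueSpec], distortions: list[tuple[int, str, float]]
) -> None:
    for site, parameter, value in distortions:
        if parameter in ("phi", "psi", "omega"):
            setattr(specs[site], parameter, value)
        else:
            specs[site].overrides[parameter] = value


def _min_nonlocal_ca_distance(structure: Structure) -> float:
    """Smallest CA-CA distance between residues more than 4 apart in
    sequence; large values mean the chain cannot contact itself."""
    ca = np.array([r.atom("CA").position for r in structure.residues()])
    n = len(ca)
    best = np.inf
    for i in range(n):
        for j in range(i + 5, n):
            best = min(best, float(np.linalg.norm(ca[i] - ca[j])))
    return best


def _uniform_specs(
    n: int, phi: float, psi: float, res_name: str = "ALA"
) -> list[ResidueSpec]:
    return [ResidueSpec(res_name, phi, psi, 180.0) for _ in range(n)]


def make_fixture(spec: FixtureSpec) -> Structure:
    """Build the structure described by ``spec``."""
    targets = GeometryTargets.load()
    n = spec.length

    if spec.kind == "lone_helix":
        specs = _uniform_specs(n, *HELIX, spec.res_name)
        _apply_distortions(specs, spec.distortions)
        return build_backbone(specs, spec.plddt)

    if spec.kind == "lone_strand":
        specs = _uniform_specs(n, *STRAND, spec.res_name)
        _apply_distortions(specs, spec.distortions)
        return build_backbone(specs, spec.plddt)

    if spec.kind == "ppii":
        specs = _uniform_specs(n, *PPII, "PRO")
        _apply_distortions(specs, spec.distortions)
        return build_backbone(specs, spec.plddt)

    if spec.kind == "helix_bundle":
        a = _canonicalize_axis(
            build_backbone(_uniform_specs(n, *HELIX, spec.res_name), spec.plddt, "A")
        )
        b = _canonicalize_axis(
            build_backbone(_uniform_specs(n, *HELIX, spec.res_name), spec.plddt, "B")
        )
        flip = np.diag([1.0, -1.0, -1.0])  # antiparallel: rotate pi about x
        az = np.radians(BUNDLE_AZIMUTH)
        spin = np.array(
            [
                [np.cos(az), -np.sin(az), 0.0],
                [np.sin(az), np.cos(az), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        transform(b, flip @ spin, np.array([BUNDLE_SEPARATION, 0.0, BUNDLE_Z_SHIFT]))
        st = Structure(source_format="pdb", title="helix bundle")
        st.chains["A"] = a.chains["A"]
        st.chains["B"] = b.chains["B"]
        return st

    if spec.kind == "barbed_coil":
        rng = np.random.default_rng(spec.seed)
        # wide smooth arcs: dihedrals jitter around one base point drawn
        # from the high-psi / high-phi band instead of varying freely.
        # Base points whose arc curls back on itself are rejected, since
        # the emulated regime is by definition unpacked: wide loops that
        # afford essentially no steric contacts.
        best_specs, best_dist = None, -np.inf
        for _ in range(25):
            phi0 = rng.uniform(-15.0 + COIL_JITTER, 170.0 - COIL_JITTER)
            psi0 = rng.uniform(60.0 + COIL_JITTER, 170.0 - COIL_JITTER)
            phis = phi0 + rng.uniform(-COIL_JITTER, COIL_JITTER, size=n)
            psis = psi0 + rng.uniform(-COIL_JITTER, COIL_JITTER, size=n)
            trial = [
                ResidueSpec(spec.res_name, float(phis[i]), float(psis[i]), 180.0)
                for i in range(n)
            ]
            d = _min_nonlocal_ca_distance(build_backbone(trial, spec.plddt))
            if d > best_dist:
                best_specs, best_dist = trial, d
            if d > 10.0:  # no heavy-atom pair can reach the contact gap
                break
        specs = best_specs
        # distort peptide bonds: bond i is the junction preceding residue i
        cnca_ideal = targets.ideal("C-N-CA")
        cnca_sigma = targets.sigma("C-N-CA")
        for i in range(1, n):
            if rng.random() < spec.omega_fraction:
                if rng.random() < 0.5:
                    specs[i].omega = float(rng.choice([-TWISTED_OMEGA, TWISTED_OMEGA]))
                else:
                    specs[i].omega = CIS_OMEGA
            if rng.random() < spec.cnca_fraction:
                specs[i].overrides["C-N-CA"] = float(
                    cnca_ideal + cnca_sigma * rng.normal(-4.0, 1.0)
                )
        _apply_distortions(specs, spec.distortions)
        return build_backbone(specs, spec.plddt)

    if spec.kind == "mixed":
        # helix + PPII + barbed coil segments, spatially separated so chain
        # breaks appear between them
        seg_len = max(4, n // 3)
        pieces = [
            make_fixture(
                FixtureSpec("lone_helix", seg_len, spec.plddt, seed=spec.seed)
            ),
            make_fixture(FixtureSpec("ppii", seg_len, spec.plddt, seed=spec.seed)),
            make_fixture(
                FixtureSpec(
                    "barbed_coil", max(3, n - 2 * seg_len), spec.plddt, seed=spec.seed
                )
            ),
        ]
        st = Structure(source_format="pdb", title="mixed fixture")
        st.chains["A"] = []
        offset = 0.0
        seq = 1
        for piece in pieces:
            coords = np.array(
                [a.position for r in piece.residues() for a in r.atoms]
            )
            shift = offset - coords[:, 0].min()
            transform(piece, None, np.array([shift, 0.0, 0.0]))
            coords = np.array(
                [a.position for r in piece.residues() for a in r.atoms]
            )
            offset = coords[:, 0].max() + 20.0
            for res in piece.residues():
                res.chain_id = "A"
                res.seq_num = seq
                seq += 1
                st.chains["A"].append(res)
        return st

    raise AssertionError("unreachable")
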