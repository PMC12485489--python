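"""Runtime configuration: every numeric threshold of the analysis in one place.

Defaults reproduce the published behaviour of the mode classifier; all of
them can be overridden from a YAML file or from CLI ``key=value`` pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: kinemage colors per mode (figure-legend convention)
DEFAULT_MODE_COLORS = {
    "predictive": "blue",
    "unpacked_high_plddt": "gray",
    "near_predictive": "green",
    "pseudostructure": "gold",
    "barbed_wire": "red",
    "unphysical": "purple",
}


@dataclass
class Config:
    """Analysis thresholds and output options.

    Attributes
    ----------
    plddt_cutoff:
        Boundary between low and high model confidence.  Residues with
        pLDDT >= this value are treated as high confidence (inclusive).
    contact_gap_max:
        Maximum van der Waals surface gap (A) for a steric contact.
    cutoff_helix_coil, cutoff_strand:
        Packing-score thresholds (contacts per heavy atom over a
        five-residue window) above which a residue counts as packed.
        Strands get a lower bar because their intra-sheet contacts are
        excluded from the count.
    window_halfwidth:
        Half-width of the packing window in residues.
    seq_separation_min:
        Same-chain contacts at sequence distance <= this are ignored.
    z_cutoff:
        |z| beyond which a covalent bond/angle is an outlier.
    cis_max, twisted_min, twisted_max:
        Omega classification: |omega| <= cis_max is cis; twisted when
        twisted_min < |omega| < twisted_max; trans otherwise.
    chain_break_distance:
        C(i-1)-N(i) distance (A) above which a chain break is declared.
    ca_angle_min, ca_angle_max:
        CA(i-1)-CA(i)-CA(i+1) pseudo-angle limits outside of which the
        residue is a CA-geometry outlier.
    helix/strand CA-trace bins:
        Secondary-structure assignment windows on CA distances (A) and
        pseudo-dihedrals (deg).
    """

    plddt_cutoff: float = 70.0
    contact_gap_max: float = 0.5
    cutoff_helix_coil: float = 0.6
    cutoff_strand: float = 0.35
    window_halfwidth: int = 2
    seq_separation_min: int = 4
    z_cutoff: float = 4.0
    cis_max: float = 30.0
    twisted_min: float = 30.0
    twisted_max: float = 150.0
    chain_break_distance: float = 2.5
    ca_angle_min: float = 70.0
    ca_angle_max: float = 155.0
    high_psi_min: float = 60.0
    high_psi_max: float = 170.0
    upper_right_phi_min: float = -15.0
    upper_right_phi_max: float = 170.0
    helix_ca3_min: float = 4.5
    helix_ca3_max: float = 6.0
    helix_dihedral_min: float = 35.0
    helix_dihedral_max: float = 65.0
    strand_ca2_min: float = 6.2
    strand_ca2_max: float = 7.2
    strand_dihedral_min_abs: float = 120.0
    helix_min_len: int = 4
    strand_min_len: int = 3
    mode_colors: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MODE_COLORS)
    )
    rama_table: str | None = None  # path overriding the packaged map
    ca_table: str | None = None
    radii_table: str | None = None
    geometry_table: str | None = None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def updated(self, **kwargs: Any) -> "Config":
        return dataclasses.replace(self, **kwargs)


def default_config() -> Config:
    return Config()
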