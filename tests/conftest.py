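"""Shared fixtures and independent reference implementations.

The reference implementations here (all-pairs contact scan,
simultaneous-evaluation smoothing) are deliberately written differently
from the package code so they can serve as oracles.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from barbedwire.backbone_geometry import ResidueSpec, build_backbone
from barbedwire.config import Config
from barbedwire.contact_packing import atom_radius
from barbedwire.mode_classifier import Mode
from barbedwire.secondary_structure import element_ids


@pytest.fixture
def helix12():
    return build_backbone(
        [ResidueSpec("ALA", -57.0, -47.0, 180.0) for _ in range(12)], plddt=90.0
    )


@pytest.fixture
def ppii10():
    return build_backbone(
        [ResidueSpec("PRO", -75.0, 150.0, 180.0) for _ in range(10)], plddt=40.0
    )


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 {b1:5.2f}           N
ATOM      2  CA  ALA A   1       1.459   0.000   0.000  1.00 {b1:5.2f}           C
ATOM      3  C   ALA A   1       2.005   1.423   0.000  1.00 {b1:5.2f}           C
ATOM      4  O   ALA A   1       1.246   2.394   0.000  1.00 {b1:5.2f}           O
ATOM      5  N   ALA A   2       3.330   1.536   0.000  1.00 {b2:5.2f}           N
ATOM      6  CA  ALA A   2       3.979   2.840   0.000  1.00 {b2:5.2f}           C
ATOM      7  C   ALA A   2       5.501   2.693   0.000  1.00 {b2:5.2f}           C
ATOM      8  O   ALA A   2       6.026   1.581   0.000  1.00 {b2:5.2f}           O
ATOM      9  N   ALA A   3       6.191   3.829   0.000  1.00 {b3:5.2f}           N
ATOM     10  CA  ALA A   3       7.650   3.843   0.000  1.00 {b3:5.2f}           C
ATOM     11  C   ALA A   3       8.207   5.262   0.000  1.00 {b3:5.2f}           C
ATOM     12  O   ALA A   3       7.442   6.228   0.000  1.00 {b3:5.2f}           O
END
"""


@pytest.fixture
def minimal_pdb_path(tmp_path):
    def write(b1=90.0, b2=45.0, b3=30.0, name="mini.pdb"):
        path = tmp_path / name
        path.write_text(MINIMAL_PDB.format(b1=b1, b2=b2, b3=b3))
        return path

    return write


def naive_contacts(structure, elements, radii, config=None):
    """O(n^2) all-pairs contact enumeration, independent of the KD-tree
    path.  Returns a set of frozensets of (global residue idx, atom name)."""
    config = config or Config()
    elem = element_ids(structure, elements)
    atoms = []
    gi = 0
    for ci, (chain_id, residues) in enumerate(structure.chains.items()):
        for pi, res in enumerate(residues):
            e = elem[chain_id][pi]
            for atom in res.atoms:
                if atom.is_hydrogen:
                    continue
                atoms.append(
                    (
                        gi,
                        ci,
                        pi,
                        -1 if e is None else e,
                        atom.name,
                        atom.position,
                        atom_radius(atom.name, atom.element, radii),
                    )
                )
            gi += 1
    found = set()
    for a, b in itertools.combinations(atoms, 2):
        ra, ca, pa, ea, na, xa, rada = a
        rb, cb, pb, eb, nb, xb, radb = b
        if ra == rb:
            continue
        if ca == cb:
            if abs(pa - pb) <= config.seq_separation_min:
                continue
            if ea >= 0 and ea == eb:
                continue
        if np.linalg.norm(xa - xb) - (rada + radb) <= config.contact_gap_max:
            found.add(frozenset([(ra, na), (rb, nb)]))
    return found


B, P, N = Mode.BARBED_WIRE, Mode.PSEUDOSTRUCTURE, Mode.NEAR_PREDICTIVE


def reference_smooth(modes):
    """Two-pass smoothing by simultaneous run evaluation via groupby."""

    def runs(seq):
        out = []
        start = 0
        for mode, group in itertools.groupby(seq):
            length = len(list(group))
            out.append((mode, start, length))
            start += length
        return out

    def one_pass(seq, target, flanks):
        new = list(seq)
        rs = runs(seq)
        for k, (mode, start, length) in enumerate(rs):
            if mode is not target or length > 2:
                continue
            if k == 0 or k == len(rs) - 1:
                continue  # touches a terminus
            left = rs[k - 1][0]
            right = rs[k + 1][0]
            if left is right and left in flanks:
                for i in range(start, start + length):
                    new[i] = left
        return new

    seq = one_pass(list(modes), P, (B, N))
    return one_pass(seq, B, (P,))
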