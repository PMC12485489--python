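"""Renderers for classifier results: text, JSON, pruned PDB, kinemage."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

from . import __version__
from .config import Config
from .mode_classifier import DEFAULT_SELECTION, Mode, ResidueAnnotation, mode_counts
from .structure_io import Structure, write_structure

log = logging.getLogger(__name__)


def _record(ann: ResidueAnnotation) -> dict:
    return {
        "chain_id": ann.chain_id,
        "seq_num": ann.seq_num,
        "icode": ann.icode,
        "res_name": ann.res_name,
        "plddt": round(ann.plddt, 2),
        "ss": ann.ss,
        "packing_score": round(ann.packing_score, 6),
        "packed": ann.packed,
        "rama_outlier": ann.flags.rama_outlier,
        "rama_upper_right": ann.flags.rama_upper_right,
        "high_psi_band": ann.flags.high_psi_band,
        "omega_state": ann.flags.omega_state,
        "ca_geom_outlier": ann.flags.ca_geom_outlier,
        "bond_geom_outlier": ann.flags.bond_geom_outlier,
        "cnca_outlier": ann.flags.cnca_outlier,
        "signature_outlier": ann.signature_outlier,
        "high_outlier_density": ann.high_outlier_density,
        "mode_raw": ann.mode_raw.value,
        "mode": ann.mode.value,
        "label": ann.label,
    }


def write_json(
    annotations: list[ResidueAnnotation],
    path: str | Path,
    config: Config | None = None,
) -> None:
    """One JSON document: metadata plus ordered per-residue records."""
    config = config or Config()
    doc = {
        "tool": "barbedwire",
        "version": __version__,
        "config": config.to_dict(),
        "mode_counts": mode_counts(annotations),
        "residues": [_record(a) for a in annotations],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def write_text(annotations: list[ResidueAnnotation], path: str | Path) -> None:
    """Tab-separated per-residue annotation table."""
    cols = list(_record(annotations[0]).keys()) if annotations else []
    lines = ["\t".join(cols)]
    for ann in annotations:
        rec = _record(ann)
        lines.append("\t".join(str(rec[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def write_selection(
    structure: Structure,
    annotations: list[ResidueAnnotation],
    path: str | Path,
    modes: Iterable[Mode | str] | None = None,
) -> int:
    """Write a PDB containing only residues whose (post-smoothing) mode is
    selected; defaults to predictive + near-predictive.  Returns the
    number of residues written."""
    selected = frozenset(Mode(m) for m in (modes or DEFAULT_SELECTION))
    keep_keys = {
        (a.chain_id, a.seq_num, a.icode) for a in annotations if a.mode in selected
    }
    if not keep_keys:
        log.warning("no residues in selected modes %s", sorted(m.value for m in selected))
    write_structure(structure, path, keep=lambda r: r.key in keep_keys)
    return len(keep_keys)


def write_kinemage(
    structure: Structure,
    annotations: list[ResidueAnnotation],
    path: str | Path,
    config: Config | None = None,
) -> None:
    """Kinemage markup: a CA trace, one togglable balllist per mode with a
    ball at each CA of that mode, and a labellist carrying the Lprocg
    label of every residue."""
    config = config or Config()
    ann_by_key = {(a.chain_id, a.seq_num, a.icode): a for a in annotations}
    lines = [
        "@kinemage 1",
        "@title {barbedwire mode annotation}",
        "@group {mode annotation} dominant",
    ]

    lines.append("@vectorlist {CA trace} color= white")
    for chain_id, residues in structure.chains.items():
        first = True
        for res in residues:
            ca = res.atom("CA")
            if ca is None:
                log.warning("residue %s %d has no CA; skipped", chain_id, res.seq_num)
                first = True
                continue
            x, y, z = ca.position
            marker = "P " if first else ""
            lines.append(
                f"{{{res.res_name} {chain_id}{res.seq_num}}}{marker}"
                f"{x:.3f} {y:.3f} {z:.3f}"
            )
            first = False

    for mode in Mode:
        color = config.mode_colors.get(mode.value, "white")
        lines.append(
            f"@balllist {{{mode.value}}} color= {color} radius= 0.4 master= {{{mode.value}}}"
        )
        for chain_id, residues in structure.chains.items():
            for res in residues:
                ann = ann_by_key.get(res.key)
                ca = res.atom("CA")
                if ann is None or ca is None or ann.mode is not mode:
                    continue
                x, y, z = ca.position
                lines.append(
                    f"{{{res.res_name} {chain_id}{res.seq_num}}}{x:.3f} {y:.3f} {z:.3f}"
                )

    lines.append("@labellist {Lprocg} color= white master= {labels}")
    for chain_id, residues in structure.chains.items():
        for res in residues:
            ann = ann_by_key.get(res.key)
            ca = res.atom("CA")
            if ann is None or ca is None:
                continue
            x, y, z = ca.position
            lines.append(f"{{{ann.label}}}{x:.3f} {y:.3f} {z:.3f}")

    Path(path).write_text("\n".join(lines) + "\n")
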