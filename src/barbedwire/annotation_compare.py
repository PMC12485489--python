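"""Overlap of prediction modes with external disorder annotations.

Consumes a user-supplied JSON of per-residue annotation ranges keyed by
feature name (the MobiDB convention: 1-based inclusive residue numbers)
and reports, per mode, the fraction of retained residues inside each
feature.  To keep the comparison to unambiguous mode cores, residues of
the low-pLDDT modes are pruned aggressively: only pre-smoothing
same-mode runs that still have at least three residues after trimming
three from each end contribute.  High-pLDDT residues are retained by the
plain pLDDT >= 70 rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import Config
from .mode_classifier import Mode, ResidueAnnotation

PRUNED_MODES = (Mode.BARBED_WIRE, Mode.PSEUDOSTRUCTURE, Mode.NEAR_PREDICTIVE)
HIGH_PLDDT_GROUP = "high_plddt"

MIN_CORE = 3
TRIM = 3


@dataclass(frozen=True)
class AnnotationTrack:
    feature: str
    ranges: tuple[tuple[int, int], ...]  # 1-based inclusive, normalized

    def __contains__(self, seq_num: int) -> bool:
        return any(s <= seq_num <= e for s, e in self.ranges)


def _normalize(ranges) -> tuple[tuple[int, int], ...]:
    spans = sorted((int(s), int(e)) for s, e in ranges)
    for s, e in spans:
        if s > e:
            raise ValueError(f"invalid range {s}..{e}")
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def load_tracks(path: str | Path) -> list[AnnotationTrack]:
    """Read {feature: [[start, end], ...]} JSON into annotation tracks."""
    data = json.loads(Path(path).read_text())
    return [AnnotationTrack(feat, _normalize(ranges)) for feat, ranges in data.items()]


def prune_segments(
    annotations: list[ResidueAnnotation],
    min_core: int = MIN_CORE,
    trim: int = TRIM,
    config: Config | None = None,
) -> dict[int, str]:
    """Select the residues that enter the overlap statistics.

    Returns {index into annotations -> group name}.  For each maximal
    same-mode PRE-smoothing run of barbed wire / pseudostructure /
    near-predictive, the first and last ``trim`` residues are dropped and
    the remainder retained iff it has at least ``min_core`` residues
    (runs shorter than trim*2 + min_core contribute nothing).  High-pLDDT
    residues are retained unconditionally under the plain cutoff rule.
    """
    config = config or Config()
    retained: dict[int, str] = {}
    for idx, ann in enumerate(annotations):
        if ann.plddt >= config.plddt_cutoff:
            retained[idx] = HIGH_PLDDT_GROUP

    i = 0
    n = len(annotations)
    while i < n:
        ann = annotations[i]
        j = i
        while (
            j + 1 < n
            and annotations[j + 1].chain_id == ann.chain_id
            and annotations[j + 1].mode_raw is ann.mode_raw
        ):
            j += 1
        if ann.mode_raw in PRUNED_MODES:
            core = range(i + trim, j - trim + 1)
            if len(core) >= min_core:
                for k in core:
                    retained[k] = ann.mode_raw.value
        i = j + 1
    return retained


def overlap_fractions(
    annotations: list[ResidueAnnotation],
    tracks: list[AnnotationTrack],
    retained: dict[int, str] | None = None,
    config: Config | None = None,
) -> pd.DataFrame:
    """Tidy table (mode, feature, n_retained, n_overlap, fraction).

    Groups with zero retained residues are absent from the table.
    Raises if a track's numbering extends past the structure, which
    indicates a structure/annotation numbering mismatch.
    """
    if retained is None:
        retained = prune_segments(annotations, config=config)
    max_seq = max((a.seq_num for a in annotations), default=0)
    for track in tracks:
        for s, e in track.ranges:
            if s < 1 or e > max_seq:
                raise ValueError(
                    f"annotation track {track.feature!r} range {s}..{e} does not fit "
                    f"residue numbering 1..{max_seq}: numbering mismatch?"
                )
    rows = []
    groups = sorted(set(retained.values()))
    for group in groups:
        members = [idx for idx, g in retained.items() if g == group]
        for track in tracks:
            n_overlap = sum(
                1 for idx in members if annotations[idx].seq_num in track
            )
            rows.append(
                {
                    "mode": group,
                    "feature": track.feature,
                    "n_retained": len(members),
                    "n_overlap": n_overlap,
                    "fraction": n_overlap / len(members),
                }
            )
    return pd.DataFrame(rows, columns=["mode", "feature", "n_retained", "n_overlap", "fraction"])
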