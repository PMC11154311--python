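"""Na+ accessibility of the GTP pocket.

An ion is "near" the GTP when its minimum-image distance to the *nearest*
GTP atom is at or below the cutoff (default 4.5 A) — a contact-shell
criterion over the whole molecule, configurable to a subset of GTP atoms
(e.g. phosphate oxygens only) through the role map.  Per-state summaries
use the population standard deviation (divisor n), since they describe the
realised frame counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .io import AtomRoleMap, Trajectory

DEFAULT_CUTOFF = 4.5


@dataclass
class IonCountSeries:
    """Per-frame count of Na+ ions within ``cutoff`` of the GTP."""

    counts: np.ndarray
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise DataError("ion counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


def count_ions_near_gtp(
    frame_coords,
    roles: AtomRoleMap,
    cutoff: float = DEFAULT_CUTOFF,
    box=None,
) -> int:
    """Number of Na+ ions within ``cutoff`` of any GTP atom in one frame."""
    from MDAnalysis.lib.distances import distance_array

    gtp = roles.group("GTP_ATOMS")
    if gtp.size == 0:
        raise DataError("GTP_ATOMS role resolved to an empty atom set")
    na = roles.group("NA_IONS")
    if na.size == 0:
        return 0
    frame_coords = np.asarray(frame_coords, dtype=np.float64)
    box_arr = None if box is None else np.asarray(box, dtype=np.float32)
    d = distance_array(frame_coords[na], frame_coords[gtp], box=box_arr)
    return int(np.count_nonzero(d.min(axis=1) <= cutoff))


def count_series(
    traj: Trajectory, roles: AtomRoleMap, cutoff: float = DEFAULT_CUTOFF
) -> IonCountSeries:
    """Vectorised per-frame ion counts over a whole trajectory."""
    gtp = roles.group("GTP_ATOMS")
    if gtp.size == 0:
        raise DataError("GTP_ATOMS role resolved to an empty atom set")
    na = roles.group("NA_IONS")
    if na.size == 0:
        return IonCountSeries(np.zeros(traj.n_frames, dtype=int), cutoff)
    box = traj.box
    if box is None:
        delta = traj.coords[:, na, None, :] - traj.coords[:, gtp, :][:, None, :, :]
        dmin = np.sqrt(np.sum(delta**2, axis=3)).min(axis=2)
        counts = np.count_nonzero(dmin <= cutoff, axis=1)
    else:
        per_frame_box = np.ndim(box) == 2
        counts = np.array(
            [
                count_ions_near_gtp(
                    traj.coords[f],
                    roles,
                    cutoff=cutoff,
                    box=box[f] if per_frame_box else box,
                )
                for f in range(traj.n_frames)
            ]
        )
    return IonCountSeries(counts, cutoff)


@dataclass
class IonStateSummary:
    mean: float
    sd: float
    n: int


def ion_summary_by_state(counts: IonCountSeries, labels) -> dict[str, IonStateSummary]:
    """Per-state mean and population SD of the ion counts.

    States with zero frames are absent from the result (they appear as
    "-" in tabulated output).
    """
    label_arr = np.asarray(getattr(labels, "labels", labels))
    if len(label_arr) != len(counts):
        raise DataError(
            f"length mismatch: {len(counts)} ion counts vs {len(label_arr)} labels"
        )
    out: dict[str, IonStateSummary] = {}
    for state in np.unique(label_arr):
        sel = counts.counts[label_arr == state]
        out[str(state)] = IonStateSummary(
            mean=float(sel.mean()), sd=float(sel.std(ddof=0)), n=int(sel.size)
        )
    return out
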