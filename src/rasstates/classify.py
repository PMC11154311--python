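"""Frame-wise conformational state assignment and occupancy statistics.

Each frame is assigned to one of::

    S1         state 1 ("inactive"): Thr35-Mg2+ bond broken
    S2_OX      state 2, Tyr32 toward the GTP pocket
    S2_OY      state 2, Tyr32 parallel to the pocket, toward Ala18
    S2_OZ      state 2, Tyr32 toward bulk solvent (GAP-binding compatible)
    UNASSIGNED outside all signatures

by a fixed decision cascade on the classifier distances::

    S1     if d_OG35_Mg  > t_mg
    S2_OX  if d_OH32_Og  <= t_ox
    S2_OY  if d_OH32_O18 <= t_oy
    S2_OZ  if d_OH32_Og  <= t_oz_max
    else UNASSIGNED

The default thresholds sit between the characteristic per-state distance
centers (2.0/2.7/4.3/7.5/11.3 A); the centers are distribution modes, not
published cutoffs, so every threshold is configurable.  Raw labels are
debounced with a centered label-mode filter before dwell segments and
transitions are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .features import FeatureFrame, FeatureSeries

S1 = "S1"
S2_OX = "S2_OX"
S2_OY = "S2_OY"
S2_OZ = "S2_OZ"
UNASSIGNED = "UNASSIGNED"

#: Canonical label order used for occupancy vectors and transition matrices.
LABELS = (S1, S2_OX, S2_OY, S2_OZ, UNASSIGNED)
LABEL_CODE = {lab: i for i, lab in enumerate(LABELS)}


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds (Angstrom) and smoothing window (frames)."""

    t_mg: float = 2.6
    t_ox: float = 4.5
    t_oy: float = 6.5
    t_oz_max: float = 10.0
    smoothing_window: int = 5

    def __post_init__(self):
        if not (self.t_mg < self.t_ox < self.t_oz_max):
            raise ConfigError(
                f"thresholds must satisfy t_mg < t_ox < t_oz_max "
                f"(got {self.t_mg}, {self.t_ox}, {self.t_oz_max})"
            )
        if self.t_oy <= 0:
            raise ConfigError(f"t_oy must be positive (got {self.t_oy})")
        w = self.smoothing_window
        if w < 1 or w % 2 == 0:
            raise ConfigError(f"smoothing_window must be an odd integer >= 1 (got {w})")


@dataclass
class StateLabelSeries:
    """Per-frame labels with dwell-segment and transition structure."""

    raw: np.ndarray  # cascade labels before smoothing
    labels: np.ndarray  # smoothed labels
    segments: list  # (label, start, stop_exclusive, length)
    transitions: list  # (from_label, to_label, frame of arrival)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_frames(self) -> int:
        return len(self.labels)


@dataclass
class OccupancyReport:
    """Pooled state occupancies (fractions over all labels sum to 1)."""

    fractions: dict[str, float]
    counts: dict[str, int]
    n_frames: int
    n_trajectories: int
    mean_dwell: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fractions": self.fractions,
            "counts": self.counts,
            "n_frames": self.n_frames,
            "n_trajectories": self.n_trajectories,
            "mean_dwell_frames": self.mean_dwell,
        }


def classify_frame(f: FeatureFrame, cfg: ClassifierConfig | None = None) -> str:
    """Assign a single frame; total on finite inputs."""
    cfg = cfg or ClassifierConfig()
    if f.d_OG35_Mg > cfg.t_mg:
        return S1
    if f.d_OH32_Og <= cfg.t_ox:
        return S2_OX
    if f.d_OH32_O18 <= cfg.t_oy:
        return S2_OY
    if f.d_OH32_Og <= cfg.t_oz_max:
        return S2_OZ
    return UNASSIGNED


def _cascade_codes(features: FeatureSeries, cfg: ClassifierConfig) -> np.ndarray:
    d_mg = features.column("d_OG35_Mg")
    d_ox = features.column("d_OH32_Og")
    d_o18 = features.column("d_OH32_O18")
    return np.select(
        [d_mg > cfg.t_mg, d_ox <= cfg.t_ox, d_o18 <= cfg.t_oy, d_ox <= cfg.t_oz_max],
        [LABEL_CODE[S1], LABEL_CODE[S2_OX], LABEL_CODE[S2_OY], LABEL_CODE[S2_OZ]],
        default=LABEL_CODE[UNASSIGNED],
    ).astype(np.int64)


def mode_filter(codes: np.ndarray, window: int, n_labels: int = len(LABELS)) -> np.ndarray:
    """Centered label-mode filter with ties broken toward the previous output.

    The window is truncated at the series edges.  When several labels tie
    for the window mode, the previous frame's smoothed label wins if it is
    among the winners; otherwise the frame's own raw label; otherwise the
    first winner in canonical label order.
    """
    codes = np.asarray(codes, dtype=np.int64)
    n = len(codes)
    if window == 1 or n == 0:
        return codes.copy()
    half = window // 2
    onehot = np.zeros((n + 1, n_labels), dtype=np.int64)
    onehot[np.arange(1, n + 1), codes] = 1
    cum = np.cumsum(onehot, axis=0)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    win_counts = cum[hi] - cum[lo]
    max_counts = win_counts.max(axis=1)
    n_winners = (win_counts == max_counts[:, None]).sum(axis=1)
    out = win_counts.argmax(axis=1)
    for i in np.flatnonzero(n_winners > 1):
        winners = np.flatnonzero(win_counts[i] == max_counts[i])
        prev = out[i - 1] if i > 0 else codes[i]
        if prev in winners:
            out[i] = prev
        elif codes[i] in winners:
            out[i] = codes[i]
        else:
            out[i] = winners[0]
    return out


def _segments_from_codes(codes: np.ndarray) -> list:
    boundaries = np.flatnonzero(np.diff(codes) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    stops = np.concatenate([boundaries, [len(codes)]])
    return [
        (LABELS[codes[s]], int(s), int(e), int(e - s)) for s, e in zip(starts, stops)
    ]


def classify_series(
    features: FeatureSeries, cfg: ClassifierConfig | None = None
) -> StateLabelSeries:
    """Classify every frame, smooth, and rebuild segments/transitions.

    Deterministic: identical features and configuration always yield
    identical labels.
    """
    cfg = cfg or ClassifierConfig()
    if len(features) == 0:
        raise DataError("cannot classify an empty feature series")
    raw_codes = _cascade_codes(features, cfg)
    smooth_codes = mode_filter(raw_codes, cfg.smoothing_window)
    segments = _segments_from_codes(smooth_codes)
    transitions = [
        (segments[k - 1][0], segments[k][0], segments[k][1])
        for k in range(1, len(segments))
    ]
    labels = np.asarray(LABELS, dtype=object)
    return StateLabelSeries(
        raw=labels[raw_codes],
        labels=labels[smooth_codes],
        segments=segments,
        transitions=transitions,
    )


def occupancy(labels) -> OccupancyReport:
    """Pooled occupancy over one or several :class:`StateLabelSeries`.

    Pooling is frame-weighted ("over all the performed simulations"):
    fractions equal total per-label frame counts divided by total frames.
    """
    series_list = labels if isinstance(labels, (list, tuple)) else [labels]
    if not series_list:
        raise DataError("occupancy requires at least one label series")
    total = sum(len(s) for s in series_list)
    if total == 0:
        raise DataError("occupancy requires at least one labeled frame")
    counts = {lab: 0 for lab in LABELS}
    dwell_sums = {lab: 0 for lab in LABELS}
    dwell_counts = {lab: 0 for lab in LABELS}
    for s in series_list:
        labs, cnts = np.unique(np.asarray(s.labels), return_counts=True)
        for lab, c in zip(labs, cnts):
            counts[str(lab)] += int(c)
        for lab, _, _, length in s.segments:
            dwell_sums[lab] += length
            dwell_counts[lab] += 1
    fractions = {lab: counts[lab] / total for lab in LABELS}
    mean_dwell = {
        lab: (dwell_sums[lab] / dwell_counts[lab] if dwell_counts[lab] else None)
        for lab in LABELS
    }
    return OccupancyReport(
        fractions=fractions,
        counts=counts,
        n_frames=total,
        n_trajectories=len(series_list),
        mean_dwell=mean_dwell,
    )


def transitions(labels: StateLabelSeries) -> np.ndarray:
    """5x5 transition-count matrix over the smoothed labels.

    Entry (i, j) counts boundary crossings from ``LABELS[i]`` to
    ``LABELS[j]``; the diagonal is zero.  Total transitions equal the
    number of segments minus one.
    """
    mat = np.zeros((len(LABELS), len(LABELS)), dtype=int)
    for frm, to, _frame in labels.transitions:
        mat[LABEL_CODE[frm], LABEL_CODE[to]] += 1
    return mat
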