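"""Per-frame geometric features of the Ras G-domain.

Five inter-atomic distances characterise the GTP-bound conformational
(sub)states (all in Angstrom):

* ``d_OG35_Mg``   - Thr35 side-chain O to the catalytic Mg2+; the bond is
  intact in state 2 (~2.0 A) and broken in state 1.
* ``d_OH32_Og``   - Tyr32 ring OH to the GTP gamma-phosphate oxygen;
  ~2.7 A when Tyr32 points into the nucleotide pocket (2OX), ~7.5 A when it
  faces bulk solvent (2OZ), ~11.3 A in the Ala18-facing orientation (2OY).
* ``d_OH32_O18``  - Tyr32 OH to the Ala18 backbone O; ~4.3 A in 2OY only.
* ``d_O12_Og``    - residue-12 backbone O to the gamma oxygen; shifts from
  ~5.3 A (Gly12) above 8 A under the G12V mutation.
* ``d_OH32_OH40`` - Tyr32 OH to Tyr40 OH, monitoring switch-I collapse.

Two membrane reaction coordinates complete the per-frame record: the angle
between the beta-1 strand direction (residues 2-5) and the membrane normal,
and the Calpha distance E132-L184 measuring HVR stretch (absent for
solution-only systems without an HVR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io import FEATURE_COLUMNS, AtomRoleMap, Trajectory

DISTANCE_ROLE_PAIRS = {
    "d_O12_Og": ("O12", "OGAMMA"),
    "d_OH32_O18": ("OH32", "O18"),
    "d_OG35_Mg": ("OG35", "MG"),
    "d_OH32_Og": ("OH32", "OGAMMA"),
    "d_OH32_OH40": ("OH32", "OH40"),
}

DISTANCE_NAMES = tuple(DISTANCE_ROLE_PAIRS)


@dataclass(frozen=True)
class FeatureFrame:
    """Feature values of a single trajectory frame."""

    frame: int
    d_O12_Og: float
    d_OH32_O18: float
    d_OG35_Mg: float
    d_OH32_Og: float
    d_OH32_OH40: float
    rc_angle: float
    rc_dist: float | None = None
    time_ns: float | None = None

    def distances(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DISTANCE_NAMES}


@dataclass
class FeatureSeries:
    """Ordered per-frame features with provenance."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in FEATURE_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"feature table is missing columns {missing}")
        frames = self.table["frame"].to_numpy()
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise DataError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.table)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    @property
    def has_rc_dist(self) -> bool:
        return bool(np.any(np.isfinite(self.table["rc_dist_A"].to_numpy(dtype=float))))

    def frame(self, i: int) -> FeatureFrame:
        row = self.table.iloc[i]
        rc_dist = float(row["rc_dist_A"])
        time_ns = float(row["time_ns"])
        return FeatureFrame(
            frame=int(row["frame"]),
            rc_angle=float(row["rc_angle_deg"]),
            rc_dist=None if np.isnan(rc_dist) else rc_dist,
            time_ns=None if np.isnan(time_ns) else time_ns,
            **{name: float(row[name]) for name in DISTANCE_NAMES},
        )


def pair_distance(a, b, box=None):
    """Euclidean distance between positions ``a`` and ``b`` in Angstrom.

    Accepts single points ``(3,)`` or frame stacks ``(F, 3)``.  If ``box``
    (MDAnalysis ``[lx, ly, lz, alpha, beta, gamma]``) is given, the
    minimum-image convention is applied (via MDAnalysis); without a box the
    plain Euclidean distance is evaluated in double precision.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    single = a.ndim == 1
    a2 = np.atleast_2d(a)
    b2 = np.atleast_2d(b)
    if a2.shape != b2.shape:
        raise DataError(f"position shape mismatch: {a2.shape} vs {b2.shape}")
    if box is None:
        d = np.linalg.norm(a2 - b2, axis=1)
    else:
        from MDAnalysis.lib.distances import calc_bonds

        d = calc_bonds(a2, b2, box=np.asarray(box, dtype=np.float32))
    return float(d[0]) if single else np.asarray(d, dtype=float)


def beta1_angle(points, normal=(0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, [0, 180]) between the beta-1 direction and ``normal``.

    ``points`` are the four Calpha positions of residues 2-5.  The strand
    direction is the first principal axis of the four points, oriented from
    the smallest-numbered residue toward the largest; for collinear points
    this reduces to the simple end-to-end vector.
    """
    points = np.asarray(points, dtype=float)
    if points.shape != (4, 3):
        raise DataError(f"beta1_angle expects 4 Calpha positions, got shape {points.shape}")
    return float(_beta1_angles(points[None], np.asarray(normal, dtype=float))[0])


def _beta1_angles(points: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Vectorised beta-1 tilt angle for ``points`` of shape (F, 4, 3)."""
    n = np.asarray(normal, dtype=float)
    n_norm = np.linalg.norm(n)
    if n_norm == 0:
        raise ConfigError("membrane normal must be a nonzero vector")
    n = n / n_norm
    centered = points - points.mean(axis=1, keepdims=True)
    cov = np.einsum("fki,fkj->fij", centered, centered)
    w, v = np.linalg.eigh(cov)
    if np.any(w[:, -1] <= 1e-12):
        raise DataError("degenerate beta-1 geometry: the four Calpha positions coincide")
    axis = v[:, :, -1]
    head = points[:, 3, :] - points[:, 0, :]
    sign = np.sign(np.einsum("fi,fi->f", axis, head))
    sign[sign == 0] = 1.0
    axis = axis * sign[:, None]
    cosang = np.clip(axis @ n, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def extract_features(
    traj: Trajectory,
    roles: AtomRoleMap,
    membrane_normal=(0.0, 0.0, 1.0),
    times_ns=None,
) -> FeatureSeries:
    """Compute the five classifier distances and the reaction coordinates.

    One :class:`FeatureFrame` row per trajectory frame.  ``rc_dist`` is
    present iff the L184 Calpha role is resolved (membrane-anchored,
    HVR-containing systems).  Distances use the minimum-image convention
    when the trajectory carries a periodic box.
    """
    coords = traj.coords
    n_frames = coords.shape[0]
    box = traj.box
    constant_box = box is not None and np.ndim(box) == 1

    def dist(i: int, j: int) -> np.ndarray:
        if box is None:
            return pair_distance(coords[:, i, :], coords[:, j, :])
        if constant_box:
            return pair_distance(coords[:, i, :], coords[:, j, :], box=box)
        return np.array(
            [
                pair_distance(coords[f, i, :], coords[f, j, :], box=box[f])
                for f in range(n_frames)
            ]
        )

    data: dict[str, np.ndarray] = {"frame": np.arange(n_frames)}
    if times_ns is None:
        times_ns = traj.times_ns
    data["time_ns"] = (
        np.asarray(times_ns, dtype=float) if times_ns is not None else np.full(n_frames, np.nan)
    )
    for name, (role_a, role_b) in DISTANCE_ROLE_PAIRS.items():
        data[name] = dist(roles.scalar(role_a), roles.scalar(role_b))

    beta1_idx = roles.group("BETA1_CA")
    data["rc_angle_deg"] = _beta1_angles(coords[:, beta1_idx, :], np.asarray(membrane_normal))

    if roles.has("L184_CA") and roles.has("E132_CA"):
        e132 = int(roles.group("E132_CA")[0])
        l184 = int(roles.group("L184_CA")[0])
        data["rc_dist_A"] = dist(e132, l184)
    else:
        data["rc_dist_A"] = np.full(n_frames, np.nan)

    table = pd.DataFrame(data, columns=FEATURE_COLUMNS)
    bad = ~np.isfinite(table[list(DISTANCE_NAMES)].to_numpy())
    if bad.any():
        raise DataError("non-finite distance encountered during feature extraction")
    return FeatureSeries(table=table, provenance={"role_map": roles.digest()})


def rc_pair(features: FeatureSeries) -> np.ndarray:
    """Paired (rc_angle, rc_dist) series for 2D histogramming, shape (F, 2).

    Raises :class:`DataError` for solution-only systems, where the HVR
    stretch coordinate does not exist.
    """
    if len(features) and not features.has_rc_dist:
        raise DataError(
            "rc_dist is absent (solution-only system without HVR); "
            "the 2D reaction-coordinate map requires a membrane-bound system"
        )
    return np.column_stack(
        [features.column("rc_angle_deg"), features.column("rc_dist_A")]
    )


@dataclass
class RCHistogram:
    """2D count grid over (tilt angle, HVR distance)."""

    counts: np.ndarray
    angle_edges: np.ndarray
    dist_edges: np.ndarray
    n_excluded: int


def histogram2d(pairs, angle_bins, dist_bins) -> RCHistogram:
    """Bin (angle, dist) pairs on the given monotone bin edges.

    The grid sums to the number of in-range pairs; out-of-range pairs are
    excluded and reported in ``n_excluded``.
    """
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    angle_bins = np.asarray(angle_bins, dtype=float)
    dist_bins = np.asarray(dist_bins, dtype=float)
    for name, edges in (("angle_bins", angle_bins), ("dist_bins", dist_bins)):
        if edges.size < 2:
            raise ConfigError(f"{name} must contain at least two bin edges")
        if not np.all(np.diff(edges) > 0):
            raise ConfigError(f"{name} must be strictly increasing")
    counts, ae, de = np.histogram2d(pairs[:, 0], pairs[:, 1], bins=[angle_bins, dist_bins])
    counts = counts.astype(int)
    return RCHistogram(
        counts=counts,
        angle_edges=ae,
        dist_edges=de,
        n_excluded=int(len(pairs) - counts.sum()),
    )
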