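"""Per-(sub)state structural statistics over Calpha coordinates.

All operations take plain ``(frames, n_residues, 3)`` Calpha coordinate
arrays (slice a trajectory with the CA_TRACE role first).  Superposition is
least-squares rigid-body fitting (QCP, via MDAnalysis) on a configurable
fit set; the default pipeline fit set is the G-domain core excluding both
switch loops, so that switch mobility does not leak into core fluctuations.

Provided statistics: RMSD to a reference structure, time-weighted
per-residue RMSF pooled over the frames of one state, Calpha essential-
dynamics PCA (covariance eigendecomposition with per-residue mode
mobility), and the dynamic cross-correlation matrix (DCCM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = [
    "SuperposeResult",
    "RMSFProfile",
    "PCAResult",
    "CrossCorrMatrix",
    "superpose",
    "rmsd_series",
    "rmsf_by_state",
    "pca",
    "cross_correlation",
    "core_fit_indices",
]


def core_fit_indices(resids, switch_i=(30, 40), switch_ii=(58, 76)):
    """Positions of residues outside both switch regions (default fit set)."""
    resids = np.asarray(resids)
    in_si = (resids >= switch_i[0]) & (resids <= switch_i[1])
    in_sii = (resids >= switch_ii[0]) & (resids <= switch_ii[1])
    return np.flatnonzero(~(in_si | in_sii))


@dataclass
class SuperposeResult:
    rotation: np.ndarray  # (3, 3)
    mobile_centroid: np.ndarray
    reference_centroid: np.ndarray
    rmsd: float  # over the report set, after fitting

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid transform to ``coords`` (n, 3)."""
        return (np.asarray(coords) - self.mobile_centroid) @ self.rotation.T + (
            self.reference_centroid
        )


def _as_indices(idx, n):
    if idx is None:
        return np.arange(n)
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise DataError("fit set must be non-empty")
    return idx


def _check_fit_points(points: np.ndarray) -> None:
    if len(points) < 3:
        raise DataError(f"superposition needs >= 3 fit points, got {len(points)}")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DataError("superposition fit points are collinear or coincident")


def superpose(mobile, reference, fit_set=None, report_set=None) -> SuperposeResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal rotation/translation is computed on ``fit_set`` (atom
    positions, default all); the returned RMSD is evaluated after the fit
    over ``report_set`` (default: the fit set), which may differ — e.g. fit
    on the stable core, report on switch I.
    """
    from MDAnalysis.analysis.align import rotation_matrix

    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise DataError(
            f"superpose: shape mismatch {mobile.shape} vs {reference.shape}"
        )
    fit_idx = _as_indices(fit_set, len(mobile))
    _check_fit_points(mobile[fit_idx])
    _check_fit_points(reference[fit_idx])
    mc = mobile[fit_idx].mean(axis=0)
    rc = reference[fit_idx].mean(axis=0)
    rot, _ = rotation_matrix(mobile[fit_idx] - mc, reference[fit_idx] - rc)
    result = SuperposeResult(
        rotation=np.asarray(rot, dtype=float),
        mobile_centroid=mc,
        reference_centroid=rc,
        rmsd=0.0,
    )
    rep_idx = fit_idx if report_set is None else _as_indices(report_set, len(mobile))
    moved = result.apply(mobile[rep_idx])
    result.rmsd = float(np.sqrt(np.mean(np.sum((moved - reference[rep_idx]) ** 2, axis=1))))
    return result


def rmsd_series(coords, reference, fit_set=None, report_set=None) -> np.ndarray:
    """Per-frame RMSD to ``reference`` after per-frame superposition."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return np.array(
        [
            superpose(frame, reference, fit_set=fit_set, report_set=report_set).rmsd
            for frame in coords
        ]
    )


def _superpose_stack(frames: np.ndarray, reference: np.ndarray, fit_idx) -> np.ndarray:
    out = np.empty_like(frames)
    for k, frame in enumerate(frames):
        out[k] = superpose(frame, reference, fit_set=fit_idx).apply(frame)
    return out


def _fit_to_mean(frames: np.ndarray, fit_idx, iterate: bool = False) -> np.ndarray:
    """Two-pass mean-structure superposition (optionally to a fixed point).

    Pass 1 fits every frame to the first frame and takes the mean; pass 2
    refits every frame to that mean.  With ``iterate=True`` the
    mean/refit cycle continues until the mean moves by < 1e-10 A.
    """
    aligned = _superpose_stack(frames, frames[0], fit_idx)
    for _ in range(100 if iterate else 1):
        mean = aligned.mean(axis=0)
        aligned = _superpose_stack(frames, mean, fit_idx)
        if not iterate:
            break
        new_mean = aligned.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < 1e-10:
            break
    return aligned


@dataclass
class RMSFProfile:
    """Per-residue Calpha RMSF (Angstrom) over the frames of one state."""

    values: np.ndarray
    state: str
    n_frames: int
    n_trajectories: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise DataError("RMSF values must be non-negative")


def _pool_state_frames(ca_coords, labels, state):
    coords_list = ca_coords if isinstance(ca_coords, (list, tuple)) else [ca_coords]
    labels_list = labels if isinstance(labels, (list, tuple)) else [labels]
    if len(coords_list) != len(labels_list):
        raise DataError(
            f"{len(coords_list)} coordinate blocks vs {len(labels_list)} label series"
        )
    picked = []
    for coords, labs in zip(coords_list, labels_list):
        coords = np.asarray(coords, dtype=float)
        lab_arr = np.asarray(getattr(labs, "labels", labs))
        if len(lab_arr) != len(coords):
            raise DataError(
                f"label length {len(lab_arr)} does not match frame count {len(coords)}"
            )
        sel = coords[lab_arr == state]
        if len(sel):
            picked.append(sel)
    if not picked:
        raise DataError(f"no frames carry state {state}")
    return np.concatenate(picked, axis=0), len(coords_list)


def rmsf_by_state(ca_coords, labels, state, fit_set=None, iterate=False) -> RMSFProfile:
    """Time-weighted per-residue RMSF over all frames of ``state``.

    Frames of the requested state are pooled across trajectories (frame-
    weighted), superposed onto their mean structure (two-pass), and
    ``RMSF_i = sqrt(<|r_i - <r_i>|^2>)`` is evaluated per residue.
    """
    frames, n_traj = _pool_state_frames(ca_coords, labels, state)
    if len(frames) < 2:
        raise DataError(f"state {state} has {len(frames)} frame(s); need >= 2 for RMSF")
    fit_idx = _as_indices(fit_set, frames.shape[1])
    aligned = _fit_to_mean(frames, fit_idx, iterate=iterate)
    mean = aligned.mean(axis=0)
    msf = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)
    return RMSFProfile(
        values=np.sqrt(msf), state=state, n_frames=len(frames), n_trajectories=n_traj
    )


@dataclass
class PCAResult:
    """Essential-dynamics PCA of superposed Calpha coordinates.

    ``eigenvalues`` is the full descending spectrum (A^2);
    ``eigenvectors`` holds the top ``n_modes`` unit-norm modes as columns
    (3N components); ``mobility[i, k]`` is residue i's displacement
    amplitude along mode k, ``sqrt(lambda_k) * |v_k,i|`` in Angstrom.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mobility: np.ndarray
    n_frames: int
    cov_trace: float = 0.0  # trace of the covariance actually diagonalised

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def pca(ca_coords, fit_set=None, n_modes=10, n_mobility_modes=3) -> PCAResult:
    """Covariance eigendecomposition of superposed Calpha coordinates.

    ``ca_coords`` may be a single (F, N, 3) array or a list of such arrays
    (pooled frames of one substate).  Frames are superposed onto their mean
    (two-pass) on ``fit_set``; the 3Nx3N population covariance of the
    flattened deviations is diagonalised with ``numpy.linalg.eigh``.
    """
    if isinstance(ca_coords, (list, tuple)):
        ca_coords = np.concatenate([np.asarray(c, dtype=float) for c in ca_coords])
    frames = np.asarray(ca_coords, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise DataError("PCA requires at least 2 frames of (N, 3) coordinates")
    n_res = frames.shape[1]
    fit_idx = _as_indices(fit_set, n_res)
    aligned = _fit_to_mean(frames, fit_idx)
    mean = aligned.mean(axis=0)
    x = (aligned - mean).reshape(len(frames), -1)
    cov = x.T @ x / len(frames)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    n_modes = min(n_modes, v.shape[1])
    modes = v[:, :n_modes]
    k = min(n_mobility_modes, n_modes)
    per_res = modes[:, :k].reshape(n_res, 3, k)
    mobility = np.sqrt(w[:k])[None, :] * np.linalg.norm(per_res, axis=1)
    return PCAResult(
        eigenvalues=w,
        eigenvectors=modes,
        mobility=mobility,
        n_frames=len(frames),
        cov_trace=float(np.trace(cov)),
    )


@dataclass
class CrossCorrMatrix:
    """Normalised dynamic cross-correlation matrix of residue motions."""

    matrix: np.ndarray
    n_frames: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise DataError("cross-correlation matrix must be square")


def cross_correlation(ca_coords, fit_set=None, superpose_frames=True) -> CrossCorrMatrix:
    """DCCM: ``C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>)``.

    Deviations are taken from each residue's mean position over frames
    superposed onto the mean structure (set ``superpose_frames=False`` to
    correlate raw laboratory-frame motions).  Residues with zero variance
    get zero rows/columns (diagonal 1) and trigger a warning.
    """
    if isinstance(ca_coords, (list, tuple)):
        ca_coords = np.concatenate([np.asarray(c, dtype=float) for c in ca_coords])
    frames = np.asarray(ca_coords, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise DataError("cross-correlation requires at least 2 frames")
    if superpose_frames:
        fit_idx = _as_indices(fit_set, frames.shape[1])
        frames = _fit_to_mean(frames, fit_idx)
    dev = frames - frames.mean(axis=0)
    inner = np.einsum("fik,fjk->ij", dev, dev) / len(frames)
    var = np.diag(inner).copy()
    zero = var <= 1e-15
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} residue(s) have zero variance; "
            "their correlations are reported as 0",
            stacklevel=2,
        )
        var[zero] = 1.0
    norm = np.sqrt(np.outer(var, var))
    mat = inner / norm
    mat[zero, :] = 0.0
    mat[:, zero] = 0.0
    np.fill_diagonal(mat, 1.0)
    mat = np.clip((mat + mat.T) / 2.0, -1.0, 1.0)
    return CrossCorrMatrix(matrix=mat, n_frames=len(frames))
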