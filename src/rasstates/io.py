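"""Structure/trajectory input and pipeline table output.

Structures are PDB v3.3 files; trajectories are DCD, XTC, or multi-model
PDB.  All coordinates are exposed in Angstrom regardless of on-disk units
(MDAnalysis performs the unit conversion).  Semantic atom roles (the atoms
named in the state-classification distances) are resolved here once and
carried as plain integer indices thereafter.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DataError,
    RoleResolutionError,
    StructureFormatError,
    TrajectoryFormatError,
)
from . import regions

# Scalar roles: exactly one atom each.
SCALAR_ROLES = ("OG35", "MG", "OH32", "OGAMMA", "O12", "O18", "OH40")
# Group roles: ordered index lists.
GROUP_ROLES = ("CA_TRACE", "GTP_ATOMS", "NA_IONS", "BETA1_CA", "E132_CA", "L184_CA")

#: Feature-table column order (units in the header line written to CSV).
FEATURE_COLUMNS = [
    "frame",
    "time_ns",
    "d_O12_Og",
    "d_OH32_O18",
    "d_OG35_Mg",
    "d_OH32_Og",
    "d_OH32_OH40",
    "rc_angle_deg",
    "rc_dist_A",
]


@dataclass
class Structure:
    """Atom records of a single PDB model, coordinates in Angstrom."""

    serials: np.ndarray
    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    source: Path | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureFormatError("coordinates must be an (n_atoms, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise StructureFormatError("structure contains non-finite coordinates")
        if np.any(np.asarray(self.resids) < 1):
            raise StructureFormatError("residue numbers must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.resids))


@dataclass
class Trajectory:
    """Per-frame coordinates (frames x atoms x 3, Angstrom)."""

    coords: np.ndarray
    times_ns: np.ndarray | None = None
    box: np.ndarray | None = None  # [lx, ly, lz, alpha, beta, gamma] or per-frame

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryFormatError("trajectory coordinates must be (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise TrajectoryFormatError("trajectory must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class AtomRoleMap:
    """Binding of semantic atom roles to indices of a concrete structure."""

    scalars: dict[str, int]
    groups: dict[str, np.ndarray]
    n_atoms: int

    def __post_init__(self):
        for role, idx in self.scalars.items():
            if not (0 <= int(idx) < self.n_atoms):
                raise RoleResolutionError(f"role {role}: index {idx} out of range")
        for role, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
                raise RoleResolutionError(f"role {role}: index out of range")
            self.groups[role] = idx

    def scalar(self, role: str) -> int:
        if role not in self.scalars:
            raise RoleResolutionError(f"scalar role {role} is not resolved")
        return self.scalars[role]

    def group(self, role: str) -> np.ndarray:
        if role not in self.groups:
            raise RoleResolutionError(f"group role {role} is not resolved")
        return self.groups[role]

    def has(self, role: str) -> bool:
        return role in self.scalars or (role in self.groups and self.groups[role].size > 0)

    def digest(self) -> str:
        """Stable hash of the mapping, used for provenance."""
        payload = {
            "scalars": {k: int(v) for k, v in sorted(self.scalars.items())},
            "groups": {k: [int(i) for i in v] for k, v in sorted(self.groups.items())},
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RoleRules:
    """Selection rules binding roles to atoms; defaults follow PDB naming.

    Residue numbers use 5UHV crystal numbering.  HETATM residue names are
    matched case-insensitively with configurable synonyms (e.g. "SOD" for
    sodium).  The GTP gamma-oxygen role accepts any of ``gamma_oxygen_names``
    and binds the one closest to OH32 in the reference structure, fixed
    thereafter.
    """

    thr35_resid: int = 35
    thr35_atom: str = "OG1"
    tyr32_resid: int = 32
    tyr40_resid: int = 40
    tyr_oh_atom: str = "OH"
    res12_resid: int = 12
    res18_resid: int = 18
    backbone_o_atom: str = "O"
    gtp_resnames: tuple[str, ...] = ("GTP", "GNP", "GSP", "GTN")
    mg_resnames: tuple[str, ...] = ("MG", "MG2")
    na_resnames: tuple[str, ...] = ("NA", "SOD", "NA+")
    gamma_oxygen_names: tuple[str, ...] = ("O1G", "O2G", "O3G")
    g_domain: tuple[int, int] = regions.G_DOMAIN
    beta1: tuple[int, int] = regions.BETA1
    e132_resid: int = regions.E132
    l184_resid: int = regions.L184


def _first_bad_pdb_line(path: Path) -> str:
    """Best-effort localisation of a malformed ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38])
                        float(line[38:46])
                        float(line[46:54])
                    except (ValueError, IndexError):
                        return f" (first malformed record at line {lineno}: {line.rstrip()!r})"
    except OSError:
        pass
    return ""


def read_structure(path) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    All ATOM and HETATM records are kept in file order.  Files using
    insertion codes are rejected (crystal numbering must be unambiguous);
    duplicate atom serials are accepted with a warning.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"structure file does not exist: {path}")
    if path.stat().st_size == 0:
        raise StructureFormatError(f"structure file is empty: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="PDB")
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise StructureFormatError(
            f"failed to parse PDB file {path}: {exc}{_first_bad_pdb_line(path)}"
        ) from exc
    atoms = u.atoms
    if len(atoms) == 0:
        raise StructureFormatError(f"no ATOM/HETATM records found in {path}")

    icodes = getattr(atoms, "icodes", None)
    if icodes is not None and any(str(c).strip() for c in icodes):
        raise StructureFormatError(
            f"{path}: insertion codes are not supported (residue numbering must match 5UHV)"
        )

    serials = np.asarray(getattr(atoms, "ids", np.arange(1, len(atoms) + 1)), dtype=int)
    uniq, counts = np.unique(serials, return_counts=True)
    if np.any(counts > 1):
        warnings.warn(
            f"{path}: duplicate atom serial numbers {uniq[counts > 1][:5].tolist()}; "
            "file order preserved",
            stacklevel=2,
        )

    try:
        elements = np.asarray(atoms.elements, dtype=str)
    except Exception:  # noqa: BLE001 - elements are optional in PDB
        elements = np.array([name.strip()[:1] for name in atoms.names], dtype=str)
    try:
        chains = np.asarray(atoms.chainIDs, dtype=str)
    except Exception:  # noqa: BLE001
        chains = np.asarray(atoms.segids, dtype=str)

    return Structure(
        serials=serials,
        names=np.asarray(atoms.names, dtype=str),
        resnames=np.asarray(atoms.resnames, dtype=str),
        resids=np.asarray(atoms.resids, dtype=int),
        chains=chains,
        elements=elements,
        coords=np.array(atoms.positions, dtype=float),
        source=path,
    )


def _check_multimodel_pdb(path: Path, n_atoms: int) -> None:
    """Validate that every MODEL of a multi-model PDB has ``n_atoms`` atoms."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                in_model, saw_model, current = True, True, 0
            elif line.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif line.startswith(("ATOM", "HETATM")):
                current += 1
    if saw_model and in_model:
        raise TrajectoryFormatError(
            f"{path}: truncated multi-model PDB (MODEL without ENDMDL)"
        )
    if not saw_model:
        counts = [current]
    bad = [c for c in counts if c != n_atoms]
    if bad:
        raise TrajectoryFormatError(
            f"{path}: frame with {bad[0]} atoms does not match structure ({n_atoms} atoms)"
        )


def read_trajectory(path, structure: Structure) -> Trajectory:
    """Read a coordinate trajectory matching ``structure``.

    Supports DCD, XTC (and other MDAnalysis-readable binary formats) plus
    multi-model PDB.  Coordinates are returned in Angstrom regardless of the
    on-disk unit; a truncated or atom-count-mismatched file raises
    :class:`TrajectoryFormatError` rather than silently short-reading.
    """
    from MDAnalysis.coordinates.core import get_reader_for

    path = Path(path)
    if not path.exists():
        raise TrajectoryFormatError(f"trajectory file does not exist: {path}")
    if path.suffix.lower() in {".pdb", ".ent"}:
        _check_multimodel_pdb(path, structure.n_atoms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader_cls = get_reader_for(str(path))
            reader = reader_cls(str(path))
    except Exception as exc:  # noqa: BLE001
        raise TrajectoryFormatError(f"cannot open trajectory {path}: {exc}") from exc

    try:
        expected = reader.n_frames
    except Exception:  # noqa: BLE001 - streaming readers may not know
        expected = None
    n_file = getattr(reader, "n_atoms", None)
    if n_file is not None and n_file != structure.n_atoms:
        raise TrajectoryFormatError(
            f"atom count mismatch: trajectory {path} has {n_file} atoms, "
            f"structure has {structure.n_atoms}"
        )

    frames, times, boxes = [], [], []
    try:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=DeprecationWarning)
            warnings.filterwarnings("ignore", message="Reader has no dt information")
            for ts in reader:
                if ts.positions.shape[0] != structure.n_atoms:
                    raise TrajectoryFormatError(
                        f"frame {ts.frame} has {ts.positions.shape[0]} atoms, "
                        f"structure has {structure.n_atoms}"
                    )
                frames.append(np.array(ts.positions, dtype=float))
                times.append(float(ts.time) if ts.time is not None else np.nan)
                dims = ts.dimensions
                boxes.append(np.array(dims, dtype=float) if dims is not None else None)
    except TrajectoryFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - truncated/corrupt frames
        raise TrajectoryFormatError(f"error while reading {path}: {exc}") from exc
    finally:
        reader.close()

    if not frames:
        raise TrajectoryFormatError(f"{path}: trajectory contains no frames")
    if expected is not None and len(frames) != expected:
        raise TrajectoryFormatError(
            f"{path}: short read ({len(frames)} of {expected} frames)"
        )

    times_arr = np.asarray(times)
    times_ns = times_arr / 1000.0 if np.all(np.isfinite(times_arr)) else None

    box = None
    if all(b is not None for b in boxes) and boxes:
        stack = np.stack(boxes)
        if np.any(stack[:, :3] > 0):
            box = stack[0] if np.allclose(stack, stack[0]) else stack

    return Trajectory(coords=np.stack(frames), times_ns=times_ns, box=box)


def _pick_one(role: str, idx: np.ndarray, structure: Structure, hint: str) -> int:
    if idx.size == 1:
        return int(idx[0])
    if idx.size == 0:
        # list nearby candidates to make the error actionable
        raise RoleResolutionError(
            f"cannot resolve mandatory role {role}: no atom matches {hint}; "
            f"candidates: {_candidates(structure, hint)}"
        )
    raise RoleResolutionError(
        f"cannot resolve role {role}: {idx.size} atoms match {hint} "
        f"(serials {structure.serials[idx][:5].tolist()})"
    )


def _candidates(structure: Structure, hint: str) -> str:
    names = sorted(set(structure.names.tolist()))
    return f"atom names present include {names[:15]}"


def resolve_roles(structure: Structure, rules: RoleRules | None = None) -> AtomRoleMap:
    """Bind every semantic atom role to atom indices of ``structure``.

    Deterministic: the same structure and rules always give the same map.
    The gamma-phosphate oxygen (OGAMMA) is chosen among the candidate names
    as the one closest to OH32 in the structure's coordinates, so the
    OH32-Ogamma distance refers to one fixed atom across all frames.
    """
    rules = rules or RoleRules()
    names = np.char.upper(structure.names.astype(str))
    resnames = np.char.upper(structure.resnames.astype(str))
    resids = structure.resids

    def match(resid=None, name=None, resname_set=None):
        mask = np.ones(structure.n_atoms, dtype=bool)
        if resid is not None:
            mask &= resids == resid
        if name is not None:
            mask &= names == name.upper()
        if resname_set is not None:
            mask &= np.isin(resnames, [r.upper() for r in resname_set])
        return np.flatnonzero(mask)

    scalars: dict[str, int] = {}
    scalars["OG35"] = _pick_one(
        "OG35", match(rules.thr35_resid, rules.thr35_atom), structure,
        f"residue {rules.thr35_resid} atom {rules.thr35_atom}",
    )
    scalars["OH32"] = _pick_one(
        "OH32", match(rules.tyr32_resid, rules.tyr_oh_atom), structure,
        f"residue {rules.tyr32_resid} atom {rules.tyr_oh_atom}",
    )
    scalars["OH40"] = _pick_one(
        "OH40", match(rules.tyr40_resid, rules.tyr_oh_atom), structure,
        f"residue {rules.tyr40_resid} atom {rules.tyr_oh_atom}",
    )
    # O12 binds the backbone O at position 12 whatever the residue type is
    # (Gly in WT, Val in G12V).
    scalars["O12"] = _pick_one(
        "O12", match(rules.res12_resid, rules.backbone_o_atom), structure,
        f"residue {rules.res12_resid} atom {rules.backbone_o_atom}",
    )
    scalars["O18"] = _pick_one(
        "O18", match(rules.res18_resid, rules.backbone_o_atom), structure,
        f"residue {rules.res18_resid} atom {rules.backbone_o_atom}",
    )
    scalars["MG"] = _pick_one(
        "MG", match(name="MG", resname_set=rules.mg_resnames), structure,
        f"atom MG in residue {'/'.join(rules.mg_resnames)}",
    )

    gtp_idx = np.flatnonzero(np.isin(resnames, [r.upper() for r in rules.gtp_resnames]))
    if gtp_idx.size == 0:
        raise RoleResolutionError(
            f"cannot resolve role GTP_ATOMS: no residue named "
            f"{'/'.join(rules.gtp_resnames)}; residues present: "
            f"{sorted(set(resnames.tolist()))[:15]}"
        )
    gamma_idx = gtp_idx[np.isin(names[gtp_idx], [n.upper() for n in rules.gamma_oxygen_names])]
    if gamma_idx.size == 0:
        raise RoleResolutionError(
            f"cannot resolve role OGAMMA: GTP residue has no atom named "
            f"{'/'.join(rules.gamma_oxygen_names)}; GTP atoms: "
            f"{structure.names[gtp_idx].tolist()}"
        )
    oh32_pos = structure.coords[scalars["OH32"]]
    dists = np.linalg.norm(structure.coords[gamma_idx] - oh32_pos, axis=1)
    scalars["OGAMMA"] = int(gamma_idx[int(np.argmin(dists))])

    lo, hi = rules.g_domain
    ca_mask = (names == "CA") & (resids >= lo) & (resids <= hi)
    # Exclude HETATM-style residues that happen to contain a CA-named atom.
    ca_mask &= ~np.isin(resnames, [r.upper() for r in rules.gtp_resnames])
    ca_idx = np.flatnonzero(ca_mask)
    ca_idx = ca_idx[np.argsort(resids[ca_idx], kind="stable")]

    b_lo, b_hi = rules.beta1
    beta1_idx = ca_idx[(resids[ca_idx] >= b_lo) & (resids[ca_idx] <= b_hi)]
    if beta1_idx.size != 4:
        raise RoleResolutionError(
            f"cannot resolve role BETA1_CA: expected 4 CA atoms in residues "
            f"{b_lo}-{b_hi}, found {beta1_idx.size}"
        )

    groups: dict[str, np.ndarray] = {
        "CA_TRACE": ca_idx,
        "GTP_ATOMS": gtp_idx,
        "NA_IONS": np.flatnonzero(
            np.isin(resnames, [r.upper() for r in rules.na_resnames]) & (names == "NA")
        ),
        "BETA1_CA": beta1_idx,
    }
    e132 = match(rules.e132_resid, "CA")
    groups["E132_CA"] = e132[:1]
    l184 = match(rules.l184_resid, "CA")
    groups["L184_CA"] = l184[:1]  # optional: absent for solution-only systems

    return AtomRoleMap(scalars=scalars, groups=groups, n_atoms=structure.n_atoms)


# ---------------------------------------------------------------------------
# table / matrix output


def write_feature_table(features, labels, path) -> Path:
    """Write the per-frame feature+label table as CSV.

    One row per frame; distances in Angstrom, angle in degrees (the units
    are part of the column names).  ``labels`` may be None to write features
    only.  Values round-trip at the printed precision (6 decimals).
    """
    path = Path(path)
    table = features.table.copy()
    if labels is not None:
        if len(labels.labels) != len(table):
            raise DataError(
                f"feature/label length mismatch: {len(table)} features vs "
                f"{len(labels.labels)} labels"
            )
        table["raw_label"] = labels.raw
        table["smoothed_label"] = labels.labels
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.6f")
    return path


def read_feature_table(path) -> pd.DataFrame:
    """Read back a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path)


def write_labels_csv(labels, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "frame": np.arange(len(labels.labels)),
            "raw_label": labels.raw,
            "smoothed_label": labels.labels,
        }
    ).to_csv(path, index=False)
    return path


def write_occupancy_json(report, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_occupancy_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_matrix(matrix, path, header: str = "") -> Path:
    """Plain-text matrix with a ``#`` header line of metadata."""
    path = Path(path)
    np.savetxt(path, np.asarray(matrix), fmt="%.8g", header=header)
    return path


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)
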