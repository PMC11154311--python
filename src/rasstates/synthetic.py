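"""Seeded synthetic N-Ras trajectories for end-to-end pipeline testing.

No MD trajectories of this system are publicly deposited, so every pipeline
stage is exercised against a generator that emulates, per conformational
(sub)state: the characteristic inter-atomic distance distributions, a
Markov state-switching sequence with prescribed stationary occupancies and
mean dwell time, state-dependent switch-loop noise on a 165/186-residue
Calpha trace, membrane reaction-coordinate distributions, and Poisson Na+
placements near the GTP.

Scenario presets (``solution_WT``, ``solution_G12V``, ``membrane_WT``,
``membrane_G12V``) carry the published per-state distance centers,
occupancy percentages, and ion means.  Published percentages that do not
sum to 100 leave an explicit residual: it is emitted as a background state
whose geometry matches no classifier signature (reported downstream as
UNASSIGNED); for membrane systems, where state 1 has no published
percentage, state 1 absorbs the remainder instead.

The construction of each frame is tree-structured — every classifier
distance constrains exactly one atom relative to an already-placed one —
so each sampled distance is realised exactly (no rejection sampling).
Geometry is deliberately schematic: this is a feature-level emulator, not
a physical protein model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import regions
from .classify import LABELS, S1, S2_OX, S2_OY, S2_OZ, UNASSIGNED
from .errors import ConfigError, DataError
from .io import Structure, Trajectory

STATES = LABELS  # S1, S2_OX, S2_OY, S2_OZ, UNASSIGNED
DISTANCE_NAMES = ("d_O12_Og", "d_OH32_O18", "d_OG35_Mg", "d_OH32_Og", "d_OH32_OH40")

_N_DECOYS = 10
_SHELL_CAPACITY = 12
_ION_CUTOFF = 4.5
_CA_SPACING = 3.8
_FRAME_DT_NS = 0.1


def _distance_table(genotype: str) -> dict:
    """Per-state (mean, sd) in Angstrom for the five classifier distances.

    Means are the characteristic per-state centers; the residue-12 backbone
    oxygen to gamma-oxygen distance shifts from 5.3 A to above 8 A under
    G12V.  Standard deviations are calibration choices (no published
    widths): 0.4 A default, tighter for the intact Thr35-Mg bond, wider for
    the loosely-held state-1 and bulk-facing-OZ geometries.
    """
    o12 = 8.5 if genotype == "G12V" else 5.3
    return {
        S1: {
            "d_O12_Og": (o12, 0.4),
            "d_OH32_O18": (13.0, 1.0),
            "d_OG35_Mg": (6.0, 1.5),
            "d_OH32_Og": (14.0, 2.0),
            "d_OH32_OH40": (4.4, 0.4),
        },
        S2_OX: {
            "d_O12_Og": (o12, 0.4),
            "d_OH32_O18": (13.0, 0.4),
            "d_OG35_Mg": (2.0, 0.15),
            "d_OH32_Og": (2.7, 0.4),
            "d_OH32_OH40": (11.6, 0.4),
        },
        S2_OY: {
            "d_O12_Og": (o12, 0.4),
            "d_OH32_O18": (4.3, 0.4),
            "d_OG35_Mg": (2.0, 0.15),
            "d_OH32_Og": (11.3, 0.4),
            "d_OH32_OH40": (11.6, 0.4),
        },
        S2_OZ: {
            "d_O12_Og": (o12, 0.4),
            "d_OH32_O18": (13.0, 0.4),
            "d_OG35_Mg": (2.0, 0.15),
            "d_OH32_Og": (7.5, 1.0),
            "d_OH32_OH40": (11.6, 0.4),
        },
        UNASSIGNED: {
            "d_O12_Og": (o12, 0.4),
            "d_OH32_O18": (13.0, 0.4),
            "d_OG35_Mg": (2.0, 0.15),
            "d_OH32_Og": (12.5, 0.4),
            "d_OH32_OH40": (11.6, 0.4),
        },
    }


#: Tilt-angle / HVR-distance (mean, sd) pairs per state for membrane runs.
#: Published evidence is qualitative (contour-plot descriptions), so these
#: encode only the described shapes: narrow/specific for WT state 1 and
#: the compact-HVR OY/OZ substates, medium-stretched OX, wide for G12V.
_RC_WT = {
    S1: (35.0, 4.0, 9.0, 1.0),
    S2_OX: (55.0, 10.0, 15.0, 3.0),
    S2_OY: (45.0, 6.0, 8.0, 1.5),
    S2_OZ: (50.0, 6.0, 8.0, 1.5),
    UNASSIGNED: (90.0, 25.0, 12.0, 4.0),
}
_RC_G12V = {
    S1: (60.0, 25.0, 14.0, 5.0),
    S2_OX: (80.0, 8.0, 15.0, 2.0),
    S2_OY: (70.0, 25.0, 14.0, 5.0),
    S2_OZ: (50.0, 6.0, 8.0, 1.5),
    UNASSIGNED: (90.0, 25.0, 12.0, 4.0),
}

#: Switch-loop noise scale (A) per state: state 1 fluctuates most (both
#: switches), OY's switch II approaches state-1 levels, OZ is the
#: quietest; the core uses ``core_noise``.
_SWITCH_NOISE = {S1: 3.0, S2_OX: 1.2, S2_OY: 2.0, S2_OZ: 0.8, UNASSIGNED: 2.0}


@dataclass
class SyntheticSpec:
    """Full parameterisation of the synthetic-trajectory generator."""

    name: str
    pi: dict[str, float]
    tau: float
    n_frames: int
    seed: int
    distances: dict[str, dict[str, tuple[float, float]]]
    lam: dict[str, float | None]
    membrane: bool = False
    genotype: str = "WT"
    rc: dict[str, tuple[float, float, float, float]] | None = None
    rc_angle_solution: tuple[float, float] = (90.0, 30.0)
    switch_noise: dict[str, float] = field(default_factory=lambda: dict(_SWITCH_NOISE))
    core_noise: float = 0.4
    box_edge: float | None = None

    def __post_init__(self):
        if self.n_frames < 1:
            raise ConfigError(f"n_frames must be >= 1 (got {self.n_frames})")
        if self.tau < 1:
            raise ConfigError(f"mean dwell tau must be >= 1 frame (got {self.tau})")
        unknown = set(self.pi) - set(STATES)
        if unknown:
            raise ConfigError(f"unknown states in pi: {sorted(unknown)}")
        if any(p < 0 for p in self.pi.values()):
            raise ConfigError("stationary probabilities must be non-negative")
        if abs(sum(self.pi.values()) - 1.0) > 1e-9:
            raise ConfigError(f"pi must sum to 1 (got {sum(self.pi.values()):.12f})")
        for state in self.support():
            table = self.distances.get(state)
            if table is None:
                raise ConfigError(f"no distance parameters for state {state}")
            for dist_name in DISTANCE_NAMES:
                if dist_name not in table:
                    raise ConfigError(f"state {state}: missing distance {dist_name}")
                mu, sd = table[dist_name]
                if not (np.isfinite(mu) and mu > 0):
                    raise ConfigError(
                        f"infeasible distance {dist_name} for state {state}: "
                        f"mean must be a positive finite length (got {mu})"
                    )
                if not (np.isfinite(sd) and sd > 0):
                    raise ConfigError(
                        f"state {state}: {dist_name} sd must be positive (got {sd})"
                    )
            lam = self.lam.get(state)
            if lam is None or lam < 0:
                raise ConfigError(
                    f"state {state}: ion Poisson mean must be >= 0 (got {lam})"
                )
            if self.membrane:
                if self.rc is None or state not in self.rc:
                    raise ConfigError(f"membrane scenario needs RC parameters for {state}")
                ang, ang_sd, dist, dist_sd = self.rc[state]
                if not (0.0 < ang < 180.0) or ang_sd <= 0 or dist <= 0 or dist_sd <= 0:
                    raise ConfigError(f"state {state}: invalid RC parameters")

    def support(self) -> list[str]:
        return [s for s in STATES if self.pi.get(s, 0.0) > 0.0]

    @property
    def n_residues(self) -> int:
        return regions.HVR_END if self.membrane else regions.G_DOMAIN[1]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["distances"] = {
            s: {k: tuple(v) for k, v in table.items()}
            for s, table in d["distances"].items()
        }
        if d.get("rc"):
            d["rc"] = {s: tuple(v) for s, v in d["rc"].items()}
        if d.get("rc_angle_solution") is not None:
            d["rc_angle_solution"] = tuple(d["rc_angle_solution"])
        return cls(**d)


def scenario_names() -> list[str]:
    return ["solution_WT", "solution_G12V", "membrane_WT", "membrane_G12V"]


def make_scenario(name: str, n_frames: int, tau: float = 50.0, seed: int = 0) -> SyntheticSpec:
    """Build a preset :class:`SyntheticSpec` by scenario name.

    Occupancies follow the published per-scenario percentages; the
    UNASSIGNED entry carries the residual of percentages that do not sum
    to 100 (see module docstring).  Ion means follow the published
    per-state table; the background state's mean is unconstrained and set
    to 0.5.  G12V scenarios never sample the GAP-compatible OZ substate.
    """
    presets: dict[str, dict] = {
        "solution_WT": dict(
            pi={S1: 0.40, S2_OX: 0.30, S2_OY: 0.20, S2_OZ: 0.03, UNASSIGNED: 0.07},
            lam={S1: 2.53, S2_OX: 0.56, S2_OY: 0.40, S2_OZ: 0.15, UNASSIGNED: 0.5},
            membrane=False,
            genotype="WT",
        ),
        "solution_G12V": dict(
            pi={S1: 0.95, S2_OX: 0.0, S2_OY: 0.0, S2_OZ: 0.0, UNASSIGNED: 0.05},
            lam={S1: 1.56, S2_OX: None, S2_OY: None, S2_OZ: None, UNASSIGNED: 0.5},
            membrane=False,
            genotype="G12V",
        ),
        "membrane_WT": dict(
            pi={S1: 0.37, S2_OX: 0.55, S2_OY: 0.06, S2_OZ: 0.02, UNASSIGNED: 0.0},
            lam={S1: 1.72, S2_OX: 0.42, S2_OY: 0.75, S2_OZ: 0.06, UNASSIGNED: 0.5},
            membrane=True,
            genotype="WT",
        ),
        "membrane_G12V": dict(
            pi={S1: 0.37, S2_OX: 0.10, S2_OY: 0.30, S2_OZ: 0.0, UNASSIGNED: 0.23},
            lam={S1: 2.30, S2_OX: 1.23, S2_OY: 0.88, S2_OZ: None, UNASSIGNED: 0.5},
            membrane=True,
            genotype="G12V",
        ),
    }
    if name not in presets:
        raise ConfigError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        )
    p = presets[name]
    return SyntheticSpec(
        name=name,
        pi=p["pi"],
        tau=tau,
        n_frames=n_frames,
        seed=seed,
        distances=_distance_table(p["genotype"]),
        lam=p["lam"],
        membrane=p["membrane"],
        genotype=p["genotype"],
        rc=(_RC_G12V if p["genotype"] == "G12V" else _RC_WT) if p["membrane"] else None,
    )


@dataclass
class SyntheticTruth:
    """Ground-truth per-frame state labels with a generator-parameter echo."""

    labels: np.ndarray
    spec: SyntheticSpec

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SyntheticResult:
    structure: Structure
    trajectory: Trajectory
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# state sequence


def sample_state_sequence(pi: dict[str, float], tau: float, n_frames: int, rng) -> np.ndarray:
    """Markov state sequence with stationary distribution exactly ``pi``.

    At every step the chain redraws its state from ``pi`` with probability
    1/tau and stays put otherwise, so states with ``pi == 0`` are never
    emitted, the stationary law is exactly ``pi``, and the integrated
    autocorrelation factor is exactly ``2*tau - 1`` (effective sample size
    ``n / (2*tau - 1)``).  ``tau = 1`` gives i.i.d. draws.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    states = [s for s in STATES if pi.get(s, 0.0) > 0.0]
    probs = np.array([pi[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    if n_frames < 1:
        raise ConfigError("n_frames must be >= 1")
    codes_support = rng.choice(len(states), size=n_frames, p=probs)
    resample = rng.random(n_frames) < (1.0 / tau)
    resample[0] = True
    # forward-fill: each frame takes the most recent resampled draw
    draw_idx = np.where(resample, np.arange(n_frames), 0)
    draw_idx = np.maximum.accumulate(draw_idx)
    seq_support = codes_support[draw_idx]
    state_codes = np.array([LABELS.index(s) for s in states])
    return state_codes[seq_support]


# ---------------------------------------------------------------------------
# topology and template geometry


def _role_atom_for(resid: int) -> tuple[str, str] | None:
    """Extra (atom name, element) carried by classifier-relevant residues."""
    return {
        12: ("O", "O"),
        18: ("O", "O"),
        32: ("OH", "O"),
        35: ("OG1", "O"),
        40: ("OH", "O"),
    }.get(resid)


def _resname_for(resid: int, genotype: str) -> str:
    special = {
        12: "VAL" if genotype == "G12V" else "GLY",
        18: "ALA",
        32: "TYR",
        35: "THR",
        40: "TYR",
        132: "GLU",
        184: "LEU",
    }
    return special.get(resid, "ALA")


class _Topology:
    """Atom bookkeeping for the synthetic system (order is file order)."""

    def __init__(self, spec: SyntheticSpec):
        self.n_residues = spec.n_residues
        names, resnames, resids, elements, records = [], [], [], [], []
        self.ca_index: dict[int, int] = {}
        self.role_index: dict[str, int] = {}
        for resid in range(1, self.n_residues + 1):
            resname = _resname_for(resid, spec.genotype)
            self.ca_index[resid] = len(names)
            names.append("CA")
            resnames.append(resname)
            resids.append(resid)
            elements.append("C")
            records.append("ATOM")
            extra = _role_atom_for(resid)
            if extra is not None:
                atom_name, element = extra
                self.role_index[f"{atom_name}{resid}"] = len(names)
                names.append(atom_name)
                resnames.append(resname)
                resids.append(resid)
                elements.append(element)
                records.append("ATOM")
        gtp_names = ["PG", "O1G", "O2G", "O3G", "PB", "O3B"]
        self.gtp_index = {}
        for atom_name in gtp_names:
            self.gtp_index[atom_name] = len(names)
            names.append(atom_name)
            resnames.append("GTP")
            resids.append(self.n_residues + 15)
            elements.append("P" if atom_name.startswith("P") else "O")
            records.append("HETATM")
        self.mg_index = len(names)
        names.append("MG")
        resnames.append("MG")
        resids.append(self.n_residues + 16)
        elements.append("MG")
        records.append("HETATM")
        self.n_ions = _N_DECOYS + _SHELL_CAPACITY
        self.na_indices = []
        for k in range(self.n_ions):
            self.na_indices.append(len(names))
            names.append("NA")
            resnames.append("NA")
            resids.append(self.n_residues + 20 + k)
            elements.append("NA")
            records.append("HETATM")
        self.names = np.array(names)
        self.resnames = np.array(resnames)
        self.resids = np.array(resids, dtype=int)
        self.elements = np.array(elements)
        self.records = np.array(records)
        self.n_atoms = len(names)
        self.na_indices = np.array(self.na_indices, dtype=int)

def _template_coords(topo: _Topology) -> np.ndarray:
    """Reference coordinates: a 2OX-like arrangement of the role atoms,
    a helix-like Calpha curve, and decoy ion positions."""
    xyz = np.zeros((topo.n_atoms, 3))
    for resid, idx in topo.ca_index.items():
        t = 0.6 * resid
        xyz[idx] = (28.0 + 5.0 * np.cos(t), 5.0 * np.sin(t), 1.5 * resid - 130.0)
    o1g = np.array([0.0, 2.0, 0.0])
    oh32 = o1g + 2.7 * np.array([0.0, -1.0, 0.0])
    xyz[topo.gtp_index["PG"]] = (0.0, 3.2, 0.0)
    xyz[topo.gtp_index["O1G"]] = o1g
    xyz[topo.gtp_index["O2G"]] = (0.9, 3.9, 0.6)
    xyz[topo.gtp_index["O3G"]] = (-0.9, 3.9, -0.6)
    xyz[topo.gtp_index["PB"]] = (0.0, 4.8, 0.8)
    xyz[topo.gtp_index["O3B"]] = (0.7, 4.4, 1.5)
    xyz[topo.mg_index] = (0.0, 0.0, 0.0)
    xyz[topo.role_index["OG135"]] = (2.0, 0.0, 0.0)
    xyz[topo.role_index["OH32"]] = oh32
    xyz[topo.role_index["O18"]] = oh32 + 13.0 * np.array([0.6, -0.8, 0.0])
    xyz[topo.role_index["O12"]] = o1g + 5.3 * np.array([1.0, 0.0, 0.0])
    xyz[topo.role_index["OH40"]] = oh32 + 11.6 * np.array([-0.6, -0.8, 0.0])
    for k, idx in enumerate(topo.na_indices):
        ang = 2.0 * np.pi * k / topo.n_ions
        xyz[idx] = (30.0 * np.cos(ang), 30.0 * np.sin(ang), 5.0)
    return xyz


def _positive_normal(rng, mu: float, sd: float, size: int, lower: float = 0.05) -> np.ndarray:
    """Gaussian draws resampled until strictly positive (> ``lower``)."""
    out = rng.normal(mu, sd, size=size)
    for _ in range(100):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mu, sd, size=int(bad.sum()))
    raise DataError(
        f"could not draw a positive distance from N({mu}, {sd}); "
        "the distance specification is infeasible"
    )


def _unit_vectors(rng, size: int) -> np.ndarray:
    v = rng.standard_normal((size, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return v / norms


# ---------------------------------------------------------------------------
# frame emission


def emit_frames(state_codes: np.ndarray, spec: SyntheticSpec, rng_geom, rng_ions) -> np.ndarray:
    """Deterministic geometric realisation of a state sequence.

    Returns coordinates of shape (frames, atoms, 3).  Per frame: the Mg
    sits at the origin with the gamma-oxygen at a fixed 2.0 A coordination
    offset; OG35 lies along +x at the sampled Thr35-Mg distance; OH32,
    O18, O12 and OH40 are placed on spheres realising their sampled
    distances exactly; the Calpha trace is the template curve with
    state-scaled Gaussian switch noise; beta-1 is laid collinear at the
    sampled membrane-tilt angle; Na+ ions are Poisson-placed in the 4.5 A
    GTP shell with 10 decoys far outside it.
    """
    topo = _Topology(spec)
    template = _template_coords(topo)
    state_codes = np.asarray(state_codes, dtype=int)
    n_frames = len(state_codes)
    coords = np.tile(template, (n_frames, 1, 1))

    o1g = template[topo.gtp_index["O1G"]]

    # --- Calpha trace noise (state-scaled on the switch loops)
    resids = np.arange(1, topo.n_residues + 1)
    si = (resids >= regions.SWITCH_I[0]) & (resids <= regions.SWITCH_I[1])
    sii = (resids >= regions.SWITCH_II[0]) & (resids <= regions.SWITCH_II[1])
    sigma = np.full((n_frames, topo.n_residues), spec.core_noise)
    switch_scale = np.array([spec.switch_noise.get(lab, spec.core_noise) for lab in LABELS])
    per_frame_switch = switch_scale[state_codes]
    sigma[:, si | sii] = per_frame_switch[:, None]
    ca_idx = np.array([topo.ca_index[r] for r in resids])
    coords[:, ca_idx, :] += rng_geom.standard_normal((n_frames, topo.n_residues, 3)) * sigma[:, :, None]

    # --- role atoms, grouped by state so distances come from that state's law
    for label in STATES:
        code = LABELS.index(label)
        idx = np.flatnonzero(state_codes == code)
        if idx.size == 0:
            continue
        m = idx.size
        table = spec.distances[label]
        d = {
            name: _positive_normal(rng_geom, *table[name], size=m)
            for name in DISTANCE_NAMES
        }
        coords[idx, topo.role_index["OG135"], :] = 0.0
        coords[idx, topo.role_index["OG135"], 0] = d["d_OG35_Mg"]
        u_oh32 = _unit_vectors(rng_geom, m)
        u_oh32[:, 1] = -np.abs(u_oh32[:, 1])  # keep Tyr32 off the phosphate side
        oh32 = o1g + d["d_OH32_Og"][:, None] * u_oh32
        coords[idx, topo.role_index["OH32"], :] = oh32
        coords[idx, topo.role_index["O18"], :] = (
            oh32 + d["d_OH32_O18"][:, None] * _unit_vectors(rng_geom, m)
        )
        coords[idx, topo.role_index["O12"], :] = (
            o1g + d["d_O12_Og"][:, None] * _unit_vectors(rng_geom, m)
        )
        coords[idx, topo.role_index["OH40"], :] = (
            oh32 + d["d_OH32_OH40"][:, None] * _unit_vectors(rng_geom, m)
        )

        # --- beta-1 strand laid collinear at the sampled tilt angle
        if spec.membrane:
            ang_mu, ang_sd, dist_mu, dist_sd = spec.rc[label]
        else:
            ang_mu, ang_sd = spec.rc_angle_solution
            dist_mu = dist_sd = None
        theta = np.clip(rng_geom.normal(ang_mu, ang_sd, size=m), 0.5, 179.5)
        phi = rng_geom.uniform(0.0, 2.0 * np.pi, size=m)
        st = np.sin(np.radians(theta))
        u_beta = np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(np.radians(theta))])
        beta_resids = range(regions.BETA1[0], regions.BETA1[1] + 1)
        beta_idx = np.array([topo.ca_index[r] for r in beta_resids])
        center = template[beta_idx].mean(axis=0)
        for k in range(4):
            coords[idx, beta_idx[k], :] = center + (k - 1.5) * _CA_SPACING * u_beta

        # --- HVR stretch: L184 at the sampled distance from E132
        if spec.membrane:
            dist = _positive_normal(rng_geom, dist_mu, dist_sd, size=m)
            e132 = coords[idx, topo.ca_index[regions.E132], :]
            coords[idx, topo.ca_index[regions.L184], :] = (
                e132 + dist[:, None] * _unit_vectors(rng_geom, m)
            )

    # --- ions: Poisson count in the GTP shell, the rest parked far away
    gtp_idx = np.array(list(topo.gtp_index.values()))
    gtp_pos = template[gtp_idx]
    lam_per_frame = np.array(
        [spec.lam[LABELS[c]] if spec.lam.get(LABELS[c]) is not None else 0.0 for c in state_codes]
    )
    k_shell = np.minimum(rng_ions.poisson(lam_per_frame), _SHELL_CAPACITY)
    far = _unit_vectors(rng_ions, n_frames * topo.n_ions) * (
        25.0 + 10.0 * rng_ions.random(n_frames * topo.n_ions)[:, None]
    )
    coords[:, topo.na_indices, :] = far.reshape(n_frames, topo.n_ions, 3)
    total_shell = int(k_shell.sum())
    if total_shell:
        host = rng_ions.integers(0, len(gtp_idx), size=total_shell)
        radii = _ION_CUTOFF * rng_ions.random(total_shell) ** (1.0 / 3.0)
        pts = gtp_pos[host] + radii[:, None] * _unit_vectors(rng_ions, total_shell)
        frame_of = np.repeat(np.arange(n_frames), k_shell)
        slot_of = np.concatenate([np.arange(k) for k in k_shell if k > 0])
        coords[frame_of, topo.na_indices[slot_of], :] = pts
    return coords


def emit_frame(state: str, spec: SyntheticSpec, rng_geom=None, rng_ions=None) -> np.ndarray:
    """Single-frame convenience wrapper around :func:`emit_frames`."""
    if state not in STATES:
        raise ConfigError(f"unknown state {state!r}")
    rng_geom = np.random.default_rng(rng_geom) if not hasattr(rng_geom, "normal") else rng_geom
    rng_ions = rng_ions if hasattr(rng_ions, "poisson") else rng_geom
    codes = np.array([LABELS.index(state)])
    return emit_frames(codes, spec, rng_geom, rng_ions)[0]


def build_structure(spec: SyntheticSpec) -> Structure:
    """Reference :class:`Structure` (template coordinates) for ``spec``."""
    topo = _Topology(spec)
    return Structure(
        serials=np.arange(1, topo.n_atoms + 1),
        names=topo.names,
        resnames=topo.resnames,
        resids=topo.resids,
        chains=np.full(topo.n_atoms, "A"),
        elements=topo.elements,
        coords=_template_coords(topo),
    )


def generate(spec: SyntheticSpec) -> SyntheticResult:
    """Generate a complete synthetic dataset (deterministic under the seed).

    Three independent seed substreams drive the state sequence, the
    geometry, and the ion placement, so e.g. enabling/adjusting ions never
    perturbs the state sequence.
    """
    ss = np.random.SeedSequence(spec.seed)
    seq_ss, geom_ss, ion_ss = ss.spawn(3)
    rng_states = np.random.default_rng(seq_ss)
    rng_geom = np.random.default_rng(geom_ss)
    rng_ions = np.random.default_rng(ion_ss)

    state_codes = sample_state_sequence(spec.pi, spec.tau, spec.n_frames, rng_states)
    coords = emit_frames(state_codes, spec, rng_geom, rng_ions)
    box = (
        np.array([spec.box_edge, spec.box_edge, spec.box_edge, 90.0, 90.0, 90.0])
        if spec.box_edge
        else None
    )
    traj = Trajectory(
        coords=coords,
        times_ns=np.arange(spec.n_frames) * _FRAME_DT_NS,
        box=box,
    )
    labels = np.asarray(LABELS, dtype=object)[state_codes]
    return SyntheticResult(
        structure=build_structure(spec),
        trajectory=traj,
        truth=SyntheticTruth(labels=labels, spec=spec),
    )


def write_synthetic(result: SyntheticResult, out_dir, traj_format: str = "dcd") -> dict:
    """Write structure PDB + trajectory + truth CSV + generator spec JSON.

    ``traj_format`` is ``"dcd"`` (binary) or ``"pdb"`` (multi-model text).
    The outputs round-trip through :mod:`rasstates.io` and the synthetic
    PDB resolves every atom role.
    """
    import MDAnalysis as mda

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out_dir}: {exc}") from exc
    if traj_format not in {"dcd", "pdb"}:
        raise ConfigError(f"traj_format must be 'dcd' or 'pdb' (got {traj_format!r})")

    spec = result.truth.spec
    topo = _Topology(spec)
    st = result.structure
    n_res_total = len(np.unique(st.resids))
    resindex = np.searchsorted(np.unique(st.resids), st.resids)
    u = mda.Universe.empty(
        n_atoms=st.n_atoms,
        n_residues=n_res_total,
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", st.names)
    u.add_TopologyAttr("elements", st.elements)
    u.add_TopologyAttr("record_types", topo.records)
    res_ids_unique = np.unique(st.resids)
    u.add_TopologyAttr("resids", res_ids_unique)
    first_of_res = np.searchsorted(st.resids, res_ids_unique)
    u.add_TopologyAttr("resnames", st.resnames[first_of_res])
    u.atoms.positions = st.coords

    pdb_path = out_dir / "model.pdb"
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        u.atoms.write(str(pdb_path))

    traj = result.trajectory
    traj_path = out_dir / ("traj.dcd" if traj_format == "dcd" else "traj.pdb")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        with mda.Writer(str(traj_path), n_atoms=st.n_atoms, multiframe=True) as writer:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                if traj.box is not None:
                    u.dimensions = traj.box if np.ndim(traj.box) == 1 else traj.box[f]
                writer.write(u.atoms)

    truth_path = out_dir / "truth.csv"
    with open(truth_path, "w") as fh:
        fh.write("frame,state\n")
        for f, lab in enumerate(result.truth.labels):
            fh.write(f"{f},{lab}\n")

    spec_path = out_dir / "spec.json"
    with open(spec_path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "structure": pdb_path,
        "trajectory": traj_path,
        "truth": truth_path,
        "spec": spec_path,
    }
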