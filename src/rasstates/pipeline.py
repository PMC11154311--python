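"""End-to-end orchestration: synthesize / analyze / compare.

These functions back the command-line interface but are equally usable as
library calls.  ``analyze`` runs the full chain — read inputs, resolve atom
roles, extract features, classify, and compute occupancy, transitions,
per-state RMSF/PCA/DCCM, ion summaries and the membrane reaction-coordinate
histogram — and writes every output with a checksum manifest, so a run is
reproducible and diffable byte-for-byte under a fixed seed and config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, regions
from .classify import (
    LABELS,
    ClassifierConfig,
    classify_series,
    occupancy,
    transitions,
)
from .ensemble import core_fit_indices, cross_correlation, pca, rmsf_by_state
from .errors import ConfigError, DataError
from .features import extract_features, histogram2d, rc_pair
from .io import (
    RoleRules,
    read_structure,
    read_trajectory,
    resolve_roles,
    write_feature_table,
    write_labels_csv,
    write_matrix,
    write_occupancy_json,
)
from .ions import count_series, ion_summary_by_state
from .synthetic import SyntheticSpec, generate, make_scenario, write_synthetic

log = logging.getLogger("rasstates")


@dataclass
class RunConfig:
    """Serializable configuration of an analysis run."""

    structure: str = ""
    trajectory: str = ""
    out_dir: str = "rasstates_out"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    switch_i: tuple[int, int] = regions.SWITCH_I
    switch_ii: tuple[int, int] = regions.SWITCH_II
    fit_on_core: bool = True  # exclude switches from the superposition fit set
    n_modes: int = 10
    min_state_frames: int = 10  # per-state statistics need at least this many
    ion_cutoff: float = 4.5
    membrane_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rc_angle_bins: int = 36
    rc_dist_bins: int = 30
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("classifier"), dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        for key in ("switch_i", "switch_ii", "membrane_normal"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def cmd_synthesize(
    scenario: str,
    n_frames: int,
    out_dir,
    tau: float = 50.0,
    seed: int = 0,
    traj_format: str = "dcd",
    spec: SyntheticSpec | None = None,
) -> dict:
    """Generate a synthetic dataset on disk; returns the written paths."""
    if spec is None:
        spec = make_scenario(scenario, n_frames=n_frames, tau=tau, seed=seed)
    log.info("synthesizing scenario %s: %d frames, tau=%g, seed=%d",
             spec.name, spec.n_frames, spec.tau, spec.seed)
    result = generate(spec)
    paths = write_synthetic(result, out_dir, traj_format=traj_format)
    log.info("wrote %s", ", ".join(str(p) for p in paths.values()))
    return paths


@dataclass
class AnalysisResult:
    """In-memory results of one analysis run plus the files written."""

    features: object
    labels: object
    occupancy: object
    transition_matrix: np.ndarray
    ion_summary: dict | None
    paths: dict[str, Path]


def cmd_analyze(config: RunConfig) -> AnalysisResult:
    """Run the full conformational-state analysis described by ``config``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name):
        log.info("stage: %s", name)

    stage("read inputs")
    structure = read_structure(config.structure)
    roles = resolve_roles(structure, RoleRules())
    traj = read_trajectory(config.trajectory, structure)

    stage("feature extraction")
    feats = extract_features(traj, roles, membrane_normal=config.membrane_normal)

    stage("classification")
    labels = classify_series(feats, config.classifier)
    paths["features"] = write_feature_table(feats, labels, out_dir / "features.csv")
    paths["labels"] = write_labels_csv(labels, out_dir / "labels.csv")

    stage("occupancy and transitions")
    occ = occupancy(labels)
    paths["occupancy"] = write_occupancy_json(occ, out_dir / "occupancy.json")
    tmat = transitions(labels)
    pd.DataFrame(tmat, index=LABELS, columns=LABELS).to_csv(out_dir / "transitions.csv")
    paths["transitions"] = out_dir / "transitions.csv"

    stage("per-state ensemble statistics")
    ca_idx = roles.group("CA_TRACE")
    ca = traj.coords[:, ca_idx, :]
    ca_resids = structure.resids[ca_idx]
    fit_set = (
        core_fit_indices(ca_resids, config.switch_i, config.switch_ii)
        if config.fit_on_core
        else None
    )
    for state in LABELS:
        n_state = int(occ.counts.get(state, 0))
        if n_state < max(2, config.min_state_frames):
            continue
        profile = rmsf_by_state(ca, labels, state, fit_set=fit_set)
        pd.DataFrame(
            {"residue": ca_resids, "rmsf_A": profile.values, "state": state}
        ).to_csv(out_dir / f"rmsf_{state}.csv", index=False)
        paths[f"rmsf_{state}"] = out_dir / f"rmsf_{state}.csv"

        sel = ca[np.asarray(labels.labels) == state]
        res = pca(sel, fit_set=fit_set, n_modes=config.n_modes)
        meta = f"state={state} frames={res.n_frames} fit=core" if config.fit_on_core else (
            f"state={state} frames={res.n_frames} fit=all"
        )
        paths[f"pca_{state}_eigenvalues"] = write_matrix(
            res.eigenvalues[: config.n_modes][:, None],
            out_dir / f"pca_{state}_eigenvalues.txt",
            header=f"{meta} units=A^2 (descending)",
        )
        paths[f"pca_{state}_eigenvectors"] = write_matrix(
            res.eigenvectors,
            out_dir / f"pca_{state}_eigenvectors.txt",
            header=f"{meta} columns=modes rows=3N components",
        )
        pd.DataFrame(
            res.mobility,
            columns=[f"mode{k + 1}_A" for k in range(res.mobility.shape[1])],
        ).assign(residue=ca_resids).to_csv(
            out_dir / f"pca_{state}_mobility.csv", index=False
        )
        paths[f"pca_{state}_mobility"] = out_dir / f"pca_{state}_mobility.csv"

        dccm = cross_correlation(sel, fit_set=fit_set)
        paths[f"dccm_{state}"] = write_matrix(
            dccm.matrix, out_dir / f"dccm_{state}.txt", header=meta
        )

    stage("ion accessibility")
    ion_summary = None
    if roles.has("NA_IONS") and roles.has("GTP_ATOMS"):
        counts = count_series(traj, roles, cutoff=config.ion_cutoff)
        ion_summary = ion_summary_by_state(counts, labels)
        payload = {
            state: {"mean": s.mean, "sd": s.sd, "n": s.n}
            for state, s in ion_summary.items()
        }
        with open(out_dir / "ion_summary.json", "w") as fh:
            json.dump({"cutoff_A": config.ion_cutoff, "per_state": payload}, fh,
                      indent=2, sort_keys=True)
            fh.write("\n")
        paths["ion_summary"] = out_dir / "ion_summary.json"
        pd.DataFrame(
            {
                "frame": np.arange(len(counts)),
                "label": labels.labels,
                "ion_count": counts.counts,
            }
        ).to_csv(out_dir / "ion_counts.csv", index=False)
        paths["ion_counts"] = out_dir / "ion_counts.csv"

    stage("reaction-coordinate histogram")
    if feats.has_rc_dist:
        pairs = rc_pair(feats)
        angle_edges = np.linspace(0.0, 180.0, config.rc_angle_bins + 1)
        dmax = float(np.nanmax(pairs[:, 1])) + 1e-9
        dist_edges = np.linspace(0.0, max(dmax, 1.0), config.rc_dist_bins + 1)
        hist = histogram2d(pairs, angle_edges, dist_edges)
        paths["rc_histogram"] = write_matrix(
            hist.counts,
            out_dir / "rc_histogram.txt",
            header=(
                f"rows=angle bins {angle_edges[0]}..{angle_edges[-1]} deg, "
                f"cols=dist bins {dist_edges[0]:.2f}..{dist_edges[-1]:.2f} A, "
                f"excluded={hist.n_excluded}"
            ),
        )

    stage("manifest")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {
            "structure": str(config.structure),
            "trajectory": str(config.trajectory),
        },
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in paths.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = out_dir / "manifest.json"

    return AnalysisResult(
        features=feats,
        labels=labels,
        occupancy=occ,
        transition_matrix=tmat,
        ion_summary=ion_summary,
        paths=paths,
    )


def cmd_compare(report_a: dict, report_b: dict) -> list[dict]:
    """Per-state occupancy deltas and ratios between two occupancy reports.

    Each report is the dict form of an occupancy JSON.  The ratio B/A is
    reported as ``inf`` (flagged) when a state is absent from A but present
    in B.
    """
    fa = report_a.get("fractions")
    fb = report_b.get("fractions")
    if fa is None or fb is None:
        raise DataError("occupancy reports must contain a 'fractions' mapping")
    if set(fa) != set(fb):
        raise DataError(
            f"mismatched label sets: {sorted(fa)} vs {sorted(fb)}"
        )
    rows = []
    for label in LABELS:
        if label not in fa:
            continue
        a, b = float(fa[label]), float(fb[label])
        if a > 0:
            ratio, flagged = b / a, False
        elif b > 0:
            ratio, flagged = float("inf"), True
        else:
            ratio, flagged = float("nan"), True
        rows.append(
            {
                "label": label,
                "fraction_a": a,
                "fraction_b": b,
                "delta": b - a,
                "ratio_b_over_a": ratio,
                "ratio_flagged": flagged,
            }
        )
    return rows


def format_compare_table(rows: list[dict]) -> str:
    lines = [f"{'state':<11} {'A':>8} {'B':>8} {'delta':>8} {'B/A':>8}"]
    for r in rows:
        ratio = r["ratio_b_over_a"]
        ratio_s = "-" if ratio != ratio else ("inf" if ratio == float("inf") else f"{ratio:.3f}")
        lines.append(
            f"{r['label']:<11} {r['fraction_a']:>8.4f} {r['fraction_b']:>8.4f} "
            f"{r['delta']:>+8.4f} {ratio_s:>8}"
        )
    return "\n".join(lines)
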