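"""Shared fixtures: tiny hand-built PDB files and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from rasstates import synthetic


def pdb_line(
    serial,
    name,
    resname,
    resid,
    x,
    y,
    z,
    record="ATOM",
    chain="A",
    icode=" ",
    element="",
):
    """One fixed-column PDB v3.3 ATOM/HETATM record."""
    return (
        f"{record:<6}{serial:5d} {name:<4} {resname:>3} {chain}{resid:4d}{icode}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}"
    )


def make_pdb(lines, path):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def minimal_ras_pdb(tmp_path):
    """Smallest structure on which every mandatory atom role resolves.

    Calpha trace for residues 1..6 plus the role-carrying residues, one
    GTP, one Mg, two Na ions; 5UHV-style numbering.
    """
    lines = []
    serial = 1

    def add(name, resname, resid, xyz, record="ATOM", element=""):
        nonlocal serial
        lines.append(pdb_line(serial, name, resname, resid, *xyz, record=record, element=element))
        serial += 1

    for resid in range(1, 7):
        add("CA", "ALA", resid, (float(resid), 0.0, float(resid)))
    add("CA", "GLY", 12, (12.0, 0.0, 0.0))
    add("O", "GLY", 12, (12.5, 1.0, 0.0))
    add("CA", "ALA", 18, (18.0, 0.0, 0.0))
    add("O", "ALA", 18, (18.5, 1.0, 0.0))
    add("CA", "TYR", 32, (32.0, 0.0, 0.0))
    add("OH", "TYR", 32, (3.0, 5.0, 0.0))
    add("CA", "THR", 35, (35.0, 0.0, 0.0))
    add("OG1", "THR", 35, (2.0, 0.0, 0.0))
    add("CA", "TYR", 40, (40.0, 0.0, 0.0))
    add("OH", "TYR", 40, (40.5, 1.0, 0.0))
    add("CA", "GLU", 132, (52.0, 0.0, 0.0))
    add("PG", "GTP", 200, (0.0, 3.0, 0.0), record="HETATM", element="P")
    add("O1G", "GTP", 200, (0.0, 2.0, 0.0), record="HETATM", element="O")
    add("O2G", "GTP", 200, (0.9, 3.7, 0.5), record="HETATM", element="O")
    add("O3G", "GTP", 200, (-0.9, 3.7, -0.5), record="HETATM", element="O")
    add("MG", "MG", 201, (0.0, 0.0, 0.0), record="HETATM", element="MG")
    add("NA", "NA", 202, (1.0, 1.0, 1.0), record="HETATM", element="NA")
    add("NA", "NA", 203, (30.0, 30.0, 30.0), record="HETATM", element="NA")
    return make_pdb(lines, tmp_path / "minimal_ras.pdb")


@pytest.fixture
def small_spec():
    """Small solution-WT generator spec for fast unit tests."""
    return synthetic.make_scenario("solution_WT", n_frames=400, tau=20, seed=11)


@pytest.fixture(scope="session")
def membrane_dataset():
    """One in-memory membrane-WT dataset shared across tests (read-only)."""
    spec = synthetic.make_scenario("membrane_WT", n_frames=1500, tau=25, seed=5)
    return synthetic.generate(spec)


def pure_state_spec(state, scenario="solution_WT", n_frames=1000, seed=7, sd=None):
    """Spec emitting a single state, optionally with uniform distance SD."""
    spec = synthetic.make_scenario(scenario, n_frames=n_frames, tau=1.0, seed=seed)
    pi = {s: 0.0 for s in spec.pi}
    pi[state] = 1.0
    distances = spec.distances
    if sd is not None:
        distances = {
            s: {k: (mu, sd) for k, (mu, _) in table.items()}
            for s, table in distances.items()
        }
    return synthetic.SyntheticSpec(
        name=f"pure_{state}",
        pi=pi,
        tau=1.0,
        n_frames=n_frames,
        seed=seed,
        distances=distances,
        lam=spec.lam,
        membrane=spec.membrane,
        genotype=spec.genotype,
        rc=spec.rc,
    )
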