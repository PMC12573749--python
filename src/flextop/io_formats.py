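"""Readers and writers: PDB structures, mol2 screening queries, CSV
frames tables, OpenDX volumetric maps, and the YAML configuration file.

File formats keep their native units (PDB/mol2/DX: Angstrom); internal
state is nm.  The conversion factor is exactly 10.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure.io.pdb as pdb

from .core import NM_TO_ANGSTROM, EnvironmentAtom, TrajectoryFrame
from .dynamics import Trajectory
from .errors import LookupErrorAtom, ParseError
from .gridfield import ScalarField

FRAMES_COLUMNS = ["step", "particle", "x", "y", "z", "q", "sigma", "epsilon"]


def read_structure(
    path: str | Path, parameter_table: dict[str, tuple[float, float, float]]
) -> list[EnvironmentAtom]:
    """Read environment atoms from a PDB file (ATOM/HETATM records).

    ``parameter_table`` maps atom names to (q [e], sigma [nm],
    epsilon [kJ/mol]).  Coordinates are converted from Angstrom to nm.
    Water residues (HOH/WAT/SOL/TIP3) are tagged as solvent.
    """
    path = Path(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        if not pdb_file.lines or not any(
            line.startswith(("ATOM", "HETATM")) for line in pdb_file.lines
        ):
            return []
        structure = pdb_file.get_structure(model=1)
    except Exception as err:  # biotite raises several parse-error types
        raise ParseError(f"malformed PDB file {path}: {err}") from err

    solvent_residues = {"HOH", "WAT", "SOL", "TIP3"}
    atoms: list[EnvironmentAtom] = []
    for i in range(structure.array_length()):
        name = str(structure.atom_name[i])
        if name not in parameter_table:
            raise LookupErrorAtom(
                f"atom {name!r} (index {i}) has no entry in the parameter table"
            )
        q, sigma, epsilon = parameter_table[name]
        atoms.append(
            EnvironmentAtom(
                position=np.asarray(structure.coord[i], dtype=float) / NM_TO_ANGSTROM,
                q=float(q),
                sigma=float(sigma),
                epsilon=float(epsilon),
                solvent=str(structure.res_name[i]) in solvent_residues,
                name=name,
            )
        )
    return atoms


def write_mol2_query(frame: TrajectoryFrame, path: str | Path, name: str = "ft_query") -> None:
    """Write one frame as a TRIPOS mol2 screening query.

    Every particle is exported with the artificial atom type Carbon and
    its current partial charge (USER_CHARGES); the bond section is
    empty, as the particles carry no covalent topology.  Coordinates
    are converted from nm to Angstrom.
    """
    n = len(frame.q)
    pos = frame.positions * NM_TO_ANGSTROM
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{n} 0 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for i in range(n):
        lines.append(
            f"{i + 1:>4} C{i + 1:<3} {pos[i, 0]:>10.4f} {pos[i, 1]:>10.4f} "
            f"{pos[i, 2]:>10.4f} C {1:>2} FTQ {frame.q[i]:>9.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    Path(path).write_text("\n".join(lines) + "\n")


def write_frames_table(trajectory: Trajectory | list[TrajectoryFrame], path: str | Path) -> None:
    """Write a trajectory as a long-form CSV (one row per particle per frame)."""
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else trajectory
    rows = []
    for frame in frames:
        for i in range(len(frame.q)):
            rows.append(
                (
                    frame.step,
                    i,
                    frame.positions[i, 0],
                    frame.positions[i, 1],
                    frame.positions[i, 2],
                    frame.q[i],
                    frame.sigma[i],
                    frame.epsilon[i],
                )
            )
    table = pd.DataFrame(rows, columns=FRAMES_COLUMNS)
    if len(table) and not np.isfinite(table[FRAMES_COLUMNS[2:]].to_numpy()).all():
        raise ValueError("refusing to write non-finite values to the frames table")
    table.to_csv(path, index=False)


def read_frames_table(path: str | Path) -> list[TrajectoryFrame]:
    """Read a frames-table CSV back into TrajectoryFrame objects."""
    try:
        table = pd.read_csv(path)
    except Exception as err:
        raise ParseError(f"cannot parse frames table {path}: {err}") from err
    if list(table.columns) != FRAMES_COLUMNS:
        raise ParseError(
            f"frames table {path} has columns {list(table.columns)}, "
            f"expected {FRAMES_COLUMNS}"
        )
    frames = []
    for step, group in table.groupby("step", sort=True):
        group = group.sort_values("particle")
        frames.append(
            TrajectoryFrame(
                step=int(step),
                positions=group[["x", "y", "z"]].to_numpy(),
                q=group["q"].to_numpy(),
                sigma=group["sigma"].to_numpy(),
                epsilon=group["epsilon"].to_numpy(),
            )
        )
    frames.sort(key=lambda f: f.step)
    return frames


def write_frames_pdb(trajectory: Trajectory | list[TrajectoryFrame], path: str | Path) -> None:
    """Dump FT particles as a multi-model PDB for visualization.

    Each saved frame becomes one MODEL; particles are written as HETATM
    carbon records (residue FTP) with coordinates in Angstrom and the
    partial charge stored in the B-factor column.
    """
    import biotite.structure as struc

    frames = trajectory.frames if isinstance(trajectory, Trajectory) else trajectory
    if not frames:
        raise ValueError("cannot write a PDB dump of an empty trajectory")
    n = len(frames[0].q)
    stack = struc.AtomArrayStack(len(frames), n)
    stack.coord = np.stack([f.positions * NM_TO_ANGSTROM for f in frames])
    stack.chain_id = np.full(n, "A")
    stack.res_id = np.arange(1, n + 1)
    stack.res_name = np.full(n, "FTP")
    stack.atom_name = np.array([f"C{i + 1}" for i in range(n)])
    stack.element = np.full(n, "C")
    stack.hetero = np.full(n, True)
    stack.set_annotation("b_factor", frames[0].q.astype(float))
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def write_opendx(field: ScalarField, path: str | Path, name: str = "flextop field") -> None:
    """Write a scalar field as an OpenDX volumetric file for visualization."""
    nx, ny, nz = field.spec.shape
    d = field.spec.spacing
    ox, oy, oz = field.spec.origin
    buf = io.StringIO()
    buf.write(f"# {name}\n")
    buf.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
    buf.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
    buf.write(f"delta {d:.6f} 0 0\ndelta 0 {d:.6f} 0\ndelta 0 0 {d:.6f}\n")
    buf.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
    buf.write(
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
    )
    flat = field.values.ravel(order="C")
    for i in range(0, len(flat), 3):
        buf.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
    buf.write('attribute "dep" string "positions"\n')
    buf.write('object "regular positions regular connections" class field\n')
    buf.write('component "positions" value 1\n')
    buf.write('component "connections" value 2\n')
    buf.write('component "data" value 3\n')
    Path(path).write_text(buf.getvalue())


DEFAULT_CONFIG = {
    "system": {
        "n_particles": 10,
        "timestep": 0.002,
        "friction": 1.0,
        "temperature": 300.0,
        "seed": 0,
    },
    "forces": {
        "supercharge": 1.5,
        "ft_ft_elec": "physical",
        "ft_ft_lj": True,
        "continuity_cutoff": 0.25,
        "continuity_k": 10000.0,
        "continuity_pairing": "closest",
        "attr_A": 941.5,
        "attr_B": 275.3,
        "attr_C": 200.0,
        "attr_center": 0.3,
        "attr_offset": 0.25,
        "coulomb_constant": 138.935456,
        "centroid_d0": 0.9,
        "centroid_k": 1000.0,
        "charge_target_sum": 0.0,
        "charge_s_max": 0.08,
        "nonbonded_cutoff": None,
    },
    "schedule": {
        "production_temperature": 300.0,
        "heating_steps": 2000,
        "production_steps": 20000,
        "restrained_first_stage": False,
    },
    "output": {
        "save_every": 100,
        "out_dir": "flextop_out",
    },
}


def read_config(path: str | Path) -> dict:
    """Read the sectioned YAML configuration, merged over the defaults."""
    with open(path) as fh:
        try:
            user = yaml.safe_load(fh) or {}
        except yaml.YAMLError as err:
            raise ParseError(f"malformed configuration {path}: {err}") from err
    config = {section: dict(values) for section, values in DEFAULT_CONFIG.items()}
    for section, values in user.items():
        if section not in config:
            raise ParseError(f"unknown configuration section {section!r} in {path}")
        config[section].update(values or {})
    return config


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def force_params_from_config(config: dict):
    """Build a ForceParams block from the ``forces`` config section."""
    from .core import (
        AttrForceParams,
        CentroidRestraintParams,
        ChargeConstraintParams,
        ContinuityParams,
        ForceParams,
    )

    f = config["forces"]
    return ForceParams(
        continuity=ContinuityParams(
            cutoff=f["continuity_cutoff"],
            k=f["continuity_k"],
            pairing=f.get("continuity_pairing", "closest"),
        ),
        attr_force=AttrForceParams(
            A=f["attr_A"],
            B=f["attr_B"],
            C=f["attr_C"],
            center=f.get("attr_center", 0.3),
            offset=f.get("attr_offset", 0.25),
        ),
        coulomb_constant=f.get("coulomb_constant", 138.935456),
        centroid=CentroidRestraintParams(d0=f["centroid_d0"], k=f["centroid_k"]),
        charge_constraint=ChargeConstraintParams(
            target_sum=f["charge_target_sum"], s_max=f["charge_s_max"]
        ),
        supercharge=f["supercharge"],
        ft_ft_elec=f["ft_ft_elec"],
        ft_ft_lj=f["ft_ft_lj"],
        nonbonded_cutoff=f["nonbonded_cutoff"],
    )
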