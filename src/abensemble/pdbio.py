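"""Multi-model PDB reading/writing, role assignment and CSV output.

Reading is backed by Biopython's PDB parser; every model must contain the
same atoms in the same order (one topology, T frames). Writing emits
fixed-width ATOM/HETATM records at standard PDB precision (3 decimals),
so a read-write round trip preserves coordinates to 0.001 Angstrom.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser

from .chemistry import ION_RESNAMES_DEFAULT, WATER_RESNAMES_DEFAULT
from .core import Atom, ConfigurationError, Ensemble, StructureModel


class PDBFormatError(ValueError):
    """The PDB file violates the one-topology/T-frames contract."""


DEFAULT_CONFIG: dict[str, Any] = {
    "chains": {"heavy": "H", "light": "L", "antigen": ["A"]},
    "water_names": list(WATER_RESNAMES_DEFAULT),
    "ion_names": list(ION_RESNAMES_DEFAULT),
    "cdrs": {},
    "criteria": {},
    "seed": 0,
    "stride": 1,
    "bin_width": 10.0,
    "linkage_threshold": 11.0,
    "similarity_threshold": 0.8,
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON configuration and merge it over the defaults."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        user = json.loads(text)
    else:
        user = yaml.safe_load(text)
    if not isinstance(user, Mapping):
        raise ConfigurationError(f"{path}: config must be a mapping")
    cfg = {**DEFAULT_CONFIG, **user}
    cfg["chains"] = {**DEFAULT_CONFIG["chains"], **dict(user.get("chains", {}))}
    return cfg


def assign_roles(
    chain_residue_names: Mapping[str, set[str]], config: Mapping[str, Any]
) -> dict[str, str]:
    """Map each chain id to heavy/light/antigen/water/ion.

    Protein roles come from ``config["chains"]``; remaining chains are
    classified by their residue names against the configured water and ion
    name lists.
    """
    chains_cfg = config.get("chains", {})
    water_names = set(config.get("water_names", WATER_RESNAMES_DEFAULT))
    ion_names = set(config.get("ion_names", ION_RESNAMES_DEFAULT))
    roles: dict[str, str] = {}
    antigen = chains_cfg.get("antigen", [])
    antigen_chains = [antigen] if isinstance(antigen, str) else list(antigen)
    explicit = {}
    for role_name, key in (("heavy", "heavy"), ("light", "light")):
        cid = chains_cfg.get(key)
        if cid is not None:
            explicit[cid] = role_name
    for cid in antigen_chains:
        explicit[cid] = "antigen"
    # chains named in the role map but absent are tolerated: the apo form
    # legitimately lacks the antigen (and usually solvent) chains
    for cid, resnames in chain_residue_names.items():
        if cid in explicit:
            roles[cid] = explicit[cid]
        elif resnames <= water_names:
            roles[cid] = "water"
        elif resnames <= ion_names:
            roles[cid] = "ion"
        elif resnames <= (water_names | ion_names):
            # mixed solvent chain: split impossible at chain level
            raise ConfigurationError(
                f"chain {cid!r} mixes water and ion residues; give them separate chains"
            )
        else:
            raise ConfigurationError(
                f"chain {cid!r} has no role in the config and is not water/ion "
                f"(residues: {sorted(resnames)})"
            )
    return roles


def read_ensemble(path: str | Path, config: Mapping[str, Any] | None = None) -> Ensemble:
    """Read a (multi-)model PDB into an :class:`Ensemble`.

    All models must have identical atom counts and order. Roles are
    assigned from *config*; masses come from standard atomic weights.
    """
    config = {**DEFAULT_CONFIG, **(config or {})}
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    models = list(structure)
    if not models:
        raise PDBFormatError(f"{path}: no models found")

    def model_atoms(m):
        out = []
        for chain in m:
            for residue in chain:
                het, resid, icode = residue.id
                if icode.strip():
                    warnings.warn(
                        f"{path}: insertion code {icode!r} at residue {resid} is "
                        "folded into the preceding residue id",
                        stacklevel=2,
                    )
                for atom in residue:
                    out.append((chain.id, residue.resname.strip(), int(resid), atom))
        return out

    first = model_atoms(models[0])
    n_expected = len(first)
    frames = np.empty((len(models), n_expected, 3), dtype=float)
    for mi, m in enumerate(models):
        rows = first if mi == 0 else model_atoms(m)
        if len(rows) != n_expected:
            raise PDBFormatError(
                f"model {mi + 1}: expected {n_expected} atoms, found {len(rows)}"
            )
        if mi > 0:
            for j, ((c0, r0, i0, a0), (c1, r1, i1, a1)) in enumerate(zip(first, rows)):
                if (c0, r0, i0, a0.get_name()) != (c1, r1, i1, a1.get_name()):
                    raise PDBFormatError(
                        f"model {mi + 1}: atom {j} is "
                        f"{c1}/{r1}{i1}/{a1.get_name()}, expected "
                        f"{c0}/{r0}{i0}/{a0.get_name()}"
                    )
        frames[mi] = [row[3].get_coord() for row in rows]

    atoms: list[Atom] = []
    chain_resnames: dict[str, set[str]] = {}
    for serial, (cid, resname, resid, a) in enumerate(first, start=1):
        element = (a.element or "").strip() or _element_from_name(a.get_name())
        atoms.append(
            Atom(
                serial=serial,
                name=a.get_name(),
                element=element,
                residue_name=resname,
                residue_id=resid,
                chain_id=cid,
            )
        )
        chain_resnames.setdefault(cid, set()).add(resname)
    roles = assign_roles(chain_resnames, config)
    model = StructureModel(atoms=atoms, roles=roles)
    if not model.has_hydrogens():
        warnings.warn(
            f"{path}: structure contains no hydrogen atoms; hydrogen-bond "
            "analysis will refuse it",
            stacklevel=2,
        )
    return Ensemble(model, frames, frame_stride_ps=config.get("frame_stride_ps"))


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if stripped[:1].isdigit():
        stripped = stripped.lstrip("0123456789")
    if stripped.upper() in ("NA", "CL", "MG", "MN", "ZN", "BR"):
        return stripped.upper()
    return stripped[:1].upper()


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ATOM/HETATM/TER/ENDMDL)."""
    model = ensemble.topology
    lines: list[str] = []
    multi = ensemble.n_frames > 1
    for t in range(ensemble.n_frames):
        if multi:
            lines.append(f"MODEL     {t + 1:>4d}")
        prev_chain = None
        for i, atom in enumerate(model.atoms):
            role = model.roles.get(atom.chain_id, "")
            record = "HETATM" if role in ("water", "ion") else "ATOM  "
            if prev_chain is not None and atom.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = atom.chain_id
            x, y, z = ensemble.frames[t, i]
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"{record}{atom.serial % 100000:>5d} {name:<4s} "
                f"{atom.residue_name:>3s} {atom.chain_id:1s}{atom.residue_id % 10000:>4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2s}"
            )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(records: Any, path: str | Path) -> None:
    """Write any tabular result as CSV (header always, floats at 6
    significant digits, deterministic row order)."""
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows and dataclasses.is_dataclass(rows[0]):
            rows = [dataclasses.asdict(r) for r in rows]
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6g")
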