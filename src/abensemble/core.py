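"""Domain types: atoms, structures, ensembles and atom selections.

Coordinates are in Angstrom throughout. Residue ids are taken verbatim
from the source PDB (1-based, possibly non-contiguous). Frames are assumed
pre-wrapped/whole: no periodic-boundary imaging is applied anywhere, and
all distances are direct Euclidean distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chemistry import BACKBONE_ATOMS, element_mass

ROLE_NAMES = ("heavy", "light", "antigen", "water", "ion")

ResidueKey = tuple[str, int]  # (chain_id, residue_id)


class ConfigurationError(ValueError):
    """A role map, selection or criteria configuration is inconsistent."""


@dataclass(frozen=True)
class Atom:
    """A single atom of the topology.

    ``is_hydrogen`` is derived from the element symbol; masses are standard
    atomic weights in Da.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    mass: float = 0.0
    is_hydrogen: bool = False

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): empty element")
        if self.mass == 0.0:
            object.__setattr__(self, "mass", element_mass(self.element))
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")
        object.__setattr__(self, "is_hydrogen", self.element.strip().upper() == "H")


@dataclass
class StructureModel:
    """Topology: an ordered list of atoms plus chain-level role assignments.

    Roles map each chain id to one of ``heavy | light | antigen | water |
    ion``. Atom order is stable and defines the coordinate layout of every
    :class:`Ensemble` frame.
    """

    atoms: list[Atom]
    roles: dict[str, str] = field(default_factory=dict)
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self):
        for chain, role in self.roles.items():
            if role not in ROLE_NAMES:
                raise ConfigurationError(f"chain {chain!r}: unknown role {role!r}")
        self._build_caches()

    def _build_caches(self) -> None:
        self._coords_cache = None
        self._names = np.array([a.name for a in self.atoms])
        self._elements = np.array([a.element.upper() for a in self.atoms])
        self._resnames = np.array([a.residue_name for a in self.atoms])
        self._resids = np.array([a.residue_id for a in self.atoms])
        self._chains = np.array([a.chain_id for a in self.atoms])
        self._is_h = np.array([a.is_hydrogen for a in self.atoms])
        self._masses = np.array([a.mass for a in self.atoms])
        # residues as contiguous runs of atoms
        self._residues: list[tuple[ResidueKey, str, np.ndarray]] = []
        start = 0
        for i in range(1, len(self.atoms) + 1):
            if i == len(self.atoms) or (
                self.atoms[i].chain_id,
                self.atoms[i].residue_id,
            ) != (self.atoms[start].chain_id, self.atoms[start].residue_id):
                a0 = self.atoms[start]
                self._residues.append(
                    ((a0.chain_id, a0.residue_id), a0.residue_name, np.arange(start, i))
                )
                start = i
        seen = {}
        for key, _, idx in self._residues:
            if key in seen:
                raise ValueError(f"residue {key} is not a contiguous run of atoms")
            seen[key] = idx
        self._residue_index = seen

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return self._masses

    @property
    def is_hydrogen(self) -> np.ndarray:
        return self._is_h

    @property
    def residues(self) -> list[tuple[ResidueKey, str, np.ndarray]]:
        """List of ``((chain_id, residue_id), residue_name, atom_indices)``."""
        return self._residues

    def residue_atoms(self, key: ResidueKey) -> np.ndarray:
        return self._residue_index[key]

    def residue_key_of(self, atom_index: int) -> ResidueKey:
        a = self.atoms[atom_index]
        return (a.chain_id, a.residue_id)

    def role_of_chain(self, chain_id: str) -> str:
        try:
            return self.roles[chain_id]
        except KeyError:
            raise ConfigurationError(f"chain {chain_id!r} has no assigned role") from None

    def chains_with_role(self, *wanted: str) -> list[str]:
        return [c for c, r in self.roles.items() if r in wanted]

    def role_indices(self, *wanted: str) -> np.ndarray:
        """Sorted atom indices of every chain whose role is in *wanted*."""
        chains = set(self.chains_with_role(*wanted))
        return np.flatnonzero(np.isin(self._chains, sorted(chains)))

    def has_hydrogens(self) -> bool:
        return bool(self._is_h.any())


@dataclass
class Ensemble:
    """A topology plus T coordinate frames (T x N x 3, Angstrom)."""

    topology: StructureModel
    frames: np.ndarray
    frame_stride_ps: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (T, N, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def subset(self, indices: np.ndarray) -> "Ensemble":
        """New ensemble restricted to *indices* (topology order preserved)."""
        indices = np.asarray(sorted(int(i) for i in indices))
        atoms = [self.topology.atoms[i] for i in indices]
        chains = {a.chain_id for a in atoms}
        roles = {c: r for c, r in self.topology.roles.items() if c in chains}
        model = StructureModel(atoms=atoms, roles=roles)
        return Ensemble(model, self.frames[:, indices, :], self.frame_stride_ps)


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection.

    All stated fields are intersected; ``None`` means "no constraint".
    Residue ids may be given as explicit ids or inclusive ``(lo, hi)``
    ranges. Evaluation is deterministic and returns indices in topology
    order.
    """

    chain_ids: tuple[str, ...] | None = None
    residue_ids: tuple[int, ...] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    residue_names: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None
    heavy_only: bool = False
    roles: tuple[str, ...] | None = None

    @staticmethod
    def backbone(
        chain_ids: Sequence[str] | None = None,
        residue_ranges: Sequence[tuple[int, int]] | None = None,
    ) -> "SelectionSpec":
        """Backbone = {N, CA, C, O}; the convention used for superposition
        and PCA selections."""
        return SelectionSpec(
            chain_ids=tuple(chain_ids) if chain_ids else None,
            residue_ranges=tuple(map(tuple, residue_ranges)) if residue_ranges else None,
            atom_names=BACKBONE_ATOMS,
        )


def select(model: StructureModel, spec: SelectionSpec) -> np.ndarray:
    """Evaluate *spec* on *model*, returning sorted atom indices.

    An empty result is a warning, not an error.
    """
    mask = np.ones(model.n_atoms, dtype=bool)
    if spec.roles is not None:
        chains = set(model.chains_with_role(*spec.roles))
        mask &= np.isin(model._chains, sorted(chains))
    if spec.chain_ids is not None:
        mask &= np.isin(model._chains, list(spec.chain_ids))
    if spec.residue_ids is not None or spec.residue_ranges is not None:
        rmask = np.zeros(model.n_atoms, dtype=bool)
        if spec.residue_ids is not None:
            rmask |= np.isin(model._resids, list(spec.residue_ids))
        if spec.residue_ranges is not None:
            for lo, hi in spec.residue_ranges:
                rmask |= (model._resids >= lo) & (model._resids <= hi)
        mask &= rmask
    if spec.residue_names is not None:
        mask &= np.isin(model._resnames, list(spec.residue_names))
    if spec.atom_names is not None:
        mask &= np.isin(model._names, list(spec.atom_names))
    if spec.heavy_only:
        mask &= ~model._is_h
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {spec} matched no atoms", stacklevel=2)
    return idx


def union_select(model: StructureModel, specs: Iterable[SelectionSpec]) -> np.ndarray:
    """Union of several selections, in topology order."""
    out: set[int] = set()
    for spec in specs:
        out.update(select(model, spec).tolist())
    return np.array(sorted(out), dtype=int)
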