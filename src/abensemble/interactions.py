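"""Geometric detection of interface interactions.

Detects, per frame, the interaction classes of an antibody-antigen
interface: direct hydrogen bonds, salt bridges, cation-pi, pi-stacking,
hydrophobic residue contacts, bridging-water hydrogen bonds, bulk-solvent
hydrogen bonds and ion contacts. All thresholds are inclusive (``<=`` for
distances, closed angle windows) and configurable via
:class:`InteractionCriteria`; the defaults are the standard antibody
interface criteria (heavy-atom interface cutoff 4.5 A, donor-acceptor
3.5 A with a 120-180 deg donor-H-acceptor angle, charged-pair 4.5 A,
ring-centroid cutoffs 6 A, hydrophobic 4.5 A).

Distances are direct Euclidean (input frames are assumed whole, no
periodic imaging). Pair searches use a k-d tree and are exactly
equivalent to an all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .chemistry import (
    AROMATIC_RINGS,
    CATION_PI_ATOMS,
    HYDROPHOBIC_ATOMS,
    NEGATIVE_ATOMS,
    POSITIVE_ATOMS,
)
from .core import Ensemble, ResidueKey, StructureModel

KINDS = (
    "hbond_direct",
    "hbond_bridge",
    "hbond_solvent",
    "salt_bridge",
    "cation_pi",
    "pi_stack",
    "hydrophobic_residue",
    "ion_contact",
)

INTRAMOLECULAR_KINDS = (
    "hbond_direct",
    "salt_bridge",
    "cation_pi",
    "pi_stack",
    "hydrophobic_residue",
)


class MissingHydrogensError(ValueError):
    """Hydrogen-bond analysis requires explicit hydrogens."""


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance and angle thresholds for interaction identification."""

    interface_heavy_cutoff: float = 4.5
    hbond_da_cutoff: float = 3.5
    hbond_angle_range: tuple[float, float] = (120.0, 180.0)
    salt_cutoff: float = 4.5
    cation_pi_cutoff: float = 6.0
    cation_pi_angle_windows: tuple[tuple[float, float], ...] = ((0.0, 60.0), (120.0, 180.0))
    pi_stack_cutoff: float = 6.0
    hydrophobic_cutoff: float = 4.5
    donor_h_max_dist: float = 1.25
    include_his_cations: bool = False

    def __post_init__(self):
        for name in (
            "interface_heavy_cutoff",
            "hbond_da_cutoff",
            "salt_cutoff",
            "cation_pi_cutoff",
            "pi_stack_cutoff",
            "hydrophobic_cutoff",
            "donor_h_max_dist",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for lo, hi in (self.hbond_angle_range,) + self.cation_pi_angle_windows:
            if not (0.0 <= lo <= hi <= 180.0):
                raise ValueError("angle windows must lie within [0, 180]")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected contact: type, participants and measured geometry."""

    frame: int
    kind: str
    atoms: tuple[int, ...]
    residues: tuple[ResidueKey, ...]
    distance: float
    angle: float | None = None


@dataclass
class InteractionSummary:
    """Per-frame interaction counts by kind with their mean and sd."""

    counts: pd.DataFrame  # T rows, one column per kind
    mode: str
    records: list[InteractionRecord] | None = None

    @property
    def means(self) -> pd.Series:
        return self.counts.mean(axis=0)

    @property
    def sds(self) -> pd.Series:
        return self.counts.std(axis=0, ddof=0)


# ---------------------------------------------------------------------------
# geometry helpers


def _pairs_within(coords_a: np.ndarray, idx_a, coords_all, idx_b, cutoff: float):
    """All (i, j) index pairs with ||x_i - x_j|| <= cutoff, i from idx_a,
    j from idx_b. k-d tree backed; identical to an all-pairs scan."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        return []
    tree_b = cKDTree(coords_all[idx_b])
    out = []
    # inclusive threshold under floating point: a pair at exactly the cutoff
    # must be found even when its computed distance rounds up by an ulp
    for k, neigh in enumerate(
        cKDTree(coords_all[idx_a]).query_ball_tree(tree_b, cutoff * (1 + 1e-12) + 1e-9)
    ):
        for m in neigh:
            out.append((int(idx_a[k]), int(idx_b[m])))
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _vector_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _ring_centroid_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit-plane centroid and unit normal (SVD) of ring atoms."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


# ---------------------------------------------------------------------------
# per-structure typing context


@dataclass
class InteractionContext:
    """Precomputed atom typing for one topology.

    Donor-hydrogen association assigns each hydrogen to the nearest N/O/S
    within ``donor_h_max_dist`` (default 1.25 A) in the same residue, so
    no CONECT records are required. Donors are N/O/S atoms with at least
    one associated hydrogen; acceptors are N/O atoms.
    """

    model: StructureModel
    donor_h: list[tuple[int, int]]  # (donor heavy atom, hydrogen)
    acceptors: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    cations: np.ndarray
    rings: list[tuple[ResidueKey, np.ndarray]]
    hydrophobic: np.ndarray
    donors_by_atom: dict[int, list[int]] = field(default_factory=dict)

    @classmethod
    def from_model(
        cls,
        model: StructureModel,
        coords: np.ndarray,
        criteria: InteractionCriteria | None = None,
    ) -> "InteractionContext":
        criteria = criteria or InteractionCriteria()
        names = model._names
        elements = model._elements
        donor_h: list[tuple[int, int]] = []
        acceptors: list[int] = []
        positive: list[int] = []
        negative: list[int] = []
        cations: list[int] = []
        rings: list[tuple[ResidueKey, np.ndarray]] = []
        hydrophobic: list[int] = []
        cation_table = dict(CATION_PI_ATOMS)
        if criteria.include_his_cations:
            cation_table["HIP"] = ("CZ",)  # approximate imidazolium centre
        for key, resname, idx in model.residues:
            res_elements = elements[idx]
            res_names = names[idx]
            heavy_nos = idx[np.isin(res_elements, ("N", "O", "S"))]
            hydrogens = idx[res_elements == "H"]
            for h in hydrogens:
                if heavy_nos.size == 0:
                    continue
                d = np.linalg.norm(coords[heavy_nos] - coords[h], axis=1)
                j = int(np.argmin(d))
                if d[j] <= criteria.donor_h_max_dist:
                    donor_h.append((int(heavy_nos[j]), int(h)))
            acceptors.extend(idx[np.isin(res_elements, ("N", "O"))].tolist())
            for table, bucket in ((POSITIVE_ATOMS, positive), (NEGATIVE_ATOMS, negative)):
                wanted = table.get(resname, ())
                bucket.extend(idx[np.isin(res_names, wanted)].tolist())
            wanted = cation_table.get(resname, ())
            cations.extend(idx[np.isin(res_names, wanted)].tolist())
            for ring_names in AROMATIC_RINGS.get(resname, ()):
                ring_idx = idx[np.isin(res_names, ring_names)]
                if 0 < ring_idx.size < 5:
                    raise ValueError(
                        f"residue {key} {resname}: aromatic ring has only "
                        f"{ring_idx.size} of {len(ring_names)} atoms"
                    )
                if ring_idx.size >= 5:
                    rings.append((key, ring_idx))
            wanted = HYDROPHOBIC_ATOMS.get(resname, ())
            hydrophobic.extend(idx[np.isin(res_names, wanted)].tolist())
        donors_by_atom: dict[int, list[int]] = {}
        for d, h in donor_h:
            donors_by_atom.setdefault(d, []).append(h)
        return cls(
            model=model,
            donor_h=donor_h,
            acceptors=np.array(sorted(acceptors), dtype=int),
            positive=np.array(sorted(positive), dtype=int),
            negative=np.array(sorted(negative), dtype=int),
            cations=np.array(sorted(cations), dtype=int),
            rings=rings,
            hydrophobic=np.array(sorted(hydrophobic), dtype=int),
            donors_by_atom=donors_by_atom,
        )


# ---------------------------------------------------------------------------
# detectors


def define_interface(
    coords: np.ndarray,
    model: StructureModel,
    fv_sel: np.ndarray,
    ag_sel: np.ndarray,
    criteria: InteractionCriteria | None = None,
) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Interface residues: any non-hydrogen atom pair, one from each
    selection, within the heavy-atom cutoff."""
    criteria = criteria or InteractionCriteria()
    fv_sel = np.asarray(fv_sel, dtype=int)
    ag_sel = np.asarray(ag_sel, dtype=int)
    if fv_sel.size == 0 or ag_sel.size == 0:
        raise ValueError("interface definition requires two non-empty selections")
    if np.intersect1d(fv_sel, ag_sel).size:
        raise ValueError("Fv and antigen selections must be disjoint")
    is_h = model.is_hydrogen
    fv_heavy = fv_sel[~is_h[fv_sel]]
    ag_heavy = ag_sel[~is_h[ag_sel]]
    fv_res: set[ResidueKey] = set()
    ag_res: set[ResidueKey] = set()
    for i, j in _pairs_within(coords, fv_heavy, coords, ag_heavy, criteria.interface_heavy_cutoff):
        fv_res.add(model.residue_key_of(i))
        ag_res.add(model.residue_key_of(j))
    return fv_res, ag_res


def _hbonds_directional(
    coords, model, ctx, donor_idx, acceptor_idx, criteria, frame, kind
) -> list[InteractionRecord]:
    """Hydrogen bonds with the donor in donor_idx and the acceptor in
    acceptor_idx: heavy donor-acceptor distance <= cutoff and
    donor-H-acceptor angle inside the closed angle window."""
    donor_set = set(np.asarray(donor_idx, dtype=int).tolist())
    acc_set = set(np.asarray(acceptor_idx, dtype=int).tolist())
    donors = [(d, h) for (d, h) in ctx.donor_h if d in donor_set]
    acceptors = np.array(sorted(acc_set & set(ctx.acceptors.tolist())), dtype=int)
    if not donors or acceptors.size == 0:
        return []
    lo, hi = criteria.hbond_angle_range
    d_atoms = np.array(sorted({d for d, _ in donors}), dtype=int)
    close = _pairs_within(coords, d_atoms, coords, acceptors, criteria.hbond_da_cutoff)
    close_by_donor: dict[int, list[int]] = {}
    for d, a in close:
        close_by_donor.setdefault(d, []).append(a)
    records = []
    for d, h in donors:
        for a in close_by_donor.get(d, []):
            if a == d or model.residue_key_of(a) == model.residue_key_of(d):
                continue
            ang = _angle_deg(coords[d], coords[h], coords[a])
            if lo - 1e-9 <= ang <= hi + 1e-9:
                dist = float(np.linalg.norm(coords[d] - coords[a]))
                records.append(
                    InteractionRecord(
                        frame=frame,
                        kind=kind,
                        atoms=(d, h, a),
                        residues=(model.residue_key_of(d), model.residue_key_of(a)),
                        distance=dist,
                        angle=ang,
                    )
                )
    return records


def detect_hydrogen_bonds(
    coords: np.ndarray,
    model: StructureModel,
    ctx: InteractionContext,
    donor_candidates: np.ndarray,
    acceptor_candidates: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
    kind: str = "hbond_direct",
) -> list[InteractionRecord]:
    """One record per (donor-H, acceptor) pair meeting both criteria.

    Raises :class:`MissingHydrogensError` when the donor candidate set
    contains no associated hydrogens (rather than silently returning
    zero bonds).
    """
    criteria = criteria or InteractionCriteria()
    donor_set = set(np.asarray(donor_candidates, dtype=int).tolist())
    if not any(d in donor_set for d, _ in ctx.donor_h):
        raise MissingHydrogensError(
            "donor candidate set contains no N/O/S atom with an associated hydrogen"
        )
    return _hbonds_directional(
        coords, model, ctx, donor_candidates, acceptor_candidates, criteria, frame, kind
    )


def _hbonds_between(coords, model, ctx, idx_a, idx_b, criteria, frame, kind):
    """Hydrogen bonds in either donor/acceptor direction between two
    disjoint selections."""
    recs = _hbonds_directional(coords, model, ctx, idx_a, idx_b, criteria, frame, kind)
    recs += _hbonds_directional(coords, model, ctx, idx_b, idx_a, criteria, frame, kind)
    return recs


def detect_salt_bridges(
    coords: np.ndarray,
    model: StructureModel,
    ctx: InteractionContext,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Side-chain N/O pairs of oppositely charged residues within the
    salt-bridge cutoff, one selection on each side."""
    criteria = criteria or InteractionCriteria()
    set_a = set(np.asarray(idx_a, dtype=int).tolist())
    set_b = set(np.asarray(idx_b, dtype=int).tolist())
    records = []
    for pos_side, neg_side in ((set_a, set_b), (set_b, set_a)):
        pos = np.array(sorted(set(ctx.positive.tolist()) & pos_side), dtype=int)
        neg = np.array(sorted(set(ctx.negative.tolist()) & neg_side), dtype=int)
        for i, j in _pairs_within(coords, pos, coords, neg, criteria.salt_cutoff):
            records.append(
                InteractionRecord(
                    frame=frame,
                    kind="salt_bridge",
                    atoms=(i, j),
                    residues=(model.residue_key_of(i), model.residue_key_of(j)),
                    distance=float(np.linalg.norm(coords[i] - coords[j])),
                )
            )
    return records


def detect_cation_pi(
    coords: np.ndarray,
    model: StructureModel,
    ctx: InteractionContext,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Cation within the centroid cutoff of an aromatic ring, with the
    centroid->cation vector inside one of the closed angle windows around
    the ring normal. Both cation/ring orientations across the two
    selections are scanned."""
    criteria = criteria or InteractionCriteria()
    set_a = set(np.asarray(idx_a, dtype=int).tolist())
    set_b = set(np.asarray(idx_b, dtype=int).tolist())
    records = []
    for cat_side, ring_side in ((set_a, set_b), (set_b, set_a)):
        cats = [c for c in ctx.cations.tolist() if c in cat_side]
        rings = [(key, ridx) for key, ridx in ctx.rings if set(ridx.tolist()) <= ring_side]
        for c in cats:
            for key, ridx in rings:
                centroid, normal = _ring_centroid_normal(coords[ridx])
                dist = float(np.linalg.norm(coords[c] - centroid))
                if dist > criteria.cation_pi_cutoff:
                    continue
                ang = _vector_angle_deg(coords[c] - centroid, normal)
                if any(
                    lo - 1e-9 <= ang <= hi + 1e-9
                    for lo, hi in criteria.cation_pi_angle_windows
                ):
                    records.append(
                        InteractionRecord(
                            frame=frame,
                            kind="cation_pi",
                            atoms=(c,) + tuple(ridx.tolist()),
                            residues=(model.residue_key_of(c), key),
                            distance=dist,
                            angle=ang,
                        )
                    )
    return records


def detect_pi_stacking(
    coords: np.ndarray,
    model: StructureModel,
    ctx: InteractionContext,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Ring pairs across the two selections with centroid-centroid
    distance within the cutoff. Distance-only: no angle criterion is
    applied."""
    criteria = criteria or InteractionCriteria()
    set_a = set(np.asarray(idx_a, dtype=int).tolist())
    set_b = set(np.asarray(idx_b, dtype=int).tolist())
    rings_a = [(key, r) for key, r in ctx.rings if set(r.tolist()) <= set_a]
    rings_b = [(key, r) for key, r in ctx.rings if set(r.tolist()) <= set_b]
    records = []
    for key_a, ra in rings_a:
        ca = coords[ra].mean(axis=0)
        for key_b, rb in rings_b:
            if key_a == key_b and set(ra.tolist()) == set(rb.tolist()):
                continue
            cb = coords[rb].mean(axis=0)
            dist = float(np.linalg.norm(ca - cb))
            if dist <= criteria.pi_stack_cutoff:
                records.append(
                    InteractionRecord(
                        frame=frame,
                        kind="pi_stack",
                        atoms=tuple(ra.tolist()) + tuple(rb.tolist()),
                        residues=(key_a, key_b),
                        distance=dist,
                    )
                )
    return records


def detect_hydrophobic(
    coords: np.ndarray,
    model: StructureModel,
    ctx: InteractionContext,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Hydrophobic contacts counted by residue pair: one record per
    residue pair with at least one qualifying atom pair within the
    cutoff (atom-level multiplicities collapsed)."""
    criteria = criteria or InteractionCriteria()
    set_a = set(np.asarray(idx_a, dtype=int).tolist())
    set_b = set(np.asarray(idx_b, dtype=int).tolist())
    hyd = set(ctx.hydrophobic.tolist())
    ha = np.array(sorted(hyd & set_a), dtype=int)
    hb = np.array(sorted(hyd & set_b), dtype=int)
    best: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for i, j in _pairs_within(coords, ha, coords, hb, criteria.hydrophobic_cutoff):
        ra, rb = model.residue_key_of(i), model.residue_key_of(j)
        if ra == rb:
            continue
        pair = (ra, rb) if (ra <= rb) else (rb, ra)
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        if pair not in best or dist < best[pair]:
            best[pair] = dist
    return [
        InteractionRecord(frame=frame, kind="hydrophobic_residue", atoms=(), residues=pair, distance=d)
        for pair, d in sorted(best.items())
    ]


def detect_bridging_waters(
    coords: np.ndarray,
    model: StructureModel,
    ctx: InteractionContext,
    fv_sel: np.ndarray,
    ag_sel: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> tuple[list[InteractionRecord], set[ResidueKey]]:
    """First-order bridging waters and their antibody-side hydrogen bonds.

    A water bridges when, in the same frame, it forms at least one
    hydrogen bond (either donor/acceptor direction) to the Fv selection
    and at least one to the antigen selection. Returns one
    ``hbond_bridge`` record per antibody-side hydrogen bond through a
    bridging water, plus the set of bridging water residue keys.
    Water-to-water chains are not followed (first order only).
    """
    criteria = criteria or InteractionCriteria()
    water_idx = model.role_indices("water")
    records: list[InteractionRecord] = []
    bridging: set[ResidueKey] = set()
    if water_idx.size == 0:
        return records, bridging
    water_keys = {model.residue_key_of(int(i)) for i in water_idx}
    for key in sorted(water_keys):
        widx = model.residue_atoms(key)
        fv_bonds = _hbonds_between(coords, model, ctx, widx, fv_sel, criteria, frame, "hbond_bridge")
        if not fv_bonds:
            continue
        ag_bonds = _hbonds_between(coords, model, ctx, widx, ag_sel, criteria, frame, "hbond_bridge")
        if ag_bonds:
            bridging.add(key)
            records.extend(fv_bonds)
    return records, bridging


def detect_solvent_hbonds(
    coords: np.ndarray,
    model: StructureModel,
    ctx: InteractionContext,
    fv_sel: np.ndarray,
    exclude_waters: set[ResidueKey],
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Hydrogen bonds between the Fv selection and non-bridging (bulk)
    waters."""
    criteria = criteria or InteractionCriteria()
    water_idx = model.role_indices("water")
    keep = np.array(
        [i for i in water_idx.tolist() if model.residue_key_of(i) not in exclude_waters],
        dtype=int,
    )
    if keep.size == 0:
        return []
    return _hbonds_between(coords, model, ctx, fv_sel, keep, criteria, frame, "hbond_solvent")


def detect_ion_contacts(
    coords: np.ndarray,
    model: StructureModel,
    ctx: InteractionContext,
    fv_sel: np.ndarray,
    ion_sel: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> list[InteractionRecord]:
    """Ion contacts: any (ion, Fv nitrogen/oxygen) pair within the
    salt-bridge cutoff."""
    criteria = criteria or InteractionCriteria()
    fv_sel = np.asarray(fv_sel, dtype=int)
    ion_sel = np.asarray(ion_sel, dtype=int)
    fv_no = fv_sel[np.isin(model._elements[fv_sel], ("N", "O"))]
    records = []
    for i, j in _pairs_within(coords, ion_sel, coords, fv_no, criteria.salt_cutoff):
        records.append(
            InteractionRecord(
                frame=frame,
                kind="ion_contact",
                atoms=(i, j),
                residues=(model.residue_key_of(i), model.residue_key_of(j)),
                distance=float(np.linalg.norm(coords[i] - coords[j])),
            )
        )
    return records


def count_intramolecular(
    coords: np.ndarray,
    model: StructureModel,
    ctx: InteractionContext,
    sel: np.ndarray,
    criteria: InteractionCriteria | None = None,
    frame: int = 0,
) -> dict[str, int]:
    """All interaction kinds evaluated within one molecule.

    Sequence-adjacent residue pairs (i+1, i+2, i+3) are included; only
    same-residue pairs are excluded (every detector already does so).
    """
    criteria = criteria or InteractionCriteria()
    sel = np.asarray(sel, dtype=int)
    recs: list[InteractionRecord] = []
    recs += _hbonds_directional(coords, model, ctx, sel, sel, criteria, frame, "hbond_direct")
    # within one selection the two-sided scans double-count unordered pairs
    salt = detect_salt_bridges(coords, model, ctx, sel, sel, criteria, frame)
    seen = set()
    for r in salt:
        key = tuple(sorted(r.atoms))
        if key not in seen:
            seen.add(key)
            recs.append(r)
    cpi = detect_cation_pi(coords, model, ctx, sel, sel, criteria, frame)
    seen = set()
    for r in cpi:
        key = tuple(sorted(r.atoms))
        if key not in seen:
            seen.add(key)
            recs.append(r)
    pis = detect_pi_stacking(coords, model, ctx, sel, sel, criteria, frame)
    seen = set()
    for r in pis:
        key = tuple(sorted(r.residues)) + tuple(sorted(r.atoms))
        if key not in seen:
            seen.add(key)
            recs.append(r)
    recs += detect_hydrophobic(coords, model, ctx, sel, sel, criteria, frame)
    counts = {k: 0 for k in INTRAMOLECULAR_KINDS}
    for r in recs:
        counts[r.kind] += 1
    return counts


# ---------------------------------------------------------------------------
# trajectory summaries


def summarize_trajectory(
    ensemble: Ensemble,
    mode: str = "fluctuating_interface",
    reference_interface: tuple[set[ResidueKey], set[ResidueKey]] | None = None,
    criteria: InteractionCriteria | None = None,
    keep_records: bool = False,
) -> InteractionSummary:
    """Count every intermolecular interaction class per frame.

    ``fixed_interface`` restricts all detectors to a reference residue
    selection (typically derived from a crystal structure) and requires
    *reference_interface*; ``fluctuating_interface`` scans the full
    cross-molecule atom set every frame, so all interactions are captured
    as the system fluctuates. Bulk-solvent hydrogen bonds are counted for
    the antibody interface residues (reference set in fixed mode,
    recomputed per frame in fluctuating mode), including their hydrogens.
    """
    if mode not in ("fixed_interface", "fluctuating_interface"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fixed_interface" and reference_interface is None:
        raise ValueError("fixed_interface mode requires reference_interface")
    model = ensemble.topology
    criteria = criteria or InteractionCriteria()
    if not model.has_hydrogens():
        raise MissingHydrogensError(
            "structure has no hydrogen atoms; hydrogen-bond analysis requires "
            "explicit hydrogens"
        )
    ctx = InteractionContext.from_model(model, ensemble.frames[0], criteria)
    fv_all = model.role_indices("heavy", "light")
    ag_all = model.role_indices("antigen")
    ion_idx = model.role_indices("ion")
    if fv_all.size == 0 or ag_all.size == 0:
        raise ValueError("trajectory summary requires Fv and antigen selections")

    def atoms_of_residues(keys: Iterable[ResidueKey]) -> np.ndarray:
        out: list[int] = []
        for key in keys:
            out.extend(model.residue_atoms(key).tolist())
        return np.array(sorted(out), dtype=int)

    if mode == "fixed_interface":
        fv_ref, ag_ref = reference_interface
        fv_det = atoms_of_residues(fv_ref)
        ag_det = atoms_of_residues(ag_ref)
    rows = []
    all_records: list[InteractionRecord] = []
    for t in range(ensemble.n_frames):
        coords = ensemble.frames[t]
        if mode == "fluctuating_interface":
            fv_det, ag_det = fv_all, ag_all
            fv_int_res, _ = define_interface(coords, model, fv_all, ag_all, criteria)
            fv_solvent = atoms_of_residues(fv_int_res)
        else:
            fv_solvent = fv_det
        recs: list[InteractionRecord] = []
        recs += _hbonds_between(coords, model, ctx, fv_det, ag_det, criteria, t, "hbond_direct")
        recs += detect_salt_bridges(coords, model, ctx, fv_det, ag_det, criteria, t)
        recs += detect_cation_pi(coords, model, ctx, fv_det, ag_det, criteria, t)
        recs += detect_pi_stacking(coords, model, ctx, fv_det, ag_det, criteria, t)
        recs += detect_hydrophobic(coords, model, ctx, fv_det, ag_det, criteria, t)
        bridge_recs, bridging = detect_bridging_waters(
            coords, model, ctx, fv_det, ag_det, criteria, t
        )
        recs += bridge_recs
        recs += detect_solvent_hbonds(coords, model, ctx, fv_solvent, bridging, criteria, t)
        if ion_idx.size:
            recs += detect_ion_contacts(coords, model, ctx, fv_all, ion_idx, criteria, t)
        row = {k: 0 for k in KINDS}
        for r in recs:
            row[r.kind] += 1
        rows.append(row)
        if keep_records:
            all_records.extend(recs)
    counts = pd.DataFrame(rows, columns=list(KINDS))
    return InteractionSummary(counts=counts, mode=mode, records=all_records if keep_records else None)


def nonsolvent_fraction(summary: InteractionSummary) -> dict[str, float]:
    """Percentages of intermolecular interactions not formed with bulk
    solvent, from per-kind mean counts.

    Returns ``nonsolvent_pct`` (all kinds minus bulk-solvent hydrogen
    bonds, over the total including them; bridging waters count as
    intermolecular), ``nonsolvent_nonhydrophobic_pct`` (additionally
    excluding hydrophobic residue contacts) and ``hydrophobic_pct``.
    """
    means = summary.means
    total = float(means.sum())
    if total <= 0:
        raise ValueError("no interactions detected; percentage undefined")
    solvent = float(means["hbond_solvent"])
    hydrophobic = float(means["hydrophobic_residue"])
    return {
        "nonsolvent_pct": 100.0 * (total - solvent) / total,
        "nonsolvent_nonhydrophobic_pct": 100.0 * (total - solvent - hydrophobic) / total,
        "hydrophobic_pct": 100.0 * hydrophobic / total,
        "total_mean_interactions": total,
    }
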