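"""Per-CDR dihedral-state analysis.

A CDR's backbone phi/psi time series is histogrammed per dihedral on a
circular grid; bins holding at least 1.5% of frames form peaks
(circularly contiguous super-threshold runs), and the joint vector of
per-dihedral peak labels defines a conformational state. States
populated for less than 1% of the trajectory, together with all frames
falling in sub-threshold bins, are pooled into a rare fraction. Kept
states are compared by circular similarity (1 = identical mean torsions,
0 = all torsions opposed by 180 deg); apo/holo states with similarity
>= 0.8 are considered the same conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Ensemble


@dataclass
class TorsionSeries:
    """Backbone torsion time series for one CDR: T frames x D dihedrals,
    degrees in (-180, 180]."""

    cdr_id: str
    labels: tuple[tuple[int, str], ...]  # (residue_id, "phi" | "psi")
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise ValueError("values must be (T, D) matching the labels")
        if ((self.values <= -180.0) | (self.values > 180.0)).any():
            raise ValueError("torsions must lie in (-180, 180]")


@dataclass
class DihedralState:
    """One CDR conformation: per-dihedral circular-mean torsions plus the
    fraction of frames it occupies."""

    means: np.ndarray  # degrees, per dihedral
    population: float
    member_frames: np.ndarray
    labels: tuple[tuple[int, str], ...] = ()


@dataclass
class StateSet:
    """Kept dihedral states of one trajectory plus the rare fraction."""

    cdr_id: str
    states: list[DihedralState]
    rare_fraction: float
    peak_bin_fraction: float = 0.015
    rare_state_fraction: float = 0.01
    bin_width: float = 10.0
    labels: tuple[tuple[int, str], ...] = ()

    @property
    def n_states(self) -> int:
        return len(self.states)

    def check_partition(self, tol: float = 1e-9) -> None:
        total = sum(s.population for s in self.states) + self.rare_fraction
        if abs(total - 1.0) > tol:
            raise AssertionError(f"populations + rare_fraction = {total}, not 1")


@dataclass
class MatchReport:
    """Apo/holo state correspondence by circular similarity."""

    similarity: np.ndarray  # apo states x holo states, in [0, 1]
    matched: list[tuple[int, int, float]]
    apo_unique: int
    holo_unique: int
    matched_population_apo: float
    matched_population_holo: float
    threshold: float = 0.8


# ---------------------------------------------------------------------------


def _wrap_deg(angles: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    wrapped = np.mod(np.asarray(angles, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def circular_mean_deg(values: np.ndarray) -> float:
    """Circular mean of angles in degrees, in (-180, 180]."""
    rad = np.radians(values)
    mean = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    return float(_wrap_deg(mean))


def dihedral_angles(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral of the four atom positions (arrays broadcast over
    frames), IUPAC sign convention, degrees in (-180, 180].

    Raises for degenerate (collinear) geometry where the torsion is
    undefined.
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if (np.linalg.norm(n1, axis=-1) < 1e-10).any() or (
        np.linalg.norm(n2, axis=-1) < 1e-10
    ).any():
        raise ValueError("dihedral undefined: three consecutive atoms are collinear")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    # sign flipped so that the result follows the IUPAC convention
    # (positive = clockwise looking from atom 2 to atom 3)
    return _wrap_deg(-np.degrees(np.arctan2(y, x)))


def compute_backbone_torsions(
    ensemble: Ensemble,
    chain_id: str,
    residue_range: tuple[int, int],
    cdr_id: str = "",
    include_flanking: bool = True,
) -> TorsionSeries:
    """phi/psi time series for the residues of one loop.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    The first residue's phi and the last residue's psi use flanking
    framework residues when present, otherwise those dihedrals are
    dropped.
    """
    model = ensemble.topology
    lo, hi = residue_range

    def backbone_atom(resid: int, name: str, required: bool) -> int | None:
        try:
            idx = model.residue_atoms((chain_id, resid))
        except KeyError:
            if required:
                raise ValueError(f"residue {chain_id}/{resid} missing from structure")
            return None
        hits = idx[model._names[idx] == name]
        if hits.size == 0:
            if required:
                raise ValueError(f"residue {chain_id}/{resid}: missing backbone atom {name}")
            return None
        return int(hits[0])

    labels: list[tuple[int, str]] = []
    quads: list[tuple[int, int, int, int]] = []
    for resid in range(lo, hi + 1):
        n = backbone_atom(resid, "N", required=True)
        ca = backbone_atom(resid, "CA", required=True)
        c = backbone_atom(resid, "C", required=True)
        if resid > lo:
            c_prev = backbone_atom(resid - 1, "C", required=True)
        elif include_flanking:
            c_prev = backbone_atom(resid - 1, "C", required=False)
        else:
            c_prev = None
        if c_prev is not None:
            labels.append((resid, "phi"))
            quads.append((c_prev, n, ca, c))
        if resid < hi:
            n_next = backbone_atom(resid + 1, "N", required=True)
        elif include_flanking:
            n_next = backbone_atom(resid + 1, "N", required=False)
        else:
            n_next = None
        if n_next is not None:
            labels.append((resid, "psi"))
            quads.append((n, ca, c, n_next))
    frames = ensemble.frames
    values = np.empty((frames.shape[0], len(quads)))
    for d, (i0, i1, i2, i3) in enumerate(quads):
        values[:, d] = dihedral_angles(
            frames[:, i0], frames[:, i1], frames[:, i2], frames[:, i3]
        )
    return TorsionSeries(cdr_id=cdr_id or f"{chain_id}{lo}-{hi}", labels=tuple(labels), values=values)


# ---------------------------------------------------------------------------


def _peak_labels_per_dihedral(
    values: np.ndarray, peak_bin_fraction: float, bin_width: float
) -> np.ndarray:
    """Assign each frame a peak label for one dihedral; -1 = noise
    (sub-threshold bin). Peaks are maximal circularly contiguous runs of
    bins each holding >= peak_bin_fraction of frames."""
    n_bins = round(360.0 / bin_width)
    T = values.shape[0]
    bin_idx = np.floor((values + 180.0) / bin_width).astype(int) % n_bins
    counts = np.bincount(bin_idx, minlength=n_bins)
    super_threshold = counts >= peak_bin_fraction * T
    peak_of_bin = np.full(n_bins, -1, dtype=int)
    if super_threshold.all():
        peak_of_bin[:] = 0
    else:
        label = -1
        prev = False
        for b in range(n_bins):
            if super_threshold[b]:
                if not prev:
                    label += 1
                peak_of_bin[b] = label
            prev = super_threshold[b]
        # circular contiguity: merge a run crossing the -180/180 seam
        if super_threshold[0] and super_threshold[-1] and label > 0:
            first = peak_of_bin[0]
            last = peak_of_bin[-1]
            peak_of_bin[peak_of_bin == last] = first
    return peak_of_bin[bin_idx]


def build_states(
    series: TorsionSeries,
    peak_bin_fraction: float = 0.015,
    rare_state_fraction: float = 0.01,
    bin_width: float = 10.0,
) -> StateSet:
    """Histogram-peak state construction for one CDR.

    Each frame receives a per-dihedral peak label; a state is a realized
    joint label vector with no noise labels. States below the rare-state
    threshold and all noise-containing frames pool into
    ``rare_fraction``.
    """
    if abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 360")
    T, D = series.values.shape
    if T < 100:
        raise ValueError("state construction needs at least 100 frames")
    frame_labels = np.column_stack(
        [
            _peak_labels_per_dihedral(series.values[:, d], peak_bin_fraction, bin_width)
            for d in range(D)
        ]
    )
    clean = (frame_labels >= 0).all(axis=1)
    states: list[DihedralState] = []
    if clean.any():
        keys, inverse = np.unique(frame_labels[clean], axis=0, return_inverse=True)
        clean_frames = np.flatnonzero(clean)
        for k in range(keys.shape[0]):
            members = clean_frames[inverse == k]
            pop = members.size / T
            if pop < rare_state_fraction:
                continue
            means = np.array(
                [circular_mean_deg(series.values[members, d]) for d in range(D)]
            )
            states.append(
                DihedralState(
                    means=means,
                    population=pop,
                    member_frames=members,
                    labels=series.labels,
                )
            )
    states.sort(key=lambda s: (-s.population, tuple(s.means)))
    rare = 1.0 - sum(s.population for s in states)
    out = StateSet(
        cdr_id=series.cdr_id,
        states=states,
        rare_fraction=rare,
        peak_bin_fraction=peak_bin_fraction,
        rare_state_fraction=rare_state_fraction,
        bin_width=bin_width,
        labels=series.labels,
    )
    out.check_partition()
    return out


def circular_similarity(
    a: DihedralState, b: DihedralState, aggregation: str = "mean"
) -> float:
    """Circular similarity of two states' mean torsions.

    Per dihedral, the circular absolute difference (in [0, 180]) is
    normalized to a score 1 - delta/180; the state score aggregates over
    dihedrals (arithmetic mean by default, ``aggregation="min"`` for the
    strictest-dihedral variant): 1 for identical means, 0 when every
    dihedral is opposed by 180 deg. Invariant to adding multiples of
    360 deg to any angle.
    """
    if a.labels and b.labels and a.labels != b.labels:
        raise ValueError("states are defined over different dihedrals")
    da = np.asarray(a.means, dtype=float)
    db = np.asarray(b.means, dtype=float)
    if da.shape != db.shape:
        raise ValueError("states have different numbers of dihedrals")
    delta = np.abs(_wrap_deg(da - db))  # circular difference in [0, 180]
    scores = 1.0 - delta / 180.0
    if aggregation == "mean":
        return float(np.mean(scores))
    if aggregation == "min":
        return float(np.min(scores))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def match_states(apo: StateSet, holo: StateSet, threshold: float = 0.8) -> MatchReport:
    """Greedy one-to-one apo/holo state matching in descending similarity
    order; pairs at or above the threshold count as the same
    conformation."""
    if apo.labels and holo.labels and apo.labels != holo.labels:
        raise ValueError("state sets are defined over different dihedrals")
    na, nh = len(apo.states), len(holo.states)
    sim = np.zeros((na, nh))
    for i, sa in enumerate(apo.states):
        for j, sh in enumerate(holo.states):
            sim[i, j] = circular_similarity(sa, sh)
    order = sorted(
        ((i, j) for i in range(na) for j in range(nh)),
        key=lambda ij: (-sim[ij], ij[0], ij[1]),
    )
    used_a: set[int] = set()
    used_h: set[int] = set()
    matched: list[tuple[int, int, float]] = []
    for i, j in order:
        if sim[i, j] < threshold:
            break
        if i in used_a or j in used_h:
            continue
        used_a.add(i)
        used_h.add(j)
        matched.append((i, j, float(sim[i, j])))
    return MatchReport(
        similarity=sim,
        matched=matched,
        apo_unique=na - len(used_a),
        holo_unique=nh - len(used_h),
        matched_population_apo=sum(apo.states[i].population for i, _, _ in matched),
        matched_population_holo=sum(holo.states[j].population for _, j, _ in matched),
        threshold=threshold,
    )


def compare_sampling(apo: StateSet, holo: StateSet, tolerance: int = 0) -> str:
    """Classify a CDR by kept-state counts: ``more_apo`` when the apo
    trajectory has more states than the holo one (beyond *tolerance*),
    ``more_holo`` for the reverse, else ``equal``."""
    diff = apo.n_states - holo.n_states
    if diff > tolerance:
        return "more_apo"
    if diff < -tolerance:
        return "more_holo"
    return "equal"
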