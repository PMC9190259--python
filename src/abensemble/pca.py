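"""Cartesian-space CDR sampling: superposition, mass-weighted PCA,
average-linkage clustering and the DRES ensemble-overlap score.

Apo and holo ensembles are superposed on the V_H/V_L interface backbone,
a shared PCA basis is fitted on the concatenated mass-weighted CDR
backbone coordinates, and each ensemble's frames are projected onto the
first three principal components. Conformations are flat clusters of an
average-linkage dendrogram cut at a Euclidean distance threshold
(default 11, in mass-weighted-Angstrom PC units: coordinates are scaled
by sqrt(mass) before the covariance, so PC distances carry sqrt(Da)*A
units). Ensemble overlap is the Jensen-Shannon divergence between
Gaussian kernel density estimates of the two projected ensembles,
ranging 0 (identical) to ln 2 (no overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import gaussian_kde

from .core import Ensemble

LN2 = float(np.log(2.0))


@dataclass
class PCAModel:
    """Mass-weighted PCA of CDR backbone coordinates."""

    mean: np.ndarray  # 3n-dim mass-weighted mean structure
    eigenvectors: np.ndarray  # (3n, k) orthonormal columns, descending
    eigenvalues: np.ndarray  # descending, >= 0
    atom_indices: np.ndarray
    sqrt_masses: np.ndarray  # per atom

    @property
    def variance_explained(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues * 0.0


@dataclass
class Projection:
    """Frames of one ensemble in PC space."""

    source: str  # "apo" | "holo"
    coordinates: np.ndarray  # (T, k)
    rmsd_to_reference: np.ndarray | None = None  # (T,) Angstrom


@dataclass
class ClusterResult:
    labels: np.ndarray  # (T,) dense in [0, n_clusters)
    n_clusters: int
    threshold: float
    linkage: str = "average"
    metric: str = "euclidean"


@dataclass
class DRESScore:
    value: float  # nats, in [0, ln 2]
    n_samples: int
    bandwidth_rule: str
    seed: int


# ---------------------------------------------------------------------------


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det = +1) aligning centred *mobile* onto
    centred *reference* in the least-squares sense."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    return u @ flip @ vt


def superpose(
    ensemble: Ensemble,
    reference_coords: np.ndarray,
    align_sel: np.ndarray,
) -> Ensemble:
    """Rigid-body least-squares fit of every frame onto the reference over
    the alignment selection (all atoms are moved; only align_sel drives
    the fit). Reflections are rejected: rotations are proper."""
    align_sel = np.asarray(align_sel, dtype=int)
    if align_sel.size < 3:
        raise ValueError("superposition needs at least 3 alignment atoms")
    ref = reference_coords[align_sel]
    ref_centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(ref_centered, tol=1e-8) < 2:
        raise ValueError("alignment selection is degenerate (collinear atoms)")
    ref_mean = ref.mean(axis=0)
    out = np.empty_like(ensemble.frames)
    for t in range(ensemble.n_frames):
        frame = ensemble.frames[t]
        mob = frame[align_sel]
        mob_mean = mob.mean(axis=0)
        rot = kabsch_rotation(mob - mob_mean, ref_centered)
        out[t] = (frame - mob_mean) @ rot + ref_mean
    return Ensemble(ensemble.topology, out, ensemble.frame_stride_ps)


def fit_pca(
    apo: Ensemble,
    holo: Ensemble,
    cdr_sel: np.ndarray,
    masses: np.ndarray | None = None,
    cdr_sel_holo: np.ndarray | None = None,
) -> PCAModel:
    """Shared PCA basis from the concatenated (apo then holo) aligned
    frames: coordinates are weighted by sqrt(mass) per atom before the
    covariance is formed and diagonalized.

    When the two ensembles index the same atoms differently (e.g. the
    apo form is an Fv-only subset), pass the holo indices separately;
    the two selections must describe the same atoms (checked by mass).
    """
    cdr_sel = np.asarray(cdr_sel, dtype=int)
    cdr_sel_h = cdr_sel if cdr_sel_holo is None else np.asarray(cdr_sel_holo, dtype=int)
    if cdr_sel.size != cdr_sel_h.size:
        raise ValueError("apo and holo CDR selections differ in size")
    if not np.allclose(
        apo.topology.masses[cdr_sel], holo.topology.masses[cdr_sel_h]
    ):
        raise ValueError("apo and holo CDR selections are not the same atoms")
    total_frames = apo.n_frames + holo.n_frames
    if total_frames < 4:
        raise ValueError("PCA needs at least 4 frames in total")
    if masses is None:
        masses = apo.topology.masses[cdr_sel]
    sqrt_m = np.sqrt(np.asarray(masses, dtype=float))
    x = np.concatenate([apo.frames[:, cdr_sel, :], holo.frames[:, cdr_sel_h, :]], axis=0)
    xw = (x * sqrt_m[None, :, None]).reshape(total_frames, -1)
    mean = xw.mean(axis=0)
    cov = np.cov(xw - mean, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCAModel(
        mean=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        atom_indices=cdr_sel,
        sqrt_masses=sqrt_m,
    )


def project(
    model: PCAModel,
    ensemble: Ensemble,
    first_k: int = 3,
    source: str = "",
    reference_coords: np.ndarray | None = None,
    sel: np.ndarray | None = None,
) -> Projection:
    """Project an ensemble's mass-weighted CDR coordinates onto the first
    *k* principal components; optionally attach the per-frame CDR RMSD to
    a reference structure. *sel* overrides the fitting selection when
    this ensemble indexes the same atoms differently."""
    if first_k > model.eigenvectors.shape[1]:
        raise ValueError(
            f"requested {first_k} components, model has {model.eigenvectors.shape[1]}"
        )
    sel = model.atom_indices if sel is None else np.asarray(sel, dtype=int)
    xw = (ensemble.frames[:, sel, :] * model.sqrt_masses[None, :, None]).reshape(
        ensemble.n_frames, -1
    )
    coords = (xw - model.mean) @ model.eigenvectors[:, :first_k]
    rmsd = None
    if reference_coords is not None:
        diff = ensemble.frames[:, sel, :] - reference_coords[sel][None]
        rmsd = np.sqrt((diff**2).sum(axis=2).mean(axis=1))
    return Projection(source=source, coordinates=coords, rmsd_to_reference=rmsd)


def cluster_projections(proj: Projection, threshold: float = 11.0) -> ClusterResult:
    """Average-linkage agglomerative clustering of the projected frames,
    cut where the Euclidean merge distance exceeds the threshold."""
    points = proj.coordinates
    if points.shape[0] < 2:
        raise ValueError("clustering needs at least 2 frames")
    z = linkage(points, method="average", metric="euclidean")
    flat = fcluster(z, t=threshold, criterion="distance")
    # relabel densely by first appearance for determinism
    labels = np.empty_like(flat)
    mapping: dict[int, int] = {}
    for i, c in enumerate(flat):
        if c not in mapping:
            mapping[c] = len(mapping)
        labels[i] = mapping[c]
    return ClusterResult(labels=labels, n_clusters=len(mapping), threshold=threshold)


def dres(
    apo_proj: Projection,
    holo_proj: Projection,
    seed: int = 0,
    n_samples: int = 10000,
    bw_method: str = "silverman",
) -> DRESScore:
    """Dimensionality-reduction ensemble similarity.

    Gaussian KDEs are fitted to the two projected ensembles and their
    Jensen-Shannon divergence (natural log) is estimated by Monte-Carlo
    sampling from the 50/50 mixture, then clipped to [0, ln 2]. Identical
    frame sets give exactly 0; fully disjoint ensembles approach ln 2.
    """
    a = np.asarray(apo_proj.coordinates, dtype=float)
    b = np.asarray(holo_proj.coordinates, dtype=float)
    if a.shape[0] < 10 or b.shape[0] < 10:
        raise ValueError("DRES needs at least 10 frames per ensemble")
    kde_a = gaussian_kde(a.T, bw_method=bw_method)
    kde_b = gaussian_kde(b.T, bw_method=bw_method)
    rng = np.random.default_rng(seed)
    n_a = n_samples // 2
    n_b = n_samples - n_a
    # sample from each mixture component with a seeded generator
    sa = kde_a.resample(n_a, seed=rng)
    sb = kde_b.resample(n_b, seed=rng)

    def _expect_log_ratio(samples: np.ndarray, own: gaussian_kde, other: gaussian_kde) -> float:
        p = own.evaluate(samples)
        q = other.evaluate(samples)
        m = 0.5 * (p + q)
        good = p > 0
        return float(np.mean(np.log(p[good] / m[good])))

    jsd = 0.5 * _expect_log_ratio(sa, kde_a, kde_b) + 0.5 * _expect_log_ratio(
        sb, kde_b, kde_a
    )
    value = float(np.clip(jsd, 0.0, LN2))
    return DRESScore(value=value, n_samples=n_samples, bandwidth_rule=bw_method, seed=seed)
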