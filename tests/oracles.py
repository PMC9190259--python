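"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive: all-pairs double loops, explicit
O(T^3) agglomeration, hand-written Gaussian mixtures with grid
quadrature. No code is shared with the package's detection or
clustering paths beyond the atom-typing tables.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dist(a, b):
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def angle_deg(a, b, c):
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def brute_hbonds(coords, donor_h_pairs, acceptors, da_cutoff=3.5, angle_range=(120.0, 180.0)):
    """All (donor, hydrogen, acceptor) triples meeting both criteria."""
    out = set()
    for d, h in donor_h_pairs:
        for a in acceptors:
            if a == d:
                continue
            if dist(coords[d], coords[a]) <= da_cutoff:
                ang = angle_deg(coords[d], coords[h], coords[a])
                if angle_range[0] <= ang <= angle_range[1]:
                    out.add((d, h, a))
    return out


def brute_salt(coords, positives, negatives, cutoff=4.5):
    out = set()
    for p in positives:
        for n in negatives:
            if dist(coords[p], coords[n]) <= cutoff:
                out.add((p, n))
    return out


def brute_cation_pi(coords, cations, rings, cutoff=6.0, windows=((0, 60), (120, 180))):
    """rings: list of index arrays. Centroid and normal recomputed here
    via an explicit cross-product plane fit."""
    out = set()
    for c in cations:
        for ri, ring in enumerate(rings):
            pts = coords[list(ring)]
            centroid = pts.mean(axis=0)
            # normal as mean cross product of consecutive edge vectors
            normal = np.zeros(3)
            for k in range(len(pts)):
                normal += np.cross(pts[k] - centroid, pts[(k + 1) % len(pts)] - centroid)
            normal /= np.linalg.norm(normal)
            if dist(coords[c], centroid) > cutoff:
                continue
            v = coords[c] - centroid
            cosang = np.dot(v, normal) / np.linalg.norm(v)
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if any(lo <= ang <= hi for lo, hi in windows):
                out.add((c, ri))
    return out


def brute_pi_stack(coords, rings_a, rings_b, cutoff=6.0):
    out = set()
    for i, ra in enumerate(rings_a):
        for j, rb in enumerate(rings_b):
            ca = coords[list(ra)].mean(axis=0)
            cb = coords[list(rb)].mean(axis=0)
            if dist(ca, cb) <= cutoff:
                out.add((i, j))
    return out


def brute_hydrophobic_residues(coords, atoms_a, atoms_b, residue_of, cutoff=4.5):
    """Residue pairs with at least one qualifying atom pair within the
    cutoff; same-residue pairs excluded."""
    out = set()
    for i in atoms_a:
        for j in atoms_b:
            ra, rb = residue_of(i), residue_of(j)
            if ra == rb:
                continue
            if dist(coords[i], coords[j]) <= cutoff:
                out.add(tuple(sorted((ra, rb))))
    return out


def brute_water_bridges(coords, water_residues, fv_donor_h, fv_acceptors,
                        ag_donor_h, ag_acceptors, max_order=1):
    """Waters connected to both molecules through hydrogen-bond chains of
    up to *max_order* waters. Returns the set of first-order bridging
    waters when max_order=1; with higher order, waters reachable through
    water-water chains are included (used to confirm the package counts
    first order only)."""

    def hbonded(widx, donor_h, acceptors):
        w_dh = _water_dh(coords, widx)
        w_acc = [widx[0]]  # water oxygen
        direct = brute_hbonds(coords, w_dh, acceptors)
        back = brute_hbonds(coords, donor_h, w_acc)
        return bool(direct or back)

    bridging = set()
    for key, widx in water_residues.items():
        to_fv = hbonded(widx, fv_donor_h, fv_acceptors)
        to_ag = hbonded(widx, ag_donor_h, ag_acceptors)
        if to_fv and to_ag:
            bridging.add(key)
    if max_order > 1:
        # follow one extra water-water hop
        for key, widx in water_residues.items():
            if key in bridging:
                continue
            to_fv = hbonded(widx, fv_donor_h, fv_acceptors)
            to_ag = hbonded(widx, ag_donor_h, ag_acceptors)
            for key2, widx2 in water_residues.items():
                if key2 == key:
                    continue
                linked = hbonded(
                    widx,
                    [(d, h) for d, h in _water_dh(coords, widx2)],
                    list(widx2),
                )
                if linked:
                    to_fv2 = hbonded(widx2, fv_donor_h, fv_acceptors)
                    to_ag2 = hbonded(widx2, ag_donor_h, ag_acceptors)
                    if (to_fv and to_ag2) or (to_ag and to_fv2):
                        bridging.add(key)
    return bridging


def _water_dh(coords, widx):
    widx = list(widx)
    o = widx[0]
    return [(o, h) for h in widx[1:]]


# ---------------------------------------------------------------------------


def average_linkage_clusters(points: np.ndarray, threshold: float) -> list[set[int]]:
    """Naive O(T^3) unweighted average-linkage agglomeration: repeatedly
    merge the two clusters with the smallest mean inter-point distance
    while that distance is <= threshold."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    clusters: list[set[int]] = [{i} for i in range(n)]
    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for i, j in itertools.combinations(range(len(clusters)), 2):
            dd = np.mean([d[p, q] for p in clusters[i] for q in clusters[j]])
            if dd < best_d - 1e-12:
                best_d = dd
                best = (i, j)
        if best_d > threshold:
            break
        i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters


# ---------------------------------------------------------------------------


def silverman_kde_logpdf(data: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Hand-written Gaussian KDE with Silverman's factor and full data
    covariance (matching the standard definition: H = cov * factor^2)."""
    data = np.atleast_2d(data)
    if data.shape[0] < data.shape[1]:
        data = data.T
    n, d = data.shape
    factor = (n * (d + 2) / 4.0) ** (-1.0 / (d + 4))
    cov = np.cov(data, rowvar=False, ddof=1) * factor**2
    cov = np.atleast_2d(cov)
    inv = np.linalg.inv(cov)
    logdet = np.linalg.slogdet(2 * np.pi * cov)[1]
    diff = x[:, None, :] - data[None, :, :]
    expo = -0.5 * np.einsum("mnd,de,mne->mn", diff, inv, diff)
    return -math.log(n) - 0.5 * logdet + _logsumexp(expo)


def _logsumexp(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=1, keepdims=True))).ravel()


def jsd_quadrature(data_a: np.ndarray, data_b: np.ndarray, n_grid: int = 33, pad: float = 4.0) -> float:
    """Jensen-Shannon divergence (nats) between Silverman-KDE densities
    of two 3-D samples, by Riemann quadrature on a regular grid."""
    allpts = np.vstack([data_a, data_b])
    lo = allpts.min(axis=0) - pad
    hi = allpts.max(axis=0) + pad
    axes = [np.linspace(lo[k], hi[k], n_grid) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dv = np.prod([(ax[1] - ax[0]) for ax in axes])
    log_p = silverman_kde_logpdf(data_a, grid)
    log_q = silverman_kde_logpdf(data_b, grid)
    p = np.exp(log_p)
    q = np.exp(log_q)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_p = np.where(p > 0, p * (np.log(p) - np.log(m)), 0.0)
        term_q = np.where(q > 0, q * (np.log(q) - np.log(m)), 0.0)
    return float(0.5 * (term_p + term_q).sum() * dv)


# ---------------------------------------------------------------------------


def circular_mean_grid(angles_deg: np.ndarray, step: float = 0.01) -> float:
    """Circular mean by grid minimization of the mean squared circular
    distance (independent of the resultant-vector formula)."""
    candidates = np.arange(-180.0, 180.0, step)
    a = np.asarray(angles_deg)[:, None]
    delta = np.abs((a - candidates[None, :] + 180.0) % 360.0 - 180.0)
    cost = (delta**2).mean(axis=0)
    best = candidates[int(np.argmin(cost))]
    return float(best if best != -180.0 else 180.0)
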