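"""Frame-level trajectory analyses: superposition, polar contacts,
overlap summaries, and clustering of electrostatic-potential maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import DegenerateGeometryError, SingularGeometryError
from .gridfield import (
    ChargedParticleSet,
    GridSpec,
    clip_ep,
    density_grid,
    ep_grid,
    electrostatic_overlap,
    shape_overlap,
    shared_grid,
)

#: Polar-interaction threshold on the prefactor-free electrostatic
#: proxy sum q_i q_j / r_ij [e^2/nm]; contacts strictly below this are
#: reported.
POLAR_PROXY_THRESHOLD = -0.3

#: Default frame subsampling stride for polar-interaction statistics.
POLAR_FRAME_STRIDE = 10


@dataclass
class PolarContact:
    """A flagged polar interaction between the FT group and one site."""

    site_id: str
    role: str  # donor | acceptor (assigned from the dominant pair's charges)
    energy_proxy: float  # e^2/nm, no Coulomb prefactor


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix R, translation t, rmsd) such that
    ``mobile @ R.T + t`` best fits ``reference``.  The rotation is
    always proper (det = +1); reflections are never returned.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must have identical (n, 3) shapes")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    # rank-deficient cross-covariance: collinear or coincident points
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = rc - rot @ mc
    fitted = mobile @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rot, t, rmsd


def polar_proxy(
    pos_a: np.ndarray, q_a: np.ndarray, pos_b: np.ndarray, q_b: np.ndarray
) -> float:
    """Prefactor-free electrostatic proxy sum_{i,j} q_i q_j / r_ij [e^2/nm].

    Positions in nm.  Symmetric in group order.
    """
    pos_a = np.asarray(pos_a, dtype=float).reshape(-1, 3)
    pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 3)
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    r = np.sqrt(np.einsum("...k,...k->...", diff, diff))
    if r.size and float(r.min()) <= 0.0:
        raise SingularGeometryError("coincident atoms in polar-interaction proxy")
    return float((np.asarray(q_a)[:, None] * np.asarray(q_b)[None, :] / r).sum())


def detect_polar_interactions(
    ft_positions: np.ndarray,
    ft_charges: np.ndarray,
    sites: dict[str, tuple[np.ndarray, np.ndarray]],
    threshold: float = POLAR_PROXY_THRESHOLD,
) -> list[PolarContact]:
    """Flag (FT group, site) pairings whose proxy is below the threshold.

    ``sites`` maps a residue-or-site id to its (positions [nm],
    charges [e]).  The inequality is strict: a proxy exactly at the
    threshold is not reported.  The role is a charge-sign heuristic on
    the dominant (most negative q_i q_j / r) pair: a positively charged
    site partner is labelled a donor, a negative one an acceptor.
    """
    contacts: list[PolarContact] = []
    ft_positions = np.asarray(ft_positions, dtype=float).reshape(-1, 3)
    ft_charges = np.asarray(ft_charges, dtype=float)
    for site_id, (pos_b, q_b) in sites.items():
        pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 3)
        q_b = np.asarray(q_b, dtype=float)
        diff = ft_positions[:, None, :] - pos_b[None, :, :]
        r = np.sqrt(np.einsum("...k,...k->...", diff, diff))
        if r.size and float(r.min()) <= 0.0:
            raise SingularGeometryError(f"coincident atoms at site {site_id}")
        terms = ft_charges[:, None] * q_b[None, :] / r
        proxy = float(terms.sum())
        if proxy < threshold:
            j = int(np.argmin(terms) % terms.shape[1])
            role = "donor" if q_b[j] > 0 else "acceptor"
            contacts.append(PolarContact(site_id=site_id, role=role, energy_proxy=proxy))
    return contacts


def best_overlap_summary(
    frames: list[ChargedParticleSet],
    references: list[ChargedParticleSet],
    spacing: float = 1.0,
    shape_cutoffs: tuple[float, ...] = (0.6, 0.7),
    elec_cutoffs: tuple[float, ...] = (0.3, 0.5),
) -> pd.DataFrame:
    """Best shape and electrostatic overlaps of frames against references.

    For each reference, the maximum over all frames of O_S and O_E is
    recorded; the summary row aggregates min/avg/max across references
    and counts how many references exceed each cutoff.  All fields are
    computed on one shared grid covering every input set.
    """
    if not frames:
        raise ValueError("empty frame set")
    if not references:
        raise ValueError("empty reference set")
    spec = shared_grid(list(frames) + list(references), spacing=spacing)
    frame_dens = [density_grid(f, spec) for f in frames]
    frame_clip = [clip_ep(ep_grid(f, spec)) for f in frames]
    rows = []
    def safe_oe(a, b):
        # two maps with no clipped features carry no electrostatic
        # signature; score them as uncorrelated rather than undefined
        if np.abs(a.values).sum() + np.abs(b.values).sum() == 0:
            return 0.0
        return electrostatic_overlap(a, b)

    for ri, ref in enumerate(references):
        ref_dens = density_grid(ref, spec)
        ref_clip = clip_ep(ep_grid(ref, spec))
        best_os = max(shape_overlap(fd, ref_dens) for fd in frame_dens)
        best_oe = max(safe_oe(fc, ref_clip) for fc in frame_clip)
        rows.append({"reference": ri, "best_O_S": best_os, "best_O_E": best_oe})
    table = pd.DataFrame(rows)
    summary = {
        "O_S_min": table["best_O_S"].min(),
        "O_S_avg": table["best_O_S"].mean(),
        "O_S_max": table["best_O_S"].max(),
        "O_E_min": table["best_O_E"].min(),
        "O_E_avg": table["best_O_E"].mean(),
        "O_E_max": table["best_O_E"].max(),
    }
    for c in shape_cutoffs:
        summary[f"O_S>{c}"] = int((table["best_O_S"] > c).sum())
    for c in elec_cutoffs:
        summary[f"O_E>{c}"] = int((table["best_O_E"] > c).sum())
    table.attrs["summary"] = summary
    return table


def cluster_ep_vectors(
    vectors: np.ndarray, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """KMeans over flattened clipped-EP vectors.

    Returns (labels, occupancy counts per cluster, representative index
    per cluster).  The representative of a cluster is the member vector
    nearest the cluster mean.  Deterministic for a given seed
    (k-means++ initialization, single init).
    """
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} vectors, got {n}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=1)
    labels = km.fit_predict(vectors)
    occupancy = np.bincount(labels, minlength=k)
    representatives = np.full(k, -1, dtype=int)
    for c in range(k):
        members = np.where(labels == c)[0]
        if members.size == 0:  # KMeans may leave clusters empty on degenerate data
            continue
        d = np.linalg.norm(vectors[members] - km.cluster_centers_[c], axis=1)
        representatives[c] = members[int(np.argmin(d))]
    return labels, occupancy, representatives


def cluster_ep_frames(
    frames: list[ChargedParticleSet],
    k: int,
    seed: int = 0,
    spacing: float = 1.0,
    spec: GridSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster frames by their clipped electrostatic-potential maps.

    Each frame is gridded on a shared grid, the EP map is clipped to a
    ternary field, flattened, and partitioned with KMeans.  Returns
    (labels, occupancy counts, centroid-frame indices), where the
    centroid frame of a cluster is the member nearest the cluster mean.
    """
    if not frames:
        raise ValueError("empty frame set")
    if spec is None:
        spec = shared_grid(frames, spacing=spacing)
    vectors = np.stack([clip_ep(ep_grid(f, spec)).values.ravel() for f in frames])
    return cluster_ep_vectors(vectors, k, seed=seed)
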