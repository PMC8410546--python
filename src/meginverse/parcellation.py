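"""ROI-level machinery: PCA time courses, fPAD, mean neighbor correlation,
and leadfield-influence-driven atlas reduction.

Parcellation summarizes each ROI by the first principal component of its
dipole time courses; the rank-1 back-projection (time course times PC1
loading vector) is what the parcellated variance-explained analysis
forward-maps. Atlas reduction allocates a target ROI count across
anatomical clusters proportionally to their leadfield influence
(``||L_omega|| = sum_{j in omega} ||L_j||``) and then greedily merges the
weakest adjacent ROIs within each cluster until the allocation is met.
The greedy merge automates what is, for real atlases, an anatomy-guided
manual choice; it aims only at a more uniform influence distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import Atlas, Leadfield, SourceEstimate
from .resolution import ResolutionMatrix


@dataclass
class ROITimecourses:
    """First-PC summary of each ROI: time course, loading vector, variance."""

    data: np.ndarray  # (n_rois, n_samples)
    mixing_columns: list[np.ndarray]  # per-ROI unit loading over its dipoles
    explained_variance_fraction: np.ndarray  # per ROI, in (0, 1]


@dataclass
class AtlasReductionPlan:
    roi_influence: np.ndarray  # per original ROI
    cluster_influence: np.ndarray  # per cluster
    allocated_counts: np.ndarray  # per cluster
    merges: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    # each merge: (cluster_id, tuple of original ROI ids merged into one)


def _pc1(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of (n_dipoles, T) data.

    Returns (timecourse, unit loading vector, explained variance fraction).
    Sign convention: sum of loadings positive (first nonzero entry positive
    on a tie) so results are deterministic.
    """
    centered = block - block.mean(axis=1, keepdims=True)
    if block.shape[0] == 1:
        return centered[0].copy(), np.ones(1), 1.0
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    loading = u[:, 0]
    tot = np.sum(s**2)
    frac = float(s[0] ** 2 / tot) if tot > 0 else 1.0
    sgn = np.sum(loading)
    if sgn == 0:
        nz = loading[loading != 0]
        sgn = nz[0] if nz.size else 1.0
    if sgn < 0:
        loading = -loading
    return loading @ centered, loading, frac


def roi_timecourse_pca(est: SourceEstimate | np.ndarray, atlas: Atlas) -> ROITimecourses:
    """One representative time course per ROI via the first principal
    component of its dipole time courses."""
    data = est.data if isinstance(est, SourceEstimate) else np.asarray(est, dtype=float)
    if data.shape[0] != atlas.n_dipoles:
        raise ValueError("estimate and atlas disagree on dipole count")
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    courses = np.empty((atlas.n_rois, data.shape[1]))
    loadings, fracs = [], np.empty(atlas.n_rois)
    for roi in range(1, atlas.n_rois + 1):
        members = atlas.roi_members(roi)
        tc, loading, frac = _pc1(data[members])
        courses[roi - 1] = tc
        loadings.append(loading)
        fracs[roi - 1] = frac
    return ROITimecourses(data=courses, mixing_columns=loadings, explained_variance_fraction=fracs)


def parcellate_rank1(data: np.ndarray, atlas: Atlas) -> np.ndarray:
    """Replace each ROI's dipole block with its rank-1 PC1 reconstruction."""
    out = np.empty_like(data, dtype=float)
    for roi in range(1, atlas.n_rois + 1):
        members = atlas.roi_members(roi)
        tc, loading, _ = _pc1(data[members])
        out[members] = np.outer(loading, tc)
    return out


def fpad(r: ResolutionMatrix, atlas: Atlas, absolute: bool = True) -> np.ndarray:
    """Fractional peak activity displacement per ROI.

    For ROI omega: the fraction of its dipoles whose PSF peak lies outside
    omega. Zero PAD everywhere implies zero fPAD for every atlas.
    """
    if r.matrix.shape[0] != atlas.n_dipoles:
        raise ValueError("resolution matrix and atlas disagree on dipoles")
    m = np.abs(r.matrix) if absolute else r.matrix
    peaks = np.argmax(m, axis=0)  # per column i: dipole of max |PSF_i|
    defined = np.any(r.matrix != 0, axis=0)
    out = np.empty(atlas.n_rois)
    for roi in range(1, atlas.n_rois + 1):
        members = atlas.roi_members(roi)
        ok = members[defined[members]]
        if ok.size == 0:
            out[roi - 1] = np.nan
            continue
        outside = atlas.dipole_roi[peaks[ok]] != roi
        out[roi - 1] = outside.mean()
    return out


def mean_neighbor_correlation(
    tc: ROITimecourses, atlas: Atlas, absolute: bool = False
) -> tuple[float, int]:
    """Mean zero-lag Pearson correlation over adjacent ROI pairs.

    High values indicate strong spatial leakage between neighboring
    regions. Signed by default (``absolute=True`` averages |r|). Pairs with
    a constant time course are excluded; returns ``(mNC, n_excluded)``.
    """
    if not atlas.roi_adjacency:
        raise ValueError("atlas has no adjacent ROI pairs")
    centered = tc.data - tc.data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    vals, excluded = [], 0
    for a, b in sorted(atlas.roi_adjacency):
        ia, ib = a - 1, b - 1
        if norms[ia] == 0 or norms[ib] == 0:
            excluded += 1
            continue
        c = float(centered[ia] @ centered[ib] / (norms[ia] * norms[ib]))
        vals.append(abs(c) if absolute else c)
    if not vals:
        raise ValueError("all adjacent pairs excluded (constant time courses)")
    return float(np.mean(vals)), excluded


def roi_influence(leadfield: Leadfield, atlas: Atlas) -> np.ndarray:
    """Per-ROI influence over the sensors: sum of member column norms."""
    if leadfield.n_dipoles != atlas.n_dipoles:
        raise ValueError("leadfield and atlas disagree on dipoles")
    out = np.zeros(atlas.n_rois)
    np.add.at(out, atlas.dipole_roi - 1, leadfield.column_norms)
    return out


def cluster_influence(roi_infl: np.ndarray, atlas: Atlas) -> np.ndarray:
    """Per-cluster influence: sum of member ROI influences."""
    out = np.zeros(atlas.n_clusters)
    np.add.at(out, atlas.roi_cluster - 1, roi_infl)
    return out


def allocate_roi_counts(
    cluster_infl: np.ndarray,
    target_total: int,
    current_counts: np.ndarray,
) -> np.ndarray:
    """Apportion a target ROI count across clusters by influence.

    Largest-remainder apportionment proportional to ``cluster_infl`` with a
    floor of one ROI per cluster and a cap at each cluster's current ROI
    count; the result sums exactly to ``target_total``.
    """
    cluster_infl = np.asarray(cluster_infl, dtype=float)
    current_counts = np.asarray(current_counts, dtype=int)
    n = cluster_infl.size
    if target_total < n:
        raise ValueError("target must allow at least one ROI per cluster")
    if target_total > current_counts.sum():
        raise ValueError("target exceeds the current total ROI count")
    quotas = target_total * cluster_infl / cluster_infl.sum()
    counts = np.clip(np.floor(quotas).astype(int), 1, current_counts)
    remainders = quotas - np.floor(quotas)
    # distribute the shortfall by largest remainder among clusters with headroom
    while counts.sum() < target_total:
        headroom = counts < current_counts
        if not headroom.any():
            raise RuntimeError("no headroom left to reach the target")
        order = np.lexsort((np.arange(n), -remainders))
        for idx in order:
            if headroom[idx]:
                counts[idx] += 1
                remainders[idx] = -np.inf
                break
    # floors may have pushed the sum above target: trim smallest remainders
    while counts.sum() > target_total:
        reducible = counts > 1
        order = np.lexsort((np.arange(n), remainders))
        for idx in order:
            if reducible[idx]:
                counts[idx] -= 1
                remainders[idx] = np.inf
                break
        else:
            raise RuntimeError("cannot trim below one ROI per cluster")
    return counts


def _roi_adjacency_from_dipoles(dipole_roi: np.ndarray, neighbor_pairs: np.ndarray) -> set:
    adj = set()
    for i, j in neighbor_pairs:
        a, b = int(dipole_roi[i]), int(dipole_roi[j])
        if a != b:
            adj.add((min(a, b), max(a, b)))
    return adj


def greedy_merge(
    atlas: Atlas,
    leadfield: Leadfield,
    allocated_counts: np.ndarray,
) -> tuple[Atlas, AtlasReductionPlan]:
    """Reduce each cluster to its allocated ROI count by greedy merging.

    Within each cluster, the lowest-influence ROI is merged with its
    lowest-influence adjacent ROI in the same cluster, repeatedly, until
    the cluster holds its allocated count. Influence is additive under
    merging, so the total is conserved and the distribution becomes more
    uniform. Raises if a cluster's ROIs are too disconnected to reach the
    allocation.
    """
    infl0 = roi_influence(leadfield, atlas)
    cl_infl = cluster_influence(infl0, atlas)
    allocated_counts = np.asarray(allocated_counts, dtype=int)

    # mutable state: ROI -> set of original ROIs, influence, cluster, adjacency
    groups: dict[int, set[int]] = {r: {r} for r in range(1, atlas.n_rois + 1)}
    infl = {r: float(infl0[r - 1]) for r in groups}
    cluster_of = {r: int(atlas.roi_cluster[r - 1]) for r in groups}
    adj: dict[int, set[int]] = {r: set() for r in groups}
    for a, b in atlas.roi_adjacency:
        adj[a].add(b)
        adj[b].add(a)

    merges: list[tuple[int, tuple[int, ...]]] = []
    for cluster in range(1, atlas.n_clusters + 1):
        target = int(allocated_counts[cluster - 1])
        members = [r for r in groups if cluster_of[r] == cluster]
        while len(members) > target:
            candidates = sorted(members, key=lambda r: (infl[r], r))
            merged = False
            for weak in candidates:
                partners = [p for p in adj[weak] if cluster_of.get(p) == cluster]
                if not partners:
                    continue
                partner = min(partners, key=lambda p: (infl[p], p))
                keep, drop = (weak, partner) if weak < partner else (partner, weak)
                groups[keep] |= groups[drop]
                infl[keep] += infl[drop]
                for nb in adj[drop]:
                    if nb != keep:
                        adj[nb].discard(drop)
                        adj[nb].add(keep)
                        adj[keep].add(nb)
                adj[keep].discard(drop)
                adj[keep].discard(keep)
                del groups[drop], infl[drop], cluster_of[drop], adj[drop]
                merges.append((cluster, tuple(sorted(groups[keep]))))
                members = [r for r in groups if cluster_of[r] == cluster]
                merged = True
                break
            if not merged:
                raise RuntimeError(
                    f"cluster {cluster}: disconnected ROIs, cannot reach {target}"
                )

    # relabel surviving ROIs 1..n in ascending original-id order
    survivors = sorted(groups)
    new_id = {old: i + 1 for i, old in enumerate(survivors)}
    orig_to_new = np.empty(atlas.n_rois + 1, dtype=int)
    for keep, members_set in groups.items():
        for orig in members_set:
            orig_to_new[orig] = new_id[keep]
    dipole_roi = orig_to_new[atlas.dipole_roi]
    roi_cluster = np.array([cluster_of[r] for r in survivors], dtype=int)
    new_adj = {
        (min(new_id[a], new_id[b]), max(new_id[a], new_id[b]))
        for a in survivors
        for b in adj[a]
    }
    reduced = Atlas(dipole_roi=dipole_roi, roi_cluster=roi_cluster, roi_adjacency=new_adj)
    plan = AtlasReductionPlan(
        roi_influence=infl0,
        cluster_influence=cl_infl,
        allocated_counts=allocated_counts,
        merges=merges,
    )
    return reduced, plan


def reduce_atlas(
    atlas: Atlas, leadfield: Leadfield, target_total: int
) -> tuple[Atlas, AtlasReductionPlan]:
    """Full reduction: influence -> allocation -> greedy merge."""
    infl = roi_influence(leadfield, atlas)
    cl_infl = cluster_influence(infl, atlas)
    current = np.bincount(atlas.roi_cluster - 1, minlength=atlas.n_clusters)
    counts = allocate_roi_counts(cl_infl, target_total, current)
    return greedy_merge(atlas, leadfield, counts)
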