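"""Data-driven parcellization of the cortical surface.

The reference prior of the MEM solver lives on a partition of the (in-field
-of-view) cortex into K connected parcels.  The partition is data driven:
a multivariate source prelocalization (MSP) score in [0, 1] quantifies each
vertex's contribution to the measured data subspace, and parcels are grown
breadth-first along the mesh from the strict local maxima of that score.
Within each parcel, a row-stochastic smoothness operator W(sigma) couples
vertices by geodesic neighborhood order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import CorticalMesh

__all__ = ["Parcellation", "SmoothnessOperator", "msp_scores", "grow_parcels", "smoothness_operator"]


@dataclass
class Parcellation:
    """Partition of the in-FOV vertex set into K edge-connected parcels.

    ``labels[v]`` is the parcel id of vertex v, or -1 outside the field of
    view.  ``seed_vertices[k]`` is the score maximum parcel k grew from.
    """

    labels: np.ndarray
    K: int
    seed_vertices: np.ndarray

    def parcel_vertices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)

    def validate(self, mesh: CorticalMesh) -> None:
        if self.K < 1:
            raise ValueError("need at least one parcel")
        in_fov = self.labels >= 0
        if not np.any(in_fov):
            raise ValueError("empty parcellation")
        for k in range(self.K):
            members = self.parcel_vertices(k)
            if members.size == 0:
                raise ValueError(f"parcel {k} is empty")
            if not _is_connected(mesh, members):
                raise ValueError(f"parcel {k} is not edge-connected")


def _is_connected(mesh: CorticalMesh, members: np.ndarray) -> bool:
    member_set = set(int(v) for v in members)
    seen = {int(members[0])}
    stack = [int(members[0])]
    while stack:
        v = stack.pop()
        for u in mesh.neighbors[v]:
            u = int(u)
            if u in member_set and u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == len(member_set)


@dataclass
class SmoothnessOperator:
    """Row-stochastic within-parcel smoothing W(v,u) ~ sigma^order(v,u)."""

    matrix: np.ndarray
    sigma: float
    vertices: np.ndarray        # parcel vertex ids, aligned with matrix rows


def msp_scores(Y, A) -> np.ndarray:
    """Multivariate source prelocalization score per vertex, in [0, 1].

    Each time sample (column of Y) is normalized to unit norm; the
    principal channel subspace U_r capturing 95% of the energy of the
    normalized data is extracted by SVD; the score of vertex v is the
    squared projection of its unit-normalized sensitivity column onto U_r.
    Zero-sensitivity columns score 0.
    """
    y = Y.values if hasattr(Y, "values") else np.asarray(Y, dtype=float)
    a = A.matrix() if hasattr(A, "matrix") else np.asarray(A, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need at least 2 time samples for MSP")
    norms = np.linalg.norm(y, axis=0)
    ok = norms > 0
    yn = y[:, ok] / norms[ok]
    u, s, _ = np.linalg.svd(yn, full_matrices=False)
    energy = np.cumsum(s**2) / np.sum(s**2)
    r = int(np.searchsorted(energy, 0.95) + 1)
    ur = u[:, :r]
    colnorm = np.linalg.norm(a, axis=0)
    score = np.zeros(a.shape[1])
    nz = colnorm > 0
    proj = ur.T @ (a[:, nz] / colnorm[nz])
    score[nz] = np.sum(proj**2, axis=0)
    return np.clip(score, 0.0, 1.0)


def grow_parcels(
    mesh: CorticalMesh,
    scores: np.ndarray,
    fov_mask: np.ndarray | None = None,
    neighborhood_radius: int = 1,
) -> Parcellation:
    """Region growing from strict local maxima of the MSP score.

    Seeds are vertices whose score strictly exceeds all in-FOV neighbors
    within ``neighborhood_radius`` mesh hops.  Growth proceeds in
    breadth-first rounds: each unassigned in-FOV vertex adjacent to at
    least one parcel joins the adjacent parcel whose *seed* score is
    highest (ties to the lower parcel id).  With no strict maxima (uniform
    scores) the whole FOV collapses to a single parcel.  In-FOV components
    unreachable from any seed become their own parcels.
    """
    scores = np.asarray(scores, dtype=float)
    n = mesh.n_vertices
    if fov_mask is None:
        fov_mask = np.ones(n, dtype=bool)
    fov = np.asarray(fov_mask, dtype=bool)
    if not np.any(fov):
        raise ValueError("empty field of view")

    nbrs = mesh.neighbors
    seeds = []
    for v in np.flatnonzero(fov):
        ring = _hop_neighborhood(mesh, int(v), neighborhood_radius)
        ring = [u for u in ring if fov[u] and u != v]
        if all(scores[v] > scores[u] for u in ring):
            seeds.append(int(v))

    labels = np.full(n, -1, dtype=int)
    if not seeds:
        # degenerate flat score: one parcel per connected FOV component
        comps = _fov_components(mesh, fov)
        seed_list = []
        for k, comp in enumerate(comps):
            labels[comp] = k
            seed_list.append(int(comp[np.argmax(scores[comp])]))
        return Parcellation(labels=labels, K=len(comps), seed_vertices=np.array(seed_list))

    # parcel ids ordered by descending seed score then ascending vertex id
    seeds = sorted(seeds, key=lambda v: (-scores[v], v))
    seed_arr = np.array(seeds, dtype=int)
    for k, v in enumerate(seeds):
        labels[v] = k

    changed = True
    while changed:
        changed = False
        claims = {}
        for v in np.flatnonzero((labels == -1) & fov):
            cand = [labels[u] for u in nbrs[v] if labels[u] >= 0]
            if cand:
                # highest seed score wins; seeds sorted so lower id = higher score
                claims[int(v)] = min(cand)
        for v, k in claims.items():
            labels[v] = k
            changed = True

    leftover = (labels == -1) & fov
    if np.any(leftover):
        comps = _fov_components(mesh, leftover)
        k = len(seeds)
        extra_seeds = []
        for comp in comps:
            labels[comp] = k
            extra_seeds.append(int(comp[np.argmax(scores[comp])]))
            k += 1
        seed_arr = np.concatenate([seed_arr, np.array(extra_seeds, dtype=int)])

    p = Parcellation(labels=labels, K=int(labels.max()) + 1, seed_vertices=seed_arr)
    return p


def _hop_neighborhood(mesh: CorticalMesh, v: int, radius: int) -> list:
    seen = {v}
    frontier = [v]
    for _ in range(radius):
        nxt = []
        for u in frontier:
            for w in mesh.neighbors[u]:
                w = int(w)
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        frontier = nxt
    seen.discard(v)
    return sorted(seen)


def _fov_components(mesh: CorticalMesh, mask: np.ndarray) -> list:
    remaining = set(int(v) for v in np.flatnonzero(mask))
    comps = []
    while remaining:
        start = min(remaining)
        comp = {start}
        stack = [start]
        remaining.discard(start)
        while stack:
            v = stack.pop()
            for u in mesh.neighbors[v]:
                u = int(u)
                if u in remaining:
                    remaining.discard(u)
                    comp.add(u)
                    stack.append(u)
        comps.append(np.array(sorted(comp), dtype=int))
    return comps


def smoothness_operator(
    mesh: CorticalMesh,
    parcel_vertices,
    sigma: float = 0.6,
    max_order: int = 3,
) -> SmoothnessOperator:
    """Within-parcel smoothness W(v,u) ~ sigma^o(v,u), rows normalized to 1.

    o(v,u) is the geodesic neighborhood order (hop count) computed inside
    the parcel subgraph; entries beyond ``max_order`` are zero.  sigma = 0
    gives the identity (0^0 = 1 on the diagonal).
    """
    verts = np.asarray(list(parcel_vertices), dtype=int)
    m = len(verts)
    index = {int(v): i for i, v in enumerate(verts)}
    member = set(index)
    W = np.zeros((m, m))
    for i, v in enumerate(verts):
        # BFS within the parcel up to max_order hops
        order = {int(v): 0}
        frontier = [int(v)]
        for o in range(1, max_order + 1):
            nxt = []
            for u in frontier:
                for w in mesh.neighbors[u]:
                    w = int(w)
                    if w in member and w not in order:
                        order[w] = o
                        nxt.append(w)
            frontier = nxt
        for u, o in order.items():
            W[i, index[u]] = sigma**o if o > 0 else 1.0
    W /= W.sum(axis=1, keepdims=True)
    return SmoothnessOperator(matrix=W, sigma=float(sigma), vertices=verts)
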