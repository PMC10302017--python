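"""Deformable registration by discrete displacement labeling on a minimum
spanning tree.

Blocks of pixels are graph nodes; each node carries a candidate displacement
label w = (f, g) (h = 0 in 2-D).  The energy

    E(w) = sum_i S(w_i) + kappa * sum_(l,m) R(w_l, w_m)

combines a block SSD data term with a squared-Euclidean label difference on
tree edges, and is minimized *exactly* by two-pass dynamic programming on
the minimum spanning tree of the block graph.  A coarse-to-fine pyramid
handles displacements beyond the label range; each level's update is kept
only if it does not increase the full-resolution energy, so the energy trace
across levels is non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# graph containers
# ---------------------------------------------------------------------------


@dataclass
class MRFGraph:
    grid_shape: tuple  # (rows, cols) of blocks
    block_size: int
    neighbor_pairs: list  # all 4-neighbor (u, v) pairs, u < v
    tree_edges: list  # MST subset as (u, v, cost)

    @property
    def n_nodes(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]


@dataclass
class DisplacementField:
    """Per-node displacement labels (row, col) in voxels."""

    labels: np.ndarray  # (rows, cols, 2)
    label_range: float
    label_step: float
    block_size: int = 1

    def dense(self, image_shape) -> np.ndarray:
        """Bilinear upsampling of block labels to a dense (2, H, W) field."""
        h, w = image_shape
        rows, cols = self.labels.shape[:2]
        out = np.empty((2, h, w))
        # block centers -> pixel coordinates; linear interp between centers
        ry = (np.arange(h) + 0.5) / self.block_size - 0.5
        rx = (np.arange(w) + 0.5) / self.block_size - 0.5
        yy, xx = np.meshgrid(np.clip(ry, 0, rows - 1), np.clip(rx, 0, cols - 1), indexing="ij")
        for c in range(2):
            out[c] = ndimage.map_coordinates(
                self.labels[:, :, c], [yy, xx], order=1, mode="nearest"
            )
        return out


@dataclass
class EnergyBreakdown:
    data_term: float
    reg_term: float
    kappa: float

    @property
    def total(self) -> float:
        return self.data_term + self.reg_term


# ---------------------------------------------------------------------------
# MST over blocks
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, a):
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.p[rb] = ra
        return True


def _block_view(image: np.ndarray, block: int) -> np.ndarray:
    h, w = image.shape
    rows, cols = h // block, w // block
    return image[: rows * block, : cols * block].reshape(rows, block, cols, block)


def build_mst(image: np.ndarray, block_size: int) -> MRFGraph:
    """4-neighbor block graph with mean-absolute-difference edge costs and
    its minimum spanning tree (Kruskal, lexicographic tie-break)."""
    h, w = image.shape
    rows, cols = h // block_size, w // block_size
    if rows * cols < 2 or rows < 1 or cols < 1:
        raise ValueError("need at least 2 blocks")
    if rows < 2 and cols < 2:
        raise ValueError("block grid must be at least 2 blocks in one direction")
    bv = _block_view(image, block_size)
    edges = []
    pairs = []

    def node(r, c):
        return r * cols + c

    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                cost = float(np.abs(bv[r, :, c] - bv[r, :, c + 1]).mean())
                edges.append((cost, node(r, c), node(r, c + 1)))
                pairs.append((node(r, c), node(r, c + 1)))
            if r + 1 < rows:
                cost = float(np.abs(bv[r, :, c] - bv[r + 1, :, c]).mean())
                edges.append((cost, node(r, c), node(r + 1, c)))
                pairs.append((node(r, c), node(r + 1, c)))
    edges.sort()  # (cost, u, v): ties break lexicographically by node index
    uf = _UnionFind(rows * cols)
    tree = []
    for cost, u, v in edges:
        if uf.union(u, v):
            tree.append((u, v, cost))
    return MRFGraph(
        grid_shape=(rows, cols), block_size=block_size, neighbor_pairs=pairs, tree_edges=tree
    )


def minimum_tree_cost_bruteforce(n_nodes: int, cost_lookup) -> float:
    """Exhaustive minimum spanning-tree cost over all spanning trees (oracle).

    Enumerates Pruefer sequences; usable for n_nodes <= 9.
    """
    import heapq
    import itertools

    if n_nodes == 2:
        return cost_lookup(0, 1)
    best = np.inf
    for seq in itertools.product(range(n_nodes), repeat=n_nodes - 2):
        # decode the Pruefer sequence into its edge list
        deg = [1] * n_nodes
        for node in seq:
            deg[node] += 1
        total = 0.0
        avail = [i for i in range(n_nodes) if deg[i] == 1]
        heapq.heapify(avail)
        for node in seq:
            leaf = heapq.heappop(avail)
            total += cost_lookup(leaf, node)
            deg[node] -= 1
            if deg[node] == 1:
                heapq.heappush(avail, node)
        total += cost_lookup(heapq.heappop(avail), heapq.heappop(avail))
        best = min(best, total)
    return best


# ---------------------------------------------------------------------------
# label machinery
# ---------------------------------------------------------------------------


def label_offsets(label_range: float, label_step: float) -> np.ndarray:
    """All (dy, dx) candidate displacements on the label grid.

    Ordered by displacement magnitude so that cost ties (flat image regions)
    resolve to the smallest motion — a deterministic, physically sensible
    tie-break.
    """
    steps = np.arange(-label_range, label_range + 1e-9, label_step)
    dy, dx = np.meshgrid(steps, steps, indexing="ij")
    offs = np.stack([dy.ravel(), dx.ravel()], axis=1)  # (L, 2)
    order = np.lexsort((offs[:, 1], offs[:, 0], (offs**2).sum(1)))
    return offs[order]


def _data_costs(fixed: np.ndarray, moving: np.ndarray, block: int, offsets: np.ndarray):
    """S(i, l): block sum of squared differences under each displacement."""
    h, w = fixed.shape
    rows, cols = h // block, w // block
    L = len(offsets)
    S = np.empty((rows * cols, L))
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    for li, (dy, dx) in enumerate(offsets):
        if dy == int(dy) and dx == int(dx):
            shifted = np.roll(moving, (-int(dy), -int(dx)), axis=(0, 1))
        else:
            shifted = ndimage.map_coordinates(
                moving, [yy + dy, xx + dx], order=1, mode="nearest"
            )
        diff2 = (fixed - shifted) ** 2
        S[:, li] = (
            diff2[: rows * block, : cols * block]
            .reshape(rows, block, cols, block)
            .sum(axis=(1, 3))
            .reshape(-1)
        )
    return S


def _pairwise_table(offsets: np.ndarray) -> np.ndarray:
    """R(l, m) = squared Euclidean distance between label displacements."""
    d = offsets[:, None, :] - offsets[None, :, :]
    return (d**2).sum(-1)


def tree_dp_minimize(tree_edges, data_costs: np.ndarray, pair_costs: np.ndarray, kappa: float):
    """Exact MAP labeling on a tree by two-pass dynamic programming.

    Leaves-to-root min-sum message passing, then root-to-leaves argmin
    back-tracking.  Returns (labels, minimum energy).
    """
    n, L = data_costs.shape
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v, *_ in tree_edges:
        adj[u].append(v)
        adj[v].append(u)
    root = 0
    order = []
    parent = np.full(n, -1)
    stack = [root]
    seen = np.zeros(n, bool)
    seen[root] = True
    while stack:
        u = stack.pop()
        order.append(u)
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                parent[v] = u
                stack.append(v)
    if not seen.all():
        raise ValueError("tree edges do not span all nodes")
    cost = data_costs.astype(float).copy()  # running node costs incl. children
    argmin_child = {}
    kR = kappa * pair_costs
    for u in reversed(order):
        p = parent[u]
        if p < 0:
            continue
        # message to parent: for each parent label, best child label
        tbl = cost[u][:, None] + kR  # (L_child, L_parent)
        argmin_child[u] = np.argmin(tbl, axis=0)
        cost[p] += tbl[argmin_child[u], np.arange(L)]
    labels = np.empty(n, dtype=int)
    labels[root] = int(np.argmin(cost[root]))
    energy = float(cost[root][labels[root]])
    for u in order[1:]:
        labels[u] = int(argmin_child[u][labels[parent[u]]])
    return labels, energy


def brute_force_tree_energy(tree_edges, data_costs: np.ndarray, pair_costs: np.ndarray,
                            kappa: float) -> float:
    """Exhaustive minimum of the labeling energy over all L^n assignments.

    Independent oracle for the dynamic program: enumerates every assignment
    (incrementally, node by node in an order where each node joins an
    already-enumerated node, so each assignment costs O(1) to extend).
    Uses numba when available; pure python otherwise.  Exponential — small
    problems only.
    """
    n, L = data_costs.shape
    # order nodes so each has its single tree parent earlier in the order
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v, *_ in tree_edges:
        adj[u].append(v)
        adj[v].append(u)
    order = [0]
    parent = np.full(n, -1)
    seen = {0}
    i = 0
    while i < len(order):
        u = order[i]
        i += 1
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                order.append(v)
    porder = np.array([order.index(parent[u]) if parent[u] >= 0 else -1 for u in order])
    data = np.ascontiguousarray(data_costs[order], dtype=np.float64)
    kR = np.ascontiguousarray(kappa * pair_costs, dtype=np.float64)
    try:
        if n == 6:
            return float(_bf6_numba(data, kR, porder.astype(np.int64)))
        return float(_bf_numba(data, kR, porder.astype(np.int64)))
    except ImportError:
        return float(_bf_python(data, kR, porder))


def _bf_python(data, kR, porder):
    n, L = data.shape
    best = np.inf
    labels = np.zeros(n, dtype=int)
    partial = np.zeros(n + 1)

    def rec(d):
        nonlocal best
        if d == n:
            if partial[n] < best:
                best = partial[n]
            return
        for l in range(L):
            labels[d] = l
            e = data[d, l]
            if porder[d] >= 0:
                e += kR[l, labels[porder[d]]]
            partial[d + 1] = partial[d] + e
            rec(d + 1)

    rec(0)
    return best


_BF_NUMBA = None
_BF6_NUMBA = None


def _bf6_numba(data, kR, porder):
    """Six-node specialization: an explicit loop nest over all L^6
    assignments with prefix sums hoisted per level (same enumeration, less
    interpreter state)."""
    global _BF6_NUMBA
    if _BF6_NUMBA is None:
        import numba

        @numba.njit(cache=True, fastmath=True)
        def bf6(data, kRT, porder):
            L = data.shape[1]
            best = np.inf
            lab = np.zeros(6, dtype=np.int64)
            p1, p2, p3, p4, p5 = porder[1], porder[2], porder[3], porder[4], porder[5]
            d5 = data[5]
            for l0 in range(L):
                lab[0] = l0
                e0 = data[0, l0]
                for l1 in range(L):
                    lab[1] = l1
                    e1 = e0 + data[1, l1] + kRT[lab[p1], l1]
                    for l2 in range(L):
                        lab[2] = l2
                        e2 = e1 + data[2, l2] + kRT[lab[p2], l2]
                        for l3 in range(L):
                            lab[3] = l3
                            e3 = e2 + data[3, l3] + kRT[lab[p3], l3]
                            row5 = kRT[lab[p5]] if p5 != 4 else kRT[0]
                            for l4 in range(L):
                                lab[4] = l4
                                e4 = e3 + data[4, l4] + kRT[lab[p4], l4]
                                if p5 == 4:
                                    row = kRT[l4]
                                else:
                                    row = row5
                                m = np.inf
                                for l5 in range(L):
                                    e5 = d5[l5] + row[l5]
                                    if e5 < m:
                                        m = e5
                                if e4 + m < best:
                                    best = e4 + m
            return best

        _BF6_NUMBA = bf6
    return _BF6_NUMBA(data, kR, porder)


def _bf_numba(data, kR, porder):
    global _BF_NUMBA
    if _BF_NUMBA is None:
        import numba

        @numba.njit(cache=True)
        def bf(data, kR, porder):
            n, L = data.shape
            labels = np.full(n, -1, dtype=np.int64)
            partial = np.zeros(n + 1)
            best = np.inf
            d = 0
            while d >= 0:
                labels[d] += 1
                if labels[d] >= L:
                    labels[d] = -1
                    d -= 1
                    continue
                e = data[d, labels[d]]
                if porder[d] >= 0:
                    e += kR[labels[d], labels[porder[d]]]
                partial[d + 1] = partial[d] + e
                if d == n - 1:
                    if partial[n] < best:
                        best = partial[n]
                else:
                    d += 1
            return best

        _BF_NUMBA = bf
    return _BF_NUMBA(data, kR, porder)


# ---------------------------------------------------------------------------
# registration driver
# ---------------------------------------------------------------------------


def _energy_of(labels_idx, offsets, tree_edges, data_costs, pair_costs, kappa):
    data = float(data_costs[np.arange(len(labels_idx)), labels_idx].sum())
    reg = kappa * float(
        sum(pair_costs[labels_idx[u], labels_idx[v]] for u, v, *_ in tree_edges)
    )
    return EnergyBreakdown(data_term=data, reg_term=reg, kappa=kappa)


def _register_single_level(fixed, moving, block, label_range, label_step, kappa):
    graph = build_mst(fixed, block)
    offsets = label_offsets(label_range, label_step)
    S = _data_costs(fixed, moving, block, offsets)
    R = _pairwise_table(offsets)
    labels_idx, _ = tree_dp_minimize(graph.tree_edges, S, R, kappa)
    rows, cols = graph.grid_shape
    lab = offsets[labels_idx].reshape(rows, cols, 2)
    energy = _energy_of(labels_idx, offsets, graph.tree_edges, S, R, kappa)
    return lab, energy, graph


def _downsample(img: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return img
    h, w = img.shape
    return img[: h - h % f, : w - w % f].reshape(h // f, f, w // f, f).mean(axis=(1, 3))


def _full_res_energy(fixed, moving, field_dense, block, kappa, label_range, label_step):
    """Eq.-15-style energy of a dense field evaluated at full resolution."""
    from .phantoms import warp_image

    warped = warp_image(moving, field_dense, order=1)
    h, w = fixed.shape
    rows, cols = h // block, w // block
    diff2 = (fixed - warped)[: rows * block, : cols * block]
    data = float((diff2**2).sum())
    # block-average field as node labels; squared label distance on 4-neighbors
    fy = _downsample(field_dense[0], block)
    fx = _downsample(field_dense[1], block)
    reg = float(((np.diff(fy, axis=0)) ** 2 + (np.diff(fx, axis=0)) ** 2).sum())
    reg += float(((np.diff(fy, axis=1)) ** 2 + (np.diff(fx, axis=1)) ** 2).sum())
    return data + kappa * reg


def mrf_register(
    fixed: np.ndarray,
    moving: np.ndarray,
    block_size: int = 6,
    label_range: float = 3.0,
    label_step: float = 1.0,
    kappa: float = 0.5,
    levels: int = 3,
):
    """Coarse-to-fine MST-MRF registration.

    Returns ``(DisplacementField, EnergyBreakdown, energy_history)`` where
    the field maps ``fixed`` pixel positions into ``moving`` (backward
    warping: warp(moving, field) ~ fixed) and the history holds the
    full-resolution energy after each accepted pyramid level.
    """
    if fixed.shape != moving.shape:
        raise ValueError("images must share a shape")
    h, w = fixed.shape
    if label_range == 0:
        graph = build_mst(fixed, block_size)
        rows, cols = graph.grid_shape
        lab = np.zeros((rows, cols, 2))
        offsets = np.zeros((1, 2))
        S = _data_costs(fixed, moving, block_size, offsets)
        energy = _energy_of(np.zeros(rows * cols, int), offsets, graph.tree_edges, S,
                            np.zeros((1, 1)), kappa)
        return (
            DisplacementField(lab, label_range, label_step, block_size),
            energy,
            [energy.total],
        )
    from .phantoms import warp_image

    if levels == 1:
        step = min(label_step, 0.5)  # sub-voxel refinement at the finest level
        lab, breakdown, _ = _register_single_level(
            fixed, moving, block_size, label_range, step, kappa)
        return (
            DisplacementField(lab, label_range, step, block_size),
            breakdown,
            [breakdown.total],
        )

    field = np.zeros((2, h, w))
    best_e = _full_res_energy(fixed, moving, field, block_size, kappa, label_range, label_step)
    history = []
    for lev in range(levels - 1, -1, -1):
        f = 2**lev
        fx = _downsample(fixed, f)
        mv_warped = warp_image(moving, field, order=3)
        mw = _downsample(mv_warped, f)
        step = label_step if lev > 0 else min(label_step, 0.5)
        blk = max(2, block_size // f)
        if min(fx.shape) // blk < 2:
            blk = max(1, min(fx.shape) // 2)
        lab, breakdown, graph = _register_single_level(fx, mw, blk, label_range, step, kappa)
        dfield = DisplacementField(lab, label_range, step, blk)
        delta = dfield.dense(fx.shape) * f  # voxels at full resolution
        delta_full = np.stack(
            [
                ndimage.zoom(delta[c], (h / delta.shape[1], w / delta.shape[2]), order=1)
                for c in range(2)
            ]
        )
        # compose: new_field(p) = field(p + delta(p)) + delta(p)
        yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
        comp = np.stack(
            [
                ndimage.map_coordinates(field[c], [yy + delta_full[0], xx + delta_full[1]],
                                        order=1, mode="nearest")
                for c in range(2)
            ]
        )
        cand = comp + delta_full
        e = _full_res_energy(fixed, moving, cand, block_size, kappa, label_range, label_step)
        if e <= best_e:
            field = cand
            best_e = e
        history.append(best_e)
    rows, cols = h // block_size, w // block_size
    lab_final = np.stack(
        [_downsample(field[0], block_size), _downsample(field[1], block_size)], axis=-1
    )
    final_field = DisplacementField(lab_final, label_range, min(label_step, 0.5), block_size)
    # exact energy of the final blockwise labeling
    offsets = lab_final.reshape(-1, 2)
    graph = build_mst(fixed, block_size)
    S_diag = _data_costs_at(fixed, moving, block_size, offsets)
    reg = kappa * float(
        sum(((offsets[u] - offsets[v]) ** 2).sum() for u, v, *_ in graph.tree_edges)
    )
    breakdown = EnergyBreakdown(data_term=float(S_diag.sum()), reg_term=reg, kappa=kappa)
    return final_field, breakdown, history


def _data_costs_at(fixed, moving, block, per_node_offsets):
    """Block SSD when every node has its own displacement."""
    h, w = fixed.shape
    rows, cols = h // block, w // block
    field = DisplacementField(
        per_node_offsets.reshape(rows, cols, 2), 0, 1, block
    ).dense(fixed.shape)
    from .phantoms import warp_image

    warped = warp_image(moving, field, order=1)
    diff2 = (fixed - warped)[: rows * block, : cols * block]
    return diff2.reshape(rows, block, cols, block).sum(axis=(1, 3)).reshape(-1)


def warp(image: np.ndarray, f: DisplacementField | np.ndarray) -> np.ndarray:
    """Backward-warp an image by a block or dense displacement field."""
    from .phantoms import warp_image

    dense = f.dense(image.shape) if isinstance(f, DisplacementField) else np.asarray(f)
    return warp_image(image, dense, order=3)


# ---------------------------------------------------------------------------
# target registration error
# ---------------------------------------------------------------------------


def tre(ground_truth_field: np.ndarray, estimated_field: np.ndarray, landmarks: np.ndarray) -> float:
    """Mean Euclidean distance between true and estimated displacements at
    landmark positions (third component treated as zero in 2-D).

    ``landmarks`` is (N, 2) in (row, col) voxel coordinates; fields are
    (2, H, W) (or (3, ...) with a z component).
    """
    landmarks = np.atleast_2d(np.asarray(landmarks, dtype=float))
    if landmarks.shape[0] < 1:
        raise ValueError("need at least one landmark")
    tl = np.asarray(ground_truth_field, dtype=float)
    td = np.asarray(estimated_field, dtype=float)
    h, w = tl.shape[-2:]
    if np.any(landmarks < 0) or np.any(landmarks[:, 0] > h - 1) or np.any(landmarks[:, 1] > w - 1):
        raise ValueError("landmark outside the field domain")
    coords = [landmarks[:, 0], landmarks[:, 1]]
    errs2 = np.zeros(len(landmarks))
    ncomp = max(tl.shape[0], td.shape[0])
    for c in range(ncomp):
        a = (
            ndimage.map_coordinates(tl[c], coords, order=1, mode="nearest")
            if c < tl.shape[0]
            else 0.0
        )
        b = (
            ndimage.map_coordinates(td[c], coords, order=1, mode="nearest")
            if c < td.shape[0]
            else 0.0
        )
        errs2 = errs2 + (a - b) ** 2
    return float(np.mean(np.sqrt(errs2)))
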