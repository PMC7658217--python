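"""Pseudotime, branch probabilities, entropy, imputation and gene trends.

The multiscale diffusion components define the metric space. Pseudotime
starts as shortest-path distance from a chosen start cell over the kNN
graph and is refined by Gaussian-weighted waypoint perspectives until
convergence. Terminal states are detected at diffusion-component extrema
with high pseudotime. Branch probabilities come from an absorbing Markov
chain on a forward-biased version of the graph; the entropy of each cell's
absorption vector is its differentiation potential (high in multipotent
intermediates, exactly zero at terminal states). Diffusion imputation
applies powers of the Markov operator to the expression matrix, and gene
trends are branch-weighted kernel regressions of imputed expression on
pseudotime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.base import BaseEstimator

from .config import TrajectoryParams
from .diffusion import DiffusionOperator, build_knn
from .io import ValidationError
from .preprocess import ExpressionMatrix

_MAX_REFINE_ITER = 25


@dataclass
class TrajectoryResult:
    """Pseudotime in [0,1], terminal set, branch probabilities, entropy."""

    pseudotime: np.ndarray
    start_cell: int
    terminal_cells: np.ndarray
    branch_probs: np.ndarray  # (n, n_terminals), rows sum to 1
    entropy: np.ndarray
    waypoints: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _knn_graph(components: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetric kNN graph weighted by Euclidean distance."""
    graph = build_knn(components, k)
    n = components.shape[0]
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix(
        (graph.distances.ravel(), (rows, graph.indices.ravel())), shape=(n, n)
    )
    return A.maximum(A.T)


def _require_connected(adj: sp.csr_matrix) -> None:
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValidationError(
            f"kNN graph has {n_comp} connected components (sizes {sizes.tolist()}); "
            "increase k or subset the data"
        )


def select_waypoints(
    components: np.ndarray,
    n_waypoints: int,
    start_cell: int,
) -> np.ndarray:
    """Deterministic farthest-point waypoint sampling seeded at the start cell.

    Max-min sampling runs independently along each component dimension;
    the per-dimension lists are interleaved, de-duplicated and truncated
    to ``n_waypoints``. The start cell is always first.
    """
    components = np.asarray(components, dtype=float)
    n, d = components.shape
    if n_waypoints < 1:
        raise ValidationError("n_waypoints must be >= 1")
    if n_waypoints >= n:
        return np.concatenate(
            [[start_cell], np.delete(np.arange(n), start_cell)]
        )
    # sample up to n_waypoints per dimension so the interleaved union can
    # always be filled even when dimensions nominate the same cells
    per_dim = n_waypoints
    lists = []
    for j in range(d):
        x = components[:, j]
        chosen = [start_cell]
        min_dist = np.abs(x - x[start_cell])
        for _ in range(per_dim):
            nxt = int(np.argmax(min_dist))
            if min_dist[nxt] == 0:
                break
            chosen.append(nxt)
            min_dist = np.minimum(min_dist, np.abs(x - x[nxt]))
        lists.append(chosen[1:])
    waypoints = [start_cell]
    seen = {start_cell}
    for round_idx in range(per_dim):
        for lst in lists:
            if round_idx < len(lst) and lst[round_idx] not in seen:
                seen.add(lst[round_idx])
                waypoints.append(lst[round_idx])
        if len(waypoints) >= n_waypoints:
            break
    return np.array(waypoints[:n_waypoints], dtype=int)


def compute_pseudotime(
    components: np.ndarray,
    start_cell: int,
    params: TrajectoryParams | None = None,
    return_raw: bool = False,
):
    """Waypoint-refined pseudotime from a start cell, min-max scaled to [0,1].

    The initial ordering is shortest-path distance from the start cell over
    the kNN graph (edge length = Euclidean distance in the multiscale
    space). Each refinement pass replaces every cell's pseudotime with the
    Gaussian-kernel-weighted average over waypoints of the waypoint's
    pseudotime plus the signed graph distance to the cell (negative for
    cells currently earlier than the waypoint), until the maximum change
    drops below ``tol`` or 25 iterations.
    """
    params = params or TrajectoryParams()
    params.validate()
    components = np.asarray(components, dtype=float)
    n = components.shape[0]
    adj = _knn_graph(components, min(params.k, n - 1))
    _require_connected(adj)
    waypoints = select_waypoints(components, params.n_waypoints, start_cell)
    D = dijkstra(adj, directed=False, indices=waypoints)
    start_row = int(np.flatnonzero(waypoints == start_cell)[0])
    pt = D[start_row].copy()

    sdv = D.std()
    if sdv == 0:
        sdv = 1.0
    W = np.exp(-0.5 * (D / sdv) ** 2)
    W /= W.sum(axis=0, keepdims=True)

    scale = pt.max() if pt.max() > 0 else 1.0
    for _ in range(_MAX_REFINE_ITER):
        wp_pt = pt[waypoints]
        # perspective of each waypoint on each cell: wp_pt +/- graph distance
        sign = np.where(pt[None, :] < wp_pt[:, None], -1.0, 1.0)
        persp = wp_pt[:, None] + sign * D
        new_pt = (W * persp).sum(axis=0)
        new_pt -= new_pt[start_cell]
        shift = np.abs(new_pt - pt).max()
        pt = new_pt
        if shift < params.tol * scale:
            break
    raw = np.maximum(pt, 0.0)
    raw[start_cell] = 0.0
    span = raw.max()
    normalized = raw / span if span > 0 else raw
    if return_raw:
        return normalized, raw, adj, waypoints
    return normalized


def find_terminal_states(
    components: np.ndarray,
    pseudotime: np.ndarray,
    k: int = 15,
    terminal_cells: np.ndarray | None = None,
) -> np.ndarray:
    """Detect terminal cells at component extrema with high pseudotime.

    Candidates are the argmin/argmax cells of every component column.
    A candidate is an *endpoint* when its pseudotime is maximal within
    its own k-neighborhood up to a small slack (mid-branch extrema have
    later neighbors, true endpoints do not). Endpoints whose pseudotime
    exceeds the 75th percentile of the population are retained, then
    de-duplicated so no two retained cells share a k-neighborhood
    (higher-pseudotime cells win). User-supplied ``terminal_cells``
    bypass detection entirely.
    """
    if terminal_cells is not None:
        return np.asarray(terminal_cells, dtype=int)
    components = np.asarray(components, dtype=float)
    pseudotime = np.asarray(pseudotime, dtype=float)
    candidates = np.unique(
        np.concatenate([components.argmax(axis=0), components.argmin(axis=0)])
    )
    graph = build_knn(components, min(k, components.shape[0] - 1))
    slack = 0.002 * (pseudotime.max() - pseudotime.min())
    endpoint = np.array(
        [
            pseudotime[c] >= pseudotime[graph.indices[c]].max() - slack
            for c in candidates
        ]
    )
    if endpoint.any():
        candidates = candidates[endpoint]
    cutoff = np.percentile(pseudotime, 75)
    retained = candidates[pseudotime[candidates] > cutoff]
    if retained.size == 0:
        raise ValidationError(
            "no terminal-state candidates above the pseudotime cutoff; "
            "supply terminal cells manually"
        )
    order = retained[np.argsort(pseudotime[retained])[::-1]]
    kept: list[int] = []
    for c in order:
        neighborhood = set(graph.indices[c].tolist()) | {int(c)}
        clash = any(
            kc in neighborhood or int(c) in set(graph.indices[kc].tolist())
            for kc in kept
        )
        if not clash:
            kept.append(int(c))
    return np.array(sorted(kept), dtype=int)


def absorption_probabilities(
    P: sp.spmatrix | np.ndarray,
    terminal_cells: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Absorption probabilities and entropy for an absorbing Markov chain.

    ``P`` is row-stochastic over all states; rows of terminal states are
    ignored (treated as absorbing). Returns ``(branch_probs, entropy)``
    where ``branch_probs[i, t]`` is the probability that a walk from state
    ``i`` is absorbed at ``terminal_cells[t]`` and entropy is the natural-
    log Shannon entropy of each row.
    """
    P = sp.csr_matrix(P)
    n = P.shape[0]
    terminal_cells = np.asarray(terminal_cells, dtype=int)
    if terminal_cells.size == 0:
        raise ValidationError("terminal_cells must be nonempty")
    is_terminal = np.zeros(n, dtype=bool)
    is_terminal[terminal_cells] = True
    transient = np.flatnonzero(~is_terminal)

    branch = np.zeros((n, terminal_cells.size))
    branch[terminal_cells, np.arange(terminal_cells.size)] = 1.0
    if transient.size:
        Q = P[transient][:, transient]
        R = P[transient][:, terminal_cells]
        A = sp.eye(transient.size, format="csc") - Q.tocsc()
        B = spla.spsolve(A, sp.csc_matrix(R))
        B = np.asarray(B.todense()) if sp.issparse(B) else np.atleast_2d(B)
        B = B.reshape(transient.size, terminal_cells.size)
        row_sums = B.sum(axis=1, keepdims=True)
        ok = row_sums.ravel() > 1e-8
        B[ok] /= row_sums[ok]
        branch[transient] = B
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(branch > 0, np.log(branch), 0.0)
    entropy = -(branch * logp).sum(axis=1)
    entropy[entropy < 0] = 0.0
    entropy[terminal_cells] = 0.0
    return branch, entropy


def branch_probabilities(
    components: np.ndarray,
    pseudotime: np.ndarray,
    terminal_cells: np.ndarray,
    k: int = 15,
    slack: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Branch probabilities from a forward-biased absorbing random walk.

    A directed chain keeps edge i->j of the kNN graph iff
    ``pt(j) > pt(i) - slack * sigma_i`` where sigma_i is the standard
    deviation of pseudotime differences to i's neighbors. Edge weights
    are adaptive Gaussian kernels on component-space distances, rows are
    normalized, terminal cells are made absorbing, and the fundamental
    linear system is solved. Transient cells with no forward path to any
    terminal are assigned to the nearest terminal by graph distance with a
    warning.
    """
    components = np.asarray(components, dtype=float)
    pseudotime = np.asarray(pseudotime, dtype=float)
    terminal_cells = np.asarray(terminal_cells, dtype=int)
    if terminal_cells.size == 0:
        raise ValidationError("terminal_cells must be nonempty")
    n = components.shape[0]
    k = min(k, n - 1)
    graph = build_knn(components, k)

    dt = pseudotime[graph.indices] - pseudotime[:, None]
    sigma = dt.std(axis=1)
    sigma[sigma == 0] = max(np.median(sigma[sigma > 0]), 1e-12) if (sigma > 0).any() else 1e-12
    keep = dt > -slack * sigma[:, None]

    bw = graph.distances[:, max(1, k // 2) - 1].copy()
    bw[bw == 0] = 1.0
    w = np.exp(-(graph.distances**2) / bw[:, None] ** 2)
    w = np.where(keep, w, 0.0)

    rows = np.repeat(np.arange(n), k)
    P = sp.csr_matrix((w.ravel(), (rows, graph.indices.ravel())), shape=(n, n))
    is_terminal = np.zeros(n, dtype=bool)
    is_terminal[terminal_cells] = True

    # reachability: cells from which some terminal is reachable
    reach = _reaches_terminal(P, terminal_cells)
    stranded = np.flatnonzero(~reach & ~is_terminal)
    if stranded.size:
        warnings.warn(
            f"{stranded.size} cells have no forward path to a terminal state; "
            "assigning them to the nearest terminal by graph distance"
        )
        P = P.tolil()
        for i in stranded:
            P.rows[i], P.data[i] = [], []
        P = P.tocsr()

    deg = np.asarray(P.sum(axis=1)).ravel()
    dead = np.flatnonzero((deg == 0) & ~is_terminal)
    alive = deg > 0
    P = sp.diags(np.where(alive, 1.0 / np.maximum(deg, 1e-300), 0.0)) @ P
    # rows for dead/stranded cells are empty; give them a self-loop so the
    # linear system stays well posed, then overwrite their result below
    P = P.tolil()
    for i in np.union1d(stranded, dead):
        P[i, i] = 1.0
    P = P.tocsr()

    fallback = np.union1d(stranded, dead)
    solve_terminals = terminal_cells
    # temporarily treat fallback cells as absorbing so spsolve is nonsingular
    branch, entropy = absorption_probabilities(
        P, np.union1d(solve_terminals, fallback)
    )
    # columns: union sorted — map back to terminal columns only
    union = np.union1d(solve_terminals, fallback)
    col_of = {int(t): j for j, t in enumerate(union)}
    term_cols = [col_of[int(t)] for t in terminal_cells]
    branch = branch[:, term_cols]

    if fallback.size:
        undirected = _knn_graph(components, k)
        dist_to_term = dijkstra(undirected, directed=False, indices=terminal_cells)
        nearest = np.argmin(dist_to_term[:, fallback], axis=0)
        branch[fallback] = 0.0
        branch[fallback, nearest] = 1.0

    row_sums = branch.sum(axis=1, keepdims=True)
    bad = row_sums.ravel() <= 1e-8
    if bad.any():
        undirected = _knn_graph(components, k)
        dist_to_term = dijkstra(undirected, directed=False, indices=terminal_cells)
        nearest = np.argmin(dist_to_term[:, bad], axis=0)
        branch[bad] = 0.0
        branch[np.flatnonzero(bad), nearest] = 1.0
        row_sums = branch.sum(axis=1, keepdims=True)
    branch = np.clip(branch / row_sums, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(branch > 0, np.log(branch), 0.0)
    entropy = -(branch * logp).sum(axis=1)
    entropy[entropy < 0] = 0.0
    entropy[terminal_cells] = 0.0
    return branch, entropy


def _reaches_terminal(P: sp.csr_matrix, terminal_cells: np.ndarray) -> np.ndarray:
    """Boolean mask of states with a directed path to any terminal."""
    n = P.shape[0]
    Pt = (P > 0).T.tocsr()
    reach = np.zeros(n, dtype=bool)
    frontier = list(np.asarray(terminal_cells, dtype=int))
    reach[frontier] = True
    while frontier:
        nxt = Pt[frontier].tocoo().col
        new = np.unique(nxt[~reach[nxt]])
        reach[new] = True
        frontier = new.tolist()
    return reach


def impute_diffusion(
    op: DiffusionOperator,
    expr: ExpressionMatrix,
    t: int = 3,
) -> ExpressionMatrix:
    """MAGIC-style smoothing: apply the Markov operator ``t`` times.

    ``P^t`` is never materialized; each imputed value stays within the
    input range of its gene because ``P`` is row-stochastic.
    """
    if t < 1:
        raise ValidationError("t must be >= 1")
    X = expr.values
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    for _ in range(t):
        X = op.P @ X
    return ExpressionMatrix(
        values=np.asarray(X),
        layer="imputed",
        barcodes=expr.barcodes.copy(),
        features=expr.features.reset_index(drop=True),
    )


def gene_trends(
    values: np.ndarray,
    pseudotime: np.ndarray,
    branch_weights: np.ndarray,
    grid: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Branch-weighted Gaussian kernel regression of expression on pseudotime.

    Evaluated on a uniform grid over [0, 1]; bandwidth by Silverman's rule
    on the pseudotime values. Weights are the branch probabilities of the
    queried terminal state.
    """
    values = np.asarray(values, dtype=float).ravel()
    pseudotime = np.asarray(pseudotime, dtype=float).ravel()
    w = np.asarray(branch_weights, dtype=float).ravel()
    if np.any((w < -1e-9) | (w > 1 + 1e-9)):
        raise ValidationError("branch weights must lie in [0, 1]")
    w = np.clip(w, 0.0, 1.0)
    if w.sum() == 0:
        raise ValidationError("all branch weights are zero")
    n = len(pseudotime)
    sd = pseudotime.std()
    bw = 1.06 * sd * n ** (-1 / 5) if sd > 0 else 0.05
    bw = max(bw, 1e-3)
    xs = np.linspace(0.0, 1.0, grid)
    kern = np.exp(-0.5 * ((xs[:, None] - pseudotime[None, :]) / bw) ** 2) * w[None, :]
    denom = kern.sum(axis=1)
    # guard empty windows far from any weighted cell
    denom[denom == 0] = np.nan
    fitted = kern @ values / denom
    if np.isnan(fitted).any():
        valid = ~np.isnan(fitted)
        fitted = np.interp(xs, xs[valid], fitted[valid])
    return xs, fitted


class TrajectoryModel(BaseEstimator):
    """Absorbing-chain trajectory inference over multiscale components.

    ``fit(X, start_cell=...)`` takes the multiscale diffusion components
    (cells x components; the first ``n_components`` columns are used) and
    produces ``pseudotime_``, ``terminal_cells_``, ``branch_probs_``,
    ``entropy_``, ``waypoints_`` and a :class:`TrajectoryResult` in
    ``result_``.
    """

    def __init__(
        self,
        n_components: int = 10,
        k: int = 15,
        n_waypoints: int = 500,
        tol: float = 1e-3,
        slack: float = 1.0,
    ):
        self.n_components = n_components
        self.k = k
        self.n_waypoints = n_waypoints
        self.tol = tol
        self.slack = slack

    def fit(self, X, y=None, start_cell: int = 0, terminal_cells=None) -> "TrajectoryModel":
        from .diffusion import DiffusionSpace

        if isinstance(X, DiffusionSpace):
            # metric space = eigengap-selected structure components;
            # terminal scan covers the first n_components multiscale columns
            metric_comps = X.structure_components
            scan_comps = X.components[:, : self.n_components]
        else:
            X = np.asarray(X, dtype=float)
            metric_comps = X[:, : self.n_components]
            scan_comps = metric_comps
        params = TrajectoryParams(
            n_components=min(self.n_components, scan_comps.shape[1]),
            k=self.k,
            n_waypoints=self.n_waypoints,
            tol=self.tol,
        )
        pt, _raw, _adj, waypoints = compute_pseudotime(
            metric_comps, start_cell, params, return_raw=True
        )
        terminals = find_terminal_states(
            scan_comps, pt, k=self.k, terminal_cells=terminal_cells
        )
        branch, entropy = branch_probabilities(
            metric_comps, pt, terminals, k=self.k, slack=self.slack
        )
        self.pseudotime_ = pt
        self.terminal_cells_ = terminals
        self.branch_probs_ = branch
        self.entropy_ = entropy
        self.waypoints_ = waypoints
        self.result_ = TrajectoryResult(
            pseudotime=pt,
            start_cell=start_cell,
            terminal_cells=terminals,
            branch_probs=branch,
            entropy=entropy,
            waypoints=waypoints,
        )
        return self
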