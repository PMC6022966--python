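"""Ensemble k-NN graph pseudotime (Wanderlust-style, linear trajectories).

Cells are embedded by a pairwise distance on their full expression
profiles (correlation distance on per-gene standardized log expression
by default). An ensemble of k-nearest-neighbor graphs is built, each
graph retaining a random l-of-k subsample of every cell's neighbors;
per graph, the trajectory of a cell is its weighted shortest-path
distance from a start cell, and the pseudotime (PT) is the across-graph
mean rescaled to [0, 1]. The start cell is the cell with maximal
stromal signature activity; orientation is fixed so that cells with
high proliferative activity receive high PT. PT is unit-free: it orders
cells but carries no time scale.

A two-segment regression of PT against normalized cell rank detects an
initial "slow component" — a flat early stretch of the PT curve — and
reports its breakpoint PT* when the two-segment fit reduces the
residual sum of squares sufficiently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats

from .scoring import gsz_score

_MIN_EDGE_WEIGHT = 1e-12


def pairwise_distances(matrix: pd.DataFrame, metric: str = "spearman") -> pd.DataFrame:
    """Cell-cell distance matrix on a genes x cells table.

    ``spearman`` (default) is 1 - Spearman rank correlation between cell
    columns — correlation on gene ranks, robust to the outlying values
    that dropout zeros produce on the standardized log scale.
    ``correlation`` is 1 - Pearson r; ``euclidean`` the plain L2
    distance. Both correlation metrics are undefined when a cell has
    zero variance across genes (e.g. a noise-free matrix carrying a
    single identical module); a dedicated error points at the euclidean
    alternative.
    """
    x = matrix.to_numpy(dtype=float).T  # cells x genes
    if metric in ("spearman", "correlation"):
        if metric == "spearman":
            x = scipy.stats.rankdata(x, axis=1)
        if np.any(x.std(axis=1) == 0):
            raise ValueError(
                f"{metric} distance undefined: some cell has zero variance "
                "across genes; use metric='euclidean'")
        dist = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(x, metric="correlation"))
    elif metric == "euclidean":
        dist = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(x, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose 'spearman', "
                         "'correlation' or 'euclidean'")
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


@dataclass
class GraphEnsemble:
    """An ensemble of subsampled k-NN graphs over the same cells."""

    graphs: list[nx.Graph]
    cell_ids: list[str]
    k: int
    l: int
    n_graphs: int
    metric: str
    seed: int

    def params(self) -> dict:
        return {"k": self.k, "l": self.l, "n_graphs": self.n_graphs,
                "metric": self.metric, "seed": self.seed}


def _bridge_components(graph: nx.Graph, dist: np.ndarray,
                       ids: list[str]) -> None:
    """Connect a fragmented graph with minimal-distance inter-component edges.

    Repeatedly adds the globally shortest edge joining two distinct
    components until the graph is connected. Deterministic: ties resolve
    to the lowest flat index of the distance matrix.
    """
    index_of = {c: i for i, c in enumerate(ids)}
    while True:
        components = list(nx.connected_components(graph))
        if len(components) <= 1:
            return
        labels = np.empty(len(ids), dtype=int)
        for ci, comp in enumerate(components):
            for cell in comp:
                labels[index_of[cell]] = ci
        cross = labels[:, None] != labels[None, :]
        masked = np.where(cross, dist, np.inf)
        flat = int(np.argmin(masked))
        i, j = divmod(flat, len(ids))
        graph.add_edge(ids[i], ids[j], weight=max(dist[i, j], _MIN_EDGE_WEIGHT))


def build_knn_ensemble(matrix: pd.DataFrame, k: int = 16, l: int = 8,
                       n_graphs: int = 20, metric: str = "spearman",
                       seed: int = 0) -> GraphEnsemble:
    """Build the ensemble of l-of-k subsampled nearest-neighbor graphs.

    Per graph, each cell keeps a uniform without-replacement sample of
    ``l`` of its ``k`` nearest neighbors; edges are symmetrized (an edge
    exists if either endpoint selected it) and weighted by distance.
    Fragmented graphs are repaired with minimal bridging edges so every
    ensemble member is connected. With ``l == k`` there is no subsampling
    randomness and all graphs are identical.
    """
    ids = list(matrix.columns)
    n_cells = len(ids)
    if n_cells < 3:
        raise ValueError("need at least 3 cells to build a k-NN graph")
    if k >= n_cells:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n_cells})")
    if not 1 <= l <= k:
        raise ValueError(f"l={l} must satisfy 1 <= l <= k={k}")
    if n_graphs < 1:
        raise ValueError("n_graphs must be >= 1")

    dist = pairwise_distances(matrix, metric=metric).to_numpy()
    # nearest first, self excluded; mergesort keeps ties deterministic
    neighbor_order = np.argsort(dist, axis=1, kind="mergesort")
    knn = np.empty((n_cells, k), dtype=int)
    for i in range(n_cells):
        row = neighbor_order[i]
        knn[i] = row[row != i][:k]

    rng = np.random.default_rng(seed)
    graphs: list[nx.Graph] = []
    for _ in range(n_graphs):
        graph = nx.Graph()
        graph.add_nodes_from(ids)
        for i in range(n_cells):
            if l == k:
                chosen = knn[i]
            else:
                chosen = knn[i][rng.choice(k, size=l, replace=False)]
            for j in chosen:
                graph.add_edge(ids[i], ids[int(j)],
                               weight=max(dist[i, int(j)], _MIN_EDGE_WEIGHT))
        _bridge_components(graph, dist, ids)
        graphs.append(graph)
    return GraphEnsemble(graphs=graphs, cell_ids=ids, k=k, l=l,
                         n_graphs=n_graphs, metric=metric, seed=seed)


@dataclass
class PseudotimeResult:
    """Per-cell pseudotime in [0, 1] with its provenance."""

    pt: pd.Series
    start_cell: str
    oriented: bool
    per_graph_distances: pd.DataFrame
    params: dict = field(default_factory=dict)


def compute_pseudotime(ensemble: GraphEnsemble, start_cell: str) -> PseudotimeResult:
    """Average shortest-path trajectories over the ensemble and rescale.

    Per graph, a cell's trajectory value is its weighted shortest-path
    distance from ``start_cell``; PT is the across-graph mean, affinely
    rescaled to [0, 1] with PT(start_cell) = 0.
    """
    if start_cell not in ensemble.cell_ids:
        raise KeyError(f"start cell {start_cell!r} not in ensemble")
    ids = ensemble.cell_ids
    distances = np.empty((ensemble.n_graphs, len(ids)))
    for g, graph in enumerate(ensemble.graphs):
        lengths = nx.single_source_dijkstra_path_length(graph, start_cell,
                                                        weight="weight")
        missing = [c for c in ids if c not in lengths]
        if missing:  # bridging guarantees connectivity; violation is a bug
            raise RuntimeError(
                f"internal error: cells unreachable after bridging: {missing[:5]}")
        distances[g] = [lengths[c] for c in ids]
    mean_dist = distances.mean(axis=0)
    span = mean_dist.max() - mean_dist.min()
    if span <= 0:
        raise ValueError("all cells equidistant from start: pseudotime undefined")
    pt = (mean_dist - mean_dist.min()) / span
    return PseudotimeResult(
        pt=pd.Series(pt, index=ids, name="pt"),
        start_cell=start_cell,
        oriented=False,
        per_graph_distances=pd.DataFrame(distances, columns=ids),
        params=ensemble.params(),
    )


def select_start_cell(standardized: pd.DataFrame, stromal_set: list[str],
                      lam: float = 0.0) -> str:
    """Cell with maximal stromal GSZ; ties break to the smaller cell id.

    High stromal signature activity marks early progression, so the
    stromal-high cell anchors PT = 0.
    """
    gsz = gsz_score(standardized, stromal_set, lam=lam, set_name="stromal").values
    best = gsz.max()
    candidates = sorted(gsz.index[gsz == best])
    return candidates[0]


def _decile_means(pt: pd.Series, values: pd.Series) -> tuple[float, float]:
    order = pt.sort_values(kind="mergesort").index
    n_decile = max(1, int(np.ceil(len(order) / 10)))
    bottom = values.loc[order[:n_decile]].mean()
    top = values.loc[order[-n_decile:]].mean()
    return float(bottom), float(top)


def orient_pseudotime(result: PseudotimeResult,
                      proliferative_gsz: pd.Series) -> PseudotimeResult:
    """Flip PT if proliferative activity decreases along it.

    Compares the mean proliferative GSZ of the top and bottom PT deciles;
    if the top decile is less proliferative, PT becomes 1 - PT and the
    anchor cell is re-assigned to the new PT = 0 cell. Idempotent, and an
    involution on a deliberately flipped input.
    """
    missing = result.pt.index.difference(proliferative_gsz.index)
    if len(missing):
        raise ValueError(f"proliferative GSZ missing for cells: {list(missing[:5])}")
    bottom, top = _decile_means(result.pt, proliferative_gsz)
    if top < bottom:
        new_pt = 1.0 - result.pt
        new_start = new_pt.idxmin()
        return replace(result, pt=new_pt.rename("pt"), start_cell=str(new_start),
                       oriented=True)
    return replace(result, oriented=True)


@dataclass
class BreakpointResult:
    """Two-segment fit of PT against normalized cell rank.

    ``pt_star`` is the fitted PT at the breakpoint — the boundary of the
    initial slow component — and is reported only when the two-segment
    fit reduces the residual sum of squares of a single line by at least
    ``threshold`` (relative).
    """

    pt_star: float | None
    slope_early: float
    slope_late: float
    improvement: float
    breakpoint_rank: float
    threshold: float


def detect_slow_component(pt, threshold: float = 0.25) -> BreakpointResult:
    """Fit one- and two-segment lines to the sorted PT-vs-rank curve.

    ``pt`` may be a PseudotimeResult or a per-cell PT vector. The
    breakpoint is scanned over interior ranks; the candidate minimizing
    the total squared error of a continuous two-segment fit wins.
    """
    values = pt.pt if isinstance(pt, PseudotimeResult) else pd.Series(pt)
    y = np.sort(values.to_numpy(dtype=float))
    n = len(y)
    if n < 20:
        raise ValueError("slow-component detection needs >= 20 cells")
    x = np.arange(n) / (n - 1)

    one_segment = np.polynomial.polynomial.polyfit(x, y, 1)
    rss1 = float(np.sum((y - np.polynomial.polynomial.polyval(x, one_segment)) ** 2))

    best = None
    for b in range(3, n - 3):  # interior ranks: >= 3 points per segment
        knot = x[b]
        design = np.column_stack([np.ones(n), x, np.clip(x - knot, 0.0, None)])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        rss2 = float(np.sum((design @ coef - y) ** 2))
        if best is None or rss2 < best[0]:
            best = (rss2, knot, coef)
    rss2, knot, coef = best
    # an (essentially) exact single line has no meaningful breakpoint
    if rss1 <= 1e-12 * n:
        improvement = 0.0
    else:
        improvement = max(0.0, (rss1 - rss2) / rss1)
    pt_at_break = float(coef[0] + coef[1] * knot)
    return BreakpointResult(
        pt_star=pt_at_break if improvement >= threshold else None,
        slope_early=float(coef[1]),
        slope_late=float(coef[1] + coef[2]),
        improvement=improvement,
        breakpoint_rank=float(knot),
        threshold=threshold,
    )


class WanderlustPseudotime:
    """Pseudotime model over one culture's expression matrix.

    Parameters
    ----------
    standardized
        Genes x cells table of per-gene standardized log expression
        (:func:`ptdyn.preprocessing.log_standardize` output).
    stromal_genes, proliferative_genes
        Anchor signatures: the stromal-high cell starts the trajectory,
        and orientation puts proliferative-high cells at high PT.
    k, l, n_graphs, metric
        Ensemble construction parameters; ``l`` of each cell's ``k``
        nearest neighbors are retained per graph.

    Each culture should be fitted separately — the trajectory model is
    linear (non-branching), and mixing genetic backgrounds confounds the
    ordering.
    """

    def __init__(self, standardized: pd.DataFrame, stromal_genes: list[str],
                 proliferative_genes: list[str], k: int = 16, l: int = 8,
                 n_graphs: int = 20, metric: str = "spearman",
                 lam: float = 0.0):
        self.standardized = standardized
        self.stromal_genes = list(stromal_genes)
        self.proliferative_genes = list(proliferative_genes)
        self.k = k
        self.l = l
        self.n_graphs = n_graphs
        self.metric = metric
        self.lam = lam

    @classmethod
    def from_fpkm(cls, matrix: pd.DataFrame, stromal_genes, proliferative_genes,
                  **kwargs) -> "WanderlustPseudotime":
        """Convenience constructor from an FPKM-scale matrix."""
        from .preprocessing import log_standardize
        return cls(log_standardize(matrix), stromal_genes, proliferative_genes,
                   **kwargs)

    def fit(self, seed: int, start_cell: str | None = None,
            orient: bool = True) -> "PseudotimeResults":
        """Build the ensemble, order cells, orient, and wrap the results.

        ``orient=False`` skips the proliferative-signature orientation,
        useful when the start cell is supplied from external knowledge.
        """
        ensemble = build_knn_ensemble(self.standardized, k=self.k, l=self.l,
                                      n_graphs=self.n_graphs, metric=self.metric,
                                      seed=seed)
        if start_cell is None:
            start_cell = select_start_cell(self.standardized, self.stromal_genes,
                                           lam=self.lam)
        raw = compute_pseudotime(ensemble, start_cell)
        if orient:
            proliferative = gsz_score(self.standardized, self.proliferative_genes,
                                      lam=self.lam, set_name="proliferative").values
            raw = orient_pseudotime(raw, proliferative)
        return PseudotimeResults(self, raw, ensemble)


class PseudotimeResults:
    """Fitted pseudotime with diagnostics.

    Attributes
    ----------
    pt : pandas.Series
        Per-cell pseudotime in [0, 1].
    start_cell : str
        The anchor cell (PT = 0 after orientation).
    """

    def __init__(self, model: WanderlustPseudotime, result: PseudotimeResult,
                 ensemble: GraphEnsemble):
        self.model = model
        self.result = result
        self.ensemble = ensemble
        self._breakpoint: BreakpointResult | None = None

    @property
    def pt(self) -> pd.Series:
        return self.result.pt

    @property
    def start_cell(self) -> str:
        return self.result.start_cell

    @property
    def params(self) -> dict:
        return dict(self.result.params)

    def breakpoint(self, threshold: float = 0.25) -> BreakpointResult:
        """Slow-component breakpoint (PT*) of the PT-vs-rank curve."""
        if self._breakpoint is None or self._breakpoint.threshold != threshold:
            self._breakpoint = detect_slow_component(self.result, threshold)
        return self._breakpoint

    def summary(self) -> str:
        bp = self.breakpoint()
        lines = [
            "Ensemble k-NN pseudotime",
            "=" * 48,
            f"cells                 {len(self.pt)}",
            f"start cell            {self.start_cell}",
            f"oriented              {self.result.oriented}",
            f"k / l / n_graphs      {self.ensemble.k} / {self.ensemble.l} / "
            f"{self.ensemble.n_graphs}",
            f"metric                {self.ensemble.metric}",
            f"seed                  {self.ensemble.seed}",
            "-" * 48,
            f"slow component        {'present' if bp.pt_star is not None else 'absent'}",
            f"PT*                   "
            f"{'%.3f' % bp.pt_star if bp.pt_star is not None else '--'}",
            f"early / late slope    {bp.slope_early:.3f} / {bp.slope_late:.3f}",
            f"2-segment RSS gain    {bp.improvement:.3f}",
        ]
        return "\n".join(lines)
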