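"""Differential expression dynamics along precomputed lineages.

Given a lineage (ordered cells with pseudotime, condition labels, and a 2D
embedding), the workflow is:

1. screen for *dynamic* genes with a covariate-adjusted Moran's I
   autocorrelation test on a kNN graph of the embedding, separately per
   condition (q < 0.05 and z above a threshold);
2. compress each condition's cells into meta-cells (default 500) by a sliding
   window along pseudotime;
3. smooth each gene's meta-cell profile with a local-linear smoother and
   integrate it over the common pseudotime support;
4. score divergence as the absolute difference of the two conditions' areas
   under the curve (the *differential expression score*; default call
   threshold 50 in pseudotime x log-expression units);
5. for gene sets, average member genes per meta-cell, log-transform, and test
   condition differences with a label-permutation pattern test whose per-gene
   p-values can be combined with the logit method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .dataset import Dataset
from .hurdle import bh_adjust
from .simulate import LineageView, seed_sequence

__all__ = [
    "KnnGraph",
    "MoranResult",
    "MetaCellMatrix",
    "ScoreTable",
    "build_knn_graph",
    "morans_test",
    "select_dynamic_genes",
    "make_metacells",
    "smooth_curve",
    "de_score",
    "pathway_trajectory",
    "combine_p_logit",
    "TrajectoryDivergence",
]


# ----------------------------------------------------------------- kNN graph

@dataclass
class KnnGraph:
    """Symmetric non-negative weights with zero diagonal over a set of cells."""

    weights: np.ndarray
    k: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if (w.sum(axis=1) == 0).any():
            raise ValueError("every node needs at least one neighbor")


def build_knn_graph(embedding: np.ndarray, k: int) -> KnnGraph:
    """Union-symmetrized k-nearest-neighbor graph with row-standardized weights.

    Euclidean distances; ties broken deterministically by index order.
    """
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    if not np.isfinite(emb).all():
        raise ValueError("embedding must be finite")
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} cells, got {n}")
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1, algorithm="brute").fit(emb)
    _, idx = nn.kneighbors(emb)
    adj = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k_eff]
        adj[i, neigh] = 1.0
    adj = np.maximum(adj, adj.T)  # union symmetrization
    w = adj / adj.sum(axis=1, keepdims=True)
    return KnnGraph(weights=w, k=k_eff)


# --------------------------------------------------------------- Moran test

@dataclass
class MoranResult:
    I: float
    expected_I: float
    var_I: float
    z: float
    p: float
    q: float = np.nan
    status: str = "ok"


def morans_test(y, g: KnnGraph, X: np.ndarray | None = None) -> MoranResult:
    """Moran's I on covariate-residualized values with randomization moments.

    ``y`` is residualized on ``X`` (an intercept is used when ``X`` is None);
    I = (N/W) * sum_ij w_ij r_i r_j / sum_i r_i^2, with the usual
    randomization-null expectation and variance, and a one-sided (positive
    autocorrelation) normal p-value — dynamic genes cluster on the graph.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    ss = float(r @ r)
    if ss <= 1e-12 * n:
        return MoranResult(np.nan, np.nan, np.nan, np.nan, np.nan, status="zero variance")
    w = g.weights
    W = float(w.sum())
    I = (n / W) * float(r @ w @ r) / ss

    e_i = -1.0 / (n - 1)
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    rs, cs = w.sum(axis=1), w.sum(axis=0)
    s2 = float(((rs + cs) ** 2).sum())
    b2 = n * float((r**4).sum()) / ss**2
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * W * W) - b2 * (
        (n * n - n) * s1 - 2 * n * s2 + 6 * W * W
    )
    den = (n - 1) * (n - 2) * (n - 3) * W * W
    var = num / den - e_i * e_i
    var = max(var, 1e-300)
    z = (I - e_i) / np.sqrt(var)
    p = float(stats.norm.sf(z))
    return MoranResult(I=I, expected_I=e_i, var_I=var, z=z, p=p)


def select_dynamic_genes(
    results: dict[str, MoranResult], q_max: float = 0.05, stat_min: float = 10.0,
    on: str = "z",
) -> set[str]:
    """Genes with BH q < q_max and z (or I, with ``on='I'``) >= stat_min.

    The published rule "adjusted p < 0.05 and Moran's I >= 10" can only refer
    to the z-statistic since the coefficient itself is bounded near 1; the
    threshold therefore applies to ``z`` by default.
    """
    named = [(gene, r) for gene, r in results.items() if r.status == "ok"]
    if not named:
        return set()
    q = bh_adjust([r.p for _, r in named])
    out = set()
    for (gene, r), qv in zip(named, q):
        r.q = float(qv)
        value = r.z if on == "z" else r.I
        if qv < q_max and value >= stat_min:
            out.add(gene)
    return out


# --------------------------------------------------------------- meta-cells

@dataclass
class MetaCellMatrix:
    """Sliding-window averages along pseudotime for one condition."""

    values: pd.DataFrame  # meta-cells x genes
    pseudotime: np.ndarray
    condition: str
    window: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pseudotime) < 0):
            raise ValueError("meta-cell pseudotime must be nondecreasing")


def make_metacells(
    lv: LineageView, d: Dataset, n_meta: int = 500, condition: str | None = None
) -> dict[str, MetaCellMatrix] | MetaCellMatrix:
    """Compress a lineage into meta-cells per condition.

    Window length is ``max(2, ceil(n_cells / 50))``; window starts are evenly
    spaced so exactly ``min(n_meta, n_cells - w + 1)`` windows are produced.
    Meta-cell expression is the mean normalized expression over the window.
    """
    if d.norm is None:
        raise ValueError("normalized layer missing; run normalize_log first")
    conditions = [condition] if condition else list(dict.fromkeys(lv.condition))
    out = {}
    norm_cols = d.cells.index.get_indexer(pd.Index(lv.cell_ids))
    if (norm_cols < 0).any():
        raise KeyError("lineage references cells absent from the dataset")
    for cond in conditions:
        mask = lv.condition == cond
        t = lv.pseudotime[mask]
        cols = norm_cols[mask]
        n_cells = len(t)
        expr = np.asarray(d.norm[:, cols].todense())  # genes x cells, pseudotime order
        w = max(2, int(np.ceil(n_cells / 50)))
        if n_cells < w:
            warnings.warn(
                f"condition {cond!r} has {n_cells} cells < window {w}; "
                "emitting a single whole-lineage meta-cell"
            )
            starts = np.array([0])
            w = n_cells
        else:
            n_windows = min(n_meta, n_cells - w + 1)
            starts = np.unique(
                np.round(np.linspace(0, n_cells - w, n_windows)).astype(int)
            )
        csum = np.cumsum(np.pad(expr, ((0, 0), (1, 0))), axis=1)
        tsum = np.cumsum(np.pad(t, (1, 0)))
        vals = (csum[:, starts + w] - csum[:, starts]) / w
        meta_t = (tsum[starts + w] - tsum[starts]) / w
        out[cond] = MetaCellMatrix(
            values=pd.DataFrame(vals.T, columns=d.genes.index),
            pseudotime=meta_t,
            condition=cond,
            window=w,
        )
    return out[condition] if condition else out


# ---------------------------------------------------------------- smoothing

def _local_linear(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float) -> np.ndarray:
    """Tricube-weighted local-linear smoother evaluated on ``grid``."""
    n = len(x)
    m = max(2, int(np.ceil(span * n)))
    # distances from each grid point to every sample point
    dist = np.abs(grid[:, None] - x[None, :])
    h = np.partition(dist, m - 1, axis=1)[:, m - 1]
    h = np.maximum(h, 1e-12)
    u = np.clip(dist / h[:, None], 0.0, 1.0)
    wgt = (1.0 - u**3) ** 3
    # closed-form weighted linear fit per grid point
    sw = wgt.sum(axis=1)
    sx = (wgt * x).sum(axis=1)
    sy = (wgt * y).sum(axis=1)
    sxx = (wgt * x * x).sum(axis=1)
    sxy = (wgt * x * y).sum(axis=1)
    denom = sw * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(np.abs(denom) > 1e-12, (sw * sxy - sx * sy) / denom, 0.0)
        intercept = (sy - slope * sx) / sw
    return intercept + slope * grid


def smooth_curve(
    m: MetaCellMatrix,
    gene: str,
    grid: np.ndarray | None = None,
    grid_size: int = 500,
    span: float = 0.3,
    grid_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Local-linear smoothed expression curve for one gene on a pseudotime grid.

    Returns ``(grid, fitted)``.  When scoring two conditions, pass the same
    explicit ``grid`` (spanning the intersection of their pseudotime ranges).
    """
    if len(m.pseudotime) < 10:
        raise ValueError("need at least 10 meta-cells to smooth")
    if grid is None:
        lo, hi = grid_range if grid_range else (m.pseudotime[0], m.pseudotime[-1])
        if hi <= lo:
            raise ValueError("conditions have no common pseudotime support")
        grid = np.linspace(lo, hi, grid_size)
    y = m.values[gene].to_numpy(dtype=float)
    return grid, _local_linear(m.pseudotime, y, grid, span)


def common_grid(a: MetaCellMatrix, b: MetaCellMatrix, grid_size: int = 500) -> np.ndarray:
    lo = max(a.pseudotime[0], b.pseudotime[0])
    hi = min(a.pseudotime[-1], b.pseudotime[-1])
    if hi <= lo:
        raise ValueError("conditions have disjoint pseudotime ranges")
    return np.linspace(lo, hi, grid_size)


# ------------------------------------------------------------------- scoring

@dataclass
class ScoreTable:
    """Per-gene AUC-difference scores with the calling rule applied."""

    frame: pd.DataFrame  # columns: auc_control, auc_case, de_score, called
    threshold: float

    @property
    def called(self) -> pd.Index:
        return self.frame.index[self.frame["called"]]

    def summary(self) -> str:
        f = self.frame
        return "\n".join(
            [
                f"Differential expression score (threshold {self.threshold})",
                f"genes scored   {len(f)}",
                f"genes called   {int(f['called'].sum())}",
                f"max score      {f['de_score'].max():.1f}" if len(f) else "max score      n/a",
            ]
        )


def de_score(
    grid: np.ndarray,
    curve_control: np.ndarray,
    curve_case: np.ndarray,
    threshold: float = 50.0,
) -> tuple[float, float, float, bool]:
    """AUC by trapezoid rule; score = |auc_case - auc_control|; called at >= threshold."""
    if len(curve_control) != len(grid) or len(curve_case) != len(grid):
        raise ValueError("curves must share the evaluation grid")
    auc_c = float(np.trapezoid(curve_control, grid))
    auc_d = float(np.trapezoid(curve_case, grid))
    score = abs(auc_d - auc_c)
    return auc_c, auc_d, score, score >= threshold


# -------------------------------------------------------- pathway aggregates

def _pattern_stat(
    t: np.ndarray, y: np.ndarray, labels: np.ndarray, grid: np.ndarray, span: float
) -> float:
    ctrl = labels == 0
    a = _local_linear(t[ctrl], y[ctrl], grid, span)
    b = _local_linear(t[~ctrl], y[~ctrl], grid, span)
    return float(np.trapezoid((a - b) ** 2, grid))


def pattern_test(
    t: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 200,
    n_bins: int = 20,
    span: float = 0.3,
    grid_size: int = 100,
    seed: int = 0,
) -> float:
    """Permutation test for a condition difference in a pseudotime profile.

    Statistic: integrated squared difference of the two conditions' smoothed
    curves.  Null: condition labels permuted within pseudotime bins, which
    preserves the pseudotime distribution of each condition.
    """
    labels = np.asarray(labels)
    lo, hi = float(t.min()), float(t.max())
    grid = np.linspace(lo, hi, grid_size)
    obs = _pattern_stat(t, y, labels, grid, span)
    bins = np.clip(
        np.searchsorted(np.linspace(lo, hi, n_bins + 1)[1:-1], t, side="right"),
        0,
        n_bins - 1,
    )
    rng = np.random.default_rng(seed_sequence(seed, "pattern"))
    exceed = 0
    perm = labels.copy()
    for _ in range(n_perm):
        for b in range(n_bins):
            sel = np.flatnonzero(bins == b)
            if len(sel) > 1:
                perm[sel] = perm[sel[rng.permutation(len(sel))]]
        if _pattern_stat(t, y, perm, grid, span) >= obs:
            exceed += 1
    return (1.0 + exceed) / (1.0 + n_perm)


def pathway_trajectory(
    metacells: dict[str, MetaCellMatrix],
    gene_set: set[str],
    grid_size: int = 200,
    span: float = 0.3,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Pathway-average trajectory per condition plus per-gene pattern-test p's.

    Per meta-cell, member-gene expression is averaged and log(1 + .)
    transformed; the two conditions' smoothed aggregate curves are returned
    together with per-gene permutation p-values (BH-adjusted) for
    condition-dependent dynamics.
    """
    conds = sorted(metacells)
    present = [g for g in gene_set if g in metacells[conds[0]].values.columns]
    missing = sorted(set(gene_set) - set(present))
    if not present:
        raise ValueError(f"no gene of the set is present in the meta-cell matrix")
    a, b = (metacells[c] for c in conds[:2])
    grid = common_grid(a, b, grid_size)
    curves = {}
    for cond in conds[:2]:
        m = metacells[cond]
        agg = np.log1p(m.values[present].mean(axis=1).to_numpy())
        curves[cond] = _local_linear(m.pseudotime, agg, grid, span)

    t_all = np.concatenate([a.pseudotime, b.pseudotime])
    labels = np.concatenate([np.zeros(len(a.pseudotime), int), np.ones(len(b.pseudotime), int)])
    p_genes = {}
    for gi, gene in enumerate(present):
        y_all = np.concatenate(
            [a.values[gene].to_numpy(float), b.values[gene].to_numpy(float)]
        )
        p_genes[gene] = pattern_test(
            t_all, y_all, labels, n_perm=n_perm, span=span, seed=seed + gi
        )
    genes = list(p_genes)
    q = bh_adjust([p_genes[g] for g in genes])
    per_gene = pd.DataFrame({"p": [p_genes[g] for g in genes], "q": q}, index=genes)
    return {"grid": grid, "curves": curves, "per_gene": per_gene, "missing": missing}


# --------------------------------------------------------- p-value combining

def combine_p_logit(p, eps: float = 1e-15) -> float:
    """Logit-method meta p-value.

    C = -sum logit(p_i); t = C / sqrt(k pi^2 (5k + 2) / (3 (5k + 4))); the
    meta p is the upper tail of Student's t with 5k + 4 degrees of freedom.
    Boundary p-values are clamped to [eps, 1 - eps] with a warning.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values at {0, 1} clamped for the logit transform")
        p = np.clip(p, eps, 1.0 - eps)
    k = p.size
    c = -np.sum(np.log(p / (1.0 - p)))
    scale = np.sqrt(k * np.pi**2 * (5 * k + 2) / (3.0 * (5 * k + 4)))
    t = c / scale
    return float(stats.t.sf(t, df=5 * k + 4))


# ------------------------------------------------------------ model object

@dataclass
class TrajectoryResults:
    """Dynamic-gene screen plus divergence scores for one lineage."""

    scores: ScoreTable
    dynamic_genes: dict[str, set[str]]
    candidate_genes: set[str]
    moran: dict[str, dict[str, MoranResult]] = field(repr=False, default_factory=dict)

    def summary(self) -> str:
        dyn = {c: len(s) for c, s in self.dynamic_genes.items()}
        return "\n".join(
            [
                "Trajectory divergence analysis",
                f"dynamic genes per condition  {dyn}",
                f"candidate (union)            {len(self.candidate_genes)}",
                self.scores.summary(),
            ]
        )

    def plot_gene(self, analysis: "TrajectoryDivergence", gene: str, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = analysis.grid
        for cond, m in analysis.metacells.items():
            ax.scatter(m.pseudotime, m.values[gene], s=4, alpha=0.3)
            _, fitted = smooth_curve(m, gene, grid=grid, span=analysis.span)
            ax.plot(grid, fitted, label=cond)
        ax.set_xlabel("pseudotime")
        ax.set_ylabel("normalized expression")
        ax.set_title(gene)
        ax.legend()
        return ax


class TrajectoryDivergence:
    """End-to-end differential-dynamics model for one lineage.

    ``TrajectoryDivergence(dataset, lineage).fit()`` screens dynamic genes per
    condition with the covariate-adjusted Moran test, builds meta-cells,
    smooths candidate genes and scores the AUC difference.
    """

    def __init__(
        self,
        dataset: Dataset,
        lineage: LineageView,
        k: int = 15,
        n_meta: int = 500,
        span: float = 0.3,
        grid_size: int = 500,
        q_max: float = 0.05,
        stat_min: float = 10.0,
        score_threshold: float = 50.0,
        covariates: tuple[str, ...] = (),
    ):
        self.dataset = dataset
        self.lineage = lineage
        self.k = k
        self.n_meta = n_meta
        self.span = span
        self.grid_size = grid_size
        self.q_max = q_max
        self.stat_min = stat_min
        self.score_threshold = score_threshold
        self.covariates = covariates
        self.metacells: dict[str, MetaCellMatrix] = {}
        self.grid: np.ndarray | None = None

    def _condition_moran(self, cond: str) -> dict[str, MoranResult]:
        lv = self.lineage
        d = self.dataset
        mask = lv.condition == cond
        graph = build_knn_graph(lv.embedding[mask], self.k)
        cols = d.cells.index.get_indexer(pd.Index(lv.cell_ids[mask]))
        expr = np.asarray(d.norm[:, cols].todense())
        cells = d.cells.iloc[cols]
        X = np.ones((mask.sum(), 1))
        if self.covariates:
            parts = [X]
            for cov in self.covariates:
                col = cells[cov]
                if pd.api.types.is_numeric_dtype(col):
                    parts.append(col.to_numpy(float)[:, None])
                else:
                    parts.append(pd.get_dummies(col, drop_first=True, dtype=float).to_numpy())
            X = np.column_stack(parts)
        return {
            gene: morans_test(expr[gi], graph, X)
            for gi, gene in enumerate(d.genes.index)
        }

    def fit(self) -> TrajectoryResults:
        conds = list(dict.fromkeys(self.lineage.condition))
        if "control" in conds:  # control first so score columns are labelled right
            conds = ["control"] + [c for c in conds if c != "control"]
        if len(conds) < 2:
            raise ValueError("both conditions must be present for differential scoring")
        moran = {c: self._condition_moran(c) for c in conds}
        dynamic = {
            c: select_dynamic_genes(moran[c], self.q_max, self.stat_min) for c in conds
        }
        candidates = set().union(*dynamic.values())
        self.metacells = make_metacells(self.lineage, self.dataset, self.n_meta)
        a, b = (self.metacells[c] for c in conds[:2])
        self.grid = common_grid(a, b, self.grid_size)
        rows = []
        for gene in sorted(candidates):
            _, ca = smooth_curve(a, gene, grid=self.grid, span=self.span)
            _, cb = smooth_curve(b, gene, grid=self.grid, span=self.span)
            auc_a, auc_b, score, called = de_score(
                self.grid, ca, cb, self.score_threshold
            )
            rows.append((gene, auc_a, auc_b, score, called))
        frame = pd.DataFrame(
            rows, columns=["gene_id", "auc_control", "auc_case", "de_score", "called"]
        ).set_index("gene_id")
        return TrajectoryResults(
            scores=ScoreTable(frame=frame, threshold=self.score_threshold),
            dynamic_genes=dynamic,
            candidate_genes=candidates,
            moran=moran,
        )
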