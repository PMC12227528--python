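"""Per-cell-type DEG burden from fixed-size resampled draws.

Cluster sizes differ wildly between cell types, and DEG counts grow with the
number of cells tested; drawing a fixed number of cells (default 500) from
each diagnosis group per cell type makes DEG counts comparable across cell
types.  The draw is repeated (default 10 times) and cell types are compared
by exact two-sided Mann-Whitney U tests on their replicate DEG counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset
from .de import DEConfig, build_design, _fit_all_genes
from .hurdle import bh_adjust
from .simulate import seed_sequence

__all__ = ["BurdenTable", "BurdenAnalysis", "burden_analysis", "compare_burden", "mannwhitney_exact"]


@dataclass
class BurdenTable:
    """Long-format (cell_type, replicate) -> DEG count, plus the policy used."""

    frame: pd.DataFrame  # columns: cell_type, replicate, n_deg
    draw_size: int
    n_replicates: int
    config: DEConfig
    excluded: list[str]

    def mean_burden(self) -> pd.Series:
        return self.frame.groupby("cell_type", observed=True)["n_deg"].mean()

    def summary(self) -> str:
        means = self.mean_burden().sort_values(ascending=False)
        lines = [
            f"DEG burden ({self.draw_size} cells/group, {self.n_replicates} replicates)",
            "mean DEG count by cell type:",
        ]
        lines += [f"  {ct:<12s} {m:8.1f}" for ct, m in means.items()]
        if self.excluded:
            lines.append(f"excluded (too few cells): {', '.join(self.excluded)}")
        return "\n".join(lines)

    def plot_box(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = self.mean_burden().sort_values(ascending=False).index
        data = [self.frame.loc[self.frame["cell_type"] == ct, "n_deg"] for ct in order]
        ax.boxplot(data, tick_labels=list(order))
        ax.set_ylabel("DEG count")
        return ax


class BurdenAnalysis:
    """``BurdenAnalysis(dataset, config).fit(draw_size, n_replicates)``.

    Per cell type and replicate: draw ``draw_size`` cells per diagnosis group
    without replacement (no donor balancing — the fixed draw is the
    normalizer), fit the hurdle test per gene with the full covariate design,
    and count genes passing the calling rule.
    """

    def __init__(self, dataset: Dataset, config: DEConfig | None = None):
        if dataset.norm is None:
            raise ValueError("normalized layer missing; run normalize_log first")
        self.dataset = dataset
        self.config = config or DEConfig()

    def _eligible(self, draw_size: int) -> tuple[list[str], list[str]]:
        counts = self.dataset.cells.groupby(
            ["cell_type", "diagnosis"], observed=True
        ).size().unstack(fill_value=0)
        ok, excluded = [], []
        for ct, row in counts.iterrows():
            if row.get("case", 0) >= draw_size and row.get("control", 0) >= draw_size:
                ok.append(ct)
            else:
                excluded.append(ct)
        return ok, excluded

    def _replicate_count(self, cell_type: str, replicate: int, draw_size: int) -> int:
        cfg = self.config
        d = self.dataset
        cells = d.cells[d.cells["cell_type"] == cell_type]
        rng = np.random.default_rng(
            seed_sequence(cfg.seed, cell_type, replicate, "burden")
        )
        chosen = []
        for level in ("control", "case"):
            ids = np.sort(cells.index[cells["diagnosis"] == level].to_numpy())
            chosen.append(rng.choice(ids, size=draw_size, replace=False))
        idx = pd.Index(np.concatenate(chosen))
        pos = d.cells.index.get_indexer(idx)
        norm = np.asarray(d.norm[:, pos].todense())
        sub = d.cells.loc[idx]
        design = build_design(sub, cfg.covariates, cfg.test_term)
        frame = _fit_all_genes(norm, design, d.genes.index, cfg.test_term)
        raw_design = build_design(sub, (), cfg.test_term)
        raw = _fit_all_genes(norm, raw_design, d.genes.index, cfg.test_term)
        ok = frame["p"].notna()
        q = np.full(len(frame), np.nan)
        q[ok.to_numpy()] = bh_adjust(frame.loc[ok, "p"].to_numpy())
        called = (
            (q < cfg.q_threshold)
            & (frame["log2fc_model"].abs().to_numpy() >= np.log2(cfg.fc_threshold))
            & (raw["log2fc_model"].abs().to_numpy() >= cfg.raw_log2fc_min)
        )
        return int(np.nansum(called))

    def fit(self, draw_size: int = 500, n_replicates: int = 10) -> BurdenTable:
        eligible, excluded = self._eligible(draw_size)
        if not eligible:
            raise ValueError(
                f"no cell type has {draw_size} cells in both groups; "
                "reduce draw_size"
            )
        records = [
            (ct, r, self._replicate_count(ct, r, draw_size))
            for ct in eligible
            for r in range(n_replicates)
        ]
        frame = pd.DataFrame.from_records(
            records, columns=["cell_type", "replicate", "n_deg"]
        )
        return BurdenTable(
            frame=frame,
            draw_size=draw_size,
            n_replicates=n_replicates,
            config=self.config,
            excluded=excluded,
        )


def burden_analysis(
    d: Dataset,
    cfg: DEConfig | None = None,
    draw_size: int = 500,
    n_replicates: int = 10,
) -> BurdenTable:
    """Fixed-size resampled DEG counts per cell type (see module docs)."""
    return BurdenAnalysis(d, cfg).fit(draw_size=draw_size, n_replicates=n_replicates)


def mannwhitney_exact(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact null for n <= 20 per side and no ties,
    normal approximation with tie correction otherwise.  Returns (U, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (not ties and max(len(x), len(y)) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_burden(b: BurdenTable) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests on replicate DEG counts, BH-adjusted."""
    groups = {
        ct: g["n_deg"].to_numpy()
        for ct, g in b.frame.groupby("cell_type", observed=True)
    }
    for ct, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"cell type {ct!r} has fewer than 2 replicates")
    rows = []
    for a, c in itertools.combinations(sorted(groups), 2):
        u, p = mannwhitney_exact(groups[a], groups[c])
        rows.append((a, c, u, p))
    out = pd.DataFrame(rows, columns=["cell_type_a", "cell_type_b", "U", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else out["p"]
    return out
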