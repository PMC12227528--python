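"""Donor-balanced differential expression with a donor-label permutation null.

Per-cell-type workflow (mirroring the case-control study design this package
models): donors contributing fewer cells than a quarter of the per-donor
average are dropped, an equal number of cells is drawn from every remaining
donor, the hurdle test is fitted per gene with the full covariate design, and
the routine is repeated (default 10 times) with the per-gene p-value and model
fold change taken as the median across repeats.  Calls require a BH q-value
below threshold, a combined model fold change of at least ``fc_threshold``
(default 14%), and a covariate-free "raw" refit fold change of at least
``raw_log2fc_min`` on the log2 scale.

Because cells of one donor are not independent, the analytic p-values can be
anti-conservative when donor effects are real; the donor-label permutation
null (all cells of a donor move together, group sizes preserved) provides
empirical p-values and an empirical FDR that are exact at the donor level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataset import Dataset
from .hurdle import (
    CollinearDesignError,
    HurdleModel,
    NotDetectedError,
    bh_adjust,
)
from .fitters import SingularDesignError
from .simulate import seed_sequence

__all__ = [
    "DEConfig",
    "DEResults",
    "NullDistribution",
    "CellTypeDE",
    "select_balanced_cells",
    "run_de",
    "permutation_null",
    "interaction_lrt",
    "build_design",
]

_LN2 = np.log(2.0)

DEFAULT_COVARIATES = ("detection_rate", "age", "sex", "capture_batch", "seq_batch")


@dataclass
class DEConfig:
    """Calling thresholds and resampling policy for one contrast."""

    q_threshold: float = 0.05
    fc_threshold: float = 1.14
    raw_log2fc_min: float = 0.1
    n_repeats: int = 10
    contributor_min_frac: float = 0.25
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    test_term: str = "diagnosis"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold is a ratio and must exceed 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 <= self.contributor_min_frac < 1.0:
            raise ValueError("contributor_min_frac must be in [0, 1)")


class BalancedDesignError(ValueError):
    """A diagnosis group retains fewer than 2 donors."""


def build_design(
    cells: pd.DataFrame,
    covariates: tuple[str, ...],
    test_term: str = "diagnosis",
    case_level: str = "case",
    extra: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Design matrix: intercept, 0/1 test term, then covariates.

    Numeric covariates enter as-is; categorical ones are dummy-coded with the
    first level dropped.  Columns constant over the supplied cells are
    removed (the test term excepted — a constant test term is an error at fit
    time, not here).
    """
    design = pd.DataFrame(index=cells.index)
    design["Intercept"] = 1.0
    design[test_term] = (cells[test_term] == case_level).astype(float)
    for cov in covariates:
        if cov not in cells.columns:
            raise KeyError(f"covariate {cov!r} not in cell table")
        col = cells[cov]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            design[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                design[c] = dummies[c]
    if extra:
        for name, values in extra.items():
            design[name] = np.asarray(values, dtype=float)
    keep = [
        c
        for c in design.columns
        if c in ("Intercept", test_term) or design[c].nunique() > 1
    ]
    return design[keep]


def select_balanced_cells(
    d: Dataset, cell_type: str, cfg: DEConfig, repeat_index: int = 0
) -> pd.Index:
    """Donor-balanced cell draw for one resampling repeat.

    Donors contributing fewer cells than ``contributor_min_frac`` times the
    per-donor average are removed; from each retained donor exactly
    ``min(counts)`` cells are drawn without replacement, seeded by
    ``(cfg.seed, cell_type, repeat_index)``.
    """
    cells = d.cells[d.cells["cell_type"] == cell_type]
    if cells.empty:
        raise ValueError(f"no cells of type {cell_type!r}")
    counts = cells.groupby("donor_id", observed=True).size()
    cutoff = cfg.contributor_min_frac * counts.mean()
    retained = counts[counts >= cutoff] if cfg.contributor_min_frac > 0 else counts
    kept = cells[cells["donor_id"].isin(retained.index)]
    for level, grp in kept.groupby("diagnosis", observed=True):
        if grp["donor_id"].nunique() < 2:
            raise BalancedDesignError(
                f"group {level!r} has fewer than 2 donors after the contributor filter"
            )
    if kept["diagnosis"].nunique() < 2:
        raise BalancedDesignError("both diagnosis groups must be present")
    n_eq = int(retained.min())
    rng = np.random.default_rng(seed_sequence(cfg.seed, cell_type, repeat_index, "balance"))
    chosen: list[np.ndarray] = []
    for donor in retained.index:  # donor order fixed by groupby (sorted)
        # sort ids so the draw depends only on the id set, not on column order
        ids = np.sort(kept.index[kept["donor_id"] == donor].to_numpy())
        if len(ids) == n_eq:
            chosen.append(ids)
        else:
            chosen.append(rng.choice(ids, size=n_eq, replace=False))
    return pd.Index(np.concatenate(chosen))


@dataclass
class DEResults:
    """Per-gene table for one cell type/contrast plus contrast metadata."""

    frame: pd.DataFrame
    cell_type: str
    config: DEConfig
    n_repeats_run: int = 0
    interaction: bool = False

    @property
    def called(self) -> pd.Index:
        return self.frame.index[self.frame["called"]]

    def summary(self) -> str:
        f = self.frame
        tested = f["status"].eq("ok").sum()
        lines = [
            f"Differential expression — cell type {self.cell_type}",
            f"genes tested        {tested} / {len(f)}",
            f"repeats             {self.n_repeats_run}",
            f"called (q<{self.config.q_threshold}, |log2FC|>={np.log2(self.config.fc_threshold):.3f}, "
            f"|raw|>={self.config.raw_log2fc_min})  {int(f['called'].sum())}",
            f"median |log2FC| among calls  "
            f"{f.loc[f['called'], 'log2fc_model'].abs().median():.3f}"
            if f["called"].any()
            else "median |log2FC| among calls  n/a",
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None):
        """Volcano plot: model log2 fold change vs -log10 q."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.frame
        q = np.clip(f["q"].to_numpy(float), 1e-300, 1.0)
        ax.scatter(f["log2fc_model"], -np.log10(q), s=6,
                   c=np.where(f["called"], "crimson", "grey"), alpha=0.6)
        ax.set_xlabel("model log2 FC")
        ax.set_ylabel("-log10 q")
        ax.set_title(self.cell_type)
        return ax


def _fit_all_genes(
    norm: np.ndarray, design: pd.DataFrame, gene_ids, test_term: str
) -> pd.DataFrame:
    """Fit the hurdle model for every gene on a fixed design; never drops genes."""
    records = []
    for gi, gene in enumerate(gene_ids):
        y = norm[gi]
        try:
            r = HurdleModel(y, design, test_term=test_term).fit()
            records.append((gene, r.chi2, r.df, r.p, r.log2fc_model, r.status))
        except NotDetectedError:
            records.append((gene, np.nan, 0, np.nan, np.nan, "not detected"))
        except (CollinearDesignError, SingularDesignError):
            records.append((gene, np.nan, 0, np.nan, np.nan, "collinear"))
    return pd.DataFrame.from_records(
        records, columns=["gene_id", "chi2", "df", "p", "log2fc_model", "status"]
    ).set_index("gene_id")


class CellTypeDE:
    """Model object for one cell type's case-control contrast.

    ``CellTypeDE(dataset, cell_type, config).fit()`` runs the donor-balanced
    repeated hurdle analysis and returns :class:`DEResults`.
    """

    def __init__(self, dataset: Dataset, cell_type: str, config: DEConfig | None = None):
        self.dataset = dataset
        self.cell_type = cell_type
        self.config = config or DEConfig()

    # -- single-repeat statistics (shared by observed run and permutations) --
    def _repeat_stats(self, diagnosis: pd.Series, repeat_index: int) -> pd.DataFrame:
        cfg = self.config
        d = self.dataset
        work = d.cells.copy()
        work["diagnosis"] = diagnosis
        proxy = Dataset.__new__(Dataset)  # light view: reuse matrices, swap labels
        proxy.counts = d.counts
        proxy.genes = d.genes
        proxy.norm = d.norm
        proxy.cells = work
        idx = select_balanced_cells(proxy, self.cell_type, cfg, repeat_index)
        pos = d.cells.index.get_indexer(idx)
        norm = np.asarray(d.norm[:, pos].todense())
        design = build_design(work.loc[idx], cfg.covariates, cfg.test_term)
        return _fit_all_genes(norm, design, d.genes.index, cfg.test_term)

    def _aggregate(self, per_repeat: list[pd.DataFrame]) -> pd.DataFrame:
        genes = per_repeat[0].index
        p_mat = np.column_stack([r["p"].to_numpy(float) for r in per_repeat])
        fc_mat = np.column_stack([r["log2fc_model"].to_numpy(float) for r in per_repeat])
        chi_mat = np.column_stack([r["chi2"].to_numpy(float) for r in per_repeat])
        with np.errstate(invalid="ignore"):
            p_med = np.nanmedian(p_mat, axis=1)
            fc_med = np.nanmedian(fc_mat, axis=1)
            chi_med = np.nanmedian(chi_mat, axis=1)
            n_sig = np.nansum(p_mat < self.config.q_threshold, axis=1).astype(int)
        status = np.where(np.isnan(p_med), per_repeat[0]["status"], "ok")
        out = pd.DataFrame(
            {
                "chi2": chi_med,
                "p": p_med,
                "log2fc_model": fc_med,
                "n_repeats_significant": n_sig,
                "status": status,
            },
            index=genes,
        )
        return out

    def _raw_log2fc(self, diagnosis: pd.Series | None = None) -> pd.Series:
        """Diagnosis-only refit on the full cell set of this cell type."""
        d = self.dataset
        mask = (d.cells["cell_type"] == self.cell_type).to_numpy()
        pos = np.flatnonzero(mask)
        norm = np.asarray(d.norm[:, pos].todense())
        cells = d.cells.iloc[pos]
        if diagnosis is not None:
            cells = cells.copy()
            cells["diagnosis"] = diagnosis.loc[cells.index]
        design = build_design(cells, (), self.config.test_term)
        raw = _fit_all_genes(norm, design, d.genes.index, self.config.test_term)
        return raw["log2fc_model"]

    def fit(self) -> DEResults:
        cfg = self.config
        observed = self.dataset.cells["diagnosis"]
        per_repeat = [
            self._repeat_stats(observed, r) for r in range(cfg.n_repeats)
        ]
        frame = self._aggregate(per_repeat)
        ok = frame["p"].notna()
        q = np.full(len(frame), np.nan)
        q[ok.to_numpy()] = bh_adjust(frame.loc[ok, "p"].to_numpy())
        frame["q"] = q
        frame["log2fc_raw"] = self._raw_log2fc()
        frame["called"] = (
            (frame["q"] < cfg.q_threshold)
            & (frame["log2fc_model"].abs() >= np.log2(cfg.fc_threshold))
            & (frame["log2fc_raw"].abs() >= cfg.raw_log2fc_min)
        ).fillna(False)
        frame["cell_type"] = self.cell_type
        return DEResults(
            frame=frame,
            cell_type=self.cell_type,
            config=cfg,
            n_repeats_run=cfg.n_repeats,
        )


def run_de(d: Dataset, cell_type: str, cfg: DEConfig | None = None) -> DEResults:
    """Donor-balanced repeated hurdle DE for one cell type (see module docs)."""
    return CellTypeDE(d, cell_type, cfg).fit()


# ------------------------------------------------------------- permutation

@dataclass
class NullDistribution:
    """Donor-label permutation null for one cell type."""

    observed: DEResults
    null_chi2: np.ndarray  # pooled across genes x permutations
    empirical_p: pd.Series
    empirical_fdr: float
    n_permutations: int
    permuted_call_counts: np.ndarray

    def summary(self) -> str:
        return "\n".join(
            [
                f"Donor-label permutation null — {self.observed.cell_type}",
                f"permutations        {self.n_permutations}",
                f"pooled null size    {self.null_chi2.size}",
                f"observed calls      {int(self.observed.frame['called'].sum())}",
                f"mean permuted calls {self.permuted_call_counts.mean():.2f}",
                f"empirical FDR       {self.empirical_fdr:.3f}",
            ]
        )


def _donor_assignments(
    donors: np.ndarray, n_case: int, n_perm: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], int]:
    """Distinct case-donor subsets; enumerated when few, sampled otherwise."""
    from math import comb

    n = len(donors)
    total = comb(n, n_case)
    if total <= n_perm:
        combos = [np.array(c) for c in itertools.combinations(range(n), n_case)]
        return [donors[c] for c in combos], total
    seen = set()
    out: list[np.ndarray] = []
    while len(out) < n_perm:
        pick = tuple(sorted(rng.choice(n, size=n_case, replace=False).tolist()))
        if pick in seen:
            continue
        seen.add(pick)
        out.append(donors[list(pick)])
    return out, len(out)


def permutation_null(
    d: Dataset, cell_type: str, cfg: DEConfig | None = None, n_perm: int = 10
) -> NullDistribution:
    """Shuffle diagnosis labels across donors (cells move with their donor).

    Per-gene empirical p pools the permuted chi-squares of *all* genes (with
    10 permutations, per-gene nulls alone have resolution 1/11); the empirical
    FDR at the calling threshold is mean permuted call count over observed
    call count, capped at 1.
    """
    cfg = cfg or DEConfig()
    model = CellTypeDE(d, cell_type, cfg)
    observed = model.fit()

    cells = d.cells
    donor_diag = (
        cells[cells["cell_type"] == cell_type]
        .groupby("donor_id", observed=True)["diagnosis"]
        .agg(lambda s: s.iloc[0])
    )
    if (cells.groupby("donor_id", observed=True)["diagnosis"].nunique() > 1).any():
        raise ValueError("diagnosis must be constant within donor")
    donors = donor_diag.index.to_numpy()
    n_case = int((donor_diag == "case").sum())
    rng = np.random.default_rng(seed_sequence(cfg.seed, cell_type, "permutation"))
    assignments, n_actual = _donor_assignments(donors, n_case, n_perm, rng)

    fc_floor = np.log2(cfg.fc_threshold)
    null_pool: list[np.ndarray] = []
    call_counts = []
    for k, case_donors in enumerate(assignments):
        perm_diag = pd.Series(
            np.where(cells["donor_id"].isin(case_donors), "case", "control"),
            index=cells.index,
        )
        perm_cfg = replace(cfg, seed=cfg.seed + 100_003 * (k + 1))
        perm_model = CellTypeDE(d, cell_type, perm_cfg)
        per_repeat = [
            perm_model._repeat_stats(perm_diag, r) for r in range(cfg.n_repeats)
        ]
        agg = perm_model._aggregate(per_repeat)
        ok = agg["p"].notna()
        qv = np.full(len(agg), np.nan)
        qv[ok.to_numpy()] = bh_adjust(agg.loc[ok, "p"].to_numpy())
        raw_fc = perm_model._raw_log2fc(perm_diag).to_numpy(float)
        calls = (
            (qv < cfg.q_threshold)
            & (agg["log2fc_model"].abs().to_numpy() >= fc_floor)
            & (np.abs(raw_fc) >= cfg.raw_log2fc_min)
        )
        call_counts.append(int(np.nansum(calls)))
        null_pool.append(agg["chi2"].to_numpy(float))

    pool = np.concatenate(null_pool)
    pool = pool[~np.isnan(pool)]
    obs_chi2 = observed.frame["chi2"].to_numpy(float)
    sorted_pool = np.sort(pool)
    n_ge = pool.size - np.searchsorted(sorted_pool, obs_chi2, side="left")
    emp_p = (1.0 + n_ge) / (1.0 + pool.size)
    emp_p = pd.Series(np.where(np.isnan(obs_chi2), np.nan, emp_p), index=observed.frame.index)

    n_obs_calls = int(observed.frame["called"].sum())
    mean_perm_calls = float(np.mean(call_counts)) if call_counts else 0.0
    fdr = min(1.0, mean_perm_calls / n_obs_calls) if n_obs_calls > 0 else 1.0
    return NullDistribution(
        observed=observed,
        null_chi2=pool,
        empirical_p=emp_p,
        empirical_fdr=fdr,
        n_permutations=n_actual,
        permuted_call_counts=np.asarray(call_counts),
    )


# ------------------------------------------------------------- interaction

def interaction_lrt(
    d: Dataset,
    cell_type: str,
    interacting_covariate: str,
    cfg: DEConfig | None = None,
) -> DEResults:
    """Per-gene LRT for a diagnosis x covariate interaction in both components.

    The full design adds the product column; the chi-square sums both
    components' LRTs for dropping it.  Genes with BH q < 0.05 are flagged.
    """
    cfg = cfg or DEConfig()
    cells = d.cells[d.cells["cell_type"] == cell_type]
    if cells.empty:
        raise ValueError(f"no cells of type {cell_type!r}")
    cov = cells[interacting_covariate]
    if not pd.api.types.is_numeric_dtype(cov):
        raise ValueError("interacting covariate must be numeric")
    for level, grp in cells.groupby("diagnosis", observed=True):
        if grp[interacting_covariate].nunique() < 2:
            raise ValueError(
                f"covariate {interacting_covariate!r} constant within group {level!r}; "
                "interaction inestimable"
            )
    covariates = tuple(
        c for c in cfg.covariates if c != interacting_covariate
    ) + (interacting_covariate,)
    diag01 = (cells["diagnosis"] == "case").astype(float)
    product = (diag01 * cov.astype(float)).to_numpy()
    term = f"{cfg.test_term}:{interacting_covariate}"
    design = build_design(cells, covariates, cfg.test_term, extra={term: product})
    pos = d.cells.index.get_indexer(cells.index)
    norm = np.asarray(d.norm[:, pos].todense())
    frame = _fit_all_genes(norm, design, d.genes.index, term)
    ok = frame["p"].notna()
    q = np.full(len(frame), np.nan)
    q[ok.to_numpy()] = bh_adjust(frame.loc[ok, "p"].to_numpy())
    frame["q"] = q
    frame["called"] = (frame["q"] < 0.05).fillna(False)
    frame["cell_type"] = cell_type
    return DEResults(
        frame=frame, cell_type=cell_type, config=cfg, n_repeats_run=1, interaction=True
    )
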