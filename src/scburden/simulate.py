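"""Synthetic multi-donor case-control counts and genotype-divergent lineages.

Both generators produce data with *known truth* so that every downstream stage
(hurdle DE, burden, trajectory scoring) can be validated for recovery, type-I
error and calibration.

``simulate_dataset`` draws hurdle-structured counts: a Bernoulli detection
component on the logit scale and a zero-truncated negative-binomial positive
component on the log scale, both carrying a shared donor random intercept,
per-gene nuisance-covariate effects, and a diagnosis effect restricted to the
true DE genes of each cell type.

``simulate_lineage`` draws cells along a pseudotime axis with smooth per-gene
mean curves on the log-normalized scale; a configurable fraction of dynamic
genes additionally receive a condition-specific bump whose exact
area-under-curve gap is recorded as truth for the differential-expression
score.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import Dataset

__all__ = [
    "SimConfig",
    "LineageSimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_lineage",
    "seed_sequence",
]


def seed_sequence(*keys) -> np.random.SeedSequence:
    """Deterministic, platform-independent seed derivation from mixed keys.

    Strings are hashed with crc32 so the stream depends only on the key values,
    never on interpreter hash randomization.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode("utf-8")))
        elif isinstance(k, (bool, np.bool_)):
            ints.append(int(k))
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.SeedSequence(ints)


@dataclass
class SimConfig:
    """Study design for the case-control generator.

    Defaults describe a modest snRNA-seq study: 5 donors per group, two cell
    types, 1,000 well-expressed genes with baseline negative-binomial means
    log-uniform in [10, 60] counts, moderate overdispersion, high but not
    saturated detection, and mild donor and nuisance-covariate variation.
    True DE genes receive a log2 fold change of ``log2fc_de`` (random sign per
    gene) on the positive-component mean and ``detection_shift_de`` logits
    (same sign) on detection.
    """

    n_donors_per_group: int = 5
    cells_per_donor: int | tuple[int, int] = 100
    n_cell_types: int = 2
    n_genes: int = 1000
    frac_de: float | tuple[float, ...] = 0.1
    log2fc_de: float = 1.0
    detection_shift_de: float = 1.0
    donor_sd: float = 0.05
    nb_dispersion: float = 2.0
    baseline_logmean_range: tuple[float, float] = (np.log(10.0), np.log(60.0))
    detection_logit_range: tuple[float, float] = (1.5, 3.5)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.05, "capture_batch": 0.05}
    )
    frac_mito: float = 0.02
    frac_ribo: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = self.frac_de if isinstance(self.frac_de, (tuple, list)) else (self.frac_de,)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("frac_de must be in [0, 1]")
        if isinstance(self.frac_de, (tuple, list)) and len(self.frac_de) != self.n_cell_types:
            raise ValueError("per-cell-type frac_de must have n_cell_types entries")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_donors_per_group < 2:
            raise ValueError(
                "need at least 2 donors per group (donor-label permutation "
                "null is undefined otherwise)"
            )


@dataclass
class LineageSimConfig:
    """Design for the lineage generator (one lineage, two conditions)."""

    n_cells_per_condition: int = 500
    n_genes: int = 300
    frac_dynamic: float = 0.2
    frac_divergent: float = 0.5
    divergence_amplitude: float = 1.0
    dynamic_amplitude: float = 1.0
    pseudotime_range: tuple[float, float] = (0.0, 10.0)
    noise_sd: float = 0.2
    embedding_noise_sd: float = 0.2
    bump_shape: str = "rectangle"
    depth: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_divergent <= 1.0:
            raise ValueError("frac_divergent must be in [0, 1]")
        if self.divergence_amplitude < 0:
            raise ValueError("divergence_amplitude must be >= 0")
        lo, hi = self.pseudotime_range
        if not hi > lo:
            raise ValueError("pseudotime_range must have positive width")
        if self.bump_shape not in ("rectangle", "cosine"):
            raise ValueError("bump_shape must be 'rectangle' or 'cosine'")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data.

    ``de_genes`` maps cell type -> {gene_id: signed true log2FC on the
    positive-component mean}; ``divergent_genes`` maps gene_id -> true
    area-under-curve gap between condition mean curves.
    """

    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    dynamic_genes: set[str] = field(default_factory=set)
    divergent_genes: dict[str, float] = field(default_factory=dict)
    donor_effects: dict[str, float] = field(default_factory=dict)
    donor_gene_effects: np.ndarray | None = None  # genes x donors, log scale

    def de_gene_set(self, cell_type: str) -> set[str]:
        return set(self.de_genes.get(cell_type, {}))


# ------------------------------------------------------------------ helpers

def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _truncated_nbinom(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Zero-truncated NB draws, vectorized; variance = mean + mean^2 / theta."""
    p = theta / (theta + mean)
    out = rng.negative_binomial(theta, p)
    zero = out == 0
    # redraw zeros until none remain; geometric convergence
    for _ in range(200):
        if not zero.any():
            break
        out[zero] = rng.negative_binomial(theta, p[zero])
        zero = out == 0
    out[zero] = 1  # unreachable in practice
    return out


def _gene_effects(rng: np.random.Generator, n_genes: int, sd: float) -> np.ndarray:
    return rng.normal(0.0, sd, size=n_genes) if sd > 0 else np.zeros(n_genes)


# ------------------------------------------------------- case-control counts

def simulate_dataset(cfg: SimConfig) -> tuple[Dataset, SimTruth]:
    """Draw a hurdle-structured multi-donor case-control dataset.

    Fully reproducible from ``cfg.seed``; returns the Dataset (counts only —
    run :func:`scburden.dataset.normalize_log` for the normalized layer) and
    the :class:`SimTruth`.
    """
    rng = np.random.default_rng(seed_sequence(cfg.seed, "dataset"))
    n_genes = cfg.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)])
    cell_types = [f"CT{i}" for i in range(cfg.n_cell_types)]

    # donors ---------------------------------------------------------------
    n_donors = 2 * cfg.n_donors_per_group
    donor_ids = np.array([f"D{i:02d}" for i in range(n_donors)])
    diagnosis = np.array(
        ["control"] * cfg.n_donors_per_group + ["case"] * cfg.n_donors_per_group
    )
    donor_age = rng.uniform(20.0, 70.0, size=n_donors).round(1)
    donor_sex = rng.integers(0, 2, size=n_donors)  # 0 = F, 1 = M
    donor_capture = rng.integers(0, 2, size=n_donors)
    donor_seq = rng.integers(0, 2, size=n_donors)
    # gene-specific donor random intercepts: a donor effect shared by all genes
    # would cancel under depth normalization, whereas the (1|ind) term of a
    # per-gene mixed model targets gene-level donor variation
    if cfg.donor_sd > 0:
        U = rng.normal(0.0, cfg.donor_sd, size=(cfg.n_genes, n_donors))
    else:
        U = np.zeros((cfg.n_genes, n_donors))

    # per-gene baselines ---------------------------------------------------
    lo, hi = cfg.baseline_logmean_range
    m_g = rng.uniform(lo, hi, size=n_genes)
    a_g = rng.uniform(*cfg.detection_logit_range, size=n_genes)
    ct_offsets = {ct: rng.normal(0.0, 0.1, size=n_genes) for ct in cell_types}

    cov_sd = cfg.covariate_effects or {}
    beta_age = _gene_effects(rng, n_genes, cov_sd.get("age", 0.0))
    beta_sex = _gene_effects(rng, n_genes, cov_sd.get("sex", 0.0))
    beta_batch = _gene_effects(rng, n_genes, cov_sd.get("capture_batch", 0.0))

    # true DE structure per cell type --------------------------------------
    truth = SimTruth(
        donor_effects={donor_ids[i]: float(U[:, i].mean()) for i in range(n_donors)},
        donor_gene_effects=U,
    )
    fracs = (
        tuple(cfg.frac_de)
        if isinstance(cfg.frac_de, (tuple, list))
        else (cfg.frac_de,) * cfg.n_cell_types
    )
    # DE gene signs are drawn with the flux-balancing probability: a 2x
    # increase adds more UMIs than a 0.5x decrease removes, so symmetric signs
    # would shift every cell's library composition and give all null genes a
    # real (nonzero) relative-abundance change between groups.  Balancing the
    # expected UMI flux keeps the null genes' truth at exactly zero on the
    # depth-normalized scale the hurdle test operates on.
    f = abs(cfg.log2fc_de)
    a_mid = float(np.mean(cfg.detection_logit_range))
    det_up = _sigmoid(a_mid + cfg.detection_shift_de) / _sigmoid(a_mid)
    det_dn = _sigmoid(a_mid - cfg.detection_shift_de) / _sigmoid(a_mid)
    w_up = 2.0**f * det_up - 1.0
    w_dn = 1.0 - 2.0**-f * det_dn
    p_up = w_dn / (w_up + w_dn) if (w_up + w_dn) > 0 else 0.5
    de_lfc = {}
    for ct, frac in zip(cell_types, fracs):
        n_de = int(round(frac * n_genes))
        if n_de > 0:
            idx = rng.choice(n_genes, size=n_de, replace=False)
            signs = np.where(rng.random(n_de) < p_up, 1.0, -1.0)
            lfc = np.zeros(n_genes)
            lfc[idx] = signs * cfg.log2fc_de
        else:
            lfc = np.zeros(n_genes)
        de_lfc[ct] = lfc
        truth.de_genes[ct] = {
            gene_ids[i]: float(lfc[i]) for i in np.flatnonzero(lfc != 0.0)
        }

    # cells ----------------------------------------------------------------
    if isinstance(cfg.cells_per_donor, tuple):
        n_cells_donor = rng.integers(
            cfg.cells_per_donor[0], cfg.cells_per_donor[1] + 1, size=n_donors
        )
    else:
        n_cells_donor = np.full(n_donors, int(cfg.cells_per_donor))
    total_cells = int(n_cells_donor.sum())

    cell_donor = np.repeat(np.arange(n_donors), n_cells_donor)
    cell_ct = rng.integers(0, cfg.n_cell_types, size=total_cells)
    cell_ids = np.array([f"C{i:06d}" for i in range(total_cells)])

    age_c = (donor_age[cell_donor] - 45.0) / 10.0  # centered/scaled internally
    sex_c = donor_sex[cell_donor].astype(float)
    batch_c = donor_capture[cell_donor].astype(float)
    is_case = (diagnosis[cell_donor] == "case").astype(float)

    counts = np.zeros((n_genes, total_cells), dtype=np.int64)
    ln2 = np.log(2.0)
    for d in range(n_donors):
        for t_i, ct in enumerate(cell_types):
            cols = np.flatnonzero((cell_donor == d) & (cell_ct == t_i))
            if cols.size == 0:
                continue
            nc = cols.size
            case = is_case[cols][0]
            lfc = de_lfc[ct]
            # gene x cell linear predictors
            covar = (
                np.outer(beta_age, age_c[cols])
                + np.outer(beta_sex, sex_c[cols])
                + np.outer(beta_batch, batch_c[cols])
            )
            eta_det = a_g[:, None] + U[:, d][:, None] + covar + (
                cfg.detection_shift_de * np.sign(lfc) * case
            )[:, None]
            p_det = 1.0 / (1.0 + np.exp(-eta_det))
            detected = rng.random((n_genes, nc)) < p_det
            log_mu = (
                m_g[:, None]
                + ct_offsets[ct][:, None]
                + U[:, d][:, None]
                + covar
                + (ln2 * lfc * case)[:, None]
            )
            mu = np.exp(log_mu)
            block = np.zeros((n_genes, nc), dtype=np.int64)
            det_idx = np.nonzero(detected)
            if det_idx[0].size:
                block[det_idx] = _truncated_nbinom(rng, mu[det_idx], cfg.nb_dispersion)
            counts[:, cols] = block

    genes = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    genes["gene_symbol"] = gene_ids
    n_mito = int(round(cfg.frac_mito * n_genes))
    n_ribo = int(round(cfg.frac_ribo * n_genes))
    mito_flag = np.zeros(n_genes, dtype=bool)
    ribo_flag = np.zeros(n_genes, dtype=bool)
    mito_flag[:n_mito] = True
    ribo_flag[n_mito : n_mito + n_ribo] = True
    genes["pct_mito_flag"] = mito_flag
    genes["pct_ribo_flag"] = ribo_flag

    cells = pd.DataFrame(
        {
            "donor_id": donor_ids[cell_donor],
            "diagnosis": diagnosis[cell_donor],
            "cell_type": np.array(cell_types)[cell_ct],
            "age": donor_age[cell_donor],
            "sex": np.where(donor_sex[cell_donor] == 1, "M", "F"),
            "capture_batch": np.array(["capA", "capB"])[donor_capture[cell_donor]],
            "seq_batch": np.array(["seqA", "seqB"])[donor_seq[cell_donor]],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )

    dataset = Dataset(counts=sp.csr_matrix(counts), cells=cells, genes=genes)
    return dataset, truth


# ------------------------------------------------------------------ lineages

@dataclass
class LineageView:
    """Ordered cells along one lineage: pseudotime, condition, 2D embedding."""

    cell_ids: np.ndarray
    pseudotime: np.ndarray
    condition: np.ndarray
    embedding: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.pseudotime, kind="stable")
        self.cell_ids = np.asarray(self.cell_ids)[order]
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)[order]
        self.condition = np.asarray(self.condition)[order]
        self.embedding = np.asarray(self.embedding, dtype=float)[order]
        if np.any(self.pseudotime < 0):
            raise ValueError("pseudotime must be non-negative")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LineageView":
        return cls(
            cell_ids=frame.index.to_numpy(),
            pseudotime=frame["pseudotime"].to_numpy(dtype=float),
            condition=frame["condition"].to_numpy(),
            embedding=frame[["emb_x", "emb_y"]].to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pseudotime": self.pseudotime,
                "condition": self.condition,
                "emb_x": self.embedding[:, 0],
                "emb_y": self.embedding[:, 1],
            },
            index=pd.Index(self.cell_ids, name="cell_id"),
        )


def _bump(t: np.ndarray, lo: float, hi: float, amplitude: float, shape: str) -> np.ndarray:
    """Condition-specific divergence over the middle half of [lo, hi]."""
    width = hi - lo
    a, b = lo + 0.25 * width, lo + 0.75 * width
    if shape == "rectangle":
        return amplitude * ((t >= a) & (t <= b)).astype(float)
    x = (t - a) / (b - a)
    out = np.zeros_like(t)
    inside = (x >= 0) & (x <= 1)
    out[inside] = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * x[inside]))
    return out


def _bump_auc(lo: float, hi: float, amplitude: float, shape: str) -> float:
    width = hi - lo
    if shape == "rectangle":
        return amplitude * width / 2.0
    return amplitude * width / 4.0  # mean of raised cosine is A/2 over half-range


def simulate_lineage(cfg: LineageSimConfig) -> tuple[Dataset, LineageView, SimTruth]:
    """Draw one lineage with two conditions and known trajectory truth.

    Expression is generated directly on the log-normalized scale (mean curve
    plus Gaussian noise); counts are obtained by inverting the log1p transform
    at a fixed per-cell depth so the returned Dataset carries both a count
    matrix and a ``norm`` layer whose truth is exact on the scale the
    trajectory scoring operates on.
    """
    rng = np.random.default_rng(seed_sequence(cfg.seed, "lineage"))
    lo, hi = cfg.pseudotime_range
    n = cfg.n_cells_per_condition
    n_genes = cfg.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)])

    t = np.concatenate([rng.uniform(lo, hi, size=n), rng.uniform(lo, hi, size=n)])
    condition = np.array(["control"] * n + ["case"] * n)
    cell_ids = np.array([f"L{i:06d}" for i in range(2 * n)])

    # baselines high enough that dynamic + divergence excursions never hit the
    # clip at zero, so the recorded AUC-gap truth is exact
    baseline = rng.uniform(3.5, 5.5, size=n_genes)
    n_dyn = int(round(cfg.frac_dynamic * n_genes))
    dyn_idx = rng.choice(n_genes, size=n_dyn, replace=False) if n_dyn else np.array([], int)
    n_div = int(round(cfg.frac_divergent * n_dyn))
    div_idx = rng.choice(dyn_idx, size=n_div, replace=False) if n_div else np.array([], int)
    div_sign = rng.choice([-1.0, 1.0], size=n_genes)

    # smooth dynamic mean curves: low-order cosine series, bounded amplitude
    n_basis = 3
    coef = np.zeros((n_genes, n_basis))
    if n_dyn:
        raw = rng.normal(0.0, 1.0, size=(n_dyn, n_basis))
        norms = np.linalg.norm(raw, axis=1, keepdims=True)
        coef[dyn_idx] = cfg.dynamic_amplitude * raw / np.maximum(norms, 1e-12)
    phase = (t - lo) / (hi - lo)
    basis = np.stack([np.cos(np.pi * (j + 1) * phase) for j in range(n_basis)])  # (B, cells)

    mean = baseline[:, None] + coef @ basis  # genes x cells
    if n_div:
        bump = _bump(t, lo, hi, cfg.divergence_amplitude, cfg.bump_shape)
        case_mask = (condition == "case").astype(float)
        mean[div_idx] += div_sign[div_idx][:, None] * (bump * case_mask)[None, :]

    y = mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    y = np.clip(y, 0.0, None)

    counts = np.rint(np.expm1(y) * cfg.depth / 10_000.0).astype(np.int64)
    embedding = np.column_stack([t, np.zeros_like(t)]) + rng.normal(
        0.0, cfg.embedding_noise_sd, size=(2 * n, 2)
    )

    genes = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    genes["gene_symbol"] = gene_ids
    genes["pct_mito_flag"] = False
    genes["pct_ribo_flag"] = False
    cells = pd.DataFrame(
        {
            "donor_id": np.where(condition == "case", "Dcase", "Dctrl"),
            "diagnosis": condition,
            "cell_type": "lineage",
            "age": 0.0,
            "sex": "F",
            "capture_batch": "capA",
            "seq_batch": "seqA",
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    dataset = Dataset(
        counts=sp.csr_matrix(counts),
        cells=cells,
        genes=genes,
        norm=sp.csr_matrix(y),
    )

    truth = SimTruth(
        dynamic_genes=set(gene_ids[dyn_idx]),
        divergent_genes={
            gene_ids[i]: _bump_auc(lo, hi, cfg.divergence_amplitude, cfg.bump_shape)
            for i in div_idx
        },
    )
    view = LineageView(
        cell_ids=cell_ids, pseudotime=t, condition=condition, embedding=embedding
    )
    return dataset, view, truth
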