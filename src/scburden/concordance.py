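"""Cross-list and cross-dataset concordance statistics.

Enrichment of DEG lists in reference gene sets (hypergeometric, with the
detected-gene universe as background), Fisher overlap tests between DEG
lists, fold-change correlation between two DE runs, transcription-factor
target projection coverage, and cluster expression-profile similarity on
top markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset

__all__ = [
    "GeneList",
    "TFTargetMap",
    "EnrichmentResult",
    "read_gene_list",
    "read_gmt",
    "read_tf_target_map",
    "risk_gene_filter",
    "hypergeom_enrichment",
    "fisher_overlap",
    "fc_correlation",
    "tf_target_coverage",
    "cluster_similarity",
]


@dataclass
class GeneList:
    """Named set of gene symbols with optional per-gene labels (ranks, flags)."""

    name: str
    genes: set[str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class TFTargetMap:
    """Transcription factor -> target gene sets."""

    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [tf for tf, t in self.targets.items() if not t]
        if empty:
            raise ValueError(f"TF {empty[0]!r} has an empty target set")


def read_gene_list(path, name: str | None = None) -> GeneList:
    """One symbol per line, or two tab-separated columns (symbol, label)."""
    genes, labels = set(), {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            genes.add(parts[0])
            if len(parts) > 1:
                labels[parts[0]] = parts[1]
    return GeneList(name=name or str(path), genes=genes, labels=labels)


def read_gmt(path) -> dict[str, GeneList]:
    """GMT gene sets: name, description, then member symbols, tab-separated."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = GeneList(name=parts[0], genes=set(parts[2:]))
    return out


def read_tf_target_map(path) -> TFTargetMap:
    """Two-column TSV: TF symbol, target symbol."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["tf", "target"], comment="#")
    targets: dict[str, set[str]] = {}
    for tf, grp in frame.groupby("tf"):
        targets[str(tf)] = set(grp["target"].astype(str))
    return TFTargetMap(targets=targets)


def risk_gene_filter(gl: GeneList, max_rank: int = 3, syndromic_label: str = "syndromic") -> GeneList:
    """High-confidence risk genes: numeric rank <= max_rank or the syndromic flag."""
    keep = set()
    for g in gl.genes:
        label = gl.labels.get(g, "")
        if label.lower() == syndromic_label:
            keep.add(g)
            continue
        try:
            if int(label) <= max_rank:
                keep.add(g)
        except ValueError:
            pass
    return GeneList(name=f"{gl.name}|rank<={max_rank}+{syndromic_label}", genes=keep,
                    labels={g: gl.labels[g] for g in keep if g in gl.labels})


@dataclass
class EnrichmentResult:
    overlap: int
    sample_size: int
    list_size: int
    background_size: int
    p: float
    fold_enrichment: float
    q: float = np.nan
    clipped: int = 0

    def summary(self) -> str:
        return (
            f"overlap {self.overlap}/{self.sample_size} against list of "
            f"{self.list_size} in background {self.background_size}; "
            f"fold {self.fold_enrichment:.2f}, p = {self.p:.3g}"
        )


def hypergeom_enrichment(
    sample: GeneList, reference: GeneList, background: GeneList
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``sample`` in ``reference``.

    The background is the detected-gene universe; sample genes outside it are
    reported and clipped.  p = P(overlap >= observed) under the hypergeometric
    null, via exact log-combinatorics (scipy's survival function).
    """
    bg = background.genes
    if len(bg) < len(sample.genes & bg):
        raise ValueError("background smaller than sample")
    samp = sample.genes & bg
    clipped = len(sample.genes) - len(samp)
    ref = reference.genes & bg
    if len(samp) > len(bg):
        raise ValueError("sample exceeds background")
    k = len(samp & ref)
    M, n, N = len(bg), len(ref), len(samp)
    p = float(stats.hypergeom.sf(k - 1, M, n, N)) if N and n else 1.0
    if N and n:
        fold = (k / N) / (n / M)
    else:
        fold = np.nan
    return EnrichmentResult(
        overlap=k, sample_size=N, list_size=n, background_size=M,
        p=min(p, 1.0), fold_enrichment=fold, clipped=clipped,
    )


def fisher_overlap(a: GeneList, b: GeneList, universe: GeneList) -> tuple[float, float]:
    """Exact conditional two-sided Fisher test on the 2x2 overlap table.

    Returns ``(p, odds_ratio)``.
    """
    u = universe.genes
    if not u:
        raise ValueError("empty universe")
    sa, sb = a.genes & u, b.genes & u
    n11 = len(sa & sb)
    n12 = len(sa - sb)
    n21 = len(sb - sa)
    n22 = len(u) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return float(p), float(odds)


def fc_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    mode: str = "union_expressed",
    fc_col: str = "log2fc_model",
) -> dict:
    """Pearson correlation of log2 fold changes between two DE runs.

    ``mode='union_expressed'`` correlates over all genes tested in both runs;
    ``'shared_called'`` restricts to genes called in both.  Also reports the
    sign-concordance fraction over genes called in both runs.
    """
    shared = a.index.intersection(b.index)
    if mode == "shared_called":
        shared = shared[(a.loc[shared, "called"]) & (b.loc[shared, "called"])]
    else:
        ok = a.loc[shared, fc_col].notna() & b.loc[shared, fc_col].notna()
        shared = shared[ok]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    x = a.loc[shared, fc_col].to_numpy(float)
    y = b.loc[shared, fc_col].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": np.nan, "p": np.nan, "n": len(shared),
                "sign_concordance": np.nan, "status": "undefined correlation"}
    r, p = stats.pearsonr(x, y)
    called = a.index.intersection(b.index)
    called = called[(a.loc[called, "called"]) & (b.loc[called, "called"])]
    if len(called):
        sc = float(
            np.mean(
                np.sign(a.loc[called, fc_col]) == np.sign(b.loc[called, fc_col])
            )
        )
    else:
        sc = np.nan
    return {"r": float(r), "p": float(p), "n": len(shared),
            "sign_concordance": sc, "status": "ok"}


def tf_target_coverage(
    tf_degs: GeneList, tfmap: TFTargetMap, target_degs: GeneList, background: GeneList
) -> dict:
    """Coverage of a DEG list by predicted targets of dysregulated TFs.

    Predicted set = union of targets of the DE transcription factors present
    in the map; coverage = fraction of ``target_degs`` predicted; enrichment
    of the predicted set within ``target_degs`` against the background by the
    (unadjusted) hypergeometric test.
    """
    tfs = tf_degs.genes & set(tfmap.targets)
    if not tfs:
        return {"coverage": np.nan, "enrichment": None, "n_tfs": 0,
                "status": "no DE transcription factor in map"}
    predicted = set().union(*(tfmap.targets[tf] for tf in tfs))
    tgt = target_degs.genes & background.genes
    coverage = len(tgt & predicted) / len(tgt) if tgt else np.nan
    enr = hypergeom_enrichment(
        GeneList("target_degs", tgt),
        GeneList("predicted", predicted),
        background,
    )
    return {"coverage": coverage, "enrichment": enr, "n_tfs": len(tfs), "status": "ok"}


def _cluster_profiles(d: Dataset, labels: pd.Series) -> pd.DataFrame:
    """Per-cluster mean counts -> CPM -> log1p; clusters with < 3 cells dropped."""
    counts = np.asarray(d.counts.todense(), dtype=float)
    profiles = {}
    for cluster, grp in d.cells.groupby(labels, observed=True):
        if len(grp) < 3:
            import warnings

            warnings.warn(f"cluster {cluster!r} has < 3 cells; excluded")
            continue
        pos = d.cells.index.get_indexer(grp.index)
        mean = counts[:, pos].mean(axis=1)
        cpm = mean / max(mean.sum(), 1e-300) * 1e6
        profiles[cluster] = np.log1p(cpm)
    return pd.DataFrame(profiles, index=d.genes.index)


def _top_markers(profiles: pd.DataFrame, top_k: int) -> set[str]:
    markers: set[str] = set()
    for cluster in profiles.columns:
        rest = profiles.drop(columns=cluster).mean(axis=1)
        diff = (profiles[cluster] - rest).sort_values(ascending=False)
        markers.update(diff.index[:top_k])
    return markers


def cluster_similarity(
    a: Dataset,
    labels_a: pd.Series,
    b: Dataset,
    labels_b: pd.Series,
    top_k: int = 20,
) -> pd.DataFrame:
    """Pearson correlation matrix between cluster profiles of two datasets.

    Profiles are per-cluster CPM-log means over the union of the top ``top_k``
    one-vs-rest markers from every cluster of both datasets; rows are clusters
    of ``a``, columns clusters of ``b``.
    """
    shared = a.genes.index.intersection(b.genes.index)
    if shared.empty:
        raise ValueError("datasets share no genes")
    pa = _cluster_profiles(a, labels_a).loc[shared]
    pb = _cluster_profiles(b, labels_b).loc[shared]
    markers = sorted(_top_markers(pa, top_k) | _top_markers(pb, top_k))
    pa, pb = pa.loc[markers], pb.loc[markers]
    out = pd.DataFrame(index=pa.columns, columns=pb.columns, dtype=float)
    for ca in pa.columns:
        for cb in pb.columns:
            x, y = pa[ca].to_numpy(), pb[cb].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                out.loc[ca, cb] = np.nan
            else:
                out.loc[ca, cb] = stats.pearsonr(x, y)[0]
    return out
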