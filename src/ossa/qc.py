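"""Quality control, cluster-based size factors, log-normalization, per-sample
highly variable genes, and PCA.

QC thresholds are tissue-class specific: bone marrow cells tolerate a 0.2
mitochondrial fraction and need at least 1000 UMIs, while meninges and brain
cells use 0.3/0.6 and 500 UMIs, all capped at 50,000 UMIs; genes expressed
in fewer than 10 surviving cells are dropped, and cells with a doublet score
above 0.1 are removed.  Size factors follow a cluster-aware median-of-ratios
scheme: cells are clustered on a kNN graph in PCA space of total-count
log1p-normalized data, each cluster's mean profile is compared with the
overall mean profile, and the per-cluster ratio scales the cell's library
size.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.linalg

from .io import CellMatrix, NormalizedLayer
from ._utils import logger

_FILTER_ORDER = ("mito", "umi_min", "umi_max", "doublet")


@dataclasses.dataclass
class QCThresholds:
    mito_max: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"bone": 0.2, "meninges": 0.3, "brain": 0.6}
    )
    umi_min: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"bone": 1000, "meninges": 500, "brain": 500}
    )
    umi_max: int = 50000
    min_cells_per_gene: int = 10
    doublet_max: float = 0.1

    def validate(self) -> "QCThresholds":
        for cls, v in self.mito_max.items():
            if not (0.0 < v <= 1.0):
                raise ValueError(f"mito_max[{cls!r}] must be in (0,1]")
        for cls, v in self.umi_min.items():
            if v >= self.umi_max:
                raise ValueError(f"umi_min[{cls!r}] must be below umi_max")
        return self


@dataclasses.dataclass
class QCReport:
    removed_mito: int = 0
    removed_umi_min: int = 0
    removed_umi_max: int = 0
    removed_doublet: int = 0
    removed_genes: int = 0
    cells_in: int = 0
    cells_out: int = 0
    genes_in: int = 0
    genes_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


@dataclasses.dataclass
class PCAResult:
    """Exact PCA: per-cell scores, non-increasing explained variances
    (eigenvalues, s_j^2 / (n-1)), and orthonormal gene loadings."""

    scores: np.ndarray  # cells x K
    eigenvalues: np.ndarray  # K
    loadings: np.ndarray  # genes x K
    n_components: int
    gene_ids: np.ndarray | None = None


@dataclasses.dataclass
class HVGSelection:
    per_sample: dict  # sample_id -> DataFrame(gene_id, mean, dispersion, norm_dispersion, selected)
    combined: pd.DataFrame  # gene_id, support, median_norm_dispersion
    genes: list  # ordered selected gene ids


def apply_qc(cohort: CellMatrix, thresholds: QCThresholds | None = None) -> tuple[CellMatrix, QCReport]:
    """Remove failing cells (mito → umi_min → umi_max → doublet, each cell
    attributed to the first filter that removes it) then under-expressed
    genes."""
    thresholds = (thresholds or QCThresholds()).validate()
    report = QCReport(cells_in=cohort.n_cells, genes_in=cohort.n_genes)
    classes = cohort.cells["tissue_class"].astype(str)
    unknown = [c for c in set(classes) if c not in thresholds.mito_max or c not in thresholds.umi_min]
    if unknown:
        raise ValueError(f"unknown tissue_class labels: {sorted(unknown)}")
    if cohort.n_cells == 0:
        return cohort, report

    mito_lim = classes.map(thresholds.mito_max).to_numpy(dtype=float)
    umi_lo = classes.map(thresholds.umi_min).to_numpy(dtype=float)
    mito = cohort.cells["mito_fraction"].to_numpy(dtype=float)
    umi = cohort.cells["total_umi"].to_numpy(dtype=float)
    dscore = cohort.cells["doublet_score"].to_numpy(dtype=float)

    fail_mito = mito > mito_lim
    fail_lo = umi < umi_lo
    fail_hi = umi > thresholds.umi_max
    fail_dbl = dscore > thresholds.doublet_max
    alive = np.ones(cohort.n_cells, dtype=bool)
    for name, fail in zip(_FILTER_ORDER, (fail_mito, fail_lo, fail_hi, fail_dbl)):
        hit = alive & fail
        setattr(report, f"removed_{name}", int(hit.sum()))
        alive &= ~fail

    kept = cohort.subset(cell_idx=np.flatnonzero(alive))
    expressed_in = np.asarray((kept.counts > 0).sum(axis=0)).ravel()
    gene_keep = expressed_in >= thresholds.min_cells_per_gene
    report.removed_genes = int((~gene_keep).sum())
    out = kept.subset(gene_idx=np.flatnonzero(gene_keep))
    report.cells_out = out.n_cells
    report.genes_out = out.n_genes
    return out, report


def _total_normal_log(counts: sp.csr_matrix, target_sum: float = 1e4) -> sp.csr_matrix:
    total = np.asarray(counts.sum(axis=1)).ravel()
    scale = np.divide(target_sum, total, out=np.zeros_like(total, dtype=float), where=total > 0)
    X = sp.csr_matrix(counts, dtype=np.float64)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return X


def cluster_for_size_factors(
    cohort: CellMatrix,
    k_neighbors: int = 30,
    min_cluster: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Partition cells for size-factor pooling.

    Community detection (Leiden, resolution 1) on a k-nearest-neighbor graph
    built in PCA space of total-count (target 10,000) log1p data; clusters
    below ``min_cluster`` cells are merged into the neighboring cluster they
    share the most graph edges with.
    """
    n = cohort.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n <= min_cluster:
        return np.zeros(n, dtype=np.int64)
    from sklearn.neighbors import kneighbors_graph
    import igraph
    import leidenalg

    X = _total_normal_log(cohort.counts)
    pca = compute_pca_matrix(X, n_components=min(50, n - 1, cohort.n_genes))
    k = min(k_neighbors, n - 1)
    adj = kneighbors_graph(pca.scores, n_neighbors=k, mode="connectivity")
    adj = adj + adj.T  # symmetrize; weights irrelevant for connectivity
    adj = sp.coo_matrix(sp.triu(adj, k=1))
    g = igraph.Graph(n=n, edges=list(zip(adj.row.tolist(), adj.col.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=1.0,
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=np.int64)
    adj_full = sp.csr_matrix(
        (np.ones(len(adj.row) * 2), (np.r_[adj.row, adj.col], np.r_[adj.col, adj.row])),
        shape=(n, n),
    )
    labels = _merge_small_clusters(labels, adj_full, min_cluster)
    # relabel consecutively in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    first = {}
    for lab in labels:
        if lab not in first:
            first[lab] = len(first)
    return np.asarray([first[lab] for lab in labels], dtype=np.int64)


def _merge_small_clusters(labels: np.ndarray, adj: sp.csr_matrix, min_cluster: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        ids, sizes = np.unique(labels, return_counts=True)
        if len(ids) <= 1:
            break
        small = ids[sizes < min_cluster]
        if small.size == 0:
            break
        # merge the smallest offender into its most connected neighbor
        c = small[np.argmin(sizes[np.isin(ids, small)])]
        members = labels == c
        conn = np.asarray(adj[members].sum(axis=0)).ravel()
        best, best_edges = None, -1.0
        for other in ids:
            if other == c:
                continue
            e = conn[labels == other].sum()
            if e > best_edges:
                best, best_edges = other, e
        labels[members] = best
    return labels


def compute_size_factors(cohort: CellMatrix, clusters: np.ndarray) -> np.ndarray:
    """Cluster-median-of-ratios size factors.

    θ_c = median over genes expressed in both profiles of (cluster mean /
    overall mean); s_i = θ_c(i) · total_umi_i / mean(total_umi in cluster),
    rescaled to mean 1.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != cohort.n_cells:
        raise ValueError("cluster labels must align with cells")
    overall = np.asarray(cohort.counts.mean(axis=0)).ravel()
    total = cohort.cells["total_umi"].to_numpy(dtype=float)
    s = np.empty(cohort.n_cells, dtype=float)
    for c in np.unique(clusters):
        members = clusters == c
        prof = np.asarray(cohort.counts[members].mean(axis=0)).ravel()
        both = (prof > 0) & (overall > 0)
        if not both.any():
            raise ValueError(f"cluster {c} shares no expressed genes with the overall profile")
        theta = float(np.median(prof[both] / overall[both]))
        s[members] = theta * total[members] / total[members].mean()
    if np.any(s <= 0):
        raise ValueError("non-positive size factor (cluster of empty cells?)")
    return s / s.mean()


def log_normalize(cohort: CellMatrix, size_factors: np.ndarray) -> NormalizedLayer:
    """values = ln(count / s_i + 1); sparsity (zeros) preserved."""
    s = np.asarray(size_factors, dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    X = sp.csr_matrix(cohort.counts, dtype=np.float64, copy=True)
    X = sp.diags(1.0 / s) @ X
    X.data = np.log1p(X.data)
    return NormalizedLayer(
        values=sp.csr_matrix(X),
        size_factors=s,
        gene_ids=cohort.genes["gene_id"].to_numpy(),
    )


def select_hvgs(
    layer: NormalizedLayer,
    samples: Sequence[str],
    n_per_sample: int = 4000,
    n_bins: int = 20,
) -> HVGSelection:
    """Per-sample highly variable genes by bin-normalized dispersion.

    Dispersion (variance/mean) is computed on de-logged (expm1) normalized
    values; genes are binned by mean into ``n_bins`` quantile bins and the
    dispersion is centered/scaled by the bin median and MAD.  The combined
    set ranks genes by the number of supporting samples (tie-break: median
    normalized dispersion) and truncates to ``n_per_sample``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    samples = np.asarray(samples)
    if len(samples) != layer.n_cells:
        raise ValueError("sample labels must align with cells")
    gene_ids = layer.gene_ids
    expm1 = sp.csr_matrix(layer.values, copy=True)
    expm1.data = np.expm1(expm1.data)
    per_sample: dict[str, pd.DataFrame] = {}
    for sample in pd.unique(samples):
        mask = samples == sample
        if mask.sum() < 2:
            logger.warning("sample %s has < 2 cells; skipped for HVG selection", sample)
            continue
        sub = expm1[mask]
        mean = np.asarray(sub.mean(axis=0)).ravel()
        sq = np.asarray(sub.multiply(sub).mean(axis=0)).ravel()
        var = (sq - mean**2) * mask.sum() / max(mask.sum() - 1, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            disp = np.where(mean > 0, var / mean, 0.0)
        norm_disp = _bin_normalize(mean, disp, n_bins)
        # constant genes: guard against floating-point noise in the variance
        eligible = var > 1e-12 + 1e-10 * mean**2
        # descending dispersion, ties broken by gene id for order invariance
        order = np.lexsort((gene_ids, -norm_disp))
        order = order[eligible[order]]
        selected = np.zeros(len(gene_ids), dtype=bool)
        selected[order[:n_per_sample]] = True
        per_sample[str(sample)] = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "mean": mean,
                "dispersion": disp,
                "norm_dispersion": norm_disp,
                "selected": selected,
            }
        )
    if not per_sample:
        raise ValueError("no sample with >= 2 cells")
    support = np.zeros(len(gene_ids), dtype=int)
    disp_stack = []
    for frame in per_sample.values():
        support += frame["selected"].to_numpy(dtype=int)
        disp_stack.append(frame["norm_dispersion"].to_numpy())
    med_disp = np.median(np.vstack(disp_stack), axis=0)
    combined = pd.DataFrame(
        {"gene_id": gene_ids, "support": support, "median_norm_dispersion": med_disp}
    )
    combined = combined.sort_values(
        ["support", "median_norm_dispersion", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    chosen = combined[combined["support"] > 0].head(n_per_sample)
    return HVGSelection(
        per_sample=per_sample, combined=combined, genes=chosen["gene_id"].tolist()
    )


def _bin_normalize(mean: np.ndarray, disp: np.ndarray, n_bins: int) -> np.ndarray:
    """Center/scale dispersions by their mean-bin median and MAD."""
    expressed = mean > 0
    norm = np.zeros_like(disp)
    if expressed.sum() == 0:
        return norm
    qs = np.quantile(mean[expressed], np.linspace(0, 1, n_bins + 1))
    bins = np.searchsorted(qs[1:-1], mean, side="right")
    for b in range(n_bins):
        members = expressed & (bins == b)
        if members.sum() == 0:
            continue
        d = disp[members]
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        if mad == 0:
            mad = 1.0  # flat bin: dispersions identical, all z-scores 0
        norm[members] = (d - med) / mad
    return norm


def compute_pca_matrix(X, n_components: int = 50, center: bool = True) -> PCAResult:
    """Exact PCA of a (possibly sparse) cells × genes matrix via thin SVD.

    Component signs are fixed so each component's largest-magnitude gene
    loading is positive; eigenvalue_j = s_j^2 / (n − 1).
    """
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 cells")
    K = min(n_components, n - 1, X.shape[1])
    dense = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    if center:
        dense = dense - dense.mean(axis=0, keepdims=True)
    U, s, Vt = scipy.linalg.svd(dense, full_matrices=False, lapack_driver="gesdd")
    U, s, Vt = U[:, :K], s[:K], Vt[:K]
    # deterministic sign convention
    flip = np.sign(Vt[np.arange(K), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U * s[None, :]
    eigenvalues = s**2 / (n - 1)
    return PCAResult(
        scores=scores, eigenvalues=eigenvalues, loadings=Vt.T, n_components=K
    )


def compute_pca(
    layer: NormalizedLayer,
    genes: Sequence[str] | None = None,
    n_components: int = 50,
    center: bool = True,
) -> PCAResult:
    """PCA of the log-normalized layer restricted to a gene subset."""
    if genes is None:
        idx = np.arange(len(layer.gene_ids))
    else:
        pos = {g: i for i, g in enumerate(layer.gene_ids)}
        idx = np.asarray([pos[g] for g in genes if g in pos], dtype=int)
        if idx.size == 0:
            raise ValueError("no requested gene present in the layer")
    res = compute_pca_matrix(layer.values[:, idx], n_components=n_components, center=center)
    res.gene_ids = layer.gene_ids[idx]
    return res
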