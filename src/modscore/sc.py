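"""Single-cell processing: QC filtering, marker DE, and per-cell scoring.

Implements the single-cell stage used to define the in-vivo phenotypic
modulation axis of smooth muscle cells: per-cell QC on detected features,
total counts and mitochondrial percentage; library-size log-normalization;
rank-based cluster-vs-cluster marker detection; a per-cell signature score
(mean of per-gene z-scores); and construction of the oriented in-vivo
modulation gene reference consumed by the composite score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

#: the default 7-gene phenotypic-modulation signature (top markers of
#: chondromyocyte-like modulated SMCs vs differentiated SMCs)
MODULATION_SIGNATURE = ["IBSP", "TMEM119", "VCAM1", "DCN", "LUM", "MXRA5", "PDPN"]


@dataclass
class CellMatrix:
    """Sparse cell x gene counts with per-gene mito annotation and labels."""

    counts: sparse.csr_matrix
    cell_ids: List[str]
    gene_symbols: List[str]
    mito_mask: np.ndarray
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length mismatch")
        if len(self.gene_symbols) != n_genes:
            raise ValueError("gene_symbols length mismatch")
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        if self.mito_mask.shape != (n_genes,):
            raise ValueError("mito_mask must align to genes")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def qc_metrics(self) -> pd.DataFrame:
        """Per-cell features (genes with count>0), total counts, mito percent."""
        c = self.counts
        features = np.asarray((c > 0).sum(axis=1)).ravel()
        total = np.asarray(c.sum(axis=1)).ravel()
        mito = np.asarray(c[:, self.mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_pct = np.where(total > 0, 100.0 * mito / np.maximum(total, 1), 0.0)
        return pd.DataFrame(
            {"n_features": features, "total_counts": total, "mito_pct": mito_pct},
            index=self.cell_ids,
        )

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        keep = np.asarray(keep)
        ids = [self.cell_ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool else [
            self.cell_ids[i] for i in keep
        ]
        return CellMatrix(
            counts=self.counts[keep],
            cell_ids=ids,
            gene_symbols=self.gene_symbols,
            mito_mask=self.mito_mask,
            labels=self.labels.loc[ids] if self.labels is not None else None,
        )


@dataclass
class QCParams:
    """Cell QC bounds. Exclusion is strict ("less than" / "more than"), so a
    cell sitting exactly on a bound (500 or 4000 features, 15000 counts,
    20% mito) is retained."""

    min_features: int = 500
    max_features: int = 4000
    max_counts: int = 15000
    max_mito_pct: float = 20.0

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        if min(self.min_features, self.max_counts) <= 0 or self.max_mito_pct <= 0:
            raise ValueError("QC bounds must be positive")


def qc_filter(
    m: CellMatrix, params: QCParams | None = None
) -> tuple[CellMatrix, pd.Series]:
    """Apply per-cell QC; returns (retained CellMatrix, per-rule exclusion counts).

    A cell is retained iff min_features <= n_features <= max_features AND
    total_counts <= max_counts AND mito_pct <= max_mito_pct. The counts
    Series reports, per rule, how many cells violated it (a cell can violate
    several rules and is counted under each).
    """
    if params is None:
        params = QCParams()
    qc = m.qc_metrics()
    viol = pd.DataFrame(
        {
            "low_features": qc["n_features"] < params.min_features,
            "high_features": qc["n_features"] > params.max_features,
            "high_counts": qc["total_counts"] > params.max_counts,
            "high_mito": qc["mito_pct"] > params.max_mito_pct,
        }
    )
    keep = ~viol.any(axis=1)
    return m.subset_cells(keep.to_numpy()), viol.sum(axis=0)


def normalize_log(m: CellMatrix, scale: float = 1e4) -> np.ndarray:
    """Depth-normalized log counts: x = ln(1 + count/total * scale).

    Returns a dense cells x genes array. Cells with zero total counts must be
    filtered out first (raises otherwise).
    """
    total = np.asarray(m.counts.sum(axis=1)).ravel()
    if (total == 0).any():
        raise ValueError("zero-total cell present; run qc_filter first")
    x = m.counts.multiply(scale / total[:, None]).toarray()
    return np.log1p(x)


def rank_markers(
    norm: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    gene_symbols: Sequence[str],
) -> pd.DataFrame:
    """Rank-sum marker test of group A vs group B on normalized expression.

    Per gene: two-sided Wilcoxon rank-sum (Mann-Whitney, normal approximation
    with tie correction) p-value, BH adjustment over genes, and
    log2fc = log2((mean expm1 in A + 1) / (mean expm1 in B + 1)); positive
    log2fc means higher in A. Genes constant across both groups get p = 1.
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    xa = norm[a]
    xb = norm[b]
    if xa.shape[0] < 3 or xb.shape[0] < 3:
        raise ValueError("both groups need >= 3 cells")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(
            xa, xb, axis=0, alternative="two-sided", method="asymptotic"
        )
        pvalue = np.asarray(res.pvalue, dtype=float)
    pvalue = np.where(np.isfinite(pvalue), pvalue, 1.0)
    # constant genes (all ties) -> no evidence
    const = np.ptp(norm[np.concatenate([a, b])], axis=0) == 0
    pvalue = np.where(const, 1.0, pvalue)
    padj = multipletests(pvalue, method="fdr_bh")[1]
    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "padj": padj, "tested": True},
        index=list(gene_symbols),
    )


def percell_modulation_score(
    norm: np.ndarray,
    gene_symbols: Sequence[str],
    signature: Sequence[str] = MODULATION_SIGNATURE,
) -> pd.Series:
    """Per-cell signature score: mean of per-gene z-scores over the signature.

    Each signature gene's normalized expression is z-scored across all cells
    (genes with zero variance contribute 0); the score is the mean over
    signature genes present in the matrix. Missing genes raise a warning;
    an entirely absent signature raises. Higher scores indicate cells whose
    expression is shifted toward the modulated phenotype.
    """
    sym = {g: i for i, g in enumerate(gene_symbols)}
    present = [g for g in signature if g in sym]
    missing = [g for g in signature if g not in sym]
    if not present:
        raise ValueError("no signature gene present in matrix")
    if missing:
        warnings.warn(f"signature genes missing from matrix: {missing}")
    x = norm[:, [sym[g] for g in present]]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.mean(axis=1), name="modulation_score")


def build_modulation_reference(
    m: CellMatrix,
    modulated_clusters: Iterable,
    differentiated_clusters: Iterable,
    padj_cut: float = 0.05,
) -> pd.DataFrame:
    """Oriented in-vivo modulation gene list from cluster labels.

    Runs :func:`rank_markers` comparing the pooled modulated clusters against
    the pooled differentiated clusters, keeps genes with padj < padj_cut (no
    fold-change gate), and assigns each a direction sign: +1 up in modulated
    cells, -1 up in differentiated cells. Genes with a log2fc of exactly 0
    are dropped. Passing a single cluster as the modulated set gives the
    chondromyocyte-only axis variant.

    Returns a DataFrame indexed by gene with columns ``invivo_log2fc`` and
    ``sign``.
    """
    if m.labels is None:
        raise ValueError("CellMatrix has no cluster labels")
    lab = m.labels.to_numpy()
    mod = np.flatnonzero(np.isin(lab, list(modulated_clusters)))
    diff = np.flatnonzero(np.isin(lab, list(differentiated_clusters)))
    if len(mod) == 0 or len(diff) == 0:
        raise ValueError("both cluster groups must be non-empty")
    norm = normalize_log(m)
    de = rank_markers(norm, mod, diff, m.gene_symbols)
    sig = de[(de["padj"] < padj_cut) & (de["log2fc"] != 0)]
    if sig.empty:
        raise ValueError("no significant marker genes at the given padj cut")
    ref = pd.DataFrame(
        {
            "invivo_log2fc": sig["log2fc"],
            "sign": np.where(sig["log2fc"] > 0, 1, -1).astype(int),
        },
        index=sig.index,
    )
    return ref
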