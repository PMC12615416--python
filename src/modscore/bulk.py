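"""Bulk RNA-seq differential expression for two-condition perturbation designs.

This module covers the bulk stage of the pipeline: TPM computation used to
validate overexpression of a transduced construct, the low-count gene
pre-filter, a negative-binomial Wald test for treated-vs-control contrasts,
Benjamini-Hochberg multiplicity adjustment, and the DEG calling rules
(adjusted p and absolute log2 fold-change cutoffs, with a stringent-p
profile for very large transcriptomic shifts).

The NB test here is deliberately simple and fully documented: median-of-ratios
library-size normalization, method-of-moments dispersion (pooled across genes
by default), a pseudocounted log2 fold change of normalized group means, and a
delta-method Wald statistic. It is not a reimplementation of any published
package; calibration is established by the simulation tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTROL = "control"
TREATED = "treated"

#: floor applied to method-of-moments dispersion estimates
DISPERSION_FLOOR = 1e-8

#: pseudocount added to normalized group means before taking log2 ratios
LFC_PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Integer gene x sample count table with lengths and condition labels.

    Parameters
    ----------
    counts
        Genes (rows) by samples (columns) DataFrame of nonnegative integers.
    gene_lengths
        Effective gene length in bp, indexed like ``counts`` rows.
    condition
        Maps each sample id to ``"control"`` or ``"treated"``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            raise ValueError("gene_lengths missing for some genes")
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            raise ValueError("condition missing for some samples")
        bad = set(self.condition.unique()) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples(self, group: str) -> pd.Index:
        return self.condition.index[self.condition == group]

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        genes = pd.Index(genes)
        return CountMatrix(
            counts=self.counts.loc[genes],
            gene_lengths=self.gene_lengths.loc[genes],
            condition=self.condition.copy(),
        )


@dataclass
class DEGCallParams:
    """DEG significance rule: ``padj < padj_cut`` and ``|log2FC| > lfc_cut``.

    Both inequalities are strict. The default profile is padj < 0.05 with
    |log2FC| > 1.5; :meth:`stringent` gives the padj < 1e-10 profile used for
    contrasts with very large transcriptomic shifts.
    """

    padj_cut: float = 0.05
    lfc_cut: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.padj_cut <= 1):
            raise ValueError("padj_cut must be in (0, 1]")
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be nonnegative")

    @classmethod
    def stringent(cls) -> "DEGCallParams":
        return cls(padj_cut=1e-10, lfc_cut=1.5)


def compute_tpm(m: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million per sample.

    TPM_g = (c_g / l_g) / sum_h (c_h / l_h) * 1e6, so each column sums to 1e6.
    Raises on all-zero samples (the normalization is undefined).
    """
    rate = m.counts.div(m.gene_lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        zero = list(denom.index[denom == 0])
        raise ValueError(f"all-zero sample(s), TPM undefined: {zero}")
    return rate.div(denom, axis=1) * 1e6


def overexpression_fold(
    tpm: pd.DataFrame, condition: pd.Series, gene: str
) -> float:
    """Fold increase of a gene's mean TPM in treated over control samples."""
    if gene not in tpm.index:
        raise KeyError(f"gene {gene!r} not in TPM matrix")
    ctrl = condition.index[condition == CONTROL]
    trt = condition.index[condition == TREATED]
    if len(ctrl) == 0 or len(trt) == 0:
        raise ValueError("both condition groups must be non-empty")
    mean_ctrl = float(tpm.loc[gene, ctrl].mean())
    mean_trt = float(tpm.loc[gene, trt].mean())
    if mean_ctrl == 0:
        raise ZeroDivisionError(f"control mean TPM of {gene!r} is zero")
    return mean_trt / mean_ctrl


def prefilter_genes(
    m: CountMatrix, min_count: int = 10, min_samples: int = 4
) -> pd.Index:
    """Genes with at least ``min_count`` counts in at least ``min_samples`` samples.

    The defaults keep genes with >=10 counts in >=4 samples, i.e. one full
    replicate group in a 4+4 design. Input gene order is preserved.
    """
    if min_samples > m.counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds n_samples={m.counts.shape[1]}"
        )
    ok = (m.counts >= min_count).sum(axis=1) >= min_samples
    return m.gene_ids[ok]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Ratios are taken to the per-gene geometric mean over genes expressed in
    every sample; falls back to total-count scaling when no such gene exists.
    Factors are rescaled to geometric mean 1.
    """
    c = np.asarray(counts, dtype=float)
    all_pos = (c > 0).all(axis=1)
    if all_pos.any():
        logc = np.log(c[all_pos])
        log_geo = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - log_geo, axis=0))
    else:
        totals = c.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with all-zero counts; cannot normalize")
        sf = totals / totals.mean()
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _moment_dispersion(y_a: np.ndarray, y_b: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion from normalized counts.

    Uses the within-group variance pooled over the two groups and the pooled
    mean; alpha_g = (var - mu) / mu^2 under var = mu + alpha mu^2.
    """
    n_a, n_b = y_a.shape[1], y_b.shape[1]
    var_a = y_a.var(axis=1, ddof=1)
    var_b = y_b.var(axis=1, ddof=1)
    pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    mu = (y_a.sum(axis=1) + y_b.sum(axis=1)) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu) / mu**2
    return alpha


def nb_wald_test(
    m: CountMatrix,
    dispersion: str = "pooled",
    pseudocount: float = LFC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Treated-vs-control NB Wald test for every gene in ``m``.

    ``dispersion="pooled"`` (default) uses a single dispersion for all genes,
    the median of the positive per-gene method-of-moments estimates; with only
    a few replicates per group this borrows strength across genes the way
    shrinkage estimators do, and is what keeps the test calibrated at n = 4.
    ``dispersion="per-gene"`` uses the raw per-gene estimates (floored).

    Returns a DataFrame indexed by gene with columns ``base_mean``, ``log2fc``,
    ``se``, ``stat``, ``pvalue``, ``padj`` and ``tested``. Run after
    :func:`prefilter_genes`; BH adjustment is over all rows of the input.
    """
    ctrl = m.samples(CONTROL)
    trt = m.samples(TREATED)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >=2 samples per condition")

    sf = size_factors(m.counts)
    y = np.asarray(m.counts, dtype=float) / np.asarray(sf)[None, :]
    col = {s: i for i, s in enumerate(m.sample_ids)}
    y_t = y[:, [col[s] for s in trt]]
    y_c = y[:, [col[s] for s in ctrl]]
    n_t, n_c = y_t.shape[1], y_c.shape[1]

    mu_t = y_t.mean(axis=1)
    mu_c = y_c.mean(axis=1)
    base_mean = y.mean(axis=1)

    alpha_g = _moment_dispersion(y_t, y_c)
    if dispersion == "pooled":
        # mean over all finite per-gene estimates, negatives included: each
        # per-gene moment estimate is unbiased but right-skewed, so the mean
        # pools them without the downward bias a median would introduce
        finite = alpha_g[np.isfinite(alpha_g)]
        alpha = float(finite.mean()) if finite.size else DISPERSION_FLOOR
        alpha = max(alpha, DISPERSION_FLOOR)
    elif dispersion == "per-gene":
        alpha = np.where(np.isfinite(alpha_g), alpha_g, DISPERSION_FLOOR)
        alpha = np.maximum(alpha, DISPERSION_FLOOR)
    else:
        raise ValueError("dispersion must be 'pooled' or 'per-gene'")

    log2fc = np.log2((mu_t + pseudocount) / (mu_c + pseudocount))

    # delta method on log2 of pseudocounted group means, NB variance mu+a*mu^2
    var_mean_t = (mu_t + alpha * mu_t**2) / n_t
    var_mean_c = (mu_c + alpha * mu_c**2) / n_c
    se = np.sqrt(
        var_mean_t / (mu_t + pseudocount) ** 2
        + var_mean_c / (mu_c + pseudocount) ** 2
    ) / math.log(2)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2 * stats.norm.sf(np.abs(stat))
    padj = multipletests(pvalue, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "tested": True,
        },
        index=m.gene_ids,
    )


def call_degs(
    table: pd.DataFrame, params: DEGCallParams | None = None
) -> pd.DataFrame:
    """Apply the DEG rule to a DE table.

    A gene is called iff padj < padj_cut AND |log2fc| > lfc_cut, both strict.
    Returns the called rows with a ``direction`` column (+1 up, -1 down),
    preserving input order. Untested rows (``tested == False``) never call.
    """
    if params is None:
        params = DEGCallParams()
    tested = table["tested"] if "tested" in table else pd.Series(True, index=table.index)
    called = (
        tested.astype(bool)
        & (table["padj"] < params.padj_cut)
        & (table["log2fc"].abs() > params.lfc_cut)
    )
    out = table.loc[called, ["log2fc", "padj"]].copy()
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out
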