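"""Normalization and transforms applied before the liquid-association screen.

The screen assumes every gene vector is marginally normal with mean 0 and
variance 1.  Raw RNA-seq counts are first depth/length normalized (RPKM),
low/flat genes are filtered, then each gene is mapped onto normal scores
(rank-based inverse-normal transform) and standardized:

    value_i = Phi^{-1}((rank_i - 0.5) / n)

with average ranks over ties.  Because the normal scores of a tie-free
vector are a fixed set of values depending only on n, the transform makes
every gene's marginal distribution identical, and Pearson correlation of
transformed genes is a rank correlation of the raw data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyResultError, InputError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def rpkm(counts, gene_lengths, library_sizes) -> pd.DataFrame:
    """Reads-per-kilobase-per-million normalization.

    value = count * 1e9 / (gene_length * library_size), per cell.

    Parameters
    ----------
    counts
        genes x samples DataFrame (or array) of non-negative read counts.
    gene_lengths
        Per-gene transcript length in base pairs (aligned with rows).
    library_sizes
        Per-sample total mapped reads (aligned with columns).
    """
    counts = pd.DataFrame(counts)
    lengths = np.asarray(gene_lengths, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if lengths.shape[0] != counts.shape[0]:
        raise InputError(
            f"gene_lengths has {lengths.shape[0]} entries for {counts.shape[0]} genes"
        )
    if libs.shape[0] != counts.shape[1]:
        raise InputError(
            f"library_sizes has {libs.shape[0]} entries for {counts.shape[1]} samples"
        )
    bad = np.nonzero(lengths <= 0)[0]
    if bad.size:
        raise InputError(f"non-positive gene length for gene(s) at rows {bad[:5].tolist()}")
    bad = np.nonzero(libs <= 0)[0]
    if bad.size:
        raise InputError(f"non-positive library size for sample(s) at columns {bad[:5].tolist()}")
    values = counts.to_numpy(dtype=float) * 1e9 / (lengths[:, None] * libs[None, :])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def rpkm_from_files(counts_path, lengths_path, metadata_path) -> ExpressionMatrix:
    """RPKM-normalize a counts TSV using a two-column gene-length TSV.

    ``counts_path``: genes x samples TSV (gene id in the first column).
    ``lengths_path``: TSV with columns gene_id, length (base pairs).
    Library sizes are the per-sample column sums of the counts table.
    """
    counts = ExpressionMatrix.from_tsv(counts_path, metadata_path)
    lengths = pd.read_csv(lengths_path, sep="\t")
    if lengths.shape[1] < 2:
        raise InputError("gene-length TSV needs columns gene_id, length")
    lengths = lengths.set_index(lengths.columns[0])[lengths.columns[1]]
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise InputError(f"gene lengths missing for: {missing[:5]}")
    values = rpkm(
        counts.values,
        lengths.reindex(counts.gene_ids).to_numpy(dtype=float),
        counts.values.sum(axis=0).to_numpy(dtype=float),
    )
    return ExpressionMatrix(values, counts.groups)


def filter_genes(
    matrix: ExpressionMatrix,
    min_median_expression: float = 1.0,
    min_variance: float = 0.0,
) -> ExpressionMatrix:
    """Keep genes with median >= min_median_expression and variance >= min_variance.

    Variance uses the sample (n-1) denominator.  Genes with exactly zero
    variance are always dropped (they cannot be rank-normalized).  Gene
    order is preserved; removals are logged.
    """
    if min_median_expression < 0 or min_variance < 0:
        raise InputError("filter thresholds must be >= 0")
    vals = matrix.to_array()
    medians = np.median(vals, axis=1)
    variances = np.var(vals, axis=1, ddof=1)
    keep = (medians >= min_median_expression) & (variances >= min_variance) & (variances > 0)
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "filter_genes: removed %d of %d genes (median < %g, variance < %g or 0)",
            removed, matrix.n_genes, min_median_expression, min_variance,
        )
    if not keep.any():
        raise EmptyResultError("gene filter removed every gene")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.groups)


def normal_score_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform of one gene vector.

    Maps value_i -> Phi^{-1}((rank_i - 0.5)/n) with average ranks over ties;
    invariant under strictly monotone transforms of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise InputError("normal_score_transform requires a 1-d vector of length >= 3")
    if np.all(x == x[0]):
        raise InputError("constant vector: all ranks tied, gene should have been filtered")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def standardize(values) -> np.ndarray:
    """Center to mean 0 and scale to unit sample variance (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    sd = np.std(x, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise InputError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def normalize_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene normal-score transform followed by standardization.

    The result satisfies, for every gene row, |mean| < 1e-8 and
    |variance - 1| < 1e-6, and each row is a permutation of a fixed set of
    normal scores (exact marginal normality by construction).
    """
    vals = matrix.to_array()
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        out[i] = standardize(normal_score_transform(vals[i]))
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.groups)
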