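"""Switch-gene evaluation by supervised classification.

A random forest (10,000 trees by default, sqrt-of-features mtry) is
trained to classify the sample groups from switch-gene expression.  Gene
importance is mean decrease accuracy (MDA): for every tree, the drop in
out-of-bag accuracy when one gene's values are permuted among that tree's
out-of-bag samples, averaged over trees — the permutation importance of
the classical randomForest package.  Classifier performance is summarized
by an ROC curve on out-of-bag class probabilities, and per-gene group
differences by one-way ANOVA with Tukey HSD post-hoc comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils import check_random_state
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InputError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for cut, stars in STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


@dataclass
class ImportanceReport:
    """Per-gene MDA importance with the forest settings that produced it."""

    table: pd.DataFrame          # gene, mda, rank (descending importance)
    oob_error: float
    oob_scores: pd.DataFrame     # per-sample out-of-bag class probabilities
    n_trees: int
    mtry: int
    seed: int
    classes: tuple

    def ranking(self) -> list[str]:
        return list(self.table["gene"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    operating_threshold: float

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class GroupComparison:
    gene: str
    f_statistic: float
    anova_p: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, stars


def _oob_masks(forest: RandomForestClassifier, n_samples: int) -> list[np.ndarray]:
    """Out-of-bag mask per tree, reconstructed from each tree's bootstrap seed.

    Mirrors scikit-learn's bootstrap draw (randint(0, n, n) from the
    tree's random_state); the reconstruction is cross-checked against the
    forest's own OOB votes in the test suite.
    """
    masks = []
    for tree in forest.estimators_:
        rs = check_random_state(tree.random_state)
        sampled = rs.randint(0, n_samples, n_samples)
        mask = np.ones(n_samples, dtype=bool)
        mask[sampled] = False
        masks.append(mask)
    return masks


def fit_switch_classifier(
    matrix: ExpressionMatrix,
    genes,
    labels=None,
    n_trees: int = 10_000,
    seed: int = 0,
) -> ImportanceReport:
    """Train the forest on the given genes and compute OOB-based MDA.

    ``labels`` defaults to the matrix's group labels (multi-class).
    mtry is floor(sqrt(p)) features per split.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise InputError("classifier needs at least 2 genes")
    sub = matrix.subset_genes(genes)
    X = sub.to_array().T  # samples x features
    y = np.asarray(matrix.groups.values if labels is None else labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise InputError("classification needs at least 2 classes in the labels")
    n, p = X.shape
    mtry = max(1, int(np.sqrt(p)))
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    oob_error = 1.0 - float(forest.oob_score_)

    rng = np.random.default_rng(seed)
    masks = _oob_masks(forest, n)
    drops = np.zeros((len(forest.estimators_), p))
    used = np.zeros(len(forest.estimators_), dtype=bool)
    for t, (tree, mask) in enumerate(zip(forest.estimators_, masks)):
        m = int(mask.sum())
        if m < 2:
            continue
        used[t] = True
        Xo = X[mask]
        yo = y[mask]
        # one batched predict per tree: original OOB block + one permuted
        # block per feature
        blocks = [Xo]
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(m), j]
            blocks.append(Xp)
        pred = tree.predict(np.vstack(blocks))
        pred = forest.classes_[pred.astype(int)] if pred.dtype.kind in "fiu" else pred
        base_acc = float(np.mean(pred[:m] == yo))
        for j in range(p):
            acc = float(np.mean(pred[(j + 1) * m:(j + 2) * m] == yo))
            drops[t, j] = base_acc - acc
    if not used.any():
        raise InputError("no tree had enough out-of-bag samples for MDA")
    mda = drops[used].mean(axis=0)
    order = np.lexsort((genes, -mda))
    table = pd.DataFrame(
        {"gene": np.asarray(genes)[order], "mda": mda[order],
         "rank": np.arange(1, p + 1)}
    )
    oob_scores = pd.DataFrame(
        forest.oob_decision_function_, index=sub.sample_ids, columns=forest.classes_
    )
    logger.info("forest: %d trees, mtry=%d, OOB error %.3f; top gene %s",
                n_trees, mtry, oob_error, table["gene"].iloc[0])
    return ImportanceReport(
        table=table, oob_error=oob_error, oob_scores=oob_scores,
        n_trees=n_trees, mtry=mtry, seed=seed, classes=tuple(forest.classes_),
    )


def roc_auc(class_scores, binary_labels, operating_threshold: float = 0.5) -> RocResult:
    """ROC curve and trapezoidal AUC for scores of the positive class.

    Ties in the scores are handled by placing all tied samples at one
    threshold, which makes the trapezoidal AUC equal the Mann-Whitney
    rank statistic (ties counted 1/2).
    """
    s = np.asarray(class_scores, dtype=float)
    yb = np.asarray(binary_labels).astype(bool)
    n_pos = int(yb.sum())
    n_neg = int((~yb).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yb[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cuts = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y_sorted)[cuts]
    fp = np.cumsum(~y_sorted)[cuts]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[cuts]]
    auc = float(np.trapezoid(tpr, fpr))
    sens = float(np.mean(s[yb] >= operating_threshold))
    spec = float(np.mean(s[~yb] < operating_threshold))
    return RocResult(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
        sensitivity=sens, specificity=spec,
        operating_threshold=operating_threshold,
    )


def anova_tukey(values, labels) -> GroupComparison:
    """One-way ANOVA plus Tukey HSD pairwise comparisons for one gene."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [v[lab == g] for g in np.unique(lab)]
    if len(groups) < 2:
        raise InputError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InputError("every group needs at least 2 samples")
    if all(np.allclose(g, g.mean()) and np.isclose(g.mean(), v.mean()) for g in groups):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(v, lab)
    frame = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    pairwise = pd.DataFrame(
        {
            "group_a": frame["group1"].astype(str),
            "group_b": frame["group2"].astype(str),
            "mean_diff": frame["meandiff"].astype(float),
            "p_adj": np.asarray(tukey.pvalues, dtype=float),
            "stars": [significance_stars(q) for q in np.asarray(tukey.pvalues, float)],
        }
    )
    return GroupComparison(
        gene="", f_statistic=float(f_stat), anova_p=float(p), pairwise=pairwise
    )


def group_comparison_table(matrix: ExpressionMatrix, genes) -> pd.DataFrame:
    """ANOVA + Tukey rows for several genes, one row per gene and pair."""
    rows = []
    for gene in genes:
        comp = anova_tukey(matrix.gene(gene), matrix.groups.values)
        for r in comp.pairwise.itertuples(index=False):
            rows.append(
                {
                    "gene": gene, "f_statistic": comp.f_statistic,
                    "anova_p": comp.anova_p, "group_a": r.group_a,
                    "group_b": r.group_b, "mean_diff": r.mean_diff,
                    "p_adj": r.p_adj, "stars": r.stars,
                }
            )
    return pd.DataFrame(rows)
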