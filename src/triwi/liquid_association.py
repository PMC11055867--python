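"""Binned modified liquid association (MLA) over gene triplets.

A triplet Z/{X, Y} asks whether the co-expression of the unordered pair
(X, Y) changes with the level of a third "switch" gene Z.  Samples are
split into M equal-frequency bins by ascending Z and the statistic is

    MLA(Z/{X, Y}) = (1/M) * sum_i  rho_i * zbar_i

where rho_i is the Pearson correlation of X and Y within bin i and zbar_i
is the mean of (standardized) Z in bin i.  A pair whose correlation flips
sign along Z picks up large |MLA|; a static pair averages to ~0 because
the bin means of a standardized Z are symmetric about zero.

Significance is assessed by permuting Z across samples (re-binning each
time), either as an empirical permutation p-value or as a normal-tail
p-value using the permutation null's moments (needed when the target
significance is far below the 1/(B+1) resolution of B permutations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyResultError, InputError
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BinSpec", "BinSummary", "TripletScore", "ScreenResult", "SignificantSet",
    "bin_by_z", "mla_score", "screen_all_triplets", "permutation_pvalue",
    "compute_pvalues", "adjust_pvalues", "significant_triplets",
]


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class BinSpec:
    """Equal-frequency binning of samples by ascending Z.

    ``assignment[s]`` is the bin index (0-based) of sample s.  Bin sizes
    differ by at most one; remainder samples go to the lowest-index bins.
    Ties in Z are broken by sample position (stable sort).
    """

    M: int
    assignment: np.ndarray

    @property
    def bin_indices(self) -> list[np.ndarray]:
        return [np.nonzero(self.assignment == i)[0] for i in range(self.M)]

    @property
    def sizes(self) -> list[int]:
        return [int((self.assignment == i).sum()) for i in range(self.M)]


@dataclass(frozen=True)
class BinSummary:
    """Per-bin summary entering the MLA formula."""

    rho: float      # Pearson correlation of X and Y within the bin
    z_bar: float    # mean of Z within the bin
    size: int


@dataclass
class TripletScore:
    """One Z/{X, Y} candidate.  The pair is stored in sorted order."""

    z_gene: str
    x_gene: str
    y_gene: str
    mla: float
    bins: list[BinSummary] | None = None
    p_raw: float | None = None
    p_bonferroni: float | None = None
    p_bh: float | None = None

    def __post_init__(self) -> None:
        if self.z_gene in (self.x_gene, self.y_gene) or self.x_gene == self.y_gene:
            raise InputError("triplet genes must be three distinct identifiers")
        if self.x_gene > self.y_gene:
            self.x_gene, self.y_gene = self.y_gene, self.x_gene


@dataclass
class ScreenResult:
    """Ranked triplet table plus the settings that produced it.

    ``table`` columns: z, x, y, mla and, once p-values are computed,
    p_raw, p_perm, p_normal, p_bonferroni, p_bh.  ``n_total`` is the number
    of triplets enumerated (the default multiple-testing family size),
    which can exceed ``len(table)`` when top_k truncation applied.
    """

    table: pd.DataFrame
    M: int
    n_total: int
    top_k: int
    B: int | None = None
    seed: int | None = None
    p_method: str | None = None
    family_size: int | None = None

    def triplets(self) -> list[TripletScore]:
        out = []
        for row in self.table.itertuples(index=False):
            out.append(
                TripletScore(
                    z_gene=row.z, x_gene=row.x, y_gene=row.y, mla=row.mla,
                    p_raw=getattr(row, "p_raw", None),
                    p_bonferroni=getattr(row, "p_bonferroni", None),
                    p_bh=getattr(row, "p_bh", None),
                )
            )
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def meta(self) -> dict:
        return {
            "M": self.M, "n_total": self.n_total, "top_k": self.top_k,
            "B": self.B, "seed": self.seed, "p_method": self.p_method,
            "family_size": self.family_size,
        }


@dataclass
class SignificantSet:
    """Triplets passing the adjusted-p threshold, order preserved."""

    table: pd.DataFrame
    criterion: str
    alpha: float

    def triplets(self) -> list[TripletScore]:
        return ScreenResult(self.table, 0, 0, 0).triplets()


# ---------------------------------------------------------------- operations

def bin_by_z(z_values, M: int = 3) -> BinSpec:
    """Equal-frequency bins over ascending Z; remainder to lowest bins."""
    z = np.asarray(z_values, dtype=float)
    if M < 2:
        raise InputError("M must be >= 2")
    n = z.size
    if n < 3 * M:
        raise InputError(f"need at least 3*M={3 * M} samples for M={M} bins, got {n}")
    order = np.argsort(z, kind="stable")
    base, rem = divmod(n, M)
    sizes = [base + 1 if i < rem else base for i in range(M)]
    assignment = np.empty(n, dtype=np.intp)
    start = 0
    for i, s in enumerate(sizes):
        assignment[order[start:start + s]] = i
        start += s
    return BinSpec(M=M, assignment=assignment)


def _bin_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r of two within-bin vectors; 0 (with warning) if degenerate."""
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        logger.warning("zero within-bin variance; correlation set to 0")
        return 0.0
    return float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))


def mla_score(x, y, z, binspec: BinSpec) -> tuple[float, list[BinSummary]]:
    """Evaluate the MLA formula for one triplet over a given binning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size == binspec.assignment.size):
        raise InputError("x, y, z and the bin assignment must have equal length")
    bins: list[BinSummary] = []
    total = 0.0
    for idx in binspec.bin_indices:
        rho = _bin_corr(x[idx], y[idx])
        z_bar = float(z[idx].mean())
        bins.append(BinSummary(rho=rho, z_bar=z_bar, size=idx.size))
        total += rho * z_bar
    return total / binspec.M, bins


def _chunk_slices(n: int, M: int) -> list[slice]:
    base, rem = divmod(n, M)
    sizes = [base + 1 if i < rem else base for i in range(M)]
    out, start = [], 0
    for s in sizes:
        out.append(slice(start, start + s))
        start += s
    return out


def _mla_all_pairs(V: np.ndarray, z: np.ndarray, M: int) -> tuple[np.ndarray, np.ndarray]:
    """MLA of every gene pair against one Z vector.

    Returns (S, z_bars) where S[i, j] is the MLA of pair (i, j) and z_bars
    the per-bin means of z.  Rows of V with zero within-bin variance
    contribute correlation 0 for that bin.
    """
    G, n = V.shape
    order = np.argsort(z, kind="stable")
    S = np.zeros((G, G))
    z_bars = np.empty(M)
    for b, sl in enumerate(_chunk_slices(n, M)):
        idx = order[sl]
        Vb = V[:, idx]
        Vc = Vb - Vb.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.einsum("ij,ij->i", Vc, Vc))
        zero = norms == 0.0
        norms[zero] = 1.0  # rows flagged zero contribute rho = 0
        Vc /= norms[:, None]
        C = Vc @ Vc.T
        if zero.any():
            C[zero, :] = 0.0
            C[:, zero] = 0.0
        np.clip(C, -1.0, 1.0, out=C)
        z_bars[b] = z[idx].mean()
        S += C * z_bars[b]
    S /= M
    return S, z_bars


def screen_all_triplets(
    matrix: ExpressionMatrix, M: int = 3, top_k: int = 200_000
) -> ScreenResult:
    """Evaluate MLA for every triplet and keep the top_k by |MLA|.

    Every choice of switch gene Z combined with every unordered pair
    {X, Y} not containing Z is evaluated: G * C(G-1, 2) triplets.
    p-values are computed afterwards (for retained triplets only) by
    :func:`compute_pvalues`.
    """
    if top_k < 1:
        raise InputError("top_k must be >= 1")
    V = matrix.to_array()
    G, n = V.shape
    if G < 3:
        raise InputError("need at least 3 genes to form a triplet")
    if n < 3 * M:
        raise InputError(f"need at least 3*M={3 * M} samples, got {n}")
    genes = np.asarray(matrix.gene_ids)
    iu, ju = np.triu_indices(G, k=1)
    n_pairs = iu.size
    n_total = G * ((G - 1) * (G - 2)) // 2

    z_col = np.empty(n_total, dtype=np.intp)
    x_col = np.empty(n_total, dtype=np.intp)
    y_col = np.empty(n_total, dtype=np.intp)
    mla_col = np.empty(n_total, dtype=float)
    pos = 0
    for zi in range(G):
        S, _ = _mla_all_pairs(V, V[zi], M)
        keep = (iu != zi) & (ju != zi)
        k = int(keep.sum())
        z_col[pos:pos + k] = zi
        x_col[pos:pos + k] = iu[keep]
        y_col[pos:pos + k] = ju[keep]
        mla_col[pos:pos + k] = S[iu[keep], ju[keep]]
        pos += k
    assert pos == n_total

    if top_k < n_total:
        part = np.argpartition(-np.abs(mla_col), top_k - 1)[:top_k]
    else:
        part = np.arange(n_total)
    # deterministic ranking: descending |MLA|, ties by (z, x, y) index
    sel = part[np.lexsort((y_col[part], x_col[part], z_col[part], -np.abs(mla_col[part])))]

    gx, gy = genes[x_col[sel]], genes[y_col[sel]]
    swap = gx > gy  # canonical pair order by gene id
    gx[swap], gy[swap] = gy[swap], gx[swap]
    table = pd.DataFrame({"z": genes[z_col[sel]], "x": gx, "y": gy, "mla": mla_col[sel]})
    logger.info("screened %d triplets over %d genes, retained %d", n_total, G, len(table))
    return ScreenResult(table=table, M=M, n_total=n_total, top_k=top_k)


def _random_permutations(rng: np.random.Generator, B: int, n: int) -> np.ndarray:
    return np.argsort(rng.random((B, n)), axis=1)


def permutation_pvalue(x, y, z, M: int = 3, B: int = 999, seed: int = 0) -> float:
    """Permutation p-value of one triplet's |MLA| (permute Z, re-bin).

    Uses the add-one convention p = (1 + #{|MLA_perm| >= |MLA_obs|}) / (B + 1),
    so the smallest attainable value is 1/(B+1).
    """
    if B < 99:
        raise InputError("B must be >= 99")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    obs, _ = mla_score(x, y, z, bin_by_z(z, M))
    null = _permuted_mla_pair(x, y, z, M, B, np.random.default_rng(seed))
    return (1 + int(np.sum(np.abs(null) >= abs(obs)))) / (B + 1)


def _permuted_mla_pair(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, M: int, B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized permutation null of MLA for a single pair (B draws)."""
    n = z.size
    perms = _random_permutations(rng, B, n)
    Zp = z[perms]                                  # (B, n)
    order = np.argsort(Zp, axis=1, kind="stable")
    mla = np.zeros(B)
    for sl in _chunk_slices(n, M):
        idx = order[:, sl]
        xb = x[idx]
        yb = y[idx]
        xc = xb - xb.mean(axis=1, keepdims=True)
        yc = yb - yb.mean(axis=1, keepdims=True)
        num = np.einsum("ij,ij->i", xc, yc)
        den = np.sqrt(np.einsum("ij,ij->i", xc, xc) * np.einsum("ij,ij->i", yc, yc))
        rho = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        zb = np.take_along_axis(Zp, idx, axis=1).mean(axis=1)
        mla += np.clip(rho, -1.0, 1.0) * zb
    return mla / M


def compute_pvalues(
    screen: ScreenResult,
    matrix: ExpressionMatrix,
    B: int = 999,
    seed: int = 0,
    method: str = "normal",
) -> ScreenResult:
    """Attach permutation-based p-values to every retained triplet.

    For each switch gene, Z is permuted B times and the full pair-MLA
    matrix recomputed per permutation, giving each retained triplet an
    empirical tail count and the first two moments of its permutation
    null.  ``method='permutation'`` uses the empirical p (resolution
    1/(B+1)); ``method='normal'`` uses a two-sided normal tail with the
    triplet's own null mean but the null SD pooled across all retained
    triplets, which resolves p-values far below 1/(B+1) for large
    multiple-testing families.  Pooling is justified by the screen's
    rank-normalized input — every triplet's null is built from the same
    marginal normal scores — and mirrors the parametric null of
    model-based liquid-association screens; ``method='normal_per_triplet'``
    keeps each triplet's own (noisier, data-conditional) SD instead.

    Both columns (p_perm, p_normal) are stored; p_raw follows ``method``.
    """
    if B < 99:
        raise InputError("B must be >= 99")
    if method not in ("normal", "normal_per_triplet", "permutation"):
        raise InputError(f"unknown p-value method: {method!r}")
    V = matrix.to_array()
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    table = screen.table.copy()
    zi = table["z"].map(gene_index).to_numpy()
    xi = table["x"].map(gene_index).to_numpy()
    yi = table["y"].map(gene_index).to_numpy()
    obs = np.abs(table["mla"].to_numpy())

    counts = np.zeros(len(table), dtype=np.int64)
    s1 = np.zeros(len(table))
    s2 = np.zeros(len(table))
    root = np.random.SeedSequence(seed)
    z_order = np.unique(zi)
    children = root.spawn(len(z_order))
    for child, z_gene in zip(children, z_order):
        rows = np.nonzero(zi == z_gene)[0]
        rng = np.random.default_rng(child)
        z = V[z_gene]
        n = z.size
        perms = _random_permutations(rng, B, n)
        sub_genes = np.unique(np.concatenate([xi[rows], yi[rows]]))
        remap = {g: k for k, g in enumerate(sub_genes)}
        rx = np.array([remap[g] for g in xi[rows]])
        ry = np.array([remap[g] for g in yi[rows]])
        Vsub = V[sub_genes]
        for b in range(B):
            S, _ = _mla_all_pairs(Vsub, z[perms[b]], screen.M)
            vals = S[rx, ry]
            counts[rows] += np.abs(vals) >= obs[rows]
            s1[rows] += vals
            s2[rows] += vals * vals
    p_perm = (1 + counts) / (B + 1)
    mean = s1 / B
    var = np.maximum(s2 / B - mean**2, 0.0) * B / (B - 1)
    if method == "normal_per_triplet":
        sd = np.sqrt(var)
    else:
        sd = np.full(len(table), np.sqrt(var.mean()))
    with np.errstate(divide="ignore", invalid="ignore"):
        zscore = np.where(sd > 0, (np.abs(table["mla"].to_numpy() - mean)) / sd, 0.0)
    p_normal = np.clip(2 * stats.norm.sf(zscore), np.finfo(float).tiny, 1.0)
    table["p_perm"] = p_perm
    table["p_normal"] = p_normal
    table["p_raw"] = p_perm if method == "permutation" else p_normal
    return ScreenResult(
        table=table, M=screen.M, n_total=screen.n_total, top_k=screen.top_k,
        B=B, seed=seed, p_method=method, family_size=screen.family_size,
    )


def adjust_pvalues(p_list, method: str = "bonferroni", m_total: int | None = None) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment with explicit family size.

    ``m_total`` may exceed the number of supplied p-values (tests not
    retained are treated as non-significant members of the family);
    it defaults to the list length, where BH matches the standard step-up.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise InputError(f"family size {m} smaller than number of p-values {p.size}")
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, p.size + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(adj, 1.0)
        return out
    raise InputError(f"unknown adjustment method: {method!r}")


def adjust_screen(screen: ScreenResult, m_total: int | None = None) -> ScreenResult:
    """Attach p_bonferroni and p_bh columns (family defaults to all triplets)."""
    if "p_raw" not in screen.table.columns:
        raise InputError("compute p-values before adjusting them")
    m = screen.n_total if m_total is None else m_total
    table = screen.table.copy()
    table["p_bonferroni"] = adjust_pvalues(table["p_raw"], "bonferroni", m)
    table["p_bh"] = adjust_pvalues(table["p_raw"], "bh", m)
    out = ScreenResult(
        table=table, M=screen.M, n_total=screen.n_total, top_k=screen.top_k,
        B=screen.B, seed=screen.seed, p_method=screen.p_method, family_size=m,
    )
    return out


def significant_triplets(
    screen: ScreenResult, alpha: float = 0.001, criterion: str = "bonferroni"
) -> SignificantSet:
    """Subset with adjusted p below alpha, screen order preserved."""
    col = {"bonferroni": "p_bonferroni", "bh": "p_bh"}.get(criterion)
    if col is None:
        raise InputError(f"criterion must be 'bonferroni' or 'bh', got {criterion!r}")
    if col not in screen.table.columns:
        raise InputError("adjusted p-values not computed; call adjust_screen first")
    table = screen.table[screen.table[col] < alpha].reset_index(drop=True)
    if table.empty:
        logger.warning("no triplet passes %s-adjusted p < %g", criterion, alpha)
    else:
        logger.info("%d of %d retained triplets pass %s-adjusted p < %g",
                    len(table), len(screen.table), criterion, alpha)
    return SignificantSet(table=table, criterion=criterion, alpha=alpha)


def read_screen_tsv(path, meta: dict | None = None) -> ScreenResult:
    """Load a screen table written by :meth:`ScreenResult.to_tsv`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"screen table not found: {path}")
    table = pd.read_csv(path, sep="\t")
    meta = meta or {}
    return ScreenResult(
        table=table,
        M=meta.get("M", 3),
        n_total=meta.get("n_total", len(table)),
        top_k=meta.get("top_k", len(table)),
        B=meta.get("B"),
        seed=meta.get("seed"),
        p_method=meta.get("p_method"),
        family_size=meta.get("family_size"),
    )
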