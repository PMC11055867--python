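"""Mutual-information network with ARACNE-style pruning.

All gene pairs are scored by mutual information; edges whose
Bonferroni-corrected permutation p-value clears alpha are kept, then the
data-processing inequality (DPI) prunes the weakest edge of every
remaining triangle (a likely indirect interaction) when its MI falls
below (1 - tolerance) times the smaller of the other two.

The default MI estimator is the Gaussian-copula one on normal scores,
MI = -1/2 * ln(1 - r^2) with r the Pearson correlation of the
rank-normalized vectors — consistent here because the screen's input is
already marginally normal, and monotone in |r| so permutation tests on MI
and on |r| coincide.  A binned plug-in estimator is kept as a
nonparametric cross-check.

Edges are undirected: mutual information is symmetric and the network is
used for path existence only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .liquid_association import TripletScore
from .matrix import ExpressionMatrix
from .preprocessing import normal_score_transform

logger = logging.getLogger(__name__)


def mutual_information(x, y, estimator: str = "gaussian_rank") -> float:
    """Mutual information of two vectors, in nats.  Symmetric, >= 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("vectors must have equal length")
    if x.size < 10:
        raise InputError("mutual information needs at least 10 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InputError("mutual information undefined for a constant vector")
    if estimator == "gaussian_rank":
        r = np.corrcoef(normal_score_transform(x), normal_score_transform(y))[0, 1]
        r2 = min(r * r, 1.0 - 1e-15)
        return float(-0.5 * np.log1p(-r2))
    if estimator == "binned":
        nb = int(np.ceil(np.sqrt(x.size)))
        bx = _equal_frequency_bins(x, nb)
        by = _equal_frequency_bins(y, nb)
        joint = np.zeros((nb, nb))
        np.add.at(joint, (bx, by), 1.0)
        joint /= x.size
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = joint * np.log(joint / (px * py))
        return float(max(np.nansum(terms), 0.0))
    raise InputError(f"unknown MI estimator: {estimator!r}")


def _equal_frequency_bins(v: np.ndarray, nb: int) -> np.ndarray:
    order = np.argsort(v, kind="stable")
    out = np.empty(v.size, dtype=np.intp)
    out[order] = np.minimum(np.arange(v.size) * nb // v.size, nb - 1)
    return out


@dataclass
class MutualInfoNetwork:
    """Edge table plus the surviving (significant, unpruned) graph."""

    edges: pd.DataFrame  # gene_a, gene_b, mi, p_raw, p_bonferroni, significant, dpi_pruned
    graph: nx.Graph      # surviving edges only
    alpha: float
    dpi_tolerance: float
    B: int
    seed: int
    estimator: str

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, lineterminator="\n")


def aracne_network(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    dpi_tolerance: float = 0.15,
    B: int | None = None,
    seed: int = 0,
    estimator: str = "gaussian_rank",
) -> MutualInfoNetwork:
    """All-pairs MI network, permutation-tested and DPI-pruned.

    The permutation null permutes each probe's sample order relative to
    the rest (one shared permutation per replicate across pairs — common
    random numbers; each pair's marginal null is exact).  The Bonferroni
    family is the number of gene pairs.  ``B`` defaults to
    ceil(4 * n_pairs / alpha), the smallest round count at which the
    1/(B+1) resolution sits comfortably below the Bonferroni threshold.
    """
    G = matrix.n_genes
    if G < 3:
        raise InputError("ARACNE needs at least 3 genes")
    genes = np.asarray(matrix.gene_ids)
    V = matrix.to_array()
    n = V.shape[1]
    scores = np.empty_like(V)
    for i in range(G):
        scores[i] = normal_score_transform(V[i])
    S = scores - scores.mean(axis=1, keepdims=True)
    S /= np.sqrt(np.einsum("ij,ij->i", S, S))[:, None]

    iu, ju = np.triu_indices(G, k=1)
    n_pairs = iu.size
    if B is None:
        B = int(np.ceil(4 * n_pairs / alpha))
    C = S @ S.T
    r_obs = np.abs(C[iu, ju])

    rng = np.random.default_rng(seed)
    counts = np.zeros(n_pairs, dtype=np.int64)
    chunk = max(1, min(B, int(2e6 // (G * n) + 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        stacked = S[:, perms].transpose(1, 0, 2).reshape(b * G, n)  # (b*G, n)
        Cp = (stacked @ S.T).reshape(b, G, G)
        counts += (np.abs(Cp[:, iu, ju]) >= r_obs[None, :]).sum(axis=0)
        done += b
    p_raw = (1 + counts) / (B + 1)
    p_bonf = np.minimum(p_raw * n_pairs, 1.0)
    significant = p_bonf < alpha

    r2 = np.minimum(C[iu, ju] ** 2, 1.0 - 1e-15)
    mi = -0.5 * np.log1p(-r2)
    if estimator == "binned":
        mi = np.array([
            mutual_information(V[i], V[j], estimator="binned") for i, j in zip(iu, ju)
        ])
    elif estimator != "gaussian_rank":
        raise InputError(f"unknown MI estimator: {estimator!r}")

    # DPI on the significant graph: prune the weakest edge of each triangle
    # (decisions taken on the original MI values, applied simultaneously)
    mi_of = {}
    adj: dict[int, set[int]] = {g: set() for g in range(G)}
    for k in np.nonzero(significant)[0]:
        a, b_ = int(iu[k]), int(ju[k])
        mi_of[(a, b_)] = mi[k]
        adj[a].add(b_)
        adj[b_].add(a)
    pruned: set[tuple[int, int]] = set()
    for a, b_ in list(mi_of):
        for c_ in adj[a] & adj[b_]:
            trio = {
                (a, b_): mi_of[(a, b_)],
                tuple(sorted((a, c_))): mi_of[tuple(sorted((a, c_)))],
                tuple(sorted((b_, c_))): mi_of[tuple(sorted((b_, c_)))],
            }
            weakest = min(trio, key=lambda e: (trio[e], e))
            others = [v for e, v in trio.items() if e != weakest]
            if trio[weakest] < (1.0 - dpi_tolerance) * min(others):
                pruned.add(weakest)

    dpi_flag = np.zeros(n_pairs, dtype=bool)
    for k in range(n_pairs):
        if (int(iu[k]), int(ju[k])) in pruned:
            dpi_flag[k] = True
    surviving = significant & ~dpi_flag

    edges = pd.DataFrame(
        {
            "gene_a": genes[iu], "gene_b": genes[ju], "mi": mi,
            "p_raw": p_raw, "p_bonferroni": p_bonf,
            "significant": significant, "dpi_pruned": dpi_flag,
        }
    )
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for k in np.nonzero(surviving)[0]:
        graph.add_edge(genes[iu[k]], genes[ju[k]], mi=float(mi[k]))
    logger.info(
        "ARACNE: %d pairs, %d significant (Bonferroni < %g), %d DPI-pruned, %d surviving",
        n_pairs, int(significant.sum()), alpha, int((significant & dpi_flag).sum()),
        int(surviving.sum()),
    )
    return MutualInfoNetwork(
        edges=edges, graph=graph, alpha=alpha, dpi_tolerance=dpi_tolerance,
        B=B, seed=seed, estimator=estimator,
    )


def triplet_grn_support(
    network: MutualInfoNetwork,
    triplet: TripletScore,
    max_mediators: int = 3,
) -> tuple[bool, dict, str | None]:
    """Does Z reach both X and Y through at most ``max_mediators`` intermediates?

    Returns (supported, {'x': path length or None, 'y': ...}, reason).
    A path of length L edges has L - 1 mediators, so support requires
    shortest-path length <= max_mediators + 1 to each pair member.
    """
    g = network.graph
    for gene in (triplet.z_gene, triplet.x_gene, triplet.y_gene):
        if gene not in g:
            return False, {}, f"gene {gene!r} absent from network"
    lengths = {}
    for key, target in (("x", triplet.x_gene), ("y", triplet.y_gene)):
        try:
            lengths[key] = nx.shortest_path_length(g, triplet.z_gene, target)
        except nx.NetworkXNoPath:
            lengths[key] = None
    supported = all(
        l is not None and l <= max_mediators + 1 for l in lengths.values()
    )
    reason = None if supported else "no sufficiently short path from Z to the pair"
    return supported, lengths, reason
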