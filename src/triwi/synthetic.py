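"""Synthetic expression cohorts with planted switch-gene triplets.

The generator emulates the statistical structure the triplet screen
targets: three sample groups (defaults 42/33/28, the study design sizes),
background genes that are pure noise, and planted triplets Z/{X, Y} in
which the correlation of the pair flips across equal-frequency terciles of
the switch gene Z, while Z's mean may shift by group.

Planted pairs are generated conditionally on the Z-tercile (a Gaussian
mixture over strata) so the correlation switch is realized directly.  In
addition, X and Y are coupled to Z with correlation ``switch_coupling``;
a switch gene that modulates its targets is also co-expressed with them,
and without marginal dependence a planted triplet would be invisible to
the mutual-information network used for relevance checks.  The inner pair
correlation is solved per stratum so that the *total* within-stratum
correlation of (X, Y) hits the requested target despite the shared Z
component.

``effect_mode='population'`` draws the pair from a bivariate normal with
the target correlation (the realized sample correlation then fluctuates
around the target); ``effect_mode='empirical'`` constructs vectors whose
sample correlations equal the targets exactly, which is useful for
deterministic demonstrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .liquid_association import bin_by_z
from .matrix import ExpressionMatrix
from .preprocessing import standardize
from .annotations import AnnotationCatalog, Term

DEFAULT_GROUP_SIZES = (42, 33, 28)
DEFAULT_GROUP_NAMES = ("NP-NP", "NP-IT", "CS-IT")
N_STRATA = 3  # generation mirrors the default M=3 analysis binning


@dataclass(frozen=True)
class PlantedTriplet:
    """Parameters of one planted switch-gene triplet."""

    z_gene: str
    x_gene: str
    y_gene: str
    r_low: float = 0.70
    r_mid: float = 0.0
    r_high: float = -0.65
    z_group_shift: tuple[float, ...] = (1.1, 0.0, -1.1)
    switch_coupling: float = 0.5

    def __post_init__(self) -> None:
        names = {self.z_gene, self.x_gene, self.y_gene}
        if len(names) != 3:
            raise InputError("planted triplet genes must be three distinct identifiers")
        for r in (self.r_low, self.r_mid, self.r_high):
            if not -1.0 < r < 1.0:
                raise InputError(f"stratum correlation {r} outside (-1, 1)")
        if not 0.0 <= abs(self.switch_coupling) < 1.0:
            raise InputError("switch_coupling must lie in (-1, 1)")

    @property
    def stratum_correlations(self) -> tuple[float, float, float]:
        return (self.r_low, self.r_mid, self.r_high)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic cohort (seed included)."""

    n_genes: int
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    group_names: tuple[str, ...] = DEFAULT_GROUP_NAMES
    planted_triplets: tuple[PlantedTriplet, ...] = ()
    background_correlation: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    effect_mode: str = "population"
    expression_scale: str = "gaussian"

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.group_names):
            raise InputError("group_sizes and group_names must have equal length")
        if any(g < 2 for g in self.group_sizes):
            raise InputError("every group needs at least 2 samples")
        n = sum(self.group_sizes)
        if n < 3 * N_STRATA:
            raise InputError(f"cohort of {n} samples cannot form {N_STRATA} strata of >= 3")
        if self.n_genes < 3 * len(self.planted_triplets) + 10:
            raise InputError(
                "n_genes must be at least 3 * n_triplets + 10 "
                f"(got {self.n_genes} for {len(self.planted_triplets)} triplets)"
            )
        if not 0.0 <= self.background_correlation < 1.0:
            raise InputError("background_correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be positive")
        if self.effect_mode not in ("population", "empirical"):
            raise InputError(f"unknown effect_mode {self.effect_mode!r}")
        if self.expression_scale not in ("gaussian", "lognormal"):
            raise InputError(f"unknown expression_scale {self.expression_scale!r}")
        for t in self.planted_triplets:
            if len(t.z_group_shift) != len(self.group_sizes):
                raise InputError("z_group_shift length must match the number of groups")
        # triplets may share a switch gene (with identical shift) but a gene
        # cannot serve two different roles
        roles: dict[str, str] = {}
        for t in self.planted_triplets:
            for g, role in ((t.z_gene, "switch"), (t.x_gene, "pair"), (t.y_gene, "pair")):
                if roles.get(g, role) != role:
                    raise InputError(f"gene {g!r} planted in conflicting roles")
                roles[g] = role
        shifts: dict[str, tuple] = {}
        for t in self.planted_triplets:
            prev = shifts.setdefault(t.z_gene, t.z_group_shift)
            if prev != t.z_group_shift:
                raise InputError(
                    f"switch gene {t.z_gene!r} planted with inconsistent group shifts"
                )


@dataclass
class SyntheticTruth:
    """Record of what was planted and how it was realized."""

    config: SyntheticConfig
    gene_roles: dict[str, str]
    strata: dict[str, list[list[int]]]                  # z gene -> per-stratum sample idx
    realized_correlations: dict[tuple[str, str, str], tuple[float, ...]]

    def planted_keys(self) -> list[tuple[str, str, str]]:
        return list(self.realized_correlations)

    def to_json(self, path) -> None:
        payload = {
            "config": _config_dict(self.config),
            "gene_roles": self.gene_roles,
            "strata": self.strata,
            "realized_correlations": {
                "|".join(k): list(v) for k, v in self.realized_correlations.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["planted_triplets"] = [asdict(t) for t in config.planted_triplets]
    return d


def _unit(v: np.ndarray) -> np.ndarray:
    """Center and scale to unit sample variance (ddof=1)."""
    v = v - v.mean()
    sd = np.sqrt(v @ v / (v.size - 1))
    if sd == 0:
        raise InputError("degenerate draw while constructing planted pair")
    return v / sd


def _residualize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        v = v - (v @ b) / (b @ b) * b
    return v


def _inner_correlation(target: float, coupling: float, v_hat: float) -> float:
    """Pair correlation of the Z-independent components giving a total
    within-stratum correlation of ``target`` when both members carry a
    ``coupling * Z`` term with within-stratum Z variance ``v_hat``."""
    c2v = coupling**2 * v_hat
    w2 = 1.0 - coupling**2
    rho = (target * (c2v + w2) - c2v) / w2
    if not -1.0 < rho < 1.0:
        raise InputError(
            f"stratum correlation target {target} unreachable with "
            f"switch_coupling {coupling} (implied inner correlation {rho:.3f})"
        )
    return rho


def generate_cohort(config: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate one cohort; returns the matrix and the planted truth."""
    n = sum(config.group_sizes)
    group_of = np.repeat(np.arange(len(config.group_sizes)), config.group_sizes)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    group_labels = [config.group_names[g] for g in group_of]

    planted_genes: list[str] = []
    for t in config.planted_triplets:
        for g in (t.z_gene, t.x_gene, t.y_gene):
            if g not in planted_genes:
                planted_genes.append(g)
    n_background = config.n_genes - len(planted_genes)
    background_genes = []
    i = 1
    while len(background_genes) < n_background:
        name = f"G{i:04d}"
        if name not in planted_genes:
            background_genes.append(name)
        i += 1
    gene_ids = planted_genes + background_genes

    root = np.random.SeedSequence(config.seed)
    ss_z, ss_pairs, ss_background = root.spawn(3)

    values = np.empty((config.n_genes, n))
    row_of = {g: i for i, g in enumerate(gene_ids)}
    gene_roles = {g: "background" for g in gene_ids}
    strata: dict[str, list[list[int]]] = {}
    realized: dict[tuple[str, str, str], tuple[float, ...]] = {}

    # switch genes: one draw per distinct Z, mean shifted by group
    z_values: dict[str, np.ndarray] = {}
    z_seeds = ss_z.spawn(len({t.z_gene for t in config.planted_triplets}) or 1)
    for k, z_gene in enumerate(dict.fromkeys(t.z_gene for t in config.planted_triplets)):
        shift = next(t.z_group_shift for t in config.planted_triplets if t.z_gene == z_gene)
        rng = np.random.default_rng(z_seeds[k])
        raw = rng.normal(loc=np.asarray(shift)[group_of], scale=1.0, size=n)
        z = standardize(raw)
        z_values[z_gene] = z
        values[row_of[z_gene]] = z
        gene_roles[z_gene] = "switch"
        spec = bin_by_z(z, N_STRATA)
        idx_lists = spec.bin_indices
        if min(len(ix) for ix in idx_lists) < 3:
            raise InputError("a Z stratum would contain fewer than 3 samples")
        strata[z_gene] = [ix.tolist() for ix in idx_lists]

    pair_seeds = ss_pairs.spawn(max(len(config.planted_triplets), 1))
    for t, seed in zip(config.planted_triplets, pair_seeds):
        rng = np.random.default_rng(seed)
        z = z_values[t.z_gene]
        idx_lists = [np.asarray(ix) for ix in strata[t.z_gene]]
        c = t.switch_coupling
        w = np.sqrt(1.0 - c**2)
        x = np.empty(n)
        y = np.empty(n)
        for idx, target in zip(idx_lists, t.stratum_correlations):
            zc = z[idx]
            v_hat = float(np.var(zc, ddof=1))
            rho = _inner_correlation(target, c, v_hat)
            m = idx.size
            if config.effect_mode == "population":
                cov = [[1.0, rho], [rho, 1.0]]
                uv = rng.multivariate_normal([0.0, 0.0], cov, size=m)
                u, v = uv[:, 0], uv[:, 1]
            else:  # empirical: realize the sample correlation exactly
                if m < 5:
                    raise InputError("empirical effect_mode needs >= 5 samples per stratum")
                ones = np.ones(m)
                zc_c = _residualize(zc.copy(), [ones])
                u = _unit(_residualize(rng.normal(size=m), [ones, zc_c]))
                v0 = _unit(_residualize(rng.normal(size=m), [ones, zc_c, u]))
                v = rho * u + np.sqrt(1.0 - rho**2) * v0
            x[idx] = c * zc + w * u
            y[idx] = c * zc + w * v
        values[row_of[t.x_gene]] = x
        values[row_of[t.y_gene]] = y
        gene_roles[t.x_gene] = "pair_member"
        gene_roles[t.y_gene] = "pair_member"
        realized[(t.z_gene, t.x_gene, t.y_gene)] = tuple(
            float(np.corrcoef(x[idx], y[idx])[0, 1]) for idx in idx_lists
        )

    rng_bg = np.random.default_rng(ss_background)
    if n_background:
        noise = rng_bg.normal(scale=config.noise_sd, size=(n_background, n))
        if config.background_correlation > 0:
            shared = rng_bg.normal(scale=config.noise_sd, size=n)
            rho = config.background_correlation
            noise = np.sqrt(rho) * shared[None, :] + np.sqrt(1 - rho) * noise
        values[len(planted_genes):] = noise

    if config.expression_scale == "lognormal":
        base = rng_bg.lognormal(mean=np.log(10.0), sigma=1.0, size=config.n_genes)
        values = base[:, None] * np.exp(0.7 * values)

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        pd.Series(group_labels, index=sample_ids, name="group"),
    )
    truth = SyntheticTruth(
        config=config, gene_roles=gene_roles, strata=strata,
        realized_correlations=realized,
    )
    return matrix, truth


def generate_annotations(
    truth: SyntheticTruth,
    n_terms: int = 20,
    term_size_range: tuple[int, int] = (4, 8),
    level_range: tuple[int, int] = (3, 9),
    seed: int = 0,
    include_switch: bool = True,
    n_fillers: int = 1,
) -> AnnotationCatalog:
    """Annotation catalog with a guaranteed deep co-term per planted triplet.

    For every planted triplet one term of level > 6 contains X and Y (plus
    Z when ``include_switch``, the default, since a switch gene plausibly
    shares its targets' process) and ``n_fillers`` random filler genes.
    The remaining terms are random gene sets with levels drawn from
    ``level_range``.
    """
    genes = sorted(truth.gene_roles)
    if term_size_range[1] > len(genes):
        raise InputError("term_size_range exceeds the number of genes")
    rng = np.random.default_rng(seed)
    terms: dict[str, Term] = {}
    tid = 0
    for (z, x, y) in truth.planted_keys():
        core = [x, y] + ([z] if include_switch else [])
        pool = [g for g in genes if g not in core]
        fillers = list(rng.choice(pool, size=min(n_fillers, len(pool)), replace=False))
        level = int(rng.integers(7, max(level_range[1], 7) + 1))
        tid += 1
        terms[f"T{tid:04d}"] = Term(
            name=f"planted process {tid}", level=level, genes=frozenset(core + fillers)
        )
    while len(terms) < n_terms:
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        members = frozenset(rng.choice(genes, size=size, replace=False))
        level = int(rng.integers(level_range[0], level_range[1] + 1))
        tid += 1
        terms[f"T{tid:04d}"] = Term(name=f"random set {tid}", level=level, genes=members)
    return AnnotationCatalog(terms=terms, universe=frozenset(genes))


def generate_counts(
    matrix: ExpressionMatrix,
    gene_lengths=None,
    library_sizes=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Poisson read counts whose RPKM re-normalization tracks the input.

    Counts are drawn per gene/sample with mean
    expression * length * library_size / 1e9, so applying
    :func:`triwi.preprocessing.rpkm` to the counts recovers the input
    matrix up to sampling noise.  The input must be on a non-negative
    (abundance) scale, e.g. a cohort generated with
    ``expression_scale='lognormal'``.

    Returns (counts DataFrame, gene_lengths, library_sizes).
    """
    vals = matrix.to_array()
    if (vals < 0).any():
        raise InputError(
            "generate_counts needs non-negative expression values; "
            "use expression_scale='lognormal' when generating the cohort"
        )
    rng = np.random.default_rng(seed)
    if gene_lengths is None:
        gene_lengths = rng.integers(500, 5001, size=matrix.n_genes).astype(float)
    gene_lengths = np.asarray(gene_lengths, dtype=float)
    if library_sizes is None:
        library_sizes = rng.integers(10_000_000, 30_000_001, size=matrix.n_samples).astype(float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (gene_lengths <= 0).any() or (library_sizes <= 0).any():
        raise InputError("gene lengths and library sizes must be positive")
    mean = vals * gene_lengths[:, None] * library_sizes[None, :] / 1e9
    counts = rng.poisson(mean)
    return (
        pd.DataFrame(counts, index=matrix.values.index, columns=matrix.values.columns),
        gene_lengths,
        library_sizes,
    )
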