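"""Stage orchestration behind the command-line interface.

Each stage reads its inputs from, and writes its outputs to, the run's
output directory in plain diffable formats (TSV, GMT, JSON), so stages
can be re-run individually and every number in the final report is
recomputable from files on disk.  All randomness flows from the single
``seed`` in the configuration; re-running a stage with the same
configuration reproduces its outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import AnnotationCatalog
from .classification import fit_switch_classifier, group_comparison_table, roc_auc
from .diagnostics import fdr_curve, plot_diagnostics, switch_event_rate
from .errors import EmptyResultError, InputError
from .grn import aracne_network, triplet_grn_support, MutualInfoNetwork
from .liquid_association import (
    ScreenResult,
    TripletScore,
    adjust_screen,
    bin_by_z,
    compute_pvalues,
    read_screen_tsv,
    screen_all_triplets,
    significant_triplets,
)
from .matrix import ExpressionMatrix
from .preprocessing import filter_genes, normalize_matrix
from .relevance import coenrichment_check, conditional_correlations, enrich
from .synthetic import (
    PlantedTriplet,
    SyntheticConfig,
    generate_annotations,
    generate_cohort,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "output_dir": "triwi_out",
    "synthetic": {
        "n_genes": 20,
        "group_sizes": [42, 33, 28],
        "group_names": ["NP-NP", "NP-IT", "CS-IT"],
        "planted_triplets": [
            {
                "z_gene": "Zsw", "x_gene": "Xpa", "y_gene": "Ypa",
                "r_low": 0.70, "r_mid": 0.0, "r_high": -0.65,
                "z_group_shift": [1.1, 0.0, -1.1],
                "switch_coupling": 0.5,
            }
        ],
        "background_correlation": 0.0,
        "noise_sd": 1.0,
        "effect_mode": "empirical",
        "expression_scale": "gaussian",
        "annotations": {
            "n_terms": 15, "term_size_range": [4, 8],
            "level_range": [3, 9], "n_fillers": 1,
        },
    },
    "inputs": None,  # alternatively: {expression, metadata, gmt} paths
    "preprocessing": {"min_median_expression": None, "min_variance": 0.0},
    "screen": {
        "M": 3, "top_k": 200_000, "B": 1999, "p_method": "normal",
        "criterion": "bonferroni", "alpha": 0.001, "family_size": None,
    },
    "diagnostics": {"n_thresholds": 8, "n_monte_carlo": 10_000, "plot": False},
    "grn": {"alpha": 0.05, "dpi_tolerance": 0.15, "B": None, "estimator": "gaussian_rank"},
    "relevance": {"min_level": 7, "alpha_bh": 0.05, "max_mediators": 3},
    "classify": {
        "n_trees": 10_000, "positive_group": "NP-NP",
        "operating_threshold": 0.5, "min_switch_genes": 2,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class PipelineConfig:
    """Resolved configuration: defaults overlaid with the user's YAML."""

    raw: dict = field(default_factory=lambda: dict(DEFAULT_CONFIG))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        try:
            user = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise InputError(f"malformed YAML config {path}: {exc}")
        if not isinstance(user, dict):
            raise InputError("config must be a YAML mapping")
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise InputError(f"unknown config sections: {sorted(unknown)}")
        return cls(raw=_merge(DEFAULT_CONFIG, user))

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the global seed (< 2**31)."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.raw, sort_keys=True))


# ------------------------------------------------------------------- stages

def _write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing stage output: {path} (run the upstream stage first)")
    return json.loads(path.read_text())


def _synthetic_config(config: PipelineConfig) -> SyntheticConfig:
    s = config["synthetic"]
    triplets = tuple(
        PlantedTriplet(
            z_gene=t["z_gene"], x_gene=t["x_gene"], y_gene=t["y_gene"],
            r_low=float(t.get("r_low", 0.70)),
            r_mid=float(t.get("r_mid", 0.0)),
            r_high=float(t.get("r_high", -0.65)),
            z_group_shift=tuple(t.get("z_group_shift", [1.1, 0.0, -1.1])),
            switch_coupling=float(t.get("switch_coupling", 0.5)),
        )
        for t in s["planted_triplets"]
    )
    return SyntheticConfig(
        n_genes=int(s["n_genes"]),
        group_sizes=tuple(int(g) for g in s["group_sizes"]),
        group_names=tuple(s["group_names"]),
        planted_triplets=triplets,
        background_correlation=float(s["background_correlation"]),
        noise_sd=float(s["noise_sd"]),
        seed=config.seed,
        effect_mode=s["effect_mode"],
        expression_scale=s["expression_scale"],
    )


def stage_simulate(config: PipelineConfig) -> dict:
    """Generate the synthetic cohort, annotations and truth record."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    syn = _synthetic_config(config)
    matrix, truth = generate_cohort(syn)
    matrix.to_tsv(out / "expression.tsv", out / "metadata.tsv")
    ann = config["synthetic"]["annotations"]
    catalog = generate_annotations(
        truth,
        n_terms=int(ann["n_terms"]),
        term_size_range=tuple(ann["term_size_range"]),
        level_range=tuple(ann["level_range"]),
        seed=config.stage_seed("annotations"),
        n_fillers=int(ann["n_fillers"]),
    )
    catalog.to_gmt(out / "annotations.gmt")
    truth.to_json(out / "truth.json")
    summary = {
        "n_genes": matrix.n_genes, "n_samples": matrix.n_samples,
        "n_planted_triplets": len(syn.planted_triplets),
        "n_terms": len(catalog.terms),
    }
    logger.info("simulate: %s", summary)
    return summary


def _load_inputs(config: PipelineConfig) -> tuple[ExpressionMatrix, Path]:
    """Expression matrix and GMT path, from user files or the simulate stage."""
    inputs = config["inputs"]
    out = config.output_dir
    if inputs:
        for key in ("expression", "metadata", "gmt"):
            if key not in inputs:
                raise InputError(f"inputs section lacks {key!r}")
        matrix = ExpressionMatrix.from_tsv(inputs["expression"], inputs["metadata"])
        return matrix, Path(inputs["gmt"])
    matrix = ExpressionMatrix.from_tsv(out / "expression.tsv", out / "metadata.tsv")
    return matrix, out / "annotations.gmt"


def stage_preprocess(config: PipelineConfig) -> dict:
    """Filter and rank-normalize the expression matrix."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    matrix, _ = _load_inputs(config)
    pp = config["preprocessing"]
    n_before = matrix.n_genes
    if pp["min_median_expression"] is not None:
        matrix = filter_genes(
            matrix,
            min_median_expression=float(pp["min_median_expression"]),
            min_variance=float(pp["min_variance"]),
        )
    normalized = normalize_matrix(matrix)
    normalized.to_tsv(out / "normalized.tsv", out / "normalized_metadata.tsv")
    summary = {"n_genes_in": n_before, "n_genes_out": normalized.n_genes,
               "n_samples": normalized.n_samples}
    logger.info("preprocess: %s", summary)
    return summary


def _load_normalized(config: PipelineConfig) -> ExpressionMatrix:
    out = config.output_dir
    return ExpressionMatrix.from_tsv(out / "normalized.tsv", out / "normalized_metadata.tsv")


def stage_screen(config: PipelineConfig) -> dict:
    """Enumerate and score all triplets; attach raw and adjusted p-values."""
    out = config.output_dir
    matrix = _load_normalized(config)
    sc = config["screen"]
    screen = screen_all_triplets(matrix, M=int(sc["M"]), top_k=int(sc["top_k"]))
    screen = compute_pvalues(
        screen, matrix, B=int(sc["B"]), seed=config.stage_seed("screen"),
        method=sc["p_method"],
    )
    screen = adjust_screen(screen, m_total=sc["family_size"])
    screen.to_tsv(out / "triplets.tsv")
    _write_json(out / "screen_meta.json", screen.meta())
    sig = significant_triplets(screen, alpha=float(sc["alpha"]), criterion=sc["criterion"])
    sig.table.to_csv(out / "significant_triplets.tsv", sep="\t", index=False,
                     lineterminator="\n")
    summary = {
        "n_triplets_total": screen.n_total, "n_retained": len(screen.table),
        "n_significant": len(sig.table), "criterion": sc["criterion"],
        "alpha": sc["alpha"],
    }
    logger.info("screen: %s", summary)
    return summary


def _load_screen(config: PipelineConfig) -> ScreenResult:
    out = config.output_dir
    return read_screen_tsv(out / "triplets.tsv", _read_json(out / "screen_meta.json"))


def _load_significant(config: PipelineConfig) -> pd.DataFrame:
    path = config.output_dir / "significant_triplets.tsv"
    if not path.exists():
        raise InputError(f"missing stage output: {path} (run the screen stage first)")
    return pd.read_csv(path, sep="\t")


def stage_diagnose(config: PipelineConfig) -> dict:
    """FDR curve and switch-gene event-rate profile."""
    out = config.output_dir
    screen = _load_screen(config)
    matrix = _load_normalized(config)
    dg = config["diagnostics"]
    curve = fdr_curve(screen)
    curve.to_tsv(out / "fdr_curve.tsv")
    p = screen.table["p_raw"].to_numpy()
    lo, hi = float(p.min()), float(np.median(p))
    thresholds = np.geomspace(lo, hi, int(dg["n_thresholds"]))
    profile = switch_event_rate(
        screen, thresholds, n_genes=matrix.n_genes,
        n_monte_carlo=int(dg["n_monte_carlo"]),
        seed=config.stage_seed("diagnostics"),
    )
    profile.to_tsv(out / "event_rate.tsv")
    if dg["plot"]:
        plot_diagnostics(curve, profile, out / "diagnostics.png")
    summary = {
        "n_fdr_points": len(curve.points),
        "n_event_rate_points": len(profile.points),
        "strictest_observed_rate": float(profile.points["observed_rate"].iloc[0]),
        "strictest_random_rate": float(profile.points["random_rate"].iloc[0]),
    }
    logger.info("diagnose: %s", summary)
    return summary


def stage_grn(config: PipelineConfig) -> dict:
    """Mutual-information network over all screened genes."""
    out = config.output_dir
    matrix = _load_normalized(config)
    g = config["grn"]
    network = aracne_network(
        matrix, alpha=float(g["alpha"]), dpi_tolerance=float(g["dpi_tolerance"]),
        B=g["B"], seed=config.stage_seed("grn"), estimator=g["estimator"],
    )
    network.to_tsv(out / "network.tsv")
    _write_json(out / "grn_meta.json", {
        "alpha": network.alpha, "dpi_tolerance": network.dpi_tolerance,
        "B": network.B, "estimator": network.estimator,
        "n_edges_surviving": int(network.graph.number_of_edges()),
    })
    summary = {
        "n_pairs": len(network.edges),
        "n_significant": int(network.edges["significant"].sum()),
        "n_pruned": int((network.edges["significant"] & network.edges["dpi_pruned"]).sum()),
        "n_surviving": int(network.graph.number_of_edges()),
    }
    logger.info("grn: %s", summary)
    return summary


def _load_network(config: PipelineConfig) -> MutualInfoNetwork:
    import networkx as nx

    out = config.output_dir
    path = out / "network.tsv"
    if not path.exists():
        raise InputError(f"missing stage output: {path} (run the grn stage first)")
    edges = pd.read_csv(path, sep="\t")
    meta = _read_json(out / "grn_meta.json")
    graph = nx.Graph()
    matrix = _load_normalized(config)
    graph.add_nodes_from(matrix.gene_ids)
    surviving = edges[edges["significant"] & ~edges["dpi_pruned"]]
    for row in surviving.itertuples(index=False):
        graph.add_edge(row.gene_a, row.gene_b, mi=row.mi)
    return MutualInfoNetwork(
        edges=edges, graph=graph, alpha=meta["alpha"],
        dpi_tolerance=meta["dpi_tolerance"], B=meta["B"], seed=0,
        estimator=meta["estimator"],
    )


def stage_relevance(config: PipelineConfig) -> dict:
    """Co-enrichment + network support for each significant triplet."""
    out = config.output_dir
    matrix = _load_normalized(config)
    _, gmt_path = _load_inputs(config)
    catalog = AnnotationCatalog.from_gmt(gmt_path, universe=matrix.gene_ids)
    sig = _load_significant(config)
    if sig.empty:
        raise EmptyResultError("no significant triplets to verify")
    network = _load_network(config)
    rl = config["relevance"]
    query = sorted(set(sig["z"]) | set(sig["x"]) | set(sig["y"]))
    records = enrich(query, catalog, min_level=int(rl["min_level"]),
                     alpha_bh=float(rl["alpha_bh"]))
    pd.DataFrame(
        [
            {
                "term_id": r.term_id, "term_name": r.term_name, "level": r.level,
                "overlap": r.overlap, "term_size": r.term_size,
                "query_size": r.query_size, "universe_size": r.universe_size,
                "p_raw": r.p_raw, "p_bh": r.p_bh,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in records
        ]
    ).to_csv(out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n")

    M = int(config["screen"]["M"])
    verdicts = []
    profiles = []
    for row in sig.itertuples(index=False):
        triplet = TripletScore(z_gene=row.z, x_gene=row.x, y_gene=row.y, mla=row.mla)
        verdict = coenrichment_check(triplet, records, catalog)
        supported, lengths, reason = triplet_grn_support(
            network, triplet, max_mediators=int(rl["max_mediators"])
        )
        z = matrix.gene(triplet.z_gene)
        profile = conditional_correlations(
            matrix.gene(triplet.x_gene), matrix.gene(triplet.y_gene), z, bin_by_z(z, M)
        )
        for b, ((zmin, zmax), r) in enumerate(zip(profile.z_ranges, profile.correlations)):
            profiles.append(
                {"z": row.z, "x": row.x, "y": row.y, "bin": b,
                 "z_min": zmin, "z_max": zmax, "r": r}
            )
        verdicts.append(
            {
                "z": row.z, "x": row.x, "y": row.y, "mla": float(row.mla),
                "coenriched": bool(verdict.coenriched),
                "supporting_terms": list(verdict.supporting_terms),
                "grn_supported": bool(supported),
                "grn_path_lengths": lengths,
                "grn_reason": reason,
                "relevant": bool(verdict.coenriched and supported),
                "conditional_correlations": profile.correlations,
            }
        )
    _write_json(out / "verdicts.json", verdicts)
    pd.DataFrame(profiles).to_csv(
        out / "conditional_correlations.tsv", sep="\t", index=False, lineterminator="\n"
    )
    summary = {
        "n_enriched_terms": len(records),
        "n_triplets_checked": len(verdicts),
        "n_coenriched": sum(v["coenriched"] for v in verdicts),
        "n_grn_supported": sum(v["grn_supported"] for v in verdicts),
        "n_relevant": sum(v["relevant"] for v in verdicts),
    }
    logger.info("relevance: %s", summary)
    return summary


def stage_classify(config: PipelineConfig) -> dict:
    """Random-forest importance of switch genes, ROC, per-gene ANOVA/Tukey."""
    out = config.output_dir
    matrix = _load_normalized(config)
    screen = _load_screen(config)
    sig = _load_significant(config)
    cl = config["classify"]
    switch_genes = list(dict.fromkeys(sig["z"]))
    # pad from the ranked screen so the forest has enough features
    for z in screen.table["z"]:
        if len(switch_genes) >= int(cl["min_switch_genes"]):
            break
        if z not in switch_genes:
            switch_genes.append(z)
    if len(switch_genes) < 2:
        raise EmptyResultError("fewer than 2 switch-gene candidates to classify on")
    logger.info("classify: using switch genes %s", switch_genes)
    report = fit_switch_classifier(
        matrix, switch_genes, n_trees=int(cl["n_trees"]),
        seed=config.stage_seed("classify"),
    )
    report.to_tsv(out / "importance.tsv")
    positive = cl["positive_group"]
    if positive not in report.oob_scores.columns:
        raise InputError(f"positive_group {positive!r} not among classes "
                         f"{list(report.oob_scores.columns)}")
    scores = report.oob_scores[positive].to_numpy()
    labels = (matrix.groups.values == positive)
    roc = roc_auc(scores, labels, operating_threshold=float(cl["operating_threshold"]))
    roc.to_tsv(out / "roc.tsv")
    comparison = group_comparison_table(matrix, switch_genes)
    comparison.to_csv(out / "group_comparison.tsv", sep="\t", index=False,
                      lineterminator="\n")
    _write_json(out / "classify_meta.json", {
        "switch_genes": switch_genes, "n_trees": report.n_trees,
        "mtry": report.mtry, "oob_error": report.oob_error,
        "positive_group": positive,
        "auc": roc.auc, "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
    })
    summary = {
        "n_switch_genes": len(switch_genes), "oob_error": report.oob_error,
        "top_gene": report.table["gene"].iloc[0], "auc": roc.auc,
        "sensitivity": roc.sensitivity, "specificity": roc.specificity,
    }
    logger.info("classify: %s", summary)
    return summary


def stage_report(config: PipelineConfig, stage_summaries: dict | None = None) -> dict:
    """Aggregate stage outputs into one JSON report."""
    out = config.output_dir
    report = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.raw,
        "stages": stage_summaries or {},
    }
    verdicts_path = out / "verdicts.json"
    if verdicts_path.exists():
        report["verdicts"] = json.loads(verdicts_path.read_text())
    meta_path = out / "classify_meta.json"
    if meta_path.exists():
        report["classification"] = json.loads(meta_path.read_text())
    _write_json(out / "report.json", report)
    return report


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "screen": stage_screen,
    "diagnose": stage_diagnose,
    "grn": stage_grn,
    "relevance": stage_relevance,
    "classify": stage_classify,
}


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order and write the final report."""
    summaries = {}
    order = ["simulate", "preprocess", "screen", "diagnose", "grn", "relevance", "classify"]
    if config["inputs"]:
        order.remove("simulate")
    for name in order:
        summaries[name] = STAGES[name](config)
    return stage_report(config, summaries)
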