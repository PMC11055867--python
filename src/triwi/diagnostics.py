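"""Global sanity checks on a triplet screen.

Two diagnostics accompany the screen:

* the FDR curve — BH-adjusted p-value as a function of -log10(raw p),
  showing where a given FDR threshold falls on the significance axis;
* the switch-gene event rate — among triplets significant at a p-value
  cutoff, the number of distinct switch (Z) genes per significant
  triplet, compared with the rate expected if Z genes were assigned
  uniformly at random.  Biology concentrates switch roles in few genes,
  so the observed rate should fall far below the random rate.

For k significant triplets over a universe of g genes the random rate has
the closed form  g * (1 - (1 - 1/g)^k) / k  (expected distinct values in
k uniform draws, divided by k); a Monte-Carlo estimate and its SD are
reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InputError
from .liquid_association import ScreenResult

logger = logging.getLogger(__name__)


@dataclass
class FdrCurve:
    """Points (neg_log10_p, bh_fdr); FDR is non-increasing along the curve."""

    points: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class EventRateProfile:
    """Observed vs random switch-gene event rate over a p-value grid."""

    points: pd.DataFrame  # threshold, n_significant, observed_rate, random_rate, mc_rate, mc_sd
    n_genes: int

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False, lineterminator="\n")


def fdr_curve(screen: ScreenResult) -> FdrCurve:
    """BH FDR versus -log10(raw p), one point per distinct raw p-value."""
    table = screen.table
    if table.empty:
        raise EmptyResultError("cannot build an FDR curve from an empty screen")
    if "p_raw" not in table.columns or "p_bh" not in table.columns:
        raise InputError("screen lacks raw/BH p-values; compute and adjust them first")
    grouped = (
        table.groupby("p_raw", sort=True)["p_bh"].min().reset_index()
        .sort_values("p_raw", ascending=True)
    )
    neg_log = -np.log10(grouped["p_raw"].to_numpy())
    fdr = grouped["p_bh"].to_numpy()
    # BH step-up already enforces monotonicity when the family is complete;
    # enforce the envelope explicitly for truncated tables
    fdr = np.maximum.accumulate(fdr)
    points = pd.DataFrame({"neg_log10_p": neg_log[::-1], "bh_fdr": fdr[::-1]})
    return FdrCurve(points=points.reset_index(drop=True))


def random_event_rate(g: int, k: int) -> float:
    """Expected distinct genes per draw for k uniform draws from g genes."""
    if g < 1 or k < 1:
        raise InputError("g and k must be positive")
    return g * (1.0 - (1.0 - 1.0 / g) ** k) / k


def switch_event_rate(
    screen: ScreenResult,
    thresholds,
    n_genes: int,
    n_monte_carlo: int = 10_000,
    seed: int = 0,
) -> EventRateProfile:
    """Observed vs random distinct-switch-gene rate at each p cutoff."""
    table = screen.table
    if "p_raw" not in table.columns:
        raise InputError("screen lacks raw p-values")
    if n_genes < 1:
        raise InputError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    p = table["p_raw"].to_numpy()
    for t in sorted(float(t) for t in thresholds):
        mask = p <= t
        k = int(mask.sum())
        if k == 0:
            logger.info("threshold %g has no significant triplets; point omitted", t)
            continue
        observed = table.loc[mask, "z"].nunique() / k
        closed = random_event_rate(n_genes, k)
        draws = rng.integers(0, n_genes, size=(n_monte_carlo, k))
        distinct = np.array([np.unique(d).size for d in draws]) / k
        rows.append(
            {
                "threshold": t,
                "n_significant": k,
                "observed_rate": observed,
                "random_rate": closed,
                "mc_rate": float(distinct.mean()),
                "mc_sd": float(distinct.std(ddof=1)),
            }
        )
    if not rows:
        raise EmptyResultError("no threshold produced any significant triplet")
    return EventRateProfile(points=pd.DataFrame(rows), n_genes=n_genes)


def plot_diagnostics(curve: FdrCurve, profile: EventRateProfile, path) -> None:
    """Two-panel figure: FDR curve and event-rate comparison."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(curve.points["neg_log10_p"], curve.points["bh_fdr"], lw=1.2)
    ax1.set_xlabel(r"$-\log_{10}(p)$")
    ax1.set_ylabel("BH FDR")
    ax1.set_title("FDR vs significance")
    pts = profile.points
    ax2.plot(-np.log10(pts["threshold"]), pts["observed_rate"], "o-", label="observed")
    ax2.errorbar(
        -np.log10(pts["threshold"]), pts["mc_rate"], yerr=2 * pts["mc_sd"],
        fmt="s--", label="random (MC, ±2 SD)",
    )
    ax2.plot(-np.log10(pts["threshold"]), pts["random_rate"], ":", label="random (closed form)")
    ax2.set_xlabel(r"$-\log_{10}$(p cutoff)")
    ax2.set_ylabel("distinct switch genes / significant triplets")
    ax2.set_title("Switch-gene event rate")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
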