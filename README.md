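# triwi — three-way gene-interaction screening

`triwi` detects **dynamic co-expression**: gene pairs {X, Y} whose
correlation changes — even flips sign — with the expression level of a
third *switch* gene Z. Such triplets Z/{X, Y} point at genes that
control state changes in a tissue (for example, an inflammation-driving
switch gene elevated in nasal-polyp tissue), which makes them natural
therapeutic-target candidates. The package is aimed at researchers
analyzing grouped bulk expression cohorts (disease / paired / control)
who want a tested, reproducible implementation of the whole screen:
statistic, significance, diagnostics, biological-relevance checks and
switch-gene ranking.

## The statistic

Samples are split into M equal-frequency bins by ascending Z (M = 3,
i.e. terciles, by default) and each triplet is scored by the binned
liquid-association statistic

```
MLA(Z/{X,Y}) = (1/M) · Σᵢ ρ̂ᵢ · Z̄ᵢ
```

where ρ̂ᵢ is the Pearson correlation of X and Y within bin i and Z̄ᵢ the
mean of standardized Z in bin i. Genes are first rank-normalized
(inverse-normal transform of ranks) and standardized, so the score is
invariant to monotone distortions of the expression scale. Significance
comes from permuting Z and re-binning (empirical or pooled-moment normal
tails), with Bonferroni and Benjamini–Hochberg adjustment over the full
triplet family. Downstream stages verify significant triplets
biologically (gene-set co-enrichment of the pair; short paths from Z to
both pair members in an ARACNE-style mutual-information network) and
rank switch genes by random-forest permutation importance. A synthetic
cohort generator with planted sign-flipping triplets makes the entire
pipeline runnable and testable offline. See `docs/methods.md` for the
full model description.

## Worked example

```python
import numpy as np
from triwi import bin_by_z, mla_score, standardize

# 9 samples, 3 bins; the pair correlation is -1 in the low-Z bin,
# 0 in the middle and +1 in the high-Z bin
z = standardize(np.arange(1.0, 10.0))
x = np.tile([1.0, 2.0, 3.0], 3)
y = np.concatenate([[3, 2, 1], [1, 3, 1], [1, 2, 3]]).astype(float)

mla, bins = mla_score(x, y, z, bin_by_z(z, M=3))
print(round(mla, 4), [round(b.rho, 2) for b in bins])
```

```
0.7303 [-1.0, 0.0, 1.0]
```

The bin means of standardized Z are (−1.0955, 0, +1.0955), so the score
is ((−1)(−1.0955) + 0 + (+1)(+1.0955))/3 = 0.7303: a full sign flip
along Z produces a large score, while any Z-independent correlation
would cancel to ≈ 0.

## Pipeline demo

```sh
triwi run-all                      # built-in synthetic demo configuration
triwi init-config my.yaml          # write the default config to edit
triwi run-all --config my.yaml
```

The default configuration simulates a 20-gene cohort with the study
design sizes (42/33/28 samples in groups NP-NP / NP-IT / CS-IT) and one
planted triplet whose pair correlation is +0.70 in the low-Z tercile
and −0.65 in the high-Z tercile, then runs every stage. Typical output
(seed 1):

```
screen:    3420 triplets, 1 significant (Bonferroni-adjusted p < 0.001)
relevance: 1 co-enriched, 1 GRN-supported  -> 1 biologically relevant
classify:  top switch gene Zsw, AUC 0.80
```

with the planted triplet recovered at conditional correlations
r_low = 0.73 / r_high = −0.62 and its high-Z range starting at 0.45 on
the standardized scale. Each stage writes plain TSV/JSON into the output
directory (`triplets.tsv`, `fdr_curve.tsv`, `event_rate.tsv`,
`network.tsv`, `enrichment.tsv`, `verdicts.json`, `importance.tsv`,
`roc.tsv`, `report.json`), and re-running with the same configuration
reproduces every file byte for byte. Real cohorts plug in through the
`inputs:` section of the config (expression TSV + sample metadata TSV +
GMT gene sets, with `level=<int>` tags in the GMT description field).

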