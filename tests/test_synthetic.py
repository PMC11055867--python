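import json

import numpy as np
import pytest
from scipy import stats

from triwi import (
    InputError,
    PlantedTriplet,
    SyntheticConfig,
    generate_annotations,
    generate_cohort,
    generate_counts,
    permutation_pvalue,
    rpkm,
)


def big_strata_config(effect_mode="population", seed=0):
    """Three large groups so per-stratum correlations are tightly estimated."""
    return SyntheticConfig(
        n_genes=13,
        group_sizes=(1000, 1000, 1000),
        planted_triplets=(
            PlantedTriplet("Z", "X", "Y", r_low=0.7, r_mid=0.0, r_high=-0.65),
        ),
        seed=seed,
        effect_mode=effect_mode,
    )


class TestGenerateCohort:
    def test_shape_forced_by_config(self):
        config = SyntheticConfig(n_genes=150, group_sizes=(42, 33, 28), seed=1)
        matrix, truth = generate_cohort(config)
        assert matrix.values.shape == (150, 103)
        assert set(truth.gene_roles.values()) == {"background"}
        assert list(matrix.groups.value_counts()[["NP-NP", "NP-IT", "CS-IT"]]) == [42, 33, 28]

    def test_determinism_byte_identical(self, tmp_path):
        config = SyntheticConfig(
            n_genes=25, planted_triplets=(PlantedTriplet("Z", "X", "Y"),), seed=11
        )
        m1, t1 = generate_cohort(config)
        m2, t2 = generate_cohort(config)
        assert m1.values.equals(m2.values)
        t1.to_json(tmp_path / "a.json")
        t2.to_json(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_planted_correlations_recovered_at_large_n(self):
        """Realized stratum correlations approach (+0.7, 0, -0.65) targets."""
        devs = []
        for seed in range(50):
            _, truth = generate_cohort(big_strata_config(seed=seed))
            realized = truth.realized_correlations[("Z", "X", "Y")]
            devs.append(np.abs(np.subtract(realized, (0.7, 0.0, -0.65))))
        assert np.max(devs) < 0.1

    def test_empirical_mode_exact(self):
        _, truth = generate_cohort(big_strata_config(effect_mode="empirical"))
        realized = truth.realized_correlations[("Z", "X", "Y")]
        np.testing.assert_allclose(realized, (0.7, 0.0, -0.65), atol=1e-10)

    def test_roles_cover_planted_genes_once(self, planted_cohort):
        _, truth = planted_cohort
        roles = truth.gene_roles
        assert roles["Zsw"] == "switch"
        assert roles["Xpa"] == roles["Ypa"] == "pair_member"
        assert sum(r != "background" for r in roles.values()) == 3

    def test_unplanted_triplet_is_null(self):
        """r_low=r_mid=r_high=0, no shift, no coupling: the 'planted' triplet
        behaves exactly like background (uniform permutation p over seeds)."""
        pvals = []
        for seed in range(60):
            config = SyntheticConfig(
                n_genes=13,
                planted_triplets=(
                    PlantedTriplet(
                        "Z", "X", "Y", r_low=0.0, r_mid=0.0, r_high=0.0,
                        z_group_shift=(0.0, 0.0, 0.0), switch_coupling=0.0,
                    ),
                ),
                seed=seed,
            )
            matrix, _ = generate_cohort(config)
            pvals.append(
                permutation_pvalue(
                    matrix.gene("X"), matrix.gene("Y"), matrix.gene("Z"),
                    B=99, seed=seed + 1000,
                )
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=12, planted_triplets=(PlantedTriplet("Z", "X", "Y"),)),
            dict(n_genes=20, group_sizes=(1, 5, 5)),
            dict(n_genes=20, noise_sd=0.0),
            dict(n_genes=20, background_correlation=1.0),
            dict(n_genes=20, effect_mode="exact"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InputError):
            SyntheticConfig(**kwargs)

    def test_conflicting_roles_rejected(self):
        with pytest.raises(InputError):
            SyntheticConfig(
                n_genes=30,
                planted_triplets=(
                    PlantedTriplet("Z", "X", "Y"),
                    PlantedTriplet("X", "A", "B"),  # X cannot be switch and pair
                ),
            )

    def test_shared_switch_gene_allowed(self):
        config = SyntheticConfig(
            n_genes=30,
            planted_triplets=(
                PlantedTriplet("Z", "X1", "Y1"),
                PlantedTriplet("Z", "X2", "Y2"),
            ),
        )
        matrix, truth = generate_cohort(config)
        assert truth.gene_roles["Z"] == "switch"
        assert len(truth.realized_correlations) == 2

    def test_background_correlation_induces_dependence(self):
        config = SyntheticConfig(n_genes=40, background_correlation=0.5, seed=3)
        matrix, _ = generate_cohort(config)
        corr = np.corrcoef(matrix.to_array())
        off_diag = corr[np.triu_indices(40, k=1)]
        assert off_diag.mean() > 0.3


class TestGenerateAnnotations:
    def test_coterm_present_and_deep(self, planted_cohort):
        _, truth = planted_cohort
        catalog = generate_annotations(truth, n_terms=20, seed=0)
        assert len(catalog.terms) == 20
        co = [t for t in catalog.terms.values() if {"Xpa", "Ypa"} <= t.genes]
        assert co and all(t.level > 6 for t in co[:1])
        # the co-term survives the deep-term filter used by enrichment
        filtered = catalog.filtered(min_level=7)
        assert any({"Xpa", "Ypa"} <= t.genes for t in filtered.terms.values())

    def test_deterministic(self, planted_cohort):
        _, truth = planted_cohort
        a = generate_annotations(truth, n_terms=15, seed=4)
        b = generate_annotations(truth, n_terms=15, seed=4)
        assert a.terms == b.terms

    def test_oversized_terms_rejected(self, planted_cohort):
        _, truth = planted_cohort
        with pytest.raises(InputError):
            generate_annotations(truth, n_terms=5, term_size_range=(40, 50))


class TestGenerateCounts:
    def _lognormal_cohort(self, seed=0):
        config = SyntheticConfig(
            n_genes=60, planted_triplets=(PlantedTriplet("Z", "X", "Y"),),
            seed=seed, expression_scale="lognormal",
        )
        return generate_cohort(config)[0]

    def test_zero_expression_gives_zero_counts(self):
        matrix = self._lognormal_cohort()
        matrix.values.iloc[5] = 0.0
        counts, _, _ = generate_counts(matrix, seed=1)
        assert (counts.iloc[5] == 0).all()

    def test_rpkm_round_trip_rank_correlation(self):
        """Per-gene Spearman between input expression and re-normalized RPKM."""
        rhos = []
        for seed in range(10):
            matrix = self._lognormal_cohort(seed=seed)
            counts, lengths, libs = generate_counts(matrix, seed=seed + 100)
            back = rpkm(counts, lengths, libs)
            for i in range(matrix.n_genes):
                rho = stats.spearmanr(matrix.to_array()[i], back.to_numpy()[i]).statistic
                rhos.append(rho)
        assert np.median(rhos) > 0.9

    def test_uniform_lengths_and_libraries_proportional(self):
        matrix = self._lognormal_cohort()
        counts, _, _ = generate_counts(
            matrix, gene_lengths=np.full(60, 2000.0),
            library_sizes=np.full(103, 2e7), seed=2,
        )
        mean = matrix.to_array() * 2000.0 * 2e7 / 1e9
        big = mean > 50
        ratio = counts.to_numpy()[big] / mean[big]
        assert abs(ratio.mean() - 1) < 0.02

    def test_negative_expression_rejected(self, planted_cohort):
        matrix, _ = planted_cohort  # gaussian scale has negatives
        with pytest.raises(InputError):
            generate_counts(matrix)
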