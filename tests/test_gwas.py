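"""Case-control stratification: labels, markers, trend test, adjustment."""

import numpy as np
import pytest
from scipy import stats

from pcaudit.colors import CohortConfig, ColorSpec, generate_cohort
from pcaudit.gwas import (
    CaseControlDesign,
    adjustment_experiment,
    association_scan,
    cochran_armitage_trend,
    simulate_labels,
    simulate_markers,
)
from pcaudit.pca import PCA
from tests.conftest import color


@pytest.fixture
def structured_cohort():
    """Majority Red (300) with a minority Blue (20) — the stratified design."""
    return generate_cohort(
        CohortConfig(members=((color("Red"), 300), (color("Blue"), 20)), seed=0)
    )


@pytest.fixture
def unstructured_cohort():
    spec = ColorSpec("Grey", (0.5, 0.5, 0.5), 0.01)
    return generate_cohort(CohortConfig(members=((spec, 200),), seed=3))


class TestSimulateLabels:
    def test_random_mode_even_split(self, unstructured_cohort):
        design = CaseControlDesign(labeling="random", seed=1)
        labels = simulate_labels(unstructured_cohort, design)
        assert labels.sum() == 100

    def test_structured_minority_all_controls(self, structured_cohort):
        design = CaseControlDesign(labeling="structured", minority_label="Blue", seed=1)
        labels = simulate_labels(structured_cohort, design)
        blue = np.asarray(structured_cohort.sample_labels == "Blue")
        assert labels.sum() == 160
        assert not labels[blue].any()

    def test_deterministic(self, structured_cohort):
        design = CaseControlDesign(minority_label="Blue", seed=8)
        a = simulate_labels(structured_cohort, design)
        b = simulate_labels(structured_cohort, design)
        assert np.array_equal(a, b)

    def test_minority_exceeding_control_arm_rejected(self):
        data = generate_cohort(
            CohortConfig(members=((color("Red"), 10), (color("Blue"), 30)), seed=0)
        )
        design = CaseControlDesign(minority_label="Blue", seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_labels(data, design)

    def test_odd_cohort_rejected(self):
        data = generate_cohort(CohortConfig(members=((color("Red"), 5),), seed=0))
        with pytest.raises(ValueError, match="even"):
            simulate_labels(data, CaseControlDesign(labeling="random"))


class TestSimulateMarkers:
    def test_dosages_and_flags(self, structured_cohort):
        design = CaseControlDesign(
            minority_label="Blue", n_null_markers=30, n_causal_markers=10, seed=2
        )
        labels = simulate_labels(structured_cohort, design)
        markers, causal = simulate_markers(structured_cohort, labels, design)
        assert markers.p == 40
        assert causal.sum() == 10 and not causal[:30].any()
        assert np.isin(markers.values, (0, 1, 2)).all()

    def test_null_effect_gives_equivalent_marker_frequencies(self, unstructured_cohort):
        design = CaseControlDesign(
            labeling="random",
            effect_size=0.0,
            freq_spread=0.0,
            n_null_markers=300,
            n_causal_markers=300,
            seed=4,
        )
        labels = simulate_labels(unstructured_cohort, design)
        markers, causal = simulate_markers(unstructured_cohort, labels, design)
        f_null = markers.values[:, ~causal].mean() / 2
        f_causal = markers.values[:, causal].mean() / 2
        assert abs(f_null - f_causal) < 0.02

    def test_deterministic(self, structured_cohort):
        design = CaseControlDesign(minority_label="Blue", seed=5)
        labels = simulate_labels(structured_cohort, design)
        a, _ = simulate_markers(structured_cohort, labels, design)
        b, _ = simulate_markers(structured_cohort, labels, design)
        assert np.array_equal(a.values, b.values)


class TestCochranArmitage:
    def test_hand_computed_2x3_table(self):
        # cases 10/20/10, controls 20/20/0 by genotype 0/1/2:
        # chi2 = 80/7 by direct evaluation of the trend formula
        dosage = np.array([0] * 30 + [1] * 40 + [2] * 10)
        is_case = np.array([True] * 10 + [False] * 20
                           + [True] * 20 + [False] * 20
                           + [True] * 10)
        chi2, p = cochran_armitage_trend(dosage, is_case)
        assert chi2 == pytest.approx(80 / 7, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(80 / 7, 1), abs=1e-12)

    def test_permutation_p_matches(self):
        dosage = np.array([0] * 30 + [1] * 40 + [2] * 10)
        is_case = np.array([True] * 10 + [False] * 20
                           + [True] * 20 + [False] * 20
                           + [True] * 10)
        chi2_obs, p_asym = cochran_armitage_trend(dosage, is_case)
        rng = np.random.default_rng(0)
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(is_case)
            chi2, _ = cochran_armitage_trend(dosage, perm)
            hits += chi2 >= chi2_obs - 1e-12
        p_perm = hits / n_perm
        assert abs(p_perm - p_asym) < 3 * np.sqrt(p_asym * (1 - p_asym) / n_perm) + 5e-3

    def test_monomorphic_marker(self):
        chi2, p = cochran_armitage_trend(np.ones(20, dtype=int), np.arange(20) < 10)
        assert chi2 == 0.0 and p == 1.0


class TestAssociationScan:
    def test_identical_arms_never_significant(self):
        g = np.array([0, 1, 2] * 20)
        labels = np.array([True, False] * 30)
        g = np.concatenate([g[labels], g[~labels]])  # same dosage distribution per arm
        labels = np.array([True] * 30 + [False] * 30)
        scan = association_scan(g[:, None], labels)
        assert scan.table.p.iloc[0] > 0.5

    def test_wald_p_matches_permutation_on_toy(self, unstructured_cohort):
        design = CaseControlDesign(
            labeling="random", n_null_markers=1, n_causal_markers=0,
            freq_spread=0.0, seed=6,
        )
        labels = simulate_labels(unstructured_cohort, design)
        markers, _ = simulate_markers(unstructured_cohort, labels, design)
        scan = association_scan(markers, labels)
        p_wald = float(scan.table.p.iloc[0])
        g = markers.values[:, 0]
        rng = np.random.default_rng(1)
        stat_obs = abs(np.corrcoef(g, labels)[0, 1])
        hits = sum(
            abs(np.corrcoef(g, rng.permutation(labels))[0, 1]) >= stat_obs - 1e-12
            for _ in range(1000)
        )
        p_perm = hits / 1000
        assert abs(p_perm - p_wald) < 3 * np.sqrt(max(p_wald, 0.01) * 0.99 / 1000) + 0.05

    def test_power_exceeds_analytic_oracle_threshold(self):
        # log-OR 1.0 split +/-0.5 between arms at n=500/500: compare the
        # empirical detection rate with a two-proportion normal-approximation
        # power computation on allele counts
        spec = ColorSpec("Grey", (0.5, 0.5, 0.5), 0.01)
        data = generate_cohort(CohortConfig(members=((spec, 1000),), seed=7))
        design = CaseControlDesign(
            labeling="random", effect_size=1.0, freq_spread=0.0,
            n_null_markers=0, n_causal_markers=100,
            base_freq_range=(0.3, 0.7), seed=7,
        )
        labels = simulate_labels(data, design)
        markers, causal = simulate_markers(data, labels, design)
        scan = association_scan(markers, labels, causal_flags=causal)
        power_emp = scan.true_positive_count / 100

        # analytic oracle at the central base frequency f0 = 0.5
        f_case = 1 / (1 + np.exp(-0.5))
        f_ctrl = 1 / (1 + np.exp(0.5))
        n_alleles = 2 * 500
        se = np.sqrt(
            f_case * (1 - f_case) / n_alleles + f_ctrl * (1 - f_ctrl) / n_alleles
        )
        z = (f_case - f_ctrl) / se
        power_analytic = stats.norm.sf(stats.norm.isf(0.025) - z)
        assert power_emp > 0.8
        assert abs(power_emp - power_analytic) < 0.15

    def test_type_one_calibration_within_binomial_envelope(self, unstructured_cohort):
        design = CaseControlDesign(
            labeling="random", n_null_markers=600, n_causal_markers=0,
            effect_size=0.0, freq_spread=0.0, alpha=0.05, seed=3,
        )
        labels = simulate_labels(unstructured_cohort, design)
        markers, causal = simulate_markers(unstructured_cohort, labels, design)
        for cov in (None, PCA(markers).fit().scores[:, :2]):
            scan = association_scan(markers, labels, cov, causal)
            m = 600 - scan.n_excluded
            rej = int((scan.table.loc[~scan.table.excluded, "p"] < 0.05).sum())
            lo, hi = stats.binom.ppf([0.005, 0.995], m, 0.05)
            assert lo <= rej <= hi


class TestAdjustmentExperiment:
    def test_single_replicate_reproducible(self, structured_cohort):
        design = CaseControlDesign(
            minority_label="Blue", n_null_markers=20, n_causal_markers=5, seed=9
        )
        a = adjustment_experiment(structured_cohort, design, replicates=1)
        b = adjustment_experiment(structured_cohort, design, replicates=1)
        assert a.table.equals(b.table)

    def test_effect_size_monotonicity_of_true_positives(self, structured_cohort):
        tps = []
        for effect in (0.3, 1.5):
            design = CaseControlDesign(
                minority_label="Blue", effect_size=effect,
                n_null_markers=10, n_causal_markers=20,
                adjust_pcs=(0,), seed=10,
            )
            comp = adjustment_experiment(structured_cohort, design, replicates=3)
            tps.append(comp.table.tp.mean())
        assert tps[1] >= tps[0]

    def test_structured_design_adjustment_loses_true_positives(self, structured_cohort):
        design = CaseControlDesign(
            labeling="structured", minority_label="Blue",
            n_null_markers=40, n_causal_markers=15,
            effect_size=1.0, adjust_pcs=(0, 2), seed=0,
        )
        comp = adjustment_experiment(structured_cohort, design, replicates=6)
        st = comp.sign_test_tp(2)
        assert st["n_worse"] > st["n_better"]
        agg = comp.aggregate().set_index("n_pcs")
        assert agg.loc[2, "median_causal_p"] >= agg.loc[0, "median_causal_p"]

    def test_summary_mentions_sign_test(self, structured_cohort):
        design = CaseControlDesign(
            minority_label="Blue", n_null_markers=10, n_causal_markers=5,
            adjust_pcs=(0, 2), seed=11,
        )
        comp = adjustment_experiment(structured_cohort, design, replicates=2)
        assert "sign test" in comp.summary()
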