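"""Signature selection, feature matching, projection and guideline evaluation."""

import numpy as np
import pandas as pd
import pytest

from metabotype import (
    SIGNATURE_EFFECTS,
    HumanCohortSpec,
    confusion_report,
    default_preclinical_spec,
    guideline_classify,
    match_features,
    project_cohort,
    select_signature,
    simulate_human_cohort,
    simulate_preclinical,
    subgroup_compare,
)
from metabotype.screen import UnivariateResult

# The 11 reference (q, VIP) pairs of the predictive plasma signature.
REFERENCE_SIGNATURE = {
    "PC 38:4": (0.009, 2.21),
    "LPC 18:0": (0.03, 1.85),
    "PC 36:4": (0.01, 1.83),
    "DG 36:4": (0.009, 2.03),
    "DG 34:3": (0.009, 1.86),
    "DG 34:2": (0.04, 1.70),
    "TG 46:0": (0.04, 1.17),
    "ChoE (17:0)": (0.01, 1.75),
    "ChoE (18:0)": (0.03, 1.72),
    "ChoE (16:0)": (0.04, 1.61),
    "ChoE (18:1)": (0.04, 1.59),
}


def univ_from_pairs(pairs: dict) -> UnivariateResult:
    table = pd.DataFrame(
        {
            "p_value": [q / 2 for q, _ in pairs.values()],
            "q_value": [q for q, _ in pairs.values()],
            "fold_change": 1.3,
        },
        index=pd.Index(pairs.keys(), name="metabolite"),
    )
    return UnivariateResult(table=table, case="case", control="control")


class TestSelectSignature:
    def test_reference_pairs_plus_failing_rows(self):
        pairs = dict(REFERENCE_SIGNATURE)
        # five fabricated rows, each failing at least one criterion
        pairs.update({
            "SM 34:1": (0.20, 1.9),    # q too large
            "PC 34:2": (0.01, 0.4),    # VIP too small
            "TG 54:2": (0.06, 1.2),    # q fails
            "Alanine": (0.04, 1.0),    # VIP exactly 1.0 -> strict boundary excludes
            "Glucose": (0.5, 0.2),     # both fail
        })
        univ = univ_from_pairs(pairs)
        vips = pd.Series({m: v for m, (_, v) in pairs.items()})
        sig = select_signature(univ, vips, q_max=0.05, vip_min=1.0)
        assert set(sig.members) == set(REFERENCE_SIGNATURE)
        # ordered by VIP descending
        assert sig.table["vip"].is_monotonic_decreasing
        assert sig.members[0] == "PC 38:4"

    def test_no_feature_passing_gives_empty_signature(self):
        univ = univ_from_pairs({"A": (0.5, 2.0), "B": (0.01, 0.5)})
        vips = pd.Series({"A": 2.0, "B": 0.5})
        sig = select_signature(univ, vips)
        assert len(sig) == 0

    def test_disjoint_feature_sets_error(self):
        univ = univ_from_pairs({"A": (0.01, 2.0)})
        with pytest.raises(ValueError, match="no features"):
            select_signature(univ, pd.Series({"B": 2.0}))


class TestMatchFeatures:
    def test_identical_lists_full_coverage(self):
        m = match_features(["PC 38:4", "Alanine"], ["PC 38:4", "Alanine"])
        assert m.coverage == 1.0 and m.missing == []

    def test_case_fold_matching(self):
        m = match_features(["PC 38:4"], ["pc 38:4"])
        assert m.mapping == {"PC 38:4": "pc 38:4"}

    def test_disjoint_lists(self):
        m = match_features(["A", "B"], ["C"])
        assert m.coverage == 0.0 and m.missing == ["A", "B"]


class TestProjectCohort:
    def test_self_projection_reproduces_training_classes(self):
        table, _ = simulate_preclinical(default_preclinical_spec(seed=1))
        res, cls = project_cohort(table, table, mode="full")
        fitted_class = res.fitted_values >= 0.5
        np.testing.assert_array_equal(cls["at_risk"].to_numpy(), fitted_class)

    def test_low_coverage_rejected(self):
        table, _ = simulate_preclinical(default_preclinical_spec(seed=1))
        reduced = table.subset_features(table.feature_names[:60])
        with pytest.raises(ValueError, match="cover"):
            project_cohort(table, reduced, min_coverage=0.8)

    def test_signature_effect_recovers_latent_class(self):
        accs = []
        for seed in range(8):
            train, _ = simulate_preclinical(default_preclinical_spec(seed=seed))
            spec = HumanCohortSpec(signature_effect=1.4, seed=seed)
            human, _, truth = simulate_human_cohort(spec, list(SIGNATURE_EFFECTS))
            _, cls = project_cohort(train, human)
            risk = (truth.labels == "at_risk").to_numpy()
            pred = cls["at_risk"].to_numpy()
            accs.append(0.5 * (pred[risk].mean() + (~pred[~risk]).mean()))
        assert np.median(accs) >= 0.75

    def test_signature_only_mode(self):
        train, _ = simulate_preclinical(default_preclinical_spec(seed=2))
        spec = HumanCohortSpec(signature_effect=1.4, seed=2)
        human, _, truth = simulate_human_cohort(spec, list(SIGNATURE_EFFECTS))
        res, cls = project_cohort(
            train, human, mode="signature-only", signature=list(SIGNATURE_EFFECTS)
        )
        assert res.feature_names == list(SIGNATURE_EFFECTS)
        risk = (truth.labels == "at_risk").to_numpy()
        pred = cls["at_risk"].to_numpy()
        assert 0.5 * (pred[risk].mean() + (~pred[~risk]).mean()) > 0.6


class TestGuidelineClassify:
    @pytest.mark.parametrize(
        "tg,category,risk",
        [
            (1.69, "normal", False),
            (1.70, "borderline", True),
            (2.29, "borderline", True),
            (2.30, "high", True),
            (5.59, "high", True),
            (6.0, "severe", True),
        ],
    )
    def test_thresholds(self, tg, category, risk):
        cat, at_risk = guideline_classify(tg)
        assert cat == category and at_risk == risk

    def test_monotone_in_tg(self):
        order = ["normal", "borderline", "high", "severe"]
        tg = np.linspace(0.2, 8.0, 200)
        cats, _ = guideline_classify(tg)
        ranks = [order.index(c) for c in cats]
        assert np.all(np.diff(ranks) >= 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            guideline_classify(0.0)


class TestConfusionReport:
    def test_perfect_agreement(self):
        r = confusion_report([True, False, True], [True, False, True])
        assert r.accuracy == r.sensitivity == r.specificity == 1.0

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(0)
        pred = rng.random(100) < 0.5
        ref = rng.random(100) < 0.4
        r = confusion_report(pred, ref)
        assert r.tp == sum(p and t for p, t in zip(pred, ref))
        assert r.fp == sum(p and not t for p, t in zip(pred, ref))
        assert r.tn == sum((not p) and (not t) for p, t in zip(pred, ref))
        assert r.fn == sum((not p) and t for p, t in zip(pred, ref))
        assert r.n == 100

    def test_metrics_self_consistent(self):
        r = confusion_report([True] * 27 + [False] * 7 + [True] * 44 + [False] * 62,
                             [True] * 34 + [False] * 106)
        d = r.to_dict()
        assert abs(d["accuracy"] - (r.tp + r.tn) / r.n) < 1e-12
        assert abs(d["sensitivity"] - r.tp / (r.tp + r.fn)) < 1e-12
        assert abs(d["specificity"] - r.tn / (r.tn + r.fp)) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_report([True], [True, False])


@pytest.fixture(scope="module")
def projected():
    train, _ = simulate_preclinical(default_preclinical_spec(seed=3))
    spec = HumanCohortSpec(signature_effect=1.4, seed=3)
    human, clinical, truth = simulate_human_cohort(spec, list(SIGNATURE_EFFECTS))
    _, cls = project_cohort(train, human)
    return cls, clinical, human


class TestSubgroupCompare:
    def test_sizes_partition_guideline_normal(self, projected):
        cls, clinical, human = projected
        report = subgroup_compare(cls, clinical, human)
        _, risk = guideline_classify(clinical["tg_mmol_l"].to_numpy())
        assert report.n_concordant_healthy + report.n_discordant_at_risk == int((~risk).sum())

    def test_coupled_lipids_shift_upward(self):
        """Discordant (model-at-risk) subjects carry higher coupled lipids."""
        wins = {k: 0 for k in ["tg_mmol_l", "tc_mmol_l", "ldl_mmol_l", "apob_g_l"]}
        n_seeds = 10
        for seed in range(n_seeds):
            train, _ = simulate_preclinical(default_preclinical_spec(seed=seed))
            spec = HumanCohortSpec(signature_effect=1.4, seed=seed)
            human, clinical, _ = simulate_human_cohort(spec, list(SIGNATURE_EFFECTS))
            _, cls = project_cohort(train, human)
            report = subgroup_compare(cls, clinical, human)
            t = report.clinical_tests
            for k in wins:
                if t.loc[k, "mean_discordant"] > t.loc[k, "mean_concordant"]:
                    wins[k] += 1
        for k, w in wins.items():
            assert w >= 0.8 * n_seeds, f"{k} shifted upward in only {w}/{n_seeds} seeds"

    def test_zero_coupling_null_calibrated(self):
        flagged = 0
        n_seeds = 6
        for seed in range(n_seeds):
            train, _ = simulate_preclinical(default_preclinical_spec(seed=seed))
            spec = HumanCohortSpec(signature_effect=1.4, clinical_coupling={}, seed=seed)
            human, clinical, _ = simulate_human_cohort(spec, list(SIGNATURE_EFFECTS))
            _, cls = project_cohort(train, human)
            report = subgroup_compare(cls, clinical, human)
            flagged += int(report.clinical_tests["significant_fdr"].sum())
        assert flagged <= n_seeds  # FDR-level false positives only

    def test_small_subgroup_warns_without_tests(self):
        cls = pd.DataFrame(
            {"at_risk": [True, False, False, False], "score": 0.5},
            index=[f"s{i}" for i in range(4)],
        )
        clinical = pd.DataFrame(
            {"tg_mmol_l": [1.0, 1.1, 1.2, 1.3]}, index=cls.index
        )
        from conftest import make_table

        features = make_table(np.ones((4, 3)) + np.arange(4)[:, None], cohort="human")
        report = subgroup_compare(cls, clinical, features)
        assert report.warnings and report.clinical_tests is None
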