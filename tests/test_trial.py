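"""Trial statistics and termination tables on hand-checkable inputs."""

import math

import numpy as np
import pandas as pd
import pytest

from afvtrial import trial
from afvtrial.trial import (
    TrialDesign,
    cohens_d,
    fisher_exact_2x2,
    paired_t,
    summarize,
    termination_table,
    two_sample_t,
)


class TestCohensD:
    def test_textbook_value(self):
        """Means 2 vs 0 with pooled SD 1 -> d = 2."""
        a = [1.0, 2.0, 3.0]            # mean 2, sd 1
        b = [-1.0, 0.0, 1.0]           # mean 0, sd 1
        assert cohens_d(a, b) == pytest.approx(2.0)

    def test_identical_samples_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_zero_variance_flagged(self):
        assert math.isnan(cohens_d([0.0, 0.0], [2.0, 2.0]))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [2.0, 3.0])


class TestTTests:
    def test_hand_computed_equal_variance_t(self):
        """A={1,2,3}, B={4,5,6}: t = -3/sqrt(2/3) = -3.674."""
        t, p = two_sample_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert 0 < p < 0.05

    def test_identical_samples_t_zero_p_one(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_paired_shift_detected_with_matching_sign(self):
        rng = np.random.default_rng(1)
        before = rng.normal(0, 1, 20)
        after = before + 0.5
        t, p = paired_t(before, after)
        assert t < 0                   # after is larger
        assert p < 1e-6

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_degenerate_paired_variance_flagged(self):
        t, p = paired_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert math.isnan(t) and math.isnan(p)


class TestFisher:
    def test_printed_class_ic_contrast_significant(self):
        """12/100 vs 26/100 terminations: two-sided exact p < 0.05."""
        p = fisher_exact_2x2(12, 100, 26, 100)
        assert p < 0.05

    def test_equal_rates_not_significant(self):
        assert fisher_exact_2x2(10, 100, 10, 100) == pytest.approx(1.0)


# Per-drug termination counts (out of 25 per genotype) as printed.
PRINTED_COUNTS = {
    ("flecainide", "low"): (2, 4),
    ("flecainide", "high"): (4, 7),
    ("propafenone", "low"): (3, 5),
    ("propafenone", "high"): (3, 10),
    ("amiodarone", "low"): (10, 11),
    ("amiodarone", "high"): (16, 11),
    ("sotalol", "low"): (4, 8),
    ("sotalol", "high"): (9, 17),
    ("dronedarone", "low"): (11, 11),
    ("dronedarone", "high"): (16, 7),
}

CLASS_OF = {"flecainide": "IC", "propafenone": "IC", "amiodarone": "III",
            "sotalol": "III", "dronedarone": "III"}


def printed_cases() -> pd.DataFrame:
    """Expand the published per-drug termination counts into case rows."""
    rows = []
    for (drug, dose), (k_wt, k_px) in PRINTED_COUNTS.items():
        for genotype, k in [("wild_type", k_wt), ("pitx2_deficient", k_px)]:
            for i in range(25):
                rows.append({"genotype": genotype, "drug": drug, "dose": dose,
                             "drug_class": CLASS_OF[drug],
                             "terminated": i < k})
    return pd.DataFrame(rows)


class TestTerminationTable:
    def test_published_summary_rows_from_their_counts(self):
        """Percentage arithmetic on the published aggregate counts."""
        rates = trial.termination_rates_from_counts({
            "overall": (180, 500),
            "class_IC": (38, 200),
            "class_III": (131, 300),
            "class_IC_wild_type": (12, 100),
            "class_IC_pitx2": (26, 100),
        })
        assert rates["overall"] == pytest.approx(36.0)
        assert rates["class_IC"] == pytest.approx(19.0)
        assert rates["class_III"] == pytest.approx(43.7, abs=0.05)
        assert rates["class_IC_wild_type"] == pytest.approx(12.0)
        assert rates["class_IC_pitx2"] == pytest.approx(26.0)

    def test_pipeline_table_from_per_drug_counts(self):
        """The case-level table reproduces the per-drug sub-rows; note the
        published class rows (38/200, 131/300) are what the per-drug counts
        sum to."""
        table = termination_table(printed_cases())
        assert table.loc["all_aads", "overall_n"] == 500
        assert table.loc["class_IC", "overall_terminated"] == 38
        assert table.loc["class_IC", "overall_pct"] == pytest.approx(19.0)
        assert table.loc["class_III", "overall_terminated"] == 131
        assert table.loc["class_III", "overall_pct"] == pytest.approx(43.7, abs=0.05)
        assert table.loc["class_IC", "wild_type_pct"] == pytest.approx(12.0)
        assert table.loc["class_IC", "pitx2_deficient_pct"] == pytest.approx(26.0)
        assert table.loc["amiodarone_high", "overall_pct"] == pytest.approx(54.0)
        assert table.loc["sotalol_high", "pitx2_deficient_pct"] == pytest.approx(68.0)

    def test_class_and_genotype_contrasts_tested(self):
        table = termination_table(printed_cases())
        p = table.attrs["p_values"]
        assert p["class_IC_vs_III"] < 0.001
        assert p["IC_wt_vs_pitx2"] < 0.05
        assert p["III_wt_vs_pitx2"] > 0.5

    def test_zero_terminations_zero_percent(self):
        df = printed_cases()
        df["terminated"] = False
        table = termination_table(df)
        assert table.loc["all_aads", "overall_pct"] == 0.0

    def test_no_drug_cases_rejected(self):
        df = printed_cases()
        df["drug"] = "none"
        with pytest.raises(ValueError):
            termination_table(df)


class TestDesignAndSummaries:
    def test_case_count_arithmetic(self):
        d = TrialDesign(substrate_seeds=(0, 1), drugs=(), include_baseline=True)
        assert len(d.cases()) == 4                 # 2 seeds x 2 genotypes

    def test_full_grid_matches_study_structure(self):
        """25 replicates x (1 baseline + 10 drug-doses) per genotype."""
        d = TrialDesign(substrate_seeds=tuple(range(25)))
        cases = d.cases()
        assert len(cases) == 25 * 2 * 11
        per_genotype = sum(1 for c in cases if c["genotype"] == "wild_type")
        assert per_genotype == 25 + 250

    def test_case_seed_expansion_is_stable_and_bounded(self):
        seeds = [trial.case_seed(5, i) for i in range(100)]
        assert len(set(seeds)) == 100
        assert all(0 <= s < 2**31 for s in seeds)
        assert seeds == [trial.case_seed(5, i) for i in range(100)]

    def test_terminated_cases_excluded_from_wave_means(self):
        """Early-terminated cases keep NaN wave metrics and drop out of the
        summary means while remaining in the termination table."""
        rows = []
        for seed in range(4):
            for drug, dose, term in [("none", None, False),
                                     ("sotalol", "low", seed < 2)]:
                rows.append({
                    "genotype": "wild_type", "drug": drug, "dose": dose,
                    "drug_class": "III" if drug != "none" else None,
                    "seed": seed, "terminated": term,
                    "apd90": 200.0, "cv": 0.5, "mean_smax": 0.6,
                    "mean_afcl": math.nan if term else 150.0 + seed,
                    "peak_df": math.nan if term else 8.0,
                    "mean_df": math.nan if term else 6.0,
                    "ps_number": math.nan if term else 100.0,
                    "ps_lifespan": math.nan if term else 50.0,
                })
        df = pd.DataFrame(rows)
        summaries = summarize(df)
        ephys = summaries["ephys"]
        row = ephys.loc[("wild_type/AAD", "mean_afcl")]
        assert row["n"] == 2                       # the two non-terminated
        assert row["mean"] == pytest.approx(152.5)
        table = termination_table(df)
        assert table.loc["all_aads", "overall_n"] == 4
        assert table.loc["all_aads", "overall_terminated"] == 2

    def test_deltas_pair_against_matched_baseline(self):
        rows = []
        for seed in (0, 1):
            rows.append({"genotype": "wild_type", "drug": "none", "dose": None,
                         "drug_class": None, "seed": seed, "terminated": False,
                         **{f: 100.0 for f in trial.METRIC_FIELDS}})
            rows.append({"genotype": "wild_type", "drug": "flecainide",
                         "dose": "low", "drug_class": "IC", "seed": seed,
                         "terminated": False,
                         **{f: 130.0 for f in trial.METRIC_FIELDS}})
        deltas = summarize(pd.DataFrame(rows))["deltas"]
        assert len(deltas) == 2
        assert (deltas["delta_mean_afcl"] == 30.0).all()
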