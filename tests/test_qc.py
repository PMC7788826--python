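"""Maternal-contamination QC: sex inference, SNP scoring, model recovery, genotypes."""

import numpy as np
import pandas as pd
import pytest

from pmdecon import (
    SampleSheet,
    SimulationConfig,
    ValidationError,
    estimate_contamination,
    fit_contamination_model,
    infer_sex,
    match_genotypes,
    simulate_cell_profiles,
    snp_outlier_score,
)
from pmdecon.qc import CONTAMINATION_THRESHOLD, genotype_calls
from pmdecon.simulate import SNP_CENTERS, contaminate_samples

CONTAM_GRID = [round(0.05 * i, 2) for i in range(11)]


def _sheet(y_norms, sexes=None, x_norms=None):
    n = len(y_norms)
    return SampleSheet(
        pd.DataFrame(
            dict(
                sample_id=[f"s{i}" for i in range(n)],
                cell_type=["TB"] * n,
                trimester=["term"] * n,
                reported_sex=sexes or ["unknown"] * n,
                y_norm=y_norms,
                x_norm=x_norms or [1.0] * n,
            )
        )
    )


def _contamination_cohort(seed=20260921, n_clean=12, reps_m=3, reps_f=8):
    """Males/females contaminated along the c grid with their own mother's DNA."""
    cfg = SimulationConfig(
        cell_types=("TB",), n_probes=700, n_replicates_per_type=260,
        n_hypo_dmcs_per_type=20, n_hyper_dmcs_per_type=10, n_pmd_blocks=2,
        pmd_block_size=10, n_imprint_probes=20, n_repeat_probes=40,
        n_gestational_dmcs_per_type=10, trimesters=("term",),
        n_villi_per_trimester=0, seed=seed,
    )
    ds = simulate_cell_profiles(cfg)
    sheet = ds.samples.data
    males = sheet[sheet.reported_sex == "M"].sample_id.tolist()
    females = sheet[sheet.reported_sex == "F"].sample_id.tolist()
    frac, mi, fi = {}, 0, 0
    for _ in range(n_clean):
        frac[males[mi]] = 0.0
        mi += 1
    for c in CONTAM_GRID:
        for _ in range(reps_m):
            frac[males[mi]] = c
            mi += 1
    for c in CONTAM_GRID:
        for _ in range(reps_f):
            frac[females[fi]] = c
            fi += 1
    ids = males[:mi] + females[:fi]
    contaminate_samples(ds, frac, np.random.default_rng(seed + 1))
    cohort = SampleSheet(ds.samples.data.set_index("sample_id").loc[ids].reset_index())
    snp_probes = ds.annotation.data.index[ds.annotation.data.snp_probe]
    snp_beta = ds.beta.data.loc[snp_probes, ids]
    truth = pd.DataFrame(
        dict(sample_id=ids, true_c=[frac[s] for s in ids],
             sex=["M" if s in males else "F" for s in ids])
    )
    return ds, cohort, snp_beta, truth


@pytest.fixture(scope="module")
def contamination_cohort():
    return _contamination_cohort()


class TestInferSex:
    def test_separated_clusters_called_m_and_f(self):
        calls = infer_sex(_sheet([1.0, 1.0, 0.1, 0.1]))
        assert list(calls.inferred_sex) == ["M", "M", "F", "F"]

    def test_half_contaminated_male_flagged_ambiguous(self):
        # a male at c = 0.5 sits at y ~ 0.55, far from both clusters
        y = [1.0, 0.99, 1.01, 1.0, 0.1, 0.11, 0.09, 0.1, 0.55]
        calls = infer_sex(_sheet(y))
        assert calls.inferred_sex.iloc[-1] == "ambiguous"
        assert set(calls.inferred_sex.iloc[:4]) == {"M"}

    def test_reported_vs_inferred_mismatch_recorded(self):
        calls = infer_sex(_sheet([1.0, 0.1], sexes=["F", "F"]))
        assert bool(calls.sex_mismatch.iloc[0])  # reported F, inferred M
        assert not bool(calls.sex_mismatch.iloc[1])

    def test_identical_y_norm_cannot_infer(self):
        with pytest.raises(ValidationError, match="reported_sex"):
            infer_sex(_sheet([0.5, 0.5, 0.5]))


class TestSnpOutlierScore:
    def test_pure_genotypes_score_zero(self):
        beta = pd.DataFrame({"s": [0.05] * 30 + [0.5] * 15 + [0.95] * 14})
        assert snp_outlier_score(beta).iloc[0] == 0.0

    def test_hand_computed_displacement(self):
        """Half the SNPs at a center, half displaced to 0.275 -> score 0.1125."""
        n = 59
        values = [0.05] * 30 + [0.275] * 29
        beta = pd.DataFrame({"s": values})
        # brute-force nearest-center check: 0.275 is nearer 0.5 (0.225) than 0.05 (0.225)?
        brute = np.mean([min(abs(v - c) for c in SNP_CENTERS) for v in values])
        score = snp_outlier_score(beta).iloc[0]
        assert score == pytest.approx(brute)
        assert score == pytest.approx((30 * 0.0 + 29 * 0.225) / 59)

    def test_too_few_snps_rejected(self):
        beta = pd.DataFrame({"s": [0.05] * 5})
        with pytest.raises(ValidationError, match=">= 10"):
            snp_outlier_score(beta)

    def test_score_monotone_in_contamination(self, contamination_cohort):
        _, _, snp_beta, truth = contamination_cohort
        scores = snp_outlier_score(snp_beta)
        females = truth[truth.sex == "F"].copy()
        females["score"] = scores.loc[females.sample_id].to_numpy()
        by_c = females.groupby("true_c")["score"].mean()
        assert (by_c.diff().dropna() > -1e-3).all()


class TestContaminationModel:
    def test_clean_males_anchor_near_zero_intercept(self):
        scores = pd.Series([0.0, 0.0, 0.0, 0.05, 0.10], index=list("abcde"))
        y = pd.Series([1.0, 1.0, 1.0, 0.8, 0.6], index=list("abcde"))
        model = fit_contamination_model(scores, y)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert model.slope > 0

    def test_degenerate_scores_rejected(self):
        scores = pd.Series([0.01, 0.01, 0.01])
        y = pd.Series([1.0, 0.9, 0.8])
        with pytest.raises(ValidationError, match="degenerate"):
            fit_contamination_model(scores, y)

    def test_fewer_than_three_males_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            fit_contamination_model(pd.Series([0.0, 0.1]), pd.Series([1.0, 0.5]))

    def test_slope_positive_with_contaminated_males(self, contamination_cohort):
        ds, cohort, snp_beta, truth = contamination_cohort
        sex = infer_sex(cohort).set_index("sample_id")
        males = truth[truth.sex == "M"].sample_id
        scores = snp_outlier_score(snp_beta)
        model = fit_contamination_model(
            scores.loc[males], sex.loc[males, "y_norm"],
            y_female_ref=float(sex.loc[sex.inferred_sex == "F", "y_norm"].median()),
        )
        assert model.slope > 0


class TestEstimateContamination:
    def test_grid_recovery_male_and_female(self, contamination_cohort):
        """Per contamination level, mean male error <= 0.05 and female <= 0.10."""
        _, cohort, snp_beta, truth = contamination_cohort
        report = estimate_contamination(cohort, snp_beta)
        merged = report.merge(truth, on="sample_id")
        by_level = (
            merged.groupby(["sex", "true_c"])["contamination"].mean().reset_index()
        )
        by_level["err"] = (by_level.contamination - by_level.true_c).abs()
        assert by_level.loc[by_level.sex == "M", "err"].max() <= 0.05
        assert by_level.loc[by_level.sex == "F", "err"].max() <= 0.10

    def test_estimate_monotone_in_true_contamination(self, contamination_cohort):
        _, cohort, snp_beta, truth = contamination_cohort
        report = estimate_contamination(cohort, snp_beta).merge(truth, on="sample_id")
        by_c = report.groupby("true_c")["contamination"].mean()
        assert (by_c.diff().dropna() > -0.02).all()

    def test_pass_flag_strict_at_threshold(self, contamination_cohort):
        _, cohort, snp_beta, truth = contamination_cohort
        report = estimate_contamination(cohort, snp_beta)
        assert (report.pass_qc == (report.contamination < CONTAMINATION_THRESHOLD)).all()
        # strictness: a sample estimated exactly at 0.35 must fail
        assert not bool(0.35 < CONTAMINATION_THRESHOLD)

    def test_clean_male_passes_with_zero_estimate(self, contamination_cohort):
        _, cohort, snp_beta, truth = contamination_cohort
        report = estimate_contamination(cohort, snp_beta).merge(truth, on="sample_id")
        clean_males = report[(report.sex == "M") & (report.true_c == 0.0)]
        assert (clean_males.contamination < 0.05).all()
        assert clean_males.pass_qc.all()


class TestMatchGenotypes:
    def test_identical_samples_fully_concordant(self):
        beta = pd.DataFrame(
            {"a": [0.05] * 30 + [0.5] * 29, "b": [0.05] * 30 + [0.5] * 29}
        )
        conc, assign = match_genotypes(beta)
        assert conc.loc["a", "b"] == 1.0
        assert assign.inferred_group.nunique() == 1

    def test_unrelated_pairs_match_closed_form(self, rng):
        """Unrelated donors at allele frequency 0.5: E[concordance] = 0.375."""
        n_pairs, n_snps = 1000, 59
        total = 0.0
        for _ in range(n_pairs):
            g1 = rng.binomial(2, 0.5, n_snps)
            g2 = rng.binomial(2, 0.5, n_snps)
            beta = pd.DataFrame(
                {"a": SNP_CENTERS[g1], "b": SNP_CENTERS[g2]}
            )
            conc, _ = match_genotypes(beta, threshold=2.0)
            total += conc.loc["a", "b"]
        assert abs(total / n_pairs - 0.375) < 0.03

    def test_calls_robust_to_moderate_contamination(self, rng):
        """Two aliquots of one donor at c = 0.2 still match (concordance >= 0.8)."""
        g = rng.binomial(2, 0.5, 59)
        g_m = np.clip(g + rng.choice([-1, 0, 1], 59), 0, 2)  # mother: one shared allele
        clean = SNP_CENTERS[g]
        contaminated = 0.8 * clean + 0.2 * SNP_CENTERS[g_m]
        beta = pd.DataFrame({"a": clean, "b": contaminated})
        conc, assign = match_genotypes(beta)
        assert conc.loc["a", "b"] >= 0.8
        assert assign.inferred_group.nunique() == 1

    def test_sheet_donor_agreement_on_simulated_cohort(self, small_dataset):
        ann = small_dataset.annotation.data
        snp_probes = ann.index[ann.snp_probe]
        term = small_dataset.samples.data.query("trimester == 'term'")
        ids = term.sample_id.tolist()[:30]
        snp_beta = small_dataset.beta.data.loc[snp_probes, ids]
        sheet = SampleSheet(term[term.sample_id.isin(ids)].reset_index(drop=True))
        conc, assign = match_genotypes(snp_beta, sheet)
        # samples of one donor (cells + villi) share genotype; no mismatch expected
        assert not assign.donor_mismatch.any()

    def test_genotype_calls_discretize_to_nearest_center(self):
        beta = pd.DataFrame({"s": [0.0, 0.3, 0.6, 1.0] + [0.05] * 10})
        calls = genotype_calls(beta)
        assert list(calls["s"].iloc[:4]) == [0, 1, 1, 2]
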