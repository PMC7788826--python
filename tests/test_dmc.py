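"""Moderated differential methylation: oracle agreement, thresholds, enrichment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from pmdecon import (
    BetaMatrix,
    ProbeAnnotation,
    ValidationError,
    call_dmcs,
    call_gestational_dmcs,
    enrichment_analysis,
    enrichment_test,
    fit_moderated,
    gene_promoter_dmc_summary,
    one_vs_all_dmcs,
)
from pmdecon.dmc import trigamma_inverse
from pmdecon.simulate import SimulationConfig, simulate_cell_profiles


def _fixture_beta(rng, n_probes=20, n1=5, n0=7):
    mu = rng.uniform(0.2, 0.8, n_probes)
    sd = rng.uniform(0.02, 0.12, n_probes)  # heterogeneous -> finite prior df
    eff = np.zeros(n_probes)
    eff[: n_probes // 3] = rng.uniform(-0.2, 0.2, n_probes // 3)
    x = np.array(
        [
            np.concatenate(
                [rng.normal(mu[g] + eff[g], sd[g], n1), rng.normal(mu[g], sd[g], n0)]
            )
            for g in range(n_probes)
        ]
    )
    x = np.clip(x, 0.01, 0.99)
    beta = BetaMatrix(
        pd.DataFrame(x, index=[f"cg{i:04d}" for i in range(n_probes)],
                     columns=[f"s{i}" for i in range(n1 + n0)])
    )
    group = np.array([True] * n1 + [False] * n0)
    return beta, group


def _oracle_moderated(x: np.ndarray, group: np.ndarray):
    """Independent step-by-step re-implementation of the moderated test.

    Plain loops, scipy special functions, and a bisection (not Newton)
    trigamma inverse; shares no code with the implementation under test.
    """
    idx1, idx0 = np.where(group)[0], np.where(~group)[0]
    n1, n0 = len(idx1), len(idx0)
    G = x.shape[0]
    delta, s2 = np.zeros(G), np.zeros(G)
    for g in range(G):
        a, b = x[g, idx1], x[g, idx0]
        delta[g] = a.mean() - b.mean()
        s2[g] = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (n1 + n0 - 2)
    dg = float(n1 + n0 - 2)
    e = np.log(s2) - special.digamma(dg / 2) + np.log(dg / 2)
    target = np.var(e, ddof=1) - special.polygamma(1, dg / 2)
    if target > 0:
        inv = optimize.brentq(lambda z: special.polygamma(1, z) - target, 1e-6, 1e8)
        d0 = 2 * inv
        s0 = np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2))
        s_tilde = (d0 * s0 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    else:
        d0, s0 = np.inf, float(np.mean(s2))
        s_tilde = np.full(G, s0)
        df_total = np.inf
    v = 1 / n1 + 1 / n0
    t = delta / np.sqrt(s_tilde * v)
    p = 2 * stats.t.sf(np.abs(t), df_total)
    return t, p, d0, s0


class TestFitModerated:
    def test_matches_independent_oracle_to_1e8(self, rng):
        beta, group = _fixture_beta(rng)
        table, hp = fit_moderated(beta, group, comparison="oracle")
        t_o, p_o, d0_o, s0_o = _oracle_moderated(beta.values, group)
        assert np.abs(table.t_mod.to_numpy() - t_o).max() < 1e-8
        assert np.abs(table.p.to_numpy() - p_o).max() < 1e-8
        assert hp.d0 == pytest.approx(d0_o, rel=1e-8)
        assert hp.s0_sq == pytest.approx(s0_o, rel=1e-8)

    def test_matches_limma_ebayes(self, rng, tmp_path):
        """Cross-check against the Bioconductor reference implementation."""
        beta, group = _fixture_beta(rng, n_probes=40)
        beta.data.to_csv(tmp_path / "beta.csv")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv('{tmp_path}/beta.csv', row.names=1))
            design <- cbind(Intercept=1, Group=c({','.join(str(int(g)) for g in group)}))
            fit <- eBayes(lmFit(x, design))
            write.csv(data.frame(t=fit$t[,'Group'], p=fit$p.value[,'Group']),
                      '{tmp_path}/limma.csv')
            """
        )
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {proc.stderr[-200:]}")
        table, _ = fit_moderated(beta, group)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        assert np.abs(table.t_mod.to_numpy() - ref.t.to_numpy()).max() < 1e-10
        assert np.abs(table.p.to_numpy() - ref.p.to_numpy()).max() < 1e-10

    def test_equal_group_means_give_null_statistics(self):
        x = np.tile([0.4, 0.4, 0.4, 0.4, 0.4, 0.4], (3, 1)).astype(float)
        x[1:, :3] += 0.05  # give other probes variance so s2 > 0
        x[1:, 3:] += 0.05
        x[2] += np.array([0.01, -0.01, 0.0, 0.01, -0.01, 0.0])
        beta = BetaMatrix(pd.DataFrame(x, index=list("abc"), columns=[f"s{i}" for i in range(6)]))
        table, _ = fit_moderated(beta, np.array([True] * 3 + [False] * 3))
        assert table.loc[table.probe_id == "a", "delta_beta"].iloc[0] == 0.0
        assert table.loc[table.probe_id == "a", "t_mod"].iloc[0] == 0.0
        assert table.loc[table.probe_id == "a", "p"].iloc[0] == 1.0

    def test_zero_prior_df_recovers_ordinary_t(self, rng):
        beta, group = _fixture_beta(rng)
        table, _ = fit_moderated(beta, group, prior_df=0.0)
        t_plain = stats.ttest_ind(
            beta.values[:, group].T, beta.values[:, ~group].T, equal_var=True
        )
        assert np.abs(table.t_mod.to_numpy() - t_plain.statistic).max() < 1e-10
        assert np.abs(table.p.to_numpy() - t_plain.pvalue).max() < 1e-10

    def test_identical_variances_give_infinite_prior_df(self, rng):
        """When every probe has the same s2, d0 = inf and t = delta/(s0 sqrt(v))."""
        n1 = n0 = 3
        base = np.array([0.0, 0.03, -0.03])
        x = np.stack([0.4 + np.concatenate([base, base]),
                      0.6 + np.concatenate([base, base]),
                      0.5 + np.concatenate([base, base])])
        beta = BetaMatrix(pd.DataFrame(x, index=list("abc"),
                                       columns=[f"s{i}" for i in range(6)]))
        table, hp = fit_moderated(beta, np.array([True] * n1 + [False] * n0))
        assert np.isinf(hp.d0)
        v = 1 / n1 + 1 / n0
        expected = table.delta_beta / np.sqrt(hp.s0_sq * v)
        assert np.allclose(table.t_mod, expected)

    def test_small_group_rejected(self, rng):
        beta, _ = _fixture_beta(rng)
        with pytest.raises(ValidationError, match=">= 2"):
            fit_moderated(beta, np.array([True] + [False] * 11))

    def test_trigamma_inverse_round_trip(self):
        for y in (1e-4, 0.01, 0.5, 3.0, 100.0):
            x = trigamma_inverse(y)
            assert special.polygamma(1, x) == pytest.approx(y, rel=1e-9)


class TestCallDmcs:
    def _table(self, delta, p_bonf):
        return pd.DataFrame(dict(probe_id=["cg1"], comparison=["x"],
                                 delta_beta=[delta], p_bonf=[p_bonf]))

    def test_passing_probe_called_with_direction(self):
        out = call_dmcs(self._table(0.30, 0.001))
        assert bool(out.is_dmc.iloc[0]) and out.direction.iloc[0] == "more"

    def test_delta_boundary_is_strict(self):
        assert not call_dmcs(self._table(0.25, 0.001)).is_dmc.iloc[0]

    def test_p_boundary_is_strict(self):
        assert not call_dmcs(self._table(0.30, 0.01)).is_dmc.iloc[0]

    def test_counts_monotone_in_thresholds(self, rng):
        beta, group = _fixture_beta(rng, n_probes=60)
        table, _ = fit_moderated(beta, group)
        n_loose = call_dmcs(table, p_bonf_max=0.05, delta_min=0.05).is_dmc.sum()
        n_tight_p = call_dmcs(table, p_bonf_max=0.01, delta_min=0.05).is_dmc.sum()
        n_tight_d = call_dmcs(table, p_bonf_max=0.05, delta_min=0.15).is_dmc.sum()
        assert n_tight_p <= n_loose and n_tight_d <= n_loose


class TestOneVsAll:
    def test_max_mean_cell_has_positive_delta(self, small_dataset):
        table, _ = one_vs_all_dmcs(small_dataset.beta, small_dataset.samples,
                                   trimester="term")
        beta = small_dataset.beta
        sheet = small_dataset.samples.data
        term = sheet[(sheet.trimester == "term") & ~sheet.cell_type.isin(["CV", "mixture"])]
        probe = small_dataset.truth.dmc_probes("HB", "hyper")[0]
        means = {c: beta.data.loc[probe, term[term.cell_type == c].sample_id].mean()
                 for c in small_dataset.config.cell_types}
        top_cell = max(means, key=means.get)
        row = table[(table.probe_id == probe) &
                    (table.comparison == f"{top_cell}_vs_all")]
        assert row.delta_beta.iloc[0] > 0


class TestGestational:
    def test_planted_trimester_shifts_called_as_increase(self, default_dataset):
        table, _ = call_gestational_dmcs(default_dataset.beta, default_dataset.samples)
        truth = default_dataset.truth.probes
        for cell in ("TB", "HB"):
            planted = truth.loc[(truth.role == "gest_dmc")
                                & (truth.gest_cell_type == cell), "probe_id"]
            sub = table[(table.comparison == f"{cell}_term_vs_first")
                        & table.probe_id.isin(planted)]
            called = sub[sub.is_dmc]
            # Bonferroni over 20k probes with a +0.10 shift and 10 donors per
            # trimester leaves moderate power; the direction must be exact
            assert len(called) / len(planted) > 0.75
            assert (called.direction == "increase").all()

    def test_missing_trimester_skipped_with_warning(self, rng):
        beta, _ = _fixture_beta(rng, n_probes=12, n1=4, n0=4)
        sheet = pd.DataFrame(dict(
            sample_id=[f"s{i}" for i in range(8)],
            cell_type=["TB"] * 4 + ["HB"] * 4,
            trimester=["first", "first", "term", "term"] + ["term"] * 4,
        ))
        from pmdecon import SampleSheet

        with pytest.warns(UserWarning, match="HB"):
            table, _ = call_gestational_dmcs(beta, SampleSheet(sheet))
        assert set(table.comparison) == {"TB_term_vs_first"}


class TestEnrichment:
    def test_chi2_matches_direct_formula(self):
        """{DMC: 30 in/70 out; rest: 100 in/900 out} vs hand-computed Pearson."""
        is_dmc = np.repeat([True, False], [100, 1000])
        in_el = np.concatenate([np.repeat([True, False], [30, 70]),
                                np.repeat([True, False], [100, 900])])
        row = enrichment_test(is_dmc, in_el, element="x")
        obs = np.array([[30, 70], [100, 900]], dtype=float)
        rows, cols, n = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(rows, cols) / n
        chi2_hand = float(np.sum((obs - expected) ** 2 / expected))
        assert row["chi2"] == pytest.approx(chi2_hand, abs=5e-3)
        assert row["chi2"] == pytest.approx(34.89, abs=0.01)

    def test_fold_one_and_zero_chi2_at_background(self):
        """Observed frequency equal to background: fold = 1, chi2 = 0, ns."""
        is_dmc = np.repeat([True, False], [100, 900])
        in_el = np.concatenate([np.repeat([True, False], [10, 90]),
                                np.repeat([True, False], [90, 810])])
        row = enrichment_test(is_dmc, in_el, element="x")
        assert row["fold"] == pytest.approx(1.0)
        assert row["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert row["call"] == "ns"

    def test_background_uses_all_tested_probes(self):
        is_dmc = np.repeat([True, False], [100, 1000])
        in_el = np.concatenate([np.repeat([True, False], [30, 70]),
                                np.repeat([True, False], [100, 900])])
        row = enrichment_test(is_dmc, in_el)
        assert row["expected_frac"] == pytest.approx(130 / 1100)
        assert row["observed_frac"] == pytest.approx(0.30)

    def test_empty_element_rejected(self):
        with pytest.raises(ValidationError, match="covers no"):
            enrichment_test(np.array([True, False]), np.array([False, False]))

    def test_planted_hypo_dmcs_enriched_in_their_annotation(self, small_dataset):
        table, _ = one_vs_all_dmcs(small_dataset.beta, small_dataset.samples,
                                   trimester="term", cell_types=["TB"])
        enr = enrichment_analysis(table, small_dataset.annotation)
        assert not enr.empty
        assert {"comparison", "fold", "chi2", "call"} <= set(enr.columns)


class TestPromoterSummary:
    def _annotation(self, n_genes=50, probes_per_gene=4):
        rows = []
        pid = 0
        for g in range(n_genes):
            for _ in range(probes_per_gene):
                rows.append(dict(probe_id=f"cg{pid:05d}", chrom="chr1", pos=pid * 100 + 1,
                                 island_context="island", gene_context="promoter",
                                 gene=f"G{g:03d}"))
                pid += 1
        return ProbeAnnotation(pd.DataFrame(rows))

    def test_fraction_zero_and_one_extremes(self):
        ann = self._annotation(n_genes=2)
        all_g0 = [f"cg{p:05d}" for p in range(4)]
        per_gene, _ = gene_promoter_dmc_summary(set(all_g0), ann)
        per_gene = per_gene.set_index("gene")
        assert per_gene.loc["G000", "fraction"] == 1.0
        assert per_gene.loc["G001", "fraction"] == 0.0

    def test_independent_dmc_assignment_is_binomial(self, rng):
        """DMC status independent of gene at rate r -> mean fraction within 2 SE of r."""
        ann = self._annotation(n_genes=200, probes_per_gene=5)
        r = 0.3
        dmc = set(ann.data.probe_id[rng.random(len(ann.data)) < r])
        per_gene, by_count = gene_promoter_dmc_summary(dmc, ann)
        se = np.sqrt(r * (1 - r) / 5 / 200)
        assert abs(per_gene.fraction.mean() - r) < 2 * se
        assert "smoothed_fraction" in by_count.columns
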