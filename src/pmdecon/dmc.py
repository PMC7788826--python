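"""Differential methylation with empirical-Bayes moderated statistics.

Each probe is fitted with an ordinary least-squares two-group model (one cell
type vs the pooled rest, or term vs first trimester within a cell type).  The
residual variances s2_g (d_g degrees of freedom each) are shrunk toward a
prior via the standard moment-matching scheme on z_g = log s2_g:

    e_g  = z_g - psi(d_g/2) + log(d_g/2)
    psi'(d0/2) = var(e) - mean(psi'(d_g/2))      (solved for d0; d0 = inf
                                                  when the RHS is <= 0)
    s0^2 = exp(mean(e) + psi(d0/2) - log(d0/2))  (d0 finite; else mean(s2_g))

with psi the digamma and psi' the trigamma function.  The posterior variance
s~2_g = (d0 s0^2 + d_g s2_g) / (d0 + d_g) yields the moderated t statistic
t_g = delta_g / (s~_g sqrt(v)) on d0 + d_g degrees of freedom, where v is the
coefficient variance factor 1/n1 + 1/n0 of the group-indicator design.

A differentially methylated CpG (DMC) requires a Bonferroni-adjusted p-value
strictly below 0.01 AND |delta beta| strictly above a threshold (0.25 for
one-vs-all cell contrasts, 0.05 for gestational-age contrasts).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import BetaMatrix, ProbeAnnotation, SampleSheet, ValidationError

P_BONF_MAX = 0.01
DELTA_MIN_CELL = 0.25
DELTA_MIN_GESTATIONAL = 0.05
NON_CELL_LABELS = ("CV", "mixture")


@dataclasses.dataclass
class EBayesHyperparams:
    """Prior degrees of freedom (may be inf) and prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is the explicit "no moderation" override; estimation itself
        # always yields d0 > 0
        if not (self.d0 >= 0 and self.s0_sq > 0):
            raise ValidationError("empirical-Bayes hyperparameters must be nonnegative")


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # asymptotic start: trigamma(x) ~ 1/x for large x
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def fit_moderated(
    beta: BetaMatrix | pd.DataFrame,
    group: pd.Series | np.ndarray,
    comparison: str = "",
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, EBayesHyperparams]:
    """Per-probe two-group moderated test.

    ``group`` is a boolean indicator over the matrix columns (True = target
    group); delta beta is mean(target) - mean(rest).  Missing betas are
    excluded pairwise; probes with fewer than 2 usable samples in either
    group get missing statistics.  ``prior_df`` overrides the estimated d0
    (0 recovers the ordinary two-sample t; inf gives full shrinkage).

    Returns ``(table, hyperparams)`` with columns: probe_id, comparison,
    delta_beta, s2, df_resid, t_mod, df_total, p, p_bonf.
    """
    data = beta.data if isinstance(beta, BetaMatrix) else beta
    g = np.asarray(group, dtype=bool)
    if g.shape != (data.shape[1],):
        raise ValidationError("group indicator length must match the number of samples")
    if g.sum() < 2 or (~g).sum() < 2:
        raise ValidationError(
            f"comparison {comparison or '<unnamed>'!r} needs >= 2 samples per group "
            f"(got {int(g.sum())} vs {int((~g).sum())})"
        )
    x1 = data.to_numpy()[:, g]
    x0 = data.to_numpy()[:, ~g]
    n1 = (~np.isnan(x1)).sum(axis=1).astype(float)
    n0 = (~np.isnan(x0)).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(np.where(np.isnan(x1), np.nan, x1), axis=1)
        m0 = np.nanmean(np.where(np.isnan(x0), np.nan, x0), axis=1)
        ss = np.nansum((x1 - m1[:, None]) ** 2, axis=1) + np.nansum((x0 - m0[:, None]) ** 2, axis=1)
    usable = (n1 >= 2) & (n0 >= 2)
    delta = np.where(usable, m1 - m0, np.nan)
    dg = np.where(usable, n1 + n0 - 2.0, np.nan)
    s2 = np.where(usable, ss / np.where(usable, dg, 1.0), np.nan)
    v = np.where(usable, 1.0 / n1 + 1.0 / n0, np.nan)

    est = usable & (s2 > 0)
    if prior_df is not None:
        d0 = float(prior_df)
        s0_sq = float(np.nanmean(s2[est])) if est.any() else 1.0
    elif est.sum() < 2:
        d0, s0_sq = np.inf, float(np.nanmean(s2[est])) if est.any() else 1.0
    else:
        z = np.log(s2[est])
        e = z - special.digamma(dg[est] / 2.0) + np.log(dg[est] / 2.0)
        e_mean = float(np.mean(e))
        e_var = float(np.var(e, ddof=1))
        target = e_var - float(np.mean(special.polygamma(1, dg[est] / 2.0)))
        if target > 0:
            d0 = 2.0 * trigamma_inverse(target)
            s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0 = np.inf
            s0_sq = float(np.mean(s2[est]))

    if d0 == 0:
        s_tilde = s2
        df_total = dg
    elif np.isinf(d0):
        s_tilde = np.full_like(s2, s0_sq)
        df_total = np.full_like(dg, np.inf)
    else:
        s_tilde = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = delta / np.sqrt(s_tilde * v)
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    n_tested = int(np.isfinite(p).sum())
    p_bonf = np.minimum(1.0, p * n_tested)
    table = pd.DataFrame(
        dict(
            probe_id=data.index, comparison=comparison, delta_beta=delta, s2=s2,
            df_resid=dg, t_mod=t_mod, df_total=df_total, p=p, p_bonf=p_bonf,
        )
    )
    return table, EBayesHyperparams(d0=d0, s0_sq=s0_sq)


def call_dmcs(
    table: pd.DataFrame,
    p_bonf_max: float = P_BONF_MAX,
    delta_min: float = DELTA_MIN_CELL,
    directions: tuple[str, str] = ("less", "more"),
) -> pd.DataFrame:
    """Flag DMCs (strict thresholds) and assign a direction from sign(delta)."""
    out = table.copy()
    out["is_dmc"] = (out["p_bonf"] < p_bonf_max) & (out["delta_beta"].abs() > delta_min)
    out["is_dmc"] = out["is_dmc"].fillna(False)
    out["direction"] = np.where(out["delta_beta"] < 0, directions[0], directions[1])
    out.loc[out["delta_beta"].isna(), "direction"] = ""
    return out


def one_vs_all_dmcs(
    beta: BetaMatrix,
    samples: SampleSheet,
    cell_types: list[str] | None = None,
    trimester: str | None = None,
    p_bonf_max: float = P_BONF_MAX,
    delta_min: float = DELTA_MIN_CELL,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, dict[str, EBayesHyperparams]]:
    """One-vs-all moderated tests for every cell type (villi excluded).

    Bonferroni correction is applied within each comparison across its tested
    probes.  Returns the concatenated DMC table and the per-comparison
    hyperparameters.
    """
    df = samples.data
    if trimester is not None:
        df = df[df["trimester"] == trimester]
    cell_df = df[~df["cell_type"].isin(NON_CELL_LABELS)]
    cells = cell_types or sorted(cell_df["cell_type"].unique())
    ids = [s for s in cell_df["sample_id"] if s in set(beta.sample_ids)]
    sub = beta.subset_samples(ids)
    labels = cell_df.set_index("sample_id").loc[ids, "cell_type"]
    tables, hypers = [], {}
    for cell in cells:
        name = f"{cell}_vs_all"
        table, hp = fit_moderated(sub, (labels == cell).to_numpy(), comparison=name, prior_df=prior_df)
        tables.append(call_dmcs(table, p_bonf_max=p_bonf_max, delta_min=delta_min))
        hypers[name] = hp
    return pd.concat(tables, ignore_index=True), hypers


def call_gestational_dmcs(
    beta: BetaMatrix,
    samples: SampleSheet,
    cell_types: list[str] | None = None,
    p_bonf_max: float = P_BONF_MAX,
    delta_min: float = DELTA_MIN_GESTATIONAL,
) -> tuple[pd.DataFrame, dict[str, EBayesHyperparams]]:
    """Term-vs-first-trimester moderated tests within each cell type.

    delta beta is term minus first, so direction ``increase`` means DNAm
    rises toward term.  Cell types missing a trimester are skipped with a
    warning.
    """
    df = samples.data[~samples.data["cell_type"].isin(NON_CELL_LABELS)]
    cells = cell_types or sorted(df["cell_type"].unique())
    tables, hypers = [], {}
    for cell in cells:
        sel = df[(df["cell_type"] == cell) & df["sample_id"].isin(set(beta.sample_ids))]
        n_first = (sel["trimester"] == "first").sum()
        n_term = (sel["trimester"] == "term").sum()
        if n_first < 2 or n_term < 2:
            warnings.warn(
                f"cell type {cell!r} lacks a trimester ({n_first} first, {n_term} term); skipped",
                stacklevel=2,
            )
            continue
        ids = list(sel["sample_id"])
        sub = beta.subset_samples(ids)
        is_term = (sel.set_index("sample_id").loc[ids, "trimester"] == "term").to_numpy()
        name = f"{cell}_term_vs_first"
        table, hp = fit_moderated(sub, is_term, comparison=name)
        tables.append(
            call_dmcs(table, p_bonf_max=p_bonf_max, delta_min=delta_min,
                      directions=("decrease", "increase"))
        )
        hypers[name] = hp
    if not tables:
        raise ValidationError("no cell type has both trimesters")
    return pd.concat(tables, ignore_index=True), hypers


def dmc_recovery(table: pd.DataFrame, truth) -> dict:
    """Confusion-matrix summary of one-vs-all calls against planted truth.

    Restricted to probes whose cell-specific DMC truth is defined: baseline,
    planted-DMC, gestational and repeat probes.  PMD and imprint probes are
    excluded from the universe because they carry genuine planted cell-type
    differences by construction -- calling them is correct, not a false
    discovery.  Returns the minimum per-cell-type sensitivity and the maximum
    per-cell-type false-discovery proportion.
    """
    roles = truth.probes.set_index("probe_id")["role"]
    universe = set(roles[roles.isin(["baseline", "dmc", "gest_dmc", "repeat"])].index)
    sens, fdp = [], []
    for comparison, sub in table.groupby("comparison"):
        cell = comparison.split("_vs_")[0]
        planted = set(truth.dmc_probes(cell))
        if not planted:
            continue
        called = set(sub.loc[sub["is_dmc"], "probe_id"]) & universe
        tp = len(called & planted)
        sens.append(tp / len(planted))
        fdp.append((len(called) - tp) / max(len(called), 1))
    return dict(sensitivity=min(sens), fdp=max(fdp), n_comparisons=len(sens))


def enrichment_test(
    is_dmc: np.ndarray,
    in_element: np.ndarray,
    element: str = "",
    comparison: str = "",
    direction: str = "",
    n_tests: int = 1,
    p_bonf_max: float = P_BONF_MAX,
) -> dict:
    """Chi-squared enrichment of a DMC set in a genomic element.

    The 2x2 table is (DMC vs non-DMC) x (in-element vs not); the Pearson
    chi-squared has no continuity correction.  The background (expected)
    frequency is the fraction of ALL tested probes in the element, and
    fold = observed DMC fraction / background fraction.
    """
    is_dmc = np.asarray(is_dmc, dtype=bool)
    in_element = np.asarray(in_element, dtype=bool)
    if not in_element.any():
        raise ValidationError(f"element {element!r} covers no tested probes")
    if not is_dmc.any():
        raise ValidationError("empty DMC set")
    a = int(np.sum(is_dmc & in_element))
    b = int(np.sum(is_dmc & ~in_element))
    c = int(np.sum(~is_dmc & in_element))
    d = int(np.sum(~is_dmc & ~in_element))
    observed = a / (a + b)
    expected = (a + c) / (a + b + c + d)
    fold = observed / expected if expected > 0 else np.nan
    if min(a + b, c + d, a + c, b + d) == 0:
        chi2, p = np.nan, np.nan
    else:
        chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    p_bonf = min(1.0, p * n_tests) if np.isfinite(p) else np.nan
    if np.isfinite(p_bonf) and p_bonf < p_bonf_max:
        call = "enriched" if fold > 1 else "depleted"
    else:
        call = "ns"
    return dict(
        comparison=comparison, direction=direction, element=element,
        observed_frac=observed, expected_frac=expected, fold=fold,
        chi2=float(chi2), p=float(p) if np.isfinite(p) else np.nan,
        p_bonf=float(p_bonf) if np.isfinite(p_bonf) else np.nan, call=call,
    )


def enrichment_analysis(
    dmc_table: pd.DataFrame,
    annotation: ProbeAnnotation,
    p_bonf_max: float = P_BONF_MAX,
) -> pd.DataFrame:
    """Enrichment of every (comparison, direction) DMC set in every element.

    Elements: the four island contexts, the six gene contexts, enhancers and
    PMDs.  Bonferroni correction spans all element x comparison x direction
    rows tested.
    """
    ann = annotation.data
    elements: dict[str, pd.Series] = {}
    for value in ann["island_context"].unique():
        elements[str(value)] = ann["island_context"] == value
    for value in ann["gene_context"].unique():
        elements[str(value)] = ann["gene_context"] == value
    elements["enhancer"] = ann["enhancer"]
    elements["pmd"] = ann["pmd"]

    jobs = []
    for (comparison, direction), sub in dmc_table.groupby(["comparison", "direction"]):
        if direction == "" or not sub["is_dmc"].any():
            continue
        tested = sub.dropna(subset=["p"]).set_index("probe_id")
        shared = tested.index.intersection(ann.index)
        tested = tested.loc[shared]
        for element, mask in elements.items():
            jobs.append((comparison, direction, element, tested, mask.loc[shared]))
    n_tests = len(jobs)
    rows = []
    for comparison, direction, element, tested, mask in jobs:
        if not mask.any():
            continue
        rows.append(
            enrichment_test(
                tested["is_dmc"].to_numpy(), mask.to_numpy(), element=element,
                comparison=comparison, direction=direction, n_tests=n_tests,
                p_bonf_max=p_bonf_max,
            )
        )
    return pd.DataFrame(rows)


def gene_promoter_dmc_summary(
    dmc_probes: set[str] | pd.Index,
    annotation: ProbeAnnotation,
    smooth_window: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene promoter DMC burden.

    For each gene with promoter probes: the number of promoter probes, how
    many are a DMC for at least one cell type, and the fraction.  The second
    frame is a background curve: mean fraction by promoter-probe count with a
    centered running mean over counts.  Genes with zero promoter probes are
    omitted by construction.
    """
    ann = annotation.data
    promoters = ann[(ann["gene_context"] == "promoter") & (ann["gene"] != "")]
    if promoters.empty:
        raise ValidationError("annotation has no promoter probes with gene assignments")
    dmc_set = set(dmc_probes)
    per_gene = (
        promoters.assign(is_dmc=promoters["probe_id"].isin(dmc_set))
        .groupby("gene")
        .agg(n_promoter_probes=("probe_id", "size"), n_dmc=("is_dmc", "sum"))
        .reset_index()
    )
    per_gene["fraction"] = per_gene["n_dmc"] / per_gene["n_promoter_probes"]
    by_count = (
        per_gene.groupby("n_promoter_probes")["fraction"].mean().rename("mean_fraction").reset_index()
    )
    by_count["smoothed_fraction"] = (
        by_count["mean_fraction"].rolling(smooth_window, center=True, min_periods=1).mean()
    )
    return per_gene, by_count
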