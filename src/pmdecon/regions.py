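"""Region-level methylome summaries.

Three placenta-characteristic features summarized at the region level:

* **PMD interval occupancy** -- for probes inside partially methylated
  domains (after removing CpG-island, shore and promoter probes, which the
  array over-covers), the percentage of per-cell-type probe means falling in
  each 20% methylation interval;
* **imprinted-region intermediate fractions** -- the fraction of imprint
  probes whose per-cell-type mean lies in the closed [0.25, 0.75] band (the
  expected signature of monoallelic methylation), split by placental-specific
  vs non-placental-specific imprint category;
* **repetitive-element means** -- per-sample mean beta over Alu, LINE1 and
  all probes, with per-cell-type contrasts against chorionic villi from a
  linear model on the per-sample summaries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import BetaMatrix, ProbeAnnotation, SampleSheet, ValidationError

PMD_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
PMD_BIN_LABELS = ("[0,0.2)", "[0.2,0.4)", "[0.4,0.6)", "[0.6,0.8)", "[0.8,1.0]")
IMPRINT_RANGE = (0.25, 0.75)


def _group_means(beta: BetaMatrix, samples: SampleSheet, probes: pd.Index) -> dict:
    """Per (cell type, trimester): mean beta per probe across the group's samples."""
    df = samples.data
    out = {}
    for (cell, trim), sub in df.groupby(["cell_type", "trimester"]):
        ids = [s for s in sub["sample_id"] if s in set(beta.sample_ids)]
        if not ids:
            continue
        out[(cell, trim)] = beta.data.loc[probes, ids].mean(axis=1)
    return out


def pmd_interval_fractions(
    beta: BetaMatrix,
    samples: SampleSheet,
    annotation: ProbeAnnotation,
) -> pd.DataFrame:
    """Percentage of PMD probes per 20% methylation interval.

    Restricted to probes flagged ``pmd`` whose island context is neither
    island nor shore and whose gene context is not promoter.  Bins are
    lower-closed, upper-open, with the last bin closed at 1.0; each row sums
    to 100%.
    """
    ann = annotation.data
    qualifying = ann[
        ann["pmd"]
        & ~ann["island_context"].isin(("island", "shore"))
        & (ann["gene_context"] != "promoter")
    ]
    probes = qualifying.index.intersection(beta.probe_ids)
    if len(probes) == 0:
        raise ValidationError("no qualifying PMD probes after island/shore/promoter exclusion")
    rows = []
    for (cell, trim), means in _group_means(beta, samples, probes).items():
        m = means.dropna().to_numpy()
        counts, _ = np.histogram(m, bins=PMD_BINS)
        pct = 100.0 * counts / counts.sum()
        rows.append(dict(cell_type=cell, trimester=trim, n_probes=len(m),
                         **dict(zip(PMD_BIN_LABELS, pct))))
    return pd.DataFrame(rows)


def imprint_intermediate_fraction(
    beta: BetaMatrix,
    samples: SampleSheet,
    annotation: ProbeAnnotation,
    lo: float = IMPRINT_RANGE[0],
    hi: float = IMPRINT_RANGE[1],
) -> pd.DataFrame:
    """Fractions of imprint-probe means below / inside / above [lo, hi].

    One row per (cell type, trimester, imprint category); the closed
    intermediate band [0.25, 0.75] is the expected imprinted signature.  The
    three fractions partition the probes, so they sum to one.  Empty
    categories are omitted with a warning.
    """
    ann = annotation.data
    rows = []
    for category in ("placental_specific", "non_placental_specific"):
        probes = ann.index[ann["imprint_category"] == category].intersection(beta.probe_ids)
        if len(probes) == 0:
            warnings.warn(f"imprint category {category!r} has no probes; omitted", stacklevel=2)
            continue
        for (cell, trim), means in _group_means(beta, samples, probes).items():
            m = means.dropna().to_numpy()
            rows.append(
                dict(
                    cell_type=cell, trimester=trim, imprint_category=category, n_probes=len(m),
                    frac_below=float(np.mean(m < lo)),
                    frac_intermediate=float(np.mean((m >= lo) & (m <= hi))),
                    frac_above=float(np.mean(m > hi)),
                )
            )
    return pd.DataFrame(rows)


def repeat_mean_dnam(
    beta: BetaMatrix,
    samples: SampleSheet,
    annotation: ProbeAnnotation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample repeat-element mean methylation and cell-vs-villi contrasts.

    Means are computed per sample over the Alu set, the LINE1 set and all
    probes.  Contrasts: within each trimester and probe set, a linear model
    of the per-sample means on the cell-type indicator (CV = reference)
    gives the mean difference of each cell type vs villi and a two-sided p.
    Without CV samples the contrasts are omitted (means still returned).
    """
    ann = annotation.data
    sets = {
        "Alu": ann.index[ann["repeat_class"] == "Alu"],
        "LINE1": ann.index[ann["repeat_class"] == "LINE1"],
        "all": ann.index,
    }
    sheet = samples.data.set_index("sample_id")
    mean_rows = []
    for sample in beta.sample_ids:
        row = dict(
            sample_id=sample,
            cell_type=sheet.loc[sample, "cell_type"],
            trimester=sheet.loc[sample, "trimester"],
        )
        for name, probes in sets.items():
            shared = probes.intersection(beta.probe_ids)
            row[f"mean_{name}"] = float(beta.data.loc[shared, sample].mean())
        mean_rows.append(row)
    means = pd.DataFrame(mean_rows)

    contrast_rows = []
    for trim, sub in means.groupby("trimester"):
        cv = sub[sub["cell_type"] == "CV"]
        if len(cv) == 0:
            warnings.warn(f"no CV samples in trimester {trim!r}; contrasts omitted", stacklevel=2)
            continue
        cells = [c for c in sub["cell_type"].unique() if c != "CV"]
        design = pd.get_dummies(
            pd.Categorical(sub["cell_type"], categories=["CV"] + cells), drop_first=True
        ).astype(float)
        design.insert(0, "const", 1.0)
        for name in sets:
            fit = sm.OLS(sub[f"mean_{name}"].to_numpy(), design.to_numpy()).fit()
            for i, cell in enumerate(cells, start=1):
                contrast_rows.append(
                    dict(trimester=trim, cell_type=cell, probe_set=name,
                         mean_difference=float(fit.params[i]), p=float(fit.pvalues[i]))
                )
    return means, pd.DataFrame(contrast_rows)
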