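"""Selection of cell-discriminating reference probes.

For each cell type a one-vs-rest two-group ANOVA F statistic is computed at
every probe, and the top probes in each methylation direction (hypomethylated
and hypermethylated relative to the pooled rest) are retained.  With the
default 50 probes per direction and 6 cell types this yields the canonical
600-probe deconvolution reference.  A probe that ranks for several cell types
is assigned to the one where its F is largest, and the losing cell types
backfill from their own ranking.  Reference entries are per-cell-type mean
beta over that cell type's samples at the selected probes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet, ValidationError

NON_CELL_LABELS = ("CV", "mixture")


class SelectionError(ValueError):
    """Probe selection cannot satisfy the request."""


@dataclasses.dataclass
class ReferenceMatrix:
    """Selected probes x cell types signature with selection provenance."""

    means: pd.DataFrame  # selected probes x cell types, mean beta
    provenance: pd.DataFrame  # probe_id, cell_type, direction, f_stat

    def __post_init__(self) -> None:
        if self.provenance["probe_id"].duplicated().any():
            raise ValidationError("reference selects a probe twice")
        per_dir = self.provenance.groupby(["cell_type", "direction"]).size().unstack(fill_value=0)
        if per_dir.shape[1] == 2 and not (per_dir["hypo"] == per_dir["hyper"]).all():
            raise ValidationError("unequal hypo/hyper probe counts for some cell type")
        vals = self.means.to_numpy()
        if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
            raise ValidationError("reference means outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.means.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.means.columns)


def _cell_sample_groups(samples: SampleSheet, cell_types: list[str] | None) -> dict[str, list[str]]:
    df = samples.data
    cells = df.loc[~df["cell_type"].isin(NON_CELL_LABELS), "cell_type"].unique().tolist()
    if cell_types is not None:
        cells = [c for c in cell_types if c in cells]
    return {c: list(df.loc[df["cell_type"] == c, "sample_id"]) for c in cells}


def rank_probes_f(
    beta: BetaMatrix,
    samples: SampleSheet,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """One-vs-rest two-group ANOVA F and direction, per probe and cell type.

    For cell type k at probe g, the two groups are k's samples and the pooled
    samples of all other cell types (villi/mixtures excluded).  With two
    groups the F statistic is the squared pooled two-sample t.  Direction is
    the sign of mean(k) - mean(rest): ``hypo`` when negative.  Missing betas
    are excluded pairwise.  Returns a long frame: probe_id, cell_type,
    f_stat, direction, mean_target, mean_rest.
    """
    groups = _cell_sample_groups(samples, cell_types)
    for cell, ids in groups.items():
        if len(ids) < 2:
            raise ValidationError(f"cell type {cell!r} has {len(ids)} sample(s); need >= 2")
    all_cell_samples = [s for ids in groups.values() for s in ids]
    data = beta.data[all_cell_samples]
    frames = []
    for cell, ids in groups.items():
        x1 = data[ids].to_numpy()
        x0 = data[[s for s in all_cell_samples if s not in set(ids)]].to_numpy()
        n1 = (~np.isnan(x1)).sum(axis=1)
        n0 = (~np.isnan(x0)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            m1 = np.nanmean(x1, axis=1)
            m0 = np.nanmean(x0, axis=1)
            ssw = np.nansum((x1 - m1[:, None]) ** 2, axis=1) + np.nansum(
                (x0 - m0[:, None]) ** 2, axis=1
            )
            n = n1 + n0
            grand = (n1 * m1 + n0 * m0) / n
            ssb = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
            df_within = n - 2
            f = np.where(ssw > 0, ssb / 1.0 / (ssw / np.maximum(df_within, 1)), np.where(ssb > 0, np.inf, 0.0))
        f = np.where((n1 >= 2) & (n0 >= 2), f, np.nan)
        frames.append(
            pd.DataFrame(
                dict(probe_id=beta.probe_ids, cell_type=cell, f_stat=f,
                     direction=np.where(m1 < m0, "hypo", "hyper"),
                     mean_target=m1, mean_rest=m0)
            )
        )
    return pd.concat(frames, ignore_index=True)


def pick_reference_probes(
    ranked: pd.DataFrame,
    beta: BetaMatrix,
    samples: SampleSheet,
    n_per_direction: int = 50,
) -> ReferenceMatrix:
    """Pick the top-F probes per cell type and direction into a reference.

    Claims are processed in globally descending F order (ties broken by probe
    id), which simultaneously assigns duplicated probes to the cell type with
    the larger F and backfills the losers from their own ranking.
    """
    if n_per_direction <= 0:
        raise SelectionError("n_per_direction must be positive")
    groups = _cell_sample_groups(samples, None)
    cells = [c for c in groups if c in set(ranked["cell_type"])]
    quota = {(c, d): n_per_direction for c in cells for d in ("hypo", "hyper")}
    pool = ranked.dropna(subset=["f_stat"]).sort_values(
        ["f_stat", "probe_id"], ascending=[False, True], kind="mergesort"
    )
    assigned: dict[str, tuple[str, str, float]] = {}
    for row in pool.itertuples(index=False):
        key = (row.cell_type, row.direction)
        if quota.get(key, 0) <= 0 or row.probe_id in assigned:
            continue
        assigned[row.probe_id] = (row.cell_type, row.direction, row.f_stat)
        quota[key] -= 1
    shortfall = {k: v for k, v in quota.items() if v > 0}
    if shortfall:
        detail = ", ".join(f"{c}/{d}: {v} short" for (c, d), v in shortfall.items())
        raise SelectionError(f"insufficient probes to fill the reference ({detail})")
    provenance = pd.DataFrame(
        [(p, c, d, f) for p, (c, d, f) in assigned.items()],
        columns=["probe_id", "cell_type", "direction", "f_stat"],
    ).sort_values(["cell_type", "direction", "f_stat"], ascending=[True, True, False])
    probes = provenance["probe_id"].tolist()
    means = pd.DataFrame(
        {c: beta.data.loc[probes, ids].mean(axis=1) for c, ids in groups.items()},
        index=pd.Index(probes, name="probe_id"),
    )
    return ReferenceMatrix(means=means, provenance=provenance.reset_index(drop=True))


def build_reference(
    beta: BetaMatrix,
    samples: SampleSheet,
    trimester: str | None = None,
    n_per_direction: int = 50,
) -> ReferenceMatrix:
    """Trimester-specific reference construction.

    For the first-trimester reference, first-trimester cell samples are
    augmented with term eSTB and nRBC profiles (those populations are present
    in early gestation but were profiled at term).
    """
    df = samples.data
    if trimester is None:
        keep = df
    elif trimester == "first":
        keep = df[
            (df["trimester"] == "first")
            | ((df["trimester"] == "term") & df["cell_type"].isin(("eSTB", "nRBC")))
        ]
        # drop first-trimester rows for the term-augmented cell types so each
        # cell type comes from a single gestational window
        keep = keep[
            ~((keep["trimester"] == "first") & keep["cell_type"].isin(("eSTB", "nRBC")))
        ]
    else:
        keep = df[df["trimester"] == trimester]
    subset = SampleSheet(keep.reset_index(drop=True))
    cell_samples = [
        s for s in subset.sample_ids if s in set(beta.sample_ids)
    ]
    sub_beta = beta.subset_samples(cell_samples)
    sub_sheet = SampleSheet(subset.data[subset.data["sample_id"].isin(cell_samples)].reset_index(drop=True))
    ranked = rank_probes_f(sub_beta, sub_sheet)
    return pick_reference_probes(ranked, sub_beta, sub_sheet, n_per_direction=n_per_direction)


def write_reference(ref: ReferenceMatrix, path) -> None:
    out = ref.means.copy()
    prov = ref.provenance.set_index("probe_id")
    out["target_cell_type"] = prov["cell_type"]
    out["direction"] = prov["direction"]
    out["f_stat"] = prov["f_stat"]
    out.to_csv(path, sep="\t", float_format="%.6g", index_label="probe_id")


def read_reference(path) -> ReferenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    prov_cols = ["target_cell_type", "direction", "f_stat"]
    means = df.drop(columns=prov_cols)
    provenance = (
        df[prov_cols]
        .rename(columns={"target_cell_type": "cell_type"})
        .reset_index()
    )
    return ReferenceMatrix(means=means, provenance=provenance)
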