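"""Maternal-contamination QC.

Fetal-cell samples sorted from placental tissue can carry maternal DNA.
Because mother and fetus differ in genotype (and, for male fetuses, in sex
chromosomes), contamination leaves two quantifiable footprints on the array:

* at the 59 trimodal SNP probes, admixture of a discordant genotype pulls
  beta values away from the three genotype cluster centers (0.05/0.5/0.95);
* for male samples, maternal (female) DNA depresses the normalized
  Y-chromosome intensity in direct proportion to the contaminating fraction.

The workflow: infer sex from normalized Y intensity, score each sample by its
mean SNP-probe displacement, anchor a contamination scale on male samples
(where 1 - y_norm/y_male_reference measures the maternal fraction directly),
regress that scale on the SNP score, and apply the fitted line to female
samples.  Samples with estimated contamination >= 0.35 fail QC.  Genotype
matching on the same SNP probes verifies that cell fractions and their
matched villi come from the same donor.

The SNP outlier score is a mean absolute distance to the nearest cluster
center -- a monotone surrogate for an outlier probability; the male-trained
linear model absorbs its scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet, ValidationError
from .simulate import SNP_CENTERS

#: samples with estimated contamination at or above this fraction fail QC
CONTAMINATION_THRESHOLD = 0.35

#: minimum number of usable SNP probes for a meaningful outlier score
MIN_SNP_PROBES = 10

#: pairwise genotype concordance at or above this assigns two samples to one
#: donor (unrelated donors with allele frequency 0.5 expect 0.375)
CONCORDANCE_THRESHOLD = 0.80


@dataclasses.dataclass
class ContaminationModel:
    """Male-trained linear map from SNP outlier score to contamination.

    ``y_female_ref`` is the background Y intensity (the female centroid):
    the Y signal a fully maternal sample would show.  The male contamination
    scale is (1 - y/y_male_ref) / (1 - y_female_ref/y_male_ref), which is 1
    exactly when y equals the background.
    """

    intercept: float
    slope: float
    y_male_ref: float
    y_female_ref: float
    n_males: int
    residual_sd: float

    def male_contamination(self, y_norm) -> np.ndarray:
        scale = 1.0 - self.y_female_ref / self.y_male_ref
        return np.clip((1.0 - np.asarray(y_norm, dtype=float) / self.y_male_ref) / scale, 0.0, 1.0)


def infer_sex(samples: SampleSheet) -> pd.DataFrame:
    """Call sample sex from normalized Y intensity by 2-centroid partition.

    The high-Y centroid is called male, the low-Y centroid female.  Samples
    farther than 3 within-cluster (robust) standard deviations from both
    centroids are flagged ``ambiguous`` -- the signature of a male sample
    diluted with female DNA.  Returns a frame with ``inferred_sex`` and a
    ``sex_mismatch`` flag against ``reported_sex`` (sample-mixup check).
    """
    df = samples.data
    for col in ("y_norm", "x_norm"):
        if col not in df.columns or df[col].isna().any():
            raise ValidationError(f"sex inference requires complete {col!r} values")
    y = df["y_norm"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError(
            "all y_norm values identical; cannot infer sex -- use reported_sex instead"
        )
    # deterministic 1-D 2-means, initialized at the extremes
    lo, hi = float(y.min()), float(y.max())
    for _ in range(100):
        assign_hi = np.abs(y - hi) < np.abs(y - lo)
        new_lo, new_hi = y[~assign_hi].mean(), y[assign_hi].mean()
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    # ambiguity is judged against robust cluster centers (medians) with a
    # MAD-based spread floored at 5% of the separation, so a lone intermediate
    # point cannot drag the center/spread toward itself, and ordinary
    # replicate noise inside a tight cluster is never "ambiguous"
    med_lo = float(np.median(y[~assign_hi])) if (~assign_hi).any() else lo
    med_hi = float(np.median(y[assign_hi])) if assign_hi.any() else hi
    floor = 0.05 * abs(med_hi - med_lo)
    spread = {}
    for label, center, members in (("lo", med_lo, y[~assign_hi]), ("hi", med_hi, y[assign_hi])):
        mad_sd = 1.4826 * np.median(np.abs(members - center)) if len(members) else 0.0
        spread[label] = max(mad_sd, floor) if len(members) > 1 else 0.0
    d_lo, d_hi = np.abs(y - med_lo), np.abs(y - med_hi)
    ambiguous = (d_lo > 3 * spread["lo"]) & (d_hi > 3 * spread["hi"])
    inferred = np.where(ambiguous, "ambiguous", np.where(assign_hi, "M", "F"))
    reported = df.get("reported_sex", pd.Series("unknown", index=df.index)).to_numpy()
    mismatch = (
        np.isin(reported, ("M", "F")) & np.isin(inferred, ("M", "F")) & (reported != inferred)
    )
    return pd.DataFrame(
        dict(sample_id=df["sample_id"], inferred_sex=inferred, y_norm=y,
             reported_sex=reported, sex_mismatch=mismatch)
    )


def snp_outlier_score(
    snp_beta: pd.DataFrame | BetaMatrix,
    genotype_centers: np.ndarray = SNP_CENTERS,
) -> pd.Series:
    """Mean absolute distance to the nearest genotype center, per sample.

    ``snp_beta`` holds beta values at SNP probes (probes x samples).  Pure
    genotypes score ~0; admixture of a discordant genotype shifts betas off
    the centers and raises the score monotonically with the mixing fraction.
    """
    df = snp_beta.data if isinstance(snp_beta, BetaMatrix) else snp_beta
    values = df.to_numpy(dtype=float)
    usable = (~np.isnan(values)).sum(axis=0)
    if np.any(usable < MIN_SNP_PROBES):
        bad = df.columns[np.argmin(usable)]
        raise ValidationError(
            f"sample {bad!r} has {usable.min()} usable SNP probes; need >= {MIN_SNP_PROBES}"
        )
    dist = np.abs(values[..., None] - np.asarray(genotype_centers)[None, None, :]).min(axis=2)
    return pd.Series(np.nanmean(dist, axis=0), index=df.columns, name="snp_outlier_score")


def fit_contamination_model(
    scores: pd.Series,
    y_norm: pd.Series,
    y_female_ref: float = 0.0,
) -> ContaminationModel:
    """Fit the score -> contamination line on inferred-male samples.

    The male Y reference is the median y_norm of the cleanest males (lowest
    SNP-score tertile), guarding against contaminated males polluting the
    anchor.  Per male,

        c_Y = clip((1 - y_norm/y_ref) / (1 - y_female_ref/y_ref), 0, 1),

    so a male diluted entirely with maternal DNA (y_norm at the female
    background ``y_female_ref``) reads c_Y = 1; with a zero background this
    reduces to 1 - y_norm/y_ref.  Ordinary least squares of c_Y on the SNP
    score gives the (intercept, slope) applied to female samples.
    """
    scores, y_norm = scores.align(y_norm, join="inner")
    n = len(scores)
    if n < 3:
        raise ValidationError(f"contamination model needs >= 3 male samples, got {n}")
    s = scores.to_numpy(dtype=float)
    if np.allclose(s, s[0]):
        raise ValidationError("SNP outlier scores are degenerate (zero variance)")
    order = np.argsort(s, kind="stable")
    n_clean = max(int(np.ceil(n / 3)), 1)
    y_ref = float(np.median(y_norm.to_numpy()[order[:n_clean]]))
    if y_ref <= 0:
        raise ValidationError("male reference y_norm is nonpositive")
    if y_female_ref >= y_ref:
        raise ValidationError("female background y_norm must lie below the male reference")
    model = ContaminationModel(
        intercept=0.0, slope=1.0, y_male_ref=y_ref, y_female_ref=float(y_female_ref),
        n_males=n, residual_sd=0.0,
    )
    c_y = model.male_contamination(y_norm.to_numpy(dtype=float))
    slope, intercept = np.polyfit(s, c_y, deg=1)
    resid = c_y - (intercept + slope * s)
    model.intercept = float(intercept)
    model.slope = float(slope)
    model.residual_sd = float(np.std(resid, ddof=2)) if n > 2 else 0.0
    return model


def estimate_contamination(
    samples: SampleSheet,
    snp_beta: pd.DataFrame | BetaMatrix,
    model: ContaminationModel | None = None,
    threshold: float = CONTAMINATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample contamination report.

    Males (and ambiguous-sex samples, which are males by construction when
    heavily contaminated) get the direct Y-intensity estimate
    clip(1 - y_norm/y_ref); females get the model prediction from their SNP
    score.  ``pass_qc`` is strict: True iff c < threshold.
    """
    sex = infer_sex(samples).set_index("sample_id")
    scores = snp_outlier_score(snp_beta)
    if model is None:
        males = sex.index[sex["inferred_sex"] == "M"]
        females = sex.index[sex["inferred_sex"] == "F"]
        background = float(sex.loc[females, "y_norm"].median()) if len(females) else 0.0
        model = fit_contamination_model(
            scores.loc[males], sex.loc[males, "y_norm"], y_female_ref=background
        )
    rows = []
    for sample_id in samples.sample_ids:
        inferred = sex.loc[sample_id, "inferred_sex"]
        score = float(scores.loc[sample_id])
        y = float(sex.loc[sample_id, "y_norm"])
        if inferred == "F":
            c = model.intercept + model.slope * score
        else:
            c = model.male_contamination(y)
        c = float(np.clip(c, 0.0, 1.0))
        rows.append(
            dict(sample_id=sample_id, inferred_sex=inferred, snp_outlier_score=score,
                 y_norm=y, contamination=c, pass_qc=bool(c < threshold),
                 sex_mismatch=bool(sex.loc[sample_id, "sex_mismatch"]))
        )
    return pd.DataFrame(rows)


def genotype_calls(
    snp_beta: pd.DataFrame | BetaMatrix,
    genotype_centers: np.ndarray = SNP_CENTERS,
) -> pd.DataFrame:
    """Discretize SNP-probe betas to the nearest center: calls in {0, 1, 2}."""
    df = snp_beta.data if isinstance(snp_beta, BetaMatrix) else snp_beta
    values = df.to_numpy(dtype=float)
    calls = np.abs(values[..., None] - np.asarray(genotype_centers)[None, None, :]).argmin(axis=2)
    calls = np.where(np.isnan(values), -1, calls)
    return pd.DataFrame(calls, index=df.index, columns=df.columns, dtype=int)


def match_genotypes(
    snp_beta: pd.DataFrame | BetaMatrix,
    samples: SampleSheet | None = None,
    threshold: float = CONCORDANCE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise genotype concordance and donor assignment.

    Concordance between two samples is the fraction of SNP probes with
    identical discretized calls (missing calls excluded pairwise).  Samples
    joined by concordance >= threshold form one inferred donor group
    (connected components); where a sample sheet is given, samples whose
    inferred group disagrees with their sheet donor are flagged.
    Returns ``(concordance_matrix, assignment_table)``.
    """
    calls = genotype_calls(snp_beta).to_numpy().T  # samples x snps
    ids = list((snp_beta.data if isinstance(snp_beta, BetaMatrix) else snp_beta).columns)
    n = len(ids)
    if n < 2:
        raise ValidationError("genotype matching needs >= 2 samples")
    valid = calls >= 0
    conc = np.eye(n)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        agree = (calls[i] == calls[i + 1 :]) & both
        with np.errstate(invalid="ignore"):
            c = agree.sum(axis=1) / both.sum(axis=1)
        conc[i, i + 1 :] = conc[i + 1 :, i] = c
    conc_df = pd.DataFrame(conc, index=ids, columns=ids)

    # connected components over the >= threshold graph
    group = [-1] * n
    next_group = 0
    for i in range(n):
        if group[i] >= 0:
            continue
        stack, group[i] = [i], next_group
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(conc[u] >= threshold):
                if group[v] < 0:
                    group[v] = next_group
                    stack.append(v)
        next_group += 1
    assign = pd.DataFrame(dict(sample_id=ids, inferred_group=[f"G{g:03d}" for g in group]))
    if samples is not None:
        sheet = samples.data.set_index("sample_id")
        assign["donor_id"] = [sheet.loc[s, "donor_id"] if s in sheet.index else "" for s in ids]
        # a sheet donor must map onto exactly one inferred group and vice versa
        donor_groups = assign.groupby("donor_id")["inferred_group"].nunique()
        group_donors = assign.groupby("inferred_group")["donor_id"].nunique()
        assign["donor_mismatch"] = [
            bool(donor_groups.get(d, 0) > 1 or group_donors.get(g, 0) > 1)
            for d, g in zip(assign["donor_id"], assign["inferred_group"])
        ]
    return conc_df, assign
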