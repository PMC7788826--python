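"""EPIC-like synthetic dataset generator.

Emits beta matrices with the statistical structure the downstream analyses
assume: six sorted placental cell populations (trophoblast TB, Hofbauer HB,
endothelial EC, stromal SC, enzymatically separated syncytiotrophoblast eSTB,
nucleated red blood cells nRBC) sampled in two trimesters, plus bulk chorionic
villi (CV) mixtures of those populations.  Planted structure:

* cell-specific differentially methylated CpGs with a configurable mean shift
  (default |delta beta| = 0.30, above the 0.25 call threshold);
* gestational-age shifts (term vs first trimester) within each cell type;
* partially methylated domain (PMD) blocks: intermediate methylation in the
  trophoblast-like types, high methylation in the Hofbauer-like type;
* imprinted probes: intermediate (~0.5) in most cell types, unmethylated in
  HB/nRBC for the placental-specific category;
* repetitive-element probes with a planted Hofbauer hypermethylation shift;
* the EPIC array's 59 trimodal SNP probes, driven by per-donor genotypes;
* sex-dependent normalized X/Y intensity summaries;
* optional maternal-admixture contamination via :func:`simulate_contamination`.

Within-cell-type replicate noise is beta-distributed with concentration
``noise_precision`` (kappa): a replicate at a probe with cell mean mu is drawn
from Beta(mu*kappa, (1-mu)*kappa), which preserves the mean, respects the
[0, 1] support, and gives sd ~ 0.035 at mu = 0.5 for the default kappa = 200.
Setting kappa to ``numpy.inf`` switches noise off (replicates equal the mean).
All randomness flows from a single integer seed; regeneration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    GENE_CONTEXTS,
    ISLAND_CONTEXTS,
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)

#: beta-value cluster centers of the trimodal SNP probes (genotype 0/1/2)
SNP_CENTERS = np.array([0.05, 0.5, 0.95])

#: chorionic villi composition by trimester (fractions over the 6 cell types),
#: term eSTB-dominant and first-trimester SC-dominant
VILLI_COMPOSITION = {
    "first": {"TB": 0.16, "HB": 0.03, "EC": 0.03, "SC": 0.43, "eSTB": 0.35, "nRBC": 0.0},
    "term": {"TB": 0.20, "HB": 0.0234, "EC": 0.07, "SC": 0.12, "eSTB": 0.583, "nRBC": 0.0036},
}


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    ``n_probes`` is the probe budget; the planted feature classes (DMCs,
    gestational shifts, PMD blocks, imprints, repeats, SNPs) are assigned to
    disjoint probe sets and must fit within it.
    """

    cell_types: Sequence[str] = ("TB", "HB", "EC", "SC", "eSTB", "nRBC")
    n_replicates_per_type: int = 10
    n_probes: int = 20_000
    n_hypo_dmcs_per_type: int = 500
    n_hyper_dmcs_per_type: int = 300
    planted_delta_beta: float = 0.30
    noise_precision: float = 200.0
    n_pmd_blocks: int = 20
    pmd_block_size: int = 40
    n_imprint_probes: int = 200
    n_repeat_probes: int = 600
    repeat_hb_shift: float = 0.08
    n_snp_probes: int = 59
    n_gestational_dmcs_per_type: int = 100
    gestational_delta_beta: float = 0.10
    trimesters: Sequence[str] = ("first", "term")
    n_villi_per_trimester: int = 4
    contamination_fractions: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.planted_delta_beta <= 0.25:
            raise ConfigError("planted_delta_beta must exceed 0.25 (the DMC call threshold)")
        counts = {
            "n_replicates_per_type": self.n_replicates_per_type,
            "n_probes": self.n_probes,
            "n_hypo_dmcs_per_type": self.n_hypo_dmcs_per_type,
            "n_hyper_dmcs_per_type": self.n_hyper_dmcs_per_type,
            "n_pmd_blocks": self.n_pmd_blocks,
            "pmd_block_size": self.pmd_block_size,
            "n_imprint_probes": self.n_imprint_probes,
            "n_repeat_probes": self.n_repeat_probes,
            "n_snp_probes": self.n_snp_probes,
            "n_gestational_dmcs_per_type": self.n_gestational_dmcs_per_type,
            "n_villi_per_trimester": self.n_villi_per_trimester,
        }
        for name, value in counts.items():
            if value < 0 or (name in ("n_replicates_per_type", "n_probes") and value <= 0):
                raise ConfigError(f"{name} must be nonnegative (got {value})")
        if self.planted_budget() > self.n_probes:
            raise ConfigError(
                f"planted features need {self.planted_budget()} probes "
                f"but the budget is {self.n_probes}"
            )
        if self.noise_precision <= 0:
            raise ConfigError("noise_precision must be positive (numpy.inf disables noise)")

    def planted_budget(self) -> int:
        k = len(self.cell_types)
        return (
            k * (self.n_hypo_dmcs_per_type + self.n_hyper_dmcs_per_type)
            + k * self.n_gestational_dmcs_per_type
            + self.n_pmd_blocks * self.pmd_block_size
            + self.n_imprint_probes
            + self.n_repeat_probes
            + self.n_snp_probes
        )


@dataclasses.dataclass
class SimulationTruth:
    """Ground-truth labels for every probe and sample of a simulated dataset."""

    probes: pd.DataFrame  # probe_id, role, dmc_cell_type, dmc_direction, gest_cell_type
    samples: pd.DataFrame  # sample_id, donor_id, cell_type, trimester, sex, contamination
    genotypes: pd.DataFrame  # donors x SNP probes, calls in {0, 1, 2}
    cell_means: pd.DataFrame  # probes x "<cell>|<trimester>" population means (NaN at SNP probes)

    def dmc_probes(self, cell_type: str, direction: str | None = None) -> pd.Index:
        df = self.probes
        mask = (df["role"] == "dmc") & (df["dmc_cell_type"] == cell_type)
        if direction is not None:
            mask &= df["dmc_direction"] == direction
        return pd.Index(df.loc[mask, "probe_id"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probes": self.probes.to_dict(orient="list"),
            "samples": self.samples.to_dict(orient="list"),
            "genotypes": {
                "donors": list(self.genotypes.index),
                "snp_probes": list(self.genotypes.columns),
                "calls": self.genotypes.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload) + "\n")


@dataclasses.dataclass
class SimulatedDataset:
    beta: BetaMatrix
    samples: SampleSheet
    annotation: ProbeAnnotation
    truth: SimulationTruth
    config: SimulationConfig


def _truncated_beta(rng: np.random.Generator, a: float, b: float, lo: float, hi: float, size: int) -> np.ndarray:
    """Draw from Beta(a, b) restricted to [lo, hi] via inverse-CDF sampling."""
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size=size)
    return stats.beta.ppf(u, a, b)


def _beta_noise(rng: np.random.Generator, mean: np.ndarray, kappa: float) -> np.ndarray:
    if np.isinf(kappa):
        return mean.copy()
    mu = np.clip(mean, 1e-6, 1.0 - 1e-6)
    return rng.beta(mu * kappa, (1.0 - mu) * kappa)


def simulate_cell_profiles(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic dataset described by ``config``.

    Returns replicate-level beta values for every (cell type, trimester,
    donor) combination plus CV mixture samples, together with the sample
    sheet, probe annotation, and ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = list(config.cell_types)
    k = len(cells)
    g = config.n_probes
    trims = list(config.trimesters)

    probe_ids = np.array([f"cg{i:07d}" for i in range(g)])

    # --- assign disjoint probe roles ------------------------------------
    role = np.full(g, "baseline", dtype=object)
    dmc_cell = np.full(g, "", dtype=object)
    dmc_dir = np.full(g, "", dtype=object)
    gest_cell = np.full(g, "", dtype=object)
    imprint_cat = np.full(g, "none", dtype=object)
    repeat_cls = np.full(g, "none", dtype=object)

    # PMD blocks are contiguous probe runs (long genomic domains)
    cursor = 0
    pmd_idx = []
    for _ in range(config.n_pmd_blocks):
        pmd_idx.extend(range(cursor, cursor + config.pmd_block_size))
        cursor += config.pmd_block_size
    pmd_idx = np.array(pmd_idx, dtype=int)
    role[pmd_idx] = "pmd"

    free = np.setdiff1d(np.arange(g), pmd_idx)
    free = rng.permutation(free)
    ptr = 0

    def take(n: int) -> np.ndarray:
        nonlocal ptr
        out = free[ptr : ptr + n]
        ptr += n
        return np.sort(out)

    dmc_index: dict[tuple[str, str], np.ndarray] = {}
    for cell in cells:
        for direction, n in (("hypo", config.n_hypo_dmcs_per_type), ("hyper", config.n_hyper_dmcs_per_type)):
            idx = take(n)
            dmc_index[(cell, direction)] = idx
            role[idx] = "dmc"
            dmc_cell[idx] = cell
            dmc_dir[idx] = direction
    gest_index: dict[str, np.ndarray] = {}
    for cell in cells:
        idx = take(config.n_gestational_dmcs_per_type)
        gest_index[cell] = idx
        role[idx] = "gest_dmc"
        gest_cell[idx] = cell
    imprint_idx = take(config.n_imprint_probes)
    role[imprint_idx] = "imprint"
    half = config.n_imprint_probes // 2
    imprint_cat[imprint_idx[:half]] = "placental_specific"
    imprint_cat[imprint_idx[half:]] = "non_placental_specific"
    repeat_idx = take(config.n_repeat_probes)
    role[repeat_idx] = "repeat"
    repeat_cls[repeat_idx[: config.n_repeat_probes // 2]] = "Alu"
    repeat_cls[repeat_idx[config.n_repeat_probes // 2 :]] = "LINE1"
    snp_idx = take(config.n_snp_probes)
    role[snp_idx] = "snp"

    # --- population cell means ------------------------------------------
    # bimodal baseline: unmethylated mode near 0.1, methylated mode near 0.85
    low_mode = rng.random(g) < 0.5
    baseline = np.where(low_mode, rng.beta(2.0, 18.0, size=g), rng.beta(17.0, 3.0, size=g))

    delta = config.planted_delta_beta
    # planted DMC probes get a baseline drawn from the mode that leaves room
    # for the full shift, so clipping never erodes the planted effect
    for (cell, direction), idx in dmc_index.items():
        if direction == "hypo":
            baseline[idx] = _truncated_beta(rng, 17.0, 3.0, delta + 0.05, 0.95, len(idx))
        else:
            baseline[idx] = _truncated_beta(rng, 2.0, 18.0, 0.05, 0.95 - delta, len(idx))
    for cell, idx in gest_index.items():
        baseline[idx] = _truncated_beta(rng, 2.0, 18.0, 0.05, 0.85 - config.gestational_delta_beta, len(idx))
    baseline[repeat_idx] = _truncated_beta(rng, 17.0, 3.0, 0.5, 0.99 - config.repeat_hb_shift, len(repeat_idx))

    # means[trimester][cell] -> vector of per-probe population means
    means: dict[str, dict[str, np.ndarray]] = {}
    pmd_levels = {
        "TB": (0.30, 0.60), "eSTB": (0.30, 0.60),
        "EC": (0.55, 0.75), "SC": (0.55, 0.75),
        "HB": (0.80, 0.95), "nRBC": (0.80, 0.95),
    }
    pmd_draws = {
        cell: rng.uniform(*pmd_levels.get(cell, (0.55, 0.75)), size=len(pmd_idx)) for cell in cells
    }
    imprint_low = {"HB", "nRBC"}
    for trim in trims:
        means[trim] = {}
        for cell in cells:
            mu = baseline.copy()
            for direction, sign in (("hypo", -1.0), ("hyper", +1.0)):
                idx = dmc_index[(cell, direction)]
                mu[idx] = baseline[idx] + sign * delta
            if trim == "term":
                idx = gest_index[cell]
                mu[idx] = baseline[idx] + config.gestational_delta_beta
            mu[pmd_idx] = pmd_draws[cell]
            plac = imprint_idx[:half]
            nonplac = imprint_idx[half:]
            mu[plac] = 0.05 if cell in imprint_low else 0.5
            mu[nonplac] = 0.5
            if cell == "HB":
                mu[repeat_idx] = baseline[repeat_idx] + config.repeat_hb_shift
            means[trim][cell] = np.clip(mu, 0.01, 0.99)

    # --- donors, genotypes, sexes ---------------------------------------
    n_rep = config.n_replicates_per_type
    donors = {trim: [f"{trim[0].upper()}D{j + 1:02d}" for j in range(n_rep)] for trim in trims}
    all_donors = [d for trim in trims for d in donors[trim]]
    genotypes = pd.DataFrame(
        rng.binomial(2, 0.5, size=(len(all_donors), config.n_snp_probes)),
        index=all_donors,
        columns=probe_ids[snp_idx],
    )
    donor_sex = {d: ("M" if i % 2 == 0 else "F") for i, d in enumerate(all_donors)}

    # --- draw samples -----------------------------------------------------
    kappa = config.noise_precision
    columns: dict[str, np.ndarray] = {}
    rows = []

    def intensities(sex: str) -> tuple[float, float, float]:
        if sex == "M":
            y = max(rng.normal(1.0, 0.02), 0.0)
            x = max(rng.normal(0.55, 0.02), 0.0)
        else:
            y = max(rng.normal(0.10, 0.01), 0.0)
            x = max(rng.normal(1.0, 0.02), 0.0)
        return x, y, max(rng.normal(1.0, 0.02), 0.0)

    for trim in trims:
        for cell in cells:
            for donor in donors[trim]:
                sample_id = f"{cell}_{trim}_{donor}"
                mu = means[trim][cell].copy()
                if config.n_snp_probes:
                    mu[snp_idx] = SNP_CENTERS[genotypes.loc[donor].to_numpy()]
                columns[sample_id] = _beta_noise(rng, mu, kappa)
                x, y, auto = intensities(donor_sex[donor])
                rows.append(
                    dict(sample_id=sample_id, donor_id=donor, cell_type=cell, trimester=trim,
                         reported_sex=donor_sex[donor], x_norm=x, y_norm=y, autosomal_intensity=auto)
                )
        comp = VILLI_COMPOSITION.get(trim, VILLI_COMPOSITION["term"])
        w = np.array([comp.get(cell, 0.0) for cell in cells])
        w = w / w.sum()
        for donor in donors[trim][: config.n_villi_per_trimester]:
            sample_id = f"CV_{trim}_{donor}"
            mu = sum(w[i] * means[trim][cell] for i, cell in enumerate(cells))
            if config.n_snp_probes:
                mu[snp_idx] = SNP_CENTERS[genotypes.loc[donor].to_numpy()]
            columns[sample_id] = _beta_noise(rng, mu, kappa)
            x, y, auto = intensities(donor_sex[donor])
            rows.append(
                dict(sample_id=sample_id, donor_id=donor, cell_type="CV", trimester=trim,
                     reported_sex=donor_sex[donor], x_norm=x, y_norm=y, autosomal_intensity=auto)
            )

    beta = BetaMatrix(pd.DataFrame(columns, index=probe_ids))
    sheet_df = pd.DataFrame(rows)
    contamination = pd.Series(0.0, index=sheet_df["sample_id"])

    # --- annotation -------------------------------------------------------
    n_chroms = 22
    chrom_of = np.array([f"chr{(i % n_chroms) + 1}" for i in np.arange(g) // max(g // n_chroms, 1)])
    chrom_of = chrom_of[:g]
    pos = np.zeros(g, dtype=int)
    for chrom in np.unique(chrom_of):
        sel = chrom_of == chrom
        pos[sel] = 1000 + 500 * np.arange(sel.sum())
    island = rng.choice(ISLAND_CONTEXTS, size=g, p=(0.2, 0.2, 0.1, 0.5))
    gene_ctx = rng.choice(GENE_CONTEXTS, size=g, p=(0.15, 0.05, 0.10, 0.30, 0.05, 0.35))
    # PMD probes are mostly outside islands/shores/promoters, matching the
    # coverage-bias filter applied before PMD binning
    island[pmd_idx] = rng.choice(ISLAND_CONTEXTS, size=len(pmd_idx), p=(0.05, 0.05, 0.1, 0.8))
    gene_ctx[pmd_idx] = rng.choice(("intron", "intergenic"), size=len(pmd_idx), p=(0.45, 0.55))
    genes = np.full(g, "", dtype=object)
    promoter_idx = rng.permutation(np.flatnonzero(gene_ctx == "promoter"))
    gi, p = 0, 0
    while p < len(promoter_idx):
        size = int(rng.integers(1, 9))
        genes[promoter_idx[p : p + size]] = f"GENE{gi:05d}"
        gi += 1
        p += size
    annotation = ProbeAnnotation(
        pd.DataFrame(
            dict(
                probe_id=probe_ids, chrom=chrom_of, pos=pos,
                island_context=island, gene_context=gene_ctx, gene=genes,
                enhancer=rng.random(g) < 0.1, pmd=np.isin(np.arange(g), pmd_idx),
                imprint_category=imprint_cat, repeat_class=repeat_cls,
                snp_probe=np.isin(np.arange(g), snp_idx),
            )
        )
    )

    cell_means = pd.DataFrame(
        {f"{cell}|{trim}": means[trim][cell] for trim in trims for cell in cells},
        index=probe_ids,
    )
    cell_means.iloc[snp_idx] = np.nan  # SNP means are donor-specific

    truth = SimulationTruth(
        probes=pd.DataFrame(
            dict(probe_id=probe_ids, role=role, dmc_cell_type=dmc_cell,
                 dmc_direction=dmc_dir, gest_cell_type=gest_cell)
        ),
        samples=pd.DataFrame(
            dict(sample_id=sheet_df["sample_id"], donor_id=sheet_df["donor_id"],
                 cell_type=sheet_df["cell_type"], trimester=sheet_df["trimester"],
                 sex=sheet_df["reported_sex"], contamination=contamination.to_numpy())
        ),
        genotypes=genotypes,
        cell_means=cell_means,
    )
    dataset = SimulatedDataset(beta, SampleSheet(sheet_df), annotation, truth, config)

    if config.contamination_fractions:
        contaminate_samples(dataset, dict(config.contamination_fractions), rng)
    return dataset


def simulate_villi(
    profiles: BetaMatrix,
    composition: pd.DataFrame,
    noise_precision: float = np.inf,
    seed: int | None = None,
) -> BetaMatrix:
    """Mix cell-type mean profiles into bulk villi samples.

    ``profiles`` holds one column of mean beta per cell type; ``composition``
    is mixtures x cell types, each row on the simplex.  The villi sample is
    the weighted sum of profiles plus beta-distributed noise.
    """
    w = composition[list(profiles.sample_ids)].to_numpy(dtype=float)
    row_sums = w.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-8):
        bad = composition.index[np.argmax(np.abs(row_sums - 1.0))]
        raise ValidationError(f"composition row {bad!r} sums to {row_sums.max():.10f}, not 1")
    if np.any(w < 0):
        raise ValidationError("composition weights must be nonnegative")
    rng = np.random.default_rng(seed)
    mixed = profiles.values @ w.T
    mixed = _beta_noise(rng, mixed, noise_precision)
    return BetaMatrix(
        pd.DataFrame(mixed, index=profiles.probe_ids, columns=[str(i) for i in composition.index])
    )


def simulate_contamination(sample_beta, maternal_beta, c: float):
    """Linear maternal admixture: beta_obs = (1-c)*sample + c*maternal.

    Works elementwise on arrays/Series (betas) and on scalars (intensity
    summaries such as ``y_norm``).
    """
    if not 0.0 <= c <= 1.0:
        raise ValidationError(f"contamination fraction must be in [0, 1], got {c}")
    return (1.0 - c) * sample_beta + c * maternal_beta


@dataclasses.dataclass
class MaternalProfile:
    """A maternal (somatic, female) profile used as the contaminating source."""

    beta: pd.Series
    genotype: np.ndarray
    y_norm: float
    x_norm: float
    sex: str = "F"


def simulate_maternal_profile(
    dataset: SimulatedDataset,
    donor_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> MaternalProfile:
    """Build a maternal profile consistent with a simulated dataset.

    Somatic-like methylome: stromal-cell mean profile with fully methylated
    PMD probes, a maternal genotype at the SNP probes, and female intensity
    summaries.  When ``donor_id`` is given, the maternal genotype shares one
    allele per SNP with that donor's fetal genotype (the fetus inherited one
    maternal allele), so mother and fetus are never opposite homozygotes --
    the configuration a real contaminating mother presents.  Without a donor
    the genotype is drawn independently (an unrelated female).
    """
    rng = rng or np.random.default_rng(dataset.config.seed + 104729)
    cfg = dataset.config
    trim = cfg.trimesters[0]
    base_cell = "SC" if "SC" in cfg.cell_types else cfg.cell_types[0]
    mu = dataset.truth.cell_means[f"{base_cell}|{trim}"].to_numpy().copy()
    probes = dataset.truth.probes
    mu[(probes["role"] == "pmd").to_numpy()] = 0.88
    if donor_id is None:
        genotype = rng.binomial(2, 0.5, size=cfg.n_snp_probes)
    else:
        fetal = dataset.truth.genotypes.loc[donor_id].to_numpy()
        # transmitted allele: forced for fetal homozygotes, coin flip for hets
        transmitted = np.where(fetal == 1, rng.integers(0, 2, size=len(fetal)), fetal // 2)
        genotype = transmitted + rng.integers(0, 2, size=len(fetal))
    mu[(probes["role"] == "snp").to_numpy()] = SNP_CENTERS[genotype]
    beta = pd.Series(mu, index=dataset.beta.probe_ids)
    return MaternalProfile(beta=beta, genotype=genotype, y_norm=0.10, x_norm=1.0)


def contaminate_samples(
    dataset: SimulatedDataset,
    fractions: Mapping[str, float],
    rng: np.random.Generator | None = None,
) -> None:
    """Admix each named sample with its own donor's maternal profile.

    Mutates the dataset in place: beta values, x/y intensity summaries and
    the truth table's contamination column.  One maternal profile is built
    per donor (a mother contaminates only her own pregnancy's samples).
    """
    rng = rng or np.random.default_rng(dataset.config.seed + 104729)
    sheet = dataset.samples.data.set_index("sample_id")
    maternal_cache: dict[str, MaternalProfile] = {}
    for sample_id, c in fractions.items():
        if sample_id not in dataset.beta.sample_ids:
            raise ConfigError(f"contamination fractions name unknown sample {sample_id!r}")
        donor = sheet.loc[sample_id, "donor_id"]
        if donor not in maternal_cache:
            maternal_cache[donor] = simulate_maternal_profile(dataset, donor_id=donor, rng=rng)
        maternal = maternal_cache[donor]
        dataset.beta.data[sample_id] = simulate_contamination(
            dataset.beta.data[sample_id], maternal.beta, c
        )
        sheet.loc[sample_id, "y_norm"] = simulate_contamination(
            sheet.loc[sample_id, "y_norm"], maternal.y_norm, c
        )
        sheet.loc[sample_id, "x_norm"] = simulate_contamination(
            sheet.loc[sample_id, "x_norm"], maternal.x_norm, c
        )
        dataset.truth.samples.loc[
            dataset.truth.samples["sample_id"] == sample_id, "contamination"
        ] = c
    dataset.samples = SampleSheet(sheet.reset_index())
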