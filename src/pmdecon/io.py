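"""Readers, writers and validated containers for on-disk artifacts.

All analyses operate on beta values (methylation fraction at a CpG,
methylated / total signal, in [0, 1]).  Three tabular artifacts circulate
between pipeline stages:

* a **beta matrix** -- TSV, probes x samples, empty cell = missing;
* a **sample sheet** -- CSV with one row per sample (cell type, trimester,
  donor, sex, and optional normalized X/Y/autosomal intensity summaries);
* a **probe annotation** -- TSV with one row per probe (genomic position and
  context flags used by the enrichment and region-summary stages).

Probe positions are 1-based (array-manifest convention).  BED region files
are 0-based half-open; the conversion happens exactly once, inside
:func:`read_region_bed` / :class:`RegionSet`.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

CELL_TYPES = ("CV", "TB", "HB", "EC", "SC", "eSTB", "nRBC", "mixture")
TRIMESTERS = ("first", "term")
SEXES = ("M", "F", "unknown")
ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")
GENE_CONTEXTS = ("promoter", "5utr", "exon", "intron", "3utr", "intergenic")
IMPRINT_CATEGORIES = ("none", "placental_specific", "non_placental_specific")
REPEAT_CLASSES = ("none", "Alu", "LINE1")

#: tolerance for beta values slightly outside [0, 1] from float formatting
BETA_TOL = 1e-9


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


class ValidationError(ValueError):
    """A parsed artifact violates a domain invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Series(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise FormatError(f"duplicate {what} id(s): {', '.join(map(str, dups.index[:5]))}")


@dataclasses.dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions.

    ``data`` is a float DataFrame indexed by probe id with sample ids as
    columns; NaN marks a missing measurement.  Construction validates
    uniqueness of ids and the [0, 1] bounds.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "probe")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy(dtype=float)
        bad = (values < -BETA_TOL) | (values > 1.0 + BETA_TOL)
        if np.any(np.nan_to_num(bad, nan=False)):
            r, c = np.argwhere(np.where(np.isnan(values), False, bad))[0]
            raise FormatError(
                f"beta value {values[r, c]!r} outside [0, 1] at probe "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_probes(self, probes: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(probes)])

    def subset_samples(self, samples: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.data[list(samples)])


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a TSV beta matrix (header ``probe_id<TAB>sample1...``).

    Empty cells become missing values.  Non-numeric cells and out-of-bounds
    values are rejected with the coordinates of the offending cell.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    if raw.index.name is None or raw.shape[1] == 0:
        raise FormatError(f"{path}: expected a header row 'probe_id<TAB>sample1<TAB>...'")
    _check_unique(list(raw.index), "probe")
    _check_unique(list(raw.columns), "sample")
    numeric = raw.apply(lambda col: pd.to_numeric(col.str.strip(), errors="coerce"))
    bad = numeric.isna() & (raw.apply(lambda col: col.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at probe "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    return BetaMatrix(numeric)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.6g", na_rep="")


@dataclasses.dataclass
class SampleSheet:
    """Per-sample metadata table.

    Mandatory columns: ``sample_id``, ``cell_type``, ``trimester``.  Optional:
    ``donor_id`` (defaults to the sample id), ``reported_sex`` (defaults to
    ``unknown``) and nonnegative intensity summaries ``x_norm``, ``y_norm``,
    ``autosomal_intensity``.
    """

    data: pd.DataFrame

    MANDATORY = ("sample_id", "cell_type", "trimester")
    INTENSITY = ("x_norm", "y_norm", "autosomal_intensity")

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in self.MANDATORY if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet lacks mandatory column(s): {', '.join(missing)}")
        _check_unique(list(df["sample_id"]), "sample")
        bad_ct = sorted(set(df["cell_type"]) - set(CELL_TYPES))
        if bad_ct:
            raise ValidationError(
                f"unknown cell_type label(s) {bad_ct}; allowed: {list(CELL_TYPES)}"
            )
        bad_tri = sorted(set(df["trimester"]) - set(TRIMESTERS))
        if bad_tri:
            raise ValidationError(
                f"unknown trimester label(s) {bad_tri}; allowed: {list(TRIMESTERS)}"
            )
        if "donor_id" not in df.columns:
            df["donor_id"] = df["sample_id"]
        if "reported_sex" not in df.columns:
            df["reported_sex"] = "unknown"
        bad_sex = sorted(set(df["reported_sex"].fillna("unknown")) - set(SEXES))
        if bad_sex:
            raise ValidationError(f"unknown reported_sex label(s) {bad_sex}; allowed: {list(SEXES)}")
        for col in self.INTENSITY:
            if col in df.columns:
                vals = pd.to_numeric(df[col], errors="raise")
                if (vals.dropna() < 0).any():
                    raise ValidationError(f"column {col} must be nonnegative")
                df[col] = vals
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def samples_of(self, cell_type: str, trimester: str | None = None) -> list[str]:
        df = self.data
        mask = df["cell_type"] == cell_type
        if trimester is not None:
            mask &= df["trimester"] == trimester
        return list(df.loc[mask, "sample_id"])

    def resolve(self, beta: BetaMatrix) -> None:
        """Require every beta-matrix sample id to be present in the sheet."""
        unknown = set(beta.sample_ids) - set(self.sample_ids)
        if unknown:
            raise ValidationError(f"beta matrix samples missing from sheet: {sorted(unknown)[:5]}")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index=False, float_format="%.6g")


@dataclasses.dataclass
class ProbeAnnotation:
    """Per-probe genomic context table (one row per probe).

    Columns: probe_id, chrom, pos (1-based), island_context, gene_context,
    gene (empty when not promoter-associated), enhancer, pmd,
    imprint_category, repeat_class, snp_probe.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = ["probe_id", "chrom", "pos", "island_context", "gene_context"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"annotation lacks column(s): {', '.join(missing)}")
        _check_unique(list(df["probe_id"]), "probe")
        for col, allowed in (
            ("island_context", ISLAND_CONTEXTS),
            ("gene_context", GENE_CONTEXTS),
        ):
            bad = sorted(set(df[col]) - set(allowed))
            if bad:
                raise ValidationError(f"unknown {col} value(s) {bad}; allowed: {list(allowed)}")
        if "imprint_category" in df.columns:
            bad = sorted(set(df["imprint_category"]) - set(IMPRINT_CATEGORIES))
            if bad:
                raise ValidationError(f"unknown imprint_category value(s) {bad}")
        if "repeat_class" in df.columns:
            bad = sorted(set(df["repeat_class"]) - set(REPEAT_CLASSES))
            if bad:
                raise ValidationError(f"unknown repeat_class value(s) {bad}")
        for col, default in (
            ("gene", ""),
            ("enhancer", False),
            ("pmd", False),
            ("imprint_category", "none"),
            ("repeat_class", "none"),
            ("snp_probe", False),
        ):
            if col not in df.columns:
                df[col] = default
        for flag in ("enhancer", "pmd", "snp_probe"):
            df[flag] = df[flag].astype(bool)
        df["gene"] = df["gene"].fillna("").astype(str)
        df["pos"] = df["pos"].astype(int)
        self.data = df.set_index("probe_id", drop=False)

    def context_mask(self, column: str, value) -> pd.Series:
        return self.data[column] == value


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    for flag in ("enhancer", "pmd", "snp_probe"):
        if flag in df.columns:
            df[flag] = df[flag].astype(str).str.lower().isin(("true", "1"))
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.data.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class RegionSet:
    """A labelled set of genomic intervals (stored 0-based half-open)."""

    label: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in self.intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Containment test for a 1-based probe position."""
        tree = self._trees.get(chrom)
        return bool(tree.overlaps_point(pos_1based - 1)) if tree is not None else False

    def probe_mask(self, annotation: ProbeAnnotation) -> pd.Series:
        df = annotation.data
        return pd.Series(
            [self.contains(c, p) for c, p in zip(df["chrom"], df["pos"])],
            index=df.index,
            name=self.label,
        )


def read_region_bed(path: str | Path, label: str) -> RegionSet:
    """Read a 3+ column BED file (0-based half-open) into a :class:`RegionSet`."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has {len(fields)} column(s), need >= 3")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            intervals.append((chrom, start, end))
    return RegionSet(label=label, intervals=intervals)


def write_run_report(path: str | Path, **payload) -> None:
    """Write the JSON run report emitted by every CLI invocation."""
    import pmdecon

    payload.setdefault("pmdecon_version", pmdecon.__version__)
    payload.setdefault("numpy_version", np.__version__)
    payload.setdefault("pandas_version", pd.__version__)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
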