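"""In-silico mixture benchmark for the deconvolution estimators.

Known compositions are drawn by a recursive-uniform scheme: within a block,
the first proportion is U(0, 1) and each subsequent one is uniform on
(0, previous).  Because this biases later positions toward small values, the
whole block is repeated once per cell type with the starting position
rotated, and every row is normalized onto the simplex.  With 6 cell types and
250 rows per rotation this yields the canonical 1500 mixtures.  Mixtures are
then assembled from individual cell-sample profiles (one randomly chosen
donor sample per cell type, injecting realistic biological noise) or from
cell-type mean profiles, and each estimator is scored per cell type by R^2
(squared Pearson correlation), RMSE, MAE and mean bias.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet, ValidationError
from .reference import NON_CELL_LABELS


@dataclasses.dataclass
class MixtureDesign:
    """True mixing proportions: mixtures x cell types, rows on the simplex."""

    proportions: pd.DataFrame
    rotations: np.ndarray  # start-rotation index per row
    first_draws: np.ndarray  # pre-normalization first uniform draw per row
    seed: int | None = None

    def __post_init__(self) -> None:
        w = self.proportions.to_numpy()
        if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-12):
            raise ValidationError("mixture design rows must sum to 1 within 1e-12")

    @property
    def cell_types(self) -> list[str]:
        return list(self.proportions.columns)


def sample_mixture_proportions(
    cell_types=("TB", "HB", "EC", "SC", "eSTB", "nRBC"),
    n_per_block: int = 250,
    seed: int | None = None,
    mode: str = "draw_all",
) -> MixtureDesign:
    """Draw the rotated recursive-uniform mixture design.

    ``mode="draw_all"`` (default) draws all K proportions recursively and
    normalizes.  ``mode="remainder"`` draws K-1 and assigns the remainder to
    the last cell type of the rotation, discarding rows where the remainder
    would be negative.
    """
    if isinstance(cell_types, int):
        cell_types = [f"ct{i + 1}" for i in range(cell_types)]
    cells = list(cell_types)
    k = len(cells)
    if k < 2:
        raise ValidationError("need >= 2 cell types")
    if mode not in ("draw_all", "remainder"):
        raise ValidationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    blocks, rotations, first_draws = [], [], []
    for r in range(k):
        n_draws = k if mode == "draw_all" else k - 1
        u = rng.random((n_per_block, n_draws))
        q = np.cumprod(u, axis=1)  # q_j = u_1 * ... * u_j, i.e. q_j ~ U(0, q_{j-1})
        if mode == "remainder":
            remainder = 1.0 - q.sum(axis=1, keepdims=True)
            keep = remainder.ravel() >= 0
            q = np.hstack([q, remainder])[keep]
            u = u[keep]
        w = q / q.sum(axis=1, keepdims=True)
        # position j of the draw goes to cell (r + j) mod k
        block = np.empty_like(w)
        for j in range(k):
            block[:, (r + j) % k] = w[:, j]
        blocks.append(block)
        rotations.extend([r] * len(block))
        first_draws.extend(u[:, 0].tolist())
    proportions = pd.DataFrame(
        np.vstack(blocks),
        columns=cells,
        index=pd.RangeIndex(sum(len(b) for b in blocks), name="mixture_id"),
    )
    return MixtureDesign(
        proportions=proportions,
        rotations=np.asarray(rotations),
        first_draws=np.asarray(first_draws),
        seed=seed,
    )


def build_insilico_mixtures(
    cell_beta: BetaMatrix,
    samples: SampleSheet,
    design: MixtureDesign,
    seed: int | None = None,
    use_means: bool = False,
) -> BetaMatrix:
    """Assemble bulk profiles from cell samples under a mixture design.

    Per mixture, one donor sample per cell type is drawn uniformly at random
    (seeded) and the bulk beta is the weight-combination of those profiles.
    ``use_means=True`` mixes the per-cell-type mean profile instead.
    """
    rng = np.random.default_rng(seed)
    df = samples.data
    pools: dict[str, list[str]] = {}
    for cell in design.cell_types:
        ids = [
            s for s in df.loc[df["cell_type"] == cell, "sample_id"] if s in set(cell_beta.sample_ids)
        ]
        if not ids:
            raise ValidationError(f"no samples of cell type {cell!r} available for mixing")
        pools[cell] = ids
    w = design.proportions.to_numpy()
    n_mix = len(design.proportions)
    out = np.zeros((len(cell_beta.probe_ids), n_mix))
    for j, cell in enumerate(design.cell_types):
        if use_means:
            profile = cell_beta.data[pools[cell]].mean(axis=1).to_numpy()
            out += profile[:, None] * w[:, j][None, :]
        else:
            choice = rng.integers(0, len(pools[cell]), size=n_mix)
            cols = cell_beta.data[pools[cell]].to_numpy()
            out += cols[:, choice] * w[:, j][None, :]
    names = [f"mix{int(i):05d}" for i in design.proportions.index]
    return BetaMatrix(pd.DataFrame(out, index=cell_beta.probe_ids, columns=names))


@dataclasses.dataclass
class BenchmarkResult:
    """Per-cell-type and pooled agreement between estimates and truth."""

    per_cell_type: pd.DataFrame  # cell_type, r2, rmse, mae, bias
    overall: dict  # pooled r2, rmse, mae, bias
    method: str = ""

    def __post_init__(self) -> None:
        tbl = self.per_cell_type
        ok = tbl.dropna(subset=["rmse", "mae"])
        if ((ok["rmse"] + 1e-12) < ok["mae"]).any() or (ok["mae"] < -1e-12).any():
            raise ValidationError("metric invariant violated: need RMSE >= MAE >= 0")


def _metrics(est: np.ndarray, true: np.ndarray) -> dict:
    err = est - true
    out = dict(
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        bias=float(np.mean(err)),
    )
    if np.std(true) == 0 or np.std(est) == 0:
        out["r2"] = float("nan")
    else:
        out["r2"] = float(np.corrcoef(est, true)[0, 1] ** 2)
    return out


def evaluate(estimates: pd.DataFrame, truth: pd.DataFrame, method: str = "") -> BenchmarkResult:
    """Score composition estimates against a known design.

    ``estimates`` and ``truth`` are mixtures x cell types frames with aligned
    ids (order-insensitive).  R^2 is the squared Pearson correlation; a
    zero-variance truth column yields a missing R^2 for that cell type.
    """
    est = estimates.copy()
    est.index = [str(i) for i in est.index]
    tru = truth.copy()
    tru.index = [str(i) for i in tru.index]
    if set(est.index) != set(tru.index):
        # mixture ids may be prefixed sample names (mixNNNNN); align by order
        if len(est) != len(tru):
            raise ValidationError("estimates and truth have mismatched mixtures")
        tru.index = est.index
    tru = tru.loc[est.index, est.columns]
    rows = []
    for cell in est.columns:
        rows.append(dict(cell_type=cell, **_metrics(est[cell].to_numpy(), tru[cell].to_numpy())))
    overall = _metrics(est.to_numpy().ravel(), tru.to_numpy().ravel())
    return BenchmarkResult(per_cell_type=pd.DataFrame(rows), overall=overall, method=method)


def run_benchmark(
    cell_beta: BetaMatrix,
    samples: SampleSheet,
    ref,
    methods=("cp", "rpc", "cbs"),
    n_per_block: int = 250,
    seed: int | None = None,
    use_means: bool = False,
) -> tuple[MixtureDesign, dict[str, BenchmarkResult], dict[str, pd.DataFrame]]:
    """Full benchmark: design -> mixtures -> deconvolve -> evaluate.

    Mixtures are built on the reference probes only (deconvolution uses no
    others, and the weighted sum at any probe subset equals the subset of the
    full weighted sum).  Returns (design, {method: result}, {method: estimates}).
    """
    from .deconvolve import deconvolve

    cell_only = samples.data[~samples.data["cell_type"].isin(NON_CELL_LABELS)]
    sheet = SampleSheet(cell_only.reset_index(drop=True))
    design = sample_mixture_proportions(
        cell_types=list(ref.cell_types), n_per_block=n_per_block, seed=seed
    )
    shared = [p for p in ref.probe_ids if p in set(cell_beta.probe_ids)]
    sub = BetaMatrix(cell_beta.data.loc[shared])
    mixtures = build_insilico_mixtures(sub, sheet, design, seed=seed, use_means=use_means)
    results, estimates = {}, {}
    for method in methods:
        props = deconvolve(mixtures, ref, method=method).proportions
        estimates[method] = props
        results[method] = evaluate(props, design.proportions, method=method)
    return design, results, estimates
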