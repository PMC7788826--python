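"""Reference-based cellular deconvolution.

A bulk methylation profile y (betas at the reference probes) is modelled as a
weighted sum of cell-type signatures R: y = R w + e, with weights w on the
simplex.  Three estimators are provided:

* **CP** (constrained projection): the exact nonnegative least-squares
  solution under sum(w) = 1 (or <= 1), solved as a quadratic program by
  active-set enumeration with KKT verification -- exact for the small number
  of cell types used here;
* **RPC** (robust partial correlations): Huber M-estimation (tuning constant
  1.345, IRLS) of the unconstrained regression, followed by truncation of
  negative coefficients and renormalization to the simplex;
* **CBS** (CIBERSORT-style): linear nu-SVR on row-standardized features over
  a nu grid, choosing the nu whose fit has the lowest RMSE, then truncation
  and renormalization.

Probes missing in a sample are dropped per sample (pairwise deletion).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import NuSVR
from statsmodels.robust.norms import HuberT
from statsmodels.robust.robust_linear_model import RLM

from .io import BetaMatrix, ValidationError
from .reference import ReferenceMatrix

#: Huber tuning constant: 95% efficiency under Gaussian errors
HUBER_C = 1.345

#: default nu grid for the CBS support-vector regression
NU_GRID = (0.25, 0.5, 0.75)

METHODS = ("cp", "rpc", "cbs")


class DeconvolutionError(ValueError):
    """Deconvolution cannot proceed on the given inputs."""


def _check_reference(ref: np.ndarray, columns) -> None:
    if np.linalg.matrix_rank(ref) < ref.shape[1]:
        corr = np.corrcoef(ref.T)
        pairs = [
            f"{columns[i]}~{columns[j]}"
            for i in range(len(columns))
            for j in range(i + 1, len(columns))
            if abs(corr[i, j]) > 0.9999
        ]
        raise DeconvolutionError(
            "reference matrix is rank-deficient"
            + (f"; collinear cell-type columns: {', '.join(pairs)}" if pairs else "")
        )


def deconvolve_cp(
    y: np.ndarray,
    ref: np.ndarray,
    constraint: str = "equality",
    columns=None,
) -> np.ndarray:
    """Constrained-projection weights: argmin ||y - R w||^2, w >= 0.

    ``constraint="equality"`` enforces sum(w) = 1 exactly;
    ``constraint="inequality"`` enforces sum(w) <= 1.  Solved exactly: every
    support set's equality-constrained KKT system is solved and the solution
    satisfying primal and dual feasibility is returned.
    """
    y = np.asarray(y, dtype=float)
    ref = np.asarray(ref, dtype=float)
    k = ref.shape[1]
    columns = list(columns) if columns is not None else list(range(k))
    _check_reference(ref, columns)
    if constraint not in ("equality", "inequality"):
        raise DeconvolutionError(f"unknown constraint {constraint!r}")

    if constraint == "inequality":
        w, _ = nnls(ref, y)
        if w.sum() <= 1.0 + 1e-12:
            return w
        # the sum constraint is active; fall through to the equality solve

    gram = 2.0 * ref.T @ ref
    lin = 2.0 * ref.T @ y
    best_w, best_obj = None, np.inf
    for size in range(1, k + 1):
        for support in itertools.combinations(range(k), size):
            s = list(support)
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = gram[np.ix_(s, s)]
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.append(lin[s], 1.0)
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            w_s, lam = sol[:size], sol[size]
            if np.any(w_s < -1e-10):
                continue
            w = np.zeros(k)
            w[s] = np.clip(w_s, 0.0, None)
            # dual feasibility: the KKT multiplier of every zero weight >= 0
            grad = gram @ w - lin
            if np.any(grad[np.setdiff1d(np.arange(k), s)] + lam < -1e-8):
                continue
            obj = float(np.sum((y - ref @ w) ** 2))
            if obj < best_obj - 1e-15:
                best_obj, best_w = obj, w
    if best_w is None:  # numerically degenerate; fall back to projected NNLS
        w, _ = nnls(ref, y)
        total = w.sum()
        best_w = w / total if total > 0 else np.full(k, 1.0 / k)
    return best_w


def deconvolve_rpc(
    y: np.ndarray,
    ref: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Robust-regression weights: Huber IRLS, truncate negatives, normalize.

    Returns ``(w, converged)``.  A perfect linear fit (zero residuals) is
    detected first and returned directly, since the MAD scale estimate of the
    IRLS degenerates there.
    """
    y = np.asarray(y, dtype=float)
    ref = np.asarray(ref, dtype=float)
    coef, residual, *_ = np.linalg.lstsq(ref, y, rcond=None)
    fitted_resid = y - ref @ coef
    converged = True
    if np.max(np.abs(fitted_resid)) > 1e-10:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = RLM(y, ref, M=HuberT(HUBER_C)).fit(
                maxiter=max_iter, tol=tol, conv="coefs", scale_est="mad"
            )
        coef = np.asarray(fit.params)
        history = fit.fit_history.get("params", [])
        if len(history) >= max_iter:
            converged = False
            warnings.warn("RPC IRLS did not converge; returning last iterate", stacklevel=2)
    w = np.clip(coef, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise DeconvolutionError("all robust-regression coefficients nonpositive")
    return w / total, converged


def deconvolve_cbs(
    y: np.ndarray,
    ref: np.ndarray,
    nu_grid=NU_GRID,
    C: float = 1.0,
) -> tuple[np.ndarray, float]:
    """CIBERSORT-style nu-SVR weights.

    Features (probes) are z-scored with the reference row statistics; a
    linear-kernel nu-SVR is fitted for each nu in the grid and the fit with
    the lowest RMSE against the (standardized) observed profile wins.

    Row-centering removes the all-ones direction from the signature column
    space (the centered columns sum to zero), so the SVR coefficient vector
    is identified only up to an additive constant; the lost direction is
    restored by shifting the coefficients to sum to one -- the constraint the
    mixture weights satisfy -- before truncation.  Negative coefficients are
    then zeroed and the rest normalized.  Returns ``(w, chosen_nu)``.
    """
    y = np.asarray(y, dtype=float)
    ref = np.asarray(ref, dtype=float)
    k = ref.shape[1]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() < k:
        raise DeconvolutionError("too few discriminating probes after standardization")
    refs = (ref[keep] - mu[keep, None]) / sd[keep, None]
    ys = (y[keep] - mu[keep]) / sd[keep]
    best = None
    for nu in nu_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                svr = NuSVR(kernel="linear", nu=nu, C=C, tol=1e-6, max_iter=200_000)
                svr.fit(refs, ys)
        except Exception:
            continue
        rmse = float(np.sqrt(np.mean((svr.predict(refs) - ys) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, float(nu), svr.coef_.ravel().copy())
    if best is None:
        raise DeconvolutionError("nu-SVR failed for every nu in the grid")
    _, nu, coef = best
    coef = coef + (1.0 - coef.sum()) / k
    w = np.clip(coef, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise DeconvolutionError("all SVR coefficients nonpositive")
    return w / total, nu


@dataclasses.dataclass
class ProportionEstimates:
    """Estimated composition: samples x cell types weights on the simplex."""

    proportions: pd.DataFrame
    method: str
    diagnostics: pd.DataFrame  # per sample: n_probes_used, rmse, extra

    def __post_init__(self) -> None:
        w = self.proportions.to_numpy()
        if np.any(w < -1e-9):
            raise ValidationError("negative proportion estimate")
        if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-6):
            raise ValidationError("proportion rows must sum to 1 within 1e-6")


def deconvolve(
    beta: BetaMatrix,
    ref: ReferenceMatrix,
    method: str = "rpc",
    min_probes: int = 50,
    **kwargs,
) -> ProportionEstimates:
    """Estimate cell composition for every sample of a beta matrix.

    Reference probes absent from the matrix, or missing in a given sample,
    are dropped for that sample (>= ``min_probes`` must remain).
    """
    if method not in METHODS:
        raise DeconvolutionError(f"unknown method {method!r}; choose from {METHODS}")
    shared = [p for p in ref.probe_ids if p in set(beta.probe_ids)]
    if not shared:
        raise DeconvolutionError("no reference probes present in the beta matrix")
    refmat = ref.means.loc[shared]
    data = beta.data.loc[shared]
    rows, diags = [], []
    for sample in beta.sample_ids:
        y = data[sample].to_numpy(dtype=float)
        ok = ~np.isnan(y) & ~np.isnan(refmat.to_numpy()).any(axis=1)
        if ok.sum() < min_probes:
            raise DeconvolutionError(
                f"sample {sample!r} shares {int(ok.sum())} usable reference probes; "
                f"need >= {min_probes}"
            )
        r = refmat.to_numpy()[ok]
        extra: dict = {}
        if method == "cp":
            w = deconvolve_cp(y[ok], r, columns=ref.cell_types, **kwargs)
        elif method == "rpc":
            w, converged = deconvolve_rpc(y[ok], r, **kwargs)
            extra["converged"] = converged
        else:
            w, nu = deconvolve_cbs(y[ok], r, **kwargs)
            extra["nu"] = nu
        rmse = float(np.sqrt(np.mean((y[ok] - r @ w) ** 2)))
        rows.append(w)
        diags.append(dict(sample_id=sample, n_probes_used=int(ok.sum()), rmse=rmse, **extra))
    proportions = pd.DataFrame(rows, index=beta.sample_ids, columns=ref.cell_types)
    return ProportionEstimates(
        proportions=proportions, method=method, diagnostics=pd.DataFrame(diags)
    )
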