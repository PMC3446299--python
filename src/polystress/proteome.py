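"""Spectrum-count proteome time-course quantification and classification.

Relative protein changes across a duplicated stress time course are
quantified from label-free spectrum counts:

1. keep proteins identified with >= 2 unique peptides in at least one
   sample and (for quantitative comparison) detected in every sample;
2. calibrate each sample against a protein-wise average control with a
   no-intercept least-squares gain factor;
3. form per-replicate log2 ratios against that replicate's unstressed
   (0 min) sample and average duplicates per time point;
4. fit each averaged trajectory with a quadratic polynomial in time,
   F-test for any temporal change, and classify significant profiles as
   linear up / linear down / quadratic convex / quadratic concave.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_detected",
    "calibrate_samples",
    "log2_trajectories",
    "fit_temporal",
    "fit_temporal_matrix",
    "analyze_counts",
    "TemporalFit",
]


def parse_sample_metadata(columns) -> pd.DataFrame:
    """Parse ``condition:time:replicate`` sample identifiers."""
    rows = []
    for col in columns:
        parts = str(col).split(":")
        if len(parts) != 3:
            raise ValueError(
                f"sample id {col!r} is not of the form condition:time:replicate"
            )
        rows.append(
            {"sample": col, "condition": parts[0], "time": float(parts[1]),
             "replicate": int(parts[2])}
        )
    return pd.DataFrame(rows).set_index("sample")


def filter_detected(
    counts: pd.DataFrame,
    unique_peptides: pd.DataFrame | pd.Series,
    min_unique_peptides: int = 2,
    require_all_samples: bool = True,
) -> pd.DataFrame:
    """Subset proteins reliably identified for quantitative comparison.

    Retains proteins with at least ``min_unique_peptides`` unique
    peptides in at least one sample and, if ``require_all_samples``,
    a nonzero count in every sample.

    Parameters
    ----------
    counts : DataFrame (proteins x samples) of nonnegative integers.
    unique_peptides : per-protein-per-sample DataFrame, or a per-protein
        Series of the maximum unique-peptide count.
    """
    if counts.empty:
        warnings.warn("empty spectrum-count matrix; nothing to filter")
        return counts
    if (counts.to_numpy() < 0).any():
        raise ValueError("spectrum counts must be nonnegative")
    if isinstance(unique_peptides, pd.DataFrame):
        max_pep = unique_peptides.max(axis=1)
    else:
        max_pep = unique_peptides
    keep = max_pep.reindex(counts.index).fillna(0) >= min_unique_peptides
    if require_all_samples:
        keep &= (counts > 0).all(axis=1)
    return counts.loc[keep]


def calibrate_samples(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Least-squares gain calibration of each sample against the average control.

    The control vector is the protein-wise mean count across samples.
    For sample ``s`` the gain minimizing ``sum_i (a_s * x_is - c_i)^2``
    has the closed form ``a_s = sum_i x_is c_i / sum_i x_is^2``; the
    calibrated value is ``a_s * x_is``. Multiplying one sample by a
    constant ``k`` divides its gain by ``k`` exactly, so calibrated
    matrices are invariant to per-sample scaling.
    """
    x = counts.to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError("cannot calibrate an empty matrix")
    sumsq = (x**2).sum(axis=0)
    if (sumsq == 0).any():
        raise ValueError("all-zero sample column: calibration gain undefined")
    control = x.mean(axis=1)
    a = (x * control[:, None]).sum(axis=0) / sumsq
    factors = pd.Series(a, index=counts.columns, name="scale_factor")
    calibrated = counts.astype(float) * factors
    return factors, calibrated


def log2_trajectories(
    calibrated: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Replicate-matched log2 ratios vs 0 min, duplicates averaged.

    Each sample is referenced against the 0-minute sample of its own
    replicate: ``log2((x + q) / (x0 + q))`` with pseudocount ``q``; the
    per-replicate ratios are then averaged per time point, yielding a
    proteins x time points trajectory matrix whose 0-min column is 0 by
    construction.
    """
    meta = metadata if metadata is not None else parse_sample_metadata(
        calibrated.columns
    )
    times = sorted(meta["time"].unique())
    if 0 not in times and 0.0 not in times:
        raise ValueError("a 0-minute reference sample is required")
    per_rep = {}
    for rep, cols in meta.groupby("replicate").groups.items():
        sub = meta.loc[cols]
        ref_cols = sub.index[sub["time"] == 0]
        if len(ref_cols) != 1:
            raise ValueError(f"replicate {rep} needs exactly one 0-minute sample")
        ref = calibrated[ref_cols[0]].to_numpy(dtype=float) + pseudocount
        ratios = np.log2(
            (calibrated[sub.index].to_numpy(dtype=float) + pseudocount) / ref[:, None]
        )
        per_rep[rep] = pd.DataFrame(
            ratios, index=calibrated.index, columns=sub["time"].to_numpy()
        )
    stacked = pd.concat(per_rep.values(), axis=1)
    traj = stacked.T.groupby(level=0).mean().T
    return traj[sorted(traj.columns)]


@dataclass
class TemporalFit:
    protein_id: str
    beta0: float
    beta1: float
    beta2: float
    F: float
    p: float
    significant: bool
    category: str  # linear_up | linear_down | quadratic_convex | quadratic_concave | unchanged


def _design(timepoints: np.ndarray, encoding: str) -> tuple[np.ndarray, float, float]:
    t = np.asarray(timepoints, dtype=float)
    if encoding == "ordinal":
        t = np.arange(t.size, dtype=float)
    elif encoding != "minutes":
        raise ValueError("encoding must be 'minutes' or 'ordinal'")
    # center and scale to unit variance for conditioning
    mu, sd = t.mean(), t.std()
    if sd == 0:
        raise ValueError("time points are all identical")
    z = (t - mu) / sd
    X = np.column_stack([np.ones_like(z), z, z**2])
    return X, mu, sd


def fit_temporal_matrix(
    trajectories: np.ndarray,
    timepoints,
    alpha: float = 0.05,
    encoding: str = "minutes",
) -> pd.DataFrame:
    """Vectorized quadratic-linear regression over many trajectories.

    Fits ``y(t) = b0 + b1 z + b2 z^2`` (z the standardized time) by least
    squares to every row, computes the overall F statistic of
    (b1, b2) = (0, 0) against the intercept-only model, and classifies
    each significant profile: a significant curvature term (two-sided t
    test on b2 at the same ``alpha``) makes it quadratic convex/concave
    by the sign of b2, otherwise linear up/down by the sign of b1.

    Coefficients are reported on the original time scale (log2 units per
    minute and per minute squared).

    Rows with zero residual variance but nonzero trend are perfectly
    explained temporal changes: they are flagged significant with p = 0
    and a warning, so noiseless trajectories remain classifiable.
    """
    Y = np.atleast_2d(np.asarray(trajectories, dtype=float))
    t = np.asarray(timepoints, dtype=float)
    n = t.size
    k = 3
    if Y.shape[1] != n:
        raise ValueError("trajectory length does not match time points")
    if n < k + 1:
        raise ValueError(f"need >= {k + 1} time points for a quadratic fit")
    X, mu, sd = _design(t, encoding)

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (3, m)
    fitted = X @ beta
    resid = Y.T - fitted
    rss = (resid**2).sum(axis=0)
    tss = ((Y.T - Y.T.mean(axis=0)) ** 2).sum(axis=0)
    df_model, df_resid = k - 1, n - k
    ess = tss - rss

    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ess / df_model) / (rss / df_resid)
    # degenerate rows
    zero_resid = rss <= 1e-12 * np.maximum(tss, 1.0)
    flat = tss <= 1e-24
    F = np.where(flat, 0.0, F)
    p = stats.f.sf(F, df_model, df_resid)
    p = np.where(flat, 1.0, p)
    if (zero_resid & ~flat).any():
        warnings.warn(
            "zero residual variance: trajectory fits perfectly; p reported as 0"
        )
        F = np.where(zero_resid & ~flat, np.inf, F)
        p = np.where(zero_resid & ~flat, 0.0, p)

    # coefficient covariance for the beta2 t-test (standardized scale)
    XtX_inv = np.linalg.inv(X.T @ X)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / df_resid
        se_b2 = np.sqrt(XtX_inv[2, 2] * sigma2)
        t_b2 = beta[2] / se_b2
    p_b2 = 2 * stats.t.sf(np.abs(t_b2), df_resid)
    p_b2 = np.where(zero_resid, np.where(np.abs(beta[2]) > 1e-12, 0.0, 1.0), p_b2)

    significant = p < alpha
    quadratic = p_b2 < alpha
    category = np.full(Y.shape[0], "unchanged", dtype=object)
    up = beta[1] > 0
    convex = beta[2] > 0
    category[significant & quadratic & convex] = "quadratic_convex"
    category[significant & quadratic & ~convex] = "quadratic_concave"
    category[significant & ~quadratic & up] = "linear_up"
    category[significant & ~quadratic & ~up] = "linear_down"

    # back-transform coefficients from the standardized to the native scale
    # (minutes, or time-point index under the ordinal encoding)
    b0 = beta[0] - beta[1] * mu / sd + beta[2] * mu**2 / sd**2
    b1 = beta[1] / sd - 2 * beta[2] * mu / sd**2
    b2 = beta[2] / sd**2

    return pd.DataFrame(
        {
            "beta0": b0,
            "beta1": b1,
            "beta2": b2,
            "F": F,
            "p": p,
            "p_beta2": p_b2,
            "significant": significant,
            "category": category,
        }
    )


def fit_temporal(
    trajectory,
    timepoints,
    alpha: float = 0.05,
    encoding: str = "minutes",
    protein_id: str = "",
) -> TemporalFit:
    """Fit one protein trajectory; see :func:`fit_temporal_matrix`."""
    res = fit_temporal_matrix(
        np.asarray(trajectory, dtype=float)[None, :], timepoints, alpha, encoding
    ).iloc[0]
    return TemporalFit(
        protein_id=protein_id,
        beta0=float(res["beta0"]),
        beta1=float(res["beta1"]),
        beta2=float(res["beta2"]),
        F=float(res["F"]),
        p=float(res["p"]),
        significant=bool(res["significant"]),
        category=str(res["category"]),
    )


def analyze_counts(
    counts: pd.DataFrame,
    unique_peptides: pd.DataFrame | pd.Series,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    min_unique_peptides: int = 2,
    require_all_samples: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Full proteome stage: filter, calibrate, log2 trajectories, fits.

    Returns (per-protein fit table, averaged log2 trajectories,
    per-sample calibration factors).
    """
    detected = filter_detected(
        counts, unique_peptides, min_unique_peptides, require_all_samples
    )
    factors, calibrated = calibrate_samples(detected)
    traj = log2_trajectories(calibrated, pseudocount=pseudocount)
    fits = fit_temporal_matrix(
        traj.to_numpy(), np.asarray(traj.columns, dtype=float), alpha=alpha
    )
    fits.index = traj.index
    fits.index.name = "protein_id"
    return fits, traj, factors
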