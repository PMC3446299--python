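"""Translation-profile statistics from four-pool polysome fractionation.

A *translation profile* is the percentage of a gene's mRNA signal in each
of four pooled sucrose-gradient fractions (ordered from free mRNA to heavy
polysomes), summing to 100. Stress-induced shifts are scored with two
complementary statistics:

* the **sum of differences** ``D`` — the L1 distance between stress and
  control profiles (range 0–200), sensitive to any reshaping;
* the **translation ratio** ``R`` — the ratio of weighted scores
  ``S = sum(w_k * p_k)`` with increasing weights (default 0.1/0.2/0.3/0.4,
  so 10 <= S <= 40), sensitive to the direction of the shift: R > 1
  indicates translational up-regulation, R < 1 down-regulation.

Candidate genes pass a cutoff on either statistic; a deterministic
curation rule (codifying the co-directional movement of the pooled low
fractions 1–2 versus high fractions 3–4) then assigns a direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CallingThresholds

DEFAULT_WEIGHTS = np.array([0.1, 0.2, 0.3, 0.4])

__all__ = [
    "DEFAULT_WEIGHTS",
    "normalize_profiles",
    "sum_of_differences",
    "weighted_score",
    "translation_ratio",
    "average_over_replicates",
    "call_regulation",
    "compare_conditions",
]


def _as_2d(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[-1] != 4:
        raise ValueError(f"expected 4 fraction pools, got {a.shape[-1]}")
    return a


def normalize_profiles(raw_pools) -> tuple[np.ndarray, np.ndarray]:
    """Convert raw four-pool abundances to percentage profiles.

    Parameters
    ----------
    raw_pools : array-like, shape (n_genes, 4) or (4,)
        Nonnegative pool abundances. Rows with a missing (NaN) or
        negative pool, or with zero total signal, are invalid: a gene's
        profile is defined only with data in all four pools.

    Returns
    -------
    percentages : ndarray, shape (n_genes, 4)
        Rows sum to 100; invalid rows are all-NaN.
    valid : ndarray of bool, shape (n_genes,)
        Mask of rows that could be normalized. Invalid genes are flagged
        for exclusion, never imputed.
    """
    one_dim = np.ndim(raw_pools) == 1
    a = _as_2d(raw_pools)
    with np.errstate(invalid="ignore"):
        bad = np.isnan(a).any(axis=1) | (a < 0).any(axis=1)
    total = a.sum(axis=1)
    valid = ~bad & (total > 0)
    out = np.full_like(a, np.nan)
    out[valid] = 100.0 * a[valid] / total[valid, None]
    if one_dim:
        return out[0], valid[0]
    return out, valid


def sum_of_differences(stress, control) -> np.ndarray | float:
    """Sum of absolute per-pool percentage differences (L1 distance).

    D ranges from 0 (identical profiles) to 200 (disjoint mass).
    """
    s = _as_2d(stress)
    c = _as_2d(control)
    d = np.abs(s - c).sum(axis=1)
    return d[0] if np.isscalar(stress[0]) or np.ndim(stress) == 1 else d


def weighted_score(profile, weights=DEFAULT_WEIGHTS) -> np.ndarray | float:
    """Weighted translation score S = sum_k w_k * p_k.

    Weights must be positive and strictly increasing so that mass in
    heavier polysome fractions scores higher; with the default weights
    S lies in [10, 40].
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,) or (w <= 0).any() or (np.diff(w) <= 0).any():
        raise ValueError("weights must be 4 positive, strictly increasing factors")
    p = _as_2d(profile)
    s = p @ w
    return s[0] if np.ndim(profile) == 1 else s


def translation_ratio(s_stress, s_control) -> np.ndarray | float:
    """Translation ratio R = S_stress / S_control.

    R > 1 reflects translational up-regulation, R < 1 down-regulation.
    """
    s_control = np.asarray(s_control, dtype=float)
    if np.any(s_control <= 0):
        raise ValueError("control score must be > 0")
    return np.asarray(s_stress, dtype=float) / s_control


def average_over_replicates(d_values, r_values) -> tuple[float, float, int]:
    """Arithmetic means of D and R over replicate pairs.

    Returns (mean D, mean R, number of replicate pairs). The two
    statistics are averaged separately, after being computed per
    replicate pair.
    """
    d = np.atleast_1d(np.asarray(d_values, dtype=float))
    r = np.atleast_1d(np.asarray(r_values, dtype=float))
    if d.size == 0 or r.size == 0:
        raise ValueError("at least one replicate pair is required")
    if d.size != r.size:
        raise ValueError("D and R replicate lists differ in length")
    return float(d.mean()), float(r.mean()), int(d.size)


@dataclass
class RegulationCall:
    gene_id: str
    direction: str  # "up" | "down" | "none"
    D: float
    R: float
    passed_D_cutoff: bool
    passed_R_cutoff: bool
    passed_curation: bool
    replicate_consistent: bool


def _curation_direction(
    delta_low: float, delta_high: float, min_delta: float
) -> str:
    """Direction implied by the pooled-fraction shifts (stress - control).

    Down-regulation requires an increase in fractions 1-2 with a
    concomitant decrease in fractions 3-4; up-regulation the inverse.
    """
    if delta_low > min_delta and delta_high < -min_delta:
        return "down"
    if delta_low < -min_delta and delta_high > min_delta:
        return "up"
    return "none"


def call_regulation(
    gene_id: str,
    d_mean: float,
    r_mean: float,
    control_profiles: np.ndarray,
    stress_profiles: np.ndarray,
    thresholds: CallingThresholds | None = None,
    strict: bool = False,
) -> RegulationCall:
    """Call translational regulation for one gene.

    A gene is a candidate if the replicate-averaged D passes
    ``D_cutoff`` or the averaged R passes ``R_cutoff`` on either side
    (the two automated criteria are pooled). A direction is assigned
    only if the curation rule holds on the replicate-mean profiles; in
    strict mode every replicate pair must individually show the same
    sign pattern.

    Parameters
    ----------
    control_profiles, stress_profiles : ndarray, shape (n_pairs, 4)
        Percentage profiles for the paired replicate comparisons.
    """
    thresholds = thresholds or CallingThresholds()
    c = _as_2d(control_profiles)
    s = _as_2d(stress_profiles)
    if c.shape != s.shape:
        raise ValueError("control and stress replicate profiles must align")

    passed_d = d_mean >= thresholds.D_cutoff
    passed_r = (r_mean >= thresholds.R_cutoff) or (r_mean <= thresholds.R_cutoff_down)

    c_mean, s_mean = c.mean(axis=0), s.mean(axis=0)
    delta_low = (s_mean[0] + s_mean[1]) - (c_mean[0] + c_mean[1])
    delta_high = (s_mean[2] + s_mean[3]) - (c_mean[2] + c_mean[3])
    mean_dir = _curation_direction(delta_low, delta_high, thresholds.min_fraction_delta)

    per_rep = [
        _curation_direction(
            (sr[0] + sr[1]) - (cr[0] + cr[1]),
            (sr[2] + sr[3]) - (cr[2] + cr[3]),
            thresholds.min_fraction_delta,
        )
        for cr, sr in zip(c, s)
    ]
    consistent = mean_dir != "none" and all(d == mean_dir for d in per_rep)

    passed_curation = mean_dir != "none" and (consistent or not strict)
    direction = mean_dir if (passed_d or passed_r) and passed_curation else "none"
    return RegulationCall(
        gene_id=gene_id,
        direction=direction,
        D=d_mean,
        R=r_mean,
        passed_D_cutoff=bool(passed_d),
        passed_R_cutoff=bool(passed_r),
        passed_curation=bool(passed_curation),
        replicate_consistent=bool(consistent),
    )


def compare_conditions(
    control_pools: dict[int, pd.DataFrame],
    stress_pools: dict[int, pd.DataFrame],
    thresholds: CallingThresholds | None = None,
    strict: bool = False,
    weights=DEFAULT_WEIGHTS,
    pairing: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Full stress-vs-control translation analysis over a gene matrix.

    Parameters
    ----------
    control_pools, stress_pools : dict replicate -> DataFrame
        Raw four-pool abundance matrices (genes x 4 pools), indexed by
        gene id, one per biological replicate.
    pairing : list of (stress_replicate, control_replicate), optional
        Replicate pairing. Each stress sample is compared against the
        control of its acquisition round when the replicate keys match;
        otherwise every stress x control pair is formed and averaged.

    Returns
    -------
    DataFrame indexed by gene id with columns
    ``D, S_control, S_stress, R, n_pairs, direction, passed_D_cutoff,
    passed_R_cutoff, passed_curation, replicate_consistent, excluded``.
    Genes missing any pool in any required sample are excluded from
    calling (``excluded=True``, statistics NaN).
    """
    thresholds = thresholds or CallingThresholds()
    if not control_pools or not stress_pools:
        raise ValueError("need at least one control and one stress replicate")

    if pairing is None:
        if set(control_pools) >= set(stress_pools):
            pairing = [(r, r) for r in sorted(stress_pools)]
        else:  # fallback: all stress x all control pairs
            pairing = [
                (rs, rc) for rs in sorted(stress_pools) for rc in sorted(control_pools)
            ]

    genes = next(iter(control_pools.values())).index
    for df in list(control_pools.values()) + list(stress_pools.values()):
        if not df.index.equals(genes):
            raise ValueError("all replicate matrices must share the same gene index")

    n = len(genes)
    n_pairs = len(pairing)
    c_prof = np.empty((n_pairs, n, 4))
    s_prof = np.empty((n_pairs, n, 4))
    valid = np.ones(n, dtype=bool)
    for i, (rs, rc) in enumerate(pairing):
        cp, cv = normalize_profiles(control_pools[rc].to_numpy(dtype=float))
        sp, sv = normalize_profiles(stress_pools[rs].to_numpy(dtype=float))
        c_prof[i], s_prof[i] = cp, sp
        valid &= cv & sv

    d_pairs = np.abs(s_prof - c_prof).sum(axis=2)  # (n_pairs, n)
    w = np.asarray(weights, dtype=float)
    s_ctrl = c_prof @ w
    s_strs = s_prof @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        r_pairs = s_strs / s_ctrl

    d_mean = d_pairs.mean(axis=0)
    r_mean = r_pairs.mean(axis=0)

    records = []
    for j, gene in enumerate(genes):
        if not valid[j]:
            records.append(
                {
                    "gene_id": gene,
                    "D": np.nan,
                    "S_control": np.nan,
                    "S_stress": np.nan,
                    "R": np.nan,
                    "n_pairs": n_pairs,
                    "direction": "none",
                    "passed_D_cutoff": False,
                    "passed_R_cutoff": False,
                    "passed_curation": False,
                    "replicate_consistent": False,
                    "excluded": True,
                }
            )
            continue
        call = call_regulation(
            gene,
            float(d_mean[j]),
            float(r_mean[j]),
            c_prof[:, j, :],
            s_prof[:, j, :],
            thresholds=thresholds,
            strict=strict,
        )
        records.append(
            {
                "gene_id": gene,
                "D": call.D,
                "S_control": float(s_ctrl[:, j].mean()),
                "S_stress": float(s_strs[:, j].mean()),
                "R": call.R,
                "n_pairs": n_pairs,
                "direction": call.direction,
                "passed_D_cutoff": call.passed_D_cutoff,
                "passed_R_cutoff": call.passed_R_cutoff,
                "passed_curation": call.passed_curation,
                "replicate_consistent": call.replicate_consistent,
                "excluded": False,
            }
        )
    return pd.DataFrame.from_records(records).set_index("gene_id")
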