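"""Seeded synthetic data for the three regulatory layers.

The generator emulates the statistical structure of a stress time-course
study in fission yeast: a four-pool polysome-fractionation layer
(control plus 15/60-minute stress samples with biological repeats), an
mRNA log2-ratio expression layer over seven stress time points with a
transient trajectory peaking around 60 minutes, and a duplicated
six-time-point spectrum-count proteome layer (12 samples). Effects are
*planted* in deterministic gene blocks so every downstream statistic has
a ground-truth recovery test; all randomness flows through one seeded
``numpy`` generator, so identical configurations give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

__all__ = [
    "GroundTruth",
    "FractionPools",
    "SpectrumCounts",
    "assign_labels",
    "simulate_fraction_pools",
    "simulate_mrna_table",
    "simulate_spectrum_counts",
    "simulate_coupled_proteome",
]


@dataclass
class GroundTruth:
    """Planted per-gene labels and per-sample truth for a simulation.

    ``genes`` is indexed by gene id with one label column per layer
    (value ``"null"`` when nothing was planted) plus the per-gene mRNA
    effect size; ``scale_factors`` holds the true per-sample proteome
    gains to be recovered by calibration.
    """

    genes: pd.DataFrame
    scale_factors: pd.Series | None = None
    config: SimulationConfig | None = None


@dataclass
class FractionPools:
    """Raw four-pool abundance matrices, one per condition and replicate."""

    control: dict[int, pd.DataFrame]
    stress: dict[int, dict[int, pd.DataFrame]]  # time -> replicate -> matrix
    truth: GroundTruth = field(repr=False, default=None)


@dataclass
class SpectrumCounts:
    counts: pd.DataFrame
    unique_peptides: pd.DataFrame
    metadata: pd.DataFrame
    truth: GroundTruth = field(repr=False, default=None)


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")


def assign_labels(config: SimulationConfig) -> GroundTruth:
    """Deterministic contiguous-block assignment of planted-effect labels.

    With ``concordant=True`` (default) the translation and mRNA blocks
    coincide (up with up, down with down), emulating co-directional
    regulation of transcription and translation; protein-trajectory
    blocks follow after all mRNA/translation blocks. Only noise is
    random — the labels are a function of the configuration alone.
    """
    n = config.n_genes
    pf = config.planted_fractions
    counts = {k: int(round(pf.get(k, 0.0) * n)) for k in pf}
    n_tu = counts.get("translation_up", 0)
    n_td = counts.get("translation_down", 0)
    n_mu = counts.get("mrna_up", 0)
    n_md = counts.get("mrna_down", 0)

    genes = pd.DataFrame(
        {
            "translation_label": "null",
            "mrna_label": "null",
            "protein_label": "null",
            "mrna_effect": 0.0,
            "dropout": False,
        },
        index=_gene_ids(n),
    )
    if n == 0:
        return GroundTruth(genes=genes, config=config)

    if config.concordant:
        down_start = max(n_tu, n_mu)
        spans = {
            "translation_up": (0, n_tu),
            "mrna_up": (0, n_mu),
            "translation_down": (down_start, down_start + n_td),
            "mrna_down": (down_start, down_start + n_md),
        }
        offset = max(end for _, end in spans.values())
    else:
        offset = 0
        spans = {}
        for key, cnt in (
            ("translation_up", n_tu),
            ("translation_down", n_td),
            ("mrna_up", n_mu),
            ("mrna_down", n_md),
        ):
            spans[key] = (offset, offset + cnt)
            offset += cnt

    for key in ("protein_linear_up", "protein_linear_down",
                "protein_convex", "protein_concave"):
        cnt = counts.get(key, 0)
        spans[key] = (offset, offset + cnt)
        offset += cnt
    if offset > n:
        raise ConfigurationError(
            f"planted blocks need {offset} genes but only {n} available"
        )

    col = {"translation": "translation_label", "mrna": "mrna_label",
           "protein": "protein_label"}
    for key, (a, b) in spans.items():
        layer = key.split("_")[0]
        genes.iloc[a:b, genes.columns.get_loc(col[layer])] = key
    up = genes["mrna_label"] == "mrna_up"
    down = genes["mrna_label"] == "mrna_down"
    effect = np.where(up, config.mrna_log2_effect, 0.0) - np.where(
        down, config.mrna_log2_effect, 0.0
    )
    if config.mrna_effect_spread > 0:
        rng = np.random.default_rng(config.seed + 4)
        s = config.mrna_effect_spread
        effect = effect * rng.uniform(1 - s, 1 + s, size=n)
    genes["mrna_effect"] = effect
    return GroundTruth(genes=genes, config=config)


def _baseline_profiles(config: SimulationConfig, rng: np.random.Generator):
    """Per-gene baseline four-pool percentage profiles.

    The pooled low-fraction (1-2) mass is drawn uniformly from an
    interval that leaves at least 5 percentage points in the donor pool
    after the planted shift, so planted effects are always feasible.
    """
    n = config.n_genes
    shift = config.effect_size_shift
    lo, hi = shift + 5.0, 95.0 - shift
    if lo >= hi:
        raise ConfigurationError(
            f"effect_size_shift={shift} leaves no feasible baseline profile"
        )
    low_mass = rng.uniform(lo, hi, size=n)
    split_low = rng.uniform(0.3, 0.7, size=n)
    split_high = rng.uniform(0.3, 0.7, size=n)
    high_mass = 100.0 - low_mass
    p = np.empty((n, 4))
    p[:, 0] = low_mass * split_low
    p[:, 1] = low_mass * (1 - split_low)
    p[:, 2] = high_mass * split_high
    p[:, 3] = high_mass * (1 - split_high)
    return p


def _shift_profile(p: np.ndarray, shift: float, direction: str) -> np.ndarray:
    """Move ``shift`` percentage points between pooled fractions 1-2 and 3-4.

    ``direction="down"`` moves mass from the high (3-4) into the low
    (1-2) pool — translational down-regulation; ``"up"`` the inverse.
    The transferred mass is distributed proportionally to the baseline
    composition within the receiving and donating pools.
    """
    q = p.copy()
    low, high = p[:2].sum(), p[2:].sum()
    if direction == "down":
        q[:2] = p[:2] * (low + shift) / low
        q[2:] = p[2:] * (high - shift) / high
    elif direction == "up":
        q[:2] = p[:2] * (low - shift) / low
        q[2:] = p[2:] * (high + shift) / high
    else:
        raise ValueError(direction)
    return q


def simulate_fraction_pools(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> FractionPools:
    """Generate raw four-pool abundance matrices for control and stress.

    Null genes share an expected profile between conditions; planted
    translation-down genes move ``effect_size_shift`` percentage points
    of mass from fractions 3-4 into fractions 1-2 under stress (up genes
    the inverse). Multiplicative log-normal noise (``noise_sd_log``) is
    applied per pool measurement; replicates are independent draws.
    """
    rng = np.random.default_rng(config.seed)
    truth = truth or assign_labels(config)
    n = config.n_genes
    genes = truth.genes.index
    base = _baseline_profiles(config, rng)
    abundance = np.exp(rng.normal(np.log(50.0), 0.5, size=n))

    stress_prof = base.copy()
    labels = truth.genes["translation_label"].to_numpy()
    for j in range(n):
        if labels[j] == "translation_down":
            stress_prof[j] = _shift_profile(base[j], config.effect_size_shift, "down")
        elif labels[j] == "translation_up":
            stress_prof[j] = _shift_profile(base[j], config.effect_size_shift, "up")

    def draw(profile: np.ndarray) -> pd.DataFrame:
        mean = abundance[:, None] * profile / 100.0
        noise = (
            np.exp(rng.normal(0.0, config.noise_sd_log, size=mean.shape))
            if config.noise_sd_log > 0
            else 1.0
        )
        return pd.DataFrame(
            mean * noise, index=genes, columns=[f"pool{k}" for k in range(1, 5)]
        )

    control = {r: draw(base) for r in range(1, config.n_replicates_control + 1)}
    stress = {
        t: {r: draw(stress_prof) for r in range(1, config.n_replicates_stress + 1)}
        for t in config.stress_timepoints_min
    }
    return FractionPools(control=control, stress=stress, truth=truth)


def mrna_shape(t: np.ndarray, peak_time: float, t_last: float) -> np.ndarray:
    """Transient stress-response trajectory shape, unit peak amplitude.

    Rises linearly to full amplitude by 0.75x the peak time, holds
    through 2x the peak time, then decays linearly to half amplitude at
    the last time point — a transient that peaks around the configured
    peak (default 60 min) with partial decay afterwards.
    """
    t = np.asarray(t, dtype=float)
    rise_end = 0.75 * peak_time
    hold_end = 2.0 * peak_time
    out = np.clip(t / rise_end, 0.0, 1.0)
    if t_last > hold_end:
        decay = 1.0 - 0.5 * (t - hold_end) / (t_last - hold_end)
        out = np.where(t > hold_end, decay, out)
    return out


def simulate_mrna_table(
    config: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """mRNA log2-ratio table (genes x time points) vs the unstressed sample.

    Planted up genes follow ``+mrna_effect * shape(t)`` (down genes the
    negative), reaching the full effect from 0.75x to 2x the peak time;
    Gaussian noise of sd ``noise_sd_log / ln 2`` log2 units is added at
    stress time points. The 0-minute column is identically zero.
    """
    if not truth.genes.index.equals(_gene_ids(config.n_genes)):
        raise ValueError("ground truth does not match the configured gene universe")
    rng = np.random.default_rng(config.seed + 1)
    times = (0,) + tuple(config.mrna_timepoints_min)
    n = config.n_genes
    table = np.zeros((n, len(times)))
    if n:
        shape = mrna_shape(
            np.asarray(times, dtype=float),
            config.mrna_peak_time_min,
            max(times) if times else 0.0,
        )
        effect = truth.genes["mrna_effect"].to_numpy()
        table = effect[:, None] * shape[None, :]
        if config.noise_sd_log > 0:
            sd = config.noise_sd_log / np.log(2)
            noise = rng.normal(0.0, sd, size=table.shape)
            noise[:, 0] = 0.0  # ratio of the reference to itself
            table = table + noise
    cols = [f"{config.condition}:{t}" for t in times]
    return pd.DataFrame(table, index=truth.genes.index, columns=cols)


def _protein_trend(label: str, t: np.ndarray, effect: float) -> np.ndarray:
    """Planted mean log2 trajectory for a protein category."""
    T = t.max() if t.size else 1.0
    if label == "protein_linear_up":
        return effect * t / T
    if label == "protein_linear_down":
        return -effect * t / T
    if label == "protein_convex":
        return effect * ((2 * t / T - 1) ** 2 - 1)  # dip at mid-course
    if label == "protein_concave":
        return effect * (1 - (2 * t / T - 1) ** 2)  # bump at mid-course
    return np.zeros_like(t)


def simulate_spectrum_counts(
    config: SimulationConfig, truth: GroundTruth
) -> SpectrumCounts:
    """Spectrum-count matrix over the duplicated proteome time course.

    Counts are Poisson around per-protein means that follow the planted
    linear/quadratic log2 trajectories, multiplied by per-sample true
    gain factors (log-normal, sd ``sample_scale_sd_log``) that the
    calibration step is expected to recover. Unique-peptide counts are
    >= 2 for every protein; with ``dropout_fraction > 0`` a random
    protein subset loses 1-3 samples (count zeroed), to be excluded by
    the detected-in-all-samples filter.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_genes
    times = np.asarray(config.proteome_timepoints_min, dtype=float)
    n_rep = 2
    samples = [
        f"{config.condition}:{int(t)}:{r}"
        for t in config.proteome_timepoints_min
        for r in range(1, n_rep + 1)
    ]
    meta = pd.DataFrame(
        {
            "sample": samples,
            "condition": config.condition,
            "time": np.repeat(times, n_rep),
            "replicate": np.tile(np.arange(1, n_rep + 1), times.size),
        }
    ).set_index("sample")

    scales = pd.Series(
        np.exp(rng.normal(0.0, config.sample_scale_sd_log, size=len(samples)))
        if config.sample_scale_sd_log > 0
        else np.ones(len(samples)),
        index=meta.index,
        name="true_scale",
    )

    base = np.exp(rng.normal(np.log(config.count_depth), 0.5, size=n))
    trend = np.zeros((n, times.size))
    labels = truth.genes["protein_label"].to_numpy()
    for j in range(n):
        trend[j] = _protein_trend(labels[j], times, config.protein_log2_effect)
    mean = base[:, None] * 2.0**trend  # proteins x time points
    mean_samples = np.repeat(mean, n_rep, axis=1) * scales.to_numpy()[None, :]
    counts = rng.poisson(mean_samples).astype(int)

    peptides = 2 + rng.poisson(2.0, size=counts.shape)

    dropout = np.zeros(n, dtype=bool)
    n_drop = int(round(config.dropout_fraction * n))
    if n_drop:
        dropped = rng.choice(n, size=n_drop, replace=False)
        dropout[dropped] = True
        for j in dropped:
            k = rng.integers(1, 4)
            cols = rng.choice(len(samples), size=k, replace=False)
            counts[j, cols] = 0
    truth.genes["dropout"] = dropout
    truth.scale_factors = scales

    counts_df = pd.DataFrame(counts, index=truth.genes.index, columns=meta.index)
    pep_df = pd.DataFrame(peptides, index=truth.genes.index, columns=meta.index)
    return SpectrumCounts(
        counts=counts_df, unique_peptides=pep_df, metadata=meta, truth=truth
    )


def protein_response(
    mrna_log2: np.ndarray,
    mrna_times: np.ndarray,
    sample_times: np.ndarray,
    half_life_min: np.ndarray | float,
) -> np.ndarray:
    """First-order protein response to a relative-synthesis trajectory.

    Solves ``dP/dt = k (m(t) - P)`` per gene with ``P(0) = 1``, where
    ``m(t) = 2**x(t)`` is the relative synthesis rate implied by the
    mRNA log2 trajectory ``x`` (linearly interpolated) and
    ``k = ln 2 / half_life``. A long half-life low-passes the mRNA
    signal: rapid mRNA bursts produce delayed, damped protein changes,
    and mRNA repression barely moves long-lived proteins within the
    observation window. Returns the protein log2 levels at
    ``sample_times``.
    """
    mrna_log2 = np.atleast_2d(np.asarray(mrna_log2, dtype=float))
    n = mrna_log2.shape[0]
    k = np.log(2) / np.broadcast_to(np.asarray(half_life_min, dtype=float), (n,))
    t_end = float(max(sample_times.max(), mrna_times.max()))
    grid = np.arange(0.0, t_end + 1.0)
    m = 2.0 ** np.vstack(
        [np.interp(grid, mrna_times, row) for row in mrna_log2]
    )  # genes x grid
    P = np.ones((n, grid.size))
    for i in range(1, grid.size):
        dt = grid[i] - grid[i - 1]
        P[:, i] = P[:, i - 1] + dt * k * (m[:, i - 1] - P[:, i - 1])
    idx = np.searchsorted(grid, np.asarray(sample_times, dtype=float))
    return np.log2(P[:, idx])


def simulate_coupled_proteome(
    config: SimulationConfig,
    truth: GroundTruth,
    mrna_table: pd.DataFrame,
) -> SpectrumCounts:
    """Spectrum counts whose means low-pass filter the mRNA trajectories.

    Each protein follows the first-order synthesis/degradation response
    to its gene's mRNA trajectory (:func:`protein_response`). Proteins
    of mRNA-repressed genes get the long ``protein_half_life_repressed``
    half-life — the planted decoupling in which stable proteins buffer
    transcript repression over the observation window — while all others
    use ``protein_half_life_min``.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_genes
    mrna_times = np.array(
        [float(c.split(":")[1]) for c in mrna_table.columns]
    )
    sample_times = np.asarray(config.proteome_timepoints_min, dtype=float)
    half_life = np.full(n, config.protein_half_life_min)
    repressed = (truth.genes["mrna_label"] == "mrna_down").to_numpy()
    half_life[repressed] = config.protein_half_life_repressed_min
    traj = protein_response(
        mrna_table.to_numpy(), mrna_times, sample_times, half_life
    )

    n_rep = 2
    samples = [
        f"{config.condition}:{int(t)}:{r}"
        for t in config.proteome_timepoints_min
        for r in range(1, n_rep + 1)
    ]
    meta = pd.DataFrame(
        {
            "sample": samples,
            "condition": config.condition,
            "time": np.repeat(sample_times, n_rep),
            "replicate": np.tile(np.arange(1, n_rep + 1), sample_times.size),
        }
    ).set_index("sample")
    base = np.exp(rng.normal(np.log(config.count_depth), 0.5, size=n))
    mean = base[:, None] * 2.0**traj
    counts = rng.poisson(np.repeat(mean, n_rep, axis=1)).astype(int)
    peptides = 2 + rng.poisson(2.0, size=counts.shape)
    truth.scale_factors = pd.Series(
        np.ones(len(samples)), index=meta.index, name="true_scale"
    )
    return SpectrumCounts(
        counts=pd.DataFrame(counts, index=truth.genes.index, columns=meta.index),
        unique_peptides=pd.DataFrame(
            peptides, index=truth.genes.index, columns=meta.index
        ),
        metadata=meta,
        truth=truth,
    )
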