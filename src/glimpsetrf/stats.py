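"""Hierarchical-bootstrap inference, TRF power time courses, and latencies.

Electrodes from the same subject are not independent, so population-level
tests resample *subjects* with replacement and then electrodes within each
sampled subject with replacement (each resampled subject keeps its own
electrode count).  One-sided p-values are the fraction of bootstrap iterates
on the null side of the comparison value, floored at ``1 / n_boot``.

TRF time courses are summarized as the power (squared magnitude) of the
weights, averaged over features and electrodes; power is used because
different sites and features respond with either sign.  The encoding latency
is the lag of the peak of the band-limited 2x-upsampled average power curve
(5 ms resolution at a 100 Hz frame rate; ties break to the earliest peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats as sps


@dataclass
class HierarchicalSample:
    """Per-electrode values tagged by subject; the unit of bootstrap inference."""

    values: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.shape[0] != self.subject_ids.shape[0]:
            raise ValueError("values and subject_ids must align")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 tagged electrodes")


def _bootstrap_indices(groups: list[np.ndarray], n_boot: int,
                       rng: np.random.Generator):
    """Yield electrode index arrays for each hierarchical bootstrap iterate."""
    n_subj = len(groups)
    subj_choice = rng.integers(n_subj, size=(n_boot, n_subj))
    for it in range(n_boot):
        idx = [g[rng.integers(g.size, size=g.size)]
               for g in (groups[s] for s in subj_choice[it])]
        yield np.concatenate(idx)


def hierarchical_bootstrap(
    sample: HierarchicalSample,
    statistic=None,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    side: str = "greater",
    center: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Two-level (subject, electrode) bootstrap p-value and distribution.

    Parameters
    ----------
    statistic : callable mapping a resampled value array to a scalar; the
        default is the mean (computed on the pooled resampled electrodes).
    side : "greater" tests statistic > center (p = fraction of iterates
        <= center), "less" the reverse, "two" doubles the smaller tail.

    Returns (p_value, bootstrap distribution).
    """
    rng = np.random.default_rng(seed)
    subjects = np.unique(sample.subject_ids)
    if subjects.size < 1:
        raise ValueError("need at least one subject")
    groups = [np.flatnonzero(sample.subject_ids == s) for s in subjects]
    if sample.values.shape[0] < 2:
        raise ValueError("need more than one electrode")

    if statistic is None and sample.values.ndim == 1:
        # vectorized mean fast path: per-(iterate, slot) resample means,
        # pooled with each subject's own electrode count as weight
        n_subj = len(groups)
        sizes = np.array([g.size for g in groups], dtype=float)
        subj_choice = rng.integers(n_subj, size=(n_boot, n_subj))
        slot_means = np.empty((n_boot, n_subj))
        for s, g in enumerate(groups):
            draws = rng.integers(g.size, size=(n_boot, n_subj, g.size))
            means_all = sample.values[g][draws].mean(axis=2)
            mask = subj_choice == s
            slot_means[mask] = means_all[mask]
        weights = sizes[subj_choice]
        dist = (slot_means * weights).sum(axis=1) / weights.sum(axis=1)
    else:
        stat = statistic if statistic is not None else np.mean
        dist = np.empty(n_boot)
        for it, idx in enumerate(_bootstrap_indices(groups, n_boot, rng)):
            dist[it] = stat(sample.values[idx])

    lo = max(np.mean(dist <= center), 1.0 / n_boot)
    hi = max(np.mean(dist >= center), 1.0 / n_boot)
    if side == "greater":
        p = lo
    elif side == "less":
        p = hi
    elif side == "two":
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        raise ValueError("side must be 'greater', 'less', or 'two'")
    return float(p), dist


def trf_power_timecourse(group_weights: np.ndarray,
                         electrode_mask: np.ndarray | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SEM (over electrodes) of TRF power across lags.

    ``group_weights`` is lags x features x electrodes (one feature group of a
    :class:`~glimpsetrf.trf.TRFFit`).  Power is averaged over features, giving
    one curve per electrode; mean and the standard error over electrodes are
    returned.
    """
    w = np.asarray(group_weights, dtype=float)
    if electrode_mask is not None:
        w = w[:, :, np.asarray(electrode_mask, bool)]
    if w.shape[2] == 0:
        raise ValueError("empty electrode set")
    per_elec = (w**2).mean(axis=1)          # lags x electrodes
    mean = per_elec.mean(axis=1)
    sem = per_elec.std(axis=1, ddof=1) / np.sqrt(per_elec.shape[1]) \
        if per_elec.shape[1] > 1 else np.zeros_like(mean)
    return mean, sem


def encoding_latency(power_curve: np.ndarray,
                     lag_ms: np.ndarray,
                     upsample_factor: int = 2) -> float:
    """Latency (ms) of the peak of the band-limited upsampled power curve.

    Returns NaN for a flat curve; equal peaks resolve to the earliest.
    """
    p = np.asarray(power_curve, dtype=float)
    if p.size < 4:
        raise ValueError("power curve too short")
    if np.ptp(p) == 0:
        return float("nan")
    up = signal.resample(p, p.size * upsample_factor)
    t = np.interp(np.arange(up.size) / upsample_factor,
                  np.arange(p.size), np.asarray(lag_ms, float))
    return float(t[np.argmax(up)])


def per_electrode_latencies(group_weights: np.ndarray, lag_ms: np.ndarray,
                            upsample_factor: int = 2) -> np.ndarray:
    """Encoding latency of each electrode's feature-averaged power curve."""
    w = np.asarray(group_weights, dtype=float)
    per_elec = (w**2).mean(axis=1)
    return np.array([encoding_latency(per_elec[:, e], lag_ms, upsample_factor)
                     for e in range(per_elec.shape[1])])


def timecourse_significance(
    true_power: np.ndarray,
    shuffled_powers: np.ndarray,
    subject_ids: np.ndarray,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Per-lag flags where true TRF power exceeds shuffled-feature power.

    ``true_power`` is lags x electrodes; ``shuffled_powers`` is
    shuffles x lags x electrodes.  At each lag the hierarchical bootstrap
    tests whether the mean of (true - mean shuffled) power is > 0.
    """
    tp = np.asarray(true_power, dtype=float)
    sp_ = np.asarray(shuffled_powers, dtype=float)
    if sp_.ndim != 3:
        raise ValueError("shuffled_powers must be shuffles x lags x electrodes")
    diff = tp - sp_.mean(axis=0)
    rng = np.random.default_rng(seed)
    flags = np.zeros(tp.shape[0], dtype=bool)
    for l in range(tp.shape[0]):
        p, _ = hierarchical_bootstrap(
            HierarchicalSample(diff[l], subject_ids),
            n_boot=n_boot, seed=rng, side="greater")
        flags[l] = p < alpha
    return flags


@dataclass
class LatencyComparison:
    ranksum_p: float
    median_first_ms: float
    median_second_ms: float
    paired_mean_diff_ms: float
    paired_t: float
    paired_t_p: float
    bootstrap_p: float
    n_paired: int


def latency_comparison(
    glimpsed_latencies_ms: np.ndarray,
    masked_latencies_ms: np.ndarray,
    paired_subject_ids: np.ndarray | None = None,
    paired_glimpsed_ms: np.ndarray | None = None,
    paired_masked_ms: np.ndarray | None = None,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    alternative: str = "greater",
) -> LatencyComparison:
    """Compare masked vs glimpsed encoding latencies.

    The rank-sum test is unpaired over all significant electrodes per
    feature; the paired t test and hierarchical bootstrap run on electrodes
    significant for *both* features (``paired_*`` arguments; the unpaired
    sets are reused when omitted, assuming equal ordering).  The alternative
    is masked > glimpsed by default.
    """
    g = np.asarray(glimpsed_latencies_ms, dtype=float)
    m = np.asarray(masked_latencies_ms, dtype=float)
    g, m = g[~np.isnan(g)], m[~np.isnan(m)]
    if g.size < 3 or m.size < 3:
        return LatencyComparison(*([float("nan")] * 7), 0)
    rs = sps.mannwhitneyu(m, g, alternative=alternative)

    if paired_glimpsed_ms is None:
        paired_glimpsed_ms, paired_masked_ms = g, m
    pg = np.asarray(paired_glimpsed_ms, dtype=float)
    pm = np.asarray(paired_masked_ms, dtype=float)
    ok = ~(np.isnan(pg) | np.isnan(pm))
    pg, pm = pg[ok], pm[ok]
    diffs = pm - pg
    if diffs.size < 3:
        return LatencyComparison(float(rs.pvalue), float(np.median(g)),
                                 float(np.median(m)), *([float("nan")] * 4), 0)
    if np.ptp(diffs) == 0:
        t_stat, t_p = np.inf if diffs[0] > 0 else -np.inf, 0.0 if diffs[0] > 0 else 1.0
    else:
        tt = sps.ttest_1samp(diffs, 0.0, alternative=alternative)
        t_stat, t_p = float(tt.statistic), float(tt.pvalue)
    subj = (np.asarray(paired_subject_ids)[ok] if paired_subject_ids is not None
            else np.zeros(diffs.size, dtype=int))
    boot_p, _ = hierarchical_bootstrap(
        HierarchicalSample(diffs, subj), n_boot=n_boot, seed=seed,
        side="greater" if alternative == "greater" else alternative)
    return LatencyComparison(
        ranksum_p=float(rs.pvalue),
        median_first_ms=float(np.median(g)),
        median_second_ms=float(np.median(m)),
        paired_mean_diff_ms=float(diffs.mean()),
        paired_t=t_stat, paired_t_p=t_p,
        bootstrap_p=float(boot_p), n_paired=int(diffs.size),
    )


def _rank(a: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (midrank ties)."""
    return sps.rankdata(a, axis=-1)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = _rank(np.asarray(x, float)), _rank(np.asarray(y, float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("constant input; Spearman correlation undefined")
    return float((rx * ry).sum() / denom)


def anatomical_correlation(
    delta_z: np.ndarray,
    coordinate: np.ndarray,
    subject_ids: np.ndarray,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    side: str = "less",
) -> tuple[float, float]:
    """Spearman correlation between electrode position and encoding strength.

    Significance comes from hierarchically bootstrapping the correlation:
    each iterate resamples subjects then electrodes and recomputes rho on the
    resampled (coordinate, delta_z) pairs.  ``side="less"`` tests for a
    negative gradient (encoding decreasing along the coordinate).

    Returns (rho, bootstrap p).
    """
    dz = np.asarray(delta_z, dtype=float)
    coord = np.asarray(coordinate, dtype=float)
    if dz.size < 5:
        raise ValueError("need at least 5 electrodes with coordinates")
    if np.ptp(coord) == 0:
        raise ValueError("constant coordinate; correlation undefined")
    rho = spearman_rho(coord, dz)

    rng = np.random.default_rng(seed)
    subjects = np.unique(subject_ids)
    groups = [np.flatnonzero(np.asarray(subject_ids) == s) for s in subjects]
    n_subj = len(groups)
    # vectorized: draw all iterate index matrices, rank row-wise
    idx = np.empty((n_boot, dz.size), dtype=int)
    subj_choice = rng.integers(n_subj, size=(n_boot, n_subj))
    for it in range(n_boot):
        parts = [groups[s][rng.integers(groups[s].size, size=groups[s].size)]
                 for s in subj_choice[it]]
        idx[it] = np.concatenate(parts)
    rx = _rank(coord[idx])
    ry = _rank(dz[idx])
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        dist = (rx * ry).sum(axis=1) / denom
    dist = dist[np.isfinite(dist)]
    nb = dist.size
    lo = max(np.mean(dist <= 0.0), 1.0 / max(nb, 1))
    hi = max(np.mean(dist >= 0.0), 1.0 / max(nb, 1))
    if side == "greater":
        p = lo
    elif side == "less":
        p = hi
    elif side == "two":
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        raise ValueError("side must be 'greater', 'less', or 'two'")
    return rho, float(p)
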