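"""Group-level inference: permutation frequency-band selection,
paired condition contrasts with Bonferroni correction, pseudo-dyad
permutation validation, and score correlations.

Band selection treats the frequency axis as a family of comparisons: a
repeated-measures F statistic is computed per scale across conditions,
condition labels are shuffled within each dyad to build a null
distribution of the *maximum* F across scales, and contiguous runs of
scales whose observed F exceeds the 99th percentile of the null maxima
become candidate bands (nearby runs are merged).  Using the max-F null
controls the family-wise error over scales.

The pseudo-dyad permutation is the standard hyperscanning null: members
of different dyads never interacted, so re-pairing participant A of one
dyad with participant C of another destroys genuine inter-brain
coupling while preserving everything about the individual signals.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

__all__ = [
    "BandSelectionResult",
    "GroupTestResult",
    "frequency_f_stats",
    "permutation_band_selection",
    "paired_condition_test",
    "pseudo_pair_permutation",
    "score_correlation",
    "find_clusters",
]


@dataclass
class BandSelectionResult:
    """Outcome of the permutation frequency-band search."""

    f_values: np.ndarray
    threshold: float
    clusters: List[Tuple[int, int]]          # inclusive scale-index runs
    merged_bands: List[Tuple[float, float]]  # [f_lo, f_hi] in Hz, sorted

    @property
    def n_bands(self) -> int:
        return len(self.merged_bands)


@dataclass
class GroupTestResult:
    """Paired-t contrast over (channel pair, lag) with Bonferroni
    correction; ``significant`` holds the (pair, lag) keys with
    p < alpha / m."""

    t_values: Dict[Tuple[Tuple[str, str], int], float]
    p_values: Dict[Tuple[Tuple[str, str], int], float]
    m: int
    alpha: float
    significant: List[Tuple[Tuple[str, str], int]]


def frequency_f_stats(ins_by_condition: np.ndarray) -> np.ndarray:
    """Per-scale repeated-measures one-way F across conditions.

    ``ins_by_condition`` has shape (n_dyads, n_conditions, n_scales);
    every dyad contributes every condition.  The error term is the
    dyad x condition interaction.  For two conditions F equals the
    squared paired t.  A degenerate 0/0 (no condition effect and no
    within-dyad noise) returns 0 with a warning.
    """
    y = np.asarray(ins_by_condition, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
    n, k, _ = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 dyads and >= 2 conditions")
    grand = y.mean(axis=(0, 1), keepdims=True)
    dyad_mean = y.mean(axis=1, keepdims=True)
    cond_mean = y.mean(axis=0, keepdims=True)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=(0, 1))
    resid = y - dyad_mean - cond_mean + grand
    ss_err = (resid ** 2).sum(axis=(0, 1))
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_cond / df_cond) / (ss_err / df_err)
    bad = ~np.isfinite(f)
    if bad.any():
        warnings.warn("degenerate F (zero error variance); returning 0",
                      stacklevel=2)
        f = np.where(bad, 0.0, f)
    return f


def find_clusters(stat: np.ndarray, threshold: float) -> List[Tuple[int, int]]:
    """Maximal runs of consecutive indices with stat > threshold,
    as inclusive (start, stop) pairs."""
    above = np.asarray(stat) > threshold
    clusters = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append((start, i - 1))
            start = None
    if start is not None:
        clusters.append((start, len(above) - 1))
    return clusters


def _merge_clusters(clusters: List[Tuple[int, int]],
                    max_gap: int = 1) -> List[Tuple[int, int]]:
    """Merge clusters separated by at most ``max_gap`` scales
    (ranges that close together are treated as one band)."""
    if not clusters:
        return []
    merged = [clusters[0]]
    for lo, hi in clusters[1:]:
        plo, phi = merged[-1]
        if lo - phi - 1 <= max_gap:
            merged[-1] = (plo, hi)
        else:
            merged.append((lo, hi))
    return merged


def permutation_band_selection(ins_by_condition: np.ndarray,
                               frequencies: np.ndarray,
                               n_perm: int = 1000,
                               percentile: float = 99.0,
                               seed: Optional[int] = None,
                               pointwise: bool = False,
                               merge_gap: int = 1) -> BandSelectionResult:
    """Select frequency bands of interest by permutation.

    Condition labels are shuffled within each dyad independently; the
    null statistic is the per-permutation maximum F across scales
    (``pointwise=True`` switches to per-scale thresholds, which does not
    control the family-wise error over the frequency axis).  Scales whose
    original F exceeds the ``percentile``-th percentile of the null form
    clusters; clusters separated by at most ``merge_gap`` scales merge
    into one band.  ``frequencies`` maps scale index -> Hz for reporting.
    """
    y = np.asarray(ins_by_condition, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
    n, k, n_scales = y.shape
    if seed is None:
        raise ValueError("a seed is required for reproducible permutations")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null distribution",
                      stacklevel=2)
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.shape != (n_scales,):
        raise ValueError("frequencies must map every scale to Hz")

    f_obs = frequency_f_stats(y)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_scales)) if pointwise else np.empty(n_perm)
    perm = y.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate permutations return F=0
        for b in range(n_perm):
            for d in range(n):
                rng.shuffle(perm[d], axis=0)
            f_b = frequency_f_stats(perm)
            null[b] = f_b if pointwise else f_b.max()
    # the 'higher' order statistic keeps the exceedance level at or below
    # nominal for finite n_perm (linear interpolation is anti-conservative)
    if pointwise:
        thr = np.percentile(null, percentile, axis=0, method="higher")
        clusters = find_clusters(f_obs - thr, 0.0)
        threshold = float(np.median(thr))
    else:
        threshold = float(np.percentile(null, percentile, method="higher"))
        clusters = find_clusters(f_obs, threshold)
    merged = _merge_clusters(clusters, max_gap=merge_gap)
    bands = []
    for lo, hi in merged:
        f_band = frequencies[lo:hi + 1]
        bands.append((float(f_band.min()), float(f_band.max())))
    bands.sort()
    return BandSelectionResult(f_obs, threshold, clusters, bands)


def paired_condition_test(values_a: Dict, values_b: Dict,
                          alpha: float = 0.05) -> GroupTestResult:
    """Paired t-tests over every (channel pair, lag) key.

    ``values_a`` / ``values_b`` map (pair, lag) -> per-dyad
    band-averaged INS arrays (same dyad order in both).  Bonferroni
    m = number of keys = n_pairs x n_lags.
    """
    keys = sorted(values_a.keys())
    if sorted(values_b.keys()) != keys:
        raise ValueError("the two conditions cover different (pair, lag) keys")
    t_values, p_values, significant = {}, {}, []
    m = len(keys)
    for key in keys:
        xa = np.asarray(values_a[key], dtype=float)
        xb = np.asarray(values_b[key], dtype=float)
        if xa.shape != xb.shape:
            raise ValueError(f"dyad mismatch at {key}")
        if len(xa) < 3:
            raise ValueError("need at least 3 dyads for a paired t-test")
        d = xa - xb
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = sstats.ttest_rel(xa, xb)
        t_values[key] = float(t)
        p_values[key] = float(p)
        if p < alpha / m:
            significant.append(key)
    return GroupTestResult(t_values, p_values, m, alpha, significant)


def pseudo_pair_permutation(stat_fn: Callable[[Sequence[int]], float],
                            n_dyads: int,
                            n_perm: int = 1000,
                            seed: Optional[int] = None,
                            two_tailed_area: float = 0.05,
                            exhaustive: Optional[bool] = None):
    """Pseudo-dyad permutation test.

    ``stat_fn(assignment)`` computes the group statistic when participant
    A of dyad i is paired with participant C of dyad ``assignment[i]``;
    the identity assignment gives the observed statistic.  When the
    number of distinct re-pairings (n!) does not exceed ``n_perm`` the
    null is enumerated exhaustively (identity included); otherwise
    ``n_perm`` random permutations are drawn, flagged by
    ``sampled_with_replacement`` in the result.

    Returns a dict with the observed statistic, the null distribution,
    the two-tailed percentile position of the observed value, and the
    significance flag at ``two_tailed_area``.
    """
    if n_dyads < 4:
        warnings.warn("fewer than 4 dyads gives a very coarse null",
                      stacklevel=2)
    if seed is None:
        raise ValueError("a seed is required for reproducible permutations")
    n_distinct = math.factorial(n_dyads)
    do_exhaustive = (n_distinct <= n_perm) if exhaustive is None else exhaustive

    observed = float(stat_fn(tuple(range(n_dyads))))
    null = []
    sampled = False
    if do_exhaustive:
        for assignment in itertools.permutations(range(n_dyads)):
            null.append(float(stat_fn(assignment)))
    else:
        sampled = n_perm > n_distinct
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            null.append(float(stat_fn(tuple(rng.permutation(n_dyads)))))
    null = np.asarray(null)
    # two-tailed percentile position of the observed statistic
    frac_ge = np.mean(null >= observed)
    frac_le = np.mean(null <= observed)
    p_two = float(min(1.0, 2.0 * min(frac_ge, frac_le)))
    return {
        "observed": observed,
        "null": null,
        "p_two_tailed": p_two,
        "significant": p_two < two_tailed_area,
        "exhaustive": do_exhaustive,
        "sampled_with_replacement": sampled,
    }


def score_correlation(phase_ins: Sequence[float],
                      scores: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation between per-dyad phase-averaged INS increases
    and behavioral scores, with its two-sided p-value."""
    x = np.asarray(phase_ins, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need matched 1-D value/score vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 dyads")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values and scores must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)
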