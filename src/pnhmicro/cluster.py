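"""Cluster-based permutation test of peri-event firing rates against baseline.

The design is one condition vs its own pre-event baseline, so the
exchangeable null is built by sign flips: each trial's binned rates are
reduced to a difference vector (bin rate minus that trial's mean baseline
rate), a one-sample t statistic is computed per bin, bins with two-tailed
``p < alpha_first`` form contiguous same-sign clusters scored by the sum of
their t values, and the null distribution records, per random sign
assignment, the maximum absolute cluster mass. Each observed cluster is then
compared one-sidedly against that maximum-statistic distribution with the
standard +1-corrected Monte-Carlo p-value.

Using the maximum over *both* directions as the correcting statistic keeps
the familywise error of the whole map at ``alpha_cluster``; a
``per_direction=True`` variant corrects each direction against its own
maximum (each direction then spends the full ``alpha_cluster``, so the
two-sided familywise rate roughly doubles). For small trial counts the full
``2^n`` sign assignment set can be enumerated exactly (``exact=True``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

ALPHA_FIRST = 0.01
ALPHA_CLUSTER = 0.05
N_PERM = 10_000


@dataclass
class Cluster:
    start_bin: int  # inclusive
    end_bin: int    # inclusive
    direction: str  # "up" | "down"
    mass: float     # sum of t values (signed)
    p_value: float

    @property
    def bins(self) -> range:
        return range(self.start_bin, self.end_bin + 1)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    alpha_first: float
    alpha_cluster: float
    n_perm: int
    seed: int | None
    t_values: np.ndarray
    exact: bool = False
    excluded_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha_cluster]

    def significant_bins(self, direction: str | None = None) -> np.ndarray:
        out = []
        for c in self.significant:
            if direction is None or c.direction == direction:
                out.extend(c.bins)
        return np.asarray(sorted(out), dtype=int)


def _find_clusters(t: np.ndarray, supra: np.ndarray) -> list[tuple[int, int, float]]:
    """Contiguous same-sign runs of suprathreshold bins -> (start, end, mass)."""
    out = []
    i, n = 0, t.size
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        sign = np.sign(t[i])
        while j + 1 < n and supra[j + 1] and np.sign(t[j + 1]) == sign:
            j += 1
        out.append((i, j, float(t[i : j + 1].sum())))
        i = j + 1
    return out


def _t_and_clusters(diff: np.ndarray, t_crit: float):
    """One-sample t per bin plus its suprathreshold clusters.

    Zero-variance bins have an undefined t; they are excluded from cluster
    formation (t set to 0, below any positive threshold).
    """
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    supra = np.abs(t) > t_crit
    return t, _find_clusters(t, supra)


def _max_masses(clusters) -> tuple[float, float]:
    """(max positive mass, max |negative mass|) of a cluster list."""
    pos = max((m for _, _, m in clusters if m > 0), default=0.0)
    neg = max((-m for _, _, m in clusters if m < 0), default=0.0)
    return pos, neg


def cluster_permutation_test(
    binned: np.ndarray,
    baseline: np.ndarray,
    alpha_first: float = ALPHA_FIRST,
    alpha_cluster: float = ALPHA_CLUSTER,
    n_perm: int = N_PERM,
    seed: int | None = 0,
    per_direction: bool = False,
    exact: bool = False,
    pairing: str = "paired",
) -> ClusterResult:
    """Sign-flip cluster permutation test.

    Parameters
    ----------
    binned : (trials, bins) peri-event rates.
    baseline : (trials, baseline_bins) rates defining each trial's reference.
    pairing : how the per-trial difference vector is formed.
        ``"paired"`` (default) subtracts a cyclically assigned *single*
        baseline bin from each bin: the difference of two identically
        distributed bins is symmetric under the null regardless of how
        skewed low-count firing rates are, which keeps the sign-flip null
        calibrated. ``"mean"`` subtracts the trial's mean baseline rate
        (lower variance, but anti-conservative for skewed counts because
        the first-level t becomes left-skewed).
    exact : enumerate all ``2^n`` sign assignments instead of Monte Carlo
        (trials <= 20 only); the p-value denominator is then ``2^n``.
    """
    binned = np.asarray(binned, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if binned.ndim != 2 or baseline.ndim != 2:
        raise ValueError("binned and baseline must be 2-D (trials x bins)")
    if binned.shape[0] != baseline.shape[0]:
        raise ValueError("binned and baseline must have the same trial count")
    n_trials, n_bins = binned.shape
    if n_trials < 5 and not exact:
        raise ValueError("at least 5 trials required")
    if pairing == "mean":
        diff = binned - baseline.mean(axis=1, keepdims=True)
    elif pairing == "paired":
        n_base = baseline.shape[1]
        if n_base < 2:
            raise ValueError("paired differencing needs >= 2 baseline bins")
        # The baseline window usually consists of columns of `binned` itself;
        # a cyclic assignment must then never difference a bin against its
        # own copy. Only one offset residue can collide, so the first of two
        # candidate offsets that produces no collision is safe.
        for offset in (1, 2):
            pair_idx = (np.arange(n_bins) + offset) % n_base
            collision = any(
                np.array_equal(binned[:, j], baseline[:, pair_idx[j]])
                for j in range(n_bins)
            )
            if not collision:
                break
        diff = binned - baseline[:, pair_idx]
    else:
        raise ValueError("pairing must be 'paired' or 'mean'")

    t_crit = stats.t.ppf(1 - alpha_first / 2, df=n_trials - 1)
    sd = diff.std(axis=0, ddof=1)
    excluded = np.flatnonzero(sd == 0)
    if excluded.size == n_bins:
        return ClusterResult([], alpha_first, alpha_cluster, n_perm, seed,
                             np.zeros(n_bins), exact, excluded)
    if excluded.size:
        warnings.warn(
            f"{excluded.size} zero-variance bins excluded from cluster formation",
            stacklevel=2,
        )
    t_obs, obs_clusters = _t_and_clusters(diff, t_crit)
    if not obs_clusters:
        return ClusterResult([], alpha_first, alpha_cluster, n_perm, seed,
                             t_obs, exact, excluded)

    if exact:
        if n_trials > 20:
            raise ValueError("exact enumeration limited to 20 trials")
        signs = np.array(
            [[1 if (p >> i) & 1 else -1 for i in range(n_trials)]
             for p in range(2**n_trials)],
            dtype=float,
        )
        n_eff = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_trials))
        n_eff = n_perm

    # Sign flips leave per-trial squares unchanged, so per-permutation
    # variances come from the flipped means alone.
    sq_sum = (diff**2).sum(axis=0)
    null_pos = np.empty(n_eff)
    null_neg = np.empty(n_eff)
    inv_n = 1.0 / n_trials
    for p in range(n_eff):
        mean_p = signs[p] @ diff * inv_n
        var_p = (sq_sum - n_trials * mean_p**2) / (n_trials - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_p = np.where(var_p > 0, mean_p / np.sqrt(var_p * inv_n), 0.0)
        null_pos[p], null_neg[p] = _max_masses(
            _find_clusters(t_p, np.abs(t_p) > t_crit)
        )
    null_both = np.maximum(null_pos, null_neg)

    clusters = []
    for start, end, mass in obs_clusters:
        if per_direction:
            null = null_pos if mass > 0 else null_neg
        else:
            null = null_both
        if exact:
            p_val = float(np.sum(null >= abs(mass))) / n_eff
        else:
            p_val = (1.0 + float(np.sum(null >= abs(mass)))) / (1.0 + n_eff)
        clusters.append(
            Cluster(start, end, "up" if mass > 0 else "down", mass, p_val)
        )
    return ClusterResult(
        clusters, alpha_first, alpha_cluster, n_perm if not exact else n_eff,
        seed, t_obs, exact, excluded
    )
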