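"""Resampling statistics: hierarchical bootstrap SEM, bootstrap difference
tests with Bonferroni correction, and max-statistic permutation tests.

The bootstrap resamples trials with replacement within each
condition-by-session cell, computes the statistic per channel/site, and then
aggregates up the recording hierarchy: the LFP path averages channels within
a session, sessions within a monkey, and finally monkeys (equal weight per
monkey); the MU path averages each site across its sessions and then across
sites. The SEM is the standard deviation of the B aggregate values
(B = 1000 by default).

Frequency- or time-resolved condition differences are tested by label
permutation with the iterative max-statistic step-down correction: bins
whose observed absolute difference exceeds the 95th percentile of the
per-permutation maxima are collected, removed from the observed and every
permutation distribution, and the criterion recomputed until nothing
further exceeds it. Trial counts are equalized by seeded subselection
before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BootstrapResult:
    point_estimate: float
    sem: float
    n_bootstraps: int
    hierarchy: str = "single"
    distribution: np.ndarray = field(default=None, repr=False)


@dataclass
class PermutationResult:
    observed: np.ndarray
    significant: np.ndarray  # boolean mask per bin
    critical_values: list
    n_permutations: int
    alpha: float
    fdr: float


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        df = data.copy()
    else:
        df = pd.DataFrame({"value": np.asarray(data, dtype=float)})
    for col in ("monkey", "session", "channel"):
        if col not in df:
            df[col] = 0
    return df


def bootstrap_sem(
    data,
    statistic=np.mean,
    b: int = 1000,
    hierarchy: str = "lfp",
    rng=None,
) -> BootstrapResult:
    """Hierarchical bootstrap SEM of a per-trial statistic.

    ``data`` is a DataFrame with a ``value`` column and optional ``monkey``,
    ``session``, ``channel`` grouping columns (missing levels collapse to a
    single group, so a plain array gives the ordinary bootstrap SEM of the
    statistic). ``hierarchy`` picks the aggregation path: ``"lfp"``
    (channels -> sessions -> monkeys) or ``"mu"`` (sessions -> sites, with
    ``channel`` read as site).
    """
    df = _as_frame(data)
    if len(df) == 0:
        raise ValueError("empty data")
    rng = np.random.default_rng(rng)
    cells = []  # (monkey, session, channel) -> values
    for key, sub in df.groupby(["monkey", "session"], sort=True):
        chans = {ch: s["value"].to_numpy() for ch, s in sub.groupby("channel", sort=True)}
        n_tr = len(next(iter(chans.values())))
        if any(len(v) != n_tr for v in chans.values()):
            # channels recorded simultaneously share trials; resample jointly
            raise ValueError("channels within a session must share trial count")
        if n_tr < 1:
            raise ValueError(f"empty condition cell {key}")
        cells.append((key, chans, n_tr))

    agg = np.empty(b)
    for i in range(b):
        per_monkey: dict = {}
        for (monkey, _), chans, n_tr in cells:
            take = rng.integers(0, n_tr, size=n_tr)
            stats = [statistic(v[take]) for v in chans.values()]
            if hierarchy == "lfp":
                session_val = float(np.mean(stats))  # average channels per session
                per_monkey.setdefault(monkey, []).append(session_val)
            elif hierarchy == "mu":
                # per-site values collected across sessions, keyed by site id
                for ch, s in zip(chans.keys(), stats):
                    per_monkey.setdefault(("site", ch), []).append(float(s))
            else:
                raise ValueError(f"unknown hierarchy {hierarchy!r}")
        # lfp: mean over sessions per monkey, then over monkeys
        # mu: mean over sessions per site, then over sites
        agg[i] = float(np.mean([np.mean(v) for v in per_monkey.values()]))

    # point estimate with the same aggregation, no resampling
    per_monkey = {}
    for (monkey, _), chans, _ in cells:
        stats = [statistic(v) for v in chans.values()]
        if hierarchy == "lfp":
            per_monkey.setdefault(monkey, []).append(float(np.mean(stats)))
        else:
            for ch, s in zip(chans.keys(), stats):
                per_monkey.setdefault(("site", ch), []).append(float(s))
    point = float(np.mean([np.mean(v) for v in per_monkey.values()]))
    return BootstrapResult(point, float(np.std(agg, ddof=0)), b, hierarchy, agg)


def bootstrap_difference_test(
    cond_a,
    cond_b,
    b: int = 1000,
    comparisons: int = 1,
    alpha: float = 0.05,
    statistic=np.mean,
    hierarchy: str = "lfp",
    rng=None,
) -> dict:
    """Two-sided bootstrap test of a condition difference, Bonferroni-adjusted.

    Builds the bootstrap distribution of the difference of aggregate
    statistics and computes a two-sided p-value from its sign distribution;
    significance is assessed at alpha/comparisons.
    """
    per_alpha = alpha / comparisons
    if b < 2.0 / per_alpha:
        raise ValueError(
            f"B={b} too small to resolve two-sided alpha {per_alpha:g} (need >= {2 / per_alpha:.0f})"
        )
    rng = np.random.default_rng(rng)
    ra = bootstrap_sem(cond_a, statistic, b, hierarchy, rng)
    rb = bootstrap_sem(cond_b, statistic, b, hierarchy, rng)
    diffs = ra.distribution - rb.distribution
    sem_diff = float(np.std(diffs, ddof=0))
    point = ra.point_estimate - rb.point_estimate
    # primary p: z-test on the bootstrap difference distribution; counting
    # tail bootstraps directly is too coarse at Bonferroni-level alphas
    # (expected tail count ~ B*alpha/k) and anticonservative
    from scipy.stats import norm as _norm

    if sem_diff == 0:
        p = 1.0 if point == 0 else 0.0
    else:
        p = float(2.0 * _norm.sf(abs(point) / sem_diff))
    p_low = (np.sum(diffs <= 0) + 1) / (b + 1)
    p_high = (np.sum(diffs >= 0) + 1) / (b + 1)
    p_percentile = min(1.0, 2.0 * min(p_low, p_high))
    return {
        "difference": point,
        "p": p,
        "p_percentile": float(p_percentile),
        "significant": bool(p < per_alpha),
        "alpha_per_comparison": per_alpha,
        "sem_difference": sem_diff,
    }


def equalize_trials(cond_a: np.ndarray, cond_b: np.ndarray, rng=None):
    """Random subselection to equal trial counts (seeded)."""
    rng = np.random.default_rng(rng)
    a, b = np.asarray(cond_a, dtype=float), np.asarray(cond_b, dtype=float)
    n = min(len(a), len(b))
    if n == 0:
        raise ValueError("no trials left after equalization")
    if len(a) > n:
        a = a[rng.choice(len(a), n, replace=False)]
    if len(b) > n:
        b = b[rng.choice(len(b), n, replace=False)]
    return a, b


def permutation_test_corrected(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    fdr: float = 0.05,
    rng=None,
) -> PermutationResult:
    """Bin-wise permutation test with iterative max-statistic correction.

    ``cond_a``/``cond_b`` are (n_trials, n_bins). Labels are shuffled
    ``n_permutations`` times; the critical value is the (1 - alpha)
    percentile of the per-permutation maxima of absolute mean differences.
    Significant bins are removed and the criterion recomputed until no bin
    exceeds it (family-wise step-down; the fdr parameter is recorded for
    provenance and the default behavior is the strict step-down).
    """
    if n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    import warnings as _warnings

    if n_permutations < 100:
        _warnings.warn("fewer than 100 permutations: critical values are coarse")
    rng = np.random.default_rng(rng)
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions must share the bin grid")
    n = min(a.shape[0], b.shape[0])
    if n == 0:
        raise ValueError("no trials left after equalization")
    if a.shape[0] > n:
        a = a[rng.choice(a.shape[0], n, replace=False)]
    if b.shape[0] > n:
        b = b[rng.choice(b.shape[0], n, replace=False)]

    pooled = np.vstack([a, b])
    observed = np.abs(a.mean(axis=0) - b.mean(axis=0))
    n_bins = pooled.shape[1]
    perm_abs = np.empty((n_permutations, n_bins))
    for p in range(n_permutations):
        idx = rng.permutation(2 * n)
        pa, pb = pooled[idx[:n]], pooled[idx[n:]]
        perm_abs[p] = np.abs(pa.mean(axis=0) - pb.mean(axis=0))

    active = np.ones(n_bins, dtype=bool)
    significant = np.zeros(n_bins, dtype=bool)
    criticals = []
    while active.any():
        crit = float(np.quantile(perm_abs[:, active].max(axis=1), 1.0 - alpha))
        criticals.append(crit)
        newly = active & (observed > crit)
        if not newly.any():
            break
        significant |= newly
        active &= ~newly
    return PermutationResult(
        observed=observed,
        significant=significant,
        critical_values=criticals,
        n_permutations=n_permutations,
        alpha=alpha,
        fdr=fdr,
    )
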