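"""Group-level nonparametric inference.

Implements the testing machinery used throughout the analyses:

* Mann-Whitney U with a Hodges-Lehmann shift estimate (exact, tie-aware
  enumeration for small samples; tie-corrected normal approximation
  otherwise);
* ROC/AUC by exhaustive threshold sweep (provably equal to the rank-sum
  probability-of-correct-ordering form, which the tests verify);
* classical one-way ANOVA;
* permutation-based temporal cluster correction: contiguous runs of
  supra-threshold time bins with a common direction are scored by their
  summed statistic mass and referred to the permutation distribution of the
  maximum cluster mass, which controls the family-wise error rate over bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

from .core import (
    ArousalSeries,
    EventSeries,
    InsufficientDataError,
    ParameterError,
    VocaldyadError,
    ZeroVarianceError,
)

__all__ = [
    "MWHLResult",
    "Cluster",
    "ClusterResult",
    "mw_hl",
    "roc_auc",
    "roc_auc_arousal",
    "oneway_f",
    "permutation_cluster",
    "permutation_cluster_anova",
]

#: combined sample size at or below which the exact Mann-Whitney p is used
EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class MWHLResult:
    """Mann-Whitney U test with Hodges-Lehmann shift estimate."""

    u: float
    p: float
    hl: float
    n: int
    m: int

    @property
    def direction(self) -> int:
        return int(np.sign(self.hl))


def _rank_sum_u(real: np.ndarray, control: np.ndarray) -> tuple[float, np.ndarray]:
    """U statistic of the first sample plus mid-ranks of the combined data."""
    n = len(real)
    combined = np.concatenate([real, control])
    ranks = sps.rankdata(combined)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    return u, ranks

def _exact_mw_p(ranks: np.ndarray, n: int, u_obs: float) -> float:
    """Two-sided permutation p for U over all label assignments.

    Counts, over all C(n+m, n) assignments of the observed mid-ranks to the
    first sample, how many rank sums fall at or beyond the observed one
    (so ties are handled exactly).  The count is done by dynamic
    programming over the subset-sum distribution of doubled mid-ranks
    (mid-ranks are multiples of 1/2, so doubling makes them integers),
    which is equivalent to full enumeration.
    """
    big_n = len(ranks)
    r2 = np.rint(2.0 * np.asarray(ranks)).astype(int)
    max_sum = int(r2.sum())
    # ways[j, s] = number of j-subsets of the ranks with doubled-sum s
    ways = np.zeros((n + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in r2:
        for j in range(n - 1, -1, -1):
            ways[j + 1, r:] += ways[j, : max_sum + 1 - r]
    dist = ways[n]
    total = comb(big_n, n)
    obs2 = int(np.rint(2.0 * (u_obs + n * (n + 1) / 2.0)))
    sums = np.arange(max_sum + 1)
    n_le = float(dist[sums <= obs2].sum())
    n_ge = float(dist[sums >= obs2].sum())
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def mw_hl(real, control) -> MWHLResult:
    """Mann-Whitney U comparing ``real`` vs ``control`` with HL effect size.

    The Hodges-Lehmann estimate is the median of all n*m pairwise
    differences (real - control).  The p-value is exact (full enumeration,
    tie-aware) when the combined sample size is <= 20 and otherwise uses the
    tie-corrected normal approximation.
    """
    real = np.asarray(real, dtype=float).ravel()
    control = np.asarray(control, dtype=float).ravel()
    real = real[np.isfinite(real)]
    control = control[np.isfinite(control)]
    if real.size == 0 or control.size == 0:
        raise InsufficientDataError("mw_hl requires two non-empty samples")
    n, m = real.size, control.size
    u, ranks = _rank_sum_u(real, control)
    if n + m <= EXACT_MW_MAX_N:
        p = _exact_mw_p(ranks, n, u)
    else:
        p = float(
            sps.mannwhitneyu(real, control, alternative="two-sided", method="asymptotic").pvalue
        )
    hl = float(np.median(np.subtract.outer(real, control)))
    return MWHLResult(u=u, p=p, hl=hl, n=n, m=m)


def _mw_z(real: np.ndarray, control: np.ndarray) -> float:
    """Signed, tie-corrected normal-approximation z (no continuity correction).

    Positive z means ``real`` tends to exceed ``control``.
    """
    n, m = len(real), len(control)
    if n == 0 or m == 0:
        return np.nan
    u, ranks = _rank_sum_u(real, control)
    big_n = n + m
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1.0)))
    if var <= 0:
        return 0.0
    return float((u - n * m / 2.0) / np.sqrt(var))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(values, labels) -> float:
    """AUC of ``values`` predicting boolean ``labels`` by threshold sweep.

    The data are thresholded at every unique value; at each threshold an
    observation counts as a hit (above threshold, label true) or false alarm
    (above threshold, label false).  The resulting ROC curve is integrated
    by the trapezoid rule, which makes tied values count one half.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if values.shape != labels.shape:
        raise VocaldyadError("values and labels must have the same length")
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    pos = np.sort(values[labels])
    neg = np.sort(values[~labels])
    if pos.size == 0 or neg.size == 0:
        raise InsufficientDataError("AUC needs at least one epoch of each class")
    thresholds = np.unique(values)[::-1]
    # fraction strictly above each threshold
    tpr = (pos.size - np.searchsorted(pos, thresholds, side="right")) / pos.size
    fpr = (neg.size - np.searchsorted(neg, thresholds, side="right")) / neg.size
    fpr = np.append(fpr, 1.0)
    tpr = np.append(tpr, 1.0)
    return float(np.trapezoid(tpr, fpr))


def roc_auc_arousal(
    series: ArousalSeries,
    events: EventSeries,
    speaker: str | None = None,
    category: str | None = None,
) -> float:
    """Epoch-level AUC of one participant's arousal predicting event presence."""
    occ = events.occupancy(speaker=speaker, category=category)
    idx = series.valid
    return roc_auc(series.values[idx], occ[idx])


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------

def oneway_f(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across the given samples."""
    cleaned = []
    for g in groups:
        g = np.asarray(g, dtype=float).ravel()
        g = g[np.isfinite(g)]
        if g.size < 2:
            raise InsufficientDataError("each ANOVA group needs >= 2 values")
        cleaned.append(g)
    if len(cleaned) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    allv = np.concatenate(cleaned)
    if np.ptp(allv) == 0.0:
        raise ZeroVarianceError("all ANOVA values identical")
    res = sps.f_oneway(*cleaned)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Permutation-based temporal clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    """A maximal run of contiguous supra-threshold bins with common sign."""

    start: int  # first bin index (inclusive)
    stop: int   # last bin index (exclusive)
    sign: int
    mass: float
    p: float

    @property
    def bins(self) -> range:
        return range(self.start, self.stop)


@dataclass(frozen=True)
class ClusterResult:
    """Per-bin statistics plus permutation-corrected cluster p-values."""

    stat: np.ndarray          # per-bin statistic (signed z, or F)
    supra: np.ndarray         # per-bin cluster-forming exceedance
    clusters: tuple[Cluster, ...]
    null_max: np.ndarray      # permutation distribution of max cluster mass
    n_perm: int
    cluster_alpha: float

    def significant(self, alpha: float = 0.05) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.p <= alpha)

    def any_significant(self, alpha: float = 0.05) -> bool:
        return len(self.significant(alpha)) > 0


def _scan_clusters(stat: np.ndarray, supra: np.ndarray) -> list[tuple[int, int, int, float]]:
    """Maximal same-sign runs of supra-threshold bins: (start, stop, sign, mass)."""
    out: list[tuple[int, int, int, float]] = []
    n = len(stat)
    b = 0
    while b < n:
        if not supra[b] or not np.isfinite(stat[b]) or stat[b] == 0.0:
            b += 1
            continue
        sign = 1 if stat[b] > 0 else -1
        start = b
        mass = 0.0
        while b < n and supra[b] and np.isfinite(stat[b]) and (stat[b] > 0) == (sign > 0):
            mass += abs(stat[b])
            b += 1
        out.append((start, b, sign, mass))
    return out


def _max_cluster_mass(stat: np.ndarray, supra: np.ndarray) -> float:
    runs = _scan_clusters(stat, supra)
    return max((mass for *_, mass in runs), default=0.0)


def _cluster_p(mass: float, null_max: np.ndarray) -> float:
    return float((1 + np.sum(null_max >= mass - 1e-12)) / (len(null_max) + 1))


def _validate_pb(real: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    real = np.asarray(real, dtype=float)
    control = np.asarray(control, dtype=float)
    if real.ndim != 2 or control.shape != real.shape:
        raise VocaldyadError("real and control must be (participants x bins) of equal shape")
    if real.shape[0] < 8:
        raise InsufficientDataError(
            f"cluster test needs >= 8 participants, got {real.shape[0]}"
        )
    return real, control


def permutation_cluster(
    real,
    control,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed=None,
    mode: str = "swap",
) -> ClusterResult:
    """Permutation-based temporal cluster test of real vs control profiles.

    Parameters
    ----------
    real, control : (participants x bins) arrays
        Per-participant per-bin values (NaN allowed; a participant enters a
        bin only when both conditions are finite there).
    mode : "swap" or "signflip"
        "swap" permutes the real/control labels within each participant and
        suits observed-vs-resampled-control comparisons.  "signflip"
        requires the control to be all zeros (comparison against a chance
        level of 0) and flips the sign of each participant's profile.

    Procedure: per bin, a signed tie-corrected Mann-Whitney z compares real
    vs control across participants; bins with two-sided p < ``cluster_alpha``
    form clusters of contiguous, same-sign bins scored by the sum of |z|;
    each observed cluster mass is referred to the permutation distribution
    of the maximum cluster mass, p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    real, control = _validate_pb(real, control)
    if mode not in ("swap", "signflip"):
        raise ParameterError(f"unknown permutation mode {mode!r}")
    n_part, n_bins = real.shape
    pairwise = np.isfinite(real) & np.isfinite(control)
    if mode == "signflip" and not np.all(control[pairwise] == 0.0):
        raise ParameterError("signflip mode requires an all-zero control")
    rng = np.random.default_rng(seed)
    z_crit = float(sps.norm.ppf(1.0 - cluster_alpha / 2.0))

    # Per-bin mid-ranks of the fixed combined sample (for the swap fast path)
    rank_real = np.zeros((n_part, n_bins))
    rank_ctrl = np.zeros((n_part, n_bins))
    n_b = pairwise.sum(axis=0)
    sigma = np.zeros(n_bins)
    z_obs = np.full(n_bins, np.nan)
    for b in range(n_bins):
        idx = pairwise[:, b]
        nb = int(n_b[b])
        if nb == 0:
            continue
        combined = np.concatenate([real[idx, b], control[idx, b]])
        ranks = sps.rankdata(combined)
        rank_real[idx, b] = ranks[:nb]
        rank_ctrl[idx, b] = ranks[nb:]
        big_n = 2 * nb
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
        var = nb * nb / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1.0)))
        sigma[b] = np.sqrt(var) if var > 0 else 0.0
        z_obs[b] = _mw_z(real[idx, b], control[idx, b])

    offset = n_b * (n_b + 1) / 2.0 + n_b * n_b / 2.0  # rank-sum -> centred U
    null_max = np.empty(n_perm)
    if mode == "swap":
        swaps = rng.integers(0, 2, size=(n_perm, n_part)).astype(float)
        ranksum = swaps @ rank_ctrl + (1.0 - swaps) @ rank_real  # (n_perm, n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            z_null = np.where(sigma > 0, (ranksum - offset) / sigma, 0.0)
        for i in range(n_perm):
            z = z_null[i]
            null_max[i] = _max_cluster_mass(z, np.abs(z) > z_crit)
    else:
        zeros = np.zeros(n_part)
        for i in range(n_perm):
            flips = rng.choice([-1.0, 1.0], size=n_part)
            z = np.full(n_bins, np.nan)
            for b in range(n_bins):
                idx = pairwise[:, b]
                if n_b[b] == 0:
                    continue
                z[b] = _mw_z(real[idx, b] * flips[idx], zeros[idx])
            z_finite = np.where(np.isfinite(z), z, 0.0)
            null_max[i] = _max_cluster_mass(z_finite, np.abs(z_finite) > z_crit)

    z_for_scan = np.where(np.isfinite(z_obs), z_obs, 0.0)
    supra = np.abs(z_for_scan) > z_crit
    clusters = tuple(
        Cluster(start, stop, sign, mass, _cluster_p(mass, null_max))
        for start, stop, sign, mass in _scan_clusters(z_for_scan, supra)
    )
    return ClusterResult(
        stat=z_obs,
        supra=supra,
        clusters=clusters,
        null_max=null_max,
        n_perm=n_perm,
        cluster_alpha=cluster_alpha,
    )


def _anova_f_bins(values: np.ndarray, row_ok: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way F per bin on a (P, G, B) array of group means.

    ``row_ok[p, b]`` marks participants contributing all G group values at
    bin b.  Returns (F, p) per bin (NaN where < 2 usable participants).
    """
    n_part, n_groups, n_bins = values.shape
    w = row_ok.astype(float)[:, None, :]  # (P, 1, B)
    x = np.where(np.isfinite(values), values, 0.0) * w
    n = row_ok.sum(axis=0).astype(float)  # usable participants per bin
    with np.errstate(invalid="ignore", divide="ignore"):
        gmean = x.sum(axis=0) / n  # (G, B)
        grand = gmean.mean(axis=0)  # (B,)
        ssb = n * ((gmean - grand) ** 2).sum(axis=0)
        ssw = (((x - gmean[None]) * w) ** 2).sum(axis=(0, 1))
        df1 = n_groups - 1
        df2 = n_groups * (n - 1)
        f = (ssb / df1) / (ssw / df2)
    bad = (n < 2) | ~np.isfinite(f)
    f = np.where(bad, np.nan, f)
    p = np.where(bad, np.nan, sps.f.sf(np.where(bad, 1.0, f), df1, np.maximum(df2, 1)))
    return f, p


def permutation_cluster_anova(
    group_values,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed=None,
) -> ClusterResult:
    """Cluster-corrected repeated one-way ANOVA across groups over time bins.

    ``group_values`` is (participants x groups x bins): per-participant group
    means (e.g. partner-arousal trajectories for each vocaliser-arousal
    quartile).  Per bin a one-way F is computed across groups on
    participant-level means; bins with p < ``cluster_alpha`` form contiguous
    clusters scored by summed F; the null permutes group labels within each
    participant (one permutation per participant, shared across bins).
    """
    values = np.asarray(group_values, dtype=float)
    if values.ndim != 3:
        raise VocaldyadError("group_values must be (participants x groups x bins)")
    n_part, n_groups, n_bins = values.shape
    if n_part < 8:
        raise InsufficientDataError(f"cluster ANOVA needs >= 8 participants, got {n_part}")
    if n_groups < 2:
        raise InsufficientDataError("cluster ANOVA needs >= 2 groups")
    rng = np.random.default_rng(seed)
    row_ok = np.isfinite(values).all(axis=1)  # (P, B)

    f_obs, p_obs = _anova_f_bins(values, row_ok)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        order = np.argsort(rng.random((n_part, n_groups)), axis=1)
        permuted = np.take_along_axis(values, order[:, :, None], axis=1)
        f_null, p_null = _anova_f_bins(permuted, row_ok)
        f_finite = np.where(np.isfinite(f_null), f_null, 0.0)
        null_max[i] = _max_cluster_mass(f_finite, np.nan_to_num(p_null, nan=1.0) < cluster_alpha)

    f_finite = np.where(np.isfinite(f_obs), f_obs, 0.0)
    supra = np.nan_to_num(p_obs, nan=1.0) < cluster_alpha
    clusters = tuple(
        Cluster(start, stop, sign, mass, _cluster_p(mass, null_max))
        for start, stop, sign, mass in _scan_clusters(f_finite, supra)
    )
    return ClusterResult(
        stat=f_obs,
        supra=supra,
        clusters=clusters,
        null_max=null_max,
        n_perm=n_perm,
        cluster_alpha=cluster_alpha,
    )
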