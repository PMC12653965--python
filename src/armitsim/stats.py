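"""Inferential layer: exact Mann–Whitney U, chance levels, KDE, absolute risk.

Small behavioural cohorts (here 4-24 subjects per group) sit squarely in
the regime where the Mann–Whitney U null distribution must be
enumerated rather than approximated, so the exact test is implemented
by direct enumeration of all C(n1+n2, n1) rank assignments, with
mid-ranks (and permutation over the observed values) under ties.  The
Gaussian KDE and the absolute-risk (risk-difference / number needed to
harm) calculation mirror the downstream risk analysis applied to
per-subject success rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

#: sample-size bound below which the exact enumeration is used by default
EXACT_LIMIT = 20


def chance_level(stage_id: str) -> float:
    """Expected success of uniform-random selection among lit holes.

    0.5 for C12 (one rewarded of two lit) and 0.25 for C13 (one of
    four).  C11 has no chance level — both lit holes are rewarded —
    so requesting it is an error.
    """
    if stage_id == "C12":
        return 0.5
    if stage_id == "C13":
        return 0.25
    raise ValueError(f"chance level undefined for stage {stage_id!r}")


def below_chance_flag(success_rate: float, stage_id: str) -> bool:
    """True iff the rate is strictly below the stage's chance level."""
    return float(success_rate) < chance_level(stage_id)


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-sided Mann–Whitney U comparison."""

    u_statistic: float  # U of the first sample
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" | "normal-approximation"


def _u_from_ranks(rank_sum: float, n1: int) -> float:
    return rank_sum - n1 * (n1 + 1) / 2.0


def mann_whitney_exact(sample_a: Sequence[float], sample_b: Sequence[float],
                       method: str = "auto", tail: str = "doubled") -> GroupComparison:
    """Two-sided Mann–Whitney U test with exact small-sample enumeration.

    For ``n1 + n2 <= 20`` (or ``method="exact"``) the permutation null is
    enumerated exactly over all C(n1+n2, n1) assignments of the pooled
    mid-ranks, which handles ties by construction.  Larger samples fall
    back to the tie-corrected, continuity-corrected normal
    approximation.

    ``tail`` selects the two-sided rule: ``"doubled"`` doubles the
    smaller one-sided tail and caps at 1 (common software behaviour);
    ``"both"`` sums the probability of outcomes at least as far from the
    null mean n1*n2/2 in either direction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if tail not in ("doubled", "both"):
        raise ValueError("tail must be 'doubled' or 'both'")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # mid-ranks under ties
    u_obs = _u_from_ranks(ranks[:n1].sum(), n1)

    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    use_exact = method == "exact" or (method == "auto" and n1 + n2 <= EXACT_LIMIT)

    if use_exact:
        p = _exact_p(ranks, n1, u_obs, tail)
        return GroupComparison(float(u_obs), p, n1, n2, "exact")
    return GroupComparison(float(u_obs), _normal_p(ranks, n1, n2, u_obs), n1, n2,
                           "normal-approximation")


def _exact_p(ranks: np.ndarray, n1: int, u_obs: float, tail: str) -> float:
    n = ranks.size
    mean_u = n1 * (n - n1) / 2.0
    total = math.comb(n, n1)
    n_le = n_ge = n_far = 0
    offset = n1 * (n1 + 1) / 2.0
    d_obs = abs(u_obs - mean_u)
    eps = 1e-9
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
        if abs(u - mean_u) >= d_obs - eps:
            n_far += 1
    if tail == "doubled":
        p = 2.0 * min(n_le, n_ge) / total
    else:
        p = n_far / total
    return min(1.0, p)


def _normal_p(ranks: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return 1.0
    z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(var_u)  # continuity corrected
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


# ---------------------------------------------------------------------------
# Kernel density estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KDEResult:
    """Gaussian KDE evaluated on a grid spanning the data +/- 5 bandwidths."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    return 0.9 * spread * v.size ** (-1 / 5)


def kde_density(values: Sequence[float], bandwidth="silverman",
                grid_size: int = 512) -> KDEResult:
    """Gaussian kernel density estimate of a sample.

    ``density(x) = (1 / (n h)) * sum_i phi((x - v_i) / h)``, evaluated on
    a uniform grid covering the data +/- 5 bandwidths.  With an
    automatic bandwidth the sample needs >= 2 distinct values; pass an
    explicit ``bandwidth`` for degenerate samples.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if bandwidth == "silverman":
        if np.unique(v).size < 2:
            raise ValueError("automatic bandwidth needs >= 2 distinct values; "
                             "pass an explicit bandwidth")
        h = silverman_bandwidth(v)
    else:
        h = float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    grid = np.linspace(v.min() - 5 * h, v.max() + 5 * h, grid_size)
    density = norm.pdf((grid[:, None] - v[None, :]) / h).sum(axis=1) / (v.size * h)
    return KDEResult(grid, density, h)


def kde_cdf_below(values: Sequence[float], threshold: float,
                  bandwidth="silverman") -> float:
    """Exact cumulative mass of the Gaussian KDE below ``threshold``.

    The KDE is a Gaussian mixture, so its CDF is the mean of the
    component normal CDFs — no grid integration error.
    """
    v = np.asarray(values, dtype=float)
    if bandwidth == "silverman":
        if np.unique(v).size < 2:
            raise ValueError("automatic bandwidth needs >= 2 distinct values")
        h = silverman_bandwidth(v)
    else:
        h = float(bandwidth)
    return float(norm.cdf((threshold - v) / h).mean())


# ---------------------------------------------------------------------------
# Absolute risk
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskEstimate:
    """Absolute risk of below-chance performance attributable to exposure."""

    p_exposed: float
    p_control: float

    @property
    def risk_difference(self) -> float:
        return self.p_exposed - self.p_control

    @property
    def nnh(self) -> float | None:
        """Number needed to harm, 1/|risk difference|; None at zero difference."""
        rd = self.risk_difference
        return None if rd == 0 else 1.0 / abs(rd)


def absolute_risk(control_flags: Sequence[bool],
                  exposed_flags: Sequence[bool]) -> RiskEstimate:
    """Risk estimate from empirical below-chance proportions per group."""
    control = np.asarray(control_flags, dtype=bool)
    exposed = np.asarray(exposed_flags, dtype=bool)
    if control.size == 0 or exposed.size == 0:
        raise ValueError("both groups must be non-empty")
    return RiskEstimate(p_exposed=float(exposed.mean()), p_control=float(control.mean()))


def absolute_risk_kde(control_rates: Sequence[float], exposed_rates: Sequence[float],
                      stage_id: str = "C12", bandwidth="silverman") -> RiskEstimate:
    """Risk estimate with KDE smoothing: per-group KDE mass below chance."""
    thr = chance_level(stage_id)
    return RiskEstimate(
        p_exposed=kde_cdf_below(exposed_rates, thr, bandwidth),
        p_control=kde_cdf_below(control_rates, thr, bandwidth))


def holm_adjust(p_values: Sequence[float]) -> list:
    """Holm step-down adjusted p-values (optional; unadjusted is the default report)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj.tolist()
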