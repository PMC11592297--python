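"""Nonparametric longitudinal statistics battery.

The design: paired visits are compared with the Wilcoxon signed-rank test,
two-sided first; only when the two-sided test rejects at level alpha is a
one-sided follow-up run to report the direction of change.  Rank-based
effect sizes r = |z| / sqrt(n) are graded small (< 0.3), moderate
(0.3 <= r < 0.5) or large (>= 0.5).  Post-treatment vs healthy-control
contrasts use the Mann-Whitney U test with the same two-stage gate, and
severity-stage contrasts use Kruskal-Wallis with Dunn's post-hoc z tests.

Sample-size machinery: the paired-t sample size from the noncentral-t
power equation, inflated by the Wilcoxon signed-rank test's asymptotic
relative efficiency — the conservative minimum-ARE bound 0.864 by default,
or the normal-theory 3/pi.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedComparisonResult",
    "GroupComparisonResult",
    "KruskalDunnResult",
    "PowerSpec",
    "MIN_ARE",
    "NORMAL_ARE",
    "wilcoxon_signed_rank",
    "effect_size_r",
    "mann_whitney",
    "kruskal_dunn",
    "estimate_sample_size",
    "simulate_power",
]

#: Worst-case ARE of the Wilcoxon signed-rank test vs the paired t-test.
MIN_ARE = 0.864
#: ARE under normally distributed differences.
NORMAL_ARE = 3.0 / math.pi

_GRADE_CUTS = (0.3, 0.5)  # small < 0.3 <= moderate < 0.5 <= large


class InsufficientDataError(ValueError):
    """Raised when a test precondition on sample size is violated."""


@dataclass
class PairedComparisonResult:
    n_pairs: int
    statistic: float
    p_two_sided: float
    p_one_sided: float | None
    effect_r: float
    effect_grade: str
    direction: str  # 'increase' or 'decrease' (after relative to before)
    feature: str = ""
    layer: str = ""
    week_pair: tuple | None = None

    @property
    def significant(self) -> bool:
        return self.p_one_sided is not None


@dataclass
class GroupComparisonResult:
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U of group a
    p_two_sided: float
    p_one_sided: float | None
    effect_r: float
    effect_grade: str
    direction: str  # 'increase': group a tends larger than group b
    feature: str = ""
    layer: str = ""


@dataclass
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    df: int
    omnibus_rejected: bool
    pairwise: pd.DataFrame | None
    excluded_groups: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


@dataclass
class PowerSpec:
    """Design parameters for the paired Wilcoxon sample-size estimate."""

    alpha: float = 0.05
    power: float = 0.9
    effect_dz: float = 0.5
    are_method: str = "min_are"  # min_are | normal_are | none

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.effect_dz <= 0:
            raise ValueError("effect_dz must be positive")
        if self.are_method not in ("min_are", "normal_are", "none"):
            raise ValueError("are_method must be one of min_are, normal_are, none")


def effect_size_r(z_statistic: float, n_pairs: int) -> tuple[float, str]:
    """Rank effect size r = |z|/sqrt(n) and its grade.

    Grades: small (r < 0.3), moderate (0.3 <= r < 0.5), large (r >= 0.5).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    r = abs(z_statistic) / math.sqrt(n_pairs)
    if r < _GRADE_CUTS[0]:
        grade = "small"
    elif r < _GRADE_CUTS[1]:
        grade = "moderate"
    else:
        grade = "large"
    return r, grade


def _signed_rank_z(d: np.ndarray) -> tuple[float, float]:
    """(W+, z) of the signed-rank statistic via the tie-corrected normal
    approximation with continuity correction.  Used for effect sizes
    regardless of whether the p-value came from the exact distribution."""
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return w_plus, 0.0
    dev = w_plus - mu
    dev -= 0.5 * np.sign(dev)  # continuity correction
    return w_plus, float(dev / math.sqrt(var))


def wilcoxon_signed_rank(
    x_before, x_after, alpha: float = 0.05
) -> PairedComparisonResult:
    """Two-stage paired Wilcoxon: two-sided gate, then one-sided follow-up.

    Zero differences are dropped (the classical Wilcoxon convention).  The
    exact null distribution is used for n <= 25 without ties; otherwise
    the tie- and continuity-corrected normal approximation.  The one-sided
    p is computed, in the direction of the observed rank sums, only when
    the two-sided test rejects at ``alpha``.
    """
    x_before = np.asarray(x_before, dtype=float)
    x_after = np.asarray(x_after, dtype=float)
    if x_before.shape != x_after.shape:
        raise ValueError("paired samples must have equal length")
    d = x_after - x_before
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise InsufficientDataError(
            f"only {n} nonzero paired differences (need at least 5)"
        )
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    p_two = float(res.pvalue)
    w_plus, z = _signed_rank_z(d)
    direction = "increase" if w_plus > n * (n + 1) / 4.0 else "decrease"
    p_one = None
    if p_two < alpha:
        alt = "greater" if direction == "increase" else "less"
        p_one = float(
            sps.wilcoxon(d, alternative=alt, method=method, correction=True).pvalue
        )
    r, grade = effect_size_r(z, n)
    return PairedComparisonResult(n, w_plus, p_two, p_one, r, grade, direction)


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected continuity-corrected z of the Mann-Whitney U of ``a``."""
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0
    dev = u1 - mu
    dev -= 0.5 * np.sign(dev)
    return float(dev / math.sqrt(var))


def mann_whitney(group_a, group_b, alpha: float = 0.05) -> GroupComparisonResult:
    """Two-stage Mann-Whitney U: two-sided gate, then directional follow-up.

    Exact for small untied samples, otherwise the tie-corrected normal
    approximation with continuity correction.  ``direction='increase'``
    means group a tends to exceed group b.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("empty group")
    if min(a.size, b.size) < 3:
        raise InsufficientDataError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p_two = float(res.pvalue)
    u1 = float(res.statistic)
    direction = "increase" if u1 > a.size * b.size / 2.0 else "decrease"
    p_one = None
    if p_two < alpha:
        alt = "greater" if direction == "increase" else "less"
        p_one = float(sps.mannwhitneyu(a, b, alternative=alt, method=method).pvalue)
    z = _rank_sum_z(a, b)
    r, grade = effect_size_r(z, a.size + b.size)
    return GroupComparisonResult(a.size, b.size, u1, p_two, p_one, r, grade, direction)


def kruskal_dunn(
    groups: dict, alpha: float = 0.05, adjust: str = "holm"
) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus with Dunn's pairwise post-hoc z tests.

    Groups with fewer than 2 observations are excluded with a recorded
    warning.  Pairwise p-values use the pooled-rank Dunn z statistic with
    tie correction, adjusted by ``adjust`` ('holm' default, 'none' for raw
    p-values).  The pairwise table is populated only when the omnibus test
    rejects at ``alpha``.
    """
    clean = {}
    excluded, warns = [], []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            excluded.append(name)
            warns.append(f"group {name!r} excluded: n={v.size} < 2")
        else:
            clean[name] = v
    if len(clean) < 2:
        raise InsufficientDataError("need at least 2 groups with n >= 2")
    names = sorted(clean)
    if np.unique(np.concatenate([clean[k] for k in names])).size == 1:
        # all observations identical: no evidence of any group difference
        return KruskalDunnResult(0.0, 1.0, len(names) - 1, False, None, excluded, warns)
    h, p = sps.kruskal(*[clean[k] for k in names])
    rejected = bool(p < alpha)
    pairwise = _dunn_table(clean, names, adjust, alpha) if rejected else None
    return KruskalDunnResult(float(h), float(p), len(names) - 1, rejected, pairwise, excluded, warns)


def _dunn_table(clean: dict, names: list, adjust: str, alpha: float) -> pd.DataFrame:
    pooled = np.concatenate([clean[k] for k in names])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    pos = 0
    for k in names:
        sz = clean[k].size
        mean_ranks[k] = ranks[pos : pos + sz].mean()
        sizes[k] = sz
        pos += sz
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            se = math.sqrt(base_var * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
            p_raw = 2.0 * sps.norm.sf(abs(z))
            rows.append(dict(group_a=gi, group_b=gj, z=z, p_raw=min(1.0, p_raw)))
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adj"] = table["p_raw"]
    else:
        table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method=adjust)[1]
    table["significant"] = table["p_adj"] < alpha
    return table


# ---------------------------------------------------------------------------
# Sample size and power
# ---------------------------------------------------------------------------

def _paired_t_power(n: int, dz: float, alpha: float) -> float:
    df = n - 1
    nc = dz * math.sqrt(n)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def estimate_sample_size(spec: PowerSpec, n_max: int = 100000) -> int:
    """Smallest paired sample size reaching the target power.

    Finds the minimal n whose two-sided noncentral-t paired-test power at
    effect ``dz`` reaches ``spec.power``, then inflates it for the
    Wilcoxon signed-rank test by the chosen asymptotic relative
    efficiency: ``min_are`` divides by 0.864 (conservative bound),
    ``normal_are`` by 3/pi, ``none`` returns the t-test n.  The search
    starts at n = 2, the smallest size with a defined t statistic.
    """
    n_t = None
    for n in range(2, n_max + 1):
        if _paired_t_power(n, spec.effect_dz, spec.alpha) >= spec.power:
            n_t = n
            break
    if n_t is None:
        raise ValueError(f"no n <= {n_max} reaches power {spec.power}")
    are = {"min_are": MIN_ARE, "normal_are": NORMAL_ARE, "none": 1.0}[spec.are_method]
    return math.ceil(n_t / are)


def simulate_power(
    spec: PowerSpec, n: int, n_reps: int = 10000, seed: int = 0
) -> float:
    """Empirical power of the two-sided Wilcoxon signed-rank test.

    Draws ``n_reps`` cohorts of n paired differences from
    Normal(spec.effect_dz, 1), applies the two-sided test at
    ``spec.alpha`` (tie- and continuity-corrected normal approximation;
    continuous data make ties almost surely absent) and returns the
    rejection fraction.
    """
    if n < 5:
        raise InsufficientDataError("n must be at least 5")
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} is small; power estimate will be noisy")
    rng = np.random.default_rng(seed)
    d = rng.normal(spec.effect_dz, 1.0, size=(n_reps, n))
    res = sps.wilcoxon(d, axis=1, alternative="two-sided", method="approx", correction=True)
    return float((res.pvalue < spec.alpha).mean())
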