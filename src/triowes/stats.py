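"""Case-control burden statistics for 2x2 exposure tables.

The point estimate is the sample cross-product odds ratio ad/bc.  The
confidence interval is the exact conditional (Cornfield-type) interval
obtained by inverting Fisher's exact test under Fisher's noncentral
hypergeometric distribution: with both margins fixed and X = the
exposed-case cell,

    P(X = k | psi)  proportional to  C(m1, k) C(m2, n1-k) psi**k ,

the lower bound is the psi with P(X >= a | psi) = alpha/2 and the upper
bound the psi with P(X <= a | psi) = alpha/2.  With ten cases and ten
controls per arm these exact bounds are the only interval consistent
with small-sample inference; large-sample (Woolf) intervals are offered
for comparison.  A mid-p variant (half weight on the observed table) is
also available.

Companion tests: Pearson chi-square without continuity correction
(2x2 closed form, general 2xk observed-vs-expected), two-sided Fisher
exact, and the pooled-variance two-sample t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats as sps


class TableError(ValueError):
    """Raised for structurally invalid contingency tables."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case-control exposure table.

    a = cases exposed, b = cases unexposed, c = controls exposed,
    d = controls unexposed.
    """

    a: int
    b: int
    c: int
    d: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise TableError(f"negative cell in {self.cells}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def transpose_groups(self) -> "ContingencyTable":
        """Swap the case and control rows."""
        return ContingencyTable(self.c, self.d, self.a, self.b, self.label)


def odds_ratio(t: ContingencyTable) -> float:
    """Sample cross-product odds ratio ad / bc.

    Returns ``inf`` when bc = 0 with ad > 0 and ``nan`` when both
    products vanish (undefined); no exception is raised.
    """
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


# ---------------------------------------------------------------------------
# noncentral hypergeometric machinery


def _nchg_logweights(m1: int, m2: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and log binomial weights of X ~ FNCHG(m1, m2, n1, psi)."""
    lo, hi = max(0, n1 - m2), min(m1, n1)
    ks = np.arange(lo, hi + 1)
    logw = np.array([
        math.lgamma(m1 + 1) - math.lgamma(k + 1) - math.lgamma(m1 - k + 1)
        + math.lgamma(m2 + 1) - math.lgamma(n1 - k + 1) - math.lgamma(m2 - n1 + k + 1)
        for k in ks
    ])
    return ks, logw


def _nchg_pmf(log_psi: float, ks: np.ndarray, logw: np.ndarray) -> np.ndarray:
    logp = logw + ks * log_psi
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def _tail_upper(log_psi: float, a: int, ks: np.ndarray, logw: np.ndarray,
                mid_p: bool) -> float:
    """P(X >= a | psi), or the mid-p analogue with half weight on X = a."""
    p = _nchg_pmf(log_psi, ks, logw)
    w = np.where(ks > a, 1.0, np.where(ks == a, 0.5 if mid_p else 1.0, 0.0))
    return float(p @ w)


def _tail_lower(log_psi: float, a: int, ks: np.ndarray, logw: np.ndarray,
                mid_p: bool) -> float:
    p = _nchg_pmf(log_psi, ks, logw)
    w = np.where(ks < a, 1.0, np.where(ks == a, 0.5 if mid_p else 1.0, 0.0))
    return float(p @ w)


_LOG_PSI_LO, _LOG_PSI_HI = math.log(1e-12), math.log(1e12)


def _invert_tail(f: Callable[[float], float], target: float) -> float:
    """Solve f(log psi) = target by bisection; f must be monotone
    increasing in psi.  Bisection to ~1e-13 on log psi."""
    lo, hi = _LOG_PSI_LO, _LOG_PSI_HI
    flo, fhi = f(lo) - target, f(hi) - target
    if flo > 0:
        return math.exp(lo)
    if fhi < 0:
        return math.exp(hi)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if f(mid) - target <= 0:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi))


def exact_or_ci(t: ContingencyTable, level: float = 0.95, *,
                mid_p: bool = False) -> tuple[float, float]:
    """Exact conditional confidence interval for the odds ratio.

    With ``mid_p=False`` (default) the bounds are the classical
    Cornfield exact bounds; ``mid_p=True`` gives the less conservative
    mid-p interval.  Tables with the observed cell at the edge of the
    conditional support get 0 / +inf bounds.
    """
    if not 0.0 < level < 1.0:
        raise TableError(f"level must be in (0,1), got {level}")
    m1, m2 = t.n_cases, t.n_controls
    n1 = t.a + t.c
    if m1 == 0 or m2 == 0 or n1 == 0 or (t.b + t.d) == 0:
        raise TableError(f"table {t.cells} has an empty margin")
    ks, logw = _nchg_logweights(m1, m2, n1)
    a = t.a
    alpha = (1.0 - level) / 2.0
    # lower bound: psi with P(X >= a | psi) = alpha (upper tail increases in psi)
    if a == ks[0] and not mid_p:
        lo = 0.0
    else:
        lo = _invert_tail(lambda lp: _tail_upper(lp, a, ks, logw, mid_p), alpha)
        if lo <= 1e-12 + 1e-15:
            lo = 0.0
    # upper bound: psi with P(X <= a | psi) = alpha (lower tail decreases in psi)
    if a == ks[-1] and not mid_p:
        hi = math.inf
    else:
        hi = _invert_tail(lambda lp: -_tail_lower(lp, a, ks, logw, mid_p), -alpha)
        if hi >= 1e12 - 1e-3:
            hi = math.inf
    return lo, hi


def conditional_mle_or(t: ContingencyTable) -> float:
    """Conditional maximum-likelihood odds ratio: the psi with
    E[X | psi] = a under the noncentral hypergeometric model."""
    m1, m2 = t.n_cases, t.n_controls
    n1 = t.a + t.c
    ks, logw = _nchg_logweights(m1, m2, n1)
    if t.a == ks[0]:
        return 0.0
    if t.a == ks[-1]:
        return math.inf

    def mean_minus_a(lp: float) -> float:
        return float(ks @ _nchg_pmf(lp, ks, logw)) - t.a

    return _invert_tail(mean_minus_a, 0.0)


def woolf_or_ci(t: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Large-sample logit (Woolf) interval; for comparison only —
    it cannot reproduce exact small-sample bounds."""
    a, b, c, d = t.cells
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane correction
    lor = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    return math.exp(lor - z * se), math.exp(lor + z * se)


# ---------------------------------------------------------------------------
# classical tests


def pearson_chi_square(table: ContingencyTable | Sequence[Sequence[float]]
                       ) -> tuple[float, float]:
    """Pearson chi-square without continuity correction.

    2x2 tables use the closed form n(ad-bc)^2 / (r1 r2 c1 c2); general
    2xk tables the observed-vs-expected sum with k-1 df.  A zero margin
    yields (nan, nan) rather than an exception.
    """
    if isinstance(table, ContingencyTable):
        obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    else:
        obs = np.asarray(table, dtype=float)
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return math.nan, math.nan
    n = obs.sum()
    if obs.shape == (2, 2):
        (a, b), (c, d) = obs
        stat = n * (a * d - b * c) ** 2 / (rows[0] * rows[1] * cols[0] * cols[1])
    else:
        exp = np.outer(rows, cols) / n
        stat = float(((obs - exp) ** 2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return float(stat), float(sps.chi2.sf(stat, df))


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities
    no larger than the observed table's)."""
    return float(sps.fisher_exact([[t.a, t.b], [t.c, t.d]])[1])


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Student's pooled-variance two-sample t test, two-sided."""
    if len(x) < 2 or len(y) < 2:
        raise TableError("each group needs at least 2 values")
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# assembled burden result


@dataclass
class BurdenResult:
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_level: float
    chi2_stat: float
    chi2_p: float
    fisher_p: float
    method_notes: str = ""

    def to_dict(self) -> dict[str, object]:
        return {
            "label": self.table.label,
            "a": self.table.a, "b": self.table.b,
            "c": self.table.c, "d": self.table.d,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "chi2_stat": self.chi2_stat, "chi2_p": self.chi2_p,
            "fisher_p": self.fisher_p,
            "method_notes": self.method_notes,
        }


def compute_burden(t: ContingencyTable, level: float = 0.95) -> BurdenResult:
    """Odds ratio with exact conditional CI plus chi-square and Fisher p."""
    o = odds_ratio(t)
    try:
        lo, hi = exact_or_ci(t, level)
        cmle = conditional_mle_or(t)
        notes = (f"exact conditional (Cornfield) CI; "
                 f"conditional MLE OR = {cmle:.4g}")
    except TableError:
        lo, hi = math.nan, math.nan
        notes = "empty margin: exact CI undefined"
    stat, p = pearson_chi_square(t)
    return BurdenResult(
        table=t, odds_ratio=o, ci_low=lo, ci_high=hi, ci_level=level,
        chi2_stat=stat, chi2_p=p, fisher_p=fisher_exact(t),
        method_notes=notes)


# ---------------------------------------------------------------------------
# exposure tables from classified cohorts


def build_exposure_table(trios: Iterable, qualifier: Callable[[object], bool],
                         label: str = "") -> ContingencyTable:
    """Count probands into a 2x2 exposure-by-outcome table.

    ``qualifier`` is a pure predicate on a trio (e.g. "proband carries
    at least one qualifying panel variant"); exposure is its truth
    value.  Every proband is counted exactly once; a proband without a
    group label is an error.
    """
    a = b = c = d = 0
    for trio in trios:
        grp = trio.proband_affected
        if grp not in ("epilepsy", "no_epilepsy"):
            raise TableError(
                f"proband {trio.proband_id} has no case/control label")
        exposed = bool(qualifier(trio))
        if grp == "epilepsy":
            a, b = (a + 1, b) if exposed else (a, b + 1)
        else:
            c, d = (c + 1, d) if exposed else (c, d + 1)
    return ContingencyTable(a, b, c, d, label)
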