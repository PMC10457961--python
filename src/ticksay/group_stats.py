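"""One-way ANOVA, Tukey HSD and compact letter displays for bioassay groups.

Implements the classic fixed-effects one-way analysis of variance — from raw
replicate values or from printed summary statistics (mean, sample SD, n per
group) — followed by Tukey's honestly-significant-difference multiple
comparison at a chosen family-wise level, and the compact letter display used
as superscripts in efficacy tables.  The studentized-range quantile behind
Tukey's test is computed from first principles (numerical integration of the
distribution's CDF plus root finding) rather than table lookup.

Recomputing ANOVAs from summary statistics matters in this domain: published
acaricide bioassays typically print only per-group mean ± SD, and the
summary-based decomposition

    SSB = sum n_i (mean_i - grand_mean)^2,   SSW = sum (n_i - 1) SD_i^2

recovers exactly the F statistic of the raw-data ANOVA.
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "PairwiseComparison",
    "LetterDisplay",
    "anova_oneway_raw",
    "anova_oneway_summary",
    "t_critical_two_sided",
    "studentized_range_quantile",
    "tukey_hsd",
    "pairwise_t",
    "compact_letters",
    "full_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean, sample SD (n-1 denominator) and replicate count."""

    labels: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    ns: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if not (len(self.means) == len(self.sds) == len(self.ns) == k):
            raise ValueError("labels/means/sds/ns lengths differ")
        if any(sd < 0 for sd in self.sds):
            raise ValueError("SD must be >= 0")

    @classmethod
    def from_raw(
        cls, groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
    ) -> "GroupSummary":
        labels = tuple(labels) if labels else tuple(f"g{i}" for i in range(len(groups)))
        arrays = [np.asarray(g, dtype=float) for g in groups]
        return cls(
            labels=labels,
            means=tuple(float(a.mean()) for a in arrays),
            sds=tuple(float(a.std(ddof=1)) for a in arrays),
            ns=tuple(len(a) for a in arrays),
        )


@dataclass(frozen=True)
class AnovaResult:
    """Fixed-effects one-way ANOVA outcome.

    ``degenerate`` flags the boundary case MSW = 0 with MSB > 0, where F is
    reported as +inf and p as the limiting 0.
    """

    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    ms_between: float
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseComparison:
    """One pair of a multiple-comparison procedure (order-symmetric)."""

    group_a: str
    group_b: str
    mean_difference: float
    critical_span: float
    significant: bool
    alpha: float
    method: str


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: groups share a letter iff not significantly
    different."""

    letters: Mapping[str, frozenset[str]]

    def as_strings(self) -> dict[str, str]:
        return {g: "".join(sorted(ls)) for g, ls in self.letters.items()}


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def anova_oneway_raw(
    groups: Sequence[Sequence[float]],
) -> AnovaResult:
    """One-way ANOVA from raw per-group values.

    Requires >= 2 groups with >= 2 values each; raises if every value in the
    dataset is identical (no variance to partition).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    summary = GroupSummary.from_raw(arrays)
    allvals = np.concatenate(arrays)
    if np.all(allvals == allvals[0]):
        raise ValueError("all values identical: ANOVA undefined")
    return anova_oneway_summary(summary)


def anova_oneway_summary(summary: GroupSummary) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group mean/SD/n triples.

    Identical to :func:`anova_oneway_raw` when the summary was computed from
    the raw data (up to floating point).
    """
    means = np.asarray(summary.means, dtype=float)
    sds = np.asarray(summary.sds, dtype=float)
    ns = np.asarray(summary.ns, dtype=int)
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, n_total - k
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0:
        if msb == 0:
            raise ValueError("all values identical: ANOVA undefined")
        return AnovaResult(
            F=math.inf,
            df_between=df_b,
            df_within=df_w,
            p=0.0,
            ms_within=0.0,
            ms_between=msb,
            degenerate=True,
        )
    F = msb / msw
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(
        F=F,
        df_between=df_b,
        df_within=df_w,
        p=p,
        ms_within=msw,
        ms_between=msb,
    )


# ---------------------------------------------------------------------------
# Critical values
# ---------------------------------------------------------------------------


def t_critical_two_sided(df: int, alpha: float) -> float:
    """Two-sided critical value of Student's t: the 1 - alpha/2 quantile."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.t.ppf(1 - alpha / 2, df))


# Gauss-Legendre nodes reused across quantile evaluations.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(240)


def _range_cdf_inf(q: float, k: int) -> float:
    """P(range of k iid standard normals < q)."""
    if q <= 0:
        return 0.0
    lo, hi = -8.0, 8.0
    z = 0.5 * (hi - lo) * _GL_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _GL_WEIGHTS
    phi = np.exp(-0.5 * z**2) / math.sqrt(2 * math.pi)
    inner = (special.ndtr(z) - special.ndtr(z - q)) ** (k - 1)
    return float(k * np.sum(w * phi * inner))


def _studentized_range_cdf(q: float, k: int, df: int) -> float:
    """CDF of the studentized range Q(k, df) by numerical integration.

    Integrates the infinite-df range CDF against the density of
    S = sqrt(chi2_df / df); for df > 10,000 the S distribution is treated as
    degenerate at 1.
    """
    if q <= 0:
        return 0.0
    if df > 10_000:
        return _range_cdf_inf(q, k)
    ln_norm = (
        math.log(2.0)
        + (df / 2.0) * math.log(df / 2.0)
        - special.gammaln(df / 2.0)
    )

    def outer(s: float) -> float:
        if s <= 0:
            return 0.0
        ln_f = ln_norm + (df - 1) * math.log(s) - df * s * s / 2.0
        return math.exp(ln_f) * _range_cdf_inf(q * s, k)

    val, _ = integrate.quad(outer, 0, np.inf, limit=200, epsabs=1e-10, epsrel=1e-9)
    return float(val)


def studentized_range_quantile(
    k: int, df: int, alpha: float, tol: float = 1e-6
) -> float:
    """Upper-alpha quantile of the studentized range distribution.

    Computed by bisection (Brent's method) on the numerically integrated CDF
    to ``tol`` on the quantile.  Satisfies the analytic identity
    ``q(2, df, alpha) = sqrt(2) * t_{1 - alpha/2, df}``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    target = 1.0 - alpha

    def f(q: float) -> float:
        return _studentized_range_cdf(q, k, df) - target

    lo, hi = 1e-6, 10.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError(
                f"studentized range quantile did not bracket: k={k} df={df} "
                f"alpha={alpha}, CDF({hi / 2:.1f})={f(hi / 2) + target:.6f}"
            )
    try:
        return float(optimize.brentq(f, lo, hi, xtol=tol))
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"studentized range quantile failed to converge for k={k}, "
            f"df={df}, alpha={alpha}: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------


def _pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None,
    alpha: float,
    method: str,
) -> list[PairwiseComparison]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    labels = list(labels) if labels else [f"g{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("labels/groups lengths differ")
    anova = anova_oneway_raw(arrays)
    msw = anova.ms_within
    k = len(arrays)
    if method == "tukey":
        crit_factor = studentized_range_quantile(k, anova.df_within, alpha)

        def span(ni: int, nj: int) -> float:
            return crit_factor * math.sqrt(msw / 2.0 * (1.0 / ni + 1.0 / nj))

    elif method == "pairwise-t":
        crit_factor = t_critical_two_sided(anova.df_within, alpha)

        def span(ni: int, nj: int) -> float:
            return crit_factor * math.sqrt(msw * (1.0 / ni + 1.0 / nj))

    else:
        raise ValueError(f"unknown method {method!r}")

    comparisons = []
    for (i, a), (j, b) in itertools.combinations(enumerate(arrays), 2):
        diff = float(a.mean() - b.mean())
        crit = span(len(a), len(b))
        comparisons.append(
            PairwiseComparison(
                group_a=labels[i],
                group_b=labels[j],
                mean_difference=diff,
                critical_span=crit,
                # MSW = 0: every nonzero difference is significant (flagged
                # upstream through AnovaResult.degenerate).
                significant=abs(diff) > crit,
                alpha=alpha,
                method=method,
            )
        )
    return comparisons


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[PairwiseComparison]:
    """Tukey's HSD over all group pairs.

    Significant iff ``|mean_i - mean_j| > q(k, df_within, alpha) *
    sqrt(MSW/2 * (1/n_i + 1/n_j))`` — the Tukey–Kramer form, which reduces
    to classic HSD for balanced designs.
    """
    return _pairwise(groups, labels, alpha, "tukey")


def pairwise_t(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[PairwiseComparison]:
    """Unadjusted pairwise t comparisons using the pooled ANOVA MSW."""
    return _pairwise(groups, labels, alpha, "pairwise-t")


# ---------------------------------------------------------------------------
# Compact letter display
# ---------------------------------------------------------------------------


def _letter_names() -> Iterable[str]:
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def compact_letters(comparisons: Sequence[PairwiseComparison]) -> LetterDisplay:
    """Insert-and-absorb letter assignment from all-pairs comparisons.

    Guarantees the defining iff: two groups share at least one letter exactly
    when their comparison is non-significant.  The letter count is not
    guaranteed minimal.  Raises on incomplete or asymmetric/conflicting
    input.
    """
    sig: dict[frozenset[str], bool] = {}
    groups: list[str] = []
    for c in comparisons:
        key = frozenset((c.group_a, c.group_b))
        if len(key) != 2:
            raise ValueError(f"self-comparison {c.group_a!r}")
        if key in sig and sig[key] != c.significant:
            raise ValueError(f"conflicting significance for pair {sorted(key)}")
        sig[key] = c.significant
        for g in (c.group_a, c.group_b):
            if g not in groups:
                groups.append(g)
    expected = {frozenset(p) for p in itertools.combinations(groups, 2)}
    if set(sig) != expected:
        raise ValueError("comparisons do not cover all pairs of the group set")

    classes: list[set[str]] = [set(groups)]
    for pair, significant in sig.items():
        if not significant:
            continue
        a, b = sorted(pair)
        new_classes: list[set[str]] = []
        for cls in classes:
            if a in cls and b in cls:
                new_classes.append(cls - {a})
                new_classes.append(cls - {b})
            else:
                new_classes.append(cls)
        # absorb: drop classes contained in another
        classes = [
            cls
            for i, cls in enumerate(new_classes)
            if cls
            and not any(
                cls < other or (cls == other and i > j)
                for j, other in enumerate(new_classes)
            )
        ]

    letters: dict[str, set[str]] = {g: set() for g in groups}
    for name, cls in zip(_letter_names(), classes):
        for g in cls:
            letters[g].add(name)

    display = LetterDisplay({g: frozenset(ls) for g, ls in letters.items()})
    # verify the iff invariant before returning
    for pair, significant in sig.items():
        a, b = sorted(pair)
        shared = bool(display.letters[a] & display.letters[b])
        if shared == significant:
            raise RuntimeError(
                f"letter display violates iff invariant for pair ({a}, {b})"
            )
    return display


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def full_report(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    response: str = "response",
) -> dict:
    """ANOVA + Tukey + letters as a JSON-serialisable report."""
    labels = list(labels) if labels else [f"g{i}" for i in range(len(groups))]
    anova = anova_oneway_raw(groups)
    comparisons = tukey_hsd(groups, alpha=alpha, labels=labels)
    letters = compact_letters(comparisons)
    return {
        "response": response,
        "F": anova.F,
        "df": [anova.df_between, anova.df_within],
        "p": anova.p,
        "ms_within": anova.ms_within,
        "alpha": alpha,
        "comparisons": [
            {
                "pair": [c.group_a, c.group_b],
                "difference": c.mean_difference,
                "critical_span": c.critical_span,
                "significant": c.significant,
            }
            for c in comparisons
        ],
        "letters": letters.as_strings(),
    }
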