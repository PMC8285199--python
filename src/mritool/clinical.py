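"""Two-group clinical statistics and rating-scale conventions.

Covers the statistical layer of a two-arm treatment comparison: two-sample
t-tests computed from mean +/- SD summaries, Pearson chi-square (optionally
Yates-corrected) and Fisher exact tests on 2x2 incidence tables, incidence
percentages, and direction-aware interpretation of UPDRS / MoCA / MMSE
score changes (UPDRS: higher is worse; MoCA: 30-point scale, > 26 normal;
MMSE: lower is worse). The significance threshold is two-sided 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError, InputError

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD summary of one group (n >= 2, sd >= 0)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise InputError(f"group {self.label!r} needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise InputError(f"group {self.label!r} has negative sd {self.sd}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Event counts out of group sizes for two groups."""

    label_a: str
    events_a: int
    n_a: int
    label_b: str
    events_b: int
    n_b: int

    def __post_init__(self):
        for label, events, n in ((self.label_a, self.events_a, self.n_a),
                                 (self.label_b, self.events_b, self.n_b)):
            if n < 1:
                raise InputError(f"group {label!r} must have n >= 1")
            if not (0 <= events <= n):
                raise InputError(
                    f"group {label!r}: events={events} outside [0, {n}]"
                )

    def counts(self) -> np.ndarray:
        """2x2 observed table: rows groups, columns (event, no event)."""
        return np.array([
            [self.events_a, self.n_a - self.events_a],
            [self.events_b, self.n_b - self.events_b],
        ], dtype=float)

    def swapped(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.label_b, self.events_b, self.n_b,
                                   self.label_a, self.events_a, self.n_a)


@dataclass(frozen=True)
class ScaleSpec:
    """Clinical rating scale metadata: name, direction, range, cutoff."""

    name: str
    direction: Literal["higher_is_worse", "higher_is_better"]
    max_score: Optional[int] = None
    normal_cutoff: Optional[int] = None


SCALES = {
    "UPDRS": ScaleSpec("UPDRS", "higher_is_worse"),
    "MoCA": ScaleSpec("MoCA", "higher_is_better", max_score=30, normal_cutoff=26),
    "MMSE": ScaleSpec("MMSE", "higher_is_better", max_score=30),
}


def t_test_from_summaries(a: GroupSummary, b: GroupSummary,
                          variant: Literal["pooled", "welch"] = "pooled"):
    """Two-sample t-test from summary statistics.

    Returns (t, degrees of freedom, two-sided p). ``pooled`` is the
    classical equal-variance test; ``welch`` does not pool.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise DegenerateInputError(
                "t statistic undefined: both sds are zero and means equal"
            )
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n,
        equal_var=(variant == "pooled"),
    )
    if variant == "pooled":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(table: ContingencyTable2x2,
                   correction: Literal["none", "yates"] = "none"):
    """Pearson chi-square on a 2x2 table, 1 degree of freedom.

    Returns (statistic, two-sided p, warning-or-None). The warning flags
    expected counts below 5, where the asymptotic test is unreliable and
    :func:`fisher_exact_2x2` is preferable.
    """
    obs = table.counts()
    if obs.sum(axis=0).min() == 0:
        raise DegenerateInputError(
            "degenerate table: a column margin (all events or all "
            "non-events) is zero"
        )
    stat, p, _, expected = stats.chi2_contingency(
        obs, correction=(correction == "yates")
    )
    warning = None
    if expected.min() < 5:
        warning = (
            f"minimum expected count {expected.min():.2f} < 5; "
            "consider the Fisher exact test"
        )
    return float(stat), float(p), warning


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Exact two-sided p: total probability of tables (with the same
    margins) no more likely than the observed one."""
    _, p = stats.fisher_exact(table.counts().astype(int), alternative="two-sided")
    return float(p)


def incidence_percent(table: ContingencyTable2x2, group: str) -> float:
    """Incidence of the event in one group, as a percentage."""
    if group == table.label_a:
        return 100.0 * table.events_a / table.n_a
    if group == table.label_b:
        return 100.0 * table.events_b / table.n_b
    raise InputError(
        f"unknown group {group!r}; table has {table.label_a!r}, {table.label_b!r}"
    )


@dataclass(frozen=True)
class ScoreChange:
    outcome: Literal["improved", "worsened", "unchanged"]
    crossed_normal: bool = False


def interpret_score_change(scale, before: float, after: float) -> ScoreChange:
    """Direction-aware classification of a before/after score change.

    For a higher-is-worse scale (UPDRS) a decrease is an improvement; for
    higher-is-better scales (MoCA, MMSE) an increase is. When the scale
    defines a normality cutoff, crossing it upward on improvement (or
    downward on worsening) sets ``crossed_normal``.
    """
    if isinstance(scale, str):
        if scale not in SCALES:
            raise ConfigurationError(
                f"unknown scale {scale!r}; known: {sorted(SCALES)}"
            )
        scale = SCALES[scale]
    if after == before:
        return ScoreChange("unchanged")
    raw_up = after > before
    improved = raw_up != (scale.direction == "higher_is_worse")
    crossed = False
    if scale.normal_cutoff is not None:
        lo, hi = sorted((before, after))
        crossed = lo <= scale.normal_cutoff < hi
    return ScoreChange("improved" if improved else "worsened", crossed)
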