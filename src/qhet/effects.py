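"""Per-study log odds ratio estimation and Cochran's Q statistics.

The effect of interest for a two-arm study with binomial outcomes is the
log odds ratio theta = logit(p_T) - logit(p_C).  Each study is summarised
by a 2x2 table of event counts and arm sizes.  Log odds are estimated with
the Gart 1/2-corrected logit ``L_a(x) = log[(x + a) / (n - x + a)]`` with
``a = 1/2``, the unique choice that removes all O(1/n) bias terms, and the
variance by the matching four-term sum of reciprocals.  Cochran's Q is the
inverse-variance weighted sum of squared deviations of the per-study
effects from their weighted mean.

Two flavours of Q are provided: :func:`cochran_q` on 1/2-corrected
estimates (the statistic the gamma-referenced test uses) and
:func:`q_standard`, the conventional statistic that applies no correction
except where a zero cell would make the log odds or its variance
undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StudyTable",
    "MetaDataset",
    "EffectEstimate",
    "adjusted_log_odds",
    "estimate_effect",
    "estimate_effects",
    "pooled_effect",
    "cochran_q",
    "q_standard",
]


@dataclass(frozen=True)
class StudyTable:
    """A single 2x2 study: events and arm sizes for treatment and control.

    Attributes
    ----------
    x : int
        Events in the treatment arm.
    n_t : int
        Treatment arm size.
    y : int
        Events in the control arm.
    n_c : int
        Control arm size.
    """

    x: int
    n_t: int
    y: int
    n_c: int

    def __post_init__(self) -> None:
        for name in ("x", "n_t", "y", "n_c"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_t < 1 or self.n_c < 1:
            raise ValueError("both arms must have at least one subject")
        if self.x > self.n_t:
            raise ValueError(f"treatment events {self.x} exceed arm size {self.n_t}")
        if self.y > self.n_c:
            raise ValueError(f"control events {self.y} exceed arm size {self.n_c}")

    @property
    def n(self) -> int:
        """Total study size N = n_t + n_c."""
        return self.n_t + self.n_c

    @property
    def q(self) -> float:
        """Control-arm fraction q = n_c / N."""
        return self.n_c / self.n

    def has_zero_cell(self) -> bool:
        """True if any of the four cells (events or non-events) is zero."""
        return self.x in (0, self.n_t) or self.y in (0, self.n_c)

    def sample_odds_ratio(self) -> float:
        """Raw cross-product odds ratio x(n_c - y) / [y(n_t - x)].

        Requires all four cells positive; raises ``ZeroDivisionError``
        otherwise.
        """
        return (self.x * (self.n_c - self.y)) / (self.y * (self.n_t - self.x))


class MetaDataset:
    """An ordered collection of 2x2 studies entering one meta-analysis.

    Order is preserved for reporting, but every statistic computed from a
    dataset is invariant to it.  Homogeneity tests require ``K >= 2``.
    """

    def __init__(self, studies: Iterable[StudyTable]):
        self.studies: tuple[StudyTable, ...] = tuple(studies)
        if len(self.studies) < 1:
            raise ValueError("a MetaDataset needs at least one study")

    @classmethod
    def from_arrays(cls, x, n_t, y, n_c) -> "MetaDataset":
        cols = [np.asarray(a) for a in (x, n_t, y, n_c)]
        if len({c.shape for c in cols}) != 1 or cols[0].ndim != 1:
            raise ValueError("x, n_t, y, n_c must be equal-length 1-D sequences")
        return cls(
            StudyTable(int(xi), int(nti), int(yi), int(nci))
            for xi, nti, yi, nci in zip(*cols)
        )

    @property
    def k(self) -> int:
        """Number of studies K."""
        return len(self.studies)

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    def __getitem__(self, i):
        return self.studies[i]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Counts as four integer arrays (x, n_t, y, n_c) of length K."""
        return (
            np.array([s.x for s in self.studies]),
            np.array([s.n_t for s in self.studies]),
            np.array([s.y for s in self.studies]),
            np.array([s.n_c for s in self.studies]),
        )


@dataclass(frozen=True)
class EffectEstimate:
    """1/2-corrected effect summary for one study.

    ``theta_hat`` is the corrected log odds ratio, ``zeta_hat`` the
    corrected control-arm log odds (the nuisance parameter), ``var_hat``
    the Gart variance estimate and ``weight`` its reciprocal.
    """

    theta_hat: float
    zeta_hat: float
    var_hat: float
    weight: float


def adjusted_log_odds(x: int, n: int, a: float = 0.5) -> float:
    """Adjusted empirical logit ``L_a(x) = log[(x + a) / (n - x + a)]``.

    With ``a = 1/2`` this is the minimum-asymptotic-bias estimator of
    logit(p) for x ~ Binomial(n, p); with ``a = 0`` it is the raw sample
    logit, defined only for interior counts.
    """
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if a < 0:
        raise ValueError("a must be nonnegative")
    if a == 0 and (x == 0 or x == n):
        raise ValueError(f"logit undefined for x={x}, n={n} with a=0")
    return math.log((x + a) / (n - x + a))


def estimate_effect(table: StudyTable) -> EffectEstimate:
    """1/2-corrected log odds ratio, control log odds, variance and weight.

    The variance estimate is the four-term reciprocal sum
    ``1/(x+1/2) + 1/(n_t-x+1/2) + 1/(y+1/2) + 1/(n_c-y+1/2)``, which is
    finite and positive for every table.
    """
    lt = adjusted_log_odds(table.x, table.n_t)
    lc = adjusted_log_odds(table.y, table.n_c)
    var = (
        1.0 / (table.x + 0.5)
        + 1.0 / (table.n_t - table.x + 0.5)
        + 1.0 / (table.y + 0.5)
        + 1.0 / (table.n_c - table.y + 0.5)
    )
    return EffectEstimate(theta_hat=lt - lc, zeta_hat=lc, var_hat=var, weight=1.0 / var)


def estimate_effects(dataset: MetaDataset) -> list[EffectEstimate]:
    """Per-study :func:`estimate_effect` over a dataset, preserving order."""
    return [estimate_effect(s) for s in dataset]


def pooled_effect(estimates: Sequence[EffectEstimate]) -> float:
    """Inverse-variance weighted mean of the per-study log odds ratios."""
    if not estimates:
        raise ValueError("need at least one estimate")
    num = math.fsum(e.weight * e.theta_hat for e in estimates)
    den = math.fsum(e.weight for e in estimates)
    return num / den


def cochran_q(estimates: Sequence[EffectEstimate]) -> float:
    """Cochran's Q: weighted sum of squared deviations from the pooled mean.

    ``Q = sum_i w_i (theta_i - theta_w)^2`` with inverse-variance weights.
    Nonnegative; zero exactly when all effects coincide.
    """
    if len(estimates) < 2:
        raise ValueError("Q requires at least two studies")
    tw = pooled_effect(estimates)
    q = math.fsum(e.weight * (e.theta_hat - tw) ** 2 for e in estimates)
    return max(q, 0.0)


def q_standard(dataset: MetaDataset) -> float:
    """The conventional Q statistic with corrections only where forced.

    Tables whose four cells are all positive enter with the raw sample
    logit (``a = 0``) and variance ``1/x + 1/(n_t-x) + 1/y + 1/(n_c-y)``.
    Any table containing a zero cell has 1/2 added to all four of its
    cells (and only that table), which is the usual zero-cell continuity
    handling in meta-analysis software.
    """
    if dataset.k < 2:
        raise ValueError("Q requires at least two studies")
    ests = []
    for t in dataset:
        a = 0.5 if t.has_zero_cell() else 0.0
        lt = adjusted_log_odds(t.x, t.n_t, a)
        lc = adjusted_log_odds(t.y, t.n_c, a)
        var = (
            1.0 / (t.x + a)
            + 1.0 / (t.n_t - t.x + a)
            + 1.0 / (t.y + a)
            + 1.0 / (t.n_c - t.y + a)
        )
        ests.append(
            EffectEstimate(theta_hat=lt - lc, zeta_hat=lc, var_hat=var, weight=1.0 / var)
        )
    return cochran_q(ests)
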