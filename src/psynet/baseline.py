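"""Baseline tendency estimation per characteristic.

For each characteristic, the prevalence within each outcome group is
given a Beta posterior (expression counts plus a proper prior offset).
The probability that the IMPV-group prevalence exceeds the MC-group
prevalence is

    P(X > Y) = integral_0^1 f_A(x) F_B(x) dx,   X ~ Beta(A), Y ~ Beta(B),

evaluated by adaptive quadrature. Characteristics whose probability
reaches the 90% rule in either direction are flagged. A standard set of
epidemiological statistics (odds ratio, absolute risk reduction,
population attributable risk percent) is attached, oriented with
exposure = characteristic expressed and outcome = IMPV.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import integrate, special

from .cohort import Cohort, CohortValidationError, Outcome


class UnlabeledCohortError(CohortValidationError):
    pass


class UndefinedStatisticError(ValueError):
    """PAR% is undefined when there are no IMPV children at all."""


#: Default proper prior: one pseudo-count per cell. Jeffreys (0.5, 0.5)
#: is the common alternative.
DEFAULT_PRIOR = (1.0, 1.0)

#: Float slack so that e.g. p = 0.1 clears the complement of a 0.9 rule
#: (1 - 0.9 is not exactly representable).
_EPS = 1e-9


def clears_threshold(p: float, min_prob: float) -> Optional[str]:
    """"IMPV" when p >= min_prob, "MC" when p <= 1 - min_prob, else None."""
    if p >= min_prob - _EPS:
        return "IMPV"
    if p <= 1.0 - min_prob + _EPS:
        return "MC"
    return None


@dataclass(frozen=True)
class BetaParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError(f"Beta parameters must be finite and > 0, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = expressed & IMPV, b = expressed & MC,
    c = not expressed & IMPV, d = not expressed & MC."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"contingency cell {name} is negative")

    @property
    def n_impv(self) -> int:
        return self.a + self.c

    @property
    def n_mc(self) -> int:
        return self.b + self.d


@dataclass(frozen=True)
class EpiStats:
    odds_ratio: float
    arr: float  # absolute risk reduction (risk_exposed - risk_unexposed)
    par_pct: float  # population attributable risk percent
    correction_applied: bool


@dataclass(frozen=True)
class BaselineResult:
    characteristic: str
    beta_impv: BetaParams
    beta_mc: BetaParams
    p_higher_impv: float
    epi: EpiStats
    counts: ContingencyTable

    def leaning(self, min_prob: float = 0.9) -> Optional[str]:
        """"IMPV"/"MC" when the probability clears ``min_prob`` toward
        that group, else None."""
        return clears_threshold(self.p_higher_impv, min_prob)


def beta_posterior(k: int, n: int, prior: tuple[float, float] = DEFAULT_PRIOR) -> BetaParams:
    """Beta posterior for a prevalence from k expressions out of n."""
    a0, b0 = prior
    if not (a0 > 0 and b0 > 0):
        raise ValueError("prior offsets must be strictly positive")
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return BetaParams(k + a0, n - k + b0)


def prob_greater(A: BetaParams, B: BetaParams) -> float:
    """P(X > Y) for X ~ Beta(A), Y ~ Beta(B), by adaptive quadrature.

    Evaluates the definite integral of f_A(x) * F_B(x) over [0, 1] to
    absolute accuracy well below 1e-6.
    """
    a1, b1 = A.alpha, A.beta
    a2, b2 = B.alpha, B.beta
    log_norm = special.betaln(a1, b1)

    def integrand(x: float) -> float:
        if x <= 0.0 or x >= 1.0:
            return 0.0
        log_pdf = (a1 - 1.0) * math.log(x) + (b1 - 1.0) * math.log1p(-x) - log_norm
        return math.exp(log_pdf) * float(special.betainc(a2, b2, x))

    points = sorted({A.mean, B.mean})
    val, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-9, epsrel=1e-9,
                            limit=500, points=points)
    return min(max(val, 0.0), 1.0)


def epi_stats(t: ContingencyTable) -> EpiStats:
    """Odds ratio, ARR and PAR% with exposure = expressed, outcome = IMPV.

    Zero cells are handled by the Haldane-Anscombe correction (+0.5 to
    every cell), flagged via ``correction_applied``.
    """
    if t.n_impv == 0:
        raise UndefinedStatisticError("no IMPV children: overall risk is 0, PAR% undefined")
    if t.n_mc == 0:
        raise ValueError("MC group is empty")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    correction = 0 in (t.a, t.b, t.c, t.d)
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    risk_exposed = a / (a + b)
    risk_unexposed = c / (c + d)
    arr = risk_exposed - risk_unexposed
    overall = (a + c) / (a + b + c + d)
    par_pct = 100.0 * (overall - risk_unexposed) / overall
    return EpiStats(odds_ratio, arr, par_pct, correction)


def contingency_for(cohort: Cohort, members: Sequence[str] | str) -> ContingencyTable:
    """2x2 expression-by-outcome table for a characteristic or tuple entity.

    A child counts as exposed when expressing *all* members.
    """
    if isinstance(members, str):
        members = (members,)
    if cohort.outcome_labels is None:
        raise UnlabeledCohortError("cohort has no outcome labels")
    unknown = set(members) - set(cohort.catalog.ids)
    if unknown:
        raise CohortValidationError(f"unknown characteristic ids: {sorted(unknown)}")
    a = b = c = d = 0
    mem = set(members)
    for r in cohort.records:
        expressed = mem <= r.characteristics
        impv = cohort.outcome_labels[r.child_id] is Outcome.IMPV
        if expressed and impv:
            a += 1
        elif expressed:
            b += 1
        elif impv:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def baseline_scan(
    cohort: Cohort,
    prior: tuple[float, float] = DEFAULT_PRIOR,
    min_prob: float = 0.9,
) -> tuple[list[BaselineResult], list[BaselineResult]]:
    """One BaselineResult per catalog characteristic, plus the flagged subset.

    Flagged: p_higher_impv >= min_prob (IMPV-leaning) or
    <= 1 - min_prob (MC-leaning).
    """
    if cohort.outcome_labels is None:
        raise UnlabeledCohortError("baseline scan requires a labeled cohort")
    results: list[BaselineResult] = []
    flagged: list[BaselineResult] = []
    for cid in cohort.catalog.ids:
        t = contingency_for(cohort, cid)
        bi = beta_posterior(t.a, t.n_impv, prior)
        bm = beta_posterior(t.b, t.n_mc, prior)
        p = prob_greater(bi, bm)
        res = BaselineResult(cid, bi, bm, p, epi_stats(t), t)
        results.append(res)
        if clears_threshold(p, min_prob) is not None:
            flagged.append(res)
    return results, flagged


def baseline_to_frame(results: Iterable[BaselineResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "characteristic": r.characteristic,
                "k_impv": r.counts.a,
                "n_impv": r.counts.n_impv,
                "k_mc": r.counts.b,
                "n_mc": r.counts.n_mc,
                "alpha_impv": r.beta_impv.alpha,
                "beta_impv": r.beta_impv.beta,
                "alpha_mc": r.beta_mc.alpha,
                "beta_mc": r.beta_mc.beta,
                "p_higher_impv": r.p_higher_impv,
                "odds_ratio": r.epi.odds_ratio,
                "arr": r.epi.arr,
                "par_pct": r.epi.par_pct,
                "correction_applied": r.epi.correction_applied,
            }
        )
    return pd.DataFrame(rows)


def write_baseline(results: Iterable[BaselineResult], path: str | Path) -> None:
    baseline_to_frame(results).to_csv(path, index=False)
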