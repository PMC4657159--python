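"""Conversion between population and case/asymptomatic allele frequencies.

A case-control study reports the risk-allele frequency in patients (u) and in
asymptomatic individuals (x); a variant database reports the population
frequency (p) and the odds ratio (OR).  With disease prevalence P the three
are tied together by the mixing identity

    p = u P + x (1 - P)

and the allele-level odds ratio

    OR = [u / (1 - u)] / [x / (1 - x)].

This module converts in both directions.  Going from (p, OR, P) to (u, x)
means solving the two identities simultaneously: substituting
x = (p - uP)/(1 - P) into the odds ratio gives a quadratic in u,

    (OR - 1) P u^2 - [OR (P + p) + 1 - P - p] u + OR p = 0,

whose admissible root (u in [p, 1], x >= 0) is unique for OR != 1.  The
system is solved exactly; no approximation is involved.  A variant observed
only in patients (x = 0) has infinite OR, in which case u = p / P directly.

Protective alleles (OR < 1) are re-oriented so the modeled allele is always
the risk allele: p -> 1 - p, OR -> 1/OR, with the flip recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CaseControlFrequencies",
    "PolymorphismRecord",
    "population_freq_from_case_control",
    "odds_ratio_from_freqs",
    "orient_risk_allele",
    "solve_case_control_freqs",
    "parse_odds_ratio",
]

_INF_TOKENS = {"inf", "+inf", "infinity", "∞", "+∞"}


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def parse_odds_ratio(token: float | str) -> float:
    """Parse an odds ratio from a number or a table cell.

    Accepts "inf", "Inf", "∞" (and signed variants) for a variant seen only
    in patients; an empty cell is also treated as infinite since that is the
    only situation in which source tables leave the OR blank.
    """
    if isinstance(token, str):
        stripped = token.strip()
        if stripped == "" or stripped.lower() in _INF_TOKENS:
            return math.inf
        value = float(stripped)
    else:
        value = float(token)
    if not value > 0.0:
        raise ValueError(f"odds ratio must be positive, got {token!r}")
    return value


@dataclass(frozen=True)
class CaseControlFrequencies:
    """Risk/non-risk allele frequencies in patients (u, v) and asymptomatic
    individuals (x, y), with v = 1 - u and y = 1 - x exactly."""

    u: float
    x: float

    def __post_init__(self) -> None:
        _check_prob(self.u, "u")
        _check_prob(self.x, "x")

    @property
    def v(self) -> float:
        return 1.0 - self.u

    @property
    def y(self) -> float:
        return 1.0 - self.x

    def population_freq(self, prevalence: float) -> float:
        """Mix case and asymptomatic frequencies back to the population p."""
        return population_freq_from_case_control(self.u, self.x, prevalence)


@dataclass(frozen=True)
class PolymorphismRecord:
    """One variant's published summary inputs.

    Either the population risk-allele frequency ``pop_freq`` or the pair
    (``case_freq``, ``asymptomatic_freq``) must be supplied; prevalence and
    odds ratio are always required.  ``model`` selects autosomal dominant
    (carriers at risk) or autosomal recessive (homozygotes at risk);
    ``relative`` selects whose recurrence risk is modeled.
    """

    identifier: str
    disease: str
    prevalence: float
    odds_ratio: float
    pop_freq: float | None = None
    case_freq: float | None = None
    asymptomatic_freq: float | None = None
    model: str = "AD"
    relative: str = "offspring"
    anchor: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(
                f"prevalence must lie in (0, 1), got {self.prevalence!r}")
        if not self.odds_ratio > 0.0:
            raise ValueError(
                f"odds ratio must be positive, got {self.odds_ratio!r}")
        if self.pop_freq is None and (self.case_freq is None
                                      or self.asymptomatic_freq is None):
            raise ValueError(
                "need pop_freq or both case_freq and asymptomatic_freq")
        for name in ("pop_freq", "case_freq", "asymptomatic_freq"):
            value = getattr(self, name)
            if value is not None:
                _check_prob(value, name)
        if math.isinf(self.odds_ratio) and self.asymptomatic_freq not in (None, 0.0):
            raise ValueError(
                "infinite odds ratio requires asymptomatic_freq = 0")
        if self.model not in ("AD", "AR"):
            raise ValueError(f"model must be 'AD' or 'AR', got {self.model!r}")
        if self.relative not in ("offspring", "sibling"):
            raise ValueError(
                f"relative must be 'offspring' or 'sibling', got {self.relative!r}")

    def population_frequency(self) -> float:
        """The population risk-allele frequency, computed from (u, x, P) if
        not given directly."""
        if self.pop_freq is not None:
            return self.pop_freq
        return population_freq_from_case_control(
            self.case_freq, self.asymptomatic_freq, self.prevalence)


def population_freq_from_case_control(u: float, x: float, P: float) -> float:
    """Population risk-allele frequency p = uP + x(1 - P).

    Patients make up a fraction P of the population and asymptomatic
    individuals the rest, so the population frequency is the
    prevalence-weighted mixture of the two group frequencies.  The
    complementary identity q = vP + y(1 - P) holds by construction.
    """
    _check_prob(u, "u")
    _check_prob(x, "x")
    _check_prob(P, "P")
    return u * P + x * (1.0 - P)


def odds_ratio_from_freqs(u: float, x: float) -> float:
    """Allele-level odds ratio (u/v)/(x/y) = u(1-x) / ((1-u)x).

    Returns ``inf`` when the allele is absent in asymptomatic individuals
    (x = 0, u > 0) and 1 when the two groups do not differ.
    """
    _check_prob(u, "u")
    _check_prob(x, "x")
    if u == 1.0:
        raise ValueError("u = 1 gives undefined case odds")
    if u == x:
        return 1.0
    if x == 0.0:
        return math.inf
    return (u * (1.0 - x)) / ((1.0 - u) * x)


def orient_risk_allele(p: float, odds_ratio: float) -> tuple[float, float, bool]:
    """Ensure the modeled allele is the risk allele.

    Returns ``(p, OR, flipped)``.  For OR >= 1 the inputs pass through; for
    a protective allele (OR < 1) the complementary allele is modeled
    instead: frequency 1 - p, odds ratio 1/OR, flip flag set.
    """
    _check_prob(p, "p")
    if not odds_ratio > 0.0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio!r}")
    if odds_ratio >= 1.0:
        return p, odds_ratio, False
    return 1.0 - p, 1.0 / odds_ratio, True


def solve_case_control_freqs(p: float, odds_ratio: float,
                             P: float) -> CaseControlFrequencies:
    """Solve (u, x) exactly from (p, OR, P).

    The solution satisfies p = uP + x(1-P) and OR = u(1-x)/((1-u)x)
    simultaneously.  For finite OR it is the admissible root of the
    quadratic in u (u >= p, x >= 0); the quadratic is evaluated with the
    cancellation-safe product form of the roots.  For OR = inf the allele
    is confined to patients, so x = 0 and u = p / P; p > P is then
    infeasible (u would exceed 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p!r}")
    if not 0.0 < P < 1.0:
        raise ValueError(f"P must lie in (0, 1), got {P!r}")
    if not odds_ratio >= 1.0:
        raise ValueError(
            "solver requires OR >= 1; orient protective alleles first "
            f"(got {odds_ratio!r})")

    if math.isinf(odds_ratio):
        if p > P:
            raise ValueError(
                f"OR = inf is infeasible for p = {p} > P = {P}: "
                "an allele confined to patients cannot exceed prevalence")
        return CaseControlFrequencies(u=p / P, x=0.0)

    if odds_ratio == 1.0:
        return CaseControlFrequencies(u=p, x=p)

    OR = odds_ratio
    a = (OR - 1.0) * P
    b = -(OR * (P + p) + 1.0 - P - p)
    c = OR * p
    # b < 0 always, so -b + sqrt(disc) never cancels; the second root comes
    # from the product c/a (Citardauq) to avoid subtracting near-equal terms.
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        raise ValueError("no real solution for (u, x); inputs inconsistent")
    sqrt_disc = math.sqrt(disc)
    root_large = (-b + sqrt_disc) / (2.0 * a)
    root_small = (2.0 * c) / (-b + sqrt_disc)

    candidates = []
    for u in (root_small, root_large):
        if not 0.0 <= u <= 1.0:
            continue
        x = (p - u * P) / (1.0 - P)
        if x < -1e-12:
            continue
        x = max(x, 0.0)
        if u + 1e-12 >= p:  # the risk allele must be enriched in cases
            candidates.append((u, x))
    if not candidates:
        raise ValueError(
            f"no admissible root in (0, 1) for p={p}, OR={OR}, P={P}")
    u, x = candidates[0]
    return CaseControlFrequencies(u=u, x=x)
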