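"""Falconer liability-threshold machinery and the per-variant pipeline.

The liability-threshold model places every individual on a latent standard
normal liability scale; disease occurs above a threshold z_K fixed by the
group incidence K.  Patients are the upper tail, with mean liability
a_K = phi(z_K)/K above the population median.  Heritability follows from
the regression of relatives' liability on probands': for first-degree
relatives (coefficient of relationship r = 1/2)

    h^2 = 2 (z_P - z_Q) / a_P

where z_P is the population threshold at prevalence P, z_Q the threshold at
the relatives' incidence Q, and a_P the mean liability of patients drawn
from the general population.

The end-to-end per-variant estimate chains: orient the risk allele ->
solve the case/asymptomatic allele frequencies -> first-degree recurrence
Q -> Falconer h^2.  The result of that chain is the heritability a single
polymorphism contributes, written h_p^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm

from .frequencies import (
    CaseControlFrequencies,
    PolymorphismRecord,
    orient_risk_allele,
    solve_case_control_freqs,
)
from .recurrence import (
    RecurrenceResult,
    attributable_excess,
    combined_incidence,
    first_degree_incidence,
)

__all__ = [
    "LiabilityStats",
    "HeritabilityEstimate",
    "upper_tail_threshold",
    "mean_liability_of_affected",
    "liability_stats",
    "falconer_h2_first_degree",
    "polymorphism_heritability",
    "combined_heritability",
    "variants_needed",
]


@dataclass(frozen=True)
class LiabilityStats:
    """Threshold and patient mean liability for one group incidence."""

    K: float               # group incidence
    threshold: float       # z_K, standard deviations
    mean_affected: float   # a_K = phi(z_K)/K, standard deviations


@dataclass(frozen=True)
class HeritabilityEstimate:
    """h_p^2 of one variant with every intermediate retained for audit."""

    record: PolymorphismRecord
    solved_freqs: CaseControlFrequencies
    recurrence: RecurrenceResult
    threshold_P: float
    threshold_Q: float
    mean_affected_P: float
    h_p2: float
    flipped: bool = False
    warnings: tuple[str, ...] = ()


def upper_tail_threshold(K: float) -> float:
    """Standard-normal threshold whose upper-tail probability is ``K``."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"incidence must lie in (0, 1), got {K!r}")
    return float(norm.isf(K))


def mean_liability_of_affected(K: float) -> float:
    """Mean liability of the affected tail, phi(z_K)/K.

    This is the mean of a standard normal truncated below at z_K, so it
    always exceeds the threshold itself for K < 1/2.
    """
    z = upper_tail_threshold(K)
    return float(norm.pdf(z)) / K


def liability_stats(K: float) -> LiabilityStats:
    z = upper_tail_threshold(K)
    return LiabilityStats(K=K, threshold=z, mean_affected=float(norm.pdf(z)) / K)


def falconer_h2_first_degree(P: float, Q: float) -> float:
    """Falconer heritability from population prevalence and first-degree
    recurrence: h^2 = 2 (z_P - z_Q)/a_P.

    A recurrence below the prevalence yields a negative estimate; it is
    returned signed, with a warning, because clamping would mask input
    errors (e.g. a protective allele left unoriented).
    """
    z_P = upper_tail_threshold(P)
    z_Q = upper_tail_threshold(Q)
    a_P = mean_liability_of_affected(P)
    h2 = 2.0 * (z_P - z_Q) / a_P
    if h2 < 0.0:
        warnings.warn(
            f"recurrence Q = {Q} below prevalence P = {P}: negative h^2 "
            f"({h2:.4g}) returned unclamped", stacklevel=2)
    return h2


def polymorphism_heritability(record: PolymorphismRecord,
                              par_convention: str = "allele",
                              flip_protective: bool = True) -> HeritabilityEstimate:
    """End-to-end h_p^2 for one variant record.

    Pipeline: orient the risk allele (OR < 1 flips to the complementary
    allele unless ``flip_protective`` is off) -> solve the exact
    case/asymptomatic frequencies (u, x) -> first-degree recurrence Q ->
    Falconer first-degree h^2.  All intermediates are kept on the result.
    """
    notes: list[str] = []
    p = record.population_frequency()
    OR = record.odds_ratio
    flipped = False
    if flip_protective:
        p, OR, flipped = orient_risk_allele(p, OR)
        if flipped:
            notes.append("protective allele re-oriented (OR inverted)")
    elif OR < 1.0:
        notes.append("protective allele modeled as-is (flip disabled)")

    if record.case_freq is not None and not flipped and (
            record.asymptomatic_freq is not None):
        solved = CaseControlFrequencies(u=record.case_freq,
                                        x=record.asymptomatic_freq)
    else:
        solved = solve_case_control_freqs(p, OR, record.prevalence)

    if record.relative == "sibling":
        notes.append(
            "sibling recurrence requested: not valid for possibly de novo "
            "variants; offspring is the safe default")

    rec = first_degree_incidence(record.prevalence, solved.u, p,
                                 record.model, record.relative,
                                 par_convention)
    z_P = upper_tail_threshold(record.prevalence)
    z_Q = upper_tail_threshold(rec.Q)
    a_P = mean_liability_of_affected(record.prevalence)
    h2 = 2.0 * (z_P - z_Q) / a_P
    return HeritabilityEstimate(
        record=record,
        solved_freqs=solved,
        recurrence=rec,
        threshold_P=z_P,
        threshold_Q=z_Q,
        mean_affected_P=a_P,
        h_p2=h2,
        flipped=flipped,
        warnings=tuple(notes),
    )


def combined_heritability(P: float,
                          records: Sequence[PolymorphismRecord],
                          relative: str = "offspring",
                          par_convention: str = "allele",
                          flip_protective: bool = True) -> float:
    """Joint heritability of several variants of one disease.

    Per-variant excess incidences add on top of the shared prevalence and
    the Falconer step is applied once to the combined recurrence.  The
    result lies between the largest single h_p^2 and the sum of the
    singles (the threshold map is concave in Q over the relevant range).
    """
    if not records:
        return 0.0
    components = []
    for record in records:
        if record.prevalence != P:
            raise ValueError(
                f"record {record.identifier!r} has prevalence "
                f"{record.prevalence}, expected shared {P}")
        p = record.population_frequency()
        OR = record.odds_ratio
        if flip_protective:
            p, OR, _ = orient_risk_allele(p, OR)
        solved = solve_case_control_freqs(p, OR, P)
        components.append((solved.u, p, record.model))
    Q = combined_incidence(P, components, relative, par_convention)
    return falconer_h2_first_degree(P, Q)


def variants_needed(P: float, target_h2: float, u: float, p: float,
                    model: str, relative: str = "offspring",
                    par_convention: str = "allele") -> int:
    """Smallest number of identical independent variants whose additive
    excesses reach a target heritability.

    Inverts the Falconer relation for the recurrence the target requires,
    z_Q* = z_P - target * a_P / 2, and divides the needed excess Q* - P by
    the single-variant excess, rounding up; a floating-point guard walks
    the integer up/down so the returned N is exactly the threshold count.
    """
    if not 0.0 < target_h2:
        raise ValueError(f"target_h2 must be positive, got {target_h2!r}")
    excess = attributable_excess(P, u, p, model, relative, par_convention)
    if excess <= 0.0:
        raise ValueError("single-variant excess must be positive")
    z_P = upper_tail_threshold(P)
    a_P = mean_liability_of_affected(P)
    z_Q_needed = z_P - target_h2 * a_P / 2.0
    Q_needed = float(norm.sf(z_Q_needed))
    n = max(1, int(-((P - Q_needed) // excess)))  # ceil((Q_needed - P)/excess)

    def attained(k: int) -> float:
        Q = P + k * excess
        if Q >= 1.0:
            max_k = max(1, int((1.0 - P) / excess) - 1)
            max_h2 = falconer_h2_first_degree(P, P + max_k * excess)
            raise ValueError(
                f"incidence saturates at N = {k} before reaching the target "
                f"h^2; maximum attainable is {max_h2:.4f} at N = {max_k}")
        return falconer_h2_first_degree(P, Q)

    while attained(n) < target_h2:
        n += 1
    while n > 1 and attained(n - 1) >= target_h2:
        n -= 1
    return n
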