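"""Recurrence risk of a disease in first-degree relatives due to one variant.

The chain is: the risk genotype has frequency X1 in the general population
and Y1 among first-degree relatives of patients (computed by feeding a
proband at Hardy-Weinberg equilibrium with the *case* allele frequency u
through the kinship algebra).  The variant accounts for a share of the
prevalence P given by its population attributable risk (PAR); relatives of
the patients carrying the risk genotype see that share inflated by the
enrichment ratio Y1/X1.  The incidence among first-degree relatives is then

    Q = P + PAR * (Y1/X1 - 1).

Two PAR conventions are exposed:

``allele`` (default)
    PAR = P (1 - v/q) at the allele level; under the recessive model it is
    further multiplied by u^2/(u^2 + 2uv), the fraction of risk-allele
    holders among patients who carry the risk genotype.

``genotype``
    PAR = P (G_case - X1)/(1 - X1) with G_case the risk-genotype mass among
    patients (dominant: 1 - v^2; recessive: u^2).  This is the convention
    consistent with a penetrance-based generative model: it equals
    (f1 - f0)(Y1 - X1) for the penetrance pair that reproduces (P, u, p),
    which is what a family simulation measures.

Closed forms for Y1 (proband at HWE(u) pushed through the sibling/offspring
distributions):

    dominant,  sibling:   Y1 = 1 - (q + v)^2 / 4
    dominant,  offspring: Y1 = 1 - q v
    recessive, sibling:   Y1 = (u + p)^2 / 4
    recessive, offspring: Y1 = u p

The arithmetic-geometric mean inequality gives Y_offspring >= Y_sibling
under the dominant model (equality iff v = q) and the reverse under the
recessive model (equality iff u = p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "RecurrenceResult",
    "population_risk_genotype_freq",
    "relative_risk_genotype_freq",
    "attributable_excess",
    "first_degree_incidence",
    "combined_incidence",
]

MODELS = ("AD", "AR")
RELATIVES = ("offspring", "sibling")
PAR_CONVENTIONS = ("allele", "genotype")


def _validate(model: str, relative: str = "offspring",
              par_convention: str = "allele") -> None:
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    if relative not in RELATIVES:
        raise ValueError(
            f"relative must be one of {RELATIVES}, got {relative!r}")
    if par_convention not in PAR_CONVENTIONS:
        raise ValueError(
            f"par_convention must be one of {PAR_CONVENTIONS}, "
            f"got {par_convention!r}")


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class RecurrenceResult:
    """Risk-genotype frequencies and first-degree incidence for one variant."""

    X1: float        # risk-genotype frequency, general population
    Y1: float        # risk-genotype frequency, first-degree relatives
    excess: float    # Q - P attributable to the variant
    Q: float         # incidence among first-degree relatives
    model: str
    relative: str
    par_convention: str = "allele"


def population_risk_genotype_freq(p: float, model: str) -> float:
    """Frequency X1 of the risk genotype(s) in the general population.

    Dominant: carriers, 1 - q^2.  Recessive: homozygotes, p^2.
    """
    _check_prob(p, "p")
    _validate(model)
    q = 1.0 - p
    return 1.0 - q * q if model == "AD" else p * p


def case_risk_genotype_freq(u: float, model: str) -> float:
    """Risk-genotype mass among patients, with case genotypes at HWE(u)."""
    _check_prob(u, "u")
    _validate(model)
    v = 1.0 - u
    return 1.0 - v * v if model == "AD" else u * u


def relative_risk_genotype_freq(u: float, p: float, model: str,
                                relative: str) -> float:
    """Frequency Y1 of the risk genotype(s) among first-degree relatives.

    The proband's genotype distribution is Hardy-Weinberg at the case
    allele frequency u; the relative's distribution follows from the
    kinship algebra, collapsed here to closed forms.
    """
    _check_prob(u, "u")
    _check_prob(p, "p")
    _validate(model, relative)
    q = 1.0 - p
    v = 1.0 - u
    if model == "AD":
        if relative == "sibling":
            return 1.0 - (q + v) ** 2 / 4.0
        return 1.0 - q * v
    if relative == "sibling":
        return (u + p) ** 2 / 4.0
    return u * p


def attributable_excess(P: float, u: float, p: float, model: str,
                        relative: str,
                        par_convention: str = "allele") -> float:
    """The increment Q - P in first-degree incidence due to the variant."""
    _check_prob(P, "P")
    _validate(model, relative, par_convention)
    if p == 0.0:
        raise ValueError("p = 0 leaves the risk-genotype ratio undefined")
    q = 1.0 - p
    v = 1.0 - u
    X1 = population_risk_genotype_freq(p, model)
    Y1 = relative_risk_genotype_freq(u, p, model, relative)
    enrichment = Y1 / X1 - 1.0
    if par_convention == "allele":
        par = P * (1.0 - v / q)
        if model == "AR":
            # only homozygotes among risk-allele holders are risk genotypes
            par *= u * u / (u * u + 2.0 * u * v) if u > 0.0 else 0.0
    else:
        G_case = case_risk_genotype_freq(u, model)
        par = P * (G_case - X1) / (1.0 - X1)
    return par * enrichment


def first_degree_incidence(P: float, u: float, p: float, model: str,
                           relative: str,
                           par_convention: str = "allele") -> RecurrenceResult:
    """Incidence Q = P + attributable excess among first-degree relatives.

    Raises on saturation (Q >= 1): a variant cannot push a probability past
    one, and clamping would silently hide inconsistent inputs.
    """
    excess = attributable_excess(P, u, p, model, relative, par_convention)
    Q = P + excess
    if Q >= 1.0:
        raise ValueError(
            f"first-degree incidence saturates: P + excess = {Q} >= 1")
    return RecurrenceResult(
        X1=population_risk_genotype_freq(p, model),
        Y1=relative_risk_genotype_freq(u, p, model, relative),
        excess=excess,
        Q=Q,
        model=model,
        relative=relative,
        par_convention=par_convention,
    )


def combined_incidence(P: float,
                       components: Sequence[tuple[float, float, str]],
                       relative: str = "offspring",
                       par_convention: str = "allele") -> float:
    """Joint first-degree incidence of several variants of one disease.

    Each component is (u, p, model).  Under additivity of liabilities the
    per-variant excesses simply add on top of the shared prevalence:
    Q = P + sum_i excess_i.
    """
    _check_prob(P, "P")
    total = P
    for u, p, model in components:
        total += attributable_excess(P, u, p, model, relative, par_convention)
    if total >= 1.0:
        raise ValueError(
            f"combined first-degree incidence saturates: Q = {total} >= 1")
    return total
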