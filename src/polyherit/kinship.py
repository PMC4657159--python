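"""Genotype-probability algebra for a biallelic autosomal locus.

Everything here is symbolic in the population frequency ``p`` of allele A
(``q = 1 - p``); which allele is the *risk* allele is decided upstream.
The module provides Hardy-Weinberg genotype distributions, the Bayesian
posterior for a parent's genotype given the allele it transmitted to the
proband, closed-form genotype distributions for a sibling or an offspring
of a proband with an arbitrary genotype distribution, and a full
joint-pedigree enumeration that serves as an independent oracle for the
closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

__all__ = [
    "GENOTYPES",
    "GenotypeDistribution",
    "JointPedigreeRow",
    "hwe_distribution",
    "parental_posterior",
    "sibling_distribution",
    "offspring_distribution",
    "enumerate_sibling_joint",
    "enumerate_offspring_joint",
    "joint_rows_to_text",
]

GENOTYPES = ("AA", "Aa", "aa")
GenotypeLabel = Literal["AA", "Aa", "aa"]

#: Tolerance within which a genotype distribution must sum to one.
NORM_TOL = 1e-12


def _check_freq(p: float, name: str = "p") -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probabilities of the three genotypes (AA, Aa, aa) of one individual."""

    alpha: float  # P(AA)
    beta: float   # P(Aa)
    gamma: float  # P(aa)

    def __post_init__(self) -> None:
        for name, value in (("alpha", self.alpha), ("beta", self.beta),
                            ("gamma", self.gamma)):
            if not -NORM_TOL <= value <= 1.0 + NORM_TOL:
                raise ValueError(f"{name} must be a probability, got {value!r}")
        total = self.alpha + self.beta + self.gamma
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"genotype probabilities must sum to 1 (got {total!r})")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def __getitem__(self, genotype: str) -> float:
        try:
            return dict(zip(GENOTYPES, self.as_tuple()))[genotype]
        except KeyError:
            raise KeyError(f"unknown genotype label {genotype!r}") from None

    def carrier_mass(self) -> float:
        """Probability of carrying at least one A allele (AA or Aa)."""
        return self.alpha + self.beta

    def homozygote_mass(self) -> float:
        """Probability of the AA genotype."""
        return self.alpha


@dataclass(frozen=True)
class JointPedigreeRow:
    """One configuration of a proband's pedigree with its joint probability.

    ``parent_genotypes`` holds (father, mother) for the sibling pedigree and
    (spouse,) for the offspring pedigree.  ``branch`` disambiguates the two
    transmitted-allele assignments of a heterozygous proband in the sibling
    pedigree (the allele the father contributed), and is empty otherwise.
    """

    proband_genotype: str
    parent_genotypes: tuple[str, ...]
    relative_genotype: str
    joint_probability: float
    branch: str = ""


def hwe_distribution(p: float) -> GenotypeDistribution:
    """Hardy-Weinberg genotype distribution (p^2, 2pq, q^2) at allele frequency ``p``."""
    _check_freq(p)
    q = 1.0 - p
    return GenotypeDistribution(p * p, 2.0 * p * q, q * q)


def parental_posterior(
    proband_genotype: str,
    p: float,
    transmitted_allele: str | None = None,
) -> GenotypeDistribution:
    """Posterior genotype distribution of the parent who transmitted one allele.

    Given the allele a parent passed to the proband, Bayes' rule over the
    Hardy-Weinberg prior collapses to "the other allele is a fresh draw from
    the population": a parent known to have transmitted A is AA with
    probability ``p`` and Aa with probability ``q``, and symmetrically for a.

    For a homozygous proband the transmitted allele is implied; for an Aa
    proband the caller must name it (``"A"`` or ``"a"``).
    """
    _check_freq(p)
    if proband_genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype label {proband_genotype!r}")
    if proband_genotype == "AA":
        transmitted = "A"
    elif proband_genotype == "aa":
        transmitted = "a"
    else:
        if transmitted_allele not in ("A", "a"):
            raise ValueError(
                "an Aa proband needs transmitted_allele='A' or 'a'")
        transmitted = transmitted_allele
    q = 1.0 - p
    if transmitted == "A":
        return GenotypeDistribution(p, q, 0.0)
    return GenotypeDistribution(0.0, p, q)


def sibling_distribution(proband: GenotypeDistribution,
                         p: float) -> GenotypeDistribution:
    """Genotype distribution of a full sibling of the proband.

    Closed forms obtained by summing the joint pedigree enumeration
    (parents reconstructed by Bayes from the proband, second child by
    Mendelian segregation)::

        P(AA) = {a(1+p)^2 + b p(1+p) + g p^2} / 4
        P(Aa) = {a(1+p)q + b(1+pq) + g p(1+q)} / 2
        P(aa) = {a q^2 + b(1+q)q + g(1+q)^2} / 4

    with (a, b, g) the proband's genotype probabilities.
    """
    _check_freq(p)
    a, b, g = proband.as_tuple()
    q = 1.0 - p
    aa = (a * (1.0 + p) ** 2 + b * p * (1.0 + p) + g * p * p) / 4.0
    het = (a * (1.0 + p) * q + b * (1.0 + p * q) + g * p * (1.0 + q)) / 2.0
    rr = (a * q * q + b * (1.0 + q) * q + g * (1.0 + q) ** 2) / 4.0
    return GenotypeDistribution(aa, het, rr)


def offspring_distribution(proband: GenotypeDistribution,
                           p: float) -> GenotypeDistribution:
    """Genotype distribution of an offspring of the proband and a random mate.

    The mate is at Hardy-Weinberg equilibrium, so the proband's transmitted
    allele meets an independent population draw::

        P(AA) = a p + b p/2
        P(Aa) = a q + b/2 + g p
        P(aa) = b q/2 + g q
    """
    _check_freq(p)
    a, b, g = proband.as_tuple()
    q = 1.0 - p
    return GenotypeDistribution(
        a * p + b * p / 2.0,
        a * q + b / 2.0 + g * p,
        b * q / 2.0 + g * q,
    )


# Mendelian segregation: P(child genotype | father genotype, mother genotype).
def _mendel(father: str, mother: str) -> dict[str, float]:
    def alleles(g: str) -> tuple[str, ...]:
        return ("A", "A") if g == "AA" else (("a", "a") if g == "aa" else ("A", "a"))

    out = {g: 0.0 for g in GENOTYPES}
    for fa in alleles(father):
        for ma in alleles(mother):
            child = "".join(sorted((fa, ma)))  # "AA", "Aa", "aa"
            out[child] += 0.25
    return out


def _proband_branches(
    proband: GenotypeDistribution, p: float
) -> Iterable[tuple[str, str, float, GenotypeDistribution, GenotypeDistribution]]:
    """Split the proband distribution into transmitted-allele assignments.

    Yields (proband genotype, branch label, weight, father posterior,
    mother posterior).  A homozygous proband fixes both transmitted alleles;
    a heterozygous proband splits, with weight beta/2 each, into the
    assignment where the father contributed A and the one where he
    contributed a.
    """
    a, b, g = proband.as_tuple()
    post_A = parental_posterior("Aa", p, "A")   # parent transmitted A
    post_a = parental_posterior("Aa", p, "a")   # parent transmitted a
    if a > 0.0:
        yield "AA", "", a, post_A, post_A
    if b > 0.0:
        yield "Aa", "A_from_father", b / 2.0, post_A, post_a
        yield "Aa", "a_from_father", b / 2.0, post_a, post_A
    if g > 0.0:
        yield "aa", "", g, post_a, post_a


def enumerate_sibling_joint(proband: GenotypeDistribution,
                            p: float) -> list[JointPedigreeRow]:
    """Enumerate every (proband, father, mother, sibling) configuration.

    Parents are reconstructed from the proband by the transmitted-allele
    posterior; the sibling is a second Mendelian draw from the same parents.
    The marginal over the sibling column equals :func:`sibling_distribution`,
    and the rows sum to one — both are tested invariants.
    """
    _check_freq(p)
    rows: list[JointPedigreeRow] = []
    for pro_g, branch, weight, father_post, mother_post in _proband_branches(
            proband, p):
        for fg in GENOTYPES:
            pf = father_post[fg]
            if pf == 0.0:
                continue
            for mg in GENOTYPES:
                pm = mother_post[mg]
                if pm == 0.0:
                    continue
                for sg, ps in _mendel(fg, mg).items():
                    if ps == 0.0:
                        continue
                    rows.append(JointPedigreeRow(
                        proband_genotype=pro_g,
                        parent_genotypes=(fg, mg),
                        relative_genotype=sg,
                        joint_probability=weight * pf * pm * ps,
                        branch=branch,
                    ))
    return rows


def enumerate_offspring_joint(proband: GenotypeDistribution,
                              p: float) -> list[JointPedigreeRow]:
    """Enumerate every (proband, spouse, offspring) configuration.

    The spouse is an independent Hardy-Weinberg draw at frequency ``p``;
    the offspring follows Mendelian segregation.  The marginal over the
    offspring column equals :func:`offspring_distribution`.
    """
    _check_freq(p)
    spouse = hwe_distribution(p)
    a, b, g = proband.as_tuple()
    rows: list[JointPedigreeRow] = []
    for pro_g, f in zip(GENOTYPES, (a, b, g)):
        if f == 0.0:
            continue
        for sg in GENOTYPES:
            ps = spouse[sg]
            if ps == 0.0:
                continue
            for og, po in _mendel(pro_g, sg).items():
                if po == 0.0:
                    continue
                rows.append(JointPedigreeRow(
                    proband_genotype=pro_g,
                    parent_genotypes=(sg,),
                    relative_genotype=og,
                    joint_probability=f * ps * po,
                ))
    return rows


def marginal_relative(rows: Iterable[JointPedigreeRow]) -> GenotypeDistribution:
    """Sum joint rows into the relative's genotype distribution."""
    mass = {g: 0.0 for g in GENOTYPES}
    for row in rows:
        mass[row.relative_genotype] += row.joint_probability
    return GenotypeDistribution(mass["AA"], mass["Aa"], mass["aa"])


def joint_rows_to_text(rows: Iterable[JointPedigreeRow], sep: str = "\t") -> str:
    """Serialize joint rows to delimited text for debugging/audit."""
    header = sep.join(
        ["proband", "branch", "parents", "relative", "joint_probability"])
    lines = [header]
    for row in rows:
        lines.append(sep.join([
            row.proband_genotype,
            row.branch or "-",
            "/".join(row.parent_genotypes),
            row.relative_genotype,
            repr(row.joint_probability),
        ]))
    return "\n".join(lines) + "\n"
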