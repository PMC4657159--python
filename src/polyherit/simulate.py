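"""Stochastic oracles: family simulation and bivariate liability simulation.

The closed-form recurrence machinery makes claims about conditional
probabilities in pedigrees; these simulators check them from the generative
side.

``simulate_families`` draws nuclear families from an explicit penetrance
model — Hardy-Weinberg mating, exact Mendelian segregation, disease as a
Bernoulli draw given genotype — conditions on an affected proband, and
reports empirical risk-genotype frequency in the chosen relative (Y1),
relative disease frequency (Q) and case allele frequency (u).  The
penetrance pair is obtained by inverting the (P, u, p) parameterization, so
the simulation and the closed forms describe the same population.

``simulate_liability_pairs`` draws proband/relative liabilities from a
bivariate standard normal with correlation h^2/2 (narrow-sense additive
sharing of first-degree relatives, no dominance or shared environment) and
measures the recurrence among relatives of affected probands — the forward
model whose inverse is Falconer's estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .liability import upper_tail_threshold
from .recurrence import case_risk_genotype_freq, population_risk_genotype_freq

__all__ = [
    "PenetrancePair",
    "SimulationSummary",
    "penetrances_from_marginals",
    "simulate_families",
    "simulate_liability_pairs",
]


@dataclass(frozen=True)
class PenetrancePair:
    """Disease probability for the non-risk genotype (f0) and the risk
    genotype (f1); f1*X1 + f0*(1 - X1) equals the prevalence by
    construction."""

    f0: float
    f1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= self.f1 <= 1.0:
            raise ValueError(
                f"need 0 <= f0 <= f1 <= 1, got f0={self.f0!r}, f1={self.f1!r}")


@dataclass(frozen=True)
class SimulationSummary:
    """Empirical estimates with binomial standard errors and provenance."""

    n: int
    seed: int
    estimates: dict[str, float] = field(default_factory=dict)
    standard_errors: dict[str, float] = field(default_factory=dict)
    n_affected: int = 0

    def to_text(self, sep: str = "\t") -> str:
        lines = [sep.join(["quantity", "estimate", "standard_error"])]
        for key in self.estimates:
            lines.append(sep.join([
                key, repr(self.estimates[key]),
                repr(self.standard_errors[key]),
            ]))
        lines.append(sep.join(["n", str(self.n), ""]))
        lines.append(sep.join(["n_affected", str(self.n_affected), ""]))
        lines.append(sep.join(["seed", str(self.seed), ""]))
        return "\n".join(lines) + "\n"


def _binom_se(est: float, n: int) -> float:
    return float(np.sqrt(est * (1.0 - est) / n)) if n > 0 else float("nan")


def penetrances_from_marginals(P: float, u: float, p: float,
                               model: str) -> PenetrancePair:
    """Invert (P, u, p) into the genotype penetrances (f0, f1).

    The risk genotype has population mass X1 and mass G_case among patients
    (case genotypes at HWE(u)), so Bayes gives f1 = P*G_case/X1 and
    f0 = P*(1 - G_case)/(1 - X1).  Infeasible combinations (f1 > 1, or an
    inverted gradient f1 < f0) are rejected with the violated bound named.
    """
    if not 0.0 < P < 1.0:
        raise ValueError(f"P must lie in (0, 1), got {P!r}")
    X1 = population_risk_genotype_freq(p, model)
    if X1 == 0.0:
        raise ValueError("p = 0 gives an empty risk-genotype class")
    G_case = case_risk_genotype_freq(u, model)
    f1 = P * G_case / X1
    f0 = P * (1.0 - G_case) / (1.0 - X1)
    if f1 > 1.0:
        raise ValueError(
            f"infeasible marginals: f1 = P*G_case/X1 = {f1:.6g} > 1; the "
            "stated case enrichment cannot come from any penetrance")
    if f1 < f0:
        raise ValueError(
            f"infeasible marginals: f1 = {f1:.6g} < f0 = {f0:.6g}; "
            "the allele would be protective, orient it first")
    return PenetrancePair(f0=f0, f1=f1)


def _hwe_genotypes(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    """Risk-allele counts (0, 1, 2) for n Hardy-Weinberg individuals."""
    return rng.binomial(2, p, size=n)


def _transmit(rng: np.random.Generator, genotypes: np.ndarray) -> np.ndarray:
    """One gamete per individual: carries the risk allele w.p. genotype/2."""
    return (rng.random(genotypes.shape) < genotypes / 2.0).astype(np.int8)


def _is_risk(genotypes: np.ndarray, model: str) -> np.ndarray:
    return genotypes >= 1 if model == "AD" else genotypes == 2


def simulate_families(p: float, penetrances: PenetrancePair, model: str,
                      relative: str, n: int, seed: int) -> SimulationSummary:
    """Simulate ``n`` nuclear families and condition on an affected proband.

    Offspring mode: the proband is a population draw at HWE(p), the spouse
    another, and the child gets one gamete from each.  Sibling mode: both
    parents are population draws and proband and sibling are two
    independent Mendelian children.  Disease status is an independent
    Bernoulli draw given genotype for every individual.

    Returns empirical Y1 (relative risk-genotype frequency), Q (relative
    disease frequency) and u (proband risk-allele frequency), all among
    families with an affected proband, with binomial standard errors.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if relative not in ("offspring", "sibling"):
        raise ValueError(f"unknown relative {relative!r}")
    rng = np.random.default_rng(seed)

    if relative == "offspring":
        proband = _hwe_genotypes(rng, p, n)
        spouse = _hwe_genotypes(rng, p, n)
        rel = _transmit(rng, proband) + _transmit(rng, spouse)
    else:
        father = _hwe_genotypes(rng, p, n)
        mother = _hwe_genotypes(rng, p, n)
        proband = _transmit(rng, father) + _transmit(rng, mother)
        rel = _transmit(rng, father) + _transmit(rng, mother)

    def affected(genotypes: np.ndarray) -> np.ndarray:
        f = np.where(_is_risk(genotypes, model), penetrances.f1,
                     penetrances.f0)
        return rng.random(genotypes.shape) < f

    keep = affected(proband)
    n_aff = int(keep.sum())
    if n_aff == 0:
        raise RuntimeError(
            f"no affected probands in {n} families; increase n")
    rel = rel[keep]
    proband = proband[keep]

    y1_hat = float(_is_risk(rel, model).mean())
    q_hat = float(affected(rel).mean())
    u_hat = float(proband.mean() / 2.0)
    estimates = {"X1_hat": float(_is_risk(_hwe_genotypes(rng, p, n), model).mean()),
                 "Y1_hat": y1_hat, "Q_hat": q_hat, "u_hat": u_hat}
    ses = {
        "X1_hat": _binom_se(estimates["X1_hat"], n),
        "Y1_hat": _binom_se(y1_hat, n_aff),
        "Q_hat": _binom_se(q_hat, n_aff),
        "u_hat": _binom_se(u_hat, 2 * n_aff),
    }
    return SimulationSummary(n=n, seed=seed, estimates=estimates,
                             standard_errors=ses, n_affected=n_aff)


def simulate_liability_pairs(h2: float, K: float, n: int,
                             seed: int) -> SimulationSummary:
    """Simulate proband/first-degree-relative liability pairs.

    Liabilities are bivariate standard normal with correlation h^2/2; both
    are thresholded at the upper-tail quantile of ``K``.  Reports the
    recurrence Q among relatives of affected probands and the h^2 recovered
    from it by the first-degree Falconer estimator.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must lie in [0, 1], got {h2!r}")
    z = upper_tail_threshold(K)
    rng = np.random.default_rng(seed)
    r = h2 / 2.0
    l1 = rng.standard_normal(n)
    l2 = r * l1 + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    affected = l1 > z
    n_aff = int(affected.sum())
    if n_aff == 0:
        raise RuntimeError(f"no affected probands among {n} pairs")
    q_hat = float((l2[affected] > z).mean())
    estimates = {"Q_hat": q_hat}
    ses = {"Q_hat": _binom_se(q_hat, n_aff)}
    if 0.0 < q_hat < 1.0:
        from .liability import falconer_h2_first_degree, mean_liability_of_affected
        h2_rec = falconer_h2_first_degree(K, q_hat)
        estimates["h2_recovered"] = h2_rec
        # delta method: dh2/dQ = 2 / (a_K * phi(z_Q))
        z_q = upper_tail_threshold(q_hat)
        ses["h2_recovered"] = float(
            2.0 * ses["Q_hat"] / (mean_liability_of_affected(K) * norm.pdf(z_q)))
    return SimulationSummary(n=n, seed=seed, estimates=estimates,
                             standard_errors=ses, n_affected=n_aff)
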