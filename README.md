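# polyherit

**Heritability of a single polymorphism from three published numbers.**

Genome-wide association studies report, for each disease-associated variant,
a prevalence *P*, an odds ratio *OR*, and a risk-allele frequency *p* — and
then struggle to say how much of a disease's heritability that one variant
explains. Quantitative-genetic estimators built on penetrance break down
entirely for variants observed only in patients (*OR* = +∞), which is
exactly the situation for several disease-associated copy-number variants
(CNVs). `polyherit` implements a recurrence-risk route that stays finite in
that limit, for geneticists and epidemiologists working from literature-level
summary statistics rather than genotype data.

## The method

For a biallelic autosomal variant with risk-allele frequency *u* in patients
and *p* in the population (*v* = 1 − *u*, *q* = 1 − *p*):

1. **Case frequencies.** Given (*p*, *OR*, *P*), solve
   *p* = *uP* + *x*(1 − *P*) and *OR* = *u*(1 − *x*)/((1 − *u*)*x*)
   exactly (a quadratic in *u*). When *OR* = ∞: *x* = 0 and *u* = *p*/*P*.
   Protective alleles (*OR* < 1) are re-oriented first.
2. **Risk genotype in relatives.** With the proband's genotypes at
   Hardy–Weinberg equilibrium in *u*, Bayesian reconstruction of the parents
   and Mendelian segregation give the risk-genotype frequency *Y*₁ in a
   first-degree relative (dominant model, offspring: *Y*₁ = 1 − *qv*),
   against the population frequency *X*₁ (dominant: 1 − *q*²).
3. **Recurrence.** The variant accounts for the population-attributable-risk
   share *P*(1 − *v*/*q*) of prevalence; relatives see it enriched by
   *Y*₁/*X*₁, so the first-degree incidence is
   *Q* = *P* + *P*(1 − *v*/*q*)(*Y*₁/*X*₁ − 1)
   (recessive model: an extra factor *u*²/(*u*² + 2*uv*)).
4. **Falconer step.** With liability thresholds *z*_P, *z*_Q and the mean
   patient liability *a*_P = φ(*z*_P)/*P*, the variant's heritability is

   *h*_p² = 2 (*z*_P − *z*_Q) / *a*_P.

Per-variant recurrence excesses add across variants of one disease before
the Falconer step, giving joint heritabilities and a "how many variants of
this size would explain *h*² = 0.4" calculator. Monte Carlo validators
(penetrance-based family simulation, bivariate-normal liability pairs) check
the algebra from the generative side. See `docs/methods.md` for assumptions,
conventions and limitations.

## Worked example

```sh
python examples/worked_example.py
```

```
case frequency u = 0.0039, asymptomatic x = 0.0, prevalence P = 0.01
population risk-allele frequency p = uP + x(1-P) = 3.9e-05

risk-genotype (carrier) frequency, population:      X1 = 7.79985e-05
risk-genotype frequency, offspring of patients:     Y1 = 0.00393885
first-degree recurrence Q = P + PAR*(Y1/X1 - 1)     Q  = 0.0119112

liability threshold at P:  z_P = +2.32635 SD
liability threshold at Q:  z_Q = +2.25998 SD
mean liability of patients: a_P = +2.6652 SD

h_p^2 = 2 (z_P - z_Q) / a_P = 0.0498
```

A duplication found in 0.39% of schizophrenia patients and no asymptomatic
individuals explains ~5% of the liability variance on its own. The other
example scripts replicate a published twenty-variant trial table
(`replicate_trial_table.py`), combine four schizophrenia CNVs into a joint
*h*² of 0.1172 and count variants needed for a target heritability
(`combine_variants.py`), and run the simulation validators
(`simulation_checks.py`).

Programmatic use mirrors the scripts:

```python
import math
from polyherit import PolymorphismRecord, polymorphism_heritability

rec = PolymorphismRecord("16p11.2_dup", "schizophrenia", prevalence=0.01,
                         odds_ratio=math.inf, pop_freq=3.9e-5)
polymorphism_heritability(rec).h_p2   # 0.0498
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the reference quantities end to end from the published inputs —
the worked-example population frequency and recurrence threshold, and the
four per-variant *h*_p² values that anchor the replication (three
schizophrenia CNVs with infinite OR and a type-2-diabetes CNV requiring the
finite-OR solver) — and writes them as JSON.
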