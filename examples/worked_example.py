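"""Single-variant heritability, step by step.

Walks the full chain for a schizophrenia-associated 16p11.2 duplication
CNV found only in patients (case allele frequency 0.0039, absent in
asymptomatic individuals, prevalence 1%): population frequency, liability
thresholds, first-degree recurrence, and the resulting h_p^2.
"""

import math

from polyherit import (
    PolymorphismRecord,
    polymorphism_heritability,
    population_freq_from_case_control,
)

u, x, P = 0.0039, 0.0, 0.01
p = population_freq_from_case_control(u, x, P)
print(f"case frequency u = {u}, asymptomatic x = {x}, prevalence P = {P}")
print(f"population risk-allele frequency p = uP + x(1-P) = {p:.6g}")

record = PolymorphismRecord(
    identifier="scz_16p11.2_dup", disease="schizophrenia",
    prevalence=P, odds_ratio=math.inf, pop_freq=p,
    model="AD", relative="offspring")
est = polymorphism_heritability(record)

rec = est.recurrence
print(f"\nrisk-genotype (carrier) frequency, population:      X1 = {rec.X1:.6g}")
print(f"risk-genotype frequency, offspring of patients:     Y1 = {rec.Y1:.6g}")
print(f"first-degree recurrence Q = P + PAR*(Y1/X1 - 1)     Q  = {rec.Q:.6g}")
print(f"\nliability threshold at P:  z_P = {est.threshold_P:+.5f} SD")
print(f"liability threshold at Q:  z_Q = {est.threshold_Q:+.5f} SD")
print(f"mean liability of patients: a_P = {est.mean_affected_P:+.4f} SD")
print(f"\nh_p^2 = 2 (z_P - z_Q) / a_P = {est.h_p2:.4f}")
print("\nA single CNV confined to patients explains about 5% of the")
print("liability variance of a disease with prevalence 1%.")
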