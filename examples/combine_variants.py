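"""Joint heritability of several variants, and how many are needed.

Combines the four schizophrenia CNVs observed only in patients into one
joint h^2 (their per-variant recurrence excesses add on the prevalence
before the liability step), then asks how many variants of a given effect
size it would take to explain a heritability of 0.4 at prevalence 1%.
"""

import math

from polyherit import (
    PolymorphismRecord,
    combined_heritability,
    polymorphism_heritability,
    variants_needed,
)

P = 0.01
cnv_freqs = {"16p11.2 dup": 3.9e-05, "22q11.2 del": 3.5e-05,
             "NRXN1 del": 1.6e-05, "AS/PWS dup": 1.2e-05}
records = [
    PolymorphismRecord(name, "schizophrenia", P, math.inf, pop_freq=p)
    for name, p in cnv_freqs.items()
]

print("per-variant h_p^2 (dominant model, offspring recurrence):")
singles = []
for record in records:
    h2 = polymorphism_heritability(record).h_p2
    singles.append(h2)
    print(f"  {record.identifier:<14} p = {record.pop_freq:.1e}   "
          f"h_p^2 = {h2:.4f}")

joint = combined_heritability(P, records)
print(f"\njoint h^2 of the four CNVs: {joint:.4f}")
print(f"(between the largest single, {max(singles):.4f}, and the sum, "
      f"{sum(singles):.4f}: the threshold map is concave in the recurrence)")
print("Four CNVs explain ~15% of a twin-study heritability of ~0.8.")

print("\nvariants needed to explain h^2 = 0.4 at P = 0.01, if each variant")
print("is confined to patients (u = p/P) at the given population frequency:")
for p in (1e-05, 4e-05, 1.6e-04):
    n = variants_needed(P, 0.4, u=p / P, p=p, model="AD")
    print(f"  p = {p:.0e}: N = {n}")
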