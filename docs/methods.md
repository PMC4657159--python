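# Methods

## Model

A biallelic autosomal variant is summarized by its disease prevalence `P`,
allele-level odds ratio `OR`, and risk-allele frequency `p` in the general
population (`u` in patients, `x` in asymptomatic individuals; complements
`q`, `v`, `y`). Disease liability is standard normal with a threshold at the
upper-tail quantile of the group incidence; heritability is the share of
liability variance attributable to the variant, obtained from the excess
disease recurrence the variant induces in first-degree relatives.

The chain has four stages, each a pure function:

1. **Frequency solve** (`polyherit.frequencies`). `p = uP + x(1-P)` and
   `OR = u(1-x)/((1-u)x)` are solved *exactly* for `(u, x)`: substituting
   `x = (p-uP)/(1-P)` yields `(OR-1)P u² - [OR(P+p)+1-P-p] u + OR p = 0`,
   whose admissible root (`p ≤ u ≤ 1`, `x ≥ 0`) is unique for `OR ≠ 1`.
   The linear coefficient is strictly negative, so the larger root comes
   from `(-b+√Δ)/2a` and the smaller from the product form `2c/(-b+√Δ)`;
   no catastrophic cancellation for small `p`. `OR = ∞` (variant observed
   only in patients) short-circuits to `x = 0`, `u = p/P`, rejected as
   infeasible when `p > P`. Protective alleles (`OR < 1`) are re-oriented
   (`p → 1-p`, `OR → 1/OR`) before solving, and the flip is recorded.

2. **Kinship algebra** (`polyherit.kinship`). The proband's genotype
   distribution is Hardy–Weinberg at `u`. Each parent's genotype, given the
   allele it transmitted, has the Bayesian posterior "other allele is a
   fresh population draw" — `(p, q, 0)` over `(AA, Aa, aa)` for a parent
   that transmitted `A`. A heterozygous proband splits with weight 1/2 into
   the two transmitted-allele assignments. Siblings are a second Mendelian
   draw from the reconstructed parents; offspring pair the proband's gamete
   with a Hardy–Weinberg spouse. The closed forms (e.g. sibling
   `P(AA) = {α(1+p)² + βp(1+p) + γp²}/4`, offspring `P(AA) = αp + βp/2`)
   are verified against the full joint enumeration to 1e−12 on random
   inputs; Hardy–Weinberg probands are a fixed point of both maps.

3. **Recurrence** (`polyherit.recurrence`). Risk-genotype frequency in the
   population `X1` (dominant: carriers `1-q²`; recessive: homozygotes `p²`)
   and in relatives `Y1` (dominant offspring `1-qv`, dominant sibling
   `1-(q+v)²/4`, recessive offspring `up`, recessive sibling `(u+p)²/4`).
   First-degree incidence `Q = P + PAR·(Y1/X1 - 1)`, with `Q ≥ 1` raised
   as saturation, never clamped.

4. **Liability step** (`polyherit.liability`). `z_K = Φ⁻¹(1-K)` via
   `scipy.stats.norm.isf`; mean patient liability `a_K = φ(z_K)/K`;
   `h_p² = 2(z_P - z_Q)/a_P`, i.e. regression on the proband's *general
   population* patient mean with relationship coefficient 1/2. This variant
   of the estimator is the one consistent with the reference triple
   (z_P = 2.32635, a_P = 2.6652, z_Q = 2.25998 → h² = 0.0498). Negative
   estimates (Q < P) are returned signed with a warning.

Multi-variant combination adds the per-variant excesses to the shared `P`
before a single Falconer step; the result lies strictly between the largest
single h_p² and the sum of singles because the threshold map is concave in
`Q` over the relevant range. `variants_needed` inverts the Falconer relation
for the required recurrence and rounds the excess ratio up, with an integer
walk guarding the floating boundary (a naive increment loop is the test
oracle).

## PAR conventions

The default attributable-risk factor is the **allele-level** PAR
`P(1 - v/q)`, with the additional recessive factor `u²/(u²+2uv)`; it is the
convention the reference results use, and it is deliberately conservative.
A penetrance-consistent alternative, `par_convention="genotype"`, uses
`P(G_case - X1)/(1 - X1)` with `G_case` the patients' risk-genotype mass
(dominant `1-v²`, recessive `u²`). This equals `(f1 - f0)(Y1 - X1)` for the
penetrance pair `(f0, f1)` that reproduces the marginals (see below), which
is what a generative family simulation actually measures — for the dominant
model it collapses to `P(1 - v²/q²)(Y1/X1 - 1)`, roughly twice the
allele-level excess for rare variants. The family simulator therefore
validates the genotype convention and *documents* the conservative bias of
the default rather than gating it.

## Defaults and parameters

| parameter | default | why |
|---|---|---|
| `model` | `AD` | dominance form of CNVs is usually unknown; the dominant estimate is the upper end of the dominant–recessive bracket and the convention of the reference table |
| `relative` | `offspring` | germline variants, including *de novo* ones, are transmitted to offspring; a sibling's recurrence is invalid for possibly *de novo* CNVs (the sibling path stays available and attaches a caveat) |
| `par_convention` | `allele` | reproduces the reference results; conservative |
| `flip_protective` | `True` | the recurrence equations presuppose a risk allele |
| normalization tolerance | 1e−12 | floating probabilities throughout; no rational arithmetic, all consumers are float |

## Simulators: what they emulate, what they do not

`simulate_families` draws nuclear families with Hardy–Weinberg mating,
exact Mendelian segregation, and disease as an independent Bernoulli draw
per individual given genotype, using the penetrance pair
`f1 = P·G_case/X1`, `f0 = P(1-G_case)/(1-X1)` inverted from `(P, u, p)`
(infeasible marginals, `f1 > 1`, are rejected — the stated case enrichment
then cannot arise from any penetrance). It conditions on an affected
proband and reports empirical `Y1`, `Q`, `u` with binomial standard errors.
No linkage disequilibrium, assortative mating, shared environment,
multi-locus effects, or ascertainment beyond a single affected proband: a
green simulation check establishes the *algebra* under the model's own
assumptions, not the realism of those assumptions for any actual disease.

One approximation is inherent and quantified: the closed forms take case
genotypes at HWE(`u`), while penetrance-based ascertainment yields a
slightly different AA:Aa split among affected carriers. At the validation
point (`P = 0.1`, `p = 0.05`, `u = 0.15`) this shifts the offspring
recurrence by ≈0.0015, about 1.5 standard errors at n = 10⁶ — inside the
3-SE comparison band, and an order of magnitude smaller than the
allele-vs-genotype PAR separation (≈7 SE) the check is designed to resolve.

`simulate_liability_pairs` draws proband/relative liabilities from a
bivariate standard normal with correlation `h²/2` (narrow-sense additive
sharing; no dominance, which for first-degree relatives other than full
sibs is exact and for sibs an assumption). Falconer's estimator is a
linearization: against the exact bivariate-normal recurrence it is biased
low, e.g. recovered 0.2873 for true h² = 0.3 at K = 0.05 — within 3 SE of a
10⁶-pair run for K ≤ 0.1 (and at K = 0.01 up to h² = 0.5), but the bias
exceeds that resolution for simultaneously large prevalence and
heritability (h² = 0.5, K = 0.2: bias ≈ −0.018). Tests therefore compare
the simulator to the exact recurrence and the estimator's bias to the exact
truth separately, rather than relying on one seed's noise to absorb both.

## Numerical and design choices

- **Exact solve vs "approximated solutions".** The case-frequency step is
  solved exactly. This reproduces the reference worked example and the four
  anchor rows of the bundled table to printed precision. Several other
  published rows (both autism CNVs' printed values, 22q11.2, 15q11.3,
  13q14.2, the OR < 1 SNP rows, the ALS rows) are *not* reproduced from
  their printed `(OR, P, p)` inputs — differences range from 2% to
  several-fold — indicating source-specific case frequencies or an
  unspecified approximation upstream of the printed values. Those rows are
  carried in the fixture flagged `anchor=False` for side-by-side display
  and are never asserted numerically.
- **Protective SNP rows.** How the reference results handled OR < 1 rows is
  unstated; this package re-orients them and says so in the result's
  warnings column. The two printed OR < 1 values are among the
  non-reproduced rows under either handling.
- **Thresholds from unrounded Q.** All intermediates are carried at full
  precision; printed 4-decimal output is a formatting concern of the table
  writer only (a `.full.tsv` sidecar keeps machine precision).
- **Degenerate inputs.** `p = 0` (undefined enrichment ratio), `u = 1`
  (undefined case odds), saturating `Q ≥ 1`, and `OR = ∞` with `p > P` all
  raise with the violated constraint named; nothing is clamped.

## Known limitations

- Intermediate dominance (heterozygote OR strictly between 1 and the
  homozygote OR) is bracketed by the AD and AR results, not computed.
- X-linked and multi-allelic variants are out of scope.
- Combination across variants assumes independent loci and additive
  excesses; interactions and linkage are not modeled.
- The estimator inherits Falconer's linearization bias (see above), which
  is material only for common, highly heritable phenotypes.
- Total-disease heritability denominators (turning an h_p² into "x% of the
  heritability") are external inputs and not estimated here.
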