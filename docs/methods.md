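# Methods

## SILAC stoichiometry model

A SILAC pair mixes a heavy-lysine-labeled genotype with a light genotype.
For any peptide species, the H/L intensity ratio r estimates the relative
contribution of the two genotypes to that species' pool. Three effects must
be removed before the ratio can be read as a stoichiometry:

1. **Incomplete label incorporation.** A fraction (1 − e) of the heavy
   genotype's protein carries light lysine and is counted in the light
   channel. e is estimated from a heavy-labeled-only reference sample: with
   perfect incorporation its H/L ratios would be infinite; in practice the
   median reference ratio s̃ gives e = s̃/(1 + s̃). Measured ratios are then
   corrected by inverting the two-channel mixing model:
   ra = |x/(1 − x)| with x = (1/e)·r/(1 + r). When x ≥ 1 the observed heavy
   fraction exceeds the labeling ceiling (pure-heavy species measured with
   noise); such ratios are flagged as *saturated*, excluded from medians,
   and counted in the audit output rather than propagated as the finite but
   meaningless value |x/(1 − x)| would give.
2. **Protein-level loading.** Site-peptide ratios are divided by the median
   efficiency-corrected ratio of the same protein's non-site peptides, so
   per-state stoichiometry is not confounded by total-protein differences.
3. **Conversion to a fraction.** The normalized ratio pn maps to a
   fractional-heavy value H = (1/e)·pn/(1 + pn), clamped into [0, 1]
   (clamps counted and logged). %H is the median H × 100; %L = 100 − %H.

Significance per modification state is a two-sided Mann-Whitney U comparing
the state's log2 efficiency-corrected ratios with a theoretical H = L null
derived from the reference set: each reference ratio is
efficiency-corrected to sa, its implied heavy fraction y = sa/(1 + sa) is
halved (what a true 1:1 contribution would show), and mapped back to a
ratio sn = (y/2)/(1 − y/2). The map is bounded — sn → 1 as sa → ∞ — and
ratios that saturate the efficiency correction take the limit value sn = 1.
This arises by construction, not only through noise: because e is estimated
from the reference median, the median reference ratio itself lands exactly
on x = 1. The audit output records `null_assumes_eq2_correction: true` to
flag that the same correction transform is applied to the reference set as
to measured ratios.

**Three-state inference by mass conservation.** Where one genotype of a pair
can be assumed homogeneous (all-unmodified, or all-dihydroxylated), the
other genotype's share of that state is 100 ÷ (H/L) of the state's median
pair ratio, capped at 100. Two such pair estimates give the third state by
conservation: %mono = 100 − %unmod − %di; inputs whose sum exceeds 100 are
rejected as inconsistent rather than truncated.

## TMT two-condition model

Reporter-ion intensities of two channels are compared per PSM. PSMs are
first deduplicated by QuanResultID, keeping the highest-summed-intensity row
per identifier. Non-site PSMs give the protein-loading correction
f = Σch1/Σch2 (an intensity-weighted estimator — deliberately the plain
ratio of sums, not a mean of ratios). Site PSMs are grouped by modification
state; each contributes log2((ch1/ch2)/f). PSMs with a zero or missing
reporter channel are excluded with a logged count (no imputation on the TMT
side: reporter ions of confidently identified PSMs rarely drop to zero, and
an intensity floor would bias the correction sums). The per-state summary is
the mean fold change on the ratio scale (mean of 2^log2 values); because the
choice of average matters for skewed ratio distributions, the geometric mean
(2^mean) is emitted alongside. The test against "no change" is the two-sided
Wilcoxon signed-rank on the log2 ratios versus zero; zeros are dropped by
the usual signed-rank convention (count logged) and an all-zero input warns
and returns p = 1.

## Statistical tests

Both nonparametric tests delegate to SciPy. Mann-Whitney uses the exact
null distribution when both samples have fewer than 20 observations and no
ties occur, otherwise the normal approximation with midranks and tie
correction. Wilcoxon is exact up to n = 25 without ties, otherwise the
normal approximation with continuity correction. The test suite verifies
both exact paths against brute-force enumeration (all pooled-sample splits;
all 2^n sign assignments). Two-sided p-values are computed as the
probability of a statistic at least as far from its null mean, which for
these symmetric null distributions equals the doubled smaller tail.

## Peptide-mass arithmetic

Monoisotopic residue masses come from pyteomics' standard table; constants
are proton 1.00727646 Da, water 18.010565 Da, oxygen addition 15.994915 Da,
deamidation 0.984016 Da, TMT reagent 229.162932 Da (the 10/6-plex reagent
mass, which reproduces the published inclusion list), and the heavy-lysine
(13C6, 15N2) delta computed from isotope masses, 8.014199 Da. Published
inclusion-list and SIM parent masses are matched to within 5 ppm rather
than to printed decimals: the printed values sit ~1–3 ppm from
standard-table arithmetic, presumably reflecting the acquisition software's
internal constants, and we do not attempt to reverse-engineer those.
Digestion: LysC cleaves C-terminal to K; trypsin C-terminal to K/R with the
standard not-before-proline exception; coordinates are 1-based inclusive
and at zero missed cleavages the peptides tile the protein exactly. SILAC
feature pairing accepts a light/heavy pair when the heavy mass is within
4 ppm (default) of light + nK × 8.014199; ppm is computed relative to the
heavier member, candidate pairs are accepted closest first with ties broken
by lower identifier, so matching is deterministic and order-independent.

## PSM filtering and imputation (SILAC)

Only PSMs flagged high-confidence and unique are used. Retained rows
missing exactly one intensity channel keep their single peak: the missing
channel is imputed with the minimum observed intensity of that channel
across the filtered table of the same experiment (the observed minimum
proxies the detection floor), the row is flagged `imputed`, and ratios are
recomputed from intensities after imputation. Rows with both channels
missing and no precomputed ratio are dropped.

## Synthetic-data generator

The SILAC generator emulates a mixed pair at configurable mixing ratio with
per-genotype state fractions at the target proline. Defaults are the
wild-type-versus-partially-modified design: heavy genotype (0, 0, 1),
light genotype (0.32, 0.60, 0.08), e = 0.95, 1:1 mixing, 200 site PSMs per
state, 50 non-site target-protein PSMs, 100 heavy-only reference PSMs, and
multiplicative lognormal ratio noise with σ = 0.25 (natural-log scale).
Mislabeling is modeled minimally and consistently with the correction
transform: a fraction (1 − e) of heavy-genotype molecules appears in the
light channel, so the expected state ratio is
e·mix·f_H / (f_L + (1 − e)·mix·f_H). A state absent from one genotype
yields single-channel PSMs; a state absent from both yields none. Base peak
areas are lognormal around 10^6 with σ = 2 natural-log units (3–4 decades,
as in whole-lysate runs), and the table includes 300 PSMs of co-enriched
40S proteins at the protein-loading ratio — they are not quantified but set
a realistic per-channel minimum for the imputation floor. The TMT generator
uses a narrower intensity spread (σ = 0.5 ln units — a purified
single-protein digest, where the summed-intensity correction factor would
otherwise be dominated by a few extreme PSMs), 200 background PSMs, 50
site PSMs per state, ratio noise σ = 0.3, a loading offset of 3 between
channels, and state fold changes (1, 1, 1.6) mirroring a
dihydroxylation-promoting condition.

What the generator does **not** emulate: correlated noise across PSMs of
the same peptide, retention-time or charge-state structure, isotopic
impurity of TMT reporters, identification errors, and intensity-dependent
ratio variance. Passing round-trip tests therefore demonstrate correctness
of the estimation chain under the stated noise model, not robustness to
every artifact of real acquisitions.

At σ = 0 every pipeline estimate equals generator truth exactly (to
floating point) at 1:1 mixing; the test suite asserts this, plus
statistical recovery over 60 seeds at the default noise levels (per-state
%L within ±2 percentage points; per-state fold changes within ±10%, each in
at least 95% of seeds), plus Mann-Whitney level calibration (rejection rate
within [0.03, 0.07] at α = 0.05 over 1000 null replicates of two size-50
samples). These problem sizes keep the full suite fast while leaving the
Monte-Carlo margins comfortable.

## Numerical and interface choices

- **Medians** are interpolated for even counts (numpy convention). The
  order-statistic (m+1)/2 definition used in the derivation of e presumes
  odd counts; for odd counts the two coincide.
- Percentages are reported to 6 significant digits in TSV output and full
  precision in JSON; p-values are never rounded.
- The pipelines are deterministic given an input table; only the generator
  consumes a seed, which is recorded in the output header.
- TSV is the canonical dialect (tab-delimited, `#` comments, UTF-8); CSV is
  accepted on read. Vendor column headers are mapped via a `column_map`
  config entry rather than guessed. Modification strings such as
  `dioxidation@P62` are parsed into state labels when no explicit state
  column is present.
- CLI exit codes: 0 success, 2 input/validation error, 1 internal error.

## Known limitations

- Single-site, three-state model; no multi-site combinatorics.
- Two-channel TMT only; no isotopic-impurity correction matrix.
- The labeling-efficiency correction assumes one labeled amino acid
  (lysine) and LysC-style digestion, where every peptide carries at least
  one labeled residue; tryptic arginine-terminated peptides from a
  lysine-labeling experiment would violate the mixing model.
- The minimum-intensity imputation floor makes %H estimates for
  single-channel states a function of the table's dynamic range; values
  below ~1% should be read as "at or below the detection floor", not as
  precise stoichiometries.
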