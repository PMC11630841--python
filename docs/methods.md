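# Methods

## Pipeline model

`famrescue` operationalizes a simple observation: within a protein family,
AlphaFold-style predictors often produce a mixture of confident
(mean domain plDDT ≥ 70) and unconfident members, and the confident models can
be recycled as structural templates to re-predict the unconfident ones. The
pipeline stages and their contracts:

**Family profiling.** Member domain plDDTs (arithmetic mean of the per-residue
plDDT over the Pfam-style 1-based inclusive domain span) are binned into 100
equal bins on [0, 100] (bin k covers [k−1, k), last bin right-closed) and
normalized by the maximum count so the tallest bin is 1. Peak candidates are
local maxima above a minimum relative height of 0.03; plateaus resolve to
their midpoint bin (left bin on even-width plateaus). A minimum peak distance
of 19 bins is enforced greedily: candidates are accepted in order of
descending height — ties to the lower bin — and anything closer than 19 bins
to an accepted peak is discarded. The reference peak finder leaves the order
of equal-height candidates unspecified (its priority sort is unstable), so the
filter is implemented here with that fixed, oracle-tested tie rule.
Peaks are classed by their bin-center plDDT: low < 50 ≤ medium < 70 ≤ high
(bin centers differ from edges by 0.5 plDDT, below scientific resolution).
A family is *rescuable bimodal* with ≥ 100 members (configurable), one high
peak and one medium-or-low peak. When a fixed number of families is wanted,
families are ranked by the balance score |n<70 − n≥70| / n (ascending; ties to
the larger family, then lexicographic id) — "most balanced" is not formalized
in the source methodology, so this score is this package's own definition.

**Cohort strata.** The remodelling cohort uses different boundaries from the
peak classes on purpose: low < 70 ≤ medium < 90 ≤ high, up to `per_stratum`
(default 10) proteins per stratum, complete proteins prioritized over
fragments, the residual choice being a seeded uniform draw. A deficit in one
stratum is not transferred to another — simpler and auditable. The boundary
value 90 is assigned to the high stratum so strata are disjoint and
exhaustive.

**Template bank and prediction modes.** Baseline (no-template, MSA-enabled)
predictions are run once per cohort protein and cached. Models with baseline
mean plDDT ≥ 70 (inclusive) form the family's template bank, sorted by
descending plDDT; at most `max_templates` (default 4, a common predictor
limit) are passed per request. A protein's own baseline model is *not*
excluded from its template set by default, mirroring the positive control in
which confident proteins are remodelled with themselves as template;
`exclude_self_template=True` switches this off. Each cohort protein is then
re-predicted with templates + MSA and with templates + single sequence, and
the higher-plDDT result is the *best pick* (ties go to the lower-variance MSA
mode). *Rescued* means baseline < 70 and best pick ≥ 70 — "increased above
70" is read as ≥ 70, consistent with the ≥ 70 template-confidence convention;
the threshold and its strictness are configurable.

**Alignment identity.** Percent identity to the closest template uses global
Needleman–Wunsch/Gotoh alignment with BLOSUM62 and affine gaps, default
open −11 / extend −1 (a gap of length k costs open + (k−1)·extend). The
source methodology does not state its gap scores, so absolute identities may
differ from it by a few percent. The identity denominator is the total number
of alignment columns, gaps included — the conservative choice; the ambiguous
residue X scores 0 against everything. Closest-template ties break to the
higher alignment score, then the lexicographically smaller template id.

**Statistics.** Deltas are computed on the low-baseline subset
(baseline < 70), on whole-protein mean plDDT (domain-restricted deltas are
carried as extra columns). Wilcoxon signed-rank tests are paired and
one-sided, dropping zero differences, with midrank ties; the exact null is
used for n ≤ 25 nonzero differences and the continuity-corrected normal
approximation above. When every paired difference is zero the standalone test
raises a degenerate-data error; inside `summarize` this case is reported as
statistic 0.0, p = 1.0 ("no evidence"), which keeps a perfectly null pipeline
summarizable. Pearson correlations use the product-moment r with the
two-sided t-test p. No multiple-testing correction is applied — p-values are
reported raw.

## Synthetic data generator

The generator exists so every stage is testable without structure-prediction
hardware. One family = a random 80-residue consensus; each member draws a
mixture component (default weights 0.5/0.5), a target mean domain plDDT from
a truncated normal on [0, 100] (defaults: means 45 and 88, sd 2.0 — tight
components so that histogram peak recovery at ~100 draws per component is
informative), and a per-site mutation rate
`identity_decay × (1 − target/100) × U(0.5, 1.5)` (identity_decay default
0.8), so low-confidence members are also the most diverged and span
identities from ~90% down toward the 30% floor, as real rescue cohorts do.
Per-residue plDDT profiles are the target mean plus smoothed Gaussian noise,
with extra noise and a downward offset outside the domain; the domain is
re-centered on the target so the truth table's domain plDDT is exact.
Cα coordinates are an idealized helix trace — enough to write valid
single-chain PDB/mmCIF files, not meaningful geometry. Fragments are flagged
at rate `fragment_fraction` (default 0.1) but not physically truncated.

**Mock prediction backend.** Baseline requests replay the generated model.
Template-mode requests compute the identity to the closest supplied template
and apply an expected gain linear in identity:
`gain × (identity − 30) / 70` with `gain = 40` at full identity. Below the
30% identity floor the single-sequence expectation goes negative (a distant
template actively misleads), while the MSA expectation is floored at zero,
scaled by 0.4, and with probability 0.25 the MSA run ignores the templates
entirely. Gaussian mode noise has sd 12 (single) vs 6 (MSA). These defaults
were derived from the reported per-mode variance decomposition of the real
study (identity-driven signal ≈ 9 vs 3.5 plDDT sd, residual spread ≈ 12.5 vs
6), so the harness reproduces its qualitative findings: template gains grow
with identity, the single-sequence mode is higher-gain/higher-risk, its
identity correlation is the stronger one, and the best pick dominates both.
Results are deterministic per (request seed, protein id, mode) regardless of
call order. The response model is a test harness encoding those qualitative
behaviours, not a scientific claim about any predictor.

**What passing tests do and do not show.** The synthetic families have no real
evolutionary covariance, no realistic geometry, no MSA depth effects, and
their plDDT response to templates is the constructed model above. Green tests
demonstrate that the orchestration, selection rules, alignment, statistics and
reports are correct and deterministic — not that any particular real protein
family will be rescued at any particular rate.

## Problem sizes and numerical choices

The shipped study scale is 10 families × 30 members (≈ 230 modelled proteins
after profiling filters, ≈ 100 low-confidence baselines), which exercises
every code path with comfortable statistical power for the paired tests.
Peak-detector and aligner correctness are verified against brute-force
enumeration oracles (500 random histograms; 200 random sequence pairs of
length ≤ 6, where exhaustive enumeration of the global alignment space is
feasible). plDDT values survive a PDB/mmCIF round trip to within 0.01 (the
B-factor column carries two decimals). Model files must be single-chain;
multi-chain input is an error rather than a silent chain pick. Nonstandard
residues map to X and keep their plDDT entry so domain spans stay in
register.

## Known limitations

- The command backend trusts the external predictor to honour the MSA flag
  and template directory; it validates only the output contract (exactly one
  readable single-chain model).
- Fragment members are flagged, never truncated, so fragment-specific
  alignment effects are not emulated.
- The balance-score family ranking and the identity denominator are this
  package's own definitions where the source methodology is silent; both are
  configurable or documented above.
- Histogram peak localization at ±2 bins requires reasonably tight
  plDDT modes; very broad families localize more coarsely (the detector is
  still correct — the histogram argmax is simply a noisy mode estimator).
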