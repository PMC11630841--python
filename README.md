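# famrescue

Rescue low-confidence AlphaFold models with high-confidence templates from the
same protein family.

## The problem

Across a Pfam-style protein family, AlphaFold models can vary wildly in
predicted confidence (plDDT, a 0–100 per-residue score stored in the B-factor
column of the deposited model). Many families are *bimodal*: one subset of
members is modelled confidently (mean domain plDDT ≥ 70) and another is not.
`famrescue` implements the rescue strategy for such families:

1. **Profile** each family's domain plDDT values into a 1–100 binned,
   0–1 max-normalized histogram and detect peaks (`scipy`-style local maxima,
   minimum height 0.03, minimum distance 19 bins). A family is *rescuable*
   when it has ≥ 100 members, one high peak (≥ 70) and one medium/low peak.
2. **Select** a stratified cohort per family — up to 10 proteins each from the
   low (< 70), medium (70–< 90) and high (≥ 90) strata, complete proteins
   before fragments.
3. **Re-predict** every cohort protein through a pluggable backend in three
   modes: no-template + MSA (baseline), templates + MSA, and templates +
   single sequence (MSA off). Templates are the within-family baseline models
   with mean plDDT ≥ 70.
4. **Best pick**: per protein, keep the template-mode model with the higher
   mean plDDT. A protein is **rescued** when its baseline was below 70 and the
   best pick reaches 70.
5. **Report** paired statistics: per-mode plDDT deltas (mean ± sd), one-sided
   Wilcoxon signed-rank tests against the baseline, and Pearson correlations
   between the gain and the percent identity to the closest template
   (Needleman–Wunsch/Gotoh global alignment, BLOSUM62, affine gaps
   open −11 / extend −1).

Running an actual structure-prediction network is out of scope: the backend is
a contract. The package ships a stochastic mock backend (gains grow linearly
with closest-template identity above a 30% identity floor; single-sequence
mode is higher-gain but higher-variance) and a command adapter for any
ColabFold-style external predictor. With the mock backend plus the synthetic
family generator, every stage runs deterministically in seconds on a laptop —
which is what the test suite does.

## Worked example

`examples/03_rescue_study.py` generates ten synthetic bimodal families of 30
members, runs the full pipeline with the mock backend and prints:

```
proteins modelled: 231
low-confidence baselines (plDDT < 70): 100
rescued (best pick >= 70): 22 (22%)
  delta plDDT template_msa: +4.3 +/- 6.6
  delta plDDT template_single: +14.7 +/- 13.8
  delta plDDT best_pick: +16.9 +/- 11.0
best pick vs baseline: Wilcoxon one-sided p = 6.19e-18
identity-vs-gain Pearson r: single 0.52, MSA 0.24
```

Reading the numbers: of 231 proteins modelled, 100 had a low-confidence
baseline; templates lifted 22 of them over the plDDT 70 threshold. The
single-sequence mode gains more on average but with much larger spread than
the MSA mode, the best pick dominates both, and the gain correlates with the
identity to the closest template — more strongly when the MSA is off, because
with an MSA present the templates contribute less (and are sometimes ignored).

The other examples profile a single family, compute alignment identities, and
show the external-predictor command adapter. There is also a thin CLI:

```sh
famrescue synth --families 10 --members 30 --seed 1 --out study/
famrescue run --models study/models --domains study/domains.tsv \
              --backend mock --min-members 20 --seed 1 --out results.csv
famrescue report --results results.csv --out summary.json
```

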