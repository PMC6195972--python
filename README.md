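# tner — tri-nucleotide-context background error suppression for ctDNA panels

Ultra-deep targeted sequencing of cell-free DNA (cfDNA) can reveal tumor
mutations at allele fractions around 0.1%, but technical background errors
occur at comparable rates, so a variant caller needs a per-position model of
the background to tell signal from noise. The background is usually estimated
from a small cohort of healthy controls (a dozen subjects or so), which makes
naive per-position estimates — and especially per-position Gaussian outlier
models — unstable.

This package implements an empirical-Bayes alternative. Error reads at panel
position *j* are modeled as binomial,

```
X_ij ~ Binomial(N_j, π_ij)
```

and the position-specific background rate π_ij is given a conjugate beta
prior shared by all positions in the same **tri-nucleotide context** (TNC) —
the substituted base, pyrimidine-canonicalized, plus its 5′ and 3′ neighbours;
96 classes in total. The prior mean μ̂_i and concentration ν̂_i of context *i*
are estimated by the method of moments from the spread of per-position rates
within the context. The reported background at a position is a shrinkage
estimate,

```
π̃_ij = w_ij μ̂_i + (1 − w_ij) π̂_ij,      w_ij = μ̂_i / (μ̂_i + π̂_ij)
```

where π̂_ij is the (germline-masked) mean alternate-allele fraction across
the healthy cohort. The modified weight shrinks less where the position
itself is noisy, so genuinely hot positions keep their elevated background.
The detection threshold is the upper 1 − α/2 Clopper–Pearson bound at the
shrunk rate and the cohort mean depth N_j,

```
B_ij = BetaQuantile(1 − α/2; N_j π̃_ij + 1, N_j (1 − π̃_ij))
```

An observed alternate fraction below B_ij is "polished" (reassigned to the
reference allele); at or above it, retained as a candidate mutation. A
per-position Gaussian outlier model (the conventional approach, with a
variance floor) is included as a comparator, along with a simulation and
evaluation harness (spike-in truth sets, ROC sweeps, leave-one-out panel
metrics).

The intended users are developers of liquid-biopsy variant-calling pipelines:
the polisher sits between consensus/dedup pileup generation and the variant
caller.

## Worked example

```python
import tner

panel = tner.random_panel(5000, seed=7)                       # synthetic 5 kb panel
cohort, _ = tner.synth_cohort(panel, n_subjects=14,
                              coverage=12000, seed=8)         # 14 healthy subjects
results = tner.TNERBackground(cohort, panel).fit()
print(results.summary())

# spike 25 variants at 0.075% AF into the cohort-average background
spiked, truth = tner.spike_signals(results.to_bmer(), 25, 0.00075, seed=9)
sample = tner.simulate_counts(spiked, 10000, seed=10)

polish = results.polish(sample, alpha=0.01)
raw, pol = tner.panel_metrics(sample), polish.panel_metrics()
print(f"error-free positions: {raw.error_free_fraction:.1%} raw -> "
      f"{pol.error_free_fraction:.1%} polished")
print(f"panel-wide error rate: {raw.error_rate:.2e} raw -> {pol.error_rate:.2e}")
print(f"detected: {tner.spike_in_sensitivity(results, sample, truth, 0.01)}/{len(truth)}")
```

prints

```
TNER background model
======================================================
panel positions              5000
  modeled                    5000
(position, alt) pairs       15000
subjects                       14
mean background rate    9.090e-06
mean cohort depth         12000.0

TNC priors (method of moments)
------------------------------------------------------
defined contexts               96 / 96
mu_hat  min/median/max 0.000e+00 / 3.592e-06 / 7.469e-05
nu_hat  min/median/max 4.874e+02 / 3.583e+03 / 1.000e+06

error-free positions: 93.4% raw -> 99.6% polished
panel-wide error rate: 3.13e-05 raw -> 3.34e-06
detected: 21/25
```

Polishing removes almost all background (99.6% of positions carry only
reference reads afterwards, a tenfold drop in the panel-wide error rate)
while retaining 21 of the 25 spiked 0.075%-fraction variants — the misses are
draws that landed below the ~5×10⁻⁴ detection limit at this depth.

The same workflow is available from the shell:

```
tner simulate --positions 20000 --signals 150 --af 0.00075 --seed 17 --out-dir sim/
tner build-background --panel sim/panel.tsv --cohort-dir sim/cohort --out profile.tsv
tner polish --background profile.tsv --panel sim/panel.tsv --sample sim/sample.tsv \
            --alpha 0.01 --out polished.tsv --decisions decisions.tsv
tner evaluate roc --sim-dir sim/ --out roc.tsv --plot roc.png
```

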