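# emolba

Hierarchical Bayesian modelling of pleasant/unpleasant feeling reports as
an evidence-accumulation race, for experiments that manipulate
**anticipated effort**: before each normed affective picture, a cue
announces whether the upcoming visual search will be easy (feature search)
or difficult (conjunction search), and the question is whether anticipating
effort changes how fast emotional evidence accumulates — not merely how
cautiously people respond.

The package is for cognitive and affective scientists who want the full
analysis chain as tested, reusable code: synthetic experiment generation,
preregistered-style preprocessing, linear ballistic accumulator (LBA)
likelihoods, hierarchical DE-MCMC estimation, convergence and
model-comparison machinery, and default-prior Bayes-factor inference.

## The model

Each report is a race between two LBA accumulators — one for the
*normative* response (matching the picture's valence norm: norm < 5 on the
1–9 scale makes "unpleasant" normative) and one for the *aberrant*
response. Accumulator *i* starts at `k_i ~ U(0, A)`, rises linearly at
`d_i ~ N(mean_v_i, sv)` (drawn per trial; `sv = 1` fixes the scale), and
responds at boundary `b = A + B`; RT adds a non-decision time `t0`. The
(choice, RT) likelihood is the defective density
`f_winner(t − t0) · [1 − F_loser(t − t0)]`.

Two models are estimated hierarchically over the 2 (pleasantness) × 2
(difficulty) design: a **null** model (5 subject-level parameters, no cell
effects) and a **core** model (14: `A`, `t0` shared; `B`,
`mean_v.normative`, `mean_v.aberrant` split by cell), with
truncated-Normal population distributions and the prior table
`A:(2, 0.6)`, `B:(2, 0.6)`, `t0:(0.3, 0.1)`, `mean_v.normative:(2, 0.8)`,
`mean_v.aberrant:(0.5, 0.8)`. Fits are compared by participant-summed DIC
under a Gelman-Rubin < 1.10 convergence gate, and the fitted drift rates
feed 2×2 repeated-measures Bayesian ANOVAs and JZS paired t-tests with
default priors. See `docs/methods.md` for the full account.

## Worked example: parameter recovery

The package's central claim is that the estimation machinery recovers
known generating parameters. Generate 12 subjects × 480 trials with the
reported drift-rate cell means as population truth, fit the core model at
the scaled-down sampler profile, and compare:

```python
from emolba import (GeneratorConfig, gen_dataset, prepare_subject_data,
                    sample_posterior, SamplerConfig)

cfg = GeneratorConfig(n_participants=12, blocks=8, trials_per_block=60)
trials, truth = gen_dataset(cfg, seed=3)
fit = sample_posterior(prepare_subject_data(trials), "core",
                       SamplerConfig(n_chains=24, n_burn=500,
                                     n_sample=1500, thin=3, seed=1))
pm = fit.population_means()
for name, v in truth.population_loc.items():
    print(f"{name:42s} truth {v:6.3f} recovered {pm[name]:6.3f}")
print("max rhat", fit.max_rhat())
```

Output (about 5 minutes on one core):

```
A                                          truth  2.000 recovered  1.837
t0                                         truth  0.300 recovered  0.223
B[unpleasant,easy]                         truth  2.000 recovered  1.882
B[unpleasant,difficult]                    truth  2.000 recovered  1.902
B[pleasant,easy]                           truth  2.000 recovered  1.874
B[pleasant,difficult]                      truth  2.000 recovered  1.921
mean_v.normative[unpleasant,easy]          truth  2.942 recovered  2.866
mean_v.normative[unpleasant,difficult]     truth  3.172 recovered  3.023
mean_v.normative[pleasant,easy]            truth  2.239 recovered  2.171
mean_v.normative[pleasant,difficult]       truth  2.148 recovered  2.259
mean_v.aberrant[unpleasant,easy]           truth  0.017 recovered -0.103
mean_v.aberrant[unpleasant,difficult]      truth  0.017 recovered -0.199
mean_v.aberrant[pleasant,easy]             truth  0.742 recovered  0.595
mean_v.aberrant[pleasant,difficult]        truth  0.742 recovered  0.810
max rhat 1.0753859300438076
```

Every population location is recovered within ±0.30 drift units (the
near-zero aberrant drifts sit within that band too — they are the hardest
case, since their accumulators win only a few percent of races), the
unpleasant > pleasant ordering of the normative drifts is preserved, and
the largest Gelman-Rubin statistic over all population and subject
parameters is under the 1.10 acceptability bound. On a ratio-scale drift,
effort effects read directly as percentages:
`percent_change(3.172, 2.942)` → `7.82`.

## Command-line pipeline

Every stage is also a CLI subcommand writing self-describing artifacts
(config + seed in each manifest; identical seed → identical manifests):

```bash
emolba simulate   --out run/ --seed 1
emolba preprocess --out run/
emolba fit        --out run/ --model null --model core --seed 1
emolba compare    --out run/
emolba banova     --out run/ --seed 1
emolba report     --out run/
```

`report` assembles the manipulation check (search RT/error by cue), the
four-step exclusion audit, R-hat and DIC tables, BANOVA Bayes factors and
the percent-change summary into `run/report.json`.

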