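# respiro

Nonlinear complexity analysis of breath-by-breath respiratory dynamics.

Healthy spontaneous breathing is not metronomic: both the inter-breath
interval (IBI) and the breath-by-breath lung volume (LV) fluctuate with
fractal, weakly chaotic structure.  In obstructive disease — asthma in
particular — these fluctuations become more regular, lose long-range
correlation, and the rhythm and volume series synchronize.  `respiro`
quantifies this with four nonlinear indices per subject and evaluates
their diagnostic value in separating healthy from asthmatic breathing and
asthma subtypes (controlled/uncontrolled, atopic/non-atopic):

* **DFA** — detrended fluctuation analysis scaling exponent α
  (0.5 = uncorrelated, 1.0 = 1/f fractal, 1.5 = integrated random walk);
* **SampEn(m, r)** — sample entropy, −ln A/B with A, B the counts of
  (m+1)- and m-point template matches within r·SD (Chebyshev distance,
  no self-matches); lower = more regular;
* **cross-SampEn** — the two-series analogue between IBI and LV;
  lower = stronger rate–volume synchronization;
* **LLE** — largest Lyapunov exponent (Rosenstein's method, with delay
  from average mutual information and embedding dimension from false
  nearest neighbors); positive = sensitive dependence on initial
  conditions.

Per-subject profiles feed a weighted sparse-representation classifier
(WSRC) evaluated by leave-one-out cross-validation, and single indices are
evaluated with ROC curves, Youden cut-offs and exact binomial confidence
intervals.  Because no breathing recordings are distributed, a synthetic
generator produces waveforms, breath series and whole cohorts with known
ground truth; see `docs/methods.md` for the model and its limits.

## Worked example

Simulate one healthy-like subject (60 min of breathing: mean interval
3.51 s, CV 0.13, mean volume 0.64 L, CV 0.27, 1/f fluctuation drivers) and
compute its complexity profile:

```python
import respiro as r

ibi, lv = r.gen_breath_series(r.BreathSpec(seed=42))
prof = r.complexity_profile(ibi, lv)
for name, value in prof.as_row().items():
    print(f"{name:20s} {value: .3f}")
```

```
DFA_IBI               1.008
DFA_LV                0.986
SampEn_IBI            1.635
SampEn_LV             1.525
LLE_IBI              -0.015
LLE_LV                0.097
CrossSampEn_IBI_LV    1.632
mean_IBI              3.510
CV_IBI                0.129
mean_LV               0.641
CV_LV                 0.281
```

The DFA exponents sit at ≈ 1.0, the 1/f value expected for healthy
breathing (and for the β = 1 drivers the generator used); the summary
statistics recover the specification (3.51 s, CV 0.13, 0.64 L).  The LLE
near zero says the stochastic drivers produce no low-dimensional chaos —
on a logistic-map series the same estimator returns ≈ 0.69 ≈ ln 2.

A full synthetic study — four groups (healthy, controlled atopic,
uncontrolled atopic, uncontrolled non-atopic) of ten subjects, profiling,
WSRC classification of the three binary tasks and per-index ROC reports —
runs from the command line:

```sh
respiro run --seed 1 --out results/
respiro evaluate --cohort results/cohort.csv --index DFA_IBI \
    --task asthma_vs_healthy --out roc.json
```

`simulate`, `preprocess`, `analyze` and `classify` subcommands expose the
individual stages; every artifact is stamped with the config hash and seed,
and a rerun with the same configuration is bit-identical.

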