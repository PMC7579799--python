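# difagree

Measurement invariance and cross-informant agreement for paired-informant
Likert questionnaires.

When a child rates their own health-related quality of life (HRQoL) and a
parent rates it for them, score differences mix two things: a real
difference in perception, and *differential item functioning* (DIF) — items
that children and parents read differently even at the same underlying
trait level. `difagree` implements the iterative hybrid ordinal logistic
regression / item response theory (OLR/IRT) analysis that separates the
two, with Monte-Carlo empirical decision thresholds, plus the scale-level
agreement statistics (paired t, pooled-SD effect size, agreement ICC) and
DIF-corrected scores. It is aimed at biostatisticians and patient-reported
outcome researchers working with dyadic designs such as PedsQL 4.0
child/parent reports.

## The model

Each subscale is analyzed on its own latent trait θ. A graded response
model, P(Y ≥ k | θ) = logistic(a(θ − b_k)), is calibrated on the pooled
two-group data by EM marginal maximum likelihood, and respondents receive
EAP trait scores. Conditioning on θ, three nested proportional-odds models
are fitted per item:

    Model 1: logit P(Y ≥ k) = α_k + β1·θ
    Model 2: logit P(Y ≥ k) = α_k + β1·θ + β2·group
    Model 3: logit P(Y ≥ k) = α_k + β1·θ + β2·group + β3·θ·group

Uniform DIF is the likelihood-ratio test of β2 (Models 1 vs 2), non-uniform
DIF of β3 (Models 2 vs 3), each on χ²(1). Magnitude is quantified by the
McFadden pseudo-R² change and the Crane–van Belle–Larson proportionate β1
change. Flagged items get group-specific IRT parameters and the trait is
re-estimated, iterating until the flag set stabilizes (purification).
Decision thresholds are per-item empirical quantiles from a no-DIF
parametric bootstrap conditioned on the observed calibration (default 1000
replicates, α = 0.01), instead of nominal χ² critical values. At the scale
level, uniform-DIF items that bias in opposite directions cancel at the
domain level; uncancelled ones are removed and agreement statistics
(paired t, effect size |m₁−m₂|/√((s₁²+s₂²)/2), agreement ICC) are
recomputed on the retained items. See `docs/methods.md` for assumptions and
numerical details.

Because real dyadic PRO datasets of this kind are rarely shareable, the
package includes a synthetic dyad generator (correlated latent traits,
GRM responses, configurable uniform/non-uniform DIF injection) used by the
whole test battery.

## Worked example

```python
from difagree import (HybridDIFModel, CrossInformantAgreement,
                      generate_dyads, preset_scenarios)

# 500 dyads, one 5-item subscale, item_3 thresholds shifted 0.6 for parents
data = generate_dyads(preset_scenarios(seed=42)["one_uniform"])

model = HybridDIFModel(data, "scale", groups=("child", "parent"))
result = model.fit(thresholds="montecarlo", nrep=200, alpha=0.01, seed=42)
print(result.summary())

agree = CrossInformantAgreement(data, ("child", "parent"),
                                dif_results={"scale": result}).fit()
print(agree.summary())
```

The DIF summary prints (columns abridged):

```
Hybrid OLR/IRT DIF analysis — subscale 'scale', groups 'child' (ref) vs 'parent' (focal)
iterations: 3 (fixed point)
flagged items: {'item_3': 'uniform'}

         p_nonuniform  thr_p_nonuniform  p_uniform  thr_p_uniform  delta_r2_uniform     flag
item_id
item_1         0.6409            0.0148     0.4388         0.0212            0.0002     none
item_2         0.4631            0.0035     0.5140         0.0045            0.0001     none
item_3         0.0800            0.0098     0.0000         0.0051            0.0322  uniform
item_4         0.9306            0.0182     0.2640         0.0189            0.0004     none
item_5         0.9168            0.0129     0.0633         0.0002            0.0012     none
```

item_3's uniform p-value (< 10⁻⁴) beats its Monte-Carlo threshold and its
ΔR² (0.0322) exceeds the empirical magnitude criterion, while the
non-uniform test is quiet — the injected location DIF, correctly typed.
The agreement summary then shows the raw and DIF-corrected blocks (item_3
removed: a lone uniform item has no opposite-direction partner to cancel
against):

```
scale         pair  corrected  mean_1  sd_1  mean_2  sd_2  effect_size   es_label  icc      p
scale child|parent      False   50.49 19.97   53.92 20.93         0.17 negligible 0.35 0.0011
scale child|parent       True    50.41 20.20   51.58 21.57        0.06 negligible 0.32 0.2853
```

The corrected child/parent effect size (0.06, p = 0.29) moves toward the
DIF-free generating truth (no real group difference) relative to the raw
score (0.17, p = 0.001): the apparent parent-child disagreement was mostly
the one biased item.

A config-driven run of the same pipeline (DIF tables per subscale,
agreement tables, iteration traces, one `results.json` bundle):

```
difagree run --config run.yaml --seed 7 --out-dir results/
```

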