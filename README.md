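# erpbss

Blind source separation of event-related potential (ERP) difference
waves with a sparse recurrent neural network, a group-ICA baseline, and
a source-similarity comparison battery.

## The problem

An ERP difference wave (deviant − standard, face − car, target −
frequent, ...) mixes the activity of several underlying neural sources:
each source has a fixed scalp projection and a time-varying,
single-polarity magnitude, and the electrodes record their sum.
Classical group ICA recovers exactly `n_channels − 1` maximally
independent components from common-average-referenced data — usually
far more sources than the data need, with arbitrary polarity.

`erpbss` implements an alternative: a stack of simple recurrent layers
with ReLU activations is trained, with subject-level difference waves
as labels, to map a condition-indicator step pulse to the multi-channel
waveform,

    z⁽¹⁾[t] = ReLU(x[t] W_f⁽¹⁾ + z⁽¹⁾[t−1] W_r⁽¹⁾ + b⁽¹⁾)
    z⁽ᵐ⁾[t] = ReLU(z⁽ᵐ⁻¹⁾[t] W_f⁽ᵐ⁾ + z⁽ᵐ⁾[t−1] W_r⁽ᵐ⁾ + b⁽ᵐ⁾)   m = 2, 3
    z⁽⁴⁾[t] = ReLU(z⁽³⁾[t] W_f⁽⁴⁾ + z⁽⁴⁾[t−1] W_r⁽⁴⁾)            (no bias)
    ŷ[t]   = z⁽⁴⁾[t] W_out                                        (linear)

Training is two-phase, full-batch Adam: phase 1 minimises the mean
squared reconstruction error; phase 2 adds an L1 penalty on the last
hidden layer's activity (α_L1 ‖Z⁽⁴⁾‖₁) and an L2 penalty on the output
weights (α_L2 ‖W_out‖²). The L1 term drives most units to zero: the
surviving units' activation time courses are non-negative source
waveforms, and their rows of `W_out` are the corresponding scalp maps —
the decomposition chooses its own source count instead of inheriting
the channel count.

Sources from both methods are compared with Pearson correlation and MSE
of their projections against the grand-average difference waves, the
Shannon entropy of each source's |r| profile across conditions
(0 = specific to one difference wave), pairwise k-NN mutual information
(k = 3), and the similarity score

    SS(i, j) = MI(xᵢ, xⱼ) + |r(xᵢ, xⱼ)| + |r(wᵢ, wⱼ)|

with absolute correlations because ICA components have arbitrary sign.

Everything is testable offline: a synthetic generator simulates
multi-subject difference-wave datasets from known non-negative sources
and smooth scalp maps, with amplitude/latency jitter and smooth noise,
so sparsification and source recovery can be asserted against ground
truth.

## Worked example

```python
from erpbss import (RNNConfig, SparseRNN, GroupICA, build_tensors,
                    generate_ground_truth, generate_subjects, match_sources)

gt = generate_ground_truth(n_sources=6, seed=0)          # 4 conditions, 28 ch
dws = generate_subjects(gt, n_subjects_per_condition=20, seed=1)
res = SparseRNN(build_tensors(dws),
                RNNConfig(n_hidden=32, max_iterations=2500, alpha_l1=2e-4,
                          seed=0)).fit()
print(res.summary())
m = match_sources(res.sources(), gt)
print("matched |r|:", m.correlations.round(3))
```

prints (timing aside):

```
Sparse RNN decomposition
==========================================================
layers: 4 x 32 units   instances: 80   samples: 101
alpha_l1=0.0002  alpha_l2=0.01  lr=0.001  seed=0
----------------------------------------------------------
phase1: 2500 iterations, best loss 0.227495 (start 0.872526)
phase2: 1767 iterations, best loss 0.322412 (start 0.684994)
active sources: 9 of 32
----------------------------------------------------------
condition      r        MSE
C1           0.9781   0.0089295
C2           0.9950     0.01307
C3           0.9885   0.0095254
C4           0.9888    0.013987
matched |r|: [0.985 0.992 0.996 0.999 0.989 0.991]
```

Read: of 32 available units only 9 stay active after L1 fine-tuning
(the 6 planted sources plus 3 small residual units), every condition's
reconstruction correlates r > 0.97 with its grand-average difference
wave, and optimal assignment matches all 6 ground-truth sources at
|r| > 0.98 on their projections. The same dataset run through
`GroupICA(dws).fit(seed=0)` always returns 27 components (28 channels,
common average reference).

A command-line interface mirrors the library:

```bash
erpbss simulate --seed 0 --outdir sim
erpbss fit sim/dataset.npz --seed 0 --outdir fit
erpbss ica sim/dataset.npz --seed 0 --outdir ica
erpbss compare fit/rnn_sources.npz ica/ica_sources.npz \
       --dataset sim/dataset.npz --seed 0 --outdir cmp
erpbss report fit/rnn_model.npz --tensors fit/tensors.npz \
       --dataset sim/dataset.npz --outdir figs
erpbss demo --seed 0 --outdir demo_out     # all of the above in one go
```

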