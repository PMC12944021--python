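# densehar

Dense (frame-level) human activity recognition from dual accelerometers.

Wearable-sensor studies in digital health increasingly need to know *what a
person is doing at every instant* — walking, running, standing, negotiating
stairs, sitting, lying, cycling — from raw tri-axial acceleration recorded at
the lower back and right thigh (six channels, 50 Hz, units g). Classic
pipelines assign one label per multi-second window, which blurs transitions
and breaks on variable-length free-living recordings. `densehar` instead
labels **every frame**: each model maps an n×T window to a T×C matrix of
per-frame class probabilities, for arbitrary T, with no input padding.

The package is aimed at movement-science and digital-health researchers who
want to train, cross-validate and transfer such models between cohorts —
in particular from a young cohort (nine activities) to an older cohort
(six-activity subset, slower dynamics) — entirely on CPU, with a bundled
synthetic cohort simulator so the whole pipeline runs with no data download.

## What is inside

- **Sequence labellers** (`densehar.models`) in pure NumPy with hand-written
  backward passes: 1-D CNN with `o_t = ReLU(Σᵢ wᵢ·x_{t+i−1} + b)`; GRU with
  `z_t = σ(W_z x_t + U_z h_{t−1} + b_z)`,
  `r_t = σ(W_r x_t + U_r h_{t−1} + b_r)`,
  `h̃_t = tanh(W_h x_t + U_h (r_t ∘ h_{t−1}) + b_h)`,
  `h_t = (1−z_t) ∘ h_{t−1} + z_t ∘ h̃_t` (optionally bidirectional); and the
  two hybrids ConvRec (conv → GRU) and ReConv (GRU → conv), all
  frame-count-preserving.
- **Training harness** (`densehar.training`): per-frame cross-entropy +
  Adam, random hyperparameter search over the published grids (50 draws per
  family), leave-one-participant-out cross-validation (LOPO-CV) with a hard
  leakage guard, cohort pooling.
- **Cross-cohort ensemble & metrics** (`densehar.ensemble`): per-frame
  majority vote across the LOPO fold models with a summed-probability
  tie-break; per-class / macro / support-weighted precision, recall, F1 and
  accuracy over the union label set; confusion matrices; paired t-tests on
  per-participant weighted F1.
- **Signal plumbing** (`densehar.io`): HARTH-style CSV reader/writer,
  lossless non-overlapping windowing (T = 200 frames = 4 s for training),
  anti-aliased polyphase downsampling to 25/20/15/10 Hz, sensor-site channel
  selection.
- **Synthetic cohorts** (`densehar.synthetic`): a semi-Markov activity
  process (realistic dwell times, strong class imbalance) driving a
  gravity + harmonics + noise signal model, with a young profile (22
  participants, nine activities) and an old profile (18 participants, six
  activities, slower and damped dynamics).
- **Experiments + CLI** (`densehar.experiments`, `densehar` console
  script): architecture comparison, sampling-frequency ablation,
  sensor-location ablation, window-length check, combined-cohort training.

See `docs/methods.md` for the model equations, training protocol, simulator
assumptions and known limitations.

## Worked example

Train the reduced GRU preset on a synthetic young cohort and score a
participant the model never saw:

```python
import numpy as np
from densehar import (
    compute_metrics, desk_profiles, generate_cohort, reduced_gru_preset,
    TrainingConfig, train_model,
)
from densehar.training import split_by_participant, windows_from_recordings

# a small synthetic cohort: 8 participants x ~5 min of dual-sensor data
young_profile, old_profile, activity_models = desk_profiles()
cohort = generate_cohort(young_profile, activity_models, seed=0)

train_recs, val_recs, test_recs = split_by_participant(cohort, seed=0)
tcfg = TrainingConfig(seed=0, max_epochs=10, patience=3, batch_size=32)
model, history = train_model(
    reduced_gru_preset(),
    windows_from_recordings(train_recs, tcfg.window_len),
    windows_from_recordings(val_recs, tcfg.window_len),
    tcfg,
)

held_out = test_recs[0]  # a participant the model never saw
frame_probs = model.predict(held_out.signal)
report = compute_metrics(
    frame_probs.argmax_labels, held_out.labels.labels,
    label_names=held_out.labels.label_map,
)
print(f"frames scored: {held_out.signal.n_frames}")
print(f"weighted F1  : {report.weighted['f1']:.3f}")
print(f"accuracy     : {report.accuracy:.3f}")
print(report.to_frame().to_string(index=False))
```

Output (a couple of minutes on one CPU):

```
frames scored: 15705
weighted F1  : 0.993
accuracy     : 0.994
        class  precision   recall       f1  accuracy  support
      walking   0.973451 0.979757 0.976594  0.996307     1235
     standing   0.984700 0.979903 0.982295  0.996307     1642
      sitting   0.999416 1.000000 0.999708  0.999873     3423
        lying   1.000000 0.999782 0.999891  0.999873     9183
  cycling_sit   0.807512 1.000000 0.893506  0.997389      172
cycling_stand   1.000000 0.180000 0.305085  0.997389       50
        macro   0.960847 0.856574 0.859513  0.997856    15705
     weighted   0.994077 0.993569 0.992802  0.999184    15705
```

Every frame of the held-out recording gets a label. The dominant postural and
ambulatory classes are recognised almost perfectly, while the rare
standing-cycling class (50 frames here) is mostly confused with its
postural neighbours — the weighted average is high because weights are class
support shares, the macro average is pulled down by the rare classes.
(This synthetic problem is deliberately easier than real free-living data;
see `docs/methods.md` for what the simulator does and does not emulate.)

The same pipeline from the shell:

```sh
densehar simulate --cohort young --seed 0 --out data/young
densehar lopo --scale desk --seed 0 --out results/lopo
densehar experiment --name frequency --seed 0 --out results/freq
```

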