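# eeglike

Interval temporal decision forests for EEG liking classification.

## The problem

Can the subjective experience of *liking* something — here, a painting viewed
in a gallery — be read out of the EEG, and expressed as an explicit, inspectable
rule rather than an opaque score?  `eeglike` implements a symbolic pipeline for
that question, aimed at researchers working with multichannel EEG recorded
during naturalistic viewing, where each trial is a minute-long observation
labelled with an integer liking score on a 0–50 visual-analog scale.

The pipeline:

1. **Spectral decomposition** (`eeglike.spectra`) — each trial is resampled
   from 512 Hz to 104 Hz (Nyquist 52 Hz) and converted by a short-time Fourier
   transform (50 ms windows, 20 ms steps) into 13 log₁₀ band-power series per
   electrode, the bands F₁…F₁₃ tiling (0, 52] Hz in 4 Hz steps and grouping
   into the standard δ/θ/α/β/γ wavebands.
2. **Measure catalog** (`eeglike.measures`) — 25 scalar time-series measures
   (minimum, maximum, average, plus 22 canonical features: histogram modes Z5/Z10,
   run statistics, autocorrelation timescales, spectral summaries, symbolic
   entropies, fluctuation analysis, periodicity), applicable to whole band
   series or to sub-intervals of them.
3. **Variance screening** (`eeglike.screening`) — liking scores are binned into
   like/dislike under thresholds ⟨<25, ≥25⟩, ⟨<17, ≥34⟩ or ⟨<10, ≥41⟩; the
   min-max-normalized variance of every (electrode, band, measure) feature
   ranks electrodes (*e-score*) and measures (*m-score*), label-blind.
4. **Interval temporal decision forests** (`eeglike.temporal_forest`) — the
   classifier's splits are *interval-relativized* propositions: "does there
   EXIST an interval, reachable from the current reference interval through one
   of Allen's 13 interval relations (meets, later, begins, ends, during,
   overlaps, their inverses, equals), on which measure *m* of electrode *e* in
   band F*ᵢ* satisfies *v* ≥ θ?"  Trees grow greedily by Shannon information
   gain; forests are 100-tree bagged ensembles with majority vote.
5. **Evaluation** (`eeglike.evaluation`) — Monte-Carlo leave-*p*-out
   cross-validation (*p* = 10, 10 repetitions) reporting accuracy, sensitivity
   (likes recognized), specificity (dislikes recognized) and average accuracy
   ((sens+spec)/2), plus a label-shuffle chance-level control and the
   3 binnings × 4 band sets × 3 electrode counts = 36-configuration grid.
6. **Rule extraction** (`eeglike.rules`) — every tree converts to explicit
   interval-temporal-logic rules such as

   ```
   ⟨L⟩(Z10(E1 F10)≥0.5) ∧ [L](Z10(E2 F11)<0.81) ⇒ like
   ```

   ("some later interval has Z10 of E1's F₁₀ band ≥ 0.5, and no later interval
   has Z10 of E2's F₁₁ band ≥ 0.81"), with a parser that round-trips the
   rendered text and a rule evaluator provably equivalent to tree prediction.

Because gallery EEG of this kind is typically proprietary, the package ships a
first-class synthetic generator (`eeglike.syndata`): band-limited background
noise on every channel, a two-component truncated-normal mixture of liking
scores (non-normal, symmetric about 25), and a γ-range (36–44 Hz) oscillatory
burst planted on target channels during a random sub-window of "like" trials.
Recordings round-trip through EDF+ (read back via MNE) or plain delimited text.

## Worked example

```python
import dataclasses
from eeglike import syndata, workbench
from eeglike.evaluation import CVConfig

cfg = workbench.RunConfig(
    out_dir="runs/demo",
    sim=syndata.SimConfig(n_subjects=8, n_paintings=12, n_channels=6,
                          trial_seconds=15, blank_seconds=5, seed=11),
    binning="D34", bands="gamma", n_electrodes=5, n_measures=1,
    cv=CVConfig(p=10, repetitions=5), master_seed=5,
)
art = workbench.run_pipeline(cfg)
print(art["screening"].electrode_ranking)
print(art["cv_result"].summary())
```

prints

```
['E1', 'E2', 'E3', 'E4', 'E6', 'E5']
acc 100±0  avg-acc 100±0  sens 100±0  spec 100±0
```

— the screen ranks the two burst-carrying channels (E1, E2) first, and the
forest classifies held-out trials perfectly on this strongly separable
synthetic study.  `runs/demo/rules.txt` then contains the extracted rules
(thresholds print at full precision so they parse back exactly):

```
⟨A⟩(C(E1 F9)≥32.20000000000027) ⇒ like
[A](C(E1 F9)<32.20000000000027) ⇒ dislike
```

("some interval met by the reference carries a long run of above-mean γ-band
power on E1").  The same stages are scriptable from the shell:

```bash
eeglike simulate --config cfg.yaml --out data/ --seed 1 --format edf
eeglike run-all --config cfg.yaml --out runs/demo --seed 5
```

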