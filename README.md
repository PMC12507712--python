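# mi-erd

Offline analysis of motor-imagery (MI) EEG experiments that test whether
virtual-reality embodiment priming changes sensorimotor desynchronization.
The package is aimed at BCI researchers who need a reproducible, scriptable
version of the classic EEGLAB-style workflow: preprocessing of 32-channel
10-20 recordings, alpha-band event-related desynchronization (ERD)
quantification, hemispheric lateralization, embodiment-questionnaire scoring,
embodiment-to-ERD regression models, and CSP + shrinkage-LDA classification —
plus a synthetic-data generator that makes every stage testable by parameter
recovery without access to raw recordings.

## The quantities at the core

For each trial the event-related spectral perturbation is the dB change of
alpha-band (8–12 Hz) power against the symmetric pre-cue baseline,

    ERSP(f, t) = 10 log10( P(f, t) / P_baseline(f) ),

converted to a percentage power change

    ERD(%) = (10^(ERSP/10) − 1) · 100,

so negative ERD is desynchronization. Per-trial ERD is averaged over 1–5 s
post-cue (the first second is excluded as reaction time) at the sensorimotor
electrodes C3 and C4. The lateralization index summarizes contralateral
dominance across left- and right-hand trials:

    LI = ( (ERD_C3(left) − ERD_C4(left)) + (ERD_C4(right) − ERD_C3(right)) ) / 2,

positive when the hemisphere contralateral to the imagined hand
desynchronizes more strongly. Embodiment is scored from 7-point Likert items
into seven composites (appearance, response, ownership, multi-sensory,
agency, their mean = embodiment, physical presence), conditions are compared
with Mann–Whitney U tests, ERD presence is tested per subject with one-sample
Wilcoxon signed-rank tests against 0 %, and embodiment–ERD/LI relations are
fitted with OLS and random-intercept mixed models (ML, so AIC/BIC are
comparable). Left/right discriminability uses six common spatial patterns,
log variance-fraction features, Ledoit–Wolf shrinkage LDA, and ten-fold Monte
Carlo cross-validation with stratified 80/20 splits.

## Worked example

```python
from mi_erd import (SimulationConfig, generate_recording, PreprocessParams,
                    preprocess_continuous, epoch_and_reject, compute_ersp,
                    ersp_to_erd, window_mean_erd)
from mi_erd.tfr_erd import summarize_subject

cfg = SimulationConfig(seed=2)          # 15 trials/class, 250 Hz, 32 channels,
rec, truth = generate_recording(cfg)    # injected ERD: contra -40 %, ipsi -20 %

clean, report = preprocess_continuous(rec, PreprocessParams())
epochs = epoch_and_reject(clean)
erd = ersp_to_erd(compute_ersp(epochs.select(channels=["C3", "C4"])))
print(summarize_subject(window_mean_erd(erd, channels=["C3", "C4"])))
```

prints (seed 2):

```
{'erd_c3_left': -22.89541223064235, 'erd_c3_right': -37.9201372517772,
 'erd_c4_left': -37.656247304895615, 'erd_c4_right': -20.708839467657878,
 'li_pct': 15.986066429186293}
```

i.e. the chain recovers the injected contralateral (−40 %) and ipsilateral
(−20 %) suppression and the implied lateralization index of 20 % to within a
few percentage points, limited by in-band background-noise fluctuation over
15 trials per class.

A whole synthetic cohort runs from the shell:

```bash
mi-erd run --out report/ --seed 1 --n-subjects 13
mi-erd synth --out data/ --seed 1 --n-subjects 3     # BrainVision triples
mi-erd bci-eval --recording data/S01.vhdr --seed 1   # CSP+LDA accuracy
```

`mi-erd run` writes the per-subject table, the ERD/LI condition comparison,
the questionnaire comparison, the LR/LME model table and scalp-map values as
CSV, plus a JSON report carrying the seed and config hash.

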