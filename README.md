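# hypkernel

Hypothesis kernel analysis for action-unit models of facial-expression
categorization: turn qualitative hypotheses like *"happy is expressed
with AU6 + AU12"* into predictive classifiers, score them against
forced-choice behavior, bound what any such model could achieve, explain
performance causally by AU ablation, and automatically build optimized,
culture-accented models.

It is written for researchers in affective and social cognition who work
with Facial Action Coding System (FACS) descriptions of expressions and
trial-level categorization data, and for methodologists interested in
prediction–explanation–exploration workflows for categorical behavior.

## The method in brief

A hypothesis is embedded as one or more *configuration* vectors **m** in
a canonical 33-dimensional AU space (compound AUs expanded, bilateral AUs
split into left/right); a stimulus is its vector **s** of peak AU
amplitudes in [0, 1]. For each category the model scores

&nbsp;&nbsp;score(s, category) = max over configurations m of cos(s, m),

probabilities follow by softmax over the covered categories, and
performance is the one-vs-rest AUROC of each category's prediction column
against each participant's actual choices (chance 0.5, maximum 1,
Mann–Whitney tie handling). A categorical **noise ceiling** — the AUROC
of the empirical conditional label distribution over repeats of the same
stimulus — bounds what any stimulus-based model can reach. **Ablation**
removes single AUs from a model and measures ΔAUROC; AUs whose removal
hurts are performance-critical, AUs whose removal helps are
performance-detrimental. **Exploration** adds the critical and removes
the detrimental AUs per culture and evaluates the optimized models on
held-out participants, faces and stimuli. A **data-driven** model can
also be estimated from behavior via per-participant point-biserial
correlations (significant at uncorrected α = 0.05), aggregated across
participants by proportion weighting, and evaluated
leave-one-participant-out.

Seven published basic-emotion models (Darwin 1872; Friesen & Ekman 1978;
Matsumoto et al. 2008; Cordaro et al. 2018 reference and ICP; Keltner et
al. 2019; Jack et al. 2014) ship as a registry, with a parser for the
configuration notation (`+`, optional AUs after commas, `(25 ∨ 26)`
alternations, multiple configurations per emotion). A bundled simulator
generates the whole experiment — random-AU stimuli, softmax responders
with lapses, an "other" option, and planted culture accents — so every
stage runs end to end without any external data.

## Worked example

```bash
hypkernel simulate --n-participants 10 --n-trials 300 --n-shared 60 --seed 7 --out trials.csv
hypkernel predict --trials trials.csv --out auroc.csv
hypkernel noise-ceiling --trials trials.csv --n-boot 200 --min-observations 2 --seed 7 --out ceiling.json
```

The first command writes 6,000 trials (two cultures × 10 participants ×
300 trials, including the "other" responses that `predict` then
excludes). Averaging `auroc.csv` per model gives:

```
cordaro_2018_icp      0.668
cordaro_2018_ref      0.668
darwin_1872           0.754
friesen_ekman_1978    0.690
jack_2014             0.655
keltner_2019          0.709
matsumoto_2008        0.714
```

Every published model predicts the simulated behavior well above chance
(0.5), and none reaches the noise ceiling for the repeated-stimulus
block reported in `ceiling.json`:

```
anger 0.901  disgust 0.895  fear 0.898  happy 0.920  sadness 0.883  surprise 0.878
```

(bootstrap SDs ≈ 0.008). The gap between a model and the ceiling is
explainable-but-unexplained variance; 1 − ceiling is irreducible
between-participant disagreement. Splitting `auroc.csv` by culture shows
the planted bias (WE 0.732 vs EA 0.657): the simulated WE responders use
the published configurations verbatim while EA responders carry accent
edits. Running `hypkernel explore --trials trials.csv --seed 1 --out
explore/` derives those accents from ablation maps on the train split and
evaluates culture-accented models on the held-out split, where the bias
disappears.

The same operations are available as a library (`hypkernel.kernel`,
`hypkernel.noise_ceiling`, `hypkernel.ablation`, `hypkernel.data_driven`,
`hypkernel.simulate`); see `docs/methods.md` for the model's assumptions
and numerical choices.

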