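# wmlpatterns

Spatial patterns of cerebral white-matter lesions (WML) and the risk of
progression to mild cognitive impairment (MCI) or dementia.

In elderly cohorts, WML volume on T2-weighted MRI predicts cognitive decline
only weakly; *where* the lesions sit may matter as much as how many there
are.  `wmlpatterns` implements a bottom-up discovery pipeline for this
question, aimed at biostatisticians and neuro-epidemiologists working with
longitudinal cohort data:

1. **Descriptors.** From lobar lesion volumes (frontal, parietal, temporal,
   occipital, in ml) it computes the total volume
   `V = V_f + V_p + V_t + V_o` and the four relative regional volumes
   `WMLr_r = 100 · V_r / V` (%), separating lesion *location* from *load*.
2. **Pattern discovery.** A binary CART is grown over the five descriptors
   against the outcome "incident MCI/dementia during follow-up": at every
   node, all descriptors are tested with **all** candidate thresholds (the
   midpoints between successive distinct observed values) and the pair
   minimizing the weighted Gini impurity
   `(n_L/n)·G(L) + (n_R/n)·G(R)`, `G = 1 − Σ p_i²`, is kept; growth stops
   when a leaf would hold fewer than 6 subjects.  Because a single tree on a
   few hundred subjects is unstable, the retained model is a **consensus**
   over 10-fold cross-validation: at the root, and again inside the root's
   `≥` branch, the descriptor used by a strict majority of the 10 fold trees
   is kept with its threshold set to the modal value.  The depth-2 consensus
   defines three lesion patterns — pattern 1 (low total load), pattern 2
   (high load, spared temporal region) and pattern 3 (high load with
   temporal WMLr at or above threshold, the at-risk group).
3. **Hazard modelling.** Pattern membership enters delayed-entry Cox
   proportional-hazards models on the **age** timescale (a subject is at
   risk only between baseline age and exit age; Efron ties), through a
   ladder of adjustment sets from demographics up to full brain volumetrics.
   Onset of a visit-detected event is dated halfway between the last
   cognitively normal visit and the diagnosing visit.
4. **Synthetic cohorts.** Because the motivating study's data are not
   public, a calibrated generator produces cohorts with the same statistical
   skeleton — zero-inflated log-normal lobar volumes with published means
   and SDs, a planted three-pattern geography (total threshold 1.587 ml,
   temporal WMLr threshold 0.65%), an age-increasing event hazard multiplied
   by 2.28 for true pattern-3 subjects, scheduled visits at 0/2/4/7 years,
   and death/loss-to-follow-up censoring — so the whole pipeline is testable
   end to end, and the estimators can be validated by parameter recovery.

## Worked example

```python
from wmlpatterns import GeneratorConfig, run_pipeline

report = run_pipeline(generator_config=GeneratorConfig(), outdir="out", seed=1)
print(open("out/report.txt").read())
```

prints (abridged):

```
Consensus tree
--------------
root:   total_wml >= 1.578  (votes {'total_wml': 10})
second: temporal_wmlr >= 0.213  (votes {'temporal_wmlr': 9, 'parietal_wmlr': 1})
pattern counts: 1: 308, 2: 25, 3: 93

Follow-up
---------
person-years: 2165.5
incidence (per 1000 py): overall 46.2, MCI 42.0, dementia 4.2

Hazard ratios
-------------
model 5 (n=394, events=99): pattern 2 vs 1: 0.60 (0.19-1.94); pattern 3 vs 1: 2.91 (1.88-4.48)

Truth vs recovered
------------------
root: total_wml at 1.578 (true total threshold 1.587 ml)
second: temporal_wmlr at 0.213 (true temporal WMLr threshold 0.65%)
pattern agreement: 94.8%
```

Reading this: on one synthetic cohort of 426 subjects the 10-fold consensus
unanimously picks total WML volume at the root, recovering the planted
1.587 ml threshold to within one observation spacing (1.578), and picks
temporal WMLr as the second descriptor in 9 of 10 folds (its threshold is
the hardest quantity to localize — see `docs/methods.md`).  The fully
adjusted Cox model estimates a pattern-3 vs pattern-1 hazard ratio of 2.91
(95% CI 1.88–4.48) against a planted 2.28, with the pattern-2 group showing
no excess risk — the qualitative signature the pipeline is designed to
detect.  Dementia incidence (4.2/1000 person-years) and MCI incidence
(42/1000) land at realistic elderly-cohort magnitudes.

The same stages are available as a CLI:

```bash
wmlpatterns simulate --seed 1 --out cohort.csv --truth truth.csv
wmlpatterns features --cohort cohort.csv --out features.csv
wmlpatterns fit-tree --cohort cohort.csv --seed 1 --out consensus.json
wmlpatterns assign --consensus consensus.json --features features.csv --out patterns.csv
wmlpatterns report --config cfg.json --seed 1 --outdir out
wmlpatterns recovery-study --replicates 100 --seed 1 --what thresholds --out rec.csv
```

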