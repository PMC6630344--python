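# cvstree

Genetic-algorithm feature selection for binary regression trees that
predict the **CVS-Q** score — the 16-item Computer Vision Syndrome
questionnaire used in occupational eye-health studies of visual display
terminal (VDT) workers.

## What it does

Hospital staff and other screen workers report ocular symptoms on the
CVS-Q: each of 16 symptoms is scored by recoding frequency × intensity
({0,1,2,4} → {0,1,1,2}), totals run 0–32, and a score **≥ 6** classifies
the worker as symptomatic (suffering CVS).  Given a cohort table of a
few hundred mostly-binary predictors (departments, shifts, ocular
history, lens wear, seniority in years, daily screen hours), the package
searches for the variable subsets that best predict the score:

1. draw a random 80/20 train/validation split;
2. evolve a population of bit-mask chromosomes with a genetic algorithm
   (single-point crossover, per-bit mutation, elitism, truncation
   selection), where a mask's fitness is the validation RMSE of the
   least-squares regression tree `T(x) = Σ_m μ_m B_m(x)` fitted on the
   masked training columns;
3. stop when the best RMSE has not improved by more than 0.01% within
   the stall window;
4. repeat over many independent resamples and report, per variable, the
   fraction of replicas whose winning mask includes it (inclusion-
   frequency importance), the per-score absolute-error profile, and a
   plain all-variable tree baseline for comparison.

Because the original hospital data are confidential, the package ships
a synthetic-cohort generator with the published marginal structure
(343 subjects, 255 predictors, ~57% symptomatic) and a planted
tree-structured signal with known ground truth, plus the study's
published count tables for exact descriptive checks (e.g. response rate
80.69% = 539/668, prevalence 56.9% = 195/343, contact-lens wearers
75.5% vs 53.4%, chi-square p = 0.003).

## Worked example

```bash
# 1. simulate a small cohort with a planted 5-variable signal
cvstree simulate --subjects 400 --binary 55 --continuous 5 --seed 1 --out demo

# 2. run 20 replicas of the GA + tree protocol
cvstree select --input demo/cohort.csv --meta demo/cohort.meta.yaml \
    --replicas 20 --seed 1 --pop-size 16 --pm 0.02 --elitism 0.1 \
    --stall 30 --max-generations 200 --min-node-size 10 --max-depth 10 \
    --out demo/run
```

which prints

```
20 replicas done; mean validation RMSE 2.359295; top variable occupational_seniority_years (inclusion 100.0%)
```

and writes `importance.csv`, whose head is

```
variable,count,fraction
occupational_seniority_years,20,1.0
vdt_hours_work,20,1.0
contact_lens_wearer,18,0.9
rotating_shifts_with_nights,15,0.75
ind_016,13,0.65
ind_041,13,0.65
```

Four of the five planted variables (listed in
`demo/ground_truth.yaml`) head the inclusion ranking at this small
20-replica demo scale; the weakest planted effect (conjunctivitis
history, a +2 score shift) sits at 0.40 here and needs more replicas to
separate from the noise variables hovering near one half.  The mean
held-out RMSE of ~2.36 score points compares against a generator noise
standard deviation of 2.  `replicas.csv`,
`error_profile.csv`, `fitness_traces.csv` and a config echo land next to
it.  The descriptive layer is available as
`cvstree describe --fixture --out report.csv` (stratified prevalence
with chi-square tests, recomputed from the published counts) and
`cvstree exclusions` (eligibility-rule ledger).

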