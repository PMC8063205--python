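# radkinetics

Longitudinal radiomics kinetics of irradiated mandibular bone: does the
*temporal trajectory* of CT texture features predict osteoradionecrosis
(ORN) better than a single pre-treatment snapshot or a simple before/after
change?

Osteoradionecrosis is a late, debilitating complication of head-and-neck
radiotherapy. The analysis implemented here follows mandibular subvolumes
(VOIs) — an ORN lesion region and a same-dose Control region per patient —
across CT scans at months 0, 2 and 6, and compares five classifier
representations of the resulting feature time series:

* **baseline** — month-0 radiomic features;
* **delta2 / delta6** — relative feature change from month 0 to month 2 / 6;
* **trajectory** — multivariate functional principal component (MFPCA)
  scores of the spline-completed monthly feature curves;
* **ensemble** — average of the baseline and trajectory predictions.

The core statistical object is the MFPCA trajectory encoding. Each VOI's
feature series x_ij(t) (VOI i, feature j) is completed to a dense monthly
curve by a natural cubic spline, expanded per feature as

    x_ij(t) ≈ μ_j(t) + Σ_a ξ_ija φ_ja(t)

by quadrature-weighted univariate FPCA, and the stacked score vectors
Ξ_i = (ξ_ija)_{j,a} are eigendecomposed, (1/(n−1)) ΞᵀΞ c_m = ν_m c_m,
giving per-VOI multivariate scores ρ_im = Ξ_i·c_m that encode the *shape*
of the joint trajectory, not just its endpoints. Those scores feed a
patient-grouped Monte-Carlo cross-validated random forest, and predictions
are scored by ROC/AUC with DeLong or bootstrap confidence intervals and a
Youden-optimal operating threshold.

Because the motivating clinical cohort is private, the package ships a
first-class synthetic cohort generator with controllable placement of the
discriminative signal: at baseline, in the net change, or purely in the
trajectory shape (a month-2 detour invisible to both a baseline and a
6-month delta model). That last scenario is the argument for trajectory
modelling, made testable.

## Worked example

```bash
python analysis/01_simulate_cohorts.py   # cohorts for every signal scenario
python analysis/05_compare_models.py     # the five-model benchmark
```

The benchmark (10 shape-signal cohorts of 100 VOIs/arm, effect size 1.5,
noise 0.2; 3 no-signal cohorts) prints:

```
cohort representation  mean   std
  none       baseline 0.464 0.055
  none         delta2 0.494 0.015
  none         delta6 0.459 0.053
  none       ensemble 0.492 0.042
  none     trajectory 0.531 0.042
 shape       baseline 0.487 0.042
 shape         delta2 1.000 0.000
 shape         delta6 0.473 0.043
 shape       ensemble 0.986 0.005
 shape     trajectory 0.994 0.003

trajectory - baseline = +0.507; trajectory - delta6 = +0.521 (shape cohorts)
```

Reading: when the signal lives only in the trajectory's shape, the
baseline and 6-month-delta models sit at chance (AUC ≈ 0.5) while the
MFPCA trajectory model is near-perfect; the 2-month delta also sees this
particular detour because it *is* a 0→2 change. On no-signal cohorts every
model stays near chance, as it should. A full single-cohort pipeline run
(43 VOIs, the study-shaped design) with ROC curves, Youden cutoffs and
confusion matrices is `analysis/06_evaluate_and_report.py`, or from the
shell:

```bash
radkinetics simulate --seed 2 --signal-mode shape --out cohort.csv
radkinetics run --seed 7 --out results/run
```

Every run writes a manifest (effective configuration, per-stage seeds,
SHA-256 of each output), and two runs with one seed are byte-identical.

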