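# hiwinter

Two-phase epigenome-wide analysis of **high-order gene–smoking
interactions** on overall survival in early-stage non-small cell lung
cancer (NSCLC), built as a tested, reusable pipeline. It is written for
biostatisticians and epigenomics analysts who want to run — or audit —
this class of survival interaction scan: probe/sample quality control
for 450K-style beta-value matrices, a fast stratified Cox engine with
factorial interaction expansion, a hill-climbing discovery/validation
scan with FDR control, an integrated risk score with subgroup survival
analyses, time-dependent ROC/AUC model comparison, and a
methylation–expression cis-regulation follow-up. A synthetic multi-center
cohort generator with plantable interaction effects makes the whole
pipeline testable end to end without patient-level data.

## The model

For patient *i* in histology stratum *s* (LUAD/LUSC), a stratified Cox
proportional-hazards model

    h_i(t) = h_0s(t) · exp( Σ_j α_j·covariate_ij + Σ_S β_S·Π_{v∈S} x_iv )

where the covariates are age, sex, smoking status, clinical stage and
study center, and the factorial sum runs over all products of the k
interacting variables: pack-years of smoking and k−1 CpG probes
(methylation on the 0–100 percent scale, so hazard ratios are per 1
percentage point). The scan escalates greedily from a validated
(k−1)-way interaction: every remaining probe is slotted into the order-k
model and the Wald test of the single highest-order coefficient is
recorded. A probe is confirmed when it reaches **FDR-q ≤ 0.05 in the
discovery cohort**, **P ≤ 0.05 in an independent validation cohort**,
and the effect directions agree. The integrated risk score (TRIUNE) is
the fitted model's linear predictor — covariates, main effects and all
interaction products with their fitted weights.

## Worked example

Simulate a discovery and a validation cohort (600 patients each, 40
probes) with a four-way interaction planted at log-HR −3e-5 per
(pack-year × %³) on three probes, then scan the fourth slot given the
two known partners:

```python
from hiwinter import discovery_config, simulate_bundle, scan_order_k, two_phase_decide

coef = {"E:G1:G2:X": -3e-5}
cd = discovery_config(seed=21, n_probes=40, n_per_center=300, centers=("A", "B"),
                      planted_coefficients=coef)
cv = discovery_config(seed=22, n_probes=40, n_per_center=300, centers=("C", "D"),
                      planted_coefficients=coef)
bd, bv = simulate_bundle(cd), simulate_bundle(cv)

scan = scan_order_k(bd.cohort, bd.beta, "pack_years", ("cg05293407", "cg00060500"))
print(scan[["hr", "ci_low", "ci_high", "p", "q"]].head(3))
```

```
                hr  ci_low  ci_high        p        q
probe
cg16658473 0.99996 0.99995  0.99997 2.68e-18 1.02e-16
cg09000036 0.99999 0.99998  0.99999 0.000429  0.00814
cg09000015 1.00001 1.00000  1.00002  0.00507   0.0642
```

The planted probe tops the scan with a per-1% interaction HR of 0.99996
(four-way HRs are necessarily close to 1 because the coefficient applies
to a product of four variables). The two-phase rule then confirms it and
refits the pooled cohort:

```python
dec = two_phase_decide(scan, bv.cohort, bv.beta, cohort_disc=bd.cohort, beta_disc=bd.beta)
```

```
winner cg16658473: HR_disc 0.99996 q=1.02e-16 | HR_valid 0.99996 p=7.69e-20 | passed=True
combined: HR 0.99997 (95% CI 0.99996-0.99997), p=4.13e-38
```

Downstream, quartiles of the integrated score stratify survival
monotonically (marginal hazard ratios vs the lowest-risk quartile), and
the nested model comparison shows the interaction terms adding
discrimination on top of the clinical covariates:

```
group    n  events   hr  ci_low  ci_high        p
2      150      70 1.42   0.997     2.02   0.0522
3      150      83 1.97     1.4     2.77 0.000109
4      150     102 3.86    2.76     5.41 3.01e-15

AUC           3.0    5.0        C-index
covariates  0.574  0.641        0.569
three_way   0.594  0.670        0.584
four_way    0.665  0.736        0.656

cov->4way @3y: dAUC 0.091 (+15.79%), p=0.0002 [ipcw_wald]
```

A command-line interface mirrors the library
(`hiwinter simulate / qc / scan / triune / evaluate / cis / run`); `hiwinter
run --config run.yaml` executes the full two-phase pipeline from files
and writes per-stage tables plus JSON manifests.

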