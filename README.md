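# smmsubtypes

Genetic subtyping of smoldering multiple myeloma (SMM) from binary
driver-alteration matrices.

SMM is an asymptomatic plasma-cell condition that precedes multiple myeloma
(MM), with an average progression risk of ~10% per year but wide
patient-to-patient variation. Clinical risk models such as the 20-2-20 stage
(M-protein >2 g/dL, involved/uninvolved free-light-chain ratio >20,
bone-marrow plasma cells >20%) capture tumor burden but not the tumor's
molecular makeup. This package implements a genetics-first pipeline:

1. **Alteration matrix** — a validated binary patients × features matrix of
   driver SNVs, arm/focal copy-number alterations, IgH/MYC translocations,
   and summative ploidy flags (hyperdiploid: >48 chromosomes; hypodiploid:
   <45).
2. **Consensus binary matrix factorization (BMF)** — X ≈ W·H with W
   (patients × K) and H (K × features) binary, fit by a penalty method
   (multiplicative updates on ‖X − WH‖²_F + λ‖W∘W − W‖² + λ‖H∘H − H‖² with
   an increasing λ schedule) plus a greedy bit-flip polish. Repeated seeded
   restarts yield a patient × patient co-assignment (consensus) matrix that
   is cut by Ward/Euclidean hierarchical clustering into K subtypes; K is
   chosen from silhouette (Dice dissimilarity), residual, variance
   explained, and generalized Kullback–Leibler diagnostics.
3. **Cluster enrichment** — per (cluster, feature) one-sided Fisher exact
   tests with Benjamini–Hochberg control (enriched: q < 0.1), ranking each
   subtype's landmark alterations.
4. **Subtype classifier** — a random forest on features shared between
   cohorts and carried by ≥3 patients, with stratified 5-fold CV and a
   randomized hyperparameter search, for transferring subtypes to external
   cohorts.
5. **Clinical outcomes** — 20-2-20 staging, evolving-biomarker detection
   (eMP: ≥25% M-protein rise within 12 months with ≥0.5 g/dL absolute
   minimum; eHb: ≥0.5 g/dL hemoglobin drop within 12 months), Kaplan–Meier
   curves with Greenwood intervals, log-rank tests, Cox proportional
   hazards (Efron ties), Harrell's C-index, and nested-model comparison.
6. **Synthetic cohorts** — a generator that plants six subtypes (HL1–HL4
   "hyperdiploid-like", TL1–TL2 "translocation-like") in a sparse binary
   matrix with a summative hyperdiploidy feature, risk-group-specific
   exponential time to progression (medians 2.6 / 5.2 / 11 years for
   high / intermediate / low risk), calibrated censoring, and
   evolving-biomarker series, so the whole pipeline is testable without
   restricted patient-level data.

## Worked example

```sh
smmsubtypes --seed 7 --outdir run run-all \
    --stages simulate,cluster,enrich,survival,report
```

simulates a 214-patient cohort, subtypes it at K = 6 with 100 consensus BMF
runs, ranks enriched features, and fits the survival layer. The printed
summary ends with:

```
## Top enriched features per cluster

- cluster 0: del1p (q=2.8e-24), ATM (q=1.1e-20), t(14;20) (q=1.6e-18), del16q (q=7.1e-18), TP53 (q=5.4e-17)
- cluster 1: MAX (q=3.5e-21), gain9 (q=2.2e-18), NRAS (q=7.6e-17), gain5 (q=1.2e-15), TRAF3 (q=9.7e-12)
...

## Risk-group survival

- intermediate: median TTP 6.4 years
- high: median TTP 2.9 years
- low: median TTP 15.1 years
- clinical vs clinical+genetic: C 0.561 -> 0.651, LR chi2 32.0 (p=1.1e-07)
```

Each cluster is read off by its landmark alterations: cluster 0 above is the
HL2 analog (16q/1p deletions, t(14;20), TP53/ATM), cluster 1 the HL1 analog
(NRAS/TRAF3/MAX with trisomy-like gains). The survival block shows the
planted risk gradient (high-risk subtypes progress fastest) and that adding
the genetic risk group to the 20-2-20 clinical stage raises the concordance
index of the progression model — the package's central clinical claim. At
n = 87–214 the medians carry visible sampling noise; the calibration
quantities below pin them down at larger n.

The same analyses are available as a library; see the module docstrings
(`smmsubtypes.bmf`, `smmsubtypes.consensus`, `smmsubtypes.outcomes`, ...)
and `docs/methods.md`.

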