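# foxscreen

A triage toolkit for high-throughput flow-cytometry phenotypic screens that
read out FoxP3 expression in CD4+ T cells. It covers the full desk-side
pipeline:

- **`foxscreen.synth`** — synthetic 384-well plate simulator with ground-truth
  labels: lymphocyte/debris/doublet scatter mixtures, CD4/FoxP3 staining,
  injected compound effects (FoxP3 up/down modulation, toxicity-driven scatter
  shifts, additive autofluorescence) and continuous-acquisition streams with
  per-well sip windows, shakes and rinse blocks.
- **`foxscreen.flow`** — minimal FCS 3.0/3.1 list-mode I/O, plate-layout CSVs,
  spillover compensation, event-rate-based segmentation of a continuous
  stream into wells, and stain-control validation of the well assignment
  (including off-by-k shift diagnosis).
- **`foxscreen.gating`** — hierarchical gating (lymphocytes → singlets →
  CD4+ → FoxP3+/−) with polygon, ratio-band, fixed and KDE-based automatic
  thresholds; per-well summary tables (FoxP3% of CD4, FSC-H MFI, V450 MFIs).
- **`foxscreen.plate_qc`** — Z′-factor = 1 − 3(σp+σn)/|μp−μn| from DMSO
  positives and CD4-only negatives; plates pass at Z′ ≥ 0.5.
- **`foxscreen.triage`** — ±50% hit calling vs. plate DMSO mean, FSC-H
  Δratio toxicity outliers (±3SD, screen or plate scope), V450 stain-ratio
  autofluorescence grading (high / low-moderate), all-channels-open
  interference profiling, ROC evaluation against viability truth, and the
  compiled per-compound triage report.
- **`foxscreen.dose_response`** — DMSO normalization and four-parameter
  logistic log(inhibitor)-vs-response IC50 fitting (variable-slope or fixed
  top=100/bottom=0), with multi-start initialization and optional
  profile-likelihood CIs.

## CLI

```sh
foxscreen simulate  --out-dir sim/ --n-events 1000 --seed 1 --stream
foxscreen segment   --stream sim/stream.fcs --layout sim/layout.csv --out-dir wells/
foxscreen qc        --summaries wells.csv --out qc.csv
foxscreen triage    --summaries wells.csv --scope screen --out report.csv
foxscreen fit-ic50  --in dr.csv --model variable_slope --out fits.csv
```

`wells.csv` is a per-well summary table as produced by
`foxscreen.gating.summarize_plate` (columns: `plate_id, well, role,
compound_id, foxp3_pct_cd4, fsch_mfi, v450_mfi_pos, v450_mfi_neg, ...`).

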