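# transddi

Transporter-mediated drug–drug-interaction (DDI) analysis, from raw
transporter-assay plate data to mechanistic static predictions of
victim-drug exposure change.

Metformin is cleared almost entirely by active renal secretion: basolateral
uptake into proximal tubule cells by OCT2, then apical efflux into urine by
MATE1. Co-medications that inhibit these transporters (cimetidine,
trimethoprim, pyrimethamine) raise metformin plasma exposure in the clinic.
`transddi` implements the complete in-vitro-to-in-vivo workflow used to
attribute such interactions to a specific transporter:

1. **Uptake assay processing** — scintillation counts (dpm) → pmol via
   specific activity, protein normalization (pmol/mg), vector-control
   correction, uptake-ratio QC, and linear-incubation-window detection
   (`transddi.uptake`).
2. **Kinetics and inhibition fitting** — Michaelis–Menten
   v = V·S/(Kₘ+S) for Kₘ/Vₘₐₓ; four- or five-parameter logistic fits of
   percent-control inhibition for IC₅₀, with Ki = IC₅₀/(1+S/Kₘ)
   (Cheng–Prusoff, competitive inhibition) (`transddi.kinetics`).
3. **Caco-2 permeability** — bidirectional apparent permeability
   Pₐₚₚ = (dQ/dt)/(A·C₀), mass balance, lucifer-yellow monolayer-integrity
   gating, efflux ratio, and an equivalence test for inhibitor effects on
   absorptive permeability (`transddi.permeability`).
4. **Mechanistic static DDI engine** — fraction excreted from mass balance
   (f_e = renal fraction × active fraction), regulatory ratio screens
   (unbound Cmax/Ki ≥ 0.1 systemic; [I₂]/Ki ≥ 10 intestinal, with
   [I₂] = dose/250 mL), and the adapted Rowland–Matin prediction

   **fold-ΔAUC = 1 / ( f_e/(1 + [I]/Kᵢ) + (1 − f_e) )**

   scored against observed clinical AUC changes (`transddi.static_model`).
5. **Synthetic plates** — seeded generators for every assay design with
   known ground truth, so the whole pipeline is testable without deposited
   raw data (`transddi.synthetic`).

It is written for DMPK / drug-transporter scientists who want these
calculations reproducible and unit-tested rather than living in a
spreadsheet.

## Worked example

The bundled clinical input set (`transddi.load_metformin_ddi()`) carries the
perpetrator pharmacokinetics, determined Ki values, and observed AUC changes
for the metformin case study:

```python
from transddi import load_metformin_ddi, predict_all, fold_auc

inp = load_metformin_ddi()
print(round(fold_auc(0.66, 7.68, 1.22), 2))   # cimetidine vs MATE1 -> 2.32

pset = predict_all(inp.perpetrators, inp.ki_table, inp.dispositions)
print(pset.to_frame().head(6).to_string(index=False))
```

```
2.32
perpetrator transporter   fe route  cmax_total  i_unbound     ki  ratio_systemic  flag_systemic  fold_auc  fold_auc_reported
 cimetidine        OCT2 0.66    iv         9.6       7.68 207.00        0.037101          False  1.024182               1.02
 cimetidine        OCT2 0.39  oral         9.6       7.68 207.00        0.037101          False  1.014149               1.01
 cimetidine        OCT2 0.66    iv         5.1       4.08 207.00        0.019710          False  1.012922               1.01
 cimetidine        OCT2 0.39  oral         5.1       4.08 207.00        0.019710          False  1.007596               1.01
 cimetidine       MATE1 0.66    iv         9.6       7.68   1.22        6.295082           True  2.323032               2.32
 cimetidine       MATE1 0.39  oral         9.6       7.68   1.22        6.295082           True  1.507248               1.51
```

Reading the cimetidine rows: against OCT2 the unbound Cmax/Ki ratio (0.037)
sits below the 0.1 regulatory cut-off and the predicted AUC change is
negligible (1.02-fold), whereas against MATE1 the ratio is 6.30 and the
model predicts a 2.32-fold AUC increase with the intravenous f_e of 0.66,
or 1.51-fold with the oral-mass-balance f_e of 0.39 — the oral scenario
sits much closer to the observed 1.46-fold clinical interaction. Scoring
all five prediction–observation pairs:

```bash
$ transddi compare
...
fe=0.39: deltas span 2-11
fe=0.66: deltas span 39-86
```

i.e. predictions made with the oral-route f_e land within 2–11 percentage
points of the observed percent AUC increases, versus 39–86 points for the
intravenous f_e — the quantitative signature of metformin's flip-flop
kinetics.

The CLI mirrors the pipeline stages (`transddi run | simulate | fit-km |
fit-ic50 | papp | predict | compare | validate | report`); `transddi run
--seed 1 --out-dir out/` executes simulate→fit→papp→predict→compare→report
end-to-end and logs artifact hashes for reproducibility.

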