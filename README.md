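# cmsig

Translate consensus-molecular-subtype (CMS) classifiers into compact,
assayable prognostic biomarker panels.

Colorectal cancer splits into four expression-defined consensus subtypes
(CMS1 immune, CMS2 canonical, CMS3 metabolic, CMS4 mesenchymal — the
poor-prognosis one). Subtyping captures real biology but needs genome-wide
expression, which keeps it out of routine care. `cmsig` implements a
translation pipeline that distils a subtype classifier into a small panel
of measurable features (genes, or image-derived radiomic features) that
carries the subtypes' prognostic content:

1. **Functional spectra** — each sample's expression profile is reduced to
   per-gene-set ssGSEA scores: genes are ranked within the sample and the
   enrichment score is the integrated difference between the weighted
   in-set cumulative distribution (weights ∝ rankᵅ, α = 0.25) and the
   unweighted out-of-set one.
2. **Deep features** — a fully connected network (input → 128 → 32 → 10 → 4)
   classifies samples into CMS1–4 from the spectra; the K = 10 activations
   of its last hidden layer are the deep features **d**₁…**d**₁₀.
3. **Signature distillation** — per deep feature: the top 10 raw features
   by |Pearson r|, then the 3 most variable of those by median absolute
   deviation (MAD); the deduplicated union is the signature.
4. **Risk model** — univariate Cox screen (Wald p < 0.05), multivariate Cox
   (Efron ties) on the survivors, risk score RS = Σⱼ βⱼ zⱼ on
   training-standardized features, and a high/low cutoff at the maximum
   Youden index (J = sensitivity + specificity − 1) of the IPCW
   time-dependent ROC at 5 years.
5. **Validation** — Kaplan–Meier / log-rank, high-vs-low hazard ratio,
   Harrell's C-index, 2/3/5-year AUCs, hypergeometric subtype enrichment of
   the high-risk group, immune-infiltration contrasts across 28 immune-cell
   sets, and radiomic-feature ↔ pathway Pearson correlation maps.

No external cohorts are required: `cmsig.simulate` generates cohorts with
planted subtype programs, subtype-dependent exponential hazards, embedded
immune programs and pathway-linked radiomic features, together with the
ground truth needed to score recovery.

## Worked example

`examples/05_risk_model.py` runs the whole pipeline on one simulated
cohort (n = 600, 2000 genes, seed 7) and prints:

```
screen retained 12/21 signature genes
risk cutoff (max Youden, 5-year horizon): +0.147
risk groups: 250 high / 350 low
log-rank p = 5.80e-23
high-vs-low HR = 2.91 [2.33-3.63]
C-index = 0.654
AUC at 2/3/5 years: 0.689 / 0.727 / 0.741
5-year survival: high 0.14, low 0.53
```

The 21-gene signature (all members land in the planted subtype programs;
see `examples/04_distill_signature.py`) splits the cohort into groups whose
hazards differ almost three-fold — the planted CMS4 hazard contrast,
recovered end-to-end from expression alone. The other examples walk the
individual stages: cohort simulation, spectra, classifier and deep
features, distillation, and the downstream biology checks (CMS4 enrichment
of the high-risk group, immune infiltration, radiomic–pathway maps).

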