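# metaphen

Metabolic-phenotyping analysis in Python: indirect-calorimetry energy
expenditure, extracellular-flux (Seahorse-style) parameterization, ¹³C
stable-isotope enrichment, plasma-metabolome statistics and single-cell QC —
each paired with a synthetic-data generator carrying known ground truth.

The package targets studies that ask whether a genotype (here, APOE4
carriage) shifts whole-body and cellular glucose handling toward aerobic
glycolysis: lower resting energy expenditure, a blunted post-glucose VO₂
rise, elevated plasma lactate, higher ECAR / lower OCR in astrocytes, and a
larger fully-labeled (m+3) lactate pool after a [U-¹³C]glucose tracer.

## Core quantities

Energy expenditure from gas exchange uses the abbreviated Weir equation
(VO₂, VCO₂ in mL/min):

    EE [kcal/day] = 1.44 · (3.94 · VO₂ + 1.11 · VCO₂),   RER = VCO₂ / VO₂

A session has three periods — rest, cognitive challenge, glucose challenge —
each analyzed after a 5-min steady-state buffer. REE is the windowed mean of
per-sample EE; the cognitive and feeding components are AUC contrasts
against rest:

    CEE = AUC(EE, cognitive) − AUC(EE, rest)
    TEF = AUC(EE, glucose)  − AUC(EE, rest)

Mouse cage runs are averaged in 30-min bins and summarized over light cycles
only, per diet phase (chow vs high-carbohydrate), with the diet-induced
delta tested per genotype and body mass handled by ANCOVA.

Flux plates: glycolysis = ECAR(post-glucose) − baseline, glycolytic capacity
= ECAR(post-oligomycin) − baseline, reserve = capacity − glycolysis; fuel
dependency/capacity/flexibility come from inhibitor-order OCR arms.

Isotope tracing: measured isotopologue intensities are corrected for natural
¹³C by inverting the binomial convolution matrix M[i,j] = C(n−j, i−j)·
p^(i−j)·(1−p)^(n−i); fractional enrichment is Σᵢ (i/n)·fᵢ.

Plasma metabolomics: >75 % presence filter, imputation (iterative
tree-based, kNN or half-minimum), per-metabolite tests with
Benjamini–Hochberg FDR, and hypergeometric metabolite-set enrichment.

Single-cell QC: drop cells with <50 or >50 000 UMIs or >30 % mitochondrial
reads; remove <250-cell clusters positive for multiple cell types' markers;
annotate clusters by marker expression; score gene panels (e.g. glycolysis)
as sums of normalized expression.

## Worked example

```python
from metaphen import calorimetry as cal, synthetic_data as syn

cfg = syn.CohortConfig(n_per_group=1, noise_sd=0.0,
                       ree_mean=1500.0, ree_effect=-150.0,
                       tef_gain=0.15, cog_gain=0.05, seed=1)
subjects, traces = syn.gen_ic_cohort(cfg)

row = subjects.iloc[4]          # first young female E4 carrier
s = cal.summarize_subject(traces[4])
print(row.group, row.sex, row.age_band)
print(f"REE {s.ree:.1f} kcal/day  TEF {s.tef:.3f}  CEE {s.cee:.3f}")
```

prints

```
E4+ F young
REE 1350.0 kcal/day  TEF 3.480  CEE 1.160
```

The carrier's REE is the 1500 kcal/day stratum mean plus the configured
−150 kcal/day shift, recovered exactly at zero noise. TEF is the glucose −
rest AUC contrast: a 15 % EE rise held over the 24.75-min analysis window of
a 1350 kcal/day subject gives 0.15 · 1350 · 24.75/1440 ≈ 3.48 kcal, and CEE
the corresponding 5 % cognitive rise (≈ 1.16 kcal).

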