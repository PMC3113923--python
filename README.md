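# metmem

Classify disease-induced gene expression changes by their responsiveness to
therapy — built for the three-arm rodent studies used to characterize
**metabolic memory** in the diabetic retina, where insulin replacement
normalizes most, but not all, of the diabetes-altered transcriptome.

## Who this is for

Researchers analyzing three-arm expression studies (healthy control /
diseased / treated) on BeadArray-style platforms, who want the classic
treatment-response workflow as a tested, scriptable library instead of a
chain of vendor GUIs: detection-call filtering, average normalization,
t-test + fold-change differential expression, a rule-based partition of
disease-responsive probes by treated-arm expression, qPCR confirmation
statistics, and phenotype correlation — plus a synthetic-study generator
with ground truth, so every stage can be validated without animal data.

## The model

The study design has arms **ND** (non-diabetic), **D** (diabetic) and
**DI** (insulin-treated diabetic) at two timepoints (1 month, pre-insulin;
3 months, after 1.5 months of insulin in DI).

**Differential expression.** For each probe kept by the detection filter
(present/marginal calls, detection *p* ≤ 0.05, in 100% of samples of at
least one arm), a probe is DE between ND and D iff

&nbsp;&nbsp;&nbsp;&nbsp;*p*(t-test) &lt; 0.05 **and** |FC| &gt; 1.2 (both strict),

with signed fold changes on linear-scale group means
(FC = −2 means halved).

**Insulin-response partition.** Each DE probe gets exactly one label via an
ordered decision tree on the two secondary comparisons:

1. ND-vs-DI significant, direction opposite to ND-vs-D → **Inverted**
2. ND-vs-DI significant, same direction → **NotNormalized**
3. else D-vs-DI significant → **Normalized**
4. else → **PartiallyNormalized**

**Temporal refinement.** Combining 1-month DE status with the 3-month
label: changes already present before insulin are **Rescued /
PartiallyRescued / NotRescued**; changes absent at 1 month are
**Prevented / PartiallyPrevented / NotPrevented**. NotRescued and
NotPrevented genes are the operational signature of metabolic memory.

**qPCR confirmation.** Relative expression by 2<sup>−ΔΔCt</sup> with an
endogenous control (β-actin); ΔΔCt is referenced to the ND arm at the same
timepoint. Three-month panels are tested by one-way ANOVA with
Student–Newman–Keuls post-hoc (critical values from the studentized-range
distribution, computed numerically); one-month panels by two-tailed t-test.

## Worked example

```python
import metmem as mm

config = mm.PipelineConfig(seed=42, simulation={"n_probes": 3000})
report = mm.run_pipeline(config, outdir="pipeline_output")
print(mm.render_report(report))
```

prints (abridged):

```
metmem pipeline report (config 056957f844f99bb9)
probes: 3000  detected: 1480  DE (ND vs D): 240

category                probes  percent
Normalized                 103      43%
PartiallyNormalized         34      14%
NotNormalized               99      41%
Inverted                     4       2%
total                      240     100%

qPCR confirmation: 26/27 genes (96%)
glucose @M1: ND 108±18 (n=8), D 333±13 (n=8) [t-test p=6.77e-08]
```

Reading it: of 3,000 simulated probes, 1,480 cleared the detection filter
and 240 were altered by diabetes; each altered probe was then placed in
exactly one insulin-response category (counts sum to the DE total, with
integer percentages of that total). The simulated 27-gene confirmation
panel reproduces a 96% confirmation rate, and the biometric lines show the
expected hyperglycemia of untreated diabetic animals. Re-running with the
same seed reproduces every output byte-for-byte; the config hash ties each
results file to its parameters.

The `examples/` directory walks through each capability in isolation, and
the same stages are available as shell subcommands
(`metmem simulate | preprocess | de | classify | qpcr | correlate | run |
report`). Deposited data in GEO series-matrix format can be fed in via
`expression_dialect="geo_series_matrix"`.

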