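# polytome

Polysome-profiling translatome analysis for bacteria: from polysome-fraction
array intensities to per-gene ribosome occupancy and ribosome density,
two-condition translational-regulation classes, steady-state decomposition of
mRNA levels into transcription/degradation/dilution rate constants,
regulation-pattern clustering, and functional-category enrichment. A
synthetic-experiment generator with planted ground truth stands in for raw
arrays, so every stage of the pipeline can be validated by parameter
recovery.

The package is aimed at people analysing sucrose-gradient polysome profiling
read out fraction-by-fraction (arrays or sequencing summarised to per-gene
signals), and at anyone who wants a ground-truthed sandbox for such
pipelines.

## The quantities

For each gene, the mRNA population is distributed over gradient fractions
S1..Sk (S1 = free mRNA or mRNA with an incomplete ribosome, S2 = monosome,
S3..Sk = polysomes of increasing size). Writing *p_f* for the gene's mRNA
proportion in fraction *f*:

- **ribosome occupancy** = Σ_{f≥2} *p_f* — the fraction of the gene's mRNA
  engaged in translation;
- **peak fraction** — the argmax of *p_f* over S2..Sk, called with a
  bootstrap on residuals (resampled within fraction across replicate series,
  10 000 iterations, 95% confidence; ambiguous calls widen to adjacent
  fractions);
- **ribosome density** = ribosomes(peak fraction) / CDS length × 100 —
  ribosomes per 100 nt, using the gradient's fraction → ribosome-count
  calibration; densities above the steric ceiling of 100/30 = 3.33
  ribosomes/100 nt (one 30-nt footprint per ribosome) are flagged aberrant.

Across two conditions (stress vs optimal growth), occupancy is compared by a
per-gene Student test on the per-series values and density by exact
comparison of the peak ribosome counts; the call pair maps to a regulation
class (up, down, antagonistic, unregulated, occupancy-only).

At steady state, mRNA level, half-life and growth rate decompose into rate
constants:

    k_deg = ln 2 / t_half
    k_trans · gene_copies = (k_deg + μ) · [mRNA]

Stress/optimal ratios of k_trans, k_deg, μ, density and occupancy (plus a
reference column of 1) are clustered with Ward linkage to expose regulation
patterns; gene subsets are tested for category enrichment with the
hypergeometric upper tail.

## Worked example

```python
import polytome as pt

report = pt.run_all(pt.RunConfig(seed=1))   # 1948 genes, 5 series, 2 conditions
print(report.to_text())
```

prints (abridged):

```
gene funnel:
      genes_on_array: 1948
           expressed: 1939
         peak_called: 1831
     single_fraction: 1745
        non_aberrant: 1742
     both_conditions: 1636
regulation classes: antagonistic 690, down 867, up 79
stress: median occupancy 0.741, median density 0.765, engaged 59.0%
optimal: median occupancy 0.686, median density 1.296, engaged 61.0%
mu ratio (stress/optimal): 0.0568
k_deg ratio of mean half-lives: 0.5133
recovery vs planted truth:
  class_accuracy: 0.9743
  mean_abs_occupancy_error: 0.0337
  peak_call_accuracy: 0.9931
```

The funnel counts the genes surviving each filter (expressed → peak called →
single-fraction peak → density below the 3.33 ceiling → measured in both
conditions). The medians say translation under amino-acid starvation shifts
to higher occupancy but lower density; the recovery block compares every
estimate with the planted truth — with five series and log-normal spot noise
(σ = 0.2), peak calls are right 99% of the time, occupancy is recovered to
±0.03, and 97% of genes land in their planted regulation class.

The statsmodels-style objects are available individually: build a
`TranslatomeModel` from normalized profiles and `fit()` it to a
`TranslatomeResults` table; feed two of those plus half-life/mRNA inputs to
`RegulationModel` for the ratio table and Ward clustering. A thin CLI mirrors
the stages: `polytome simulate|normalize|translatome|enrich|run`.

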