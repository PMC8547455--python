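# arnis

Growth rates of individual bacterial lineages from spike-in normalized
amplicon time series.

Amplicon (16S rRNA or functional-gene) read counts are compositional:
library depth and PCR bias make raw reads incomparable across samples, so
they cannot track the growth of any one population through time. When a
defined number of cells of a taxon absent from the environment — an
**internal standard** — is spiked into every sample before filtration, the
per-sample ratio

    ARNIS ratio of phylotype i = reads(i) / reads(internal standard)

is proportional to the absolute abundance of phylotype *i* per unit
volume, up to a constant phylotype-specific bias factor. Constant factors
cancel in log-slopes, so for an exponentially growing population the
specific growth rate μ (in day⁻¹, with μ = ∂B/B × 1/∂t) is the slope of
the ordinary least-squares regression of ln(ratio) on time. This package
implements that analysis end to end for grazer-removal / nutrient-
amendment manipulation experiments:

- **`arnis.core`** — typed TSV readers/writers and dataset validation
  (counts × metadata × taxonomy alignment, nonzero standard everywhere);
- **`arnis.ratios`** — prevalence filtering (presets 10 reads / 15 % of
  samples for 16S, 3 / 15 % for *puf*M), ratio computation, growth-curve
  assembly per phylotype × treatment × replicate;
- **`arnis.growth`** — per-replicate log-linear fits over the exponential
  window (default 0–24 h) gated at R² > 0.6, replicate-averaged rates,
  bulk community summaries, and count-based net growth rates for
  microscopy comparisons;
- **`arnis.classify`** — fold changes F/C (top-down release) and F+P/F
  (bottom-up release), threshold derivation as a percentile of the
  fold-change distribution, and response groups I / II / III / NR;
- **`arnis.diversity`** — Shannon diversity and Bray–Curtis
  dissimilarities;
- **`arnis.simulate`** — a calibrated synthetic-data generator for the
  full 3-treatment × 3-replicate × 6-time-point design with multinomial
  sequencing, lognormal PCR bias, and ground truth for recovery testing.

## Worked example

```python
from arnis import (SyntheticConfig, simulate_dataset, validate_dataset,
                   compute_arnis, build_growth_curves, estimate_rates,
                   fold_changes, classify_records, recovery_report)

data = simulate_dataset(SyntheticConfig(seed=1))          # 200 phylotypes
validated = validate_dataset(data.counts, data.metadata, data.taxonomy)
curves = build_growth_curves(compute_arnis(validated), data.metadata)
rates = estimate_rates(curves, window=(0, 24), r2_min=0.6)
records = classify_records(fold_changes(rates), 1.3)
report = recovery_report(data.truth, rates, records)
print(report.per_treatment.round(3))
print(f"label accuracy: {report.label_accuracy:.3f}")
```

prints

```
  treatment   rmse  mean_bias  pearson_r    n  coverage
0         C  0.058      0.004      0.964  199     0.995
1         F  0.082      0.016      0.997  198     0.990
2        FP  0.162      0.046      0.996  200     1.000
label accuracy: 0.872
```

i.e. with ~127,000 reads per sample the pipeline recovers the true
filtered-treatment growth rates with Pearson *r* ≈ 0.997 and an RMSE of
~0.08 day⁻¹, and assigns 87 % of phylotypes to their true response group.
The same steps are available from a shell:

```sh
arnis simulate --seed 1 --out-dir run/
arnis arnis --counts run/counts.tsv --metadata run/metadata.tsv \
      --taxonomy run/taxonomy.tsv --standard-id IS --out run/ratios.tsv
arnis fit --ratios run/ratios.tsv --metadata run/metadata.tsv --out run/rates.tsv
arnis classify --rates run/rates.tsv --out run/responses.tsv
```

or in one step via `arnis run --config run.yaml`, which also writes a
provenance manifest.

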