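# hlacomposite

Tools for evaluating and improving HLA genotype predictions made from
pseudobulk single-cell RNA-seq data, and for summarizing allele-specific
expression (ASE) at HLA loci once a genotype is in hand.

The HLA locus is the most polymorphic region of the human genome, and
computational genotypers (arcasHLA, OptiType, PHLAT, HLAminer, ...) applied
to pooled single-cell reads disagree with molecular genotyping — and with
each other — in locus- and tool-specific ways. This package provides the
bespoke statistical layer for benchmarking and combining such predictions:

- **Field-resolved concordance metrics.** With a maximum one-to-one matching
  of predicted against ground-truth alleles at field resolution *f*,

  - `success = correct / (correct + incorrect)` — ignores missing calls,
  - `accuracy = correct / (correct + incorrect + absent)` — a
    Bray–Curtis-style similarity that penalizes failed predictions and takes
    only the values {0, 0.5, 1} at a diploid locus.

  Comparison at field *f* uses the full allele prefix (`02:01` vs `01:01`,
  never `xx:01` vs `xx:01`). Agreement between two predictions is accuracy
  with one prediction playing the truth role, and the agreement expected of
  two independent predictions is the product of their accuracies.
- **HLA-DRB345 copy-number inference.** Each DRB1 haplotype carries 0 or 1
  of the paralogs DRB3/DRB4/DRB5, so a diploid sample has 0–2 copies of
  each and at most 2 in total. A k-nearest-neighbor classifier on the ratio
  of paralog-mapped to DRB1-mapped reads predicts each paralog's copy
  number; quality is scored with the Hand & Till multiclass AUC
  (M = 2/(c(c−1)) · Σ_{i<j} Â(i,j)) and a Manhattan-distance similarity
  standardized to the maximum distance of 6. Ranked DRB345 calls are then
  filtered to the top *n* alleles, *n* being the predicted copy number.
- **Composite genotyping.** A decision tree learns which genotyper is most
  accurate from (1) which tools produced a valid genotype, (2) the locus,
  and (3) the field level, and the composite genotype copies the selected
  tool's call per sample × locus × field.
- **ASE effect sizes.** Per cell, observed biallelic counts vs the balanced
  expectation give a log-odds ln(a/b) with variance 1/a + 1/b + 2/(T/2)
  (continuity-corrected at zeros); cells are pooled by inverse-variance
  weighting in a DerSimonian–Laird random-effects model, so low-count cells
  cannot dominate the summary.
- **Sequence-diversity profiles.** Per-column 2-bit Shannon entropy of an
  HLA allele alignment (gaps excluded) with a rolling (default 100 bp) mean.
- **A synthetic-study generator** producing all of the above inputs —
  diploid cohorts with DRB1↔DRB345 linkage, noisy callsets, copy-number-
  proportional read counts, skewed per-cell counts — with known ground
  truth, so every method is testable end to end without any sequencing data.

## Worked example

```python
from hlacomposite import (
    simulate_study, summarize_concordance, summarize_groups,
    compute_ratio_features, train_copy_number_model,
)
from hlacomposite.drb_copynumber import evaluate_holdout
from hlacomposite.synthetic import SimulationConfig

study = simulate_study(SimulationConfig(seed=7, n_samples=120))

s = summarize_concordance(study["calls"], study["truth"], [1, 2])
print(s[(s.metric == "accuracy") & (s.field_level == 2)]
      .groupby("genotyper")["value"].mean().round(3))
```

```
genotyper
simA    0.812
simB    0.858
simC    0.782
simD    0.374
```

Mean 2-field accuracy per simulated genotyper: the low-error tools sit
near 0.8 (their residual gap is substitution noise, dropout, and spurious
DRB345 calls), while the deliberately noisy `simD` falls below 0.4.

```python
feats = compute_ratio_features(study["read_counts"])
model = train_copy_number_model(feats, study["copy_numbers"], seed=7)
print(evaluate_holdout(model, feats, study["copy_numbers"]))
```

```
{'auc': {'DRB3': 1.0, 'DRB4': 1.0, 'DRB5': 1.0}, 'mean_similarity': 1.0, ...}
```

With per-copy read ratios of 0.45 and noise σ = 0.05 the three copy-number
classes are well separated, and the kNN classifier scores a holdout
Hand & Till AUC of 1.0 with perfect copy-number similarity.

```python
print(summarize_groups(study["cell_counts"]).round(4).to_string(index=False))
```

```
group  summary_log_odds     se  tau2  n_cells  reference_allele
   g1            1.0665 0.0496   0.0      200                 0
```

The pooled ASE log-odds 1.07 ± 0.05 recovers the planted per-cell skew of
ln 3 ≈ 1.0986 within two standard errors; τ² = 0 reflects the homogeneous
simulation.

The same stages are scriptable from the shell:

```sh
hlacomposite simulate --seed 7 --n-samples 120 --out study/
hlacomposite concordance --pred study/calls.tsv --truth study/truth.tsv --fields 1,2
hlacomposite drb-cn --reads study/read_counts.tsv --truth-cn study/copy_numbers_truth.tsv --seed 7
hlacomposite ase --counts study/cell_counts.tsv
hlacomposite run --seed 7 --out run/      # full pipeline + manifest
```

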