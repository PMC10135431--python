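# ribolens

Multi-layer post-transcriptional analysis of paired **total-RNA
(transcriptome)** and **polysome-RNA (translatome)** sequencing across age
groups, with a synthetic-data generator that plants recoverable ground
truth for every analysis layer.

Polysome profiling separates mRNAs engaged by multiple ribosomes from the
bulk transcript pool, so sequencing both fractions from the same animals
lets one ask not just *which genes change with age* but *how*: through
transcript abundance, through translational efficiency, or through
translational buffering. `ribolens` implements the full analysis stack for
such a design — four age groups (3, 6, 12, 20 months), matched
total/polysome libraries per subject — end to end:

| layer | module | what it computes |
|---|---|---|
| QC & normalization | `ribolens.preprocess` | depth-anchored abundance filter `N = median_i(8·10⁶ / lib_i)`, TMM factors, log₂ CPM, correlation-IQR outlier flags, location-scale empirical-Bayes batch adjustment, PCA |
| differential expression | `ribolens.diffexpr` | moderated t-tests of log₂ CPM on the six pairwise age contrasts with batch in the design; BH `q < 0.05` and `|log₂FC| > log₂ 1.2` |
| regulatory modes | `ribolens.regmodes` | per-gene analysis of partial variance (ANCOVA): `polysome = α + β·total + γ·I(group)` — γ is the translational effect; genes become **abundance** / **translation** / **buffering** / none calls per contrast |
| alternative splicing | `ribolens.splicing` | the seven local event types (SE, A5, A3, MX, RI, AF, AL) from transcript exon chains; `PSI = TPM(inclusion) / TPM(both forms)`; ΔPSI tested against an expression-stratified empirical null |
| polyadenylation | `ribolens.apa` | terminal fragments (final two exons), 25-nt 3′-end site grouping, positional psi ∈ [0, 1] (0 = proximal, 1 = distal), Welch tests of Δpsi |
| trajectories | `ribolens.trajectories` | z-scored 4-point age profiles, co-expression similarity on linearly interpolated profiles, circular SOM clustering, cluster count by Gaussian-mixture BIC |
| enrichment | `ribolens.enrichment` | hypergeometric ORA and permutation GSEA over four ranked axes (total RNA, translated, translation, buffering) |
| synthetic data | `ribolens.synthetic` | the study design with planted modes, ΔPSI, Δpsi, and trajectory classes — negative-binomial counts anchored at 8×10⁶ reads |

## Worked example

Simulate a two-group paired experiment with 50 planted genes per regulatory
mode (log₂ effect 1.0, per-sample noise sd 0.25) and classify:

```python
import collections
from ribolens import synthetic, regmodes

total, poly, samples, truth = synthetic.simulate_mode_matrices(
    1000,
    {"abundance": (50, 1.0), "translation": (50, 1.0), "buffering": (50, 1.0)},
    seed=0,
)
calls = regmodes.fit_regulatory(total, poly, samples, [(20, 6)])
counts, multi = regmodes.summarize_modes(calls)
print(counts)
```

```
mode      abundance  translation  buffering  none
contrast
20v6             47           52         52   849
```

Of the 150 planted genes, 146 are recalled with the correct label
(sensitivity 0.973, precision 0.967 against the planted truth): abundance
genes move both fractions congruently, translation genes move polysomes
with flat total RNA, buffering genes the reverse.

The whole pipeline runs from one YAML config:

```sh
ribolens simulate --config config.yaml --seed 7 --outdir sim/
ribolens run      --config config.yaml --seed 7
```

which writes per-stage TSVs (normalized matrices, DE tables per contrast,
regulatory calls, a SUPPA-like events file with PSI and ΔPSI tables, APA
site/psi tables, trajectory clusters, enrichment results) plus a
`manifest.json` of output checksums — two runs with the same seed are
byte-identical.

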