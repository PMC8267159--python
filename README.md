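# mratlas

A two-sample Mendelian randomization (MR) toolkit for building causal
"atlases" of trait–disease relationships from GWAS summary statistics.

It implements the full analysis pipeline end to end:

- **`summary_data`** — TSV readers/writers with per-row validation, p-value
  instrument selection (default 5×10⁻⁸), greedy LD clumping (r² ≤ 0.001
  within 10,000 kb), and allele harmonization with frequency-based
  resolution of palindromic variants.
- **`estimators`** — Wald ratio, inverse-variance-weighted combination
  (fixed / multiplicative / additive heterogeneity handling), MR-Egger
  regression, and the weighted-median estimator with parametric-bootstrap
  SEs; instrument-count dispatch (J=1 → Wald, J=2 → IVW, J≥3 → IVW + Egger
  + weighted median).
- **`sensitivity`** — single-SNP and leave-one-out analyses, Cochran's Q,
  the Egger intercept (directional pleiotropy) test, funnel data, and the
  three-stage MR-PRESSO battery (global / outlier / distortion) with its
  conditional logic.
- **`power`** — instrument R², the instrument-strength F-statistic, and
  analytic power at four assumed odds ratios (1.10, 1.20, 1.33, 1.50) for
  binary outcomes, with weak-instrument flags (F < 10, power < 80%).
- **`pipeline`** — orchestration of every exposure × outcome pair, headline
  estimate selection (with optional Egger substitution under detected
  directional pleiotropy), Bonferroni tiering
  (significant / suggestive / null), and the bidirectional MR network among
  significant traits.
- **`simulate`** — a summary-level GWAS generator with known ground truth:
  configurable causal effect, balanced/directional pleiotropy (InSIDE
  holding or not), planted outliers, block-AR(1) LD matrices, and a
  miniature trait-panel fixture for end-to-end tests.

## CLI

```bash
# power/F diagnostics for a binary outcome
mratlas power --r2 0.08 --n-cases 11348 --n-controls 15861 --trait zinc

# synthetic exposure/outcome pair with truth table
mratlas simulate --j 30 --beta 0.2 --seed 7 --out-prefix scratch/demo

# full atlas from a YAML config (see `mratlas atlas --help` for keys)
mratlas atlas --config config.yaml --out-dir results/
```

The atlas run writes `results.tsv` (one row per exposure × outcome ×
method), per-pair sensitivity bundles, a network edge list when at least two
traits are significant, and `run_log.json` with the seeds and thresholds
used.

## Reproducibility

Every stochastic routine (weighted-median bootstrap, MR-PRESSO simulations,
data generation) takes an explicit seed; the pipeline derives per-pair seeds
from a single master seed by stable hashing, so a re-run with the same
configuration is byte-identical.
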