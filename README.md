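# puseq

Positive–unlabeled (PU) learning for sequence-based identification of
membrane-binding peripheral protein domains.

Given a FASTA of known positives and a larger FASTA of unlabeled sequences,
the package mines *reliable negatives* (RN) from the unlabeled pool with the
spy technique, expands the RN set iteratively, and trains a final classifier
on positives vs. the converged RN set. The residual undecided set Q is the
candidate list for follow-up. Two protocol variants are provided: the
original (one spy draw, then RN expansion by the 0.5 posterior rule) and a
modified variant that draws a fresh spy set every iteration.

## Layout

| module              | role                                                                  |
| ------------------- | --------------------------------------------------------------------- |
| `puseq.datasets`    | FASTA I/O, validation, greedy identity-based redundancy reduction, holdout splits |
| `puseq.seqfeatures` | 104-feature encoding: net charge, hydrophobicity/helix/sheet propensity sums, amino-acid composition (20), local-environment composition (4 × 20) |
| `puseq.classifier`  | inner classifier contract: entropy-criterion decision tree with Laplace-smoothed leaf probabilities (default), random-forest plug-in |
| `puseq.pu_core`     | spy selection, spy threshold, RN extraction and expansion loops, final model |
| `puseq.synthetic`   | seeded two-population benchmark generator (basic-enriched positives vs acidic-enriched negatives, hidden positives planted in U) |
| `puseq.evaluation`  | accuracy / sensitivity, positives-only holdout protocol, stratified CV |
| `puseq.cli`         | `puseq` command with `simulate`, `features`, `run`, `predict`, `evaluate` |

## CLI quick start

```bash
# generate the default synthetic benchmark (200 positives, 1000 unlabeled
# with 20% hidden positives)
puseq simulate --out-dir bench --seed 42

# run the full protocol: 40-positive holdout, spy extraction, RN expansion,
# final classifier + holdout sensitivity
puseq run --positives bench/positives.fa --unlabeled bench/unlabeled.fa \
          --out-dir results --seed 42

# score new sequences with the trained model
puseq predict --model results/model.pkl --fasta bench/unlabeled.fa \
              --out results/predictions.tsv
```

`puseq run` writes `rn_ids.txt`, `q_ids.txt`, a per-iteration `history.tsv`
(iteration, |RN|, |Q|, threshold — plot-ready convergence curves),
`model.pkl`, `manifest.tsv` and `metrics.json`. All commands accept a
`--seed` and are fully deterministic for fixed inputs and seed.

## Spy threshold

The threshold after each training round is the largest score at which at
least a `1 - spy_noise` fraction of spies is still classified positive
(`spy_noise = 0` gives the strict all-spies minimum). The default
`spy_noise = 0.15` follows the noise-level convention of the original spy
technique: a single outlier positive drawn as a spy would otherwise pin the
threshold to the bottom of the score range and block RN extraction.

## Notes

- Sequences may contain the ambiguity codes B, Z, X, U, O; they are accepted
  on input and excluded from all feature counts and window means.
- Feature scales (Kyte–Doolittle hydrophobicity, Chou–Fasman helix/sheet
  propensities, the charge map) and the environment window/thresholds are
  injectable through `FeatureConfig` / a YAML feature-config file.
- `greedy_identity_reduce` is a desk-scale stand-in for CD-HIT-style
  clustering (greedy longest-first, pairwise identity under global alignment
  with match=1/mismatch=0/gap=−1, denominator = shorter length). For
  full-scale Swiss-Prot reproduction use CD-HIT itself at 40% (positives) /
  20% (unlabeled).
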