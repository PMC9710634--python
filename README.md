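# fedpca

Simulated **federated principal component analysis** for horizontally
partitioned data (samples split across sites, all sites sharing the feature
axis), aimed at gene-expression-style matrices.

The package simulates a star-topology federation in-process: clients own row
blocks, the aggregator combines only the parameters the clients "send", and
every exchange is recorded in a communication log so traffic can be checked
against closed-form cost predictions.

## Algorithms

| name       | kind        | per-client upload        | idea |
|------------|-------------|--------------------------|------|
| `p-cov`    | exact       | d×d                      | sum local Gram matrices, eigendecompose |
| `ap-cov`   | approximate | d×k′ + k′                | sum rank-k′ proxy covariances rebuilt from local truncated SVDs |
| `ap-stack` | approximate | d×k′ + k′                | SVD of the vertically stacked scaled local subspaces (equivalent to `ap-cov`) |
| `qr-pca`   | exact       | min(n_s,d)×d             | stack local R factors, re-factor, SVD |
| `sub-it`   | exact       | d×k per iteration (both directions) | federated block power iteration, no covariance materialized |

The exact methods reproduce the centralized eigendecomposition to numerical
precision for any partition, however skewed; the approximate methods degrade
when sites are small relative to k′.

Also included:

* **federation_core** — partitioning (by sizes, or a `sample_id → site_id`
  file), federated centering/scaling via summary statistics, message logs.
* **evaluation** — sign-folded per-eigenvector angles, Frobenius
  reconstruction error/ratio against the centralized oracle, and the
  closed-form communication-cost model.
* **synthetic_data** — low-rank-plus-noise matrices with a controlled
  spectrum, Dirichlet-skewed site sizes (with presets mirroring real
  multi-site cohort layouts), per-site batch-effect mean shifts, and a greedy
  (LPT) meta-site grouping heuristic.
* **resample_viz** — privacy-aware visualization: sites share only points
  resampled from a Gaussian fitted to their local projections, never the
  exact projections themselves.

Out of scope by design: vertical partitioning, real network transport /
relay platforms, homomorphic encryption, secure multiparty aggregation and
differential privacy (knowledge-disclosure properties of the exchanged
parameters are discussed in the source literature; none are implemented
here), and sparse single-cell input formats.

## CLI

```bash
# synthesize a 300×50 matrix over 8 skewed sites with batch effects
fedpca simulate --n 300 --d 50 --rank 10 --noise-sd 0.1 \
    --sites 8 --alpha 0.3 --shift-scale 2.0 --seed 1 --out-prefix demo

# run one (or all) federated algorithms and compare to the centralized oracle
fedpca run --algorithm sub-it --input demo_matrix.tsv --sites demo_sites.tsv \
    --k 10 --epsilon 1e-9 --against-centralized --out-dir out/

# compare two saved eigenvector TSVs on a matrix
fedpca evaluate --input demo_matrix.tsv \
    --federated out/sub-it_eigenvectors.tsv \
    --reference out/sub-it_eigenvectors.tsv --out eval.json

# one client's privacy-aware global view (own exact + foreign resampled points)
fedpca resample --input demo_matrix.tsv --sites demo_sites.tsv \
    --eigenvectors out/sub-it_eigenvectors.tsv --out view.tsv --plot view.png
```

`fedpca run` writes per-algorithm eigenvector/eigenvalue/projection TSVs, a
communication-log JSON, a report JSON (accuracy + predicted vs recorded
traffic) and a `run_log.json` with the full configuration echo; identical
configuration and seed give byte-identical artifacts.

Matrices are TSV (CSV via `--csv`) with a header row and a row-label column;
gene-expression tables with features as rows load via
`--orientation features-rows`.

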