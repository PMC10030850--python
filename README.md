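# omicsubtyper

Multi-omics subgroup identification pipeline: per-omic preprocessing,
autoencoder-based non-linear integration, consensus K-means clustering with
PAC-based model selection, statistical subgroup characterization, and
two-level classifier fusion for predicting subgroup labels of new (possibly
single-omic) samples. A seeded synthetic multi-omics generator makes every
stage testable without any external data.

## Pipeline stages

1. **preprocess** — per-omic filtering (strict-greater sparsity thresholds),
   KNN imputation (K=5), top-variance feature selection, min-max scaling,
   and column-wise stacking over the sample intersection. Omic kinds:
   F1 mRNA (FPKM-like), F2 miRNA (RPKM-like), F3 methylation beta values,
   F4 protein (RPPA level-4-like).
2. **integrate** — under-complete autoencoder (ReLU, MSE, Adam, mini-batches
   of 24, 90/10 train–validation split, early stopping with patience 5);
   the bottleneck activations are the latent representation. A standardized
   PCA baseline is included. Implemented on a small deterministic numpy MLP
   engine (`nn.py`) — no deep-learning framework required.
3. **cluster** — consensus K-means: many without-replacement subsamples
   (default 1000 × 80%), co-clustering fractions per sample pair, empirical
   CDF of the consensus entries, PAC = CDF(0.9) − CDF(0.1) per K, and
   selection of the K with minimal PAC (with optional exclusion of K values
   that merely reproduce a known partition, ARI-flagged). Final labels come
   from K-means on the consensus-matrix rows. Silhouette and
   Calinski–Harabasz metrics are provided.
4. **characterize** — Kaplan–Meier curves and G-group log-rank tests for OS
   and DFS; per-feature one-way ANOVA with Tukey HSD post-hoc and BH FDR;
   a methylation route (sd > 0.2 filter, quantile normalization, log2
   transform, per-probe F-tests); one-vs-rest two-sided Fisher exact tests
   for mutations (BH, q ≤ 0.05) and binarized copy-number segments
   (|segmean| ≥ 0.3, raw p ≤ 0.01).
5. **classify** — per-feature-set L0 trio (RBF-SVM with sigmoid-calibrated
   probabilities, random forest, one-hidden-layer FFNN with dropout 0.1,
   L2 activity 1e-4, L1 weight 1e-5); decision-level fusion either linearly
   (P_L = α·P_SVM + β·P_RF + γ·P_FFNN, simplex grid search in steps of
   0.05) or via a stacked meta-learner (logistic regression or FFNN) on the
   concatenated probabilities P_C, with or without a 60/40 holdout.
   Feature-level fusion and single-omic (e.g. methylation-only) prediction
   routing are supported.

## CLI

```sh
omicsubtyper simulate --n 300 --clusters 5 --effect 3.0 --seed 7 --out data/
omicsubtyper preprocess --omic F1=data/F1_mrna.tsv --omic F4=data/F4_protein.tsv --out pp/
omicsubtyper integrate --stack pp/stack.tsv --arch 64,32,16 --seed 7 --out latent/
omicsubtyper cluster --latent latent/latent.tsv --kmin 2 --kmax 8 --resamples 100 --seed 7 --out clusters/
omicsubtyper characterize --labels clusters/labels.tsv --clinical data/clinical.tsv --mutations data/mutations.tsv --out chz/
omicsubtyper train-classifiers --labels clusters/labels.tsv --features F3=pp/processed_F3_methylation.tsv --fusion linear --seed 7 --out models/
omicsubtyper run --config pipeline.yaml        # everything from one YAML
```

Inputs are plain TSV: samples × features with a `sample_id` first column;
missing entries as empty or `NA`. Mutation and segment-mean tables are
features × samples.

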