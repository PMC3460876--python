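# pcdt — physicochemical distance transformation for protein sequences

`pcdt` converts variable-length protein sequences into fixed-length feature
vectors that encode local sequence-order correlations of amino-acid
physicochemical properties, and wraps the surrounding machinery for remote
homology detection: AAIndex1 parsing and normalization, profile-based
feature extraction with pseudo-count smoothing, per-family SVM
classification with discriminant feature ranking, and ROC/ROC50 benchmark
evaluation.

## The transform

Each usable property scale in an AAIndex1 flat file is z-normalized over the
20 standard residues (population standard deviation). For a protein
`A_1 … A_L`, a normalized index `j`, and a lag `lam = 1 … beta`, the feature

    component(j, lam) = mean over i of (I_j(A_i) − I_j(A_{i+lam}))²

averages the squared property difference over all residue pairs separated by
`lam` positions. The feature vector concatenates the components index-major,
lag-minor; its length is `n_indices × beta` (531 × 8 = 4248 with the full
AAIndex1 after filtering, at the default `beta = 8`).

The profile-based variant derives, from a query-anchored multiple alignment,
an L×20 matrix of pseudo-count-smoothed target frequencies, reads off the
n-th most frequent residue per position (n = 1, 2), transforms each derived
sequence, and concatenates — length `n_indices × beta × n`.

## Command line

```sh
pcdt simulate  --out-dir sim --families 4 --seed 7       # synthetic fixtures
pcdt transform --fasta seqs.fasta --aaindex aaindex1.txt --beta 8 --out feats.tsv
pcdt profile   --msa aligned.fasta --n 2 --out-profile prof.tsv --out-fasta derived.fasta
pcdt benchmark --bench-dir sim/benchmark --aaindex sim/toy_aaindex1.txt \
               --kernel auto --seed 7 --models-dir models --out results.tsv
pcdt weights   --model models/fam00.npz --top-k 10 --out weights.tsv
```

`benchmark` expects one subdirectory per family containing
`train_pos.fasta`, `train_neg.fasta`, `test_pos.fasta`, `test_neg.fasta`.
Kernels are quadratic `(1 + x·y)²` or RBF (median-distance width), cosine
normalized, selected per family by cross-validated ROC when `--kernel auto`.
All outputs are deterministic for a fixed seed.

## Library sketch

| module | contents |
| --- | --- |
| `pcdt.aaindex` | AAIndex1 parser/writer, incomplete/all-zero filtering, z-normalization, `NormalizedIndexSet` |
| `pcdt.pdt` | `transform`, `transform_batch`, `pdt_component`, `pair_distance`, feature layout/annotations |
| `pcdt.profiles` | alignment filtering, pseudo-counts (BLOSUM62-implied frequencies or raw scores), target frequencies, `nth_sequence`, `profile_pdt` |
| `pcdt.classify` | `train_family`, `select_kernel`, `discriminant_weights`, `rank_features`, model serialization |
| `pcdt.evaluate` | `roc_score`, `roc50_score`, `run_benchmark`, `chop_experiment`, benchmark directory I/O |
| `pcdt.synthetic` | toy index tables, planted-lag protein families, degenerate single-sequence profiles |

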