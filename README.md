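# ecnbs

Network-level statistical inference for functional connectomes using
**edge-centric networks** (ecNBS), together with its standard comparators —
cNBS (node-centric constrained NBS), NBS (max-component-size permutation
inference) and edge-level Storey-FDR — plus a synthetic-data generator and a
subsampling benchmark harness measuring power, FDR and strong/weak FWER.

## What it does

1. **Edge-centric network construction** (`ecnbs.edge_networks`): edge values
   are collected across subjects into edge vectors; all pairs of edge vectors
   are correlated into an edge-by-edge "edge connectome"; correlations are
   mapped to distances `d = 2(1 − r)` (range 0–4), weighted by a Gaussian
   kernel (σ = 0.252 by default) and partitioned into *n* edge-centric
   networks by normalized cut on the symmetric normalized Laplacian (k-means
   on the edge connectome rows is available as a variant).
2. **Inference** (`ecnbs.inference`): per-edge t statistics (two-sample
   pooled t for binary phenotypes, correlation t for continuous ones) are
   averaged within each network; a permutation null (1000 relabelings by
   default) yields percentile p-values which are Simes/Benjamini–Hochberg
   corrected across networks. cNBS is the identical procedure over the
   N(N+1)/2 edge groups induced by a node partition. NBS thresholds edge
   statistics at t = 3.1 and tests connected-component extents against a
   max-component-size null. Edge-level inference uses parametric one-tailed
   p-values with Storey q-values.
3. **Benchmarking** (`ecnbs.benchmark`): repeated random subsamples (40/80/120
   subjects, 500 repetitions) are scanned with both one-tailed hypotheses;
   detections are classified true/false against ground-truth effect signs
   (full-sample Cohen's d, or planted truth for synthetic data), yielding
   per-component power, sliding-window power-vs-effect-size curves
   (width 0.1, 75% overlap), FDR (empty repetitions score 0), strong FWER,
   and weak FWER under a label-shuffled null mode.
4. **Synthetic data** (`ecnbs.synthetic`): additive-Gaussian stacks with
   planted edge communities (shared per-community subject factors) and
   binary/continuous phenotype effects calibrated so the *population* effect
   size equals the target (Cohen's d, or Pearson r).

## Conventions

* Edges are the strict upper triangle of the symmetric connectivity matrix,
  indexed 0-based and **row-major**: edge `(i, j)`, `i < j`, has linear index
  `i(2N − i − 1)/2 + (j − i − 1)`. A 268-node connectome has 35,778 edges.
* Binary group differences are signed *first phenotype level minus second*.
* Permutation p-values use the add-one rule `(1 + #{null ≥ obs}) / (1 + P)`.
* Dense E×E matrices limit edge-network construction to desk scale
  (E up to a few thousand); full-atlas runs would require blocked
  computation, which is out of scope here.

## Command line

```bash
# synthetic dataset with one planted community effect (d = 0.8)
ecnbs simulate --n-nodes 20 --n-subjects 200 --n-communities 10 \
      --effect 3=0.8 --seed 1 --out data/

# edge-centric networks by normalized cut
ecnbs build-networks --stack data/stack.tsv --n 10 --method ncut --out nets/

# inference (ecnbs | cnbs | nbs | edgefdr)
ecnbs infer --stack data/stack.tsv --phenotype data/phenotype.tsv \
      --method ecnbs --partition nets/edge_partition_ncut_n10.tsv \
      --nperm 1000 --direction both --seed 1 --out result.tsv

# subsampling benchmark from a YAML config
ecnbs benchmark --config bench.yaml --out report/
```

Stacks are accepted as a directory of per-subject delimited square matrices,
a single HDF5 file (`/values`, `/n_nodes`, `/subject_ids`), or a
subjects-by-edges table with a header row of edge indices. Partitions are
two-column text files with a `# kind=node|edge n=<count>` header; phenotypes
are two-column `(subject_id, value)` text.

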