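# mircoord

Regulatory coordination of genomically clustered miRNAs on a miRNA–TF
regulatory network.

Animal miRNA genes are often organized in genomic clusters — runs of
precursor miRNAs within ~10 kb of each other that tend to be transcribed as
one unit. `mircoord` asks how the miRNAs of one cluster coordinate their
downstream regulation on a directed network whose nodes are transcription
factors (TFs), miRNAs and non-TF protein-coding genes. The toolkit is a
Python library with an `examples/` directory of narrative scripts and a thin
`mircoord` command-line pipeline, aimed at systems-biology researchers who
have (or simulate) a miRNA annotation, a family table and a regulatory
network in SIF format.

## What it computes

**Cluster calling and classification.** Precursor miRNAs on one chromosome
are chained transitively whenever consecutive genes lie within a cutoff
(default 10 kb, with a configurable maximum-span constraint). A cluster's
family diversity is its normalized Shannon entropy

    E_fam = −(1/ln N_fam) Σ_i p_i ln p_i ,

where `p_i` is the fraction of members in family *i*. `E_fam = 0` defines a
**homo-cluster** (one family, one seed sequence, hence near-identical target
repertoires); `E_fam > 0` a **hetero-cluster**.

**Target overlap.** For miRNAs *i, j* with target sets of sizes `l_i`, `l_j`
sharing `s` targets,

    TO_ij = s / (min(l_i, l_j) + 1) ∈ [0, 1) ,

computed at a bounded number of regulation steps (steps = 1: direct targets;
steps = k: everything reachable by a directed path of length ≤ k; "closure":
full reachability). The mean-TO-versus-steps curve per pair category (homo /
hetero / size-matched random clusters) localizes *when* coordination
appears: direct for homo-clusters, after ≥ 3 steps (miRNA → TF → TF →
target) for hetero-clusters.

**Dense modules.** MCODE (Bader–Hogue) on the undirected projection:
vertices are weighted by `k_max ×` density of the highest k-core of their
closed neighborhood, complexes grow from high-weight seeds over neighbors
within a score cutoff, then are post-processed (2-core filter, haircut,
optional fluff). A module cluster entropy `E_c` (same normalized entropy,
over the genomic-cluster labels of a module's miRNAs) measures whether a
module's miRNAs come from one cluster (`E_c = 0`) or many (`E_c = 1`).

**Permutation tests.** Three null models with the never-zero estimator
`p = (1 + #{null ≥ obs}) / (1 + B)` (B = 1000 by default): size-preserving
random miRNA clusters (isolated miRNAs as size-1 pseudo-clusters), random
per-module miRNA membership with counts kept, and label permutation of
pooled pair TO values for category contrasts.

**Synthetic scenarios.** A generator plants all of the above — clusters that
chain exactly at the cutoff, homo-clusters sharing a tunable fraction of a
direct-target pool, hetero-clusters with private TF chains converging after
a tunable number of steps, dense TF+miRNA modules, background regulation —
and records the ground truth, plus a `null_mode` that relabels the network's
miRNA nodes uniformly at random, the exchangeable null for every test.

## Worked example

```bash
python examples/04_permutation_tests.py
```

prints, on the default planted scenario (seed 3):

```
homo-clustered miRNA enrichment in modules: observed avg/module=1.27  p=0.000999
hetero-clustered miRNA enrichment in modules: observed avg/module=1.27  p=0.002997
module cluster entropy: observed=0.000  p=0.002037 (direction: lower than random)
steps=1: homo-vs-random dTO=0.727 p=0.000999; hetero-vs-random dTO=-0.005 p=0.99
steps=3: homo-vs-random dTO=0.720 p=0.000999; hetero-vs-random dTO=0.442 p=0.000999
```

Reading: both homo- and hetero-clustered miRNAs concentrate in dense modules
(enrichment p < 0.01); each module's miRNAs come from a single genomic
cluster (average `E_c = 0`, significantly below random); homo-clustered
pairs already share direct targets (mean TO 0.73 above random at one step),
while hetero-clustered pairs look like random pairs at step 1 and only
separate from them at step 3, the planted convergence depth.

The other examples cover cluster calling and the cutoff scan (`01`), the
three-step convergence motif (`02`), MCODE module recovery (`03`) and the
full file-based pipeline (`05`). The same stages are available from the
shell:

```bash
mircoord simulate --preset default --seed 3 --out-dir data/
mircoord clusters --annotation data/mirna_annotation.gff3 --family-table data/mirna_families.tsv
mircoord overlap  --annotation data/mirna_annotation.gff3 --family-table data/mirna_families.tsv \
                  --sif data/regulatory_network.sif --tf-list data/tf_list.txt --steps 1,2,3,closure
```

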