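# annonet

Interpretable sparse neural networks for genotype-to-phenotype prediction.

Complex-trait prediction from genotypes usually faces a choice between
interpretable linear models (polygenic scores, LASSO) and black-box neural
networks too memory-hungry for millions of variants. annonet takes a third
route: the network's connections are defined *exclusively* by biological
annotations. Variants connect only to the genes they fall in, genes connect
only to their pathways or to tissues in which they are differentially
expressed, so every neuron is a named biological entity and every learnable
weight is the effect of one entity on another:

    y_j = activation( Σ_{i ∈ links(j)} x_i · w_ij + B_j )

with batch normalisation (no learnable scale/shift) before every layer, so
weights read as standardised effects. The simplest network — variants →
genes → outcome — is ~n_genes parallel regressions feeding a single logistic
regression, but trained jointly and extensible with pathway, exon, and
tissue-expression layers. After training, per-node importance is the sum of
weight products over all output-to-node paths, normalised within each layer.

The package is aimed at statistical geneticists and ML researchers who want
to prototype annotation-driven architectures: it ships connectivity
builders, the sparse trainer, the importance/export machinery, a
cohort-faithful data pipeline (VCF/text → chunked HDF5, zero-variance
filtering, kinship-aware stratified splits), a LASSO baseline plus
capacity-matched random-network comparator, and a liability-threshold
simulator so the whole method is testable without any real cohort.

## Worked example

```python
import numpy as np
from annonet import (SimulationConfig, simulate_dataset, build_snp_gene_matrix,
                     assemble, train, TrainConfig, evaluate_scores,
                     relative_importance, theoretical_max_auc)
from annonet.workflows import stratified_split_arrays

# synthetic cohort: 5,000 samples, 20 genes x 10 variants, h2 = 0.5,
# 10% of variants causal, balanced cases/controls
data = simulate_dataset(SimulationConfig(h2=0.5, seed=3))

cm, _ = build_snp_gene_matrix(data.annotation, data.variant_ids)
net = assemble([cm])                       # SNP->gene->output, tanh/sigmoid
sets = stratified_split_arrays(data.genotypes.astype(float),
                               data.labels.astype(float), seed=3)
train(net, *sets["train"], *sets["val"],
      TrainConfig(learning_rate=0.01, l1_penalty=1e-5, max_epochs=50, seed=0))

print(evaluate_scores(sets["test"][1], net.predict(sets["test"][0]))["auc"])
print(theoretical_max_auc(0.5, 0.5))

table = relative_importance(net)
genes = table[table.level == 1]
print(genes.nlargest(3, "relative_importance")[["node_id", "relative_importance"]])
```

Output:

```
0.8129433936595456
0.8333333332353113
    node_id  relative_importance
211  gene11             0.144068
219  gene19             0.123088
207  gene07             0.107375
```

The trained network reaches a test AUC of 0.81 against a theoretical
ceiling of 0.83 — the best possible AUC for any genotype-based classifier
at heritability 0.5 and prevalence 0.5 under the liability-threshold model
— and the importance table ranks genes by their share of absolute
path-product mass (causal genes concentrate at the top; with 10% polygenicity
the signal here is spread over many genes).

A command-line interface mirrors the library
(`annonet simulate | convert | split | annot build | train | interpret |
baseline | bound | randomize-network`); see `annonet --help`.

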