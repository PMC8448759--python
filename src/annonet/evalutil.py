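"""Baselines and performance bounds.

Three reference points for judging an annotation-defined network:

* an L1-penalised logistic regression (a single sigmoid neuron over all
  variants, trained with the same loop and loss as the networks);
* a comparator network with the same number of connections placed uniformly
  at random, which isolates the value of the biological prior from raw
  model capacity; and
* the genetics-only performance ceiling implied by monozygotic-twin
  concordance and disease prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import ConnectivityMatrix
from .sparsenet import (NetworkSpec, SparseLayer, TrainConfig, TrainResult,
                        all_to_one, train)


def lasso_baseline(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    variant_ids,
    l1_penalty: float = 0.0,
    cfg: TrainConfig | None = None,
) -> TrainResult:
    """Single-neuron sigmoid model with L1-penalised weights.

    With ``l1_penalty = 0`` and class weights of one this is plain logistic
    regression fitted by gradient descent; coefficients live in
    ``result.net.layers[0].w`` and the intercept in ``layers[0].b``. Batch
    normalisation is disabled so the coefficients stay on the dosage scale
    and are directly comparable to a reference logistic regression.
    """
    cm = all_to_one(list(variant_ids), level_label="variant->output")
    net = NetworkSpec(layers=[SparseLayer(cm, "sigmoid")],
                      task="classification",
                      batchnorm_before_each_layer=False)
    if cfg is None:
        cfg = TrainConfig(l1_penalty=l1_penalty)
    else:
        from dataclasses import replace
        cfg = replace(cfg, l1_penalty=l1_penalty)
    return train(net, X_train, y_train, X_val, y_val, cfg)


def random_connectivity(template: ConnectivityMatrix, seed: int = 0,
                        max_retries: int = 100) -> ConnectivityMatrix:
    """Same shape and link count as the template, links placed uniformly.

    Links are sampled without duplicates; draws are rejected until every
    output node keeps at least one link (at most ``max_retries`` attempts),
    so comparisons against the annotated network are capacity-matched by
    construction.
    """
    rng = np.random.default_rng(seed)
    n_in, n_out, n_links = template.n_inputs, template.n_outputs, template.n_links
    total = n_in * n_out
    if n_links > total:
        raise ValueError("more links than cells")
    if n_links < n_out:
        raise ValueError("cannot cover every output node with so few links")
    for _ in range(max_retries):
        flat = rng.choice(total, size=n_links, replace=False)
        row, col = np.divmod(flat, n_out)
        if np.unique(col).size == n_out:
            return ConnectivityMatrix(
                template.input_names, template.output_names, row, col,
                template.level_label + " (randomized)",
            )
    raise RuntimeError(
        f"could not cover all {n_out} outputs with {n_links} random links "
        f"in {max_retries} attempts"
    )


@dataclass
class UpperBoundInputs:
    """Population quantities bounding a genetics-only classifier."""

    mz_concordance: float  # P(both MZ twins affected | one affected)
    prevalence: float
    n_cases: int
    n_controls: int

    def __post_init__(self):
        if not (0.0 <= self.mz_concordance <= 1.0):
            raise ValueError("mz_concordance must be in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("counts must be non-negative")


def upper_bound(inputs: UpperBoundInputs) -> dict:
    """Confusion-matrix ceiling for a perfect genotype-only classifier.

    A classifier with complete genetic information cannot identify cases
    more reliably than the monozygotic-twin concordance rate c, and cannot
    misclassify controls less often than the prevalence K. The expected
    bounds are therefore sensitivity <= c, specificity <= 1 - K, and

        accuracy <= (c * n_cases + (1 - K) * n_controls) / n.
    """
    c, k = inputs.mz_concordance, inputs.prevalence
    n = inputs.n_cases + inputs.n_controls
    if n == 0:
        raise ValueError("empty dataset")
    acc = (c * inputs.n_cases + (1.0 - k) * inputs.n_controls) / n
    return {"accuracy": acc, "sensitivity": c, "specificity": 1.0 - k}
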