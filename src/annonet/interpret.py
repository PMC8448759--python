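"""Turn trained weights into per-node biological importance and exports.

Because batch normalisation carries no learnable affine terms, every
learnable parameter on a root-to-input path is a link weight. The
contribution of an input variant is the sum over all paths from the output
to that variant of the product of link weights along the path; the
importance of any intermediate node (gene, pathway, tissue) is the sum of
the path products routed through it. This is a first-order measure — the
activation nonlinearity is deliberately ignored, so importance reads like an
effect size, not a significance test.

Within each layer, relative importance is each node's share of the layer's
total absolute importance, so shares sum to one even when signs mix.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .sparsenet import NetworkSpec


def _weight_matrices(net: NetworkSpec) -> list[sp.csr_matrix]:
    return [layer._weight_matrix() for layer in net.layers]


def _level_names(net: NetworkSpec) -> list[tuple]:
    """Node names per level: level 0 = inputs, level K = output node."""
    names = [net.layers[0].cm.input_names]
    for layer in net.layers:
        names.append(layer.cm.output_names)
    return names


def _prefix_suffix(net: NetworkSpec):
    """Column sums of prefix products and suffix path-products per level.

    ``c[l][j]`` sums, over all inputs, the products of weights on paths from
    any input to node j at level l. ``s[l][j]`` is the product of weights
    summed over all paths from node j to the output.
    """
    Ws = _weight_matrices(net)
    K = len(Ws)
    c = [np.ones(net.layers[0].n_in)]
    for W in Ws:
        c.append(np.asarray(W.T @ c[-1]).ravel())
    s = [None] * (K + 1)
    s[K] = np.ones(1)
    for l in range(K - 1, -1, -1):
        s[l] = np.asarray(Ws[l] @ s[l + 1]).ravel()
    return c, s


def snp_contributions(net: NetworkSpec) -> np.ndarray:
    """Per-input sum over all root-to-input paths of the weight products."""
    _, s = _prefix_suffix(net)
    return s[0]


def normalized_weights(net: NetworkSpec, X: np.ndarray) -> list[np.ndarray]:
    """Per-link weights scaled by the empirical std of their source activation.

    ``X`` should be drawn from the training distribution; each layer's input
    (after its batch normalisation, inference mode) is captured and the
    standard deviation of the source node's activation multiplies every link
    weight leaving that node. A constant activation yields a zero normalised
    weight.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate activation stds")
    _, _, layer_inputs = net.forward(X, training=False, capture=True)
    scaled = []
    for layer, xin in zip(net.layers, layer_inputs):
        stds = xin.std(axis=0)
        scaled.append(layer.w * stds[layer.rows])
    return scaled


def relative_importance(
    net: NetworkSpec,
    X: np.ndarray | None = None,
    positions: Mapping[str, tuple] | None = None,
) -> pd.DataFrame:
    """Importance table covering every node in the network exactly once.

    Columns: ``node_id``, ``level`` (0 = inputs), ``layer_label``,
    ``importance`` (signed path-product sum), ``relative_importance``
    (share of the layer's absolute importance, summing to 1 per layer),
    ``raw_weight`` (sum of the node's outgoing link weights),
    ``normalized_weight`` (outgoing weights scaled by the node's activation
    std; requires ``X``), ``path`` (ancestor chain following the strongest
    outgoing link at each level), and optional ``chrom``/``pos``.
    """
    names = _level_names(net)
    c, s = _prefix_suffix(net)
    Ws = _weight_matrices(net)
    norm_w = normalized_weights(net, X) if X is not None else None

    # strongest-outgoing-link parent pointer per node, for the path column
    parent_ptr: list[np.ndarray] = []
    for layer in net.layers:
        ptr = np.full(layer.n_in, -1, dtype=np.int64)
        best = np.zeros(layer.n_in)
        for k in range(layer.w.size):
            i, j = layer.rows[k], layer.cols[k]
            if ptr[i] < 0 or abs(layer.w[k]) > best[i]:
                ptr[i] = j
                best[i] = abs(layer.w[k])
        parent_ptr.append(ptr)

    rows = []
    for l, level_names in enumerate(names):
        imp = c[l] * s[l]
        denom = np.abs(imp).sum()
        rel = np.abs(imp) / denom if denom > 0 else np.full_like(imp, 1.0 / len(imp))
        if l < len(net.layers):
            layer = net.layers[l]
            raw_out = np.zeros(len(level_names))
            np.add.at(raw_out, layer.rows, layer.w)
            if norm_w is not None:
                nrm_out = np.zeros(len(level_names))
                np.add.at(nrm_out, layer.rows, norm_w[l])
            else:
                nrm_out = np.full(len(level_names), np.nan)
            label = layer.cm.level_label
        else:
            raw_out = np.full(len(level_names), np.nan)
            nrm_out = np.full(len(level_names), np.nan)
            label = "output"
        for j, node in enumerate(level_names):
            path = []
            lev, idx = l, j
            while lev < len(net.layers):
                idx = parent_ptr[lev][idx]
                if idx < 0:
                    break
                path.append(names[lev + 1][idx])
                lev += 1
            row = {
                "node_id": node,
                "level": l,
                "layer_label": label,
                "importance": float(imp[j]),
                "relative_importance": float(rel[j]),
                "raw_weight": float(raw_out[j]),
                "normalized_weight": float(nrm_out[j]),
                "path": tuple(path),
            }
            if positions is not None and node in positions:
                row["chrom"], row["pos"] = positions[node]
            rows.append(row)
    return pd.DataFrame(rows)


def manhattan_export(
    table: pd.DataFrame,
    level: int | str = 1,
    positions: Mapping[str, tuple] | None = None,
) -> pd.DataFrame:
    """Per-node (chrom, pos, node, value) records sorted by genomic coordinate.

    ``value`` is the absolute normalised weight between the selected layer
    and its successor (falling back to the absolute raw weight when no data
    batch was supplied to :func:`relative_importance`). ``level`` selects by
    layer index or by ``layer_label``.
    """
    if isinstance(level, str):
        sub = table[table["layer_label"] == level].copy()
    else:
        sub = table[table["level"] == level].copy()
    if sub.empty:
        raise ValueError(f"no nodes at layer {level!r}")
    value = sub["normalized_weight"].where(
        sub["normalized_weight"].notna(), sub["raw_weight"]
    )
    sub["value"] = value.abs()
    if positions is not None:
        sub["chrom"] = sub["node_id"].map(lambda n: positions[n][0])
        sub["pos"] = sub["node_id"].map(lambda n: positions[n][1])
    if "chrom" not in sub or "pos" not in sub:
        raise ValueError("genomic positions required for a Manhattan export")
    out = sub[["chrom", "pos", "node_id", "value"]].sort_values(
        ["chrom", "pos"], kind="stable"
    )
    return out.reset_index(drop=True)


def sunburst_export(net: NetworkSpec, omit_levels: int = 1) -> dict:
    """Nested hierarchy rooted at the output node for sunburst plotting.

    Each ring is one network level read outward from the output; a node's
    angular share within its ring is its relative importance. Levels below
    ``omit_levels`` (default: the input/variant level) are omitted; pass 2 to
    also drop the gene ring, as is usual for pathway networks. Zero-importance
    nodes keep a zero-width sector rather than disappearing.

    A child sector nested under a parent carries the absolute path-product
    mass routed through that specific link, normalised within the ring, so
    ring shares always sum to one.
    """
    names = _level_names(net)
    c, s = _prefix_suffix(net)
    K = len(net.layers)
    if not (0 <= omit_levels <= K):
        raise ValueError("omit_levels out of range")

    # ring totals: absolute path mass over the links leaving each level
    ring_total = {}
    for l in range(omit_levels, K):
        layer = net.layers[l]
        mass = np.abs(c[l][layer.rows] * layer.w * s[l + 1][layer.cols])
        ring_total[l] = float(mass.sum())

    def build(level: int, idx: int) -> dict:
        node = {"id": names[level][idx], "level": level}
        if level > omit_levels:
            layer = net.layers[level - 1]
            children = []
            for k in range(layer.w.size):
                if layer.cols[k] != idx:
                    continue
                i = layer.rows[k]
                mass = abs(c[level - 1][i] * layer.w[k] * s[level][idx])
                child = build(level - 1, i)
                total = ring_total.get(level - 1, 0.0)
                child["value"] = mass / total if total > 0 else 0.0
                children.append(child)
            node["children"] = sorted(children, key=lambda d: d["id"])
        return node

    root = build(K, 0)
    root["value"] = 1.0
    return root
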