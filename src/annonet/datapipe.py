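"""Genotype I/O, filtering, and cohort-faithful train/val/test splitting.

Genotype matrices arrive as VCF (GT or DS fields, via pysam) or as a simple
additive text table (samples in rows, variants in columns) and are converted
to a chunked HDF5 store supporting both sample-major and variant-major
access, or kept in memory for small cohorts. Conversion streams variants in
fixed-size chunks so peak memory does not scale with the total variant
count.

Splitting reproduces a family-aware case-control protocol: all members of
any kinship component above the relatedness threshold go to the training
set, while validation and test sets contain only unrelated samples, with
the case/control ratio preserved per set (60/20/20 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import pysam
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

DEFAULT_CHUNK_VARIANTS = 4096
DEFAULT_KINSHIP_THRESHOLD = 0.0625  # ~2nd degree relatives


class ConversionError(ValueError):
    """Raised on malformed genotype input."""


@dataclass
class GenotypeDataset:
    """Dosage matrix with sample and variant metadata.

    ``dosages`` is either an in-memory ndarray or an open h5py dataset of
    shape (n_samples, n_variants); values are allele dosages in {0, 1, 2}
    or fractional [0, 2] for imputed data.
    """

    dosages: object
    sample_ids: tuple
    variant_ids: tuple
    chrom: tuple = ()
    pos: tuple = ()
    labels: pd.Series | None = None
    kinship: pd.DataFrame | None = None  # columns: id1, id2, coefficient
    n_imputed: int = 0
    _h5file: object = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def matrix(self) -> np.ndarray:
        return np.asarray(self.dosages[:], dtype=float)

    def iter_variant_chunks(self, chunk_size: int = DEFAULT_CHUNK_VARIANTS):
        """Variant-major iteration: yields (variant_slice, block) pairs."""
        for start in range(0, self.n_variants, chunk_size):
            stop = min(start + chunk_size, self.n_variants)
            yield slice(start, stop), np.asarray(self.dosages[:, start:stop], dtype=float)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        return GenotypeDataset(
            dosages=np.asarray(self.dosages[:], dtype=float)[:, keep],
            sample_ids=self.sample_ids,
            variant_ids=tuple(self.variant_ids[i] for i in keep),
            chrom=tuple(self.chrom[i] for i in keep) if self.chrom else (),
            pos=tuple(self.pos[i] for i in keep) if self.pos else (),
            labels=self.labels, kinship=self.kinship, n_imputed=self.n_imputed,
        )

    def close(self):
        if self._h5file is not None:
            self._h5file.close()
            self._h5file = None


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------

def _store_writer(out: str | Path | None, n_samples: int):
    """Returns (append(block), finalize() -> (dosages, h5file))."""
    if out is None:
        blocks: list[np.ndarray] = []
        return blocks.append, lambda: (
            np.hstack(blocks) if blocks else np.empty((n_samples, 0)), None)
    fh = h5py.File(out, "w")
    ds = fh.create_dataset(
        "dosages", shape=(n_samples, 0), maxshape=(n_samples, None),
        chunks=(min(n_samples, 1024), 256), dtype="f4",
    )

    def append(block: np.ndarray):
        old = ds.shape[1]
        ds.resize((n_samples, old + block.shape[1]))
        ds[:, old:] = block

    return append, lambda: (ds, fh)


def _dosages_from_record(rec, n_samples: int):
    """Dosage vector for one VCF record; returns (values, n_imputed)."""
    values = np.empty(n_samples, dtype=float)
    missing = np.zeros(n_samples, dtype=bool)
    use_ds = "DS" in rec.format if rec.format else False
    for i, sample in enumerate(rec.samples.itervalues()):
        if use_ds and sample.get("DS") is not None:
            values[i] = float(sample["DS"])
            continue
        gt = sample.get("GT")
        if gt is None or all(a is None for a in gt):
            missing[i] = True
            values[i] = np.nan
            continue
        if len(gt) != 2:
            raise ConversionError(
                f"mixed/non-diploid genotype at {rec.chrom}:{rec.pos} "
                f"sample index {i} (ploidy {len(gt)})"
            )
        values[i] = sum(1 for a in gt if a is not None and a > 0)
    n_missing = int(missing.sum())
    if n_missing:
        if n_missing == n_samples:
            values[:] = 0.0
        else:
            values[missing] = values[~missing].mean()
    return values, n_missing


def convert(
    path: str | Path,
    out: str | Path | None = None,
    labels: pd.Series | None = None,
    kinship: pd.DataFrame | None = None,
    chunk_size: int = DEFAULT_CHUNK_VARIANTS,
) -> GenotypeDataset:
    """Convert a VCF or additive text table into a :class:`GenotypeDataset`.

    ``out`` selects a chunked HDF5 store (required for cohorts that do not
    fit in memory); otherwise the matrix is held in memory. Missing genotypes
    are imputed to the per-variant mean and counted. Conversion is lossless
    for dosages.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        return _convert_vcf(path, out, labels, kinship, chunk_size)
    return _convert_raw(path, out, labels, kinship)


def _convert_vcf(path, out, labels, kinship, chunk_size) -> GenotypeDataset:
    vf = pysam.VariantFile(str(path))
    samples = tuple(vf.header.samples)
    if not samples:
        raise ConversionError("VCF contains no samples")
    append, finalize = _store_writer(out, len(samples))
    variant_ids, chroms, poss = [], [], []
    buffer: list[np.ndarray] = []
    n_imputed = 0
    for rec in vf:
        vid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        values, n_miss = _dosages_from_record(rec, len(samples))
        n_imputed += n_miss
        variant_ids.append(vid)
        chroms.append(str(rec.chrom))
        poss.append(int(rec.pos))
        buffer.append(values)
        if len(buffer) >= chunk_size:
            append(np.column_stack(buffer))
            buffer = []
    if buffer:
        append(np.column_stack(buffer))
    vf.close()
    dosages, fh = finalize()
    if n_imputed:
        logger.info("convert: imputed %d missing genotypes to variant means", n_imputed)
    return GenotypeDataset(
        dosages=dosages, sample_ids=samples, variant_ids=tuple(variant_ids),
        chrom=tuple(chroms), pos=tuple(poss), labels=labels, kinship=kinship,
        n_imputed=n_imputed, _h5file=fh,
    )


def _convert_raw(path, out, labels, kinship) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ConversionError("duplicate or missing sample ids in text table")
    values = df.to_numpy(dtype=float)
    n_imputed = int(np.isnan(values).sum())
    if n_imputed:
        col_mean = np.nanmean(values, axis=0)
        idx = np.where(np.isnan(values))
        values[idx] = col_mean[idx[1]]
        logger.info("convert: imputed %d missing genotypes to variant means", n_imputed)
    append, finalize = _store_writer(out, values.shape[0])
    append(values)
    dosages, fh = finalize()
    return GenotypeDataset(
        dosages=dosages, sample_ids=tuple(df.index.astype(str)),
        variant_ids=tuple(df.columns.astype(str)), labels=labels,
        kinship=kinship, n_imputed=n_imputed, _h5file=fh,
    )


def export_raw(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the dosage matrix as an additive text table (round-trippable)."""
    df = pd.DataFrame(ds.matrix(), index=list(ds.sample_ids),
                      columns=list(ds.variant_ids))
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="label")


def read_kinship(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = ["id1", "id2", "coefficient"]
    df["coefficient"] = df["coefficient"].astype(float)
    return df


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_zero_variance(ds: GenotypeDataset) -> tuple[GenotypeDataset, int]:
    """Drop variants with a single distinct dosage value; returns (ds, n_removed)."""
    keep_mask = np.zeros(ds.n_variants, dtype=bool)
    for sl, block in ds.iter_variant_chunks():
        keep_mask[sl] = block.min(axis=0) != block.max(axis=0)
    n_removed = int((~keep_mask).sum())
    if n_removed:
        logger.info("filter_zero_variance: removed %d monomorphic variants", n_removed)
    return ds.subset_variants(np.flatnonzero(keep_mask)), n_removed


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

class SplitError(ValueError):
    pass


def split_samples(
    labels: pd.Series,
    kinship: pd.DataFrame | None = None,
    kinship_threshold: float = DEFAULT_KINSHIP_THRESHOLD,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> pd.Series:
    """Assign each sample to train/val/test.

    Connected components of the kinship graph above the threshold go wholly
    to the training set; validation and test sets are filled with unrelated
    samples by per-class stratified sampling so the case/control ratio is
    preserved in every set (within one sample per stratum). Raises
    :class:`SplitError` when relatedness leaves too few unrelated samples to
    reach the requested validation/test sizes.
    """
    if abs(sum(ratios) - 1.0) > 1e-9 or any(r < 0 for r in ratios):
        raise SplitError("ratios must be non-negative and sum to 1")
    samples = list(labels.index.astype(str))
    y = labels.to_numpy()
    rng = np.random.default_rng(seed)

    related: set[str] = set()
    if kinship is not None and len(kinship):
        g = nx.Graph()
        strong = kinship[kinship["coefficient"] > kinship_threshold]
        g.add_edges_from(zip(strong["id1"].astype(str), strong["id2"].astype(str)))
        for comp in nx.connected_components(g):
            related |= comp
    related &= set(samples)

    assignment = pd.Series("train", index=pd.Index(samples, name="sample"))
    for cls in np.unique(y):
        cls_samples = [s for s, yy in zip(samples, y) if yy == cls]
        n_cls = len(cls_samples)
        n_val = int(round(ratios[1] * n_cls))
        n_test = int(round(ratios[2] * n_cls))
        pool = [s for s in cls_samples if s not in related]
        if len(pool) < n_val + n_test:
            max_frac = len(pool) / n_cls
            raise SplitError(
                f"class {cls!r}: only {len(pool)}/{n_cls} unrelated samples; "
                f"requested val+test fraction {ratios[1] + ratios[2]:.2f} exceeds "
                f"achievable {max_frac:.2f}"
            )
        chosen = rng.permutation(pool)
        assignment.loc[list(chosen[:n_val])] = "val"
        assignment.loc[list(chosen[n_val:n_val + n_test])] = "test"
    return assignment


def split(ds: GenotypeDataset, kinship_threshold: float = DEFAULT_KINSHIP_THRESHOLD,
          ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
          seed: int = 0) -> pd.Series:
    """Dataset-level wrapper around :func:`split_samples`."""
    if ds.labels is None:
        raise SplitError("dataset has no labels")
    labels = ds.labels.reindex(list(ds.sample_ids))
    if labels.isna().any():
        raise SplitError("labels missing for some samples")
    return split_samples(labels, ds.kinship, kinship_threshold, ratios, seed)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_scores(y_true: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> dict:
    """AUC (trapezoidal over all thresholds) and accuracy at the cut-off."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    auc = float(roc_auc_score(y_true, scores)) if len(np.unique(y_true)) > 1 else float("nan")
    acc = float(np.mean((scores > threshold).astype(int) == y_true))
    return {"auc": auc, "accuracy": acc, "n": int(y_true.size)}


def evaluate(model, ds: GenotypeDataset, assignment: pd.Series,
             set_label: str = "test") -> dict:
    """Evaluate a trained network on one split of a dataset."""
    mask = np.array([assignment[s] == set_label for s in ds.sample_ids])
    if not mask.any():
        raise SplitError(f"no samples in set {set_label!r}")
    X = ds.matrix()[mask]
    y = ds.labels.reindex(list(ds.sample_ids)).to_numpy()[mask]
    return evaluate_scores(y, model.predict(X))
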