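import numpy as np
import pytest

from annonet.annotations import ConnectivityMatrix


def random_connectivity_matrix(rng, n_in, n_out, n_links, label="rand"):
    """Uniform random connectivity covering every output at least once."""
    assert n_out <= n_links <= n_in * n_out
    while True:
        flat = rng.choice(n_in * n_out, size=n_links, replace=False)
        row, col = np.divmod(flat, n_out)
        if np.unique(col).size == n_out:
            return ConnectivityMatrix(
                tuple(f"in{i:03d}" for i in range(n_in)),
                tuple(f"out{j:03d}" for j in range(n_out)),
                row, col, label,
            )


def dense_mask_and_weights(layer):
    """Dense 0/1 mask and dense weight matrix mirroring a sparse layer."""
    mask = np.zeros((layer.n_in, layer.n_out))
    dense = np.zeros((layer.n_in, layer.n_out))
    for k, (i, j) in enumerate(zip(layer.rows, layer.cols)):
        mask[i, j] = 1.0
        dense[i, j] = layer.w[k]
    return mask, dense


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def four_variant_cm():
    """The 4-variant / 2-gene toy: v1,v2 -> gA; v3,v4 -> gB."""
    return ConnectivityMatrix(
        ("v1", "v2", "v3", "v4"), ("gA", "gB"),
        np.array([0, 1, 2, 3]), np.array([0, 0, 1, 1]), "SNP->gene",
    )


def write_toy_vcf(path, variants, sample_names, gts=None, ds=None):
    """Write a minimal uncompressed VCF.

    ``variants``: list of (chrom, pos, vid); ``gts``: per-variant list of GT
    strings; ``ds``: per-variant list of dosage floats (uses the DS field).
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">',
    ]
    chroms = sorted({c for c, _, _ in variants})
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names))
    for k, (chrom, pos, vid) in enumerate(variants):
        if ds is not None and ds[k] is not None:
            fmt, fields = "DS", [f"{val:g}" for val in ds[k]]
        else:
            fmt, fields = "GT", list(gts[k])
        lines.append(f"{chrom}\t{pos}\t{vid}\tA\tG\t.\tPASS\t.\t{fmt}\t"
                     + "\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path
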