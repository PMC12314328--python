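import numpy as np
import pytest

from bach1sig.iotables import DERecord, GeneModel, Peak


@pytest.fixture
def write(tmp_path):
    """Write text to a temp file and return the path."""

    def _write(name, text):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def make_gene(gene_id="GENE1", chrom="chr1", start=0, end=5000, strand="."):
    return GeneModel(gene_id, chrom, start, end, strand)


def make_peak(peak_id="pk1", chrom="chr1", start=900, end=1100, log2_ratio=1.0):
    return Peak(peak_id, chrom, start, end, log2_ratio)


def make_de(gene_id="GENE1", log2fc=3.0, padj=1e-6):
    return DERecord(gene_id, log2fc, padj)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
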