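import numpy as np
import pandas as pd
import pysam
import pytest

from spliceamp.gene_model import Exon, GeneModel
from spliceamp.junction_quant import JunctionTable, mark_annotated
from spliceamp.synthetic import synthetic_dmd_model


@pytest.fixture(scope="session")
def toy_plus():
    """3-exon plus-strand gene: exons (101-200), (301-400), (501-600)."""
    return GeneModel(
        "toy+",
        "chr1",
        "+",
        (Exon(1, 101, 200), Exon(2, 301, 400), Exon(3, 501, 600)),
    )


@pytest.fixture(scope="session")
def toy_minus():
    """4-exon minus-strand gene (exon 1 genomically highest)."""
    return GeneModel(
        "toy-",
        "chr2",
        "-",
        (
            Exon(1, 2001, 2100),
            Exon(2, 1601, 1700),
            Exon(3, 1101, 1200),
            Exon(4, 501, 600),
        ),
    )


@pytest.fixture(scope="session")
def dmd_model():
    return synthetic_dmd_model()


def build_table(model, counts_by_junction):
    """JunctionTable from {(donor, acceptor): {sample: count}}."""
    samples = sorted({s for v in counts_by_junction.values() for s in v})
    index = pd.MultiIndex.from_tuples(
        sorted(counts_by_junction), names=["donor", "acceptor"]
    )
    df = pd.DataFrame(
        {
            s: [counts_by_junction[j].get(s, 0) for j in index]
            for s in samples
        },
        index=index,
        dtype=np.int64,
    )
    return JunctionTable(
        chrom=model.chrom, counts=df, annotated=mark_annotated(df.index, model)
    )


@pytest.fixture
def sam_writer(tmp_path):
    """Write a SAM file from (name, flag, ref_start_1based, cigar) tuples."""

    def write(model, reads, filename="reads.sam", chrom_len=None):
        lo, hi = model.span
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": model.chrom, "LN": chrom_len or hi + 1000}],
        }
        path = tmp_path / filename
        reads = sorted(reads, key=lambda r: r[2])
        with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
            for name, flag, start1, cigar in reads:
                a = pysam.AlignedSegment(sam.header)
                a.query_name = name
                a.flag = flag
                a.reference_id = 0
                a.reference_start = start1 - 1
                a.mapping_quality = 60
                a.cigarstring = cigar
                sam.write(a)
        return path

    return write
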