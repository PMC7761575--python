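import numpy as np
import pytest

from amplihap.io_formats import GeneModel
from amplihap.synthetic_data import preset_study


@pytest.fixture(scope="session")
def preset():
    return preset_study(seed=0)


@pytest.fixture()
def toy_gene():
    """A 120 bp single-exon gene: 30 bp promoter, short UTRs, 60 bp CDS."""
    rng = np.random.default_rng(42)
    promoter = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
    utr5 = "".join("ACGT"[i] for i in rng.integers(0, 4, 10))
    body = "ATG" + "GGTCTTACCGCAAAGGATCCGTTCGAATGC" + "TTTGCAGGCACCAAGGCAT"[:18] + "TATGA"[-3:]
    # build a clean 60 bp CDS: ATG + 18 codons + TAA
    codons = ["ATG"] + ["GGT", "CTT", "ACC", "GCA", "AAG", "GAT", "CCG", "TTC",
                        "GAA", "TGC", "TTT", "GCA", "GGC", "ACC", "AAG", "GCA",
                        "TAC", "CAT"] + ["TAA"]
    cds = "".join(codons)
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
    seq = promoter + utr5 + cds + utr3
    return GeneModel(
        gene_id="toy",
        sequence=seq,
        promoter_span=(0, 30),
        exon_spans=((30, len(seq)),),
        cds_spans=((40, 40 + len(cds)),),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
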