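import numpy as np
import pytest

from boolimp import PairSpec, RelationKind, generate_dataset, transform_log2

CLASSIC_TSV = """\
#OTU ID\tS1\tS2
4306262\t0\t7
1000986\t3\t1
4446058\t15\t0
"""

CLASSIC_TSV_TAX = """\
#OTU ID\tS1\tS2\ttaxonomy
4306262\t0\t7\tk__Bacteria; p__Firmicutes
1000986\t3\t1\tk__Bacteria; p__Actinobacteria
"""

MAPPING_TSV = """\
#SampleID\tenv_biome\tbody_site
S1\tsoil\t
S2\thuman gut\tfeces
S3\tocean\twater
S4\t\tskin
"""


@pytest.fixture
def classic_tsv(tmp_path):
    p = tmp_path / "table.tsv"
    p.write_text(CLASSIC_TSV)
    return p


@pytest.fixture
def classic_tsv_tax(tmp_path):
    p = tmp_path / "table_tax.tsv"
    p.write_text(CLASSIC_TSV_TAX)
    return p


@pytest.fixture
def mapping_tsv(tmp_path):
    p = tmp_path / "map.tsv"
    p.write_text(MAPPING_TSV)
    return p


@pytest.fixture
def planted_abundance():
    """Log2 matrix with one planted equivalent and one planted high_low pair."""
    cm, truth = generate_dataset(
        n_samples=500,
        n_microbes=10,
        planted=[PairSpec(RelationKind.EQUIVALENT), PairSpec(RelationKind.HIGH_LOW)],
        seed=42,
    )
    return transform_log2(cm), truth
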