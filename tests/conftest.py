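import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tfdosage import GeneRecord, classify, default_config, generate


@pytest.fixture(scope="session")
def default_data():
    """One full default-config synthetic data set (all features)."""
    return generate(default_config(seed=11))


@pytest.fixture(scope="session")
def default_labels(default_data):
    return classify(default_data.frame, default_data.evidence)


@pytest.fixture
def tiny_records():
    """A hand-built six-gene catalog exercising every field."""
    return [
        GeneRecord(
            gene_id="g1", symbol="A1", is_tf=True, tf_family="Nuclear receptor",
            cds_length=300, dn=0.01, ds=0.2, pli=0.97, hipred=0.9, pnull=0.01,
            ppi_degree=400, ppi_tf_fraction=0.25, mrna_level=6.1,
            expression_levels={"S1": "high", "S2": "low"},
            dbd_sizes=[120], has_activation_domain=True,
        ),
        GeneRecord(
            gene_id="g2", is_tf=True, tf_family="C2H2-ZF", is_kzfp=True,
            cds_length=1500, pli=0.1, hipred=0.2, pnull=0.95,
            has_repressor_domain=True,
        ),
        GeneRecord(gene_id="g3", is_tf=True, tf_family="Unknown", pli=0.4, hipred=0.3),
        GeneRecord(gene_id="g4", cds_length=900, pli=0.2, hipred=0.1, ds=0.0, dn=0.0),
        GeneRecord(gene_id="g5", pli=0.6, hipred=0.1),
        GeneRecord(gene_id="g6"),
    ]
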