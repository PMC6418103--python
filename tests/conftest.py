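import numpy as np
import pytest

from thindex.simulate import default_panel
from thindex.variants import PanelDefinition, VariantRecord


@pytest.fixture
def small_panel() -> PanelDefinition:
    return PanelDefinition(name="mini", genes=frozenset({"APC", "KRAS", "TP53", "BRAF", "PIK3CA"}))


@pytest.fixture
def full_panel() -> PanelDefinition:
    return default_panel(381)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_record(vaf=40.0, gene="APC", depth=100, **kwargs):
    """Variant record with counts consistent with the requested VAF."""
    alt = int(round(depth * vaf / 100.0))
    defaults = dict(
        chrom="chr5",
        pos=112_175_000,
        ref_allele="C",
        alt_allele="T",
        gene=gene,
        ref_count=depth - alt,
        alt_count=alt,
        vaf=100.0 * alt / depth,
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)
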