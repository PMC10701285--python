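import numpy as np
import pandas as pd
import pytest

from cttkit.omics_io import OmicsBundle


@pytest.fixture
def tiny_bundle() -> OmicsBundle:
    """Deterministic 4-gene x 10-sample bundle with all layers present."""
    genes = ["GA", "GB", "GC", "GD"]
    samples = [f"S{i}" for i in range(10)]
    rng = np.random.default_rng(42)
    expr = pd.DataFrame(rng.standard_normal((4, 10)), index=genes, columns=samples)
    mut = pd.DataFrame(0, index=genes, columns=samples)
    mut.loc["GA", ["S0", "S1", "S2"]] = 1
    cnv = pd.DataFrame(rng.normal(0, 0.3, (4, 10)), index=genes, columns=samples)
    meth = pd.DataFrame(rng.beta(2, 2, (4, 10)), index=genes, columns=samples)
    bundle = OmicsBundle(genes=genes, samples=samples, expression=expr,
                         mutation=mut, cnv=cnv, methylation=meth)
    bundle.validate()
    return bundle


@pytest.fixture
def pair_table() -> pd.DataFrame:
    return pd.DataFrame({"gene_a": ["GA", "GB"], "gene_b": ["GB", "GC"]})
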