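import numpy as np
import pandas as pd
import pytest

from colocgap.sumstats import SumStatsTable
from colocgap.synthetic import simulate_ld_panel


def make_table(
    study_id="s",
    trait_type="quantitative",
    chrom="1",
    pos=(100, 200, 300),
    ref="A",
    alt="G",
    beta=0.1,
    se=0.05,
    pvalue=0.5,
    maf=0.3,
    n=1000,
):
    k = len(pos)
    df = pd.DataFrame(
        {
            "chrom": [chrom] * k,
            "pos": list(pos),
            "ref": [ref] * k if isinstance(ref, str) else list(ref),
            "alt": [alt] * k if isinstance(alt, str) else list(alt),
            "beta": [beta] * k if np.isscalar(beta) else list(beta),
            "se": [se] * k if np.isscalar(se) else list(se),
            "pvalue": [pvalue] * k if np.isscalar(pvalue) else list(pvalue),
            "maf": [maf] * k if np.isscalar(maf) else list(maf),
            "n": [n] * k if np.isscalar(n) else list(n),
        }
    )
    return SumStatsTable(study_id, trait_type, df)


@pytest.fixture
def small_panel():
    return simulate_ld_panel(20, 200, 0.95, 100_000, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
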