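import numpy as np
import pandas as pd
import pytest

from cismr.sumstats import AssocSet, two_sided_p


def make_assoc(trait_id="trait", variants=None, betas=None, ses=None,
               chrom="1", positions=None, eafs=None, alleles=None,
               trait_type="quantitative", n=10_000.0):
    """Hand-build a small AssocSet for unit tests."""
    m = len(betas)
    variants = variants or [f"rs{i+1}" for i in range(m)]
    positions = positions or [1000 * (i + 1) for i in range(m)]
    ses = ses if ses is not None else [0.1] * m
    eafs = eafs if eafs is not None else [0.3] * m
    alleles = alleles or [("A", "G")] * m
    z = np.asarray(betas) / np.asarray(ses)
    df = pd.DataFrame({
        "variant_id": variants, "chrom": str(chrom), "pos": positions,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": eafs, "beta": betas, "se": ses,
        "pval": two_sided_p(z), "n": n,
    })
    return AssocSet(trait_id, df, trait_type)


@pytest.fixture
def assoc_factory():
    return make_assoc
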