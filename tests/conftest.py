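import numpy as np
import pandas as pd
import pytest

import mlgwas as m


@pytest.fixture(scope="session")
def small_dataset():
    """150 lines x 200 SNPs with planted QTL and a 3-env, 3-rep trial."""
    g, truth, ratings = m.simulate_dataset(
        n_lines=150, n_snps=200, n_chromosomes=5, n_envs=3, n_reps=3, seed=11
    )
    return g, truth, ratings


@pytest.fixture(scope="session")
def adjusted(small_dataset):
    g, truth, ratings = small_dataset
    res = m.AdjustedMeans(ratings).fit()
    X = g.imputed().loc[g.line_ids]
    y = res.adjusted_scores.loc[g.line_ids]
    cls = res.classes.loc[g.line_ids]
    return X, y, cls, res


@pytest.fixture(scope="session")
def vip_fit(small_dataset, adjusted):
    g, _, _ = small_dataset
    X, y, _, _ = adjusted
    return m.PLSVIP(X, y, max_components=8, cv_folds=10, seed=11,
                    snp_meta=g.snp_meta).fit()


def toy_genotypes(dosages, line_prefix="L", chrom="1"):
    """Small GenotypeMatrix from a plain array (helper for unit tests)."""
    d = np.asarray(dosages)
    n, p = d.shape
    meta = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, p + 1) * 100, "ref": "A", "alt": "C"},
        index=[f"s{j}" for j in range(p)],
    )
    return m.GenotypeMatrix(
        line_ids=[f"{line_prefix}{i}" for i in range(n)],
        snp_ids=[f"s{j}" for j in range(p)],
        dosages=d,
        snp_meta=meta,
    )
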