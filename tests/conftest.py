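import numpy as np
import pytest

import eplink


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort that keeps every pipeline stage cheap."""
    return eplink.SimConfig(
        n_enhancers=30, n_genes=45, n_true_pairs=24, n_null_pairs=24,
        n_background_probes=30, chrom_length=3_000_000, seed=11,
    )


@pytest.fixture(scope="session")
def small_synthetic(small_config):
    return eplink.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_normexpr(small_synthetic):
    counts = small_synthetic.cohort.counts
    return eplink.filter_and_log(counts, eplink.tmm_normalise(counts))


@pytest.fixture(scope="session")
def small_table(small_synthetic, small_normexpr):
    return eplink.assemble_features(
        small_synthetic.truth_pairs, small_synthetic.cohort, small_normexpr
    )


@pytest.fixture(scope="session")
def small_split(small_table):
    table = small_table.subset(np.arange(len(small_table)))
    return eplink.split_train_test(table, seed=11)


@pytest.fixture(scope="session")
def trained_small(small_split):
    train_table, _ = small_split
    cfg = eplink.TrainConfig(seed=11, epochs=10)
    return eplink.train(train_table, config=cfg)


def separable_table(n: int = 200, seed: int = 0, informative: int = 2,
                    shift: float = 3.0) -> eplink.FeatureTable:
    """Toy 11-feature table with two linearly separable label clusters."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 11))
    y = rng.integers(0, 2, size=n)
    X[:, informative] += shift * y
    pairs = [
        eplink.CandidatePair(f"enh{i:03d}", f"gene{i:03d}", "chrT", 1000 + i, int(y[i]))
        for i in range(n)
    ]
    table = eplink.FeatureTable(pairs=pairs, X=X, labels=y.astype(int))
    table.fit_standardiser(np.arange(n))
    return table
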