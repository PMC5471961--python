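import numpy as np
import pytest

import tfcircuit as tc


@pytest.fixture(scope="session")
def small_benchmark() -> tc.SyntheticDataset:
    """A small two-condition dataset with two planted activity changes."""
    return tc.make_benchmark(
        tc.BenchmarkConfig(
            n_genes=40, n_tfs=8, density=0.3, n_samples=6,
            sigma=0.1, n_perturbed=1, activity_factor=3.0, seed=42,
        )
    )


@pytest.fixture(scope="session")
def fitted_pair(small_benchmark):
    """EM fits of both conditions of the small benchmark plus their contrast."""
    ds = small_benchmark
    ref = tc.infer(ds.expr_ref, ds.conn, tc.InferenceConfig(seed=5))
    alt = tc.infer(ds.expr_alt, ds.conn, tc.InferenceConfig(seed=6))
    result = tc.compare(ref, alt, ds.conn)
    return ds, ref, alt, result


@pytest.fixture
def tiny_expression() -> tc.ExpressionMatrix:
    return tc.ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        label="tiny",
    )


@pytest.fixture
def tiny_connectivity() -> tc.ConnectivityMatrix:
    return tc.ConnectivityMatrix(
        gene_ids=["gA", "gB", "gC"],
        tf_ids=["f1", "f2"],
        entries=np.array([[1, 0], [1, 1], [0, 1]]),
    )


def random_instance(seed: int, n_genes=5, n_tfs=3, n_samples=4, density=0.6, sigma=0.3):
    """A small random aligned (expression, connectivity) pair."""
    rng = np.random.default_rng(seed)
    entries = (rng.random((n_genes, n_tfs)) < density).astype(np.int8)
    for f in range(n_tfs):
        if entries[:, f].sum() == 0:
            entries[rng.integers(n_genes), f] = 1
    conn = tc.ConnectivityMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        tf_ids=[f"f{j}" for j in range(n_tfs)],
        entries=entries,
    )
    W = rng.standard_normal((n_genes, n_tfs)) * entries
    c = rng.standard_normal((n_tfs, n_samples))
    mu = rng.standard_normal(n_genes)
    e = mu[:, None] + W @ c + sigma * rng.standard_normal((n_genes, n_samples))
    expr = tc.ExpressionMatrix(
        gene_ids=list(conn.gene_ids),
        sample_ids=[f"s{j}" for j in range(n_samples)],
        values=e,
    )
    return expr, conn
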