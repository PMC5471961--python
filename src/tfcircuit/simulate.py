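"""Synthetic two-condition benchmarks with planted regulatory changes.

Real inputs to the pipeline are a conserved-motif binding catalogue and
normalized expression compendia; neither is needed for testing the
method.  This module generates their statistical stand-ins: a sparse
Bernoulli binding topology, Gaussian ground-truth weights/concentrations/
baselines, and expression sampled from the same bilinear model the
inference assumes,

    e = mu + (T o W) c + noise.

A "perturbation" multiplies selected TFs' weight columns (activity) and/or
concentration rows (abundance) in the alternate condition, so recovery of
the planted TF set by ``infer`` + ``compare`` can be scored exactly.

Default sizes (200 genes x 20 TFs, density 0.2, 8 samples per condition,
noise SD 0.1, 3 TFs perturbed at 3x activity) are a scaled-down regulon:
dense enough that every TF has a handful of targets, small enough that a
full inference runs in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .io import ConnectivityMatrix, ExpressionMatrix, write_connectivity, write_expression

_SEED_MOD = 2**31


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % _SEED_MOD for s in ss.generate_state(n, dtype=np.uint64)]


@dataclass
class GroundTruth:
    """True parameters of one condition of the generative model."""

    conn: ConnectivityMatrix
    W: np.ndarray               # genes x TFs, zero off support
    c: np.ndarray               # TFs x samples
    mu: np.ndarray              # genes
    sigma: float
    label: str = ""

    def mean_expression(self) -> np.ndarray:
        return self.mu[:, None] + self.W @ self.c

    @property
    def n_samples(self) -> int:
        return self.c.shape[1]


@dataclass
class BenchmarkConfig:
    n_genes: int = 200
    n_tfs: int = 20
    density: float = 0.2
    n_samples: int = 8
    sigma: float = 0.1
    w_scale: float = 1.0
    c_scale: float = 1.0
    mu_scale: float = 0.0
    n_perturbed: int = 3
    activity_factor: float = 3.0
    concentration_factor: float = 1.0
    tail_df: float | None = None   # draw W and c from a scaled t instead of a Gaussian
    seed: int = 0


@dataclass
class SyntheticDataset:
    """A ready two-condition benchmark with known ground truth."""

    conn: ConnectivityMatrix
    W_true: np.ndarray
    c_true_ref: np.ndarray
    c_true_alt: np.ndarray
    W_true_alt: np.ndarray
    mu_true: np.ndarray
    sigma_true: float
    expr_ref: ExpressionMatrix
    expr_alt: ExpressionMatrix
    perturbed_tfs: set[tuple[str, float, float]] = field(default_factory=set)
    seed: int = 0
    config: BenchmarkConfig = field(default_factory=BenchmarkConfig)

    @property
    def perturbed_tf_ids(self) -> set[str]:
        return {t for t, _, _ in self.perturbed_tfs}

    def true_signal(self, condition: str) -> np.ndarray:
        """Noise-free regulatory signal (T o W) c of a condition."""
        if condition == "ref":
            return self.W_true @ self.c_true_ref
        if condition == "alt":
            return self.W_true_alt @ self.c_true_alt
        raise ValidationError(f"unknown condition {condition!r}")


def simulate_connectivity(
    n_genes: int, n_tfs: int, density: float, seed: int
) -> ConnectivityMatrix:
    """Bernoulli(density) binding topology with no empty TF column.

    A TF that ends up with zero targets would have an unidentifiable
    concentration, so any all-zero column is repaired by wiring in one
    uniformly chosen target gene.
    """
    if not 0 < density <= 1:
        raise ValidationError("density must lie in (0, 1]")
    if n_genes < 1 or n_tfs < 1:
        raise ValidationError("need at least one gene and one TF")
    if density * n_genes < 1:
        raise ValidationError("density x n_genes must be >= 1 so every TF can have a target")
    rng = np.random.default_rng(seed)
    entries = (rng.random((n_genes, n_tfs)) < density).astype(np.int8)
    for f in range(n_tfs):
        if entries[:, f].sum() == 0:
            entries[rng.integers(n_genes), f] = 1
    width_g = len(str(n_genes))
    width_f = len(str(n_tfs))
    return ConnectivityMatrix(
        gene_ids=[f"g{i + 1:0{width_g}d}" for i in range(n_genes)],
        tf_ids=[f"tf{j + 1:0{width_f}d}" for j in range(n_tfs)],
        entries=entries,
    )


def _draw(rng: np.random.Generator, shape, scale: float, tail_df: float | None) -> np.ndarray:
    if tail_df is None:
        return scale * rng.standard_normal(shape)
    if tail_df <= 2:
        raise ValidationError("tail_df must exceed 2 for a finite variance")
    # scaled t with matched variance, for misspecification tests
    t = rng.standard_t(tail_df, size=shape)
    return scale * t * np.sqrt((tail_df - 2.0) / tail_df)


def simulate_ground_truth(
    conn: ConnectivityMatrix,
    n_samples: int,
    seed: int,
    w_scale: float = 1.0,
    c_scale: float = 1.0,
    mu_scale: float = 0.0,
    sigma: float = 0.1,
    tail_df: float | None = None,
    label: str = "ref",
) -> GroundTruth:
    """Draw true weights, concentrations and baselines for one condition."""
    if n_samples < 1:
        raise ValidationError("n_samples must be positive")
    if sigma < 0 or w_scale < 0 or c_scale < 0:
        raise ValidationError("scales must be non-negative")
    rng = np.random.default_rng(seed)
    W = _draw(rng, conn.entries.shape, w_scale, tail_df) * conn.entries
    c = _draw(rng, (conn.n_tfs, n_samples), c_scale, tail_df)
    mu = mu_scale + rng.standard_normal(conn.n_genes)
    return GroundTruth(conn=conn, W=W, c=c, mu=mu, sigma=sigma, label=label)


def plant_perturbation(
    truth: GroundTruth,
    tf_ids: set[str] | list[str],
    activity_factor: float,
    concentration_factor: float,
    label: str = "alt",
) -> GroundTruth:
    """Alternate-condition truth with selected TFs rescaled.

    The activity factor multiplies the TF's weight column, the
    concentration factor its concentration row; everything else is shared
    with the reference condition.  A factor of 0 is a hard knock-out.
    """
    index = {t: j for j, t in enumerate(truth.conn.tf_ids)}
    unknown = [t for t in tf_ids if t not in index]
    if unknown:
        raise ValidationError(f"unknown TF id(s) in perturbation: {unknown}")
    W = truth.W.copy()
    c = truth.c.copy()
    for t in tf_ids:
        j = index[t]
        W[:, j] *= activity_factor
        c[j, :] *= concentration_factor
    return GroundTruth(conn=truth.conn, W=W, c=c, mu=truth.mu.copy(), sigma=truth.sigma, label=label)


def simulate_expression(truth: GroundTruth, seed: int) -> ExpressionMatrix:
    """Sample expression from the bilinear model with i.i.d. Gaussian noise."""
    rng = np.random.default_rng(seed)
    noise = truth.sigma * rng.standard_normal((truth.conn.n_genes, truth.n_samples))
    values = truth.mean_expression() + noise
    return ExpressionMatrix(
        gene_ids=list(truth.conn.gene_ids),
        sample_ids=[f"s{j + 1}" for j in range(truth.n_samples)],
        values=values,
        label=truth.label,
    )


def make_benchmark(config: BenchmarkConfig | None = None) -> SyntheticDataset:
    """Compose topology, truth, perturbation and expression sampling.

    All randomness derives from ``config.seed`` through independent child
    streams, so the dataset regenerates bit-exactly from its manifest.
    """
    config = config or BenchmarkConfig()
    if not 0 <= config.n_perturbed <= config.n_tfs:
        raise ValidationError("n_perturbed must lie in [0, n_tfs]")
    s_conn, s_truth, s_pick, s_ref, s_alt = _spawn_seeds(config.seed, 5)

    conn = simulate_connectivity(config.n_genes, config.n_tfs, config.density, s_conn)
    truth_ref = simulate_ground_truth(
        conn,
        config.n_samples,
        s_truth,
        w_scale=config.w_scale,
        c_scale=config.c_scale,
        mu_scale=config.mu_scale,
        sigma=config.sigma,
        tail_df=config.tail_df,
        label="ref",
    )
    rng_pick = np.random.default_rng(s_pick)
    picked = sorted(
        rng_pick.choice(conn.tf_ids, size=config.n_perturbed, replace=False).tolist()
    )
    truth_alt = plant_perturbation(
        truth_ref, picked, config.activity_factor, config.concentration_factor, label="alt"
    )
    expr_ref = simulate_expression(truth_ref, s_ref)
    expr_alt = simulate_expression(truth_alt, s_alt)
    return SyntheticDataset(
        conn=conn,
        W_true=truth_ref.W,
        c_true_ref=truth_ref.c,
        c_true_alt=truth_alt.c,
        W_true_alt=truth_alt.W,
        mu_true=truth_ref.mu,
        sigma_true=config.sigma,
        expr_ref=expr_ref,
        expr_alt=expr_alt,
        perturbed_tfs={
            (t, config.activity_factor, config.concentration_factor) for t in picked
        },
        seed=config.seed,
        config=replace(config),
    )


def write_benchmark(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write expression/connectivity tables plus a regeneration manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr_ref": out / "expr_ref.tsv",
        "expr_alt": out / "expr_alt.tsv",
        "connectivity": out / "connectivity.tsv",
        "manifest": out / "manifest.yaml",
    }
    write_expression(dataset.expr_ref, paths["expr_ref"])
    write_expression(dataset.expr_alt, paths["expr_alt"])
    write_connectivity(dataset.conn, paths["connectivity"])
    manifest = {
        "generator": "tfcircuit.simulate.make_benchmark",
        "config": dict(vars(dataset.config)),
        "perturbed_tfs": sorted(dataset.perturbed_tf_ids),
        "files": {k: str(v.name) for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def benchmark_from_manifest(path) -> SyntheticDataset:
    """Regenerate a dataset bit-exactly from a written manifest."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    return make_benchmark(BenchmarkConfig(**manifest["config"]))
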