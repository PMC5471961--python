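"""EM inference of TF activities and concentrations.

The generative model for one condition is the bilinear Gaussian

    e_gs = mu_g + sum_f T_gf W_gf c_fs + v_gs,      v_gs ~ N(0, sigma^2)

where ``e`` is the logged expression matrix (genes x samples), ``T`` the
binary binding topology, ``W`` the TF-gene interaction strengths (TFA),
``c`` the TF concentrations (TFC, one column per sample), ``mu`` the
per-gene baseline and ``v`` i.i.d. spherical Gaussian noise.

Inference treats the connected entries of ``W`` as latent variables with
independent N(0, alpha) priors, and ``c``, ``mu``, ``sigma^2`` as
parameters.  Because genes are conditionally independent given ``c``, the
E-step factorizes over genes into exact Gaussian (ridge-type) posteriors;
the M-step has closed-form generalized-least-squares updates.  The EM
lower bound is therefore monotone, which the test suite checks.

Three gauge freedoms of the bilinear model are handled explicitly:

* scale — ``(W_f, c_f) -> (a W_f, c_f / a)`` leaves the likelihood
  unchanged; the fixed prior variance ``alpha`` pins the scale of ``W``
  softly.  Only the product ``(T o W) c`` is sharply identified.
* sign — ``(W_f, c_f) -> (-W_f, -c_f)``; resolved after convergence by
  flipping each TF so that its mean concentration over samples is >= 0.
* mean — adding a constant ``d_f`` to a concentration row while
  subtracting ``W d`` from the baseline changes nothing; resolved by
  defining the baseline as the part of mean expression *orthogonal* to
  the regulatory directions (least-squares re-gauge after convergence),
  so constant regulatory input is credited to the TFs, not to ``mu``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .errors import ComputationError, ValidationError
from .io import ConnectivityMatrix, ExpressionMatrix, _canon

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class InferenceConfig:
    """Knobs of the EM fit.

    prior_variance
        Variance ``alpha`` of the zero-mean Gaussian prior on each
        connected weight.  Fixed, not optimized; it pins the W/c scale.
    tolerance
        Relative change of the objective below which EM stops.
    min_sigma2
        Floor on the noise variance, keeping the bound finite on
        noiseless data.
    """

    prior_variance: float = 1.0
    max_iterations: int = 3000
    tolerance: float = 1e-6
    seed: int = 0
    min_sigma2: float = 1e-8

    def __post_init__(self) -> None:
        if self.prior_variance <= 0:
            raise ValidationError("prior_variance must be positive")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.min_sigma2 <= 0:
            raise ValidationError("min_sigma2 must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be a positive integer")


@dataclass
class _SupportGroup:
    """Genes sharing the same number of connected TFs, for batched solves."""

    k: int
    genes: np.ndarray   # (n,) gene row indices
    idx: np.ndarray     # (n, k) connected TF column indices


@dataclass
class ModelState:
    """Mutable EM state; produced by :func:`initialize_state`."""

    E: np.ndarray               # genes x samples expression
    T: np.ndarray               # genes x TFs binary mask
    support: list[np.ndarray]   # per-gene indices of connected TFs
    groups: list[_SupportGroup]
    c: np.ndarray               # TFs x samples
    mu: np.ndarray              # genes
    sigma2: float
    config: InferenceConfig
    W_mean: np.ndarray | None = None
    W_cov: list[np.ndarray] | None = None   # per-group (n, k, k) posterior covariances
    W_logdet: np.ndarray | None = None      # per-gene log|Sigma_g|

    @property
    def n_genes(self) -> int:
        return self.E.shape[0]

    @property
    def n_samples(self) -> int:
        return self.E.shape[1]

    @property
    def n_tfs(self) -> int:
        return self.T.shape[1]

    def gene_posterior(self, g: int) -> tuple[np.ndarray, np.ndarray]:
        """(mean, covariance) of the connected-weight posterior of gene g."""
        if self.W_mean is None or self.W_cov is None:
            raise ComputationError("posterior not computed yet (run e_step)")
        idx = self.support[g]
        for grp, cov in zip(self.groups, self.W_cov):
            where = np.nonzero(grp.genes == g)[0]
            if where.size:
                return self.W_mean[g, idx], cov[where[0]]
        return np.zeros(0), np.zeros((0, 0))


@dataclass
class InferenceResult:
    """Posterior summaries of one EM fit on one condition/dataset."""

    gene_ids: list[str]
    tf_ids: list[str]
    sample_ids: list[str]
    W_mean: np.ndarray          # genes x TFs, zero off support
    W_var: np.ndarray           # genes x TFs marginal posterior variances
    c: np.ndarray               # TFs x samples
    mu: np.ndarray              # genes
    sigma2: float
    objective_trace: np.ndarray
    converged: bool
    config: InferenceConfig
    label: str = ""
    c_summary: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.c_summary = self.c.mean(axis=1)

    def reconstruction(self) -> np.ndarray:
        """Model mean ``mu + (T o W) c`` on the expression scale."""
        return self.mu[:, None] + self.W_mean @ self.c


def _check_aligned(expr: ExpressionMatrix, conn: ConnectivityMatrix) -> None:
    if [_canon(g) for g in expr.gene_ids] != [_canon(g) for g in conn.gene_ids]:
        raise ValidationError(
            "expression and connectivity gene universes differ; run align_inputs first"
        )


def initialize_state(
    expr: ExpressionMatrix, conn: ConnectivityMatrix, config: InferenceConfig
) -> ModelState:
    """Deterministic-given-seed starting point for EM.

    The baseline takes the per-gene sample mean, the noise variance the
    overall residual variance around it, and concentrations start at
    standard-normal draws so the first E-step sees a full-rank design.
    """
    _check_aligned(expr, conn)
    if expr.n_samples < 1:
        raise ValidationError("expression matrix has no samples")
    if conn.n_tfs < 1:
        raise ValidationError("connectivity matrix has no TFs")
    E = np.array(expr.values, dtype=float)
    T = conn.entries.astype(float)
    mu = E.mean(axis=1)
    resid = E - mu[:, None]
    sigma2 = max(float(np.mean(resid**2)), config.min_sigma2)
    rng = np.random.default_rng(config.seed)
    c = rng.standard_normal((conn.n_tfs, expr.n_samples))
    support = [np.nonzero(T[g])[0] for g in range(E.shape[0])]
    by_k: dict[int, list[int]] = {}
    for g, idx in enumerate(support):
        if idx.size:
            by_k.setdefault(idx.size, []).append(g)
    groups = [
        _SupportGroup(
            k=k,
            genes=np.array(genes, dtype=int),
            idx=np.stack([support[g] for g in genes]),
        )
        for k, genes in sorted(by_k.items())
    ]
    return ModelState(
        E=E, T=T, support=support, groups=groups, c=c, mu=mu, sigma2=sigma2, config=config
    )


def e_step(state: ModelState) -> ModelState:
    """Exact per-gene Gaussian posterior over the connected weights.

    For gene g with connected TF set F_g, the design is X = c[F_g]^T
    (samples x |F_g|) and the posterior is

        Sigma_g = (X^T X / sigma^2 + I / alpha)^-1
        m_g     = Sigma_g X^T (e_g - mu_g) / sigma^2

    The prior term makes the precision positive definite for any design,
    including duplicate samples and more TFs than samples.  The moments
    are computed through a batched SVD of the design rather than by
    factorizing the precision matrix: each spectral direction is
    regularized and inverted separately, which stays accurate even when
    the noise variance sits at its floor and the precision is extremely
    ill-conditioned (e.g. noiseless data, or a single sample).
    """
    alpha = state.config.prior_variance
    s2 = state.sigma2
    G, F = state.n_genes, state.n_tfs
    S = state.n_samples
    W_mean = np.zeros((G, F))
    W_cov: list[np.ndarray] = []
    W_logdet = np.zeros(G)
    R = state.E - state.mu[:, None]
    for grp in state.groups:
        X = state.c[grp.idx, :].transpose(0, 2, 1)   # (n, S, k) design per gene
        try:
            U, d, Vh = np.linalg.svd(X)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - svd rarely fails
            raise ComputationError(
                f"SVD of the E-step design failed (support size {grp.k})"
            ) from exc
        r = min(S, grp.k)
        d2 = np.zeros((len(grp.genes), grp.k))
        d2[:, :r] = d * d
        # posterior eigenvalues s2*a / (a d^2 + s2); zero modes revert to the prior
        eig = s2 * alpha / (alpha * d2 + s2)
        V = Vh.transpose(0, 2, 1)
        Sigma = (V * eig[:, None, :]) @ Vh
        Ur = np.einsum("nsj,ns->nj", U[:, :, :r], R[grp.genes])
        coef = np.zeros((len(grp.genes), grp.k))
        coef[:, :r] = alpha * d * Ur / (alpha * d * d + s2)
        mean = np.einsum("nkj,nj->nk", V, coef)
        W_mean[grp.genes[:, None], grp.idx] = mean
        W_cov.append(Sigma)
        W_logdet[grp.genes] = np.log(eig).sum(axis=1)
    state.W_mean = W_mean
    state.W_cov = W_cov
    state.W_logdet = W_logdet
    return state


def m_step(state: ModelState) -> ModelState:
    """Closed-form parameter updates given the W posterior moments.

    ``c`` solves one generalized-least-squares system shared by all
    samples, with the per-gene second moment E[w_g w_g^T] = Sigma_g +
    m_g m_g^T scattered into TF coordinates; ``mu`` re-centers the
    residual; ``sigma^2`` absorbs both the squared residual and the
    posterior W variance.  Each update is a coordinate ascent step of the
    EM bound, so the bound stays monotone.
    """
    if state.W_mean is None or state.W_cov is None:
        raise ComputationError("m_step called before e_step")
    G, F, S = state.n_genes, state.n_tfs, state.n_samples

    A = np.zeros((F, F))
    for grp, Sigma in zip(state.groups, state.W_cov):
        m = state.W_mean[grp.genes[:, None], grp.idx]
        contrib = Sigma + m[:, :, None] * m[:, None, :]
        np.add.at(A, (grp.idx[:, :, None], grp.idx[:, None, :]), contrib)
    B = state.W_mean.T @ (state.E - state.mu[:, None])
    try:
        cf = cho_factor(A, lower=True)
        state.c = cho_solve(cf, B)
    except LinAlgError as exc:
        raise ComputationError("concentration update system not positive definite") from exc

    fit = state.W_mean @ state.c
    state.mu = (state.E - fit).mean(axis=1)
    state.sigma2 = max(_expected_sse(state) / (G * S), state.config.min_sigma2)
    return state


def _expected_sse(state: ModelState) -> float:
    """E[sum of squared residuals] under the W posterior."""
    fit = state.W_mean @ state.c
    resid = state.E - state.mu[:, None] - fit
    sse = float(np.sum(resid**2))
    for grp, Sigma in zip(state.groups, state.W_cov):
        Cg = state.c[grp.idx, :]                     # (n, k, S)
        sse += float(np.einsum("nij,nis,njs->", Sigma, Cg, Cg))
    return sse


def objective(state: ModelState) -> float:
    """EM lower bound: expected complete-data log-likelihood + W entropy."""
    if state.W_mean is None or state.W_cov is None:
        raise ComputationError("objective requires posterior W moments (run e_step)")
    alpha = state.config.prior_variance
    G, S = state.n_genes, state.n_samples
    n_connected = sum(idx.size for idx in state.support)

    ll = -0.5 * G * S * (_LOG2PI + np.log(state.sigma2))
    ll -= _expected_sse(state) / (2.0 * state.sigma2)

    ew2 = float(np.sum(state.W_mean**2)) + sum(
        float(np.trace(S_g, axis1=1, axis2=2).sum()) for S_g in state.W_cov
    )
    ll -= 0.5 * n_connected * (_LOG2PI + np.log(alpha)) + ew2 / (2.0 * alpha)

    entropy = 0.5 * n_connected * (1.0 + _LOG2PI) + 0.5 * float(state.W_logdet.sum())
    return float(ll + entropy)


def _fix_signs(W_mean: np.ndarray, c: np.ndarray) -> None:
    """Resolve the per-TF sign gauge: mean concentration >= 0, in place."""
    flip = c.mean(axis=1) < 0
    c[flip, :] *= -1.0
    W_mean[:, flip] *= -1.0


def _fix_mean_gauge(W_mean: np.ndarray, c: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Resolve the baseline/concentration mean gauge.

    A constant shift ``d`` of the concentration rows compensated by
    ``mu -> mu - W d`` leaves the likelihood unchanged, so the data do
    not determine the mean of ``c``.  The convention adopted here
    attributes every part of the baseline explicable through the
    regulatory directions to the TFs: ``d = argmin ||mu - W d||`` via
    least squares, after which the reported baseline is orthogonal to
    the columns of ``W``.  Returns the re-gauged baseline.
    """
    if W_mean.shape[1] == 0:
        return mu
    d, *_ = np.linalg.lstsq(W_mean, mu, rcond=None)
    c += d[:, None]
    return mu - W_mean @ d


def infer(
    expr: ExpressionMatrix,
    conn: ConnectivityMatrix,
    config: InferenceConfig | None = None,
) -> InferenceResult:
    """Fit the bilinear model to one dataset by EM.

    Callers run this once per condition (e.g. wild-type and knock-out at
    each time point) and compare the resulting fits downstream.
    Non-convergence within ``max_iterations`` is reported via the
    ``converged`` flag and a warning, not an error.
    """
    config = config or InferenceConfig()
    state = initialize_state(expr, conn, config)
    trace: list[float] = []
    converged = False
    for _ in range(config.max_iterations):
        e_step(state)
        m_step(state)
        obj = objective(state)
        if trace:
            prev = trace[-1]
            if abs(obj - prev) < config.tolerance * max(abs(prev), 1.0):
                trace.append(obj)
                converged = True
                break
        trace.append(obj)
    if not converged:
        logger.warning(
            "EM did not converge in %d iterations (last relative change %.3g)",
            config.max_iterations,
            abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1.0) if len(trace) > 1 else np.nan,
        )

    # final E-step so reported W moments match the final parameters
    e_step(state)
    W_var = np.zeros_like(state.W_mean)
    for grp, Sigma in zip(state.groups, state.W_cov):
        W_var[grp.genes[:, None], grp.idx] = np.diagonal(Sigma, axis1=1, axis2=2)
    W_mean = state.W_mean.copy()
    c = state.c.copy()
    mu = _fix_mean_gauge(W_mean, c, state.mu.copy())
    _fix_signs(W_mean, c)

    return InferenceResult(
        gene_ids=list(expr.gene_ids),
        tf_ids=list(conn.tf_ids),
        sample_ids=list(expr.sample_ids),
        W_mean=W_mean,
        W_var=W_var,
        c=c,
        mu=mu,
        sigma2=state.sigma2,
        objective_trace=np.array(trace),
        converged=converged,
        config=replace(config),
        label=expr.label,
    )
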