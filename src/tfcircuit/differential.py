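"""Differential analysis of TF activity between two conditions.

The quantity compared is the concentration-normalized activity
``A_gf = |W_gf / c_f|`` on the binding support, so that flagged changes
reflect a shift in how strongly a TF acts on a gene beyond any shift in
the TF's abundance.  The difference ``D = A_ref - A_alt`` is thresholded
at ``k`` sample standard deviations of its support entries (k = 2 by
default, i.e. the 95% band of a Gaussian): a pair is significant iff
``|D_gf| > cutoff``.  ``D > 0`` means the interaction is stronger in the
reference (wild-type) condition — labeled "Down" (down-regulated after
the perturbation); ``D < 0`` is labeled "Up".

TF-level calls use the same k-SD idea applied to per-TF summaries (mean
absolute weight ``S_f`` for activity, mean concentration for abundance),
centered on the median difference so a few strongly responding TFs do not
shift the reference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import ConnectivityMatrix
from .inference import InferenceResult

REGULATION_DOWN = "Down"   # stronger in reference / wild-type
REGULATION_UP = "Up"       # stronger in alternate / knock-out


@dataclass
class NormalizedActivity:
    """|W/c| on the binding support; zero elsewhere."""

    gene_ids: list[str]
    tf_ids: list[str]
    A: np.ndarray
    label: str = ""
    epsilon: float = 1e-6
    clamped_tfs: list[str] = field(default_factory=list)


@dataclass
class FlaggedPair:
    gene_id: str
    tf_id: str
    difference: float
    regulation: str


@dataclass
class DifferentialResult:
    gene_ids: list[str]
    tf_ids: list[str]
    D: np.ndarray
    cutoff: float
    k: float
    epsilon: float
    flagged_pairs: list[FlaggedPair]
    S_ref: np.ndarray
    S_alt: np.ndarray
    c_ref: np.ndarray
    c_alt: np.ndarray
    flagged_tfs_activity: dict[str, str]
    flagged_tfs_concentration: dict[str, str]
    ref_label: str = ""
    alt_label: str = ""

    @property
    def flagged_genes(self) -> list[str]:
        """Genes with at least one significant pair, sorted."""
        return sorted({p.gene_id for p in self.flagged_pairs})


def normalized_activity(
    W: np.ndarray,
    c_summary: np.ndarray,
    conn: ConnectivityMatrix,
    epsilon: float = 1e-6,
    label: str = "",
) -> NormalizedActivity:
    """Scale each TF's weights by its summary concentration.

    TFs whose |concentration| falls below ``epsilon`` are clamped to the
    floor (the ratio is otherwise unbounded) and reported.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    W = np.asarray(W, dtype=float)
    c_summary = np.asarray(c_summary, dtype=float)
    if W.shape != conn.entries.shape or c_summary.shape != (conn.n_tfs,):
        raise ValidationError("W / c_summary dimensions do not match the connectivity matrix")
    denom = np.maximum(np.abs(c_summary), epsilon)
    clamped = [t for t, c in zip(conn.tf_ids, c_summary) if abs(c) < epsilon]
    A = np.abs(W) / denom[None, :]
    A = np.where(conn.entries == 1, A, 0.0)
    return NormalizedActivity(
        gene_ids=list(conn.gene_ids),
        tf_ids=list(conn.tf_ids),
        A=A,
        label=label,
        epsilon=epsilon,
        clamped_tfs=clamped,
    )


def activity_difference(A_ref: NormalizedActivity, A_alt: NormalizedActivity) -> np.ndarray:
    """Entrywise reference-minus-alternate normalized activity."""
    if A_ref.gene_ids != A_alt.gene_ids or A_ref.tf_ids != A_alt.tf_ids:
        raise ValidationError("normalized activities live on different gene/TF universes")
    return A_ref.A - A_alt.A


def significance_cutoff(D: np.ndarray, conn: ConnectivityMatrix, k: float = 2.0) -> float:
    """``k`` sample standard deviations of the support entries of D.

    Structural zeros off the binding support are excluded so sparsity
    does not deflate the spread estimate.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    support = np.asarray(D, dtype=float)[conn.entries == 1]
    if support.size < 2:
        raise ValidationError("need at least 2 support entries to estimate a cutoff")
    return float(k * np.std(support, ddof=1))


def flag_interactions(
    D: np.ndarray, conn: ConnectivityMatrix, cutoff: float
) -> list[FlaggedPair]:
    """Pairs with |difference| strictly above the cutoff, with regulation labels."""
    if cutoff < 0:
        raise ValidationError("cutoff must be non-negative")
    D = np.asarray(D, dtype=float)
    rows, cols = np.nonzero((np.abs(D) > cutoff) & (conn.entries == 1))
    return [
        FlaggedPair(
            gene_id=conn.gene_ids[g],
            tf_id=conn.tf_ids[f],
            difference=float(D[g, f]),
            regulation=REGULATION_DOWN if D[g, f] > 0 else REGULATION_UP,
        )
        for g, f in zip(rows, cols)
    ]


def average_strength(W: np.ndarray, conn: ConnectivityMatrix) -> np.ndarray:
    """Mean absolute interaction weight of each TF over its targets, S_f."""
    W = np.asarray(W, dtype=float)
    if W.shape != conn.entries.shape:
        raise ValidationError("W dimensions do not match the connectivity matrix")
    n_targets = conn.entries.sum(axis=0)
    if np.any(n_targets == 0):
        bad = [t for t, n in zip(conn.tf_ids, n_targets) if n == 0]
        raise ValidationError(f"TF(s) with no targets: {bad} (drop them at alignment)")
    return np.abs(W * conn.entries).sum(axis=0) / n_targets


def flag_tfs(
    tf_ids: list[str],
    v_ref: np.ndarray,
    v_alt: np.ndarray,
    k: float = 2.0,
) -> dict[str, str]:
    """TFs whose summary change is an outlier among all TFs.

    The per-TF difference ``delta = v_ref - v_alt`` is compared against a
    band of ``k`` sample SDs centered on the *median* delta.  A flagged TF
    above the median is "Down" (stronger in the reference), below is "Up".
    """
    v_ref = np.asarray(v_ref, dtype=float)
    v_alt = np.asarray(v_alt, dtype=float)
    if len(tf_ids) < 3:
        raise ValidationError("need at least 3 TFs to flag outliers")
    if v_ref.shape != (len(tf_ids),) or v_alt.shape != (len(tf_ids),):
        raise ValidationError("summary vectors do not match the TF universe")
    delta = v_ref - v_alt
    med = float(np.median(delta))
    sd = float(np.std(delta, ddof=1))
    flags: dict[str, str] = {}
    for tf, d in zip(tf_ids, delta):
        if abs(d - med) > k * sd:
            flags[tf] = REGULATION_DOWN if d > med else REGULATION_UP
    return flags


def compare(
    ref: InferenceResult,
    alt: InferenceResult,
    conn: ConnectivityMatrix,
    k: float = 2.0,
    epsilon: float = 1e-6,
) -> DifferentialResult:
    """Full two-condition differential analysis.

    Combines normalized-activity differencing with pair- and TF-level
    flagging.  ``ref`` is conventionally the wild-type fit and ``alt`` the
    perturbed (e.g. knock-out) fit.
    """
    if ref.tf_ids != alt.tf_ids or ref.gene_ids != alt.gene_ids:
        raise ValidationError("reference and alternate fits live on different universes")
    if ref.gene_ids != conn.gene_ids or ref.tf_ids != conn.tf_ids:
        raise ValidationError("fits are not aligned with the connectivity matrix")

    A_ref = normalized_activity(ref.W_mean, ref.c_summary, conn, epsilon, label=ref.label)
    A_alt = normalized_activity(alt.W_mean, alt.c_summary, conn, epsilon, label=alt.label)
    D = activity_difference(A_ref, A_alt)
    cutoff = significance_cutoff(D, conn, k=k)
    pairs = flag_interactions(D, conn, cutoff)

    S_ref = average_strength(ref.W_mean, conn)
    S_alt = average_strength(alt.W_mean, conn)
    return DifferentialResult(
        gene_ids=list(conn.gene_ids),
        tf_ids=list(conn.tf_ids),
        D=D,
        cutoff=cutoff,
        k=k,
        epsilon=epsilon,
        flagged_pairs=pairs,
        S_ref=S_ref,
        S_alt=S_alt,
        c_ref=ref.c_summary.copy(),
        c_alt=alt.c_summary.copy(),
        flagged_tfs_activity=flag_tfs(conn.tf_ids, S_ref, S_alt, k=k),
        flagged_tfs_concentration=flag_tfs(conn.tf_ids, ref.c_summary, alt.c_summary, k=k),
        ref_label=ref.label,
        alt_label=alt.label,
    )
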