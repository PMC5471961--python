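"""Result persistence and end-to-end orchestration.

``run_pipeline`` wires the stages together for one two-condition
contrast: read and align inputs, fit each condition by EM, run the
differential analysis, render the three figures, and leave a manifest of
every artifact with its SHA-256 checksum plus the fully resolved
configuration, so any number in any output table can be traced back to
the exact parameters and seeds that produced it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from ._version import __version__
from .errors import TFCircuitError, ValidationError
from .inference import InferenceConfig, InferenceResult, infer
from .io import (
    TFAnnotation,
    align_inputs,
    read_annotation,
    read_connectivity,
    read_expression,
    read_matrix,
    write_matrix,
)
from .viz import PlotSpec, change_heatmap, limpet_plot, strength_plot

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# persistence


def save_inference(result: InferenceResult, prefix) -> dict[str, str]:
    """Write W/Wvar/c/mu tables and a metadata document under a prefix."""
    prefix = str(prefix)
    paths = {
        "W": f"{prefix}.W.tsv",
        "Wvar": f"{prefix}.Wvar.tsv",
        "c": f"{prefix}.c.tsv",
        "mu": f"{prefix}.mu.tsv",
        "meta": f"{prefix}.meta.yaml",
    }
    write_matrix(result.W_mean, result.gene_ids, result.tf_ids, paths["W"], kind="W")
    write_matrix(result.W_var, result.gene_ids, result.tf_ids, paths["Wvar"], kind="Wvar")
    write_matrix(result.c, result.tf_ids, result.sample_ids, paths["c"], kind="c")
    write_matrix(
        np.asarray(result.mu)[:, None], result.gene_ids, ["mu"], paths["mu"], kind="mu"
    )
    meta = {
        "tool": f"tfcircuit {__version__}",
        "label": result.label,
        "sigma2": float(result.sigma2),
        "converged": bool(result.converged),
        "n_iterations": int(len(result.objective_trace)),
        "objective_trace": [float(x) for x in result.objective_trace],
        "config": asdict(result.config),
    }
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths


def load_inference(prefix) -> InferenceResult:
    prefix = str(prefix)
    W = read_matrix(f"{prefix}.W.tsv")
    Wvar = read_matrix(f"{prefix}.Wvar.tsv")
    c = read_matrix(f"{prefix}.c.tsv")
    mu = read_matrix(f"{prefix}.mu.tsv")
    with open(f"{prefix}.meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    return InferenceResult(
        gene_ids=[str(g) for g in W.index],
        tf_ids=[str(t) for t in W.columns],
        sample_ids=[str(s) for s in c.columns],
        W_mean=W.to_numpy(),
        W_var=Wvar.to_numpy(),
        c=c.to_numpy(),
        mu=mu.to_numpy()[:, 0],
        sigma2=float(meta["sigma2"]),
        objective_trace=np.asarray(meta["objective_trace"], dtype=float),
        converged=bool(meta["converged"]),
        config=InferenceConfig(**meta["config"]),
        label=str(meta.get("label", "")),
    )


def save_differential(result: diff.DifferentialResult, prefix) -> dict[str, str]:
    """Write D, flagged pairs, per-TF summary/flags and metadata."""
    prefix = str(prefix)
    paths = {
        "D": f"{prefix}.D.tsv",
        "pairs": f"{prefix}.pairs.tsv",
        "tf_flags": f"{prefix}.tf_flags.tsv",
        "meta": f"{prefix}.meta.yaml",
    }
    write_matrix(result.D, result.gene_ids, result.tf_ids, paths["D"], kind="D")
    pairs = pd.DataFrame(
        [(p.gene_id, p.tf_id, p.difference, p.regulation) for p in result.flagged_pairs],
        columns=["gene_id", "tf_id", "difference", "regulation"],
    )
    with open(paths["pairs"], "w") as fh:
        fh.write(f"# tfcircuit {__version__} pairs cutoff={result.cutoff!r}\n")
        pairs.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    flags = pd.DataFrame(
        {
            "tf_id": result.tf_ids,
            "S_ref": result.S_ref,
            "S_alt": result.S_alt,
            "c_ref": result.c_ref,
            "c_alt": result.c_alt,
            "activity_flag": [
                result.flagged_tfs_activity.get(t, "") for t in result.tf_ids
            ],
            "concentration_flag": [
                result.flagged_tfs_concentration.get(t, "") for t in result.tf_ids
            ],
        }
    )
    with open(paths["tf_flags"], "w") as fh:
        fh.write(f"# tfcircuit {__version__} tf_flags\n")
        flags.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    meta = {
        "tool": f"tfcircuit {__version__}",
        "ref_label": result.ref_label,
        "alt_label": result.alt_label,
        "cutoff": float(result.cutoff),
        "k": float(result.k),
        "epsilon": float(result.epsilon),
        "n_flagged_pairs": len(result.flagged_pairs),
        "flagged_tfs_activity": dict(result.flagged_tfs_activity),
        "flagged_tfs_concentration": dict(result.flagged_tfs_concentration),
    }
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths


def load_differential(prefix) -> diff.DifferentialResult:
    prefix = str(prefix)
    D = read_matrix(f"{prefix}.D.tsv")
    pairs_df = pd.read_csv(f"{prefix}.pairs.tsv", sep="\t", comment="#")
    flags_df = pd.read_csv(f"{prefix}.tf_flags.tsv", sep="\t", comment="#")
    with open(f"{prefix}.meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    pairs = [
        diff.FlaggedPair(str(r.gene_id), str(r.tf_id), float(r.difference), str(r.regulation))
        for r in pairs_df.itertuples()
    ]
    return diff.DifferentialResult(
        gene_ids=[str(g) for g in D.index],
        tf_ids=[str(t) for t in D.columns],
        D=D.to_numpy(),
        cutoff=float(meta["cutoff"]),
        k=float(meta["k"]),
        epsilon=float(meta["epsilon"]),
        flagged_pairs=pairs,
        S_ref=flags_df["S_ref"].to_numpy(dtype=float),
        S_alt=flags_df["S_alt"].to_numpy(dtype=float),
        c_ref=flags_df["c_ref"].to_numpy(dtype=float),
        c_alt=flags_df["c_alt"].to_numpy(dtype=float),
        flagged_tfs_activity=dict(meta.get("flagged_tfs_activity", {})),
        flagged_tfs_concentration=dict(meta.get("flagged_tfs_concentration", {})),
        ref_label=str(meta.get("ref_label", "")),
        alt_label=str(meta.get("alt_label", "")),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    expression_ref: str
    expression_alt: str
    connectivity: str
    output_dir: str
    dialect: str = "matrix"
    annotation: str | None = None
    ref_label: str = "ref"
    alt_label: str = "alt"
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    k_sd: float = 2.0
    epsilon: float = 1e-6
    plot: PlotSpec = field(default_factory=PlotSpec)

    def validate(self) -> None:
        for name in ("expression_ref", "expression_alt", "connectivity"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise ValidationError(f"{name} file does not exist: {path}")
        if self.annotation is not None and not Path(self.annotation).is_file():
            raise ValidationError(f"annotation file does not exist: {self.annotation}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def load_run_config(path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML document; keyword overrides win."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    doc.update({k: v for k, v in overrides.items() if v is not None})
    inference = InferenceConfig(**doc.pop("inference", {}))
    plot = PlotSpec(**doc.pop("plot", {}))
    try:
        return RunConfig(inference=inference, plot=plot, **doc)
    except TypeError as exc:
        raise ValidationError(f"bad run config: {exc}") from None


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute infer (per condition) -> compare -> plots; return the manifest.

    On a stage failure the partial manifest is still written with a
    FAILED marker before the error propagates.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": f"tfcircuit {__version__}",
        "config": config.to_dict(),
        "status": "FAILED",
        "files": {},
    }
    artifacts: dict[str, str] = {}

    def finish() -> None:
        manifest["files"] = {k: {"path": v, "sha256": _sha256(v)} for k, v in artifacts.items()}
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    try:
        expr_ref = read_expression(config.expression_ref, label=config.ref_label)
        expr_alt = read_expression(config.expression_alt, label=config.alt_label)
        conn_raw = read_connectivity(config.connectivity, dialect=config.dialect)
        annotation = read_annotation(config.annotation) if config.annotation else TFAnnotation()

        expr_ref, conn, report = align_inputs(expr_ref, conn_raw)
        expr_alt, conn_alt, _ = align_inputs(expr_alt, conn_raw)
        if conn_alt.tf_ids != conn.tf_ids or conn_alt.gene_ids != conn.gene_ids:
            raise ValidationError(
                "the two expression files cover different gene universes; "
                "restrict them to common genes first"
            )
        manifest["alignment"] = {
            "n_genes": report.n_genes,
            "n_tfs": report.n_tfs,
            "dropped_tfs": report.dropped_tfs,
            "n_dropped_expression_genes": len(report.dropped_expression_genes),
            "n_dropped_connectivity_genes": len(report.dropped_connectivity_genes),
        }

        fits: dict[str, InferenceResult] = {}
        for tag, expr in (("ref", expr_ref), ("alt", expr_alt)):
            fit = infer(expr, conn, config.inference)
            fits[tag] = fit
            artifacts.update(
                {f"{tag}.{k}": v for k, v in save_inference(fit, out / tag).items()}
            )
            logger.info(
                "inferred %s: sigma2=%.4g converged=%s iterations=%d",
                tag, fit.sigma2, fit.converged, len(fit.objective_trace),
            )

        result = diff.compare(
            fits["ref"], fits["alt"], conn, k=config.k_sd, epsilon=config.epsilon
        )
        artifacts.update(
            {f"compare.{k}": v for k, v in save_differential(result, out / "compare").items()}
        )
        logger.info(
            "cutoff=%.4g flagged pairs=%d activity TFs=%s concentration TFs=%s",
            result.cutoff,
            len(result.flagged_pairs),
            sorted(result.flagged_tfs_activity),
            sorted(result.flagged_tfs_concentration),
        )

        ext = config.plot.output_format
        limpet = out / f"limpet.{ext}"
        limpet_plot(result, annotation, config.plot, limpet)
        strength = out / f"strength.{ext}"
        strength_plot(
            result.tf_ids, result.S_ref, result.S_alt, config.k_sd,
            annotation, config.plot, strength,
        )
        heat = out / f"heatmap.{ext}"
        matrix = np.column_stack([result.S_ref, result.S_alt, result.c_ref, result.c_alt])
        labels = [
            f"S {config.ref_label}", f"S {config.alt_label}",
            f"c {config.ref_label}", f"c {config.alt_label}",
        ]
        change_heatmap(matrix, result.tf_ids, labels, annotation, config.plot, heat)
        artifacts.update(
            {"plot.limpet": str(limpet), "plot.strength": str(strength), "plot.heatmap": str(heat)}
        )

        manifest["status"] = "OK"
        manifest["summary"] = {
            "cutoff": float(result.cutoff),
            "n_flagged_pairs": len(result.flagged_pairs),
            "flagged_tfs_activity": dict(result.flagged_tfs_activity),
            "flagged_tfs_concentration": dict(result.flagged_tfs_concentration),
            "seed": config.inference.seed,
        }
        finish()
        return manifest
    except TFCircuitError:
        finish()
        raise
    except Exception:  # keep the partial manifest on unexpected failures too
        finish()
        raise
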