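"""End-to-end pipeline configuration and orchestration.

``PipelineConfig`` gathers every stage parameter with defaults equal to
the study constants the package implements: DMP |Δβ| ≥ 0.2 with normal
mean β ≤ 0.1 at FDR 0.01, 1000-repeat 70/30 LASSO weight scoring,
100-repeat logistic ROC, and the three cutoff sets
(45/38/40 with the two-gene ΔCT < 10 rule; 45/38/43 with ΔCT < 15;
40.67/36.8/36.23) with ACTB validity at CT ≤ 40.

``run_pipeline`` runs simulate → discover → call → evaluate, writes all
stage outputs as TSV, and records a manifest (config hash, seed,
package versions) so a rerun with the same config is bit-identical for
the seeded stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, calling, discovery, io, performance, simulate

logger = logging.getLogger("methylpanel")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


def _check(condition: bool, name: str, message: str) -> None:
    if not condition:
        raise ValueError(f"invalid {name}: {message}")


@dataclass
class PipelineConfig:
    """All stage parameters of the end-to-end synthetic pipeline."""

    seed: int = 0
    # tissue generator (overrides onto TissueSimSpec defaults)
    tissue: dict = field(default_factory=dict)
    # qPCR generator: the "a2_like" preset plus overrides
    qpcr: dict = field(default_factory=dict)
    # discovery
    delta_cutoff: float = 0.2
    control_cutoff: float = 0.1
    fdr_level: float = 0.01
    lasso_repeats: int = 1000
    train_fraction: float = 0.7
    # calling
    algorithm: str = "balancing"
    include_alx4: bool = True
    # performance
    roc_repeats: int = 100
    ct_ceiling: float = 50.0
    ci_method: str = "wilson_cc"

    def __post_init__(self) -> None:
        _check(0 <= self.seed < 2**31, "seed", "must be a nonnegative 31-bit integer")
        _check(0 < self.delta_cutoff <= 1, "delta_cutoff", "must be in (0, 1]")
        _check(0 <= self.control_cutoff <= 1, "control_cutoff", "must be in [0, 1]")
        _check(0 < self.fdr_level < 1, "fdr_level", "must be in (0, 1)")
        _check(self.lasso_repeats >= 1, "lasso_repeats", "must be ≥ 1")
        _check(0 < self.train_fraction < 1, "train_fraction", "must be in (0, 1)")
        _check(
            self.algorithm in calling.CUTOFF_PRESETS,
            "algorithm",
            f"must be one of {sorted(calling.CUTOFF_PRESETS)}",
        )
        _check(self.roc_repeats >= 1, "roc_repeats", "must be ≥ 1")
        _check(self.ct_ceiling > 0, "ct_ceiling", "must be positive")
        _check(
            self.ci_method in ("wilson_cc", "wilson", "clopper_pearson", "wald"),
            "ci_method",
            "unknown CI method",
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; missing keys take the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic pipeline and write a report bundle.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: tissue simulation + discovery ---------------------------
    tissue_spec = simulate.TissueSimSpec(**{"seed": config.seed, **config.tissue})
    cohort = simulate.simulate_tissue_cohort(tissue_spec)
    io.write_matrix(cohort.meth, out / "methylation.tsv")
    io.write_matrix(cohort.expr, out / "expression.tsv")
    io.write_labels(cohort.labels, out / "tissue_labels.tsv")
    cohort.probe_to_gene.rename("gene_id").rename_axis("probe_id").to_frame().reset_index().to_csv(
        out / "probe_to_gene.tsv", sep="\t", index=False
    )

    dmp = discovery.compute_dmp(
        cohort.meth,
        cohort.labels,
        delta_cutoff=config.delta_cutoff,
        control_cutoff=config.control_cutoff,
        fdr_level=config.fdr_level,
    )
    deg = discovery.compute_deg(cohort.expr, cohort.labels, fdr_level=config.fdr_level)
    corr = discovery.correlate_meth_expr(
        cohort.meth, cohort.expr, cohort.probe_to_gene, labels=cohort.labels
    )
    candidates = discovery.select_candidates(dmp, deg, corr, cohort.probe_to_gene)
    dmp.to_csv(out / "dmp.tsv", sep="\t", index=False)
    deg.to_csv(out / "deg.tsv", sep="\t", index=False)
    corr.to_csv(out / "correlation.tsv", sep="\t", index=False)
    logger.info("discovery: %d DMPs, %d DEGs, %d candidates",
                int(dmp["significant"].sum()), int(deg["significant"].sum()), len(candidates))

    if candidates:
        # feature per candidate gene: its representative probe's beta values
        rep_probe = corr.set_index("gene_id")["probe_id"].reindex(candidates)
        features = cohort.meth.loc[rep_probe].T
        features.columns = candidates
        scores, lasso_report = discovery.lasso_weight_scoring(
            features,
            (cohort.labels == "tumor").astype(int).to_numpy(),
            n_repeats=config.lasso_repeats,
            train_fraction=config.train_fraction,
            seed=config.seed,
        )
        scores.to_csv(out / "weight_scores.tsv", sep="\t", index=False)
    else:
        lasso_report = {"note": "no candidate genes; weight scoring skipped"}
    (out / "candidates.txt").write_text("\n".join(candidates) + ("\n" if candidates else ""))

    # --- stage 2: qPCR simulation + calling + evaluation ------------------
    qpcr_spec = simulate.a2_like_spec(seed=config.seed, **config.qpcr)
    wells = simulate.simulate_qpcr_cohort(qpcr_spec)
    io.write_well_table(wells, out / "wells.tsv")

    calls = calling.call_cohort(
        wells, algorithm=config.algorithm, include_alx4=config.include_alx4
    )
    io.write_calls(calls, out / "calls.tsv")
    summary = performance.confusion_summary(calls, ci_method=config.ci_method)
    summary.to_frame().to_csv(out / "performance.tsv", sep="\t", index=False)
    logger.info(
        "calling (%s): sensitivity %.1f%%, specificity %.1f%%, PL %.1f%%, "
        "accuracy %.1f%% (%d invalid)",
        config.algorithm,
        summary.sensitivity.percent,
        summary.specificity.percent,
        summary.pl_detection.percent,
        summary.accuracy.percent,
        summary.n_invalid,
    )

    # marker-removal comparison
    calls_no_alx4 = calling.call_cohort(wells, algorithm=config.algorithm, include_alx4=False)
    summary_no_alx4 = performance.confusion_summary(calls_no_alx4, ci_method=config.ci_method)
    comparison = pd.concat(
        [
            summary.to_frame().assign(variant="mALX4 present"),
            summary_no_alx4.to_frame().assign(variant="mALX4 absent"),
        ],
        ignore_index=True,
    )
    comparison.to_csv(out / "alx4_comparison.tsv", sep="\t", index=False)

    # duplicate concordance on single-well calls
    per_well = calling.single_well_calls(wells, config.algorithm)
    kappa = performance.cohens_kappa(per_well[1], per_well[2])

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_candidates": len(candidates),
        "lasso": lasso_report,
        "performance": {
            "sensitivity_percent": round(summary.sensitivity.percent, 1),
            "specificity_percent": round(summary.specificity.percent, 1),
            "pl_detection_percent": round(summary.pl_detection.percent, 1),
            "accuracy_percent": round(summary.accuracy.percent, 1),
            "n_invalid": summary.n_invalid,
        },
        "duplicate_kappa": round(kappa.kappa, 3),
        "duplicate_agreement": round(kappa.observed_agreement, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
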