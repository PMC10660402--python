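"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators:

* :func:`simulate_tissue_cohort` — a tumor/normal tissue cohort of
  450K-style methylation beta values and RSEM-scale expression, with a
  configurable number of planted informative markers: probes
  hypermethylated in tumors (normal mean at a low control level, tumor
  mean shifted up by a Δβ effect) whose paired genes are down- (or up-)
  regulated and negatively correlated with methylation through a
  Gaussian copula.
* :func:`simulate_qpcr_cohort` — a plasma qPCR cohort (CRC / PL / NED
  subjects, duplicate wells) where each marker channel of each well is
  methylation-positive with a group- and gene-specific probability,
  drawing a finite CT when positive and the undetermined sentinel when
  not; the ACTB internal control is drawn independently per well, and a
  configurable fraction of wells is made invalid (ACTB above the
  validity cutoff).

Both generators are fully determined by their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .calling import ACTB, GENES

__all__ = [
    "TissueSimSpec",
    "QpcrSimSpec",
    "TissueCohort",
    "simulate_tissue_cohort",
    "simulate_qpcr_cohort",
    "a2_like_spec",
    "A2_OPERATING_POINT",
]


def _check(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ValueError(f"invalid {fieldname}: {message}")


@dataclass(frozen=True)
class TissueSimSpec:
    """Parameters of the tissue-cohort generator.

    Defaults emulate a TCGA-like colorectal cohort: many more tumors
    than adjacent normals, a small set of strongly hypermethylated
    informative probes on a low normal-tissue background, and
    moderately dispersed beta values.
    """

    n_tumor: int = 396
    n_normal: int = 35
    n_probes: int = 1000
    n_informative: int = 10
    delta_beta_effect: float = 0.45
    control_beta_level: float = 0.05
    beta_concentration: float = 30.0
    expr_effect_log2fc: float = -2.0
    meth_expr_coupling: float = -0.7
    expr_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_probes"):
            _check(getattr(self, name) >= 1, name, "must be ≥ 1")
        _check(0 <= self.n_informative <= self.n_probes, "n_informative",
               "must lie in [0, n_probes]")
        _check(0 < self.delta_beta_effect <= 1, "delta_beta_effect", "must be in (0, 1]")
        _check(0 <= self.control_beta_level < 1, "control_beta_level", "must be in [0, 1)")
        _check(self.beta_concentration > 0, "beta_concentration", "must be positive")
        _check(-1 <= self.meth_expr_coupling <= 0, "meth_expr_coupling",
               "must be in [-1, 0]")
        _check(self.expr_log2_sd > 0, "expr_log2_sd", "must be positive")


@dataclass
class TissueCohort:
    """Generated tissue cohort: matrices, labels, map and ground truth."""

    meth: pd.DataFrame  # probes × samples, beta values in [0, 1]
    expr: pd.DataFrame  # genes × samples, nonnegative RSEM scale
    labels: pd.Series  # sample -> "tumor" | "normal"
    probe_to_gene: pd.Series  # probe -> gene
    informative: pd.Series  # probe -> bool ground truth


def _beta_from_normal(u: np.ndarray, mean: np.ndarray, concentration: float) -> np.ndarray:
    """Map standard-normal draws through a Beta(mean·c, (1−mean)·c) quantile."""
    eps = 1e-6
    mean = np.clip(mean, eps, 1 - eps)
    a = mean * concentration
    b = (1 - mean) * concentration
    return stats.beta.ppf(stats.norm.cdf(u), a, b)


def simulate_tissue_cohort(spec: TissueSimSpec) -> TissueCohort:
    """Generate one tissue cohort from a :class:`TissueSimSpec`.

    Informative probes have normal-group mean beta at
    ``control_beta_level`` and tumor mean shifted up by
    ``delta_beta_effect``; their paired genes carry an
    ``expr_effect_log2fc`` shift in tumors plus a latent-normal
    coupling giving a negative methylation–expression correlation of
    roughly ``meth_expr_coupling``.  All other probes and genes share
    one null distribution across both groups.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_tumor + spec.n_normal
    is_tumor = np.zeros(n_samples, dtype=bool)
    is_tumor[: spec.n_tumor] = True
    width = len(str(max(n_samples, spec.n_probes)))
    samples = [
        f"{'T' if t else 'N'}{i:0{width}d}" for i, t in enumerate(is_tumor, start=1)
    ]
    probes = [f"probe_{i:0{width}d}" for i in range(1, spec.n_probes + 1)]
    genes = [f"gene_{i:0{width}d}" for i in range(1, spec.n_probes + 1)]

    informative = np.zeros(spec.n_probes, dtype=bool)
    informative[: spec.n_informative] = True

    # per-probe group means
    null_means = rng.uniform(0.05, 0.95, size=spec.n_probes)
    mean_matrix = np.tile(null_means[:, None], (1, n_samples))
    if spec.n_informative:
        tumor_mean = min(spec.control_beta_level + spec.delta_beta_effect, 1.0 - 1e-6)
        mean_matrix[np.ix_(informative, ~is_tumor)] = spec.control_beta_level
        mean_matrix[np.ix_(informative, is_tumor)] = tumor_mean

    u = rng.standard_normal((spec.n_probes, n_samples))
    meth = _beta_from_normal(u, mean_matrix, spec.beta_concentration)

    baseline = rng.uniform(6.0, 12.0, size=spec.n_probes)
    w = rng.standard_normal((spec.n_probes, n_samples))
    rho = spec.meth_expr_coupling
    latent = np.where(
        informative[:, None],
        rho * u + np.sqrt(1 - rho * rho) * w,
        w,
    )
    log2_expr = (
        baseline[:, None]
        + np.where(informative[:, None], spec.expr_effect_log2fc, 0.0) * is_tumor[None, :]
        + spec.expr_log2_sd * latent
    )
    expr = np.exp2(log2_expr)

    index = pd.Index(probes, name="probe_id")
    return TissueCohort(
        meth=pd.DataFrame(meth, index=index, columns=samples),
        expr=pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples),
        labels=pd.Series(
            np.where(is_tumor, "tumor", "normal"), index=samples, name="group"
        ),
        probe_to_gene=pd.Series(genes, index=index, name="gene_id"),
        informative=pd.Series(informative, index=index, name="informative"),
    )


# --------------------------------------------------------------------------
# plasma qPCR cohort

_DEFAULT_CT_DIST: Mapping[str, tuple[float, float]] = {
    "mSEPT9": (38.0, 2.5),
    "mALX4": (37.5, 1.5),
    "mSDC2": (38.0, 2.0),
}


@dataclass(frozen=True)
class QpcrSimSpec:
    """Parameters of the plasma qPCR cohort generator.

    ``detect_prob`` maps group (CRC/PL/NED) to per-gene probabilities
    that a well's marker channel is methylation-positive; positive
    channels draw CT ~ Normal(loc, scale) per ``ct_positive_dist``
    (clipped to stay positive), negative channels carry the
    undetermined sentinel.  ACTB is drawn per well from
    ``ct_actb_dist``; with probability ``invalid_rate`` a well's ACTB
    is pushed above the validity cutoff instead.
    """

    n_crc: int = 75
    n_pl: int = 40
    n_ned: int = 171
    detect_prob: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            g: {gene: 0.0 for gene in GENES} for g in ("CRC", "PL", "NED")
        }
    )
    ct_positive_dist: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CT_DIST)
    )
    ct_actb_dist: tuple[float, float] = (29.0, 1.5)
    invalid_rate: float = 0.0
    actb_validity_cutoff: float = 40.0
    n_wells: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_crc", "n_pl", "n_ned"):
            _check(getattr(self, name) >= 1, name, "must be ≥ 1")
        _check(self.n_wells >= 1, "n_wells", "must be ≥ 1")
        _check(0 <= self.invalid_rate <= 1, "invalid_rate", "must be in [0, 1]")
        for group in ("CRC", "PL", "NED"):
            _check(group in self.detect_prob, "detect_prob", f"missing group {group}")
            for gene in GENES:
                p = self.detect_prob[group].get(gene)
                _check(p is not None, "detect_prob", f"missing {group}/{gene}")
                _check(0 <= p <= 1, "detect_prob",
                       f"{group}/{gene} probability {p} outside [0, 1]")
        for gene in GENES:
            _check(gene in self.ct_positive_dist, "ct_positive_dist", f"missing {gene}")


def simulate_qpcr_cohort(spec: QpcrSimSpec) -> pd.DataFrame:
    """Generate a long well table: ``n_wells`` rows per subject.

    Columns: ``sample_id, group, well, ct_msept9, ct_malx4, ct_msdc2,
    ct_actb`` with NaN for undetermined channels.
    """
    rng = np.random.default_rng(spec.seed)
    groups = (
        ["CRC"] * spec.n_crc + ["PL"] * spec.n_pl + ["NED"] * spec.n_ned
    )
    n = len(groups)
    width = len(str(n))
    sample_ids = [f"{g}_{i:0{width}d}" for i, g in enumerate(groups, start=1)]

    rows = []
    col_of = {"mSEPT9": "ct_msept9", "mALX4": "ct_malx4", "mSDC2": "ct_msdc2"}
    for sid, group in zip(sample_ids, groups):
        for well in range(1, spec.n_wells + 1):
            row: dict = {"sample_id": sid, "group": group, "well": well}
            for gene in GENES:
                if rng.random() < spec.detect_prob[group][gene]:
                    loc, scale = spec.ct_positive_dist[gene]
                    row[col_of[gene]] = max(float(rng.normal(loc, scale)), 1.0)
                else:
                    row[col_of[gene]] = np.nan
            if rng.random() < spec.invalid_rate:
                row["ct_actb"] = float(
                    rng.uniform(spec.actb_validity_cutoff + 0.5, spec.actb_validity_cutoff + 5.0)
                )
            else:
                loc, scale = spec.ct_actb_dist
                row["ct_actb"] = max(float(rng.normal(loc, scale)), 1.0)
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "well", "ct_msept9", "ct_malx4", "ct_msdc2", "ct_actb"]
    )


# Hand-tuned so that balancing-algorithm calls on a large simulated cohort
# land near the assay's reported operating point (sensitivity ≈ 0.827,
# specificity ≈ 0.901, PL detection ≈ 0.550).  The probabilities are
# approximations chosen for that purpose, not measured quantities.
_A2_DETECT_PROB: Mapping[str, Mapping[str, float]] = {
    "CRC": {"mSEPT9": 0.66, "mALX4": 0.40, "mSDC2": 0.45},
    "PL": {"mSEPT9": 0.38, "mALX4": 0.22, "mSDC2": 0.38},
    "NED": {"mSEPT9": 0.175, "mALX4": 0.05, "mSDC2": 0.03},
}

#: Sensitivity / specificity / PL-detection the "a2-like" preset is tuned
#: to produce under the balancing algorithm.
A2_OPERATING_POINT = {"sensitivity": 0.827, "specificity": 0.901, "pl_detection": 0.550}


def a2_like_spec(seed: int = 0, **overrides) -> QpcrSimSpec:
    """The "a2-like" preset cohort: 75 CRC, 40 PL, 171 NED, two wells.

    Detection probabilities are hand-tuned approximations such that the
    balancing algorithm reproduces the assay operating point in
    :data:`A2_OPERATING_POINT` up to binomial error.
    """
    params = dict(
        n_crc=75,
        n_pl=40,
        n_ned=171,
        detect_prob={g: dict(v) for g, v in _A2_DETECT_PROB.items()},
        invalid_rate=0.0,
        seed=seed,
    )
    params.update(overrides)
    return QpcrSimSpec(**params)
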