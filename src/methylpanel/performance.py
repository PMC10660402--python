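"""Diagnostic-performance evaluation for a three-group screening cohort.

Subjects belong to one of three groups: CRC (colorectal cancer), PL
(precancerous lesion / adenoma), NED (no evidence of disease).  The
headline metrics are

* sensitivity   = positive CRC / all CRC,
* specificity   = negative NED / all NED,
* PL detection  = positive PL  / all PL,
* accuracy      = (positive CRC + negative NED) / (CRC + NED).

Accuracy deliberately excludes PL subjects: a screening assay is judged
on separating cancer from disease-free, while adenoma detection is
reported separately.  Binomial 95% confidence intervals default to the
Wilson score interval with continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = [
    "Rate",
    "PerformanceSummary",
    "proportion_ci",
    "confusion_summary",
    "stratified_rates",
    "youden_cutoff",
    "cohens_kappa",
    "KappaResult",
    "sample_size_ci_width",
    "roc_logistic",
    "RocReport",
    "RepeatedSplitLogisticRoc",
]


# --------------------------------------------------------------------------
# binomial rates and confidence intervals


@dataclass(frozen=True)
class Rate:
    """A binomial rate with its 95% confidence interval."""

    successes: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return 100.0 * self.estimate


def proportion_ci(
    successes: int | float,
    n: int | float,
    method: str = "wilson_cc",
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Binomial confidence interval for ``successes`` out of ``n``.

    ``wilson_cc`` (default) is the Wilson score interval with
    continuity correction, the convention of the classic VassarStats
    calculator; ``wilson`` and ``clopper_pearson`` (exact) and ``wald``
    are also available.

    Non-integer ``successes`` are accepted for the score/Wald methods
    (useful for planning at an expected proportion); the exact method
    rounds to the nearest integer count.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if successes < 0 or successes > n:
        raise ValueError(f"successes must lie in [0, n], got {successes}/{n}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    p = successes / n
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    if method == "wald":
        half = z * math.sqrt(p * (1 - p) / n)
        return max(0.0, p - half), min(1.0, p + half)
    if method == "wilson":
        centre = (p + z * z / (2 * n)) / (1 + z * z / n)
        half = (z / (1 + z * z / n)) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
        return max(0.0, centre - half), min(1.0, centre + half)
    if method == "wilson_cc":
        # Newcombe (1998) method 4: Wilson score with continuity correction
        if successes == 0:
            low = 0.0
        else:
            low = (
                2 * n * p
                + z * z
                - 1
                - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
            ) / (2 * (n + z * z))
        if successes == n:
            high = 1.0
        else:
            high = (
                2 * n * p
                + z * z
                + 1
                + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
            ) / (2 * (n + z * z))
        return max(0.0, low), min(1.0, high)
    if method == "clopper_pearson":
        x = int(round(successes))
        alpha = 1 - confidence
        low = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
        high = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
        return float(low), float(high)
    raise ValueError(f"unknown CI method {method!r}")


def _rate(successes: int, n: int, method: str = "wilson_cc") -> Rate:
    if n == 0:
        return Rate(0, 0, float("nan"), float("nan"), float("nan"))
    low, high = proportion_ci(successes, n, method=method)
    return Rate(successes, n, successes / n, low, high)


# --------------------------------------------------------------------------
# confusion summary and stratified rates


@dataclass(frozen=True)
class PerformanceSummary:
    """Headline assay metrics with counts and 95% CIs."""

    sensitivity: Rate
    specificity: Rate
    pl_detection: Rate
    accuracy: Rate
    n_invalid: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("sensitivity", "specificity", "pl_detection", "accuracy"):
            r: Rate = getattr(self, name)
            rows.append(
                {
                    "metric": name,
                    "percent": round(r.percent, 1),
                    "successes": r.successes,
                    "n": r.n,
                    "ci_low_percent": round(100 * r.ci_low, 1),
                    "ci_high_percent": round(100 * r.ci_high, 1),
                }
            )
        return pd.DataFrame(rows)


def confusion_summary(
    calls: pd.DataFrame,
    labels: pd.Series | Mapping[str, str] | None = None,
    ci_method: str = "wilson_cc",
) -> PerformanceSummary:
    """Headline metrics from a per-sample call table.

    ``calls`` needs columns ``sample_id`` and ``status`` plus a
    ``group`` column (CRC/PL/NED) unless ``labels`` maps sample ids to
    groups.  INVALID/ERROR samples are excluded with their count
    retained on the summary.
    """
    df = calls.copy()
    if labels is not None:
        lab = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
        df["group"] = df["sample_id"].map(lab)
    if "group" not in df.columns:
        raise ValueError("calls need a 'group' column or a labels mapping")
    n_invalid = int((~df["status"].isin(["POSITIVE", "NEGATIVE"])).sum())
    df = df[df["status"].isin(["POSITIVE", "NEGATIVE"])]
    pos = df["status"] == "POSITIVE"
    counts = {
        g: (int((pos & (df["group"] == g)).sum()), int((df["group"] == g).sum()))
        for g in ("CRC", "PL", "NED")
    }
    tp, n_crc = counts["CRC"]
    pl_pos, n_pl = counts["PL"]
    ned_pos, n_ned = counts["NED"]
    tn = n_ned - ned_pos
    return PerformanceSummary(
        sensitivity=_rate(tp, n_crc, ci_method),
        specificity=_rate(tn, n_ned, ci_method),
        pl_detection=_rate(pl_pos, n_pl, ci_method),
        accuracy=_rate(tp + tn, n_crc + n_ned, ci_method),
        n_invalid=n_invalid,
    )


def summary_from_counts(
    crc_positive: int,
    n_crc: int,
    ned_negative: int,
    n_ned: int,
    pl_positive: int = 0,
    n_pl: int = 0,
    ci_method: str = "wilson_cc",
) -> PerformanceSummary:
    """PerformanceSummary straight from contingency counts."""
    return PerformanceSummary(
        sensitivity=_rate(crc_positive, n_crc, ci_method),
        specificity=_rate(ned_negative, n_ned, ci_method),
        pl_detection=_rate(pl_positive, n_pl, ci_method),
        accuracy=_rate(crc_positive + ned_negative, n_crc + n_ned, ci_method),
    )


def stratified_rates(
    calls: pd.DataFrame,
    strata: pd.DataFrame,
    strata_columns: Sequence[str],
    ci_method: str = "wilson_cc",
) -> pd.DataFrame:
    """Positive detection rate per stratum per group.

    ``strata`` maps ``sample_id`` to covariate columns (age band,
    gender, tumor location, stage class ...).  For every stratum value
    of every requested column the positives/tested count is computed
    per group; pooling the strata of any one column reproduces the
    group totals exactly (the strata partition each group).
    """
    df = calls[calls["status"].isin(["POSITIVE", "NEGATIVE"])].merge(
        strata, on="sample_id", how="left"
    )
    if "group" not in df.columns:
        raise ValueError("calls/strata need a 'group' column")
    rows = []
    for col in strata_columns:
        for stratum, chunk in df.groupby(col, dropna=True, observed=True):
            for group, gchunk in chunk.groupby("group", observed=True):
                npos = int((gchunk["status"] == "POSITIVE").sum())
                n = len(gchunk)
                r = _rate(npos, n, ci_method)
                rows.append(
                    {
                        "stratum_type": col,
                        "stratum": stratum,
                        "group": group,
                        "positives": npos,
                        "tested": n,
                        "rate_percent": round(r.percent, 1) if n else float("nan"),
                        "ci_low_percent": round(100 * r.ci_low, 1) if n else float("nan"),
                        "ci_high_percent": round(100 * r.ci_high, 1) if n else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def pool_strata(rates: pd.DataFrame, stratum_type: str, group: str) -> tuple[int, int]:
    """Pool one partition of one group back to (positives, tested)."""
    sel = rates[(rates["stratum_type"] == stratum_type) & (rates["group"] == group)]
    return int(sel["positives"].sum()), int(sel["tested"].sum())


# --------------------------------------------------------------------------
# cutoff selection


def youden_cutoff(
    scores: Sequence[float],
    labels: Sequence[int],
    positive_below: bool = True,
) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity.

    Parameters
    ----------
    scores : array-like
        One score per sample (e.g. a gene's CT value).
    labels : array-like of {0, 1}
        1 = diseased.
    positive_below : bool
        True (CT semantics): a sample is called positive when its score
        is strictly below the cutoff.  False: positive when above.

    Returns
    -------
    (cutoff, sensitivity, specificity) at the optimum.  Candidate
    cutoffs are midpoints between consecutive distinct scores plus
    sentinels below/above all scores; ties in sensitivity+specificity
    are broken toward the more specific cutoff (fewer positives).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("both classes required")
    finite = scores[np.isfinite(scores)]
    uniq = np.unique(finite)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    lo, hi = (uniq[0] - 1.0, uniq[-1] + 1.0) if len(uniq) else (0.0, 1.0)
    candidates = np.concatenate([[lo], mids, [hi]])
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best = None
    # most-specific candidates first, so a strictly better J is required
    # to displace them: ties resolve toward the more specific cutoff
    ordered = candidates if positive_below else candidates[::-1]
    for c in ordered:
        called = (scores < c) if positive_below else (scores > c)
        sens = (called & (labels == 1)).sum() / n_pos
        spec = ((~called) & (labels == 0)).sum() / n_neg
        j = sens + spec
        if best is None or j > best[0]:
            best = (j, c, sens, spec)
    assert best is not None
    return best[1], best[2], best[3]


# --------------------------------------------------------------------------
# duplicate concordance


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with agreement, CI and normal-approximation p."""

    kappa: float
    ci_low: float
    ci_high: float
    p_value: float
    observed_agreement: float
    n: int


def cohens_kappa(
    calls_well1: Sequence,
    calls_well2: Sequence,
    confidence: float = 0.95,
) -> KappaResult:
    """Chance-corrected agreement between the two wells of each sample.

    Standard Cohen's kappa on the k×k agreement table with the
    large-sample standard error for the CI and a null-hypothesis
    (kappa = 0) normal approximation for the p-value.
    """
    a = pd.Series(list(calls_well1))
    b = pd.Series(list(calls_well2))
    if len(a) != len(b):
        raise ValueError("call vectors must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("empty call vectors")
    cats = sorted(set(a) | set(b), key=str)
    table = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats), dropna=False
    ).reindex(index=cats, columns=cats, fill_value=0)
    obs = table.to_numpy(dtype=float) / n
    po = float(np.trace(obs))
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    pe = float(row @ col)
    if pe == 1.0:
        kappa = 1.0 if po == 1.0 else 0.0
        return KappaResult(kappa, kappa, kappa, 1.0, po, n)
    kappa = (po - pe) / (1 - pe)
    # Fleiss, Cohen & Everitt (1969) asymptotic variance of kappa-hat
    k = len(cats)
    sum1 = sum(
        obs[i, i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(k)
    )
    sum2 = sum(
        obs[i, j] * (col[i] + row[j]) ** 2
        for i in range(k)
        for j in range(k)
        if i != j
    )
    var = (
        sum1 + (1 - kappa) ** 2 * sum2 - (kappa - pe * (1 - kappa)) ** 2
    ) / (n * (1 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    # null SE for testing kappa = 0
    var0 = (
        pe + pe * pe - sum(row[i] * col[i] * (row[i] + col[i]) for i in range(k))
    ) / (n * (1 - pe) ** 2)
    se0 = math.sqrt(max(var0, 1e-300))
    p = 2 * stats.norm.sf(abs(kappa) / se0)
    return KappaResult(
        kappa=kappa,
        ci_low=kappa - z * se,
        ci_high=kappa + z * se,
        p_value=float(p),
        observed_agreement=po,
        n=n,
    )


# --------------------------------------------------------------------------
# planning


def sample_size_ci_width(
    expected_p: float,
    max_width: float,
    confidence: float = 0.95,
    method: str = "wald",
    n_max: int = 1_000_000,
) -> int:
    """Smallest n whose CI width at the expected proportion is ≤ max_width.

    Used to plan a diagnostic-accuracy cohort: e.g. an expected
    sensitivity of 0.83 with a desired full CI width of 0.08 at 95%
    confidence.  The CI is evaluated at successes = expected_p·n (the
    exact method rounds the count).
    """
    if not 0 <= expected_p <= 1:
        raise ValueError("expected_p must be in [0, 1]")
    if max_width <= 0:
        raise ValueError("max_width must be positive")
    if max_width >= 1:
        return 1
    ci_method = {"wald": "wald", "wilson": "wilson", "exact": "clopper_pearson"}.get(method)
    if ci_method is None:
        raise ValueError(f"unknown method {method!r}")
    # Wald width shrinks as 1/sqrt(n); start the scan near the closed form
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    guess = max(1, int(4 * z * z * expected_p * (1 - expected_p) / max_width**2) - 5)
    for n in range(1 if method == "exact" else guess, n_max + 1):
        low, high = proportion_ci(expected_p * n, n, method=ci_method, confidence=confidence)
        if high - low <= max_width:
            return n
    raise RuntimeError("no n up to n_max satisfies the width constraint")


# --------------------------------------------------------------------------
# repeated-split univariate logistic ROC


@dataclass
class RocReport:
    """Per-gene and combined-rule AUCs over repeated 70/30 splits."""

    per_gene_auc: pd.DataFrame  # columns: gene, mean_auc, sd_auc
    cutoffs: dict[str, float]  # Youden cutoff per gene on full data
    combined_auc_mean: float
    combined_auc_sd: float
    combined_mode: str
    n_repeats: int


class RepeatedSplitLogisticRoc:
    """Univariate logistic ROC evaluation with repeated 70/30 splits.

    For each marker's CT values (undetermined imputed to ``ct_ceiling``)
    a single-covariate logistic regression is fitted on a stratified
    70% training split and its AUC measured on the held-out 30%,
    repeated ``n_repeats`` times.  A combined any-marker-positive rule
    (positive when any marker's CT is below its cutoff) is scored the
    same way; its cutoffs are either per-gene Youden cutoffs learned on
    the training split (``combined_mode="youden"``) or a fixed cutoff
    set (``combined_mode="fixed"``, ``fixed_cutoffs`` required).

    Attributes (after :meth:`fit`)
    ------------------------------
    report_ : RocReport
    cutoffs_ : dict mapping gene to the full-data Youden cutoff.
    """

    def __init__(
        self,
        n_repeats: int = 100,
        train_fraction: float = 0.7,
        ct_ceiling: float = 50.0,
        combined_mode: str = "youden",
        fixed_cutoffs: Mapping[str, float] | None = None,
        random_state: int | None = None,
    ):
        self.n_repeats = n_repeats
        self.train_fraction = train_fraction
        self.ct_ceiling = ct_ceiling
        self.combined_mode = combined_mode
        self.fixed_cutoffs = fixed_cutoffs
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "train_fraction": self.train_fraction,
            "ct_ceiling": self.ct_ceiling,
            "combined_mode": self.combined_mode,
            "fixed_cutoffs": self.fixed_cutoffs,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "RepeatedSplitLogisticRoc":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y: Sequence[int]) -> "RepeatedSplitLogisticRoc":
        """Evaluate on per-sample CT features ``X`` (one column per gene).

        ``y`` is the binary disease label (1 = CRC or PL, 0 = NED).
        """
        if self.combined_mode not in ("youden", "fixed"):
            raise ValueError("combined_mode must be 'youden' or 'fixed'")
        if self.combined_mode == "fixed" and not self.fixed_cutoffs:
            raise ValueError("fixed combined_mode needs fixed_cutoffs")
        X = X.astype(float).fillna(self.ct_ceiling)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        genes = list(X.columns)
        splitter = StratifiedShuffleSplit(
            n_splits=self.n_repeats,
            train_size=self.train_fraction,
            random_state=self.random_state,
        )
        aucs: dict[str, list[float]] = {g: [] for g in genes}
        combined: list[float] = []
        for train_idx, test_idx in splitter.split(X, y):
            Xtr, Xte = X.iloc[train_idx], X.iloc[test_idx]
            ytr, yte = y[train_idx], y[test_idx]
            cutoffs = {}
            for g in genes:
                # lbfgs with slight L2 keeps separable fits finite
                model = LogisticRegression(C=1e6, max_iter=1000)
                model.fit(Xtr[[g]], ytr)
                prob = model.predict_proba(Xte[[g]])[:, 1]
                aucs[g].append(roc_auc_score(yte, prob))
                if self.combined_mode == "youden":
                    cutoffs[g], _, _ = youden_cutoff(
                        Xtr[g].to_numpy(), ytr, positive_below=True
                    )
                else:
                    cutoffs[g] = float(self.fixed_cutoffs[g])
            any_pos = np.zeros(len(yte), dtype=bool)
            for g in genes:
                any_pos |= Xte[g].to_numpy() < cutoffs[g]
            combined.append(roc_auc_score(yte, any_pos.astype(float)))
        self.cutoffs_ = {
            g: youden_cutoff(X[g].to_numpy(), y, positive_below=True)[0] for g in genes
        }
        per_gene = pd.DataFrame(
            {
                "gene": genes,
                "mean_auc": [float(np.mean(aucs[g])) for g in genes],
                "sd_auc": [float(np.std(aucs[g], ddof=1)) if self.n_repeats > 1 else 0.0 for g in genes],
            }
        )
        self.report_ = RocReport(
            per_gene_auc=per_gene,
            cutoffs=self.cutoffs_,
            combined_auc_mean=float(np.mean(combined)),
            combined_auc_sd=float(np.std(combined, ddof=1)) if self.n_repeats > 1 else 0.0,
            combined_mode=self.combined_mode,
            n_repeats=self.n_repeats,
        )
        return self


def roc_logistic(
    features: pd.DataFrame,
    labels: Sequence[int],
    n_repeats: int = 100,
    train_fraction: float = 0.7,
    ct_ceiling: float = 50.0,
    combined_mode: str = "youden",
    fixed_cutoffs: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> RocReport:
    """Functional wrapper over :class:`RepeatedSplitLogisticRoc`."""
    est = RepeatedSplitLogisticRoc(
        n_repeats=n_repeats,
        train_fraction=train_fraction,
        ct_ceiling=ct_ceiling,
        combined_mode=combined_mode,
        fixed_cutoffs=fixed_cutoffs,
        random_state=seed,
    )
    est.fit(features, labels)
    return est.report_
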