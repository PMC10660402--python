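"""Tissue-cohort biomarker discovery.

The discovery chain screens Illumina 450K-style methylation beta values
and RSEM-scale expression from a tumor/normal tissue cohort:

1. DMP calling — per probe, the tumor−normal difference of mean beta
   (Δβ), a two-sided t-test, and Benjamini–Hochberg FDR control; a
   probe is a differentially methylated position when |Δβ| ≥ 0.2, the
   normal-group mean beta is ≤ 0.1 (selecting markers unmethylated in
   normal tissue, hence usable in a methylation-specific assay), and
   the BH q-value is ≤ 0.01.
2. DEG calling — the same test on log2(expression + 1).
3. Methylation–expression correlation — Spearman, Pearson and Kendall
   coefficients per gene across samples.
4. Candidate selection — genes that are DMP and DEG with a negative
   Spearman coefficient.
5. LASSO weight scoring — repeated stratified 70/30 splits; on each
   training split an L1-penalized logistic regression (penalty chosen
   by internal cross-validation) is fitted and the nonzero-coefficient
   genes counted as selected; genes are ranked by selection frequency
   with mean held-out sensitivity/specificity reported alongside.

The selectors are scikit-learn-style estimators operating on
samples × features arrays; the module-level ``compute_*`` functions
accept the probes × samples matrices of this package's on-disk layout
and return tidy result frames.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

__all__ = [
    "benjamini_hochberg",
    "DmpSelector",
    "DegSelector",
    "compute_dmp",
    "compute_deg",
    "correlate_meth_expr",
    "select_candidates",
    "LassoStabilitySelector",
    "lasso_weight_scoring",
]


def benjamini_hochberg(
    p_values: Sequence[float], level: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns ``(reject, q_values)``: the step-up rejection flags at the
    given FDR level and the monotone (cumulative-minimum adjusted)
    q-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    reject, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return reject, q


def _group_masks(labels: Sequence, case_label, control_label) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    case = labels == case_label
    control = labels == control_label
    if case.sum() < 2 or control.sum() < 2:
        raise ValueError(
            f"need at least 2 samples per group, got {int(case.sum())} "
            f"{case_label!r} and {int(control.sum())} {control_label!r}"
        )
    return case, control


def _welch_rows(
    X: np.ndarray, case: np.ndarray, control: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided t-test with the degenerate-row convention:
    both groups constant and equal means → p = 1; both constant with
    different means → p = 0 (infinite evidence)."""
    with warnings.catch_warnings():
        # constant rows trigger scipy's catastrophic-cancellation warning;
        # they are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(X[:, case], X[:, control], axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    var_case = X[:, case].var(axis=1)
    var_control = X[:, control].var(axis=1)
    degenerate = (var_case == 0) & (var_control == 0)
    diff = X[:, case].mean(axis=1) - X[:, control].mean(axis=1)
    p[degenerate & (diff == 0)] = 1.0
    t[degenerate & (diff == 0)] = 0.0
    p[degenerate & (diff != 0)] = 0.0
    t[degenerate & (diff != 0)] = np.sign(diff[degenerate & (diff != 0)]) * np.inf
    return t, p


class _TwoGroupSelector:
    """Shared fit machinery for the DMP/DEG selectors."""

    def __init__(
        self,
        fdr_level: float = 0.01,
        case_label="tumor",
        control_label="normal",
        equal_var: bool = False,
    ):
        self.fdr_level = fdr_level
        self.case_label = case_label
        self.control_label = control_label
        self.equal_var = equal_var

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in self.__init__.__code__.co_varnames[1 : self.__init__.__code__.co_argcount]
        }

    def set_params(self, **params):
        valid = self.get_params()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def get_support(self) -> np.ndarray:
        return self.significant_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.significant_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


class DmpSelector(_TwoGroupSelector):
    """Differentially-methylated-position selector.

    ``fit(X, y)`` takes a samples × probes beta-value array and group
    labels; a probe is significant when |Δβ| ≥ ``delta_cutoff``, the
    control-group mean beta is ≤ ``control_cutoff`` and the BH q-value
    is ≤ ``fdr_level``.

    Fitted attributes: ``delta_beta_``, ``control_mean_beta_``,
    ``t_stat_``, ``p_value_``, ``q_value_``, ``significant_``.
    """

    def __init__(
        self,
        delta_cutoff: float = 0.2,
        control_cutoff: float = 0.1,
        fdr_level: float = 0.01,
        case_label="tumor",
        control_label="normal",
        equal_var: bool = False,
    ):
        super().__init__(fdr_level, case_label, control_label, equal_var)
        self.delta_cutoff = delta_cutoff
        self.control_cutoff = control_cutoff

    def get_params(self, deep: bool = True) -> dict:
        return {
            "delta_cutoff": self.delta_cutoff,
            "control_cutoff": self.control_cutoff,
            "fdr_level": self.fdr_level,
            "case_label": self.case_label,
            "control_label": self.control_label,
            "equal_var": self.equal_var,
        }

    def fit(self, X, y) -> "DmpSelector":
        X = np.asarray(X, dtype=float)
        if np.any((X < 0) | (X > 1)):
            raise ValueError("beta values must lie in [0, 1]")
        case, control = _group_masks(y, self.case_label, self.control_label)
        Xt = X.T  # features × samples
        self.delta_beta_ = Xt[:, case].mean(axis=1) - Xt[:, control].mean(axis=1)
        self.control_mean_beta_ = Xt[:, control].mean(axis=1)
        self.t_stat_, self.p_value_ = _welch_rows(Xt, case, control, self.equal_var)
        reject, self.q_value_ = benjamini_hochberg(self.p_value_, self.fdr_level)
        self.significant_ = (
            reject
            & (np.abs(self.delta_beta_) >= self.delta_cutoff)
            & (self.control_mean_beta_ <= self.control_cutoff)
        )
        return self


class DegSelector(_TwoGroupSelector):
    """Differentially-expressed-gene selector on log2(x + 1) expression.

    Significance is by BH FDR alone.  Fitted attributes:
    ``log2_mean_diff_``, ``t_stat_``, ``p_value_``, ``q_value_``,
    ``significant_``.
    """

    def fit(self, X, y) -> "DegSelector":
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("expression values must be nonnegative")
        case, control = _group_masks(y, self.case_label, self.control_label)
        L = np.log2(X + 1.0).T  # genes × samples
        self.log2_mean_diff_ = L[:, case].mean(axis=1) - L[:, control].mean(axis=1)
        self.t_stat_, self.p_value_ = _welch_rows(L, case, control, self.equal_var)
        self.significant_, self.q_value_ = benjamini_hochberg(self.p_value_, self.fdr_level)
        return self


def compute_dmp(
    meth: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    delta_cutoff: float = 0.2,
    control_cutoff: float = 0.1,
    fdr_level: float = 0.01,
    case_label: str = "tumor",
    control_label: str = "normal",
    equal_var: bool = False,
) -> pd.DataFrame:
    """DMP results for a probes × samples beta matrix.

    Returns a frame with columns ``probe_id, delta_beta,
    control_mean_beta, t_stat, p_value, q_value, significant``.
    """
    lab = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    y = lab.reindex(meth.columns)
    if y.isna().any():
        raise ValueError("every sample column needs a group label")
    sel = DmpSelector(
        delta_cutoff, control_cutoff, fdr_level, case_label, control_label, equal_var
    ).fit(meth.to_numpy(dtype=float).T, y.to_numpy())
    return pd.DataFrame(
        {
            "probe_id": meth.index,
            "delta_beta": sel.delta_beta_,
            "control_mean_beta": sel.control_mean_beta_,
            "t_stat": sel.t_stat_,
            "p_value": sel.p_value_,
            "q_value": sel.q_value_,
            "significant": sel.significant_,
        }
    )


def compute_deg(
    expr: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    fdr_level: float = 0.01,
    case_label: str = "tumor",
    control_label: str = "normal",
    equal_var: bool = False,
) -> pd.DataFrame:
    """DEG results for a genes × samples RSEM-scale expression matrix."""
    lab = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    y = lab.reindex(expr.columns)
    if y.isna().any():
        raise ValueError("every sample column needs a group label")
    sel = DegSelector(fdr_level, case_label, control_label, equal_var).fit(
        expr.to_numpy(dtype=float).T, y.to_numpy()
    )
    return pd.DataFrame(
        {
            "gene_id": expr.index,
            "log2_mean_diff": sel.log2_mean_diff_,
            "t_stat": sel.t_stat_,
            "p_value": sel.p_value_,
            "q_value": sel.q_value_,
            "significant": sel.significant_,
        }
    )


def correlate_meth_expr(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    probe_to_gene: pd.Series | Mapping[str, str],
    labels: pd.Series | Mapping[str, str] | None = None,
    case_label: str = "tumor",
    control_label: str = "normal",
) -> pd.DataFrame:
    """Spearman / Pearson / Kendall correlation per gene.

    ``probe_to_gene`` maps probe ids to gene ids.  When several probes
    map to one gene, the probe with the largest |Δβ| (if ``labels`` are
    given) or the largest beta variance (otherwise) represents the
    gene.  Coefficients are computed across the samples shared by both
    matrices; zero-variance vectors yield NaN coefficients flagged in
    the ``degenerate`` column.
    """
    mapping = (
        probe_to_gene if isinstance(probe_to_gene, pd.Series) else pd.Series(dict(probe_to_gene))
    )
    shared = meth.columns.intersection(expr.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    meth = meth[shared]
    expr = expr[shared]

    if labels is not None:
        lab = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
        y = lab.reindex(shared)
        case = (y == case_label).to_numpy()
        control = (y == control_label).to_numpy()
        score = np.abs(
            meth.to_numpy()[:, case].mean(axis=1) - meth.to_numpy()[:, control].mean(axis=1)
        )
    else:
        score = meth.to_numpy().var(axis=1)
    score = pd.Series(score, index=meth.index)

    rows = []
    for gene, probes in mapping.groupby(mapping):
        probes = probes.index.intersection(meth.index)
        if len(probes) == 0 or gene not in expr.index:
            continue
        probe = score.loc[probes].idxmax()
        m = meth.loc[probe].to_numpy(dtype=float)
        e = expr.loc[gene].to_numpy(dtype=float)
        degenerate = m.var() == 0 or e.var() == 0
        if degenerate:
            sp = pe = kt = float("nan")
        else:
            sp = stats.spearmanr(m, e).statistic
            pe = stats.pearsonr(m, e).statistic
            kt = stats.kendalltau(m, e).statistic
        rows.append(
            {
                "gene_id": gene,
                "probe_id": probe,
                "spearman": sp,
                "pearson": pe,
                "kendall": kt,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def select_candidates(
    dmp: pd.DataFrame,
    deg: pd.DataFrame,
    corr: pd.DataFrame,
    probe_to_gene: pd.Series | Mapping[str, str] | None = None,
) -> list[str]:
    """Candidate biomarkers: significant DMP ∧ significant DEG ∧ ρ < 0.

    DMP results are keyed by probe; ``probe_to_gene`` (or a
    ``gene_id`` column already present on the DMP frame) lifts them to
    gene level — a gene is DMP-significant when any of its probes is.
    """
    if "gene_id" in dmp.columns:
        dmp_genes = set(dmp.loc[dmp["significant"], "gene_id"])
    else:
        if probe_to_gene is None:
            raise ValueError("need probe_to_gene to lift DMP probes to genes")
        mapping = (
            probe_to_gene
            if isinstance(probe_to_gene, pd.Series)
            else pd.Series(dict(probe_to_gene))
        )
        sig_probes = dmp.loc[dmp["significant"], "probe_id"]
        dmp_genes = set(mapping.reindex(sig_probes).dropna())
    deg_genes = set(deg.loc[deg["significant"], "gene_id"])
    neg_corr = set(corr.loc[corr["spearman"] < 0, "gene_id"])
    return sorted(dmp_genes & deg_genes & neg_corr)


class LassoStabilitySelector:
    """Repeated-split L1-logistic selection frequency ("weight scoring").

    On each of ``n_repeats`` stratified ``train_fraction`` /
    ``1 − train_fraction`` splits, an L1-penalized logistic regression
    is fitted on the training part with the penalty chosen by ``cv``-fold
    internal cross-validation; a feature counts as selected when its
    coefficient is nonzero.  Held-out sensitivity and specificity at
    probability threshold 0.5 are recorded per repeat.

    Fitted attributes
    -----------------
    selection_frequency_ : ndarray, per-feature fraction of repeats selected.
    mean_test_sensitivity_, mean_test_specificity_ : float
    ranking_ : ndarray of feature indices, most frequently selected first
        (ties broken by mean |coefficient|, then feature order).
    mean_abs_coef_ : ndarray
    """

    def __init__(
        self,
        n_repeats: int = 1000,
        train_fraction: float = 0.7,
        cv: int = 5,
        Cs: int = 10,
        random_state: int | None = None,
    ):
        self.n_repeats = n_repeats
        self.train_fraction = train_fraction
        self.cv = cv
        self.Cs = Cs
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "train_fraction": self.train_fraction,
            "cv": self.cv,
            "Cs": self.Cs,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "LassoStabilitySelector":
        valid = self.get_params()
        for key, value in params.items():
            if key not in valid:
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "LassoStabilitySelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"labels must be binary, got classes {classes!r}")
        y01 = (y == classes[1]).astype(int)
        if min((y01 == 0).sum(), (y01 == 1).sum()) < 10:
            raise ValueError("need at least 10 samples per class")
        rng = np.random.RandomState(self.random_state)
        n_features = X.shape[1]
        scaler = StandardScaler()
        selected = np.zeros(n_features)
        coef_abs = np.zeros(n_features)
        sens_list, spec_list = [], []
        for _ in range(self.n_repeats):
            # resample on the (very unlikely, stratified) degenerate split
            for _attempt in range(10):
                Xtr, Xte, ytr, yte = train_test_split(
                    X,
                    y01,
                    train_size=self.train_fraction,
                    stratify=y01,
                    random_state=rng.randint(0, 2**31 - 1),
                )
                if len(np.unique(ytr)) == 2 and len(np.unique(yte)) == 2:
                    break
            # standardize on the training split only (glmnet convention);
            # the L1 penalty is meaningless across unequal feature scales
            Xtr = scaler.fit_transform(Xtr)
            Xte = scaler.transform(Xte)
            model = LogisticRegressionCV(
                penalty="l1",
                solver="liblinear",
                Cs=self.Cs,
                cv=self.cv,
                max_iter=1000,
                random_state=rng.randint(0, 2**31 - 1),
            )
            with warnings.catch_warnings():
                # sklearn 1.8+ renames the L1 spelling; liblinear+penalty
                # stays correct throughout the transition
                warnings.simplefilter("ignore", FutureWarning)
                model.fit(Xtr, ytr)
            coefs = model.coef_.ravel()
            selected += coefs != 0
            coef_abs += np.abs(coefs)
            pred = (model.predict_proba(Xte)[:, 1] >= 0.5).astype(int)
            sens_list.append(((pred == 1) & (yte == 1)).sum() / max((yte == 1).sum(), 1))
            spec_list.append(((pred == 0) & (yte == 0)).sum() / max((yte == 0).sum(), 1))
        self.classes_ = classes
        self.selection_frequency_ = selected / self.n_repeats
        self.mean_abs_coef_ = coef_abs / self.n_repeats
        self.mean_test_sensitivity_ = float(np.mean(sens_list))
        self.mean_test_specificity_ = float(np.mean(spec_list))
        order = np.lexsort(
            (np.arange(n_features), -self.mean_abs_coef_, -self.selection_frequency_)
        )
        self.ranking_ = order
        return self

    def get_support(self, threshold: float = 0.5) -> np.ndarray:
        return self.selection_frequency_ >= threshold


def lasso_weight_scoring(
    features: pd.DataFrame,
    labels: Sequence,
    n_repeats: int = 1000,
    train_fraction: float = 0.7,
    cv: int = 5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Weight scores for a samples × genes feature frame.

    Returns ``(scores, report)``: a frame with columns ``gene_id,
    selection_frequency, mean_abs_coef, rank`` sorted by rank, and a
    report dict with the mean held-out sensitivity/specificity.
    """
    sel = LassoStabilitySelector(
        n_repeats=n_repeats, train_fraction=train_fraction, cv=cv, random_state=seed
    ).fit(features.to_numpy(dtype=float), np.asarray(labels))
    rank = np.empty(len(features.columns), dtype=int)
    rank[sel.ranking_] = np.arange(1, len(features.columns) + 1)
    scores = pd.DataFrame(
        {
            "gene_id": features.columns,
            "selection_frequency": sel.selection_frequency_,
            "mean_abs_coef": sel.mean_abs_coef_,
            "rank": rank,
        }
    ).sort_values("rank", ignore_index=True)
    report = {
        "mean_test_sensitivity": sel.mean_test_sensitivity_,
        "mean_test_specificity": sel.mean_test_specificity_,
        "n_repeats": n_repeats,
        "train_fraction": train_fraction,
    }
    return scores, report
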