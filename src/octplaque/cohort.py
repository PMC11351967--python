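"""Cohort-level inference: group comparison, redundancy pruning,
logistic regression and ROC analysis.

The cascade mirrors a standard lesion-outcome study design:

1. compare each feature between outcome groups (two-sample pooled
   t-test for continuous features, Pearson chi-square for binary
   flags);
2. prune redundant features using pairwise Spearman |ρ| with a fixed
   threshold, keeping in each correlated group the feature with the
   smallest univariate p-value (hierarchical clustering on 1 − |ρ|
   orders the correlation heatmap);
3. fit single-predictor logistic regressions (odds ratios with Wald
   95% CIs), carry the univariate-significant features into a joint
   multivariate fit;
4. score the multivariate-significant feature(s) by empirical AUC with
   a stratified bootstrap CI, and report the Youden-optimal cutoff (the
   observed threshold maximizing sensitivity + specificity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .features import FEATURE_NAMES, VP_FEATURE_NAMES

__all__ = [
    "StatsConfig",
    "UnivariateResult",
    "RocResult",
    "GroupComparison",
    "PruneResult",
    "compare_groups",
    "spearman_prune",
    "univariate_logistic",
    "multivariate_logistic",
    "roc_analysis",
    "run_pipeline",
]

OUTCOME_COLUMN = "CV death"

#: Coefficient magnitude beyond which a logistic fit is treated as
#: separated (odds ratios ~e±15 are not estimable from cohort-scale data).
_SEPARATION_COEF = 15.0


@dataclass(frozen=True)
class StatsConfig:
    """Knobs of the statistical cascade.

    ``welch``: use Welch's unequal-variance t-test instead of the pooled
    Student test.  ``prune_threshold``: Spearman |ρ| above which two
    features are redundant.  ``alpha``: significance level used for the
    univariate → multivariate hand-off and for the final call.
    ``n_boot``: bootstrap replicates for the AUC CI.
    """

    prune_threshold: float = 0.9
    alpha: float = 0.05
    n_boot: int = 2000
    seed: int = 0
    welch: bool = False
    categorical: tuple[str, ...] = VP_FEATURE_NAMES


@dataclass
class UnivariateResult:
    feature: str
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    coef: float
    separated: bool = False
    n: int = 0


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    optimal_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    n_boot: int


@dataclass
class GroupComparison:
    feature: str
    kind: str  # "continuous" | "categorical"
    summary_pos: str  # mean±SD or count (%) in the event group
    summary_neg: str
    p_value: float


@dataclass
class PruneResult:
    retained: list[str]
    dropped: dict[str, str]  # dropped feature -> retained feature it yielded to
    correlation: pd.DataFrame
    linkage: np.ndarray | None
    heatmap_order: list[str]


def _feature_columns(table: pd.DataFrame, outcome: str) -> list[str]:
    known = [c for c in FEATURE_NAMES if c in table.columns]
    extra = [c for c in table.columns if c not in known and c != outcome]
    return known + extra


def _check_outcome(y: pd.Series) -> None:
    vals = set(pd.unique(y.dropna()))
    if not vals <= {0, 1}:
        raise ValueError(f"outcome must be binary 0/1, got values {sorted(vals)}")
    if len(vals) < 2:
        raise ValueError("outcome has a single class; both groups must be present")


def compare_groups(
    table: pd.DataFrame,
    outcome: str = OUTCOME_COLUMN,
    config: StatsConfig | None = None,
) -> list[GroupComparison]:
    """Per-feature comparison between the two outcome groups.

    Continuous features use a two-sample t-test (pooled variance by
    default, Welch behind the config flag); binary flags use a Pearson
    chi-square without continuity correction.  Missing values are
    dropped per feature; a zero-variance feature reports a missing p
    with a warning.
    """
    config = config or StatsConfig()
    _check_outcome(table[outcome])
    y = table[outcome].astype(int)
    rows: list[GroupComparison] = []
    for col in _feature_columns(table, outcome):
        x = pd.to_numeric(table[col], errors="coerce")
        ok = x.notna() & y.notna()
        xp, xn = x[ok & (y == 1)], x[ok & (y == 0)]
        if col in config.categorical:
            tab = np.array(
                [
                    [(xp == 1).sum(), (xp == 0).sum()],
                    [(xn == 1).sum(), (xn == 0).sum()],
                ]
            )
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                warnings.warn(f"degenerate 2x2 table for {col!r}; p set missing")
                p = np.nan
            else:
                p = float(stats.chi2_contingency(tab, correction=False)[1])
            rows.append(
                GroupComparison(
                    feature=col,
                    kind="categorical",
                    summary_pos=f"{int((xp == 1).sum())} ({100 * (xp == 1).mean():.1f}%)",
                    summary_neg=f"{int((xn == 1).sum())} ({100 * (xn == 1).mean():.1f}%)",
                    p_value=p,
                )
            )
        else:
            if len(xp) < 2 or len(xn) < 2 or (xp.std(ddof=1) == 0 and xn.std(ddof=1) == 0):
                if len(xp) and len(xn) and np.allclose(xp.mean(), xn.mean()):
                    p = 1.0  # identical constant groups: no evidence of difference
                else:
                    warnings.warn(f"zero-variance or tiny feature {col!r}; p set missing")
                    p = np.nan
            else:
                p = float(
                    stats.ttest_ind(xp, xn, equal_var=not config.welch).pvalue
                )
            rows.append(
                GroupComparison(
                    feature=col,
                    kind="continuous",
                    summary_pos=f"{xp.mean():.2f} ± {xp.std(ddof=1):.2f}" if len(xp) else "–",
                    summary_neg=f"{xn.mean():.2f} ± {xn.std(ddof=1):.2f}" if len(xn) else "–",
                    p_value=p,
                )
            )
    return rows


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """MLE logistic fit; returns (params, bse, pvalues, separated)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            return None, None, None, True
    params, bse, pvals = res.params, res.bse, res.pvalues
    separated = bool(
        np.any(np.abs(params[1:]) > _SEPARATION_COEF) or not np.all(np.isfinite(bse))
    )
    return params, bse, pvals, separated


def univariate_logistic(
    table: pd.DataFrame,
    features: list[str] | None = None,
    outcome: str = OUTCOME_COLUMN,
) -> list[UnivariateResult]:
    """Single-predictor logistic regression per feature.

    Odds ratio = exp(coefficient) with a Wald 95% CI.  Complete or
    quasi-complete separation is flagged (infinite-bound CI) rather than
    raised.  Rows with a missing value in the feature are dropped for
    that feature only.
    """
    _check_outcome(table[outcome])
    features = features if features is not None else _feature_columns(table, outcome)
    y_all = table[outcome].astype(float)
    out: list[UnivariateResult] = []
    for col in features:
        x = pd.to_numeric(table[col], errors="coerce")
        ok = x.notna() & y_all.notna()
        y = y_all[ok].to_numpy()
        if len(np.unique(y)) < 2 or x[ok].nunique() < 2:
            out.append(
                UnivariateResult(col, np.nan, np.nan, np.nan, np.nan, np.nan, True, int(ok.sum()))
            )
            continue
        X = sm.add_constant(x[ok].to_numpy())
        params, bse, pvals, separated = _fit_logit(y, X)
        if params is None or separated:
            direction = np.sign(np.corrcoef(x[ok], y)[0, 1]) if params is None else np.sign(params[1])
            out.append(
                UnivariateResult(
                    feature=col,
                    p_value=np.nan,
                    odds_ratio=np.inf if direction >= 0 else 0.0,
                    ci_low=0.0,
                    ci_high=np.inf,
                    coef=np.inf if direction >= 0 else -np.inf,
                    separated=True,
                    n=int(ok.sum()),
                )
            )
            continue
        b, se = params[1], bse[1]
        out.append(
            UnivariateResult(
                feature=col,
                p_value=float(pvals[1]),
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.959963984540054 * se)),
                ci_high=float(np.exp(b + 1.959963984540054 * se)),
                coef=float(b),
                separated=False,
                n=int(ok.sum()),
            )
        )
    return out


def multivariate_logistic(
    table: pd.DataFrame,
    selected: list[str],
    outcome: str = OUTCOME_COLUMN,
) -> pd.DataFrame:
    """Joint MLE logistic fit of the selected features.

    Returns a coefficient table (coef, OR, Wald 95% CI, p).  A
    rank-deficient design raises an error naming the collinear columns.
    An events-per-variable ratio below 10 is logged as a warning, since
    Wald inference is then optimistic.
    """
    if not selected:
        raise ValueError("no features selected for the multivariate model")
    _check_outcome(table[outcome])
    sub = table[selected + [outcome]].apply(pd.to_numeric, errors="coerce").dropna()
    if sub[outcome].nunique() < 2:
        raise ValueError("outcome has a single class after listwise deletion")
    y = sub[outcome].to_numpy(dtype=float)
    Xf = sub[selected].to_numpy(dtype=float)
    if len(y) <= len(selected):
        raise ValueError("need more records than predictors")

    X = sm.add_constant(Xf, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(Xf, rowvar=False)
        pairs = [
            (selected[i], selected[j])
            for i in range(len(selected))
            for j in range(i + 1, len(selected))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {pairs}")

    events = int(min((y == 1).sum(), (y == 0).sum()))
    if events / len(selected) < 10:
        warnings.warn(
            f"events-per-variable {events}/{len(selected)} < 10; "
            "multivariate Wald inference may be unstable"
        )

    params, bse, pvals, separated = _fit_logit(y, X)
    if params is None:
        raise ValueError("multivariate fit failed to converge (separation)")
    z = 1.959963984540054
    rows = []
    for i, name in enumerate(selected, start=1):
        rows.append(
            {
                "feature": name,
                "coef": float(params[i]),
                "odds_ratio": float(np.exp(params[i])),
                "ci_low": float(np.exp(params[i] - z * bse[i])),
                "ci_high": float(np.exp(params[i] + z * bse[i])),
                "p_value": float(pvals[i]),
                "separated": bool(separated and abs(params[i]) > _SEPARATION_COEF),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def spearman_prune(
    table: pd.DataFrame,
    threshold: float = 0.9,
    outcome: str = OUTCOME_COLUMN,
    univariate_p: dict[str, float] | None = None,
) -> PruneResult:
    """Redundancy pruning by pairwise Spearman correlation.

    Builds the |ρ| matrix over all features, an average-linkage
    hierarchical clustering on distance 1 − |ρ| (used only to order the
    heatmap), and greedily prunes: within each connected group of
    features pairwise-linked at |ρ| > threshold, the feature with the
    smallest univariate p-value is kept and the rest dropped, ties
    broken by canonical feature order.  Constant features are excluded
    from the correlation with a warning.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 records for rank correlation")
    cols = _feature_columns(table, outcome)
    X = table[cols].apply(pd.to_numeric, errors="coerce")
    constant = [c for c in cols if X[c].nunique(dropna=True) < 2]
    if constant:
        warnings.warn(f"constant features excluded from correlation: {constant}")
    cols = [c for c in cols if c not in constant]
    X = X[cols]

    corr = X.corr(method="spearman").abs()

    linkage = None
    order = cols
    if len(cols) > 2:
        dist = 1.0 - corr.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        linkage = hierarchy.average(squareform(dist, checks=False))
        order = [cols[i] for i in hierarchy.leaves_list(linkage)]

    if univariate_p is None:
        univariate_p = {
            r.feature: r.p_value for r in univariate_logistic(table, cols, outcome)
        }

    # connected components of the |rho| > threshold graph
    adj = corr.to_numpy() > threshold
    np.fill_diagonal(adj, False)
    n = len(cols)
    comp = -np.ones(n, dtype=int)
    for i in range(n):
        if comp[i] >= 0:
            continue
        stack, comp[i] = [i], i
        while stack:
            j = stack.pop()
            for k in np.nonzero(adj[j])[0]:
                if comp[k] < 0:
                    comp[k] = i
                    stack.append(k)

    retained: list[str] = []
    dropped: dict[str, str] = {}
    for root in sorted(set(comp)):
        members = [cols[i] for i in np.nonzero(comp == root)[0]]
        if len(members) == 1:
            retained.append(members[0])
            continue

        def sort_key(name: str) -> tuple[float, int]:
            p = univariate_p.get(name, np.nan)
            return (p if np.isfinite(p) else np.inf, cols.index(name))

        keep = min(members, key=sort_key)
        retained.append(keep)
        for m in members:
            if m != keep:
                dropped[m] = keep
    retained.sort(key=cols.index)
    return PruneResult(
        retained=retained,
        dropped=dropped,
        correlation=corr,
        linkage=linkage,
        heatmap_order=order,
    )


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Empirical AUC as the Mann–Whitney U statistic, ties counted half."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_analysis(
    scores: np.ndarray,
    outcome: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Empirical AUC with stratified-bootstrap CI and Youden cutoff.

    The AUC is the Mann–Whitney probability that a random case outscores
    a random control, ties counted half.  The 95% CI is the percentile
    interval over bootstrap resamples drawn within each outcome class.
    The optimal cutoff is the observed score maximizing
    sensitivity + specificity for the rule ``score ≥ cutoff``; ties go
    to the smallest such threshold (favouring sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and outcome must align")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")

    pos, neg = scores[y == 1], scores[y == 0]
    auc = mann_whitney_auc(pos, neg)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        boots[b] = mann_whitney_auc(bp, bn)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])

    thresholds = np.unique(scores)  # ascending
    pos_sorted, neg_sorted = np.sort(pos), np.sort(neg)
    # rule "score >= thr": sensitivity = P(pos >= thr), specificity = P(neg < thr)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    youden = sens + spec
    best = int(np.argmax(youden + 1e-12 >= youden.max()))  # smallest thr on ties
    best_thr, best_sens, best_spec = float(thresholds[best]), float(sens[best]), float(spec[best])
    return RocResult(
        auc=auc,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        optimal_cutoff=best_thr,
        sensitivity_at_cutoff=best_sens,
        specificity_at_cutoff=best_spec,
        n_boot=n_boot,
    )


def run_pipeline(
    table: pd.DataFrame,
    config: StatsConfig | None = None,
    outcome: str = OUTCOME_COLUMN,
) -> dict:
    """Run the full cascade and return a JSON-serializable report.

    Stages: group comparison → Spearman pruning → univariate logistic on
    the retained features → multivariate logistic on the
    univariate-significant ones → ROC for each multivariate-significant
    feature.  Deterministic given ``config.seed``.
    """
    config = config or StatsConfig()
    if outcome not in table.columns:
        raise ValueError(f"outcome column {outcome!r} missing from table")
    _check_outcome(table[outcome])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comparison = compare_groups(table, outcome, config)
        uni_all = univariate_logistic(table, outcome=outcome)
        p_by_feature = {r.feature: r.p_value for r in uni_all}
        prune = spearman_prune(
            table, config.prune_threshold, outcome, univariate_p=p_by_feature
        )
        uni = [r for r in uni_all if r.feature in prune.retained]
        selected = [
            r.feature
            for r in uni
            if np.isfinite(r.p_value) and r.p_value < config.alpha
        ]
        multi_rows: list[dict] = []
        significant: list[str] = []
        if selected:
            multi = multivariate_logistic(table, selected, outcome)
            multi_rows = [
                {"feature": name, **{k: multi.loc[name, k] for k in multi.columns}}
                for name in multi.index
            ]
            significant = [
                name
                for name in multi.index
                if np.isfinite(multi.loc[name, "p_value"])
                and multi.loc[name, "p_value"] < config.alpha
            ]
        roc_blocks = {}
        for name in significant:
            sub = table[[name, outcome]].apply(pd.to_numeric, errors="coerce").dropna()
            res = roc_analysis(
                sub[name].to_numpy(),
                sub[outcome].to_numpy(),
                n_boot=config.n_boot,
                seed=config.seed,
            )
            roc_blocks[name] = vars(res)

    return {
        "header": {
            "n_lesions": int(len(table)),
            "n_events": int(table[outcome].sum()),
            "outcome": outcome,
            "config": {
                "prune_threshold": config.prune_threshold,
                "alpha": config.alpha,
                "n_boot": config.n_boot,
                "seed": config.seed,
                "welch": config.welch,
            },
        },
        "group_comparison": [vars(r) for r in comparison],
        "pruning": {
            "retained": prune.retained,
            "dropped": prune.dropped,
            "n_retained": len(prune.retained),
            "heatmap_order": prune.heatmap_order,
        },
        "univariate": [vars(r) for r in uni],
        "multivariate": {
            "selected": selected,
            "coefficients": multi_rows,
            "significant": significant,
        },
        "roc": roc_blocks,
    }
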