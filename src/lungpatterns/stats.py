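"""Statistical evaluation layer: OLS with AIC, forward selection by partial
F-tests, Welch's heteroscedastic ANOVA with Games-Howell post hoc pairwise
comparisons, Cohen's d, Pearson / point-biserial correlation, and logistic
classification with ROC analysis.

AIC uses the Gaussian-likelihood form ``n ln(RSS/n) + 2p`` with the error
variance counted among the p parameters; constants common to all models are
dropped, so only AIC differences are meaningful.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import expit


@dataclass
class OLSFit:
    coefficients: np.ndarray  # intercept first
    rss: float
    r2: float
    n: int
    k: int  # predictors, excluding intercept

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        return self.coefficients[0] + x @ self.coefficients[1:]


@dataclass
class AnovaResult:
    f_stat: float
    df1: float
    df2: float
    p_value: float


@dataclass
class PairwiseComparison:
    group_a: object
    group_b: object
    mean_diff: float
    q_stat: float
    df: float
    p_value: float


@dataclass
class ClassifierEval:
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: np.ndarray  # (m, 2) of (FPR, TPR)
    separated: bool = False


def ols_fit(x: np.ndarray, y: np.ndarray) -> OLSFit:
    """Least squares with intercept; r2 = 1 - RSS/TSS."""
    y = np.asarray(y, float).ravel()
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.size == 0:
        x = x.reshape(len(y), 0)
    n, k = x.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        bad = []
        base = np.ones((n, 1))
        for j in range(k):
            cand = np.column_stack([base, x[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(j)
            else:
                base = cand
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return OLSFit(coefficients=coef, rss=rss, r2=r2, n=n, k=k)


def aic_ols(fit: OLSFit) -> float:
    """AIC = n ln(RSS/n) + 2p with p = k + 2 (intercept and error variance)."""
    if fit.rss <= 0:
        warnings.warn("zero residual sum of squares; AIC is -inf")
        return float("-inf")
    return fit.n * float(np.log(fit.rss / fit.n)) + 2.0 * (fit.k + 2)


def partial_f_test(fit_reduced: OLSFit, fit_full: OLSFit):
    """F statistic and p-value for adding (k_full - k_red) predictors."""
    df_num = fit_full.k - fit_reduced.k
    df_den = fit_full.n - (fit_full.k + 1)
    if df_num <= 0 or df_den <= 0:
        raise ValueError("full model must add predictors and keep residual df")
    f = ((fit_reduced.rss - fit_full.rss) / df_num) / (fit_full.rss / df_den)
    f = max(f, 0.0)
    return f, float(sps.f.sf(f, df_num, df_den))


def forward_select(x: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """Greedy forward selection: add the largest-partial-F candidate while its
    p-value is <= alpha.  Returns (ordered selected indices, final OLSFit)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float).ravel()
    n, k = x.shape
    if n <= k + 2:
        raise ValueError("need n > k + 2")
    selected: list[int] = []
    current = ols_fit(x[:, []], y)  # intercept-only
    tss = current.rss
    remaining = list(range(k))
    while remaining:
        if current.rss <= 1e-12 * tss:  # perfect fit: no residual left to explain
            break
        fits = [(j, ols_fit(x[:, selected + [j]], y)) for j in remaining]
        stats = [(partial_f_test(current, fit)[0], j, fit) for j, fit in fits]
        f_best, j_best, fit_best = max(stats, key=lambda t: t[0])
        p_best = float(sps.f.sf(f_best, 1, fit_best.n - (fit_best.k + 1)))
        if p_best > alpha:
            break
        selected.append(j_best)
        remaining.remove(j_best)
        current = fit_best
    return selected, current


def _group_stats(groups):
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, float).ravel() for g in groups]
    for i, g in enumerate(arrs):
        if len(g) < 2:
            raise ValueError(f"group {i} needs at least 2 observations")
        if g.var(ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance")
    n = np.array([len(g) for g in arrs], float)
    mean = np.array([g.mean() for g in arrs])
    var = np.array([g.var(ddof=1) for g in arrs])
    return arrs, n, mean, var


def welch_anova(groups) -> AnovaResult:
    """Welch's heteroscedastic one-way ANOVA with Welch-Satterthwaite df."""
    _, n, mean, var = _group_stats(groups)
    k = len(n)
    w = n / var
    w_sum = w.sum()
    mean_w = (w * mean).sum() / w_sum
    a = (w * (mean - mean_w) ** 2).sum() / (k - 1)
    tmp = (((1.0 - w / w_sum) ** 2) / (n - 1.0)).sum()
    b = 1.0 + 2.0 * (k - 2.0) / (k ** 2 - 1.0) * tmp
    f = a / b
    df1 = k - 1.0
    df2 = (k ** 2 - 1.0) / (3.0 * tmp)
    return AnovaResult(f_stat=float(f), df1=df1, df2=float(df2),
                       p_value=float(sps.f.sf(f, df1, df2)))


def games_howell(groups, labels=None) -> list[PairwiseComparison]:
    """Games-Howell pairwise comparisons; p from the studentized range
    distribution with the full number of groups and Welch-Satterthwaite df."""
    _, n, mean, var = _group_stats(groups)
    k = len(n)
    if labels is None:
        labels = list(range(k))
    out = []
    for i, j in itertools.combinations(range(k), 2):
        se2 = var[i] / n[i] + var[j] / n[j]
        q = abs(mean[i] - mean[j]) / np.sqrt(se2 / 2.0)
        df = se2 ** 2 / ((var[i] / n[i]) ** 2 / (n[i] - 1)
                         + (var[j] / n[j]) ** 2 / (n[j] - 1))
        p = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
        out.append(PairwiseComparison(group_a=labels[i], group_b=labels[j],
                                      mean_diff=float(mean[i] - mean[j]),
                                      q_stat=float(q), df=float(df), p_value=p))
    return out


def cohens_d(a, b) -> float:
    """Standardised mean difference with df-weighted pooled variance."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    kind: str  # "pearson" or "point_biserial"


def correlation(x, y) -> CorrelationResult:
    """Pearson r for numeric x; point-biserial (Pearson on 0/1) for binary x."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    uniq = np.unique(x)
    binary = len(uniq) == 2 and set(uniq).issubset({0.0, 1.0})
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p),
                             kind="point_biserial" if binary else "pearson")


def _newton_logistic(design: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                     max_iter: int = 100):
    beta = np.zeros(design.shape[1])
    converged = False
    for _ in range(max_iter):
        p = expit(design @ beta)
        w = p * (1.0 - p)
        grad = design.T @ (y - p)
        hess = (design * w[:, None]).T @ design + 1e-12 * np.eye(len(beta))
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.abs(step).max() < tol:
            converged = True
            break
    return beta, converged


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC swept over all score cutpoints (predict positive when score >= cut)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = labels[order]
    n1 = lab.sum()
    n0 = len(lab) - n1
    tp = np.cumsum(lab)
    fp = np.cumsum(1 - lab)
    # keep the last index of each tied score block
    distinct = np.r_[s[1:] != s[:-1], True]
    tpr = tp[distinct] / n1
    fpr = fp[distinct] / n0
    return np.vstack([np.array([0.0, 0.0]), np.column_stack([fpr, tpr])])


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC with midrank tie handling."""
    ranks = sps.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def logistic_eval(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5):
    """ML logistic fit (Newton) + confusion/ROC evaluation at the threshold.

    Complete separation is flagged with a warning; coefficients and the
    evaluation are still reported.  Returns (coefficients, ClassifierEval).
    """
    x = np.asarray(scores, float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    design = np.column_stack([np.ones(len(y)), x])
    beta, converged = _newton_logistic(design, y)
    prob = expit(design @ beta)
    separated = (not converged) or (prob[y == 1].min() > prob[y == 0].max()
                                    and np.abs(beta).max() > 20)
    if separated:
        warnings.warn("possible complete separation; coefficients are unstable")
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    ev = ClassifierEval(
        confusion=np.array([[tn, fp], [fn, tp]]),
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=auc_mann_whitney(prob, y.astype(int)),
        roc_points=roc_curve_points(prob, y.astype(int)),
        separated=separated,
    )
    return beta, ev
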