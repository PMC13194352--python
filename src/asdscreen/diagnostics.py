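"""ROC analysis, Youden cut-offs, resampled AUCs, and logistic regression.

The discrimination analysis follows the diagnostic-evaluation protocol
of the reference study:

* AUC by the non-parametric (Mann-Whitney) estimator, ties counted half;
* standard error by the Hanley-McNeil exponential approximation (a
  DeLong variance is available as an alternative) and 95 % CI as
  ``auc +/- 1.96 * se`` clipped to [0, 1];
* optimal cut-off maximizing the Youden index J = sens + spec - 1 with
  the positive decision rule ``score >= cutoff`` (higher index => ASD);
  reported cut-offs are midpoints between adjacent distinct scores;
* stratified 10-fold cross-validated AUC and stratified bootstrap
  (1,000 resamples) bias-corrected AUC with percentile CI;
* multivariable binary logistic regression with Wald chi-square
  statistics and per-unit odds ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ROCResult",
    "LogitResult",
    "roc_auc",
    "roc_points",
    "auc_se_ci",
    "delong_se",
    "ci_from_auc_se",
    "youden_cutoff",
    "crossval_auc",
    "bootstrap_auc",
    "logistic_fit",
    "or_from_beta",
    "diagnostic_report",
]


def _check_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must align")
    if not set(np.unique(labels)) == {0, 1}:
        raise ValueError("need both classes present (labels 0 and 1)")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """Non-parametric AUC: P(score_case > score_control) + 0.5 P(tie).

    Computed from mid-ranks, which is exactly the Mann-Whitney estimator
    and equals the trapezoidal area under the empirical ROC curve.
    """
    scores, labels = _check_labels(scores, labels)
    ranks = sstats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC: one row per candidate threshold (score >= thr positive).

    Thresholds are midpoints between adjacent distinct scores plus
    sentinels below/above the score range, so the curve runs from
    (sens=1, spec=0) to (sens=0, spec=1).
    """
    scores, labels = _check_labels(scores, labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    n1 = labels.sum()
    n0 = labels.size - n1
    rows = []
    for thr in thresholds:
        pos = scores >= thr
        sens = float((pos & (labels == 1)).sum() / n1)
        spec = float((~pos & (labels == 0)).sum() / n0)
        rows.append({"threshold": float(thr), "sensitivity": sens,
                     "specificity": spec})
    return pd.DataFrame(rows)


def auc_se_ci(auc: float, n_cases: int, n_controls: int):
    """Hanley-McNeil SE and normal 95 % CI for a non-parametric AUC.

    Uses the exponential approximation Q1 = A/(2-A), Q2 = 2A^2/(1+A);
    the CI is ``auc +/- 1.96 * se`` clipped to [0, 1].
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("counts must be >= 1")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1 - a) + (n_cases - 1) * (q1 - a * a) + (n_controls - 1) * (q2 - a * a)
    ) / (n_cases * n_controls)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = ci_from_auc_se(a, se)
    return se, lo, hi


def ci_from_auc_se(auc: float, se: float):
    """Normal 95 % CI ``auc +/- 1.96*se``, clipped to [0, 1]."""
    return float(max(auc - 1.96 * se, 0.0)), float(min(auc + 1.96 * se, 1.0))


def delong_se(scores, labels) -> float:
    """DeLong standard error of the Mann-Whitney AUC (alternative to
    Hanley-McNeil; not the default in reports)."""
    scores, labels = _check_labels(scores, labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = cases.size, controls.size
    # placement values
    v10 = np.array([(np.sum(c > controls) + 0.5 * np.sum(c == controls)) / n
                    for c in cases])
    v01 = np.array([(np.sum(cases > c0) + 0.5 * np.sum(cases == c0)) / m
                    for c0 in controls])
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    return float(np.sqrt(var))


def youden_cutoff(scores, labels):
    """Cut-off maximizing J = sens + spec - 1 (decision rule: score >= cutoff).

    The reported cut-off is the midpoint between the adjacent distinct
    scores bracketing the optimum; ties in J break toward higher
    sensitivity (lower cut-off). Returns (cutoff, sens, spec, J).
    """
    pts = roc_points(scores, labels)
    j = pts["sensitivity"] + pts["specificity"] - 1.0
    jmax = j.max()
    # thresholds ascend, sensitivity is non-increasing: the first argmax
    # has the highest sensitivity
    i = int(np.flatnonzero(np.isclose(j, jmax, atol=1e-12))[0])
    row = pts.iloc[i]
    return (
        float(row["threshold"]),
        float(row["sensitivity"]),
        float(row["specificity"]),
        float(jmax),
    )


def crossval_auc(scores, labels, k: int = 10, seed: int | None = None,
                 n_repeats: int = 10):
    """Repeated stratified k-fold held-out AUC for a single score.

    A univariate index needs no fitting, but fold-wise evaluation
    reflects the variability a cross-validated ROC would show; the fold
    split is repeated ``n_repeats`` times to stabilize the estimate.
    Returns ``(mean_auc, (ci_lo, ci_hi))`` with a normal CI on the fold
    mean.
    """
    scores, labels = _check_labels(scores, labels)
    if scores.size < k:
        raise ValueError("need n >= k")
    fold_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    fold_aucs = []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(fold_seeds[r]))
        for _, test_idx in skf.split(scores.reshape(-1, 1), labels):
            fold_aucs.append(roc_auc(scores[test_idx], labels[test_idx]))
    fold_aucs = np.asarray(fold_aucs)
    mean = float(fold_aucs.mean())
    se = float(fold_aucs.std(ddof=1) / np.sqrt(k * n_repeats))
    return mean, (max(mean - 1.96 * se, 0.0), min(mean + 1.96 * se, 1.0))


def bootstrap_auc(scores, labels, n_boot: int = 1000, seed: int | None = None):
    """Stratified bootstrap of the AUC: bias-corrected point estimate and
    2.5/97.5 percentile CI.

    Bias correction: ``2*auc_full - mean(auc_boot)``. Cases and controls
    are resampled separately so every resample contains both classes.
    Returns ``(auc_bc, (ci_lo, ci_hi))``.
    """
    scores, labels = _check_labels(scores, labels)
    rng = np.random.default_rng(seed)
    full = roc_auc(scores, labels)
    case_idx = np.flatnonzero(labels == 1)
    ctrl_idx = np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ci = rng.choice(case_idx, case_idx.size, replace=True)
        co = rng.choice(ctrl_idx, ctrl_idx.size, replace=True)
        idx = np.concatenate([ci, co])
        boots[b] = roc_auc(scores[idx], labels[idx])
    bc = float(2.0 * full - boots.mean())
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return bc, (float(lo), float(hi))


@dataclass
class LogitResult:
    """Multivariable logistic fit: per-covariate effects and odds ratios."""

    names: list
    beta: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    p: np.ndarray
    odds_ratio: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    intercept: float
    intercept_se: float
    converged: bool
    n_iter: int
    dropped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variable": self.names,
                "beta": self.beta,
                "se": self.se,
                "wald_chi2": self.wald,
                "odds_ratio": self.odds_ratio,
                "or_ci_low": self.or_ci_low,
                "or_ci_high": self.or_ci_high,
                "p": self.p,
            }
        )
        const = pd.DataFrame(
            {
                "variable": ["constant"],
                "beta": [self.intercept],
                "se": [self.intercept_se],
                "wald_chi2": [(self.intercept / self.intercept_se) ** 2],
                "odds_ratio": [np.nan],
                "or_ci_low": [np.nan],
                "or_ci_high": [np.nan],
                "p": [2 * sstats.norm.sf(abs(self.intercept / self.intercept_se))],
            }
        )
        return pd.concat([df, const], ignore_index=True)


class PerfectSeparationError(RuntimeError):
    """The outcome is perfectly separated by a linear combination of
    covariates; maximum-likelihood estimates do not exist."""


def logistic_fit(design, outcomes, names=None, tol: float = 1e-8) -> LogitResult:
    """Maximum-likelihood binary logistic regression (Newton/IRLS).

    ``design`` is the covariate matrix without an intercept column (one
    is added). Zero-variance covariates are dropped and reported in
    ``dropped``. Perfect separation raises
    :class:`PerfectSeparationError`. SEs come from the observed
    information matrix; Wald = (beta/se)^2 with p from chi-square(1); OR
    CIs are ``exp(beta +/- 1.96*se)``.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(outcomes).size != 1:
        X = X.T
    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    X = X[:, keep]
    names = [names[j] for j in keep]
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")

    Xc = sm.add_constant(X, has_constant="add")
    with np.errstate(all="ignore"):
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, method="newton", tol=tol, maxiter=200)
            params = np.asarray(fit.params)
            bse = np.asarray(fit.bse)  # may raise on a singular Hessian
        except Exception as exc:  # statsmodels raises on hard separation
            raise PerfectSeparationError(str(exc)) from exc
    # soft separation: fitted probabilities collapse to 0/1
    pred = fit.predict(Xc)
    eps = 1e-8
    if np.all((pred < eps) | (pred > 1 - eps)) or not np.all(np.isfinite(bse)):
        raise PerfectSeparationError("fitted probabilities are all 0 or 1")
    beta, se = params[1:], bse[1:]
    wald = (beta / se) ** 2
    p = sstats.chi2.sf(wald, df=1)
    or_, lo, hi = or_from_beta(beta, se)
    return LogitResult(
        names=names,
        beta=beta,
        se=se,
        wald=wald,
        p=p,
        odds_ratio=or_,
        or_ci_low=lo,
        or_ci_high=hi,
        intercept=float(params[0]),
        intercept_se=float(bse[0]),
        converged=bool(fit.mle_retvals.get("converged", True)),
        n_iter=int(fit.mle_retvals.get("iterations", 0)),
        dropped=dropped,
    )


def or_from_beta(beta, se):
    """Odds ratio and 95 % CI from a logistic coefficient and its SE."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    return np.exp(beta), np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)


def diagnostic_report(
    cohort: pd.DataFrame,
    score_cols,
    group_col: str = "group",
    positive: str = "ASD",
    cv_k: int = 10,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Full discrimination analysis for each score column plus the
    multivariable logistic model over all of them.

    Returns a JSON-serializable dict: per-score ROC/AUC/cut-off and
    resampled AUCs, and the logistic coefficient table.
    """
    labels = (cohort[group_col] == positive).astype(int).to_numpy()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(2 * len(list(score_cols)))
    report = {"scores": {}, "logistic": None}
    for i, col in enumerate(score_cols):
        scores = cohort[col].to_numpy(dtype=float)
        auc = roc_auc(scores, labels)
        se, lo, hi = auc_se_ci(auc, int(labels.sum()), int((1 - labels).sum()))
        cutoff, sens, spec, j = youden_cutoff(scores, labels)
        cv_seed = int(child[2 * i].generate_state(1)[0] % (2**31))
        bs_seed = int(child[2 * i + 1].generate_state(1)[0] % (2**31))
        k_eff = min(cv_k, int(labels.sum()), int((1 - labels).sum()))
        if k_eff >= 2:
            cv_mean, cv_ci = crossval_auc(scores, labels, k=k_eff, seed=cv_seed)
        else:
            cv_mean, cv_ci = None, (None, None)
        bc, bc_ci = bootstrap_auc(scores, labels, n_boot=n_boot, seed=bs_seed)
        report["scores"][col] = {
            "auc": auc,
            "se": se,
            "ci95": [lo, hi],
            "cutoff": cutoff,
            "sensitivity": sens,
            "specificity": spec,
            "youden_j": j,
            "cv_auc": cv_mean,
            "cv_ci95": list(cv_ci),
            "bootstrap_auc_bc": bc,
            "bootstrap_ci95": list(bc_ci),
            "roc": roc_points(scores, labels).to_dict(orient="list"),
        }
    X = cohort[list(score_cols)].to_numpy(dtype=float)
    try:
        logit = logistic_fit(X, labels, names=list(score_cols))
        report["logistic"] = json.loads(logit.to_frame().to_json(orient="records"))
    except PerfectSeparationError as exc:
        report["logistic"] = {"error": f"perfect separation: {exc}"}
    return report
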