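"""Signature scoring and survival/covariate statistics.

The per-sample signature score is the plain sum of the signature genes'
expression values. Samples are dichotomized at the median score (strictly
above = "high"), survival is summarized by the Kaplan-Meier product-limit
estimator, group separation is tested with the unstratified two-sample
log-rank test, and the score's relation to clinical covariates is assessed
with univariate GLMs: a Gaussian linear model (score as response) for
continuous/ordinal features, logistic regression (score as predictor) for
binary features.

All estimators here are implemented from first principles; established
survival/GLM libraries serve only as cross-validation oracles in the test
suite, never at run time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import Signature, normalize_gene_id


@dataclass
class SurvivalCurve:
    times: np.ndarray       # distinct event times, ascending
    at_risk: np.ndarray     # n_i just before each event time
    deaths: np.ndarray      # d_i at each event time
    survival: np.ndarray    # S(t_i), product-limit
    censor_times: np.ndarray  # times of right-censored observations


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]


@dataclass
class GlmResult:
    feature: str
    family: str             # "gaussian" or "binomial"
    estimate: float
    std_error: float
    statistic: float
    p_value: float
    n: int
    converged: bool = True


def signature_score(
    expression: pd.DataFrame, signature: Signature | Sequence[str]
) -> tuple[pd.Series, float]:
    """Per-sample sum of signature-gene expression.

    `expression` is genes x samples. Signature genes absent from the matrix
    are logged and skipped; the returned coverage is the fraction found.
    Raises ValueError if no signature gene is present.
    """
    genes = signature.members if isinstance(signature, Signature) else signature
    wanted = {normalize_gene_id(g) for g in genes}
    index_norm = expression.index.map(normalize_gene_id)
    mask = index_norm.isin(wanted)
    found = set(index_norm[mask])
    missing = wanted - found
    if not found:
        raise ValueError("no signature genes present in the expression matrix")
    if missing:
        warnings.warn(
            f"{len(missing)}/{len(wanted)} signature genes absent from the "
            "expression matrix; skipped"
        )
    scores = expression.loc[np.asarray(mask)].sum(axis=0)
    scores.name = "score"
    return scores, len(found) / len(wanted)


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples 'high' (score strictly above the median) or 'low'.

    The median is the 50th percentile (midpoint of the middle two values for
    even n); median-tied samples go to 'low'. A degenerate all-equal input
    yields everyone 'low' with a warning.
    """
    med = float(np.median(scores.to_numpy(dtype=float)))
    groups = pd.Series(
        np.where(scores.to_numpy(dtype=float) > med, "high", "low"),
        index=scores.index, name="group",
    )
    if (groups == "low").all():
        warnings.warn("median split degenerate: all samples assigned to 'low'")
    return groups


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i;
    samples censored at an event time remain at risk at that time (censoring
    ordered after deaths at ties).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival times")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n_i = np.array([(t >= et).sum() for et in event_times], dtype=float)
    d_i = np.array([((t == et) & (e == 1)).sum() for et in event_times], dtype=float)
    surv = np.cumprod(1.0 - d_i / n_i) if len(event_times) else np.array([])
    return SurvivalCurve(
        times=event_times, at_risk=n_i, deaths=d_i, survival=surv,
        censor_times=np.sort(t[e == 0]),
    )


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence[str]
) -> LogRankResult:
    """Unstratified two-sample log-rank test.

    At each distinct event time j with n_j at risk (n_1j in group 1) and d_j
    total deaths: E_1j = d_j n_1j / n_j and
    V_j = d_j (n_1j/n_j)(1 - n_1j/n_j)(n_j - d_j)/(n_j - 1);
    chi-square = (sum(O_1j - E_1j))^2 / sum V_j on 1 df.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {labels}")
    for lab in labels:
        if (g == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    if e.sum() == 0:
        warnings.warn("no events observed; log-rank p set to 1")
        return LogRankResult(0.0, 1, 1.0,
                             {lab: 0.0 for lab in labels},
                             {lab: 0.0 for lab in labels})

    in1 = g == labels[0]
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    obs1 = 0.0
    exp1 = 0.0
    for et in event_times:
        at_risk = t >= et
        n_j = at_risk.sum()
        n_1j = (at_risk & in1).sum()
        d_j = ((t == et) & (e == 1)).sum()
        d_1j = ((t == et) & (e == 1) & in1).sum()
        e_1j = d_j * n_1j / n_j
        obs1 += d_1j
        exp1 += e_1j
        o_minus_e += d_1j - e_1j
        if n_j > 1:
            var += d_j * (n_1j / n_j) * (1 - n_1j / n_j) * (n_j - d_j) / (n_j - 1)
    chi2 = (o_minus_e**2) / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    total_events = float(e.sum())
    observed = {labels[0]: float(obs1), labels[1]: total_events - float(obs1)}
    expected = {labels[0]: float(exp1), labels[1]: total_events - float(exp1)}
    return LogRankResult(float(chi2), 1, p, observed, expected)


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[~np.isnan(x)])
    return len(vals) == 2


def _gaussian_fit(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, float]:
    """Simple linear regression y ~ x by least squares; returns slope, SE, t, p."""
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = (xc**2).sum()
    if sxx == 0:
        return float("nan"), float("nan"), float("nan"), float("nan")
    slope = (xc * yc).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    df = n - 2
    sigma2 = (resid**2).sum() / df
    se = float(np.sqrt(sigma2 / sxx))
    tstat = slope / se if se > 0 else float("nan")
    p = 2.0 * float(stats.t.sf(abs(tstat), df)) if se > 0 else float("nan")
    return float(slope), se, float(tstat), p


def _logistic_irls(
    y: np.ndarray, x: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[float, float, bool]:
    """Logistic regression y ~ 1 + x by IRLS; returns slope, SE, converged."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            break
        z = eta + (y - mu) / np.maximum(w, 1e-12)
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        if np.abs(beta_new - beta).max() < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se = float("nan")
    # perfect separation inflates |beta| and SE together; flag it
    if not converged or abs(beta[1]) > 25:
        return float(beta[1]), float("nan"), False
    return float(beta[1]), se, True


def univariate_glm(
    cohort: pd.DataFrame,
    feature: str,
    score_col: str = "score",
    binary: bool | None = None,
) -> GlmResult:
    """Univariate GLM relating the signature score to one clinical feature.

    The score is standardized (mean 0, SD 1) first. Non-binary features are
    fit with a Gaussian linear model score ~ feature (slope, SE, t, p);
    binary features with logistic regression feature ~ score (slope, SE,
    Wald z, p). Non-convergence or separation yields a flagged result with
    NaN SE rather than an exception.
    """
    sub = cohort[[score_col, feature]].dropna()
    y_raw = sub[score_col].to_numpy(dtype=float)
    x = sub[feature].to_numpy(dtype=float)
    score = (y_raw - y_raw.mean()) / y_raw.std(ddof=0)
    if binary is None:
        binary = _is_binary(x)
    if binary:
        lo, hi = np.unique(x)[0], np.unique(x)[-1]
        yb = (x == hi).astype(float)
        slope, se, converged = _logistic_irls(yb, score)
        if not np.isfinite(se):
            return GlmResult(feature, "binomial", slope, float("nan"),
                             float("nan"), float("nan"), len(sub), converged=False)
        z = slope / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        return GlmResult(feature, "binomial", slope, se, z, p, len(sub))
    slope, se, tstat, p = _gaussian_fit(score, x)
    return GlmResult(feature, "gaussian", slope, se, tstat, p, len(sub))
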