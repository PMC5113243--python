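"""Hierarchical statistics for octant-level aneurysm data.

The response is the per-octant wall ``suv_max``.  Because octants are nested
in slices and slices in patients, fixed effects are estimated with a linear
mixed-effects model carrying three random intercepts: patient, slice (nested
in patient) and octant number (1-8, modelled per patient).  The fitter is a
profiled REML/ML estimator specialised to random-intercept structures: the
residual variance is profiled out, the three variance ratios are optimised by
Nelder-Mead, and all per-patient linear algebra goes through the Woodbury
identity so a full cohort fit takes well under a second.

AIC model comparisons (backward elimination, null-vs-full) use ML fits;
reported coefficients and variance components come from REML, the standard
resolution when both are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "LMEFit",
    "ROCResult",
    "GroupComparison",
    "fit_lme",
    "backward_eliminate",
    "compare_null_full",
    "roc_analysis",
    "group_compare",
    "high_low_stress_split",
    "FULL_MODEL_TERMS",
    "STRESS_TERMS",
]

#: fixed-effect terms of the full multivariate model (plus intercept)
FULL_MODEL_TERMS = (
    "norm_stress",
    "ilt_ratio",
    "calcium_ratio",
    "outer_diameter",
    "lumen_diameter",
    "norm_stress:ilt_ratio",
)

#: the terms involving structural stress, removed to form the null model
STRESS_TERMS = ("norm_stress", "norm_stress:ilt_ratio")

_GROUPINGS = ("patient", "slice", "octant")
_BOUNDARY_SD = 1e-5  # variance ratio below which a component is "pinned at 0"


@dataclass
class LMEFit:
    """Result of a linear mixed-effects fit.

    ``psi`` holds the random-intercept variances keyed by grouping
    (``patient``, ``slice``, ``octant``); ``fixed_effects`` is a DataFrame
    with estimate, SE and Wald p-value per term.
    """

    fixed_effects: pd.DataFrame
    psi: dict
    residual_variance: float
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    formula: str
    reml: bool
    converged: bool
    boundary: dict = field(default_factory=dict)

    @property
    def random_sd(self) -> dict:
        out = {k: float(np.sqrt(v)) for k, v in self.psi.items()}
        out["residual"] = float(np.sqrt(self.residual_variance))
        return out

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])


def _design_matrix(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    """Intercept plus main effects and ``a:b`` product interactions."""
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for t in terms:
        if t in ("1", "Intercept"):
            continue
        if ":" in t:
            a, b = t.split(":")
            cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        else:
            cols.append(df[t].to_numpy(float))
        names.append(t)
    return np.column_stack(cols), names


def _patient_blocks(df: pd.DataFrame, X: np.ndarray, y: np.ndarray) -> list[dict]:
    """Per-patient sufficient statistics for the Woodbury likelihood."""
    blocks = []
    for _, idx in df.groupby("patient_id", sort=True).indices.items():
        Xi, yi = X[idx], y[idx]
        ni = len(idx)
        sl = pd.factorize(df["slice_index"].to_numpy()[idx])[0]
        oc = pd.factorize(df["octant_index"].to_numpy()[idx])[0]
        Zs = np.zeros((ni, sl.max() + 1))
        Zs[np.arange(ni), sl] = 1.0
        Zo = np.zeros((ni, oc.max() + 1))
        Zo[np.arange(ni), oc] = 1.0
        U = np.column_stack([np.ones((ni, 1)), Zs, Zo])
        blocks.append(
            dict(
                qs=(1, Zs.shape[1], Zo.shape[1]),
                UtU=U.T @ U,
                UtX=U.T @ Xi,
                Uty=U.T @ yi,
                XtX=Xi.T @ Xi,
                Xty=Xi.T @ yi,
                yty=float(yi @ yi),
                n=ni,
            )
        )
    return blocks


def _profiled_crit(log_gamma, blocks, n, p, reml):
    """-2 log-likelihood profiled over beta and the residual variance.

    ``gamma`` are the three random-intercept variances expressed as ratios to
    the residual variance, in grouping order (patient, slice, octant).
    """
    g = np.exp(np.clip(log_gamma, -40.0, 40.0))
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yVy = 0.0
    logdetW = 0.0
    for b in blocks:
        d = np.repeat(g, b["qs"])
        M = b["UtU"].copy()
        M[np.diag_indices_from(M)] += 1.0 / np.maximum(d, 1e-300)
        cf = np.linalg.cholesky(M)
        logdetW += float(np.sum(np.log(d))) + 2.0 * float(np.sum(np.log(np.diag(cf))))
        # A' W^{-1} B = A'B - (U'A)' M^{-1} (U'B)   for W = I + U D U'
        sUX = np.linalg.solve(M, b["UtX"])
        sUy = np.linalg.solve(M, b["Uty"])
        XtVX += b["XtX"] - b["UtX"].T @ sUX
        XtVy += b["Xty"] - b["UtX"].T @ sUy
        yVy += b["yty"] - float(b["Uty"] @ sUy)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = float(yVy - 2.0 * beta @ XtVy + beta @ XtVX @ beta)
    rss = max(rss, 1e-300)
    if reml:
        s2 = rss / (n - p)
        crit = (
            (n - p) * np.log(2 * np.pi)
            + (n - p) * np.log(s2)
            + logdetW
            + float(np.linalg.slogdet(XtVX)[1])
            + (n - p)
        )
    else:
        s2 = rss / n
        crit = n * np.log(2 * np.pi) + n * np.log(s2) + logdetW + n
    return crit, beta, s2, XtVX


def fit_lme(
    table: pd.DataFrame,
    fixed_terms=("norm_stress",),
    reml: bool = True,
    start_gamma=(0.1, 0.01, 0.1),
) -> LMEFit:
    """Fit ``suv_max ~ fixed_terms`` with patient/slice/octant random intercepts.

    Parameters
    ----------
    table : DataFrame
        Octant records; must carry ``patient_id``, ``slice_index``,
        ``octant_index``, ``suv_max`` and every column a fixed term names.
    fixed_terms : sequence of str
        Main effects by column name, interactions as ``"a:b"``.  The
        intercept is always included.
    reml : bool
        Restricted ML (reported coefficients) or ML (AIC comparisons).

    A variance component driven to the boundary is pinned at zero and
    flagged in ``LMEFit.boundary`` rather than raised as an error.
    """
    for grouping, col in zip(_GROUPINGS, ("patient_id", "slice_index", "octant_index")):
        if table[col].nunique() < 2:
            raise ValueError(f"grouping {grouping!r} needs >= 2 levels")
    y = table["suv_max"].to_numpy(float)
    X, names = _design_matrix(table, fixed_terms)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        const = [nm for nm in names[1:] if np.ptp(X[:, names.index(nm)]) == 0]
        raise ValueError(
            "rank-deficient fixed-effects design; drop constant or collinear "
            f"terms (constant: {const or 'none'})"
        )
    blocks = _patient_blocks(table, X, y)

    fun = lambda lg: _profiled_crit(lg, blocks, n, p, reml)[0]
    res = minimize(
        fun,
        np.log(np.asarray(start_gamma, float)),
        method="Nelder-Mead",
        options=dict(xatol=1e-7, fatol=1e-9, maxiter=4000, maxfev=6000),
    )
    crit, beta, s2, XtVX = _profiled_crit(res.x, blocks, n, p, reml)
    gamma = np.exp(res.x)
    boundary = {grp: bool(g < _BOUNDARY_SD) for grp, g in zip(_GROUPINGS, gamma)}
    gamma = np.where(gamma < _BOUNDARY_SD, 0.0, gamma)
    psi = {grp: float(g * s2) for grp, g in zip(_GROUPINGS, gamma)}

    cov_beta = s2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    fe = pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": pvals}, index=pd.Index(names, name="term")
    )

    loglik = -0.5 * crit
    k = p + 4  # fixed effects + three variance components + residual
    aic = 2.0 * k - 2.0 * loglik
    return LMEFit(
        fixed_effects=fe,
        psi=psi,
        residual_variance=float(s2),
        loglik=float(loglik),
        aic=float(aic),
        n_params=k,
        n_obs=n,
        formula="suv_max ~ 1 + " + " + ".join(t for t in fixed_terms if t not in ("1",)),
        reml=reml,
        converged=bool(res.success),
        boundary=boundary,
    )


def _removable(terms) -> list[str]:
    """Terms removable under marginality: mains stay while their interaction lives."""
    protected = set()
    for t in terms:
        if ":" in t:
            protected.update(t.split(":"))
    return [t for t in terms if ":" in t or t not in protected]


def backward_eliminate(
    table: pd.DataFrame, full_terms=FULL_MODEL_TERMS
) -> tuple[LMEFit, pd.DataFrame]:
    """AIC backward elimination over the fixed-effect structure.

    Starting from ``full_terms``, repeatedly drop the single term whose
    removal most decreases the ML AIC, never dropping a main effect while its
    interaction remains; stop when no removal lowers AIC.  Returns the final
    model refit by REML and the elimination trace (ML AICs).
    """
    terms = list(full_terms)
    current = fit_lme(table, terms, reml=False)
    trace = [{"step": 0, "removed": None, "terms": "+".join(terms), "aic": current.aic}]
    step = 0
    while True:
        candidates = _removable(terms)
        if not candidates:
            break
        fits = {
            t: fit_lme(table, [u for u in terms if u != t], reml=False) for t in candidates
        }
        best = min(fits, key=lambda t: fits[t].aic)
        if fits[best].aic >= current.aic:
            break
        terms.remove(best)
        current = fits[best]
        step += 1
        trace.append(
            {"step": step, "removed": best, "terms": "+".join(terms) or "1", "aic": current.aic}
        )
    final = fit_lme(table, terms, reml=True)
    return final, pd.DataFrame(trace)


def compare_null_full(
    table: pd.DataFrame,
    full_terms=FULL_MODEL_TERMS,
    stress_terms=STRESS_TERMS,
) -> dict:
    """AIC gain from including structural stress in the multivariate model.

    Both models are fit by ML on the same rows; returns
    ``delta_aic = AIC(null) - AIC(full)`` (positive favours keeping stress).
    """
    null_terms = [t for t in full_terms if t not in stress_terms]
    full = fit_lme(table, full_terms, reml=False)
    null = fit_lme(table, null_terms, reml=False)
    return {
        "delta_aic": float(null.aic - full.aic),
        "aic_full": full.aic,
        "aic_null": null.aic,
        "full": full,
        "null": null,
    }


@dataclass
class ROCResult:
    """Empirical ROC of one predictor against the high-uptake label."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float | None
    youden_threshold: float | None
    youden_j: float | None
    n: int
    n_positive: int
    defined: bool


def _roc_one(score: np.ndarray, label: np.ndarray) -> ROCResult:
    n_pos = int(label.sum())
    if n_pos == 0 or n_pos == len(label):
        return ROCResult(
            thresholds=np.array([]),
            sensitivity=np.array([]),
            specificity=np.array([]),
            auc=None,
            youden_threshold=None,
            youden_j=None,
            n=len(label),
            n_positive=n_pos,
            defined=False,
        )
    fpr, tpr, thr = _sk_roc_curve(label, score)
    area = float(_sk_auc(fpr, tpr))
    j = tpr - fpr
    best = j >= j.max() - 1e-12
    # ties at the maximum resolve to the lowest threshold
    finite = np.isfinite(thr)
    cand = np.where(best & finite)[0]
    youden_thr = float(thr[cand].min()) if cand.size else float("nan")
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=area,
        youden_threshold=youden_thr,
        youden_j=float(j.max()),
        n=len(label),
        n_positive=n_pos,
        defined=True,
    )


def roc_analysis(
    table: pd.DataFrame,
    predictor: str = "norm_stress",
    suv_cutpoint: float = 2.0,
    ilt_strata=(None, 0.33, 0.67),
) -> dict:
    """ROC of ``predictor`` for high uptake (suv_max > cutpoint), by ILT stratum.

    ``ilt_strata`` entries are lower ILT-ratio cutoffs (``None`` = all
    octants).  Keys of the returned dict are ``"all"`` or ``"ilt>0.33"`` etc.
    """
    out = {}
    label_all = (table["suv_max"].to_numpy(float) > suv_cutpoint).astype(int)
    score_all = table[predictor].to_numpy(float)
    for cut in ilt_strata:
        if cut is None:
            key, m = "all", np.ones(len(table), bool)
        else:
            key, m = f"ilt>{cut:g}", table["ilt_ratio"].to_numpy(float) > cut
        out[key] = _roc_one(score_all[m], label_all[m])
    return out


@dataclass
class GroupComparison:
    method: str
    statistic: float
    p: float
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    n_a: int
    n_b: int
    flag: str | None = None


def _median_iqr(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(x)), (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


def group_compare(values_a, values_b, method: str = "auto", shapiro_alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison: Student t when both groups pass a Shapiro
    normality gate, Mann-Whitney otherwise (or on request)."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    if method == "auto":
        try:
            normal = (
                sps.shapiro(a).pvalue > shapiro_alpha
                and sps.shapiro(b).pvalue > shapiro_alpha
            )
        except ValueError:  # constant data
            normal = False
        method = "ttest" if normal else "mannwhitney"
    if method == "ttest":
        stat, p = sps.ttest_ind(a, b)
    elif method == "mannwhitney":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    ma, ia = _median_iqr(a)
    mb, ib = _median_iqr(b)
    return GroupComparison(
        method=method,
        statistic=float(stat),
        p=float(min(p, 1.0)),
        median_a=ma,
        iqr_a=ia,
        median_b=mb,
        iqr_b=ib,
        n_a=len(a),
        n_b=len(b),
    )


def high_low_stress_split(
    table: pd.DataFrame,
    stress_threshold: float = 0.45,
    ilt_cutoff: float = 0.67,
    method: str = "auto",
) -> GroupComparison:
    """Compare SUV_max between high- and low-stress octants in an ILT stratum.

    The stratum is ``ilt_ratio > ilt_cutoff``; high stress means
    ``norm_stress > stress_threshold``.  Group a is high stress.
    """
    stratum = table[table["ilt_ratio"].to_numpy(float) > ilt_cutoff]
    if len(stratum) == 0:
        raise ValueError("empty ILT stratum")
    hi = stratum[stratum["norm_stress"] > stress_threshold]["suv_max"].to_numpy(float)
    lo = stratum[stratum["norm_stress"] <= stress_threshold]["suv_max"].to_numpy(float)
    if len(hi) < 3 or len(lo) < 3:
        gc = GroupComparison(
            method="none",
            statistic=float("nan"),
            p=float("nan"),
            median_a=float(np.median(hi)) if len(hi) else float("nan"),
            iqr_a=(float("nan"), float("nan")),
            median_b=float(np.median(lo)) if len(lo) else float("nan"),
            iqr_b=(float("nan"), float("nan")),
            n_a=len(hi),
            n_b=len(lo),
            flag="degenerate-group",
        )
        return gc
    return group_compare(hi, lo, method=method)
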