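"""Cohort statistics: age-model selection, FDR, repeatability, conversions.

For each regional water-fraction outcome two nested ordinary least-squares
models are fitted,

    LM:  WF = b0 + b1*Age + b2*Sex + b3*Volume + e
    QM:  WF = b0 + b1*Age^2 + b2*Age + b3*Sex + b4*Volume + e

and compared with the extra-sum-of-squares ANOVA F-test for the Age^2
term; the quadratic model is selected when that test is significant at
``alpha``.  Age p-values across the nine (ROI x water fraction) outcomes
are adjusted with the Benjamini-Hochberg false-discovery-rate procedure.
Repeatability of repeated scans is summarized Bland-Altman style, and the
link between organ-level CSF (ventricle volume) and tissue-level CSF
(regional CSFF) by Spearman rank correlation.

Two scalar conversions translate measured fractions to volume terms: the
CSF volume fraction ``V_CSF = water_content * CSFF`` and the
compartment-shift arithmetic showing how a loss of intra/extra-cellular
water content propagates into the (relative) fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "fit_lm_qm",
    "select_model",
    "fdr_adjust",
    "bland_altman",
    "spearman_corr",
    "csff_to_vcsf",
    "compartment_shift",
    "analyze_cohort",
]


@dataclass
class RegressionResult:
    """Selected age model for one regional water-fraction outcome."""

    outcome: str
    model: str                    # "LM" or "QM"
    params: dict[str, float]
    bse: dict[str, float]
    age_p: float                  # reported age p-value (see select_model)
    age_p_linear: float           # Wald p of the Age coefficient
    age_p_quadratic: float | None # Wald p of Age^2 (QM only)
    anova_f: float
    anova_p: float
    n: int


@dataclass
class BlandAltmanResult:
    """Repeatability summary of paired measurements."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int


def _design(table: pd.DataFrame, quadratic: bool) -> tuple[pd.DataFrame, pd.Series]:
    cols = {"const": 1.0, "age": table["age_years"]}
    if quadratic:
        cols["age_sq"] = table["age_years"] ** 2
    cols["sex"] = table["sex"]
    cols["volume"] = table["normalized_volume"]
    X = pd.DataFrame(cols, index=table.index)
    return X


def fit_lm_qm(table: pd.DataFrame, outcome: tuple[str, str]):
    """OLS fits of the nested linear and quadratic age models.

    ``table`` is the tidy cohort table (one row per subject x ROI);
    ``outcome`` is ``(roi, wf)`` with wf in {"mwf", "iewf", "csff"}.
    Returns ``(lm_fit, qm_fit)`` as statsmodels results.
    """
    roi, wf = outcome
    sub = table[table["roi"] == roi]
    if sub.empty:
        raise ValueError(f"no rows for ROI '{roi}'")
    y = sub[wf]
    if y.isna().any() or sub[["age_years", "sex", "normalized_volume"]].isna().any().any():
        raise ValueError(f"missing values in outcome/covariates for {outcome}")
    if len(sub) < 6:
        raise ValueError("need n >= 6 subjects to fit the 5-parameter QM")
    for col in ("sex", "normalized_volume", "age_years"):
        if sub[col].nunique() < 2:
            raise ValueError(f"design is rank deficient: column '{col}' is constant")
    lm = sm.OLS(y, _design(sub, quadratic=False)).fit()
    qm = sm.OLS(y, _design(sub, quadratic=True)).fit()
    return lm, qm


def select_model(lm, qm, alpha: float = 0.05, outcome: str = "") -> RegressionResult:
    """ANOVA selection between the nested linear and quadratic models.

    The extra-sum-of-squares statistic ``F = (RSS_LM - RSS_QM) /
    (RSS_QM / (n - 5))`` on (1, n-5) degrees of freedom tests whether the
    Age^2 term is needed; QM is chosen iff its p-value is below alpha.
    The reported age p-value is the ANOVA p of the Age^2 term under QM and
    the Wald p of the Age coefficient under LM.  When both models fit
    exactly (RSS_QM = RSS_LM = 0) the parsimonious LM is kept.
    """
    if lm.nobs != qm.nobs:
        raise ValueError("LM and QM were fitted on different data")
    n = int(qm.nobs)
    rss_lm = float(lm.ssr)
    rss_qm = float(qm.ssr)
    df_denom = n - 5
    if df_denom <= 0:
        raise ValueError("too few observations for the QM F-test")
    if rss_qm <= 0:
        if rss_lm <= rss_qm + 1e-30:
            f_stat, p_anova = 0.0, 1.0        # both exact: keep LM
        else:
            f_stat, p_anova = np.inf, 0.0
    else:
        f_stat = (rss_lm - rss_qm) / (rss_qm / df_denom)
        f_stat = max(f_stat, 0.0)
        p_anova = float(sps.f.sf(f_stat, 1, df_denom))
    use_qm = p_anova < alpha
    fit = qm if use_qm else lm
    age_p_lin = float(fit.pvalues["age"])
    age_p_quad = float(qm.pvalues["age_sq"]) if use_qm else None
    return RegressionResult(
        outcome=outcome,
        model="QM" if use_qm else "LM",
        params={k: float(v) for k, v in fit.params.items()},
        bse={k: float(v) for k, v in fit.bse.items()},
        age_p=p_anova if use_qm else age_p_lin,
        age_p_linear=age_p_lin,
        age_p_quadratic=age_p_quad,
        anova_f=float(f_stat),
        anova_p=p_anova,
        n=n,
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bland_altman(scan1, scan2) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of repeated measurements.

    ``bias = mean(scan1 - scan2)``; limits are ``bias +/- 1.96 sd`` of the
    differences (sample sd, ddof=1).
    """
    a = np.asarray(scan1, dtype=float)
    b = np.asarray(scan2, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired measurements of equal length")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n=a.size,
    )


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation p-value.

    Ties receive average ranks.  Zero rank variance in either input makes
    the correlation undefined and returns ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def csff_to_vcsf(csff: float, water_content: float) -> float:
    """CSF volume fraction from CSFF and tissue water content (both in [0,1]).

    A signal fraction refers to the water signal only; scaling by the
    tissue's water content (g water per mL tissue) converts it to a
    per-tissue-volume CSF fraction.  Returns the fraction (e.g. 0.0332);
    format as percent with one decimal for display.
    """
    if not (0 <= csff <= 1) or not (0 <= water_content <= 1):
        raise ValueError("csff and water_content must lie in [0, 1]")
    return water_content * csff


def compartment_shift(
    initial: tuple[float, float, float], new_iew: float
) -> tuple[float, float]:
    """Fraction changes when the intra/extra-cellular content alone changes.

    ``initial`` is the per-pool water content (g/mL) of (myelin water,
    intra/extra-cellular water, CSF).  The intra/extra-cellular content is
    replaced by ``new_iew`` and fractions recomputed over the new total;
    returns ``(delta_IEWF, delta_CSFF)`` in percentage points (new minus
    old).  Illustrates that relative fractions understate absolute water
    loss: reducing IEW from 0.90 to 0.76 g/mL in a (0.05, 0.90, 0.05)
    voxel lowers IEWF by only 1.6 points while raising CSFF by 0.8.
    """
    mw, iew, csf = initial
    if min(mw, iew, csf) < 0 or new_iew < 0:
        raise ValueError("water contents must be >= 0")
    old_total = mw + iew + csf
    new_total = mw + new_iew + csf
    if old_total <= 0 or new_total <= 0:
        raise ValueError("total water content must be > 0")
    d_iewf = (new_iew / new_total - iew / old_total) * 100.0
    d_csff = (csf / new_total - csf / old_total) * 100.0
    return d_iewf, d_csff


def analyze_cohort(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[RegressionResult]]:
    """Run the full nine-outcome regression analysis with FDR adjustment.

    Fits LM/QM for every (ROI, water fraction) pair present in the tissue
    rows, selects per outcome, then BH-adjusts the nine reported age
    p-values.  Returns a summary table and the per-outcome results.
    """
    rois = [r for r in table["roi"].unique() if r != "lateral_ventricles"]
    results = []
    for roi in sorted(rois):
        for wf in ("mwf", "iewf", "csff"):
            lm, qm = fit_lm_qm(table, (roi, wf))
            results.append(select_model(lm, qm, alpha=alpha, outcome=f"{roi}:{wf}"))
    adj = fdr_adjust([r.age_p for r in results])
    rows = []
    for r, p_adj in zip(results, adj):
        rows.append(
            dict(
                outcome=r.outcome,
                model=r.model,
                age_p=r.age_p,
                age_p_fdr=float(p_adj),
                age_p_linear=r.age_p_linear,
                age_p_quadratic=r.age_p_quadratic,
                anova_f=r.anova_f,
                anova_p=r.anova_p,
                n=r.n,
            )
        )
    return pd.DataFrame(rows), results


def plot_age_trends(table: pd.DataFrame, wf: str = "csff", ax=None):
    """Scatter of a water fraction versus age with quadratic trend lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for roi, sub in table[table["roi"] != "lateral_ventricles"].groupby("roi"):
        sub = sub.sort_values("age_years")
        ax.scatter(sub["age_years"], sub[wf], s=12, alpha=0.6, label=roi)
        coef = np.polyfit(sub["age_years"], sub[wf], 2)
        grid = np.linspace(sub["age_years"].min(), sub["age_years"].max(), 100)
        ax.plot(grid, np.polyval(coef, grid))
    ax.set_xlabel("age (years)")
    ax.set_ylabel(wf.upper())
    ax.legend()
    return ax
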