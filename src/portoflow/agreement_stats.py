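"""Method-comparison and diagnostic-accuracy statistics.

Implements the validation layer of the study: Bland-Altman limits of
agreement with confidence intervals, ICC(2,1) absolute agreement, Lin's
concordance correlation coefficient, empirical ROC/AUC with a DeLong
interval, threshold diagnostics with exact (Clopper-Pearson) binomial
intervals and log-method likelihood-ratio intervals, and the per-group
summary table with significance flags against the control group.

Conventions: the reference (invasive) series is ``x``, the test (model)
series is ``y``; differences are ``d = y - x``.  "Portal hypertension"
means FPP strictly greater than the threshold (default 12 mmHg).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UndefinedStatisticError

DEFAULT_THRESHOLD_MMHG = 12.0
LOA_Z = 1.96  # limits of agreement are bias +/- 1.96 SD by definition


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias: float
    sd_diff: float
    bias_ci: tuple[float, float]
    loa_upper: float
    loa_lower: float
    loa_upper_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    alpha: float


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanResult:
    """Limits-of-agreement analysis of test series ``y`` against reference
    ``x``.

    bias = mean(y - x); LoA = bias +/- 1.96 * SD(d).  The bias interval is
    the usual t interval; each LoA interval uses the variance
    ``s^2 (1/n + 1.96^2 / (2(n-1)))`` with t(n-1) quantiles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D series of equal length")
    n = len(x)
    if n < 3:
        raise ParameterError(f"need n >= 3 pairs, got {n}")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bland_altman_from_summary(bias, sd, n, alpha)


def bland_altman_from_summary(bias: float, sd_diff: float, n: int, alpha: float = 0.05) -> BlandAltmanResult:
    """The same CI arithmetic from summary statistics only, so published
    bias/SD pairs can be checked without the underlying data."""
    if n < 3:
        raise ParameterError(f"need n >= 3, got {n}")
    t = float(stats.t.ppf(1 - alpha / 2, n - 1))
    se_bias = sd_diff / math.sqrt(n)
    se_loa = sd_diff * math.sqrt(1.0 / n + LOA_Z**2 / (2.0 * (n - 1)))
    upper = bias + LOA_Z * sd_diff
    lower = bias - LOA_Z * sd_diff
    return BlandAltmanResult(
        n=n, bias=bias, sd_diff=sd_diff,
        bias_ci=(bias - t * se_bias, bias + t * se_bias),
        loa_upper=upper, loa_lower=lower,
        loa_upper_ci=(upper - t * se_loa, upper + t * se_loa),
        loa_lower_ci=(lower - t * se_loa, lower + t * se_loa),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# ICC(2,1) and Lin's CCC
# ---------------------------------------------------------------------------

def icc_absolute_agreement(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measures, from the two-way ANOVA mean squares; F-based CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ParameterError("need two equal-length series with n >= 3")
    M = np.column_stack([x, y])
    n, k = M.shape
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_total = float(((M - grand) ** 2).sum())
    if ss_total == 0:
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    msb = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msj = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    mse = float(
        ((M - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    ) / ((n - 1) * (k - 1))
    icc = (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)
    if mse == 0 and msj <= mse:
        return 1.0, (1.0, 1.0)
    # Satterthwaite df for the F bounds (McGraw & Wong)
    denom = n * (1.0 - icc)
    if denom <= 0:
        return icc, (icc, icc)
    a = k * icc / denom
    b = 1.0 + k * icc * (n - 1) / denom
    num = (a * msj + b * mse) ** 2
    den = (a * msj) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else n - 1
    f1 = float(stats.f.ppf(1 - alpha / 2, n - 1, v))
    f2 = float(stats.f.ppf(1 - alpha / 2, v, n - 1))
    lower = n * (msb - f1 * mse) / (f1 * (k * msj + (k * n - k - n) * mse) + n * msb)
    upper = n * (f2 * msb - mse) / (k * msj + (k * n - k - n) * mse + n * f2 * msb)
    return float(icc), (float(lower), float(upper))


def lin_ccc(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z interval.

    ccc = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2) using 1/n (biased)
    moments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ParameterError("need two equal-length series with n >= 3")
    n = len(x)
    mx, my = float(x.mean()), float(y.mean())
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise UndefinedStatisticError("CCC undefined: zero variance in both series")
    ccc = 2.0 * sxy / denom
    if abs(ccc) >= 1.0 or sx2 == 0 or sy2 == 0:
        return float(ccc), (float(ccc), float(ccc))
    r = sxy / math.sqrt(sx2 * sy2)
    if r == 0:
        # variance formula degenerates; fall back to the plain Fisher-z SE
        se_z = 1.0 / math.sqrt(n - 3) if n > 3 else float("inf")
    else:
        u = (mx - my) / (sx2 * sy2) ** 0.25
        c2 = ccc * ccc
        se_z2 = (
            (1 - r * r) * c2 / ((1 - c2) * r * r)
            + 2 * ccc**3 * (1 - ccc) * u * u / (r * (1 - c2) ** 2)
            - ccc**4 * u**4 / (2 * r * r * (1 - c2) ** 2)
        ) / (n - 2)
        se_z = math.sqrt(max(se_z2, 0.0))
    z = math.atanh(ccc)
    zc = float(stats.norm.ppf(1 - alpha / 2))
    return float(ccc), (math.tanh(z - zc * se_z), math.tanh(z + zc * se_z))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Empirical AUC by Mann-Whitney pair counting (ties count 1/2) with a
    DeLong confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ParameterError("both classes must be present")
    # pairwise indicator matrix psi(pos_i, neg_j)
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-positive structural components
    v01 = psi.mean(axis=0)  # per-negative
    s10 = float(np.var(v10, ddof=1)) if len(pos) > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if len(neg) > 1 else 0.0
    var = s10 / len(pos) + s01 / len(neg)
    z = float(stats.norm.ppf(1 - alpha / 2))
    half = z * math.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


# ---------------------------------------------------------------------------
# Threshold diagnostics
# ---------------------------------------------------------------------------

def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Beta-quantile) proportion interval."""
    if not (0 <= successes <= n) or n < 1:
        raise ParameterError(f"invalid counts: {successes} of {n}")
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


@dataclass(frozen=True)
class LikelihoodRatioCI:
    lr_pos: float
    lr_pos_ci: tuple[float, float]
    lr_pos_defined: bool
    lr_neg: float
    lr_neg_ci: tuple[float, float]
    lr_neg_defined: bool


def likelihood_ratio_ci(tp: int, fn: int, fp: int, tn: int, alpha: float = 0.05) -> LikelihoodRatioCI:
    """Log-method (Simel) intervals for LR+ and LR-.

    When a cell makes a ratio degenerate (sensitivity or specificity of 0
    or 1) the point value is still reported (possibly 0 or inf) but the
    interval is flagged undefined with one-sided NaN bounds.
    """
    for c in (tp, fn, fp, tn):
        if c < 0:
            raise ParameterError("confusion counts must be >= 0")
    n_pos, n_neg = tp + fn, fp + tn
    if n_pos < 1 or n_neg < 1:
        raise ParameterError("each row of the 2x2 table needs at least one subject")
    se = tp / n_pos
    sp = tn / n_neg
    z = float(stats.norm.ppf(1 - alpha / 2))

    if sp < 1 and se > 0:
        lr_pos = se / (1 - sp)
        se_ln = math.sqrt((1 - se) / (se * n_pos) + sp / ((1 - sp) * n_neg))
        pos_ci = (lr_pos * math.exp(-z * se_ln), lr_pos * math.exp(z * se_ln))
        pos_defined = True
    else:
        lr_pos = float("inf") if sp == 1 else 0.0
        pos_ci = (float("nan"), float("nan"))
        pos_defined = False

    if sp > 0 and se < 1:
        lr_neg = (1 - se) / sp
        se_ln = math.sqrt(se / ((1 - se) * n_pos) + (1 - sp) / (sp * n_neg))
        neg_ci = (lr_neg * math.exp(-z * se_ln), lr_neg * math.exp(z * se_ln))
        neg_defined = True
    else:
        lr_neg = 0.0 if se == 1 else float("inf")
        neg_ci = (float("nan"), float("nan"))
        neg_defined = False
    return LikelihoodRatioCI(lr_pos, pos_ci, pos_defined, lr_neg, neg_ci, neg_defined)


@dataclass(frozen=True)
class DiagnosticReport:
    threshold: float
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity_pct: float
    sensitivity_ci_pct: tuple[float, float]
    specificity_pct: float
    specificity_ci_pct: tuple[float, float]
    lr: LikelihoodRatioCI
    auc: float
    auc_ci: tuple[float, float]
    alpha: float

    def to_dict(self) -> dict:
        return {
            "threshold_mmHg": self.threshold,
            "confusion": {"TP": self.tp, "FN": self.fn, "FP": self.fp, "TN": self.tn},
            "sensitivity_pct": self.sensitivity_pct,
            "sensitivity_ci_pct": list(self.sensitivity_ci_pct),
            "specificity_pct": self.specificity_pct,
            "specificity_ci_pct": list(self.specificity_ci_pct),
            "lr_pos": self.lr.lr_pos, "lr_pos_ci": list(self.lr.lr_pos_ci),
            "lr_neg": self.lr.lr_neg, "lr_neg_ci": list(self.lr.lr_neg_ci),
            "auc": self.auc, "auc_ci": list(self.auc_ci),
        }


def diagnostic_metrics(scores, labels, threshold: float = DEFAULT_THRESHOLD_MMHG,
                       alpha: float = 0.05) -> DiagnosticReport:
    """Diagnostic accuracy of ``scores`` for the condition ``labels`` at a
    strict ``score > threshold`` positivity call."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ParameterError("both classes must be present")
    calls = scores > threshold
    tp = int(np.sum(calls & labels))
    fn = int(np.sum(~calls & labels))
    fp = int(np.sum(calls & ~labels))
    tn = int(np.sum(~calls & ~labels))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = clopper_pearson(tp, tp + fn, alpha)
    spec_ci = clopper_pearson(tn, tn + fp, alpha)
    auc, auc_ci = roc_auc(scores, labels, alpha)
    return DiagnosticReport(
        threshold=float(threshold), tp=tp, fn=fn, fp=fp, tn=tn,
        sensitivity_pct=100.0 * sens,
        sensitivity_ci_pct=(100.0 * sens_ci[0], 100.0 * sens_ci[1]),
        specificity_pct=100.0 * spec,
        specificity_ci_pct=(100.0 * spec_ci[0], 100.0 * spec_ci[1]),
        lr=likelihood_ratio_ci(tp, fn, fp, tn, alpha),
        auc=auc, auc_ci=auc_ci, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Combined agreement report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementReport:
    n: int
    bland_altman: BlandAltmanResult
    icc: float
    icc_ci: tuple[float, float]
    ccc: float
    ccc_ci: tuple[float, float]
    alpha: float

    def to_dict(self) -> dict:
        ba = self.bland_altman
        return {
            "n": self.n,
            "bias": ba.bias, "bias_ci": list(ba.bias_ci), "sd_diff": ba.sd_diff,
            "loa_upper": ba.loa_upper, "loa_upper_ci": list(ba.loa_upper_ci),
            "loa_lower": ba.loa_lower, "loa_lower_ci": list(ba.loa_lower_ci),
            "icc": self.icc, "icc_ci": list(self.icc_ci),
            "ccc": self.ccc, "ccc_ci": list(self.ccc_ci),
        }


def compute_agreement(x, y, alpha: float = 0.05) -> AgreementReport:
    """Bland-Altman + ICC(2,1) + CCC of test series ``y`` vs reference ``x``."""
    ba = bland_altman(x, y, alpha)
    if np.array_equal(np.asarray(x, dtype=float), np.asarray(y, dtype=float)):
        icc, icc_ci = 1.0, (1.0, 1.0)
        ccc, ccc_ci = 1.0, (1.0, 1.0)
    else:
        icc, icc_ci = icc_absolute_agreement(x, y, alpha)
        ccc, ccc_ci = lin_ccc(x, y, alpha)
    return AgreementReport(n=ba.n, bland_altman=ba, icc=icc, icc_ci=icc_ci,
                           ccc=ccc, ccc_ci=ccc_ci, alpha=alpha)


# ---------------------------------------------------------------------------
# Group summary table
# ---------------------------------------------------------------------------

def _extract_quantity(cohort, quantity: str) -> dict[str, np.ndarray]:
    values: dict[str, list[float]] = {}
    for r in cohort.records:
        if quantity == "fpp":
            v = r.fpp_true_mmhg
        elif quantity.startswith(("diameter:", "velocity:")):
            kind, vessel = quantity.split(":", 1)
            ms = [m for m in r.doppler if m.vessel == vessel]
            if not ms:
                raise ParameterError(f"no measurement for vessel {vessel!r}")
            v = ms[0].d_us_mm if kind == "diameter" else ms[0].v_max_cm_s
        else:
            raise ParameterError(
                f"unknown quantity {quantity!r}; expected 'fpp', 'diameter:<vessel>' "
                "or 'velocity:<vessel>'"
            )
        values.setdefault(r.group, []).append(v)
    return {g: np.asarray(v) for g, v in values.items()}


def group_table(cohort, quantity: str = "fpp", control_label: str = "Control",
                alpha: float = 0.05) -> pd.DataFrame:
    """Per-group mean +/- SD with significance flags against the control
    group.

    Test selection follows the study's rule: Shapiro-Wilk normality per
    group, Student's t-test when both groups pass, Mann-Whitney U
    otherwise (groups of n < 3 are too small for the normality check and
    are treated as normal).
    """
    groups = _extract_quantity(cohort, quantity)
    if len(groups) < 2:
        raise ParameterError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 animals")
    if control_label not in groups:
        raise ParameterError(f"control group {control_label!r} absent")

    def _normal(v: np.ndarray) -> bool:
        if len(v) < 3 or np.ptp(v) == 0:
            return True
        return stats.shapiro(v).pvalue >= alpha

    control = groups[control_label]
    rows = []
    for g in cohort_group_order(groups, control_label):
        v = groups[g]
        mean, sd = float(np.mean(v)), float(np.std(v, ddof=1))
        if g == control_label:
            p, test, flag = float("nan"), "", False
        else:
            if _normal(v) and _normal(control):
                test = "t"
                p = float(stats.ttest_ind(v, control, equal_var=True).pvalue)
            else:
                test = "mann-whitney"
                p = float(stats.mannwhitneyu(v, control, alternative="two-sided").pvalue)
            flag = p < 0.05
        rows.append(
            {
                "group": g, "n": len(v), "mean": mean, "sd": sd,
                "summary": f"{mean:.1f} ± {sd:.1f}" + ("*" if flag else ""),
                "p_vs_control": p, "significant": flag, "test": test,
            }
        )
    return pd.DataFrame(rows)


def cohort_group_order(groups: dict, control_label: str) -> list[str]:
    ordered = [control_label] + sorted(g for g in groups if g != control_label)
    return ordered


# ---------------------------------------------------------------------------
# Plots (optional outputs)
# ---------------------------------------------------------------------------

def plot_bland_altman(x, y, path, alpha: float = 0.05) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = bland_altman(x, y, alpha)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2, y - x, s=18)
    for val, style in ((res.bias, "-"), (res.loa_upper, "--"), (res.loa_lower, "--")):
        ax.axhline(val, linestyle=style, color="k", linewidth=0.8)
    ax.set_xlabel("mean of FPP and vFPP (mmHg)")
    ax.set_ylabel("vFPP - FPP (mmHg)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(scores, labels, path, alpha: float = 0.05) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    thresholds = np.concatenate([[-np.inf], np.sort(np.unique(scores)), [np.inf]])
    tpr = [np.mean(scores[labels] > t) for t in thresholds]
    fpr = [np.mean(scores[~labels] > t) for t in thresholds]
    auc, _ = roc_auc(scores, labels, alpha)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], "k:", linewidth=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
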