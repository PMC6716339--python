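"""Method-comparison statistics between a test device and a criterion.

For each daily outcome (zone minutes, MVPA, steps, AEE, TEE) compared
between two instruments the battery computes:

* Pearson r with a paired nonparametric bootstrap percentile CI (and
  Spearman's rho as a secondary, rank-based coefficient);
* ICC(2,1) — two-way random effects, absolute agreement, single measures —
  with its F-distribution 95% CI;
* mean absolute percentage error (MAPE) of the test relative to the
  criterion;
* Bland–Altman mean difference and 95% limits of agreement with CIs
  (a positive mean difference means the test device overreports);
* a Shapiro–Wilk normality p-value for the paired differences;
* verbal interpretation labels (Evans bands for r; the poor/moderate/good/
  excellent ICC categories spanned by the ICC's 95% CI);
* sensitivity/specificity of the test device for a daily step target.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for these data (e.g. constant vector)."""


@dataclass
class PairedOutcomes:
    """Aligned per-subject values of one outcome from two instruments.

    Pairs with a missing (non-finite) entry on either side are dropped and
    logged, mirroring pairwise-complete analysis of subjects whose devices
    failed.
    """

    outcome_name: str
    test: np.ndarray
    criterion: np.ndarray
    subject_ids: Sequence[str]

    def __post_init__(self) -> None:
        t = np.asarray(self.test, dtype=float)
        c = np.asarray(self.criterion, dtype=float)
        ids = list(self.subject_ids)
        if not (len(t) == len(c) == len(ids)):
            raise ValueError("test, criterion and subject_ids must be aligned")
        keep = np.isfinite(t) & np.isfinite(c)
        if not keep.all():
            dropped = [i for i, k in zip(ids, keep) if not k]
            log.info("%s: dropped %d incomplete pair(s): %s",
                     self.outcome_name, len(dropped), dropped)
        self.test, self.criterion = t[keep], c[keep]
        self.subject_ids = [i for i, k in zip(ids, keep) if k]

    @property
    def n(self) -> int:
        return len(self.test)

    def require(self, n_min: int) -> None:
        if self.n < n_min:
            raise UndefinedStatisticError(
                f"{self.outcome_name}: need >= {n_min} complete pairs, have {self.n}"
            )


# --- correlation -----------------------------------------------------------

def pearson_bootstrap(pairs: PairedOutcomes, n_boot: int = 1000,
                      seed: int = 0) -> Tuple[float, Tuple[float, float]]:
    """Sample Pearson r and its percentile bootstrap 95% CI.

    Paired case resampling: subjects are resampled with replacement,
    keeping each subject's two measurements together.  Degenerate resamples
    (constant on either side) are dropped.
    """
    pairs.require(3)
    x, y = pairs.test, pairs.criterion
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            f"{pairs.outcome_name}: correlation undefined for a constant vector"
        )
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pairs.n, size=(n_boot, pairs.n))
    xs, ys = x[idx], y[idx]
    xd = xs - xs.mean(axis=1, keepdims=True)
    yd = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xd ** 2).sum(axis=1) * (yd ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rb = (xd * yd).sum(axis=1) / denom
    rb = rb[np.isfinite(rb)]
    lo, hi = np.percentile(rb, [2.5, 97.5])
    return r, (float(lo), float(hi))


def spearman_rho(pairs: PairedOutcomes) -> float:
    pairs.require(3)
    return float(stats.spearmanr(pairs.test, pairs.criterion).statistic)


def icc_agreement(pairs: PairedOutcomes, alpha: float = 0.05
                  ) -> Tuple[float, Tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    From the two-way ANOVA mean squares with n subjects (rows) and k = 2
    instruments (columns):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    The CI uses the F-distribution method for ICC(A,1): the lower/upper
    bounds invert F quantiles with Satterthwaite degrees of freedom for the
    column/error mixture.  Because the model penalises systematic offsets
    between instruments, the estimate can be negative; it is capped at 1.
    """
    pairs.require(3)
    x = np.column_stack([pairs.test, pairs.criterion])  # n × k
    n, k = x.shape
    grand = x.mean()
    if np.ptp(x) == 0:
        raise UndefinedStatisticError(
            f"{pairs.outcome_name}: ICC undefined with zero total variance"
        )
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedStatisticError(
            f"{pairs.outcome_name}: ICC undefined with zero total variance"
        )
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:  # identical instruments: CI degenerates
        return 1.0, (1.0, 1.0)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
    else:
        v = (n - 1) * (k - 1)
    fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
    fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    return float(min(icc, 1.0)), (float(lower), float(min(upper, 1.0)))


# --- error and agreement ---------------------------------------------------

def mape(pairs: PairedOutcomes) -> float:
    """Mean absolute percentage error of the test against the criterion.

    Subjects whose criterion value is exactly zero are dropped and logged
    (the ratio is undefined there); an all-zero criterion is an error.
    """
    nz = pairs.criterion != 0
    if not nz.any():
        raise UndefinedStatisticError(
            f"{pairs.outcome_name}: MAPE undefined, all criterion values are zero"
        )
    if not nz.all():
        log.info("%s: MAPE dropped %d zero-criterion subject(s)",
                 pairs.outcome_name, int((~nz).sum()))
    ratios = np.abs(pairs.test[nz] - pairs.criterion[nz]) / pairs.criterion[nz]
    return float(ratios.mean() * 100.0)


@dataclass
class BlandAltman:
    """Bland–Altman mean difference and 95% limits of agreement (LoA)."""

    mean_diff: float
    sd_diff: float
    lower_loa: float
    upper_loa: float
    mean_diff_ci: Tuple[float, float]
    lower_loa_ci: Tuple[float, float]
    upper_loa_ci: Tuple[float, float]
    n: int


def bland_altman(pairs: PairedOutcomes) -> BlandAltman:
    """Differences test − criterion; LoA = mean ± 1.96 SD.

    CIs follow the classical method-comparison recipe: a t-based interval
    for the mean difference, and Var(LoA) ≈ 3 s²/n for the limits.
    """
    pairs.require(3)
    d = pairs.test - pairs.criterion
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    t = stats.t.ppf(0.975, n - 1)
    se_mean = sd / np.sqrt(n)
    se_loa = np.sqrt(3.0 * sd ** 2 / n)
    lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    return BlandAltman(
        mean_diff=mean, sd_diff=sd, lower_loa=lower, upper_loa=upper,
        mean_diff_ci=(mean - t * se_mean, mean + t * se_mean),
        lower_loa_ci=(lower - t * se_loa, lower + t * se_loa),
        upper_loa_ci=(upper - t * se_loa, upper + t * se_loa),
        n=n,
    )


def goal_sens_spec(pairs: PairedOutcomes, goal: float = 10000
                   ) -> Tuple[Optional[float], Optional[float]]:
    """Sensitivity/specificity of the test device for a daily target.

    A subject is positive when the value is at or above the goal (reaching
    10,000 steps counts as meeting the target); the criterion defines
    truth.  A side with no criterion positives (negatives) returns None for
    sensitivity (specificity) — not applicable rather than an error.
    """
    pairs.require(1)
    test_pos = pairs.test >= goal
    crit_pos = pairs.criterion >= goal
    tp = int(np.sum(test_pos & crit_pos))
    fn = int(np.sum(~test_pos & crit_pos))
    tn = int(np.sum(~test_pos & ~crit_pos))
    fp = int(np.sum(test_pos & ~crit_pos))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec


# --- interpretation --------------------------------------------------------

_EVANS_BANDS = [(0.8, "very strong"), (0.6, "strong"), (0.4, "moderate"),
                (0.2, "weak"), (-np.inf, "very weak")]
_ICC_BANDS = [(0.9, "excellent"), (0.75, "good"), (0.5, "moderate"),
              (-np.inf, "poor")]


def interpret_pearson(r: float) -> str:
    """Evans verbal band for |r|; boundary values go to the upper band."""
    a = abs(r)
    for cut, label in _EVANS_BANDS:
        if a >= cut:
            return label
    raise AssertionError("unreachable")


def _icc_category(x: float) -> str:
    for cut, label in _ICC_BANDS:
        if x >= cut:
            return label
    raise AssertionError("unreachable")


def interpret_icc(ci: Tuple[float, float]) -> str:
    """Agreement label spanned by the ICC 95% CI (e.g. "poor to good")."""
    lo_label = _icc_category(ci[0])
    hi_label = _icc_category(ci[1])
    return lo_label if lo_label == hi_label else f"{lo_label} to {hi_label}"


# --- the assembled battery -------------------------------------------------

@dataclass
class AgreementResult:
    """Full agreement battery for one outcome × one criterion."""

    outcome_name: str
    n: int
    pearson_r: float
    pearson_ci: Tuple[float, float]
    pearson_label: str
    spearman: float
    icc: float
    icc_ci: Tuple[float, float]
    icc_label: str
    mape_pct: float
    ba: BlandAltman
    shapiro_p: float

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome_name, "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_ci_low": self.pearson_ci[0],
            "pearson_ci_high": self.pearson_ci[1],
            "pearson_label": self.pearson_label,
            "spearman_rho": self.spearman,
            "icc": self.icc, "icc_ci_low": self.icc_ci[0],
            "icc_ci_high": self.icc_ci[1], "icc_label": self.icc_label,
            "mape_pct": self.mape_pct,
            "ba_mean_diff": self.ba.mean_diff,
            "ba_lower_loa": self.ba.lower_loa,
            "ba_upper_loa": self.ba.upper_loa,
            "ba_mean_diff_ci_low": self.ba.mean_diff_ci[0],
            "ba_mean_diff_ci_high": self.ba.mean_diff_ci[1],
            "shapiro_p": self.shapiro_p,
        }


def compare(pairs: PairedOutcomes, n_boot: int = 1000, seed: int = 0) -> AgreementResult:
    """Run the whole battery on one paired outcome."""
    pairs.require(3)
    r, r_ci = pearson_bootstrap(pairs, n_boot=n_boot, seed=seed)
    rho = spearman_rho(pairs)
    icc, icc_ci = icc_agreement(pairs)
    err = mape(pairs)
    ba = bland_altman(pairs)
    d = pairs.test - pairs.criterion
    if np.ptp(d) == 0:
        shapiro_p = float("nan")  # constant differences: normality test undefined
    else:
        shapiro_p = float(stats.shapiro(d).pvalue)
    return AgreementResult(
        outcome_name=pairs.outcome_name,
        n=pairs.n,
        pearson_r=r, pearson_ci=r_ci, pearson_label=interpret_pearson(r),
        spearman=rho,
        icc=icc, icc_ci=icc_ci, icc_label=interpret_icc(icc_ci),
        mape_pct=err,
        ba=ba,
        shapiro_p=shapiro_p,
    )
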