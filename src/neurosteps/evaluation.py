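"""Agreement and algorithm-comparison statistics.

Per subject and algorithm the comparison unit is the total step count:
``pct_detected = 100 × predicted / true`` and the absolute percentage error
``100 × |predicted − true| / true``.  Following small-sample practice the
"MAPE" is summarised by median and interquartile range (the mean is also
emitted).  Algorithms are compared with a Friedman rank test after a
Shapiro–Wilk normality gate; with n subjects the smallest achievable exact
two-sided Wilcoxon signed-rank p-value is 2 × 0.5ⁿ, which bounds what any
post hoc pairwise test can show at small n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats


def _check_totals(true_totals, predicted_totals):
    t = np.asarray(true_totals, dtype=float)
    p = np.asarray(predicted_totals, dtype=float)
    if t.shape != p.shape:
        raise ValueError("true and predicted totals must have equal length")
    if np.any(t <= 0):
        raise ValueError("true totals must be strictly positive")
    return t, p


@dataclass(frozen=True)
class MapeSummary:
    values: np.ndarray     # per-subject absolute percentage errors
    median: float
    iqr: float             # Q3 − Q1
    mean: float


def mape(true_totals, predicted_totals) -> MapeSummary:
    """Per-subject absolute percentage errors with median/IQR/mean summary."""
    t, p = _check_totals(true_totals, predicted_totals)
    values = 100.0 * np.abs(p - t) / t
    q75, q25 = np.percentile(values, [75, 25])
    return MapeSummary(values=values, median=float(np.median(values)),
                       iqr=float(q75 - q25), mean=float(values.mean()))


def pct_detected(true_totals, predicted_totals) -> np.ndarray:
    """Per-subject detected percentage, 100 × predicted / true."""
    t, p = _check_totals(true_totals, predicted_totals)
    return 100.0 * p / t


def annotator_agreement(counts_a, counts_b) -> tuple[float, float]:
    """Agreement between two annotators' per-window step counts.

    Returns (MAPE %, Pearson r): the MAPE of annotator b's aggregated count
    against annotator a's (the ground truth), and the Pearson correlation of
    the per-window counts.  Zero-variance series make r undefined and are
    flagged with an error.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two aligned series of >= 2 windows")
    if a.sum() <= 0:
        raise ValueError("ground-truth total must be positive")
    mape_pct = 100.0 * abs(b.sum() - a.sum()) / a.sum()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson r undefined for a zero-variance count series")
    r = float(scipy.stats.pearsonr(a, b).statistic)
    return float(mape_pct), r


def friedman_compare(error_matrix) -> tuple[float, float]:
    """Friedman rank test across algorithms (columns) over subjects (rows).

    Ties are mid-ranked.  Degenerate input where every subject ranks all
    algorithms identically yields statistic 0, p = 1.
    """
    m = np.asarray(error_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 algorithms")
    if np.all(m == m[:, [0]]):
        return 0.0, 1.0
    if m.shape[1] >= 3:
        stat, p = scipy.stats.friedmanchisquare(*[m[:, j] for j in range(m.shape[1])])
        return float(stat), float(p)
    # two algorithms: same tie-corrected rank chi-square, df = 1
    n, k = m.shape
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, m)
    ssb = float(((ranks.sum(axis=0) - n * (k + 1) / 2) ** 2).sum())
    ties = sum(float((c**3 - c).sum())
               for c in (np.unique(row, return_counts=True)[1] for row in m))
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    stat = 12.0 * ssb / (n * k * (k + 1)) / correction
    return float(stat), float(scipy.stats.chi2.sf(stat, k - 1))


@dataclass(frozen=True)
class NormalityDecision:
    shapiro_statistic: float
    shapiro_p: float
    qq_points: tuple[np.ndarray, np.ndarray]  # theoretical vs ordered sample
    decision: str  # "parametric" | "nonparametric"


def normality_gate(values, alpha: float = 0.05,
                   force_nonparametric: bool = False) -> NormalityDecision:
    """Shapiro–Wilk gate with Q–Q coordinates for visual inspection.

    ``decision`` is nonparametric iff the Shapiro p-value ≤ α, or the caller
    overrides (as done when a borderline p together with a deviating Q–Q plot
    argues against the parametric route).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality assessment needs n >= 3")
    if np.all(x == x[0]):
        raise ValueError("degenerate constant sample; normality test undefined")
    stat, p = scipy.stats.shapiro(x)
    (theo, ordered), _ = scipy.stats.probplot(x, dist="norm")
    decision = "nonparametric" if (p <= alpha or force_nonparametric) else "parametric"
    return NormalityDecision(shapiro_statistic=float(stat), shapiro_p=float(p),
                             qq_points=(theo, ordered), decision=decision)


def wilcoxon_min_p(n: int) -> float:
    """Smallest achievable exact two-sided Wilcoxon signed-rank p at sample size n.

    When all n paired differences share one sign, the two one-sided tail has
    probability 0.5ⁿ under the null, so the two-sided floor is 2 × 0.5ⁿ
    (0.0156 at n = 7) — capped at 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(min(1.0, 2.0 * 0.5**n))


def step_rate(total_steps: float, duration_s: float) -> float:
    """Average step frequency in steps/s (e.g. 775 steps over 34.7 min)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return float(total_steps) / float(duration_s)


def mape_to_step_rate_error(mape_pct: float, reference_rate: float) -> float:
    """Translate a percentage error into steps/s at a reference step frequency.

    A 13.6 % error at the 1.66 steps/s cadence of a standardized walking test
    is 0.23 steps/s; at the 0.37 steps/s overall ADL rate it is 0.05 steps/s.
    """
    return float(mape_pct) / 100.0 * float(reference_rate)


@dataclass(frozen=True)
class AlgoComparison:
    """Per-subject and per-algorithm accuracy table plus the omnibus test."""

    per_subject: pd.DataFrame   # subject_id, algorithm, predicted, true, pct_detected, ape
    summary: pd.DataFrame       # algorithm, median/IQR of MAPE and pct detected
    friedman_statistic: float
    friedman_p: float
    normality: NormalityDecision | None


def compare_algorithms(true_totals: dict[str, float],
                       predictions: dict[str, dict[str, float]]) -> AlgoComparison:
    """Build the full algorithm comparison.

    ``true_totals``: subject → ground-truth total.  ``predictions``:
    algorithm → (subject → predicted total).  All algorithms must cover the
    same subjects.
    """
    subjects = list(true_totals)
    algorithms = list(predictions)
    rows = []
    ape_matrix = np.zeros((len(subjects), len(algorithms)))
    for j, algo in enumerate(algorithms):
        preds = predictions[algo]
        missing = [s for s in subjects if s not in preds]
        if missing:
            raise ValueError(f"algorithm {algo!r} missing subjects {missing}")
        t = np.array([true_totals[s] for s in subjects], dtype=float)
        p = np.array([preds[s] for s in subjects], dtype=float)
        ape = 100.0 * np.abs(p - t) / t
        det = 100.0 * p / t
        ape_matrix[:, j] = ape
        for i, s in enumerate(subjects):
            rows.append(dict(subject_id=s, algorithm=algo, predicted=float(p[i]),
                             true=float(t[i]), pct_detected=float(det[i]),
                             ape=float(ape[i])))
    per_subject = pd.DataFrame(rows)

    summary_rows = []
    for algo in algorithms:
        grp = per_subject[per_subject["algorithm"] == algo]
        q75a, q25a = np.percentile(grp["ape"], [75, 25])
        q75d, q25d = np.percentile(grp["pct_detected"], [75, 25])
        summary_rows.append(dict(
            algorithm=algo,
            median_mape=float(grp["ape"].median()), iqr_mape=float(q75a - q25a),
            mean_mape=float(grp["ape"].mean()),
            median_pct_detected=float(grp["pct_detected"].median()),
            iqr_pct_detected=float(q75d - q25d),
        ))
    summary = pd.DataFrame(summary_rows)

    if len(algorithms) >= 2 and len(subjects) >= 2:
        stat, p = friedman_compare(ape_matrix)
    else:
        stat, p = float("nan"), float("nan")
    normality = None
    if len(subjects) >= 3:
        try:
            normality = normality_gate(ape_matrix.ravel())
        except ValueError:
            normality = None
    return AlgoComparison(per_subject=per_subject, summary=summary,
                          friedman_statistic=stat, friedman_p=p,
                          normality=normality)
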