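"""Study-level aggregation, reproducibility statistics and group comparisons.

Aggregates per-animal onset ages into study summaries (n, mean, SD, CV),
computes the between-study coefficient of variation across repeated
cohorts, builds product-limit onset curves, and runs the standard group
comparisons used on this kind of data: log-rank, unpaired t, Mann-Whitney,
and Kruskal-Wallis with Dunn's post-hoc pairwise z tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


@dataclass(frozen=True)
class StudySummary:
    """Onset-age summary for one study and metric (censored animals excluded)."""

    study_id: str
    metric: str
    n: int
    mean_onset: float
    sd_onset: float
    cv_percent: float

    def rounded(self) -> "StudySummary":
        """Display form: means/SD/CV to 1 decimal, as conventionally printed."""
        return StudySummary(
            self.study_id, self.metric, self.n,
            round(self.mean_onset, 1), round(self.sd_onset, 1), round(self.cv_percent, 1),
        )


@dataclass(frozen=True)
class OnsetCurve:
    """Product-limit onset curve: S(age) = P(no onset by age)."""

    ages: np.ndarray          # distinct event ages (step locations)
    survival: np.ndarray      # curve value just after each age
    censor_ages: np.ndarray

    def at(self, age: float) -> float:
        idx = np.searchsorted(self.ages, age, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 x SD / mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def summarize_study(onsets: pd.DataFrame, study_id: str = "", metric: str = "") -> StudySummary:
    """Mean, sample SD (n-1 denominator) and CV of non-censored onset ages.

    ``onsets`` needs ``onset_age`` and ``censored`` columns; rows flagged
    censored are excluded, mirroring summary tables that report only animals
    with an observed onset.
    """
    obs = onsets.loc[~onsets["censored"].astype(bool), "onset_age"].to_numpy(dtype=float)
    obs = obs[~np.isnan(obs)]
    if obs.size == 0:
        raise ValueError("all onsets censored; nothing to summarize")
    if obs.size < 2:
        raise ValueError("need >= 2 non-censored onsets for an SD")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    return StudySummary(study_id, metric, int(obs.size), mean, sd, cv_percent(mean, sd))


def between_study_cv(study_means) -> float:
    """Between-study CV: 100 x sample SD of study means / mean of the means."""
    m = np.asarray(list(study_means), dtype=float)
    if m.size < 2:
        raise ValueError("need >= 2 study means")
    return cv_percent(float(m.mean()), float(m.std(ddof=1)))


def onset_survival_curve(onset_ages, censored=None) -> OnsetCurve:
    """Kaplan-Meier product-limit estimate with onset as the event.

    Censored animals (no observed onset by their last evaluable age)
    contribute risk-time only.
    """
    ages = np.asarray(onset_ages, dtype=float)
    if ages.size == 0:
        raise ValueError("need at least one animal")
    if censored is None:
        censored = np.zeros(ages.size, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(ages, event_observed=~censored)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0  # drop the t=0 anchor row
    return OnsetCurve(ages=t[keep], survival=s[keep], censor_ages=np.sort(ages[censored]))


def logrank_test(ages_a, ages_b, censored_a=None, censored_b=None) -> tuple[float, float]:
    """One-degree-of-freedom log-rank (Mantel-Cox) test on onset curves.

    Returns ``(chi_square, p_value)``.
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ca = np.zeros(a.size, dtype=bool) if censored_a is None else np.asarray(censored_a, dtype=bool)
    cb = np.zeros(b.size, dtype=bool) if censored_b is None else np.asarray(censored_b, dtype=bool)
    res = _ll_logrank(a, b, event_observed_A=~ca, event_observed_B=~cb)
    return float(res.test_statistic), float(res.p_value)


def compare_groups(onsets_a, onsets_b, test: str = "t", welch: bool = False) -> tuple[float, float]:
    """Two-sided comparison of non-censored onset ages between two groups.

    ``test`` is ``"t"`` (unpaired; pooled variance unless ``welch``) or
    ``"mann-whitney"`` (exact when sample sizes permit). Returns
    ``(statistic, p_value)``.
    """
    a = np.asarray(onsets_a, dtype=float)
    b = np.asarray(onsets_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 non-censored onsets")
    if test == "t":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            return math.inf, 0.0
        r = stats.ttest_ind(a, b, equal_var=not welch)
        return float(r.statistic), float(r.pvalue)
    if test == "mann-whitney":
        r = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if (a.size + b.size) <= 25 else "auto")
        return float(r.statistic), float(r.pvalue)
    raise ValueError(f"unknown test {test!r}; expected 't' or 'mann-whitney'")


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z statistics with tie correction, Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        k = groups[g].size
        mean_ranks[g] = ranks[start:start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
        rows.append({"group_a": g1, "group_b": g2, "z": z, "p_adjusted": p})
    return pd.DataFrame(rows)


def rank_compare_metrics(onsets_by_metric: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected) across metrics, with Dunn post-hoc.

    Returns ``(H, p_value, dunn_table)`` where the Dunn table carries the
    pairwise z statistics and Bonferroni-adjusted two-sided p values.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in onsets_by_metric.items()}
    groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        # all observations identical: no separation by construction
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups.values())
    return float(h), float(p), _dunn_pairwise(groups)


def summaries_table(onsets: pd.DataFrame) -> pd.DataFrame:
    """Per (study, metric) summary table from a tidy onsets frame.

    Expects columns ``study_id`` (optional; one pseudo-study otherwise),
    ``metric``, ``onset_age``, ``censored``.
    """
    frame = onsets.copy()
    if "study_id" not in frame.columns:
        frame["study_id"] = "study-1"
    rows = []
    for (study, metric), sub in frame.groupby(["study_id", "metric"], sort=True):
        if metric == "peak_weight" or sub["censored"].astype(bool).all():
            continue
        if (~sub["censored"].astype(bool)).sum() < 2:
            continue
        s = summarize_study(sub, study_id=str(study), metric=str(metric))
        rows.append({
            "study_id": s.study_id, "n": s.n, "metric": s.metric,
            "mean_onset": s.mean_onset, "sd_onset": s.sd_onset,
            "cv_percent": s.cv_percent,
        })
    return pd.DataFrame(rows, columns=["study_id", "n", "metric", "mean_onset",
                                       "sd_onset", "cv_percent"])
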