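"""Group-comparison and predictor-selection statistics on cohort records.

Per-timepoint comparisons across the four treatment arms use the
Kruskal–Wallis rank analysis of variance (tie-corrected H, chi-square
reference with k−1 df; an exact permutation p is available for small
samples), followed by all pairwise two-sided Wilcoxon rank-sum tests with
Bonferroni correction over the k(k−1)/2 comparisons.

Independent predictors of tumor volume change are selected by stepwise
multiple linear regression: forward entry of the candidate with the smallest
partial-F p-value below ``entry_p``, backward removal of any included
predictor whose p exceeds ``exit_p``, iterated to a fixed point (the classic
SPSS-style 0.05/0.10 defaults). For a single-predictor final model the
reported signed r equals the sample correlation between response and
predictor, carrying the coefficient's sign.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import (
    GROUPS,
    TIMEPOINTS,
    SubjectTimepointRecord,
    ValidationError,
    records_to_frame,
)

__all__ = [
    "GroupComparisonResult",
    "StepwiseResult",
    "StudyAnalysisResult",
    "kruskal_wallis",
    "pairwise_posthoc",
    "stepwise_regression",
    "run_study_analysis",
    "STUDY_ENDPOINTS",
]

#: endpoints compared per timepoint, as percent change from baseline
STUDY_ENDPOINTS = ("tumor_volume", "radc", "ktrans", "ve", "rbv", "rbf")


@dataclass
class GroupComparisonResult:
    """Omnibus Kruskal–Wallis result plus Bonferroni-corrected post-hoc pairs."""

    h_statistic: float
    df: int
    p_value: float
    posthoc: list[tuple[str, str, float, float]] = field(default_factory=list)


@dataclass
class StepwiseResult:
    """Outcome of stepwise forward/backward predictor selection."""

    selected_predictors: list[str]
    coefficients: dict[str, float]
    model_r: float  # signed correlation for a single-predictor model
    model_r_squared: float
    final_p_values: dict[str, float]
    entry_p: float
    exit_p: float
    step_log: list[dict] = field(default_factory=list)


@dataclass
class StudyAnalysisResult:
    """All per-timepoint group comparisons plus the stepwise selection."""

    comparisons: dict[tuple[str, str], GroupComparisonResult]
    stepwise: StepwiseResult | None
    endpoints: tuple[str, ...]
    timepoints: tuple[str, ...]


def _validate_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValidationError(f"need at least 2 groups, got {len(groups)}")
    clean = []
    for i, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if g.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 finite values")
        clean.append(g)
    return clean


def _h_exact_p(groups: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p: enumerate all assignments of the pooled ranks."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    ties = np.unique(pooled, return_counts=True)[1]
    tie_corr = 1.0 - (ties**3 - ties).sum() / (n**3 - n)
    if tie_corr == 0:
        return 1.0

    def h_from_partition(parts: list[np.ndarray]) -> float:
        s = sum((ranks[idx].sum() ** 2) / idx.size for idx in parts)
        return (12.0 / (n * (n + 1)) * s - 3.0 * (n + 1)) / tie_corr

    all_idx = np.arange(n)
    count = 0
    total = 0
    # enumerate index partitions into the given group sizes
    for first in itertools.combinations(all_idx, sizes[0]):
        rest1 = np.setdiff1d(all_idx, first, assume_unique=True)
        for second in itertools.combinations(rest1, sizes[1]):
            if len(sizes) == 2:
                parts = [np.asarray(first), np.asarray(second)]
                total += 1
                if h_from_partition(parts) >= h_obs - 1e-12:
                    count += 1
                continue
            rest2 = np.setdiff1d(rest1, second, assume_unique=True)
            for third in itertools.combinations(rest2, sizes[2]):
                parts = [np.asarray(first), np.asarray(second), np.asarray(third)]
                if len(sizes) == 4:
                    parts.append(np.setdiff1d(rest2, third, assume_unique=True))
                total += 1
                if h_from_partition(parts) >= h_obs - 1e-12:
                    count += 1
    return count / total


def kruskal_wallis(groups: list[np.ndarray], exact: bool = False) -> GroupComparisonResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square (k−1 df) p-value.

    All-identical data (where the tie correction degenerates to 0/0) returns
    H = 0, p = 1 by convention. ``exact=True`` replaces the chi-square p by
    full permutation enumeration, available for total n <= 15 and up to 4
    groups.
    """
    groups = _validate_groups(list(groups))
    k = len(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return GroupComparisonResult(h_statistic=0.0, df=k - 1, p_value=1.0)
    h, p = sps.kruskal(*groups)
    if exact:
        n = pooled.size
        if n > 15 or k > 4:
            raise ValidationError(
                f"exact permutation p supports total n <= 15 and <= 4 groups, "
                f"got n = {n}, k = {k}"
            )
        p = _h_exact_p(groups, float(h))
    return GroupComparisonResult(h_statistic=float(h), df=k - 1, p_value=float(p))


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p, normal approximation with tie correction."""
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return float(res.pvalue)


def pairwise_posthoc(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
    correction: str = "bonferroni",
) -> list[tuple[str, str, float, float]]:
    """All k(k−1)/2 pairwise rank-sum tests with Bonferroni adjustment.

    Returns ``(label_a, label_b, raw_p, adjusted_p)`` with
    ``adjusted_p = min(1, raw_p × n_comparisons)``.
    """
    if correction != "bonferroni":
        raise ValidationError(f"unsupported correction {correction!r}")
    groups = _validate_groups(list(groups))
    k = len(groups)
    if labels is None:
        labels = [f"group_{i}" for i in range(k)]
    if len(labels) != k:
        raise ValidationError("labels must match the number of groups")
    n_comp = k * (k - 1) // 2
    out = []
    for i, j in itertools.combinations(range(k), 2):
        raw = _ranksum_p(groups[i], groups[j])
        out.append((labels[i], labels[j], raw, min(1.0, raw * n_comp)))
    return out


def _candidate_frame(candidates) -> pd.DataFrame:
    if isinstance(candidates, pd.DataFrame):
        return candidates.astype(float)
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in candidates.items()})


def stepwise_regression(
    response: np.ndarray,
    candidates,
    entry_p: float = 0.05,
    exit_p: float = 0.10,
) -> StepwiseResult:
    """Forward/backward stepwise ordinary least squares.

    Parameters
    ----------
    response : array of shape (n,)
    candidates : DataFrame or mapping of name → vector
        Candidate predictors; a constant column is not allowed (the intercept
        is always included).
    entry_p, exit_p : float
        Entry requires the smallest candidate partial-F p-value to be below
        ``entry_p``; after every entry, included predictors with p above
        ``exit_p`` are removed (largest first). Iterates to a fixed point.

    Notes
    -----
    The partial-F test for adding one predictor equals the squared-t test of
    its coefficient, which is what is evaluated. Rank-deficient candidate
    additions are skipped with a logged warning.
    """
    y = np.asarray(response, dtype=float)
    x = _candidate_frame(candidates)
    n = y.size
    if x.shape[0] != n:
        raise ValidationError("response and candidates disagree in length")
    if n <= x.shape[1] + 2:
        raise ValidationError(
            f"need n > n_candidates + 2 observations, got n = {n} for "
            f"{x.shape[1]} candidates"
        )
    for name in x.columns:
        if np.allclose(x[name], x[name].iloc[0]):
            raise ValidationError(f"candidate {name!r} is constant")

    def fit(names: list[str]):
        design = sm.add_constant(x[names], has_constant="add")
        return sm.OLS(y, design).fit()

    included: list[str] = []
    log: list[dict] = []
    changed = True
    while changed:
        changed = False
        # forward entry
        best_name, best_p = None, np.inf
        for name in x.columns:
            if name in included:
                continue
            model = fit(included + [name])
            p = float(model.pvalues.get(name, np.nan))
            if not np.isfinite(p):
                log.append({"action": "skip", "predictor": name,
                            "reason": "rank-deficient design"})
                continue
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None and best_p < entry_p:
            included.append(best_name)
            log.append({"action": "enter", "predictor": best_name, "p": best_p})
            changed = True
        # backward elimination
        while included:
            model = fit(included)
            pvals = {name: float(model.pvalues[name]) for name in included}
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > exit_p:
                included.remove(worst)
                log.append({"action": "remove", "predictor": worst,
                            "p": pvals[worst]})
                changed = True
            else:
                break

    if included:
        model = fit(included)
        coefficients = {k: float(v) for k, v in model.params.items()}
        final_p = {name: float(model.pvalues[name]) for name in included}
        r2 = float(model.rsquared)
        if len(included) == 1:
            r = float(np.corrcoef(y, x[included[0]])[0, 1])
        else:
            r = float(np.sqrt(r2))  # multiple R; unsigned beyond one predictor
    else:
        coefficients = {}
        final_p = {}
        r2 = 0.0
        r = 0.0
    return StepwiseResult(
        selected_predictors=list(included),
        coefficients=coefficients,
        model_r=r,
        model_r_squared=r2,
        final_p_values=final_p,
        entry_p=entry_p,
        exit_p=exit_p,
        step_log=log,
    )


# --------------------------------------------------------------------------- #
# study-level orchestration
# --------------------------------------------------------------------------- #


def percent_change_table(frame: pd.DataFrame, endpoints=STUDY_ENDPOINTS) -> pd.DataFrame:
    """Per-subject percent change from the pre-treatment examination."""
    pre = frame[frame["timepoint"] == "pre"].set_index("subject_id")
    post = frame[frame["timepoint"] != "pre"]
    rows = []
    for _, row in post.iterrows():
        sid = row["subject_id"]
        if sid not in pre.index:
            raise ValidationError(f"subject {sid!r} has no pre-treatment record")
        entry = {"subject_id": sid, "group": row["group"], "timepoint": row["timepoint"]}
        for ep in endpoints:
            base = float(pre.loc[sid, ep])
            entry[f"{ep}_change"] = 100.0 * (float(row[ep]) - base) / base
        rows.append(entry)
    return pd.DataFrame(rows)


def run_study_analysis(
    records,
    endpoints=STUDY_ENDPOINTS,
    timepoints: tuple[str, ...] = tuple(tp for tp in TIMEPOINTS if tp != "pre"),
    stepwise_group: str = "ZdTha",
    stepwise_timepoint: str = "12d",
    stepwise_response: str = "tumor_volume",
    stepwise_candidates: tuple[str, ...] = ("radc", "ktrans", "ve", "rbv", "rbf"),
    entry_p: float = 0.05,
    exit_p: float = 0.10,
    run_stepwise: bool = True,
) -> StudyAnalysisResult:
    """Full inferential layer on a cohort record table.

    For every endpoint and post-treatment timepoint: Kruskal–Wallis omnibus
    across the four groups on the percent change from baseline, plus
    Bonferroni-corrected pairwise rank-sum tests. Then stepwise selection of
    the imaging-change candidates as predictors of tumor volume change in the
    configured group/timepoint subset.
    """
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = records_to_frame(list(records))

    changes = percent_change_table(frame, endpoints)
    comparisons: dict[tuple[str, str], GroupComparisonResult] = {}
    for tp in timepoints:
        sub = changes[changes["timepoint"] == tp]
        absent = [g for g in GROUPS if (sub["group"] == g).sum() < 2]
        if absent:
            raise ValidationError(
                f"timepoint {tp!r} is missing groups (or has < 2 subjects) for: "
                f"{absent}"
            )
        for ep in endpoints:
            col = f"{ep}_change"
            groups = [sub.loc[sub["group"] == g, col].to_numpy() for g in GROUPS]
            result = kruskal_wallis(groups)
            result.posthoc = pairwise_posthoc(groups, labels=list(GROUPS))
            comparisons[(ep, tp)] = result

    stepwise = None
    if run_stepwise:
        sub = changes[
            (changes["group"] == stepwise_group)
            & (changes["timepoint"] == stepwise_timepoint)
        ]
        if len(sub) <= len(stepwise_candidates) + 2:
            raise ValidationError(
                f"stepwise subset {stepwise_group!r} at {stepwise_timepoint!r} has "
                f"{len(sub)} subjects; need more than {len(stepwise_candidates) + 2}"
            )
        y = sub[f"{stepwise_response}_change"].to_numpy()
        x = sub[[f"{c}_change" for c in stepwise_candidates]]
        stepwise = stepwise_regression(y, x, entry_p=entry_p, exit_p=exit_p)

    return StudyAnalysisResult(
        comparisons=comparisons,
        stepwise=stepwise,
        endpoints=tuple(endpoints),
        timepoints=tuple(timepoints),
    )
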