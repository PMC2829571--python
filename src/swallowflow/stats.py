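"""Stimulus-effect testing: blocked Friedman tests with rank-sum post-hocs.

For every feature and each swallowing task separately: swallow-level values
are collapsed to one median per participant x stimulus cell (robust to the
unequal swallow counts segmentation produces), a participant-blocked Friedman
test across the four stimuli is run at alpha = 0.05, and — only where the
omnibus test is significant — the six pairwise stimulus comparisons are run
as two-sided Wilcoxon rank-sum tests with a Bonferroni correction at a
familywise alpha of 0.05 (adjusted p = min(1, 6 * raw p)).

No correction is applied across the 30 Friedman tests themselves; this
mirrors the original analysis and is flagged in the report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import InsufficientDataError, STIMULI, TASKS
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

ALPHA = 0.05
N_PAIRS = 6


@dataclass
class BlockMatrix:
    """Participants x 4-stimuli matrix of cell medians for one feature/task."""

    feature_name: str
    task: str
    participants: list[str]
    values: np.ndarray  # shape (n_participants, 4), stimulus order = STIMULI


@dataclass
class PairResult:
    stimulus_a: str
    stimulus_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class FeatureResult:
    feature_name: str
    friedman_statistic: float
    p_value: float
    significant: bool
    n_participants: int
    stimulus_means: dict[str, float] = field(default_factory=dict)
    stimulus_sems: dict[str, float] = field(default_factory=dict)
    posthoc: list[PairResult] = field(default_factory=list)


@dataclass
class StimulusEffectReport:
    """Per-task collection of Friedman + post-hoc results over all features."""

    task: str
    alpha: float
    features: list[FeatureResult] = field(default_factory=list)
    notes: str = ("No multiplicity correction is applied across features; "
                  "Bonferroni is applied within the 6 post-hoc pairs only.")

    @property
    def significant_features(self) -> list[str]:
        return [f.feature_name for f in self.features if f.significant]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary_markdown(self) -> str:
        """Markdown table of significant features: per-stimulus mean +- SE of
        the participant medians, and the Friedman p-value."""
        lines = [f"### Significant stimulus effects — {self.task} task",
                 "",
                 "| Feature | " + " | ".join(s.capitalize() for s in STIMULI)
                 + " | p-value |",
                 "|---" * 6 + "|"]
        for f in self.features:
            if not f.significant:
                continue
            cells = " | ".join(
                f"{f.stimulus_means[s]:.4g} ± {f.stimulus_sems[s]:.2g}"
                for s in STIMULI)
            lines.append(f"| {f.feature_name} | {cells} | {f.p_value:.4g} |")
        if len(lines) == 4:
            lines.append("| (none) |" + " |" * 5)
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_medians(table: pd.DataFrame, feature: str, task: str,
                      min_participants: int = 3) -> BlockMatrix:
    """Median per participant x stimulus cell for one feature and task.

    Missing values are ignored within a cell; participants lacking any
    stimulus entirely are dropped with a warning.  Fewer than
    ``min_participants`` complete participants raises
    :class:`InsufficientDataError`.
    """
    if table.empty:
        raise InsufficientDataError("empty feature table")
    sub = table[(table["feature_name"] == feature) & (table["task"] == task)]
    sub = sub.dropna(subset=["value"])
    if sub.empty:
        raise InsufficientDataError(f"no data for {feature!r} / {task!r}")
    cells = sub.groupby(["participant", "stimulus"])["value"].median().unstack()
    missing_cols = [s for s in STIMULI if s not in cells.columns]
    if missing_cols:
        raise InsufficientDataError(f"no data at all for stimuli {missing_cols}")
    cells = cells[list(STIMULI)]
    complete = cells.dropna()
    dropped = sorted(set(cells.index) - set(complete.index))
    if dropped:
        warnings.warn(f"dropping participants with empty cells: {dropped}",
                      stacklevel=2)
    if len(complete) < min_participants:
        raise InsufficientDataError(
            f"only {len(complete)} complete participants (< {min_participants})")
    return BlockMatrix(feature, task, list(complete.index),
                       complete.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def friedman_test(matrix: BlockMatrix | np.ndarray) -> tuple[float, float]:
    """Participant-blocked Friedman test across the four stimuli.

    Within-block midranks with tie correction, chi-square reference
    distribution with k-1 degrees of freedom.  A matrix whose rows are all
    constant carries no ranking information and returns ``(0.0, 1.0)``.
    """
    vals = matrix.values if isinstance(matrix, BlockMatrix) else np.asarray(matrix, float)
    if vals.ndim != 2 or vals.shape[1] < 3:
        raise InsufficientDataError("need a blocks x treatments matrix (k >= 3)")
    if vals.shape[0] < 3:
        raise InsufficientDataError("need at least 3 blocks (participants)")
    if np.all(np.ptp(vals, axis=1) == 0):
        return 0.0, 1.0
    stat, p = sstats.friedmanchisquare(*[vals[:, j] for j in range(vals.shape[1])])
    if not np.isfinite(stat):  # fully tied after ranking
        return 0.0, 1.0
    return float(stat), float(p)


def ranksum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample size is <= 20 and there
    are no ties; otherwise the normal approximation with tie and continuity
    corrections.  Two identical degenerate samples return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(len(a) * len(b) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def posthoc_pairwise(matrix: BlockMatrix, alpha: float = ALPHA,
                     ) -> list[PairResult]:
    """Bonferroni-corrected rank-sum tests for the six stimulus pairs.

    Each pair compares the two columns of participant medians; adjusted
    p = min(1, 6 * raw p), significant when the adjusted p < alpha
    (equivalently raw p < alpha/6 ~= 0.0083).
    """
    results = []
    for i, j in combinations(range(len(STIMULI)), 2):
        stat, p = ranksum_test(matrix.values[:, i], matrix.values[:, j])
        p_adj = min(1.0, N_PAIRS * p)
        results.append(PairResult(STIMULI[i], STIMULI[j], stat, p, p_adj,
                                  p_adj < alpha))
    return results


def run_stimulus_analysis(table: pd.DataFrame, alpha: float = ALPHA,
                          features: tuple[str, ...] = FEATURE_NAMES,
                          tasks: tuple[str, ...] = TASKS,
                          ) -> dict[str, StimulusEffectReport]:
    """Full statistical stage: one report per task over all features.

    Features that cannot be aggregated (insufficient complete participants)
    are skipped with a warning; post-hoc pairs are attached only to features
    whose Friedman test is significant.
    """
    if table.empty:
        raise InsufficientDataError("empty feature table")
    reports: dict[str, StimulusEffectReport] = {}
    for task in tasks:
        report = StimulusEffectReport(task=task, alpha=alpha)
        for feature in features:
            try:
                matrix = aggregate_medians(table, feature, task)
            except InsufficientDataError as exc:
                warnings.warn(f"{feature}/{task}: {exc}", stacklevel=2)
                continue
            stat, p = friedman_test(matrix)
            sig = bool(p < alpha)
            means = {s: float(np.mean(matrix.values[:, k]))
                     for k, s in enumerate(STIMULI)}
            sems = {s: float(sstats.sem(matrix.values[:, k]))
                    for k, s in enumerate(STIMULI)}
            result = FeatureResult(feature, stat, p, sig,
                                   len(matrix.participants), means, sems)
            if sig:
                result.posthoc = posthoc_pairwise(matrix, alpha)
            report.features.append(result)
        reports[task] = report
    return reports
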