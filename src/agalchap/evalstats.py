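"""Panel evaluation: score bins, response rates, exact and correlation tests.

Operates on :class:`~agalchap.seqio.MutationRecord` lists carrying an
integer PSSM score and a responsiveness label. The three score zones mirror
the clinical guideline: above the twilight score (> -2), at it (== -2), and
below it (< -2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError
from .responsiveness import TWILIGHT_SCORE, Call, Rule, classify
from .seqio import MutationRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinCount:
    label: str
    n_responsive: int
    n_total: int

    @property
    def pct_responsive(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        return 100.0 * self.n_responsive / self.n_total


@dataclass
class ScoreBins:
    """Responsive/total counts per integer score and per guideline zone."""

    per_score: dict[int, BinCount]
    zone_above: BinCount   # score > -2
    zone_twilight: BinCount  # score == -2
    zone_below: BinCount   # score < -2

    @property
    def n_labeled(self) -> int:
        return sum(b.n_total for b in self.per_score.values())


@dataclass
class EvaluationReport:
    """Summary of a panel evaluation."""

    bins: ScoreBins
    predicted_positive_n: int
    predicted_positive_responsive: int
    percent_responsive_predicted_positive: Optional[float]
    fisher: Optional[tuple[tuple[int, int, int, int], float]] = None
    pearson: Optional[tuple[float, float, int]] = None
    accuracy_pct: Optional[float] = None
    excluded: int = 0


def _labeled(records: Iterable[MutationRecord]) -> tuple[list[MutationRecord], int]:
    kept, dropped = [], 0
    for rec in records:
        if rec.responsive is None:
            logger.warning(
                "record at position %d has no responsiveness label; excluded",
                rec.mutation.position,
            )
            dropped += 1
        else:
            kept.append(rec)
    return kept, dropped


def bin_by_score(records: Sequence[MutationRecord]) -> ScoreBins:
    """Count responsive/total per integer score and per guideline zone.

    Records without a responsiveness label are excluded with a warning.
    """
    labeled, _ = _labeled(records)
    per: dict[int, list[int]] = {}
    zones = {"above": [0, 0], "twilight": [0, 0], "below": [0, 0]}
    for rec in labeled:
        s = rec.pssm_score
        per.setdefault(s, [0, 0])
        per[s][1] += 1
        per[s][0] += int(rec.responsive)
        key = (
            "above" if s > TWILIGHT_SCORE
            else "twilight" if s == TWILIGHT_SCORE
            else "below"
        )
        zones[key][1] += 1
        zones[key][0] += int(rec.responsive)
    per_score = {
        s: BinCount(str(s), k, n) for s, (k, n) in sorted(per.items())
    }
    return ScoreBins(
        per_score=per_score,
        zone_above=BinCount(f"> {TWILIGHT_SCORE}", *zones["above"]),
        zone_twilight=BinCount(f"== {TWILIGHT_SCORE}", *zones["twilight"]),
        zone_below=BinCount(f"< {TWILIGHT_SCORE}", *zones["below"]),
    )


def predicted_positive_rate(
    records: Sequence[MutationRecord], rule: Rule | str = Rule.THREE_ZONE
) -> tuple[int, int, float]:
    """(responsive count, predicted-positive count, percent) among records
    whose score classifies as responsive under ``rule``."""
    rule = Rule(rule)
    labeled, _ = _labeled(records)
    positives = [
        r for r in labeled if classify(r.pssm_score, rule) is Call.RESPONSIVE
    ]
    n = len(positives)
    if n == 0:
        raise UndefinedStatisticError("no predicted-positive records")
    k = sum(int(r.responsive) for r in positives)
    return k, n, 100.0 * k / n


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact p for a 2x2 count table (sum of hyper-
    geometric probabilities not exceeding that of the observed table)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def pearson_r(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-tailed t-test p-value."""
    if len(points) < 3:
        raise UndefinedStatisticError("need at least 3 points for a correlation")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def accuracy(
    records: Sequence[MutationRecord],
    rule: Rule | str = Rule.BINARY_GE_MINUS1,
    twilight_policy: str = "non_responsive",
) -> float:
    """Percent of records whose classified call matches the label.

    ``twilight_policy`` decides how a three-zone twilight call is scored:
    ``"non_responsive"`` (conservative default), ``"responsive"`` or
    ``"exclude"``.
    """
    if twilight_policy not in ("non_responsive", "responsive", "exclude"):
        raise ValueError(f"unknown twilight policy {twilight_policy!r}")
    rule = Rule(rule)
    labeled, _ = _labeled(records)
    correct = total = 0
    for rec in labeled:
        call = classify(rec.pssm_score, rule)
        if call is Call.TWILIGHT:
            if twilight_policy == "exclude":
                continue
            call = (
                Call.RESPONSIVE
                if twilight_policy == "responsive"
                else Call.NON_RESPONSIVE
            )
        total += 1
        predicted_responsive = call is Call.RESPONSIVE
        correct += int(predicted_responsive == rec.responsive)
    if total == 0:
        raise UndefinedStatisticError("no labeled records to score")
    return 100.0 * correct / total


def evaluate_panel(
    records: Sequence[MutationRecord],
    rule: Rule | str = Rule.THREE_ZONE,
    baseline: Optional[tuple[int, int]] = None,
) -> EvaluationReport:
    """Full panel evaluation.

    ``baseline``, when given as (responsive, non_responsive) reference
    counts, is contrasted with the predicted-positive outcome by a Fisher
    exact test. The per-score response curve feeds a Pearson correlation
    when at least three informative score bins exist.
    """
    rule = Rule(rule)
    labeled, dropped = _labeled(records)
    bins = bin_by_score(labeled)
    k, n, pct = predicted_positive_rate(labeled, rule)
    fisher = None
    if baseline is not None:
        table = (k, n - k, baseline[0], baseline[1])
        fisher = (table, fisher_exact([[k, n - k], list(baseline)]))
    pearson = None
    pts = [
        (float(s), b.pct_responsive)
        for s, b in bins.per_score.items()
        if b.n_total > 0
    ]
    if len(pts) >= 3:
        try:
            r, p = pearson_r(pts)
            pearson = (r, p, len(pts))
        except UndefinedStatisticError:
            pearson = None
    acc = None
    try:
        acc = accuracy(labeled, Rule.BINARY_GE_MINUS1)
    except UndefinedStatisticError:
        pass
    return EvaluationReport(
        bins=bins,
        predicted_positive_n=n,
        predicted_positive_responsive=k,
        percent_responsive_predicted_positive=pct,
        fisher=fisher,
        pearson=pearson,
        accuracy_pct=acc,
        excluded=dropped,
    )
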