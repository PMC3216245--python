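"""Scoring mutations and classifying chaperone responsiveness.

A mutation's score is the PSSM entry of the *mutant* residue at the mutated
position: conservation of the wild type enters through the matrix itself,
and a substitution seen in homologous species earns a less negative score.
Two classification rules are provided:

``binary_ge_minus1``
    responsive iff score >= -1 (the benchmark threshold of the original
    classifier).
``three_zone``
    score > -2 responsive, score == -2 twilight (no confident call),
    score < -2 non-responsive (the clinician-facing guideline).

On integers the rules agree everywhere except score -2, which the binary
rule calls non-responsive and the three-zone rule leaves open.

Experimentally, a mutant counts as responsive when its activity in DGJ-
treated cells reaches at least 15% of wild type — the lowest residual
activity consistently associated with non-classic phenotype, rounded up.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

from .errors import CoordinateError, ReferenceMismatchError, ValidationError
from .pssm import PSSM
from .seqio import MissenseMutation, SparseScoreTable

#: Activity threshold (percent of wild type) separating responsive mutants.
ACTIVITY_THRESHOLD_PCT = 15.0

#: The score at which the three-zone rule declines to make a call.
TWILIGHT_SCORE = -2


class Call(str, Enum):
    RESPONSIVE = "responsive"
    TWILIGHT = "twilight"
    NON_RESPONSIVE = "non_responsive"


class Rule(str, Enum):
    BINARY_GE_MINUS1 = "binary_ge_minus1"
    THREE_ZONE = "three_zone"


@dataclass(frozen=True)
class Prediction:
    """A classified mutation; ``active_site_warning`` flags catalytic-site
    mutations, which cannot bind the chaperone regardless of score (the
    numeric call is deliberately not overridden)."""

    mutation: Optional[MissenseMutation]
    score: int
    call: Call
    rule: Rule
    active_site_warning: bool = False


def score_mutation(
    matrix: Union[PSSM, SparseScoreTable],
    mut: MissenseMutation,
    check_wildtype: bool = False,
    delta: bool = False,
) -> int:
    """Look up the mutant residue's score at the mutation's position.

    ``matrix`` may be a full :class:`PSSM` or the packaged sparse per-
    mutation table. With ``check_wildtype`` the matrix query residue must
    match the mutation's stated wild type. ``delta`` subtracts the wild-type
    residue's score (mutant-minus-wildtype variant; not the default
    convention).
    """
    if not mut.complete:
        raise ValidationError(
            f"mutation at position {mut.position} has no mutant residue"
        )
    if isinstance(matrix, PSSM):
        if not 1 <= mut.position <= len(matrix.query):
            raise CoordinateError(
                f"position {mut.position} outside query length {len(matrix.query)}"
            )
        wt_in_matrix = matrix.query_residue(mut.position)
        lookup = matrix.score
    else:
        wt_in_matrix = matrix.query_residue(mut.position)
        if wt_in_matrix is None:
            raise CoordinateError(
                f"position {mut.position} not covered by the score table"
            )
        try:
            matrix.score(mut.position, mut.mut_residue)
        except KeyError as exc:
            raise CoordinateError(str(exc)) from None
        lookup = matrix.score
    if check_wildtype and wt_in_matrix != mut.wt_residue:
        raise ReferenceMismatchError(
            f"position {mut.position}: mutation states wild type "
            f"{mut.wt_residue} but the matrix query has {wt_in_matrix}"
        )
    score = lookup(mut.position, mut.mut_residue)
    if delta:
        score -= lookup(mut.position, wt_in_matrix)
    return score


def classify(score: int, rule: Union[Rule, str] = Rule.THREE_ZONE) -> Call:
    """Map an integer score to a responsiveness call under the given rule."""
    rule = Rule(rule)
    if rule is Rule.BINARY_GE_MINUS1:
        return Call.RESPONSIVE if score >= -1 else Call.NON_RESPONSIVE
    if score > TWILIGHT_SCORE:
        return Call.RESPONSIVE
    if score == TWILIGHT_SCORE:
        return Call.TWILIGHT
    return Call.NON_RESPONSIVE


def predict(
    matrix: Union[PSSM, SparseScoreTable],
    mut: MissenseMutation,
    rule: Union[Rule, str] = Rule.THREE_ZONE,
    check_wildtype: bool = False,
    active_site: bool = False,
) -> Prediction:
    """Score and classify a mutation in one step."""
    rule = Rule(rule)
    score = score_mutation(matrix, mut, check_wildtype=check_wildtype)
    return Prediction(
        mutation=mut,
        score=score,
        call=classify(score, rule),
        rule=rule,
        active_site_warning=active_site,
    )


def activity_call(
    activity_with_drug_pct_wt: float,
    threshold: float = ACTIVITY_THRESHOLD_PCT,
) -> bool:
    """Responsive iff DGJ-treated activity reaches ``threshold`` percent of
    wild type (inclusive)."""
    if activity_with_drug_pct_wt < 0:
        raise ValidationError("activity cannot be negative")
    return activity_with_drug_pct_wt >= threshold


def fold_increase(activity_with: float, activity_without: float) -> float:
    """Ratio of treated to untreated cellular enzyme activity."""
    if activity_without <= 0:
        raise ValidationError(
            f"baseline activity must be positive, got {activity_without}"
        )
    return activity_with / activity_without
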