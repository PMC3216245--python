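"""Checklist evaluation of the packaged AGAL mutation panels.

Recomputes the published summary figures for the two packaged panels from
the fixture tables and compares each against its expected value:

- zone counts on the literature panel (5/5 responsive above the twilight
  score, 4/6 at it, 2/8 below it);
- the pooled predicted-positive response rate (12 of 14, 86%);
- the expression panel's activity outcome (7 of 9 responsive);
- the literature panel's label composition (11 responsive, 8 not);
- agreement of every sparse-table score lookup with the panel annotations.

Percentages are rounded half away from zero to integers before comparison,
matching how the summary figures are conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .evalstats import bin_by_score, predicted_positive_rate
from .responsiveness import Rule, score_mutation
from .seqio import load_fixture_table, load_score_table


def round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class CheckItem:
    name: str
    expected: object
    computed: object

    @property
    def passed(self) -> bool:
        return self.expected == self.computed


@dataclass
class Checklist:
    items: list[CheckItem]

    @property
    def all_passed(self) -> bool:
        return all(item.passed for item in self.items)

    def lines(self) -> list[str]:
        out = []
        for it in self.items:
            mark = "PASS" if it.passed else "FAIL"
            out.append(f"[{mark}] {it.name}: expected {it.expected}, got {it.computed}")
        n_ok = sum(it.passed for it in self.items)
        out.append(f"{n_ok}/{len(self.items)} checks passed")
        return out


def panel_checklist() -> Checklist:
    """Run the full fixture evaluation and compare against the published
    panel summaries."""
    table1 = load_fixture_table("table1")
    table2 = load_fixture_table("table2")
    scores = load_score_table()

    items: list[CheckItem] = []

    bins = bin_by_score(table2)
    items.append(CheckItem(
        "literature panel, responsive above twilight zone",
        (5, 5),
        (bins.zone_above.n_responsive, bins.zone_above.n_total),
    ))
    items.append(CheckItem(
        "literature panel, responsive at twilight score",
        (4, 6),
        (bins.zone_twilight.n_responsive, bins.zone_twilight.n_total),
    ))
    items.append(CheckItem(
        "literature panel, responsive below twilight zone",
        (2, 8),
        (bins.zone_below.n_responsive, bins.zone_below.n_total),
    ))

    k, n, pct = predicted_positive_rate(table1 + table2, Rule.THREE_ZONE)
    items.append(CheckItem(
        "pooled panels, predicted-positive outcome (responsive, n, pct)",
        (12, 14, 86),
        (k, n, round_half_away(pct)),
    ))

    t1_resp = sum(int(bool(r.responsive)) for r in table1)
    items.append(CheckItem(
        "expression panel, responsive under the 15% activity rule",
        (7, 9),
        (t1_resp, len(table1)),
    ))

    t2_resp = sum(int(bool(r.responsive)) for r in table2)
    items.append(CheckItem(
        "literature panel, label composition (responsive, non-responsive)",
        (11, 8),
        (t2_resp, len(table2) - t2_resp),
    ))

    scorable = [r for r in table1 + table2 if r.mutation.complete]
    matches = sum(
        int(score_mutation(scores, r.mutation) == r.pssm_score) for r in scorable
    )
    items.append(CheckItem(
        "sparse score table reproduces all panel score annotations",
        (len(scorable), len(scorable)),
        (matches, len(scorable)),
    ))

    return Checklist(items=items)


def bin_table(records) -> list[tuple[int, int, int, float]]:
    """Per-integer-score response curve (score, responsive, total, pct) for
    plotting or inspection, over labeled records."""
    bins = bin_by_score(records)
    return [
        (s, b.n_responsive, b.n_total, b.pct_responsive)
        for s, b in bins.per_score.items()
    ]
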