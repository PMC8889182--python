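"""Reciprocal-transplant survivorship and selection statistics.

A reciprocal transplant moves coral fragments between shallow and deep
habitats in both directions (treatments S-S, S-D, D-S, D-D, origin-to-
destination). Six months later each fragment is scored alive or dead.
Survivorship contrasts between treatment groups use a one-tailed Fisher
exact test — the exact hypergeometric probability, conditional on the
table margins, of at least as many deaths in the first (hypothesised
disadvantaged) group. The fitness advantage of the native species in a
habitat is summarised by the standardized selection differential
``s = (w1 - w2) / mean(w1, w2)`` on survival proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError

logger = logging.getLogger(__name__)

STATUSES = ("alive", "dead", "discarded")

#: the four natural pairwise survivorship contrasts (first group = the
#: hypothesised disadvantaged one)
DEFAULT_CONTRASTS = (("S-D", "S-S"), ("S-D", "D-D"), ("D-S", "D-D"), ("D-S", "S-S"))

__all__ = [
    "TransplantTable",
    "FisherResult",
    "SelectionEstimate",
    "SurvivorshipReport",
    "tally_outcomes",
    "fisher_one_tailed",
    "selection_differential",
    "survivorship_report",
]


@dataclass(frozen=True)
class TransplantTable:
    """2x2 alive/dead contingency table for two treatment groups."""

    labels: tuple[str, str]
    dead: tuple[int, int]
    alive: tuple[int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.dead + self.alive):
            raise DomainError("counts must be non-negative")
        if any(d + a == 0 for d, a in zip(self.dead, self.alive)):
            raise DegenerateDataError("each group must contain at least one colony")

    @property
    def n(self) -> tuple[int, int]:
        return (self.dead[0] + self.alive[0], self.dead[1] + self.alive[1])

    @property
    def mortality(self) -> tuple[float, float]:
        """Raw mortality proportions per group."""
        return tuple(d / t for d, t in zip(self.dead, self.n))

    @property
    def mortality_pct(self) -> tuple[int, int]:
        """Mortality as whole-number percentages (reporting convention)."""
        return tuple(round(100.0 * m) for m in self.mortality)


@dataclass(frozen=True)
class FisherResult:
    """One-tailed Fisher exact test on a transplant table."""

    p_value: float
    tail: str
    table: TransplantTable

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise DomainError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class SelectionEstimate:
    """Standardized fitness (survival) advantage between two groups.

    ``s`` is signed with respect to the argument order, (w1 - w2) over the
    mean fitness; ``favored`` names the group with the higher survival and
    ``advantage`` is the corresponding non-negative magnitude.
    """

    habitat: str
    labels: tuple[str, str]
    w: tuple[float, float]
    s: float

    @property
    def favored(self) -> str:
        return self.labels[0] if self.w[0] >= self.w[1] else self.labels[1]

    @property
    def w_favored(self) -> float:
        return max(self.w)

    @property
    def w_other(self) -> float:
        return min(self.w)

    @property
    def advantage(self) -> float:
        return abs(self.s)


def tally_outcomes(outcomes: pd.DataFrame, group_a: str, group_b: str) -> TransplantTable:
    """Build the 2x2 dead/alive table for two treatments.

    ``outcomes`` needs columns ``treatment`` and ``status`` with status in
    {alive, dead, discarded}; discarded colonies (e.g. detached fragments)
    are excluded from the tallies with a logged count, never counted dead.
    """
    bad = set(outcomes["status"].unique()) - set(STATUSES)
    if bad:
        raise DomainError(f"unknown status value(s): {sorted(bad)}")
    n_discarded = int((outcomes["status"] == "discarded").sum())
    if n_discarded:
        logger.info("tally_outcomes: excluded %d discarded colonies", n_discarded)
    kept = outcomes[outcomes["status"] != "discarded"]
    counts = []
    for grp in (group_a, group_b):
        sub = kept[kept["treatment"] == grp]
        if len(sub) == 0:
            raise DegenerateDataError(f"no usable colonies in treatment {grp!r}")
        dead = int((sub["status"] == "dead").sum())
        counts.append((dead, len(sub) - dead))
    return TransplantTable(labels=(group_a, group_b),
                           dead=(counts[0][0], counts[1][0]),
                           alive=(counts[0][1], counts[1][1]))


def fisher_one_tailed(table: TransplantTable) -> FisherResult:
    """Exact one-tailed test for excess mortality in the first group.

    Conditional on the margins, the number of deaths in group A follows a
    hypergeometric distribution; the p-value is the upper tail
    P(deaths_A >= observed), i.e. the sum of the hypergeometric point
    probabilities of all margin-fixed tables at least as extreme in the
    direction of higher group-A mortality.
    """
    dead_a, dead_b = table.dead
    n_a, n_b = table.n
    total = n_a + n_b
    total_dead = dead_a + dead_b
    p = float(stats.hypergeom.sf(dead_a - 1, total, total_dead, n_a))
    return FisherResult(p_value=min(p, 1.0),
                        tail=f"mortality({table.labels[0]}) > mortality({table.labels[1]})",
                        table=table)


def selection_differential(w1: float, w2: float,
                           labels: tuple[str, str] = ("group_1", "group_2"),
                           habitat: str = "") -> SelectionEstimate:
    """Standardized selection differential between two survival proportions.

    ``s = (w1 - w2) / mean(w1, w2)`` — the fitness difference divided by
    the average fitness in the habitat. Antisymmetric in its arguments and
    bounded by |s| <= 2, with equality only when one proportion is zero.
    """
    for name, w in (("w1", w1), ("w2", w2)):
        if not (0.0 <= w <= 1.0):
            raise DomainError(f"{name} must be a proportion in [0, 1]")
    if w1 == 0.0 and w2 == 0.0:
        raise DomainError("selection differential undefined when both fitnesses are 0")
    s = (w1 - w2) / ((w1 + w2) / 2.0)
    return SelectionEstimate(habitat=habitat, labels=labels, w=(float(w1), float(w2)), s=float(s))


@dataclass(frozen=True)
class SurvivorshipReport:
    """Per-treatment mortality, pairwise Fisher contrasts and selection."""

    treatments: dict
    contrasts: list
    selection: list

    def to_dict(self) -> dict:
        return {
            "treatments": {
                trt: dict(stats_) for trt, stats_ in self.treatments.items()
            },
            "contrasts": [
                {
                    "groups": list(res.table.labels),
                    "dead": list(res.table.dead),
                    "alive": list(res.table.alive),
                    "p_value": res.p_value,
                    "tail": res.tail,
                }
                for res in self.contrasts
            ],
            "selection": [
                {
                    "habitat": est.habitat,
                    "groups": list(est.labels),
                    "survival": list(est.w),
                    "s": est.s,
                    "favored": est.favored,
                    "advantage": est.advantage,
                }
                for est in self.selection
            ],
        }

    def to_text(self) -> str:
        lines = ["Survivorship"]
        for trt, st in self.treatments.items():
            lines.append(
                f"  {trt}: n = {st['n']}, deaths = {st['deaths']}, "
                f"mortality = {st['mortality_pct']}%")
        lines.append("Contrasts")
        for res in self.contrasts:
            pct = res.table.mortality_pct
            lines.append(
                f"  {res.table.labels[0]} vs {res.table.labels[1]}: "
                f"{pct[0]}% vs {pct[1]}% mortality "
                f"(Fisher exact test: p = {res.p_value:.2g})")
        lines.append("Selection differentials")
        for est in self.selection:
            lines.append(
                f"  {est.habitat}: {est.favored} favored, "
                f"advantage = {100 * est.advantage:.0f}% "
                f"(w = {est.w_favored:.2f} vs {est.w_other:.2f})")
        return "\n".join(lines)


def survivorship_report(outcomes: pd.DataFrame,
                        contrasts: tuple = DEFAULT_CONTRASTS) -> SurvivorshipReport:
    """Full survivorship analysis of a reciprocal-transplant census.

    Produces per-treatment tallies, the pairwise one-tailed Fisher
    contrasts (by default the four natural ones: each transplanted group
    against each resident control), and the per-habitat standardized
    selection differential between the two species (deep habitat: D-D vs
    S-D; shallow habitat: S-S vs D-S).
    """
    present = [t for t in ("S-S", "S-D", "D-S", "D-D")
               if (outcomes["treatment"] == t).any()]
    if len(present) < 2:
        raise DegenerateDataError("survivorship report needs at least 2 treatments")
    kept = outcomes[outcomes["status"] != "discarded"]
    treatments: dict = {}
    for trt in present:
        sub = kept[kept["treatment"] == trt]
        deaths = int((sub["status"] == "dead").sum())
        treatments[trt] = {
            "n": int(len(sub)),
            "deaths": deaths,
            "mortality": deaths / len(sub),
            "mortality_pct": round(100.0 * deaths / len(sub)),
        }
    contrast_results = []
    for a, b in contrasts:
        if a in treatments and b in treatments:
            contrast_results.append(fisher_one_tailed(tally_outcomes(outcomes, a, b)))
    selection = []
    for habitat, native, foreign in (("deep", "D-D", "S-D"), ("shallow", "S-S", "D-S")):
        if native in treatments and foreign in treatments:
            w_native = 1.0 - treatments[native]["mortality"]
            w_foreign = 1.0 - treatments[foreign]["mortality"]
            selection.append(selection_differential(
                w_native, w_foreign, labels=(native, foreign), habitat=habitat))
    return SurvivorshipReport(treatments=treatments, contrasts=contrast_results,
                              selection=selection)
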