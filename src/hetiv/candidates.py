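"""Stage 2 preparation: the high-dimensional candidate term space.

Candidate effect modifiers come in four groups:

  a. patient characteristics (age-band dummies, sex, frailty),
  b. forced (medium/high clinical priority) comorbidities,
  c. low-priority comorbidities,
  d. interactions: every comorbidity pair, and every comorbidity with each
     base characteristic.

With 28 comorbidities and 4 base-characteristic dummies this yields
C(28,2) + 28*4 = 490 interactions and 522 terms in total.  Terms are then
screened by a minimum-volume rule: a term survives only if, among its
carriers (indicator = 1; both parents = 1 for interactions), each treatment
arm holds at least ``min_per_arm`` patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .elicitation import PrioritySet
from .simulate import BASE_CHARS, term_column


@dataclass(frozen=True)
class Term:
    name: str  # colon-joined parent names for interactions
    parents: tuple[str, ...]
    group: str  # 'a' | 'b' | 'c' | 'd'

    @property
    def is_interaction(self) -> bool:
        return len(self.parents) > 1


@dataclass
class CandidateSet:
    group_a: list[Term]
    group_b: list[Term]
    group_c: list[Term]
    group_d: list[Term]

    @property
    def terms(self) -> list[Term]:
        return self.group_a + self.group_b + self.group_c + self.group_d

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class VolumeReport:
    """Per-term carrier counts by arm and the pass/fail decision."""

    table: pd.DataFrame  # term, group, carriers, carriers_nes, carriers_es, pct_nes, passed
    min_per_arm: int
    rule: str = "carriers"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def enumerate_candidates(
    priorities: PrioritySet, base_chars: tuple[str, ...] = BASE_CHARS
) -> CandidateSet:
    """Enumerate groups a-d with deterministic (lexicographic) ordering."""
    if not (priorities.forced or priorities.low_priority):
        raise ValueError("priority set is empty")
    forced = sorted(priorities.forced)
    low = sorted(priorities.low_priority)
    comorbs = sorted(forced + low)
    seen = set(comorbs) | set(base_chars)
    if len(seen) < len(comorbs) + len(base_chars):
        raise ValueError("duplicate term names across comorbidities/base chars")

    a = [Term(c, (c,), "a") for c in base_chars]
    b = [Term(c, (c,), "b") for c in forced]
    c_ = [Term(c, (c,), "c") for c in low]
    d = [
        Term(f"{x}:{y}", (x, y), "d") for x, y in combinations(comorbs, 2)
    ] + [
        Term(f"{cm}:{bc}", (cm, bc), "d") for cm in comorbs for bc in base_chars
    ]
    d.sort(key=lambda t: t.name)
    return CandidateSet(group_a=a, group_b=b, group_c=c_, group_d=d)


def design_matrix(cohort: pd.DataFrame, terms: list[Term] | list[str]) -> pd.DataFrame:
    """Numeric columns for a list of terms (interactions as products)."""
    names = [t.name if isinstance(t, Term) else t for t in terms]
    missing = {p for n in names for p in n.split(":")} - set(cohort.columns)
    if missing:
        raise KeyError(f"cohort is missing term parents: {sorted(missing)}")
    return pd.DataFrame(
        {n: term_column(cohort, n) for n in names}, index=cohort.index
    )


def apply_volume_threshold(
    cohort: pd.DataFrame,
    candidates: CandidateSet,
    min_per_arm: int = 50,
    rule: str = "carriers",
) -> tuple[CandidateSet, VolumeReport]:
    """Drop terms whose carrier counts fail the per-arm volume rule.

    rule="carriers" (default) requires >= min_per_arm patients in each
    treatment arm among carriers of the term.  rule="both_levels" is the
    stricter variant that additionally requires the same among non-carriers.
    An empty survivor set is a valid outcome and is flagged in the report.
    """
    if rule not in ("carriers", "both_levels"):
        raise ValueError("rule must be 'carriers' or 'both_levels'")
    treat = cohort["treatment"].to_numpy()
    rows = []
    survivors: dict[str, list[Term]] = {"a": [], "b": [], "c": [], "d": []}
    for t in candidates.terms:
        carrier = term_column(cohort, t.name) == 1
        n_car = int(carrier.sum())
        n_nes = int((carrier & (treat == 1)).sum())
        n_es = n_car - n_nes
        passed = min(n_nes, n_es) >= min_per_arm
        if rule == "both_levels":
            nc = (~carrier).sum()
            nc_nes = int((~carrier & (treat == 1)).sum())
            passed = passed and min(nc_nes, nc - nc_nes) >= min_per_arm
        rows.append(
            {
                "term": t.name,
                "group": t.group,
                "carriers": n_car,
                "carriers_nes": n_nes,
                "carriers_es": n_es,
                "pct_nes": 100.0 * n_nes / n_car if n_car else float("nan"),
                "passed": passed,
            }
        )
        if passed:
            survivors[t.group].append(t)
    report = VolumeReport(pd.DataFrame(rows), min_per_arm=min_per_arm, rule=rule)
    kept = CandidateSet(
        group_a=survivors["a"],
        group_b=survivors["b"],
        group_c=survivors["c"],
        group_d=survivors["d"],
    )
    return kept, report
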