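"""Cohort-level tallies and percentage reporting.

Every percentage a report prints is recomputed from its integer counts at
emission time — no stored rate is ever echoed unverified.  Rounding is
half-up to one decimal (the convention of clinical summaries, where 88.45
prints as 88.5), not banker's rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["rate", "CohortTally", "cohort_mutation_summary"]


def rate(numerator: int, denominator: int) -> tuple[float, str]:
    """Percentage of a count pair, rounded half-up to one decimal.

    Returns (value, display string), e.g. ``rate(69, 78) -> (88.5, '88.5%')``.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    value = Decimal(numerator) / Decimal(denominator) * 100
    rounded = value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(rounded), f"{rounded}%"


@dataclass
class CohortTally:
    """Labeled integer counts with parent/child consistency checks.

    ``hierarchy`` maps a parent key to the child keys that must sum to it.
    """

    counts: dict[str, int]
    hierarchy: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.counts.items():
            if value < 0:
                raise ValueError(f"count {key!r} is negative")
        self.validate()

    def validate(self) -> None:
        for parent, children in self.hierarchy.items():
            total = sum(self.counts[c] for c in children)
            if total != self.counts[parent]:
                raise ValueError(
                    f"children of {parent!r} sum to {total}, "
                    f"expected {self.counts[parent]}"
                )

    def __getitem__(self, key: str) -> int:
        return self.counts[key]


def cohort_mutation_summary(tally: CohortTally) -> dict:
    """Structured mutation-detection report with recomputed percentages.

    Expected count keys (all integers):

    * ``actionable_total``, ``actionable_ffpe``, ``actionable_hotspot_only``
      — actionable mutations by detection source (FFPE profiling vs
      tumor-agnostic hotspot-only); the two sources must sum to the total.
    * ``patients_total``, ``patients_with_actionable``
    * ``tracked_total``, ``tracked_detected`` — FFPE-derived mutations
      selected for plasma tracking and how many were seen in plasma.
    * ``patients_ctdna_detected``, ``patients_ctdna_detected_with_hotspot``
      — baseline ctDNA detection, tumor-informed only vs including the
      hotspot panel.
    * optionally ``responders``, ``responders_clinical_response``,
      ``non_responders``, ``non_responders_progression`` for the
      response-vs-outcome concordance block.

    Every rate in the output is computed by :func:`rate` from the counts.
    """
    if not tally.counts:
        return {"counts": {}, "rates": {}}
    tally.validate()
    c = tally.counts
    rates: dict[str, float] = {}
    display: dict[str, str] = {}

    def add(name: str, num_key: str, den_key: str) -> None:
        if num_key in c and den_key in c:
            value, text = rate(c[num_key], c[den_key])
            rates[name] = value
            display[name] = f"{c[num_key]}/{c[den_key]} = {text}"

    add("actionable_ffpe_pct", "actionable_ffpe", "actionable_total")
    add("actionable_hotspot_only_pct", "actionable_hotspot_only", "actionable_total")
    add("patients_with_actionable_pct", "patients_with_actionable", "patients_total")
    add("tracked_detected_pct", "tracked_detected", "tracked_total")
    add("patients_ctdna_detected_pct", "patients_ctdna_detected", "patients_total")
    add("patients_ctdna_detected_with_hotspot_pct",
        "patients_ctdna_detected_with_hotspot", "patients_total")
    add("responders_clinical_response_pct",
        "responders_clinical_response", "responders")
    add("non_responders_progression_pct",
        "non_responders_progression", "non_responders")

    if {"actionable_ffpe", "actionable_hotspot_only", "actionable_total"} <= c.keys():
        if c["actionable_ffpe"] + c["actionable_hotspot_only"] != c["actionable_total"]:
            raise ValueError("actionable sources do not sum to the total")

    return {"counts": dict(c), "rates": rates, "display": display}


def summary_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def summary_from_json(text: str) -> dict:
    return json.loads(text)
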