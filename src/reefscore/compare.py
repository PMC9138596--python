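"""Ranking candidate designs against a common reference."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .areit import FactorSet, IndexReport, areit_index
from .design import ARUnitDesign
from .errors import ReefscoreError


@dataclass
class ComparisonSet:
    """Index reports for every candidate against one reference, ranked by
    weighted overall index (full precision), ties broken by name."""

    reference: str
    reports: dict[str, IndexReport]
    ranking: list[str]
    warnings: list[str] = field(default_factory=list)

    def top(self) -> IndexReport:
        return self.reports[self.ranking[0]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, name in enumerate(self.ranking, start=1):
            r = self.reports[name]
            rows.append(
                {
                    "rank": rank,
                    "candidate": name,
                    "EM": r.em,
                    "NM": r.nm,
                    "HM": r.hm,
                    "AREIT": r.areit,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "ranking": list(self.ranking),
            "reports": {n: r.to_dict() for n, r in self.reports.items()},
            "warnings": list(self.warnings),
        }


def compare_designs(
    reference: ARUnitDesign,
    candidates: list[ARUnitDesign],
    factors: FactorSet = FactorSet(),
) -> ComparisonSet:
    """Score and rank candidates (full-precision mode).

    Undefined-index errors propagate, naming the failing candidate and
    dimension.  Candidates whose bounding volume differs from the
    reference's by more than 5% get an equal-volume warning attached.
    """
    reports: dict[str, IndexReport] = {}
    notes: list[str] = []
    for cand in candidates:
        try:
            report = areit_index(cand, reference, factors, rounding="full")
        except ReefscoreError as exc:
            raise ReefscoreError(f"candidate {cand.name!r}: {exc}") from exc
        reports[cand.name] = report
        notes.extend(f"{cand.name}: {w}" for w in report.warnings)
    ranking = sorted(reports, key=lambda n: (-reports[n].areit, n))
    return ComparisonSet(
        reference=reference.name,
        reports=reports,
        ranking=ranking,
        warnings=notes,
    )
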