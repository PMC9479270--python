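"""Treatment-reversal intersection analysis.

A reversal transcript is one whose regulation direction flips between the
disease contrast (disease vs control) and the treatment contrast (treated
vs disease): up in disease and pushed back down by treatment, or down in
disease and restored up by treatment. The two pattern sets are the
intersections of the corresponding directed, filter-passing sets of the two
contrasts; a transcript present in only one contrast is excluded. By default
membership therefore requires passing the differential-expression filter in
BOTH contrasts; a lenient mode requiring only the disease contrast exists
for exploratory use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from lncnet.synthetic import DOWN, UP

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReversalSets:
    """The two direction-flip intersections of a three-group study.

    ``up_then_down``: up in disease vs control AND down in treated vs disease.
    ``down_then_up``: the opposite flip. ``records`` optionally carries each
    member's fold change and p-value in both contrasts.
    """

    up_then_down: frozenset[str]
    down_then_up: frozenset[str]
    records: pd.DataFrame = field(default_factory=pd.DataFrame, compare=False)

    @property
    def total(self) -> int:
        return len(self.up_then_down) + len(self.down_then_up)

    def members(self) -> frozenset[str]:
        return self.up_then_down | self.down_then_up

    def pattern_of(self, transcript_id: str) -> str:
        if transcript_id in self.up_then_down:
            return "up_then_down"
        if transcript_id in self.down_then_up:
            return "down_then_up"
        raise KeyError(transcript_id)


def reversal_sets(de_disease: dict[str, str], de_treated: dict[str, str],
                  disease_results: pd.DataFrame | None = None,
                  treated_results: pd.DataFrame | None = None,
                  require_both: bool = True) -> ReversalSets:
    """Intersect two directed DE sets into the two reversal pattern sets.

    ``de_disease`` and ``de_treated`` map transcript id to retained
    direction (Up/Down) in the disease and treatment contrasts, as produced
    by :func:`lncnet.diffexp.filter_de`. Ids with an undefined direction are
    excluded and logged. When the full contrast-result tables are supplied,
    the per-member fold changes and p-values of both contrasts are attached.

    With ``require_both=False`` (lenient mode) a transcript only needs to
    pass the filter in the disease contrast; its treatment direction is then
    read from ``treated_results`` regardless of the treatment filter.
    """
    if not require_both:
        if treated_results is None:
            raise ValueError("lenient mode requires the treated contrast results")
        full = dict(zip(treated_results["transcript_id"], treated_results["direction"]))
        de_treated = {t: full[t] for t in de_disease if t in full}
    valid = {UP, DOWN}
    for name, d in (("disease", de_disease), ("treated", de_treated)):
        for tid, direction in d.items():
            if direction not in valid:
                logger.warning("excluding %s: direction %r in %s contrast",
                               tid, direction, name)
    clean_d = {t: d for t, d in de_disease.items() if d in valid}
    clean_t = {t: d for t, d in de_treated.items() if d in valid}

    shared = set(clean_d) & set(clean_t)
    up_down = frozenset(t for t in shared if clean_d[t] == UP and clean_t[t] == DOWN)
    down_up = frozenset(t for t in shared if clean_d[t] == DOWN and clean_t[t] == UP)

    records = pd.DataFrame()
    members = sorted(up_down | down_up)
    if members and disease_results is not None and treated_results is not None:
        a = disease_results.set_index("transcript_id")
        b = treated_results.set_index("transcript_id")
        records = pd.DataFrame({
            "transcript_id": members,
            "pattern": ["up_then_down" if t in up_down else "down_then_up"
                        for t in members],
            "fc_disease": a.loc[members, "fc_magnitude"].to_numpy(),
            "p_disease": a.loc[members, "p_value"].to_numpy(),
            "fc_treated": b.loc[members, "fc_magnitude"].to_numpy(),
            "p_treated": b.loc[members, "p_value"].to_numpy(),
        })
    return ReversalSets(up_then_down=up_down, down_then_up=down_up, records=records)


def reversal_counts(reversal: ReversalSets,
                    annotation: pd.DataFrame | None = None,
                    biotype: str | None = None) -> dict[str, int]:
    """Pattern counts, optionally restricted to one biotype.

    Returns ``{"up_then_down": ..., "down_then_up": ..., "total": ...}``;
    total always equals the sum of the two pattern counts. Restricting by
    biotype requires the study annotation.
    """
    up, down = reversal.up_then_down, reversal.down_then_up
    if biotype is not None:
        if annotation is None:
            raise ValueError("biotype filtering requires an annotation table")
        of_type = set(annotation.index[annotation["biotype"] == biotype])
        up, down = up & of_type, down & of_type
    return {"up_then_down": len(up), "down_then_up": len(down),
            "total": len(up) + len(down)}
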