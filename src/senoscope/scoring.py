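"""SA-β-Gal population scores and flow-cytometry summaries.

Per-condition scores are built from manual field counts (stained / total
cells per visual field):

* ``S%`` — percent SA-β-Gal-positive cells, mean ± SE across fields (fields
  are the replication unit, so the SE is computed across per-field
  percentages, not from a pooled binomial);
* ``V%rel`` — relative survival: each treated field's cell count divided by
  the mean control count, x100, averaged over treated fields (values above
  100 are legal — proliferation under treatment);
* ``SI = S% / (100 − V%rel)`` — the selectivity index, the yield of induced
  senescent cells per unit of cell loss; undefined (not an exception) when
  V%rel >= 100.

Flow-cytometry readouts are summarised as median fluorescence intensity
(MFI) with interquartile range, using linear-interpolation quartiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SampleSizeError

__all__ = [
    "FieldCount",
    "SenescenceScore",
    "SelectivityIndex",
    "FlowSummary",
    "positive_fraction",
    "relative_survival",
    "selectivity_index",
    "flow_summary",
    "score_conditions",
]


@dataclass(frozen=True)
class FieldCount:
    """Stained / total cell counts for one visual field."""

    field_id: str
    condition: str
    n_positive: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_total < 0:
            raise DomainError("counts must be non-negative")
        if self.n_positive > self.n_total:
            raise DomainError(
                f"field {self.field_id}: n_positive ({self.n_positive}) "
                f"exceeds n_total ({self.n_total})")


@dataclass(frozen=True)
class SelectivityIndex:
    """SI value; ``defined`` is False when V%rel >= 100 (no cell loss)."""

    value: float | None
    defined: bool
    reason: str | None = None


@dataclass(frozen=True)
class SenescenceScore:
    condition: str
    s_percent: float
    s_se: float
    v_rel_percent: float | None
    si: SelectivityIndex | None
    n_fields: int


@dataclass(frozen=True)
class FlowSummary:
    condition: str
    mfi: float
    iqr: float
    n_events: int
    quartile_convention: str = "linear interpolation"


def positive_fraction(fields: Sequence[FieldCount]) -> tuple[float, float]:
    """S% across fields -> (mean, SE of the mean of per-field percentages).

    Zero-total fields are excluded with a warning; a single usable field
    yields SE 0.
    """
    usable = [f for f in fields if f.n_total > 0]
    skipped = len(fields) - len(usable)
    if skipped:
        warnings.warn(f"excluded {skipped} zero-total field(s) from S%",
                      stacklevel=2)
    if not usable:
        raise SampleSizeError("no fields with a positive total cell count")
    percents = np.array([100.0 * f.n_positive / f.n_total for f in usable])
    mean = float(percents.mean())
    se = float(percents.std(ddof=1) / np.sqrt(percents.size)) \
        if percents.size > 1 else 0.0
    return mean, se


def relative_survival(treated_fields: Sequence[FieldCount],
                      control_fields: Sequence[FieldCount]) -> float:
    """V%rel: per-field treated totals / mean control total x 100, averaged."""
    if not treated_fields or not control_fields:
        raise SampleSizeError("need at least one treated and one control field")
    control_mean = float(np.mean([f.n_total for f in control_fields]))
    if control_mean <= 0:
        raise DomainError("control mean cell count is zero")
    ratios = [100.0 * f.n_total / control_mean for f in treated_fields]
    return float(np.mean(ratios))


def selectivity_index(s_percent: float, v_rel_percent: float) -> SelectivityIndex:
    """SI = S% / (100 − V%rel); undefined result when V%rel >= 100."""
    if not 0 <= s_percent <= 100:
        raise DomainError(f"S% must lie in [0, 100], got {s_percent}")
    if v_rel_percent < 0:
        raise DomainError(f"V%rel must be >= 0, got {v_rel_percent}")
    if v_rel_percent >= 100:
        return SelectivityIndex(
            value=None, defined=False,
            reason=f"V%rel = {v_rel_percent:g} >= 100: no net cell loss")
    return SelectivityIndex(value=s_percent / (100.0 - v_rel_percent),
                            defined=True)


def flow_summary(events: Sequence[float], condition: str = "") -> FlowSummary:
    """Median fluorescence intensity with interquartile range.

    Quartiles use linear interpolation (declared on the summary).
    """
    events = np.asarray(events, dtype=float)
    if events.size < 10:
        raise SampleSizeError(f"need >= 10 flow events, got {events.size}")
    q1, q2, q3 = np.percentile(events, [25, 50, 75])
    return FlowSummary(condition=condition, mfi=float(q2),
                       iqr=float(q3 - q1), n_events=int(events.size))


def _fields_from_frame(table: pd.DataFrame) -> dict[str, list[FieldCount]]:
    grouped: dict[str, list[FieldCount]] = {}
    for row in table.itertuples(index=False):
        grouped.setdefault(str(row.condition), []).append(FieldCount(
            field_id=str(row.field_id), condition=str(row.condition),
            n_positive=int(row.n_positive), n_total=int(row.n_total)))
    return grouped


def score_conditions(counts: pd.DataFrame,
                     control_condition: str | None = None) -> pd.DataFrame:
    """Score every condition in a field-count table.

    ``counts`` columns: condition, field_id, n_positive, n_total and
    optionally ``control`` naming each condition's control for V%rel
    (overridden by ``control_condition`` when given).  Output columns:
    condition, S_percent, S_SE, V_rel, SI, SI_defined, n_fields.
    """
    grouped = _fields_from_frame(counts)
    control_map: dict[str, str | None] = {}
    if "control" in counts.columns:
        for row in counts.itertuples(index=False):
            control_map[str(row.condition)] = (
                str(row.control) if pd.notna(row.control) else None)
    rows = []
    for condition, fields in grouped.items():
        s_mean, s_se = positive_fraction(fields)
        control = control_condition or control_map.get(condition)
        v_rel = si_value = None
        si_defined = False
        if control is not None and control in grouped and control != condition:
            v_rel = relative_survival(fields, grouped[control])
            si = selectivity_index(s_mean, v_rel)
            si_value, si_defined = si.value, si.defined
        rows.append({
            "condition": condition,
            "S_percent": s_mean,
            "S_SE": s_se,
            "V_rel": v_rel,
            "SI": si_value,
            "SI_defined": si_defined,
            "n_fields": len(fields),
        })
    return pd.DataFrame(rows)
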