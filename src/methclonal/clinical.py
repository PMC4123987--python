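"""Rule-based true-recurrence / new-primary calls from clinical features.

A local recurrence is clinically a plausible regrowth of its primary (TR)
when it shares the primary's location, histological type, and is at least
as aggressive.  Conversely it is called a new primary (NP) when any of
these triggers fires:

* ``location`` — the recurrence arose 4 cm or more from the primary;
* ``type`` — the histological type differs (a mixed ductal-lobular tumor
  is compatible with either component);
* ``grade`` — the recurrence is of lower grade than the primary (a grade
  increase is compatible with regrowth);
* ``receptor_gain`` — an estrogen or progesterone receptor negative in
  the primary is positive in the recurrence, i.e. the recurrence gained a
  less-aggressive hormonal feature.  Receptor loss does not trigger, and
  HER2 (not a hormonal receptor) is not considered.

Missing values never fire a trigger; a pair with no usable feature at all
(no types, no hormonal receptors, no location) is indeterminate and
flagged rather than silently labeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import ClinicalRecord, clinical_records_from_row

__all__ = ["ClinicalCall", "classify_clinical", "classify_cohort"]

#: histological types compatible with both components of a mixed tumor
_MIXED_COMPONENTS = {"ductal", "lobular"}


@dataclass
class ClinicalCall:
    label: str | None  # "TR", "NP" or None when indeterminate
    triggers: list[str]
    indeterminate: bool = False


def _types_compatible(a: str, b: str) -> bool:
    if a == b:
        return True
    if a == "mixed" and b in _MIXED_COMPONENTS:
        return True
    if b == "mixed" and a in _MIXED_COMPONENTS:
        return True
    return False


def classify_clinical(pt: ClinicalRecord, lr: ClinicalRecord) -> ClinicalCall:
    """Classify one recurrence against its primary; returns label + rule trace."""
    no_types = pt.histological_type is None and lr.histological_type is None
    no_receptors = all(
        v is None for v in (pt.er, pt.pr, lr.er, lr.pr)
    )
    if no_types and no_receptors and lr.location_within_4cm is None:
        return ClinicalCall(label=None, triggers=[], indeterminate=True)

    triggers: list[str] = []
    if lr.location_within_4cm == 0:
        triggers.append("location")
    if (
        pt.histological_type is not None
        and lr.histological_type is not None
        and not _types_compatible(pt.histological_type, lr.histological_type)
    ):
        triggers.append("type")
    if pt.grade is not None and lr.grade is not None and lr.grade < pt.grade:
        triggers.append("grade")
    if (pt.er == "-" and lr.er == "+") or (pt.pr == "-" and lr.pr == "+"):
        triggers.append("receptor_gain")

    return ClinicalCall(label="NP" if triggers else "TR", triggers=triggers)


def classify_cohort(
    pt_table: pd.DataFrame, lr_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Apply the rule classifier to every pair of a cohort table.

    Accepts either a combined table in the packaged-fixture layout
    (columns ``pair``, ``pt_*``, ``lr_*``, ``loc``) or separate primary
    and recurrence tables sharing a ``pair`` column.  Returns one row per
    pair with the label and the fired triggers, in pair order; the result
    depends only on pair ids, not on row order.
    """
    if lr_table is None:
        combined = pt_table
    else:
        combined = pt_table.merge(lr_table, on="pair", suffixes=("", "_lr"))
    rows = []
    for _, row in combined.iterrows():
        pt = clinical_records_from_row(row, "pt")
        lr = clinical_records_from_row(row, "lr", loc="loc")
        call = classify_clinical(pt, lr)
        rows.append(
            (
                str(row["pair"]),
                call.label,
                ";".join(call.triggers),
                call.indeterminate,
            )
        )
    out = pd.DataFrame(rows, columns=["pair", "label", "triggers", "indeterminate"])
    return out.sort_values("pair", key=lambda s: s.map(_pair_sort_key)).reset_index(
        drop=True
    )


def _pair_sort_key(v: str):
    try:
        return (0, int(v))
    except (TypeError, ValueError):
        return (1, str(v))
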