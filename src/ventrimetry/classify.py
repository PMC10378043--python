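"""Ventriculomegaly classification from atrial widths.

Clinical rule: an atrial width strictly greater than 10 mm on either side is
ventriculomegaly, graded mild / moderate / severe; a left-right asymmetry
above 2.4 mm without dilatation is flagged but still normal.  Exactly
10.0 mm is normal ("wider than 10 mm" is the abnormality criterion).  The
conventional integer grade ranges leave (12, 13) mm unassigned; here the
mild bin extends to the moderate edge, so mild = (10, 13), moderate =
[13, 15], severe = > 15, with the edges configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

VM_THRESHOLD_MM = 10.0
SEVERITY_EDGES_MM = (10.0, 13.0, 15.0)
ASYMMETRY_MM = 2.4


@dataclass
class CaseClassification:
    right_mm: float
    left_mm: float
    case_label: str            # normal | ventriculomegaly
    right_grade: str           # normal | mild | moderate | severe
    left_grade: str
    asymmetry_mm: float
    asymmetry_flag: bool


def grade_ventricle(width_mm: float,
                    edges: tuple[float, float, float] = SEVERITY_EDGES_MM) -> str:
    """Severity grade of one ventricle's width."""
    if width_mm <= 0:
        raise ValueError(f"width must be positive, got {width_mm}")
    lo, mid, hi = edges
    if not lo < mid <= hi:
        raise ValueError(f"severity edges not increasing: {edges}")
    if width_mm <= lo:
        return "normal"
    if width_mm < mid:
        return "mild"
    if width_mm <= hi:
        return "moderate"
    return "severe"


def classify_case(right_mm: float, left_mm: float,
                  vm_threshold_mm: float = VM_THRESHOLD_MM,
                  severity_edges_mm: tuple[float, float, float] = SEVERITY_EDGES_MM,
                  asymmetry_mm: float = ASYMMETRY_MM) -> CaseClassification:
    """Per-case call: ventriculomegaly iff either side exceeds the threshold."""
    if right_mm <= 0 or left_mm <= 0:
        raise ValueError("widths must be positive")
    abnormal = max(right_mm, left_mm) > vm_threshold_mm
    asym = abs(left_mm - right_mm)
    return CaseClassification(
        right_mm=float(right_mm), left_mm=float(left_mm),
        case_label="ventriculomegaly" if abnormal else "normal",
        right_grade=grade_ventricle(right_mm, severity_edges_mm),
        left_grade=grade_ventricle(left_mm, severity_edges_mm),
        asymmetry_mm=float(asym),
        asymmetry_flag=bool(not abnormal and asym > asymmetry_mm),
    )


__all__ = ["VM_THRESHOLD_MM", "SEVERITY_EDGES_MM", "ASYMMETRY_MM",
           "CaseClassification", "grade_ventricle", "classify_case"]
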