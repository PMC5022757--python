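"""Bundled reference cohort: anisotropy vectors and field angles of three
soft-tissue sarcoma cases at the extremities (forearm, leg, thigh).

The cohort provides measured per-region anisotropy vectors, the integer
isotropy-error percentages reported with them, and the Euler angles of each
case's applied-field frame.  It serves as a realistic worked input and as
reference data for the frame-rotation construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .regions import AnisotropyVector
from .rotation import EulerAngles

TISSUES = ("soft_tissue", "tumor", "bone")


@dataclass(frozen=True)
class ReferenceTissue:
    vector: AnisotropyVector
    reported_error_pct: tuple[int, int, int]
    #: per-axis flag: True where the reported integer matches truncation of
    #: the isotropy-error formula; False cells are scrambled in the source
    #: report and excluded from numeric comparisons
    error_formula_consistent: tuple[bool, bool, bool]


@dataclass(frozen=True)
class ReferenceCase:
    case: str
    site: str
    angles: EulerAngles
    tissues: dict[str, ReferenceTissue]


def load_reference_cohort() -> list[ReferenceCase]:
    """Load the bundled three-case cohort."""
    raw = json.loads(
        resources.files("dticond").joinpath("data/reference_cohort.json").read_text()
    )
    cases = []
    for c in raw["cases"]:
        ang = c["angles_deg_ccw"]
        tissues = {
            name: ReferenceTissue(
                vector=AnisotropyVector(name, tuple(t["A"])),
                reported_error_pct=tuple(t["reported_error_pct"]),
                error_formula_consistent=tuple(t["error_formula_consistent"]),
            )
            for name, t in c["tissues"].items()
        }
        cases.append(
            ReferenceCase(
                case=c["case"],
                site=c["site"],
                angles=EulerAngles(ang["alpha"], ang["theta"], ang["phi"]),
                tissues=tissues,
            )
        )
    return cases
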