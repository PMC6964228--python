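"""Molecular sexing from marker amplification calls.

A sample is screened for Y-linked (male-specific) PCR markers together with
a positive control.  A failed control voids the sample; otherwise
amplification of at least one male-linked marker calls the sample male
(with a discordance flag when the markers disagree), and amplification of
none calls it female.  Because Y-hemizygous markers can only confirm
maleness, a male whose DNA fails both marker PCRs while passing the control
is miscalled female — detectable only against a registry of known sexes,
which `validate_assay` provides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["SexCall", "ValidationSummary", "call_sex", "calls_from_table", "validate_assay"]


@dataclass(frozen=True)
class SexCall:
    individual_id: str
    call: str  # 'male' | 'female' | 'failed'
    marker_evidence: Mapping[str, bool]
    control_passed: bool
    discordant: bool  # male-linked markers disagree

    def __post_init__(self) -> None:
        if (self.call == "failed") != (not self.control_passed):
            raise ValueError("call must be 'failed' exactly when the control failed")
        if self.call == "male" and not any(self.marker_evidence.values()):
            raise ValueError("a male call requires >= 1 amplified marker")


def call_sex(
    individual_id: str,
    marker_amplified: Mapping[str, bool],
    control_passed: bool,
    known_markers: Sequence[str] | None = None,
) -> SexCall:
    """Apply the sexing decision rule to one sample record.

    Control failed → 'failed'.  Otherwise >= 1 male-linked marker amplified
    → 'male' (discordant if the markers disagree); none amplified →
    'female'.
    """
    if not marker_amplified:
        raise ValueError("at least one male-linked marker column is required")
    if known_markers is not None:
        unknown = set(marker_amplified) - set(known_markers)
        if unknown:
            raise ValueError(f"unknown marker ids: {sorted(unknown)}")
    evidence = {m: bool(v) for m, v in marker_amplified.items()}
    if not control_passed:
        call = "failed"
    elif any(evidence.values()):
        call = "male"
    else:
        call = "female"
    discordant = call == "male" and not all(evidence.values())
    return SexCall(individual_id, call, evidence, bool(control_passed), discordant)


def calls_from_table(table: pd.DataFrame,
                     known_markers: Sequence[str] | None = None) -> list[SexCall]:
    """Apply `call_sex` to a long assay table (individual_id, marker_id,
    amplified, control), one call per individual."""
    calls = []
    for ind, grp in table.groupby("individual_id", sort=True):
        evidence = dict(zip(grp["marker_id"], grp["amplified"].astype(bool)))
        control_passed = (grp["control"] == "pass").all()
        calls.append(call_sex(str(ind), evidence, bool(control_passed), known_markers))
    return calls


@dataclass(frozen=True)
class ValidationSummary:
    n_known_female: int
    n_known_male: int
    females_amplifying: int          # known females amplifying any marker (expected 0)
    male_amplified_by_marker: Mapping[str, int]
    false_male: int                  # known females called male
    males_called_female: int         # known males calling female (joint marker failure)
    failed: int                      # control failures
    discordant: int                  # male calls with disagreeing markers


def validate_assay(calls: Iterable[SexCall], known_sexes: Mapping[str, str]) -> ValidationSummary:
    """Score assay calls against a registry of individuals of known sex."""
    calls = list(calls)
    missing = [c.individual_id for c in calls if c.individual_id not in known_sexes]
    if missing:
        raise ValueError(f"individuals missing from registry: {missing[:5]}")

    known_f = [c for c in calls if known_sexes[c.individual_id] == "F"]
    known_m = [c for c in calls if known_sexes[c.individual_id] == "M"]
    markers = sorted({m for c in calls for m in c.marker_evidence})
    per_marker = {
        m: sum(1 for c in known_m if c.marker_evidence.get(m, False)) for m in markers
    }
    return ValidationSummary(
        n_known_female=len(known_f),
        n_known_male=len(known_m),
        females_amplifying=sum(1 for c in known_f if any(c.marker_evidence.values())),
        male_amplified_by_marker=per_marker,
        false_male=sum(1 for c in known_f if c.call == "male"),
        males_called_female=sum(1 for c in known_m if c.call == "female"),
        failed=sum(1 for c in calls if c.call == "failed"),
        discordant=sum(1 for c in calls if c.discordant),
    )
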