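"""Obstruction group assignment from LVOT peak pressure drops.

The cohort is stratified by the Doppler-derived LVOT peak pressure drop:
obstructive at rest (R+) means a rest drop >= 30 mmHg; among subjects
non-obstructive at rest with a stress measurement, those reaching the
threshold only under stress form R-S+ and the remainder R-S-.  Threshold
comparisons are inclusive (>=) on the obstructive side; subjects obstructive
at rest are excluded from the stress comparison by definition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "REST_THRESHOLD_MMHG",
    "GroupAssignment",
    "classify_record",
    "assign_groups",
]

REST_THRESHOLD_MMHG = 30.0

#: sarcomeric and phenocopy genes whose mutations define genotype-positive HCM
SARCOMERIC_GENES = (
    "MYH7", "MYBPC3", "TNNT2", "TNNI3", "MYL2", "MYL3", "ACTC1", "TPM1",
)
PHENOCOPY_GENES = ("GLA", "PRKAG2", "LAMP2", "TTR")


@dataclass
class GroupAssignment:
    """Per-subject obstruction labels and their counts.

    ``rest_label`` is "R-" or "R+" for every subject; ``stress_label`` is
    "R-S-"/"R-S+" for subjects non-obstructive at rest with a stress
    measurement and ``None`` otherwise (missing stress, or obstructive at
    rest and hence excluded from the stress comparison).
    """

    subject_ids: list[str]
    rest_label: list[str]
    stress_label: list[str | None]
    genotype: list[str]
    counts: Counter = field(default_factory=Counter)

    def indices(self, label: str) -> list[int]:
        """Positions of subjects carrying ``label`` (rest, stress or genotype)."""
        if label in ("R-", "R+"):
            return [i for i, l in enumerate(self.rest_label) if l == label]
        if label in ("R-S-", "R-S+"):
            return [i for i, l in enumerate(self.stress_label) if l == label]
        if label in ("G-", "G+"):
            return [i for i, g in enumerate(self.genotype) if g == label]
        raise KeyError(f"unknown group label {label!r}")


def classify_record(record, rest_threshold_mmHg: float = REST_THRESHOLD_MMHG) -> str:
    """Finest applicable group label for a single subject record."""
    rest, stress = _validated_drops(record)
    if rest >= rest_threshold_mmHg:
        return "R+"
    if stress is None:
        return "R-"
    return "R-S+" if stress >= rest_threshold_mmHg else "R-S-"


def assign_groups(
    records, rest_threshold_mmHg: float = REST_THRESHOLD_MMHG
) -> GroupAssignment:
    """Partition a cohort into R-/R+ and (where possible) R-S-/R-S+.

    ``records`` is a sequence of objects with ``subject_id``,
    ``drop_rest_mmHg``, ``drop_stress_mmHg`` (None = missing) and
    ``genotype`` attributes.  Raises ``ValueError`` on negative drops.
    """
    if rest_threshold_mmHg <= 0:
        raise ValueError("threshold must be positive")
    ids, rest_labels, stress_labels, genotypes = [], [], [], []
    for record in records:
        rest, stress = _validated_drops(record)
        rest_label = "R+" if rest >= rest_threshold_mmHg else "R-"
        if rest_label == "R-" and stress is not None:
            stress_label = "R-S+" if stress >= rest_threshold_mmHg else "R-S-"
        else:
            stress_label = None
        ids.append(record.subject_id)
        rest_labels.append(rest_label)
        stress_labels.append(stress_label)
        genotypes.append(getattr(record, "genotype", "unknown"))
    counts = Counter(rest_labels)
    counts.update(l for l in stress_labels if l is not None)
    counts.update(g for g in genotypes if g in ("G-", "G+"))
    return GroupAssignment(
        subject_ids=ids,
        rest_label=rest_labels,
        stress_label=stress_labels,
        genotype=genotypes,
        counts=counts,
    )


def _validated_drops(record):
    rest = float(record.drop_rest_mmHg)
    stress = record.drop_stress_mmHg
    stress = None if stress is None else float(stress)
    if stress is not None and stress != stress:  # NaN from CSV = missing
        stress = None
    if rest < 0 or (stress is not None and stress < 0):
        raise ValueError(
            f"negative pressure drop for subject {record.subject_id!r}"
        )
    return rest, stress
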