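"""Subgroup filters over study annotations.

Mirrors the interactive tool's study-selection semantics: filter on
protocol, health status, muscle, biopsy timing, sex composition and age,
plus explicit include/exclude lists where exclusion always wins.  An empty
filter keeps every study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

from .types import (
    BiopsyTiming, HealthStatus, Muscle, Protocol, StudyAnnotation,
)

log = logging.getLogger(__name__)


def _coerce_set(values, enum_cls):
    if values is None:
        return None
    return frozenset(enum_cls.coerce(v) for v in values)


def _intersect(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return a & b


def _range_intersect(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return (max(a[0], b[0]), min(a[1], b[1]))


@dataclass(frozen=True)
class SubgroupFilter:
    """Constraint set selecting a subgroup of studies.

    ``None`` for any field means "no constraint".  ``exclude_studies`` wins
    over every other rule, including explicit inclusion.
    """

    protocols: frozenset | None = None
    health_status: frozenset | None = None
    muscles: frozenset | None = None
    biopsy_timing: frozenset | None = None
    sex_fraction_range: tuple[float, float] | None = None
    age_range: tuple[float, float] | None = None
    include_studies: frozenset | None = None
    exclude_studies: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "protocols",
                           _coerce_set(self.protocols, Protocol))
        object.__setattr__(self, "health_status",
                           _coerce_set(self.health_status, HealthStatus))
        object.__setattr__(self, "muscles", _coerce_set(self.muscles, Muscle))
        object.__setattr__(self, "biopsy_timing",
                           _coerce_set(self.biopsy_timing, BiopsyTiming))
        if self.include_studies is not None:
            object.__setattr__(self, "include_studies",
                               frozenset(map(str, self.include_studies)))
        object.__setattr__(self, "exclude_studies",
                           frozenset(map(str, self.exclude_studies)))

    def matches(self, ann: StudyAnnotation) -> bool:
        if ann.study_id in self.exclude_studies:
            return False
        if self.include_studies is not None and ann.study_id not in self.include_studies:
            return False
        if self.protocols is not None and ann.protocol not in self.protocols:
            return False
        if self.health_status is not None and ann.health_status not in self.health_status:
            return False
        if self.muscles is not None and ann.muscle not in self.muscles:
            return False
        if self.biopsy_timing is not None and ann.biopsy_timing not in self.biopsy_timing:
            return False
        if self.sex_fraction_range is not None:
            lo, hi = self.sex_fraction_range
            if not lo <= ann.sex_fraction_female <= hi:
                return False
        if self.age_range is not None:
            lo, hi = self.age_range
            if not lo <= ann.age_mean <= hi:
                return False
        return True

    def __and__(self, other: "SubgroupFilter") -> "SubgroupFilter":
        """Conjunction: a study passes f1 & f2 iff it passes both filters."""
        return SubgroupFilter(
            protocols=_intersect(self.protocols, other.protocols),
            health_status=_intersect(self.health_status, other.health_status),
            muscles=_intersect(self.muscles, other.muscles),
            biopsy_timing=_intersect(self.biopsy_timing, other.biopsy_timing),
            sex_fraction_range=_range_intersect(self.sex_fraction_range,
                                                other.sex_fraction_range),
            age_range=_range_intersect(self.age_range, other.age_range),
            include_studies=_intersect(self.include_studies,
                                       other.include_studies),
            exclude_studies=self.exclude_studies | other.exclude_studies,
        )

    def describe(self) -> dict:
        """JSON-serializable provenance record of the constraints."""
        def _names(s):
            return sorted(m.name for m in s) if s is not None else None
        return {
            "protocols": _names(self.protocols),
            "health_status": _names(self.health_status),
            "muscles": _names(self.muscles),
            "biopsy_timing": _names(self.biopsy_timing),
            "sex_fraction_range": list(self.sex_fraction_range) if self.sex_fraction_range else None,
            "age_range": list(self.age_range) if self.age_range else None,
            "include_studies": sorted(self.include_studies) if self.include_studies is not None else None,
            "exclude_studies": sorted(self.exclude_studies),
        }


def subset_studies(annotations: Iterable[StudyAnnotation],
                   flt: SubgroupFilter | None) -> list[StudyAnnotation]:
    """Order-preserving application of a subgroup filter."""
    annotations = list(annotations)
    if flt is None:
        return annotations
    kept = [a for a in annotations if flt.matches(a)]
    dropped = len(annotations) - len(kept)
    if dropped:
        log.info("subgroup filter excluded %d of %d studies", dropped,
                 len(annotations))
    return kept
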