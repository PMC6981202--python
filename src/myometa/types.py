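"""Core domain types shared across the package.

The in-memory currency of the pipeline is pandas: an :class:`ExpressionStudy`
wraps a genes x samples log2 matrix with (subject, condition) column keys, an
:class:`EffectTable` wraps the long-format per-study differential-expression
summaries that feed the random-effects stage, and meta-analysis results are
plain DataFrames with the column schema in :data:`META_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PRE = "PRE"
POST = "POST"

#: Long-format per-study effect schema (one row per gene x study).
EFFECT_COLUMNS = [
    "gene", "study_id", "logfc", "var", "n", "t", "df", "p", "fdr",
    "ci_low", "ci_high",
]

#: Pooled result schema (one row per gene within a protocol).
META_COLUMNS = [
    "gene", "protocol", "k", "mu", "se_mu", "ci_low", "ci_high", "z", "p",
    "fdr", "tau2", "Q", "I2", "estimator", "status",
]

STATUS_OK = "OK"
STATUS_TOO_FEW = "TOO_FEW_STUDIES"
STATUS_FALLBACK = "NONCONVERGED_FALLBACK"


class _CoercibleEnum(str, Enum):
    @classmethod
    def coerce(cls, value):
        if isinstance(value, cls):
            return value
        key = str(value).strip().upper()
        try:
            return cls[key]
        except KeyError:
            pass
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"{cls.__name__}: unknown value {value!r}; "
                f"expected one of {[m.name for m in cls]}"
            ) from None


class Protocol(_CoercibleEnum):
    """Intervention protocol of a study group."""

    ACUTE_AEROBIC = "acute_aerobic"
    ACUTE_RESISTANCE = "acute_resistance"
    INACTIVITY = "inactivity"
    TRAINING_AEROBIC = "training_aerobic"
    TRAINING_RESISTANCE = "training_resistance"
    TRAINING_HIIT = "training_hiit"
    TRAINING_COMBINED = "training_combined"


class Muscle(_CoercibleEnum):
    VASTUS_LATERALIS = "vastus_lateralis"
    BICEPS_BRACHII = "biceps_brachii"
    QUADRICEPS_FEMORIS = "quadriceps_femoris"


class HealthStatus(_CoercibleEnum):
    """Healthy (HLY) vs metabolically impaired (MTI: overweight/obese, T2D
    or metabolic dysregulation) study groups."""

    HLY = "hly"
    MTI = "mti"


class BiopsyTiming(_CoercibleEnum):
    """Biopsy immediately (<30 min, IMM) or after recovery (>2 h, REC)
    following acute exercise."""

    IMM = "imm"
    REC = "rec"
    UNKNOWN = "unknown"


class PlatformKind(_CoercibleEnum):
    ARRAY = "array"
    RNASEQ = "rnaseq"


class Design(_CoercibleEnum):
    PAIRED = "paired"
    UNPAIRED = "unpaired"


@dataclass
class StudyAnnotation:
    """Phenotype/protocol metadata for one study group; drives subgrouping."""

    study_id: str
    protocol: Protocol
    n_subjects: int
    muscle: Muscle = Muscle.VASTUS_LATERALIS
    sex_fraction_female: float = 0.0
    age_mean: float = 40.0
    age_sd: float = 10.0
    bmi_mean: float = 25.0
    bmi_sd: float = 2.0
    health_status: HealthStatus = HealthStatus.HLY
    biopsy_timing: BiopsyTiming = BiopsyTiming.UNKNOWN
    platform_kind: PlatformKind = PlatformKind.ARRAY

    def __post_init__(self):
        self.protocol = Protocol.coerce(self.protocol)
        self.muscle = Muscle.coerce(self.muscle)
        self.health_status = HealthStatus.coerce(self.health_status)
        self.biopsy_timing = BiopsyTiming.coerce(self.biopsy_timing)
        self.platform_kind = PlatformKind.coerce(self.platform_kind)
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError(
                f"{self.study_id}: sex_fraction_female must lie in [0, 1]"
            )
        if int(self.n_subjects) < 1:
            raise ValueError(f"{self.study_id}: n_subjects must be >= 1")
        self.n_subjects = int(self.n_subjects)


@dataclass
class ExpressionStudy:
    """One study's genes x samples log2 expression matrix.

    ``values`` carries a two-level column index (subject_id, condition) with
    condition in {PRE, POST}.  For a paired design every subject appears
    exactly once per condition.
    """

    study_id: str
    values: pd.DataFrame
    design: Design = Design.PAIRED

    def __post_init__(self):
        self.design = Design.coerce(self.design)
        cols = self.values.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError(
                f"{self.study_id}: expression columns must be "
                "(subject, condition) pairs"
            )
        bad = sorted({c for _, c in cols} - {PRE, POST})
        if bad:
            raise ValueError(
                f"{self.study_id}: unknown condition labels {bad}; "
                f"expected {PRE}/{POST}"
            )
        if self.design is Design.PAIRED:
            tally = pd.Series(0, index=sorted({s for s, _ in cols}), dtype=int)
            for subj, cond in cols:
                tally[subj] += 1 if cond == PRE else 0
            per_subject = pd.DataFrame(
                {"pre": 0, "post": 0}, index=tally.index
            )
            for subj, cond in cols:
                per_subject.loc[subj, "pre" if cond == PRE else "post"] += 1
            broken = per_subject[(per_subject["pre"] != 1) | (per_subject["post"] != 1)]
            if len(broken):
                raise ValueError(
                    f"{self.study_id}: paired design requires each subject "
                    f"exactly once per condition; offending subjects: "
                    f"{list(broken.index)}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for subj, _ in self.values.columns:
            seen.setdefault(subj, None)
        return list(seen)

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        """Genes x subjects matrix for one condition (columns = subjects)."""
        sub = self.values.loc[:, [c for c in self.values.columns if c[1] == condition]]
        sub.columns = [s for s, _ in sub.columns]
        return sub


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO terms / pathways) sharing the expression
    identifier space."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self):
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes_of(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class ComplexMap:
    """Protein/complex name -> coding genes, for fold-change projection."""

    complexes: dict[str, list[str]]

    def __post_init__(self):
        for name, genes in self.complexes.items():
            if not genes:
                raise ValueError(f"complex {name!r} has no genes")


@dataclass
class EffectTable:
    """Per-study, per-gene effects plus the contributing study annotations."""

    frame: pd.DataFrame
    studies: list[StudyAnnotation] = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in EFFECT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"effect table lacks columns {missing}")
        known = {a.study_id for a in self.studies}
        present = set(self.frame["study_id"].unique())
        orphans = sorted(present - known)
        if orphans:
            raise ValueError(f"effect rows reference unannotated studies {orphans}")
        if self.frame.duplicated(["gene", "study_id"]).any():
            raise ValueError("duplicate (gene, study_id) effect rows")

    @property
    def genes(self) -> pd.Index:
        return pd.Index(pd.unique(self.frame["gene"]))

    def annotation(self, study_id: str) -> StudyAnnotation:
        for ann in self.studies:
            if ann.study_id == study_id:
                return ann
        raise KeyError(study_id)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, studies: Iterable[StudyAnnotation]) -> "EffectTable":
        frame = pd.read_csv(path, sep="\t", na_values="NA")
        return cls(frame=frame, studies=list(studies))


def annotations_to_frame(annotations: Iterable[StudyAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append({
            "study_id": a.study_id,
            "protocol": a.protocol.name,
            "muscle": a.muscle.name,
            "sex_fraction_female": a.sex_fraction_female,
            "age_mean": a.age_mean,
            "age_sd": a.age_sd,
            "bmi_mean": a.bmi_mean,
            "bmi_sd": a.bmi_sd,
            "health_status": a.health_status.name,
            "biopsy_timing": a.biopsy_timing.name,
            "platform_kind": a.platform_kind.name,
            "n_subjects": a.n_subjects,
        })
    return pd.DataFrame(rows)


def annotations_from_frame(frame: pd.DataFrame) -> list[StudyAnnotation]:
    out = []
    for _, row in frame.iterrows():
        out.append(StudyAnnotation(
            study_id=str(row["study_id"]),
            protocol=row["protocol"],
            n_subjects=int(row["n_subjects"]),
            muscle=row.get("muscle", Muscle.VASTUS_LATERALIS),
            sex_fraction_female=float(row.get("sex_fraction_female", 0.0)),
            age_mean=float(row.get("age_mean", 40.0)),
            age_sd=float(row.get("age_sd", 10.0)),
            bmi_mean=float(row.get("bmi_mean", 25.0)),
            bmi_sd=float(row.get("bmi_sd", 2.0)),
            health_status=row.get("health_status", HealthStatus.HLY),
            biopsy_timing=row.get("biopsy_timing", BiopsyTiming.UNKNOWN),
            platform_kind=row.get("platform_kind", PlatformKind.ARRAY),
        ))
    return out
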