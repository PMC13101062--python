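"""Risk-factor feature vector encoding.

Demographics, habits, and the anatomic-site label are one-hot encoded with
an explicit "unknown" category per field (missing or unseen values map
there); age is min–max scaled to the training range, with missing ages
imputed by the training mean.  All encoder statistics are fitted on the
training split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import PatientRecord, SiteRecord, RISK_FIELDS

UNKNOWN = "unknown"

#: categorical fields in encoding order: patient risk factors then site label
CATEGORICAL_FIELDS = (*RISK_FIELDS, "anatomic_label")


@dataclass
class EncoderSpec:
    """Fitted vocabularies and age statistics; frozen after fitting."""

    vocabularies: dict[str, list[str]] = field(default_factory=dict)
    age_min: float = 0.0
    age_max: float = 1.0
    age_mean: float = 0.0

    @property
    def feature_names(self) -> list[str]:
        names = ["age"]
        for f_ in CATEGORICAL_FIELDS:
            names.extend(f"{f_}={c}" for c in self.vocabularies[f_])
        return names

    @property
    def n_features(self) -> int:
        return 1 + sum(len(v) for v in self.vocabularies.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "vocabularies": self.vocabularies,
                    "age_min": self.age_min,
                    "age_max": self.age_max,
                    "age_mean": self.age_mean,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EncoderSpec":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class RiskFactorVector:
    values: np.ndarray
    names: list[str]


def fit_encoder(
    training_patients: Sequence[PatientRecord],
    training_sites: Sequence[SiteRecord] = (),
) -> EncoderSpec:
    """Fit vocabularies and age statistics on the training population.

    Vocabularies are the observed categories (sorted) plus "unknown"; age
    min/max/mean are computed over non-missing training ages.
    """
    ages = [p.age for p in training_patients if p.age is not None]
    if not ages:
        raise ValueError("cannot fit encoder: all training ages are missing")
    spec = EncoderSpec(
        age_min=float(min(ages)), age_max=float(max(ages)), age_mean=float(np.mean(ages))
    )
    if spec.age_min >= spec.age_max:
        # single observed age: widen by one year so scaling stays defined
        spec.age_max = spec.age_min + 1.0
    for f_ in RISK_FIELDS:
        observed = sorted({getattr(p, f_) for p in training_patients} - {None})
        spec.vocabularies[f_] = [*observed, UNKNOWN]
    observed_labels = sorted({s.anatomic_label for s in training_sites})
    spec.vocabularies["anatomic_label"] = [*observed_labels, UNKNOWN]
    return spec


def encode(
    patient: PatientRecord,
    anatomic_label: Optional[str],
    spec: EncoderSpec,
) -> RiskFactorVector:
    """Encode one patient + site label into the fixed-length numeric vector.

    Pure function of its inputs: each categorical block is a one-hot (the
    "unknown" slot fires for missing or unseen values) and age is
    (age − age_min)/(age_max − age_min) with mean imputation for missing age.
    """
    age = patient.age if patient.age is not None else spec.age_mean
    scaled_age = (age - spec.age_min) / (spec.age_max - spec.age_min)
    parts = [np.array([scaled_age])]
    for f_ in CATEGORICAL_FIELDS:
        vocab = spec.vocabularies[f_]
        value = anatomic_label if f_ == "anatomic_label" else getattr(patient, f_)
        block = np.zeros(len(vocab))
        idx = vocab.index(value) if value in vocab else vocab.index(UNKNOWN)
        block[idx] = 1.0
        parts.append(block)
    return RiskFactorVector(values=np.concatenate(parts), names=spec.feature_names)


def encode_matrix(
    patients_by_id: dict[str, PatientRecord],
    sites: Sequence[SiteRecord],
    spec: EncoderSpec,
) -> np.ndarray:
    """Stack encoded vectors for a list of sites (one row per site)."""
    return np.stack(
        [encode(patients_by_id[s.patient_id], s.anatomic_label, spec).values for s in sites]
    )
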