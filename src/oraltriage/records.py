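"""Core record types shared across the pipeline.

The unit of classification is an anatomic *site* of the oral cavity.  Each
site belongs to one patient, carries a three-way expert referral label, and
references one or more white-light / autofluorescence image captures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

COHORTS = ("high_prevalence", "healthy", "low_prevalence")

REFERRAL_LABELS = ("do_not_refer", "refer_other", "refer_suspicion")

ANATOMIC_LABELS = (
    "floor_of_mouth",
    "right_lateral_tongue",
    "left_lateral_tongue",
    "right_buccal_mucosa",
    "left_buccal_mucosa",
    "other",
)

#: risk-factor fields carried by PatientRecord, in canonical order
RISK_FIELDS = (
    "gender",
    "ethnicity",
    "race",
    "cigarette",
    "smoking_tobacco",
    "smokeless_tobacco",
    "alcohol",
)


@dataclass
class PatientRecord:
    """Demographics and habits for one enrolled patient.

    Any field except ``patient_id`` and ``cohort`` may be ``None`` (missing);
    downstream encoding maps missing categoricals to an "unknown" category
    and imputes missing age with the training-set mean.
    """

    patient_id: str
    cohort: str
    age: Optional[float] = None
    gender: Optional[str] = None
    ethnicity: Optional[str] = None
    race: Optional[str] = None
    cigarette: Optional[str] = None
    smoking_tobacco: Optional[str] = None
    smokeless_tobacco: Optional[str] = None
    alcohol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")


@dataclass
class SiteRecord:
    """One imaged anatomic site with its expert referral ground truth."""

    site_id: str
    patient_id: str
    cohort: str
    anatomic_label: str
    referral_label: str
    contralateral_normal: bool = False
    image_pair_ids: list[str] = field(default_factory=list)
    #: generator-side flag: captures of this site are rendered without an AF
    #: frame, so the pairing quality filter will drop the site
    qc_fail: bool = False

    def __post_init__(self) -> None:
        if self.referral_label not in REFERRAL_LABELS:
            raise ValueError(f"unknown referral label {self.referral_label!r}")
        if self.contralateral_normal and self.referral_label != "do_not_refer":
            raise ValueError("contralateral-normal sites must be do_not_refer")

    @property
    def is_referral(self) -> bool:
        """Binarized truth: both refer categories pool to positive."""
        return self.referral_label != "do_not_refer"


@dataclass
class ImagePair:
    """One capture of a site: WL image, AF image, mucosa mask.

    ``lesion_mask`` is generator-internal ground truth for where the lesion
    phenotype was painted; it is never shown to the model.  ``af`` may be
    ``None`` for captures that fail quality control by missing one modality.
    """

    capture_id: str
    wl: Optional[np.ndarray]  # H x W x 3 uint8
    af: Optional[np.ndarray]  # H x W x 3 uint8
    mask: np.ndarray          # H x W bool
    lesion_mask: np.ndarray   # H x W bool, subset of mask

    @property
    def complete(self) -> bool:
        return self.wl is not None and self.af is not None

    def validate(self) -> None:
        shapes = {self.mask.shape, self.lesion_mask.shape}
        for img in (self.wl, self.af):
            if img is not None:
                shapes.add(img.shape[:2])
        if len(shapes) != 1:
            raise ValueError(f"capture {self.capture_id}: raster dims disagree")
        if np.any(self.lesion_mask & ~self.mask):
            raise ValueError(f"capture {self.capture_id}: lesion mask escapes mucosa mask")


def binarize_referral(label: str) -> int:
    """Pipeline-wide truth binarization: refer (either reason) = 1."""
    if label not in REFERRAL_LABELS:
        raise ValueError(f"unknown referral label {label!r}")
    return int(label != "do_not_refer")
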