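"""Quality control and the mask → crop → resize → standardize image path.

Raw captures are masked to the annotated oral mucosa, cropped to the tight
bounding box of the annotation, and resized (bilinear, aspect ratio not
preserved) to a square analysis resolution — 224×224 by default.  Per-channel
standardization statistics are fitted once per training run, on the training
split only, separately for the WL and AF modalities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.transform import resize, rotate

from .records import ImagePair, SiteRecord

SD_FLOOR = 1e-6


@dataclass
class QCResult:
    kept: list[SiteRecord]
    removed: list[SiteRecord]
    reasons: dict[str, str]  # site_id -> reason


def qc_filter(
    sites: Sequence[SiteRecord],
    image_pairs: Mapping[str, ImagePair],
    min_mean_intensity: float | None = None,
) -> QCResult:
    """Remove sites without a complete, usable WL+AF capture.

    A site is kept iff at least one of its captures has both a WL and an AF
    frame (and, optionally, a WL mean intensity inside the mask above
    ``min_mean_intensity`` — a crude stand-in for an illumination check).
    Idempotent: filtering the kept list again removes nothing.
    """
    kept, removed, reasons = [], [], {}
    for site in sites:
        ok = False
        reason = "no_captures"
        for capture_id in site.image_pair_ids:
            pair = image_pairs.get(capture_id)
            if pair is None:
                reason = "missing_capture_data"
                continue
            if not pair.complete:
                reason = "missing_wl_af_pair"
                continue
            if min_mean_intensity is not None:
                inside = pair.wl[pair.mask]
                if inside.size == 0 or inside.mean() < min_mean_intensity:
                    reason = "underilluminated"
                    continue
            ok = True
            break
        if ok:
            kept.append(site)
        else:
            removed.append(site)
            reasons[site.site_id] = reason
    return QCResult(kept=kept, removed=removed, reasons=reasons)


@dataclass
class ProcessedImage:
    """A masked, cropped, resized image ready for the model."""

    tensor: np.ndarray  # out_size x out_size x 3 float32
    modality: str       # "WL" | "AF"
    capture_id: str = ""


def mask_crop_resize(
    image: np.ndarray,
    mask: np.ndarray,
    out_size: int = 224,
    modality: str = "WL",
    capture_id: str = "",
) -> ProcessedImage:
    """Zero pixels outside the mask, crop to its bounding box, resize.

    The bounding box is the tight axis-aligned box of the mask (half-open
    pixel intervals, origin top-left, row-major); the crop is resized with
    bilinear interpolation to ``out_size`` square without preserving aspect
    ratio.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions disagree")
    if not mask.any():
        raise ValueError("empty mask: site should have been removed by QC")
    masked = image.astype(np.float64) * mask[..., None]
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    crop = masked[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    out = resize(
        crop,
        (out_size, out_size),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return ProcessedImage(
        tensor=out.astype(np.float32), modality=modality, capture_id=capture_id
    )


def mask_bounding_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(row_start, row_stop, col_start, col_stop) half-open crop intervals."""
    if not mask.any():
        raise ValueError("empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1] + 1), int(cols[0]), int(cols[-1] + 1)


@dataclass
class Standardizer:
    """Per-modality, per-channel pixel standardization statistics.

    Fitted once per training run on the training split's processed images;
    population standard deviation, floored at ``SD_FLOOR`` to guard
    degenerate (constant) channels.
    """

    mean: dict[str, np.ndarray] = field(default_factory=dict)  # modality -> (3,)
    sd: dict[str, np.ndarray] = field(default_factory=dict)
    fitted_on: str = ""

    def apply(self, image: ProcessedImage) -> ProcessedImage:
        if image.modality not in self.mean:
            raise KeyError(f"standardizer not fitted for modality {image.modality!r}")
        m = self.mean[image.modality]
        s = self.sd[image.modality]
        return ProcessedImage(
            tensor=((image.tensor - m) / s).astype(np.float32),
            modality=image.modality,
            capture_id=image.capture_id,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fitted_on": self.fitted_on,
            "mean": {k: v.tolist() for k, v in self.mean.items()},
            "sd": {k: v.tolist() for k, v in self.sd.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Standardizer":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean={k: np.asarray(v) for k, v in payload["mean"].items()},
            sd={k: np.asarray(v) for k, v in payload["sd"].items()},
            fitted_on=payload["fitted_on"],
        )


def fit_standardizer(
    training_images: Mapping[str, Iterable[ProcessedImage]] | Iterable[ProcessedImage],
    fitted_on: str = "",
) -> Standardizer:
    """Fit per-modality per-channel mean/sd over all training pixels.

    Accepts either a mapping modality -> images or a flat iterable of
    ProcessedImage (grouped by their ``modality`` attribute).
    """
    groups: dict[str, list[np.ndarray]] = {}
    if isinstance(training_images, Mapping):
        for modality, imgs in training_images.items():
            groups[modality] = [im.tensor for im in imgs]
    else:
        for im in training_images:
            groups.setdefault(im.modality, []).append(im.tensor)
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty training set for standardizer fit")
    std = Standardizer(fitted_on=fitted_on)
    for modality, tensors in groups.items():
        pixels = np.concatenate([t.reshape(-1, t.shape[-1]) for t in tensors], axis=0)
        std.mean[modality] = pixels.mean(axis=0)
        std.sd[modality] = np.maximum(pixels.std(axis=0), SD_FLOOR)
    return std


@dataclass
class AugmentConfig:
    enabled: bool = False
    flip_prob: float = 0.5
    max_rotation_deg: float = 10.0


def augment(
    image: ProcessedImage,
    rng_state: np.random.Generator | int | None,
    config: AugmentConfig = AugmentConfig(),
) -> ProcessedImage:
    """Random horizontal flip and small rotation; training mode only.

    Disabled (identity) unless ``config.enabled``; never applied to
    validation or test data by the pipeline.
    """
    if not config.enabled:
        return image
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    t = image.tensor
    if rng.random() < config.flip_prob:
        t = t[:, ::-1, :].copy()
    angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    if abs(angle) > 1e-9:
        t = rotate(t, angle, order=1, mode="edge", preserve_range=True).astype(np.float32)
    return ProcessedImage(tensor=np.ascontiguousarray(t, dtype=np.float32),
                          modality=image.modality, capture_id=image.capture_id)
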