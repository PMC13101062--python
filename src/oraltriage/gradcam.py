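"""GradCAM++ attribution for the fused multi-input classifier.

Attribution is computed per image branch: the full fused forward pass runs
(both images and the risk vector), the gradient of the referral logit is
taken back through the head into the chosen branch, and GradCAM++ weights
are formed at the feature maps entering that branch's global pool.  The
other branch and the risk vector are held as-is, so the map reflects what
the selected modality contributed to the fused decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .model import MultiInputNet, TrainedModel
from .preprocessing import ProcessedImage

EPS = 1e-12


@dataclass
class AttentionMap:
    map: np.ndarray          # out_size x out_size float in [0, 1]
    branch: str              # "wl" | "af"
    target_class: int = 1
    capture_id: str = ""


def gradcam_pp(
    model: TrainedModel | MultiInputNet,
    wl: np.ndarray,
    af: np.ndarray,
    risk: np.ndarray,
    branch: str = "wl",
    target_class: int = 1,
    out_size: int | None = None,
    capture_id: str = "",
) -> AttentionMap:
    """GradCAM++ map for one preprocessed sample.

    The map is ReLU-rectified, bilinearly upsampled to the input resolution
    (or ``out_size``), and min–max normalized to [0, 1].  An all-zero map is
    returned only when every gradient-weighted activation is non-positive
    (e.g. a dead branch).
    """
    if branch not in ("wl", "af"):
        raise ValueError("branch must be 'wl' or 'af'")
    net = model.build_net() if isinstance(model, TrainedModel) else model
    if wl.ndim == 3:
        wl, af, risk = wl[None], af[None], risk[None]
    if wl.shape[0] != 1:
        raise ValueError("gradcam_pp attributes one sample at a time")

    logits = net.forward(wl, af, risk, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    net.backward(dlogits)
    try:
        acts, grads = net.conv_activation_and_grad(branch)
    except StopIteration as exc:  # pragma: no cover - misconfigured backbone
        raise ValueError(
            f"branch {branch!r} has no global-pooled convolutional feature maps"
        ) from exc
    a = acts[0]   # C x H x W
    g = grads[0]

    # alpha_kij = g^2 / (2 g^2 + sum_ab A_kab * g^3)
    g2, g3 = g**2, g**3
    denom = 2.0 * g2 + a.sum(axis=(1, 2), keepdims=True) * g3
    alpha = np.where(np.abs(denom) > EPS, g2 / np.where(np.abs(denom) > EPS, denom, 1.0), 0.0)
    weights = (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2))  # per channel
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)

    size = out_size or wl.shape[-1]
    cam = resize(cam, (size, size), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    lo, hi = cam.min(), cam.max()
    if hi - lo > EPS:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros_like(cam)
    return AttentionMap(map=cam, branch=branch, target_class=target_class,
                        capture_id=capture_id)


def overlay(
    attention: AttentionMap,
    wl: ProcessedImage | np.ndarray,
    alpha: float = 0.4,
    cmap: str = "jet",
) -> np.ndarray:
    """Alpha-blend the colormapped attention map onto the WL image.

    The WL raster may be uint8, float in [0, 255], or a standardized tensor
    (rescaled per-image for display).  Returns an 8-bit RGB array of the
    same spatial dims.
    """
    img = wl.tensor if isinstance(wl, ProcessedImage) else np.asarray(wl)
    if img.shape[:2] != attention.map.shape:
        raise ValueError("attention map and image dimensions disagree")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    img = img.astype(np.float64)
    if img.min() < 0 or img.max() <= 1.0:  # standardized or unit-scaled input
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo + EPS) * 255.0
    heat = colormaps[cmap](attention.map)[..., :3] * 255.0
    blended = (1.0 - alpha) * img + alpha * heat
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
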