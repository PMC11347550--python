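"""Grad-CAM heatmaps for the risk score.

For each input slice, the gradient of the scalar risk score with respect to the
last convolutional feature maps is global-average-pooled into channel weights;
the weighted sum of the feature maps is rectified (negatives clipped to zero),
min-max normalized to [0, 1], and bilinearly upsampled to the input resolution.
Maps are computed per slice before the slice-mean, so each of the 12 (or 6)
input images gets its own heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from ctprog.preprocess import SlicePack
from ctprog.survnet.model import NetConfig, RiskModel, _pack_keys, pack_to_array


@dataclass
class Heatmap:
    """A [0, 1]-normalized relevance map for one input slice.

    ``source`` identifies the slice as (organ, timepoint, slice position in the
    pack). A map with no positive evidence is all zeros.
    """

    values: np.ndarray
    source: tuple[str, str, int]

    def __post_init__(self):
        v = self.values
        if v.min() < 0 or v.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")


def grad_cam(pack: SlicePack, model: RiskModel, *, upsample_to: int = 224) -> list[Heatmap]:
    """Compute one Grad-CAM heatmap per input slice of a pack.

    The target is the patient's risk score itself (the model's only output).
    Returns heatmaps in pack order (organ-major, timepoint-minor, 3 slices each).
    """
    cfg = model.config
    X = pack_to_array(pack, cfg)[None]
    model.forward_array(X)
    fmaps = model.backbone.last_feature_maps          # (n_slices, C, h, w)
    dfmaps = model.backward_array(np.ones(1), to_feature_maps=True)

    weights = dfmaps.mean(axis=(2, 3))                # GAP of gradients -> (n, C)
    cams = np.einsum("nc,nchw->nhw", weights, fmaps)
    cams = np.maximum(cams, 0.0)                      # rectify

    heatmaps = []
    keys = _pack_keys(cfg.variant)
    for i in range(cams.shape[0]):
        cam = cams[i]
        up = _sk_resize(cam.astype(float), (upsample_to, upsample_to), order=1,
                        anti_aliasing=False, preserve_range=True)
        up = np.maximum(up, 0.0)
        rng_ = up.max() - up.min()
        # normalize after upsampling so the emitted map spans exactly [0, 1]
        up = (up - up.min()) / rng_ if rng_ > 0 else np.zeros_like(up)
        organ, tp = keys[i // 3]
        heatmaps.append(Heatmap(values=up, source=(organ, tp, i % 3)))
    return heatmaps


def tumor_localization_score(heatmap: Heatmap, tumor_slice_mask: np.ndarray) -> float:
    """Mean heatmap value inside the tumor mask minus the mean outside.

    The mask is resized (nearest) to the heatmap resolution. Positive values mean
    the map concentrates on the tumor. NaN when the slice has no tumor or covers
    the entire image.
    """
    hm = heatmap.values
    mask = _sk_resize(tumor_slice_mask.astype(float), hm.shape, order=0,
                      preserve_range=True) > 0.5
    if not mask.any() or mask.all():
        return float("nan")
    return float(hm[mask].mean() - hm[~mask].mean())
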