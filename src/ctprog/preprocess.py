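"""Volume-to-model-input preprocessing: the 12-image slice pack.

Per patient and per (organ, timepoint) the pipeline is: resample to 5-mm slice
thickness, map HU through the organ's display window (abdomen WW 400 / WL 0, chest
WW 1200 / WL -600), pick the three representative axial slices (largest tumor area
first, then largest organ area), resize each to 224 x 224 with bilinear
interpolation, and standardize each image to zero mean / unit variance. A missing
follow-up chest scan is imputed by carrying the processed baseline chest images
forward (LOCF). Horizontal-flip augmentation is applied only at training time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from skimage.transform import resize as _sk_resize

from ctprog.phantom import ORGANS, TIMEPOINTS, PatientVolumeSet

IMAGE_SIZE = 224
SLICES_PER_SCAN = 3
TARGET_SLICE_MM = 5.0


@dataclass(frozen=True)
class WindowSpec:
    """CT display window: width (WW) and level (WL) in HU."""

    width: float
    level: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")


ABDOMEN_WINDOW = WindowSpec(width=400.0, level=0.0)
CHEST_WINDOW = WindowSpec(width=1200.0, level=-600.0)
DEFAULT_WINDOWS: Mapping[str, WindowSpec] = {"liver": ABDOMEN_WINDOW, "lung": CHEST_WINDOW}


@dataclass
class SlicePack:
    """The model-ready image pack for one patient.

    ``images`` maps (organ, timepoint) to an array of shape (3, 224, 224) of
    standardized slices; ``selected_indices`` and ``selection_basis`` record which
    axial slices were chosen and why ("tumor_area", "organ_area", or "pad" when an
    organ spans fewer slices than requested). ``locf_applied`` is True when the
    follow-up chest entry is a carried-forward copy of the baseline.
    """

    patient_id: str
    images: dict[tuple[str, str], np.ndarray]
    selected_indices: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    selection_basis: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    locf_applied: bool = False

    @property
    def n_images(self) -> int:
        return sum(arr.shape[0] for arr in self.images.values())


def resample_axial(volume: np.ndarray, spacing_mm: tuple[float, float, float],
                   target_mm: float = TARGET_SLICE_MM, *, order: int = 1) -> np.ndarray:
    """Resample a (z, y, x) volume to ``target_mm`` slice thickness along z only.

    Linear interpolation between neighbouring slices (``order=1``); ``order=0``
    gives nearest-neighbour, used for binary masks. In-plane resolution is
    untouched. The output z-extent matches the input within one slice.
    """
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("voxel spacings must be positive")
    zs = float(spacing_mm[0])
    vol = np.asarray(volume)
    if np.isclose(zs, target_mm):
        return vol
    nz = vol.shape[0]
    extent = (nz - 1) * zs
    new_nz = int(np.floor(extent / target_mm + 1e-9)) + 1
    pos = np.arange(new_nz) * target_mm / zs  # fractional source indices
    if order == 0:
        return vol[np.clip(np.round(pos).astype(int), 0, nz - 1)]
    lo = np.clip(np.floor(pos).astype(int), 0, nz - 1)
    hi = np.clip(lo + 1, 0, nz - 1)
    frac = (pos - lo).reshape(-1, 1, 1)
    return vol[lo] * (1.0 - frac) + vol[hi] * frac


def apply_window(hu: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Map HU to [0, 1] through a display window: clip((HU - (WL - WW/2)) / WW, 0, 1)."""
    if spec.width <= 0:
        raise ValueError("window width must be > 0")
    return np.clip((np.asarray(hu, dtype=float) - (spec.level - spec.width / 2.0))
                   / spec.width, 0.0, 1.0)


def select_slices(tumor_mask: np.ndarray, organ_mask: np.ndarray,
                  k: int = SLICES_PER_SCAN) -> tuple[list[int], list[str]]:
    """Choose the k representative axial slice indices.

    Slices containing tumor are ranked by in-plane tumor area (descending) and fill
    the list first; remaining positions are filled by not-yet-chosen slices ranked
    by organ area (descending). Ties break toward the smaller z index. If fewer
    than k slices contain any organ, the last selected index is repeated and
    flagged "pad".
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    organ_mask = np.asarray(organ_mask, dtype=bool)
    if tumor_mask.shape != organ_mask.shape:
        raise ValueError("mask shapes differ")
    if not organ_mask.any():
        raise ValueError("organ mask is empty")
    a_t = tumor_mask.reshape(tumor_mask.shape[0], -1).sum(axis=1)
    a_o = organ_mask.reshape(organ_mask.shape[0], -1).sum(axis=1)
    z = np.arange(len(a_t))

    tumor_order = [int(i) for i in np.lexsort((z, -a_t)) if a_t[i] > 0]
    indices = tumor_order[:k]
    basis = ["tumor_area"] * len(indices)
    if len(indices) < k:
        chosen = set(indices)
        organ_order = [int(i) for i in np.lexsort((z, -a_o)) if a_o[i] > 0 and i not in chosen]
        for i in organ_order[: k - len(indices)]:
            indices.append(i)
            basis.append("organ_area")
    while len(indices) < k:  # degenerate: organ spans < k slices
        indices.append(indices[-1])
        basis.append("pad")
    return indices, basis


def _standardize(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    if sd == 0:
        return np.zeros_like(img)
    return (img - img.mean()) / sd


def _process_scan(volume: np.ndarray, organ_mask: np.ndarray, tumor_mask: np.ndarray,
                  spacing: tuple[float, float, float], window: WindowSpec,
                  size: int) -> tuple[np.ndarray, list[int], list[str]]:
    vol5 = resample_axial(volume, spacing, order=1)
    org5 = resample_axial(organ_mask.astype(np.uint8), spacing, order=0) > 0
    tum5 = resample_axial(tumor_mask.astype(np.uint8), spacing, order=0) > 0
    windowed = apply_window(vol5, window)
    indices, basis = select_slices(tum5, org5)
    images = np.stack([
        _standardize(_sk_resize(windowed[i], (size, size), order=1,
                                anti_aliasing=False, preserve_range=True))
        for i in indices
    ]).astype(np.float32)
    return images, indices, basis


def assemble_pack(vols: PatientVolumeSet,
                  windows: Mapping[str, WindowSpec] = DEFAULT_WINDOWS,
                  size: int = IMAGE_SIZE) -> SlicePack:
    """Build the 12-image SlicePack for one patient.

    Baseline scans for both organs are required (inclusion criterion); an absent
    follow-up chest scan triggers LOCF from the processed chest baseline.
    """
    for organ in ORGANS:
        if (organ, "baseline") not in vols.volumes:
            raise ValueError(f"missing mandatory baseline volume for {organ}")
    images: dict[tuple[str, str], np.ndarray] = {}
    sel_idx: dict[tuple[str, str], list[int]] = {}
    sel_basis: dict[tuple[str, str], list[str]] = {}
    locf = False
    for organ in ORGANS:
        for tp in TIMEPOINTS:
            key = (organ, tp)
            if key not in vols.volumes:
                if organ == "lung" and tp == "followup":
                    base = ("lung", "baseline")
                    images[key] = images[base].copy()
                    sel_idx[key] = list(sel_idx[base])
                    sel_basis[key] = list(sel_basis[base])
                    locf = True
                    continue
                raise ValueError(f"missing volume for {key}")
            images[key], sel_idx[key], sel_basis[key] = _process_scan(
                vols.volumes[key], vols.organ_masks[key], vols.tumor_masks[key],
                vols.spacing_mm, windows[organ], size)
    return SlicePack(patient_id=vols.patient_id, images=images,
                     selected_indices=sel_idx, selection_basis=sel_basis,
                     locf_applied=locf)


def augment_flip(pack: SlicePack, p: float = 0.5,
                 seed: int | np.random.Generator | None = 0) -> SlicePack:
    """Independently mirror each image left-right with probability p (seeded)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    images = {}
    for key, arr in pack.images.items():
        out = arr.copy()
        for i in range(out.shape[0]):
            if rng.random() < p:
                out[i] = out[i, :, ::-1]
        images[key] = out
    return SlicePack(patient_id=pack.patient_id, images=images,
                     selected_indices={k: list(v) for k, v in pack.selected_indices.items()},
                     selection_basis={k: list(v) for k, v in pack.selection_basis.items()},
                     locf_applied=pack.locf_applied)
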