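"""Regional feature extraction from template-space PET volumes.

Turns a registered 4D dynamic early-phase volume, a 3D delay-phase volume and
an integer-labelled atlas into the classifier inputs: a regions x frames TAC
and a per-region mean SUVr, both normalized to the whole-cerebellum mean.
Inputs are assumed co-registered to a common template grid; spatial
normalization is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    REFERENCE_REGION,
    MinMaxParams,
    SUVrVector,
    TACMatrix,
)

__all__ = [
    "RegionMasks",
    "merge_atlas_regions",
    "regional_mean",
    "make_static_early",
    "reference_normalize",
    "extract_regional_tac",
    "extract_regional_suvr",
    "minmax_fit",
    "minmax_apply",
    "load_nifti",
    "read_mapping",
]

EARLY_STATIC_WINDOW = (120.0, 420.0)  # 2-7 min post-injection


@dataclass
class RegionMasks:
    """Boolean mask per merged region, all on one voxel grid."""

    masks: dict[str, np.ndarray]
    shape: tuple
    voxel_size: tuple | None = None

    def __post_init__(self):
        for name, m in self.masks.items():
            if m.shape != tuple(self.shape):
                raise ValueError(f"mask {name!r} not on the common grid")


def merge_atlas_regions(label_volume: np.ndarray, mapping) -> RegionMasks:
    """Merge atlas labels into named regions.

    `mapping` is {label: region} or an iterable of (label, region) pairs; a
    label mapped to two different regions is rejected. Label 0 is background;
    unmapped labels are ignored.
    """
    label_volume = np.asarray(label_volume)
    if not np.issubdtype(label_volume.dtype, np.integer):
        raise ValueError("atlas must be an integer label volume")
    if np.any(label_volume < 0):
        raise ValueError("atlas labels must be non-negative")
    if isinstance(mapping, dict):
        pairs = list(mapping.items())
    else:
        pairs = list(mapping)
    seen: dict[int, str] = {}
    for label, region in pairs:
        label = int(label)
        if label in seen and seen[label] != region:
            raise ValueError(f"label {label} mapped to both {seen[label]!r} and {region!r}")
        seen[label] = region
    masks: dict[str, np.ndarray] = {}
    for label, region in seen.items():
        if label == 0:
            continue
        m = label_volume == label
        masks[region] = masks.get(region, np.zeros(label_volume.shape, bool)) | m
    return RegionMasks(masks=masks, shape=label_volume.shape)


def regional_mean(volume: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of voxel values inside a non-empty mask."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    return float(volume[mask].mean())


def make_static_early(
    dynamic: np.ndarray, frame_schedule, window: tuple = EARLY_STATIC_WINDOW
) -> np.ndarray:
    """Duration-weighted average of frames whose midpoints lie in `window`.

    The default window is 2-7 minutes post-injection, the standard
    perfusion-surrogate window for early-phase florbetaben.
    """
    dynamic = np.asarray(dynamic, dtype=float)
    sched = np.asarray(frame_schedule, dtype=float)
    if dynamic.ndim != 4 or dynamic.shape[3] != sched.shape[0]:
        raise ValueError("dynamic volume frame count does not match the schedule")
    mid = sched[:, 0] + sched[:, 1] / 2.0
    sel = (mid >= window[0]) & (mid <= window[1])
    if not sel.any():
        raise ValueError("static window selects no frames")
    w = sched[sel, 1]
    return np.tensordot(dynamic[..., sel], w, axes=([3], [0])) / w.sum()


def reference_normalize(values, reference: float):
    """Divide regional values by the reference (cerebellar) mean."""
    if reference <= 0:
        raise ValueError("reference mean must be positive")
    return np.asarray(values, dtype=float) / reference


def extract_regional_suvr(volume: np.ndarray, masks: RegionMasks,
                          region_order: tuple[str, ...]) -> SUVrVector:
    """Per-region mean SUVr of a 3D volume, cerebellum-normalized."""
    if REFERENCE_REGION not in masks.masks:
        raise ValueError("masks must include the cerebellum reference")
    ref = regional_mean(volume, masks.masks[REFERENCE_REGION])
    if ref <= 0:
        raise ValueError("non-positive cerebellar mean")
    vals = np.array([regional_mean(volume, masks.masks[r]) for r in region_order])
    return SUVrVector(values=reference_normalize(vals, ref), regions=tuple(region_order))


def extract_regional_tac(
    dynamic: np.ndarray,
    masks: RegionMasks,
    region_order: tuple[str, ...],
    frame_schedule,
) -> TACMatrix:
    """Regional TAC from a 4D dynamic volume, cerebellum-normalized per frame.

    Each frame's regional means are divided by that frame's cerebellar mean,
    so every column is a proper SUVr and the result is invariant to any
    global (per-frame or whole-scan) intensity rescaling.
    """
    dynamic = np.asarray(dynamic, dtype=float)
    if REFERENCE_REGION not in masks.masks:
        raise ValueError("masks must include the cerebellum reference")
    missing = [r for r in region_order if r not in masks.masks]
    if missing:
        raise ValueError(f"masks missing regions: {missing}")
    n_frames = dynamic.shape[3]
    sched = np.asarray(frame_schedule, dtype=float)
    if sched.shape[0] != n_frames:
        raise ValueError("frame schedule length does not match dynamic volume")
    out = np.empty((len(region_order), n_frames))
    for t in range(n_frames):
        frame = dynamic[..., t]
        ref = regional_mean(frame, masks.masks[REFERENCE_REGION])
        if ref <= 0:
            raise ValueError(f"non-positive cerebellar mean in frame {t}")
        for gi, region in enumerate(region_order):
            out[gi, t] = regional_mean(frame, masks.masks[region]) / ref
    mid = sched[:, 0] + sched[:, 1] / 2.0
    return TACMatrix(values=out, regions=tuple(region_order), frame_mid=mid)


# ---------------------------------------------------------------------------
# Min-max scaling (fit on the training split only)
# ---------------------------------------------------------------------------

def minmax_fit(X: np.ndarray) -> MinMaxParams:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("expected a non-empty (n_samples, n_features) matrix")
    return MinMaxParams(minimum=X.min(axis=0), maximum=X.max(axis=0))


def minmax_apply(params: MinMaxParams, X: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min) per feature; affine, so out-of-range training
    values map outside [0, 1] (no clipping). Constant features map to 0."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != params.minimum.shape[0]:
        raise ValueError("feature count does not match fitted parameters")
    span = params.maximum - params.minimum
    out = np.zeros_like(X)
    nz = span > 0
    out[..., nz] = (X[..., nz] - params.minimum[nz]) / span[nz]
    return out


# ---------------------------------------------------------------------------
# File helpers
# ---------------------------------------------------------------------------

def load_nifti(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())


def load_nifti_labels(path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    labels = np.rint(data).astype(np.int32)
    if not np.allclose(data, labels, atol=1e-6):
        raise ValueError("atlas volume does not contain integer labels")
    return labels


def read_mapping(path) -> dict[int, str]:
    """Read a label->region mapping from CSV (label,region) or YAML."""
    import os

    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return {int(k): str(v) for k, v in raw.items()}
    import pandas as pd

    df = pd.read_csv(path)
    return {int(row["label"]): str(row["region"]) for _, row in df.iterrows()}


def read_frame_schedule(path) -> np.ndarray:
    """Frame schedule CSV with columns start_s, duration_s."""
    import pandas as pd

    df = pd.read_csv(path)
    return df[["start_s", "duration_s"]].to_numpy(dtype=float)
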