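"""Core data containers shared across the pipeline.

Region order is fixed package-wide: six cortical target regions followed by
the cerebellum reference. TACs are stored regions x frames in SUVr units
(each frame already divided by that frame's cerebellar mean), so a
cerebellum row, when present, is identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TARGET_REGIONS: tuple[str, ...] = (
    "frontal",
    "temporal",
    "parietal",
    "occipital",
    "anterior_cingulate",
    "posterior_cingulate",
)
REFERENCE_REGION = "cerebellum"
ALL_REGIONS: tuple[str, ...] = TARGET_REGIONS + (REFERENCE_REGION,)


@dataclass
class TACMatrix:
    """Regional time-activity curves: SUVr per region per frame."""

    values: np.ndarray  # (n_regions, n_frames)
    regions: tuple[str, ...]
    frame_mid: np.ndarray  # frame midpoints, seconds

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.frame_mid = np.asarray(self.frame_mid, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.regions):
            raise ValueError("TAC shape does not match region list")
        if self.values.shape[1] != len(self.frame_mid):
            raise ValueError("TAC frame count does not match frame midpoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC contains non-finite values")

    def target_values(self) -> np.ndarray:
        """Rows for the six target regions, in canonical order."""
        idx = [self.regions.index(r) for r in TARGET_REGIONS]
        return self.values[idx]


@dataclass
class SUVrVector:
    """Per-region delay-phase mean SUVr."""

    values: np.ndarray  # (n_regions,)
    regions: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] != len(self.regions):
            raise ValueError("SUVr length does not match region list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUVr contains non-finite values")

    def target_values(self) -> np.ndarray:
        idx = [self.regions.index(r) for r in TARGET_REGIONS]
        return self.values[idx]


@dataclass
class SubjectRecord:
    """One subject: diagnosis, amyloid reading, cognition, extracted features."""

    subject_id: str
    diagnosis: str  # "CN" | "AD"
    ab_reading: str  # "neg" | "pos"
    mmse: float
    tac: TACMatrix
    suvr: SUVrVector

    def __post_init__(self):
        if self.diagnosis not in ("CN", "AD"):
            raise ValueError(f"diagnosis must be CN or AD, got {self.diagnosis!r}")
        if self.ab_reading not in ("neg", "pos"):
            raise ValueError(f"ab_reading must be neg or pos, got {self.ab_reading!r}")
        if not 0.0 <= self.mmse <= 30.0:
            raise ValueError("MMSE outside [0, 30]")
        if self.tac.regions != self.suvr.regions:
            raise ValueError("TAC and SUVr region order differ")


@dataclass
class MinMaxParams:
    """Per-feature minimum/maximum learned from a training split."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.maximum < self.minimum):
            raise ValueError("max < min for some feature")


@dataclass
class FeatureSet:
    """Model-ready arrays for a set of subjects.

    ``tac`` holds the six target-region rows only (cerebellum is identically 1
    and carries no information); ``y`` is 1 for AD, 0 for CN.
    """

    ids: list[str]
    tac: np.ndarray  # (n, 6, n_frames)
    suvr: np.ndarray  # (n, 6)
    y: np.ndarray  # (n,) int
    ab: np.ndarray  # (n,) "neg"/"pos"
    mmse: np.ndarray  # (n,)
    frame_mid: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self):
        return len(self.ids)

    def subset(self, mask_or_idx) -> "FeatureSet":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureSet(
            ids=[self.ids[i] for i in idx],
            tac=self.tac[idx],
            suvr=self.suvr[idx],
            y=self.y[idx],
            ab=self.ab[idx],
            mmse=self.mmse[idx],
            frame_mid=self.frame_mid,
        )


def build_features(records: list[SubjectRecord]) -> FeatureSet:
    """Assemble model-ready arrays from subject records (canonical region order)."""
    if not records:
        raise ValueError("empty cohort")
    return FeatureSet(
        ids=[r.subject_id for r in records],
        tac=np.stack([r.tac.target_values() for r in records]),
        suvr=np.stack([r.suvr.target_values() for r in records]),
        y=np.array([1 if r.diagnosis == "AD" else 0 for r in records]),
        ab=np.array([r.ab_reading for r in records]),
        mmse=np.array([r.mmse for r in records]),
        frame_mid=records[0].tac.frame_mid.copy(),
    )
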