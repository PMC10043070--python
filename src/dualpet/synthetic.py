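"""Synthetic dual-phase amyloid-PET cohort generator.

Emulates the statistical structure of a dual-phase florbetaben study cohort:

* **Early phase (perfusion).** Each region's tracer delivery follows a
  gamma-variate bolus curve; the regional TAC is the per-frame ratio to the
  cerebellar curve (SUVr). AD subjects show cortical hypoperfusion — target
  region amplitudes scaled by ``1 - perfusion_effect``. Perfusion depends on
  the clinical diagnosis, not on the amyloid reading.
* **Delay phase (amyloid load).** Target-region SUVr is bimodal by amyloid
  reading: a region baseline plus ``amyloid_effect`` for read-positive
  subjects. SUVr depends on the reading, not on the diagnosis — this is what
  creates the discordant subgroups (amyloid-positive CN, amyloid-negative AD)
  that a delay-phase-only classifier cannot resolve.
* **Cognition.** MMSE drawn from diagnosis-specific truncated normals,
  independent of the imaging features given diagnosis.

Noise has two components tied to a single scale: i.i.d. Gaussian noise per
TAC cell / SUVr entry with sd ``noise_sd``, and a per-subject global
perfusion-amplitude factor with sd ``subject_noise_scale * noise_sd`` shared
across target regions and frames (biological between-subject variability that
frame-averaging cannot remove). ``noise_sd = 0`` therefore reproduces the
group-mean curves exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ALL_REGIONS,
    REFERENCE_REGION,
    TARGET_REGIONS,
    SubjectRecord,
    SUVrVector,
    TACMatrix,
)

__all__ = [
    "CohortSpec",
    "PerfusionParams",
    "perfusion_curve",
    "sample_amyloid_suvr",
    "generate_cohort",
    "frame_midpoints",
    "write_cohort_csv",
    "read_cohort_csv",
    "export_phantom",
]

#: 27 contiguous frames spanning 0-1200 s: 15 x 20 s, then 12 x 75 s.
DEFAULT_FRAME_SCHEDULE: tuple[tuple[float, float], ...] = tuple(
    [(20.0 * i, 20.0) for i in range(15)] + [(300.0 + 75.0 * i, 75.0) for i in range(12)]
)

#: Gamma-variate kinetics per region (alpha, beta): mild regional variation in
#: delivery shape so TAC ratio curves are genuinely time-varying.
_REGION_KINETICS: dict[str, tuple[float, float]] = {
    "frontal": (2.2, 95.0),
    "temporal": (2.0, 105.0),
    "parietal": (2.1, 100.0),
    "occipital": (1.9, 110.0),
    "anterior_cingulate": (2.4, 90.0),
    "posterior_cingulate": (2.3, 92.0),
    REFERENCE_REGION: (2.0, 100.0),
}

#: Relative perfusion amplitude per region (cortex slightly above cerebellum).
_REGION_AMPLITUDE: dict[str, float] = {
    "frontal": 1.25,
    "temporal": 1.15,
    "parietal": 1.20,
    "occipital": 1.30,
    "anterior_cingulate": 1.35,
    "posterior_cingulate": 1.40,
    REFERENCE_REGION: 1.0,
}

#: Delay-phase SUVr baseline for amyloid-negative subjects, per target region.
_SUVR_BASELINE: dict[str, float] = {
    "frontal": 1.10,
    "temporal": 1.08,
    "parietal": 1.12,
    "occipital": 1.05,
    "anterior_cingulate": 1.15,
    "posterior_cingulate": 1.20,
}


@dataclass
class PerfusionParams:
    """Gamma-variate bolus curve parameters: K * t^alpha * exp(-t/beta)."""

    K: float = 1.0
    alpha: float = 2.0
    beta: float = 100.0
    region_scale: float = 1.0

    def __post_init__(self):
        if self.K <= 0 or self.alpha <= 0 or self.beta <= 0 or self.region_scale <= 0:
            raise ValueError("perfusion parameters must be positive")


@dataclass
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults follow the reference cohort composition: 74 CN / 190 AD with 15
    amyloid-positive CN and 32 amyloid-negative AD; MMSE 27.5 +/- 1.7 (CN) and
    19.5 +/- 4.3 (AD) truncated to [0, 30]; 27 frames over 20 minutes.
    """

    n_cn: int = 74
    n_ad: int = 190
    n_abpos_cn: int = 15
    n_abneg_ad: int = 32
    frame_schedule: tuple = DEFAULT_FRAME_SCHEDULE
    regions: tuple[str, ...] = ALL_REGIONS
    perfusion_effect: float = 0.25
    amyloid_effect: float = 0.35
    noise_sd: float = 0.08
    subject_noise_scale: float = 2.0
    mmse_cn: tuple[float, float] = (27.5, 1.7)
    mmse_ad: tuple[float, float] = (19.5, 4.3)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cn, self.n_ad) < 0 or self.n_abpos_cn < 0 or self.n_abneg_ad < 0:
            raise ValueError("counts must be non-negative")
        if self.n_abpos_cn > self.n_cn:
            raise ValueError("n_abpos_cn exceeds n_cn")
        if self.n_abneg_ad > self.n_ad:
            raise ValueError("n_abneg_ad exceeds n_ad")
        if not 0.0 <= self.perfusion_effect < 1.0:
            raise ValueError("perfusion_effect must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if REFERENCE_REGION not in self.regions:
            raise ValueError("region list must include the cerebellum reference")
        sched = np.asarray(self.frame_schedule, dtype=float)
        if sched.ndim != 2 or sched.shape[1] != 2:
            raise ValueError("frame_schedule must be (start, duration) pairs")
        if np.any(sched[:, 1] <= 0):
            raise ValueError("frame durations must be positive")
        ends = sched[:, 0] + sched[:, 1]
        if not np.allclose(ends[:-1], sched[1:, 0]):
            raise ValueError("frames must be contiguous")

    @property
    def target_regions(self) -> tuple[str, ...]:
        return tuple(r for r in self.regions if r != REFERENCE_REGION)


def frame_midpoints(frame_schedule) -> np.ndarray:
    sched = np.asarray(frame_schedule, dtype=float)
    return sched[:, 0] + sched[:, 1] / 2.0


def perfusion_curve(params: PerfusionParams, times) -> np.ndarray:
    """Gamma-variate activity curve K * t^alpha * exp(-t/beta) * region_scale.

    Smooth and single-peaked with maximum at t = alpha * beta.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return params.K * t**params.alpha * np.exp(-t / params.beta) * params.region_scale


def _mean_tac(spec: CohortSpec, diagnosis: str) -> np.ndarray:
    """Noise-free group-mean TAC (all regions x frames), cerebellum row = 1."""
    t = frame_midpoints(spec.frame_schedule)
    alpha_c, beta_c = _REGION_KINETICS[REFERENCE_REGION]
    cereb = perfusion_curve(PerfusionParams(alpha=alpha_c, beta=beta_c), t)
    rows = []
    for region in spec.regions:
        if region == REFERENCE_REGION:
            rows.append(np.ones_like(t))
            continue
        alpha, beta = _REGION_KINETICS[region]
        scale = _REGION_AMPLITUDE[region]
        if diagnosis == "AD":
            scale *= 1.0 - spec.perfusion_effect
        curve = perfusion_curve(PerfusionParams(alpha=alpha, beta=beta, region_scale=scale), t)
        rows.append(curve / cereb)
    return np.vstack(rows)


def sample_amyloid_suvr(
    diagnosis: str, ab_reading: str, spec: CohortSpec, rng: np.random.Generator
) -> SUVrVector:
    """Draw one delay-phase SUVr vector.

    Target regions: baseline + amyloid_effect for read-positive subjects +
    Gaussian noise. The cerebellum entry is exactly 1 by construction. The
    diagnosis argument is accepted for interface symmetry; delay-phase uptake
    is driven by the amyloid reading alone.
    """
    values = np.empty(len(spec.regions))
    shift = spec.amyloid_effect if ab_reading == "pos" else 0.0
    for i, region in enumerate(spec.regions):
        if region == REFERENCE_REGION:
            values[i] = 1.0
        else:
            values[i] = _SUVR_BASELINE[region] + shift + rng.normal(0.0, spec.noise_sd)
    return SUVrVector(values=values, regions=spec.regions)


def _sample_tac(
    diagnosis: str, spec: CohortSpec, rng: np.random.Generator, mean_cache: dict
) -> TACMatrix:
    if diagnosis not in mean_cache:
        mean_cache[diagnosis] = _mean_tac(spec, diagnosis)
    mean = mean_cache[diagnosis]
    t = frame_midpoints(spec.frame_schedule)
    # shared amplitude factor: between-subject perfusion variability
    factor = 1.0 + rng.normal(0.0, spec.subject_noise_scale * spec.noise_sd)
    factor = max(factor, 0.05)
    values = mean * factor + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    cereb_idx = spec.regions.index(REFERENCE_REGION)
    values[cereb_idx, :] = 1.0
    return TACMatrix(values=values, regions=spec.regions, frame_mid=t)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))  # pragma: no cover


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort with exact diagnosis x reading stratum counts."""
    rng = np.random.default_rng(spec.seed)
    mean_cache: dict[str, np.ndarray] = {}
    records: list[SubjectRecord] = []
    plan = []
    for i in range(spec.n_cn):
        plan.append(("CN", "pos" if i < spec.n_abpos_cn else "neg"))
    for i in range(spec.n_ad):
        plan.append(("AD", "neg" if i < spec.n_abneg_ad else "pos"))
    for k, (dx, ab) in enumerate(plan):
        mu, sd = spec.mmse_cn if dx == "CN" else spec.mmse_ad
        records.append(
            SubjectRecord(
                subject_id=f"S{k:04d}",
                diagnosis=dx,
                ab_reading=ab,
                mmse=_truncnorm(rng, mu, sd, 0.0, 30.0),
                tac=_sample_tac(dx, spec, rng, mean_cache),
                suvr=sample_amyloid_suvr(dx, ab, spec, rng),
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_cohort_csv(records: list[SubjectRecord], out_dir) -> dict[str, str]:
    """Write meta.csv, tac.csv (long format) and suvr.csv under `out_dir`."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "ab_reading": [r.ab_reading for r in records],
            "mmse": [r.mmse for r in records],
        }
    )
    tac_rows = []
    suvr_rows = []
    for r in records:
        for gi, region in enumerate(r.tac.regions):
            for fi, tmid in enumerate(r.tac.frame_mid):
                tac_rows.append(
                    (r.subject_id, region, fi, tmid, r.tac.values[gi, fi])
                )
            suvr_rows.append((r.subject_id, region, r.suvr.values[gi]))
    tac = pd.DataFrame(
        tac_rows, columns=["subject_id", "region", "frame_index", "frame_mid_s", "suvr"]
    )
    suvr = pd.DataFrame(suvr_rows, columns=["subject_id", "region", "suvr"])
    paths = {
        "meta": os.path.join(out_dir, "meta.csv"),
        "tac": os.path.join(out_dir, "tac.csv"),
        "suvr": os.path.join(out_dir, "suvr.csv"),
    }
    meta.to_csv(paths["meta"], index=False)
    tac.to_csv(paths["tac"], index=False)
    suvr.to_csv(paths["suvr"], index=False)
    return paths


def read_cohort_csv(in_dir) -> list[SubjectRecord]:
    import os

    meta = pd.read_csv(os.path.join(in_dir, "meta.csv"))
    tac = pd.read_csv(os.path.join(in_dir, "tac.csv"))
    suvr = pd.read_csv(os.path.join(in_dir, "suvr.csv"))
    records = []
    for _, row in meta.iterrows():
        sid = row["subject_id"]
        t = tac[tac.subject_id == sid]
        s = suvr[suvr.subject_id == sid]
        regions = tuple(t.region.unique())
        piv = t.pivot(index="region", columns="frame_index", values="suvr").loc[list(regions)]
        fm = t[t.region == regions[0]].sort_values("frame_index").frame_mid_s.to_numpy()
        sv = s.set_index("region").loc[list(regions), "suvr"].to_numpy()
        records.append(
            SubjectRecord(
                subject_id=sid,
                diagnosis=row["diagnosis"],
                ab_reading=row["ab_reading"],
                mmse=float(row["mmse"]),
                tac=TACMatrix(values=piv.to_numpy(), regions=regions, frame_mid=fm),
                suvr=SUVrVector(values=sv, regions=regions),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Voxel phantom export (exercises the feature-extraction path end to end)
# ---------------------------------------------------------------------------

def phantom_atlas(regions: tuple[str, ...] = ALL_REGIONS):
    """A toy template-space atlas: one 2x2x2 block per region, labels 1..n.

    Returns (label_volume, mapping) where mapping is {label: region_name}.
    """
    n = len(regions)
    vol = np.zeros((2 * n, 2, 2), dtype=np.int16)
    mapping = {}
    for i, region in enumerate(regions):
        vol[2 * i : 2 * i + 2, :, :] = i + 1
        mapping[i + 1] = region
    return vol, mapping


def export_phantom(record: SubjectRecord, out_dir, scale: float = 1.0) -> dict[str, str]:
    """Write a 4D dynamic + 3D delay NIfTI phantom for one subject.

    Voxels of region g at frame t carry ``tac[g, t] * cereb_curve(t) * scale``
    (absolute activity; dividing by the cerebellar mean recovers the stored
    SUVr TAC exactly); the delay volume carries ``suvr[g] * scale``.
    """
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    regions = record.tac.regions
    atlas, mapping = phantom_atlas(regions)
    t = record.tac.frame_mid
    alpha_c, beta_c = _REGION_KINETICS[REFERENCE_REGION]
    cereb = perfusion_curve(PerfusionParams(alpha=alpha_c, beta=beta_c), t)
    dyn = np.zeros(atlas.shape + (len(t),))
    delay = np.zeros(atlas.shape)
    for label, region in mapping.items():
        gi = regions.index(region)
        dyn[atlas == label, :] = record.tac.values[gi] * cereb * scale
        delay[atlas == label] = record.suvr.values[gi] * scale
    affine = np.eye(4)
    paths = {
        "dynamic": os.path.join(out_dir, "dynamic.nii.gz"),
        "delay": os.path.join(out_dir, "delay.nii.gz"),
        "atlas": os.path.join(out_dir, "atlas.nii.gz"),
        "mapping": os.path.join(out_dir, "mapping.csv"),
    }
    nib.save(nib.Nifti1Image(dyn, affine), paths["dynamic"])
    nib.save(nib.Nifti1Image(delay, affine), paths["delay"])
    nib.save(nib.Nifti1Image(atlas.astype(np.int16), affine), paths["atlas"])
    pd.DataFrame(
        {"label": list(mapping), "region": [mapping[k] for k in mapping]}
    ).to_csv(paths["mapping"], index=False)
    return paths
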