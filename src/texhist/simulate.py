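"""Synthetic lesion phantoms and simulated cohorts with known ground truth.

No public imaging data accompany the clinical problem this package models, so
every stage is validated against phantoms generated here:

* **CT phantom** — a 0.98 mm-pixel slice of soft-tissue background (~40 HU)
  with Gaussian noise, an elliptical ROI, and a sparse set of signed Gaussian
  "blobs" of controllable diameter (mm).  A latent heterogeneity score ``z``
  scales the blob *amplitude*, so high-z lesions carry strong focal
  excursions on a smooth background — by construction this raises the
  filtered-map SD and coarse-scale kurtosis (sparse large-amplitude objects
  give heavy-tailed response histograms).  Optional air pockets (-1000 HU)
  exercise the HU-exclusion rule.
* **PET phantom** — a deliberately coarse 4 mm-pixel grid carrying a
  flat-topped hot disc (SUV ~ 8 plateau over ~1 background, softened by a
  point-spread blur) with per-pixel intra-lesional texture whose amplitude
  scales with ``z``.  The ROI is drawn slightly *outside* the lesion edge, as
  a manual ROI would be; the background pixels it captures anchor the
  histogram range, so stronger texture spreads the plateau over more bins and
  raises entropy (histogram entropy over the ROI's own [min, max] is
  scale-invariant and would otherwise barely respond).
* **Cohort** — n patients with 1-7 lesions each sharing the patient's ``z``;
  progression and death times are exponential with log-hazard ``beta * z``
  (z standardized, so beta is the log hazard ratio per SD of heterogeneity),
  progression-free survival is the minimum of progression and death, and
  censoring combines administrative follow-up with independent uniform
  dropout.  Baseline rates are calibrated so the null-z cohort has median
  PFS ~ 22 and median OS ~ 37 months under no censoring.

Everything is deterministic under a fixed seed.  ``simulate_cohort`` writes
the exact NIfTI + manifest CSV layout the readers in
:mod:`texhist.image` consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import ImageSlice, Lesion, RoiMask, write_lesion

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_lesion_phantom",
    "make_cohort",
    "simulate_cohort",
    "heterogeneity_markers",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of one synthetic lesion."""

    ct_shape: tuple[int, int] = (64, 64)
    ct_spacing_mm: tuple[float, float] = (0.98, 0.98)
    pet_shape: tuple[int, int] = (32, 32)
    pet_spacing_mm: tuple[float, float] = (4.0, 4.0)

    ct_background_hu: float = 40.0
    ct_noise_sd_hu: float = 6.0
    roi_radii_mm: tuple[float, float] = (14.0, 10.0)

    blob_count_base: float = 2.0       # Poisson rate of blobs (z-independent)
    blob_count_z_scale: float = 0.0    # rate *= exp(scale * z)
    blob_diameter_mm: tuple[float, float] = (3.0, 6.0)  # uniform range
    blob_amp_sd_hu: float = 35.0       # amplitude SD at z = 0
    blob_amp_z_scale: float = 1.0      # amplitude SD *= exp(scale * z)

    air_pocket_prob: float = 0.15
    air_pocket_radius_mm: float = 2.0
    air_hu: float = -1000.0

    pet_background_suv: float = 1.0
    pet_noise_sd_suv: float = 0.05
    pet_lesion_radius_mm: tuple[float, float] = (10.0, 18.0)  # uniform range
    pet_roi_margin: float = 1.15       # ROI radius / lesion radius
    pet_avidity_suv: float = 8.0       # plateau SUV (lognormal spread)
    pet_avidity_sd_log: float = 0.3
    pet_texture_sd_suv: float = 0.35   # intra-lesion texture SD at z = 0
    pet_texture_z_scale: float = 0.9
    pet_psf_sigma_px: float = 0.6      # scanner point-spread smoothing

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.ct_spacing_mm + self.pet_spacing_mm):
            raise ValueError("spacings must be positive")
        if not 0 <= self.air_pocket_prob <= 1:
            raise ValueError("air_pocket_prob must be in [0, 1]")


#: Median PFS/OS (months) the baseline hazards are calibrated to.
_MEDIAN_OS_MONTHS = 37.0
_MEDIAN_PFS_MONTHS = 22.0


@dataclass(frozen=True)
class CohortSpec:
    """Size, effect, and censoring structure of a simulated cohort."""

    n_patients: int = 44
    lesions_min: int = 1
    lesions_max: int = 7
    beta_pfs: float = math.log(2.5)   # log-HR per SD of heterogeneity
    beta_os: float = math.log(2.5)
    # death rate gives median OS 37 mo; progression-only rate is chosen so
    # PFS = min(progression, death) has median ~ 22 mo at z = 0
    base_rate_os: float = math.log(2.0) / _MEDIAN_OS_MONTHS
    base_rate_progression: float = math.log(2.0) * (
        1.0 / _MEDIAN_PFS_MONTHS - 1.0 / _MEDIAN_OS_MONTHS
    )
    horizon_months: float = 82.0
    dropout_uniform_upper: float = 164.0  # U(0, upper) independent dropout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 1 <= self.lesions_min <= self.lesions_max:
            raise ValueError("invalid lesion count range")
        if self.base_rate_os <= 0 or self.base_rate_progression <= 0:
            raise ValueError("baseline rates must be positive")
        if self.horizon_months <= 0:
            raise ValueError("horizon must be positive")


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _ellipse_mask(shape, center, radii_px) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / radii_px[0]) ** 2 + (
        (xx - center[1]) / radii_px[1]
    ) ** 2 <= 1.0


def make_lesion_phantom(
    spec: PhantomSpec,
    z: float = 0.0,
    rng: np.random.Generator | int | None = None,
    lesion_id: str = "L1",
    patient_id: str = "P1",
) -> Lesion:
    """Generate one paired CT/PET lesion phantom.

    ``z`` is the latent heterogeneity score (typically ~ N(0,1) across a
    cohort); higher ``z`` yields denser and stronger CT blobs and a more
    textured PET lesion.  Deterministic for a fixed ``rng`` seed.
    """
    rng = _as_rng(rng)

    # --- CT ---------------------------------------------------------------
    ct = np.full(spec.ct_shape, spec.ct_background_hu, dtype=np.float64)
    if spec.ct_noise_sd_hu > 0:
        ct += rng.normal(0.0, spec.ct_noise_sd_hu, size=spec.ct_shape)
    center = (spec.ct_shape[0] / 2.0, spec.ct_shape[1] / 2.0)
    radii_px = (
        spec.roi_radii_mm[0] / spec.ct_spacing_mm[0],
        spec.roi_radii_mm[1] / spec.ct_spacing_mm[1],
    )
    if 2 * radii_px[0] > spec.ct_shape[0] or 2 * radii_px[1] > spec.ct_shape[1]:
        raise ValueError("ROI larger than the CT grid")
    roi = _ellipse_mask(spec.ct_shape, center, radii_px)

    n_blobs = rng.poisson(spec.blob_count_base * math.exp(spec.blob_count_z_scale * z))
    amp_sd = spec.blob_amp_sd_hu * math.exp(spec.blob_amp_z_scale * z)
    yy, xx = np.mgrid[: spec.ct_shape[0], : spec.ct_shape[1]]
    for _ in range(n_blobs):
        # rejection-sample a blob center inside the ellipse
        for _try in range(100):
            cy = rng.uniform(center[0] - radii_px[0], center[0] + radii_px[0])
            cx = rng.uniform(center[1] - radii_px[1], center[1] + radii_px[1])
            if ((cy - center[0]) / radii_px[0]) ** 2 + (
                (cx - center[1]) / radii_px[1]
            ) ** 2 <= 1.0:
                break
        d_mm = rng.uniform(*spec.blob_diameter_mm)
        sigma_px = (d_mm / 2.0) / spec.ct_spacing_mm[0]
        amp = rng.normal(0.0, amp_sd)
        ct += amp * np.exp(
            -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_px**2))
        )

    if rng.random() < spec.air_pocket_prob:
        cy = rng.uniform(center[0] - radii_px[0] / 2, center[0] + radii_px[0] / 2)
        cx = rng.uniform(center[1] - radii_px[1] / 2, center[1] + radii_px[1] / 2)
        r_px = spec.air_pocket_radius_mm / spec.ct_spacing_mm[0]
        pocket = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        ct[pocket] = spec.air_hu

    ct_slice = ImageSlice(ct, spec.ct_spacing_mm, "CT")
    ct_mask = RoiMask(roi, lesion_id=lesion_id, patient_id=patient_id)

    # --- PET --------------------------------------------------------------
    pet = np.full(spec.pet_shape, spec.pet_background_suv, dtype=np.float64)
    pcenter = (spec.pet_shape[0] / 2.0, spec.pet_shape[1] / 2.0)
    r_mm = rng.uniform(*spec.pet_lesion_radius_mm)
    lr_px = (r_mm / spec.pet_spacing_mm[0], r_mm / spec.pet_spacing_mm[1])
    mr_px = (lr_px[0] * spec.pet_roi_margin, lr_px[1] * spec.pet_roi_margin)
    if 2 * mr_px[0] > spec.pet_shape[0] or 2 * mr_px[1] > spec.pet_shape[1]:
        raise ValueError("ROI larger than the PET grid")
    lesion_px = _ellipse_mask(spec.pet_shape, pcenter, lr_px)
    # the ROI is drawn just outside the lesion edge, capturing a thin rim of
    # background that anchors the histogram range
    roi_pet = _ellipse_mask(spec.pet_shape, pcenter, mr_px)

    avidity = spec.pet_avidity_suv * math.exp(
        rng.normal(0.0, spec.pet_avidity_sd_log)
    )
    pet[lesion_px] = avidity
    tex_sd = spec.pet_texture_sd_suv * math.exp(spec.pet_texture_z_scale * z)
    pet[lesion_px] += rng.normal(0.0, tex_sd, size=int(lesion_px.sum()))
    if spec.pet_psf_sigma_px > 0:
        pet = ndimage.gaussian_filter(pet, spec.pet_psf_sigma_px)
    if spec.pet_noise_sd_suv > 0:
        pet += rng.normal(0.0, spec.pet_noise_sd_suv, size=spec.pet_shape)
    pet = np.clip(pet, 0.0, None)

    pet_slice = ImageSlice(pet, spec.pet_spacing_mm, "PET")
    pet_mask = RoiMask(roi_pet, lesion_id=lesion_id, patient_id=patient_id)

    return Lesion(
        ct_slice=ct_slice,
        pet_slice=pet_slice,
        ct_mask=ct_mask,
        pet_mask=pet_mask,
        lesion_id=lesion_id,
        patient_id=patient_id,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _simulate_survival(
    z_std: np.ndarray, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential progression/death times with log-hazard beta * z_std."""
    n = z_std.size
    rate_death = spec.base_rate_os * np.exp(spec.beta_os * z_std)
    rate_prog = spec.base_rate_progression * np.exp(spec.beta_pfs * z_std)
    t_death = rng.exponential(1.0 / rate_death)
    t_prog = rng.exponential(1.0 / rate_prog)
    t_pfs = np.minimum(t_prog, t_death)  # PFS event <= OS event by construction
    censor = np.minimum(
        spec.horizon_months, rng.uniform(0.0, spec.dropout_uniform_upper, size=n)
    )
    return pd.DataFrame(
        {
            "true_pfs_months": t_pfs,
            "true_os_months": t_death,
            "censor_months": censor,
            "pfs_months": np.minimum(t_pfs, censor),
            "pfs_event": (t_pfs <= censor).astype(int),
            "os_months": np.minimum(t_death, censor),
            "os_event": (t_death <= censor).astype(int),
        }
    )


def make_cohort(
    cohort_spec: CohortSpec | None = None,
    phantom_spec: PhantomSpec | None = None,
) -> tuple[list[dict], pd.DataFrame]:
    """Simulate a cohort in memory.

    Returns ``(patients, ground_truth)``.  Each patient dict has keys
    ``patient_id``, ``lesions`` (list of :class:`~texhist.image.Lesion`), and
    the observed survival fields; ``ground_truth`` records the latent ``z``
    and uncensored event times.
    """
    cohort_spec = cohort_spec or CohortSpec()
    phantom_spec = phantom_spec or PhantomSpec()
    rng = np.random.default_rng(cohort_spec.seed)

    n = cohort_spec.n_patients
    z = rng.normal(0.0, 1.0, size=n)
    z_std = (z - z.mean()) / z.std()
    surv = _simulate_survival(z_std, cohort_spec, rng)

    width = len(str(n))
    patients = []
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        n_lesions = int(
            rng.integers(cohort_spec.lesions_min, cohort_spec.lesions_max + 1)
        )
        lesions = [
            make_lesion_phantom(
                phantom_spec,
                z=float(z_std[i]),
                rng=rng,
                lesion_id=f"L{j + 1}",
                patient_id=pid,
            )
            for j in range(n_lesions)
        ]
        rec = {"patient_id": pid, "lesions": lesions}
        rec.update(
            surv.iloc[i][
                ["pfs_months", "pfs_event", "os_months", "os_event"]
            ].to_dict()
        )
        rec["pfs_event"] = int(rec["pfs_event"])
        rec["os_event"] = int(rec["os_event"])
        patients.append(rec)

    ground_truth = surv.copy()
    ground_truth.insert(0, "patient_id", [p["patient_id"] for p in patients])
    ground_truth.insert(1, "z_std", z_std)
    ground_truth["n_lesions"] = [len(p["lesions"]) for p in patients]
    return patients, ground_truth


def simulate_cohort(
    cohort_spec: CohortSpec | None = None,
    phantom_spec: PhantomSpec | None = None,
    outdir: str | Path = "cohort",
) -> pd.DataFrame:
    """Simulate a cohort and write it to disk in the manifest layout.

    Writes per-lesion NIfTI files (CT, CT mask, PET, PET mask) under
    ``outdir/images``, plus ``manifest.csv`` and ``ground_truth.csv``.
    Returns the manifest DataFrame (paths relative to ``outdir``).
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    patients, ground_truth = make_cohort(cohort_spec, phantom_spec)

    rows = []
    for rec in patients:
        for lesion in rec["lesions"]:
            stem = f"images/{rec['patient_id']}_{lesion.lesion_id}"
            paths = {
                "ct_path": f"{stem}_ct.nii.gz",
                "ct_mask_path": f"{stem}_ct_mask.nii.gz",
                "pet_path": f"{stem}_pet.nii.gz",
                "pet_mask_path": f"{stem}_pet_mask.nii.gz",
            }
            write_lesion(
                lesion,
                outdir / paths["ct_path"],
                outdir / paths["ct_mask_path"],
                outdir / paths["pet_path"],
                outdir / paths["pet_mask_path"],
            )
            rows.append(
                {
                    "patient_id": rec["patient_id"],
                    "lesion_id": lesion.lesion_id,
                    **paths,
                    "pfs_months": rec["pfs_months"],
                    "pfs_event": rec["pfs_event"],
                    "os_months": rec["os_months"],
                    "os_event": rec["os_event"],
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    return manifest


def heterogeneity_markers(columns) -> list[str]:
    """Feature columns the generator drives *upward* with the latent ``z``.

    CT SD and kurtosis (all scales) rise with blob amplitude, and unfiltered
    PET entropy rises with intra-lesion texture.  Skewness is
    direction-ambiguous (blobs are signed) and CT entropy is not monotone
    under pure amplitude scaling, so both are excluded.
    """
    keep = []
    for c in columns:
        if c.startswith("ct_") and c.endswith(("_sd", "_kurtosis")):
            keep.append(c)
        elif c == "pet_ssf0_entropy":
            keep.append(c)
    return keep
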