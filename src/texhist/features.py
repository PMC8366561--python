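"""Histogram quantification of (slice, mask, filter) combinations.

Each texture map is summarized within the ROI by six first-order statistics:
mean, standard deviation, entropy, mean of positive pixels (MPP), skewness,
and kurtosis.  On CT, ROI pixels below -50 HU (air, gas) are excluded; the
eligibility set is decided on the *unfiltered* HU values and reused for every
filtered map of the same lesion, so all scales summarize the same pixels.

Conventions (configurable through :class:`StatConfig`):

* moments are population moments (1/n, no bias correction);
* kurtosis is excess kurtosis by default (normal -> 0);
* entropy is Shannon entropy in bits over 64 equal-width bins spanning the
  ROI's own [min, max];
* MPP is the mean over strictly positive values, missing (NaN) if none;
* skewness and kurtosis are missing when the SD is zero.

A full feature vector holds 36 CT texture entries (6 statistics x SSF
{0, 2, 3, 4, 5, 6} mm), 6 PET texture entries (unfiltered only), and three
conventional PET metrics: SUVmax, SUVmean, and tracer-uptake tumor area in
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .filtration import FilterConfig, filter_slice
from .image import ImageSlice, Lesion, RoiMask

__all__ = [
    "STATISTICS",
    "CT_SSF_MM",
    "PET_SSF_MM",
    "StatConfig",
    "FeatureVector",
    "eligible_pixels",
    "histogram_stats",
    "suv_metrics",
    "extract_features",
    "TextureFeatureExtractor",
    "feature_table",
]

STATISTICS = ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis")
CT_SSF_MM = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0)
PET_SSF_MM = (0.0,)  # PET resolution is too coarse to support filtration

CONVENTIONAL_METRICS = ("suv_max", "suv_mean", "uptake_area_px")


@dataclass(frozen=True)
class StatConfig:
    """Histogram-statistics configuration.

    entropy_bins
        Number of equal-width bins over the ROI [min, max]; default 64.
    kurtosis_convention
        "excess" (fourth standardized moment - 3) or "pearson".
    hu_exclusion_threshold
        CT ROI pixels strictly below this HU value are excluded (default -50).
    """

    entropy_bins: int = 64
    kurtosis_convention: str = "excess"
    hu_exclusion_threshold: float = -50.0

    def __post_init__(self) -> None:
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")
        if self.kurtosis_convention not in ("excess", "pearson"):
            raise ValueError("kurtosis_convention must be 'excess' or 'pearson'")


def texture_feature_name(modality: str, ssf_mm: float, stat: str) -> str:
    return f"{modality.lower()}_ssf{int(ssf_mm)}_{stat}"


def texture_feature_names() -> list[str]:
    """Canonical column order: 36 CT + 6 PET + 3 conventional."""
    names = [texture_feature_name("CT", s, st) for s in CT_SSF_MM for st in STATISTICS]
    names += [texture_feature_name("PET", s, st) for s in PET_SSF_MM for st in STATISTICS]
    names += list(CONVENTIONAL_METRICS)
    return names


@dataclass
class FeatureVector:
    """Named feature map for one lesion (or one patient after aggregation).

    ``texture`` maps (modality, ssf_mm, statistic) to a float; missing values
    are NaN, never silently dropped — the CT block always has 36 entries and
    the PET block 6.
    """

    texture: dict[tuple[str, float, str], float]
    suv_max: float
    suv_mean: float
    uptake_area_px: float

    def __post_init__(self) -> None:
        n_ct = sum(1 for (m, _, _) in self.texture if m == "CT")
        n_pet = sum(1 for (m, _, _) in self.texture if m == "PET")
        if n_ct != len(CT_SSF_MM) * len(STATISTICS):
            raise ValueError(f"CT texture block must have 36 entries, got {n_ct}")
        if n_pet != len(PET_SSF_MM) * len(STATISTICS):
            raise ValueError(f"PET texture block must have 6 entries, got {n_pet}")
        if self.uptake_area_px < 1:
            raise ValueError("uptake_area_px must be >= 1")

    def to_series(self) -> pd.Series:
        data = {
            texture_feature_name(m, s, st): v for (m, s, st), v in self.texture.items()
        }
        data["suv_max"] = self.suv_max
        data["suv_mean"] = self.suv_mean
        data["uptake_area_px"] = self.uptake_area_px
        return pd.Series(data).reindex(texture_feature_names())


# ---------------------------------------------------------------------------
# Pixel eligibility and statistics
# ---------------------------------------------------------------------------

def eligible_pixels(
    slice_: ImageSlice, mask: RoiMask, config: StatConfig | None = None
) -> np.ndarray:
    """Boolean eligibility map of ROI pixels entering the statistics.

    CT: ROI pixels with unfiltered HU >= the exclusion threshold (air and gas
    are below -50 HU).  The returned map is meant to be reused for that
    lesion's filtered texture maps.  PET: all ROI pixels.

    Raises
    ------
    ValueError
        If no pixel survives the exclusion.
    """
    config = config or StatConfig()
    if not mask.mask.any():
        raise ValueError("empty ROI mask")
    if slice_.modality == "CT":
        elig = mask.mask & (slice_.pixels >= config.hu_exclusion_threshold)
    else:
        elig = mask.mask.copy()
    if not elig.any():
        raise ValueError(
            "no eligible pixels: every ROI pixel is below "
            f"{config.hu_exclusion_threshold} HU"
        )
    return elig


def histogram_stats(
    values: np.ndarray | Sequence[float], config: StatConfig | None = None
) -> dict[str, float]:
    """Six first-order statistics of a pixel value multiset.

    Returns a dict keyed by :data:`STATISTICS`; statistics that are undefined
    for the input are NaN (MPP with no positive value; skewness/kurtosis at
    zero SD).
    """
    config = config or StatConfig()
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty value set")

    mean = float(v.mean())
    var = float(v.var())  # population variance
    sd = float(np.sqrt(var))

    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        entropy = 0.0
    else:
        counts, _ = np.histogram(v, bins=config.entropy_bins, range=(vmin, vmax))
        p = counts[counts > 0] / v.size
        entropy = float(-(p * np.log2(p)).sum())

    pos = v[v > 0]
    mpp = float(pos.mean()) if pos.size else float("nan")

    if sd == 0.0:
        skew = float("nan")
        kurt = float("nan")
    else:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
        if config.kurtosis_convention == "excess":
            kurt -= 3.0

    return {
        "mean": mean,
        "sd": sd,
        "entropy": entropy,
        "mpp": mpp,
        "skewness": skew,
        "kurtosis": kurt,
    }


def suv_metrics(pet_slice: ImageSlice, mask: RoiMask) -> tuple[float, float, int]:
    """Conventional PET quantification: (SUVmax, SUVmean, uptake area in px).

    The uptake tumor area is the ROI pixel count — the PET analogue of
    metabolic tumor area for a tracer whose uptake is receptor- rather than
    metabolism-driven.  Multiply by ``pet_slice.pixel_area_mm2`` for mm^2.
    """
    if not mask.mask.any():
        raise ValueError("empty ROI mask")
    vals = pet_slice.pixels[mask.mask]
    return float(vals.max()), float(vals.mean()), int(vals.size)


# ---------------------------------------------------------------------------
# Per-lesion extraction
# ---------------------------------------------------------------------------

def extract_features(
    lesion: Lesion,
    ssf_mm: Sequence[float] = CT_SSF_MM,
    stat_config: StatConfig | None = None,
    sigma_ratio: float = 0.5,
    truncation: float = 4.0,
    padding: str = "reflect",
) -> FeatureVector:
    """Full feature vector of one lesion.

    CT: the slice is filtered at every SSF in ``ssf_mm`` (0 = unfiltered
    control) and each texture map is summarized over the HU-eligible ROI
    pixels — 6 statistics x 6 scales = 36 entries by default.  PET: the
    unfiltered masked slice only (6 entries), plus SUVmax/SUVmean/uptake area.
    """
    stat_config = stat_config or StatConfig()
    # scales outside ssf_mm stay as explicit NaN entries so the CT block
    # always has its full 36 slots rather than silently shrinking
    texture: dict[tuple[str, float, str], float] = {
        ("CT", float(s), st): float("nan") for s in CT_SSF_MM for st in STATISTICS
    }

    ct_elig = eligible_pixels(lesion.ct_slice, lesion.ct_mask, stat_config)
    for ssf in ssf_mm:
        cfg = FilterConfig(
            ssf_mm=ssf, sigma_ratio=sigma_ratio, truncation=truncation, padding=padding
        )
        tmap = filter_slice(lesion.ct_slice, cfg)
        stats = histogram_stats(tmap.pixels[ct_elig], stat_config)
        for st, val in stats.items():
            texture[("CT", float(ssf), st)] = val

    pet_elig = eligible_pixels(lesion.pet_slice, lesion.pet_mask, stat_config)
    pet_stats = histogram_stats(lesion.pet_slice.pixels[pet_elig], stat_config)
    for st, val in pet_stats.items():
        texture[("PET", 0.0, st)] = val

    smax, smean, area = suv_metrics(lesion.pet_slice, lesion.pet_mask)
    return FeatureVector(
        texture=texture, suv_max=smax, suv_mean=smean, uptake_area_px=area
    )


class TextureFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping lesions to a tidy per-lesion feature table.

    Parameters mirror :func:`extract_features`.  ``transform`` takes a
    sequence of :class:`~texhist.image.Lesion` and returns a DataFrame with
    one row per lesion, columns ``patient_id``, ``lesion_id``, then the
    canonical 36 + 6 + 3 feature columns.
    """

    def __init__(
        self,
        ssf_mm: tuple[float, ...] = CT_SSF_MM,
        entropy_bins: int = 64,
        kurtosis_convention: str = "excess",
        hu_exclusion_threshold: float = -50.0,
        sigma_ratio: float = 0.5,
        truncation: float = 4.0,
        padding: str = "reflect",
    ) -> None:
        self.ssf_mm = ssf_mm
        self.entropy_bins = entropy_bins
        self.kurtosis_convention = kurtosis_convention
        self.hu_exclusion_threshold = hu_exclusion_threshold
        self.sigma_ratio = sigma_ratio
        self.truncation = truncation
        self.padding = padding

    def _stat_config(self) -> StatConfig:
        return StatConfig(
            entropy_bins=self.entropy_bins,
            kurtosis_convention=self.kurtosis_convention,
            hu_exclusion_threshold=self.hu_exclusion_threshold,
        )

    def fit(self, X=None, y=None) -> "TextureFeatureExtractor":
        self._stat_config()  # parameter validation
        self.feature_names_ = texture_feature_names()
        return self

    def transform(self, X: Sequence[Lesion]) -> pd.DataFrame:
        rows = []
        for lesion in X:
            fv = extract_features(
                lesion,
                ssf_mm=self.ssf_mm,
                stat_config=self._stat_config(),
                sigma_ratio=self.sigma_ratio,
                truncation=self.truncation,
                padding=self.padding,
            )
            row = fv.to_series()
            row["patient_id"] = lesion.patient_id
            row["lesion_id"] = lesion.lesion_id
            rows.append(row)
        df = pd.DataFrame(rows).reset_index(drop=True)
        cols = ["patient_id", "lesion_id"] + texture_feature_names()
        return df[cols]


def feature_table(lesions: Sequence[Lesion], **params) -> pd.DataFrame:
    """Convenience wrapper: extract features for a list of lesions."""
    return TextureFeatureExtractor(**params).fit().transform(lesions)
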