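"""Patient-level aggregation and assembly of the analysis table.

Lesion-level feature vectors are averaged to one value per patient (over the
up-to-five most avid lesions), then joined with survival outcomes and
clinical covariates from the manifest into a single analysis table — one row
per patient, deterministically ordered by patient id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureVector, texture_feature_names
from .image import MANIFEST_COLUMNS

__all__ = [
    "aggregate_patient",
    "build_analysis_table",
    "analysis_table_from_records",
    "PatientRecord",
]


@dataclass
class PatientRecord:
    patient_id: str
    features: pd.Series
    pfs_months: float
    pfs_event: int
    os_months: float
    os_event: int
    covariates: dict


def aggregate_patient(
    lesion_features: Sequence[FeatureVector] | pd.DataFrame,
    aggregator: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> pd.Series:
    """Average lesion-level features to one patient-level vector.

    Each feature is the arithmetic mean over the lesions where it is present;
    it is missing only if missing in every lesion.  The uptake area follows
    the same rule.  ``aggregator`` is a hook for alternative per-patient
    summaries (it receives the lesion-by-feature DataFrame); only the mean
    ships.
    """
    if isinstance(lesion_features, pd.DataFrame):
        df = lesion_features
    else:
        if len(lesion_features) == 0:
            raise ValueError("empty lesion feature list")
        df = pd.DataFrame([fv.to_series() for fv in lesion_features])
    if df.empty:
        raise ValueError("empty lesion feature list")
    if aggregator is not None:
        return aggregator(df)
    return df.mean(axis=0, skipna=True)


def build_analysis_table(
    manifest: pd.DataFrame,
    lesion_features: pd.DataFrame,
    lesion_limit: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Join per-lesion features with outcomes into the per-patient table.

    Parameters
    ----------
    manifest : DataFrame
        Cohort manifest (one row per lesion) with the required survival
        columns; extra columns are clinical covariates, assumed constant
        within a patient.
    lesion_features : DataFrame
        Output of :class:`~texhist.features.TextureFeatureExtractor`:
        one row per lesion with ``patient_id``/``lesion_id`` keys.
    lesion_limit : int
        Per patient, only the ``lesion_limit`` most avid lesions (largest
        per-lesion SUVmax) enter the average.

    Returns
    -------
    (table, report)
        ``table`` has one row per patient, sorted by patient_id, columns =
        features + pfs/os outcome columns + covariates.  ``report`` records
        dropped lesions and validation flags.
    """
    manifest = manifest.copy()
    manifest["patient_id"] = manifest["patient_id"].astype(str)
    feats = lesion_features.copy()
    feats["patient_id"] = feats["patient_id"].astype(str)

    outcome_cols = ["pfs_months", "pfs_event", "os_months", "os_event"]
    covariate_cols = [c for c in manifest.columns if c not in MANIFEST_COLUMNS]

    per_patient = manifest.drop_duplicates("patient_id").set_index("patient_id")
    dup_outcomes = (
        manifest.groupby("patient_id")[outcome_cols].nunique().gt(1).any(axis=1)
    )
    if dup_outcomes.any():
        raise ValueError(
            "inconsistent survival fields within patient(s): "
            f"{dup_outcomes[dup_outcomes].index.tolist()}"
        )

    missing = set(per_patient.index) - set(feats["patient_id"])
    if missing:
        raise ValueError(f"patients without extracted lesions: {sorted(missing)}")

    feature_cols = texture_feature_names()
    report: dict = {"n_patients": int(per_patient.shape[0]), "dropped_lesions": {}}

    rows = []
    for pid, group in feats.groupby("patient_id", sort=True):
        if len(group) > lesion_limit:
            keep = group.sort_values("suv_max", ascending=False, kind="stable").head(
                lesion_limit
            )
            report["dropped_lesions"][pid] = sorted(
                set(group["lesion_id"]) - set(keep["lesion_id"])
            )
            group = keep
        agg = aggregate_patient(group[feature_cols])
        agg.name = pid
        rows.append(agg)

    table = pd.DataFrame(rows)
    table.index.name = "patient_id"
    table = table.join(per_patient[outcome_cols + covariate_cols])
    table = table.sort_index()
    report["n_lesions_used"] = int(len(feats)) - sum(
        len(v) for v in report["dropped_lesions"].values()
    )
    return table, report


def analysis_table_from_records(
    records: Sequence[dict],
    lesion_limit: int = 5,
    extractor=None,
) -> pd.DataFrame:
    """Build the per-patient analysis table from in-memory cohort records.

    ``records`` is the output of :func:`texhist.simulate.make_cohort` (or any
    list of dicts with ``patient_id``, ``lesions`` and the four survival
    fields): lesions are feature-extracted, limited to the most avid
    ``lesion_limit``, and averaged per patient — the disk-free equivalent of
    running the pipeline on a written cohort.
    """
    from .features import TextureFeatureExtractor

    extractor = extractor or TextureFeatureExtractor().fit()
    lesions = [l for rec in records for l in rec["lesions"]]
    features = extractor.transform(lesions)
    manifest = pd.DataFrame(
        [
            {
                "patient_id": rec["patient_id"],
                "lesion_id": lesion.lesion_id,
                "ct_path": "", "ct_mask_path": "",
                "pet_path": "", "pet_mask_path": "",
                "pfs_months": rec["pfs_months"], "pfs_event": rec["pfs_event"],
                "os_months": rec["os_months"], "os_event": rec["os_event"],
            }
            for rec in records
            for lesion in rec["lesions"]
        ]
    )
    table, _ = build_analysis_table(manifest, features, lesion_limit)
    return table
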