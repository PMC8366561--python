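"""End-to-end orchestration: simulate -> extract -> aggregate -> survival.

``run_pipeline`` drives the full analysis from a cohort manifest to the
summary tables: per-lesion feature extraction, patient-level aggregation,
median-split univariate screening with BH correction per endpoint, and
forward-Wald Cox selection over the significant markers.  All outputs are
deterministic under a fixed config and carry a config hash and the package
version in a comment header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import build_analysis_table
from .features import TextureFeatureExtractor, texture_feature_names
from .filtration import ALLOWED_SSF_MM
from .image import MANIFEST_COLUMNS, iter_manifest_lesions, load_manifest
from .survival import ForwardWaldCoxSelector, dichotomize_at_median, km_estimate, run_univariate_screen

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("texhist")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    The defaults are the standard analysis settings: LoG filtration at
    SSF {0, 2, 3, 4, 5, 6} mm, 64-bin entropy, excess kurtosis, -50 HU
    exclusion, up to 5 lesions per patient, BH at q = 0.30 per endpoint, and
    forward-Wald Cox entry at p < 0.05 with Breslow ties.
    """

    manifest: str = "manifest.csv"
    outdir: str = "run"
    root: str = "."
    ssf_mm: tuple[float, ...] = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    sigma_ratio: float = 0.5
    entropy_bins: int = 64
    kurtosis_convention: str = "excess"
    hu_exclusion_threshold: float = -50.0
    lesion_limit: int = 5
    q: float = 0.30
    entry_p: float = 0.05
    ties: str = "breslow"
    endpoints: tuple[str, ...] = ("pfs", "os")
    markers: tuple[str, ...] | None = None  # None = all features + covariates
    seed: int = 0

    def __post_init__(self) -> None:
        bad = [s for s in self.ssf_mm if float(s) not in ALLOWED_SSF_MM]
        if bad:
            raise ValueError(f"invalid SSF value(s) {bad}; allowed: {ALLOWED_SSF_MM}")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if not 0 < self.entry_p < 1:
            raise ValueError("entry_p must be in (0, 1)")
        if self.lesion_limit < 1:
            raise ValueError("lesion_limit must be >= 1")
        unknown = [e for e in self.endpoints if e not in ("pfs", "os")]
        if unknown:
            raise ValueError(f"unknown endpoint(s) {unknown}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ssf_mm"] = list(self.ssf_mm)
        d["endpoints"] = list(self.endpoints)
        d["markers"] = list(self.markers) if self.markers else None
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis on the same data hashes identically wherever it runs)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("manifest", "outdir", "root")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    header = f"# texhist {__version__} config_hash={cfg.config_hash()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Run extract -> aggregate -> survival on a cohort manifest.

    Writes under ``config.outdir``: ``features.csv`` (per lesion),
    ``analysis_table.csv`` (per patient), per-endpoint ``screen_<ep>.csv``
    and ``cox_<ep>.csv`` reports, KM curve data for significant markers, a
    validation report, and a run log.  Returns the in-memory results.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    logger.info("config %s hash=%s version=%s",
                json.dumps(config.to_dict(), sort_keys=True),
                config.config_hash(), __version__)

    manifest = load_manifest(Path(config.root) / config.manifest)
    n_patients = manifest["patient_id"].nunique()
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    logger.info("manifest: %d lesions, %d patients", len(manifest), n_patients)

    extractor = TextureFeatureExtractor(
        ssf_mm=config.ssf_mm,
        entropy_bins=config.entropy_bins,
        kurtosis_convention=config.kurtosis_convention,
        hu_exclusion_threshold=config.hu_exclusion_threshold,
        sigma_ratio=config.sigma_ratio,
    ).fit()
    lesions = list(iter_manifest_lesions(manifest, root=config.root))
    features = extractor.transform(lesions)
    _write_csv(features, outdir / "features.csv", config)

    table, report = build_analysis_table(manifest, features, config.lesion_limit)
    _write_csv(table, outdir / "analysis_table.csv", config, index=True)
    report["config_hash"] = config.config_hash()
    report["version"] = __version__
    with open(outdir / "validation_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)

    covariate_cols = [
        c for c in manifest.columns if c not in MANIFEST_COLUMNS
    ]
    markers = list(config.markers) if config.markers else (
        texture_feature_names() + covariate_cols
    )

    results: dict = {"features": features, "table": table, "report": report}
    for endpoint in config.endpoints:
        t = table[f"{endpoint}_months"].to_numpy(dtype=float)
        e = table[f"{endpoint}_event"].to_numpy(dtype=int)
        if e.sum() < 1:
            raise ValueError(f"no events for endpoint {endpoint}")
        screen, skips = run_univariate_screen(table, endpoint, markers, q=config.q)
        screen_df = pd.DataFrame([r.to_row() for r in screen])
        _write_csv(screen_df, outdir / f"screen_{endpoint}.csv", config)
        if skips:
            logger.info("skipped markers (%s): %s", endpoint, skips)

        significant = [r for r in screen if r.significant]
        km_rows = []
        for r in significant:
            vals = table[r.marker].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            _, above, _ = dichotomize_at_median(vals)
            for label, sel in (("below", ~above), ("above", above)):
                km = km_estimate(t[finite][sel], e[finite][sel].astype(bool))
                for ti, si, ri in zip(km.timeline, km.survival, km.at_risk):
                    km_rows.append(
                        {"marker": r.marker, "group": label, "t_months": ti,
                         "survival": si, "at_risk": ri}
                    )
        if km_rows:
            _write_csv(pd.DataFrame(km_rows), outdir / f"km_{endpoint}.csv", config)

        # Candidates enter the Cox model as median-dichotomized binaries.
        candidates = pd.DataFrame(index=table.index)
        for r in significant:
            vals = table[r.marker].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            col = np.full(len(table), np.nan)
            _, above, _ = dichotomize_at_median(vals)
            col[finite] = above.astype(float)
            candidates[r.marker] = col
        candidates = candidates.dropna(axis=0)
        selector = ForwardWaldCoxSelector(entry_p=config.entry_p, ties=config.ties)
        if candidates.shape[1] > 0:
            idx = candidates.index
            selector.fit(
                candidates,
                (table.loc[idx, f"{endpoint}_months"],
                 table.loc[idx, f"{endpoint}_event"].astype(bool)),
            )
        else:
            selector.selected_ = []
            selector.summary_ = pd.DataFrame(
                columns=["coef", "HR", "CI95_low", "CI95_high", "wald_p"]
            )
            selector.trace_ = []
        _write_csv(selector.summary_, outdir / f"cox_{endpoint}.csv", config, index=True)
        with open(outdir / f"cox_{endpoint}_trace.json", "w") as fh:
            json.dump(selector.trace_, fh, indent=2)
        logger.info(
            "%s: %d markers screened, %d significant after BH(q=%.2f), "
            "Cox selected %s",
            endpoint, len(screen), len(significant), config.q, selector.selected_,
        )
        results[endpoint] = {
            "screen": screen,
            "screen_table": screen_df,
            "skip_log": skips,
            "significant": [r.marker for r in significant],
            "cox_selected": selector.selected_,
            "cox_summary": selector.summary_,
            "cox_trace": selector.trace_,
        }
    return results
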