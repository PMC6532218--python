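"""Pipeline orchestration: image -> metrics and metrics+metadata -> statistics.

Two entry points mirror the study's two phases. :func:`run_core` quantifies a
single cylinder image into a metrics row (plus overlays and a manifest);
:func:`run_cohort` joins the per-case metric table to outcomes, excludes cases
with no immunoreactivity, and produces the rank-test grid, the Q3-dichotomized
Kaplan-Meier / log-rank battery and the backward-Wald Cox models for EFS and
OS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import RunConfig
from .morphometry import COVARIATE_KEYS, CoreMetrics, analyze_core
from .stains import RGBImage
from .stats import (
    CoxBackwardModel,
    kruskal_wallis,
    km_logrank,
    mann_whitney,
    q3_dichotomize,
)

__all__ = ["run_core", "run_cohort", "load_image", "CohortReport"]

#: biomarkers entering the rank-test / survival batteries
METRIC_COLUMNS = list(CoreMetrics.NUMERIC_FIELDS)


def load_image(path: str | Path, config: RunConfig) -> RGBImage:
    """Read a TIFF/PNG core image; scale comes from the config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return RGBImage(pixels, um_per_px=config.um_per_px, core_id=path.stem)


def _manifest(config: RunConfig, extra: dict) -> dict:
    return {"config": config.to_dict(), "config_hash": config.config_hash,
            **extra}


def run_core(image_path: str | Path, config: RunConfig,
             out_dir: str | Path | None = None,
             write_overlays: bool = False) -> CoreMetrics:
    """Quantify one cylinder image; optionally write row, overlays, manifest."""
    image = load_image(image_path, config)
    analysis = analyze_core(
        image,
        stains=config.stains,
        thresholds=config.thresholds,
        zone_params=config.zone_params,
        od_floor=config.od_floor,
        nuclei_threshold=config.nuclei_threshold,
        min_nucleus_area_um2=config.min_nucleus_area_um2,
        max_nucleus_area_um2=config.max_nucleus_area_um2,
        i0=config.i0,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        row = analysis.metrics.as_dict()
        pd.DataFrame([row]).to_csv(out / f"{image.core_id}_metrics.csv",
                                   index=False)
        if write_overlays:
            iio.imwrite(out / f"{image.core_id}_zones.png",
                        (analysis.zones * 51).astype(np.uint8))
            iio.imwrite(out / f"{image.core_id}_classes.png",
                        (analysis.classes * 51).astype(np.uint8))
        manifest = _manifest(config, {"image": str(image_path),
                                      "core_id": image.core_id})
        (out / f"{image.core_id}_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return analysis.metrics


@dataclass
class CohortReport:
    """Tidy result tables of the cohort statistics battery."""

    rank_tests: pd.DataFrame  # metric x factor Mann-Whitney grid
    survival: pd.DataFrame  # per metric x endpoint: Q3, 5-yr rates, log-rank p
    cox_tables: dict  # endpoint -> per-covariate DataFrame
    cox_summaries: dict  # endpoint -> text summary
    n_cases: int
    n_excluded: int

    def significant_survival(self, alpha: float) -> pd.DataFrame:
        s = self.survival
        return s[(s["endpoint"] == "efs") & (s["logrank_p"] < alpha)]


def _rank_test_grid(df: pd.DataFrame, alpha: float) -> pd.DataFrame:
    rows = []
    factors = [k for k in COVARIATE_KEYS if k in df.columns]
    for metric in METRIC_COLUMNS:
        if metric not in df.columns:
            continue
        for factor in factors:
            groups = df[factor].astype(bool).to_numpy()
            values = df[metric].to_numpy(dtype=float)
            if groups.all() or (~groups).all():
                rows.append({"metric": metric, "factor": factor,
                             "u": np.nan, "p": np.nan, "direction": "NA"})
                continue
            res = mann_whitney(values, groups)
            med_hi = float(np.median(values[groups]))
            med_lo = float(np.median(values[~groups]))
            direction = "higher" if med_hi > med_lo else (
                "lower" if med_hi < med_lo else "equal")
            rows.append({
                "metric": metric, "factor": factor,
                "u": res.u, "p": res.p_value,
                "direction": direction,
                "significant": bool(res.p_value < alpha),
            })
    return pd.DataFrame(rows)


def _survival_battery(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    rows = []
    endpoints = {"efs": config.efs_cols, "os": config.os_cols}
    for metric in METRIC_COLUMNS:
        if metric not in df.columns:
            continue
        values = df[metric].to_numpy(dtype=float)
        try:
            split = q3_dichotomize(values)
        except ValueError:
            continue
        for name, (tcol, ecol) in endpoints.items():
            if tcol not in df.columns or ecol not in df.columns:
                continue
            row = {"metric": metric, "endpoint": name,
                   "q3": split.threshold,
                   "n_high": int(split.high.sum()),
                   "n_low": int((~split.high).sum())}
            if split.degenerate:
                row.update(logrank_stat=np.nan, logrank_p=np.nan,
                           rate5y_high=np.nan, rate5y_low=np.nan)
                warnings.warn(f"degenerate Q3 split for {metric}; survival "
                              "comparison reported as NA", stacklevel=2)
            else:
                try:
                    fit = km_logrank(df[tcol].to_numpy(dtype=float),
                                     df[ecol].to_numpy(), split.high)
                    row.update(logrank_stat=fit.logrank_stat,
                               logrank_p=fit.p_value,
                               rate5y_high=fit.km_high.five_year_rate,
                               rate5y_low=fit.km_low.five_year_rate)
                except ValueError as exc:
                    warnings.warn(f"survival test degenerate for {metric} "
                                  f"({name}): {exc}", stacklevel=2)
                    row.update(logrank_stat=np.nan, logrank_p=np.nan,
                               rate5y_high=np.nan, rate5y_low=np.nan)
            row["significant"] = bool(
                row.get("logrank_p") is not None
                and np.isfinite(row["logrank_p"])
                and row["logrank_p"] < config.alpha_significant)
            rows.append(row)
    return pd.DataFrame(rows)


def run_cohort(metrics: pd.DataFrame | str | Path,
               metadata: pd.DataFrame | str | Path | None = None,
               config: RunConfig = RunConfig(),
               out_dir: str | Path | None = None) -> CohortReport:
    """Run the full cohort statistics battery.

    ``metrics`` holds one row per case (cylinder-averaged), keyed by
    ``case_id``; ``metadata`` (covariates + outcomes) is joined on ``case_id``
    when given separately. Cases whose territorial + interterritorial %SA is
    zero are excluded as having no immunoreactivity. Results are
    order-invariant: rows are sorted by case_id before analysis.
    """
    df = _load_table(metrics)
    if metadata is not None:
        meta = _load_table(metadata)
        _check_join(df, meta)
        df = df.merge(meta, on="case_id", how="inner", validate="1:1")
    missing = [c for c in ("efs_time", "efs_event", "os_time", "os_event")
               if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks outcome columns: {missing}")

    df = df.sort_values("case_id", kind="mergesort").reset_index(drop=True)
    n_total = len(df)
    reactive = (df["terr_vn_sa"] + df["inter_vn_sa"]) > 0
    df = df[reactive].reset_index(drop=True)
    n_excluded = n_total - len(df)
    if len(df) < 4:
        raise ValueError("fewer than 4 immunoreactive cases: cohort analysis "
                         "not possible")

    rank_tests = _rank_test_grid(df, config.alpha_significant)
    survival = _survival_battery(df, config)

    cox_tables, cox_summaries = {}, {}
    factors = [k for k in COVARIATE_KEYS if k in df.columns]
    for endpoint, (tcol, ecol) in (("efs", config.efs_cols),
                                   ("os", config.os_cols)):
        cox_df = df.copy()
        covs = [f for f in factors if cox_df[f].nunique() > 1]
        # VN metrics found significant by log-rank enter as Q3 indicators
        sig = survival[(survival["endpoint"] == endpoint)
                       & (survival["significant"] == True)]  # noqa: E712
        for metric in sig["metric"]:
            ind = f"{metric}_q3_high"
            cox_df[ind] = q3_dichotomize(
                cox_df[metric].to_numpy(dtype=float)).high.astype(int)
            if cox_df[ind].nunique() > 1:
                covs.append(ind)
        if not covs or not cox_df[ecol].astype(bool).any():
            warnings.warn(f"Cox model for {endpoint} degenerate: no usable "
                          "covariates or no events", stacklevel=2)
            cox_tables[endpoint] = pd.DataFrame()
            cox_summaries[endpoint] = f"{endpoint}: not fitted (degenerate)"
            continue
        model = CoxBackwardModel(cox_df, tcol, ecol, covs)
        result = model.fit(alpha_stay=config.alpha_stay)
        cox_tables[endpoint] = result.table
        cox_summaries[endpoint] = result.summary()

    report = CohortReport(rank_tests, survival, cox_tables, cox_summaries,
                          n_cases=len(df), n_excluded=n_excluded)
    if out_dir is not None:
        _write_report(report, config, Path(out_dir))
    return report


def _load_table(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj.copy()
    path = Path(obj)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path)


def _check_join(df: pd.DataFrame, meta: pd.DataFrame) -> None:
    for name, t in (("metrics", df), ("metadata", meta)):
        if "case_id" not in t.columns:
            raise ValueError(f"{name} table lacks a case_id column")
    unmatched = set(df["case_id"]) ^ set(meta["case_id"])
    if unmatched:
        raise ValueError(f"case_id mismatch between tables: "
                         f"{sorted(unmatched)[:10]}")


def _write_report(report: CohortReport, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.rank_tests.to_csv(out / "rank_tests.csv", index=False)
    report.survival.to_csv(out / "survival_q3.csv", index=False)
    for endpoint, table in report.cox_tables.items():
        table.to_csv(out / f"cox_{endpoint}.csv",
                     index_label="covariate")
    summary = {
        "n_cases": report.n_cases,
        "n_excluded_no_immunoreactivity": report.n_excluded,
        "config_hash": config.config_hash,
        "cox": {k: v for k, v in report.cox_summaries.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(
        _manifest(config, {"outputs": sorted(p.name for p in out.iterdir())}),
        indent=2, sort_keys=True))
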