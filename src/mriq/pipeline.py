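"""End-to-end orchestration: generate/ingest -> measure -> summarize -> infer.

``run_pipeline`` drives the whole analysis over either a generated
phantom cohort (simulate mode) or on-disk NIfTI volumes with a manifest
and ROI-centre table, and writes a run directory of tidy CSV/JSON
results plus synthetic-data analogues of the study's figures.  Every
stochastic step takes the run seed; re-running with the same inputs and
seed reproduces the metrics table byte for byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

import mriq
from mriq import io as mio
from mriq import metrics as mmetrics
from mriq import phantoms as mphantoms
from mriq import stats as mstats
from mriq.io import REGIONS

__all__ = [
    "AGE_GROUP_BOUNDS",
    "AgeGroup",
    "PipelineError",
    "assign_age_group",
    "metrics_wide",
    "reliability_resample_run",
    "run_pipeline",
    "summarize_by_database",
]

#: closed-interval age bins used for grouped visual summaries only;
#: continuous-age models always use the raw ages
AGE_GROUP_BOUNDS: dict[str, tuple[float, float]] = {
    "young": (18.0, 28.0),
    "middle": (34.0, 53.0),
    "elderly": (63.0, 86.0),
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class AgeGroup:
    label: str

    def __post_init__(self) -> None:
        if self.label not in (*AGE_GROUP_BOUNDS, "unbinned"):
            raise ValueError(f"unknown age group label {self.label!r}")


def assign_age_group(age: float) -> AgeGroup:
    """Bin an age into young / middle / elderly by closed intervals.

    Ages in the gaps (29-33, 54-62) or outside [18, 86] are 'unbinned':
    they stay in continuous-age models but never in grouped summaries.
    """
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age}")
    for label, (lo, hi) in AGE_GROUP_BOUNDS.items():
        if lo <= age <= hi:
            return AgeGroup(label)
    return AgeGroup("unbinned")


def summarize_by_database(metrics: pd.DataFrame, value: str = "snr_normalized") -> pd.DataFrame:
    """Per-database mean +/- SEM tables, ordered ascending by CC SNR.

    One row per (database, contrast, quantity) where quantity is the
    per-region SNR or the CNR; SEM is sd/sqrt(n) with the sample SD,
    reported as 0 when n = 1 (the n column flags those rows).
    Ordering is ascending by the database's mean CC value within each
    contrast, ties broken lexicographically by database label.
    """
    frames = []
    snr = metrics[metrics["region"].isin([*REGIONS, "CN_pooled"])]
    g = snr.groupby(["database", "contrast", "region"], sort=True)[value]
    agg = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    agg = agg.rename(columns={"region": "quantity"})
    frames.append(agg)
    pooled = metrics[metrics["region"] == "CN_pooled"]
    if not pooled.empty:
        gc = pooled.groupby(["database", "contrast"], sort=True)["cnr_normalized"]
        aggc = gc.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
        aggc["quantity"] = "CNR"
        frames.append(aggc)
    out = pd.concat(frames, ignore_index=True)
    out["sem"] = np.where(out["n"] > 1, out["sd"].fillna(0.0) / np.sqrt(out["n"]), 0.0)
    out = out.drop(columns=["sd"])
    order = (
        out[out["quantity"] == "CC"]
        .set_index(["contrast", "database"])["mean"]
        .rename("cc_order")
    )
    out = out.join(order, on=["contrast", "database"])
    out = out.sort_values(
        by=["contrast", "cc_order", "database", "quantity"], kind="mergesort"
    ).drop(columns=["cc_order"]).reset_index(drop=True)
    return out[["database", "contrast", "quantity", "mean", "sem", "n"]]


def metrics_wide(metrics: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per scan with snr_cc / snr_cn / cnr columns plus metadata."""
    key = ["database", "subject", "contrast", "acquisition"]
    cc = metrics[metrics["region"] == "CC"].set_index(key)["snr_normalized"].rename("snr_cc")
    cn = metrics[metrics["region"] == "CN_pooled"].set_index(key)["snr_normalized"].rename("snr_cn")
    cnr = metrics[metrics["region"] == "CN_pooled"].set_index(key)["cnr_normalized"].rename("cnr")
    wide = pd.concat([cc, cn, cnr], axis=1).reset_index()
    return wide.merge(manifest, on=key, how="left", validate="one_to_one")


def _age_for_grouping(row: pd.Series) -> float:
    if not np.isnan(row["age"]):
        return float(row["age"])
    if not np.isnan(row["age_min"]) and not np.isnan(row["age_max"]):
        return 0.5 * (float(row["age_min"]) + float(row["age_max"]))
    return np.nan


def _summarize_by_age_group(wide: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, row in wide.iterrows():
        age = _age_for_grouping(row)
        if np.isnan(age):
            continue
        group = assign_age_group(age).label
        if group == "unbinned":
            continue
        for quantity in ("snr_cc", "snr_cn", "cnr"):
            rows.append({"age_group": group, "contrast": row["contrast"],
                         "quantity": quantity, "value": row[quantity]})
    if not rows:
        return pd.DataFrame(columns=["age_group", "contrast", "quantity", "mean", "sem", "n"])
    df = pd.DataFrame(rows)
    g = df.groupby(["age_group", "contrast", "quantity"], sort=True)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = np.where(out["n"] > 1, out["sd"].fillna(0.0) / np.sqrt(out["n"]), 0.0)
    return out.drop(columns=["sd"])


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    return obj


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _ttest_payload(res: mstats.TTestResult) -> dict:
    return {"t": res.t, "df": res.df, "p": res.p, "bf10": res.bf10,
            "n": res.n, "paired": res.paired, "evidence": res.evidence}


def run_pipeline(
    out_dir: str | Path,
    config: "mphantoms.PhantomConfig | None" = None,
    manifest_path: str | Path | None = None,
    roi_path: str | Path | None = None,
    simulate: bool = False,
    method: str = "contiguous",
    pooling: str = "mean",
    normalize_quantitative: bool = False,
    n_iter: int = 1000,
    seed: int = 0,
    make_plots: bool = True,
) -> Path:
    """Run the full analysis and write a run directory.

    Simulate mode generates a phantom cohort from ``config``; ingest
    mode reads volumes listed in a manifest plus an ROI-centre table.
    Outputs: ``metrics.csv``, per-database and per-age-group summaries,
    the bilateral caudate paired test, scan-time regressions, the
    age-model comparisons (with interval-age resampling when needed),
    slab-vs-whole-brain tests when both acquisitions exist, a run log,
    and figure analogues under ``figures/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("ingest"):
        if simulate:
            if config is None:
                raise ValueError("simulate mode requires a PhantomConfig")
            cohort = mphantoms.generate_cohort(config)
            scans = list(cohort.scans())
            records = cohort.records
        else:
            if manifest_path is None or roi_path is None:
                raise ValueError("ingest mode requires manifest_path and roi_path")
            records = mio.read_manifest(manifest_path)
            centers = mio.read_roi_centers(roi_path)
            scans = []
            for rec in records:
                if rec.path is None:
                    raise ValueError(f"scan {rec.key} has no volume path in the manifest")
                grid = mio.check_voxel_agreement(rec, mio.read_volume(rec.path))
                if rec.key not in centers:
                    raise ValueError(f"scan {rec.key} has no ROI centres")
                scans.append((rec, grid, centers[rec.key]))

    with _stage("measure"):
        reference = None
        if method == "volume_matched":
            reference = tuple(
                float(max(r.voxel_mm[axis] for r, _, _ in scans)) for axis in range(3)
            )
        metrics = mmetrics.measure_cohort(
            scans, method=method, reference_voxel_mm=reference,
            pooling=pooling, normalize_quantitative=normalize_quantitative,
        )
        metrics.to_csv(out / "metrics.csv", index=False)

    with _stage("summarize"):
        manifest_df = mio.manifest_to_frame(records)
        wide = metrics_wide(metrics, manifest_df)
        wb = wide[wide["acquisition"] == "wholebrain"]
        summary = summarize_by_database(metrics[metrics["acquisition"] == "wholebrain"])
        summary.to_csv(out / "summary_by_database.csv", index=False)
        age_summary = _summarize_by_age_group(wb)
        age_summary.to_csv(out / "summary_by_age_group.csv", index=False)

    results: dict = {"seed": seed, "method": method}

    with _stage("bilateral_cn_test"):
        # paired at the database-mean level, as the aggregation unit
        per_db = (
            metrics[(metrics["acquisition"] == "wholebrain") & metrics["region"].isin(["LCN", "RCN"])]
            .groupby(["database", "region"], sort=True)["snr_normalized"].mean().unstack("region")
        )
        if len(per_db) >= 2:
            res = mstats.paired_ttest(per_db["LCN"].to_numpy(), per_db["RCN"].to_numpy())
            results["lcn_vs_rcn"] = _ttest_payload(res)
            _write_json(results["lcn_vs_rcn"], out / "ttest_lcn_rcn.json")

    with _stage("scan_time_regressions"):
        per_db_cc = (
            wb.groupby("database", sort=True)
            .agg(snr_cc=("snr_cc", "mean"), voxel_volume_mm3=("voxel_volume_mm3", "mean"),
                 scan_time_s=("scan_time_s", "mean"), field_strength_t=("field_strength_t", "mean"))
            .reset_index()
        )
        reg_rows = []
        for response in ("snr_cc", "voxel_volume_mm3"):
            strata = {"pooled": per_db_cc}
            for fs in sorted(per_db_cc["field_strength_t"].dropna().unique()):
                strata[f"{fs:g}T"] = per_db_cc[per_db_cc["field_strength_t"] == fs]
            for label, sub in strata.items():
                try:
                    r = mstats.scan_time_regression(sub, response=response)
                except mstats.StatsError:
                    continue
                reg_rows.append({"response": response, "stratum": label, **vars(r)})
        if reg_rows:
            pd.DataFrame(reg_rows).to_csv(out / "scan_time_regressions.csv", index=False)

    with _stage("age_models"):
        lmm_results: dict = {}
        for contrast in sorted(wb["contrast"].unique()):
            sub = wb[wb["contrast"] == contrast]
            has_interval = (sub["age"].isna() & sub["age_min"].notna()).any()
            for response in ("snr_cc", "snr_cn", "cnr"):
                tag = f"{contrast}:{response}"
                try:
                    if has_interval:
                        summary_r = mstats.resample_age_analysis(
                            sub, response=response, n_iter=n_iter, seed=seed
                        )
                        lmm_results[tag] = {
                            "kind": "resampled", "n_iter": summary_r.n_iter,
                            "mean_p": summary_r.mean_p, "mean_bf": summary_r.mean_bf,
                            "mean_slope": float(np.mean(summary_r.slopes)),
                        }
                    else:
                        comp = mstats.fit_lmm_age(sub, response=response)
                        lmm_results[tag] = {"kind": "single", **_jsonable(comp)}
                except mstats.StatsError as exc:
                    lmm_results[tag] = {"kind": "skipped", "reason": str(exc)}
        _write_json(lmm_results, out / "lmm_age_comparisons.json")
        results["age_models"] = lmm_results

    with _stage("slab_vs_wholebrain"):
        if (wide["acquisition"] == "slab").any():
            slab_results = {}
            for response in ("snr_cc", "cnr"):
                piv = wide.pivot_table(
                    index=["database", "subject", "contrast"], columns="acquisition",
                    values=response, aggfunc="first",
                )
                if {"slab", "wholebrain"} <= set(piv.columns):
                    piv = piv.dropna()
                    pairs_s = {"/".join(k): v for k, v in piv["slab"].items()}
                    pairs_w = {"/".join(k): v for k, v in piv["wholebrain"].items()}
                    res = mstats.slab_vs_wholebrain_test(pairs_s, pairs_w)
                    slab_results[response] = _ttest_payload(res)
            if slab_results:
                _write_json(slab_results, out / "slab_vs_wholebrain.json")
                results["slab_vs_wholebrain"] = slab_results

    with _stage("log"):
        _write_json(
            {
                "package": "mriq", "version": mriq.__version__,
                "python": platform.python_version(),
                "numpy": np.__version__, "pandas": pd.__version__,
                "seed": seed, "method": method, "pooling": pooling,
                "n_iter": n_iter, "simulate": simulate,
                "n_scans": len(records), "n_metric_rows": len(metrics),
                "config": _jsonable(vars(config)) if config is not None else None,
            },
            out / "log.json",
        )

    if make_plots:
        with _stage("plots"):
            from mriq import plots as mplots

            fig_dir = out / "figures"
            fig_dir.mkdir(exist_ok=True)
            mplots.plot_database_summary(summary, fig_dir / "database_summary.png")
            reg_path = out / "scan_time_regressions.csv"
            if reg_path.exists():
                mplots.plot_scan_time(per_db_cc, fig_dir / "scan_time.png")
            if not age_summary.empty:
                mplots.plot_age_groups(age_summary, fig_dir / "age_groups.png")

    return out


def reliability_resample_run(
    config: "mphantoms.PhantomConfig",
    first_metrics: pd.DataFrame,
    extra_n: int | Mapping[int, int] = 5,
    seed: int = 0,
    subject_offset: int | None = None,
    method: str = "contiguous",
    contrast: str = "T1w",
) -> dict:
    """Draw a second, disjoint subject sample and test reproducibility.

    For each database with enough unused subjects in its pool, draws
    ``extra_n`` additional subjects (never overlapping the first
    sample), measures their volumes, and compares the second sample of
    normalized CC SNR, pooled-CN SNR and CNR against the first with a
    two-group Bayesian comparison.  BF10 < 1 supports the samples
    sharing one distribution.  Databases with too small a pool are
    skipped and listed.
    """
    offset = config.subjects_per_database if subject_offset is None else subject_offset
    first_keys = set(
        zip(first_metrics["database"], first_metrics["subject"])
    )

    def extra_for(d: int) -> int:
        if isinstance(extra_n, Mapping):
            return int(extra_n.get(d, 5))
        return int(extra_n)

    skipped: list[str] = []
    second_rows = []
    for d in range(config.n_databases):
        n_extra = extra_for(d)
        if offset + n_extra > config.database_size(d):
            skipped.append(config.database_label(d))
            continue
        for rec, grid, truth in mphantoms.iter_cohort(
            config, subject_offset=offset, subjects_per_database=n_extra, databases=(d,)
        ):
            if rec.contrast != contrast or rec.acquisition != "wholebrain":
                continue
            if (rec.database, rec.subject) in first_keys:
                raise PipelineError(
                    f"reliability sample overlaps the first sample at "
                    f"({rec.database}, {rec.subject}); samples must be disjoint"
                )
            second_rows.extend(
                mmetrics.measure_scan(grid, truth.centers, rec, method=method)
            )
    if not second_rows:
        raise PipelineError("no database had enough unused subjects for a second sample")
    second = pd.DataFrame([vars(r) for r in second_rows])

    first = first_metrics[
        (first_metrics["contrast"] == contrast) & (first_metrics["acquisition"] == "wholebrain")
    ]
    comparisons: dict[str, mstats.TTestResult] = {}
    for quantity, (region, col) in {
        "snr_cc": ("CC", "snr_normalized"),
        "snr_cn": ("CN_pooled", "snr_normalized"),
        "cnr": ("CN_pooled", "cnr_normalized"),
    }.items():
        a = first.loc[first["region"] == region, col].to_numpy()
        b = second.loc[second["region"] == region, col].to_numpy()
        comparisons[quantity] = mstats.reliability_bf_anova(a, b)
    return {
        "comparisons": comparisons,
        "second_metrics": second,
        "skipped_databases": skipped,
        "n_second_images": int(second[second["region"] == "CC"].shape[0]),
        "seed": seed,
    }
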