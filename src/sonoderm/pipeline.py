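"""End-to-end orchestration: feature extraction and the comparison stages.

Stages mirror a longitudinal treatment study: per-frame, per-layer feature
extraction; a paired Wilcoxon battery of every visit week against
baseline; a Mann-Whitney contrast of the final visit against an untreated
control arm; a Kruskal-Wallis/Dunn contrast across severity stages; and a
paired test of the clinical severity score (AKASI) before vs after
therapy.  Every stage emits a plain table; :func:`run_report` assembles a
deterministic machine-readable report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .layers import rasterize_mask, thickness_profile
from .morphology import surface_roughness, perimeter_area_ratio, area_convexhull_ratio
from .phantom import CohortBundle, load_fixture
from .stats import (
    InsufficientDataError,
    kruskal_dunn,
    mann_whitney,
    wilcoxon_signed_rank,
)
from .texture import extract_intensity_features

logger = logging.getLogger("sonoderm")

__all__ = [
    "FEATURE_COLUMNS",
    "BatchResult",
    "extract_features_batch",
    "longitudinal_compare",
    "control_compare",
    "stage_compare",
    "akasi_compare",
    "run_report",
    "validate_report",
]

_GLCM_NAMES = ("contrast", "correlation", "energy", "homogeneity")
_GLCM_DIRS = ("d0", "d45", "d90", "d135")

#: Fixed feature-column order of the FeatureRecord table.
FEATURE_COLUMNS = (
    ["thickness_mm", "tvi_mm", "sr_px", "par_per_px", "acr"]
    + ["lep_ratio", "mep_ratio", "hep_ratio", "mpi", "piv", "epi"]
    + [f"glcm_{f}_{d}" for f in _GLCM_NAMES for d in _GLCM_DIRS]
    + [f"glcm_{f}_mean" for f in _GLCM_NAMES]
)

_ID_COLUMNS = ["marker_id", "week", "layer", "arm", "stage", "frame_id"]


@dataclass
class BatchResult:
    """Feature table plus the processing log of one extraction batch."""

    table: pd.DataFrame
    log: dict = field(default_factory=dict)


def extract_layer_features(frame, ann) -> dict:
    """All per-layer features for one (frame, annotation)."""
    prof = thickness_profile(ann, frame)
    mask = rasterize_mask(ann, frame)
    row = dict(
        thickness_mm=prof.mean_mm,
        tvi_mm=prof.sd_mm,
        sr_px=surface_roughness(ann),
        par_per_px=perimeter_area_ratio(mask),
        acr=area_convexhull_ratio(mask),
    )
    feats = extract_intensity_features(frame.pixels, mask)
    row.update(
        lep_ratio=feats.lep_ratio,
        mep_ratio=feats.mep_ratio,
        hep_ratio=feats.hep_ratio,
        mpi=feats.mpi,
        piv=feats.piv,
        epi=feats.epi,
    )
    for f in _GLCM_NAMES:
        for d in _GLCM_DIRS:
            g = feats.glcm.get(d)
            row[f"glcm_{f}_{d}"] = getattr(g, f) if g is not None else float("nan")
        row[f"glcm_{f}_mean"] = feats.glcm_mean(f)
    return row


def extract_features_batch(source: CohortBundle | str | Path) -> BatchResult:
    """One FeatureRecord per frame per annotated layer.

    ``source`` is an in-memory cohort bundle or a path to a fixture
    manifest.  A frame whose SLEB is absent yields no SLEB record.  Frames
    that fail to load or process are skipped and logged; the batch always
    completes.
    """
    if not isinstance(source, CohortBundle):
        source = load_fixture(source)
    rows = []
    failures = []
    n_layers = 0
    meta = source.table.set_index("frame_id")
    for fid in source.table["frame_id"]:
        try:
            frame = source.frames[fid]
            anns = source.annotations[fid]
            info = meta.loc[fid]
            for ann in anns:
                row = dict(
                    marker_id=info["marker_id"],
                    week=int(info["week"]),
                    layer=ann.layer_name,
                    arm=info["arm"],
                    stage=int(info["stage"]),
                    frame_id=fid,
                )
                row.update(extract_layer_features(frame, ann))
                rows.append(row)
                n_layers += 1
        except Exception as exc:  # robustness: one bad frame must not kill the batch
            failures.append(dict(frame_id=fid, reason=str(exc)))
            logger.warning("frame %s skipped: %s", fid, exc)
    table = pd.DataFrame(rows, columns=_ID_COLUMNS + FEATURE_COLUMNS)
    log = dict(
        n_frames=len(source.table),
        n_processed=len(source.table) - len(failures),
        n_layer_records=n_layers,
        failures=failures,
    )
    return BatchResult(table, log)


def _result_row(res, feature: str, layer: str, extra: dict | None = None) -> dict:
    row = dict(feature=feature, layer=layer)
    if extra:
        row.update(extra)
    row.update(
        n=getattr(res, "n_pairs", None) or (res.n_a + res.n_b),
        statistic=res.statistic,
        p_two_sided=res.p_two_sided,
        p_one_sided=res.p_one_sided,
        effect_r=res.effect_r,
        effect_grade=res.effect_grade,
        direction=res.direction,
        significant=res.p_one_sided is not None,
    )
    return row


def longitudinal_compare(
    features: pd.DataFrame,
    weeks: tuple = (4, 8, 12),
    alpha: float = 0.05,
    feature_columns: list | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Paired Wilcoxon battery of every follow-up week against baseline.

    Complete-case rule: only markers with a record at week 0 and at every
    requested week enter the battery (excluded markers are counted in the
    log).  Within each (feature, layer, week) cell, pairs additionally
    require the layer at both visits — an absent SLEB drops the marker
    from SLEB cells only.  Cells with fewer than 5 pairs are recorded as
    skipped rather than tested.
    """
    feature_columns = list(feature_columns or FEATURE_COLUMNS)
    treated = features[features["arm"] == "treated"]
    required = {0, *weeks}
    per_marker_weeks = treated.groupby("marker_id")["week"].agg(set)
    complete = per_marker_weeks[per_marker_weeks.map(lambda s: required <= s)].index
    excluded = sorted(set(per_marker_weeks.index) - set(complete))
    sub = treated[treated["marker_id"].isin(complete)]
    if complete.size < 5:
        raise InsufficientDataError(
            f"only {complete.size} markers with complete follow-up (need 5)"
        )
    dup = sub.duplicated(subset=["marker_id", "week", "layer"])
    if dup.any():
        raise ValueError("multiple records per (marker, week, layer); "
                         "one frame per marker per visit is required")
    rows, skipped = [], []
    for layer, layer_df in sub.groupby("layer"):
        wide = layer_df.pivot(index="marker_id", columns="week", values=feature_columns)
        for week in weeks:
            for feat in feature_columns:
                if (feat, 0) not in wide.columns or (feat, week) not in wide.columns:
                    continue
                pair = wide[[(feat, 0), (feat, week)]].dropna()
                extra = dict(week_pair=f"0-{week}")
                try:
                    res = wilcoxon_signed_rank(
                        pair[(feat, 0)].to_numpy(), pair[(feat, week)].to_numpy(), alpha
                    )
                except InsufficientDataError as exc:
                    skipped.append(dict(feature=feat, layer=layer, week_pair=f"0-{week}",
                                        reason=str(exc)))
                    continue
                rows.append(_result_row(res, feat, layer, extra))
    table = pd.DataFrame(rows)
    log = dict(
        n_markers_input=int(per_marker_weeks.index.size),
        n_markers_complete=int(complete.size),
        excluded_markers=excluded,
        skipped_cells=skipped,
    )
    return table, log


def control_compare(
    features_week12: pd.DataFrame,
    features_control: pd.DataFrame,
    alpha: float = 0.05,
    feature_columns: list | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Final-visit vs healthy-control contrast, per feature and layer.

    Mann-Whitney U with the two-stage directional gate.  Also reports the
    fraction of frames in each arm where an SLEB was annotated.
    """
    if features_week12.empty or features_control.empty:
        raise InsufficientDataError("both arms must be nonempty")
    feature_columns = list(feature_columns or FEATURE_COLUMNS)
    rows, skipped = [], []
    for layer in sorted(set(features_week12["layer"]) & set(features_control["layer"])):
        a_df = features_week12[features_week12["layer"] == layer]
        b_df = features_control[features_control["layer"] == layer]
        for feat in feature_columns:
            a = a_df[feat].dropna().to_numpy()
            b = b_df[feat].dropna().to_numpy()
            try:
                res = mann_whitney(a, b, alpha)
            except InsufficientDataError as exc:
                skipped.append(dict(feature=feat, layer=layer, reason=str(exc)))
                continue
            rows.append(_result_row(res, feat, layer))

    def sleb_presence(df: pd.DataFrame) -> float:
        frames = df["frame_id"].nunique()
        with_sleb = df.loc[df["layer"] == "sleb", "frame_id"].nunique()
        return with_sleb / frames if frames else float("nan")

    log = dict(
        sleb_presence_treated=sleb_presence(features_week12),
        sleb_presence_control=sleb_presence(features_control),
        skipped_cells=skipped,
    )
    return pd.DataFrame(rows), log


def stage_compare(
    features_week12: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "holm",
    feature_columns: list | None = None,
    low_n_threshold: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Severity-stage contrast of final-visit features (Kruskal-Wallis + Dunn).

    Stages with fewer than 2 markers are dropped per cell with a warning;
    stages below ``low_n_threshold`` are flagged low-n but kept.
    """
    stages = features_week12.groupby("marker_id")["stage"].first()
    stage_sizes = stages.value_counts().to_dict()
    if len(stage_sizes) < 2:
        raise InsufficientDataError("all markers belong to one stage")
    warns = [
        f"stage {s} has low n={n}" for s, n in sorted(stage_sizes.items())
        if n < low_n_threshold
    ]
    feature_columns = list(feature_columns or FEATURE_COLUMNS)
    rows, pairwise_rows, skipped = [], [], []
    for layer, layer_df in features_week12.groupby("layer"):
        for feat in feature_columns:
            groups = {
                s: g[feat].dropna().to_numpy()
                for s, g in layer_df.groupby("stage")
            }
            try:
                res = kruskal_dunn(groups, alpha, adjust)
            except InsufficientDataError as exc:
                skipped.append(dict(feature=feat, layer=layer, reason=str(exc)))
                continue
            rows.append(
                dict(feature=feat, layer=layer, h_statistic=res.h_statistic,
                     p_value=res.p_value, df=res.df,
                     omnibus_rejected=res.omnibus_rejected)
            )
            if res.pairwise is not None:
                pw = res.pairwise.copy()
                pw.insert(0, "feature", feat)
                pw.insert(1, "layer", layer)
                pairwise_rows.append(pw)
    pairwise = (
        pd.concat(pairwise_rows, ignore_index=True)
        if pairwise_rows
        else pd.DataFrame(columns=["feature", "layer", "group_a", "group_b",
                                   "z", "p_raw", "p_adj", "significant"])
    )
    log = dict(stage_sizes={int(k): int(v) for k, v in stage_sizes.items()},
               warnings=warns, skipped_cells=skipped)
    return pd.DataFrame(rows), {"pairwise": pairwise, **log}


def akasi_compare(visits: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Paired before/after test of the AKASI severity score.

    Uses patients with an AKASI value at week 0 and at the final visit.
    Reports medians, the median paired difference, the Wilcoxon result,
    the rank effect size and the fraction of patients reaching complete
    clearance (score 0).
    """
    treated = visits[visits["arm"] == "treated"].dropna(subset=["akasi"])
    last_week = int(treated["week"].max())
    wide = treated.pivot_table(index="patient_id", columns="week", values="akasi")
    wide = wide[[0, last_week]].dropna()
    n = len(wide)
    if n < 5:
        raise InsufficientDataError(f"only {n} patients with paired AKASI (need 5)")
    before = wide[0].to_numpy()
    after = wide[last_week].to_numpy()
    res = wilcoxon_signed_rank(before, after, alpha)
    return dict(
        n_patients=n,
        median_before=float(np.median(before)),
        median_after=float(np.median(after)),
        median_difference=float(np.median(before - after)),
        p_two_sided=res.p_two_sided,
        p_one_sided=res.p_one_sided,
        effect_r=res.effect_r,
        effect_grade=res.effect_grade,
        direction=res.direction,
        clearance_fraction=float((after == 0).mean()),
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

_REPORT_STAGES = ("extraction", "longitudinal", "control", "stage_wise", "akasi")


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        df = obj.copy()
        df.columns = [str(c) for c in df.columns]
        return json.loads(df.to_json(orient="records"))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    return obj


def run_report(stage_outputs: dict, config: dict | None = None, seed: int | None = None) -> tuple[dict, str]:
    """Assemble the run report: JSON-ready dict plus a text summary.

    ``stage_outputs`` maps stage name (extraction, longitudinal, control,
    stage_wise, akasi) to its output; stages that did not run must be
    passed as the string ``"skipped"`` and are marked so rather than
    omitted.  The JSON is deterministic: re-running on the same fixture
    reproduces it byte for byte.
    """
    ran = [s for s in _REPORT_STAGES if stage_outputs.get(s) not in (None, "skipped")]
    if not ran:
        raise ValueError("at least one stage must have run")
    report = {"config": _jsonable(config or {}), "seed": seed, "stages": {}}
    for name in _REPORT_STAGES:
        out = stage_outputs.get(name, "skipped")
        if out is None or (isinstance(out, str) and out == "skipped"):
            report["stages"][name] = {"status": "skipped"}
        else:
            report["stages"][name] = {"status": "ok", "output": _jsonable(out)}
    validate_report(report)
    lines = [f"sonoderm run report (seed={seed})"]
    for name in _REPORT_STAGES:
        st = report["stages"][name]
        lines.append(f"  {name}: {st['status']}")
        if name == "longitudinal" and st["status"] == "ok":
            results = st["output"].get("results", [])
            nsig = sum(1 for r in results if r.get("significant"))
            lines.append(f"    {nsig}/{len(results)} cells significant")
        if name == "akasi" and st["status"] == "ok":
            o = st["output"]
            lines.append(
                f"    median {o['median_before']:.2f} -> {o['median_after']:.2f}, "
                f"r={o['effect_r']:.3f} ({o['effect_grade']}), "
                f"clearance {o['clearance_fraction']:.0%}"
            )
    return report, "\n".join(lines)


def validate_report(report: dict) -> None:
    """Structural validation of a run report (keys, stage statuses)."""
    for key in ("config", "seed", "stages"):
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    for name in _REPORT_STAGES:
        if name not in report["stages"]:
            raise ValueError(f"report missing stage {name!r}")
        status = report["stages"][name].get("status")
        if status not in ("ok", "skipped"):
            raise ValueError(f"stage {name!r} has invalid status {status!r}")
        if status == "ok" and "output" not in report["stages"][name]:
            raise ValueError(f"stage {name!r} ok but has no output")


def report_json(report: dict) -> str:
    """Canonical byte-stable JSON serialization of a report."""
    return json.dumps(report, sort_keys=True, indent=1, allow_nan=False)


def run_all(cspec, alpha: float = 0.05, feature_columns: list | None = None) -> tuple[dict, str]:
    """Generate a cohort and run every analysis stage on it.

    Returns the (report dict, text summary) of :func:`run_report`.  The
    control and stage-wise stages are marked skipped when the cohort has
    no control arm or a single severity stage.
    """
    from .phantom import generate_cohort

    bundle = generate_cohort(cspec)
    batch = extract_features_batch(bundle)
    feats = batch.table
    weeks = tuple(w for w in cspec.visits if w != 0)
    long_table, long_log = longitudinal_compare(feats, weeks, alpha, feature_columns)
    last_week = max(cspec.visits)
    wk12 = feats[(feats["arm"] == "treated") & (feats["week"] == last_week)]
    ctrl = feats[feats["arm"] == "control"]
    outputs: dict = {
        "extraction": {"log": batch.log},
        "longitudinal": {"results": long_table, "log": long_log},
    }
    if ctrl.empty:
        outputs["control"] = "skipped"
    else:
        ctrl_table, ctrl_log = control_compare(wk12, ctrl, alpha, feature_columns)
        outputs["control"] = {"results": ctrl_table, "log": ctrl_log}
    if wk12.groupby("marker_id")["stage"].first().nunique() < 2:
        outputs["stage_wise"] = "skipped"
    else:
        st_table, st_log = stage_compare(wk12, alpha, feature_columns=feature_columns)
        outputs["stage_wise"] = {"results": st_table, "log": st_log}
    try:
        outputs["akasi"] = akasi_compare(bundle.table, alpha)
    except InsufficientDataError:
        outputs["akasi"] = "skipped"
    config = dict(alpha=alpha, n_markers=cspec.n_markers, visits=list(cspec.visits),
                  n_controls=cspec.n_controls)
    return run_report(outputs, config=config, seed=cspec.seed)
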