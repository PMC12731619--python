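"""Batch orchestration: manifest-driven quantification, locomotion and stats.

A run is described by a YAML config:

.. code-block:: yaml

    images:
      manifest: images.csv        # image_id, roi, mask_<signal>..., metadata
    signals:
      azot:  {probability_threshold: 0.1,  min_size_px: 17}
      tunel: {probability_threshold: 0.05, min_size_px: 17}
    colocalization:
      - [azot, tunel]
    coloc_mode: partial
    locomotion:
      manifest: flies.csv         # fly_id, path, metadata columns
      speed_threshold_mm_s: 2.7
    stats:
      family: [genotype, diet]    # columns that define a comparison family
      group_column: timepoint
      value_column: area_percent
      adjust: bonferroni
    output_dir: out

Manifest paths are resolved relative to the config file's directory.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .locomotion import LocomotionParams, Trajectory, activity_above_threshold
from .quantify import area_fraction, colocalize
from .segmentation import SegmentationParams, segment
from .stats import GroupData, dunn_posthoc, kruskal_wallis, median_ci

__all__ = [
    "RunConfig",
    "DEFAULT_SIGNAL_PARAMS",
    "load_config",
    "run_quantification",
    "run_locomotion",
    "run_stats",
    "significance_stars",
]

log = logging.getLogger("flyquant")

# per-signal defaults from the published workflow: red/azot prob 0.1 min 17,
# green TUNEL prob 0.05 min 17, green amyloid-beta antibody prob 0.05 min 18
DEFAULT_SIGNAL_PARAMS: dict[str, SegmentationParams] = {
    "azot": SegmentationParams(0.10, 17),
    "tunel": SegmentationParams(0.05, 17),
    "abeta42": SegmentationParams(0.05, 18),
}

_METADATA_COLS = ("genotype", "diet", "timepoint")


@dataclass
class RunConfig:
    base_dir: Path
    image_manifest: Path | None = None
    signals: dict[str, SegmentationParams] = field(default_factory=dict)
    coloc_pairs: list[tuple[str, str]] = field(default_factory=list)
    coloc_mode: str = "partial"
    trajectory_manifest: Path | None = None
    locomotion: LocomotionParams = field(default_factory=LocomotionParams)
    stats_family: list[str] = field(default_factory=list)
    stats_group_column: str = "timepoint"
    stats_value_column: str = "area_percent"
    stats_adjust: str = "bonferroni"
    output_dir: Path = Path("out")
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b in self.coloc_pairs:
            if a not in self.signals or b not in self.signals:
                raise ValueError(
                    f"colocalization pair ({a}, {b}) names unconfigured signals"
                )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    raw: dict[str, Any] = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    signals: dict[str, SegmentationParams] = {}
    for name, p in (raw.get("signals") or {}).items():
        if p is None:
            if name not in DEFAULT_SIGNAL_PARAMS:
                raise ValueError(f"no default parameters for signal {name!r}")
            signals[name] = DEFAULT_SIGNAL_PARAMS[name]
        else:
            signals[name] = SegmentationParams(
                probability_threshold=float(p["probability_threshold"]),
                min_size_px=int(p["min_size_px"]),
                connectivity=int(p.get("connectivity", 8)),  # type: ignore[arg-type]
                probability_mode=p.get("probability_mode", "pixel"),
            )

    images = raw.get("images") or {}
    loco = raw.get("locomotion") or {}
    stats_cfg = raw.get("stats") or {}
    loco_params = LocomotionParams(
        speed_threshold_mm_s=float(loco.get("speed_threshold_mm_s", 2.7)),
        immobility_window_s=float(loco.get("immobility_window_s", 60.0)),
        immobility_speed_eps_mm_s=float(loco.get("immobility_speed_eps_mm_s", 0.25)),
        assay_duration_s=float(loco.get("assay_duration_s", 300.0)),
    )
    cfg = RunConfig(
        base_dir=base,
        image_manifest=base / images["manifest"] if "manifest" in images else None,
        signals=signals,
        coloc_pairs=[tuple(p) for p in raw.get("colocalization") or []],
        coloc_mode=raw.get("coloc_mode", "partial"),
        trajectory_manifest=base / loco["manifest"] if "manifest" in loco else None,
        locomotion=loco_params,
        stats_family=list(stats_cfg.get("family", [])),
        stats_group_column=stats_cfg.get("group_column", "timepoint"),
        stats_value_column=stats_cfg.get("value_column", "area_percent"),
        stats_adjust=stats_cfg.get("adjust", "bonferroni"),
        output_dir=base / raw.get("output_dir", "out"),
        seed=int(raw.get("seed", 0)),
    )
    return cfg


def _metadata(row: pd.Series) -> dict[str, Any]:
    return {c: row[c] for c in _METADATA_COLS if c in row.index}


def run_quantification(config: RunConfig) -> tuple[pd.DataFrame, int]:
    """Segment and quantify every manifest image; returns (table, n_failed).

    One row per (image, signal) plus one per configured colocalization pair.
    Per-image failures are logged and counted but do not stop the run.
    """
    if config.image_manifest is None:
        raise ValueError("config has no image manifest")
    manifest = pd.read_csv(config.image_manifest)
    manifest = manifest.sort_values("image_id", kind="mergesort")
    base = config.image_manifest.parent
    rows: list[dict[str, Any]] = []
    n_failed = 0
    for _, mrow in manifest.iterrows():
        image_id = str(mrow["image_id"])
        try:
            roi_spec = fio.read_roi(base / mrow["roi"])
            maps = {}
            roi = None
            for name, params in config.signals.items():
                mask = fio.read_raster(
                    base / mrow[f"mask_{name}"], "probability", channel_name=name
                )
                if roi is None:
                    roi = fio.roi_to_mask(roi_spec, mask.shape)
                maps[name] = segment(mask, params)
            assert roi is not None
            for name, params in config.signals.items():
                q = area_fraction(maps[name], roi)
                rows.append(
                    {
                        "image_id": image_id,
                        "signal": name,
                        "partner_signal": "",
                        "roi_area_px": q.roi_area_px,
                        "signal_area_px": q.signal_area_px,
                        "area_percent": q.area_percent,
                        "overlap_area_px": "",
                        "overlap_percent": "",
                        "params_fingerprint": params.fingerprint(),
                        **_metadata(mrow),
                    }
                )
            for a, b in config.coloc_pairs:
                c = colocalize(maps[a], maps[b], roi, mode=config.coloc_mode)  # type: ignore[arg-type]
                rows.append(
                    {
                        "image_id": image_id,
                        "signal": a,
                        "partner_signal": b,
                        "roi_area_px": int(roi.sum()),
                        "signal_area_px": "",
                        "area_percent": c.overlap_percent_of_roi,
                        "overlap_area_px": c.overlap_area_px,
                        "overlap_percent": c.overlap_percent_of_roi,
                        "params_fingerprint": config.coloc_mode,
                        **_metadata(mrow),
                    }
                )
        except Exception:  # noqa: BLE001 - per-image isolation is deliberate
            n_failed += 1
            log.exception("quantification failed for image %s", image_id)
    columns = [
        "image_id", "signal", "partner_signal", "roi_area_px", "signal_area_px",
        "area_percent", "overlap_area_px", "overlap_percent", "params_fingerprint",
    ]
    extra = [c for c in _METADATA_COLS if rows and c in rows[0]]
    df = pd.DataFrame(rows, columns=columns + extra)
    df = df.sort_values(["image_id", "signal", "partner_signal"], kind="mergesort")
    return df.reset_index(drop=True), n_failed


def run_locomotion(config: RunConfig) -> tuple[pd.DataFrame, int]:
    """Per-fly activity metric with QC; excluded flies stay in the table."""
    if config.trajectory_manifest is None:
        raise ValueError("config has no trajectory manifest")
    manifest = pd.read_csv(config.trajectory_manifest)
    manifest = manifest.sort_values("fly_id", kind="mergesort")
    base = config.trajectory_manifest.parent
    rows: list[dict[str, Any]] = []
    n_failed = 0
    for _, mrow in manifest.iterrows():
        fly_id = str(mrow["fly_id"])
        try:
            table = fio.read_trajectory_table(base / mrow["path"])
            traj = Trajectory(
                t=table["t"].to_numpy(),
                x=table["x"].to_numpy(),
                y=table["y"].to_numpy(),
                fly_id=fly_id,
            )
            res = activity_above_threshold(traj, config.locomotion)
            rows.append(
                {
                    "fly_id": fly_id,
                    "time_above_s": res.time_above_s,
                    "fraction_above": res.fraction_above,
                    "total_time_s": res.total_time_s,
                    "excluded": res.excluded,
                    "exclusion_reason": res.exclusion_reason,
                    "speed_threshold_mm_s": config.locomotion.speed_threshold_mm_s,
                    **_metadata(mrow),
                }
            )
        except Exception:  # noqa: BLE001
            n_failed += 1
            log.exception("locomotion failed for fly %s", fly_id)
    columns = [
        "fly_id", "time_above_s", "fraction_above", "total_time_s",
        "excluded", "exclusion_reason", "speed_threshold_mm_s",
    ]
    extra = [c for c in _METADATA_COLS if rows and c in rows[0]]
    df = pd.DataFrame(rows, columns=columns + extra)
    return df.sort_values("fly_id", kind="mergesort").reset_index(drop=True), n_failed


def significance_stars(p: float) -> str:
    """Published significance levels: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def run_stats(config: RunConfig, table: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis + Dunn + median CIs per comparison family.

    Families are defined by ``stats_family`` columns; within each family,
    groups come from ``stats_group_column`` over ``stats_value_column``.
    Rows flagged ``excluded`` are dropped first. Families with fewer than two
    groups are skipped with a warning.
    """
    df = table.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    if "signal" in df.columns:
        # one family per signal/partner combination on top of the config family
        fam_cols = ["signal", "partner_signal"] + config.stats_family
    else:
        fam_cols = config.stats_family
    fam_cols = [c for c in fam_cols if c in df.columns]
    value_col = config.stats_value_column
    group_col = config.stats_group_column
    for col in (value_col, group_col):
        if col not in df.columns:
            raise ValueError(f"stats column {col!r} not in the input table")
    rows: list[dict[str, Any]] = []
    grouped = df.groupby(fam_cols, dropna=False, sort=True) if fam_cols else [((), df)]
    for fam_key, fam_df in grouped:
        if not isinstance(fam_key, tuple):
            fam_key = (fam_key,)
        family = "|".join(str(v) for v in fam_key) or "all"
        groups = {
            str(g): sub[value_col].astype(float).to_numpy()
            for g, sub in fam_df.groupby(group_col, sort=True)
            if len(sub) > 0
        }
        if len(groups) < 2:
            log.warning("family %s has < 2 groups; skipped", family)
            continue
        data = GroupData(groups=groups)
        try:
            kw = kruskal_wallis(data)
            dunn = dunn_posthoc(data, adjust=config.stats_adjust)  # type: ignore[arg-type]
        except ValueError as err:
            log.warning("family %s degenerate (%s); skipped", family, err)
            continue
        for gname, vals in groups.items():
            ci = median_ci(vals, 0.95)
            rows.append(
                {
                    "family": family, "comparison": "median_ci", "group_a": gname,
                    "group_b": "", "statistic": ci.median, "p_value": "",
                    "p_adjusted": "", "stars": "", "ci_lower": ci.lower,
                    "ci_upper": ci.upper, "achieved_coverage": ci.achieved_coverage,
                    "n": len(vals),
                }
            )
        rows.append(
            {
                "family": family, "comparison": "kruskal_wallis", "group_a": "",
                "group_b": "", "statistic": kw.H, "p_value": kw.p_value,
                "p_adjusted": "", "stars": significance_stars(kw.p_value),
                "ci_lower": "", "ci_upper": "", "achieved_coverage": "",
                "n": data.n_total,
            }
        )
        for r in dunn.table.itertuples(index=False):
            rows.append(
                {
                    "family": family, "comparison": f"dunn_{dunn.adjustment}",
                    "group_a": r.group_a, "group_b": r.group_b, "statistic": r.z,
                    "p_value": r.p_raw, "p_adjusted": r.p_adjusted,
                    "stars": significance_stars(r.p_adjusted), "ci_lower": "",
                    "ci_upper": "", "achieved_coverage": "", "n": data.n_total,
                }
            )
    columns = [
        "family", "comparison", "group_a", "group_b", "statistic", "p_value",
        "p_adjusted", "stars", "ci_lower", "ci_upper", "achieved_coverage", "n",
    ]
    return pd.DataFrame(rows, columns=columns)
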