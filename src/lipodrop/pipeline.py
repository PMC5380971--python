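"""End-to-end pipelines: still-image morphometry and time-lapse dynamics.

Both pipelines are deterministic given the same inputs and
configuration; every run writes the fully resolved configuration next
to its outputs so a run can be reproduced from its own sidecar.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io as ldio
from .clustering import (
    CARDINALITY_BUCKETS,
    DEFAULT_BIN_EDGES_UM2,
    DEFAULT_THRESHOLD_PX,
    clusters_per_100_lds,
    find_clusters,
    size_histogram,
)
from .dynamics import (
    ASSOCIATED,
    classify_pair,
    detect_dissociations,
    pair_state_series,
    score_marker,
    track_droplets,
)
from .foci import FociParams, assign_foci, detect_foci
from .io import DEFAULT_PIXEL_SIZE_UM, FieldImage, max_project, read_field
from .segmentation import (
    SegmentationParams,
    detect_droplets,
    droplets_to_labelmap,
    merge_fragmented,
    segment_cells,
    segment_nuclei,
)

log = logging.getLogger("lipodrop")

__all__ = [
    "PipelineConfig",
    "MorphometryResult",
    "DynamicsResult",
    "run_morphometry",
    "run_dynamics",
    "aggregate_groups",
    "DROPLET_COLUMNS",
    "CLUSTER_COLUMNS",
    "CELL_COLUMNS",
    "EVENT_COLUMNS",
    "PAIR_COLUMNS",
]

DROPLET_COLUMNS = (
    "field", "ld_id", "cell_id", "area_um2", "equivalent_diameter_um",
    "centroid_row", "centroid_col", "mean_intensity",
)
CLUSTER_COLUMNS = (
    "field", "cell_id", "cluster_id", "n_lds", "member_ids",
    "mean_area_um2", "sd_area_um2",
)
CELL_COLUMNS = (
    "field", "cell_id", "n_lds", "n_clusters", "frac_clustered",
    "rate_2", "rate_3", "rate_4", "rate_5", "rate_6plus",
    "mean_clustered_area_um2", "sd_clustered_area_um2",
)
EVENT_COLUMNS = (
    "track_i", "track_j", "t_event_s", "run_end_s", "site_row", "site_col",
    "marker_positive", "marker_timing",
)
PAIR_COLUMNS = ("track_i", "track_j", "label", "truncated")
FOCUS_COLUMNS = (
    "focus_id", "z", "row", "col", "peak_intensity", "assigned_ld_ids",
    "at_contact_site",
)


@dataclass
class PipelineConfig:
    """Fully resolved configuration of one pipeline run.

    Round-trips losslessly through YAML (`to_yaml` / `from_yaml`).
    """

    inputs: list[str] = field(default_factory=list)
    output_dir: str = "lipodrop_out"
    channels: list[str] = field(default_factory=lambda: ["nuclei", "cytoplasm", "ld"])
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float | None = None
    frame_interval_s: float = 2.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    cluster_threshold_px: float = DEFAULT_THRESHOLD_PX
    bin_edges_um2: list[float] = field(
        default_factory=lambda: [float(e) for e in DEFAULT_BIN_EDGES_UM2]
    )
    foci: FociParams = field(default_factory=FociParams)
    # dynamics
    window_s: float = 300.0
    persistence_frames: int = 3
    max_displacement_um: float = 0.8
    max_missing: int = 2
    roi_radius_um: float = 0.3
    pre_window_frames: int = 5
    #: None = score when a marker channel is present; True = required
    score_marker_channel: bool | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_edges_um2"] = [
            "inf" if np.isinf(e) else float(e) for e in d["bin_edges_um2"]
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            seg = dict(d["segmentation"])
            for key in ("nucleus_diameter_px", "atrous_levels_small", "atrous_levels_large"):
                if key in seg and isinstance(seg[key], list):
                    seg[key] = tuple(seg[key])
            d["segmentation"] = SegmentationParams(**seg)
        if "foci" in d and isinstance(d["foci"], dict):
            d["foci"] = FociParams(**d["foci"])
        if "bin_edges_um2" in d:
            d["bin_edges_um2"] = [
                np.inf if e in ("inf", ".inf", None) else float(e)
                for e in d["bin_edges_um2"]
            ]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class MorphometryResult:
    droplets: pd.DataFrame
    clusters: pd.DataFrame
    cells: pd.DataFrame
    histogram: pd.DataFrame | None
    label_maps: dict[str, dict[str, np.ndarray]]


@dataclass
class DynamicsResult:
    pairs: pd.DataFrame
    events: pd.DataFrame
    summary: dict[str, float]


# ---------------------------------------------------------------------------
# still-image morphometry
# ---------------------------------------------------------------------------

def run_morphometry(config: PipelineConfig, write: bool = True) -> MorphometryResult:
    """Run the full hierarchy on every input field and write the tables.

    read → (max projection) → nuclei → cells → droplet detection →
    fragment merging → clusters → per-cell statistics → CSV/label maps.
    """
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    droplet_rows: list[dict] = []
    cluster_rows: list[dict] = []
    cell_rows: list[dict] = []
    label_maps: dict[str, dict[str, np.ndarray]] = {}
    all_droplets = []

    for path in config.inputs:
        name = Path(path).stem
        try:
            fi = read_field(
                path, config.channels, config.pixel_size_um, config.z_step_um
            )
        except ldio.FieldImageError as exc:
            raise RuntimeError(f"stage read: cannot process {path}: {exc}") from exc
        result = analyze_field(fi, config, name)
        droplet_rows.extend(result["droplet_rows"])
        cluster_rows.extend(result["cluster_rows"])
        cell_rows.extend(result["cell_rows"])
        label_maps[name] = result["labels"]
        all_droplets.extend(result["droplets"])
        log.info(
            "field %s: %d nuclei, %d cells, %d droplets, %d clusters",
            name,
            result["labels"]["nuclei"].max(),
            result["labels"]["cells"].max(),
            len(result["droplets"]),
            len(result["cluster_rows"]),
        )

    droplets_df = pd.DataFrame(droplet_rows, columns=DROPLET_COLUMNS)
    clusters_df = pd.DataFrame(cluster_rows, columns=CLUSTER_COLUMNS)
    cells_df = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)
    hist = (
        size_histogram(all_droplets, config.bin_edges_um2) if all_droplets else None
    )

    if write:
        ldio.write_measurements(droplets_df, out / "droplets.csv", DROPLET_COLUMNS)
        ldio.write_measurements(clusters_df, out / "clusters.csv", CLUSTER_COLUMNS)
        ldio.write_measurements(cells_df, out / "cells.csv", CELL_COLUMNS)
        if hist is not None:
            hist.to_csv(out / "size_histogram.csv")
        for name, maps in label_maps.items():
            for kind, arr in maps.items():
                ldio.write_labels(arr, out / f"{name}_{kind}.tif")
        config.to_yaml(out / "resolved_config.yaml")
    return MorphometryResult(droplets_df, clusters_df, cells_df, hist, label_maps)


def analyze_field(fi: FieldImage, config: PipelineConfig, name: str = "field") -> dict:
    """Morphometry of a single field; returns rows, records and label maps."""
    params = config.segmentation
    chans = {c: max_project(fi.channels[c]) for c in config.channels}
    nuclei = segment_nuclei(np.asarray(chans["nuclei"], dtype=float), params)
    cells = segment_cells(np.asarray(chans["cytoplasm"], dtype=float), nuclei, params)
    ld = chans["ld"]
    droplets = detect_droplets(ld, cells, params, fi.pixel_size_um)
    droplets = merge_fragmented(droplets, ld, params, fi.pixel_size_um)
    clusters = find_clusters(droplets, config.cluster_threshold_px)

    droplet_rows = [
        {
            "field": name,
            "ld_id": d.id,
            "cell_id": d.cell_id if d.cell_id is not None else pd.NA,
            "area_um2": d.area_um2,
            "equivalent_diameter_um": d.equivalent_diameter_um,
            "centroid_row": d.centroid[0],
            "centroid_col": d.centroid[1],
            "mean_intensity": d.mean_intensity,
        }
        for d in droplets
    ]
    cluster_rows = [
        {
            "field": name,
            "cell_id": c.cell_id,
            "cluster_id": k,
            "n_lds": c.n_lds,
            "member_ids": ";".join(str(m) for m in sorted(c.member_ids)),
            "mean_area_um2": c.mean_area_um2,
            "sd_area_um2": c.sd_area_um2,
        }
        for k, c in enumerate(clusters, start=1)
    ]
    cell_rows = []
    for cell_id in range(1, int(cells.max()) + 1):
        cell_droplets = [d for d in droplets if d.cell_id == cell_id]
        cell_clusters = [c for c in clusters if c.cell_id == cell_id]
        rates = clusters_per_100_lds(cell_droplets, cell_clusters)
        clustered_ids = set().union(*[c.member_ids for c in cell_clusters]) if cell_clusters else set()
        clustered_areas = [d.area_um2 for d in cell_droplets if d.id in clustered_ids]
        row = {
            "field": name,
            "cell_id": cell_id,
            "n_lds": len(cell_droplets),
            "n_clusters": len(cell_clusters),
            "frac_clustered": (
                len(clustered_ids) / len(cell_droplets) if cell_droplets else pd.NA
            ),
            "mean_clustered_area_um2": (
                float(np.mean(clustered_areas)) if clustered_areas else pd.NA
            ),
            "sd_clustered_area_um2": (
                float(np.std(clustered_areas, ddof=1)) if len(clustered_areas) > 1 else pd.NA
            ),
        }
        for k in CARDINALITY_BUCKETS:
            key = f"rate_{k}" if isinstance(k, int) else "rate_6plus"
            row[key] = rates[k] if rates is not None else pd.NA
        cell_rows.append(row)

    return {
        "droplet_rows": droplet_rows,
        "cluster_rows": cluster_rows,
        "cell_rows": cell_rows,
        "droplets": droplets,
        "labels": {
            "nuclei": nuclei,
            "cells": cells,
            "droplets": droplets_to_labelmap(droplets, ld.shape),
        },
    }


# ---------------------------------------------------------------------------
# time-lapse dynamics
# ---------------------------------------------------------------------------

def run_dynamics(
    config: PipelineConfig,
    ld_frames: np.ndarray | None = None,
    marker_frames: np.ndarray | None = None,
    write: bool = True,
) -> DynamicsResult:
    """Track droplets over a movie, classify pairs and score events.

    Frames may be passed directly or read from ``config.inputs`` (first
    path = LD movie, optional second = registered marker movie, both
    (T, H, W) TIFFs).
    """
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    if ld_frames is None:
        if not config.inputs:
            raise RuntimeError("stage read: no time-lapse input configured")
        ld_frames = ldio.read_stack(config.inputs[0])
        if len(config.inputs) > 1:
            marker_frames = ldio.read_stack(config.inputs[1])
    ld_frames = np.asarray(ld_frames)
    if ld_frames.ndim != 3:
        raise RuntimeError("stage read: time-lapse input must be a (T, H, W) stack")
    if config.score_marker_channel is True and marker_frames is None:
        raise RuntimeError(
            "stage read: marker scoring requested but no marker channel provided"
        )
    score = config.score_marker_channel is not False and marker_frames is not None
    if score and np.asarray(marker_frames).shape != ld_frames.shape:
        raise RuntimeError(
            "stage read: marker channel is not registered with the LD channel"
        )

    params = config.segmentation
    per_frame = [
        detect_droplets(ld_frames[t], None, params, config.pixel_size_um)
        for t in range(ld_frames.shape[0])
    ]
    log.info("dynamics: %d frames, mean %.1f droplets/frame",
             len(per_frame), float(np.mean([len(f) for f in per_frame])))
    tracks = track_droplets(
        per_frame, config.max_displacement_um, config.max_missing, config.pixel_size_um
    )
    series = pair_state_series(tracks, config.cluster_threshold_px)
    lut = {t.id: t for t in tracks}

    pair_rows = []
    for s in series:
        if s.states[0] != ASSOCIATED:
            continue
        c = classify_pair(s, config.window_s, config.frame_interval_s)
        pair_rows.append(
            {
                "track_i": s.pair[0],
                "track_j": s.pair[1],
                "label": c.label,
                "truncated": c.truncated,
            }
        )
    events = detect_dissociations(series, config.persistence_frames, lut)
    summary: dict[str, float] = {
        "n_pairs": float(len(pair_rows)),
        "static_fraction": (
            float(np.mean([r["label"] == "static" for r in pair_rows]))
            if pair_rows
            else float("nan")
        ),
        "n_events": float(len(events)),
    }
    if score:
        events, marker_summary = score_marker(
            events,
            marker_frames,
            config.roi_radius_um,
            config.pre_window_frames,
            config.pixel_size_um,
            ld_frames.shape[-2:],
        )
        summary.update(marker_summary)

    dt = config.frame_interval_s
    event_rows = [
        {
            "track_i": e.pair[0],
            "track_j": e.pair[1],
            "t_event_s": e.t_event * dt,
            "run_end_s": e.run_end * dt,
            "site_row": e.site[0],
            "site_col": e.site[1],
            "marker_positive": e.marker_positive,
            "marker_timing": e.marker_timing,
        }
        for e in events
    ]
    pairs_df = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
    events_df = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    if write:
        ldio.write_measurements(pairs_df, out / "pairs.csv", PAIR_COLUMNS)
        ldio.write_measurements(events_df, out / "events.csv", EVENT_COLUMNS)
        config.to_yaml(out / "resolved_config.yaml")
    return DynamicsResult(pairs_df, events_df, summary)


# ---------------------------------------------------------------------------
# foci counting
# ---------------------------------------------------------------------------

def run_foci(
    config: PipelineConfig,
    marker_stack: np.ndarray,
    droplets,
    write: bool = True,
) -> pd.DataFrame:
    """Count marker patches against an existing droplet segmentation."""
    foci = detect_foci(
        marker_stack, config.foci, config.pixel_size_um, config.z_step_um or 0.25
    )
    assigned, per_ld, per_pair = assign_foci(
        foci, droplets, config.foci, config.cluster_threshold_px, config.pixel_size_um
    )
    rows = [
        {
            "focus_id": f.id,
            "z": f.position[0],
            "row": f.position[1],
            "col": f.position[2],
            "peak_intensity": f.peak_intensity,
            "assigned_ld_ids": ";".join(str(i) for i in f.assigned_ld_ids),
            "at_contact_site": f.at_contact_site,
        }
        for f in assigned
    ]
    df = pd.DataFrame(rows, columns=FOCUS_COLUMNS)
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        ldio.write_measurements(df, out / "foci.csv", FOCUS_COLUMNS)
        per_ld_df = pd.DataFrame(
            sorted(per_ld.items()), columns=["ld_id", "n_patches"]
        )
        ldio.write_measurements(per_ld_df, out / "foci_per_ld.csv", ("ld_id", "n_patches"))
        per_pair_df = pd.DataFrame(
            [(a, b, n) for (a, b), n in sorted(per_pair.items())],
            columns=["ld_i", "ld_j", "n_patches"],
        )
        ldio.write_measurements(
            per_pair_df, out / "foci_per_contact.csv", ("ld_i", "ld_j", "n_patches")
        )
    return df


# ---------------------------------------------------------------------------
# group aggregation
# ---------------------------------------------------------------------------

def aggregate_groups(
    cells: pd.DataFrame,
    group_col: str = "group",
    value_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group mean ± s.e.m. over cells, with a two-tailed Welch t-test
    between the first two groups as a convenience summary."""
    if value_cols is None:
        value_cols = [
            c
            for c in cells.columns
            if c not in (group_col, "field", "cell_id")
            and pd.api.types.is_numeric_dtype(cells[c])
        ]
    groups = list(dict.fromkeys(cells[group_col]))
    rows = []
    for col in value_cols:
        row: dict = {"measure": col}
        series = {}
        for g in groups:
            vals = pd.to_numeric(cells.loc[cells[group_col] == g, col], errors="coerce").dropna()
            series[g] = vals
            row[f"{g}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{g}_sem"] = vals.sem() if len(vals) > 1 else np.nan
            row[f"{g}_n"] = len(vals)
        if len(groups) >= 2:
            a, b = series[groups[0]], series[groups[1]]
            if len(a) > 1 and len(b) > 1:
                row["t_pvalue"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            else:
                row["t_pvalue"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
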