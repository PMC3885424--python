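"""End-to-end orchestration of the telemetry analysis stages.

``run_pipeline`` reads every input named in the run configuration, executes
residency -> diel -> network -> Argos filtering -> track correction -> KUD
in order, and writes one CSV per stage plus a per-shark report table and a
run manifest.  Every stage is deterministic given the config; failures abort
with the stage name in the error message.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import io as tio
from .argosfilter import filter_positions, kept_positions
from .diel import diel_chi_square, diel_split, format_p
from .io import RunConfig
from .kud import activity_volumes, project_points
from .network import build_visits, max_linear_distance, transitions
from .residency import summary_table
from .tracks import bathymetric_correct, corrected_track, depth_temp_summary, \
    displacement_from_release

log = logging.getLogger("tigertrack")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelinePaths:
    detections: Path
    receivers: Path
    tags: Path
    argos: Optional[Path] = None
    depth_series: Optional[Path] = None
    track: Optional[Path] = None
    bathymetry: Optional[Path] = None


def _require(path: Optional[Path], stage: str, what: str) -> Path:
    if path is None or not Path(path).exists():
        raise StageError(f"stage '{stage}': required input '{what}' "
                         f"missing ({path})")
    return Path(path)


def run_pipeline(paths: PipelinePaths, config: RunConfig, out_dir) -> dict:
    """Run every applicable stage; returns the report bundle as a dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # ------------------------------------------------------------ residency
    det_path = _require(paths.detections, "residency", "detections")
    rec_path = _require(paths.receivers, "residency", "receivers")
    tag_path = _require(paths.tags, "residency", "tags")
    detections, det_rep = tio.read_detections(det_path)
    receivers, rec_rep = tio.read_receivers(rec_path)
    tags, tag_rep = tio.read_tags(tag_path)
    if not receivers:
        raise StageError("stage 'residency': no valid receivers")
    summary = summary_table(detections, tags, receivers,
                            ri_threshold=config.ri_threshold,
                            gap_days=config.gap_days)
    summary.to_csv(out_dir / "residency_summary.csv", index=False)
    bundle["residency"] = summary

    # ----------------------------------------------------------------- diel
    diel_rows = []
    for tag in tags:
        counts = diel_split(detections, config.utc_offset_hours,
                            tag_id=tag.tag_id)
        if counts.total == 0:
            continue
        stat, p = diel_chi_square(counts)
        diel_rows.append({"tag_id": tag.tag_id, "day": counts.day_count,
                          "night": counts.night_count,
                          "chi_square": stat, "p_value": p, "p": format_p(p)})
    diel_df = pd.DataFrame(diel_rows, columns=["tag_id", "day", "night",
                                               "chi_square", "p_value", "p"])
    diel_df.to_csv(out_dir / "diel.csv", index=False)
    bundle["diel"] = diel_df

    # -------------------------------------------------------------- network
    visits = build_visits(detections, gap_threshold_min=config.visit_gap_min)
    net_rows, edge_rows = [], []
    for tag in tags:
        mine_v = [v for v in visits if v.tag_id == tag.tag_id]
        t = transitions(mine_v, receivers)
        mine_d = [d for d in detections if d.tag_id == tag.tag_id]
        try:
            dist = max_linear_distance(mine_d, receivers,
                                       (tag.release_lon, tag.release_lat))
        except KeyError as exc:
            raise StageError(f"stage 'network': {exc}") from exc
        mean_visit = (float(np.mean([v.duration_min for v in mine_v]))
                      if mine_v else np.nan)
        net_rows.append({"tag_id": tag.tag_id, "n_visits": len(mine_v),
                         "mean_visit_min": mean_visit,
                         "max_linear_distance_km": dist})
        for (a, b), n in sorted(t.edges.items()):
            edge_rows.append({"tag_id": tag.tag_id, "from": a, "to": b,
                              "count": n})
    pd.DataFrame(net_rows).to_csv(out_dir / "network_summary.csv", index=False)
    pd.DataFrame(edge_rows, columns=["tag_id", "from", "to", "count"]
                 ).to_csv(out_dir / "network_edges.csv", index=False)
    bundle["network"] = pd.DataFrame(net_rows)

    # --------------------------------------------------------- argos filter
    if paths.argos is not None:
        argos, _ = tio.read_argos(_require(paths.argos, "filter-argos", "argos"))
        rec_by_id = {r.receiver_id: r for r in receivers}
        rows = []
        for tag in tags:
            mine = [p for p in argos if p.tag_id == tag.tag_id]
            if not mine:
                continue
            anchors = [(tag.release_time, tag.release_lon, tag.release_lat)]
            for d in detections:
                if d.tag_id == tag.tag_id and d.receiver_id in rec_by_id:
                    r = rec_by_id[d.receiver_id]
                    anchors.append((d.timestamp, r.lon, r.lat))
            decisions = filter_positions(mine, anchors,
                                         vmax_kmh=config.vmax_kmh)
            for dec in decisions:
                rows.append({"tag_id": tag.tag_id,
                             "timestamp": dec.position.timestamp.isoformat(),
                             "loc_class": dec.position.loc_class,
                             "lon": dec.position.lon, "lat": dec.position.lat,
                             "kept": dec.kept, "reason": dec.reason})
        filt_df = pd.DataFrame(rows, columns=["tag_id", "timestamp", "loc_class",
                                              "lon", "lat", "kept", "reason"])
        filt_df.to_csv(out_dir / "argos_filtered.csv", index=False)
        bundle["argos_filter"] = filt_df

    # ------------------------------------------------------- track analysis
    if paths.track is not None:
        track, _ = tio.read_track(_require(paths.track, "track", "track"))
        if paths.bathymetry is not None:
            bathy = tio.read_bathymetry(
                _require(paths.bathymetry, "track", "bathymetry"))
            corr = bathymetric_correct(track, bathy)
            track = corrected_track(corr)
        rows = []
        for tag in tags:
            mine = [p for p in track if p.tag_id == tag.tag_id]
            if mine:
                rows.append({"tag_id": tag.tag_id,
                             "max_displacement_km": displacement_from_release(
                                 mine, (tag.release_lon, tag.release_lat))})
        tio.write_track(track, out_dir / "track_corrected.csv")
        pd.DataFrame(rows, columns=["tag_id", "max_displacement_km"]
                     ).to_csv(out_dir / "track_summary.csv", index=False)
        bundle["track"] = pd.DataFrame(rows)

    # ---------------------------------------------- depth-temperature + KUD
    if paths.depth_series is not None:
        series, _ = tio.read_depth_series(
            _require(paths.depth_series, "depth-temp", "depth_series"))
        dt_rows = []
        for tag_id in sorted({r.tag_id for r in series}):
            s = depth_temp_summary([r for r in series if r.tag_id == tag_id])
            dt_rows.append({"tag_id": s.tag_id, "max_depth_m": s.max_depth_m,
                            "modal_depth_m": s.modal_depth_m,
                            "mean_depth_m": s.mean_depth_m,
                            "max_temp_c": s.max_temp_c, "min_temp_c": s.min_temp_c,
                            "modal_temp_c": s.modal_temp_c,
                            "mean_temp_c": s.mean_temp_c})
        pd.DataFrame(dt_rows).to_csv(out_dir / "depth_temp_summary.csv",
                                     index=False)
        bundle["depth_temp"] = pd.DataFrame(dt_rows)

    if paths.track is not None and paths.depth_series is not None:
        track, _ = tio.read_track(paths.track)
        series, _ = tio.read_depth_series(paths.depth_series)
        kud_rows = []
        for tag in tags:
            mine_t = [p for p in track if p.tag_id == tag.tag_id]
            mine_s = [r for r in series if r.tag_id == tag.tag_id]
            if len(mine_t) < 1 or len(mine_s) < 10:
                continue
            # pair daily positions with the day's depth samples
            by_day = {}
            for p in mine_t:
                by_day[p.date.normalize()] = p
            triples = [(p.lon, p.lat, r.depth_m)
                       for r in mine_s
                       for p in [by_day.get(r.timestamp.normalize())] if p]
            if len(triples) < 10:
                continue
            origin = (tag.release_lon, tag.release_lat)
            pts = project_points(triples, origin)
            vols = activity_volumes(pts, mass_levels=config.kud_mass_levels,
                                    grid_n=config.kud_grid_n, origin=origin)
            row = {"tag_id": tag.tag_id}
            for m, v in vols.items():
                row[f"volume_{int(round(m * 100))}_km3"] = v.volume_km3
            kud_rows.append(row)
        pd.DataFrame(kud_rows).to_csv(out_dir / "kud_volumes.csv", index=False)
        bundle["kud"] = pd.DataFrame(kud_rows)

    # ------------------------------------------------------------- manifest
    cfg_yaml = out_dir / "run_config.yaml"
    config.to_yaml(cfg_yaml)
    manifest = {
        "tigertrack_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.read_bytes()).hexdigest(),
        "inputs": {k: str(v) for k, v in vars(paths).items() if v is not None},
        "outputs": sorted(p.name for p in out_dir.glob("*.csv")),
        "validation": {"detections_rejected": det_rep.n_rejected,
                       "receivers_rejected": rec_rep.n_rejected,
                       "tags_rejected": tag_rep.n_rejected},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
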