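"""End-to-end orchestration of the analysis on one or more sessions.

Stages run in dependency order: behavior (lap segmentation, lick-stop
detection, engagement) -> position decoding (cross-condition fit and the
sigmoid inflection of lap-wise R^2 in UR) -> place fields per condition
(detection, parameters, fate ledger, reward over-representation) ->
population dynamics (PV correlations, Rewarded-cluster probability) ->
axon ramp metrics (for axon sessions).  All randomness flows from one
master seed through named substreams so stages are independently
reproducible; a rerun with identical inputs, config and seed is
bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .session import SessionRecord, BinningSpec, load_session, validate_session
from . import behavior as bhv
from . import decoding as dec
from . import placefields as pf
from . import population as pop
from . import axons as ax


STAGE_ORDER = ("behavior", "decoding", "placefields", "population", "axons")


@dataclass
class PipelineConfig:
    seed: int = 0
    train_frac: float = 0.6
    engagement_sd_mult: float = 1.5
    k_consecutive: int = 2
    n_shuffles: int = 1000
    kmeans_runs: int = 1000
    kmeans_k: int = 3
    min_engaged_laps: int = 5
    stages: tuple = STAGE_ORDER
    field_config: pf.FieldConfig = dc_field(default_factory=pf.FieldConfig)
    spec: BinningSpec = dc_field(default_factory=BinningSpec)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of the master seed."""
    child = np.random.SeedSequence([seed, abs(hash(name)) % (2 ** 31)])
    return np.random.default_rng(child)


def _analysis_laps(lap_table: bhv.LapTable, condition_key: str) -> list:
    """Laps entering place-field analysis per condition: RE_LOW restricted
    to engaged laps, R/RR complete laps."""
    if condition_key == "RE_LOW":
        return lap_table.select(condition="UR", re_label=bhv.RE_LOW,
                                engagement=bhv.ENGAGED)
    return lap_table.select(condition=condition_key)


def run_pipeline(session: SessionRecord | str | Path,
                 config: PipelineConfig | None = None,
                 is_axon_session: bool = False) -> dict:
    """Run the configured stages on one session and return the report.

    A failing stage is recorded as a structured failure and later stages
    that can still run do; results computed so far are always returned.
    """
    config = config or PipelineConfig()
    if not isinstance(session, SessionRecord):
        session = load_session(session)
    report: dict = {
        "provenance": {"version": __version__, "seed": config.seed,
                       "animal_id": session.animal_id},
        "validation": validate_session(session),
        "stages": {},
        "failures": [],
    }

    def fail(stage, exc):
        report["failures"].append({"stage": stage, "error": f"{type(exc).__name__}: {exc}"})

    # ---- behavior -------------------------------------------------------
    lap_table = None
    if "behavior" in config.stages:
        try:
            lap_table = bhv.segment_laps(session, config.spec)
            zone = bhv.anticipation_zone(session, lap_table)
            stop = bhv.detect_lick_stop_lap(session, lap_table, zone,
                                            config.k_consecutive)
            bhv.classify_engagement_approach(lap_table,
                                             config.engagement_sd_mult)
            re_low = lap_table.select(condition="UR", re_label=bhv.RE_LOW)
            engaged = [l for l in re_low if l.engagement == bhv.ENGAGED]
            report["stages"]["behavior"] = {
                "n_laps": {c: len(lap_table.select(condition=c))
                           for c in sorted({l.condition for l in lap_table})},
                "anticipation_zone_cm": zone,
                "lick_stop_lap": stop,
                "re_low_laps": len(re_low),
                "re_low_engaged": len(engaged),
                "re_low_disengaged": len(re_low) - len(engaged),
            }
        except Exception as exc:           # noqa: BLE001 - structured failure record
            fail("behavior", exc)
            lap_table = None

    # ---- decoding -------------------------------------------------------
    if "decoding" in config.stages and lap_table is not None and session.n_cells:
        try:
            result = dec.train_test_decode(session, lap_table,
                                           config.train_frac, config.spec)
            ur_r2 = [result.lap_r2[k] for k in sorted(result.lap_r2)
                     if k[0] == "UR"]
            decoding_report = {
                "lap_r2": {f"{c}:{i}": v for (c, i), v in result.lap_r2.items()},
                "error_by_position_cm": result.error_by_position.tolist(),
                "mean_r2_by_condition": {},
            }
            for cond in ("R", "UR", "RR"):
                vals = [v for (c, i), v in result.lap_r2.items() if c == cond]
                if vals:
                    decoding_report["mean_r2_by_condition"][cond] = float(np.mean(vals))
            if len(ur_r2) >= 6:
                try:
                    fit = dec.fit_inflection(ur_r2)
                    decoding_report["sigmoid"] = {
                        "a1": fit.a1, "a2": fit.a2, "x0": fit.x0, "dx": fit.dx,
                        "fit_r2": fit.r2, "inflection_lap": fit.inflection_lap,
                        "degenerate": fit.degenerate,
                    }
                except RuntimeError as exc:
                    fail("decoding.sigmoid", exc)
            report["stages"]["decoding"] = decoding_report
        except Exception as exc:           # noqa: BLE001
            fail("decoding", exc)

    # ---- place fields ---------------------------------------------------
    fields_by_condition: dict = {}
    if "placefields" in config.stages and lap_table is not None and session.n_cells:
        try:
            rng = _substream(config.seed, "placefields")
            pf_report: dict = {"conditions": {}}
            for key in ("R", "RE_LOW", "RR"):
                laps = _analysis_laps(lap_table, key)
                if len(laps) < config.min_engaged_laps:
                    warnings.warn(f"{key}: only {len(laps)} analysis laps; "
                                  "place fields skipped")
                    continue
                fields = pf.detect_place_fields(
                    session, laps, config=config.field_config, rng=rng,
                    spec=config.spec)
                fields_by_condition[key] = fields
                flat = [f for flds in fields.values() for f in flds]
                pf_report["conditions"][key] = {
                    "n_fields": len(flat),
                    "n_place_cells": sum(bool(v) for v in fields.values()),
                    "mean_reliability": float(np.mean([f.reliability for f in flat]))
                    if flat else float("nan"),
                    "mean_out_in_ratio": float(np.mean([f.out_in_ratio for f in flat]))
                    if flat else float("nan"),
                    "mean_width_cm": float(np.mean([f.width for f in flat]))
                    if flat else float("nan"),
                    "mean_intensity": float(np.mean([f.intensity for f in flat]))
                    if flat else float("nan"),
                }
                coms = [f.com for f in flat]
                if len(coms) >= 20:
                    pf_report["conditions"][key]["density"] = pf.field_density(
                        coms, session.track_length)
            if "R" in fields_by_condition:
                fate = pf.classify_fate(fields_by_condition, session.track_length)
                pf_report["fate_counts"] = fate["counts"]
                pf_report["fate_summary"] = fate["summary"]
            report["stages"]["placefields"] = pf_report
        except Exception as exc:           # noqa: BLE001
            fail("placefields", exc)

    # ---- population dynamics -------------------------------------------
    if ("population" in config.stages and lap_table is not None
            and fields_by_condition.get("R")):
        try:
            place_cells = [c for c, v in fields_by_condition["R"].items() if v]
            laps = (lap_table.select(condition="R")
                    + lap_table.select(condition="UR", re_label=bhv.RE_HIGH)
                    + _analysis_laps(lap_table, "RE_LOW")
                    + lap_table.select(condition="RR"))
            pv = pop.build_population_vectors(session, laps, place_cells,
                                              config.spec)
            prob = pop.rewarded_cluster_probability(
                pv, k=config.kmeans_k, n_runs=config.kmeans_runs,
                rng=_substream(config.seed, "kmeans"))
            report["stages"]["population"] = {
                "n_place_cells": len(place_cells),
                "lap_conditions": pv.lap_conditions,
                "cluster_probability": prob.tolist(),
            }
        except Exception as exc:           # noqa: BLE001
            fail("population", exc)

    # ---- axons ----------------------------------------------------------
    if "axons" in config.stages and lap_table is not None and is_axon_session:
        try:
            merged = ax.merge_correlated_rois(session.dff)
            laps = [l for l in lap_table if not l.partial]
            profile = ax.ramp_profile(merged[0], session, laps, config.spec)
            report["stages"]["axons"] = {
                "n_rois": session.n_cells,
                "n_merged": merged.shape[0],
                "slope_max_by_condition": {
                    key: profile.condition_mean("slope_max", key)
                    for key in sorted(set(profile.lap_re_keys))
                },
                "max_range_bins": profile.max_range,
                "min_range_bins": profile.min_range,
            }
        except Exception as exc:           # noqa: BLE001
            fail("axons", exc)

    return report


def run_sessions(session_dirs, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run the pipeline over several session directories; per-session
    reports plus a pooled fate-count ledger (element-wise sum)."""
    config = config or PipelineConfig()
    reports = {}
    pooled: dict = {}
    for d in session_dirs:
        rep = run_pipeline(d, config)
        reports[str(d)] = rep
        counts = rep.get("stages", {}).get("placefields", {}).get("fate_counts")
        if counts:
            for k, v in counts.items():
                if isinstance(v, (int, float)):
                    pooled[k] = pooled.get(k, 0) + v
                elif isinstance(v, list):
                    prev = pooled.get(k, [0] * len(v))
                    pooled[k] = [p + x for p, x in zip(prev, v)]
    result = {"sessions": reports,
              "pooled_fate_counts": pooled,
              "pooled_fate_summary": pf.summarize_fates(pooled) if pooled else {}}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as f:
            json.dump(result, f, indent=2, default=_jsonable)
    return result


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)
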