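"""Configuration-driven end-to-end runs.

A run config (YAML or JSON) describes the stimulus protocols, per-group
generator blocks (or input file paths), analysis parameters, and a
comparisons plan.  :func:`run_pipeline` executes the stages

    simulate -> calcium -> behavior -> stats -> report

writing tidy CSVs, figures, and a JSON manifest (config hash, seed, file
checksums) under the output directory.  Re-running with the same config and
seed reproduces bit-identical CSVs; any stage can be rerun from the previous
stage's on-disk outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, calcium, io, plots, stats, synthetic
from .errors import ConfigError
from .protocol import StimulusProtocol, make_protocol

__all__ = ["load_config", "validate_config", "run_pipeline", "default_demo_config"]

log = logging.getLogger("nemoresponse")

STAGES = ("simulate", "calcium", "behavior", "stats", "report")
KNOWN_TESTS = ("welch_t", "mann_whitney", "kruskal_dunn", "anova_dunnett", "anova2_sidak", "fisher_exact")
LOCOMOTION_PRESETS = {
    "adult_like": synthetic.adult_like_params,
    "dauer_like": synthetic.dauer_like_params,
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_config(config: dict) -> list[str]:
    """Return a list of diagnostics; empty iff the config is runnable."""
    diags: list[str] = []
    for stream in ("imaging", "behavior"):
        p = config.get("protocol", {}).get(stream)
        if p is None:
            diags.append(f"protocol.{stream}: missing")
            continue
        for key in ("pre_s", "pulse_s", "post_s", "frame_rate"):
            v = p.get(key)
            if v is None or not np.isfinite(v) or v <= 0:
                diags.append(f"protocol.{stream}.{key}: must be a positive number, got {v}")
    for stream in ("calcium", "behavior"):
        block = config.get(stream, {})
        has_groups = bool(block.get("groups"))
        has_input = bool(block.get("input"))
        if has_groups == has_input:
            diags.append(f"{stream}: exactly one of 'groups' (generator) or 'input' (paths) required")
    for g, spec in (config.get("calcium", {}).get("groups") or {}).items():
        mix = spec.get("class_mix", {})
        total = sum(mix.values()) if isinstance(mix, dict) else sum(mix)
        if not np.isclose(total, 1.0, atol=1e-6):
            diags.append(f"calcium.groups.{g}.class_mix: probabilities sum to {total}, expected 1")
        if spec.get("n", 0) < 1:
            diags.append(f"calcium.groups.{g}.n: must be >= 1")
    for g, spec in (config.get("behavior", {}).get("groups") or {}).items():
        preset = spec.get("params")
        if preset not in LOCOMOTION_PRESETS:
            diags.append(
                f"behavior.groups.{g}.params: unknown preset {preset!r}; "
                f"choose from {sorted(LOCOMOTION_PRESETS)}"
            )
        if spec.get("n", 0) < 1:
            diags.append(f"behavior.groups.{g}.n: must be >= 1")
    known_groups = set()
    known_groups.update((config.get("calcium", {}).get("groups") or {}).keys())
    known_groups.update((config.get("behavior", {}).get("groups") or {}).keys())
    known_groups.update((config.get("chemotaxis", {}).get("groups") or {}).keys())
    for i, comp in enumerate(config.get("comparisons", [])):
        where = f"comparisons[{i}]"
        test = comp.get("test")
        if test not in KNOWN_TESTS:
            diags.append(f"{where}.test: unknown test {test!r}; choose from {KNOWN_TESTS}")
        for g in comp.get("groups", []):
            if known_groups and g not in known_groups:
                diags.append(f"{where}.groups: group {g!r} not defined in any data stream")
        if comp.get("group") and known_groups and comp["group"] not in known_groups:
            diags.append(f"{where}.group: group {comp['group']!r} not defined")
    return diags


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stream_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _protocols(config: dict) -> dict[str, StimulusProtocol]:
    out = {}
    for stream in ("imaging", "behavior"):
        p = config["protocol"][stream]
        out[stream] = make_protocol(
            p["pre_s"], p["pulse_s"], p["post_s"], p["frame_rate"], "CO2",
            pulse_composition=p.get("composition"),
        )
        out[stream + "_air"] = make_protocol(
            p["pre_s"], p["pulse_s"], p["post_s"], p["frame_rate"], "air"
        )
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: dict, protos: dict, seed: int, out: Path) -> None:
    seeds = _stream_seeds(seed, 4)
    cal = config.get("calcium", {})
    if cal.get("groups"):
        traces, truth_rows = [], []
        group_seeds = _stream_seeds(seeds[0], len(cal["groups"]))
        for gseed, (g, spec) in zip(group_seeds, sorted(cal["groups"].items())):
            tr, th = synthetic.simulate_calcium_cohort(
                protos["imaging"],
                spec["class_mix"],
                amplitude_dist=spec.get("amplitude"),
                n=spec["n"],
                seed=gseed,
                noise_sd=cal.get("noise_sd", 0.01),
                group=g,
                neuron=cal.get("neuron", "sim"),
                post_offset_class=spec.get("post_offset_class"),
            )
            traces.extend(tr)
            truth_rows.extend(
                {
                    "animal_id": t.animal_id, "group": g,
                    "response_class": u.response_class, "amplitude_pct": u.amplitude_pct,
                    "onset_latency_s": u.onset_latency_s, "post_offset": u.post_offset,
                }
                for t, u in zip(tr, th)
            )
        air, _ = synthetic.simulate_calcium_cohort(
            protos["imaging_air"], (0.0, 0.0, 1.0), n=cal.get("n_air_controls", 12),
            seed=seeds[1], noise_sd=cal.get("noise_sd", 0.01), group="air_control",
            neuron=cal.get("neuron", "sim"),
        )
        io.write_traces_csv(traces, out / "calcium_traces.csv")
        io.write_traces_csv(air, out / "calcium_air_traces.csv")
        pd.DataFrame(truth_rows).to_csv(out / "calcium_truth.csv", index=False)
    beh = config.get("behavior", {})
    if beh.get("groups"):
        trajs = []
        group_seeds = _stream_seeds(seeds[2], 2 * len(beh["groups"]))
        k = 0
        for g, spec in sorted(beh["groups"].items()):
            params = LOCOMOTION_PRESETS[spec["params"]](frame_rate=protos["behavior"].frame_rate)
            for gas, proto in (("CO2", protos["behavior"]), ("air", protos["behavior_air"])):
                t, _ = synthetic.simulate_behavior_cohort(
                    proto, params, n=spec["n"], seed=group_seeds[k], group=g
                )
                for tr in t:
                    trajs.append(
                        behavior.Trajectory(
                            animal_id=f"{tr.animal_id}-{gas}", group=g,
                            t_s=tr.t_s, x_mm=tr.x_mm, y_mm=tr.y_mm, protocol=tr.protocol,
                        )
                    )
                k += 1
        io.write_trajectories_csv(trajs, out / "behavior_trajectories.csv")
        gas_map = pd.DataFrame(
            {"animal_id": [t.animal_id for t in trajs],
             "gas": ["air" if t.protocol.is_air_control else "CO2" for t in trajs]}
        )
        gas_map.to_csv(out / "behavior_gas_map.csv", index=False)
    chem = config.get("chemotaxis", {})
    if chem.get("groups"):
        plate_rows = []
        plate_seeds = _stream_seeds(seeds[3], len(chem["groups"]) * chem.get("n_plates", 16))
        k = 0
        for g, p_test in sorted(chem["groups"].items()):
            for plate in range(chem.get("n_plates", 16)):
                c = synthetic.simulate_chemotaxis_assay(
                    p_test, chem.get("n_worms", 20), seed=plate_seeds[k], plate_id=f"{g}-{plate:02d}"
                )
                plate_rows.append(
                    {"plate_id": c.plate_id, "group": g, "n_test": c.n_test, "n_control": c.n_control}
                )
                k += 1
        plates = pd.DataFrame(plate_rows)
        plates.to_csv(out / "chemotaxis_counts.csv", index=False)
        plates["chemotaxis_index"] = [
            stats.chemotaxis_index(stats.ChemotaxisCounts(r.n_test, r.n_control, r.plate_id))
            for r in plates.itertuples()
        ]
        plates.to_csv(out / "chemotaxis_metrics.csv", index=False)
    io.write_protocol(protos["imaging"], out / "protocol_imaging.json")
    io.write_protocol(protos["behavior"], out / "protocol_behavior.json")


def _stage_calcium(config: dict, protos: dict, out: Path, manifest_warnings: list[str]) -> None:
    cal = config.get("calcium", {})
    if cal.get("input"):
        proto = io.read_protocol(cal["input"]["protocol"])
        proto_air = io.read_protocol(cal["input"].get("air_protocol", cal["input"]["protocol"]))
        traces = io.read_traces_csv(cal["input"]["traces"], proto)
        air = io.read_traces_csv(cal["input"]["air_traces"], proto_air)
    else:
        proto = io.read_protocol(out / "protocol_imaging.json")
        proto_air = make_protocol(
            proto.segments[0].duration_s, proto.segments[1].duration_s,
            proto.segments[2].duration_s, proto.frame_rate, "air",
        )
        traces = io.read_traces_csv(out / "calcium_traces.csv", proto)
        air = io.read_traces_csv(out / "calcium_air_traces.csv", proto_air)
    analysis = cal.get("analysis", {})
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        calls, table = calcium.classify_cohort(
            traces, air,
            baseline_window=analysis.get("baseline_window"),
            response_window=analysis.get("response_window"),
            k=analysis.get("k_sd", 3.0),
            statistic=analysis.get("statistic", "extremum"),
        )
    manifest_warnings.extend(str(w.message) for w in caught)
    calls_df = pd.DataFrame(
        [
            {"animal_id": c.animal_id, "group": c.group, "max_pct": c.max_pct,
             "min_pct": c.min_pct, "response_class": c.response_class}
            for c in calls
        ]
    )
    calls_df.to_csv(out / "calcium_calls.csv", index=False)
    table.to_csv(out / "calcium_class_counts.csv", index=False)
    rts = {t.animal_id: calcium.compute_ratio_trace(t, analysis.get("baseline_window")) for t in traces}
    summaries = []
    order_json = {}
    clustering = analysis.get("clustering", {})
    for g in sorted({t.group for t in traces}):
        grp_rts = [rts[t.animal_id] for t in traces if t.group == g]
        s = calcium.cohort_mean_sem(grp_rts)
        s.insert(0, "group", g)
        summaries.append(s)
        order = calcium.order_for_heatmap(
            grp_rts,
            metric=clustering.get("metric", "euclidean"),
            linkage=clustering.get("linkage", "average"),
        )
        order_json[g] = {
            "order": [int(i) for i in order],
            "animal_ids": [grp_rts[i].animal_id for i in order],
        }
    pd.concat(summaries, ignore_index=True).to_csv(out / "calcium_mean_sem.csv", index=False)
    (out / "calcium_heatmap_order.json").write_text(json.dumps(order_json, indent=2))


def _stage_behavior(config: dict, protos: dict, out: Path) -> None:
    beh = config.get("behavior", {})
    if beh.get("input"):
        proto = io.read_protocol(beh["input"]["protocol"])
        trajs = io.read_trajectories_csv(beh["input"]["trajectories"], proto)
    else:
        proto = io.read_protocol(out / "protocol_behavior.json")
        proto_air = make_protocol(
            proto.segments[0].duration_s, proto.segments[1].duration_s,
            proto.segments[2].duration_s, proto.frame_rate, "air",
        )
        gas_map = pd.read_csv(out / "behavior_gas_map.csv").set_index("animal_id")["gas"]
        raw = io.read_trajectories_csv(out / "behavior_trajectories.csv", proto)
        trajs = [
            behavior.Trajectory(
                animal_id=t.animal_id, group=t.group, t_s=t.t_s, x_mm=t.x_mm, y_mm=t.y_mm,
                protocol=proto_air if gas_map.get(t.animal_id, "CO2") == "air" else proto,
            )
            for t in raw
        ]
    analysis = beh.get("analysis", {})
    cfg = behavior.BehaviorConfig(
        segmentation=behavior.SegmentationParams(
            pause_speed_mm_s=analysis.get("pause_speed_mm_s", 0.02),
            min_bout_s=analysis.get("min_bout_s", 0.6),
            reversal_angle_deg=analysis.get("reversal_angle_deg", 120.0),
        ),
        smooth_s=analysis.get("smooth_s", 1.0),
    )
    metrics, speed_summary = behavior.behavior_cohort_table(trajs, cfg)
    metrics.to_csv(out / "behavior_metrics.csv", index=False)
    speed_summary.to_csv(out / "behavior_speed_summary.csv", index=False)


def _stage_stats(config: dict, out: Path) -> None:
    results = []
    tables: dict[str, pd.DataFrame] = {}

    def table(name: str) -> pd.DataFrame:
        if name not in tables:
            path = out / f"{name}.csv"
            if not path.exists():
                raise ConfigError(f"comparisons reference table {name!r} but {path} does not exist")
            tables[name] = pd.read_csv(path)
        return tables[name]

    for comp in config.get("comparisons", []):
        name = comp["name"]
        test = comp["test"]
        if test in ("welch_t", "mann_whitney"):
            df = table(comp.get("table", "behavior_metrics"))
            sub = df
            if comp.get("gas") and "gas" in df.columns:
                sub = df[df["gas"] == comp["gas"]]
            groups = comp["groups"]
            vals = [sub.loc[sub["group"] == g, comp["metric"]].to_numpy() for g in groups]
            res = stats.compare_two(vals[0], vals[1], method=test)
            results.append(_result_rows(name, comp["metric"], res))
        elif test in ("kruskal_dunn", "anova_dunnett"):
            df = table(comp.get("table", "chemotaxis_metrics"))
            gd = {g: df.loc[df["group"] == g, comp["metric"]].to_numpy() for g in comp["groups"]}
            res = stats.compare_multi(gd, method=test, reference=comp.get("reference"))
            results.append(_result_rows(name, comp["metric"], res))
        elif test == "anova2_sidak":
            df = table(comp.get("table", "behavior_metrics"))
            sub = df[df["group"] == comp["group"]] if comp.get("group") else df
            long = sub.melt(
                id_vars=["animal_id", "gas"], value_vars=comp["metrics"],
                var_name="factor_b", value_name="value",
            ).rename(columns={"gas": "factor_a"})
            res = stats.compare_multi(None, method=test, design=long)
            results.append(_result_rows(name, "+".join(comp["metrics"]), res))
        elif test == "fisher_exact":
            df = table(comp.get("table", "calcium_class_counts"))
            focus = comp.get("focus_class", "excitatory")
            g1, g2 = comp["groups"]
            tab = []
            for g in (g1, g2):
                sub = df[df["group"] == g]
                in_class = int(sub.loc[sub["response_class"] == focus, "count"].sum())
                total = int(sub["count"].sum())
                tab.append([in_class, total - in_class])
            res = stats.compare_categorical(np.array(tab))
            results.append(_result_rows(name, f"class:{focus}", res))
        else:  # pragma: no cover - caught by validate_config
            raise ConfigError(f"unknown test {test!r} in comparisons entry {name!r}")
    if results:
        pd.concat(results, ignore_index=True).to_csv(out / "stats_results.csv", index=False)


def _result_rows(name: str, metric: str, res: stats.TestResult) -> pd.DataFrame:
    rows = [
        {
            "comparison": name, "metric": metric, "test": res.test_name, "contrast": "omnibus",
            "statistic": res.statistic, "p": res.p_value, "p_adj": np.nan,
            "n": json.dumps(res.n_per_group),
        }
    ]
    for ph in res.posthoc:
        rows.append(
            {
                "comparison": name, "metric": metric, "test": res.test_name,
                "contrast": f"{ph.pair[0]} vs {ph.pair[1]}", "statistic": ph.statistic,
                "p": ph.p_raw, "p_adj": ph.p_adj, "n": "",
            }
        )
    return pd.DataFrame(rows)


def _stage_report(config: dict, protos: dict, out: Path) -> None:
    proto = io.read_protocol(out / "protocol_imaging.json") if (out / "protocol_imaging.json").exists() else protos["imaging"]
    mean_sem = pd.read_csv(out / "calcium_mean_sem.csv")
    summaries = {g: df for g, df in mean_sem.groupby("group")}
    plots.plot_mean_sem_traces(summaries, proto, out / "fig_calcium_mean_sem.png")
    traces = io.read_traces_csv(out / "calcium_traces.csv", proto)
    cal = config.get("calcium", {}).get("analysis", {})
    order_json = json.loads((out / "calcium_heatmap_order.json").read_text())
    for g, info in order_json.items():
        grp = [t for t in traces if t.group == g]
        rts = [calcium.compute_ratio_trace(t, cal.get("baseline_window")) for t in grp]
        mat = np.vstack([rt.dr_pct for rt in rts])
        plots.plot_heatmap(
            mat, np.array(info["order"]), grp[0].t_s, proto,
            out / f"fig_calcium_heatmap_{g}.png", title=g,
        )
    calls = pd.read_csv(out / "calcium_calls.csv")
    plots.plot_peaks_violin(calls, out / "fig_calcium_peaks.png")
    bproto = io.read_protocol(out / "protocol_behavior.json") if (out / "protocol_behavior.json").exists() else protos["behavior"]
    speed_summary = pd.read_csv(out / "behavior_speed_summary.csv")
    plots.plot_speed_traces(speed_summary, bproto, out / "fig_speed_traces.png")
    metrics = pd.read_csv(out / "behavior_metrics.csv")
    plots.plot_behavior_violins(metrics, out / "fig_behavior_violins.png")


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(
    config: dict,
    out_dir: str | Path,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Execute the pipeline and return (and write) the run manifest."""
    diags = validate_config(config)
    if diags:
        raise ConfigError("config failed validation:\n  " + "\n  ".join(diags))
    if stages is None:
        stages = list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; valid: {STAGES}")
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protos = _protocols(config)
    manifest_warnings: list[str] = []
    t0 = time.time()
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        if stage == "simulate":
            _stage_simulate(config, protos, seed, out)
        elif stage == "calcium" and config.get("calcium"):
            _stage_calcium(config, protos, out, manifest_warnings)
        elif stage == "behavior" and config.get("behavior"):
            _stage_behavior(config, protos, out)
        elif stage == "stats":
            _stage_stats(config, out)
        elif stage == "report":
            _stage_report(config, protos, out)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "stages": [s for s in STAGES if s in stages],
        "warnings": manifest_warnings,
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": {
            p.name: _file_checksum(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".json") and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def default_demo_config() -> dict:
    """The demo configuration shipped at ``configs/demo.yaml``."""
    here = Path(__file__).resolve()
    for parent in here.parents:
        candidate = parent / "configs" / "demo.yaml"
        if candidate.exists():
            return load_config(candidate)
    raise FileNotFoundError("configs/demo.yaml not found relative to the package")
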