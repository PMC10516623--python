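"""Orchestrate simulate → process → kinetics → classify → titrate runs.

A run is driven by one structured config (YAML/JSON) with per-module
sections, executes its stages in order, and leaves a self-describing
output directory: binary traces plus metadata, the corrected FRET table,
per-molecule bleach report, dwell summary, behavioral classes, population
fractions, an optional titration result, a manifest that fully determines
a rerun, and a human-readable report.  All tables are plain delimited
text so reruns can be diffed byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import classify as cl
from . import hmm as hm
from . import population as pop
from .preprocess import FretTrace, preprocess_ensemble
from .simulate import (ConfigError, KineticScheme, PhotophysicsConfig,
                       ScenarioConfig, StateEmission, StateModel,
                       simulate_competition, simulate_ensemble,
                       simulate_titration, simulate_vectorial)
from .trace_io import read_traces, write_results_table_with_schema, write_traces

log = logging.getLogger(__name__)

DEFAULT_STAGES = ("simulate", "process", "kinetics", "classify")


class ConfigSchemaError(ValueError):
    pass


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    text = Path(source).read_text()
    return yaml.safe_load(text)


def _build_configs(cfg: dict):
    scen_kw = dict(cfg.get("scenario", {}))
    try:
        scenario = ScenarioConfig(**scen_kw)
    except (TypeError, ConfigError) as exc:
        raise ConfigSchemaError(f"scenario section: {exc}") from exc
    if scenario.mode in ("vectorial",) and "duplex_length" not in scen_kw \
            and cfg.get("require_explicit_duplex", False):
        raise ConfigSchemaError("vectorial mode requires scenario.duplex_length")
    scheme_kw = dict(cfg.get("scheme", {}))
    base_rates = {tuple(k.split("->")): v
                  for k, v in scheme_kw.pop("rates", {}).items()}
    try:
        if base_rates:
            scheme = KineticScheme(base_rates=base_rates, **scheme_kw)
        else:
            scheme = KineticScheme.default(**scheme_kw)
    except (TypeError, ConfigError) as exc:
        raise ConfigSchemaError(f"scheme section: {exc}") from exc
    try:
        photo = PhotophysicsConfig(**cfg.get("photophysics", {}))
    except (TypeError, ConfigError) as exc:
        raise ConfigSchemaError(f"photophysics section: {exc}") from exc
    palette = cfg.get("palette", {})
    model = StateModel.default(scenario.oligo_length or 9)
    for name, params in palette.items():
        if name not in model.states:
            raise ConfigSchemaError(f"palette: unknown state {name!r}")
        model.states[name] = StateEmission(**params)
    return scenario, scheme, photo, StateModel(model.states)


def _load_fret_table(out: Path, scenario: ScenarioConfig) -> list[FretTrace]:
    """Stage isolation: rebuild FretTraces from a prior run's fret.csv
    (event frames recovered from the trace sidecar when present)."""
    import pandas as pd

    fpath = out / "fret.csv"
    if not fpath.exists():
        raise ConfigSchemaError(f"stage needs process outputs "
                                f"(no fret.csv in {out})")
    df = pd.read_csv(fpath)
    event_frames: dict[str, int | None] = {}
    sidecar = out / "traces.meta.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        event_frames = dict(zip(meta.get("molecule_ids", []),
                                meta.get("event_frames", [])))
    traces = []
    for mid, sub in df.groupby("molecule_id", sort=False):
        sub = sub.sort_values("frame")
        valid = sub["valid"].to_numpy().astype(bool)
        eff = pd.to_numeric(sub["efficiency"], errors="coerce").to_numpy()
        ev = event_frames.get(str(mid))
        traces.append(FretTrace(str(mid), np.where(valid, eff, np.nan), valid,
                                scenario.frame_interval,
                                event_frame=None if ev is None else int(ev)))
    return traces


def run_scenario(config, out_dir) -> Path:
    """Execute the configured stages; returns the output directory.

    The manifest (config snapshot + seed + per-stage record counts) fully
    determines a rerun: identical manifests give identical outputs.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario, scheme, photo, model = _build_configs(cfg)
    n = int(cfg.get("n", 100))
    seed = int(cfg.get("seed", scenario.seed))
    stages = list(cfg.get("stages", DEFAULT_STAGES))
    manifest = {"version": __version__, "seed": seed, "n": n,
                "stages": stages, "config": cfg, "counts": {},
                "completed": []}
    mpath = out / "manifest.json"

    def checkpoint():
        mpath.write_text(json.dumps(manifest, indent=1, default=str))

    try:
        ens = fret = fits = classes = None
        if "simulate" in stages:
            if scenario.mode == "vectorial":
                ens = simulate_vectorial(scheme, model, photo, scenario, n, seed)
            elif scenario.mode == "competition":
                ens = simulate_competition(scheme, model, photo, scenario, n, seed)
            else:
                ens = simulate_ensemble(scheme, model, photo, scenario, n, seed)
            write_traces(ens, out / "traces.traces", "binary_traces")
            write_traces(ens, out / "traces.csv", "csv_long")
            truth_rows = [{"molecule_id": t.molecule_id,
                           "archetype": (t.truth or {}).get("archetype", ""),
                           "rate_factor": (t.truth or {}).get("rate_factor", "")}
                          for t in ens]
            write_results_table_with_schema(
                truth_rows, ["molecule_id", "archetype", "rate_factor"],
                out / "truth.csv")
            manifest["counts"]["simulate"] = len(ens)
            manifest["completed"].append("simulate")
            checkpoint()
        if "process" in stages:
            if ens is None:
                # stage isolation: resume from a prior run's trace files
                tpath = out / "traces.traces"
                if not tpath.exists():
                    raise ConfigSchemaError(
                        "process stage needs simulate outputs "
                        f"(no {tpath.name} in {out})")
                ens = read_traces(tpath, "binary_traces")
            fret = preprocess_ensemble(ens, photo)
            rows = []
            for tr in fret:
                for f in range(len(tr)):
                    rows.append({"molecule_id": tr.molecule_id, "frame": f,
                                 "efficiency": (round(tr.efficiency[f], 6)
                                                if tr.valid_mask[f] else ""),
                                 "valid": int(tr.valid_mask[f])})
            write_results_table_with_schema(
                rows, ["molecule_id", "frame", "efficiency", "valid"],
                out / "fret.csv")
            bleach_rows = [{"molecule_id": tr.molecule_id,
                            "bleach_frame": ("" if tr.bleach_frame is None
                                             else tr.bleach_frame),
                            "bleach_type": tr.bleach_type}
                           for tr in fret]
            write_results_table_with_schema(
                bleach_rows, ["molecule_id", "bleach_frame", "bleach_type"],
                out / "bleach.csv")
            manifest["counts"]["process"] = len(fret)
            manifest["completed"].append("process")
            checkpoint()
        if "kinetics" in stages:
            if fret is None:
                fret = _load_fret_table(out, scenario)
            fits = hm.fit_hmm(fret, shared_emissions=True)
            dwells = hm.dwell_summary(fret, fits)
            rows = [{"molecule_id": d.molecule_id,
                     "mean_dwell_high_s": d.mean_dwell_high or "",
                     "mean_dwell_mid_s": d.mean_dwell_mid or "",
                     "log10_dwell_high": ("" if not d.mean_dwell_high
                                          else round(np.log10(d.mean_dwell_high), 4)),
                     "log10_dwell_mid": ("" if not d.mean_dwell_mid
                                         else round(np.log10(d.mean_dwell_mid), 4)),
                     "n_transitions": d.n_transitions,
                     "occupancy_high": round(d.occupancy_high, 4)}
                    for d in dwells]
            write_results_table_with_schema(
                rows, ["molecule_id", "mean_dwell_high_s", "mean_dwell_mid_s",
                       "log10_dwell_high", "log10_dwell_mid", "n_transitions",
                       "occupancy_high"],
                out / "dwells.csv")
            manifest["counts"]["kinetics"] = len(dwells)
            manifest["completed"].append("kinetics")
            checkpoint()
        if "classify" in stages:
            if fret is None:
                fret = _load_fret_table(out, scenario)
            if fits is None and scenario.mode != "vectorial":
                fits = hm.fit_hmm(fret, shared_emissions=True)
            policy = cl.ClassPolicy(**cfg.get("classify", {}))
            by_id = {f.molecule_id: f for f in (fits or [])}
            if scenario.mode == "vectorial":
                classes = [cl.classify_vectorial(tr, policy) for tr in fret]
                labels = ("type_i", "type_ii", "type_iii", "type_iv")
            elif scenario.mode == "flow_in":
                classes = [cl.detect_locking(tr, by_id.get(tr.molecule_id),
                                             tr.event_frame, policy)
                           for tr in fret]
                labels = ("locked", "not_locked")
            else:
                classes = [cl.classify_prefolded(tr, by_id.get(tr.molecule_id),
                                                 policy) for tr in fret]
                labels = ("static_mid", "static_high", "dynamic")
            rows = [{"molecule_id": c.molecule_id, "label": c.label,
                     "n_transitions": c.n_transitions, "reason": c.reason}
                    for c in classes]
            write_results_table_with_schema(
                rows, ["molecule_id", "label", "n_transitions", "reason"],
                out / "classes.csv")
            table = cl.population_table(classes, labels=labels)
            write_results_table_with_schema(
                table, ["label", "count", "fraction", "ci_low", "ci_high"],
                out / "population.csv")
            manifest["counts"]["classify"] = len(classes)
            manifest["completed"].append("classify")
            checkpoint()
        if "titrate" in stages:
            tcfg = cfg.get("titration")
            if not tcfg:
                raise ConfigSchemaError("titrate stage needs a titration section")
            ensembles = simulate_titration(
                tcfg["concentrations_uM"], tcfg["kd_uM"],
                tcfg.get("f0", 0.30), tcfg.get("fmax", 0.85),
                int(tcfg.get("n_per_point", 500)), seed, photo=photo)
            samples = {c: pop.pool_efficiencies(preprocess_ensemble(e, photo),
                                                n_frames=scenario.short_movie_frames)
                       for c, e in ensembles.items()}
            result = pop.titrate(samples, K=int(tcfg.get("K", 2)),
                                 n_bootstrap=int(tcfg.get("n_bootstrap", 50)),
                                 seed=seed)
            rows = [{"concentration_uM": c, "high_fraction": round(f, 6),
                     "uncertainty": round(u, 6)}
                    for c, f, u in zip(result.concentrations, result.fractions,
                                       result.uncertainties)]
            write_results_table_with_schema(
                rows, ["concentration_uM", "high_fraction", "uncertainty"],
                out / "titration_points.csv")
            summary = {"kd_uM": result.kd, "f0": result.f0, "fmax": result.fmax,
                       "kd_ci_low": result.kd_ci[0] if result.kd_ci else None,
                       "kd_ci_high": result.kd_ci[1] if result.kd_ci else None,
                       "converged": result.converged,
                       "extrapolated": result.extrapolated}
            (out / "titration.json").write_text(json.dumps(summary, indent=1))
            manifest["counts"]["titrate"] = len(rows)
            manifest["completed"].append("titrate")
            checkpoint()
    except Exception:
        checkpoint()
        raise
    checkpoint()
    (out / "report.txt").write_text(report_summary(out))
    return out


def report_summary(output_dir) -> str:
    """Compose a plain-text report from whatever stage outputs exist."""
    out = Path(output_dir)
    lines = ["rsfret run report", "================="]
    mpath = out / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
        lines.append(f"seed {manifest.get('seed')}  n {manifest.get('n')}  "
                     f"stages {','.join(manifest.get('completed', []))}")
    for name, title in [("population.csv", "Population fractions"),
                        ("dwells.csv", "Dwell summary"),
                        ("titration_points.csv", "Titration points")]:
        p = out / name
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        if p.exists():
            if name == "dwells.csv":
                n_rows = max(len(p.read_text().strip().splitlines()) - 1, 0)
                lines.append(f"{n_rows} molecules with uncensored dwells "
                             "(see dwells.csv for the log-scale scatter data)")
            else:
                lines.append(p.read_text().strip())
        else:
            lines.append("absent (stage not run)")
    tpath = out / "titration.json"
    lines.append("")
    lines.append("Titration fit")
    lines.append("-------------")
    if tpath.exists():
        t = json.loads(tpath.read_text())
        ci = ""
        if t.get("kd_ci_low") is not None:
            ci = f"  (95% CI {t['kd_ci_low']:.3g}-{t['kd_ci_high']:.3g})"
        lines.append(f"Kd = {t['kd_uM']:.3g} uM{ci}  f0 = {t['f0']:.3f}  "
                     f"fmax = {t['fmax']:.3f}")
    else:
        lines.append("absent (stage not run)")
    return "\n".join(lines) + "\n"
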