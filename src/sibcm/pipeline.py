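"""Pipeline orchestration: extract -> fit -> simulate -> evaluate.

A run is driven by a plain dict (read from YAML/JSON by the CLI), executes
the configured stages in order, writes delimited matrices plus JSON sidecars,
and records a manifest with a SHA-256 digest of every output so a rerun with
identical config and inputs can be verified digest-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import coactivity, gafit, metrics
from .data_io import ParcellatedTimeSeries, load_timeseries, write_timeseries
from .dmf import DMFParameters, DivergenceError, simulate_dmf
from .fixtures import make_modular_pattern, make_synthetic_subject
from .hemo import balloon_bold


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunManifest:
    config: dict
    input_digests: dict
    version: str
    seeds: dict
    started: float
    finished: float | None = None
    outputs: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_matrix(mat: np.ndarray, path: Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for row in np.atleast_2d(mat):
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


def _require(config: dict, key: str, context: str = "config"):
    if key not in config:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return config[key]


def _load_input(config: dict) -> ParcellatedTimeSeries:
    if "input" in config:
        spec = config["input"]
        path = _require(spec, "path", "input")
        tr = _require(spec, "tr_seconds", "input")
        return load_timeseries(path, tr_seconds=tr,
                               orientation=spec.get("orientation", "time-by-region"))
    if "fixture" in config:
        spec = config["fixture"]
        seed = int(spec.get("seed", 0))
        pattern = make_modular_pattern(
            m=int(spec.get("m", 20)), n_modules=int(spec.get("n_modules", 4)),
            seed=seed,
        )
        params = DMFParameters(**spec.get("params", {}))
        bold, _ = make_synthetic_subject(
            pattern, params,
            duration_seconds=float(spec.get("duration_seconds", 300.0)),
            tr_out_seconds=float(spec.get("tr_seconds", 0.72)),
            seed=seed,
        )
        return bold
    raise ConfigError("config: need either 'input' or 'fixture'")


def run_pipeline(config: dict, out_dir) -> RunManifest:
    """Execute the configured stages; see the CLI for the config schema."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _require(config, "stages")
    known = {"extract", "fit", "simulate", "evaluate"}
    unknown = set(stages) - known
    if unknown:
        raise ConfigError(f"config: unknown stages {sorted(unknown)}")

    manifest = RunManifest(
        config=config,
        input_digests={},
        version=_version(),
        seeds={"master_seed": int(config.get("seed", 0))},
        started=time.time(),
    )
    ts = _load_input(config)
    if "input" in config:
        manifest.input_digests[str(config["input"]["path"])] = _sha256(
            config["input"]["path"]
        )

    def register(path: Path) -> None:
        manifest.outputs[path.name] = _sha256(path)

    pattern = None
    fitted = None
    if "extract" in stages:
        ecfg = config.get("extract", {})
        opts = coactivity.FusedRpcaOptions(
            lambda1=ecfg.get("lambda1"), lambda2=ecfg.get("lambda2"),
        )
        pattern, decomp = coactivity.extract_pattern(
            ts, window_length=int(ecfg.get("window_length", 30)),
            step=int(ecfg.get("step", 10)), opts=opts,
        )
        write_matrix(pattern.weights, out / "pattern.tsv")
        (out / "pattern.json").write_text(json.dumps(pattern.provenance, indent=2,
                                                     sort_keys=True))
        register(out / "pattern.tsv")
        register(out / "pattern.json")

    if "fit" in stages:
        fcfg = config.get("fit", {})
        gacfg = gafit.GAConfig(
            population_size=int(fcfg.get("population_size", 50)),
            generations=int(fcfg.get("generations", 30)),
            n_reps=int(fcfg.get("n_reps", 3)),
            master_seed=int(config.get("seed", 0)),
        )
        fitted = gafit.fit_parameters(
            ts, gacfg,
            window_length=int(config.get("extract", {}).get("window_length", 30)),
            step=int(config.get("extract", {}).get("step", 10)),
        )
        payload = {
            "best_params": dataclasses.asdict(fitted.best_params),
            "best_psac": fitted.best_psac,
            "generation_history": fitted.generation_history,
            "seeds_used": list(fitted.seeds_used),
        }
        (out / "fitted.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        register(out / "fitted.json")
        pattern = fitted.pattern

    sim_bold = None
    if "simulate" in stages:
        if pattern is None:
            raise ConfigError("simulate stage requires extract or fit first")
        scfg = config.get("simulate", {})
        params = (fitted.best_params if fitted is not None
                  else DMFParameters(**scfg.get("params", {})))
        seed = int(scfg.get("seed", config.get("seed", 0)))
        traj = simulate_dmf(
            pattern, params,
            duration_seconds=float(scfg.get("duration_seconds", 300.0))
            + float(scfg.get("burn_in_seconds", 60.0)),
            dt_seconds=float(scfg.get("dt_seconds", 0.001)),
            seed=seed,
        )
        sim_bold = balloon_bold(
            traj, tr_out_seconds=float(scfg.get("tr_seconds", ts.tr_seconds)),
            burn_in_seconds=float(scfg.get("burn_in_seconds", 60.0)),
        )
        write_timeseries(sim_bold, out / "simulated_bold.tsv")
        register(out / "simulated_bold.tsv")

    if "evaluate" in stages:
        vcfg = config.get("evaluate", {})
        target = sim_bold if sim_bold is not None else ts
        report = evaluate_series(
            target, reference=ts if sim_bold is not None else None,
            window_length=int(vcfg.get("window_length", 30)),
            step=int(vcfg.get("step", 10)),
            density=float(vcfg.get("density", 0.15)),
            band=tuple(vcfg.get("band", (0.01, 0.1))),
        )
        (out / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        register(out / "metrics.json")

    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def evaluate_series(
    ts: ParcellatedTimeSeries,
    reference: ParcellatedTimeSeries | None = None,
    window_length: int = 30,
    step: int = 10,
    density: float = 0.15,
    band: tuple[float, float] = (0.01, 0.1),
) -> dict:
    """JSON-serializable metric report, optionally against a reference."""
    fc = metrics.static_fc(ts)
    _, sigma_dfc, fcd = metrics.dynamic_fc(ts, window_length, step)
    gm = metrics.graph_metrics(fc, density=density)
    report: dict = {
        "graph": dataclasses.asdict(gm),
        "sigma_dfc_mean": float(sigma_dfc[np.triu_indices(fc.shape[0], 1)].mean()),
    }
    try:
        pd_sum = metrics.phase_dynamics(ts, band=band, window_length=window_length,
                                        step=step)
        report["synchrony"] = pd_sum.synchrony
        report["metastability"] = pd_sum.metastability
        report["integration"] = pd_sum.integration
        report["segregation"] = pd_sum.segregation
        report["isor"] = pd_sum.isor
    except metrics.NyquistError:
        report["synchrony"] = None
    if reference is not None:
        ref_fc = metrics.static_fc(reference)
        edge_r, node_r = metrics.fc_similarity(ref_fc, fc)
        _, ref_sdfc, ref_fcd = metrics.dynamic_fc(reference, window_length, step)
        report["fc_edge_r"] = edge_r
        report["fc_node_r"] = node_r
        report["dfc_r"] = metrics.dfc_similarity(ref_sdfc, sigma_dfc)
        report["fcd_ks"] = metrics.fcd_ks(ref_fcd, fcd)
        fa, pa = metrics.power_spectrum(reference)
        fb, pb = metrics.power_spectrum(ts)
        if fa.shape == fb.shape:
            report["spectral_cosine_distance"] = metrics.spectral_cosine_distance(pa, pb)
    return report


def omega_sweep(
    pattern: coactivity.CoactivityPattern,
    base_params: DMFParameters,
    omega_values,
    seeds,
    duration_seconds: float = 150.0,
    tr_out_seconds: float = 0.72,
    dt_seconds: float = 0.001,
    burn_in_seconds: float = 60.0,
    band: tuple[float, float] = (0.01, 0.1),
    window_length: int = 30,
    step: int = 10,
    density: float = 0.15,
) -> pd.DataFrame:
    """One simulation + metric row per (omega, seed); failures are flagged."""
    rows = []
    for omega in omega_values:
        if omega < 0:
            raise ValueError("omega values must be nonnegative")
        for seed in seeds:
            row = {"omega": float(omega), "seed": int(seed), "failed": False}
            try:
                params = base_params.replace(omega=float(omega))
                traj = simulate_dmf(pattern, params,
                                    duration_seconds + burn_in_seconds,
                                    dt_seconds=dt_seconds, seed=int(seed))
                bold = balloon_bold(traj, tr_out_seconds=tr_out_seconds,
                                    burn_in_seconds=burn_in_seconds)
                pd_sum = metrics.phase_dynamics(bold, band=band,
                                                window_length=window_length,
                                                step=step)
                gm = metrics.graph_metrics(metrics.static_fc(bold), density=density)
                row.update(
                    synchrony=pd_sum.synchrony, metastability=pd_sum.metastability,
                    integration=pd_sum.integration, segregation=pd_sum.segregation,
                    clustering=gm.clustering, path_length=gm.path_length,
                    global_efficiency=gm.global_efficiency,
                )
            except (DivergenceError, ValueError) as exc:
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def window_sweep(
    ts: ParcellatedTimeSeries,
    window_lengths,
    steps,
    opts: coactivity.FusedRpcaOptions | None = None,
) -> pd.DataFrame:
    """Split-half pattern stability per (window_length, step) setting."""
    rows = []
    first, second = gafit.split_half(ts)
    for w in window_lengths:
        for s in steps:
            row = {"window_length": int(w), "step": int(s), "failed": False}
            try:
                p1, _ = coactivity.extract_pattern(first, int(w), int(s), opts)
                p2, _ = coactivity.extract_pattern(second, int(w), int(s), opts)
                row["split_half_r"] = coactivity.pattern_correlation(p1, p2)
            except ValueError as exc:
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def _version() -> str:
    from . import __version__

    return __version__
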