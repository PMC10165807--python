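"""Config-driven orchestration of the analysis stages.

A run config (YAML-serializable dict wrapped in ``RunConfig``) selects
stages and carries every stage parameter, including all seeds; stages
execute in dependency order simulate -> piv -> {kinetics | orient |
strain} -> stability, each persisting its outputs so re-running a config
reproduces them byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, io, kinetics, orientation, stability, strainmap, synthgen
from .core import IlluminationSchedule, RectRegion
from .flowfield import speed_trace as _speed_trace

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

STAGES = ("simulate", "piv", "kinetics", "orient", "strain", "stability")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``params`` maps each selected stage name to its parameter dict; every
    stochastic stage must carry an explicit integer ``seed``.
    """

    stages: list[str]
    outdir: str
    params: dict[str, dict[str, Any]] = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
        if "simulate" in self.stages:
            sim = self.params.get("simulate", {})
            if "seed" not in sim:
                raise ValueError("simulate stage requires an explicit 'seed'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(stages=list(data["stages"]), outdir=str(data["outdir"]),
                   params={k: dict(v) for k, v in data.get("params", {}).items()})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {"stages": self.stages, "outdir": self.outdir, "params": self.params},
            sort_keys=False,
        ))

    def digest(self) -> str:
        blob = json.dumps(
            {"stages": self.stages, "params": self.params}, sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """What a pipeline run did: parameters, outputs, warnings, provenance."""

    stages_run: list[str]
    outputs: dict[str, list[str]]
    parameters: dict[str, dict[str, Any]]
    warnings: list[str]
    version: str
    config_hash: str
    results: dict[str, Any] = dfield(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _schedule_from_params(p: dict) -> IlluminationSchedule:
    if "schedule_file" in p:
        return io.read_schedule(p["schedule_file"])
    region = RectRegion(**p["region"]) if p.get("region") else None
    from .core import cycles_schedule

    return cycles_schedule(
        n_cycles=p.get("n_cycles", 1), on_s=p["on_s"], off_s=p["off_s"],
        intensity=p.get("intensity", 1.0), region=region,
        start_dark_s=p.get("start_dark_s", 0.0),
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the selected stages in dependency order."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        stages_run=[], outputs={}, parameters={}, warnings=[],
        version=__version__, config_hash=config.digest(),
    )

    def _require(path: Path, producer: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing input {path.name!r}: run the {producer!r} stage first "
                f"or point the config at an existing file"
            )
        return path

    ordered = [s for s in STAGES if s in config.stages]
    for stage in ordered:
        p = dict(config.params.get(stage, {}))
        report.parameters[stage] = p
        written: list[str] = []

        if stage == "simulate":
            schedule = _schedule_from_params(p)
            io.write_schedule(schedule, out / "schedule.yaml")
            written.append("schedule.yaml")
            texture = synthgen.gen_texture(
                seed=p["seed"], shape=tuple(p.get("shape", (256, 256))),
                orientation=p.get("orientation", 0.0),
                correlation_length=p.get("correlation_length", 6.0),
                px_size=p.get("px_size", 1.0),
            )
            flow = synthgen.FlowSpec(**p.get("flow", {"kind": "uniform", "speed": 1.0}))
            seq = synthgen.render_sequence(
                texture, flow, schedule, n_frames=p.get("n_frames", 10),
                dt=p.get("dt", 1.0), px_size=p.get("px_size", 1.0),
                noise_sd=p.get("noise_sd", 0.0), seed=p["seed"],
            )
            io.write_sequence(seq, out / "sequence.tif")
            written.append("sequence.tif")

        elif stage == "piv":
            seq = io.read_sequence(_require(Path(p.get("sequence", out / "sequence.tif")), "simulate"))
            schedule = io.read_schedule(_require(Path(p.get("schedule", out / "schedule.yaml")), "simulate"))
            trace = _speed_trace(
                seq, schedule, window_px=p.get("window", 32),
                overlap_px=p.get("overlap", 16),
                outlier_threshold=p.get("outlier_threshold", 2.0),
            )
            io.write_speed_trace(trace, out / "speed_trace.csv")
            written.append("speed_trace.csv")
            report.results["mean_speed_um_s"] = float(np.mean(trace.speed))

        elif stage == "kinetics":
            trace = io.read_speed_trace(_require(Path(p.get("trace", out / "speed_trace.csv")), "piv"))
            schedule = io.read_schedule(_require(Path(p.get("schedule", out / "schedule.yaml")), "simulate"))
            segs = kinetics.segment_cycles(schedule, span=(trace.times[0], trace.times[-1] + 1e-9))
            fits: dict[str, Any] = {}
            for label, a, b in segs:
                if label == "on":
                    seg = trace.restrict(a, b)
                    if len(seg) >= 5:
                        f = kinetics.fit_activation(seg)
                        fits["activation"] = {"vmax": f.vmax, "tau_on": f.tau_on,
                                              "tau_on_se": f.tau_on_se}
                        break
            try:
                seg = kinetics.normalized_deactivation_segment(trace, schedule)
                if len(seg) >= 5:
                    f2 = kinetics.fit_deactivation(seg)
                    fits["deactivation"] = {"tau_off": f2.tau_off, "tau_off_se": f2.tau_off_se}
            except (ValueError, kinetics.FitError) as exc:
                report.warnings.append(f"kinetics: deactivation fit skipped ({exc})")
            (out / "kinetics_fits.json").write_text(json.dumps(fits, indent=2))
            written.append("kinetics_fits.json")
            report.results["kinetics"] = fits

        elif stage == "orient":
            seq = io.read_sequence(_require(Path(p.get("sequence", out / "sequence.tif")), "simulate"))
            schedule = io.read_schedule(_require(Path(p.get("schedule", out / "schedule.yaml")), "simulate"))
            trace = orientation.angle_trace(
                seq, theta0=p.get("theta0", 0.0), schedule=schedule,
                sigma_grad=p.get("sigma_grad", 1.5),
                sigma_window=p.get("sigma_window", 5.0),
                coherence_min=p.get("coherence_min", 0.3),
            )
            io.write_angle_trace(trace, out / "angle_trace.csv")
            written.append("angle_trace.csv")

        elif stage == "strain":
            seq = io.read_sequence(_require(Path(p.get("sequence", out / "sequence.tif")), "simulate"))
            from .flowfield import filter_outliers, piv_pair

            fields = []
            for k in range(len(seq) - 1):
                fld = piv_pair(seq.frames[k], seq.frames[k + 1], dt=seq.dt_s,
                               px_size=seq.px_size_um, window_px=p.get("window", 32),
                               overlap_px=p.get("overlap", 16))
                fields.append(filter_outliers(fld))
            disp = strainmap.accumulate_displacement(fields, dt=seq.dt_s)
            region = RectRegion(**p["region"])
            st = strainmap.strain_trace(disp, region)
            import pandas as pd

            pd.DataFrame({"time_s": st.times, "gamma_xx": st.gamma_xx,
                          "gamma_yy": st.gamma_yy}).to_csv(out / "strain_trace.csv", index=False)
            written.append("strain_trace.csv")
            label = strainmap.classify_regime(st, eps_x=p.get("eps_x", 0.005),
                                              eps_y=p.get("eps_y", 0.005))
            report.results["regime"] = label
            report.results["delta_gamma_yy"] = st.delta_gamma_yy

        elif stage == "stability":
            df = io.read_threshold_dataset(_require(Path(p["dataset"]), "simulate"))
            fit = stability.fit_activity_coefficient(df)
            gen = stability.fit_generic_scaling(df)
            res = {"a": fit.a, "a_se": fit.se, "gA": gen.gA, "gC": gen.gC}
            (out / "stability_fit.json").write_text(json.dumps(res, indent=2))
            written.append("stability_fit.json")
            report.results["stability"] = res

        report.stages_run.append(stage)
        report.outputs[stage] = written

    report.to_json(out / "run_report.json")
    return report
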