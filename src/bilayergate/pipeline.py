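"""Configuration-driven pipeline runner with a reproducibility manifest.

A :class:`RunConfig` selects stages and carries their parameters; unknown
keys are rejected up front and every default is made explicit in the run
manifest, so any number in any output can be recomputed from the manifest
alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import InvalidParameterError
from .gating import (
    FluxTimeCourse,
    detect_levels,
    flux_normalize,
    idealize,
    open_probability,
    select_components,
)
from .geometry import HELIX_PRESETS, align_to_pore_axis, helix_kink, helix_tilt
from .io import read_pdb, read_scattering_csv, write_json
from .saxs import analyze_curve

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("bilayergate")

_STAGE_KEYS = {
    "saxs": {"input", "buffer", "orders", "phases", "q_min", "q_unit"},
    "geom": {"pdb", "presets", "pore_residues"},
    "gating": {"trace", "fs", "voltage", "filter_hz", "dead_time", "k_max"},
    "flux": {"times", "counts", "background", "valinomycin", "at_time"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` maps stage names (saxs / geom / gating / flux) to parameter
    dicts; ``out`` is the manifest path; ``seed`` feeds any stochastic
    stage.  Unknown stages or stage keys raise immediately.
    """

    stages: dict
    out: str = "run_manifest.json"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.extra:
            raise InvalidParameterError(f"unknown top-level config keys: {sorted(self.extra)}")
        for stage, params in self.stages.items():
            if stage not in _STAGE_KEYS:
                raise InvalidParameterError(f"unknown stage {stage!r}")
            bad = set(params) - _STAGE_KEYS[stage]
            if bad:
                raise InvalidParameterError(f"unknown keys in stage {stage!r}: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        stages = d.pop("stages", {})
        out = d.pop("out", "run_manifest.json")
        seed = d.pop("seed", 0)
        return cls(stages=stages, out=out, seed=seed, extra=d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _check_inputs(config: RunConfig) -> None:
    for stage, params in config.stages.items():
        for key in ("input", "buffer", "pdb", "trace"):
            p = params.get(key)
            if p is not None and not Path(p).exists():
                raise InvalidParameterError(f"stage {stage!r}: input path {p} does not exist")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write the JSON manifest.

    Any stage failure aborts the run with that stage's diagnostic; the
    manifest records inputs, explicit parameters, library versions, the
    seed, and every derived value.
    """
    _check_inputs(config)
    manifest: dict = {
        "versions": {
            "bilayergate": __version__,
            "numpy": np.__version__,
        },
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for stage, params in config.stages.items():
            log.info("running stage %s", stage)
            runner = globals()[f"_run_{stage}"]
            manifest["stages"][stage] = runner(params, config)
        manifest["warnings"] = [
            {"category": w.category.__name__, "message": str(w.message)} for w in caught
        ]
    write_json(config.out, manifest)
    return manifest


def _run_saxs(params: dict, config: RunConfig) -> dict:
    curve = read_scattering_csv(params["input"], q_unit=params.get("q_unit", "A^-1"))
    buffer = (
        read_scattering_csv(params["buffer"], q_unit=params.get("q_unit", "A^-1"))
        if params.get("buffer")
        else None
    )
    report = analyze_curve(
        curve,
        buffer=buffer,
        n_orders=int(params.get("orders", 2)),
        phases=params.get("phases"),
        q_min=float(params.get("q_min", 0.05)),
    )
    out = report.as_dict()
    out["parameters"] = {
        "input": str(params["input"]),
        "buffer": str(params.get("buffer")) if params.get("buffer") else None,
        "orders": int(params.get("orders", 2)),
        "phases": list(report.phases),
        "q_min": float(params.get("q_min", 0.05)),
        "q_unit": params.get("q_unit", "A^-1"),
    }
    return out


def _run_geom(params: dict, config: RunConfig) -> dict:
    frames = read_pdb(params["pdb"])
    pore = tuple(params.get("pore_residues", (75, 76, 77, 78, 79)))
    presets = params.get("presets", ["kcsa-m1", "kcsa-m2"])
    aligned = align_to_pore_axis(frames[0], pore_residues=pore)
    out = {
        "parameters": {
            "pdb": str(params["pdb"]),
            "pore_residues": list(pore),
            "presets": list(presets),
        },
        "helices": {},
    }
    for name in presets:
        spec = HELIX_PRESETS[name]
        tilt = helix_tilt(aligned, spec)
        kink = helix_kink(aligned, spec)
        out["helices"][name] = {
            "tilt_deg": tilt.to_dict(),
            "tilt_mean_deg": float(tilt.mean()),
            "kink_deg": kink.to_dict(),
            "kink_mean_deg": float(kink.mean()),
        }
    return out


def _run_gating(params: dict, config: RunConfig) -> dict:
    import pandas as pd

    from .gating import CurrentTrace

    df = pd.read_csv(params["trace"])
    col = df.columns[-1]
    trace = CurrentTrace(
        df[col].to_numpy(dtype=float),
        fs=float(params["fs"]),
        filter_hz=float(params.get("filter_hz", 2000.0)),
        voltage=float(params.get("voltage", 0.0)),
    )
    dead_time = float(params.get("dead_time", 0.3))
    levels = detect_levels(trace)
    ideal = idealize(trace, levels, dead_time=dead_time)
    result = {
        "parameters": {
            "trace": str(params["trace"]),
            "fs": trace.fs,
            "filter_hz": trace.filter_hz,
            "voltage": trace.voltage,
            "dead_time": dead_time,
            "k_max": int(params.get("k_max", 4)),
        },
        "levels": {
            "closed_pA": levels.closed_level,
            "open_pA": levels.open_level,
            "i_unitary_pA": levels.i_unitary,
        },
        "open_probability": open_probability(ideal),
        "n_events": len(ideal.events),
    }
    for state in ("open", "closed"):
        durs = ideal.durations(state)
        if durs.size >= 10:
            fit = select_components(durs, dead_time=dead_time, k_max=int(params.get("k_max", 4)))
            result[f"{state}_dwell_fit"] = {
                "components_ms": fit.components,
                "bic": fit.bic,
                "n_events": fit.n_events,
            }
    return result


def _run_flux(params: dict, config: RunConfig) -> dict:
    fc = FluxTimeCourse(
        times=np.asarray(params["times"], dtype=float),
        counts=np.asarray(params["counts"], dtype=float),
        background=float(params["background"]),
        valinomycin=float(params["valinomycin"]),
    )
    norm = flux_normalize(fc)
    out = {
        "parameters": {
            "background": fc.background,
            "valinomycin": fc.valinomycin,
        },
        "times_s": fc.times.tolist(),
        "normalized_uptake": norm.tolist(),
    }
    at = params.get("at_time")
    if at is not None:
        idx = int(np.argmin(np.abs(fc.times - float(at))))
        out["normalized_at_time"] = {"time_s": float(fc.times[idx]), "value": float(norm[idx])}
    return out
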