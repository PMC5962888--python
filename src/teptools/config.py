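"""Run configuration: typed, TOML-serializable, strictly validated.

A :class:`RunConfig` fully determines an end-to-end run: montage/head
geometry, simulation scenario, preprocessing thresholds, analysis windows,
source-imaging parameters and statistics options.  Unknown keys in a TOML
file are rejected so silent typos cannot change a run, and a config
round-trips load -> dump -> load unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Raised for malformed run configurations."""


@dataclass
class SimulationConfig:
    n_subjects: int = 15
    n_trials: int = 180
    fs: float = 1450.0
    g_during: float = 1.0
    g_post: float = 1.0
    seed: int = 0


@dataclass
class GeometryConfig:
    n_sources: int = 3004
    source_radius_mm: float = 76.0
    radii_mm: list = field(default_factory=lambda: [92.0, 85.0, 81.0])
    conductivities: list = field(default_factory=lambda: [0.33, 0.0042, 0.33])
    n_terms: int = 60


@dataclass
class PreprocessingConfig:
    target_fs: float = 725.0
    abs_amplitude_limit: float = 100.0
    eog_limit: float = 70.0
    hf_power_limit: float = 0.5
    band_low: float = 2.0
    band_high: float = 40.0
    baseline_ms: list = field(default_factory=lambda: [-300.0, -50.0])


@dataclass
class SourceConfig:
    snr: float = 3.0
    smoothing_sigma_mm: float = 10.0
    depth_exponent: float = 1.0
    alpha: float = 0.05
    n_permutations: int = 500


@dataclass
class StatsConfig:
    log_scale: bool = True
    alpha: float = 0.05


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    source: SourceConfig = field(default_factory=SourceConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    output_dir: str = "teptools_output"
    reduced: bool = False

    def validated(self) -> "RunConfig":
        sim, geo, pre, src = self.simulation, self.geometry, self.preprocessing, self.source
        if sim.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if sim.g_during < 0 or sim.g_post < 0:
            raise ConfigError("condition gains must be nonnegative")
        if not (geo.radii_mm[0] > geo.radii_mm[1] > geo.radii_mm[2] > 0):
            raise ConfigError("shell radii must be strictly decreasing")
        if geo.source_radius_mm >= geo.radii_mm[2]:
            raise ConfigError("source radius must lie inside the inner skull")
        if not (0 < pre.band_low < pre.band_high < pre.target_fs / 2):
            raise ConfigError("filter band outside (0, fs/2)")
        if src.n_permutations < 20:
            raise ConfigError("n_permutations must be >= 20")
        if not (0 < src.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        return self

    def effective_geometry(self) -> GeometryConfig:
        """Geometry after applying the reduced-resolution switch."""
        geo = dataclasses.replace(self.geometry)
        if self.reduced:
            geo.n_sources = min(geo.n_sources, 812)
        return geo

    def effective_n_permutations(self) -> int:
        return min(self.source.n_permutations, 100) if self.reduced else self.source.n_permutations


_SECTIONS = {
    "simulation": SimulationConfig,
    "geometry": GeometryConfig,
    "preprocessing": PreprocessingConfig,
    "source": SourceConfig,
    "stats": StatsConfig,
}


def _build_section(cls, data: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load a TOML run configuration, rejecting unknown keys."""
    import tomllib

    raw = tomllib.loads(Path(path).read_text())
    top_known = set(_SECTIONS) | {"output_dir", "reduced"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ConfigError(f"[{name}] must be a table")
            kwargs[name] = _build_section(cls, raw[name], name)
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    if "reduced" in raw:
        kwargs["reduced"] = bool(raw["reduced"])
    return RunConfig(**kwargs).validated()


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ConfigError(f"cannot serialize {type(v)} to TOML")


def dump_config(config: RunConfig, path) -> None:
    """Write the configuration as TOML (round-trips with load_config)."""
    lines = [
        f"output_dir = {_toml_value(config.output_dir)}",
        f"reduced = {_toml_value(config.reduced)}",
    ]
    for name in _SECTIONS:
        section = getattr(config, name)
        lines.append(f"\n[{name}]")
        for f in dataclasses.fields(section):
            lines.append(f"{f.name} = {_toml_value(getattr(section, f.name))}")
    Path(path).write_text("\n".join(lines) + "\n")
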