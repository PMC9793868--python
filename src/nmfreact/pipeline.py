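"""End-to-end runs: simulate (or load) → preprocess → extract → match/reactivate.

A run is described by a flat, human-editable YAML config; unknown keys are
errors so typos fail fast.  One top-level seed deterministically derives a
per-stage seed (by hashing the stage name into the seed sequence) so stages
can be re-run in isolation and the whole run is reproducible: re-running with
the same config reproduces every numeric field of the report exactly (only
timing fields differ, and they are excluded from determinism checks).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .extract import EnsembleSet, FactorizationConfig, extract_ensembles
from .match import MatchConfig, matching_score, reactivation_analysis
from .preprocess import (EventDetectionConfig, bin_traces, compute_dff,
                         detect_events, highpass_filter, zscore_rectify)
from .synthetic import (SimulationParams, generate_session_pair,
                        generate_session_trio)

logger = logging.getLogger("nmfreact")

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Malformed run configuration."""


def _stage_seed(seed: int, stage: str) -> int:
    # derive a stable 31-bit per-stage seed from the run seed and stage name
    return (int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


@dataclass(frozen=True)
class PreprocessingConfig:
    cutoff_hz: float = 0.01
    bin_frames: int = 4


@dataclass(frozen=True)
class SimulationSection:
    """Simulation request: a pair (day1/day2) or a trio (day1/rest/day2)."""

    mode: str = "pair"              # "pair" | "trio"
    n_rest_shared: int = 3          # trio only
    n_day2_from_rest: int = 2       # trio only
    n_rest_fresh: int = 0
    n_day2_fresh: int = 0
    params: SimulationParams = field(default_factory=SimulationParams)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "nmfreact_run"
    log_level: str = "INFO"
    simulation: SimulationSection | None = field(default_factory=SimulationSection)
    input_paths: tuple[str, ...] | None = None
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    events: EventDetectionConfig = field(default_factory=EventDetectionConfig)
    factorization: FactorizationConfig = field(default_factory=FactorizationConfig)
    matching: MatchConfig = field(default_factory=MatchConfig)

    def __post_init__(self) -> None:
        if self.simulation is None and not self.input_paths:
            raise ConfigError("config needs either a simulation section or input_paths")
        if self.input_paths is not None and len(self.input_paths) not in (2, 3):
            raise ConfigError("input_paths must list 2 (pair) or 3 (trio) sessions")


_SECTION_TYPES = {
    "preprocessing": PreprocessingConfig,
    "events": EventDetectionConfig,
    "factorization": FactorizationConfig,
    "matching": MatchConfig,
}


def _build_section(cls, mapping: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in config section {section!r}")
    if cls is FactorizationConfig and "rank_range" in mapping:
        mapping = {**mapping, "rank_range": tuple(mapping["rank_range"])}
    return cls(**mapping)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    top_allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    kwargs: dict = {}
    for key, val in raw.items():
        if key == "simulation":
            if val is None:
                kwargs["simulation"] = None
                continue
            sim_allowed = {f.name for f in dataclasses.fields(SimulationSection)} - {"params"}
            sim_kwargs = {k: v for k, v in val.items() if k in sim_allowed}
            param_keys = {f.name for f in dataclasses.fields(SimulationParams)}
            param_kwargs = {k: v for k, v in val.items() if k in param_keys}
            unknown = set(val) - sim_allowed - param_keys
            if unknown:
                raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)} in 'simulation'")
            kwargs["simulation"] = SimulationSection(
                **sim_kwargs, params=SimulationParams(**param_kwargs))
        elif key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], val or {}, key)
        elif key == "input_paths":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    version: str
    session_ids: list
    n_ensembles: dict
    rank_tables: dict
    event_means: dict
    matching_score: float
    planted_ms: float | None
    reactivation: dict | None
    timing_s: dict

    def to_dict(self, include_timing: bool = True) -> dict:
        doc = dataclasses.asdict(self)
        if not include_timing:
            doc.pop("timing_s")
        return doc

    def content_hash(self) -> str:
        """Stable hash of all numeric fields, timing excluded."""
        import hashlib
        payload = json.dumps(self.to_dict(include_timing=False), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _prepare_sessions(cfg: RunConfig):
    """Return (list of FluorescenceMatrix, planted ideal MS or None)."""
    if cfg.input_paths:
        for p in cfg.input_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"trace file not found: {p}")
        return [nio.read_trace_matrix(p) for p in cfg.input_paths], None
    sim = cfg.simulation
    params = dataclasses.replace(sim.params, seed=_stage_seed(cfg.seed, "simulate"))
    if sim.mode == "pair":
        ses_a, ses_b, shared_map = generate_session_pair(params)
        planted_ms = len(shared_map) / params.n_ensembles
        return [ses_a.traces, ses_b.traces], planted_ms
    if sim.mode == "trio":
        day1, rest, day2, rest_map, _ = generate_session_trio(
            params, sim.n_rest_shared, sim.n_day2_from_rest,
            sim.n_rest_fresh, sim.n_day2_fresh)
        return [day1.traces, rest.traces, day2.traces], None
    raise ConfigError(f"unknown simulation mode {sim.mode!r}")


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages in order, persisting every intermediate artifact.

    Raises the first stage error annotated with the stage name and session
    id; artifacts written before the failure are retained for debugging.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timing: dict[str, float] = {}

    t0 = time.perf_counter()
    sessions, planted_ms = _prepare_sessions(cfg)
    timing["prepare"] = time.perf_counter() - t0
    session_ids = []
    for i, ses in enumerate(sessions):
        if not ses.session_id:
            ses.session_id = f"session{i}"
        session_ids.append(ses.session_id)
        nio.write_trace_matrix(ses, out / f"{ses.session_id}_raw.csv")
    logger.info("run: %d session(s) %s, %s frames × %s neurons",
                len(sessions), session_ids, sessions[0].n_frames, sessions[0].n_neurons)

    ensembles: list[EnsembleSet] = []
    n_ens, tables, event_means = {}, {}, {}
    for ses in sessions:
        sid = ses.session_id
        try:
            t0 = time.perf_counter()
            dff = compute_dff(ses)
            counts = detect_events(dff, cfg.events)
            event_means[sid] = counts.per_session_mean
            nio.write_event_counts_csv(counts, out / f"{sid}_events.csv")
            binned = bin_traces(
                zscore_rectify(highpass_filter(dff, cfg.preprocessing.cutoff_hz)),
                cfg.preprocessing.bin_frames)
            timing[f"preprocess:{sid}"] = time.perf_counter() - t0
            logger.info("preprocess[%s]: %d frames -> %d bins × %d neurons",
                        sid, ses.n_frames, binned.n_bins, binned.n_neurons)

            t0 = time.perf_counter()
            fac_cfg = dataclasses.replace(
                cfg.factorization, seed=_stage_seed(cfg.seed, f"extract:{sid}"))
            ens, table = extract_ensembles(binned, fac_cfg)
            timing[f"extract:{sid}"] = time.perf_counter() - t0
            ensembles.append(ens)
            n_ens[sid] = ens.n_ensembles
            tables[sid] = table.to_dict()
            nio.write_ensembles_json(ens, out / f"{sid}_ensembles.json")
            nio.write_rank_table_csv(table, out / f"{sid}_rank_table.csv")
            logger.info("extract[%s]: chose rank %d (cost %.4g)",
                        sid, table.chosen_rank, ens.cost)
        except Exception as err:
            raise RuntimeError(f"stage failed for session {sid!r}: {err}") from err

    t0 = time.perf_counter()
    first, last = ensembles[0], ensembles[-1]
    match = matching_score(first, last, cfg.matching)
    nio.write_similarity_csv(match.similarity.values,
                             out / f"similarity_{first.session_id}_{last.session_id}.csv")
    nio.plot_similarity_heatmap(match.similarity.values,
                                out / f"similarity_{first.session_id}_{last.session_id}.png",
                                first.session_id, last.session_id)
    reactivation = None
    if len(ensembles) == 3:
        res = reactivation_analysis(ensembles[0], ensembles[1], ensembles[2], cfg.matching)
        reactivation = dataclasses.asdict(res)
    timing["match"] = time.perf_counter() - t0

    report = RunReport(
        config=_config_dict(cfg), version=__version__, session_ids=session_ids,
        n_ensembles=n_ens, rank_tables=tables, event_means=event_means,
        matching_score=match.matching_score, planted_ms=planted_ms,
        reactivation=reactivation, timing_s=timing)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    return report


def _config_dict(cfg: RunConfig) -> dict:
    doc = dataclasses.asdict(cfg)
    if doc.get("input_paths") is not None:
        doc["input_paths"] = list(doc["input_paths"])
    fac = doc.get("factorization")
    if fac:
        fac["rank_range"] = list(fac["rank_range"])
    return doc
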