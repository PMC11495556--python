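"""End-to-end orchestration: ingest -> dedup -> filter -> screen -> TTO.

A run is driven by a single YAML config naming either the five input
tables or a synthetic-generation block, and writes a manifest recording
input checksums, per-stage counts, the config snapshot and seeds, so
every dropped record is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .descriptives import summarize_characteristics
from .disprop import Level, Unit, ZeroCellPolicy, screen_signals
from .faers_io import ParseLog, read_quarter_tables
from .preprocess import AnalysisCase, FlowManifest, MeddraMap, assemble_case_table
from .synthetic import SyntheticConfig, generate_dataset
from .time_to_onset import DEFAULT_BIN_EDGES, collect_onsets, summarize_tto

__all__ = ["ConfigError", "DataError", "PipelineResult", "RunManifest", "run_pipeline"]


class ConfigError(ValueError):
    """Bad or incomplete run configuration."""


class DataError(RuntimeError):
    """Input data failed a fatal validation."""


@dataclass
class RunManifest:
    inputs: list[dict] = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    started: str = ""
    finished: str = ""
    status: str = "running"
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str),
                        encoding="utf-8")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def _read_term_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: RunManifest
    cases: list[AnalysisCase]
    flow: FlowManifest


def load_config(config: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    with open(config, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return data


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path) -> PipelineResult:
    """Execute the whole analysis and write all outputs to ``out_dir``.

    Outputs: manifest.json, characteristics.csv, signals_soc.csv,
    signals_pt.csv, unexpected_pt.csv, tto_summary.csv, tto_cases.csv and
    run.log. Deterministic given fixed inputs and seed. Raises
    :class:`ConfigError` before any output exists; later failures leave a
    manifest recording the failed stage.
    """
    cfg = load_config(config)
    out_dir = Path(out_dir)

    target_names = cfg.get("target_names") or []
    if not target_names:
        raise ConfigError("config must list target_names")
    level_cfg = cfg.get("level", "both")
    if level_cfg not in ("pt", "soc", "both"):
        raise ConfigError("level must be pt, soc, or both")
    unit = Unit(cfg.get("unit", Unit.PAIR.value))
    policy = ZeroCellPolicy(cfg.get("zero_cell", "undefined"))
    seed = cfg.get("seed")
    has_inputs = "inputs" in cfg
    has_synth = "synthetic" in cfg
    if has_inputs == has_synth:
        raise ConfigError("config must name either 'inputs' or a 'synthetic' block")

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed, started=_now())
    manifest_path = out_dir / "manifest.json"
    log_lines: list[str] = []
    stage = "ingest"
    try:
        parse_log = ParseLog()
        if has_synth:
            synth_cfg = dict(cfg["synthetic"])
            if seed is not None:
                synth_cfg.setdefault("seed", seed)
            scfg = SyntheticConfig.from_dict(synth_cfg)
            manifest.seed = scfg.seed
            bundle, truth = generate_dataset(scfg)
            meddra = truth.meddra_map()
            log_lines.append(f"synthetic generation: {len(bundle)} demo rows, seed {scfg.seed}")
        else:
            paths = {k: Path(v) for k, v in cfg["inputs"].items()}
            bundle, parse_log = read_quarter_tables(paths, cfg.get("quarter_label", ""))
            manifest.inputs = [
                {"table": k, "path": str(p), "sha256": _sha256(p)} for k, p in paths.items()
            ]
            if "meddra_map" not in cfg:
                raise ConfigError("config must name a meddra_map for file inputs")
            meddra = MeddraMap.from_file(cfg["meddra_map"])
            log_lines.append(
                f"ingest: {len(bundle)} demo rows, {parse_log.n_rejected} rejected rows, "
                f"{parse_log.n_warnings} warnings"
            )

        stage = "preprocess"
        cases, flow = assemble_case_table(
            bundle, target_names, meddra,
            substring=bool(cfg.get("substring_match", False)),
            year_field=cfg.get("year_field", "fda_dt"),
            log=parse_log,
        )
        if flow.target_ps == 0:
            log_lines.append("warning: no target primary-suspect reports found")
        log_lines.append(f"flow: {flow.as_dict()}")
        if flow.unmapped_pts:
            log_lines.append(f"unmapped PTs ({len(flow.unmapped_pts)}): "
                             + ", ".join(flow.unmapped_pts[:20]))

        stage = "descriptives"
        target_cases = [case for case in cases if case.is_target]
        if target_cases:
            chars = summarize_characteristics(
                target_cases, top_n_countries=int(cfg.get("top_n_countries", 5)), log=parse_log
            )
            chars.to_csv(out_dir / "characteristics.csv")

        stage = "screen"
        label_pts = _read_term_list(cfg["label_pts"]) if cfg.get("label_pts") else None
        exclusions = _read_term_list(cfg["exclusions"]) if cfg.get("exclusions") else None
        n_significant: dict[str, int] = {}
        if level_cfg in ("soc", "both"):
            soc_df = screen_signals(cases, level=Level.SOC, unit=unit, policy=policy,
                                    exclusions=exclusions)
            soc_df.to_csv(out_dir / "signals_soc.csv", index=False)
            n_significant["soc"] = int(soc_df["significant"].sum())
        if level_cfg in ("pt", "both"):
            pt_df = screen_signals(cases, level=Level.PT, unit=unit, policy=policy,
                                   exclusions=exclusions, label_pts=label_pts, meddra=meddra)
            pt_df.to_csv(out_dir / "signals_pt.csv", index=False)
            n_significant["pt"] = int(pt_df["significant"].sum())
            unexpected = pt_df[pt_df["unexpected"] == True]  # noqa: E712 - NA-aware
            unexpected.to_csv(out_dir / "unexpected_pt.csv", index=False)

        stage = "tto"
        edges = tuple(cfg.get("tto_bin_edges", DEFAULT_BIN_EDGES))
        onsets, audit = collect_onsets(cases, edges)
        summary = summarize_tto([r.tto_days for r in onsets], edges)
        summary.to_csv(out_dir / "tto_summary.csv")
        audit.to_csv(out_dir / "tto_cases.csv", index=False)
        excluded = audit["excluded_reason"].value_counts().to_dict()
        log_lines.append(f"tto: {summary.n} computable, excluded {excluded}")

        manifest.stage_counts = {
            **flow.as_dict(),
            "rejected_rows": parse_log.n_rejected,
            "parse_warnings": parse_log.n_warnings,
            "tto_computable": summary.n,
            "significant_signals": n_significant,
        }
        manifest.status = "success"
        manifest.finished = _now()
        manifest.write(manifest_path)
        (out_dir / "run.log").write_text(
            "\n".join(log_lines + parse_log.messages) + "\n", encoding="utf-8")
        return PipelineResult(out_dir=out_dir, manifest=manifest,
                              cases=cases, flow=flow)
    except ConfigError:
        raise
    except Exception:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.finished = _now()
        manifest.write(manifest_path)
        raise
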