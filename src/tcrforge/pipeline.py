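"""End-to-end orchestration: simulate -> number -> enrich -> select -> design.

A run is a pure function of its configuration and seed: every stage output
is written under the output directory and checksummed into a manifest, so
re-running with identical inputs reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .candidates import load_structural_categories, select_candidates, write_candidates_tsv
from .design import apply_plan, build_lry_plan, build_tcr_pair, write_tcr_fasta
from .enrichment import compare_v_usage, run_enrichment
from .io import (
    read_clonotype_table,
    read_gapped_fasta,
    write_clonotype_table,
    write_enrichment_report,
)
from .numbering import load_reference_germlines
from .simulate import SyntheticConfig, generate_library


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str
    synthetic: SyntheticConfig | None = None
    clonotypes_path: str | None = None
    germline_path: str | None = None
    mode: str = "ngs"
    alpha_level: float = 0.05
    categories: list[int] | None = None
    min_count: int = 5
    seed: int = 1
    design_tcrs: list[dict] = field(default_factory=list)
    stages: list[str] = field(default_factory=lambda: ["simulate", "enrich", "candidates", "design"])

    def __post_init__(self):
        if not 0 < self.alpha_level <= 1:
            raise ValueError("alpha_level must lie in (0, 1]")
        if self.synthetic is None and self.clonotypes_path is None and "simulate" in self.stages:
            raise ValueError("simulate stage requires a synthetic config")
        if self.clonotypes_path and not Path(self.clonotypes_path).exists():
            raise ValueError(f"clonotype table not found: {self.clonotypes_path}")
        if self.germline_path and not Path(self.germline_path).exists():
            raise ValueError(f"germline FASTA not found: {self.germline_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            from .simulate import PlantedEffect

            syn = raw["synthetic"]
            for key in ("planted_effects", "background_variation"):
                syn[key] = [PlantedEffect(**e) for e in syn.get(key, [])]
            if "cdr3_length_range" in syn:
                syn["cdr3_length_range"] = tuple(syn["cdr3_length_range"])
            raw["synthetic"] = SyntheticConfig(**syn)
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    files: dict[str, str]
    stage_log: list[str]
    started: str
    finished: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    syn = echo.get("synthetic")
    if syn is not None:
        syn.pop("germline_set", None)
    return echo


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages, returning (and writing) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    files: dict[str, str] = {}
    log: list[str] = []

    def record(name: str, path: Path):
        files[name] = _checksum(path)

    # germline reference
    try:
        germline_set = (
            read_gapped_fasta(config.germline_path)
            if config.germline_path
            else load_reference_germlines()
        )
    except Exception as exc:
        raise StageError("germline", exc)

    # simulate or load
    library = None
    if "simulate" in config.stages and config.synthetic is not None:
        try:
            library = generate_library(config.synthetic, seed=config.seed)
            path = out / "clonotypes.tsv"
            write_clonotype_table(library, path)
            record("clonotypes.tsv", path)
            log.append(f"simulate: {len(library)} clonotypes, {len(library.donors)} donors")
        except Exception as exc:
            raise StageError("simulate", exc)
    elif config.clonotypes_path:
        try:
            library = read_clonotype_table(config.clonotypes_path)
            log.append(f"load: {len(library)} clonotypes from {config.clonotypes_path}")
        except Exception as exc:
            raise StageError("load", exc)

    results = None
    if "enrich" in config.stages:
        if library is None:
            raise StageError("enrich", ValueError("no clonotype library available"))
        try:
            results = run_enrichment(
                library, germline_set, mode=config.mode, min_count=config.min_count
            )
            path = out / "report.tsv"
            write_enrichment_report(results, path)
            record("report.tsv", path)
            n_tested = sum(r.tested for r in results)
            log.append(f"enrich[{config.mode}]: {len(results)} pairs, {n_tested} tested")
            usage = compare_v_usage(library)
            log.append(f"usage: {len(usage)} genes compared")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("enrich", exc)

    selected = None
    if "candidates" in config.stages and results is not None:
        try:
            categories = set(config.categories) if config.categories else None
            selected = select_candidates(results, config.alpha_level, categories)
            path = out / "candidates.tsv"
            write_candidates_tsv(selected, path)
            record("candidates.tsv", path)
            log.append(f"candidates: {len(selected)} at alpha={config.alpha_level}")
        except Exception as exc:
            raise StageError("candidates", exc)

    if "design" in config.stages and config.design_tcrs:
        try:
            designed = []
            for spec_d in config.design_tcrs:
                tcr = build_tcr_pair(
                    spec_d["name"],
                    spec_d["alpha_gene"],
                    spec_d["beta_gene"],
                    spec_d["cdr3_alpha"],
                    spec_d["cdr3_beta"],
                    germline_set,
                )
                plan = build_lry_plan(tcr)
                designed.append(apply_plan(tcr, plan))
            path = out / "designed.fasta"
            write_tcr_fasta(designed, path)
            record("designed.fasta", path)
            log.append(f"design: {len(designed)} TCRs LRY-stabilized")
        except Exception as exc:
            raise StageError("design", exc)

    manifest = RunManifest(
        config=_config_echo(config),
        version=__version__,
        seed=config.seed,
        files=files,
        stage_log=log,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
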