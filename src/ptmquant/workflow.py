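"""End-to-end orchestration: convert -> summarize -> model -> adjust -> report.

A declarative YAML config drives the whole pipeline and every output is
written to one results directory together with a manifest (the fully
resolved configuration, package version and warning counts) so a run can be
reproduced from its outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, dataio
from .model import PTMAdjustmentModel


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class WorkflowConfig:
    enriched: str = ""
    global_profiling: str | None = None
    fasta: str | None = None
    dialect: str = "generic_long"
    summarization: str = "median_polish"
    impute_protein: bool = False
    moderate: bool = False
    design_kind: str = "auto"
    contrasts: list = field(default_factory=list)  # e.g. [["C2", "C1"]]
    alpha: float = 0.05
    bh_family: str = "per_contrast"
    output_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise WorkflowError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.enriched or not Path(self.enriched).exists():
            raise WorkflowError(f"config: enriched table not found: {self.enriched!r}")
        for name in ("global_profiling", "fasta"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise WorkflowError(f"config: {name} not found: {p!r}")
        if not 0 < self.alpha < 1:
            raise WorkflowError("config: alpha must be in (0,1)")


def run_workflow(config: WorkflowConfig) -> Path:
    """Execute the full pipeline; returns the results directory.

    Writes ``summaries_ptm.csv``, ``summaries_protein.csv``,
    ``results.csv``, ``summary.txt`` and ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "convert"
    try:
        contrasts = [tuple(c) for c in config.contrasts] or None
        model = PTMAdjustmentModel.from_files(
            config.enriched,
            config.global_profiling,
            dialect=config.dialect,
            fasta=config.fasta,
            contrasts=contrasts,
        )
        stage = "summarize/model/adjust"
        res = model.fit(
            summarization=config.summarization,
            impute_protein=config.impute_protein,
            moderate=config.moderate,
            design_kind=config.design_kind,
            bh_family=config.bh_family,
        )
        stage = "report"
        res.ptm_summaries.to_csv(out / "summaries_ptm.csv", index=False)
        if res.protein_summaries is not None:
            res.protein_summaries.to_csv(out / "summaries_protein.csv", index=False)
        res.table.to_csv(out / "results.csv", index=False)
        (out / "summary.txt").write_text(res.summary(config.alpha) + "\n")
        issues = res.table["issue"].value_counts(dropna=True).to_dict()
        manifest = {
            "ptmquant_version": __version__,
            "config": asdict(config),
            "n_results": int(len(res.table)),
            "n_significant": int((res.table["adj_pvalue"] <= config.alpha).sum()),
            "issue_counts": {str(k): int(v) for k, v in issues.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except WorkflowError:
        raise
    except Exception as exc:  # surface the failing stage
        raise WorkflowError(f"stage {stage!r} failed: {exc}") from exc
    return out
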