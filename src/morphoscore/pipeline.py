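"""End-to-end run orchestration: qc -> deconfound -> score -> compare.

A run is fully described by a :class:`RunConfig` (usually loaded from
YAML); outputs are written to a run directory together with a manifest
carrying the package version, a hash of the resolved config, and the
seed, so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deconfound import Deconfounder
from .io import read_cohort, read_weights, write_qc_report, write_scores
from .qc import drop_flagged, flag_outliers
from .score import MRSScorer
from .stats import cross_disorder_matrix, group_compare

_STAGES = ("qc", "deconfound", "score", "compare")


@dataclasses.dataclass
class RunConfig:
    cohort: str
    weights: list[str]
    out_dir: str
    seed: int
    norm: str = "pooled"
    control_label: str = "control"
    covariates: list[str] = dataclasses.field(default_factory=lambda: ["age", "sex", "icv"])
    rule: str = "all_rois"
    mode: str = "weighted"
    min_coverage: float = 0.8
    qc_fence_k: float = 1.5
    drop_outliers: bool = False
    compare_pairs: list[list[str]] = dataclasses.field(default_factory=list)
    cross_disorder_reference: str | None = None
    n_boot: int = 5000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        missing = [k for k in ("cohort", "weights", "out_dir", "seed") if k not in raw]
        if missing:
            raise ValueError(f"config missing required key(s): {missing}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the whole pipeline; returns the run directory.

    Emits qc_report.csv, deconfound_model.json, scores.csv,
    contributions.csv, comparisons.csv and run_manifest.json.  Re-running
    with an identical config reproduces all numeric outputs exactly.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stale = out / "INCOMPLETE"
    stale.write_text("run in progress; outputs may be stale\n")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # re-raise with the stage name attached
            raise StageError(name, exc) from exc

    cohort = stage("read", lambda: read_cohort(cfg.cohort))
    weight_sets = stage("read", lambda: [read_weights(p) for p in cfg.weights])

    qc_report = stage("qc", lambda: flag_outliers(cohort, k=cfg.qc_fence_k))
    write_qc_report(qc_report, out / "qc_report.csv")
    if cfg.drop_outliers and len(qc_report.flags):
        cohort = stage("qc", lambda: drop_flagged(cohort, qc_report))

    def _deconfound():
        dec = Deconfounder(covariates=tuple(cfg.covariates), norm=cfg.norm,
                           control_label=cfg.control_label).fit(cohort)
        return dec, dec.transform(cohort)

    dec, dev = stage("deconfound", _deconfound)
    dec.model_.to_json(out / "deconfound_model.json")

    def _score():
        scorer = MRSScorer(weights=weight_sets, rule=cfg.rule, mode=cfg.mode,
                           min_coverage=cfg.min_coverage, keep_contributions=True)
        return scorer.fit(dev).transform(dev)

    table = stage("score", _score)
    write_scores(table.scores, out / "scores.csv",
                 contributions=table.contributions,
                 contributions_path=out / "contributions.csv")

    rows = []
    groups = cohort.groups

    def _compare():
        for i, pair in enumerate(cfg.compare_pairs):
            for ws in weight_sets:
                gc = group_compare(table, groups, tuple(pair), n_boot=cfg.n_boot,
                                   seed=cfg.seed + i, score_label=ws.disorder)
                rows.append(dataclasses.asdict(gc))
        if cfg.cross_disorder_reference is not None:
            mat = cross_disorder_matrix(table, groups,
                                        reference=cfg.cross_disorder_reference,
                                        n_boot=cfg.n_boot, seed=cfg.seed)
            mat.insert(0, "score_label", mat.pop("weight_set"))
            for rec in mat.to_dict("records"):
                rows.append(rec)

    stage("compare", _compare)
    pd.DataFrame(rows).to_csv(out / "comparisons.csv", index=False)

    manifest = {
        "tool": "morphoscore",
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "outputs": ["qc_report.csv", "deconfound_model.json", "scores.csv",
                    "contributions.csv", "comparisons.csv"],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    stale.unlink()
    return out
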