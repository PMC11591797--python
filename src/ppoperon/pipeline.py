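"""End-to-end orchestration: profiles -> DE -> operons -> COG summary.

Driven by a YAML config; writes every stage artifact plus a manifest JSON
recording the package version, seed, parameters and SHA-256 checksums of
inputs and outputs, so a rerun with the same config is verifiably
identical.  Any stage failure aborts with a stage-named error and removes
partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .cog import read_cog_map, summarize_by_category
from .de import DEThresholds, read_counts, read_de_table, run_de, write_de_table
from .operons import OperonParams, infer_operons, read_gff3, write_operons
from .profiles import build_profiles, distance_matrix, read_orthogroups

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "run_synthetic_study",
    "score_recovery",
]


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    orthogroups: str
    gff3: str
    focal_genome: str
    outdir: str
    counts: str | None = None
    conditions: str | None = None
    de_table: str | None = None
    cog_map: str | None = None
    min_abs_fc: float = 2.0
    max_fdr: float = 0.05
    distance_cutoff: float = 0.001
    window_bp: int = 10_000
    require_significance: bool = True
    exclude_focal_column: bool = False
    dispersion: float | None = None
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)

    def validate(self) -> None:
        for stage, path in (("profiles", self.orthogroups), ("operons", self.gff3)):
            if not path or not os.path.exists(path):
                raise PipelineError(stage, f"input file not found: {path!r}")
        if self.de_table is None:
            if not (self.counts and self.conditions):
                raise PipelineError(
                    "de", "either de_table or counts+conditions must be given"
                )
            for path in (self.counts, self.conditions):
                if not os.path.exists(path):
                    raise PipelineError("de", f"input file not found: {path!r}")
        elif not os.path.exists(self.de_table):
            raise PipelineError("de", f"input file not found: {self.de_table!r}")
        if self.cog_map is not None and not os.path.exists(self.cog_map):
            raise PipelineError("cog", f"input file not found: {self.cog_map!r}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    outputs: dict[str, str] = {}

    def out(name: str) -> str:
        path = os.path.join(cfg.outdir, name)
        outputs[name] = path
        return path

    try:
        # --- profiles ------------------------------------------------------
        try:
            table, panel, = read_orthogroups(cfg.orthogroups)
            if cfg.focal_genome not in panel.genome_ids:
                raise ValueError(
                    f"focal genome {cfg.focal_genome!r} not a panel column"
                )
            profiles = build_profiles(
                table, panel, cfg.focal_genome,
                exclude_focal_column=cfg.exclude_focal_column,
            )
            dm = distance_matrix(profiles)
            profiles.write_tsv(out("profiles.tsv"))
            dm.write_tsv(out("distances.tsv"))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("profiles", str(exc)) from exc

        # --- differential expression --------------------------------------
        th = DEThresholds(min_abs_fc=cfg.min_abs_fc, max_fdr=cfg.max_fdr)
        try:
            if cfg.de_table is not None:
                records = read_de_table(cfg.de_table, th)
            else:
                cm = read_counts(cfg.counts, cfg.conditions)
                records = run_de(cm, th, dispersion=cfg.dispersion)
            write_de_table(records, out("de_results.tsv"))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("de", str(exc)) from exc

        # --- operon inference ----------------------------------------------
        try:
            feats = read_gff3(cfg.gff3)
            params = OperonParams(
                distance_cutoff=cfg.distance_cutoff,
                window_bp=cfg.window_bp,
                de_thresholds=th,
                require_significance=cfg.require_significance,
            )
            candidates = infer_operons(dm, feats, records, params)
            write_operons(candidates, out("operons.tsv"), out("operons.json"))
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("operons", str(exc)) from exc

        # --- COG summary ---------------------------------------------------
        if cfg.cog_map is not None:
            try:
                cog = read_cog_map(cfg.cog_map)
                summary = summarize_by_category(records, cog)
                summary.to_csv(out("cog_summary.tsv"), sep="\t", index=False)
            except Exception as exc:
                raise PipelineError("cog", str(exc)) from exc
    except Exception:
        for path in outputs.values():
            if os.path.exists(path):
                os.remove(path)
        raise

    inputs = {
        k: _sha256(p)
        for k, p in (
            ("orthogroups", cfg.orthogroups),
            ("gff3", cfg.gff3),
            ("counts", cfg.counts),
            ("conditions", cfg.conditions),
            ("de_table", cfg.de_table),
            ("cog_map", cfg.cog_map),
        )
        if p is not None
    }
    manifest = {
        "ppoperon_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "min_abs_fc": cfg.min_abs_fc,
            "max_fdr": cfg.max_fdr,
            "distance_cutoff": cfg.distance_cutoff,
            "window_bp": cfg.window_bp,
            "require_significance": cfg.require_significance,
            "exclude_focal_column": cfg.exclude_focal_column,
            "dispersion": cfg.dispersion,
            "focal_genome": cfg.focal_genome,
        },
        "input_checksums": inputs,
        "output_checksums": {k: _sha256(p) for k, p in outputs.items()},
        "n_candidates": len(candidates),
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# In-memory synthetic study (no files): generation -> inference -> scoring

def run_synthetic_study(sim_cfg, params: OperonParams | None = None,
                        th: DEThresholds | None = None) -> dict:
    """Generate a synthetic study and run the full inference in memory.

    Returns a dict with the ground truth, gene features, distance matrix,
    DE records and inferred candidates — the building block for recovery
    experiments and calibration checks.
    """
    from .simulate import (
        generate_annotation,
        generate_counts,
        generate_pangenome,
    )

    th = th or DEThresholds()
    params = params or OperonParams(de_thresholds=th)
    table, panel, truth = generate_pangenome(sim_cfg)
    features = generate_annotation(sim_cfg, truth)
    cm = generate_counts(sim_cfg, truth)
    profiles = build_profiles(table, panel, sim_cfg.focal_genome)
    dm = distance_matrix(profiles)
    records = run_de(cm, th)
    candidates = infer_operons(dm, features, records, params)
    return {
        "truth": truth,
        "features": features,
        "counts": cm,
        "distance_matrix": dm,
        "records": records,
        "candidates": candidates,
    }


def score_recovery(candidates, truth) -> dict:
    """Precision/recall of inferred candidates against planted operons.

    Precision: fraction of candidates whose member set lies inside a single
    planted operon (a candidate missing a member that failed the DE call is
    still a correct partial discovery, not a false positive).
    Recall: fraction of planted operons recovered with their exact member
    set.
    """
    planted = {frozenset(genes) for genes in truth.operon_genes.values()}
    if candidates:
        good = sum(
            1 for c in candidates
            if any(frozenset(c.member_genes) <= p for p in planted)
        )
        precision = good / len(candidates)
    else:
        precision = 1.0
    exact = sum(
        1 for c in candidates if frozenset(c.member_genes) in planted
    )
    recall = exact / len(planted) if planted else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_candidates": len(candidates),
        "n_planted": len(planted),
    }
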