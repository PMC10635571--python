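"""End-to-end orchestration: extraction -> duplex calling -> trans calling
-> contact export -> (optional) splicing overlap, with one config, one seed
and a JSON run manifest.

All stated defaults are the pipeline's operating constants: MAPQ >= 30,
connection-score cutoff 0.01 (strict), significance alpha 0.05 (strict),
minimum 2 observed contacts per tested pair.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import yaml

from . import __version__
from .annotation import parse_gtf
from .duplex import DEFAULT_SCORE_CUTOFF, call_duplex_groups, groups_to_bed12, groups_to_tsv
from .export import class_distribution, write_short_format
from .extract import (
    DEFAULT_MIN_MAPQ,
    SCOPE_INTER,
    SCOPE_INTRA,
    chimeras_to_bedpe,
    chimeras_to_tsv,
    extract_chimeras,
)
from .splicing import DEFAULT_NCRNA_CLASSES, MisoFilters, annotate_bound_events, load_events, summarize_bound, write_annotations_tsv
from .trans import DEFAULT_ALPHA, DEFAULT_MIN_CONTACTS, call_trans_interactions, filter_significant

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sam_path: str = ""
    gtf_path: str = ""
    events_path: Optional[str] = None
    exclude_contigs: List[str] = field(default_factory=list)
    min_mapq: int = DEFAULT_MIN_MAPQ
    duplex_cutoff: float = DEFAULT_SCORE_CUTOFF
    alpha: float = DEFAULT_ALPHA
    n_iter: int = 1000
    min_pair_contacts: int = DEFAULT_MIN_CONTACTS
    ncrna_classes: List[str] = field(default_factory=lambda: sorted(DEFAULT_NCRNA_CLASSES))
    seed: int = 0
    out_dir: str = "lhclip_out"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.sam_path:
            raise PipelineError("config", "sam_path is required")
        if not self.gtf_path:
            raise PipelineError("config", "gtf_path is required")
        for p in (self.sam_path, self.gtf_path, self.events_path):
            if p and not os.path.exists(p):
                raise PipelineError("config", f"input not found: {p}")


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Run every stage and return the manifest (also written to out_dir)."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: Dict = {
        "tool": "lhclip",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": asdict(cfg),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                manifest["stages"][name] = fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate stage then abort
                raise PipelineError(name, str(exc)) from exc
        return deco

    state: Dict = {}

    @stage("annotation")
    def _():
        state["ann"] = parse_gtf(cfg.gtf_path)
        return {"genes": len(state["ann"].genes),
                "transcripts": len(state["ann"].transcripts),
                "introns": len(state["ann"].intron_set())}

    @stage("extract")
    def _():
        res = extract_chimeras(
            cfg.sam_path, state["ann"], min_mapq=cfg.min_mapq,
            exclude_contigs=cfg.exclude_contigs,
        )
        state["extraction"] = res
        chimeras_to_tsv(res.chimeras, os.path.join(cfg.out_dir, "chimeras.tsv"))
        chimeras_to_bedpe(res.chimeras, os.path.join(cfg.out_dir, "chimeras.bedpe"))
        return dict(res.counts)

    @stage("duplexes")
    def _():
        res = state["extraction"]
        groups = call_duplex_groups(
            res.by_scope(SCOPE_INTRA), res.coverage, cutoff=cfg.duplex_cutoff
        )
        state["groups"] = groups
        groups_to_tsv(groups, os.path.join(cfg.out_dir, "duplex_groups.tsv"))
        groups_to_bed12(groups, os.path.join(cfg.out_dir, "duplex_groups.bed"))
        return {"groups": len(groups)}

    @stage("trans")
    def _():
        res = state["extraction"]
        inter = res.by_scope(SCOPE_INTER)
        table = call_trans_interactions(
            inter, n_iter=cfg.n_iter, seed=cfg.seed,
            alpha=cfg.alpha, min_contacts=cfg.min_pair_contacts,
        )
        state["pairs"] = table
        state["significant"] = filter_significant(
            table.dropna(subset=["p_local"]), cfg.alpha
        )
        table.to_csv(os.path.join(cfg.out_dir, "gene_pairs.tsv"), sep="\t", index=False)
        state["significant"].to_csv(
            os.path.join(cfg.out_dir, "significant_pairs.tsv"), sep="\t", index=False
        )
        return {
            "pairs_observed": int(len(table)),
            "pairs_tested": int(table["p_local"].notna().sum()) if len(table) else 0,
            "pairs_significant": int(len(state["significant"])),
            "n_iter": cfg.n_iter,
            "seed": cfg.seed,
        }

    @stage("export")
    def _():
        res = state["extraction"]
        write_short_format(
            res.chimeras, os.path.join(cfg.out_dir, "contacts.short"), ann=state["ann"]
        )
        dist = class_distribution(res.by_scope(SCOPE_INTER), state["ann"])
        dist.to_csv(os.path.join(cfg.out_dir, "class_distribution.tsv"),
                    sep="\t", index=False)
        return {"contacts": len(res.chimeras), "class_pairs": int(len(dist))}

    if cfg.events_path:
        @stage("splicing")
        def _():
            events = load_events(cfg.events_path, MisoFilters())
            sig_pairs = {
                tuple(sorted((r.gene_a, r.gene_b)))
                for r in state["significant"].itertuples()
            }
            inter = [
                c for c in state["extraction"].by_scope(SCOPE_INTER)
                if tuple(sorted((c.gene5, c.gene3))) in sig_pairs
            ]
            annotations = annotate_bound_events(
                events, inter, state["ann"], ncrna_classes=cfg.ncrna_classes
            )
            write_annotations_tsv(
                annotations, os.path.join(cfg.out_dir, "bound_events.tsv")
            )
            return {"events": len(events), **summarize_bound(annotations)}

    counts = manifest["stages"]["extract"]
    assert counts["intra"] + counts["inter"] + counts["unassigned"] == counts["chimeras"]

    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
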