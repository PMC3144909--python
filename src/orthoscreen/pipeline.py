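"""Orchestration of the three screens and the hit-list merge.

Stage order mirrors the screening protocol: (1) coding-region
consensus/coverage filter against the reference species, (2) initiation-
context strength comparison, (3) 3'UTR delimitation and miRNA target
prediction — stage 3 restricted to the union of stage-1 and stage-2 hits
(a gene hit by both is counted once). Every exclusion along the way is
logged with a reason code so the accounting is reproducible on any panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from . import consensus_screen, kozak, mirna_targets, seqio, utr_inference
from .errors import ConfigError
from .mirna_targets import TargetConfig, TargetSite
from .seqio import MiRnaRecord, OrthologPanel
from .utr_inference import NoCall, UtrCall, UtrConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every pipeline threshold in one place (YAML-loadable)."""

    consensus_threshold: float = 75.0
    seed_min: int = 7
    energy_cutoff: float = -20.0
    min_species: int = 6
    max_mismatch: int = 1
    conservation_mode: str = "consensus"
    window_length: int = 4000
    cleavage_offset: int = 19
    pas_motifs: dict[str, float] = field(
        default_factory=lambda: dict(utr_inference.DEFAULT_PAS_MOTIFS))
    all_genes: bool = False

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def utr_config(self) -> UtrConfig:
        return UtrConfig(pas_motifs=dict(self.pas_motifs),
                         cleavage_offset=self.cleavage_offset,
                         window_length=self.window_length)

    def target_config(self) -> TargetConfig:
        return TargetConfig(seed_min=self.seed_min,
                            energy_cutoff=self.energy_cutoff)


def merge_hits(coding_hits, kozak_hits) -> list[str]:
    """Sorted union of the two hit lists; a gene hit by both screens is
    counted once."""
    return sorted(set(coding_hits) | set(kozak_hits))


@dataclass
class ScreenReport:
    coding_results: list[consensus_screen.ConsensusResult]
    coding_hits: list[str]
    kozak_screen: kozak.KozakScreenResult
    kozak_hits: list[str]
    kozak_weaker: list[str]
    merged: list[str]
    utr_calls: list[UtrCall]
    sites: list[TargetSite]
    exclusions: list[tuple[str, str, str]]  # (gene, stage, reason)

    def summary(self) -> dict:
        return {
            "coding_hits": self.coding_hits,
            "kozak_hits": self.kozak_hits,
            "kozak_weaker": self.kozak_weaker,
            "merged": self.merged,
            "n_utr_calls": len(self.utr_calls),
            "n_sites": len(self.sites),
            "predicted_regulated": sorted({s.gene_symbol
                                           for s in self.sites}),
            "exclusions": [list(e) for e in self.exclusions],
        }


def run_all(
    panel: OrthologPanel,
    mirnas: list[MiRnaRecord],
    coverage_table: Mapping[str, tuple[int, int, str]],
    config: Optional[PipelineConfig] = None,
    query_species: str = "panda",
) -> ScreenReport:
    """Run all three screens in order and assemble the consolidated report.

    The pipeline is a pure function of (inputs, config): identical reruns
    produce identical reports.
    """
    if config is None:
        config = PipelineConfig()
    exclusions: list[tuple[str, str, str]] = []
    for gene, species in sorted(panel.missing):
        exclusions.append((gene, "input", f"missing_ortholog:{species}"))

    coding = consensus_screen.screen_coding(
        panel, query_species, coverage_table,
        threshold=config.consensus_threshold)
    coding_hits = [r.gene_symbol for r in coding if r.passes]

    kz = kozak.screen_kozak(panel, query_species)
    for gene, reason in sorted(kz.excluded.items()):
        exclusions.append((gene, "kozak", reason))
    kozak_hits = sorted(kz.differing)

    merged = merge_hits(coding_hits, kozak_hits)
    stage3_genes = panel.gene_symbols if config.all_genes else merged

    families = mirna_targets.filter_conserved(
        mirnas, min_species=config.min_species,
        max_mismatch=config.max_mismatch,
        reference_species=panel.reference_species,
        mode=config.conservation_mode)

    utr_calls: list[UtrCall] = []
    utr_cfg = config.utr_config()
    for gene in stage3_genes:
        rec = panel.get(gene, query_species)
        if rec is None:
            exclusions.append((gene, "utr", "missing_query_ortholog"))
            continue
        call = utr_inference.call_utr(rec, utr_cfg)
        if isinstance(call, NoCall):
            exclusions.append((gene, "utr", call.reason))
        else:
            utr_calls.append(call)

    sites = mirna_targets.predict_targets(utr_calls, families,
                                          config.target_config())
    return ScreenReport(
        coding_results=coding,
        coding_hits=coding_hits,
        kozak_screen=kz,
        kozak_hits=kozak_hits,
        kozak_weaker=sorted(kz.weaker),
        merged=merged,
        utr_calls=utr_calls,
        sites=sites,
        exclusions=exclusions,
    )


def write_outputs(report: ScreenReport, outdir: Union[str, Path]) -> None:
    """Write the consolidated TSV/JSON/BED reports for one pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqio.write_report(report.coding_results, outdir / "coding_screen.tsv")
    kozak_rows = [call
                  for gene in sorted(report.kozak_screen.calls)
                  for _, call in sorted(
                      report.kozak_screen.calls[gene].items())]
    seqio.write_report(kozak_rows, outdir / "kozak_screen.tsv")
    seqio.write_report(report.utr_calls, outdir / "utr_calls.tsv")
    seqio.write_report(report.sites, outdir / "target_sites.tsv")
    seqio.write_sites_bed(report.sites, outdir / "target_sites.bed")
    (outdir / "report.json").write_text(
        json.dumps(report.summary(), indent=2, sort_keys=True) + "\n")
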