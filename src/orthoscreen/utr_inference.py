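"""Stage 3a — putative 3'UTR delimitation by polyadenylation-signal scan.

Unannotated UTRs are delimited from the 4 kb window downstream of the CDS:
the window is scanned for polyadenylation hexamers (canonically AAUAAA,
variant AUUAAA, weighted), the top-ranked signal is selected (higher weight
first, then leftmost), and the UTR is taken to end a configurable cleavage
offset beyond the hexamer. For minus-strand genes the plus-strand segment
upstream of the gene is extracted and reverse-complemented before scanning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Union

from .errors import ConfigError
from .seqio import GeneRecord, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_PAS_MOTIFS = {"AATAAA": 1.0, "ATTAAA": 0.8}
DEFAULT_CLEAVAGE_OFFSET = 19
DEFAULT_WINDOW_LENGTH = 4000


@dataclass
class UtrConfig:
    """Tunables of the UTR caller.

    cleavage_offset: distance (nt) from the last base of the hexamer to the
    assumed cleavage/polyA site; 19 nt is within the canonical 10-30 nt
    PAS-to-cleavage spacing.
    """

    pas_motifs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAS_MOTIFS))
    cleavage_offset: int = DEFAULT_CLEAVAGE_OFFSET
    window_length: int = DEFAULT_WINDOW_LENGTH

    def __post_init__(self) -> None:
        if self.window_length < 6:
            raise ConfigError("window_length must be >= 6")
        if self.cleavage_offset < 0:
            raise ConfigError("cleavage_offset must be >= 0")
        for motif in self.pas_motifs:
            if len(motif) != 6:
                raise ConfigError(f"PAS motif {motif!r} is not a hexamer")


class PasHit(NamedTuple):
    position: int  # 1-based start of the hexamer in the window
    motif: str
    weight: float


@dataclass
class UtrCall:
    gene_symbol: str
    species: str
    utr_seq: str
    utr_length: int
    pas_motif: str
    pas_start: int         # 1-based offset from first base after the CDS
    cleavage_offset: int

    @staticmethod
    def report_header() -> list[str]:
        return ["gene_symbol", "species", "utr_length", "pas_motif",
                "pas_start"]

    def report_row(self) -> list:
        return [self.gene_symbol, self.species, self.utr_length,
                self.pas_motif, self.pas_start]


class NoCall(NamedTuple):
    gene_symbol: str
    species: str
    reason: str


def downstream_window(record: GeneRecord,
                      length: int = DEFAULT_WINDOW_LENGTH) -> str:
    """The ``length`` bases immediately 3' of the CDS, in reading
    orientation; truncated (with a warning) at the contig edge.

    Plus strand: contig bases cds_end+1 .. cds_end+length. Minus strand: the
    mirrored plus-strand segment upstream of the gene, reverse-complemented.
    """
    e = record.cds_end
    if record.strand == "+":
        window = record.contig_seq[e: e + length]
    else:
        L = len(record.contig_seq)
        # oriented positions e+1..e+length map to plus-strand
        # positions L-e-length+1..L-e
        lo = max(0, L - e - length)
        segment = record.contig_seq[lo: L - e]
        window = reverse_complement(segment)
    if len(window) < length:
        log.warning("downstream window of %s/%s truncated to %d nt at "
                    "contig edge", record.gene_symbol, record.species,
                    len(window))
    return window


def find_pas(window: str, motifs: Optional[dict[str, float]] = None
             ) -> list[PasHit]:
    """All polyadenylation hexamer occurrences (overlapping included),
    1-based, sorted by descending weight then ascending position."""
    if motifs is None:
        motifs = DEFAULT_PAS_MOTIFS
    w = window.upper().replace("U", "T")
    hits: list[PasHit] = []
    for motif, weight in motifs.items():
        m = motif.upper()
        start = w.find(m)
        while start != -1:
            hits.append(PasHit(start + 1, motif, weight))
            start = w.find(m, start + 1)
    hits.sort(key=lambda h: (-h.weight, h.position))
    return hits


def call_utr(record: GeneRecord,
             config: Optional[UtrConfig] = None) -> Union[UtrCall, NoCall]:
    """Delimit the putative 3'UTR of one gene, or return a reason-coded
    no-call when the downstream window contains no polyadenylation signal."""
    if config is None:
        config = UtrConfig()
    window = downstream_window(record, config.window_length)
    if not window:
        return NoCall(record.gene_symbol, record.species, "empty_window")
    hits = find_pas(window, config.pas_motifs)
    if not hits:
        return NoCall(record.gene_symbol, record.species, "no_pas_found")
    top = hits[0]
    utr_len = min(top.position + 5 + config.cleavage_offset, len(window))
    return UtrCall(
        gene_symbol=record.gene_symbol,
        species=record.species,
        utr_seq=window[:utr_len],
        utr_length=utr_len,
        pas_motif=top.motif,
        pas_start=top.position,
        cleavage_offset=config.cleavage_offset,
    )
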