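"""Stage 2 — translation-initiation (Kozak) context classification.

The vertebrate initiation consensus is gccRccAUGG. The classifier extracts
the 30-nt window covering positions -25..-1, +1..+5 (there is no position 0;
+1 is the A of the start codon) and tests the two positions that dominate
initiation efficiency:

* position -3: purine (A or G)
* position +4: G

Both matched -> strong (S); exactly one -> adequate (A); neither -> weak (W);
windows whose +1..+3 is not an AUG start codon are EXCLUDED from strength
comparison. -6 G and -2/-1 CC contribute to context strength but are
reported as annotations only, never used as criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .errors import InputError
from .seqio import GeneRecord, OrthologPanel

log = logging.getLogger(__name__)

WINDOW_UP = 25    # bases before +1
WINDOW_DOWN = 5   # bases from +1 on
WINDOW_LEN = WINDOW_UP + WINDOW_DOWN

# window indices: 0..24 <-> positions -25..-1; 25..29 <-> +1..+5
IDX_MINUS3 = WINDOW_UP - 3      # 22
IDX_PLUS1 = WINDOW_UP           # 25
IDX_PLUS4 = WINDOW_UP + 3       # 28

_ORDER = {"W": 0, "A": 1, "S": 2}


def position_index(pos: int) -> int:
    """Window index of a biological position (-25..-1, +1..+5; no 0)."""
    if pos == 0 or not -WINDOW_UP <= pos <= WINDOW_DOWN:
        raise InputError(f"position {pos} outside -{WINDOW_UP}..+{WINDOW_DOWN}")
    return WINDOW_UP + pos if pos < 0 else WINDOW_UP + pos - 1


@dataclass
class KozakContext:
    """The -25..+5 initiation context of one gene in one species."""

    gene_symbol: str
    species: str
    window: str
    valid: bool
    reason: Optional[str] = None


@dataclass
class KozakCall:
    context: KozakContext
    has_aug: bool
    plus4_g: bool
    minus3_r: bool
    strength: str  # S / A / W / EXCLUDED
    minus6_g: bool = False
    minus12_cc: bool = False  # CC at -2/-1, annotation only

    @property
    def pattern(self) -> tuple[bool, bool]:
        """The (-3 purine, +4 G) flag pair the comparison partitions on."""
        return (self.minus3_r, self.plus4_g)

    @staticmethod
    def report_header() -> list[str]:
        return ["gene_symbol", "species", "atg", "g_plus4", "r_minus3",
                "strength"]

    def report_row(self) -> list:
        return [self.context.gene_symbol, self.context.species,
                "y" if self.has_aug else "",
                "y" if self.plus4_g else "",
                "y" if self.minus3_r else "",
                self.strength]


def extract_context(record: GeneRecord) -> KozakContext:
    """Strand-oriented bases cds_start-25 .. cds_start+4 (1-based, no 0).

    A start codon closer than 25 bases to the contig edge yields a
    valid=False context (an outcome, not an error).
    """
    seq = record.oriented
    start = record.cds_start
    if start - WINDOW_UP < 1:
        return KozakContext(record.gene_symbol, record.species, "",
                            valid=False, reason="insufficient_upstream")
    if start + WINDOW_DOWN - 1 > len(seq):
        return KozakContext(record.gene_symbol, record.species, "",
                            valid=False, reason="insufficient_downstream")
    window = seq[start - WINDOW_UP - 1: start + WINDOW_DOWN - 1]
    return KozakContext(record.gene_symbol, record.species, window,
                        valid=True)


def classify(context: KozakContext) -> KozakCall:
    """Classify one context. Soft-masked bases are uppercased before
    testing; N (or any non-ACGT base) at a criterion position counts as a
    non-match."""
    if not context.valid:
        return KozakCall(context, has_aug=False, plus4_g=False,
                         minus3_r=False,
                         strength="EXCLUDED")
    w = context.window.upper().replace("U", "T")
    if len(w) != WINDOW_LEN:
        raise InputError(
            f"{context.gene_symbol}/{context.species}: window length "
            f"{len(w)} != {WINDOW_LEN}")
    has_aug = w[IDX_PLUS1:IDX_PLUS1 + 3] == "ATG"
    minus3_r = w[IDX_MINUS3] in "AG"
    plus4_g = w[IDX_PLUS4] == "G"
    if not has_aug:
        strength = "EXCLUDED"
    elif minus3_r and plus4_g:
        strength = "S"
    elif minus3_r or plus4_g:
        strength = "A"
    else:
        strength = "W"
    return KozakCall(context, has_aug, plus4_g, minus3_r, strength,
                     minus6_g=(w[position_index(-6)] == "G"),
                     minus12_cc=(w[position_index(-2)] == "C"
                                 and w[position_index(-1)] == "C"))


def compare_strength(query: KozakCall, reference: KozakCall) -> str:
    """'weaker' / 'same' / 'stronger' for the query under W < A < S."""
    for call, who in ((query, "query"), (reference, "reference")):
        if call.strength not in _ORDER:
            raise InputError(f"compare_strength: {who} call is EXCLUDED")
    q, r = _ORDER[query.strength], _ORDER[reference.strength]
    if q < r:
        return "weaker"
    if q > r:
        return "stronger"
    return "same"


@dataclass
class KozakScreenResult:
    """Per-gene initiation-context comparison between two species."""

    calls: dict[str, dict[str, KozakCall]]  # gene -> species -> call
    excluded: dict[str, str]                # gene -> reason code
    differing: list[str]                    # pattern differs at -3/+4
    same_pattern: list[str]
    comparison: dict[str, str]              # differing gene -> weaker/...

    @property
    def weaker(self) -> list[str]:
        return [g for g in self.differing if self.comparison[g] == "weaker"]

    @property
    def stronger(self) -> list[str]:
        return [g for g in self.differing if self.comparison[g] == "stronger"]


def screen_kozak(
    panel: OrthologPanel,
    query_species: str,
    reference_species: Optional[str] = None,
) -> KozakScreenResult:
    """Classify every gene in both species; exclude genes without an AUG in
    the query first, then partition the remainder by whether the (-3, +4)
    flag pattern differs from the reference."""
    if reference_species is None:
        reference_species = panel.reference_species
    calls: dict[str, dict[str, KozakCall]] = {}
    excluded: dict[str, str] = {}
    differing: list[str] = []
    same_pattern: list[str] = []
    comparison: dict[str, str] = {}
    for gene in panel.gene_symbols:
        qrec = panel.get(gene, query_species)
        rrec = panel.get(gene, reference_species)
        if qrec is None:
            excluded[gene] = "missing_query_ortholog"
            continue
        qcall = classify(extract_context(qrec))
        calls.setdefault(gene, {})[query_species] = qcall
        if qcall.strength == "EXCLUDED":
            excluded[gene] = (qcall.context.reason or "no_aug_start")
            continue
        if rrec is None:
            excluded[gene] = "missing_reference_ortholog"
            continue
        rcall = classify(extract_context(rrec))
        calls[gene][reference_species] = rcall
        if rcall.strength == "EXCLUDED":
            excluded[gene] = (rcall.context.reason
                              or "no_aug_start") + "_reference"
            continue
        if qcall.pattern != rcall.pattern:
            differing.append(gene)
            comparison[gene] = compare_strength(qcall, rcall)
        else:
            same_pattern.append(gene)
    return KozakScreenResult(calls, excluded, differing, same_pattern,
                             comparison)
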