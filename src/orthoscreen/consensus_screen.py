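"""Stage 1 — coding-region screen.

Each query ortholog is globally aligned against the reference-species
protein (affine-gap Needleman–Wunsch/Gotoh, BLOSUM62, gap of length L
costing open + L*extend = 11 + L), identical aligned columns are counted
against the reference length, and a gene passes when both the structure
coverage percentage (supplied as metadata) and the consensus percentage
strictly exceed the threshold (default 75%).

Percentages are reported round-half-up to two decimals, e.g. 206/271 ->
76.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple, Optional

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InputError
from .seqio import OrthologPanel

log = logging.getLogger(__name__)

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

_NEG = -1e18

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_INDEX = {aa: i for i, aa in enumerate(_BLOSUM62.alphabet)}
_B62 = np.asarray(_BLOSUM62, dtype=np.float64)


class PairwiseAlignment(NamedTuple):
    """A global pairwise alignment: two gapped strings of equal length."""

    query_aligned: str
    reference_aligned: str
    score: float


def _encode(seq: str, name: str) -> np.ndarray:
    try:
        return np.array([_B62_INDEX[c] for c in seq.upper()], dtype=np.intp)
    except KeyError as exc:
        raise InputError(f"{name}: residue {exc.args[0]!r} not in BLOSUM62 "
                         "alphabet") from exc


def align_global(
    query: str,
    reference: str,
    matrix: Optional[np.ndarray] = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    A gap of length L costs ``gap_open + L * gap_extend``; adjacent gaps in
    opposite sequences are permitted (each run opens its own gap). Ties among
    equally optimal alignments are broken deterministically, preferring gap
    placement at later query positions during traceback.
    """
    if not query or not reference:
        raise InputError("align_global requires two non-empty sequences")
    x, y = query.upper(), reference.upper()
    m, n = len(x), len(y)
    xi, yi = _encode(x, "query"), _encode(y, "reference")
    if matrix is None:
        sub = _B62[np.ix_(xi, yi)]
    else:
        sub = np.asarray(matrix)[np.ix_(xi, yi)]

    go_ge = gap_open + gap_extend
    M = np.full((m + 1, n + 1), _NEG)
    Ix = np.full((m + 1, n + 1), _NEG)  # gap in reference (consumes query)
    Iy = np.full((m + 1, n + 1), _NEG)  # gap in query (consumes reference)
    M[0, 0] = 0.0
    js = np.arange(1, n + 1, dtype=np.float64)

    for i in range(m + 1):
        if i > 0:
            best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]),
                                   Iy[i - 1])
            M[i, 1:] = sub[i - 1] + best_prev[:-1]
            M[i, 0] = _NEG
            Ix[i] = np.maximum(np.maximum(M[i - 1], Iy[i - 1]) - go_ge,
                               Ix[i - 1] - gap_extend)
        # horizontal-gap row via prefix-max scan over openers in this row
        opener = np.maximum(M[i], Ix[i])
        run = np.maximum.accumulate(
            opener[:-1] + np.arange(n, dtype=np.float64) * gap_extend)
        Iy[i, 1:] = run - gap_open - js * gap_extend
        Iy[i, 0] = _NEG

    score = max(M[m, n], Ix[m, n], Iy[m, n])

    # traceback; all scores are integer-valued sums, float equality is exact
    qa: list[str] = []
    ra: list[str] = []
    for state, mat in (("Iy", Iy), ("Ix", Ix), ("M", M)):
        if mat[m, n] == score:
            break
    i, j = m, n
    while i > 0 or j > 0:
        if state == "M":
            qa.append(x[i - 1])
            ra.append(y[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for state, mat in (("Iy", Iy), ("Ix", Ix), ("M", M)):
                if mat[i, j] == target:
                    break
        elif state == "Ix":
            qa.append(x[i - 1])
            ra.append("-")
            target = Ix[i, j]
            i -= 1
            if Ix[i, j] - gap_extend == target:
                state = "Ix"
            elif Iy[i, j] - go_ge == target:
                state = "Iy"
            else:
                state = "M"
        else:  # Iy
            qa.append("-")
            ra.append(y[j - 1])
            target = Iy[i, j]
            j -= 1
            if Iy[i, j] - gap_extend == target:
                state = "Iy"
            elif Ix[i, j] - go_ge == target:
                state = "Ix"
            else:
                state = "M"
    return PairwiseAlignment("".join(reversed(qa)), "".join(reversed(ra)),
                             float(score))


def consensus_counts(alignment: PairwiseAlignment,
                     reference: str) -> tuple[int, int]:
    """Identical aligned columns (case-insensitive, X never matches) over the
    ungapped reference length."""
    ref_degapped = alignment.reference_aligned.replace("-", "")
    if ref_degapped.upper() != reference.upper():
        raise InputError("alignment was not produced against this reference")
    count = sum(
        1
        for q, r in zip(alignment.query_aligned.upper(),
                        alignment.reference_aligned.upper())
        if q == r and q not in ("-", "X")
    )
    return count, len(reference)


def percent(count: int, total: int) -> float:
    """100*count/total, round-half-up to 2 decimals (206/271 -> 76.01)."""
    if total <= 0:
        raise InputError("percent: total must be positive")
    if not 0 <= count <= total:
        raise InputError(f"percent: count {count} outside [0, {total}]")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass
class ConsensusResult:
    """One row of the coding-region screen (per gene)."""

    gene_symbol: str
    structure_id: str
    coverage_count: int
    coverage_total: int
    consensus_count: int
    consensus_total: int
    coverage_pct: float
    consensus_pct: float
    passes: bool

    @classmethod
    def from_counts(cls, gene_symbol: str, structure_id: str,
                    coverage_count: int, coverage_total: int,
                    consensus_count: int, consensus_total: int,
                    threshold: float = 75.0) -> "ConsensusResult":
        cov = percent(coverage_count, coverage_total)
        cons = percent(consensus_count, consensus_total)
        return cls(gene_symbol, structure_id, coverage_count, coverage_total,
                   consensus_count, consensus_total, cov, cons,
                   passes=(cov > threshold and cons > threshold))

    @staticmethod
    def report_header() -> list[str]:
        return ["gene_symbol", "structure_id", "coverage_count",
                "coverage_total", "coverage_pct", "consensus_count",
                "consensus_total", "consensus_pct", "passes"]

    def report_row(self) -> list:
        return [self.gene_symbol, self.structure_id, self.coverage_count,
                self.coverage_total, f"{self.coverage_pct:.2f}",
                self.consensus_count, self.consensus_total,
                f"{self.consensus_pct:.2f}", self.passes]


def screen_coding(
    panel: OrthologPanel,
    query_species: str,
    coverage_table: Mapping[str, tuple[int, int, str]],
    threshold: float = 75.0,
) -> list[ConsensusResult]:
    """Apply the dual strict->threshold filter to every gene with a query
    protein and a structure-coverage entry; output sorted by gene symbol."""
    out: list[ConsensusResult] = []
    for gene in panel.gene_symbols:
        if gene not in coverage_table:
            continue
        qrec = panel.get(gene, query_species)
        if qrec is None or qrec.protein_seq is None:
            continue
        ref = panel.get(gene, panel.reference_species)
        if ref is None or ref.protein_seq is None:
            log.warning("screen_coding: no reference protein for %s; skipped",
                        gene)
            continue
        cov_count, cov_total, structure_id = coverage_table[gene]
        aln = align_global(qrec.protein_seq, ref.protein_seq)
        cons_count, cons_total = consensus_counts(aln, ref.protein_seq)
        out.append(ConsensusResult.from_counts(
            gene, structure_id, cov_count, cov_total, cons_count, cons_total,
            threshold=threshold))
    return out
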