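"""Independent oracles the implementation is checked against.

These deliberately avoid the package's own algorithms: the alignment oracle
enumerates every gapped alignment recursively (no dynamic programming), and
the duplex oracle re-reads the shipped parameter TSV and sums energies by
enumerating maximal paired runs.
"""

from __future__ import annotations

import csv
from importlib import resources

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11.0
GAP_EXTEND = 1.0


def brute_force_align_score(x: str, y: str,
                            gap_open: float = GAP_OPEN,
                            gap_extend: float = GAP_EXTEND) -> float:
    """Maximum global alignment score by exhaustive enumeration of all
    gapped alignments (each maximal gap run costs open + len*extend).
    Feasible for sequences up to ~8 residues."""
    best = [float("-inf")]

    def rec(i: int, j: int, score: float, state: str) -> None:
        if i == len(x) and j == len(y):
            if score > best[0]:
                best[0] = score
            return
        if i < len(x) and j < len(y):
            rec(i + 1, j + 1, score + _B62[x[i], y[j]], "M")
        if i < len(x):
            cost = gap_extend if state == "X" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "X")
        if j < len(y):
            cost = gap_extend if state == "Y" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


def load_raw_nn_table() -> tuple[dict[str, float], float, float, float]:
    """(stacks, init, terminal_au, mismatch) read directly from the TSV."""
    stacks: dict[str, float] = {}
    scalars: dict[str, float] = {}
    ref = resources.files("orthoscreen.data") / "nn_stacks.tsv"
    with resources.as_file(ref) as path, open(path, newline="") as fh:
        for row in csv.DictReader((l for l in fh if not l.startswith("#")),
                                  delimiter="\t"):
            if row["param"] == "stack":
                stacks[row["key"]] = float(row["value"])
            else:
                scalars[row["param"]] = float(row["value"])
    return (stacks, scalars["init"], scalars["terminal_au"],
            scalars["mismatch"])


_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def duplex_dg_oracle(mirna: str, window: str) -> float:
    """Independent nearest-neighbor summation for a full-length antiparallel
    register: window base i (0-based) pairs miRNA position len(mirna)-i.

    Enumerates maximal paired runs, sums stack entries over each run's
    internal steps, charges every other step the mismatch penalty, and adds
    the terminal penalty at non-GC outermost pairs.
    """
    stacks, init, term_au, mismatch = load_raw_nn_table()
    m = mirna.upper().replace("T", "U")
    w = window.upper().replace("T", "U")
    L = len(m)
    assert len(w) == L
    partner = w[::-1]

    def is_paired(j: int) -> bool:  # j: 1-based miRNA position
        duo = (m[j - 1], partner[j - 1])
        return duo in _WC or (j > 9 and duo in _WOBBLE)

    runs: list[tuple[int, int]] = []
    j = 1
    while j <= L:
        if is_paired(j):
            start = j
            while j <= L and is_paired(j):
                j += 1
            runs.append((start, j - 1))
        else:
            j += 1

    dg = init
    stack_steps = 0
    for a, b in runs:
        for j in range(a, b):
            dg += stacks[f"{m[j-1]}{m[j]}/{partner[j-1]}{partner[j]}"]
            stack_steps += 1
    dg += mismatch * (L - 1 - stack_steps)
    if runs:
        for j in (runs[0][0], runs[-1][1]):
            if (m[j - 1], partner[j - 1]) not in {("G", "C"), ("C", "G")}:
                dg += term_au
    return dg
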