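"""Stage 3b — conserved-miRNA filtering and target-site calling.

A miRNA family is retained when it is present in at least ``min_species``
species and every mature copy is within ``max_mismatch`` substitutions of
the family consensus (per-position majority, ties resolved toward the
reference species). Candidate sites on an inferred 3'UTR require a
contiguous Watson–Crick complementary run of >= ``seed_min`` nt against the
miRNA 5' nucleus (positions 1-9; G:U wobble is not accepted inside the
nucleus), and are kept when the hybridization free energy of the full-length
heteroduplex is at or below the cutoff (default -20 kcal/mol).

The duplex energy is a transparent nearest-neighbor sum over the
antiparallel, gapless register fixed by the nucleus match:

    dG = init + sum(stack terms over steps whose two positions both pair)
              + mismatch_penalty per step not fully paired
              + terminal penalty per non-GC outermost pair

Stack parameters ship as versioned package data (``data/nn_stacks.tsv``).
Absolute dG values are model-dependent; the -20 kcal/mol cutoff applies to
this model.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple, Optional

from .errors import ConfigError, InputError
from .seqio import MiRnaRecord
from .utr_inference import UtrCall

log = logging.getLogger(__name__)

NUCLEUS_REGION = 9          # miRNA positions 1..9 form the nucleus region
DEFAULT_SEED_MIN = 7
DEFAULT_ENERGY_CUTOFF = -20.0
DEFAULT_MIN_SPECIES = 6
DEFAULT_MAX_MISMATCH = 1

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class NnParameterTable:
    """Nearest-neighbor duplex parameters (kcal/mol)."""

    stack_energies: dict[str, float]
    terminal_au_penalty: float
    mismatch_penalty: float
    init_energy: float

    def __post_init__(self) -> None:
        n_wc = sum(1 for k in self.stack_energies
                   if all(tuple(p) in _WC
                          for p in zip(k[:2], k[3:])))
        if n_wc < 16:
            raise ConfigError(
                f"parameter table has {n_wc} Watson-Crick stacks; 16 required")

    @classmethod
    def from_tsv(cls, path) -> "NnParameterTable":
        stacks: dict[str, float] = {}
        scalars: dict[str, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(
                    (ln for ln in fh if not ln.startswith("#")),
                    delimiter="\t"):
                if row["param"] == "stack":
                    stacks[row["key"]] = float(row["value"])
                else:
                    scalars[row["param"]] = float(row["value"])
        try:
            return cls(stack_energies=stacks,
                       terminal_au_penalty=scalars["terminal_au"],
                       mismatch_penalty=scalars["mismatch"],
                       init_energy=scalars["init"])
        except KeyError as exc:
            raise ConfigError(f"parameter table missing {exc}") from exc

    @classmethod
    def default(cls) -> "NnParameterTable":
        ref = resources.files("orthoscreen.data") / "nn_stacks.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass
class ConservedFamily:
    family: str
    consensus_seq: str
    species_present: set[str]
    max_mismatch_observed: int


class NucleusSite(NamedTuple):
    """A nucleus match: UTR position of the first paired target base, run
    length, and the miRNA position where the run starts (5' side)."""

    utr_start: int
    nucleus_len: int
    mirna_start: int


@dataclass
class TargetSite:
    family: str
    gene_symbol: str
    utr_start: int
    nucleus_len: int
    duplex_dg: float
    passes_energy: bool
    span: int = 0  # paired footprint length on the UTR (miRNA length)

    @staticmethod
    def report_header() -> list[str]:
        return ["gene_symbol", "family", "utr_start", "nucleus_len",
                "duplex_dg", "passes_energy"]

    def report_row(self) -> list:
        return [self.gene_symbol, self.family, self.utr_start,
                self.nucleus_len, f"{self.duplex_dg:.2f}",
                self.passes_energy]


def filter_conserved(
    mirnas: list[MiRnaRecord],
    min_species: int = DEFAULT_MIN_SPECIES,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    reference_species: str = "human",
    mode: str = "consensus",
) -> list[ConservedFamily]:
    """Keep families present in >= min_species species whose every copy is
    within max_mismatch substitutions of the consensus (mode="consensus") or
    of the reference-species copy (mode="reference")."""
    if mode not in ("consensus", "reference"):
        raise ConfigError(f"unknown conservation mode {mode!r}")
    groups: dict[str, dict[str, str]] = defaultdict(dict)
    for rec in mirnas:
        if rec.species in groups[rec.family]:
            log.warning("duplicate copy of %s in %s; first kept",
                        rec.family, rec.species)
            continue
        groups[rec.family][rec.species] = rec.mature_seq

    out: list[ConservedFamily] = []
    for family in sorted(groups):
        copies = groups[family]
        if len(copies) < min_species:
            continue
        lengths = {len(s) for s in copies.values()}
        if len(lengths) != 1:
            log.warning("family %s has copies of unequal length; dropped",
                        family)
            continue
        if mode == "reference":
            if reference_species not in copies:
                log.warning("family %s lacks a %s copy; dropped in "
                            "reference mode", family, reference_species)
                continue
            anchor = copies[reference_species]
        else:
            anchor = _majority_consensus(copies, reference_species)
        worst = max(sum(a != b for a, b in zip(seq, anchor))
                    for seq in copies.values())
        if worst <= max_mismatch:
            out.append(ConservedFamily(family, anchor, set(copies), worst))
    return out


def _majority_consensus(copies: dict[str, str], reference_species: str) -> str:
    ref = copies.get(reference_species)
    consensus = []
    for i in range(len(next(iter(copies.values())))):
        counts = Counter(seq[i] for seq in copies.values())
        top = max(counts.values())
        tied = sorted(b for b, c in counts.items() if c == top)
        if len(tied) > 1 and ref is not None and ref[i] in tied:
            consensus.append(ref[i])
        else:
            consensus.append(tied[0])
    return "".join(consensus)


def _pairs(m_base: str, t_base: str, mirna_pos: int) -> bool:
    """Pair predicate: Watson-Crick anywhere; G:U only outside the nucleus
    region (positions 1..9)."""
    if (m_base, t_base) in _WC:
        return True
    return mirna_pos > NUCLEUS_REGION and (m_base, t_base) in _WOBBLE


def nucleus_match(mirna: str, utr: str,
                  seed_min: int = DEFAULT_SEED_MIN) -> list[NucleusSite]:
    """Every UTR position where >= seed_min contiguous Watson-Crick pairs
    form against the miRNA 5' nucleus (positions 1-9), antiparallel; the
    maximal run is reported once per register."""
    if seed_min < 1:
        raise ConfigError("seed_min must be >= 1")
    m, u = _rna(mirna), _rna(utr)
    region = min(NUCLEUS_REGION, len(m))
    sites: set[NucleusSite] = set()
    # register t1 = UTR position (1-based) paired with miRNA position 1;
    # miRNA position j pairs UTR position t1 - (j - 1). t1 may exceed the
    # UTR end when only the 3' part of the nucleus lies inside the UTR.
    for t1 in range(1, len(u) + region):
        run_start = None
        j = 1
        while j <= region + 1:
            tpos = t1 - (j - 1)
            ok = (j <= region and 1 <= tpos <= len(u)
                  and (m[j - 1], u[tpos - 1]) in _WC)
            if ok and run_start is None:
                run_start = j
            if not ok and run_start is not None:
                run_len = j - run_start
                if run_len >= seed_min:
                    b = j - 1  # last paired miRNA position
                    sites.add(NucleusSite(t1 - (b - 1), run_len, run_start))
                run_start = None
            j += 1
    return sorted(sites)


def _site_window(mirna: str, utr: str, site: NucleusSite
                 ) -> Optional[tuple[str, int]]:
    """UTR substring covering the full miRNA length in this register.

    Returns (window, window_start) with window_start 1-based; window index i
    (0-based) pairs miRNA position len(mirna) - i. None when the window runs
    off either UTR end.
    """
    L = len(mirna)
    b = site.mirna_start + site.nucleus_len - 1  # last nucleus-paired pos
    start = site.utr_start + b - L   # pairs miRNA position L
    end = site.utr_start + b - 1     # pairs miRNA position 1
    if start < 1 or end > len(utr):
        return None
    return utr[start - 1: end], start


def duplex_energy(mirna: str, utr: str, site: NucleusSite,
                  params: Optional[NnParameterTable] = None) -> float:
    """Nearest-neighbor hybridization dG (kcal/mol) of the full-length
    duplex in the register fixed by ``site``."""
    if params is None:
        params = NnParameterTable.default()
    m, u = _rna(mirna), _rna(utr)
    found = _site_window(m, u, site)
    if found is None:
        raise InputError("site window exceeds UTR bounds")
    window, _ = found
    L = len(m)
    partner = window[::-1]  # partner[j-1] pairs miRNA position j
    paired = [_pairs(m[j - 1], partner[j - 1], j) for j in range(1, L + 1)]

    dg = params.init_energy
    for j in range(1, L):  # step between positions j and j+1
        if paired[j - 1] and paired[j]:
            key = f"{m[j - 1]}{m[j]}/{partner[j - 1]}{partner[j]}"
            try:
                dg += params.stack_energies[key]
            except KeyError as exc:
                raise ConfigError(f"no stack entry for {key}") from exc
        else:
            dg += params.mismatch_penalty
    paired_positions = [j for j in range(1, L + 1) if paired[j - 1]]
    for j in (paired_positions[0], paired_positions[-1]) if paired_positions \
            else ():
        if (m[j - 1], partner[j - 1]) != ("G", "C") and \
                (m[j - 1], partner[j - 1]) != ("C", "G"):
            dg += params.terminal_au_penalty
    return round(dg, 10)


@dataclass
class TargetConfig:
    seed_min: int = DEFAULT_SEED_MIN
    energy_cutoff: float = DEFAULT_ENERGY_CUTOFF
    params: NnParameterTable = field(
        default_factory=NnParameterTable.default)


def predict_targets(utr_calls: list[UtrCall],
                    families: list[ConservedFamily],
                    config: Optional[TargetConfig] = None
                    ) -> list[TargetSite]:
    """Cross every conserved family with every called UTR; keep nucleus
    matches whose duplex dG <= cutoff. Output sorted by (gene, family,
    utr_start), invariant to input ordering."""
    if config is None:
        config = TargetConfig()
    out: list[TargetSite] = []
    for call in utr_calls:
        if not isinstance(call, UtrCall):
            continue
        utr_rna = _rna(call.utr_seq)
        for fam in families:
            for site in nucleus_match(fam.consensus_seq, utr_rna,
                                      config.seed_min):
                if _site_window(_rna(fam.consensus_seq), utr_rna,
                                site) is None:
                    log.warning("site at %s:%d for %s exceeds UTR bounds; "
                                "skipped", call.gene_symbol, site.utr_start,
                                fam.family)
                    continue
                dg = duplex_energy(fam.consensus_seq, utr_rna, site,
                                   config.params)
                if dg <= config.energy_cutoff:
                    out.append(TargetSite(
                        family=fam.family,
                        gene_symbol=call.gene_symbol,
                        utr_start=site.utr_start,
                        nucleus_len=site.nucleus_len,
                        duplex_dg=dg,
                        passes_energy=True,
                        span=len(fam.consensus_seq)))
    out.sort(key=lambda s: (s.gene_symbol, s.family, s.utr_start))
    return out
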