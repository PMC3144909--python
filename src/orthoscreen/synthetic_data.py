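"""Synthetic ortholog panels, loci and miRNA tables with planted ground
truth.

The generator emulates the inputs of a nine-mammal ortholog screen: per-gene
protein sets mutated to a controlled percent identity against the reference
species, genomic loci assembled as

    [50 nt upstream context, -3/+4 set per planted Kozak class]
    [CDS: start codon + one codon per residue + stop]
    [4 kb downstream region, PAS hexamers scrubbed, one planted AAUAAA]

with strand assigned randomly, plus miRNA families with controlled
cross-species mismatch counts and 3'UTR target sites planted at a chosen
nucleus length and duplex-energy band. Every planted feature is recorded in
a truth table so each pipeline stage can be checked for exact recovery.

All randomness flows from ``SimulationConfig.rng_seed`` (mandatory); a fixed
seed reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .kozak import position_index
from .mirna_targets import NnParameterTable, NucleusSite, duplex_energy
from .seqio import GeneRecord, MiRnaRecord, OrthologPanel, reverse_complement

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
_RNA_NT = "ACGU"
_NON_ATG_STARTS = ("CTG", "GTG", "TTG")
_MISMATCH_RNA = {"A": "C", "U": "C", "G": "A", "C": "A"}
_PAS_MOTIFS = ("AATAAA", "ATTAAA")

DEFAULT_SPECIES = ["human", "chimpanzee", "mouse", "rat", "dog", "cat",
                   "horse", "cow", "panda"]


@dataclass
class PlantedSitePlan:
    """A 3'UTR target site to plant: nucleus length and dG band (lo, hi],
    kcal/mol."""

    gene: str
    family: str
    nucleus_len: int
    dg_band: tuple[float, float]


@dataclass
class SimulationConfig:
    rng_seed: int
    n_genes: int = 166
    species_list: list[str] = field(
        default_factory=lambda: list(DEFAULT_SPECIES))
    reference_species: str = "human"
    query_species: str = "panda"
    protein_length: int = 300
    default_identity: float = 0.85
    identity_targets: dict[str, float] = field(default_factory=dict)
    kozak_plan: dict[tuple[str, str], str] = field(default_factory=dict)
    pas_plan: dict[tuple[str, str], Optional[int]] = field(
        default_factory=dict)
    site_plan: list[PlantedSitePlan] = field(default_factory=list)
    mirna_families: dict[str, int] = field(default_factory=dict)
    mirna_mismatched_species: dict[str, list[str]] = field(
        default_factory=dict)
    deletion_genes: set[str] = field(default_factory=set)
    window_length: int = 4000
    cleavage_offset: int = 19
    gene_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ConfigError("rng_seed is mandatory")
        for g, f in self.identity_targets.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"identity target for {g} outside [0,1]")
        for key, off in self.pas_plan.items():
            if off is not None and not 1 <= off <= self.window_length - 5:
                raise ConfigError(
                    f"PAS offset {off} for {key} outside the downstream "
                    f"window of {self.window_length} nt")
        for plan in self.site_plan:
            if not 1 <= plan.nucleus_len <= 9:
                raise ConfigError(
                    f"nucleus_len {plan.nucleus_len} outside 1..9")

    @property
    def genes(self) -> list[str]:
        if self.gene_names is not None:
            return list(self.gene_names)
        return [f"G{i:03d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SiteTruth:
    gene: str
    family: str
    utr_start: int
    nucleus_len: int
    duplex_dg: float


@dataclass
class PanelTruth:
    """Everything that was planted, keyed the way the screens report it."""

    kozak_class: dict[tuple[str, str], str]
    identity: dict[tuple[str, str], float]
    pas_offset: dict[tuple[str, str], Optional[int]]
    expected_utr_length: dict[tuple[str, str], Optional[int]]
    strand: dict[tuple[str, str], str]
    coverage_table: dict[str, tuple[int, int, str]]
    sites: list[SiteTruth]
    family_seqs: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (gene, species), cls in sorted(self.kozak_class.items()):
            rows.append({
                "gene_symbol": gene,
                "species": species,
                "kozak_class": cls,
                "identity": self.identity.get((gene, species), ""),
                "pas_offset": self.pas_offset.get((gene, species), ""),
                "expected_utr_length":
                    self.expected_utr_length.get((gene, species), ""),
                "strand": self.strand[(gene, species)],
            })
        return pd.DataFrame(rows)


def _rand_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate_protein(rng: np.random.Generator, protein: str,
                    identity: float) -> str:
    """Substitutions only; measured identity lands within +/-2 points of the
    target by construction (exactly round(L*(1-identity)) changed sites)."""
    L = len(protein)
    k = int(round(L * (1.0 - identity)))
    positions = rng.choice(L, size=k, replace=False)
    seq = list(protein)
    for p in positions:
        choices = [a for a in _AA if a != seq[p]]
        seq[p] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _scrub_motifs(seq: str, motifs: tuple[str, ...]) -> str:
    """Remove every occurrence of the given motifs by mutating each
    occurrence's middle base, iterating to a fixpoint."""
    s = list(seq)
    for _ in range(100):
        dirty = False
        text = "".join(s)
        for motif in motifs:
            idx = text.find(motif)
            while idx != -1:
                mid = idx + len(motif) // 2
                s[mid] = "C" if s[mid] != "C" else "G"
                dirty = True
                idx = text.find(motif, idx + 1)
        if not dirty:
            return "".join(s)
    raise ConfigError("motif scrubbing did not converge")


def _nucleus_patterns(family_seqs: dict[str, str]) -> tuple[str, ...]:
    """DNA 7-mers whose presence in a UTR could seed a nucleus match
    (reverse complements of every 7-window inside miRNA positions 1-9).
    Scrubbing them leaves planted sites as the only callable sites."""
    out: set[str] = set()
    for seq in family_seqs.values():
        dna = seq.replace("U", "T")
        for a in range(0, min(9, len(dna)) - 6):
            out.add(reverse_complement(dna[a:a + 7]))
    return tuple(sorted(out))


def _kozak_bases(rng: np.random.Generator, cls: str
                 ) -> tuple[str, str, str]:
    """(start codon, -3 base, +4 base) realizing a planted class.

    Unplanned loci use the fixed strong pattern (A at -3, G at +4) so that
    only planted genes can differ between species.
    """
    if cls == "default":
        return "ATG", "A", "G"
    if cls == "no-AUG":
        start = _NON_ATG_STARTS[rng.integers(len(_NON_ATG_STARTS))]
        return start, "A", "G"
    minus3_r = str(rng.choice(["A", "G"]))
    minus3_y = str(rng.choice(["C", "T"]))
    plus4_not_g = str(rng.choice(["A", "C", "T"]))
    if cls == "S":
        return "ATG", minus3_r, "G"
    if cls == "W":
        return "ATG", minus3_y, plus4_not_g
    if cls == "A":
        if rng.integers(2):
            return "ATG", minus3_r, plus4_not_g
        return "ATG", minus3_y, "G"
    raise ConfigError(f"unknown Kozak class {cls!r}")


def build_site_window(family_seq: str, nucleus_len: int,
                      dg_band: tuple[float, float],
                      params: NnParameterTable) -> tuple[str, float]:
    """Search complementarity extensions for a target window whose duplex dG
    falls in ``dg_band`` (lo, hi].

    The window pairs miRNA positions 1..nucleus_len (Watson-Crick), breaks
    pairing through the rest of the nucleus region, then extends pairing
    from position 10 outward until the energy lands in the band. Returns
    (window as DNA, dG); raises ConfigError when the band is unachievable.
    """
    m = family_seq.upper().replace("T", "U")
    L = len(m)
    lo, hi = dg_band
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    for ext in range(0, L - 9 + 1):
        paired = set(range(1, nucleus_len + 1)) | set(range(10, 10 + ext))
        partner = [comp[m[j - 1]] if j in paired else _MISMATCH_RNA[m[j - 1]]
                   for j in range(1, L + 1)]
        window_rna = "".join(reversed(partner))
        site = NucleusSite(utr_start=L - nucleus_len + 1,
                           nucleus_len=nucleus_len, mirna_start=1)
        dg = duplex_energy(m, window_rna, site, params)
        if lo < dg <= hi:
            return window_rna.replace("U", "T"), dg
    raise ConfigError(
        f"dG band ({lo}, {hi}] unachievable for family sequence {m}")


def plant_target_site(utr: str, family_seq: str, nucleus_len: int,
                      dg_band: tuple[float, float],
                      params: NnParameterTable,
                      rng: np.random.Generator,
                      max_pos: Optional[int] = None,
                      forbidden: Optional[list[tuple[int, int]]] = None
                      ) -> tuple[str, SiteTruth]:
    """Insert one target site into a DNA UTR; the truth record stores the
    position the caller should recover and the oracle-computed dG.

    ``max_pos`` restricts the insertion to the UTR prefix (so a planted site
    stays upstream of a planted polyadenylation signal); ``forbidden`` lists
    0-based half-open ranges (previous plants) the site must not overlap.
    """
    window, dg = build_site_window(family_seq, nucleus_len, dg_band, params)
    L = len(window)
    scan_end = max_pos if max_pos is not None else len(utr)
    limit = scan_end - L
    if limit < 0:
        raise ConfigError("UTR too short to hold a planted site")
    for _ in range(100):
        p = int(rng.integers(0, limit + 1))
        if any(p < hi and p + L > lo for lo, hi in (forbidden or [])):
            continue
        modified = utr[:p] + window + utr[p + L:]
        if "AATAAA" not in modified[:scan_end]:
            break
    else:
        raise ConfigError("could not place site without creating a "
                          "spurious polyadenylation signal")
    truth = SiteTruth(gene="", family="",
                      utr_start=p + L - nucleus_len + 1,
                      nucleus_len=nucleus_len, duplex_dg=dg)
    return modified, truth


def make_family_seqs(config: SimulationConfig,
                     rng: np.random.Generator) -> dict[str, str]:
    """Random 22-nt family sequences at 50% GC (a shuffled fixed base
    multiset), matching typical mature-miRNA composition and keeping every
    reasonable planted energy band reachable."""
    families = sorted(set(config.mirna_families)
                      | {p.family for p in config.site_plan})
    multiset = list("AAAAAA" + "UUUUU" + "GGGGGG" + "CCCCC")
    return {fam: "".join(rng.permutation(multiset)) for fam in families}


def make_mirnas(config: SimulationConfig, rng: np.random.Generator,
                family_seqs: dict[str, str]) -> list[MiRnaRecord]:
    """Species copies per family: ``mirna_families[fam]`` species (default
    all), each copy equal to the family sequence except one substitution in
    the species listed under ``mirna_mismatched_species``."""
    records: list[MiRnaRecord] = []
    for fam in sorted(family_seqs):
        seq = family_seqs[fam]
        n_sp = config.mirna_families.get(fam, len(config.species_list))
        species = config.species_list[:n_sp]
        mismatched = set(config.mirna_mismatched_species.get(fam, []))
        for sp in species:
            copy = seq
            if sp in mismatched:
                pos = int(rng.integers(len(seq)))
                choices = [b for b in _RNA_NT if b != seq[pos]]
                copy = seq[:pos] + choices[rng.integers(3)] + seq[pos + 1:]
            records.append(MiRnaRecord(family=fam, species=sp,
                                       mature_seq=copy))
    return records


def _build_locus(rng: np.random.Generator, config: SimulationConfig,
                 gene: str, species: str, protein_len: int,
                 params: NnParameterTable,
                 family_seqs: dict[str, str],
                 site_plans: list[PlantedSitePlan],
                 scrub_patterns: tuple[str, ...],
                 ) -> tuple[str, int, int, Optional[int], list[SiteTruth]]:
    """Oriented locus = upstream(50) + CDS + downstream(window_length).
    Returns (oriented_seq, cds_start, cds_end, pas_offset, site_truths)."""
    cls = config.kozak_plan.get((gene, species), "default")
    start_codon, minus3, plus4 = _kozak_bases(rng, cls)

    upstream = list(_rand_seq(rng, _NT, 50))
    cds_start = 51
    upstream[50 + position_index(-3) - 25] = minus3  # oriented index 47
    body = list(_rand_seq(rng, _NT, 3 * protein_len))
    body[0] = plus4
    cds = start_codon + "".join(body) + "TAA"
    cds_end = 50 + len(cds)

    downstream = _scrub_motifs(_rand_seq(rng, _NT, config.window_length),
                               scrub_patterns)

    if (gene, species) in config.pas_plan:
        pas_offset = config.pas_plan[(gene, species)]
    else:
        pas_offset = int(rng.integers(100, config.window_length - 100))

    truths: list[SiteTruth] = []
    if pas_offset is not None:
        utr_len = min(pas_offset + 5 + config.cleavage_offset,
                      config.window_length)
        occupied: list[tuple[int, int]] = []
        for plan in site_plans:
            modified, truth = plant_target_site(
                downstream, family_seqs[plan.family], plan.nucleus_len,
                plan.dg_band, params, rng,
                max_pos=max(0, pas_offset - 6),  # keep clear of the PAS
                forbidden=occupied)
            downstream = modified
            truth.gene, truth.family = gene, plan.family
            fam_len = len(family_seqs[plan.family])
            start0 = truth.utr_start + plan.nucleus_len - fam_len - 1
            occupied.append((start0, start0 + fam_len))
            if truth.utr_start + 21 > utr_len:
                raise ConfigError(
                    f"planted site for {gene}/{plan.family} falls outside "
                    "the expected UTR")
            truths.append(truth)
        downstream = (downstream[:pas_offset - 1] + "AATAAA"
                      + downstream[pas_offset + 5:])
        # a planted base just upstream can complete a premature AATAAA
        # overlapping the planted signal; break any such occurrence
        ds = list(downstream)
        while True:
            first = "".join(ds).find("AATAAA")
            if first == -1 or first == pas_offset - 1:
                break
            ds[first + 2] = "C"
        downstream = "".join(ds)
    oriented = "".join(upstream) + cds + downstream
    return oriented, cds_start, cds_end, pas_offset, truths


def make_panel(config: SimulationConfig,
               family_seqs: Optional[dict[str, str]] = None,
               rng: Optional[np.random.Generator] = None
               ) -> tuple[OrthologPanel, PanelTruth]:
    """Generate a full ortholog panel plus its planted-feature truth table."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    params = NnParameterTable.default()
    if family_seqs is None:
        family_seqs = make_family_seqs(config, rng)
    plans_by_gene: dict[str, list[PlantedSitePlan]] = {}
    for plan in config.site_plan:
        plans_by_gene.setdefault(plan.gene, []).append(plan)
    scrub_patterns = _PAS_MOTIFS + _nucleus_patterns(family_seqs)

    truth = PanelTruth(kozak_class={}, identity={}, pas_offset={},
                       expected_utr_length={}, strand={}, coverage_table={},
                       sites=[], family_seqs=dict(family_seqs))
    panel = OrthologPanel(genes={}, reference_species=config.reference_species)

    for gene in config.genes:
        ref_protein = _rand_seq(rng, _AA, config.protein_length)
        truth.coverage_table[gene] = (config.protein_length,
                                      config.protein_length,
                                      f"SYN_{gene}")
        for species in config.species_list:
            if species == config.reference_species:
                protein = ref_protein
                identity = 1.0
            else:
                identity = config.identity_targets.get(
                    gene, config.default_identity)
                protein = _mutate_protein(rng, ref_protein, identity)
                if gene in config.deletion_genes and \
                        species == config.query_species:
                    p = int(rng.integers(10, len(protein) - 14))
                    protein = protein[:p] + protein[p + 4:]
            site_plans = (plans_by_gene.get(gene, [])
                          if species == config.query_species else [])
            oriented, cds_start, cds_end, pas_offset, site_truths = \
                _build_locus(rng, config, gene, species, len(protein),
                             params, family_seqs, site_plans,
                             scrub_patterns)
            strand = "+" if rng.integers(2) else "-"
            contig = oriented if strand == "+" else \
                reverse_complement(oriented)
            record = GeneRecord(gene_symbol=gene, species=species,
                                protein_seq=protein, contig_seq=contig,
                                cds_start=cds_start, cds_end=cds_end,
                                strand=strand)
            panel.genes.setdefault(gene, {})[species] = record

            key = (gene, species)
            truth.kozak_class[key] = config.kozak_plan.get(key, "default")
            truth.identity[key] = 1.0 - round(
                len(protein) * (1.0 - identity)) / len(protein) \
                if species != config.reference_species else 1.0
            truth.pas_offset[key] = pas_offset
            truth.expected_utr_length[key] = (
                None if pas_offset is None
                else min(pas_offset + 5 + config.cleavage_offset,
                         config.window_length))
            truth.strand[key] = strand
            truth.sites.extend(site_truths)
    truth.sites.sort(key=lambda s: (s.gene, s.family, s.utr_start))
    return panel, truth


@dataclass
class SimulationResult:
    panel: OrthologPanel
    mirnas: list[MiRnaRecord]
    truth: PanelTruth

    @property
    def coverage_table(self) -> dict[str, tuple[int, int, str]]:
        return self.truth.coverage_table


def simulate(config: SimulationConfig) -> SimulationResult:
    """One-call generator: panel, miRNA table and truth, all deterministic
    from ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    family_seqs = make_family_seqs(config, rng)
    mirnas = make_mirnas(config, rng, family_seqs)
    panel, truth = make_panel(config, family_seqs=family_seqs, rng=rng)
    return SimulationResult(panel=panel, mirnas=mirnas, truth=truth)
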