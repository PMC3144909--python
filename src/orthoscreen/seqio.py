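"""Readers/writers for the on-disk formats and the single home of the
coordinate and strand conventions.

Conventions (enforced here, consumed everywhere else):

* Genomic coordinates in the CDS table are **1-based inclusive** and refer to
  positions on the **strand-oriented** sequence: for a minus-strand gene,
  position 1 is the first base of the reverse-complemented contig, and
  ``cds_start`` is the A of the start codon in reading orientation.
* BED output is 0-based half-open, per the BED standard.
* Soft-masked (lowercase) bases are preserved on read; interpretation is left
  to consumers.

File dialects
-------------
ortholog map TSV : gene_symbol, species, protein_id, gene_id
                   (empty protein_id *and* gene_id = no ortholog in that
                   species; the pair is recorded as missing)
CDS TSV          : gene_symbol, species, contig, cds_start, cds_end, strand
miRNA TSV        : family, species, mature_seq
coverage TSV     : gene_symbol, structure_id, coverage_count, coverage_total
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO

from .errors import AlphabetError, CoordinateError, FormatError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_NUC_CHARS = set("ACGTNacgtn")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYX") | set("acdefghiklmnpqrstvwyx")
_RNA_CHARS = set("ACGU")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string, case-preserving; N maps to N."""
    bad = set(seq) - _NUC_CHARS
    if bad:
        raise AlphabetError(
            f"non-nucleotide characters {sorted(bad)!r} in sequence"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneRecord:
    """One gene in one species: protein, genomic contig and CDS location.

    ``contig_seq`` is the plus-strand sequence as read from FASTA;
    ``oriented`` materializes the reading-strand view once so downstream
    modules never re-handle strand. ``cds_start``/``cds_end`` are 1-based
    inclusive positions on the oriented sequence.
    """

    gene_symbol: str
    species: str
    protein_seq: Optional[str]
    contig_seq: str
    cds_start: int
    cds_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CoordinateError(
                f"{self.gene_symbol}/{self.species}: strand must be + or -, "
                f"got {self.strand!r}"
            )
        if self.cds_start < 1 or self.cds_end < 1:
            raise CoordinateError(
                f"{self.gene_symbol}/{self.species}: coordinates are 1-based; "
                f"got cds_start={self.cds_start}, cds_end={self.cds_end}"
            )
        if self.cds_start > self.cds_end:
            raise CoordinateError(
                f"{self.gene_symbol}/{self.species}: cds_start > cds_end"
            )
        if self.cds_end > len(self.contig_seq):
            raise CoordinateError(
                f"{self.gene_symbol}/{self.species}: cds_end={self.cds_end} "
                f"beyond contig length {len(self.contig_seq)}"
            )
        bad = set(self.contig_seq) - _NUC_CHARS
        if bad:
            raise AlphabetError(
                f"{self.gene_symbol}/{self.species}: contig contains "
                f"{sorted(bad)!r}"
            )
        if self.protein_seq is not None:
            badp = set(self.protein_seq) - _AA_CHARS
            if badp:
                raise AlphabetError(
                    f"{self.gene_symbol}/{self.species}: protein contains "
                    f"{sorted(badp)!r}"
                )

    @property
    def oriented(self) -> str:
        """Strand-oriented contig (reverse complement for minus strand)."""
        if self.strand == "+":
            return self.contig_seq
        return reverse_complement(self.contig_seq)


@dataclass
class MiRnaRecord:
    """One mature miRNA copy; length is recorded, not assumed to be 22."""

    family: str
    species: str
    mature_seq: str
    length: int = field(init=False)

    def __post_init__(self) -> None:
        self.mature_seq = self.mature_seq.upper().replace("T", "U")
        bad = set(self.mature_seq) - _RNA_CHARS
        if bad:
            raise AlphabetError(
                f"miRNA {self.family}/{self.species}: contains {sorted(bad)!r}"
            )
        self.length = len(self.mature_seq)


@dataclass
class OrthologPanel:
    """Per-gene, per-species collection of GeneRecords.

    ``missing`` holds (gene, species) pairs the ortholog map declared absent;
    ``unmatched`` holds IDs present in the map but not found in the FASTA
    inputs (reported, never silently dropped).
    """

    genes: dict[str, dict[str, GeneRecord]]
    reference_species: str
    missing: set[tuple[str, str]] = field(default_factory=set)
    unmatched: list[str] = field(default_factory=list)

    def get(self, gene: str, species: str) -> Optional[GeneRecord]:
        return self.genes.get(gene, {}).get(species)

    @property
    def gene_symbols(self) -> list[str]:
        return sorted(self.genes)

    @property
    def species(self) -> list[str]:
        out: set[str] = set()
        for recs in self.genes.values():
            out.update(recs)
        return sorted(out)


def _read_fasta(path: Path) -> dict[str, str]:
    path = Path(path)
    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
            records[rec.id] = str(rec.seq)
    except FormatError:
        raise
    except Exception as exc:  # Bio raises ValueError on malformed input
        raise FormatError(f"{path}: malformed FASTA ({exc})") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _read_tsv(path: Path, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in required if c not in cols]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        return list(reader)


def read_panel(
    protein_fasta_paths: Mapping[str, Path],
    genome_fasta_paths: Mapping[str, Path],
    ortholog_tsv: Path,
    cds_tsv: Path,
    reference_species: str = "human",
) -> OrthologPanel:
    """Assemble an :class:`OrthologPanel` from per-species FASTA files plus
    the ortholog map and CDS coordinate tables.

    Every row of the ortholog map either resolves to a GeneRecord, is
    recorded in ``panel.missing`` (empty ID cells), or has its unmatched IDs
    appended to ``panel.unmatched`` with a logged warning.
    """
    proteins = {sp: _read_fasta(p) for sp, p in protein_fasta_paths.items()}
    genomes = {sp: _read_fasta(p) for sp, p in genome_fasta_paths.items()}

    cds_rows: dict[tuple[str, str], dict[str, str]] = {}
    for row in _read_tsv(Path(cds_tsv), ["gene_symbol", "species", "contig",
                                         "cds_start", "cds_end", "strand"]):
        cds_rows[(row["gene_symbol"], row["species"])] = row

    panel = OrthologPanel(genes={}, reference_species=reference_species)
    for row in _read_tsv(Path(ortholog_tsv),
                         ["gene_symbol", "species", "protein_id", "gene_id"]):
        gene, species = row["gene_symbol"], row["species"]
        pid = (row.get("protein_id") or "").strip()
        gid = (row.get("gene_id") or "").strip()
        if not pid and not gid:
            panel.missing.add((gene, species))
            continue

        protein_seq: Optional[str] = None
        if pid:
            protein_seq = proteins.get(species, {}).get(pid)
            if protein_seq is None:
                panel.unmatched.append(f"{gene}/{species}: protein {pid}")
                log.warning("unmatched protein id %s for %s/%s",
                            pid, gene, species)

        cds = cds_rows.get((gene, species))
        if cds is None:
            panel.missing.add((gene, species))
            log.warning("no CDS row for %s/%s", gene, species)
            continue
        contig_seq = genomes.get(species, {}).get(cds["contig"])
        if contig_seq is None:
            panel.unmatched.append(f"{gene}/{species}: contig {cds['contig']}")
            log.warning("unmatched contig %s for %s/%s",
                        cds["contig"], gene, species)
            continue
        record = GeneRecord(
            gene_symbol=gene,
            species=species,
            protein_seq=protein_seq,
            contig_seq=contig_seq,
            cds_start=int(cds["cds_start"]),
            cds_end=int(cds["cds_end"]),
            strand=cds["strand"],
        )
        panel.genes.setdefault(gene, {})[species] = record
    return panel


def read_mirnas(path: Path) -> list[MiRnaRecord]:
    """Read mature miRNAs from TSV (family/species/mature_seq) or FASTA with
    ``family_species`` record naming."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        out = []
        for rid, seq in _read_fasta(path).items():
            if "_" not in rid:
                raise FormatError(
                    f"{path}: miRNA id {rid!r} not in family_species form"
                )
            family, species = rid.rsplit("_", 1)
            out.append(MiRnaRecord(family=family, species=species,
                                   mature_seq=seq))
        return out
    rows = _read_tsv(path, ["family", "species", "mature_seq"])
    return [MiRnaRecord(r["family"], r["species"], r["mature_seq"])
            for r in rows]


def read_coverage_table(path: Path) -> dict[str, tuple[int, int, str]]:
    """Structure-coverage metadata: gene -> (count, total, structure_id)."""
    rows = _read_tsv(Path(path), ["gene_symbol", "structure_id",
                                  "coverage_count", "coverage_total"])
    return {r["gene_symbol"]: (int(r["coverage_count"]),
                               int(r["coverage_total"]),
                               r["structure_id"]) for r in rows}


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_tsv(path: Path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row)


def write_report(results: list, path: Path) -> None:
    """Write a stage report: TSV for .tsv paths, JSON for .json paths.

    One row per result; the schema is taken from the result type
    (ConsensusResult / KozakCall / UtrCall / TargetSite rows all provide
    ``report_row()`` and ``report_header()``).
    """
    path = Path(path)
    if results:
        header = results[0].report_header()
        rows = [r.report_row() for r in results]
    else:
        header, rows = ["gene_symbol"], []
    if path.suffix == ".json":
        payload = [dict(zip(header, row)) for row in rows]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        _write_tsv(path, header, rows)


def write_sites_bed(sites: list, path: Path) -> None:
    """BED6 of predicted target sites: 0-based half-open over the UTR,
    name = miRNA family, score = 10x|dG| capped at 1000."""
    rows = []
    for s in sites:
        start0 = s.utr_start - 1
        end = start0 + s.span
        score = min(1000, int(round(10 * abs(s.duplex_dg))))
        rows.append((s.gene_symbol, start0, end, s.family, score, "+"))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in rows:
            w.writerow(row)


def write_panel(panel: OrthologPanel, outdir: Path) -> dict[str, Path]:
    """Emit a panel back to disk in the same dialects :func:`read_panel`
    consumes. Returns the path map (per-species FASTAs + the two TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    by_species_prot: dict[str, list[tuple[str, str]]] = {}
    by_species_genome: dict[str, list[tuple[str, str]]] = {}
    orth_rows, cds_rows = [], []
    for gene in panel.gene_symbols:
        for species in sorted(panel.genes[gene]):
            rec = panel.genes[gene][species]
            pid = f"{gene}_{species}_prot" if rec.protein_seq else ""
            gid = f"{gene}_{species}_gene"
            contig = f"{gene}_{species}_locus"
            if rec.protein_seq:
                by_species_prot.setdefault(species, []).append(
                    (pid, rec.protein_seq))
            by_species_genome.setdefault(species, []).append(
                (contig, rec.contig_seq))
            orth_rows.append((gene, species, pid, gid))
            cds_rows.append((gene, species, contig, rec.cds_start,
                             rec.cds_end, rec.strand))
    for gene, species in sorted(panel.missing):
        orth_rows.append((gene, species, "", ""))
    orth_rows.sort()
    cds_rows.sort()

    for species, recs in sorted(by_species_prot.items()):
        p = outdir / f"{species}.protein.fasta"
        with open(p, "w") as fh:
            for rid, seq in recs:
                fh.write(f">{rid}\n{seq}\n")
        paths[f"protein:{species}"] = p
    for species, recs in sorted(by_species_genome.items()):
        p = outdir / f"{species}.genome.fasta"
        with open(p, "w") as fh:
            for rid, seq in recs:
                fh.write(f">{rid}\n{seq}\n")
        paths[f"genome:{species}"] = p

    orth = outdir / "orthologs.tsv"
    _write_tsv(orth, ["gene_symbol", "species", "protein_id", "gene_id"],
               orth_rows)
    paths["orthologs"] = orth
    cds = outdir / "cds.tsv"
    _write_tsv(cds, ["gene_symbol", "species", "contig", "cds_start",
                     "cds_end", "strand"], cds_rows)
    paths["cds"] = cds
    return paths


def write_mirnas(mirnas: list[MiRnaRecord], path: Path) -> None:
    _write_tsv(Path(path), ["family", "species", "mature_seq"],
               [(m.family, m.species, m.mature_seq) for m in mirnas])
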