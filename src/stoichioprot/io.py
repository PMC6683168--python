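"""Readers and writers for the pipeline's external formats.

FASTA proteomes (with ``gene=``/``chr=`` header tags), HPA-style categorical
expression tables (staining intensity x stained-cell fraction), gene ->
chromosome annotation (2-column TSV or GFF3 gene features) and GMT gene-set
collections.  Readers validate against closed vocabularies and never drop
rows silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

INTENSITY_LEVELS = ("negative", "weak", "moderate", "strong")
FRACTION_LEVELS = ("<25%", "25-75%", ">75%")

#: accepted aliases, normalised to the canonical vocabulary above
_INTENSITY_ALIASES = {"medium": "moderate"}
_FRACTION_ALIASES = {"25–75%": "25-75%"}  # en-dash variant
_MISSING_TOKENS = {"−", "-", "", "NA", "na", "n/a"}

_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")
CHROMOSOME_ORDER = _CHROMOSOMES + ("unplaced",)


class FormatError(ValueError):
    """Raised for malformed or vocabulary-violating input files."""


@dataclass
class ProteinRecord:
    """One proteome entry: identifier, gene symbol, chromosome, sequence."""

    protein_id: str
    gene_symbol: str = ""
    chromosome: str = "unplaced"
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise FormatError("protein_id must be non-empty")


@dataclass(frozen=True)
class StainingObservation:
    """One protein x one sample categorical IHC annotation.

    ``intensity``/``fraction`` are ``None`` when the observation is the
    atlas's missing marker; both are ``None`` together.
    """

    protein_id: str
    sample_id: str
    intensity: str | None
    fraction: str | None

    @property
    def missing(self) -> bool:
        return self.intensity is None


def normalize_chromosome(label: str) -> str:
    """Normalise a chromosome label to {1..22, X, Y, MT} or 'unplaced'."""
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    lab = lab.upper()
    if lab == "M":
        lab = "MT"
    return lab if lab in _CHROMOSOMES else "unplaced"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA proteome.

    Header descriptions may carry ``gene=SYMBOL`` and ``chr=LABEL`` tags.
    Duplicate identifiers and empty files are errors; record order is
    preserved and wrapped sequence lines are concatenated by the parser.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = ""
        chrom = "unplaced"
        for token in rec.description.split()[1:]:
            if token.startswith("gene="):
                gene = token[len("gene="):]
            elif token.startswith("chr="):
                chrom = normalize_chromosome(token[len("chr="):])
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(
            ProteinRecord(
                protein_id=rec.id, gene_symbol=gene, chromosome=chrom, sequence=seq
            )
        )
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    dupes = sorted(pid for pid, n in seen.items() if n > 1)
    if dupes:
        raise FormatError(f"{path}: duplicate protein ids: {', '.join(dupes)}")
    return records


def write_fasta(path: str | Path, records: Sequence[ProteinRecord], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            tags = []
            if rec.gene_symbol:
                tags.append(f"gene={rec.gene_symbol}")
            if rec.chromosome:
                tags.append(f"chr={rec.chromosome}")
            header = " ".join([rec.protein_id, *tags])
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _parse_intensity(token: str, where: str) -> str | None:
    tok = token.strip()
    if tok in _MISSING_TOKENS:
        return None
    tok = _INTENSITY_ALIASES.get(tok.lower(), tok.lower())
    if tok not in INTENSITY_LEVELS:
        raise FormatError(f"{where}: unknown staining intensity {token!r}")
    return tok


def _parse_fraction(token: str, where: str) -> str | None:
    tok = token.strip()
    if tok in _MISSING_TOKENS:
        return None
    tok = _FRACTION_ALIASES.get(tok, tok)
    if tok not in FRACTION_LEVELS:
        raise FormatError(f"{where}: unknown stained-cell fraction {token!r}")
    return tok


def read_expression_table(path: str | Path) -> list[StainingObservation]:
    """Read a TSV of (protein_id, sample_id, intensity, fraction) rows.

    The atlas missing marker (Unicode minus or plain ``-``) and empty cells
    parse to a missing observation; ``medium`` is accepted as a synonym of
    ``moderate``.  Any other token raises :class:`FormatError` with the row
    number.
    """
    observations: list[StainingObservation] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_id", "sample_id", "intensity", "fraction"]
        if header != expected:
            raise FormatError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            pid, sid, raw_int, raw_frac = parts
            where = f"{path}:{lineno}"
            intensity = _parse_intensity(raw_int, where)
            fraction = _parse_fraction(raw_frac, where)
            if (intensity is None) != (fraction is None):
                # a half-missing annotation is treated as fully missing
                intensity = None
                fraction = None
            observations.append(StainingObservation(pid, sid, intensity, fraction))
    return observations


def write_expression_table(path: str | Path, observations: Iterable[StainingObservation]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tsample_id\tintensity\tfraction\n")
        for obs in observations:
            intensity = obs.intensity if obs.intensity is not None else "−"
            fraction = obs.fraction if obs.fraction is not None else "−"
            fh.write(f"{obs.protein_id}\t{obs.sample_id}\t{intensity}\t{fraction}\n")


def read_gene_chromosomes(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping gene symbol -> chromosome label.

    Gene symbols are case-folded to upper case; chromosome labels are
    normalised to {1..22, X, Y, MT, unplaced}.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            gene, chrom = parts[0].strip(), parts[1].strip()
            if gene.lower() == "gene" and lineno == 1:
                continue
            mapping[gene.upper()] = normalize_chromosome(chrom)
    if not mapping:
        raise FormatError(f"{path}: no gene->chromosome rows found")
    return mapping


_GFF_ATTR_KEYS = ("gene_name", "Name", "gene", "ID")


def read_gene_chromosomes_gff3(path: str | Path) -> dict[str, str]:
    """Extract gene -> chromosome from GFF3 ``gene`` features.

    Only the seqid column and a gene-symbol attribute (``gene_name``,
    ``Name``, ``gene`` or ``ID``, first found) are used; ``chr`` prefixes
    are stripped and non-karyotype seqids grouped as 'unplaced'.
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(
        path, sep="\t", comment="#", names=cols, header=None, dtype=str
    )
    genes = df[df["type"] == "gene"]
    if genes.empty:
        raise FormatError(f"{path}: no gene features found")
    mapping: dict[str, str] = {}
    for seqid, attrs in zip(genes["seqid"], genes["attributes"]):
        symbol = None
        for key in _GFF_ATTR_KEYS:
            m = re.search(rf"(?:^|;){key}=([^;]+)", attrs)
            if m:
                symbol = m.group(1)
                break
        if symbol is None:
            continue
        mapping[symbol.upper()] = normalize_chromosome(seqid)
    if not mapping:
        raise FormatError(f"{path}: no named gene features found")
    return mapping


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, tab-separated members.

    Duplicate members within a set are deduplicated; a line with fewer than
    3 fields is an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and at "
                    f"least one member (got {len(parts)} fields)"
                )
            name = parts[0]
            members = {g.upper() for g in parts[2:] if g}
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(path: str | Path, sets: dict[str, Iterable[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic", *sorted(set(members))]) + "\n")
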