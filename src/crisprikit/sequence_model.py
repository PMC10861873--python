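"""Genome and annotation handling for CRISPRi guide design.

Coordinates are 0-based, half-open on the forward strand everywhere inside the
package; GFF3 input/output (1-based, inclusive) is converted at the boundary.
Strand-aware extraction returns sequences 5'->3' on the requested strand.

The central objects are :class:`Replicon` (a chromosome or plasmid, optionally
circular), :class:`GeneModel` (a target gene with its transcription start
site), and :class:`RegionOfInterest` (the promoter window upstream of the TSS
or the transcribed region, the two search spaces for CRISPRi spacers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_VALID = set("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Invalid genome or annotation input."""


@dataclass
class Replicon:
    """A named replicon: the coordinate frame for all design operations.

    Ambiguity codes (anything outside A/C/G/T) are tolerated on load and their
    positions recorded; downstream design discards any candidate window that
    touches one.
    """

    id: str
    sequence: str
    circular: bool = False
    ambiguous_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeError(f"replicon {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        self.ambiguous_positions = frozenset(
            i for i, b in enumerate(self.sequence) if b not in _VALID
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Forward-strand sequence of [start, end), wrapping iff circular."""
        n = len(self.sequence)
        if start < 0 or end > n:
            if not self.circular:
                raise GenomeError(
                    f"interval [{start}, {end}) out of range for linear "
                    f"replicon {self.id!r} of length {n}"
                )
            start %= n
            end = start + (end - start)
            doubled = self.sequence + self.sequence
            if end - start > n:
                raise GenomeError("interval longer than circular replicon")
            return doubled[start:end]
        return self.sequence[start:end]


@dataclass
class GeneModel:
    """A target gene in internal coordinates, with a strand-aware TSS."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeError(f"gene {self.gene_id!r}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise GenomeError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.tss is None:
            # strand-aware 5' end: first transcribed base
            self.tss = self.start if self.strand == "+" else self.end - 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class RegionOfInterest:
    """Promoter or transcribed search region, inheriting the gene's strand."""

    gene_id: str
    kind: str  # "promoter" | "transcribed"
    start: int
    end: int
    strand: str
    truncated: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def load_genome(path: str | Path) -> dict[str, Replicon]:
    """Read a (multi-)FASTA into Replicons keyed by id.

    Sequence ids ending in ``|circular`` (or with a ``circular=true`` token in
    the description) are flagged circular.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    replicons: dict[str, Replicon] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        rid = record.id
        circular = False
        if rid.endswith("|circular"):
            rid = rid[: -len("|circular")]
            circular = True
        elif "circular=true" in record.description.lower():
            circular = True
        if rid in replicons:
            raise GenomeError(f"duplicate replicon id {rid!r} in {path}")
        if len(record.seq) == 0:
            raise GenomeError(f"empty record {rid!r} in {path}")
        replicons[rid] = Replicon(rid, str(record.seq), circular=circular)
    if not replicons:
        raise GenomeError(f"no FASTA records found in {path}")
    return replicons


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_targets(path: str | Path, genome: dict[str, Replicon]) -> list[GeneModel]:
    """Read target genes from GFF3 (1-based inclusive) or BED (0-based half-open).

    Format is chosen by extension (.gff/.gff3 vs .bed). A GFF3 attribute
    ``tss=<1-based position>`` overrides the default strand-aware 5' end.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if suffix in {".gff", ".gff3"}:
                if len(fields) < 9:
                    raise GenomeError(f"{path}:{lineno}: GFF3 needs 9 columns")
                rid, _, _, start1, end1, _, strand, _, attrs = fields[:9]
                start, end = int(start1) - 1, int(end1)
                a = _parse_gff3_attributes(attrs)
                gene_id = a.get("ID") or a.get("Name") or f"feature_{lineno}"
                tss = int(a["tss"]) - 1 if "tss" in a else None
            elif suffix == ".bed":
                if len(fields) < 6:
                    raise GenomeError(f"{path}:{lineno}: BED6 needs 6 columns")
                rid, start_s, end_s, gene_id, _, strand = fields[:6]
                start, end = int(start_s), int(end_s)
                tss = None
            else:
                raise GenomeError(f"unrecognized target-table extension {suffix!r}")
            if strand not in "+-":
                raise GenomeError(f"{path}:{lineno}: missing or invalid strand")
            if rid not in genome:
                raise GenomeError(f"{path}:{lineno}: unknown replicon {rid!r}")
            if not 0 <= start < end <= len(genome[rid]):
                raise GenomeError(
                    f"{path}:{lineno}: interval [{start}, {end}) invalid for "
                    f"replicon {rid!r} of length {len(genome[rid])}"
                )
            if gene_id in seen:
                raise GenomeError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, rid, start, end, strand, tss=tss))
    return genes


def to_gff3_coords(gene: GeneModel) -> tuple[int, int]:
    """Internal half-open interval back to GFF3 1-based inclusive."""
    return gene.start + 1, gene.end


def derive_regions(
    gene: GeneModel, genome: dict[str, Replicon], promoter_window: int = 50
) -> tuple[RegionOfInterest, RegionOfInterest]:
    """Promoter window upstream of the TSS plus the transcribed region.

    For a + strand gene the promoter is [tss-w, tss); for a - strand gene it is
    [tss+1, tss+1+w). On a linear replicon the window is truncated at the edge
    (with a warning); on a circular one it wraps.
    """
    if promoter_window < 1:
        raise ValueError("promoter_window must be >= 1")
    rep = genome[gene.replicon_id]
    n = len(rep)
    tss = gene.tss
    if gene.strand == "+":
        p_start, p_end = tss - promoter_window, tss
    else:
        p_start, p_end = tss + 1, tss + 1 + promoter_window
    truncated = False
    if not rep.circular:
        clipped = (max(p_start, 0), min(p_end, n))
        if clipped != (p_start, p_end):
            truncated = True
            warnings.warn(
                f"promoter window for {gene.gene_id} truncated at replicon edge",
                stacklevel=2,
            )
        p_start, p_end = clipped
    promoter = RegionOfInterest(
        gene.gene_id, "promoter", p_start, p_end, gene.strand, truncated=truncated
    )
    transcribed = RegionOfInterest(
        gene.gene_id, "transcribed", gene.start, gene.end, gene.strand
    )
    return promoter, transcribed


def extract(rep: Replicon, start: int, end: int, strand: str = "+") -> str:
    """Sequence of [start, end) reported 5'->3' on the requested strand."""
    seq = rep.fetch(start, end)
    return seq if strand == "+" else revcomp(seq)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
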