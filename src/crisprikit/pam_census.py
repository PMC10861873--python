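"""PAM occurrence census across target genes and whole replicons.

Counts IUPAC-motif occurrences (both strands, overlaps included) per gene and
genome-wide. In AT-rich genomes such as gut *Bacteroides* (~35% GC), the
Cas12a PAM 5'-TTV-3' is far more frequent than the GC-dependent Cas9 PAMs,
which is the rationale for choosing a Cas12a effector for CRISPRi there. The
census quantifies that choice for any gene set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .sequence_model import GeneModel, Replicon, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PamPattern:
    """A PAM motif in IUPAC notation.

    orientation is where the motif sits relative to the protospacer:
    5' for Cas12a-type PAMs, 3' for Cas9-type PAMs.
    """

    name: str
    iupac: str
    orientation: str = "five_prime_of_protospacer"

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty PAM motif")
        for ch in self.iupac:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in PAM {self.name!r}")

    def __len__(self) -> int:
        return len(self.iupac)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.iupac):
            return False
        return all(b in IUPAC[c] for b, c in zip(window, self.iupac))


#: The nuclease panel considered for CRISPRi in AT-rich Bacteroides genomes.
DEFAULT_PATTERNS = (
    PamPattern("SpCas9", "NGG", "three_prime_of_protospacer"),
    PamPattern("Sth1Cas9", "NNAGAA", "three_prime_of_protospacer"),
    PamPattern("Cas12a", "TTV", "five_prime_of_protospacer"),
    PamPattern("NmCas9", "NNNNGATT", "three_prime_of_protospacer"),
    PamPattern("AsCas12a", "TTTV", "five_prime_of_protospacer"),
    PamPattern("SaCas9", "NGRR", "three_prime_of_protospacer"),
)


def _compile(iupac: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in iupac)
    return re.compile(f"(?=({body}))")


def scan_pattern(
    sequence: str,
    pattern: PamPattern,
    strands: str = "both",
    circular: bool = False,
) -> list[tuple[int, int, str]]:
    """All occurrences of `pattern` in `sequence`.

    Returns (start, end, strand) with forward-strand coordinates for both
    strands. Windows containing non-ACGT characters never match (the regex
    alphabet is ACGT only). On a circular sequence, occurrences spanning the
    origin are found once and reported with start < len(sequence).
    """
    if strands not in {"forward", "reverse", "both"}:
        raise ValueError(f"bad strands {strands!r}")
    m = len(pattern)
    n = len(sequence)
    seq = sequence.upper()
    search = seq + seq[: m - 1] if circular and n >= m else seq
    hits: list[tuple[int, int, str]] = []
    rx = _compile(pattern.iupac)
    if strands in {"forward", "both"}:
        for match in rx.finditer(search):
            i = match.start()
            if i < n:
                hits.append((i, i + m, "+"))
    if strands in {"reverse", "both"}:
        rc = revcomp(search)
        L = len(search)
        for match in rx.finditer(rc):
            # map revcomp coordinates back to forward; for circular input the
            # window may start in the wrapped copy, so reduce modulo n
            start = L - match.start() - m
            if circular:
                start %= n
            hits.append((start, start + m, "-"))
    hits.sort()
    # a circular seam occurrence can be found in both copies; dedupe
    seen: set[tuple[int, str]] = set()
    out = []
    for s, e, st in hits:
        if (s, st) not in seen:
            seen.add((s, st))
            out.append((s, e, st))
    return out


def count_pattern(sequence: str, pattern: PamPattern, strands: str = "both",
                  circular: bool = False) -> int:
    return len(scan_pattern(sequence, pattern, strands, circular))


def census(
    genes: list[GeneModel],
    genome: dict[str, Replicon],
    patterns: tuple[PamPattern, ...] = DEFAULT_PATTERNS,
) -> pd.DataFrame:
    """Gene x PAM occurrence matrix plus genome-wide summary rows.

    Per-gene cells count occurrences (both strands) fully inside the gene
    interval. Two extra rows, ``__genome__`` (total occurrences over all
    replicons) and ``__genome_per_kb__`` (density), summarise the whole
    genome.
    """
    rows = {}
    for gene in genes:
        rep = genome[gene.replicon_id]
        gene_seq = rep.fetch(gene.start, gene.end)
        rows[gene.gene_id] = {
            p.name: count_pattern(gene_seq, p, "both") for p in patterns
        }
    genome_counts = {p.name: 0 for p in patterns}
    total_len = 0
    for rep in genome.values():
        total_len += len(rep)
        for p in patterns:
            genome_counts[p.name] += count_pattern(
                rep.sequence, p, "both", circular=rep.circular
            )
    rows["__genome__"] = genome_counts
    rows["__genome_per_kb__"] = {
        name: 1000.0 * c / total_len for name, c in genome_counts.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df[[p.name for p in patterns]]
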