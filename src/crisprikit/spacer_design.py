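"""Rule-based enumeration, ranking and selection of CRISPRi spacers.

The design rules encode how Cas12a-based CRISPRi works in bacteria:

* in the promoter window (50 nt upstream of the TSS by default) the RNP blocks
  RNA-polymerase recruitment, so protospacers on either strand are effective;
* inside the transcribed region only gRNAs annealing to the template strand
  block elongation, i.e. the protospacer (and its 5' TTV PAM) must lie on the
  coding (nontemplate) strand;
* soft preferences break ties among valid candidates: GC content within a
  window (35-75% by default), proximity to the promoter/5' end of the gene,
  and the extended TTTV PAM over plain TTV.

Candidates with a near-identical PAM-adjacent second site anywhere in the
genome are discarded (see :mod:`crisprikit.offtarget_filter`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .offtarget_filter import OfftargetIndex
from .pam_census import PamPattern
from .sequence_model import GeneModel, Replicon, derive_regions, extract

_VALID = set("ACGT")


@dataclass
class DesignConfig:
    """Tunable parameters of the design rules."""

    spacer_length: int = 20
    promoter_window: int = 50
    gc_min: float = 0.35
    gc_max: float = 0.75
    guides_per_gene: int = 3
    array_spacers_per_gene: int = 3
    pam: PamPattern = field(
        default_factory=lambda: PamPattern("Cas12a", "TTV", "five_prime_of_protospacer")
    )
    extended_pam: str = "TTTV"
    offtarget_max_mismatch: int = 2
    five_prime_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min < self.gc_max <= 1:
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.spacer_length < 10:
            raise ValueError("spacer_length must be >= 10")
        if self.offtarget_max_mismatch < 0:
            raise ValueError("offtarget_max_mismatch must be >= 0")


@dataclass(frozen=True)
class SpacerCandidate:
    """A designable spacer: protospacer plus PAM context and rank features.

    ``spacer_sequence`` is identical to the protospacer-strand sequence;
    ``annealing`` records which strand the mature gRNA pairs with relative to
    the target gene (template / promoter_fwd / promoter_rev).
    """

    gene_id: str
    replicon_id: str
    spacer_sequence: str
    protospacer_start: int  # forward-strand genomic, half-open
    protospacer_end: int
    protospacer_strand: str
    pam_sequence: str
    pam_start: int
    pam_end: int
    region_kind: str  # promoter | transcribed
    annealing: str  # template | promoter_fwd | promoter_rev
    gc_fraction: float
    tss_offset: int
    extended_pam: bool
    ambiguous: bool = False

    @property
    def protospacer_interval(self) -> tuple[int, int]:
        return (self.protospacer_start, self.protospacer_end)

    def overlaps(self, other: "SpacerCandidate") -> bool:
        return (
            self.replicon_id == other.replicon_id
            and self.protospacer_start < other.protospacer_end
            and other.protospacer_start < self.protospacer_end
        )


@dataclass
class GeneDesignResult:
    """Design outcome for one gene: single gRNAs, array spacers, and notes."""

    gene_id: str
    grnas: list[SpacerCandidate] = field(default_factory=list)
    array_spacers: list[SpacerCandidate] = field(default_factory=list)
    #: off-target-clean candidates disjoint from the gRNAs, in rank order;
    #: array design draws replacement triples from here when folding fails
    array_pool: list[SpacerCandidate] = field(default_factory=list)
    failure_notes: list[str] = field(default_factory=list)


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length."""
    if not sequence:
        raise ValueError("empty sequence")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def _window_ok(seq: str) -> bool:
    return all(b in _VALID for b in seq)


def enumerate_candidates(
    gene: GeneModel,
    genome: dict[str, Replicon],
    config: DesignConfig | None = None,
) -> list[SpacerCandidate]:
    """Every rule-compliant spacer for one gene.

    The search space is the union of the promoter window and the gene body;
    PAM and protospacer must lie entirely inside it. A candidate straddling
    the promoter/gene boundary is classified by its protospacer 5' end.
    Transcribed-region candidates are kept only when the protospacer sits on
    the gene's coding strand (gRNA anneals to the template strand); any window
    touching an ambiguity code is dropped.
    """
    config = config or DesignConfig()
    rep = genome[gene.replicon_id]
    promoter, transcribed = derive_regions(gene, genome, config.promoter_window)
    lo = min(promoter.start, transcribed.start)
    hi = max(promoter.end, transcribed.end)
    L = config.spacer_length
    plen = len(config.pam)
    region = rep.fetch(lo, hi)
    n = len(region)
    out: list[SpacerCandidate] = []

    def tss_offset_of(proto5: int) -> int:
        return proto5 - gene.tss if gene.strand == "+" else gene.tss - proto5

    for strand in "+-":
        # i: strand-agnostic forward-coordinate cursor over PAM starts
        for i in range(n):
            if strand == "+":
                pam_start, pam_end = lo + i, lo + i + plen
                proto_start, proto_end = pam_end, pam_end + L
                proto5 = proto_start
            else:
                proto_start, proto_end = lo + i, lo + i + L
                pam_start, pam_end = proto_end, proto_end + plen
                proto5 = proto_end - 1
            if pam_start < lo or pam_end > hi or proto_start < lo or proto_end > hi:
                continue
            pam_seq = extract(rep, pam_start, pam_end, strand)
            if not config.pam.matches(pam_seq):
                continue
            spacer_seq = extract(rep, proto_start, proto_end, strand)
            if not _window_ok(spacer_seq) or not _window_ok(pam_seq):
                continue
            in_promoter = promoter.start <= proto5 < promoter.end
            in_gene = gene.start <= proto5 < gene.end
            if in_promoter:
                kind = "promoter"
                annealing = "promoter_fwd" if strand == gene.strand else "promoter_rev"
            elif in_gene:
                if strand != gene.strand:
                    continue  # gRNA would anneal to the nontemplate strand
                kind = "transcribed"
                annealing = "template"
            else:
                continue
            ext_ok = False
            ext_len = len(config.extended_pam)
            # extended PAM shares the 3' end of the PAM on the protospacer strand
            if strand == "+":
                e_start, e_end = pam_end - ext_len, pam_end
            else:
                e_start, e_end = pam_start, pam_start + ext_len
            if 0 <= e_start and e_end <= len(rep):
                ext_seq = extract(rep, e_start, e_end, strand)
                ext_ok = PamPattern("ext", config.extended_pam).matches(ext_seq)
            out.append(
                SpacerCandidate(
                    gene_id=gene.gene_id,
                    replicon_id=gene.replicon_id,
                    spacer_sequence=spacer_seq,
                    protospacer_start=proto_start,
                    protospacer_end=proto_end,
                    protospacer_strand=strand,
                    pam_sequence=pam_seq,
                    pam_start=pam_start,
                    pam_end=pam_end,
                    region_kind=kind,
                    annealing=annealing,
                    gc_fraction=gc_fraction(spacer_seq),
                    tss_offset=tss_offset_of(proto5),
                    extended_pam=ext_ok,
                )
            )
    return out


def _region_priority(c: SpacerCandidate, gene: GeneModel, config: DesignConfig) -> int:
    if c.region_kind == "promoter":
        return 0
    gene_len = gene.end - gene.start
    five_prime_span = config.five_prime_fraction * gene_len
    return 1 if 0 <= c.tss_offset < five_prime_span else 2


def rank_candidates(
    candidates: list[SpacerCandidate],
    gene: GeneModel,
    config: DesignConfig | None = None,
) -> list[SpacerCandidate]:
    """Deterministic total order implementing the soft preferences.

    Sort key, lexicographic: GC inside the window first; promoter, then 5'
    portion of the gene, then 3' portion; extended (TTTV) PAM first; smaller
    |TSS offset|; genomic coordinate and strand as final tie-breakers.
    """
    config = config or DesignConfig()

    def key(c: SpacerCandidate):
        return (
            0 if config.gc_min <= c.gc_fraction <= config.gc_max else 1,
            _region_priority(c, gene, config),
            0 if c.extended_pam else 1,
            abs(c.tss_offset),
            c.protospacer_start,
            0 if c.protospacer_strand == "+" else 1,
        )

    return sorted(candidates, key=key)


def select_guides(
    gene: GeneModel,
    genome: dict[str, Replicon],
    config: DesignConfig | None = None,
    offtarget_index: OfftargetIndex | None = None,
) -> GeneDesignResult:
    """Pick up to ``guides_per_gene`` gRNAs plus array spacers for one gene.

    Candidates are taken in rank order, dropping any with an off-target hit.
    gRNA protospacers must be pairwise distinct and are preferred
    non-overlapping (overlap is allowed only when nothing else remains).
    Array spacers must be pairwise non-overlapping and disjoint from the
    gRNAs. Shortfalls are recorded in ``failure_notes``.
    """
    config = config or DesignConfig()
    result = GeneDesignResult(gene_id=gene.gene_id)
    candidates = rank_candidates(enumerate_candidates(gene, genome, config), gene, config)
    if not candidates:
        result.failure_notes.append("no candidate spacers (no usable PAM site)")
        return result

    clean: list[SpacerCandidate] = []
    n_offtarget = 0
    for c in candidates:
        if offtarget_index is not None:
            hits = offtarget_index.find(
                c.spacer_sequence,
                exclude=(c.replicon_id, c.protospacer_start, c.protospacer_strand),
                max_mismatch=config.offtarget_max_mismatch,
            )
            if hits:
                n_offtarget += 1
                continue
        clean.append(c)
    if n_offtarget:
        result.failure_notes.append(
            f"{n_offtarget} candidate(s) discarded as off-target-prone"
        )
    if not clean:
        result.failure_notes.append("no off-target-clean candidates")
        return result

    # gRNAs: exhaust the preferred-GC tier (non-overlapping first, then
    # overlapping but distinct) before touching out-of-window candidates, so
    # overlap avoidance never costs a GC-compliant guide
    grnas: list[SpacerCandidate] = []
    gc_pass = [c for c in clean if config.gc_min <= c.gc_fraction <= config.gc_max]
    gc_fail = [c for c in clean if c not in gc_pass]
    for tier in (gc_pass, gc_fail):
        for c in tier:  # non-overlapping pass
            if len(grnas) >= config.guides_per_gene:
                break
            if any(c.overlaps(g) for g in grnas):
                continue
            grnas.append(c)
        for c in tier:  # overlap allowed when nothing else remains
            if len(grnas) >= config.guides_per_gene:
                break
            if any(
                c.protospacer_interval == g.protospacer_interval
                and c.protospacer_strand == g.protospacer_strand
                for g in grnas
            ):
                continue
            grnas.append(c)
    result.grnas = grnas
    if len(grnas) < config.guides_per_gene:
        result.failure_notes.append(
            f"only {len(grnas)} gRNA(s) designed "
            f"(wanted {config.guides_per_gene}): insufficient spacers"
        )

    # array spacers: further candidates, pairwise non-overlapping and
    # disjoint from every selected gRNA
    pool = [c for c in clean if not any(c.overlaps(g) for g in grnas)]
    result.array_pool = pool
    array_spacers: list[SpacerCandidate] = []
    for c in pool:
        if len(array_spacers) >= config.array_spacers_per_gene:
            break
        if any(c.overlaps(a) for a in array_spacers):
            continue
        array_spacers.append(c)
    if len(array_spacers) < config.array_spacers_per_gene:
        result.failure_notes.append(
            f"only {len(array_spacers)} array spacer(s) available "
            f"(wanted {config.array_spacers_per_gene}): insufficient spacers"
        )
        array_spacers = []
    result.array_spacers = array_spacers
    return result
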