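"""End-to-end library design: genome + targets + config -> designed library.

Per gene: enumerate and rank candidates, drop off-target-prone spacers,
select single gRNAs, then try to assemble a fold-validated CRISPR array from
further non-overlapping spacers. Emission of cloning-ready sequences (Gibson
fragments, CRATES oligo sets) lives in :mod:`crisprikit.cloning_output`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd


from .array_design import ArrayTranscript, RepeatUnit, design_array
from .config import RunConfig
from .offtarget_filter import build_offtarget_index
from .sequence_model import GeneModel, Replicon
from .spacer_design import GeneDesignResult, select_guides


@dataclass
class LibraryDesign:
    """Per-gene design results plus the arrays that passed fold validation."""

    results: list[GeneDesignResult]
    arrays: dict[str, ArrayTranscript] = field(default_factory=dict)

    def grna_table(self) -> pd.DataFrame:
        rows = []
        for res in self.results:
            for i, c in enumerate(res.grnas, 1):
                rows.append(
                    {
                        "gene_id": res.gene_id,
                        "member_id": f"{res.gene_id}_g{i}",
                        "spacer": c.spacer_sequence,
                        "replicon": c.replicon_id,
                        # reports use 1-based inclusive coordinates
                        "protospacer_start": c.protospacer_start + 1,
                        "protospacer_end": c.protospacer_end,
                        "strand": c.protospacer_strand,
                        "pam": c.pam_sequence,
                        "region": c.region_kind,
                        "annealing": c.annealing,
                        "gc": round(c.gc_fraction, 3),
                        "tss_offset": c.tss_offset,
                        "extended_pam": c.extended_pam,
                    }
                )
        return pd.DataFrame(rows)

    def failure_table(self) -> pd.DataFrame:
        rows = [
            {"gene_id": r.gene_id, "note": note}
            for r in self.results
            for note in r.failure_notes
        ]
        return pd.DataFrame(rows, columns=["gene_id", "note"])


def design_library(
    genome: dict[str, Replicon],
    genes: list[GeneModel],
    config: RunConfig | None = None,
    with_arrays: bool = True,
) -> LibraryDesign:
    """Design gRNAs (and arrays when possible) for every target gene."""
    config = config or RunConfig()
    dc = config.design
    index = build_offtarget_index(
        genome,
        spacer_length=dc.spacer_length,
        max_mismatch=dc.offtarget_max_mismatch,
        pam=dc.pam.iupac,
    )
    repeat = (
        RepeatUnit(config.array.repeat_name, config.array.repeat_sequence)
        if with_arrays
        else None
    )
    results: list[GeneDesignResult] = []
    arrays: dict[str, ArrayTranscript] = {}
    for gene in genes:
        res = select_guides(gene, genome, dc, offtarget_index=index)
        if with_arrays and repeat is not None and res.array_spacers:
            # top of the ranked pool; the attempt cap bounds folding work anyway
            pool = res.array_pool[:12]
            pool_seqs = [c.spacer_sequence for c in pool]
            conflicts = {
                frozenset((i, j))
                for i, j in combinations(range(len(pool)), 2)
                if pool[i].overlaps(pool[j])
            }
            transcript, reason = design_array(
                gene.gene_id,
                pool_seqs,
                repeat,
                conflicts=conflicts,
                n_units=dc.array_spacers_per_gene,
                energy_window=config.array.energy_window,
                max_structures=config.array.max_structures,
                strict=config.array.strict,
                attempt_cap=config.array.attempt_cap,
                trailing_repeat=config.array.trailing_repeat,
            )
            if transcript is not None:
                arrays[gene.gene_id] = transcript
                used = {sp for _, sp in transcript.units}
                res.array_spacers = [
                    c for c in res.array_pool if c.spacer_sequence in used
                ]
            else:
                res.array_spacers = []
                res.failure_notes.append(f"array design failed: {reason}")
        results.append(res)
    return LibraryDesign(results, arrays)


def full_complement_fraction(design: LibraryDesign, config: RunConfig | None = None) -> float:
    """Fraction of genes that received the intended number of gRNAs."""
    config = config or RunConfig()
    want = config.design.guides_per_gene
    if not design.results:
        return 0.0
    ok = sum(1 for r in design.results if len(r.grnas) >= want)
    return ok / len(design.results)
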