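"""Design-rule conformance: PAM adjacency, strand rules, ranking, selection."""

import pytest

from crisprikit.config import RunConfig
from crisprikit.fixtures import FixtureSpec, make_genome
from crisprikit.offtarget_filter import build_offtarget_index
from crisprikit.pipeline import design_library
from crisprikit.sequence_model import GeneModel, Replicon, extract, revcomp
from crisprikit.spacer_design import (
    DesignConfig,
    SpacerCandidate,
    enumerate_candidates,
    gc_fraction,
    rank_candidates,
    select_guides,
)


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 0.5), ("AAAA", 0.0), ("GCGC", 1.0)],
)
def test_gc_fraction(seq, expected):
    assert gc_fraction(seq) == expected


def test_gc_fraction_empty_errors():
    with pytest.raises(ValueError):
        gc_fraction("")


def _mini_config(**kw):
    defaults = dict(spacer_length=10, promoter_window=20)
    defaults.update(kw)
    return DesignConfig(**defaults)


def test_promoter_accepts_both_strands():
    """A TTV on each promoter strand yields promoter_fwd and promoter_rev."""
    # gene at [40, 70) on + strand; promoter [20, 40)
    seq = ["A"] * 100
    seq[22:25] = list("TTA")  # forward TTV in promoter
    # reverse-strand TTV: forward 'TAA' at 36 -> revcomp TTA on minus strand
    seq[36:39] = list("TAA")
    rep = Replicon("chr", "".join(seq))
    gene = GeneModel("g", "chr", 40, 70, "+")
    cands = enumerate_candidates(gene, {"chr": rep}, _mini_config())
    annealings = sorted(c.annealing for c in cands if c.region_kind == "promoter")
    assert "promoter_fwd" in annealings and "promoter_rev" in annealings


def test_transcribed_region_rejects_nontemplate_annealing():
    """A template-strand TTV (gRNA annealing to the nontemplate strand) in the
    gene body must not be returned."""
    seq = ["A"] * 100
    # gene [40, 70) on + strand; plant reverse-strand TTV inside the gene:
    # forward 'TAA' at 50 reads TTA on the - strand
    seq[50:53] = list("TAA")
    rep = Replicon("chr", "".join(seq))
    gene = GeneModel("g", "chr", 40, 70, "+")
    cands = enumerate_candidates(gene, {"chr": rep}, _mini_config())
    assert all(
        not (c.region_kind == "transcribed" and c.protospacer_strand != "+")
        for c in cands
    )
    # mirrored gene on - strand: a forward TTV inside the gene is nontemplate
    seq2 = ["A"] * 100
    seq2[50:53] = list("TTA")
    rep2 = Replicon("chr", "".join(seq2))
    gene2 = GeneModel("g", "chr", 40, 70, "-")
    cands2 = enumerate_candidates(gene2, {"chr": rep2}, _mini_config())
    assert all(
        not (c.region_kind == "transcribed" and c.protospacer_strand != "-")
        for c in cands2
    )


def test_pam_desert_gene_yields_no_candidates():
    spec = FixtureSpec(seed=3, genome_length=30_000, n_genes=5, pam_desert_genes=(2,))
    genome, genes = make_genome(spec)
    assert enumerate_candidates(genes[2], genome, DesignConfig()) == []
    res = select_guides(genes[2], genome, DesignConfig())
    assert res.grnas == [] and res.failure_notes


def test_candidates_reextract_from_genome(small_fixture):
    """Spacer and PAM fields must re-extract identically from the genome."""
    genome, genes = small_fixture
    config = DesignConfig()
    for gene in genes[:5]:
        for c in enumerate_candidates(gene, genome, config):
            rep = genome[c.replicon_id]
            assert c.spacer_sequence == extract(
                rep, c.protospacer_start, c.protospacer_end, c.protospacer_strand
            )
            assert c.pam_sequence == extract(
                rep, c.pam_start, c.pam_end, c.protospacer_strand
            )
            assert c.pam_sequence.startswith("TT")
            assert c.pam_sequence[2] != "T" or config.pam.matches(c.pam_sequence)
            # PAM abuts the protospacer on its 5' side
            if c.protospacer_strand == "+":
                assert c.pam_end == c.protospacer_start
            else:
                assert c.pam_start == c.protospacer_end


def _cand(gene_id="g", gc=0.5, region="promoter", ext=False, start=100,
          tss_offset=-10, strand="+"):
    L = 20
    return SpacerCandidate(
        gene_id=gene_id, replicon_id="chr", spacer_sequence="A" * L,
        protospacer_start=start, protospacer_end=start + L,
        protospacer_strand=strand, pam_sequence="TTA",
        pam_start=start - 3, pam_end=start,
        region_kind=region,
        annealing="promoter_fwd" if region == "promoter" else "template",
        gc_fraction=gc, tss_offset=tss_offset, extended_pam=ext,
    )


def test_ranking_prefers_gc_window_region_and_extended_pam():
    gene = GeneModel("g", "chr", 1000, 1100, "+")
    config = DesignConfig()
    a = _cand(gc=0.5, region="promoter", ext=True, tss_offset=-10)
    b = _cand(gc=0.5, region="transcribed", ext=False, tss_offset=80)  # 3' portion
    c = _cand(gc=0.9, region="promoter", ext=True, tss_offset=-5)  # GC outside
    d = _cand(gc=0.5, region="transcribed", ext=False, tss_offset=10)  # 5' portion
    e = _cand(gc=0.5, region="promoter", ext=False, tss_offset=-10, start=101)
    ranked = rank_candidates([c, b, e, d, a], gene, config)
    assert ranked[0] == a  # in-window GC, promoter, TTTV
    assert ranked[1] == e  # promoter but plain TTV
    assert ranked[2] == d  # 5' portion of gene
    assert ranked[3] == b  # 3' portion
    assert ranked[-1] == c  # GC outside the window loses to everything


def test_ranking_deterministic_tie_breaker():
    gene = GeneModel("g", "chr", 1000, 1100, "+")
    config = DesignConfig()
    x = _cand(start=200, tss_offset=-10)
    y = _cand(start=150, tss_offset=-10)
    first = rank_candidates([x, y], gene, config)
    assert first == rank_candidates([y, x], gene, config)
    assert first[0].protospacer_start == 150


def test_select_guides_constraints_on_fixture(small_fixture):
    genome, genes = small_fixture
    config = DesignConfig()
    index = build_offtarget_index(genome)
    for gene in genes:
        res = select_guides(gene, genome, config, offtarget_index=index)
        assert len(res.grnas) <= config.guides_per_gene
        intervals = [g.protospacer_interval for g in res.grnas]
        assert len(set(intervals)) == len(intervals)  # pairwise distinct
        for a in res.array_spacers:
            assert all(not a.overlaps(g) for g in res.grnas)
        for i, a in enumerate(res.array_spacers):
            for b in res.array_spacers[i + 1:]:
                assert not a.overlaps(b)
        gc_ok = [c for c in res.grnas
                 if config.gc_min <= c.gc_fraction <= config.gc_max]
        if len(res.grnas) == config.guides_per_gene:
            # enough candidates existed: GC window must be satisfied unless
            # the gene simply has no in-window candidates left
            all_cands = enumerate_candidates(gene, genome, config)
            n_in_window = sum(
                1 for c in all_cands
                if config.gc_min <= c.gc_fraction <= config.gc_max
            )
            if n_in_window >= config.guides_per_gene:
                assert len(gc_ok) == len(res.grnas)


def test_selection_is_deterministic(small_fixture):
    genome, genes = small_fixture
    config = DesignConfig()
    index = build_offtarget_index(genome)
    r1 = select_guides(genes[0], genome, config, offtarget_index=index)
    r2 = select_guides(genes[0], genome, config, offtarget_index=index)
    assert [c.spacer_sequence for c in r1.grnas] == [
        c.spacer_sequence for c in r2.grnas
    ]
    assert r1.failure_notes == r2.failure_notes


def test_design_library_end_to_end(small_fixture):
    genome, genes = small_fixture
    design = design_library(genome, genes, RunConfig())
    assert len(design.results) == len(genes)
    table = design.grna_table()
    assert set(table["gene_id"]) <= {g.gene_id for g in genes}
    # reported coordinates are 1-based inclusive
    row = table.iloc[0]
    assert row["protospacer_end"] - row["protospacer_start"] + 1 == 20
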