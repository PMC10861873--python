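"""Deterministic synthetic data: genomes, decoys, and screen counts.

The generator emulates the study system end to end without any download: an
AT-rich bacterial genome (~35% GC, the *Bacteroides* regime in which the TTV
PAM dominates) carrying planted intergenic sRNA-sized genes, optional
off-target decoy loci at controlled Hamming distances, and a two-condition
pooled-screen count simulation with negative-binomial noise and planted
per-gene fitness effects. All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_model import GeneModel, Replicon, revcomp, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Knobs of the synthetic genome generator."""

    seed: int = 0
    genome_length: int = 100_000
    gc: float = 0.35
    n_genes: int = 20
    gene_length: tuple[int, int] = (60, 200)
    plus_strand_fraction: float = 0.5
    promoter_window: int = 50
    circular: bool = False
    #: gene indices whose promoter+body are rewritten TTV-free (PAM deserts)
    pam_desert_genes: tuple[int, ...] = ()
    #: if set, plant at least this many forward TTV sites in each promoter
    min_promoter_ttv: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.gene_length[0] > self.gene_length[1]:
            raise ValueError("bad gene_length range")


@dataclass
class DecoySpec:
    """One planted off-target decoy: a mutated copy of a chosen spacer."""

    spacer: str
    mismatches: int
    with_pam: bool  # prepend a TTV PAM (else a non-PAM context)
    strand: str = "+"


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _desert_tile(length: int) -> np.ndarray:
    # 'GA' tiling carries no TT on either strand, hence no TTV PAM anywhere
    return np.array(list(("GA" * (length // 2 + 1))[:length]))


def make_genome(
    spec: FixtureSpec,
) -> tuple[dict[str, Replicon], list[GeneModel]]:
    """Synthesize a genome with planted, evenly spaced intergenic genes.

    Genes are placed with at least one promoter window plus spacer length of
    clearance between them; strands are drawn from the configured mix.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _random_bases(rng, spec.genome_length, spec.gc)
    margin = spec.promoter_window + 30
    slot = spec.genome_length // max(spec.n_genes, 1)
    if slot < spec.gene_length[1] + 2 * margin:
        raise ValueError("genes do not fit the genome length")
    genes: list[GeneModel] = []
    for i in range(spec.n_genes):
        length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
        wiggle = slot - length - 2 * margin
        start = i * slot + margin + int(rng.integers(0, max(wiggle, 1)))
        strand = "+" if rng.random() < spec.plus_strand_fraction else "-"
        gene = GeneModel(f"srna_{i:04d}", "chr", start, start + length, strand)
        genes.append(gene)
        w = spec.promoter_window
        prom = (start - w, start) if strand == "+" else (start + length, start + length + w)
        if i in spec.pam_desert_genes:
            lo = min(prom[0], start)
            hi = max(prom[1], start + length)
            seq[lo:hi] = _desert_tile(hi - lo)
        elif spec.min_promoter_ttv:
            # plant forward-strand TTA sites at spaced promoter offsets
            for k in range(spec.min_promoter_ttv):
                pos = prom[0] + 2 + k * max((w - 4) // spec.min_promoter_ttv, 4)
                if pos + 3 <= prom[1]:
                    seq[pos : pos + 3] = list("TTA")
    replicon = Replicon("chr", "".join(seq), circular=spec.circular)
    return {"chr": replicon}, genes


def write_genome(
    genome: dict[str, Replicon], genes: list[GeneModel], fasta: Path, gff3: Path
) -> None:
    """Write the fixture to standard FASTA + GFF3 files."""
    write_fasta(
        ((rid + ("|circular" if rep.circular else ""), rep.sequence)
         for rid, rep in genome.items()),
        fasta,
    )
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.replicon_id}\tcrisprikit\tncRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def plant_decoys(
    replicon: Replicon,
    genes: list[GeneModel],
    decoys: list[DecoySpec],
    seed: int = 0,
    pam: str = "TTV",
) -> tuple[Replicon, pd.DataFrame]:
    """Copy spacers (with controlled mismatches +- PAM) into free loci.

    Returns the modified replicon and a truth table recording where each
    decoy landed, its realized mismatch count, and whether a PAM precedes it.
    Decoy loci avoid gene bodies and promoter windows.
    """
    rng = np.random.default_rng(seed)
    seq = np.array(list(replicon.sequence))
    n = len(seq)
    forbidden: list[tuple[int, int]] = []
    w = 50
    for g in genes:
        forbidden.append((g.start - w - 30, g.end + w + 30))
    placed: list[dict] = []

    def free(lo: int, hi: int) -> bool:
        if lo < 0 or hi > n:
            return False
        for a, b in forbidden:
            if lo < b and a < hi:
                return False
        return True

    for spec in decoys:
        L = len(spec.spacer)
        site = np.array(list(spec.spacer.upper()))
        if spec.mismatches:
            pos = rng.choice(L, size=spec.mismatches, replace=False)
            for p in pos:
                choices = [b for b in "ACGT" if b != site[p]]
                site[p] = choices[rng.integers(0, 3)]
        if spec.with_pam:
            v = "ACG"[rng.integers(0, 3)]
            context = np.array(list("TT" + v))
        else:
            context = np.array(list("GGA"))  # never matches TTV
        block = np.concatenate([context, site])
        if spec.strand == "-":
            block = np.array(list(revcomp("".join(block))))
        for _ in range(10_000):
            lo = int(rng.integers(0, n - len(block)))
            if free(lo - 3, lo + len(block) + 3):
                break
        else:
            raise RuntimeError("no free locus for decoy")
        seq[lo : lo + len(block)] = block
        forbidden.append((lo - L, lo + len(block) + L))
        if spec.strand == "+":
            proto_start = lo + len(context)
        else:
            proto_start = lo
        placed.append(
            {
                "spacer": spec.spacer.upper(),
                "mismatches": spec.mismatches,
                "with_pam": spec.with_pam,
                "strand": spec.strand,
                "protospacer_start": proto_start,
                "protospacer_end": proto_start + L,
            }
        )
    new_rep = Replicon(replicon.id, "".join(seq), circular=replicon.circular)
    return new_rep, pd.DataFrame(placed)


@dataclass
class ScreenSimSpec:
    """Two-condition pooled screen simulation parameters.

    Defaults mirror the motivating screen's scale: 135 target genes with four
    library members each, three replicate pairs, ~1e6 reads per sample, and
    negative-binomial overdispersion phi = 0.1 (variance mu + phi*mu^2).
    """

    seed: int = 0
    n_genes: int = 135
    members_per_gene: int = 4
    replicates: int = 3
    depth: int = 1_000_000
    phi: float = 0.1
    baseline_sigma: float = 0.5  # log-normal spread of member abundances
    #: planted per-gene effects as log2FC (stress vs control); others are 0
    effects: dict[str, float] = field(default_factory=dict)


def simulate_manifest(spec: ScreenSimSpec, spacer_length: int = 20) -> pd.DataFrame:
    """Member table with distinct random spacers (member_id, type, spacers,
    gene_id), deterministic under the spec seed."""
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    seen: set[str] = set()
    for g in range(spec.n_genes):
        gene = f"srna_{g:04d}"
        for m in range(spec.members_per_gene):
            while True:
                sp = "".join(rng.choice(_BASES, size=spacer_length))
                if sp not in seen:
                    seen.add(sp)
                    break
            rows.append(
                {
                    "member_id": f"{gene}_m{m + 1}",
                    "type": "gRNA",
                    "spacers": sp,
                    "gene_id": gene,
                }
            )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_screen(
    spec: ScreenSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the count matrix of a two-condition screen.

    Returns (counts, sample sheet table, truth table). Member baseline
    abundances are log-normal; in the stress condition the mean of members of
    an affected gene is multiplied by 2^(planted log2FC), then per-sample
    means are renormalized to the target depth (sequencing measures relative
    abundance) and counts drawn negative-binomially.
    """
    rng = np.random.default_rng(spec.seed)
    manifest = simulate_manifest(spec)
    members = manifest["member_id"].to_numpy()
    genes = manifest["gene_id"].to_numpy()
    n = len(members)
    baseline = rng.lognormal(mean=0.0, sigma=spec.baseline_sigma, size=n)
    lfc = np.array([spec.effects.get(g, 0.0) for g in genes])
    stress_weight = baseline * np.exp2(lfc)

    counts = {}
    sheet_rows = []
    for rep in range(1, spec.replicates + 1):
        for cond, weights in (("control", baseline), ("stress", stress_weight)):
            mu = spec.depth * weights / weights.sum()
            sample = f"{cond}_{rep}"
            counts[sample] = _nb_draw(rng, mu, spec.phi)
            sheet_rows.append(
                {"sample_id": sample, "condition": cond, "replicate": rep}
            )
    count_df = pd.DataFrame(counts, index=members)
    truth = pd.DataFrame(
        {
            "gene_id": sorted(set(genes)),
        }
    )
    truth["log2fc"] = truth["gene_id"].map(lambda g: spec.effects.get(g, 0.0))
    truth["planted"] = truth["log2fc"] != 0.0
    return count_df, pd.DataFrame(sheet_rows), truth


def render_fastq(
    counts: pd.Series,
    manifest: pd.DataFrame,
    flanks: tuple[str, str],
    r1_path: Path,
    r2_path: Path,
    read_length: int = 150,
    seed: int = 0,
) -> None:
    """Write paired FASTQ for one sample: each member's spacer embedded
    between the constant flanks, with fixed high base qualities."""
    rng = np.random.default_rng(seed)
    f5, f3 = flanks
    pad5 = "".join(_random_bases(rng, 40, 0.5))
    pad3 = "".join(_random_bases(rng, 80, 0.5))
    spacer_of = dict(zip(manifest["member_id"], manifest["spacers"]))
    with open(r1_path, "w") as r1, open(r2_path, "w") as r2:
        i = 0
        for member, c in counts.items():
            amplicon = pad5 + f5 + spacer_of[member] + f3 + pad3
            fwd = amplicon[:read_length]
            rev = revcomp(amplicon)[:read_length]
            for _ in range(int(c)):
                i += 1
                r1.write(f"@read{i}/1\n{fwd}\n+\n{'I' * len(fwd)}\n")
                r2.write(f"@read{i}/2\n{rev}\n+\n{'I' * len(rev)}\n")
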