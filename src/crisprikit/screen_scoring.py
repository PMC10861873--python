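"""Pooled CRISPRi screen quantification and per-sRNA fitness calling.

The screen compares library-member abundance after growth with and without a
stressor (bile salts in the motivating experiment). Reads from the amplified
CRISPRi locus are searched for the constant vector flanks, the enclosed
spacer is matched exactly to the library manifest, and per-member counts per
sample form the count matrix. Fitness is the log2 fold change of
counts-per-million between stress and control within each replicate
(positive = enriched under stress); per-gene scores average over all members
targeting the gene, with a two-sided one-sample location test on the pooled
per-member-per-replicate values and Benjamini-Hochberg FDR across genes.
A gene is a hit when |mean log2FC| > 0.5 and FDR < 0.05.

The statistical test is deliberately transparent (CPM + pseudocount + t test
+ BH) and pluggable via the ``stat_test`` hook; count-model packages such as
edgeR/DESeq2 can be substituted upstream of :func:`aggregate_srna` by
supplying per-member fitness values directly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sequence_model import revcomp

LOG2FC_CUTOFF = 0.5
FDR_CUTOFF = 0.05


@dataclass
class LibraryManifest:
    """member_id -> spacer(s) and targeted gene."""

    members: dict[str, dict]  # member_id -> {type, spacers: [..], gene_id}

    def __post_init__(self) -> None:
        spacer_owner: dict[str, str] = {}
        for mid, rec in self.members.items():
            for sp in rec["spacers"]:
                sp = sp.upper()
                if sp in spacer_owner:
                    raise ValueError(
                        f"spacer {sp} shared by members "
                        f"{spacer_owner[sp]!r} and {mid!r}"
                    )
                spacer_owner[sp] = mid
        self._spacer_to_member = spacer_owner

    @property
    def spacer_to_member(self) -> dict[str, str]:
        return self._spacer_to_member

    def gene_of(self, member_id: str) -> str:
        return self.members[member_id]["gene_id"]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LibraryManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        members: dict[str, dict] = {}
        for _, row in df.iterrows():
            members[row["member_id"]] = {
                "type": row.get("type", "gRNA"),
                "spacers": row["spacers"].split(","),
                "gene_id": row["gene_id"],
            }
        return cls(members)


@dataclass
class SampleSheet:
    """sample_id -> (condition, replicate); conditions are control/stress."""

    samples: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        for sid, (cond, _) in self.samples.items():
            if cond not in {"control", "stress"}:
                raise ValueError(f"sample {sid!r}: condition must be control|stress")

    def replicate_pairs(self) -> list[tuple[int, str, str]]:
        """(replicate, control_sample, stress_sample) triples."""
        by_rep: dict[int, dict[str, str]] = {}
        for sid, (cond, rep) in self.samples.items():
            by_rep.setdefault(rep, {})[cond] = sid
        out = []
        for rep in sorted(by_rep):
            pair = by_rep[rep]
            if "control" in pair and "stress" in pair:
                out.append((rep, pair["control"], pair["stress"]))
        if not out:
            raise ValueError("no complete control/stress replicate pair")
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            {
                row["sample_id"]: (row["condition"], int(row["replicate"]))
                for _, row in df.iterrows()
            }
        )


@dataclass
class GuideFitness:
    member_id: str
    per_replicate: list[float]
    mean_log2fc: float


@dataclass
class SrnaFitness:
    gene_id: str
    mean_log2fc: float
    p_value: float
    fdr: float
    hit: bool
    direction: str  # enriched | depleted
    n_members: int


def _hamming_leq(a: str, b: str, k: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def _find_flank(read: str, flank: str, max_mm: int, start: int = 0) -> int:
    """Leftmost occurrence of `flank` in `read` with <= max_mm mismatches."""
    m = len(flank)
    for i in range(start, len(read) - m + 1):
        if _hamming_leq(read[i : i + m], flank, max_mm):
            return i
    return -1


def extract_spacer(
    read_pair: tuple[str, str | None],
    flank_5: str,
    flank_3: str,
    max_flank_mismatch: int = 1,
    length_bounds: tuple[int, int] = (15, 35),
) -> str | None:
    """Spacer enclosed by the constant flanks in either read or orientation.

    Returns None when the flanks are not found (within the mismatch budget)
    or the enclosed segment has an implausible length.
    """
    reads = [r for r in read_pair if r]
    for read in reads:
        for oriented in (read.upper(), revcomp(read.upper())):
            i = _find_flank(oriented, flank_5, max_flank_mismatch)
            if i < 0:
                continue
            j = _find_flank(oriented, flank_3, max_flank_mismatch, start=i + len(flank_5))
            if j < 0:
                continue
            spacer = oriented[i + len(flank_5) : j]
            if length_bounds[0] <= len(spacer) <= length_bounds[1]:
                return spacer
    return None


def _iter_fastq(path: str | Path) -> Iterable[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield seq


def count_members(
    fastq_by_sample: dict[str, tuple[str | Path, str | Path | None]],
    manifest: LibraryManifest,
    flanks: tuple[str, str] | list[tuple[str, str]],
    max_flank_mismatch: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count matrix (members x samples) from paired FASTQ amplicon reads.

    ``flanks`` may be a single (5', 3') pair or a list of pairs (e.g. the
    gRNA-cassette flanks plus the repeat-context flanks used by array
    members); the first pair that yields a manifest spacer wins. Returns
    (counts, stats) where stats holds total/matched/unmatched per sample.
    """
    flank_sets = [flanks] if isinstance(flanks, tuple) else list(flanks)
    members = list(manifest.members)
    counts = pd.DataFrame(0, index=members, columns=list(fastq_by_sample), dtype=int)
    log_rows = {}
    sp2m = manifest.spacer_to_member
    for sample, (r1_path, r2_path) in fastq_by_sample.items():
        it1 = _iter_fastq(r1_path)
        it2 = _iter_fastq(r2_path) if r2_path else None
        total = matched = 0
        for r1 in it1:
            r2 = next(it2) if it2 else None
            total += 1
            member = None
            for f5, f3 in flank_sets:
                spacer = extract_spacer((r1, r2), f5, f3, max_flank_mismatch)
                if spacer is not None and spacer in sp2m:
                    member = sp2m[spacer]
                    break
            if member is not None:
                matched += 1
                counts.loc[member, sample] += 1
        log_rows[sample] = {
            "total_reads": total,
            "matched": matched,
            "unmatched": total - matched,
        }
    return counts, pd.DataFrame.from_dict(log_rows, orient="index")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per sample."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    return counts * (1e6 / totals)


def guide_log2fc(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-member, per-replicate log2FC of CPM (stress vs control) plus mean.

    Columns: one ``rep<k>`` column per replicate pair and ``mean_log2fc``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    norm = cpm(counts)
    pairs = sheet.replicate_pairs()
    out = pd.DataFrame(index=counts.index)
    for rep, ctrl, stress in pairs:
        out[f"rep{rep}"] = np.log2(
            (norm[stress] + pseudocount) / (norm[ctrl] + pseudocount)
        )
    out["mean_log2fc"] = out.mean(axis=1)
    return out


def _ttest_vs_zero(values: np.ndarray) -> float:
    if len(values) < 2 or np.allclose(values, values[0]):
        return 1.0
    return float(stats.ttest_1samp(values, 0.0).pvalue)


def aggregate_srna(
    fitness: pd.DataFrame,
    manifest: LibraryManifest,
    stat_test: Callable[[np.ndarray], float] = _ttest_vs_zero,
    log2fc_cutoff: float = LOG2FC_CUTOFF,
    fdr_cutoff: float = FDR_CUTOFF,
) -> pd.DataFrame:
    """Per-gene fitness table with BH-corrected hit calls.

    ``fitness`` is the output of :func:`guide_log2fc`. The gene score is the
    unweighted mean of its members' mean log2FC; the p-value comes from
    ``stat_test`` applied to the pooled per-member-per-replicate values.
    """
    rep_cols = [c for c in fitness.columns if c.startswith("rep")]
    by_gene: dict[str, list[str]] = {}
    for mid in fitness.index:
        by_gene.setdefault(manifest.gene_of(mid), []).append(mid)
    rows = []
    for gene_id, mids in sorted(by_gene.items()):
        sub = fitness.loc[mids]
        pooled = sub[rep_cols].to_numpy().ravel()
        pooled = pooled[np.isfinite(pooled)]
        mean = float(sub["mean_log2fc"].mean())
        rows.append(
            {
                "gene_id": gene_id,
                "mean_log2fc": mean,
                "p_value": stat_test(pooled) if len(pooled) else np.nan,
                "n_members": len(mids),
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    assessable = df["p_value"].notna()
    df["fdr"] = np.nan
    if assessable.any():
        df.loc[assessable, "fdr"] = multipletests(
            df.loc[assessable, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    df["hit"] = (df["mean_log2fc"].abs() > log2fc_cutoff) & (df["fdr"] < fdr_cutoff)
    df["direction"] = np.where(df["mean_log2fc"] >= 0, "enriched", "depleted")
    df["neg_log10_fdr"] = -np.log10(df["fdr"])
    return df


def score_screen(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    manifest: LibraryManifest,
    pseudocount: float = 0.5,
    stat_test: Callable[[np.ndarray], float] = _ttest_vs_zero,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts -> (per-member fitness, per-gene hit table)."""
    fit = guide_log2fc(counts, sheet, pseudocount)
    return fit, aggregate_srna(fit, manifest, stat_test=stat_test)
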