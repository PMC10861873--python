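"""Genome-wide off-target search for candidate spacers.

A spacer is considered off-target-prone when a second genomic locus exists,
on either strand of any replicon, whose sequence is within a small Hamming
distance of the spacer (default <= 2 mismatches, i.e. "fewer than three") and
which is preceded on its strand by a 5'-TTV-3' PAM. Such spacers are discarded
during design because the nuclease could bind the second site.

The search is exact: a pigeonhole seed index accelerates it, and its results
are identical to a naive full scan. Splitting a spacer into ``m+1`` contiguous
parts guarantees that any window with at most ``m`` mismatches matches at
least one part exactly, so candidate positions are gathered by exact k-mer
lookup of the part seeds and then verified by full Hamming comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_model import Replicon, revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class OfftargetHit:
    """A second genomic locus similar to a spacer, with its PAM."""

    replicon_id: str
    start: int  # forward-strand protospacer interval [start, end)
    end: int
    strand: str
    mismatch_count: int
    pam_sequence: str

    @property
    def protospacer_interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _part_starts(length: int, n_parts: int) -> list[tuple[int, int]]:
    """Split [0, length) into n_parts near-equal contiguous parts."""
    base, extra = divmod(length, n_parts)
    starts, pos = [], 0
    for i in range(n_parts):
        size = base + (1 if i < extra else 0)
        starts.append((pos, size))
        pos += size
    return starts


class _StrandIndex:
    """Exact k-mer bucket index over one strand-local search sequence."""

    def __init__(self, codes: np.ndarray, k: int):
        self.codes = codes
        self.k = k
        n = len(codes) - k + 1
        if n <= 0:
            self.kmers = np.empty(0, dtype=np.int64)
            self.positions = np.empty(0, dtype=np.int64)
            return
        km = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for j in range(k):
            window = codes[j : j + n]
            km = km * 4 + np.where(window == 4, 0, window)
            bad |= window == 4
        km[bad] = -1
        order = np.argsort(km, kind="stable")
        self.kmers = km[order]
        self.positions = order.astype(np.int64)

    def lookup(self, kmer: int) -> np.ndarray:
        lo = np.searchsorted(self.kmers, kmer, side="left")
        hi = np.searchsorted(self.kmers, kmer, side="right")
        return self.positions[lo:hi]


class OfftargetIndex:
    """Seed-partition index over a whole genome for ``find`` queries.

    Results are identical to a brute-force Hamming scan of both strands of
    every replicon; circular replicons are handled by extending the search
    sequence across the origin and reporting each genomic locus once.
    """

    def __init__(
        self,
        genome: dict[str, Replicon],
        spacer_length: int = 20,
        max_mismatch: int = 2,
        pam: str = "TTV",
    ):
        if max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        self.spacer_length = spacer_length
        self.max_mismatch = max_mismatch
        self.pam = pam
        self.pam_len = len(pam)
        self.parts = _part_starts(spacer_length, max_mismatch + 1)
        self.k = min(size for _, size in self.parts)
        # per (replicon, strand): strand-local codes, offset of genomic
        # position 0 within the extended array, and the bucket index
        self._strands: list[tuple[str, str, np.ndarray, int, int, _StrandIndex]] = []
        for rid, rep in genome.items():
            n = len(rep)
            for strand in "+-":
                local = rep.sequence if strand == "+" else revcomp(rep.sequence)
                if rep.circular:
                    ext = local[-self.pam_len :] + local + local[: spacer_length - 1]
                    offset = self.pam_len
                else:
                    ext = local
                    offset = 0
                codes = _encode(ext)
                self._strands.append(
                    (rid, strand, codes, offset, n, _StrandIndex(codes, self.k))
                )

    def _pam_ok(self, codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
        ok = np.ones(len(starts), dtype=bool)
        for j, ch in enumerate(self.pam):
            col = codes[starts - self.pam_len + j]
            if ch == "N":
                ok &= col != 4
            elif ch == "V":
                ok &= (col != 3) & (col != 4)
            else:
                ok &= col == _CODE[ch]
        return ok

    def find(
        self,
        spacer: str,
        exclude: tuple[str, int, str] | None = None,
        max_mismatch: int | None = None,
    ) -> list[OfftargetHit]:
        """All PAM-adjacent near-matches of ``spacer`` in the genome.

        ``exclude`` is the intended locus as (replicon_id, forward-strand
        protospacer start, strand); an exact interval+strand match there is
        not reported ("a second genomic locus"). Overlapping shifted windows
        do count. ``max_mismatch`` may be lowered below the index default but
        not raised (the pigeonhole guarantee is built for the default).
        """
        mm = self.max_mismatch if max_mismatch is None else max_mismatch
        if mm > self.max_mismatch:
            raise ValueError("max_mismatch exceeds the index guarantee")
        L = self.spacer_length
        if len(spacer) != L:
            raise ValueError(f"spacer length {len(spacer)} != index length {L}")
        sp = _encode(spacer.upper())
        if (sp == 4).any():
            return []
        hits: list[OfftargetHit] = []
        for rid, strand, codes, offset, n, index in self._strands:
            cands: list[np.ndarray] = []
            for o, size in self.parts:
                seed = 0
                for j in range(self.k):
                    seed = seed * 4 + int(sp[o + j])
                cands.append(index.lookup(seed) - o)
            t = np.unique(np.concatenate(cands))
            # valid strand-local starts: PAM fully present, window in range,
            # one window per genomic position on circular replicons
            t = t[(t >= offset + (0 if offset else self.pam_len))]
            t = t[t + L <= len(codes)]
            if offset:  # circular: canonical starts cover each position once
                t = t[t < offset + n]
            if len(t) == 0:
                continue
            windows = codes[t[:, None] + np.arange(L)[None, :]]
            mism = (windows != sp[None, :]).sum(axis=1)
            keep = (mism <= mm) & self._pam_ok(codes, t)
            for ti, mi in zip(t[keep], mism[keep]):
                local_start = int(ti) - offset
                if strand == "+":
                    g_start = local_start % n if offset else local_start
                else:
                    g_start = (n - local_start - L) % n if offset else n - local_start - L
                if exclude is not None and exclude == (rid, g_start, strand):
                    continue
                pam_codes = codes[int(ti) - self.pam_len : int(ti)]
                pam_seq = "".join("ACGTN"[c] for c in pam_codes)
                hits.append(
                    OfftargetHit(rid, g_start, g_start + L, strand, int(mi), pam_seq)
                )
        hits.sort(key=lambda h: (h.replicon_id, h.start, h.strand))
        return hits


def build_offtarget_index(
    genome: dict[str, Replicon],
    spacer_length: int = 20,
    max_mismatch: int = 2,
    pam: str = "TTV",
) -> OfftargetIndex:
    """Build the genome-wide index used to vet candidate spacers."""
    return OfftargetIndex(genome, spacer_length, max_mismatch, pam)


def find_offtargets(
    spacer: str,
    index: OfftargetIndex,
    exclude: tuple[str, int, str] | None = None,
) -> list[OfftargetHit]:
    """Off-target hits for one spacer; empty list means the spacer is clean."""
    return index.find(spacer, exclude=exclude)
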