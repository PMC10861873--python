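"""Independent brute-force oracles used to validate the fast implementations.

Kept deliberately naive (sliding windows, character comparisons) and separate
from the package code paths they check.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def window_matches(window: str, motif: str) -> bool:
    return len(window) == len(motif) and all(
        b in IUPAC[c] for b, c in zip(window, motif)
    )


def scan_oracle(seq: str, motif: str, strands: str = "both") -> list[tuple[int, int, str]]:
    """Every motif occurrence by checking every window on both strands."""
    m = len(motif)
    hits = []
    for i in range(len(seq) - m + 1):
        w = seq[i : i + m]
        if strands in {"forward", "both"} and window_matches(w, motif):
            hits.append((i, i + m, "+"))
        if strands in {"reverse", "both"} and window_matches(rc(w), motif):
            hits.append((i, i + m, "-"))
    return sorted(hits)


def offtarget_oracle(
    spacer: str,
    genome: dict[str, str],
    max_mismatch: int = 2,
    pam: str = "TTV",
    circular: dict[str, bool] | None = None,
    exclude: tuple[str, int, str] | None = None,
) -> set[tuple[str, int, str, int]]:
    """All PAM-adjacent near-matches by exhaustive Hamming scan.

    Returns {(replicon_id, forward protospacer start, strand, mismatches)}.
    """
    circular = circular or {}
    L = len(spacer)
    plen = len(pam)
    out = set()
    for rid, seq in genome.items():
        n = len(seq)
        if circular.get(rid):
            ext = seq + seq  # generous wrap; starts restricted to [0, n)
        else:
            ext = seq
        for strand in "+-":
            for g_start in range(n):
                if g_start + L > len(ext) and not circular.get(rid):
                    break
                if strand == "+":
                    window = ext[g_start : g_start + L]
                    pam_start = g_start - plen
                    if pam_start < 0:
                        if not circular.get(rid):
                            continue
                        pam_seq = (seq + seq)[pam_start + n : pam_start + n + plen]
                    else:
                        pam_seq = ext[pam_start : pam_start + plen]
                else:
                    window = rc(ext[g_start : g_start + L])
                    pam_seq = rc(ext[g_start + L : g_start + L + plen])
                    if len(pam_seq) < plen:
                        continue
                if len(window) < L:
                    continue
                if not window_matches(pam_seq, pam):
                    continue
                mm = sum(1 for a, b in zip(window, spacer) if a != b)
                if mm > max_mismatch:
                    continue
                if exclude == (rid, g_start, strand):
                    continue
                out.add((rid, g_start, strand, mm))
    return out
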