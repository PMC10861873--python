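"""Cloning-ready sequence emission.

Single gRNAs are emitted as spacers flanked by vector homology arms for
Gibson assembly. Arrays are emitted as CRATES oligo sets: both strands of
each repeat-spacer unit, offset so that annealing each pair leaves 4-nt
single-stranded overhangs whose uniqueness (and non-palindromicity) makes the
one-pot ligation of the three units unambiguous. The first and last overhangs
join the array to the destination vector and are config-supplied constants.
"""

from __future__ import annotations

from dataclasses import dataclass

from .array_design import ArrayTranscript
from .sequence_model import revcomp

OVERHANG_LEN = 4
#: default vector-junction overhangs (destination-plasmid dependent)
DEFAULT_VECTOR_OVERHANGS = ("AATG", "GCTT")


class CloningError(ValueError):
    """Unresolvable oligo design problem (e.g., overhang clash)."""


@dataclass(frozen=True)
class GibsonFragment:
    """Spacer flanked by 5' and 3' homology arms, reported 5'->3'."""

    member_id: str
    spacer: str
    arm_5: str
    arm_3: str

    @property
    def sequence(self) -> str:
        return self.arm_5 + self.spacer + self.arm_3


@dataclass(frozen=True)
class CratesOligoSet:
    """Six oligos (top+bottom per unit) with their junction overhangs."""

    member_id: str
    oligos: tuple[tuple[str, str, str], ...]  # (name, sequence, overhang)
    junctions: tuple[tuple[int, str], ...]  # (transcript position, overhang)


def emit_gibson(member_id: str, spacer: str, arms: tuple[str, str]) -> GibsonFragment:
    """Wrap a spacer in Gibson homology arms."""
    arm5, arm3 = arms
    if not arm5 or not arm3:
        raise CloningError("both homology arms must be non-empty")
    return GibsonFragment(member_id, spacer.upper(), arm5.upper(), arm3.upper())


def _palindromic(overhang: str) -> bool:
    return overhang == revcomp(overhang)


def emit_crates(
    array: ArrayTranscript,
    member_id: str | None = None,
    vector_overhangs: tuple[str, str] = DEFAULT_VECTOR_OVERHANGS,
    max_shift: int = 3,
) -> CratesOligoSet:
    """Partition an array duplex into unit oligos with 4-nt overhangs.

    The default junction between consecutive units sits at the unit boundary,
    with the overhang equal to the first 4 nt of the downstream unit's top
    strand. When that overhang clashes (duplicate of another junction's, or
    palindromic), the boundary is shifted by +-1..max_shift nt before the
    junction is declared unresolvable.
    """
    full = array.full_sequence
    vec5, vec3 = (v.upper() for v in vector_overhangs)
    for v, label in ((vec5, "5'"), (vec3, "3'")):
        if len(v) != OVERHANG_LEN:
            raise CloningError(f"{label} vector overhang must be {OVERHANG_LEN} nt")
        if _palindromic(v):
            raise CloningError(f"{label} vector overhang {v} is palindromic")
    if vec5 == vec3:
        raise CloningError("vector overhangs must differ")

    # unit boundaries in transcript coordinates (start of each unit)
    boundaries: list[int] = []
    pos = 0
    for repeat, spacer in array.units:
        boundaries.append(pos)
        pos += len(repeat.dna_sequence) + len(spacer)
    if array.trailing_repeat:
        # trailing repeat rides with the last unit
        pass
    n_units = len(boundaries)

    # X = vec5 + full + vec3; junction j at X-coordinate jx[j]
    x_seq = vec5 + full + vec3
    jx = [0] + [OVERHANG_LEN + b for b in boundaries[1:]] + [OVERHANG_LEN + len(full)]

    chosen = [vec5]
    for j in range(1, n_units):
        base = jx[j]
        lo_limit = jx[j - 1] + OVERHANG_LEN + 1
        hi_limit = jx[j + 1] - OVERHANG_LEN - 1
        placed = False
        for shift in sorted(range(-max_shift, max_shift + 1), key=abs):
            x = base + shift
            if not lo_limit <= x <= hi_limit:
                continue
            ov = x_seq[x : x + OVERHANG_LEN]
            if len(ov) < OVERHANG_LEN or _palindromic(ov):
                continue
            # compatible = distinct from, and not reverse-complementary to,
            # every other junction overhang (else two sticky ends cross-anneal)
            taken = chosen + [vec3]
            if ov in taken or revcomp(ov) in taken:
                continue
            jx[j] = x
            chosen.append(ov)
            placed = True
            break
        if not placed:
            raise CloningError(
                f"no compatible overhang found at junction {j} of {member_id or array.gene_id}"
            )
    chosen.append(vec3)

    oligos: list[tuple[str, str, str]] = []
    mid = member_id or f"{array.gene_id}_array"
    for u in range(n_units):
        top = x_seq[jx[u] : jx[u + 1]]
        bottom = revcomp(x_seq[jx[u] + OVERHANG_LEN : jx[u + 1] + OVERHANG_LEN])
        oligos.append((f"{mid}_unit{u + 1}_top", top, chosen[u]))
        oligos.append((f"{mid}_unit{u + 1}_bottom", bottom, chosen[u + 1]))
    junctions = tuple(
        (jx[j] - OVERHANG_LEN if j > 0 else -OVERHANG_LEN, chosen[j])
        for j in range(n_units + 1)
    )
    return CratesOligoSet(mid, tuple(oligos), junctions)


def reconstruct_from_oligos(
    oligos: list[str],
    vector_overhangs: tuple[str, str] = DEFAULT_VECTOR_OVERHANGS,
) -> str:
    """Simulate annealing + ligation of a CRATES oligo set.

    Oligos may be given in any order. Pairs are annealed into duplex
    fragments (top strand plus bottom strand offset by the overhang length),
    fragments are chained by matching each fragment's 3' overhang to the next
    fragment's 5' overhang, and the unique assembled top strand between the
    vector overhangs is returned. Raises :class:`CloningError` when assembly
    is ambiguous or impossible.
    """
    vec5, vec3 = (v.upper() for v in vector_overhangs)
    seqs = [o.upper() for o in oligos]
    if len(seqs) % 2:
        raise CloningError("odd number of oligos")

    # anneal: strands a and b form a duplex iff revcomp(b) == a[4:] + w for a
    # 4-nt w; the relation is symmetric, so each duplex has two orientations
    # (either strand read as the "top"); orientation is resolved while chaining
    def _orient(a: str, b: str) -> tuple[str, str] | None:
        rb = revcomp(b)
        if len(rb) == len(a) and rb[: len(a) - OVERHANG_LEN] == a[OVERHANG_LEN:]:
            return (a, rb[-OVERHANG_LEN:])
        return None

    duplexes: list[list[tuple[str, str]]] = []  # orientations: (top, right_ov)
    used = [False] * len(seqs)
    for i, a in enumerate(seqs):
        if used[i]:
            continue
        for j, b in enumerate(seqs):
            if i == j or used[j]:
                continue
            fwd = _orient(a, b)
            if fwd is not None:
                rev = _orient(b, a)
                duplexes.append([fwd] + ([rev] if rev else []))
                used[i] = used[j] = True
                break
    if not all(used):
        raise CloningError("could not anneal all oligos into duplex fragments")

    # enumerate every complete chain (overhang-matched, ending in the 3'
    # vector overhang) by backtracking; assembly must be unique
    assemblies: set[str] = set()

    def _extend(prefix_ov: str, acc: str, pool: frozenset[int]) -> None:
        if not pool:
            if prefix_ov == vec3:
                assemblies.add(acc)
            return
        for k in pool:
            for top, right in duplexes[k]:
                if top.startswith(prefix_ov):
                    _extend(right, acc + top, pool - {k})

    _extend(vec5, "", frozenset(range(len(duplexes))))
    if not assemblies:
        raise CloningError("no complete assembly between the vector overhangs")
    if len(assemblies) > 1:
        raise CloningError("ambiguous or broken ligation chain: multiple assemblies")
    return assemblies.pop()[len(vec5):]
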