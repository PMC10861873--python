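"""CRISPR array assembly with direct-repeat folding validation.

Cas12a processes a single precursor transcript of alternating direct repeats
and spacers into individual mature gRNAs, recognizing the 3'-terminal hairpin
of each repeat. A spacer that base-pairs with a neighbouring repeat can
sequester that hairpin and abolish processing, so before an array is emitted
every repeat instance is checked against the predicted near-optimal secondary
structures of the full transcript: the instance passes if at least one
retained structure (minimum-free-energy structure plus suboptimals within an
energy window) contains every base pair of the repeat's reference hairpin.

The folding engine (ViennaRNA) sits behind the narrow :func:`fold` adapter:
sequence in, dot-bracket structures with free energies out.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

try:
    import RNA
except ImportError:  # pragma: no cover - engine availability is environmental
    RNA = None


class FoldingEngineError(RuntimeError):
    """Raised when no RNA folding engine is available or a fold fails."""


@dataclass(frozen=True)
class FoldStructure:
    """One predicted secondary structure in dot-bracket notation."""

    dot_bracket: str
    free_energy: float  # kcal/mol

    def pairs(self) -> frozenset[tuple[int, int]]:
        """Base-pair index set (i < j, 0-based) of the structure."""
        stack: list[int] = []
        out = set()
        for i, ch in enumerate(self.dot_bracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket")
                out.add((stack.pop(), i))
        if stack:
            raise ValueError("unbalanced dot-bracket")
        return frozenset(out)


@dataclass
class RepeatUnit:
    """A Cas12a direct repeat with its reference processing hairpin.

    ``reference_pairs`` are the base pairs of the 3'-terminal stem-loop of the
    isolated repeat's MFE structure, in repeat-local coordinates; they are
    derived once via :func:`reference_hairpin`.
    """

    name: str
    dna_sequence: str
    reference_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.dna_sequence = self.dna_sequence.upper().replace("U", "T")
        if not self.reference_pairs:
            self.reference_pairs = reference_hairpin(self)


@dataclass
class ArrayTranscript:
    """Ordered repeat-spacer units and the concatenated transcript."""

    gene_id: str
    units: list[tuple[RepeatUnit, str]]
    trailing_repeat: bool = False
    full_sequence: str = field(init=False)
    repeat_instance_intervals: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        parts: list[str] = []
        intervals: list[tuple[int, int]] = []
        pos = 0
        for repeat, spacer in self.units:
            intervals.append((pos, pos + len(repeat.dna_sequence)))
            parts.append(repeat.dna_sequence)
            parts.append(spacer.upper())
            pos += len(repeat.dna_sequence) + len(spacer)
        if self.trailing_repeat and self.units:
            repeat = self.units[0][0]
            intervals.append((pos, pos + len(repeat.dna_sequence)))
            parts.append(repeat.dna_sequence)
        self.full_sequence = "".join(parts)
        self.repeat_instance_intervals = intervals


@dataclass
class FoldCheckReport:
    """Per-repeat-instance folding verdicts for one array transcript."""

    instance_pass: list[bool]
    #: for each instance, index of the first retained structure containing
    #: every reference pair; None when the instance fails
    instance_structure_index: list[int | None]
    overall_pass: bool
    strict: bool = False


def fold(
    sequence: str,
    energy_window: float = 2.0,
    max_structures: int = 20,
) -> list[FoldStructure]:
    """Near-optimal structures of an RNA: MFE plus suboptimals in the window.

    ``sequence`` may be given as DNA (T is read as U). Structures are sorted
    by ascending free energy and capped at ``max_structures``;
    ``energy_window`` is in kcal/mol above the MFE.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if RNA is None:
        raise FoldingEngineError("ViennaRNA python bindings are not importable")
    rna = sequence.upper().replace("T", "U")
    fc = RNA.fold_compound(rna)
    delta_dacal = int(round(energy_window * 100))
    sols = fc.subopt(delta_dacal)
    structs = sorted(
        (FoldStructure(s.structure, round(s.energy, 2)) for s in sols),
        key=lambda x: (x.free_energy, x.dot_bracket),
    )
    return structs[:max_structures]


def reference_hairpin(repeat: RepeatUnit) -> tuple[tuple[int, int], ...]:
    """Base pairs of the 3'-terminal stem-loop of the isolated repeat's MFE.

    The terminal hairpin is the helix (with any bulges/internal loops nested
    inside it) that contains the 3'-most paired base. Raises
    :class:`FoldingEngineError` if the isolated repeat is predicted
    unstructured, in which case it cannot serve as a processing repeat.
    """
    mfe = fold(repeat.dna_sequence, energy_window=0.0, max_structures=1)[0]
    pairs = mfe.pairs()
    if not pairs:
        raise FoldingEngineError(
            f"repeat {repeat.name!r} is predicted unstructured; unusable"
        )
    j_max = max(j for _, j in pairs)
    # no pair encloses j_max, so the pair closing the terminal hairpin is the
    # one ending at j_max; keep everything nested within it
    i0 = next(i for i, j in pairs if j == j_max)
    hairpin = tuple(sorted((i, j) for i, j in pairs if i0 <= i < j <= j_max))
    return hairpin


def check_array_folding(
    array: ArrayTranscript,
    energy_window: float = 2.0,
    max_structures: int = 20,
    strict: bool = False,
) -> FoldCheckReport:
    """Validate that every repeat copy can form its processing hairpin.

    Default mode judges each repeat instance independently: it passes if any
    retained structure of the full transcript contains all of its reference
    pairs (translated to transcript coordinates). Strict mode additionally
    requires a single structure that satisfies every instance at once.
    """
    structures = fold(array.full_sequence, energy_window, max_structures)
    pair_sets = [s.pairs() for s in structures]
    instance_pass: list[bool] = []
    instance_idx: list[int | None] = []
    per_instance_ok: list[set[int]] = []
    for (start, _), (repeat, *_rest) in zip(
        array.repeat_instance_intervals,
        list(array.units) + ([array.units[0]] if array.trailing_repeat else []),
    ):
        required = {(i + start, j + start) for i, j in repeat.reference_pairs}
        ok_structs = {
            k for k, ps in enumerate(pair_sets) if required <= set(ps)
        }
        per_instance_ok.append(ok_structs)
        instance_pass.append(bool(ok_structs))
        instance_idx.append(min(ok_structs) if ok_structs else None)
    if strict:
        common = set(range(len(structures)))
        for ok in per_instance_ok:
            common &= ok
        overall = bool(common) and all(instance_pass)
    else:
        overall = all(instance_pass)
    return FoldCheckReport(instance_pass, instance_idx, overall, strict=strict)


def design_array(
    gene_id: str,
    spacers: list[str],
    repeat: RepeatUnit,
    n_units: int = 3,
    energy_window: float = 2.0,
    max_structures: int = 20,
    strict: bool = False,
    attempt_cap: int = 50,
    trailing_repeat: bool = False,
    conflicts: set[frozenset[int]] | None = None,
) -> tuple[ArrayTranscript | None, str | None]:
    """First spacer combination/ordering whose transcript passes fold checks.

    ``spacers`` are taken in rank order; triples (n_units-tuples) are tried in
    combination order and, within each, in permutation order, up to
    ``attempt_cap`` fold evaluations. ``conflicts`` lists index pairs that may
    not co-occur in one array (e.g. overlapping protospacers). Returns
    (transcript, None) on success or (None, reason) on failure.
    """
    conflicts = conflicts or set()
    usable = [
        combo
        for combo in itertools.combinations(range(len(spacers)), n_units)
        if not any(
            frozenset((a, b)) in conflicts
            for a, b in itertools.combinations(combo, 2)
        )
    ]
    if not usable:
        return None, (
            f"insufficient spacers for array "
            f"({len(spacers)} candidates, none form a compatible {n_units}-set)"
        )
    attempts = 0
    for combo in usable:
        for perm in itertools.permutations(combo):
            if attempts >= attempt_cap:
                return None, f"no passing array within {attempt_cap} attempts"
            attempts += 1
            transcript = ArrayTranscript(
                gene_id,
                [(repeat, spacers[i]) for i in perm],
                trailing_repeat=trailing_repeat,
            )
            report = check_array_folding(
                transcript, energy_window, max_structures, strict=strict
            )
            if report.overall_pass:
                return transcript, None
    return None, "improper folding of all candidate arrays"
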