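"""Exhaustive scanner for eight-metal-ligand RING arrangements.

A RING domain is recognised by eight metal-ligand (ml) residues that
coordinate two zinc ions in a cross-brace: ml1-ml2 and ml5-ml6 bind one
ion, ml3-ml4 and ml7-ml8 the other.  The scanner enumerates every octuple
of positions whose residues and inter-residue spacers satisfy the union
of the per-type consensus windows, then resolves overlapping candidates
into a deterministic set of non-overlapping domain calls.

Spacer semantics: X(n) counts residues strictly between two consecutive
ml residues, so "C x2 C" means ml positions p and p+3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .io_formats import ProteinRecord


def _window(*values: int) -> frozenset[int]:
    return frozenset(values)


def _span(lo: int, hi: int) -> frozenset[int]:
    return frozenset(range(lo, hi + 1))


@dataclass(frozen=True)
class SpacingConstraints:
    """Allowed residues per ml slot and allowed spacer lengths per gap.

    Defaults are the union over all eight RING-type consensus rows:
    residue sets ml1={C}, ml2={C,S,T}, ml3={C}, ml4={H,C}, ml5={H,C,D,G},
    ml6={C,S,T}, ml7={C}, ml8={C}; gap windows g12={2}, g23=[8,33],
    g34=[1,4], g45=[2,7], g56=[1,2], g67=[1,64], g78={1,2,3,4,10}.
    The unknown residue X never matches an ml slot but is legal in spacers.
    """

    residue_sets: tuple[frozenset[str], ...] = (
        frozenset("C"),
        frozenset("CST"),
        frozenset("C"),
        frozenset("HC"),
        frozenset("HCDG"),
        frozenset("CST"),
        frozenset("C"),
        frozenset("C"),
    )
    gap_windows: tuple[frozenset[int], ...] = (
        _window(2),
        _span(8, 33),
        _span(1, 4),
        _span(2, 7),
        _span(1, 2),
        _span(1, 64),
        _window(1, 2, 3, 4, 10),
    )

    def __post_init__(self) -> None:
        if len(self.residue_sets) != 8 or len(self.gap_windows) != 7:
            raise ValueError("need 8 residue sets and 7 gap windows")

    def strict(self) -> "SpacingConstraints":
        """Variant excluding T at ml2/ml6 (only S substitutions allowed)."""
        sets = list(self.residue_sets)
        sets[1] = sets[1] - {"T"}
        sets[5] = sets[5] - {"T"}
        return SpacingConstraints(tuple(sets), self.gap_windows)

    @classmethod
    def from_json(cls, path: str | Path) -> "SpacingConstraints":
        """Load overrides from a JSON file with keys ``residue_sets``
        (list of 8 strings) and ``gap_windows`` (list of 7 integer lists)."""
        with open(path) as fh:
            data = json.load(fh)
        kwargs = {}
        if "residue_sets" in data:
            kwargs["residue_sets"] = tuple(
                frozenset(s.upper()) for s in data["residue_sets"]
            )
        if "gap_windows" in data:
            kwargs["gap_windows"] = tuple(
                frozenset(int(v) for v in w) for w in data["gap_windows"]
            )
        return cls(**kwargs)


DEFAULT_CONSTRAINTS = SpacingConstraints()

GAP_NAMES = ("g12", "g23", "g34", "g45", "g56", "g67", "g78")


@dataclass(frozen=True)
class MlArrangement:
    """One candidate octuple of metal-ligand positions in a protein.

    Positions are 1-based; ``spacers[i]`` is the number of residues
    strictly between ml positions i+1 and i+2.
    """

    protein_id: str
    ml_positions: tuple[int, ...]
    ml_residues: tuple[str, ...]
    spacers: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.ml_positions) != 8 or len(self.ml_residues) != 8:
            raise ValueError("an arrangement has exactly 8 ml positions")
        derived = tuple(
            self.ml_positions[i + 1] - self.ml_positions[i] - 1 for i in range(7)
        )
        if not self.spacers:
            object.__setattr__(self, "spacers", derived)
        elif tuple(self.spacers) != derived:
            raise ValueError(
                f"spacers {self.spacers} inconsistent with positions "
                f"{self.ml_positions}"
            )
        if any(s < 0 for s in self.spacers):
            raise ValueError("ml positions must be strictly increasing")

    @property
    def span(self) -> tuple[int, int]:
        return (self.ml_positions[0], self.ml_positions[7])

    @property
    def span_length(self) -> int:
        return self.ml_positions[7] - self.ml_positions[0] + 1

    def overlaps(self, other: "MlArrangement") -> bool:
        a, b = self.span, other.span
        return a[0] <= b[1] and b[0] <= a[1]


def enumerate_candidates(
    protein: ProteinRecord,
    constraints: SpacingConstraints = DEFAULT_CONSTRAINTS,
) -> list[MlArrangement]:
    """Enumerate every ml octuple satisfying the constraints, exhaustively.

    Depth-first over anchor positions with window pruning; X never fills
    an ml slot.  The result is sorted by (ml1 position, ml8 position,
    full position tuple) and contains every satisfying arrangement — the
    search prunes only by constraints that would be violated, never by
    heuristics.
    """
    seq = protein.sequence
    n = len(seq)
    res_sets = constraints.residue_sets
    windows = [sorted(w) for w in constraints.gap_windows]
    out: list[MlArrangement] = []
    stack_positions = [0] * 8

    def extend(slot: int, prev_pos: int) -> None:
        # prev_pos is the 0-based index of ml[slot-1]
        for gap in windows[slot - 1]:
            pos = prev_pos + gap + 1
            if pos >= n:
                break
            if seq[pos] in res_sets[slot]:
                stack_positions[slot] = pos
                if slot == 7:
                    positions = tuple(p + 1 for p in stack_positions)
                    residues = tuple(seq[p] for p in stack_positions)
                    out.append(MlArrangement(protein.id, positions, residues))
                else:
                    extend(slot + 1, pos)

    for start in range(n):
        if seq[start] in res_sets[0]:
            stack_positions[0] = start
            extend(1, start)

    out.sort(key=lambda a: (a.ml_positions[0], a.ml_positions[7], a.ml_positions))
    return out


def resolve_overlaps(
    candidates: Sequence[MlArrangement],
    classify: Callable[[MlArrangement], "object"],
) -> list[MlArrangement]:
    """Resolve overlapping candidates into non-overlapping domain calls.

    Preference order: (1) arrangements whose assigned type's own consensus
    windows are fully satisfied; (2) earliest ml1; (3) smallest span;
    (4) lexicographically smallest position tuple.  Candidates are then
    accepted greedily in that order, skipping any that overlap an already
    accepted span.  ``classify`` must return an object with a boolean
    ``spacing_conformant`` attribute.
    """

    def key(arr: MlArrangement):
        call = classify(arr)
        return (
            0 if getattr(call, "spacing_conformant", False) else 1,
            arr.ml_positions[0],
            arr.span_length,
            arr.ml_positions,
        )

    accepted: list[MlArrangement] = []
    for arr in sorted(candidates, key=key):
        if not any(arr.overlaps(a) for a in accepted):
            accepted.append(arr)
    accepted.sort(key=lambda a: a.ml_positions[0])
    return accepted


def scan_proteins(
    proteins: Iterable[ProteinRecord],
    constraints: SpacingConstraints = DEFAULT_CONSTRAINTS,
    classify: Callable[[MlArrangement], "object"] | None = None,
) -> dict[str, list[MlArrangement]]:
    """Scan a collection of proteins; optionally resolve overlaps.

    Returns a mapping protein id -> arrangements (candidates if
    ``classify`` is None, otherwise non-overlapping resolved calls).
    """
    result: dict[str, list[MlArrangement]] = {}
    for protein in proteins:
        cands = enumerate_candidates(protein, constraints)
        if classify is not None:
            cands = resolve_overlaps(cands, classify)
        result[protein.id] = cands
    return result
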