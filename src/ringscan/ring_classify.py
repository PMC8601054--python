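"""RING-type assignment and family census.

Types are determined solely by the identities of the metal-ligand
residues, with one exception: the RING-HCa / RING-HCb split, which keys
on the spacer between ml7 and ml8 (1-2 vs 3-4 residues).  The decision
tree branches on the (ml4, ml5) pair — (H,H) RING-H2; (C,H) RING-v,
the reversed RING-HC pattern; (C,C) RING-C2; (H,D) RING-D; (H,G)
RING-G; (H,C) is RING-HC unless ml2 or ml6 carries the S/T substitution,
which makes it RING-S/T.  Each call also records whether all seven
spacers sit inside the assigned type's own consensus windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Optional, Sequence

from .domain_scan import GAP_NAMES, MlArrangement, _span, _window
from .io_formats import ProteinRecord


class RingType(str, Enum):
    RING_H2 = "RING-H2"
    RING_HCA = "RING-HCa"
    RING_HCB = "RING-HCb"
    RING_V = "RING-v"
    RING_C2 = "RING-C2"
    RING_D = "RING-D"
    RING_ST = "RING-S/T"
    RING_G = "RING-G"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The eight classified types, in census/report order.
CLASSIFIED_TYPES = tuple(t for t in RingType if t is not RingType.UNCLASSIFIED)

#: Per-type consensus spacer windows (g12..g78).
TYPE_SPACER_WINDOWS: dict[RingType, tuple[frozenset[int], ...]] = {
    RingType.RING_H2: (
        _window(2), _span(11, 33), _window(1), _window(2), _window(2),
        _span(3, 64), _window(2),
    ),
    RingType.RING_HCA: (
        _window(2), _span(10, 16), _window(1, 3), _window(2, 3), _window(1, 2),
        _span(6, 31), _window(1, 2),
    ),
    RingType.RING_HCB: (
        _window(2), _span(11, 15), _window(1), _window(2, 3), _window(2),
        _span(11, 19), _window(3, 4),
    ),
    RingType.RING_V: (
        _window(2), _span(8, 33), _window(1, 2), _window(4, 7), _window(2),
        _span(12, 30), _window(2, 10),
    ),
    RingType.RING_C2: (
        _window(2), _span(9, 15), _span(1, 4), _span(2, 7), _window(2),
        _span(1, 19), _window(2),
    ),
    RingType.RING_D: (
        _window(2), _span(13, 15), _window(1), _window(2), _window(2),
        _window(10), _window(2),
    ),
    RingType.RING_ST: (
        _window(2), _window(14), _window(1), _window(2), _window(2),
        _window(13), _window(2),
    ),
    RingType.RING_G: (
        _window(2), _span(11, 16), _window(1), _window(2), _window(2),
        _span(12, 13), _window(2),
    ),
}


@dataclass(frozen=True)
class RingDomainCall:
    """An arrangement with its assigned RING type and conformance flags."""

    arrangement: MlArrangement
    ring_type: RingType
    spacing_conformant: bool
    nonconforming_spacers: tuple[str, ...] = ()

    @property
    def protein_id(self) -> str:
        return self.arrangement.protein_id


def classify_arrangement(arr: MlArrangement) -> RingDomainCall:
    """Assign a RING type and validate spacing against that type's row."""
    ml2, ml4, ml5, ml6 = (arr.ml_residues[i] for i in (1, 3, 4, 5))
    g78 = arr.spacers[6]

    if (ml4, ml5) == ("H", "H"):
        ring_type = RingType.RING_H2
    elif (ml4, ml5) == ("C", "H"):
        ring_type = RingType.RING_V
    elif (ml4, ml5) == ("C", "C"):
        ring_type = RingType.RING_C2
    elif (ml4, ml5) == ("H", "D"):
        ring_type = RingType.RING_D
    elif (ml4, ml5) == ("H", "G"):
        ring_type = RingType.RING_G
    elif (ml4, ml5) == ("H", "C"):
        # the S/T substitution takes precedence over the HCa/HCb split
        if ml2 in ("S", "T") or ml6 in ("S", "T"):
            ring_type = RingType.RING_ST
        elif g78 in (1, 2):
            ring_type = RingType.RING_HCA
        elif g78 in (3, 4):
            ring_type = RingType.RING_HCB
        else:
            ring_type = RingType.UNCLASSIFIED
    else:
        ring_type = RingType.UNCLASSIFIED

    if ring_type is RingType.UNCLASSIFIED:
        return RingDomainCall(arr, ring_type, False, tuple(GAP_NAMES))

    windows = TYPE_SPACER_WINDOWS[ring_type]
    bad = tuple(
        name
        for name, spacer, window in zip(GAP_NAMES, arr.spacers, windows)
        if spacer not in window
    )
    return RingDomainCall(arr, ring_type, not bad, bad)


def round_percent(fraction: float, decimals: int = 2) -> float:
    """Percentage with round-half-up at the given number of decimals."""
    q = Decimal(10) ** -decimals
    return float(
        (Decimal(str(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class CensusReport:
    """Family-level summary of a set of RING domain calls."""

    type_counts: dict[RingType, int]
    type_percentages: dict[RingType, float]
    unclassified_count: int
    total_domains: int
    total_proteins: int
    domains_per_protein: dict[int, int]
    min_length: tuple[str, int]
    max_length: tuple[str, int]

    def count(self, ring_type: RingType) -> int:
        return self.type_counts.get(ring_type, 0)

    def percentage(self, ring_type: RingType) -> float:
        return self.type_percentages.get(ring_type, 0.0)


def census(
    calls: Sequence[RingDomainCall],
    proteins: Sequence[ProteinRecord],
) -> CensusReport:
    """Summarise calls into per-type counts/percentages and a histogram.

    Percentages (2 decimals, half-up) are over the classified total;
    unclassified calls are counted separately, never silently dropped.
    A call referencing a protein absent from ``proteins`` is an error.
    """
    by_id = {p.id: p for p in proteins}
    for call in calls:
        if call.protein_id not in by_id:
            raise ValueError(f"call references unknown protein {call.protein_id!r}")

    type_counts = {t: 0 for t in CLASSIFIED_TYPES}
    unclassified = 0
    per_protein = {p.id: 0 for p in proteins}
    for call in calls:
        per_protein[call.protein_id] += 1
        if call.ring_type is RingType.UNCLASSIFIED:
            unclassified += 1
        else:
            type_counts[call.ring_type] += 1

    classified_total = sum(type_counts.values())
    percentages = {
        t: round_percent(c / classified_total) if classified_total else 0.0
        for t, c in type_counts.items()
    }

    histogram: dict[int, int] = {}
    for n in per_protein.values():
        histogram[n] = histogram.get(n, 0) + 1

    shortest = min(proteins, key=lambda p: (len(p), p.id))
    longest = max(proteins, key=lambda p: (len(p), p.id))
    return CensusReport(
        type_counts=type_counts,
        type_percentages=percentages,
        unclassified_count=unclassified,
        total_domains=len(calls),
        total_proteins=len(proteins),
        domains_per_protein=histogram,
        min_length=(shortest.id, len(shortest)),
        max_length=(longest.id, len(longest)),
    )


def census_rows(report: CensusReport) -> list[dict]:
    """Flatten a census into TSV-ready rows (one per type + unclassified)."""
    rows = [
        {
            "ring_type": t.value,
            "count": report.count(t),
            "percent": f"{report.percentage(t):.2f}",
        }
        for t in CLASSIFIED_TYPES
    ]
    rows.append(
        {
            "ring_type": "unclassified",
            "count": report.unclassified_count,
            "percent": "",
        }
    )
    return rows


def calls_to_rows(calls: Iterable[RingDomainCall]) -> list[dict]:
    """Flatten calls into TSV-ready rows."""
    rows = []
    for call in calls:
        arr = call.arrangement
        row = {"protein_id": arr.protein_id}
        for i in range(8):
            row[f"ml{i + 1}_pos"] = arr.ml_positions[i]
        row["ml_residues"] = "".join(arr.ml_residues)
        for name, spacer in zip(GAP_NAMES, arr.spacers):
            row[name] = spacer
        row["start"], row["end"] = arr.span
        row["ring_type"] = call.ring_type.value
        row["spacing_conformant"] = call.spacing_conformant
        row["nonconforming_spacers"] = ",".join(call.nonconforming_spacers)
        rows.append(row)
    return rows
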