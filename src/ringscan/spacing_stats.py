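"""Spacer-length distributions and anchored flanking-residue frequencies.

Two summaries of a set of RING domain calls: per ml-pair histograms of
spacer lengths (overall and per type), and residue frequency vectors at
positions anchored to the ml sites (the data behind a sequence logo).
Anchor offsets are in ungapped protein coordinates: "ml6+4" is the
fourth residue after ml6, "ml2-1" the residue just ahead of ml2, whatever
the intervening spacer lengths are; anchored positions may land on
another ml site and are still counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .domain_scan import GAP_NAMES
from .io_formats import ProteinRecord
from .ring_classify import CLASSIFIED_TYPES, RingDomainCall, RingType

#: Anchors called out in the flanking-conservation analysis.
DEFAULT_ANCHORS = (
    "ml1+1", "ml2-1", "ml2+1", "ml4-1", "ml5-1", "ml6+2", "ml6+4", "ml7+2",
)

_ANCHOR_RE = re.compile(r"^ml([1-8])([+-]\d+)$")


def parse_anchor(anchor: str) -> tuple[int, int]:
    """Parse 'ml<k><±offset>' into (ml index 1..8, signed offset)."""
    m = _ANCHOR_RE.match(anchor)
    if not m:
        raise ValueError(f"bad anchor {anchor!r}; expected e.g. 'ml6+4'")
    return int(m.group(1)), int(m.group(2))


@dataclass(frozen=True)
class SpacingProfile:
    """Spacer-length histograms for one scope (a RING type or 'all')."""

    scope: str
    histograms: dict[str, dict[int, int]]  # gap name -> {length: count}
    n_domains: int

    def fraction(self, gap: str, length: int) -> float:
        if self.n_domains == 0:
            return 0.0
        return self.histograms[gap].get(length, 0) / self.n_domains

    def fractions(self, gap: str) -> dict[int, float]:
        return {
            length: count / self.n_domains
            for length, count in self.histograms[gap].items()
        }


def spacer_histograms(
    calls: Sequence[RingDomainCall],
    group_by_type: bool = True,
) -> list[SpacingProfile]:
    """Per ml-pair spacer histograms, for scope 'all' and per RING type.

    The 'all' profile comes first; per-type profiles follow in census
    order for the types present (unclassified included last if present).
    Bin-wise, the per-type histograms stack to the 'all' histogram.
    """
    if not calls:
        raise ValueError("no calls to summarise")

    def build(scope: str, subset: Sequence[RingDomainCall]) -> SpacingProfile:
        hists: dict[str, dict[int, int]] = {g: {} for g in GAP_NAMES}
        for call in subset:
            for gap, spacer in zip(GAP_NAMES, call.arrangement.spacers):
                hists[gap][spacer] = hists[gap].get(spacer, 0) + 1
        hists = {g: dict(sorted(h.items())) for g, h in hists.items()}
        return SpacingProfile(scope, hists, len(subset))

    profiles = [build("all", calls)]
    if group_by_type:
        order = list(CLASSIFIED_TYPES) + [RingType.UNCLASSIFIED]
        for ring_type in order:
            subset = [c for c in calls if c.ring_type is ring_type]
            if subset:
                profiles.append(build(ring_type.value, subset))
    return profiles


@dataclass(frozen=True)
class AnchorFrequencies:
    """Residue frequencies at one anchored position."""

    anchor: str
    counts: dict[str, int]
    n_resolved: int
    n_skipped: int  # anchored position fell outside the protein

    @property
    def frequencies(self) -> dict[str, float]:
        if self.n_resolved == 0:
            return {}
        return {aa: c / self.n_resolved for aa, c in self.counts.items()}

    @property
    def modal_residue(self) -> str | None:
        if not self.counts:
            return None
        return max(self.counts.items(), key=lambda kv: (kv[1], kv[0]))[0]

    @property
    def modal_fraction(self) -> float:
        if self.n_resolved == 0:
            return 0.0
        return self.counts[self.modal_residue] / self.n_resolved


@dataclass(frozen=True)
class ResidueFrequencyMatrix:
    """Frequency vectors for a set of anchors over a set of calls."""

    scope: str
    anchors: tuple[str, ...]
    per_anchor: dict[str, AnchorFrequencies] = field(default_factory=dict)

    def frequency(self, anchor: str, residue: str) -> float:
        return self.per_anchor[anchor].frequencies.get(residue, 0.0)


def flank_frequencies(
    calls: Sequence[RingDomainCall],
    proteins: Sequence[ProteinRecord],
    anchors: Iterable[str] = DEFAULT_ANCHORS,
    scope: str = "all",
) -> ResidueFrequencyMatrix:
    """Residue frequencies at ml-anchored offsets across the given calls.

    Positions outside the protein are skipped and counted per anchor.
    Each frequency vector sums to 1 over the domains where the anchored
    position exists.
    """
    anchors = tuple(anchors)
    by_id = {p.id: p for p in proteins}
    per_anchor: dict[str, AnchorFrequencies] = {}
    for anchor in anchors:
        ml_index, offset = parse_anchor(anchor)
        counts: dict[str, int] = {}
        skipped = 0
        for call in calls:
            protein = by_id.get(call.protein_id)
            if protein is None:
                raise ValueError(
                    f"call references unknown protein {call.protein_id!r}"
                )
            pos = call.arrangement.ml_positions[ml_index - 1] + offset
            if 1 <= pos <= len(protein):
                aa = protein.sequence[pos - 1]
                counts[aa] = counts.get(aa, 0) + 1
            else:
                skipped += 1
        resolved = sum(counts.values())
        per_anchor[anchor] = AnchorFrequencies(
            anchor, dict(sorted(counts.items())), resolved, skipped
        )
    return ResidueFrequencyMatrix(scope, anchors, per_anchor)


def spacing_rows(profiles: Sequence[SpacingProfile]) -> list[dict]:
    """Flatten spacing profiles into TSV-ready rows."""
    rows = []
    for profile in profiles:
        for gap in GAP_NAMES:
            for length, count in profile.histograms[gap].items():
                rows.append(
                    {
                        "scope": profile.scope,
                        "ml_pair": gap,
                        "spacer": length,
                        "count": count,
                        "fraction": f"{count / profile.n_domains:.6f}",
                    }
                )
    return rows


def logo_rows(matrix: ResidueFrequencyMatrix) -> list[dict]:
    """Flatten a residue frequency matrix into TSV-ready rows."""
    rows = []
    for anchor in matrix.anchors:
        freq = matrix.per_anchor[anchor]
        for aa, count in freq.counts.items():
            rows.append(
                {
                    "scope": matrix.scope,
                    "anchor": anchor,
                    "residue": aa,
                    "count": count,
                    "frequency": f"{count / freq.n_resolved:.6f}",
                    "skipped": freq.n_skipped,
                }
            )
    return rows
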