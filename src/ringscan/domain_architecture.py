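"""Grouping of RING proteins by additional-domain composition.

Proteins are partitioned by the multiset of their non-RING domains:
group 1 holds proteins with no additional domains, group 2 those with
one or more transmembrane segments and nothing else, and the remaining
groups are keyed by their exact domain signature, numbered in
decreasing size then lexicographic signature order.  Transmembrane
multiplicity is collapsed (one TM or five is the same group); other
domains keep their multiplicity (ANK x3 is a different signature from
ANK x1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io_formats import AnnotationRow

logger = logging.getLogger(__name__)

#: Reserved signature token for transmembrane segments.
TM_TOKEN = "TM"

_TM_NAMES = {"tm", "tmhelix", "transmembrane"}


def is_ring_domain(name: str) -> bool:
    """Case-insensitive: any name containing the token RING counts."""
    return "ring" in name.lower()


def is_tm_domain(name: str) -> bool:
    return name.lower() in _TM_NAMES


def normalise_signature(domain_names: Sequence[str]) -> tuple[str, ...]:
    """Sorted multiset of non-RING domain names; TM collapsed to one token."""
    kept = []
    has_tm = False
    for name in domain_names:
        if is_ring_domain(name):
            continue
        if is_tm_domain(name):
            has_tm = True
        else:
            kept.append(name.upper())
    signature = sorted(kept)
    if has_tm:
        signature.append(TM_TOKEN)
    return tuple(sorted(signature))


@dataclass(frozen=True)
class ArchitectureGroup:
    group_id: int
    signature: tuple[str, ...]
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ArchitectureGrouping:
    groups: tuple[ArchitectureGroup, ...]

    @property
    def n_proteins(self) -> int:
        return sum(g.size for g in self.groups)

    def group_of(self, protein_id: str) -> ArchitectureGroup:
        for g in self.groups:
            if protein_id in g.members:
                return g
        raise KeyError(protein_id)


def assign_groups(
    annotations: Sequence[AnnotationRow],
    ring_protein_ids: Sequence[str],
) -> ArchitectureGrouping:
    """Partition RING proteins into architecture groups.

    Group 1 is fixed to the empty signature (RING only, including
    proteins with no annotation rows at all); group 2 to {TM}.  The
    remaining signatures get ids 3..k by decreasing size, ties broken by
    lexicographic signature.  Annotations for proteins outside
    ``ring_protein_ids`` are skipped with a warning.  The result is a
    partition: every protein appears in exactly one group, and the
    grouping is invariant to the input row order.
    """
    ids = list(dict.fromkeys(ring_protein_ids))
    id_set = set(ids)
    per_protein: dict[str, list[str]] = {pid: [] for pid in ids}
    for row in annotations:
        if row.protein_id not in id_set:
            logger.warning(
                "annotation for %s skipped: not a RING protein", row.protein_id
            )
            continue
        per_protein[row.protein_id].append(row.domain_name)

    by_signature: dict[tuple[str, ...], list[str]] = {}
    for pid in ids:
        signature = normalise_signature(sorted(per_protein[pid]))
        by_signature.setdefault(signature, []).append(pid)

    groups: list[ArchitectureGroup] = []
    empty = tuple()
    tm_only = (TM_TOKEN,)
    groups.append(
        ArchitectureGroup(1, empty, tuple(sorted(by_signature.pop(empty, []))))
    )
    groups.append(
        ArchitectureGroup(2, tm_only, tuple(sorted(by_signature.pop(tm_only, []))))
    )
    rest = sorted(by_signature.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    for offset, (signature, members) in enumerate(rest):
        groups.append(ArchitectureGroup(3 + offset, signature, tuple(sorted(members))))

    grouping = ArchitectureGrouping(tuple(groups))
    assert grouping.n_proteins == len(ids), "grouping must partition the proteins"
    return grouping


def grouping_rows(grouping: ArchitectureGrouping) -> list[dict]:
    """Flatten a grouping into TSV-ready rows (one per protein)."""
    rows = []
    for group in grouping.groups:
        for pid in group.members:
            rows.append(
                {
                    "group_id": group.group_id,
                    "signature": "+".join(group.signature) or "(RING only)",
                    "group_size": group.size,
                    "protein_id": pid,
                }
            )
    return rows
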