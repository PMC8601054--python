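"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ringscan.domain_scan import MlArrangement, SpacingConstraints
from ringscan.io_formats import ProteinRecord
from ringscan.phylo_nj import DistanceMatrix


def build_arrangement(residues: str, spacers: tuple[int, ...],
                      protein_id: str = "p1", start: int = 1) -> MlArrangement:
    """Arrangement with the given ml residues and spacers, positions derived."""
    positions = [start]
    for s in spacers:
        positions.append(positions[-1] + s + 1)
    return MlArrangement(protein_id, tuple(positions), tuple(residues))


def brute_force_octuples(sequence: str,
                         constraints: SpacingConstraints) -> list[tuple[int, ...]]:
    """Independent enumerator: nested loops over residue-matching positions.

    Scans every position list per slot (no anchor-jump arithmetic) and
    filters on the spacer windows; returns sorted position octuples.
    """
    slots = [
        [i + 1 for i, aa in enumerate(sequence) if aa in constraints.residue_sets[s]]
        for s in range(8)
    ]
    windows = constraints.gap_windows
    results: list[tuple[int, ...]] = []

    def recurse(slot: int, chosen: list[int]) -> None:
        if slot == 8:
            results.append(tuple(chosen))
            return
        for pos in slots[slot]:
            if chosen:
                gap = pos - chosen[-1] - 1
                if gap < 0 or gap not in windows[slot - 1]:
                    continue
            recurse(slot + 1, chosen + [pos])

    recurse(0, [])
    return sorted(results, key=lambda t: (t[0], t[7], t))


def random_protein(rng: np.random.Generator, length: int,
                   alphabet: str = "ACDEFGHIKLMNPQRSTVWY",
                   protein_id: str = "rnd") -> ProteinRecord:
    letters = [alphabet[i] for i in rng.integers(0, len(alphabet), size=length)]
    return ProteinRecord(protein_id, "".join(letters))


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive lengths; returns (matrix, splits).

    Built by repeatedly joining two random clusters; leaf-to-leaf path
    sums give an exactly additive distance matrix.  ``splits`` is the
    set of non-trivial bipartitions, canonicalised to the side not
    containing the alphabetically first taxon.
    """
    ids = [f"t{i}" for i in range(n_taxa)]
    clusters: list[set[str]] = [{t} for t in ids]
    dist = {t: {u: 0.0 for u in ids} for t in ids}
    pending = [({t}, {t: 0.0}) for t in ids]  # (leafset, depth below join)
    splits: set[frozenset[str]] = set()
    while len(pending) > 1:
        i, j = sorted(rng.choice(len(pending), size=2, replace=False))
        (leaves_i, depth_i) = pending[i]
        (leaves_j, depth_j) = pending[j]
        bi = float(rng.uniform(0.1, 2.0))
        bj = float(rng.uniform(0.1, 2.0))
        for a in leaves_i:
            for b in leaves_j:
                d = depth_i[a] + bi + depth_j[b] + bj
                dist[a][b] = dist[b][a] = d
        merged_leaves = leaves_i | leaves_j
        merged_depth = {a: depth_i[a] + bi for a in leaves_i}
        merged_depth.update({b: depth_j[b] + bj for b in leaves_j})
        pending = [p for k, p in enumerate(pending) if k not in (i, j)]
        pending.append((merged_leaves, merged_depth))
        if 2 <= len(merged_leaves) <= n_taxa - 2:
            side = merged_leaves
            if ids[0] in side:
                side = set(ids) - side
            splits.add(frozenset(side))
    matrix = np.array([[dist[a][b] for b in ids] for a in ids])
    return DistanceMatrix(tuple(ids), matrix), splits


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
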