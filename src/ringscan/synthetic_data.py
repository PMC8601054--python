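"""Generators for every pipeline input, with known ground truth.

Three families of fixtures: proteins with planted RING domains built
from the per-type consensus rows (the truth table records the exact
metal-ligand octuples), codon-sequence pairs with controlled synonymous
and nonsynonymous divergence for the Ka/Ks estimator, and small
alignable protein families for tree tests.  In clean mode the
background alphabet excludes every residue that can occupy a
metal-ligand slot, so a planted octuple is provably the unique
satisfying arrangement in its protein.  All generators take an explicit
seed and emit byte-identical output for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .domain_scan import MlArrangement
from .io_formats import AMINO_ACIDS, AlignedRecord, CdsRecord, ProteinRecord
from .kaks_dating import _STOPS, synonymous_sites, translate_codon
from .ring_classify import RingType, TYPE_SPACER_WINDOWS, classify_arrangement

#: Residues that may occupy an ml slot under the union constraints.
ML_CAPABLE = frozenset("CHSTDG")

#: Background alphabet for clean mode: no residue can fill an ml slot.
CLEAN_ALPHABET = "".join(sorted(AMINO_ACIDS - ML_CAPABLE))
FULL_ALPHABET = "".join(sorted(AMINO_ACIDS))

#: Template ml residues per RING type (HCa/HCb differ only in g78).
TYPE_ML_RESIDUES: dict[RingType, tuple[str, ...]] = {
    RingType.RING_H2: tuple("CCCHHCCC"),
    RingType.RING_HCA: tuple("CCCHCCCC"),
    RingType.RING_HCB: tuple("CCCHCCCC"),
    RingType.RING_V: tuple("CCCCHCCC"),
    RingType.RING_C2: tuple("CCCCCCCC"),
    RingType.RING_D: tuple("CCCHDCCC"),
    RingType.RING_ST: tuple("CSCHCSCC"),
    RingType.RING_G: tuple("CCCHGCCC"),
}

#: Minimum clean-mode separation between planted spans: wider than the
#: widest spacer window (64), so no cross-domain octuple can bridge it.
MIN_SEPARATION = 70


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for planting domains of one RING type."""

    ring_type: RingType
    count: int = 1
    spacers: Optional[tuple[int, ...]] = None  # None = random-in-window

    def __post_init__(self) -> None:
        if self.ring_type is RingType.UNCLASSIFIED:
            raise ValueError("cannot plant an unclassified domain")
        if self.count < 1:
            raise ValueError("count must be positive")
        if self.spacers is not None:
            windows = TYPE_SPACER_WINDOWS[self.ring_type]
            for name_idx, (s, w) in enumerate(zip(self.spacers, windows)):
                if s not in w:
                    raise ValueError(
                        f"spacer {s} at gap {name_idx + 1} outside the "
                        f"{self.ring_type.value} consensus window"
                    )


@dataclass(frozen=True)
class PlantedDomain:
    protein_id: str
    ring_type: RingType
    ml_positions: tuple[int, ...]
    spacers: tuple[int, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.ml_positions[0], self.ml_positions[7])


@dataclass(frozen=True)
class TruthTable:
    planted: tuple[PlantedDomain, ...] = field(default_factory=tuple)

    def for_protein(self, protein_id: str) -> list[PlantedDomain]:
        return [p for p in self.planted if p.protein_id == protein_id]


def _draw_spacers(ring_type: RingType, rng: np.random.Generator) -> tuple[int, ...]:
    windows = TYPE_SPACER_WINDOWS[ring_type]
    return tuple(int(rng.choice(sorted(w))) for w in windows)


def _domain_string(
    ring_type: RingType,
    spacers: Sequence[int],
    alphabet: str,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, ...]]:
    """Domain sequence plus 1-based ml offsets within the domain."""
    residues = TYPE_ML_RESIDUES[ring_type]
    parts = [residues[0]]
    offsets = [1]
    for spacer, residue in zip(spacers, residues[1:]):
        parts.append("".join(rng.choice(list(alphabet), size=spacer)))
        parts.append(residue)
        offsets.append(offsets[-1] + spacer + 1)
    return "".join(parts), tuple(offsets)


def plant_domains(
    specs: Sequence[PlantSpec],
    background_len: int = 160,
    decoy_mode: str = "clean",
    seed: int = 0,
    domains_per_protein: int = 1,
) -> tuple[list[ProteinRecord], TruthTable]:
    """Generate proteins with planted RING domains and their truth table.

    Each spec plants ``count`` domains, ``domains_per_protein`` per
    protein, into backgrounds of total length ``background_len``.  In
    clean mode the background/spacer alphabet excludes C,H,S,T,D,G and
    planted spans are separated by at least 70 residues, so each
    protein's planted octuples are exactly its satisfying arrangements;
    in full-alphabet mode decoys may arise and only recall is
    guaranteed.  The truth table is validated against the emitted
    sequences before returning.
    """
    if decoy_mode not in ("clean", "full-alphabet"):
        raise ValueError(f"unknown decoy mode {decoy_mode!r}")
    alphabet = CLEAN_ALPHABET if decoy_mode == "clean" else FULL_ALPHABET
    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    planted: list[PlantedDomain] = []
    serial = 0

    queue: list[PlantSpec] = []
    for spec in specs:
        queue.extend([spec] * spec.count)

    for chunk_start in range(0, len(queue), domains_per_protein):
        chunk = queue[chunk_start:chunk_start + domains_per_protein]
        serial += 1
        pid = f"syn{serial:05d}"
        domains = []
        for spec in chunk:
            spacers = spec.spacers or _draw_spacers(spec.ring_type, rng)
            seq, offsets = _domain_string(spec.ring_type, spacers, alphabet, rng)
            domains.append((spec.ring_type, spacers, seq, offsets))
        total_domain_len = sum(len(d[2]) for d in domains)
        n_gaps = len(domains) + 1
        min_pad = MIN_SEPARATION * (len(domains) - 1)
        slack = background_len - total_domain_len - min_pad
        if slack < n_gaps:
            raise ValueError(
                f"background_len {background_len} too small to host "
                f"{len(domains)} domains of total length {total_domain_len}"
            )
        cuts = np.sort(rng.integers(0, slack + 1, size=n_gaps - 1))
        pads = np.diff(np.concatenate(([0], cuts, [slack]))).tolist()
        pieces = []
        cursor = 0
        for idx, (ring_type, spacers, seq, offsets) in enumerate(domains):
            pad = pads[idx] + (MIN_SEPARATION if idx > 0 else 0)
            pieces.append("".join(rng.choice(list(alphabet), size=pad)))
            cursor += pad
            pieces.append(seq)
            planted.append(
                PlantedDomain(
                    pid, ring_type,
                    tuple(cursor + off for off in offsets),
                    tuple(spacers),
                )
            )
            cursor += len(seq)
        pieces.append("".join(rng.choice(list(alphabet), size=pads[-1])))
        proteins.append(ProteinRecord(pid, "".join(pieces)))

    truth = TruthTable(tuple(planted))
    _validate_truth(proteins, truth)
    return proteins, truth


def _validate_truth(proteins: Sequence[ProteinRecord], truth: TruthTable) -> None:
    """Assert every planted octuple is present and correctly typed."""
    by_id = {p.id: p for p in proteins}
    for dom in truth.planted:
        protein = by_id[dom.protein_id]
        arr = MlArrangement(
            dom.protein_id,
            dom.ml_positions,
            tuple(protein.sequence[p - 1] for p in dom.ml_positions),
        )
        call = classify_arrangement(arr)
        if call.ring_type is not dom.ring_type or not call.spacing_conformant:
            raise AssertionError(
                f"planted {dom.ring_type.value} in {dom.protein_id} "
                f"re-reads as {call.ring_type.value}"
            )


# ---------------------------------------------------------------------------
# codon pairs

_NON_STOP_CODONS = sorted(
    c for c in ("".join((a, b, d)) for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in _STOPS
)


def _single_step_changes(codon: str) -> tuple[list[str], list[str]]:
    """Non-stop single-nucleotide neighbours, split (synonymous, nonsyn)."""
    syn, nonsyn = [], []
    aa = translate_codon(codon)
    for i in range(3):
        for nuc in "ACGT":
            if nuc == codon[i]:
                continue
            mutant = codon[:i] + nuc + codon[i + 1:]
            if mutant in _STOPS:
                continue
            (syn if translate_codon(mutant) == aa else nonsyn).append(mutant)
    return syn, nonsyn


def evolve_codon_pair(
    n_codons: int,
    target_ps: float,
    target_pn: float,
    seed: int,
    id_a: str = "anc",
    id_b: str = "der",
) -> tuple[CdsRecord, CdsRecord]:
    """Ancestor/derived CDS pair with controlled divergence.

    The ancestor is drawn uniformly from non-stop codons; synonymous and
    nonsynonymous single-nucleotide substitutions (at most one per
    codon, never creating a stop) are planted until the realized
    proportions, measured against the ancestor's Nei–Gojobori site
    counts, are within one substitution of ``target_ps`` x S and
    ``target_pn`` x N.  Unreachable targets raise after bounded
    attempts.  Deterministic for a fixed seed.
    """
    if not (0 <= target_ps < 0.75 and 0 <= target_pn < 0.75):
        raise ValueError("targets must lie in [0, 0.75)")
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        ancestor = [
            _NON_STOP_CODONS[i]
            for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
        ]
        s_sites = sum(synonymous_sites(c) for c in ancestor)
        n_sites = 3 * n_codons - s_sites
        want_syn = round(target_ps * s_sites)
        want_nonsyn = round(target_pn * n_sites)
        derived = list(ancestor)
        order = rng.permutation(n_codons)
        need_syn, need_nonsyn = want_syn, want_nonsyn
        for idx in order:
            if need_syn == 0 and need_nonsyn == 0:
                break
            syn, nonsyn = _single_step_changes(ancestor[idx])
            if need_syn > 0 and syn:
                derived[idx] = syn[rng.integers(0, len(syn))]
                need_syn -= 1
            elif need_nonsyn > 0 and nonsyn:
                derived[idx] = nonsyn[rng.integers(0, len(nonsyn))]
                need_nonsyn -= 1
        if need_syn == 0 and need_nonsyn == 0:
            return (
                CdsRecord(id_a, "".join(ancestor)),
                CdsRecord(id_b, "".join(derived)),
            )
    raise ValueError(
        f"targets pS={target_ps}, pN={target_pn} unreachable at {n_codons} codons"
    )


# ---------------------------------------------------------------------------
# alignable families

def _mutate(sequence: str, p: float, rng: np.random.Generator) -> str:
    out = []
    for aa in sequence:
        if rng.random() < p:
            alternatives = FULL_ALPHABET.replace(aa, "")
            out.append(alternatives[rng.integers(0, len(alternatives))])
        else:
            out.append(aa)
    return "".join(out)


def make_family_alignment(
    k_families: int,
    per_family: int,
    within_div: float,
    between_div: float,
    seed: int,
    length: int = 60,
) -> list[AlignedRecord]:
    """Equal-length protein families with planted membership in the ids.

    Family ancestors diverge from a common root at per-site probability
    ``between_div``; members diverge from their family ancestor at
    ``within_div`` (must be smaller).  Ids are ``F<k>_S<i>``, so the
    family truth is recoverable from the name.  No gaps are introduced.
    """
    if not within_div < between_div:
        raise ValueError("within-family divergence must be below between-family")
    rng = np.random.default_rng(seed)
    root = "".join(
        FULL_ALPHABET[i] for i in rng.integers(0, len(FULL_ALPHABET), size=length)
    )
    records = []
    for fam in range(1, k_families + 1):
        ancestor = _mutate(root, between_div, rng)
        for member in range(1, per_family + 1):
            records.append(
                AlignedRecord(f"F{fam}_S{member}", _mutate(ancestor, within_div, rng))
            )
    return records
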