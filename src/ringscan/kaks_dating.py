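"""Nei–Gojobori Ka/Ks estimation and molecular-clock duplication dating.

For each paralog pair the coding sequences are threaded onto the
protein alignment (each protein gap becomes one codon gap), synonymous
and nonsynonymous sites and differences are counted by the Nei–Gojobori
(1986) method — per-codon site fractions averaged over the two
sequences, multi-position codon differences averaged with equal weight
over all minimal mutational pathways that avoid stop codons — and the
proportions are Jukes–Cantor corrected: d = -(3/4)·ln(1 - (4/3)p).
Duplications are dated by T = Ks / (2λ) with λ the synonymous
substitution rate per site per year (default 1.5e-8, the flax rate),
and binned into recent vs ancient classes around a boundary age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .io_formats import AlignedRecord, CdsRecord, trim_terminal_stop

_NUCS = "ACGT"
_STOPS = set(standard_dna_table.stop_codons)
_CODON_TABLE = dict(standard_dna_table.forward_table)


def translate_codon(codon: str) -> str:
    """Amino acid for a codon, '*' for stop."""
    if codon in _STOPS:
        return "*"
    return _CODON_TABLE[codon]


def synonymous_sites(codon: str) -> float:
    """Synonymous site count of one codon: (syn changes among the 9)/3.

    Ranges over [0, 3]; changes to stop codons are not synonymous, and
    the nonsynonymous site count is the complement to 3.
    """
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = translate_codon(codon)
    syn = 0
    for i in range(3):
        for nuc in _NUCS:
            if nuc == codon[i]:
                continue
            mutant = codon[:i] + nuc + codon[i + 1:]
            if mutant not in _STOPS and translate_codon(mutant) == aa:
                syn += 1
    return syn / 3.0


def count_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Codons differing at several positions are resolved by averaging over
    all orderings of the single-nucleotide steps with equal weight;
    pathways passing through a stop codon are excluded.  If every
    pathway is blocked by stops, all pathways are used (steps through
    stops counted by amino-acid identity), so the difference count is
    never silently dropped.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        syn = nonsyn = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in _STOPS and not allow_stops and nxt != codon_b:
                return None
            if translate_codon(nxt) == translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    paths = [walk(order, False) for order in permutations(diff_positions)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, True) for order in permutations(diff_positions)]
    syn = sum(p[0] for p in valid) / len(valid)
    nonsyn = sum(p[1] for p in valid) / len(valid)
    return syn, nonsyn


@dataclass(frozen=True)
class ClockParams:
    """Molecular clock: substitutions per synonymous site per year."""

    lam: float = 1.5e-8

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("substitution rate must be positive")


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two gap-aligned codon sequences for one gene pair."""

    id_a: str
    id_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned codon sequences differ in length")

    def ungapped_columns(self) -> list[tuple[str, str]]:
        """Codon columns where neither sequence has a gap or an N."""
        out = []
        for ca, cb in zip(self.codons_a, self.codons_b):
            if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
                continue
            out.append((ca, cb))
        return out


@dataclass(frozen=True)
class KaKsResult:
    """Ka, Ks, their ratio, and the implied divergence time for one pair."""

    id_a: str
    id_b: str
    ka: Optional[float]
    ks: Optional[float]
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    saturated: bool
    t_mya: Optional[float]

    @property
    def ratio(self) -> Optional[float]:
        if self.ka is None or self.ks is None or self.ks == 0 or self.saturated:
            return None
        return self.ka / self.ks


def backtranslate_align(
    aligned_a: AlignedRecord,
    aligned_b: AlignedRecord,
    cds_a: CdsRecord,
    cds_b: CdsRecord,
) -> CodonAlignmentPair:
    """Thread CDS onto a pairwise protein alignment (one gap -> '---').

    Requires the ungapped protein length x 3 to equal the CDS length
    after terminal-stop trimming, and the CDS to translate to the
    protein under the standard code; a mismatch at any site is an error
    naming the gene and position.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"alignment rows {aligned_a.id}/{aligned_b.id} differ in length"
        )

    def codons_for(aligned: AlignedRecord, cds: CdsRecord) -> tuple[str, ...]:
        coding = trim_terminal_stop(cds.sequence)
        protein = aligned.degapped().sequence
        if len(protein) * 3 != len(coding):
            raise ValueError(
                f"{cds.id}: CDS length {len(coding)} does not match "
                f"protein length {len(protein)} x 3"
            )
        cds_codons = [coding[i:i + 3] for i in range(0, len(coding), 3)]
        for idx, (aa, codon) in enumerate(zip(protein, cds_codons), start=1):
            translated = "X" if "N" in codon else translate_codon(codon)
            if aa not in (translated, "X"):
                raise ValueError(
                    f"{cds.id}: codon {codon} at position {idx} translates to "
                    f"{translated}, protein has {aa}"
                )
        out = []
        it = iter(cds_codons)
        for aa in aligned.sequence:
            out.append("---" if aa in "-." else next(it))
        return tuple(out)

    return CodonAlignmentPair(
        aligned_a.id, aligned_b.id,
        codons_for(aligned_a, cds_a), codons_for(aligned_b, cds_b),
    )


def jukes_cantor(p: float) -> Optional[float]:
    """JC-corrected distance; None when p is at or beyond saturation (3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(
    pair: CodonAlignmentPair,
    clock: ClockParams = ClockParams(),
) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks for one aligned codon pair.

    Site counts are the per-codon synonymous fractions averaged over the
    two sequences; N + S equals three times the number of ungapped codon
    columns.  Columns containing a gap or an N in either codon are
    dropped pairwise.  The result is symmetric in its two sequences.
    """
    columns = pair.ungapped_columns()
    if not columns:
        raise ValueError(f"{pair.id_a}/{pair.id_b}: no ungapped codon columns")

    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    for ca, cb in columns:
        s_codon = (synonymous_sites(ca) + synonymous_sites(cb)) / 2.0
        s_sites += s_codon
        n_sites += 3.0 - s_codon
        sd, nd = count_codon_differences(ca, cb)
        s_diffs += sd
        n_diffs += nd

    saturated = False
    if s_sites > 0:
        ps = s_diffs / s_sites
        ks = jukes_cantor(ps)
        saturated = saturated or ks is None
    else:
        ks = None  # degenerate: no synonymous sites at all
    if n_sites > 0:
        pn = n_diffs / n_sites
        ka = jukes_cantor(pn)
        saturated = saturated or ka is None
    else:
        ka = None

    t = divergence_time(ks, clock) if ks is not None else None
    return KaKsResult(
        pair.id_a, pair.id_b, ka, ks, n_sites, s_sites, n_diffs, s_diffs,
        saturated, t,
    )


def divergence_time(ks: float, clock: ClockParams = ClockParams()) -> float:
    """T in million years from T = Ks / (2λ)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * clock.lam) / 1e6


@dataclass(frozen=True)
class DuplicationAgeBins:
    """Recent/ancient partition of dated duplication pairs."""

    boundary_mya: float
    saturation_cutoff_ks: float
    recent: tuple[KaKsResult, ...]
    ancient: tuple[KaKsResult, ...]
    excluded: tuple[KaKsResult, ...]
    recent_mean_t: Optional[float] = field(default=None)
    ancient_mean_t: Optional[float] = field(default=None)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.recent), len(self.ancient), len(self.excluded))


def bin_duplications(
    results: Sequence[KaKsResult],
    boundary_mya: float = 15.0,
    saturation_cutoff_ks: float = 3.0,
) -> DuplicationAgeBins:
    """Split dated pairs into recent (T <= boundary) and ancient classes.

    Ancient pairs must additionally have Ks at or below the saturation
    cutoff; pairs with undefined Ks, saturated correction, or Ks above
    the cutoff are excluded.  The default 15 MYA boundary sits between
    the flax mesopolyploidy (3.7-9 MYA) and palaeopolyploidy (20-44 MYA)
    windows.
    """
    if not results:
        raise ValueError("no Ka/Ks results to bin")
    recent, ancient, excluded = [], [], []
    for r in results:
        if r.ks is None or r.t_mya is None or r.saturated:
            excluded.append(r)
        elif r.t_mya <= boundary_mya:
            recent.append(r)
        elif r.ks <= saturation_cutoff_ks:
            ancient.append(r)
        else:
            excluded.append(r)

    def mean_t(rs: list[KaKsResult]) -> Optional[float]:
        if not rs:
            return None
        return sum(r.t_mya for r in rs) / len(rs)

    return DuplicationAgeBins(
        boundary_mya, saturation_cutoff_ks,
        tuple(recent), tuple(ancient), tuple(excluded),
        mean_t(recent), mean_t(ancient),
    )


def results_from_given_ks(
    pairs: Sequence,
    clock: ClockParams = ClockParams(),
) -> list[KaKsResult]:
    """Build dated results from pair rows carrying precomputed Ks/Ka.

    Used when an external tool already produced the substitution rates
    and only the clock dating / binning steps are wanted.
    """
    out = []
    for row in pairs:
        ks, ka = row.ks_given, row.ka_given
        t = divergence_time(ks, clock) if ks is not None else None
        out.append(
            KaKsResult(row.gene_a, row.gene_b, ka, ks, 0.0, 0.0, 0.0, 0.0,
                       False, t)
        )
    return out


def kaks_rows(results: Sequence[KaKsResult]) -> list[dict]:
    """Flatten results into TSV-ready rows."""

    def fmt(v: Optional[float]) -> str:
        return "" if v is None else f"{v:.6f}"

    return [
        {
            "gene_a": r.id_a,
            "gene_b": r.id_b,
            "ka": fmt(r.ka),
            "ks": fmt(r.ks),
            "ka_ks": fmt(r.ratio),
            "n_sites": f"{r.n_sites:.4f}",
            "s_sites": f"{r.s_sites:.4f}",
            "n_diffs": f"{r.n_diffs:.4f}",
            "s_diffs": f"{r.s_diffs:.4f}",
            "saturated": r.saturated,
            "t_mya": fmt(r.t_mya),
        }
        for r in results
    ]
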