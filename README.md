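# ringscan

Detection, typing and evolutionary analysis of RING zinc-finger domains in
plant proteomes.

RING-type E3 ubiquitin ligases form the largest E3 family in plants. A RING
domain is 40–60 residues carrying eight metal-ligand (ml) residues that
coordinate two zinc ions in a cross-brace: ml1–ml2 and ml5–ml6 bind one ion,
ml3–ml4 and ml7–ml8 the other. Genome-wide family surveys (such as the flax
RING family, 587 domains in 574 proteins) classify domains into the two
canonical types RING-H2 and RING-HC plus five modified types (RING-v,
RING-C2, RING-D, RING-S/T, RING-G) by the residues at the ml positions, and
characterise the family by spacer statistics, flanking-residue conservation,
domain architectures, duplication ages and phylogeny. `ringscan` implements
that whole analysis as a reusable, tested library and CLI:

- **Scanning** — exhaustive enumeration of ml octuples
  `ml1 x(g12) ml2 x(g23) … x(g78) ml8` under the union of the per-type
  consensus windows (residue sets ml1={C}, ml2={C,S,T}, ml3={C}, ml4={H,C},
  ml5={H,C,D,G}, ml6={C,S,T}, ml7={C}, ml8={C}; spacer windows g12={2},
  g23=[8,33], g34=[1,4], g45=[2,7], g56=[1,2], g67=[1,64],
  g78={1,2,3,4,10}), with deterministic resolution of overlapping candidates.
- **Typing** — the (ml4, ml5) decision tree: (H,H)→RING-H2, (C,H)→RING-v,
  (C,C)→RING-C2, (H,D)→RING-D, (H,G)→RING-G; (H,C) is RING-S/T when ml2 or
  ml6 carries S/T, otherwise RING-HCa (g78∈{1,2}) or RING-HCb (g78∈{3,4}).
  Every call records whether its spacers conform to the assigned type's own
  consensus row.
- **Statistics** — per-ml-pair spacer histograms and anchored
  flanking-residue frequencies (sequence-logo data), e.g. the conserved Trp
  at ml6+4 or Pro at ml7+2.
- **Architecture** — grouping proteins by their non-RING domain signature
  (group 1 = RING only, group 2 = RING + transmembrane segments only,
  further groups by exact signature).
- **Ka/Ks dating** — Nei–Gojobori (1986) synonymous/nonsynonymous rates on
  codon alignments back-translated from protein alignments, Jukes–Cantor
  corrected, with molecular-clock dating T = Ks/(2λ) (λ = 1.5×10⁻⁸
  substitutions/site/year for flax) and recent/ancient age binning.
- **Phylogeny** — neighbor joining on p-distances with pairwise deletion,
  bootstrap supports, newick serialization, and algorithmic clade cuts.
- **Synthetic data** — generators for proteins with planted domains, codon
  pairs with controlled divergence, and alignable families, so every stage
  is testable with known ground truth and no downloads.

## Worked example

```python
from ringscan import (PlantSpec, RingType, plant_domains,
                      enumerate_candidates, classify_arrangement,
                      census, spacer_histograms)

specs = [PlantSpec(RingType.RING_H2, count=5),
         PlantSpec(RingType.RING_HCA, count=3),
         PlantSpec(RingType.RING_V, count=2)]
proteins, truth = plant_domains(specs, seed=42)

calls = [classify_arrangement(a)
         for p in proteins for a in enumerate_candidates(p)]
report = census(calls, proteins)
for t, c in report.type_counts.items():
    if c:
        print(f"{t.value:10s} {c:3d}  {report.percentage(t):6.2f}%")
print("total domains:", report.total_domains,
      "| proteins:", report.total_proteins,
      "| per-protein histogram:", report.domains_per_protein)
profile = spacer_histograms(calls)[0]
print("g12 spacer histogram:", profile.histograms["g12"])
```

prints

```
RING-H2      5   50.00%
RING-HCa     3   30.00%
RING-v       2   20.00%
total domains: 10 | proteins: 10 | per-protein histogram: {1: 10}
g12 spacer histogram: {2: 10}
```

Ten domains were planted (five RING-H2, three RING-HCa, two RING-v), the
scanner found exactly one arrangement per protein, the classifier assigned
the planted types, and — as in every real RING domain — all ten have exactly
two residues between ml1 and ml2.

The same pipeline runs from the shell:

```bash
ringscan simulate domains --seed 5 --out sim/
ringscan run-all --in sim/proteins.fasta --out-dir results/
ringscan tree --in aligned_domains.fasta --bootstrap 100 --seed 42 \
    --out tree.nwk --clades clades.tsv
```

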