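# fossilfit

Placing a fossil fish among extant lineages from skeletal evidence.

Articulated fish fossils preserve only hard parts — vertebral and fin-ray
counts, scales, a handful of skull bones — so locating a fossil cichlid
within the living radiation needs tooling that tolerates mostly-missing
data. `fossilfit` re-implements, as a tested and reusable pipeline, the
computational workflow used to place a middle-Miocene oreochromine cichlid
(†*Oreochromimos kabchorensis*) among modern African cichlid tribes:

1. **Maximum parsimony** on morphological character matrices. A partially
   coded fossil (e.g. 6 of 28 characters observed) is inserted into a
   published NEXUS matrix and scored with Fitch small parsimony, where a
   missing cell behaves as the full state set. Search is exact
   (branch-and-bound, all most parsimonious trees) for small matrices and
   heuristic (random-addition starts + SPR hill climbing + parsimony
   ratchet) otherwise, with strict consensus, ensemble consistency/retention
   indices `CI = m/TL`, `RI = (g−TL)/(g−m)`, and nonparametric bootstrap
   support over characters.
2. **Best-fit trait-range assignment.** Per-tribe (then per-genus) pooled
   character ranges — total vertebrae `Vt`, dorsal/anal fin formulas,
   lateral-line segments `LL`, lacrimal tubules `#Lt`, supraneurals `#Sn` —
   are compared with the fossil's observed values by set intersection; the
   fossil is attributed to the group(s) compatible with **100%** of its
   observed characters, hierarchically from tribe to genus.
3. **Morphometrics.** Measurement standardisation (% of standard or body
   length), scale width/length ratios, fossil-vs-extant size factors, and a
   trend-line classifier assigning oral teeth to inner vs outer rows from
   crown width and body size.
4. **Ordination.** Gower-distance principal coordinates analysis (PCoA) of
   specimen-level meristic tables robust to missing cells, with convex-hull
   overlap summaries per genus.

A synthetic-data module generates clade-structured reference systems,
masked fossils with known ground truth, and character matrices evolved on
known trees, so the entire pipeline is testable without any downloads.

## Worked example

Generate a synthetic reference system (3 tribes × 2 genera × 4 species), a
character matrix evolved on a known 8-taxon tree, and a fossil drawn from
tribe `Tribe01` with 30% of its traits hidden; then run everything:

```bash
fossilfit simulate reference --seed 42 --clades 3 --out refs
fossilfit simulate matrix --seed 7 --taxa 8 --characters 30 --change-prob 0.1 --out sim
fossilfit run --config run.yaml
```

prints

```
fossilfit combined report
seed: 1

[parsimony] matrix
  MPTs: 2  TL: 38  CI: 0.66  RI: 0.58
  consensus: (T00,T02,T05,(T03,(T06,T07,(T01,T04)31)40)50);

[bestfit]
  tribe candidates: Tribe01
  Tribe01 genus candidates: Tribe01_Gen1

[pcoa]
  axes retained: 10; negative eigenvalues: 12
  Tribe00 vs Tribe01: disjoint, centroid distance 0.292
  Tribe00 vs Tribe02: disjoint, centroid distance 0.576
  Tribe01 vs Tribe02: disjoint, centroid distance 0.377
```

Reading the report: the heuristic search found 2 equally parsimonious trees
of length 38 steps; `CI = 0.66` says the matrix carries substantial
homoplasy (observed steps exceed the theoretical minimum by half); internal
node labels on the consensus are bootstrap percentages from 100 character
resamples. The best-fit stage recovers the generating tribe (and genus) as
the sole 100%-compatible candidate — the ground truth recorded by the
simulator was indeed `Tribe01`, genus `Tribe01_Gen1`. The PCoA section
summarises how the three tribes' meristic clusters separate on the first
two coordinate axes.

The packaged data (`fossilfit.datasets`) includes the fossil's printed
trait values and a partial Alcolapia/Oreochromis reference table
transcribed from published range compilations, which reproduce the printed
character-comparison grid (lacrimal depth separates the fossil from
*Alcolapia*; the cleithral notch and flank-scale ratio from *Oreochromis*).

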