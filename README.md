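# polyretain

Tests whether a focal gene class — the motivating case is cold-related genes
(CRGs) in plants — is preferentially retained in collinear, polyploidy-derived
genomic regions, and whether that retention enlarges and stabilises the
class's interaction network.

Whole-genome duplications (WGD, tetraploidy) and triplications (WGT,
hexaploidy) copy every gene; most duplicates are subsequently lost
(fractionation), but retention is not uniform across gene classes.  The
signature of biased retention is readable from gene order: duplicates born in
a polyploidy sit in collinear (synteny) blocks, while tandem, proximal and
dispersed duplicates do not.  `polyretain` implements the full inference
chain on top of simulated polyploid genomes with known ground truth, so every
stage is testable without downloading genomes:

1. **synthetic genomes** (`polyretain.simulate`) — an ancestral genome passes
   through an ordered series of WGD/WGT events with class-biased copy
   retention, single-gene duplication modes, and collinearity erosion by
   inversion; each surviving duplicate pair carries a latent synonymous
   distance (Ks) clustered around its event's age.
2. **homology** (`polyretain.homology`) — family identification
   (E < 1e-10, identity > 60%), anchor filtering (E < 1e-5, top five hits),
   and reciprocal-best-hit orthology with a co-ortholog expansion.
3. **collinearity** (`polyretain.collinearity`) — anchors are chained by
   dynamic programming under a maximal gap of 50 intervening genes; block
   significance comes from a permutation null (uniform anchor redraw at
   matched density), gated at p < 0.05.
4. **duplication typing** (`polyretain.classify`) — every gene gets exactly
   one of singleton / dispersed / proximal / tandem / WGD with precedence
   WGD > tandem > proximal > dispersed.
5. **event attribution** (`polyretain.events`) — blocks are assigned to named
   events (γ, β, α, …) by the Ks window containing their median anchor Ks; a
   gene reduplicated in a younger event is recounted in both events.
6. **enrichment** (`polyretain.enrichment`) — Pearson chi-squared on the 2×2
   of class × collinearity status (1 df), with I/U/D status calls
   (significant increase / unchanged / decrease).
7. **networks & robustness** (`polyretain.network`, `polyretain.robustness`)
   — a reference interactome is projected onto the polyploid gene set by
   equivalent replacement (edge (a,b) induces (x,y) for all orthologs x of a,
   y of b), and robustness is R = C/(N−Nr): the largest-connected-component
   fraction after removing Nr of N nodes at random, averaged over 100 draws.
8. **Ka/Ks** (`polyretain.kaks`) — Nei–Gojobori (NG86) synonymous and
   nonsynonymous site/difference counting with pathway averaging and
   Jukes–Cantor correction; ω = Ka/Ks > 1 flags positive selection.

## Worked example

The numbered drivers under `analysis/` run the canonical study (1200
ancestral genes, 30% focal, events γ/β/α at Ks 1.6/0.8/0.2 with retention
0.9 for focal vs 0.3 for background genes) and write tables under
`results/study/`:

```bash
python analysis/01_simulate_genome.py
python analysis/02_detect_collinearity.py
python analysis/03_classify_duplications.py
```

which prints, among other things:

```
24325 filtered anchors chained into 423 blocks, 345 significant (p < 0.05);
5577 of 6055 genes are collinear
five-way duplication summary:
  singleton     185     3.06%
  dispersed     218     3.60%
  proximal       38     0.63%
  tandem         37     0.61%
  wgd          5577    92.11%
agreement with simulated truth: 0.974
```

92% of genes in this genome are polyploidy-derived (it went through a
hexaploidy and two tetraploidies), and the rank-based classifier recovers
the simulated truth for 97% of genes.  `05_test_enrichment.py` then reports
the focal class at 96.78% collinear against the genome-wide 92.11%
(chi² = 86.9, p ≈ 1e-20, status **I**): the class-biased retention built
into the simulation is detected as a significant collinearity enrichment.
`06_project_networks.py` shows the projected focal network growing from 698
reference interactions to ~77k edges (edge/node ratio 1.99 → 20.79) and
staying at mean R = 1.000 even with half its nodes removed, while the
pre-polyploidy reference drops to 0.771 — the "bigger network, more robust"
ordering.  `07_screen_kaks.py` estimates ω near the simulated purifying
constraint of 0.2 with no spurious positive-selection flags.

The same pipeline is scriptable via the `polyretain` CLI
(`simulate`, `family`, `blocks`, `classify`, `events`, `enrich`, `network`,
`robustness`, `kaks`, `run-all`) or the `run_simulated_study` entry point.

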