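# Methods

## Scope and model

`tcscensus` reconstructs a census of two-component signal transduction
(TCS) proteins — sensor histidine kinases (HKs) and response regulators
(RRs) — from per-protein domain-hit evidence, in the style of the
comparative surveys of archaeal signal transduction. The pipeline has five
analysis stages over a shared data model (1-based, inclusive coordinates
throughout):

1. **Architecture resolution.** Raw domain hits (HMMER3 `domtblout` or a
   headered TSV) are reduced to a linear architecture. Hits are visited in
   order of ascending e-value (ties: descending bit score, then ascending
   start) and accepted iff they overlap every previously accepted hit by at
   most 30% of the shorter of the two. Accepted hits are kept verbatim (no
   boundary trimming); envelope coordinates are used because they bound the
   region that must be masked before novel-domain finding. The complement
   of the accepted segments is the protein's unassigned-gap set. For up to
   eight hits the greedy result provably equals exhaustive application of
   the acceptance rule (tested against an independent residue-set oracle).

2. **Classification.** Each architecture receives exactly one category:
   * no receiver (REC), no HisKA-like, no HATPase-like domain → `not_TCS`;
   * kinase modules without REC: HisKA + HATPase → `HK`; HisKA alone →
     `HisKA_no_HATPase` (kinase-dead, possibly phosphatase-active); HATPase
     with Hpt and/or CheW but no HisKA → `HK` flagged `cheA_like`
     (chemotaxis-kinase organisation); bare HATPase → `HK`;
   * REC together with kinase modules: REC preceding the kinase core →
     `RR`/`REC_HisK`; REC following it → `hybrid_HK`. A REC on both sides
     is counted as an RR with a warning; a REC embedded inside the core is
     counted as a hybrid HK with a warning. "N-terminal" and "C-terminal"
     are decided relative to the kinase-domain positions, not absolute
     residue position;
   * REC without kinase modules → `RR`, subclassified by a fixed output
     priority so the subclasses are disjoint: CheB methylesterase >
     DNA-binding HTH (Bat/HTH_10, LtrR-like, wHTH) > HalX > enzymatic
     output (KaiC-like ATPase, BcsA glycosyltransferase, GGDEF/EAL, PP2C,
     ...) > novel output domain > PAS/GAF-only > stand-alone REC > other.

   A REC accompanied only by an unassigned region of ≥ 70 aa is classified
   `REC_novel_OD`: the 70-aa rule is the same criterion the novel-domain
   screen uses, so "stand-alone REC plus a large unannotated extension" is
   exactly a candidate novel-output-domain regulator, not a CheY-like
   stand-alone REC. Stand-alone output domains without REC (HalX, HalOD1,
   CheB without its receiver, ...) are `not_TCS`: they belong to the domain
   families but are not census HK/RR entries.

   Proteins whose REC segment is shorter than 80 aa, or aligns to < 60% of
   the reference receiver domain, keep their call but acquire an
   `excluded_divergent` flag and are omitted from all census totals.

3. **Novel-domain delineation.** All maximal unassigned regions of ≥ 70 aa
   in REC-containing proteins (plus whole chains of proteins with no
   assigned domains at all — candidate stand-alone copies) are harvested
   and clustered by single linkage. Two regions are linked when a global
   BLOSUM62 alignment with free end gaps (open −10, extend −0.5) covers
   ≥ 70% of the shorter region and the identical residues amount to ≥ 30%
   of the shorter region. Identity is normalised by the shorter region
   rather than by aligned columns deliberately: an optimal alignment is
   free to introduce gaps to chase coincidental matches, and for unrelated
   sequences of similar residue composition the per-column identity of the
   *optimal* alignment routinely exceeds 30%, which under single linkage
   would chain unrelated regions into one family. Families report member
   count, median length, a medoid representative (maximal summed identity
   to the other members) and their architecture contexts with the family
   symbol spliced into the gap.

4. **Receiver-site analysis.** Each REC segment is aligned globally to a
   packaged CheY reference (129 aa, initiator-Met-included numbering, so
   the canonical active site is D12, D13, D57, T87, K109; the FASTA header
   records the convention). The residues at the five positions are read
   off the query, never the reference; coverage is the fraction of
   reference positions aligned. A domain whose identical residues amount
   to < 20% of the reference length is non-alignable: coverage 0, all
   positions gapped, negative verdict. A receiver is predicted
   phosphorylatable iff position 57 is Asp and at least 3 of the 4
   auxiliary positions hold their canonical residues (D/E at 12, D at 13,
   T/S at 87, K at 109). The verdict rule is a package convention (the
   underlying surveys state no formula, only that a large minority of REC
   domains may not be phosphorylated) and is configurable
   (`PhosphorylationRule`). Logo matrices give per-column residue
   frequencies (gaps excluded from the denominator) and information
   R = log2 20 − H in bits, without small-sample correction; with an
   anchor row, columns where the anchor is gapped are dropped first
   (query-anchored trimming).

5. **Census, membrane and neighborhood statistics.** Per-taxon rows count
   genomes, proteins, HKs (hybrids included), RRs, stand-alone-REC RRs
   (with percentage of all RRs) and HTH-subclass RRs; percentages are
   rounded to the nearest integer, half away from zero; zero counts render
   as an em dash. The totals row is the column-wise sum of the taxon rows.
   Per-genome statistics include the RR/HK ratio and the TCS share of
   ORFs, plus Pearson and Spearman correlations of TCS count against
   genome protein count. Membrane localisation uses supplied TM tables or,
   as a fallback, Kyte–Doolittle hydropathy (window 19, mean > 1.6,
   overlapping windows merged); `HisKA_no_HATPase` proteins are excluded
   from the kinase denominator and reported separately. Gene neighborhoods
   use a distance/strand heuristic in place of curated operon databases:
   adjacent co-oriented genes ≤ 200 nt apart are `same_operon_adjacent`
   (intergenic distance = start(downstream) − end(upstream) − 1); adjacent
   head-to-head genes (−,+ in coordinate order) are `divergent`. A
   stand-alone-REC RR within 5 genes of a CheA-type kinase or a CheB
   regulator on the same operon run is flagged `chemotaxis_associated`.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| overlap tolerance | 0.30 | fraction of shorter hit | clan-style overlaps are common |
| min unassigned region | 70 | aa | the one threshold fixed by the underlying survey methodology |
| clustering identity | 0.30 | fraction of shorter region | conventional remote-homology screen |
| clustering coverage | 0.70 | fraction of shorter region | |
| min REC length | 80 | aa | below → `excluded_divergent` |
| min REC reference coverage | 0.60 | fraction | below → `excluded_divergent` |
| rec-site identity floor | 0.20 | identical/reference length | below → non-alignable |
| TM window / cutoff | 19 / 1.6 | aa / mean hydropathy | Kyte–Doolittle fallback |
| operon max gap | 200 | nt | |
| neighbor window | 5 | genes | chemotaxis association |

All are exposed as function arguments and, where relevant, CLI options;
only the 70-aa rule should be regarded as fixed by the methodology.

## Synthetic data

The generator emits complete pipeline inputs (hit table, FASTA, GFF3, TM
table) plus a truth table, from a single seed (NumPy `default_rng`; same
profile + seed ⇒ byte-identical outputs). Three packaged lineage profiles
encode the contrasts the analysis is meant to resolve; their architecture
mixes were set from the printed per-lineage census structure and are the
study conditions, not tuning knobs:

* *haloarchaea-like*: REC-only ≈ 23% of RRs, abundant REC–HalX and
  Bat-type REC-PAS-GAF-BAT-HTH_10 regulators, HalOD1 fusions, HisKA_7TM
  sensors, frequent chemotaxis operons;
* *methanogen-like*: REC-only ≈ 43% of RRs, REC-(PAS)n regulators, hybrid
  HKs (~6% of kinases), MEDS/Cache sensors, DUF835/KaiC-like enzymatic
  outputs, elevated tandem duplication;
* *thaumarchaea-like*: REC-only ≈ 77% of RRs, NitrOD/TackOD novel-domain
  regulators, divergently transcribed REC-only/ArsR-type gene pairs.

Across profiles the kinase mixes put PAS and/or GAF on ~72% of HKs (~15–20%
both) and plant transmembrane helices on 38% of kinases, so the cytoplasmic
fraction is ~62%.

Sequence realisation: receiver domains derive from the packaged CheY
reference by i.i.d. substitution at 0.12/site with the five active-site
positions protected; a planted non-phosphorylatable receiver (rate 0.15)
carries D57→N; a planted truncated receiver (rate configurable, default 0)
is cut to 50 aa. Every non-REC domain family gets one per-run consensus
from which copies mutate at 0.10/site; planted novel-domain families use
their configured within-family identity (0.88–0.90 by default). Linkers
and generic domains are drawn from hydrophilic-biased residue models so
spurious hydropathy windows stay below the TM cutoff; transmembrane plants
are 21-residue hydrophobic runs. Filler (non-TCS) proteins carry one
generic annotation hit over most of the chain, emulating an annotated
proteome; consequently the only proteins with no hits at all are the
planted stand-alone novel-domain copies. Operons, tandem duplicates and
divergent pairs are laid out as adjacency blocks with small intra-block
intergenic gaps (40–190 nt) and large inter-block gaps (250–900 nt), so
planted operon runs are exactly the runs the neighborhood stage detects.

What the generator does **not** emulate: real archaeal codon usage or GC
content, phylogenetic correlation between genomes, hit-coordinate noise,
missed or spurious domain calls, domain-boundary ambiguity, and
compositional drift between lineages. Passing the recovery tests therefore
shows the pipeline's logic is correct under clean, well-calibrated
annotation — not that a real annotation run would be error-free.

## Numerical choices and degenerate inputs

Greedy tie-breaking (e-value, −score, start) makes resolution
deterministic and input-order invariant. Percent rounding is
half-away-from-zero to match printed-table conventions. Zero-RR taxa yield
NaN percentages (rendered as a dash), never a division error. Gap-only
logo columns report information 0 with a warning. Empty hit files parse to
empty lists; proteins without hits resolve to a single whole-chain gap.
Correlations are reported as NaN below three genomes or for constant
columns. The hybrid/REC-HisK identity (every REC+HisKA+HATPase protein is
exactly one of the two, ambiguous placements warned) is property-tested.

## Scale of the shipped experiments

Default profiles: 4 genomes × 500–800 proteins per lineage. The test
suite runs reduced instances (2 genomes × 60–250 proteins per profile,
~1,200 proteins for the end-to-end suite). The acceptance script runs 6
genomes × 250–400 proteins per lineage (~6,000 proteins), chosen to give
≥ 80 regulators per lineage so the lineage REC-only percentages are
estimated to within a few points. These sizes were fixed once, before the
recovery statistics were inspected.

## Known limitations

* The classifier is architecture-level only: no HK subfamily typing
  (HisKA vs HisKA_2 vs HWE), no phosphorelay reconstruction.
* Clustering is O(n²) pairwise alignment; it is intended for the tens to
  hundreds of regions a regulator-focused screen yields, not whole
  proteomes.
* The domain-role dictionary ships with the vocabulary of the archaeal TCS
  literature; unknown names default to role `unknown` (treated as
  candidate novel domains), so an incomplete dictionary biases toward
  `REC_novel_OD` rather than toward silent misclassification.
* The operon heuristic (strand + ≤ 200 nt) is a stand-in for curated
  operon databases and will split operons with long intergenic spacers.
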