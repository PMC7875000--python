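# Methods

`mhcscan` estimates the copy number and genomic arrangement of MHC class I
and class II loci from a genome assembly, using degenerate consensus probes
and a three-exon proximity rule, and reproduces the comparative statistics
of the 34-species long-read (TGS) bird survey from a packaged count table.
This note records the model, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## The scan

**Consensus queries.** Public MHC exon sequences (exons 2–4 of class I and
II; shorter exons are excluded below 100 bp) are clustered sequentially:
within species at ≥85% identity, within taxonomic order at ≥80%, and across
all orders at ≥50%. Clustering is greedy centroid (UCLUST-style): sequences
are visited longest-first, each joins the first established representative
it matches at the threshold, otherwise it founds a new cluster. One random
member represents each species-level cluster (seeded RNG, default seed 1).
Each terminal cluster is collapsed into one IUPAC consensus: the member
species representatives are multiply aligned (MAFFT), columns gapped in at
least half the members are dropped, and each remaining column emits the
degenerate code covering every base at within-column frequency
≥ `consensus_inclusion_fraction` (default 0.25; the majority base is always
included). Degenerate positions let one probe match diverged paralogs; a
consensus is rejected if more than half its positions are degenerate.

**Pairwise identity.** Identity is matches / aligned columns of a global
affine-gap alignment, terminal gap columns excluded, degenerate-compatible
codes counting as matches. Two scoring regimes are used deliberately:

* local search extension: match 2, mismatch −3, gap open −5, gap extend −2;
* global identity for clustering: match 2, mismatch −3, gap open −10, gap
  extend −6.

The stiffer gaps in the identity regime are essential. When a gap column
(−2) is cheaper than a mismatch (−3), the score-optimal global alignment of
two *divergent* sequences degenerates into gap shuffling and its identity
saturates near 0.52 even for unrelated random DNA — above the 50%
across-order threshold, which would then merge everything. With gaps dearer
than mismatches, random 270-mers align at ≈0.40 identity and the threshold
ladder behaves as intended.

**Homology search.** Seed-and-extend on both strands: exact matches of
`word_size` = 11 seeds (degenerate words expanded up to 64 ways; words
beyond the cap are skipped and recovered by neighbouring seeds), seeds are
grouped into candidate windows (padding ≈ max(50, query/4)), and each
window is resolved by an exact Smith–Waterman alignment of the query
against the window. This replaces heuristic x-drop truncation: the window
bounds how far an alignment can reach past its seeds, and within the window
the DP is optimal, so on test instances the hit set equals a full-matrix
local DP scan of the whole contig. Hits qualify at identity ≥ 0.75
(comfortably below the 83–95% probe-to-target similarity this family
shows) and query coverage ≥ 0.5; tandem copies inside one window are found
by recursing into the flanks of each accepted alignment. Hits carry their
gap-free alignment runs and the full query length for downstream frame
reconstruction. Hits of the same class and exon that reciprocally overlap
≥ 50% (e.g. two probes matching the same genomic exon) are collapsed to the
highest-identity hit. An external tabular search tool (e.g. `blastn
-outfmt 6`) can replace the built-in engine via a command template; the
12-column dialect is parsed into the same hit objects.

**Locus calling.** A locus is a chain of exon-2, -3 and -4 hits of one
class, on one contig and strand, with every consecutive gap (end of one hit
to start of the next) at most 2000 bp, *inclusive* — the "within 2 kb" rule
is read as consecutive-exon gaps, matching the intron spacing that
motivated it; an all-pairs reading is available behind a flag, as are
toggles for the strand and gene-order (2→3→4 on plus, 4→3→2 as encountered
on minus) requirements. Chaining is greedy left-to-right with backtracking:
the leftmost unused hit that can start a chain is completed by the nearest
downstream hit of each expected label, trying farther candidates on dead
ends; only complete chains consume hits. On 1,000 random small instances
this greedy count equals the exhaustive maximum-disjoint-chains optimum.
Hits left over are grouped by proximity into partial clusters labelled
`missing_exon`, `gap_exceeded` (the missing exon exists on the contig but
out of range) or `strand_conflict`; genomes with only partials count zero
loci.

**Pseudogene screening.** The peptide-binding exon (exon 3 of class I,
exon 2 of class II) is translated and scanned for premature TAA/TAG/TGA.
Because a local alignment may (a) trim mismatch-rich exon ends and (b)
dodge a mismatch *triplet* — which is exactly what a substituted stop codon
is — with a net-zero pair of 1-bp gaps (−10 beats −9 under the local
scoring), the screen does not follow the alignment path literally. Instead
it reconstructs the full exon window (extending the hit by the unaligned
query prefix/suffix) and translates it in the register of the alignment's
*longest* gap-free run. Micro-indels are thereby treated as alignment
artefacts; genuine frameshifts are deliberately not counted as pseudogene
evidence — only stop codons are. Counts are reported in the
`total(n_stop)` convention.

**Structure analysis.** Contigs with ≥2 called loci are the unit of
arrangement analysis. Duplicated blocks come from a self-dotplot: all
off-diagonal exact word matches (word 10; direct on constant j−i, inverted
on constant i+j), split into diagonal bands (offset jitter ≤ 50 bp), then
chained along each band with gaps ≤ 200 bp; chains spanning ≥ 2000 bp are
blocks. At 10-mer words, ≈5% divergence between copies still leaves ~60%
of words intact, so chains bridge diverged paralogs while chance matches
(rate 4^-10, ≈50 scattered pairs per 10 kb) never chain into blocks. Each
block is classified by the locus classes present in both of its spans
(≥80% of a locus span inside the block span): both classes in both copies
is co-duplication, one shared class is a class-specific duplication.
Flanks of ±10 kb per locus are exportable for external annotation, and a
plot-ready arrangement TSV replaces any figure-rendering contract.

## Comparative statistics

All statistics run over `SpeciesLocusRecord` tables (the packaged table or
a fresh run's counts substituted into it): Pearson r with t-distributed
two-sided p (missing published counts dropped pairwise, never imputed),
Spearman rho (mean ranks on ties), group medians, and the two-group
Mann–Whitney reported as the tie-corrected Kruskal–Wallis chi-square with
df = 1 — the parameterisation under which the published chi-square values
reproduce. The matched-pairs signed rank follows the same stats-package
convention the published values use: absolute differences are ranked with
zeros kept in the ranking (Pratt), zeros contribute no signed rank, and
S = (W⁺ − W⁻)/2; the plain positive-rank sum over nonzero differences is
reported alongside. The two species dropped from the "excluding outliers"
correlation are chosen generically as the two largest published-vs-
predicted class II disagreements (zebra finch and common yellowthroat on
the packaged table). One computed value knowingly differs from its printed
counterpart: the overall class II median over the 34 predicted counts is
3.0, not 3.5 (the class I median is 3.5); the table is stored as printed
and the statistic is reported as computed.

## The synthetic-data generator

The generator is the package's test instrument: it emulates exactly the
statistical structure the scan assumes, with complete ground truth.

* **Loci**: `n_class_I` = 5 and `n_class_II` = 13 by default (a
  passerine-like class II excess), distributed ~5 per contig. Exon lengths
  follow the class templates (e.g. class I e2/e3/e4 = 270/276/276 bp);
  templates are random coding sequence at GC 0.45, stop-free in frame 0.
* **Divergence**: planted exons differ from the templates by i.i.d.
  per-base substitution at 0.08 — inside the 83–95% similarity band the
  probes show against real targets. Substitution-created stops in the
  screening exon of non-pseudogene loci are re-rolled so truth flags stay
  exact. No indels by default; an indel mode (rate per base, geometric
  lengths) exists to exercise alignment robustness but is excluded from
  exact-recovery claims.
* **Introns/spacers**: introns 200–1800 bp so loci are callable under the
  2 kb rule with margin (a config with longer introns warns — that is the
  stress mode for partial-cluster paths); intergenic spacers 5–20 kb keep
  neighbouring loci unambiguous.
* **Pseudogenes**: a fraction (0.2) of loci per class, rounded
  deterministically, receive one forced in-frame stop at a random internal
  codon of the screening exon; the truth table records the position.
* **Duplication modes**: `tandem_classII` plants one class II locus unit
  (locus + 1 kb spacer, ≥2 kb total) in 3 tandem copies; `co_duplication`
  plants a [class I + class II] cassette likewise. Copies diverge at 0.02
  so block detection must chain through mismatches.
* **Fragmentation**: `ngs_like` splits every contig into 1–8 kb fragments,
  so a ~3 kb locus frequently straddles a break — reproducing, at
  assembly level, why short-read assemblies undercount MHC loci.
* All randomness flows from one `numpy` generator per config seed; the
  same config and seed reproduce the FASTA byte for byte.

The hierarchical exon corpus for consensus tests radiates from one root:
order ancestors at 0.45 per-lineage divergence (between-order identity
saturates near 0.35, safely below the 50% threshold), species at half the
within-order target (pairwise ≈ 0.88 ≥ 0.80), leaves at half the
within-species target (pairwise ≈ 0.97 ≥ 0.85).

**What passing these tests shows — and does not.** Exact recovery on 50
seeded genomes shows the chain of consensus matching, chaining and
screening is internally consistent under the stated conditions
(substitution-only divergence ≤ ~0.10, introns ≤ 1.8 kb, clean assemblies).
It does not show field accuracy on real genomes: real MHC regions carry
repeats, low-complexity tracts, alternative exon structures, allelic
variation and assembly artefacts that the generator deliberately omits.
The genome-derived counts of the published survey (e.g. 193 class II loci
in the golden-collared manakin) require the original multi-gigabase
assemblies and are not recomputed here; the packaged table carries them as
data, and the statistics layer reproduces every printed headline statistic
from it.

## Problem sizes and runtime choices

Default simulated genomes are ~300 kb over 4 contigs (18 loci) — large
enough for realistic spacing, small enough that a full
simulate→search→call→screen cycle takes ~2–3 s. The test suite runs the
recovery property over 50 seeds, the aligner-versus-full-DP comparison over
200 contig/query pairs (2–5 kb contigs), the chaining oracle over 1,000
instances, duplication recovery over 25 replicates and the
fragmentation contrast over 20 seeds; `scripts/acceptance.py` re-runs the
same computations at 25/10/10 replicates. These sizes were chosen so each
property is measured at, or above, the replication its contract states
while the whole suite stays in the minutes range.

## Known limitations

* Search is nucleotide-space only; no translated search, no HSP chaining
  across introns (the locus caller owns cross-intron logic), no e-values
  (ranking uses raw score and identity; locus calling depends on presence
  and position, not significance).
* The pseudogene screen reads one reading frame per exon (the dominant
  alignment register); exons whose true frame changes internally
  (compound indels) are screened only in that register, and frameshifts
  are not pseudogene evidence by design.
* Greedy chaining is verified optimal on random small instances, not
  proven optimal in general; pathological shared-exon layouts could in
  principle differ from the exhaustive optimum.
* Classification of classical vs nonclassical loci, flanking-gene
  annotation and phylogenetically controlled comparative analyses are out
  of scope; flank extraction and the arrangement TSV are the hand-off
  points to external tools.
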