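# mhcscan

Counting and mapping MHC class I and class II loci in bird genome
assemblies.

The Major Histocompatibility Complex is one of the most duplicated gene
families in vertebrates, and in birds — passerines especially — the number
of class I/II paralogs varies enormously between species. Short-read
assemblies collapse these near-identical copies, so copy numbers from them
(or from PCR-based population studies) are unreliable lower bounds.
Long-read (TGS) assemblies resolve the duplications, and a simple,
reproducible scan can then count loci directly. `mhcscan` implements that
scan for researchers studying immune-gene family evolution:

1. **Consensus probes** — public MHC exon sequences (exons 2–4, the
   peptide-binding region and its neighbours) are clustered hierarchically
   (within species ≥85% identity, within order ≥80%, across orders ≥50%)
   and each terminal cluster is collapsed into a degenerate IUPAC consensus
   query, so a handful of probes match diverged paralogs family-wide.
2. **Homology search** — a built-in seed-and-extend local aligner (exact
   Smith–Waterman on seed-bounded windows, degenerate-aware, both strands),
   or any external tool emitting the standard 12-column tabular format.
3. **Locus calling** — a locus is a colinear chain of exon-2, -3 and -4
   hits of one class with every consecutive gap ≤ 2 kb (the intron spacing
   of annotated MHC genes); anything less becomes an annotated partial
   cluster, not a locus.
4. **Pseudogene screening** — the peptide-binding exon (exon 3 of class I,
   exon 2 of class II) is translated in the frame established by the hit
   and premature stop codons are reported, giving counts in the
   `total(n_stop)` convention.
5. **Duplication structure** — self-dotplot word matching chains
   off-diagonal runs into duplication blocks, classified by whether the two
   copies share class I loci, class II loci, or both (co-duplication).
6. **Comparative statistics** — Pearson/Spearman correlations of predicted
   vs previously published counts, group medians, Mann–Whitney chi-squares
   and signed-rank tests over the packaged 34-species TGS survey table.

A fully seeded synthetic-genome generator plants MHC-like loci (controlled
divergence, intron lengths, pseudogenes, tandem/co-duplication cassettes,
short-read-like fragmentation) with complete ground truth, so every stage
is testable offline without downloading a genome.

## Worked example

Simulate a small genome with 3 class I and 5 class II planted loci, search
it with the generator's template probes, and call loci:

```bash
$ mhcscan simulate --out-prefix sim --seed 7 --n-class-i 3 --n-class-ii 5
wrote 2 contigs, 8 truth loci

$ mhcscan search --queries sim.queries.fasta --genome sim.fasta --out hits.tsv
wrote 24 hits to hits.tsv

$ mhcscan call-loci --hits hits.tsv --genome sim.fasta \
      --out loci.gff3 --summary summary.tsv
class I: 3(1)  class II: 5(1)
```

All 24 exon hits (8 loci × 3 exons) are recovered and chained into exactly
the 8 planted loci; `3(1)` means three class I loci of which one carries a
premature stop codon in its peptide-binding exon — here, exactly the
pseudogenes the simulator planted. `loci.gff3` records each locus and its
exon hits with class, strand and stop-codon positions.

The statistics layer reproduces the published survey's headline numbers
from the packaged table:

```bash
$ mhcscan stats --fixture --out stats.tsv && head -6 stats.tsv
statistic	value	n	p_value	groups
classII_published_vs_predicted_r	0.635866	12	0.0262508
classII_published_vs_predicted_r_excl_outliers	0.770693	10	0.00907527
classII_published_vs_predicted_nostop_r	0.662841	12	0.0188135
classI_published_vs_predicted_r	0.634395	6	0.176066
classI_vs_classII_spearman_rho	0.59011	34	0.000239419
```

Read: across the 12 species with prior class II estimates, the scan's
counts correlate with the published ones at r = 0.64 (P = 0.026), rising
to 0.77 after dropping the two largest disagreements and to 0.66 after
excluding stop-codon loci; class I and class II counts covary across all
34 species (rho = 0.59, P < 0.001).

`mhcscan run-all --config run.yaml` executes consensus → search →
call-loci → structure as one run with a checksummed manifest; see
`mhcscan --help` for the other subcommands (`consensus`, `structure`,
`simulate`).

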