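# gapmend

Reference-guided gap patching and quality control for chromosome-level
genome assemblies.

Chromosome-scale assemblies built from a single read technology usually
retain runs of `N` (gaps) where the backbone contigs could not be joined.
When a second assembly of the same species exists — for example an ONT-based
assembly of a second individual next to a HiFi-based backbone — its contigs
can patch those gaps, producing a *consensus* assembly that is gap-free on
most or all chromosomes. `gapmend` implements that reconciliation step and
the quality checks that make it trustworthy, for assembly curators who have
two assemblies and a whole-genome alignment between them:

* **gap filling** — locate every N-run, anchor donor contigs to its flanks
  through PAF or MUMmer `show-coords -rTH` alignments, splice the donor
  sequence in, and emit the patched FASTA together with an AGP, a BED of
  patch intervals, a per-gap report and a coordinate liftover map;
* **validation** — read-depth checks across every patch junction, a
  reference-free k-mer quality value, and a homozygous-variant error rate;
* **annotation** — telomere calls from terminal TTAGGG/CCCTAA density, a
  tandem-periodicity centromere-candidate scan, and telomere-to-telomere
  (T2T) classification per chromosome;
* **synteny** — chaining of filtered alignments into colinear blocks,
  coverage/identity summaries, and detection of chromosome fusions (one
  chromosome syntenic to two chromosomes of a related species);
* **simulation** — seeded generators for truth genomes with planted
  telomeres, centromeres, gaps, divergent donor assemblies and fusions, so
  the whole pipeline is testable without any external data.

## The method in brief

**Gap filling.** For a gap `[s, e)` on chromosome `c`, an alignment whose
target interval ends within `flank_window` of `s` is a *left anchor*; one
starting within `flank_window` of `e` is a *right anchor*; one covering both
flanks *spans* the gap. A spanning alignment is used directly: the donor
interval is the image of `[s, e)` under the alignment's coordinate map
(linear interpolation between endpoints). Otherwise the best-scoring
concordant anchor pair (same donor contig, same strand, donor-colinear)
brackets the gap, and the donor endpoints are extrapolated from the anchor
endpoints to the gap edges. The patch replaces the N-run
(reverse-complemented for `-` orientation); a negative donor span is
resolved by trimming up to `trim_cap` flank bases per side. Every failure
mode (missing anchor, discordant anchors, oversized span, unresolvable
overlap) is a status in the report, never a silent skip.

**One-to-one filtering.** Following the `delta-filter -l 200 -1` idiom,
alignments below a length or identity floor are dropped and a
maximum-total-score subset is selected such that no accepted record overlaps
another on target or query beyond `max_overlap_frac` of its own length
(exact selection per conflict component, greedy fallback for very large
components).

**k-mer QV.** With canonical k-mer sets `A` (assembly) and `R` (reads),
shared fraction `s = |A ∩ R| / |A|` gives per-base error
`E = 1 − s^(1/k)` and `QV = −10·log₁₀(E)`, capped when every k-mer is
shared. At `s = 0.5, k = 21`: `QV = 14.89`.

**Fusion detection.** After chaining, the union coverage of each target
chromosome is attributed to query chromosomes; a fusion is supported when at
least two query chromosomes each cover ≥ `min_frac_each` (default 20%) of
the target.

## Worked example

Simulate a small two-individual setting (two 200-kb chromosomes, two gaps
each, donor at 1% SNP divergence), then fill the gaps and inspect:

```sh
$ gapmend simulate --preset small --seed 3 --divergence 0.01 --out sim
$ gapmend gaps --fasta sim/target.fasta --bed gaps.bed
4 gaps -> gaps.bed

$ gapmend fill --target sim/target.fasta --donor sim/donor.fasta \
    --aln sim/alignments.paf --out filled
gaps found:    4
gaps filled:   4
gaps unfilled: 0
residual gaps per chromosome:
  chr01	0
  chr02	0

$ gapmend stats --fasta filled.fasta | grep -E 'n_gaps|gap_free'
  "n_gaps": 0,
  "gap_free_chrom_count": 2

$ gapmend telomeres --fasta filled.fasta | head -3
chrom	end	present	motif_copies	best_window_density	window_start	window_end
chr01	5prime	1	503	1.0000	0	500
chr01	3prime	1	501	1.0000	197000	197500
```

All four planted gaps were closed (the donor's true alignments place one
contig pair around each gap), the patched assembly is gap-free on both
chromosomes, and both chromosome ends carry dense telomere arrays — i.e.
both chromosomes are now T2T. `filled.report.tsv` records per gap the donor
contig, patch length, orientation and anchor identities;
`filled.liftover.json` maps pre-patch coordinates to the patched assembly.

The same operations are available as library functions
(`gapmend.fill_gaps`, `gapmend.kmer_qv`, `gapmend.detect_fusions`, ...); the
CLI is a thin wrapper.

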