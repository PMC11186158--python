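# Methods

This note documents the models, parameter choices and numerical conventions
behind `gapmend`, and what the simulation-based tests do and do not
demonstrate about real data.

## Coordinates and formats

All coordinates are 0-based half-open internally. BED shares that
convention; AGP (1-based inclusive) and the MUMmer `show-coords` dialect
(1-based inclusive, reverse strand encoded as `S2 > E2`) are converted at
the parsing/serialization boundary only. PAF is consumed as-is (its
coordinates are already 0-based half-open, query coordinates on the forward
strand). The `show-coords -rTH` dialect carries no raw match count, so
matches are back-computed as `round(%IDY/100 · max(LEN1, LEN2))`; identities
round-trip, match counts are approximations bounded by the printed identity
precision.

A *gap* is a maximal run of `N`/`n` of length ≥ `min_gap_len` (default 1:
every N-run counts, matching how assembly reports count raw gap numbers).
Soft-masked lowercase passes through all sequence surgery verbatim; IUPAC
ambiguity codes other than N are ordinary bases and are excluded from both
numerator and denominator of GC content, which is defined over unambiguous
bases.

## Alignment filtering

The filter mirrors a `delta-filter -l <len> -1` pass: drop records below the
length/identity floors, then select a one-to-one subset. Selection maximizes
total score subject to: no accepted record's target (or query) interval is
covered by other accepted records on the same sequence beyond
`max_overlap_frac` of its own length (union semantics). The optimum is
computed exactly per connected conflict component up to 14 records
(exhaustive subset search; components are small in practice because
conflicts require physical overlap) and greedily in descending score order
beyond that, with deterministic tie-breaks (longer block, then name and
position). An exact optimum was preferred over pure greedy selection because
greedy provably misses configurations where one high-scoring alignment
blocks two jointly better ones; the exact/greedy threshold trades
completeness against worst-case cost on pathological piles of mutually
overlapping alignments.

Score defaults to the match count; a PAF `AS` tag overrides it when present.

## Gap filling

Tunable parameters, all exposed as flags:

| parameter | default | meaning |
| --- | --- | --- |
| `flank_window` | 5 kb | how far from the gap edge an anchor alignment may end |
| `min_anchor_len` | 1 kb | minimum anchor block length |
| `max_patch_len` | 5 Mb | largest donor interval spliced in |
| `trim_cap` | 1 kb | flank bases removable per side to resolve donor overlap |

These are typical gap-closer magnitudes: anchors shorter than ~1 kb are
unreliable in repeat-rich flanks, and patches beyond a few megabases suggest
a mis-join rather than a gap.

Spanning alignments are preferred over anchor pairs; among pairs the summed
anchor score decides, with ties broken toward the smaller donor span and
then lexicographic donor name, for determinism. Coordinate projection
through an alignment uses linear interpolation between its endpoints — the
coords dialect carries no CIGAR — so projected donor endpoints can be off by
the local indel imbalance; this is acceptable for patch extraction because
junctions are re-validated by read depth downstream. When an anchor stops
short of the gap edge, the donor endpoint is extrapolated across the
unaligned stretch assuming local colinearity (the alternative — splicing
from the anchor endpoint — would duplicate the unaligned flank bases).

A negative donor span means the two anchors' donor images overlap into the
retained target flank (typically a deletion in the donor relative to the
flank). Each trimmed flank base widens the donor span by one; the deficit is
taken from the right flank first, then the left, each capped at `trim_cap`;
a larger deficit yields status `donor_overlap_unresolvable`. Patches are
spliced right-to-left per chromosome so earlier coordinates stay valid;
patched bases are uppercased (they are new consensus sequence), surrounding
case is preserved; junction positions are recorded in new coordinates.

The liftover map stores retained old-coordinate segments with their new
starts; positions inside removed N-runs or trimmed flanks report as deleted.
Monotonicity on retained positions follows from the construction and is
property-tested anyway.

## Telomeres, T2T, centromere candidates

Telomere calls count non-overlapping exact copies of TTAGGG and CCCTAA in
the outermost `end_window` = 10 kb, and take the maximum motif-covered
fraction over sliding `scan_window` = 500 bp windows; a call is positive at
density ≥ 0.4. The window/threshold pair is chosen so that a terminal array
of 50 hexamer copies (300 bp, the smallest array the recovery tests plant)
reaches density 0.6 while random sequence stays near 2·(1/4)⁶·6 ≈ 0.003;
degenerate motif variants are deliberately not counted. A chromosome is T2T
iff it has zero gaps and positive calls at both ends.

The centromere scan is an intentionally simple periodicity detector, not a
reimplementation of dedicated satellite pipelines: position *i* is "periodic"
if its 21-mer last occurred `d` bases upstream with `d` in
`period_range` = [100, 2000]; the candidate is the longest run where the
centered 10-kb moving average of that indicator stays ≥ 0.5, reported with
the modal spacing as monomer period. Centered smoothing keeps the reported
interval boundaries within ~half a monomer of the true array edges. It
detects clean tandem arrays (what the simulator plants); diverged
higher-order repeat structure in real centromeres will depress the
periodicity indicator and can fall below threshold.

## Validation

The k-mer QV uses distinct canonical k-mers (k = 21, packed 2-bit integers):
shared fraction `s` gives `E = 1 − s^(1/k)`, `QV = −10·log₁₀E`, capped at
99 when no assembly k-mer is missing from the reads. Only the method family
is standard; this implementation uses presence/absence rather than
multiplicities, the simplest faithful estimator at desk scale, and its
calibration is verified against planted single-base errors (each isolated
error removes exactly k shared k-mers, so `E ≈ m/G` for m errors on G
bases; the tests require agreement within 20%).

Junction checks take the minimum depth over `[pos − w, pos + w]` (w = 50 bp,
clipped at chromosome ends) against a depth floor (default 1: the criterion
is "completely covered"). Depth input is samtools-depth TSV or per-base
BEDGRAPH. The homozygous-variant rate counts first-sample `1/1`‖`1|1`
records with QUAL ≥ 30 and DP ≥ 5 (all flags), divided by assembly size;
records without GT are skipped and tallied.

## Synteny and fusions

Chaining merges alignments of one (target, query, strand) group when target
and query gaps to the previous member are both ≤ `max_chain_gap` = 100 kb
and query starts are monotone in the strand's direction; blocks shorter than
`min_block_len` = 10 kb are discarded. Defaults suit mammal-scale
chromosomes; sequence-level chaining only (gene-anchored microsynteny is out
of scope). Coverage summaries use interval unions. Fusion support requires
two or more query chromosomes each covering ≥ 20% of a target chromosome —
permissive enough for unequal fusion partners, strict enough that scattered
repeat-driven cross-mappings (a few percent each) never qualify.

## The simulator

The generators emulate the two-individual consensus setting: per
chromosome, a telomere array (500 hexamer copies by default), a random core
at GC 0.42 (a typical cervid genome-wide GC), a centromeric array (171-bp
random monomer — the classic mammalian satellite monomer length — repeated
to 50 kb, each copy receiving one random substitution with probability 1%),
and the mirrored telomere array. Defaults of five 1-Mb chromosomes with five
200–2000 bp gaps each define the round-trip study conditions used by the
acceptance checks; the donor is fragmented into 100–300 kb contigs,
reverse-complemented with probability 0.3, at configurable SNP divergence
(0 and 1% in the tests).

Gaps avoid telomere/centromere arrays and keep 2·`gap_margin` (20 kb)
separation; donor fragmentation breakpoints keep `gap_margin` away from gap
edges so every gap is spannable by default — tests exercise the failure
statuses directly with constructed anchor geometries instead. True
alignments are emitted from provenance, exact by construction (substitutions
only, no indels), so no aligner runs in the tests.

A single global seed fans out to per-component substreams
(`default_rng([seed, component, index])`), so adding a generator never
perturbs another's output.

**What passing tests show — and don't.** The simulations contain SNP-level
divergence but no indels, no segmental duplications and no repeat-driven
alignment ambiguity beyond the planted satellite. Byte-exact round-trip
recovery therefore validates the coordinate arithmetic, orientation
handling and bookkeeping of the pipeline, not its robustness to noisy
real-world alignments; on real data the per-gap statuses and junction-depth
checks are the intended safety net.

## Known limitations

* Projection through an alignment ignores indel structure (no CIGAR in the
  coords dialect); donor endpoints can shift by the local indel imbalance.
* The exact one-to-one selector falls back to greedy above 14-record
  conflict components.
* The centromere scan reports the longest candidate only, and assumes a
  largely homogeneous array.
* One donor assembly per run; with several donors, run the tool once per
  donor in priority order.
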