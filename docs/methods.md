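# Methods

## The neutral ORF-decay model

`simulate_decay` models a retrocopy's reading frame evolving free of
selection. Three independent mutation processes act on a sequence of
current length *L*: substitutions, 1-bp insertions and 1-bp deletions, each
with a per-site per-generation rate. Time advances in census intervals of
Δ years (default 50,000); within an interval the number of events of each
type is Poisson with mean rate·L·Δ/*g* (*g* = generation time in years),
events are applied in random order at uniformly chosen positions, and *L*
is updated between intervals. At every census the sequence is re-evaluated
for **intactness**:

* its length equals the starting length (any un-compensated indel fails
  this immediately — 1 bp is the minimal frameshifting unit);
* it begins with ATG (a destroyed start codon counts as loss; toggleable
  via `SimulationConfig.require_start_codon`);
* no in-frame stop codon (TAA/TAG/TGA) occurs strictly before the final
  complete codon. When the length is not a codon multiple (the default
  1,150 bp starting ORF is 383⅓ codons) the trailing partial codon can
  never hold a stop.

Intactness is *not* latched: a sequence that reverts (a back-substitution,
or an insertion compensating a deletion) counts as intact again at the next
census. Reversions are vanishingly rare at realistic rates but the
semantics are those of a mutate-then-scan loop.

Model simplifications, chosen deliberately: the substitution model is
Jukes–Cantor-like (uniform site choice, uniform alternative base), with no
CpG/context effects and no codon-usage awareness; indels have no length
distribution because the published rates are scalar per-site rates. Both
choices bias the survival curve slightly *upward* if anything (transition
bias raises the stop-gain fraction), so the retention test stays
conservative for its purpose of bounding neutral survival from above.

### Parameter presets

| preset | μ_sub | μ_ins | μ_del | g (yr) |
|---|---|---|---|---|
| human-like | 1.16×10⁻⁸ | 2×10⁻¹⁰ | 5.5×10⁻¹⁰ | 25 |
| mouse-like | 5.4×10⁻⁹ | 1.55×10⁻¹⁰ | 1.55×10⁻¹⁰ | 0.3 |
| nwm-like | 8.1×10⁻⁹ | 1.55×10⁻¹⁰ | 1.55×10⁻¹⁰ | 1 |

Rates are per site per generation. The New World monkey set combines the
night-monkey substitution rate with the mouse indel rates (no NWM-specific
indel estimates exist) and the short end (1 yr) of the 1–9 yr NWM sexual
maturation range; short *g* means more generations per year, i.e. the
*fastest* neutral decay, which again makes the retention flag conservative.
All three fields can be overridden in YAML/JSON config.

### Implementation and sampling

Each replicate owns an independent RNG stream spawned deterministically
from the root seed by replicate index (`SeedSequence(seed, spawn_key)`), so
trajectories are bit-reproducible and independent of replicate order. The
per-interval Poisson process is sampled exactly but efficiently: the
waiting time to the next indel-bearing interval is geometric with
p = 1−exp(−λ_indel), substitution counts for the intervening
constant-length intervals are drawn as one Poisson vector, and the indel
interval itself draws a zero-truncated Poisson for indels plus an
independent Poisson for substitutions, all applied in random order.
Stop-codon bookkeeping is incremental (O(1) per substitution, one
vectorised recount per indel), which keeps the study-scale run
(10,000 replicates × 800 censuses × 1,150 bp) near 10 s on one CPU.

`retention_test` evaluates the simulated survival probability at the
observed copy's age and flags the copy ("candidate selected") when that
probability falls below the chosen percentile threshold (default 5%; 1%
also reported). A trajectory can be precomputed and shared across many
same-aged copies.

## Frameshift-tolerant mutation mapping

`map_inactivating_mutations` aligns retrocopy nucleotides to parent amino
acids with a three-frame affine dynamic program. Moves into a cell
consuming one parent residue: a codon match (3 nt, BLOSUM62 score of the
translation), frameshift steps (4 nt scoring the translation of their
first codon, or 2 nt with no substitution score — two bases cannot be
translated), both charged an explicit frameshift penalty (default 15);
gap states insert whole retro codons or delete whole parent codons with
affine nucleotide costs (open 11, extend 1/nt). Restricting gap states to
codon granularity means every ±1 frame transition is representable *only*
as a frameshift step, which keeps event classification sharp. The
alignment is local (scores floored at zero, free ends), matching the
"longest indel-sensitive translation" notion; the traceback prefers match
over frameshift over gap and takes the leftmost optimum, so results are
deterministic.

Reported events: codon matches that translate to `*` become
`premature_stop` at the 1-based parent codon; 4-nt and 2-nt steps become
`frameshift_ins` / `frameshift_del`. Two caveats, verified by tests:
frameshift *positions* can shift by one codon (indel placement is
ambiguous when the inserted/deleted base borders a conserved codon — the
usual left-alignment ambiguity of indel calling), and mutations in the
terminal parent codons can be trimmed away by the local alignment. Stops
at interior codons are recovered exactly. Alignments scoring below
`min_score` (default 40) return status `unalignable` — this is also how
complex cases such as nested retrocopy insertions surface, rather than
being resolved.

The iterative DP is verified against an independent recursive
reference scorer (explicit gap-length loops, same move set) on toy
instances up to 30 codons.

## Annotation pipeline

Candidate hits come from 12-column tabular alignment files or from the
built-in matcher (exact 15-mer seeds, ungapped X-drop extension, ≥80%
identity, ≥25 bp) — sufficient for synthetic genomes where copies diverge
by point mutations and short indels; sensitive genome-scale homology
search is out of scope. Hits are grouped into loci by genomic proximity
(gap ≤ 5 kb, chosen above the largest generated intron so the parental
locus groups as one unit), then fragments merge when collinear on mRNA and
genome with gaps ≤ 50 bp (overlaps ≤ 30 bp tolerated, since ungapped
extension can slightly overrun an indel).

A locus is **intronless** when the genomic alignment is contiguous
(excess genomic gap ≤ 50 bp) across at least one exon–exon junction of the
parent mRNA; an excess gap ≥ 200 bp at any covered junction is intron
evidence and classifies the locus as the parental gene. The 50/200
separation splits alignment noise from real introns. A locus covering no
junction is *indeterminate* (single-exon evidence cannot distinguish), not
boolean. 5′ truncation is the first covered mRNA base of the merged locus;
on aged copies the measured value can exceed the planted one by a few tens
of bases because diverged UTR ends fail to seed (the matcher trims to the
max-scoring span) — exact on unaged copies.

The longest-ORF scan enumerates ATG-to-stop spans in the requested frames
(ORFs without a stop run to the last complete codon; the codon count
excludes the stop; ties break to the forward strand, then the 5′-most
start). The deaminase-motif scan finds H-x-E followed after a spacer of
20–40 residues by C-x-x-C, greedily N→C and non-overlapping; C-x-x-C
blocks without a paired H-x-E are reported as partial hits. Synteny
support intersects the flanking gene-name lists (1 Mbp window convention)
of a locus in two species: shared names on both sides, one side, or none.

## Expression counting

The paper-style filter is implemented directly: a read is assigned to the
unique reference containing it verbatim (forward or reverse complement —
strandedness of public datasets is unknown, so both count by default;
toggleable), `multi` if ≥2 references contain it, `none` otherwise. Reads
containing N never match ("100% identity" read strictly). Paired-end mates
are treated as independent reads. The implementation indexes reference
20-mers and verifies candidates, which is exactly equivalent to a full
substring scan (property-tested against one) but linear-time in practice.
Counts obey conservation (assigned + multi + none = total) per dataset.
The matrix step averages datasets within (species, tissue) and exposes a
log₁₀(count+1) view; rows keep reference input order, columns group
germline → brain → blood → other; datasets missing from the metadata fall
into `other` with a warning.

## The synthetic generator

`generate_dataset` emulates the statistical structure the analysis
assumes, not primate genomics in the large:

* **Parent**: a 384-codon CDS (ATG + sense codons + stop; protein length
  configurable) carrying two planted HxE…CxxC blocks at recorded
  positions. Background amino acids are drawn from an alphabet *excluding
  H and C*, so the planted blocks are provably the only motif hits; codons
  are random synonymous choices. The CDS is flanked by short UTRs
  (50/100 nt) and split over 4 exons with random introns (200–1,500 bp,
  GT…AG), always on the '+' strand of the first contig.
* **Copies**: each retrocopy is the parent mRNA, full-length with
  probability 0.6 or else 5′-truncated by a geometric draw (mean 300 nt) —
  a minimal model of the 3′ bias of target-primed reverse transcription —
  optionally carrying explicitly planted stops/frameshifts at recorded
  parent codons, then evolved for its age with the same event engine as
  the decay simulator. `orf_constrained` copies evolve under rejection of
  any single event that would break the tracked CDS window (the simplest
  mechanism that guarantees the retained-ORF phenotype; it is not a
  fitness model). Copies are inserted intronless at random positions and
  orientations into i.i.d.-uniform background contigs, with spacers of
  6–12 kb so neighbouring elements resolve as separate loci.
* **Reads**: error-free, uniform along each expressed reference, both
  orientations, deterministic under seed.

What passing tests therefore do *not* show: robustness to sequencing
error, repeat-rich backgrounds, GC/repeat-aware insertion preferences,
TSD/poly-A structure of real LINE-1 integration, or paired-end effects.
They do show that the statistical and combinatorial logic of every stage
is correct on data whose ground truth is known exactly.

## Problem sizes and numerical choices

The bundled acceptance computation uses the study-scale simulation
(10,000 replicates, 1,150 bp, 50,000-year censuses, 40 My horizon).
Cross-checks in the test suite run at reduced sizes chosen for tight
statistical bounds at interactive runtimes: Poisson-thinning agreement on
30-codon ORFs within 3 Monte-Carlo SE of exp(−m·f_stop) with f_stop from
exhaustive single-substitution enumeration; oracle equality on ≥1,000
random instances per scanning operation; 200-copy recovery runs for the
retention flags. Scores in the aligner are exact float sums of half-integer
matrix entries, so equality comparisons in tracebacks use a 10⁻⁶ epsilon
purely defensively. Degenerate inputs are defined, not special-cased:
empty trajectories, percentiles outside (0,1], non-ACGT characters, reads
longer than every reference, and loci covering no junction each have an
explicit documented behaviour.

## Known limitations

* The decay model ignores selection entirely (by design: it is the null);
  selection appears only as rejection sampling in the generator.
* Compensated indels *within* one census interval are invisible to the
  length criterion at census granularity.
* The built-in matcher is not a sensitive homology search; distant or
  heavily rearranged copies require externally produced hit files.
* Frameshift positions are left-aligned and edge-codon mutations can be
  trimmed by the local alignment (see above).
* Divergence dating, phylogenetics, and selection tests on real alignments
  (dN/dS and relatives) are outside the package's scope.
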