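"""Annotation of candidate retrocopy loci.

Takes candidate genomic hits of a parent mRNA (from a standard 12-column
tabular alignment file, or from the package's built-in exact-seed matcher)
and turns them into annotated retrocopy calls:

* merging fragmented hits into loci,
* intronless classification — the defining property of a retrocopy: the
  genomic copy runs contiguously across exon–exon junctions that are
  separated by introns at the parental locus,
* 5′-truncation measurement (target-primed reverse transcription truncates
  insertions from the 5′ end, so short retrocopies show a 3′ bias),
* longest-ORF scan,
* codon-aware mapping of inactivating mutations onto parent codons,
* HxE…CxxC deaminase-motif scanning of the encoded protein,
* shared-flank-gene synteny support between species.

All coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.  Parent mRNA coordinates are strand-normalised (always
ascending).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._codec import encode, revcomp, translate
from .alignment import FrameshiftScoring, Mutation, MutationReport, map_inactivating_mutations

__all__ = [
    "ParentGene",
    "CandidateHit",
    "MergedLocus",
    "RetrocopyCall",
    "OrfHit",
    "MotifHit",
    "MotifScan",
    "SyntenySupport",
    "merge_hits",
    "classify_intronless",
    "measure_truncation",
    "longest_orf",
    "detect_deaminase_motifs",
    "synteny_support",
    "annotate_genome",
]


@dataclass(frozen=True)
class ParentGene:
    """The intron-containing parent gene of the retrocopies under study."""

    id: str
    mrna_seq: str
    cds_interval: tuple[int, int]  # [start, end) on the mRNA
    exon_intervals: tuple[tuple[int, int], ...]  # genomic, transcription order
    strand: str = "+"
    contig: str = ""
    protein_seq: str = ""

    def __post_init__(self):
        s, e = self.cds_interval
        if not (0 <= s < e <= len(self.mrna_seq)):
            raise ValueError("CDS interval outside mRNA")
        lengths = [b - a for a, b in self.exon_intervals]
        if any(l <= 0 for l in lengths):
            raise ValueError("empty exon interval")
        if sum(lengths) != len(self.mrna_seq):
            raise ValueError("exon lengths do not sum to mRNA length")
        genomic_order = sorted(self.exon_intervals)
        expected = genomic_order if self.strand == "+" else genomic_order[::-1]
        if list(self.exon_intervals) != expected:
            raise ValueError("exons must be non-overlapping and in transcription order")
        for (a1, b1), (a2, b2) in zip(genomic_order, genomic_order[1:]):
            if a2 < b1:
                raise ValueError("exons overlap")
        prot = self.protein()
        if self.protein_seq and self.protein_seq != prot:
            raise ValueError("protein_seq does not match translate(cds)")
        if not self.protein_seq:
            object.__setattr__(self, "protein_seq", prot)

    @property
    def cds_seq(self) -> str:
        s, e = self.cds_interval
        return self.mrna_seq[s:e]

    def protein(self) -> str:
        p = translate(self.cds_seq)
        return p[:-1] if p.endswith("*") else p

    @property
    def mrna_junctions(self) -> tuple[int, ...]:
        """mRNA positions of the exon–exon junctions (transcription order)."""
        out, pos = [], 0
        for a, b in self.exon_intervals[:-1]:
            pos += b - a
            out.append(pos)
        return tuple(out)

    def intron_length_at(self, junction_index: int) -> int:
        a, b = self.exon_intervals[junction_index], self.exon_intervals[junction_index + 1]
        if self.strand == "+":
            return b[0] - a[1]
        return a[0] - b[1]


@dataclass(frozen=True)
class CandidateHit:
    """One ungapped/near-ungapped alignment fragment of the parent mRNA to
    the genome.  0-based half-open; ``q_*`` on the mRNA (always ascending),
    ``s_*`` on the contig."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    percent_identity: float = 100.0
    alignment_length: int = 0

    def __post_init__(self):
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("hit coordinates must be ascending half-open")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass
class MergedLocus:
    subject_id: str
    strand: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    hits: list[CandidateHit] = field(default_factory=list)

    @property
    def covered_span(self) -> int:
        return self.q_end - self.q_start


@dataclass(frozen=True)
class OrfHit:
    """Longest ORF in a sequence; interval includes the stop codon when one
    terminates the ORF, ``n_codons`` excludes it.  Coordinates are always on
    the forward strand of the scanned sequence."""

    start: int
    end: int
    n_codons: int
    strand: str = "+"
    frame: int = 0


@dataclass(frozen=True)
class MotifHit:
    label: str
    start: int
    end: int  # [start, end) on the protein


@dataclass
class MotifScan:
    full: list[MotifHit] = field(default_factory=list)
    partial: list[MotifHit] = field(default_factory=list)


@dataclass
class SyntenySupport:
    locus_id: str
    window: int
    shared_upstream: frozenset
    shared_downstream: frozenset
    category: str  # both_sides | one_side | none

    def __post_init__(self):
        up, down = bool(self.shared_upstream), bool(self.shared_downstream)
        expect = "both_sides" if (up and down) else ("one_side" if (up or down) else "none")
        if self.category != expect:
            raise ValueError("category inconsistent with shared-gene sets")


@dataclass
class RetrocopyCall:
    """One annotated candidate locus."""

    locus_id: str
    subject_id: str
    strand: str
    s_start: int
    s_end: int
    q_start: int
    q_end: int
    is_intronless: Optional[bool]  # None = indeterminate (no junction covered)
    truncation_5p: int
    covered_span: int
    longest_orf: OrfHit
    mutation_report: Optional[MutationReport] = None
    motif_hits: list[MotifHit] = field(default_factory=list)

    @property
    def inactivating_mutations(self) -> list[Mutation]:
        if self.mutation_report is None or self.mutation_report.status != "ok":
            return []
        return self.mutation_report.mutations


# ---------------------------------------------------------------------------
# hit merging and locus classification


def _chainable(prev: CandidateHit, nxt: CandidateHit, max_gap: int, overlap_tol: int) -> bool:
    """nxt follows prev on the genome; are they fragments of one locus?"""
    s_gap = nxt.s_start - prev.s_end
    if not -overlap_tol <= s_gap <= max_gap:
        return False
    if prev.strand == "+":
        q_gap = nxt.q_start - prev.q_end
        advances = nxt.q_end > prev.q_end
    else:
        q_gap = prev.q_start - nxt.q_end
        advances = nxt.q_start < prev.q_start
    return advances and -overlap_tol <= q_gap <= max_gap


def merge_hits(
    hits: Sequence[CandidateHit],
    max_gap: int = 50,
    overlap_tol: int = 30,
) -> list[MergedLocus]:
    """Merge collinear hit fragments into loci.

    Hits sharing subject and strand whose genomic and mRNA gaps are both at
    most ``max_gap`` (small overlaps up to ``overlap_tol`` tolerated, as
    ungapped extension may slightly overrun an indel) merge into one locus.
    Mixed strands never merge.  Output is sorted by genomic start.
    """
    groups: dict[tuple[str, str], list[CandidateHit]] = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.strand), []).append(h)
    loci: list[MergedLocus] = []
    for (subject, strand), group in groups.items():
        group.sort(key=lambda h: (h.s_start, h.s_end))
        current = [group[0]]
        for h in group[1:]:
            if _chainable(current[-1], h, max_gap, overlap_tol):
                current.append(h)
            else:
                loci.append(_build_locus(subject, strand, current))
                current = [h]
        loci.append(_build_locus(subject, strand, current))
    loci.sort(key=lambda l: (l.subject_id, l.s_start))
    return loci


def _build_locus(subject: str, strand: str, hits: list[CandidateHit]) -> MergedLocus:
    return MergedLocus(
        subject_id=subject,
        strand=strand,
        q_start=min(h.q_start for h in hits),
        q_end=max(h.q_end for h in hits),
        s_start=min(h.s_start for h in hits),
        s_end=max(h.s_end for h in hits),
        hits=list(hits),
    )


def classify_intronless(
    locus: MergedLocus | list[CandidateHit],
    parent: ParentGene,
    min_exons_bridged: int = 2,
    max_gap: int = 50,
    min_intron: int = 200,
) -> Optional[bool]:
    """Is this locus an intronless (retro)copy of the parent?

    A junction of the parent mRNA is *bridged* when the genomic alignment is
    contiguous across it (a single hit spans it, or adjacent fragments abut
    with at most ``max_gap`` excess genomic sequence); it shows *intron
    evidence* when the excess genomic gap is at least ``min_intron``.  Any
    intron evidence classifies the locus ``False`` (the parental gene
    itself); at least ``min_exons_bridged - 1`` bridged junctions classify
    it ``True``.  A locus covering no junction (or only ambiguous ones)
    returns ``None`` — single-exon evidence cannot distinguish.
    """
    hits = locus.hits if isinstance(locus, MergedLocus) else list(locus)
    if not hits:
        return None
    q_lo = min(h.q_start for h in hits)
    q_hi = max(h.q_end for h in hits)
    bridged = 0
    covered_any = False
    for junction in parent.mrna_junctions:
        if not q_lo < junction < q_hi:
            continue
        covered_any = True
        if any(h.q_start < junction < h.q_end for h in hits):
            bridged += 1
            continue
        # adjacent fragments around the junction
        left = [h for h in hits if h.q_end <= junction]
        right = [h for h in hits if h.q_start >= junction]
        if not left or not right:
            continue
        a = max(left, key=lambda h: h.q_end)
        b = min(right, key=lambda h: h.q_start)
        q_gap = b.q_start - a.q_end
        if a.strand == "+":
            s_gap = b.s_start - a.s_end
        else:
            s_gap = a.s_start - b.s_end
        excess = s_gap - q_gap
        if excess >= min_intron:
            return False
        if excess <= max_gap:
            bridged += 1
    if not covered_any:
        return None
    if bridged >= min_exons_bridged - 1:
        return True
    return None


def measure_truncation(locus: MergedLocus, parent: ParentGene) -> tuple[int, int]:
    """(5′ truncation, covered span) of the locus on the parent mRNA.

    The 5′ truncation is simply the first covered mRNA base; full-length
    copies return 0.
    """
    if locus.q_end > len(parent.mrna_seq):
        raise ValueError("locus extends beyond the parent mRNA")
    return locus.q_start, locus.q_end - locus.q_start


# ---------------------------------------------------------------------------
# ORF and motif scans


def _scan_orfs_forward(seq: str) -> list[tuple[int, int, int, int]]:
    """(start, end, n_codons, frame) for every maximal ATG-led ORF."""
    out = []
    n = len(seq)
    for frame in range(3):
        start = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in ("TAA", "TAG", "TGA"):
                out.append((start, i + 3, (i - start) // 3, frame))
                start = None
            i += 3
        if start is not None:  # open to the end: no terminating stop
            n_cod = (i - start) // 3
            out.append((start, start + 3 * n_cod, n_cod, frame))
    return out


def longest_orf(seq: str, strand_mode: str = "forward") -> OrfHit:
    """Longest ATG-to-stop ORF across the requested frames.

    ``strand_mode`` is ``"forward"`` (3 frames) or ``"both"`` (6 frames).
    Ties break to the forward strand, then the 5′-most start.  Without any
    ATG an empty ORF of length 0 is returned.  ORFs lacking a stop codon
    run to the last complete codon.
    """
    if not seq:
        raise ValueError("empty sequence")
    if strand_mode not in ("forward", "both"):
        raise ValueError("strand_mode must be 'forward' or 'both'")
    seq = seq.upper()
    encode(seq)
    candidates = []  # (n_codons, strand_rank, start, hit)
    for s, e, n_cod, frame in _scan_orfs_forward(seq):
        candidates.append((n_cod, 0, s, OrfHit(s, e, n_cod, "+", frame)))
    if strand_mode == "both":
        rc = revcomp(seq)
        L = len(seq)
        for s, e, n_cod, frame in _scan_orfs_forward(rc):
            hit = OrfHit(L - e, L - s, n_cod, "-", frame)
            candidates.append((n_cod, 1, hit.start, hit))
    if not candidates:
        return OrfHit(0, 0, 0, "+", 0)
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    best = candidates[0][3]
    if best.n_codons == 0:
        return OrfHit(0, 0, 0, "+", 0)
    return best


def detect_deaminase_motifs(
    protein_seq: str,
    min_spacer: int = 20,
    max_spacer: int = 40,
) -> MotifScan:
    """Scan a protein for the zinc-coordinating HxE…CxxC deaminase motif.

    A full hit is an H-x-E whose glutamate is followed, after a spacer of
    ``min_spacer``–``max_spacer`` residues, by C-x-x-C; hits are reported
    N→C, non-overlapping, labelled ``deaminase_domain_1``, ``…_2``, …
    C-x-x-C blocks not belonging to any full hit are reported as partial
    hits (label ``CxxC_only``).
    """
    p = protein_seq
    n = len(p)
    full: list[MotifHit] = []
    used_c: set[int] = set()
    i = 0
    while i + 2 < n:
        if p[i] == "H" and p[i + 2] == "E":
            found = None
            for c in range(i + 3 + min_spacer, min(i + 3 + max_spacer, n - 4) + 1):
                if p[c] == "C" and p[c + 3] == "C":
                    found = c
                    break
            if found is not None:
                full.append(
                    MotifHit(f"deaminase_domain_{len(full) + 1}", i, found + 4)
                )
                used_c.add(found)
                i = found + 4
                continue
        i += 1
    partial = [
        MotifHit("CxxC_only", c, c + 4)
        for c in range(n - 3)
        if p[c] == "C" and p[c + 3] == "C" and c not in used_c
        and not any(h.start <= c < h.end for h in full)
    ]
    return MotifScan(full=full, partial=partial)


def synteny_support(
    locus_id: str,
    upstream_a: Sequence[str],
    downstream_a: Sequence[str],
    upstream_b: Sequence[str],
    downstream_b: Sequence[str],
    window: int = 1_000_000,
) -> SyntenySupport:
    """Shared flank-gene support for orthology of a retrocopy locus.

    ``upstream_*``/``downstream_*`` are the gene names within ``window``
    bases on each side of the locus in the two species being compared.
    """
    if not (upstream_a or downstream_a) or not (upstream_b or downstream_b):
        warnings.warn(f"empty flank lists for {locus_id}; synteny not assessable")
    up = frozenset(upstream_a) & frozenset(upstream_b)
    down = frozenset(downstream_a) & frozenset(downstream_b)
    if up and down:
        category = "both_sides"
    elif up or down:
        category = "one_side"
    else:
        category = "none"
    return SyntenySupport(locus_id, window, up, down, category)


# ---------------------------------------------------------------------------
# the annotation pipeline


def _group_into_loci(
    hits: Sequence[CandidateHit], locus_group_gap: int
) -> list[list[CandidateHit]]:
    """Group hits into candidate loci by genomic proximity (per subject and
    strand).  The gap here must exceed intron size so that the parental
    locus groups as one unit; contiguity is judged later."""
    groups: dict[tuple[str, str], list[CandidateHit]] = {}
    for h in hits:
        groups.setdefault((h.subject_id, h.strand), []).append(h)
    loci = []
    for group in groups.values():
        group.sort(key=lambda h: (h.s_start, h.s_end))
        current = [group[0]]
        for h in group[1:]:
            if h.s_start - max(x.s_end for x in current) <= locus_group_gap:
                current.append(h)
            else:
                loci.append(current)
                current = [h]
        loci.append(current)
    loci.sort(key=lambda g: (g[0].subject_id, min(h.s_start for h in g)))
    return loci


def locus_sequence(call_or_locus, contigs: dict[str, str]) -> str:
    """Extract the (strand-corrected) genomic sequence of a locus."""
    seq = contigs[call_or_locus.subject_id][call_or_locus.s_start : call_or_locus.s_end]
    return revcomp(seq) if call_or_locus.strand == "-" else seq


def annotate_genome(
    parent: ParentGene,
    contigs: dict[str, str] | None = None,
    hits: Sequence[CandidateHit] | None = None,
    *,
    max_gap: int = 50,
    min_intron: int = 200,
    locus_group_gap: int = 5000,
    scoring: FrameshiftScoring | None = None,
    matcher_kwargs: dict | None = None,
) -> list[RetrocopyCall]:
    """Run the full annotation pipeline.

    Provide either precomputed ``hits`` (e.g. parsed from a 12-column
    tabular file) or ``contigs`` to search with the built-in exact-seed
    matcher.  Each candidate locus is classified (intronless / parental /
    indeterminate), measured for 5′ truncation, scanned for its longest ORF
    and deaminase motifs, and aligned to the parent protein to map
    inactivating mutations.
    """
    if hits is None:
        if contigs is None:
            raise ValueError("provide hits or contigs")
        from .matcher import find_candidate_hits

        hits = find_candidate_hits(
            parent.mrna_seq, contigs, query_id=parent.id, **(matcher_kwargs or {})
        )
    calls: list[RetrocopyCall] = []
    for k, group in enumerate(_group_into_loci(hits, locus_group_gap)):
        merged = merge_hits(group, max_gap=max_gap)
        strand = group[0].strand
        subject = group[0].subject_id
        locus = MergedLocus(
            subject_id=subject,
            strand=strand,
            q_start=min(h.q_start for h in group),
            q_end=max(h.q_end for h in group),
            s_start=min(h.s_start for h in group),
            s_end=max(h.s_end for h in group),
            hits=list(group),
        )
        intronless = classify_intronless(
            locus, parent, max_gap=max_gap, min_intron=min_intron
        )
        trunc, covered = measure_truncation(locus, parent)
        if contigs is not None:
            seq = locus_sequence(locus, contigs)
        else:
            seq = ""
        if seq:
            orf = longest_orf(seq, strand_mode="forward")
            report = map_inactivating_mutations(seq, parent.protein_seq, scoring)
            protein = translate(seq[orf.start : orf.end]) if orf.n_codons else ""
            protein = protein[: orf.n_codons]
            motifs = detect_deaminase_motifs(protein).full if protein else []
        else:
            orf = OrfHit(0, 0, 0, "+", 0)
            report = None
            motifs = []
        calls.append(
            RetrocopyCall(
                locus_id=f"{subject}:{locus.s_start}-{locus.s_end}({strand})",
                subject_id=subject,
                strand=strand,
                s_start=locus.s_start,
                s_end=locus.s_end,
                q_start=locus.q_start,
                q_end=locus.q_end,
                is_intronless=intronless,
                truncation_5p=trunc,
                covered_span=covered,
                longest_orf=orf,
                mutation_report=report,
                motif_hits=list(motifs),
            )
        )
    return calls
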