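"""Fully labelled synthetic datasets for exercising the whole pipeline.

Generates a deaminase-like parent gene (an ~384-codon CDS carrying two
planted HxE…CxxC zinc-coordinating motifs, split over a configurable number
of exons), plants intronless retrocopies of its mRNA into random background
contigs — 5′-truncated with the 3′ bias of target-primed reverse
transcription, aged under the neutral mutation engine or under an
ORF-preserving constraint — and simulates error-free RNA-seq reads at known
per-copy expression.  Every planted feature is recorded as ground truth, so
annotation, decay and expression modules can be tested without any external
download.

The background amino-acid alphabet of the parent excludes H and C, which
makes the two planted motif blocks provably the only HxE…CxxC hits in the
parent protein.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._codec import AA_TO_CODONS, BASES, encode, revcomp, stop_flags
from .annotate import ParentGene
from .decay import MutationParameters, PRESETS

__all__ = [
    "CopySpec",
    "GeneratorConfig",
    "PlantedCopy",
    "SyntheticDataset",
    "generate_parent",
    "plant_retrocopies",
    "simulate_reads",
    "generate_dataset",
    "evolve_copy",
]

_BACKGROUND_AA = "ADEFGIKLMNPQRSTVWY"  # 20 standard minus H and C


@dataclass(frozen=True)
class CopySpec:
    """Explicit description of one retrocopy to plant (overrides sampling)."""

    age_years: float = 0.0
    orf_constrained: bool = False
    truncation_5p: Optional[int] = None  # None -> sample from the model
    expression: int = 0
    planted_stops: tuple[int, ...] = ()  # 1-based parent codon positions
    planted_frameshifts: tuple[tuple[int, str], ...] = ()  # (codon, "ins"|"del")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    parent_codons: int = 384  # protein length incl. the initial Met
    exon_count: int = 4
    intron_range: tuple[int, int] = (200, 1500)
    utr5: int = 50
    utr3: int = 100
    motif_starts: tuple[int, int] = (64, 230)  # 0-based aa positions of the H
    motif_spacer_range: tuple[int, int] = (22, 36)
    n_retrocopies: int = 8
    p_full_length: float = 0.6
    truncation_mean: float = 300.0  # geometric mean of 5' truncation (nt)
    age_range: tuple[float, float] = (0.0, 25e6)
    p_constrained: float = 0.25
    params: MutationParameters = PRESETS["nwm-like"]
    census_interval_years: float = 50e3
    expression_range: tuple[int, int] = (0, 200)
    read_length: int = 100
    n_contigs: int = 2
    copies: Optional[tuple[CopySpec, ...]] = None

    def __post_init__(self):
        if self.parent_codons < 60:
            raise ValueError("parent must be at least 60 codons")
        if not 0 <= self.p_full_length <= 1 or not 0 <= self.p_constrained <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.age_range[1] > 50e6:
            raise ValueError("copy ages must be <= 50 My")


@dataclass
class PlantedCopy:
    """Ground truth for one planted retrocopy."""

    copy_id: str
    subject_id: str
    start: int
    end: int
    strand: str
    age_years: float
    truncation_5p: int
    orf_constrained: bool
    planted_mutations: list[dict] = field(default_factory=list)
    expected_intact: Optional[bool] = None
    expression: int = 0
    sequence: str = ""  # in mRNA orientation
    cds_start: Optional[int] = None  # within `sequence`, None if CDS truncated
    n_events: int = 0


@dataclass
class SyntheticDataset:
    parent: ParentGene
    parent_locus: tuple[str, int, int, str]  # contig, start, end, strand
    parent_motifs: list[tuple[int, int]]  # aa intervals of the planted motifs
    genome: list[tuple[str, str]]
    copies: list[PlantedCopy]
    config: GeneratorConfig

    def references(self) -> list[tuple[str, str]]:
        """Reference set for expression counting: parent mRNA + every copy."""
        return [(self.parent.id, self.parent.mrna_seq)] + [
            (c.copy_id, c.sequence) for c in self.copies
        ]

    def truth_dict(self) -> dict:
        return {
            "parent": {
                "id": self.parent.id,
                "locus": list(self.parent_locus),
                "mrna_length": len(self.parent.mrna_seq),
                "cds_interval": list(self.parent.cds_interval),
                "exon_intervals": [list(x) for x in self.parent.exon_intervals],
                "motif_intervals": [list(x) for x in self.parent_motifs],
            },
            "copies": [asdict(c) for c in self.copies],
        }

    def write(self, outdir) -> dict[str, str]:
        from . import io as rio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": str(outdir / "genome.fasta"),
            "parent_mrna": str(outdir / "parent_mrna.fasta"),
            "parent_exons": str(outdir / "parent_exons.gff3"),
            "retrocopies": str(outdir / "retrocopies.fasta"),
            "truth": str(outdir / "truth.json"),
        }
        rio.write_fasta(paths["genome"], self.genome)
        rio.write_fasta(paths["parent_mrna"], [(self.parent.id, self.parent.mrna_seq)])
        rio.write_parent_gff3(paths["parent_exons"], self.parent)
        rio.write_fasta(
            paths["retrocopies"], [(c.copy_id, c.sequence) for c in self.copies]
        )
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth_dict(), fh, indent=1)
        return paths


# ---------------------------------------------------------------------------
# parent generation


def _random_utr(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def generate_parent(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[ParentGene, list[tuple[int, int]], str, list[str]]:
    """Build the parent gene.

    Returns ``(parent_without_genomic_coords, motif_intervals, locus_seq,
    exon_seqs)`` — the genomic exon coordinates are filled in when the locus
    is placed on a contig.
    """
    n_aa = config.parent_codons
    aa = ["M"] + [
        _BACKGROUND_AA[i] for i in rng.integers(0, len(_BACKGROUND_AA), n_aa - 1)
    ]
    motifs: list[tuple[int, int]] = []
    lo, hi = config.motif_spacer_range
    for h in config.motif_starts:
        spacer = int(rng.integers(lo, hi + 1))
        c = h + 3 + spacer
        if c + 4 > n_aa:
            raise ValueError("motif does not fit in the parent protein")
        aa[h], aa[h + 2] = "H", "E"
        aa[c], aa[c + 3] = "C", "C"
        motifs.append((h, c + 4))
    codons = []
    for i, a in enumerate(aa):
        if i == 0:
            codons.append("ATG")
        else:
            options = AA_TO_CODONS[a]
            codons.append(options[int(rng.integers(len(options)))])
    stops = AA_TO_CODONS["*"]
    cds = "".join(codons) + stops[int(rng.integers(len(stops)))]
    mrna = _random_utr(config.utr5, rng) + cds + _random_utr(config.utr3, rng)

    # exonise: cut points keeping every exon >= 60 nt
    n_ex = config.exon_count
    cuts: list[int] = []
    if n_ex > 1:
        while True:
            cand = sorted(int(x) for x in rng.integers(60, len(mrna) - 60, n_ex - 1))
            if all(b - a >= 60 for a, b in zip(cand, cand[1:])):
                cuts = cand
                break
    bounds = [0] + cuts + [len(mrna)]
    exon_seqs = [mrna[a:b] for a, b in zip(bounds, bounds[1:])]
    ilo, ihi = config.intron_range
    pieces = []
    for i, ex in enumerate(exon_seqs):
        pieces.append(ex)
        if i < len(exon_seqs) - 1:
            ilen = int(rng.integers(ilo, ihi + 1))
            pieces.append("GT" + _random_utr(max(ilen - 4, 0), rng) + "AG")
    locus_seq = "".join(pieces)
    # placeholder exon coordinates (mRNA-relative); replaced at placement
    placeholder = tuple((a, b) for a, b in zip(bounds, bounds[1:]))
    parent = ParentGene(
        id="parentA3G",
        mrna_seq=mrna,
        cds_interval=(config.utr5, config.utr5 + len(cds)),
        exon_intervals=placeholder,
        strand="+",
        contig="",
    )
    return parent, motifs, locus_seq, exon_seqs


# ---------------------------------------------------------------------------
# copy evolution (single-sequence mutation engine)


def _window_intact(arr: bytearray, cds_start: int, cds_end: int, cds_len0: int) -> bool:
    if cds_end - cds_start != cds_len0:
        return False
    codes = np.frombuffer(bytes(arr[cds_start:cds_end]), dtype=np.uint8)
    if codes.size < 3 or codes[0] != 0 or codes[1] != 3 or codes[2] != 2:  # ATG
        return False
    flags = stop_flags(codes)
    return not flags[:-1].any() if flags.size else True


def evolve_copy(
    seq: str,
    params: MutationParameters,
    age_years: float,
    rng: np.random.Generator,
    *,
    cds_start: Optional[int] = None,
    cds_len: Optional[int] = None,
    constrained: bool = False,
    census_interval_years: float = 50e3,
) -> tuple[str, int, Optional[int], Optional[int]]:
    """Evolve one sequence for ``age_years`` under the mutation engine.

    Same event model as the decay simulator: per-interval Poisson counts,
    events in random order at uniform positions, 1-bp indels.  When
    ``constrained`` is set, any event that would break the ORF in the
    tracked CDS window is rejected (rejection sampling guarantees the
    retained-ORF phenotype).  Returns ``(sequence, n_events, cds_start,
    cds_end)`` with the CDS window coordinates shifted by any indels
    upstream of or inside it.
    """
    arr = bytearray(encode(seq).tobytes())
    cs = cds_start
    ce = None if cds_start is None else cds_start + int(cds_len)
    cds_len0 = cds_len
    if constrained and cs is None:
        raise ValueError("constrained evolution needs a CDS window")
    n_events = 0
    remaining = age_years
    gens_full = census_interval_years / params.generation_time
    while remaining > 1e-9:
        dt = min(census_interval_years, remaining)
        remaining -= dt
        L = len(arr)
        if L == 0:
            break
        gens = gens_full * (dt / census_interval_years)
        n_sub = int(rng.poisson(params.sub_rate * L * gens))
        n_ins = int(rng.poisson(params.ins_rate * L * gens))
        n_del = int(rng.poisson(params.del_rate * L * gens))
        events = ["s"] * n_sub + ["i"] * n_ins + ["d"] * n_del
        rng.shuffle(events)
        for e in events:
            L = len(arr)
            if L == 0:
                break
            p = int(rng.integers(L))
            if e == "s":
                old = arr[p]
                arr[p] = (old + 1 + int(rng.integers(3))) % 4
                if constrained and not _window_intact(arr, cs, ce, cds_len0):
                    arr[p] = old
                    continue
            elif e == "i":
                b = int(rng.integers(4))
                arr.insert(p + 1, b)
                ncs, nce = cs, ce
                if cs is not None:
                    if p + 1 <= cs:
                        ncs, nce = cs + 1, ce + 1
                    elif p + 1 < ce:
                        nce = ce + 1
                if constrained and not _window_intact(arr, ncs, nce, cds_len0):
                    del arr[p + 1]
                    continue
                cs, ce = ncs, nce
            else:
                old = arr[p]
                del arr[p]
                ncs, nce = cs, ce
                if cs is not None:
                    if p < cs:
                        ncs, nce = cs - 1, ce - 1
                    elif p < ce:
                        nce = ce - 1
                if constrained and not _window_intact(arr, ncs, nce, cds_len0):
                    arr.insert(p, old)
                    continue
                cs, ce = ncs, nce
            n_events += 1
    out = "".join(BASES[b] for b in arr)
    return out, n_events, cs, ce


# ---------------------------------------------------------------------------
# planting


def _sample_truncation(config: GeneratorConfig, rng: np.random.Generator, mrna_len: int) -> int:
    if rng.random() < config.p_full_length:
        return 0
    while True:
        t = int(rng.geometric(1.0 / config.truncation_mean))
        if mrna_len - t >= 50:
            return t


def _apply_planted_mutations(
    seq: str,
    cds_start: int,
    spec: CopySpec,
    rng: np.random.Generator,
) -> tuple[str, list[dict]]:
    """Plant explicit stops / 1-bp frameshifts; positions are parent codons."""
    planted: list[dict] = []
    stops = sorted(spec.planted_stops)
    shifts = sorted(spec.planted_frameshifts)
    arr = list(seq)
    for codon in stops:
        at = cds_start + 3 * (codon - 1)
        arr[at : at + 3] = list("TAA")
        planted.append({"kind": "premature_stop", "parent_codon": codon})
    # apply frameshifts right-to-left so earlier coordinates stay valid
    for codon, kind in sorted(shifts, reverse=True):
        at = cds_start + 3 * (codon - 1)
        if kind == "ins":
            arr.insert(at + 1, BASES[int(rng.integers(4))])
            planted.append({"kind": "frameshift_ins", "parent_codon": codon})
        elif kind == "del":
            del arr[at + 1]
            planted.append({"kind": "frameshift_del", "parent_codon": codon})
        else:
            raise ValueError(f"unknown frameshift kind {kind!r}")
    planted.sort(key=lambda m: m["parent_codon"])
    return "".join(arr), planted


def plant_retrocopies(
    parent: ParentGene,
    motifs: list[tuple[int, int]],
    locus_seq: str,
    exon_seqs: list[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> SyntheticDataset:
    """Build the genome: background contigs + parent locus + aged copies."""
    mrna = parent.mrna_seq
    cds_s, cds_e = parent.cds_interval
    cds_len = cds_e - cds_s

    specs: list[CopySpec] = []
    if config.copies is not None:
        specs = list(config.copies)
    else:
        lo_age, hi_age = config.age_range
        elo, ehi = config.expression_range
        for _ in range(config.n_retrocopies):
            constrained = rng.random() < config.p_constrained
            trunc = 0 if constrained else None
            specs.append(
                CopySpec(
                    age_years=float(rng.uniform(lo_age, hi_age)),
                    orf_constrained=constrained,
                    truncation_5p=trunc,
                    expression=int(rng.integers(elo, ehi + 1)),
                )
            )

    copies: list[PlantedCopy] = []
    for idx, spec in enumerate(specs):
        trunc = (
            spec.truncation_5p
            if spec.truncation_5p is not None
            else _sample_truncation(config, rng, len(mrna))
        )
        if spec.orf_constrained and trunc > cds_s:
            raise ValueError("an ORF-constrained copy cannot have a truncated CDS")
        seq0 = mrna[trunc:]
        c_start = cds_s - trunc  # may be negative when the CDS is truncated
        seq0, planted = _apply_planted_mutations(
            seq0, c_start, spec, rng
        ) if (spec.planted_stops or spec.planted_frameshifts) else (seq0, [])
        shift = sum(
            1 if m["kind"] == "frameshift_ins" else -1
            for m in planted
            if m["kind"].startswith("frameshift")
        )
        have_cds = c_start >= 0
        seq, n_ev, cs, ce = evolve_copy(
            seq0,
            config.params,
            spec.age_years,
            rng,
            cds_start=c_start if have_cds else None,
            cds_len=(cds_len + shift) if have_cds else None,
            constrained=spec.orf_constrained,
            census_interval_years=config.census_interval_years,
        )
        # judged at the ORIGINAL CDS length, as the decay criterion does:
        # planted or acquired frameshifts leave the window at a wrong length
        if have_cds and cs is not None and ce is not None and ce <= len(seq):
            intact = _window_intact(bytearray(encode(seq).tobytes()), cs, ce, cds_len)
        else:
            intact = False
        copies.append(
            PlantedCopy(
                copy_id=f"retro{idx + 1}",
                subject_id="",
                start=0,
                end=0,
                strand="+",
                age_years=spec.age_years,
                truncation_5p=trunc,
                orf_constrained=spec.orf_constrained,
                planted_mutations=planted,
                expected_intact=bool(intact),
                expression=spec.expression,
                sequence=seq,
                cds_start=cs if have_cds else None,
                n_events=n_ev + len(planted),
            )
        )

    # assemble contigs: random background with elements interleaved
    contig_ids = [f"contig{i + 1}" for i in range(config.n_contigs)]
    elements: dict[str, list[tuple[str, object]]] = {c: [] for c in contig_ids}
    elements[contig_ids[0]].append(("parent", None))
    for c in copies:
        elements[contig_ids[int(rng.integers(config.n_contigs))]].append(("copy", c))
    genome: list[tuple[str, str]] = []
    parent_locus = None
    placed_parent: Optional[ParentGene] = None
    for cid in contig_ids:
        elems = elements[cid]
        order = rng.permutation(len(elems)) if elems else []
        parts: list[str] = []
        pos = 0

        def background():
            # spacers must exceed the annotation locus-grouping gap (5 kb)
            # so neighbouring planted elements resolve as separate loci
            nonlocal pos
            n = int(rng.integers(6000, 12001))
            parts.append(_random_utr(n, rng))
            pos += n

        background()
        for oi in order:
            kind, payload = elems[int(oi)]
            if kind == "parent":
                start = pos
                parts.append(locus_seq)
                pos += len(locus_seq)
                parent_locus = (cid, start, pos, "+")
            else:
                copy = payload
                strand = "+" if rng.random() < 0.5 else "-"
                insert = copy.sequence if strand == "+" else revcomp(copy.sequence)
                start = pos
                parts.append(insert)
                pos += len(insert)
                copy.subject_id = cid
                copy.start = start
                copy.end = pos
                copy.strand = strand
            background()
        genome.append((cid, "".join(parts)))

    if parent_locus is None:
        raise AssertionError("parent locus was not placed")
    # recompute absolute exon intervals directly from the locus structure
    cid, lstart, _lend, _ = parent_locus
    abs_exons = []
    cursor = lstart
    intron_lengths = _intron_lengths(locus_seq, exon_seqs)
    for i, ex in enumerate(exon_seqs):
        abs_exons.append((cursor, cursor + len(ex)))
        cursor += len(ex)
        if i < len(exon_seqs) - 1:
            cursor += intron_lengths[i]
    placed_parent = ParentGene(
        id=parent.id,
        mrna_seq=parent.mrna_seq,
        cds_interval=parent.cds_interval,
        exon_intervals=tuple(abs_exons),
        strand="+",
        contig=cid,
    )
    return SyntheticDataset(
        parent=placed_parent,
        parent_locus=parent_locus,
        parent_motifs=list(motifs),
        genome=genome,
        copies=copies,
        config=config,
    )


def _intron_lengths(locus_seq: str, exon_seqs: list[str]) -> list[int]:
    """Recover intron lengths by walking the locus past each exon."""
    lengths = []
    pos = 0
    for i, ex in enumerate(exon_seqs):
        assert locus_seq[pos : pos + len(ex)] == ex
        pos += len(ex)
        if i < len(exon_seqs) - 1:
            nxt = exon_seqs[i + 1]
            j = locus_seq.index(nxt, pos)
            lengths.append(j - pos)
            pos = j
    return lengths


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    references: Sequence[tuple[str, str]],
    expression: dict[str, int],
    read_length: int,
    rng: np.random.Generator,
    both_strands: bool = True,
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Error-free reads drawn uniformly along each expressed reference.

    Returns ``(records, truth_counts)`` where records are (id, seq, qual)
    FASTQ tuples.  Raises when a reference is expressed but shorter than
    the read length.
    """
    records: list[tuple[str, str, str]] = []
    truth: dict[str, int] = {}
    qual = "I" * read_length
    for ref_id, seq in references:
        n = int(expression.get(ref_id, 0))
        if n < 0:
            raise ValueError("expression levels must be >= 0")
        truth[ref_id] = n
        if n == 0:
            continue
        if read_length > len(seq):
            raise ValueError(
                f"read length {read_length} exceeds reference {ref_id!r} "
                f"({len(seq)} nt)"
            )
        starts = rng.integers(0, len(seq) - read_length + 1, n)
        for i, s in enumerate(starts):
            r = seq[int(s) : int(s) + read_length]
            if both_strands and rng.random() < 0.5:
                r = revcomp(r)
            records.append((f"{ref_id}_read{i}", r, qual))
    return records, truth


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a complete labelled dataset from one seed."""
    rng = np.random.default_rng(config.seed)
    parent, motifs, locus_seq, exon_seqs = generate_parent(config, rng)
    return plant_retrocopies(parent, motifs, locus_seq, exon_seqs, config, rng)
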