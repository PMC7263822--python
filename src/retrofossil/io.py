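"""File formats, configuration and the run manifest.

Conventions: all in-memory coordinates are 0-based half-open; GFF3 output
is 1-based inclusive (the standard); 12-column tabular hit files use the
classic 1-based inclusive convention with minus-strand subject coordinates
reversed, and are normalised on read.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

from .annotate import CandidateHit, ParentGene, RetrocopyCall
from .decay import PRESETS, MutationParameters, SimulationConfig

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_blast_tabular",
    "write_blast_tabular",
    "write_parent_gff3",
    "read_parent_gff3",
    "write_calls_gff3",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "load_sim_config",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs.

    Lowercase bases are uppercased with a warning; duplicate ids raise; an
    empty file returns an empty list with a warning.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"lowercase bases in record {rec.id!r}; uppercasing")
            seq = seq.upper()
        records.append((rec.id, seq))
    if not records:
        warnings.warn(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# 12-column tabular hits (qseqid sseqid pident length mismatch gapopen
# qstart qend sstart send evalue bitscore)


def read_blast_tabular(path) -> list[CandidateHit]:
    """Parse 12-column tabular hits into normalised CandidateHits.

    Query coordinates 1-based inclusive become 0-based half-open; subject
    coordinates with start > end denote the minus strand and are swapped
    with the strand recorded.
    """
    hits: list[CandidateHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            qid, sid, pident, length = fields[0], fields[1], float(fields[2]), int(fields[3])
            qs, qe, ss, se = (int(fields[i]) for i in (6, 7, 8, 9))
            if ss <= se:
                strand, s_start, s_end = "+", ss - 1, se
            else:
                strand, s_start, s_end = "-", se - 1, ss
            hits.append(
                CandidateHit(
                    query_id=qid,
                    subject_id=sid,
                    q_start=qs - 1,
                    q_end=qe,
                    s_start=s_start,
                    s_end=s_end,
                    strand=strand,
                    percent_identity=pident,
                    alignment_length=length,
                )
            )
    return hits


def write_blast_tabular(path, hits: Sequence[CandidateHit]) -> None:
    """Inverse of :func:`read_blast_tabular` (round-trip identical fields).

    Mismatch/gapopen/evalue/bitscore carry placeholder values — the matcher
    does not model them."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.alignment_length,
                        0,
                        0,
                        h.q_start + 1,
                        h.q_end,
                        ss,
                        se,
                        "0.0",
                        "0.0",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def _mrna_to_genomic(parent: ParentGene, interval: tuple[int, int]) -> list[tuple[int, int]]:
    """Map an mRNA interval onto genomic exon pieces (plus strand only for
    now — the generator always places the parent on '+')."""
    out = []
    lo, hi = interval
    pos = 0
    for a, b in parent.exon_intervals:
        ex_len = b - a
        s = max(lo, pos)
        e = min(hi, pos + ex_len)
        if s < e:
            out.append((a + (s - pos), a + (e - pos)))
        pos += ex_len
    return out


def write_parent_gff3(path, parent: ParentGene) -> None:
    """Write gene/mRNA/exon/CDS features for the parent (1-based inclusive).

    The mRNA row records the CDS interval in mRNA coordinates as a
    ``cds_mrna`` attribute so the gene can be reconstructed losslessly."""
    contig = parent.contig or "."
    gs = min(a for a, _ in parent.exon_intervals)
    ge = max(b for _, b in parent.exon_intervals)
    cs, ce = parent.cds_interval
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"{contig}\tretrofossil\tgene\t{gs + 1}\t{ge}\t.\t{parent.strand}\t.\t"
            f"ID={parent.id}\n"
        )
        fh.write(
            f"{contig}\tretrofossil\tmRNA\t{gs + 1}\t{ge}\t.\t{parent.strand}\t.\t"
            f"ID={parent.id}.t1;Parent={parent.id};cds_mrna={cs}-{ce}\n"
        )
        for i, (a, b) in enumerate(parent.exon_intervals, start=1):
            fh.write(
                f"{contig}\tretrofossil\texon\t{a + 1}\t{b}\t.\t{parent.strand}\t.\t"
                f"ID={parent.id}.exon{i};Parent={parent.id}.t1\n"
            )
        for a, b in _mrna_to_genomic(parent, (cs, ce)):
            fh.write(
                f"{contig}\tretrofossil\tCDS\t{a + 1}\t{b}\t.\t{parent.strand}\t0\t"
                f"Parent={parent.id}.t1\n"
            )


def read_parent_gff3(path, mrna_seq: str, parent_id: str | None = None) -> ParentGene:
    """Rebuild a ParentGene from the exon/CDS annotation plus its mRNA."""
    exons: list[tuple[int, int]] = []
    contig = ""
    strand = "+"
    cds_mrna: tuple[int, int] | None = None
    gene_id = parent_id
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            ftype = fields[2]
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if ftype == "gene" and gene_id is None:
                gene_id = attrs.get("ID")
            if ftype == "mRNA" and "cds_mrna" in attrs:
                a, b = attrs["cds_mrna"].split("-")
                cds_mrna = (int(a), int(b))
            if ftype == "exon":
                contig = fields[0]
                strand = fields[6]
                exons.append((int(fields[3]) - 1, int(fields[4])))
    if not exons:
        raise ValueError(f"no exon features in {path}")
    if cds_mrna is None:
        raise ValueError(f"no cds_mrna attribute in {path}")
    exons.sort()
    if strand == "-":
        exons = exons[::-1]
    return ParentGene(
        id=gene_id or "parent",
        mrna_seq=mrna_seq,
        cds_interval=cds_mrna,
        exon_intervals=tuple(exons),
        strand=strand,
        contig=contig,
    )


def write_calls_gff3(path, calls: Sequence[RetrocopyCall]) -> None:
    """Write retrocopy calls as GFF3 features with annotation attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, start=1):
            intronless = (
                "indeterminate" if c.is_intronless is None else str(c.is_intronless).lower()
            )
            attrs = (
                f"ID=retrocall{i};intronless={intronless};"
                f"truncation_5p={c.truncation_5p};covered_span={c.covered_span};"
                f"longest_orf_codons={c.longest_orf.n_codons};"
                f"n_inactivating={len(c.inactivating_mutations)};"
                f"n_motifs={len(c.motif_hits)}"
            )
            fh.write(
                f"{c.subject_id}\tretrofossil\tpseudogenic_region\t{c.s_start + 1}\t"
                f"{c.s_end}\t.\t{c.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# metadata and config


def read_metadata_tsv(path):
    """Dataset metadata TSV: dataset_id, species, tissue, tissue_class."""
    from .expression import DatasetMeta

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["dataset_id", "species", "tissue", "tissue_class"]
        if header[: len(required)] != required:
            raise ValueError(f"metadata header must start with {required}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            out.append(DatasetMeta(*fields[:4]))
    return out


def write_metadata_tsv(path, meta) -> None:
    with open(path, "w") as fh:
        fh.write("dataset_id\tspecies\ttissue\ttissue_class\n")
        for m in meta:
            fh.write(f"{m.dataset_id}\t{m.species}\t{m.tissue}\t{m.tissue_class}\n")


def load_sim_config(path) -> tuple[MutationParameters, SimulationConfig]:
    """Load mutation parameters and simulation settings from YAML/JSON.

    A ``preset`` key selects one of the named parameter sets; explicit
    ``sub_rate``/``ins_rate``/``del_rate``/``generation_time`` keys override
    its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "preset" in raw:
        base = PRESETS[raw["preset"]]
    else:
        base = MutationParameters(
            raw["sub_rate"], raw["ins_rate"], raw["del_rate"], raw["generation_time"]
        )
    params = MutationParameters(
        sub_rate=float(raw.get("sub_rate", base.sub_rate)),
        ins_rate=float(raw.get("ins_rate", base.ins_rate)),
        del_rate=float(raw.get("del_rate", base.del_rate)),
        generation_time=float(raw.get("generation_time", base.generation_time)),
        label=raw.get("preset", base.label),
    )
    config = SimulationConfig(
        horizon_years=float(raw.get("horizon_years", 50e6)),
        census_interval_years=float(raw.get("census_interval_years", 50e3)),
        n_replicates=int(raw.get("n_replicates", 10_000)),
        seed=int(raw.get("seed", 0)),
        require_start_codon=bool(raw.get("require_start_codon", True)),
    )
    return params, config


# ---------------------------------------------------------------------------
# manifest


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, stages: list[dict], seed: int, params: dict) -> str:
    """Write the machine-readable run manifest next to the outputs.

    Each stage entry lists its inputs and output files; outputs get content
    hashes so identical configurations can be verified to reproduce
    identical artifacts."""
    from . import __version__

    outdir = Path(outdir)
    manifest = {
        "package": "retrofossil",
        "version": __version__,
        "seed": seed,
        "parameter_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": [],
    }
    for stage in stages:
        entry = {
            "name": stage["name"],
            "inputs": stage.get("inputs", []),
            "outputs": {
                str(p): _file_sha256(p) for p in stage.get("outputs", [])
            },
        }
        manifest["stages"].append(entry)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return str(path)
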