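"""Exact-match unique read assignment and the tissue expression matrix.

A read counts toward a reference (a retrocopy or the parent gene) only if
it matches the reference at 100% identity across its entire length and maps
to exactly one of the references; reads matching two or more references are
"multi", reads with any mismatch or ambiguous base are "none".  Reads
matching on the reverse complement count by default (library strandedness
unknown), and paired-end mates are treated as independent reads.

Per-dataset counts are averaged within (species, tissue) and displayed as
log10(count + 1), tissues grouped germline → brain → blood → other.
"""
from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._codec import revcomp

__all__ = [
    "ReferenceSet",
    "DatasetMeta",
    "ExpressionMatrix",
    "assign_read",
    "count_reads",
    "build_matrix",
    "TISSUE_CLASS_ORDER",
]

TISSUE_CLASS_ORDER = ("germline", "brain", "blood", "other")
RESERVED_COLUMNS = ("multi", "none")

_INDEX_K = 20


@dataclass
class ReferenceSet:
    """The query references: parent mRNA/CDS plus every retrocopy sequence.

    Builds a k-mer position index on first use so that read verification
    touches only candidate references.
    """

    records: list[tuple[str, str]]

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids")
        if any(not seq for _, seq in self.records):
            raise ValueError("empty reference sequence")
        if any(r in ids for r in RESERVED_COLUMNS):
            raise ValueError(f"reference ids {RESERVED_COLUMNS} are reserved")
        self.records = [(i, s.upper()) for i, s in self.records]
        self._index: dict[str, list[tuple[int, int]]] | None = None

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def max_length(self) -> int:
        return max(len(s) for _, s in self.records)

    def _build_index(self) -> dict[str, list[tuple[int, int]]]:
        if self._index is None:
            index: dict[str, list[tuple[int, int]]] = {}
            for ref_i, (_, seq) in enumerate(self.records):
                for p in range(len(seq) - _INDEX_K + 1):
                    index.setdefault(seq[p : p + _INDEX_K], []).append((ref_i, p))
            self._index = index
        return self._index

    def _matches(self, read: str) -> set[int]:
        """Indices of references containing ``read`` verbatim (one strand)."""
        out: set[int] = set()
        if len(read) >= _INDEX_K:
            for ref_i, p in self._build_index().get(read[:_INDEX_K], ()):
                if ref_i in out:
                    continue
                if self.records[ref_i][1][p : p + len(read)] == read:
                    out.add(ref_i)
        else:
            for ref_i, (_, seq) in enumerate(self.records):
                if read in seq:
                    out.add(ref_i)
        return out


def assign_read(read: str, refs: ReferenceSet, both_strands: bool = True) -> str:
    """Assign one read under the 100%-identity unique-mapping rule.

    Returns the unique reference id containing the read as an exact
    substring (forward or, when ``both_strands``, reverse complement);
    ``"multi"`` when two or more references contain it; ``"none"`` when no
    reference does or the read holds a base outside ACGT.
    """
    read = read.upper()
    if not read or len(read) > refs.max_length:
        return "none"
    if any(b not in "ACGT" for b in read):
        return "none"
    found = refs._matches(read)
    if both_strands:
        found |= refs._matches(revcomp(read))
    if not found:
        return "none"
    if len(found) > 1:
        return "multi"
    return refs.records[found.pop()][0]


@dataclass(frozen=True)
class DatasetMeta:
    dataset_id: str
    species: str
    tissue: str
    tissue_class: str = "other"

    def __post_init__(self):
        if self.tissue_class not in TISSUE_CLASS_ORDER:
            raise ValueError(
                f"tissue_class must be one of {TISSUE_CLASS_ORDER}, "
                f"got {self.tissue_class!r}"
            )


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(source) -> Iterable[tuple[str, str]]:
    """Yield (read_id, sequence); raises with the record index on bad input."""
    if isinstance(source, (str, Path)):
        handle = _open_maybe_gzip(source)
        close = True
    else:
        handle = source
        close = False
    i = 0
    try:
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield title.split()[0] if title else f"read{i}", seq
            i += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at index {i}: {exc}") from exc
    finally:
        if close:
            handle.close()


def count_reads(
    fastq_by_dataset: Mapping[str, object],
    refs: ReferenceSet,
    meta: Sequence[DatasetMeta],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Tally uniquely assigned reads per (dataset, reference).

    ``fastq_by_dataset`` maps dataset ids to FASTQ paths (optionally
    gzipped) or open text handles.  The result has one row per dataset and
    one column per reference, plus ``multi`` and ``none`` QC columns;
    assigned + multi + none equals the total reads of the dataset.
    """
    ids_by_dataset = {m.dataset_id: m for m in meta}
    if len(ids_by_dataset) != len(meta):
        raise ValueError("duplicate dataset ids in metadata")
    unknown = set(fastq_by_dataset) - set(ids_by_dataset)
    if unknown:
        raise ValueError(f"datasets without metadata: {sorted(unknown)}")
    columns = refs.ids + list(RESERVED_COLUMNS)
    rows = {}
    for dataset_id, source in fastq_by_dataset.items():
        counts = dict.fromkeys(columns, 0)
        for _rid, seq in _iter_fastq(source):
            counts[assign_read(seq, refs, both_strands)] += 1
        rows[dataset_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "dataset_id"
    return df.astype(np.int64)


@dataclass
class ExpressionMatrix:
    """References × (species, tissue) mean read counts with a log view."""

    raw: pd.DataFrame

    @property
    def log10(self) -> pd.DataFrame:
        return np.log10(self.raw + 1.0)

    def to_tsv(self, path, log: bool = False) -> None:
        frame = self.log10 if log else self.raw
        out = frame.copy()
        out.columns = [f"{sp}:{ti}" for sp, ti in out.columns]
        out.to_csv(path, sep="\t", index_label="reference")


def build_matrix(
    counts: pd.DataFrame,
    meta: Sequence[DatasetMeta],
) -> ExpressionMatrix:
    """Average per-dataset counts within (species, tissue).

    Reference rows keep their input order; tissue columns are grouped
    germline → brain → blood → other (then alphabetically).  Datasets whose
    id is missing from ``meta`` are assigned tissue ``"other"`` with a
    warning.
    """
    if counts.empty:
        raise ValueError("need at least one dataset")
    by_id = {m.dataset_id: m for m in meta}
    keys = []
    for dataset_id in counts.index:
        m = by_id.get(dataset_id)
        if m is None:
            warnings.warn(f"dataset {dataset_id!r} missing from metadata; tissue=other")
            m = DatasetMeta(dataset_id, "unknown", "other", "other")
        keys.append((m.species, m.tissue, m.tissue_class))
    ref_cols = [c for c in counts.columns if c not in RESERVED_COLUMNS]
    work = counts[ref_cols].copy()
    work.index = pd.MultiIndex.from_tuples(keys, names=["species", "tissue", "tissue_class"])
    mean = work.groupby(level=["species", "tissue", "tissue_class"], sort=False).mean()
    order = sorted(
        mean.index,
        key=lambda k: (TISSUE_CLASS_ORDER.index(k[2]), k[0], k[1]),
    )
    mean = mean.loc[order]
    mean.index = pd.MultiIndex.from_tuples(
        [(sp, ti) for sp, ti, _ in mean.index], names=["species", "tissue"]
    )
    return ExpressionMatrix(raw=mean.T)
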