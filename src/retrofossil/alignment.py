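"""Codon-aware, frameshift-tolerant alignment of a retrocopy to its parent.

Aligns retrocopy *nucleotides* to parent *amino acids* with a three-frame
dynamic program: a codon step consumes 3 nt against one parent residue
(BLOSUM62 score of its translation), frameshift steps consume 2 or 4 nt
against one residue (charged an explicit frameshift penalty), and gap states
insert whole retro codons or delete whole parent codons with affine
nucleotide costs.  The alignment is local (free ends), so the reported
events are those inside the best-scoring aligned block — the "longest
indel-sensitive translation" of the retrocopy.

From the traceback we read off the inactivating mutations: premature stop
codons at their parent codon position, and ±1-bp frameshifts (as
``frameshift_ins`` / ``frameshift_del``).  Tie-breaking is deterministic:
codon match is preferred over frameshift over gap, and the leftmost optimum
wins.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from ._codec import AA_BY_CODON_INDEX, encode

__all__ = [
    "FrameshiftScoring",
    "Mutation",
    "MutationReport",
    "map_inactivating_mutations",
]

NEG = -1e9


@dataclass(frozen=True)
class FrameshiftScoring:
    """Scoring for the frameshift-tolerant DP (all values are penalties > 0
    except the substitution matrix).  Gap costs are in nucleotide units:
    a k-codon gap costs ``gap_open + 3k * gap_extend``."""

    gap_open: float = 11.0
    gap_extend: float = 1.0
    frameshift: float = 15.0
    matrix_name: str = "BLOSUM62"
    min_score: float = 40.0


@dataclass(frozen=True)
class Mutation:
    """One inactivating mutation, positioned on the parent (1-based codon)."""

    kind: str  # premature_stop | frameshift_ins | frameshift_del
    parent_codon: int

    def __post_init__(self):
        if self.kind not in ("premature_stop", "frameshift_ins", "frameshift_del"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.parent_codon < 1:
            raise ValueError("codon positions are 1-based")


@dataclass
class MutationReport:
    status: str  # "ok" | "unalignable"
    mutations: list[Mutation] = field(default_factory=list)
    score: float = 0.0
    parent_span: tuple[int, int] = (0, 0)  # [start, end) in parent codons, 0-based
    retro_span: tuple[int, int] = (0, 0)  # [start, end) in retro nt


_MATRIX_CACHE: dict[str, tuple[dict[str, int], np.ndarray]] = {}


def _scoring_arrays(name: str) -> tuple[dict[str, int], np.ndarray]:
    if name not in _MATRIX_CACHE:
        mat = substitution_matrices.load(name)
        alphabet = str(mat.alphabet)
        aa_index = {aa: i for i, aa in enumerate(alphabet)}
        arr = np.array(mat, dtype=float)
        _MATRIX_CACHE[name] = (aa_index, arr)
    return _MATRIX_CACHE[name]


def _codon_aa_codes(codes: np.ndarray, aa_index: dict[str, int]) -> np.ndarray:
    """aa-index of the codon starting at each position (length n-2)."""
    n = codes.size
    if n < 3:
        return np.empty(0, dtype=np.int64)
    idx = 16 * codes[: n - 2].astype(np.int64) + 4 * codes[1 : n - 1] + codes[2:]
    aas = AA_BY_CODON_INDEX[idx]
    return np.array([aa_index[a] for a in aas], dtype=np.int64)


def map_inactivating_mutations(
    retro_seq: str,
    parent_protein: str,
    scoring: FrameshiftScoring | None = None,
) -> MutationReport:
    """Align ``retro_seq`` to ``parent_protein`` and report premature stops
    and 1-bp frameshifts at their parent codon positions.

    Returns a report with status ``"unalignable"`` when no local alignment
    reaches ``scoring.min_score``.
    """
    scoring = scoring or FrameshiftScoring()
    codes = encode(retro_seq)
    n = codes.size
    N = len(parent_protein)
    if n < 3 or N == 0:
        return MutationReport(status="unalignable")
    aa_index, S = _scoring_arrays(scoring.matrix_name)
    trans = _codon_aa_codes(codes, aa_index)  # length n-2
    stop_code = aa_index["*"]
    parent_codes = np.array(
        [aa_index.get(a, aa_index.get("X", 0)) for a in parent_protein], dtype=np.int64
    )

    fs = scoring.frameshift
    open3 = scoring.gap_open + 3 * scoring.gap_extend  # first codon of a gap
    ext3 = 3 * scoring.gap_extend  # each further codon
    ext = scoring.gap_extend

    # DP matrices over (i = retro nt consumed 0..n, j = parent aa consumed 0..N)
    M = np.full((n + 1, N + 1), NEG)
    Ix = np.full((n + 1, N + 1), NEG)  # retro codon insertions
    Iy = np.full((n + 1, N + 1), NEG)  # parent codon deletions
    B = np.zeros((n + 1, N + 1))  # best, floored at 0 (local)

    rows = np.arange(n + 1, dtype=float)
    for j in range(1, N + 1):
        pj = parent_codes[j - 1]
        bprev = B[:, j - 1]
        col = np.full(n + 1, NEG)
        # codon match: consume 3 nt
        col[3:] = bprev[:-3] + S[trans[: n - 2], pj]
        # frameshift +1: consume 4 nt, score translation of the first 3
        if n >= 4:
            cand = bprev[:-4] + S[trans[: n - 3], pj] - fs
            np.maximum(col[4:], cand, out=col[4:])
        # frameshift -1: consume 2 nt, penalty only
        cand = bprev[:-2] - fs
        np.maximum(col[2:], cand, out=col[2:])
        M[:, j] = col

        Iy[:, j] = np.maximum(bprev - open3, Iy[:, j - 1] - ext3)

        pre = np.maximum(np.maximum(M[:, j], Iy[:, j]), 0.0)
        ixc = np.full(n + 1, NEG)
        for r in range(3):
            idx = np.arange(r, n + 1, 3)
            if idx.size > 1:
                acc = np.maximum.accumulate(pre[idx] + ext * rows[idx])
                ixc[idx[1:]] = acc[:-1] - scoring.gap_open - ext * rows[idx[1:]]
        Ix[:, j] = ixc
        B[:, j] = np.maximum(pre, ixc)

    best = float(B[:, 1:].max()) if N else 0.0
    if best < scoring.min_score:
        return MutationReport(status="unalignable", score=best)

    # leftmost optimum: smallest j, then smallest i
    jj, ii = divmod(int(np.argmax(B[:, 1:].T)), n + 1)
    j, i = jj + 1, ii

    eps = 1e-6
    events: list[Mutation] = []
    end_span = (i, j)
    state = "B"
    while B[i, j] > eps or state != "B":
        if state == "B":
            if abs(B[i, j] - M[i, j]) < eps:
                state = "M"
            elif abs(B[i, j] - Iy[i, j]) < eps:
                state = "Iy"
            elif abs(B[i, j] - Ix[i, j]) < eps:
                state = "Ix"
            else:  # pragma: no cover - floor cell
                break
            continue
        if state == "M":
            pj = parent_codes[j - 1]
            v = M[i, j]
            if i >= 3 and abs(v - (B[i - 3, j - 1] + S[trans[i - 3], pj])) < eps:
                if trans[i - 3] == stop_code:
                    events.append(Mutation("premature_stop", j))
                i, j = i - 3, j - 1
            elif i >= 4 and abs(v - (B[i - 4, j - 1] + S[trans[i - 4], pj] - fs)) < eps:
                events.append(Mutation("frameshift_ins", j))
                i, j = i - 4, j - 1
            elif i >= 2 and abs(v - (B[i - 2, j - 1] - fs)) < eps:
                events.append(Mutation("frameshift_del", j))
                i, j = i - 2, j - 1
            else:  # pragma: no cover
                raise AssertionError("traceback failed in M state")
            state = "B"
        elif state == "Iy":
            if abs(Iy[i, j] - (B[i, j - 1] - open3)) < eps:
                j -= 1
                state = "B"
            else:
                j -= 1
                state = "Iy"
        else:  # Ix: opened from M/Iy/start (never from Ix itself)
            pre_val = max(M[i - 3, j], Iy[i - 3, j], 0.0)
            if abs(Ix[i, j] - (pre_val - open3)) < eps:
                i -= 3
                if abs(pre_val - M[i, j]) < eps:
                    state = "M"
                elif abs(pre_val - Iy[i, j]) < eps:
                    state = "Iy"
                else:  # pre_val == 0: the alignment starts here
                    break
            else:
                i -= 3
                state = "Ix"

    events.reverse()
    return MutationReport(
        status="ok",
        mutations=events,
        score=best,
        parent_span=(j, end_span[1]),
        retro_span=(i, end_span[0]),
    )
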