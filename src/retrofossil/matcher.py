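"""A small exact-seed, ungapped-extension matcher for synthetic genomes.

Finds candidate loci of a query mRNA in a set of contigs: exact k-mer seeds
(default 15) are extended without gaps in both directions under an X-drop
rule, then trimmed to the maximum-scoring span; hits below an identity
floor are discarded.  Indels in a copy break it into multiple hits on
adjacent diagonals, which ``annotate.merge_hits`` later stitches together.

This is deliberately not a sensitive genome-scale homology search — it
replaces the external search step only at desk scale, on genomes where the
planted copies diverge by point mutations and short indels.
"""
from __future__ import annotations

from .annotate import CandidateHit
from ._codec import revcomp

__all__ = ["find_candidate_hits"]

MATCH = 1
MISMATCH = -2


def _extend(query: str, target: str, qpos: int, tpos: int, k: int, xdrop: int):
    """Ungapped X-drop extension around an exact seed; returns the trimmed
    max-scoring span as (q0, q1, t0, t1, n_match, length) or None."""
    # extend right from the seed end
    qi, ti = qpos + k, tpos + k
    score = best = k * MATCH
    best_right = (qi, ti)
    while qi < len(query) and ti < len(target):
        score += MATCH if query[qi] == target[ti] else MISMATCH
        qi += 1
        ti += 1
        if score > best:
            best = score
            best_right = (qi, ti)
        elif best - score > xdrop:
            break
    q1, t1 = best_right
    # extend left from the seed start
    qi, ti = qpos, tpos
    score = best
    peak = best
    best_left = (qi, ti)
    while qi > 0 and ti > 0:
        qi -= 1
        ti -= 1
        score += MATCH if query[qi] == target[ti] else MISMATCH
        if score > peak:
            peak = score
            best_left = (qi, ti)
        elif peak - score > xdrop:
            break
    q0, t0 = best_left
    length = q1 - q0
    n_match = sum(1 for a, b in zip(query[q0:q1], target[t0:t1]) if a == b)
    return q0, q1, t0, t1, n_match, length


def find_candidate_hits(
    query: str,
    contigs: dict[str, str],
    query_id: str = "query",
    k: int = 15,
    min_identity: float = 0.8,
    min_length: int = 25,
    xdrop: int = 12,
) -> list[CandidateHit]:
    """Locate near-exact copies of ``query`` in ``contigs`` on both strands."""
    query = query.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        index.setdefault(query[i : i + k], []).append(i)
    hits: list[CandidateHit] = []
    for contig_id, contig_seq in contigs.items():
        contig_seq = contig_seq.upper()
        L = len(contig_seq)
        for strand in "+-":
            target = contig_seq if strand == "+" else revcomp(contig_seq)
            covered: dict[int, int] = {}  # diagonal -> rightmost extended t
            for tpos in range(len(target) - k + 1):
                for qpos in index.get(target[tpos : tpos + k], ()):
                    diag = tpos - qpos
                    if covered.get(diag, -1) >= tpos:
                        continue
                    q0, q1, t0, t1, n_match, length = _extend(
                        query, target, qpos, tpos, k, xdrop
                    )
                    covered[diag] = t1
                    if length < min_length or n_match / length < min_identity:
                        continue
                    if strand == "+":
                        s_start, s_end = t0, t1
                    else:
                        s_start, s_end = L - t1, L - t0
                    hits.append(
                        CandidateHit(
                            query_id=query_id,
                            subject_id=contig_id,
                            q_start=q0,
                            q_end=q1,
                            s_start=s_start,
                            s_end=s_end,
                            strand=strand,
                            percent_identity=100.0 * n_match / length,
                            alignment_length=length,
                        )
                    )
    # drop hits wholly contained in another hit on the same subject/strand
    hits.sort(key=lambda h: (h.subject_id, h.strand, h.s_start, -h.s_end))
    kept: list[CandidateHit] = []
    for h in hits:
        if kept and (
            h.subject_id == kept[-1].subject_id
            and h.strand == kept[-1].strand
            and h.s_start >= kept[-1].s_start
            and h.s_end <= kept[-1].s_end
        ):
            continue
        kept.append(h)
    return kept
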