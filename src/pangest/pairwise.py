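"""Local-alignment evidence: tabular hits, a built-in aligner, HSP merging.

Coverage of a sequence pair is computed from the union of the query intervals
of all retained high-scoring segment pairs (HSPs), divided by the length of
the shorter sequence (default) or the longer one (full-length mode), so split
genes, truncated transcripts and retained introns — which each surface as
several collinear HSPs — still reach full coverage.

The built-in aligner is a seed-and-extend scheme over exact k-mer seeds: each
diagonal carrying a seed is swept for maximal-scoring ungapped segments.
Insertions or deletions between two sequences (a retained intron, a split
gene) shift the diagonal and therefore yield separate HSPs, which is exactly
the representation the merging step expects.  An exhaustive local aligner is
used only as a test oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, TextIO

from .clustering import Edge, SimilarityGraph
from .seqio import AccessionSet, SequenceRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

EVALUE_WEIGHT_CAP = 300.0


def revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


@dataclass
class HSP:
    """One ungapped or gapped local-alignment segment (tabular-hit semantics).

    Coordinates are 1-based inclusive; a subject interval with
    ``s_start > s_end`` marks a reverse-strand alignment.
    """

    q_id: str
    s_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def is_self(self) -> bool:
        return self.q_id == self.s_id

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"q_start > q_end in HSP {self.q_id}->{self.s_id}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")


@dataclass
class PairwiseHit:
    """Per ordered sequence pair: merged coverage, identity and scores."""

    q_id: str
    s_id: str
    Lq: int
    Ls: int
    coverage: float
    identity: float
    covered_bp: int
    best_evalue: float
    total_bitscore: float
    strand: str


# ---------------------------------------------------------------------------
# tabular parsing
# ---------------------------------------------------------------------------

def parse_tabular_hits(
    stream: TextIO | Iterable[str],
    seqs: Optional[AccessionSet] = None,
    strict: bool = False,
) -> list[HSP]:
    """Parse 12-column tabular hits (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore).

    Unknown ids and malformed lines are skipped with a warning unless
    ``strict`` is set, in which case they raise.  Self-hits are retained (and
    flagged via :attr:`HSP.is_self`).
    """
    known = set(seqs.by_id()) if seqs is not None else None
    hsps: list[HSP] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            if strict:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            logger.warning("skipping malformed line %d (%d columns)", lineno, len(fields))
            continue
        try:
            hsp = HSP(
                q_id=fields[0],
                s_id=fields[1],
                pct_identity=float(fields[2]),
                aln_len=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
            )
        except ValueError as exc:
            if strict:
                raise ValueError(f"line {lineno}: {exc}") from exc
            logger.warning("skipping line %d: %s", lineno, exc)
            continue
        if known is not None and (hsp.q_id not in known or hsp.s_id not in known):
            if strict:
                raise KeyError(f"line {lineno}: unknown sequence id")
            logger.warning("skipping line %d: unknown id", lineno)
            continue
        hsps.append(hsp)
    return hsps


def write_tabular_hits(hsps: Iterable[HSP], stream: TextIO) -> None:
    for h in hsps:
        stream.write(
            f"{h.q_id}\t{h.s_id}\t{h.pct_identity:.2f}\t{h.aln_len}\t{h.mismatches}\t"
            f"{h.gap_opens}\t{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
            f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
        )


# ---------------------------------------------------------------------------
# built-in aligner
# ---------------------------------------------------------------------------

def _diagonal_segments(
    query: str,
    target: str,
    diag: int,
    match: int,
    mismatch: int,
    xdrop: int,
) -> list[tuple[int, int, int]]:
    """Maximal-scoring ungapped segments (q0, q1, n_matches) on one diagonal.

    ``diag = q_pos - t_pos``.  N bases never count as matches.
    """
    q0 = max(0, diag)
    q1 = min(len(query), len(target) + diag)
    segments: list[tuple[int, int, int]] = []
    score = 0
    best = 0
    seg_start = q0
    best_range: Optional[tuple[int, int]] = None
    i = q0
    while i < q1:
        qc = query[i]
        ok = qc == target[i - diag] and qc != "N"
        score += match if ok else mismatch
        if score <= 0:
            if best_range is not None:
                segments.append(best_range)
            score, best, best_range = 0, 0, None
            seg_start = i + 1
        elif score > best:
            best = score
            best_range = (seg_start, i + 1)
        elif best_range is not None and best - score >= xdrop:
            segments.append(best_range)
            score, best = 0, 0
            seg_start = i + 1
            best_range = None
        i += 1
    if best_range is not None:
        segments.append(best_range)

    out = []
    for a, b in segments:
        # trim terminal mismatches (segments should start/end on matches)
        while a < b and not (query[a] == target[a - diag] and query[a] != "N"):
            a += 1
        while b > a and not (query[b - 1] == target[b - 1 - diag] and query[b - 1] != "N"):
            b -= 1
        if b <= a:
            continue
        n_match = sum(
            1 for i in range(a, b) if query[i] == target[i - diag] and query[i] != "N"
        )
        out.append((a, b, n_match))
    return out


def _surrogate_evalue(Lq: int, Ls: int, bitscore: float) -> float:
    # Karlin-Altschul shape with fixed constants; only the ordering matters
    log10_e = math.log10(Lq) + math.log10(Ls) - bitscore * math.log10(2.0)
    if log10_e < -300:
        return 0.0
    return 10.0 ** log10_e


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    min_hsp_len: int = 30,
    min_hsp_identity: float = 90.0,
    k: int = 12,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 20,
    q_id: str = "query",
    s_id: str = "subject",
) -> list[HSP]:
    """Find high-identity local segments between two sequences on both strands.

    Returns zero or more HSPs; each reported segment has identity at least
    ``min_hsp_identity`` and length at least ``min_hsp_len``.  Segments
    separated by unalignable gaps (retained introns, split genes) come back
    as distinct HSPs.
    """
    if isinstance(a, SequenceRecord):
        q_id, qseq = a.seq_id, a.nt
    else:
        qseq = a
    if isinstance(b, SequenceRecord):
        s_id, sseq = b.seq_id, b.nt
    else:
        sseq = b
    if not qseq or not sseq:
        raise ValueError("local_align requires non-empty sequences")
    Lq, Ls = len(qseq), len(sseq)

    hsps: list[HSP] = []
    for strand, target in (("+", sseq), ("-", revcomp(sseq))):
        kmers: dict[str, list[int]] = {}
        for i in range(len(target) - k + 1):
            km = target[i : i + k]
            if "N" in km:
                continue
            kmers.setdefault(km, []).append(i)
        diagonals: set[int] = set()
        for i in range(Lq - k + 1):
            km = qseq[i : i + k]
            if "N" in km:
                continue
            for j in kmers.get(km, ()):
                diagonals.add(i - j)
        for diag in sorted(diagonals):
            for q0, q1, n_match in _diagonal_segments(
                qseq, target, diag, match, mismatch, xdrop
            ):
                seg_len = q1 - q0
                identity = 100.0 * n_match / seg_len
                if seg_len < min_hsp_len or identity < min_hsp_identity:
                    continue
                n_mismatch = seg_len - n_match
                score = n_match * match + n_mismatch * mismatch
                bitscore = 2.0 * score
                t0, t1 = q0 - diag, q1 - diag
                if strand == "+":
                    s_start, s_end = t0 + 1, t1
                else:
                    s_start, s_end = Ls - t0, Ls - t1 + 1
                hsps.append(
                    HSP(
                        q_id=q_id,
                        s_id=s_id,
                        pct_identity=round(identity, 2),
                        aln_len=seg_len,
                        mismatches=n_mismatch,
                        gap_opens=0,
                        q_start=q0 + 1,
                        q_end=q1,
                        s_start=s_start,
                        s_end=s_end,
                        evalue=_surrogate_evalue(Lq, Ls, bitscore),
                        bitscore=bitscore,
                    )
                )
    hsps.sort(key=lambda h: (-h.bitscore, h.q_start))
    return hsps


def mirror_hsp(h: HSP) -> HSP:
    """The same alignment reported with query and subject swapped."""
    if h.strand == "+":
        q_start, q_end, s_start, s_end = h.s_start, h.s_end, h.q_start, h.q_end
    else:
        q_start, q_end, s_start, s_end = h.s_end, h.s_start, h.q_end, h.q_start
    return HSP(
        q_id=h.s_id,
        s_id=h.q_id,
        pct_identity=h.pct_identity,
        aln_len=h.aln_len,
        mismatches=h.mismatches,
        gap_opens=h.gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=h.evalue,
        bitscore=h.bitscore,
    )


def all_vs_all_hsps(
    seqs: AccessionSet,
    k: int = 12,
    min_shared_kmers: int = 3,
    min_hsp_len: int = 30,
    min_hsp_identity: float = 90.0,
) -> list[HSP]:
    """Built-in all-vs-all alignment with a shared-k-mer candidate prefilter.

    Only sequence pairs sharing at least ``min_shared_kmers`` distinct k-mers
    (on either strand) are aligned; both hit directions are emitted so the
    result matches the all-vs-all tabular convention.
    """
    records = list(seqs)
    posting: dict[str, set[int]] = {}
    for i, rec in enumerate(records):
        seen = set()
        for strand_seq in (rec.nt,):
            for p in range(len(strand_seq) - k + 1):
                km = strand_seq[p : p + k]
                if "N" in km:
                    continue
                canon = min(km, revcomp(km))
                if canon not in seen:
                    posting.setdefault(canon, set()).add(i)
                    seen.add(canon)

    pair_counts: dict[tuple[int, int], int] = {}
    for members in posting.values():
        if len(members) < 2 or len(members) > 200:
            continue
        ms = sorted(members)
        for x in range(len(ms)):
            for y in range(x + 1, len(ms)):
                key = (ms[x], ms[y])
                pair_counts[key] = pair_counts.get(key, 0) + 1

    hsps: list[HSP] = []
    for (i, j), count in sorted(pair_counts.items()):
        if count < min_shared_kmers:
            continue
        found = local_align(
            records[i],
            records[j],
            min_hsp_len=min_hsp_len,
            min_hsp_identity=min_hsp_identity,
            k=k,
        )
        hsps.extend(found)
        hsps.extend(mirror_hsp(h) for h in found)
    return hsps


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _interval_union(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end + 1:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    return total + (cur_end - cur_start + 1)


def merge_hsps(
    hsps: list[HSP],
    Lq: int,
    Ls: int,
    mode: str = "shortest",
) -> PairwiseHit:
    """Aggregate the HSPs of one ordered pair into a coverage/identity summary.

    Only HSPs on the majority strand (by summed bitscore) are retained; their
    query intervals are unioned (overlaps counted once) and coverage is the
    union length over ``min(Lq, Ls)`` (``shortest`` mode) or ``max(Lq, Ls)``
    (``longest`` mode).  Identity is the alignment-length-weighted mean of the
    retained HSP identities, so short fragments do not dominate.
    """
    if not hsps:
        raise ValueError("merge_hsps requires at least one HSP")
    q_id, s_id = hsps[0].q_id, hsps[0].s_id
    if any(h.q_id != q_id or h.s_id != s_id for h in hsps):
        raise ValueError("merge_hsps requires HSPs of a single ordered pair")
    if Lq <= 0 or Ls <= 0:
        raise ValueError("sequence lengths must be positive")
    if mode not in ("shortest", "longest"):
        raise ValueError(f"unknown coverage mode {mode!r}")

    by_strand = {"+": 0.0, "-": 0.0}
    for h in hsps:
        by_strand[h.strand] += h.bitscore
    strand = "+" if by_strand["+"] >= by_strand["-"] else "-"
    retained = [h for h in hsps if h.strand == strand]

    covered = _interval_union([(h.q_start, h.q_end) for h in retained])
    denom = min(Lq, Ls) if mode == "shortest" else max(Lq, Ls)
    total_len = sum(h.aln_len for h in retained)
    identity = sum(h.pct_identity * h.aln_len for h in retained) / total_len
    return PairwiseHit(
        q_id=q_id,
        s_id=s_id,
        Lq=Lq,
        Ls=Ls,
        coverage=min(100.0, 100.0 * covered / denom),
        identity=identity,
        covered_bp=covered,
        best_evalue=min(h.evalue for h in retained),
        total_bitscore=sum(h.bitscore for h in retained),
        strand=strand,
    )


def group_hsps_by_pair(hsps: Iterable[HSP]) -> dict[tuple[str, str], list[HSP]]:
    grouped: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        grouped.setdefault((h.q_id, h.s_id), []).append(h)
    return grouped


def merge_all_pairs(
    hsps: Iterable[HSP],
    seqs: AccessionSet,
    mode: str = "shortest",
    full_length_ids: Optional[set[str]] = None,
) -> dict[tuple[str, str], PairwiseHit]:
    """Merged :class:`PairwiseHit` per ordered pair (self-pairs excluded)."""
    full_length_ids = full_length_ids or set()
    lengths = {rec.seq_id: rec.length for rec in seqs}
    merged: dict[tuple[str, str], PairwiseHit] = {}
    for (q, s), group in group_hsps_by_pair(hsps).items():
        if q == s or q not in lengths or s not in lengths:
            continue
        pair_mode = (
            "longest" if (q in full_length_ids and s in full_length_ids) else mode
        )
        merged[(q, s)] = merge_hsps(group, lengths[q], lengths[s], mode=pair_mode)
    return merged


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------

def evalue_weight(evalue: float) -> float:
    if evalue <= 0.0:
        return EVALUE_WEIGHT_CAP
    return min(EVALUE_WEIGHT_CAP, -math.log10(evalue))


def build_similarity_graph(
    hsps: Iterable[HSP],
    seqs: AccessionSet,
    min_identity: float = 95.0,
    min_coverage: float = 50.0,
    full_length_ids: Optional[set[str]] = None,
) -> SimilarityGraph:
    """Threshold merged pairwise hits into a directed similarity graph.

    An edge q->s exists iff the merged hit reaches ``min_identity`` AND
    ``min_coverage`` (both inclusive).  Coverage is computed over the longer
    sequence only when both ids are declared full-length cDNAs.  Edge weight
    is the capped ``-log10(evalue)``; self-edges are excluded and the best hit
    per (source, target accession) is indexed for BDBH/in-paralog logic.
    """
    graph = SimilarityGraph(min_identity=min_identity, min_coverage=min_coverage)
    for rec in seqs:
        graph.add_node(rec.seq_id, rec.accession, rec.length)
    merged = merge_all_pairs(hsps, seqs, mode="shortest", full_length_ids=full_length_ids)
    for (q, s), hit in sorted(merged.items()):
        if hit.identity >= min_identity and hit.coverage >= min_coverage:
            graph.add_edge(
                q,
                s,
                Edge(
                    weight=evalue_weight(hit.best_evalue),
                    bitscore=hit.total_bitscore,
                    evalue=hit.best_evalue,
                    identity=hit.identity,
                    coverage=hit.coverage,
                    covered_bp=hit.covered_bp,
                    strand=hit.strand,
                ),
            )
    return graph
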