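"""CDS-consensus inference, retained-intron flags, enrichment, expression.

Consensus CDS calls combine two evidence sources: open reading frames found
by a six-frame scan, and frame-resolved protein-homology hits on the
transcript.  When the best ORF and the best homology region agree in frame
and overlap, their union span is emitted; when they disagree, the homology
evidence wins; with a single evidence source, that source is used; with
neither, the transcript is labelled non-coding.  Emitted CDS always translate
without internal stops and have length divisible by 3.

Domain enrichment compares an "experiment" set of clusters against a
"control" set with one-sided Fisher exact tests, counting each domain at
most once per cluster (so multi-isoform clusters are not over-weighted), and
adjusts p-values with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio.Seq import Seq
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .clustering import Cluster
from .evolution import BoxStats, box_stats
from .pairwise import local_align, revcomp
from .seqio import AccessionSet, SequenceRecord

_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfCandidate:
    """A candidate coding region on a transcript.

    Coordinates are 0-based half-open on the forward strand of the
    transcript; frames are +1/+2/+3 (forward, offset 0/1/2) and -1/-2/-3
    (reverse complement).  The span excludes the stop codon, so its
    translation equals ``peptide``.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    complete5: bool
    complete3: bool
    peptide: str


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def _scan_frame(seq: str, offset: int) -> list[tuple[int, int, bool, bool]]:
    """Stop-free codon runs in one frame: (start, end, edge5, stopped3).

    Codons containing N terminate a run without acting as a stop.
    """
    runs = []
    run_start = offset
    at_edge = True
    i = offset
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if codon in _STOP_CODONS or "N" in codon:
            if i > run_start:
                runs.append((run_start, i, at_edge, codon in _STOP_CODONS))
            run_start = i + 3
            at_edge = False
        i += 3
    if i > run_start:
        runs.append((run_start, i, at_edge, False))
    return runs


def find_orfs(t: SequenceRecord, min_aa: int = 50) -> list[OrfCandidate]:
    """All maximal ORFs of at least ``min_aa`` residues across six frames.

    Each stop-free run yields one candidate: anchored at its first ATG when
    one exists (``complete5`` true), otherwise reported from the run start
    but only when the run is truncated by the sequence edge — an internal
    ATG-less run has no plausible start.  ``complete3`` marks runs ended by a
    genuine stop codon.  Candidates are sorted by peptide length descending.
    """
    candidates: list[OrfCandidate] = []
    L = len(t.nt)
    for strand_sign, seq in ((1, t.nt), (-1, revcomp(t.nt))):
        for offset in range(3):
            frame = strand_sign * (offset + 1)
            for run_start, run_end, at_edge, stopped in _scan_frame(seq, offset):
                atg = seq.find("ATG", run_start, run_end)
                while atg != -1 and (atg - run_start) % 3 != 0:
                    atg = seq.find("ATG", atg + 1, run_end)
                if atg != -1:
                    start, complete5 = atg, True
                elif at_edge:
                    start, complete5 = run_start, False
                else:
                    continue
                peptide = _translate(seq[start:run_end])
                if len(peptide) < min_aa or not peptide:
                    continue
                if strand_sign == 1:
                    fwd_start, fwd_end = start, run_end
                else:
                    fwd_start, fwd_end = L - run_end, L - start
                candidates.append(
                    OrfCandidate(
                        transcript_id=t.seq_id,
                        frame=frame,
                        start=fwd_start,
                        end=fwd_end,
                        complete5=complete5,
                        complete3=stopped,
                        peptide=peptide,
                    )
                )
    candidates.sort(key=lambda c: (-len(c.peptide), c.frame, c.start))
    return candidates


# ---------------------------------------------------------------------------
# consensus CDS
# ---------------------------------------------------------------------------

@dataclass
class HomologyHit:
    """Frame-resolved protein-homology evidence on a transcript.

    ``t_start``/``t_end`` are 0-based half-open on the transcript forward
    strand; ``frame`` follows the same +-1/2/3 convention as ORFs.
    """

    t_start: int
    t_end: int
    frame: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.t_start < 0 or self.t_end <= self.t_start:
            raise ValueError("inconsistent homology hit coordinates")


def _frame_span(L: int, frame: int, start: int, end: int) -> tuple[int, int]:
    """Snap a forward-strand span onto codon boundaries of ``frame``."""
    if frame > 0:
        offset = frame - 1
        s = start + ((offset - start) % 3)
        e = s + ((end - s) // 3) * 3
    else:
        # work from the 3' end on the reverse strand
        offset = -frame - 1
        # reverse-strand codon boundaries: positions L-offset, L-offset-3, ...
        e = end - ((end - (L - offset)) % 3)
        s = e - ((e - start) // 3) * 3
    return s, e


def _stop_free_window(nt: str, s: int, e: int, frame: int,
                      prefer_start: int, prefer_end: int) -> tuple[int, int]:
    """Largest stop-free codon stretch inside [s, e), preferring overlap with
    the [prefer_start, prefer_end) region."""
    span = nt[s:e] if frame > 0 else revcomp(nt[s:e])
    codons = [span[i : i + 3] for i in range(0, len(span), 3)]
    stretches = []
    cur = 0
    for i, codon in enumerate(codons + ["TAA"]):
        if codon in _STOP_CODONS:
            if i > cur:
                stretches.append((cur, i))
            cur = i + 1
    if not stretches:
        return s, s
    def fwd_bounds(stretch: tuple[int, int]) -> tuple[int, int]:
        c0, c1 = stretch
        if frame > 0:
            return s + 3 * c0, s + 3 * c1
        return e - 3 * c1, e - 3 * c0
    def key(stretch):
        f0, f1 = fwd_bounds(stretch)
        overlap = max(0, min(f1, prefer_end) - max(f0, prefer_start))
        return (overlap, f1 - f0)
    best = max(stretches, key=key)
    return fwd_bounds(best)


def consensus_cds(
    t: SequenceRecord,
    orfs: list[OrfCandidate],
    homology_hits: list[HomologyHit],
) -> tuple[Optional[str], Optional[str], str]:
    """Consensus CDS from ORF and homology evidence.

    Agreement (same frame, overlapping spans) assembles the union span into a
    larger CDS; disagreement defers to homology; a single evidence source is
    used as-is; no evidence labels the transcript non-coding.  Output is
    always stop-free and divisible by 3.
    """
    best_orf = orfs[0] if orfs else None
    best_hit = max(homology_hits, key=lambda h: (h.score, h.t_end - h.t_start)) if homology_hits else None

    def emit(start: int, end: int, frame: int, tag: str,
             prefer: Optional[tuple[int, int]] = None):
        s, e = _frame_span(t.length, frame, start, end)
        if prefer is None:
            prefer = (s, e)
        s, e = _stop_free_window(t.nt, s, e, frame, *prefer)
        if e <= s:
            return None, None, "non-coding"
        span = t.nt[s:e] if frame > 0 else revcomp(t.nt[s:e])
        return span, _translate(span), tag

    if best_orf is None and best_hit is None:
        return None, None, "non-coding"
    if best_hit is None:
        return emit(best_orf.start, best_orf.end, best_orf.frame, "orf")
    if best_orf is None:
        return emit(best_hit.t_start, best_hit.t_end, best_hit.frame, "homology")

    overlap = min(best_orf.end, best_hit.t_end) - max(best_orf.start, best_hit.t_start)
    if best_orf.frame == best_hit.frame and overlap > 0:
        return emit(
            min(best_orf.start, best_hit.t_start),
            max(best_orf.end, best_hit.t_end),
            best_orf.frame,
            "both",
            prefer=(best_orf.start, best_orf.end),
        )
    return emit(best_hit.t_start, best_hit.t_end, best_hit.frame, "homology")


# ---------------------------------------------------------------------------
# retained introns
# ---------------------------------------------------------------------------

def flag_retained_introns(
    transcripts: AccessionSet,
    introns: Iterable[SequenceRecord] | dict[str, str],
    min_len: int = 100,
    min_identity: float = 98.0,
) -> dict[str, bool]:
    """Flag transcripts carrying an intron alignment longer than ``min_len``
    (strictly) at ``min_identity`` or better."""
    if isinstance(introns, dict):
        intron_list = [(k, v) for k, v in introns.items()]
    else:
        intron_list = [(r.seq_id, r.nt) for r in introns]
    if not intron_list:
        raise ValueError("empty intron reference set")
    flags: dict[str, bool] = {}
    for rec in transcripts:
        flagged = False
        for intron_id, intron_nt in intron_list:
            hsps = local_align(
                intron_nt,
                rec.nt,
                min_hsp_len=min(min_len, 30),
                min_hsp_identity=min_identity,
                q_id=intron_id,
                s_id=rec.seq_id,
            )
            if any(h.aln_len > min_len and h.pct_identity >= min_identity for h in hsps):
                flagged = True
                break
        flags[rec.seq_id] = flagged
    return flags


# ---------------------------------------------------------------------------
# domain enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    domain_acc: str
    k_exp: int
    n_exp: int
    k_ctl: int
    n_ctl: int
    odds_ratio: float
    p_value: float
    fdr: float
    direction: str  # enriched | depleted


def read_domain_table(path: str | Path) -> dict[str, set[str]]:
    """TSV mapping seq_id -> domain accession ('#' comments allowed)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "seq_id":
                continue
            out.setdefault(row[0], set()).add(row[1])
    return out


def domain_enrichment(
    experiment_clusters: Iterable[Cluster],
    control_clusters: Iterable[Cluster],
    domains: dict[str, set[str]],
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Per-domain Fisher exact test of experiment vs control cluster sets.

    A domain is counted at most once per cluster, no matter how many isoforms
    carry it.  P-values are exact conditional (hypergeometric) tails per
    ``alternative`` and adjusted with Benjamini–Hochberg FDR across all
    tested domains; results are sorted by FDR.
    """
    experiment = list(experiment_clusters)
    control = list(control_clusters)
    if not experiment:
        raise ValueError("empty experiment cluster set")
    exp_ids = {c.cluster_id for c in experiment}
    ctl_ids = {c.cluster_id for c in control}
    if not exp_ids <= ctl_ids:
        warnings.warn("experiment set is not a subset of the control set")

    def cluster_domains(cluster: Cluster) -> set[str]:
        found: set[str] = set()
        for sid in cluster.all_sequences():
            found |= domains.get(sid, set())
        return found

    exp_doms = [cluster_domains(c) for c in experiment]
    ctl_doms = [cluster_domains(c) for c in control]
    tested = sorted(set().union(*exp_doms, *ctl_doms)) if (exp_doms or ctl_doms) else []
    n_exp, n_ctl = len(experiment), len(control)

    raw: list[tuple[str, int, int, float, float]] = []
    for dom in tested:
        k_exp = sum(1 for d in exp_doms if dom in d)
        k_ctl = sum(1 for d in ctl_doms if dom in d)
        table = [[k_exp, n_exp - k_exp], [k_ctl, n_ctl - k_ctl]]
        odds, p = fisher_exact(table, alternative=alternative)
        raw.append((dom, k_exp, k_ctl, odds, p))
    if not raw:
        return []
    _, fdrs, _, _ = multipletests([r[4] for r in raw], method="fdr_bh")
    results = []
    for (dom, k_exp, k_ctl, odds, p), fdr in zip(raw, fdrs):
        direction = "enriched" if k_exp / n_exp >= k_ctl / n_ctl else "depleted"
        results.append(
            EnrichmentResult(
                domain_acc=dom,
                k_exp=k_exp,
                n_exp=n_exp,
                k_ctl=k_ctl,
                n_ctl=n_ctl,
                odds_ratio=float(odds),
                p_value=float(p),
                fdr=float(fdr),
                direction=direction,
            )
        )
    results.sort(key=lambda r: (r.fdr, r.p_value, r.domain_acc))
    return results


# ---------------------------------------------------------------------------
# expression by occupancy class
# ---------------------------------------------------------------------------

def read_tpm_table(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "seq_id":
                continue
            out[row[0]] = float(row[1])
    return out


@dataclass
class ExpressionSummary:
    per_occupancy: dict[int, BoxStats]
    per_class: dict[str, BoxStats]
    cluster_expression: dict[str, float]
    n_no_data: int


def expression_by_class(
    clusters: Iterable[Cluster],
    classes: dict[str, str],
    tpm: dict[str, float],
    treat_missing_as_zero: bool = False,
) -> ExpressionSummary:
    """Cluster expression = mean TPM of members with data, summarized per
    occupancy level and per occupancy class.

    Members without a TPM value are treated as missing (not zero) unless
    ``treat_missing_as_zero``; clusters with no expressed member are excluded
    and tallied in ``n_no_data``.
    """
    if not tpm:
        raise ValueError("empty TPM table")
    cluster_expr: dict[str, float] = {}
    occupancy: dict[str, int] = {}
    no_data = 0
    for cluster in clusters:
        values = []
        for sid in cluster.all_sequences():
            if sid in tpm:
                values.append(tpm[sid])
            elif treat_missing_as_zero:
                values.append(0.0)
        if not values:
            no_data += 1
            continue
        cluster_expr[cluster.cluster_id] = sum(values) / len(values)
        occupancy[cluster.cluster_id] = cluster.occupancy
    per_occ: dict[int, list[float]] = {}
    per_cls: dict[str, list[float]] = {}
    for cid, expr in cluster_expr.items():
        per_occ.setdefault(occupancy[cid], []).append(expr)
        label = classes.get(cid)
        if label is not None:
            per_cls.setdefault(label, []).append(expr)
    return ExpressionSummary(
        per_occupancy={k: box_stats(v) for k, v in sorted(per_occ.items())},
        per_class={k: box_stats(v) for k, v in per_cls.items()},
        cluster_expression=cluster_expr,
        n_no_data=no_data,
    )
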