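"""Synthetic multi-accession pan-transcriptomes with ground truth.

The generator emulates the inputs of a same-species clustering run: gene
families assigned to core / shell / cloud occupancy classes, per-accession
copies diverged by codon-aware substitutions, and the degeneracies real
transcript sets show — redundant isoforms, truncated fragments, genes split
into two records, and retained non-coding introns — each recorded in a truth
table so every downstream module can be tested without any real data.

``divergence`` is the expected pairwise nucleotide divergence between the
copies of two accessions; each copy is mutated at ``divergence / 2`` from the
family ancestor.  A copy is never split when it is the only copy of its
family: two split halves share no alignment, so an occupancy-1 split family
would be unclusterable by construction rather than by failure of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .seqio import AccessionSet, SequenceRecord

_BASES = "ACGT"
_STOP_CODONS = ("TAA", "TAG", "TGA")
_CODON_POOL = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOP_CODONS
]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic pan-genome."""

    n_accessions: int = 6
    n_core: int = 50
    n_shell: int = 30
    n_cloud: int = 20
    divergence: float = 0.01  # expected pairwise divergence between accessions
    gene_length_range: tuple[int, int] = (300, 2400)  # bp, divisible by 3
    isoform_rate: float = 0.10
    fragment_rate: float = 0.07
    split_rate: float = 0.06
    intron_retention_rate: float = 0.07
    fragment_fraction_range: tuple[float, float] = (0.4, 0.8)
    intron_length_range: tuple[int, int] = (120, 300)
    # log-normal expression per class: (mean of log TPM, sd of log TPM)
    expression_law: dict = field(
        default_factory=lambda: {
            "core": (3.5, 0.8),
            "shell": (2.5, 0.8),
            "cloud": (0.5, 0.8),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 3:
            raise ValueError("need at least 3 accessions")
        for rate in (
            self.isoform_rate,
            self.fragment_rate,
            self.split_rate,
            self.intron_retention_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3 or lo < 90:
            raise ValueError("gene lengths must be divisible by 3 and >= 90")
        if self.n_shell and self.n_accessions < 4:
            raise ValueError("shell families need occupancies in 3..N-1, so N >= 4")


@dataclass
class FamilyTruth:
    family_id: str
    label: str  # core | shell | cloud
    members: dict[str, list[str]]  # accession -> seq ids
    occupancy: int
    tpm: dict[str, float]  # seq id -> programmed TPM


@dataclass
class TruthTable:
    families: dict[str, FamilyTruth]
    intron_registry: dict[str, tuple[int, int]]  # seq id -> (position, length)
    fragment_registry: dict[str, str]  # fragment/split seq id -> kind
    divergence: float

    def family_of(self) -> dict[str, str]:
        out = {}
        for fam in self.families.values():
            for ids in fam.members.values():
                for sid in ids:
                    out[sid] = fam.family_id
        return out

    def member_sets(self) -> dict[str, frozenset]:
        return {
            fam.family_id: frozenset(
                sid for ids in fam.members.values() for sid in ids
            )
            for fam in self.families.values()
        }

    def occupancy_of(self) -> dict[str, int]:
        return {f.family_id: f.occupancy for f in self.families.values()}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_cds(length: int, rng: np.random.Generator) -> str:
    n_codons = length // 3 - 2
    body = "".join(rng.choice(_CODON_POOL) for _ in range(n_codons))
    stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    return "ATG" + body + stop


def mutate_sequence(
    nt: str,
    rate: float,
    mode: str = "any",
    seed=None,
) -> str:
    """Substitute bases at an expected per-site rate.

    ``any`` is codon-aware when the length is divisible by 3: substitutions
    never create internal stop codons, and the first and last codons (start
    and stop) are left intact.  ``synonymous_only`` never changes the
    peptide; ``nonsynonymous_biased`` prefers amino-acid-changing (non-stop)
    substitutions where one exists.
    """
    rng = _rng(seed)
    if rate <= 0.0:
        return nt
    seq = list(nt)
    codon_aware = len(nt) % 3 == 0 and mode in ("any", "synonymous_only", "nonsynonymous_biased")
    if mode in ("synonymous_only", "nonsynonymous_biased") and not codon_aware:
        raise ValueError(f"mode {mode!r} requires length divisible by 3")

    def codon_at(i: int) -> str:
        c = 3 * (i // 3)
        return "".join(seq[c : c + 3])

    lo = 3 if codon_aware else 0
    hi = len(seq) - 3 if codon_aware else len(seq)
    n_sites = hi - lo
    n_mut = rng.binomial(n_sites, min(rate, 1.0))
    positions = rng.choice(n_sites, size=n_mut, replace=False) + lo
    for i in sorted(int(p) for p in positions):
        current = seq[i]
        choices = [b for b in _BASES if b != current]
        rng.shuffle(choices)
        old_codon = codon_at(i) if codon_aware else None
        picked = None
        fallback = None
        for base in choices:
            if not codon_aware:
                picked = base
                break
            pos_in_codon = i % 3
            new_codon = old_codon[:pos_in_codon] + base + old_codon[pos_in_codon + 1 :]
            if new_codon in _STOP_CODONS:
                continue
            syn = (
                Seq(old_codon).translate() == Seq(new_codon).translate()
            )
            if mode == "synonymous_only":
                if syn:
                    picked = base
                    break
            elif mode == "nonsynonymous_biased":
                if not syn:
                    picked = base
                    break
                fallback = fallback or base
            else:
                picked = base
                break
        if picked is None and mode == "nonsynonymous_biased":
            picked = fallback
        if picked is not None:
            seq[i] = picked
    return "".join(seq)


def degrade_copy(
    nt: str,
    kind: str,
    params: Optional[dict] = None,
    seed=None,
) -> tuple[list[str], dict]:
    """Apply one transcript degeneracy; returns pieces + a registry entry.

    ``fragment`` keeps a contiguous subsequence; ``split`` cuts the gene into
    two non-overlapping pieces covering it; ``retained_intron`` inserts a
    random non-coding stretch at a codon boundary.
    """
    rng = _rng(seed)
    params = params or {}
    if kind == "fragment":
        lo, hi = params.get("fraction_range", (0.4, 0.8))
        frac = rng.uniform(lo, hi)
        keep = max(int(len(nt) * frac), params.get("min_len", 60))
        if keep > len(nt):
            raise ValueError("fragment longer than source")
        start = int(rng.integers(0, len(nt) - keep + 1))
        return [nt[start : start + keep]], {"kind": "fragment", "start": start, "len": keep}
    if kind == "split":
        lo = int(len(nt) * params.get("min_side", 0.3))
        hi = len(nt) - lo
        if hi <= lo:
            raise ValueError("sequence too short to split")
        cut = int(rng.integers(lo, hi + 1))
        return [nt[:cut], nt[cut:]], {"kind": "split", "cut": cut}
    if kind == "retained_intron":
        lo, hi = params.get("length_range", (120, 300))
        ilen = int(rng.integers(lo, hi + 1))
        intron = "".join(rng.choice(list(_BASES)) for _ in range(ilen))
        n_codons = len(nt) // 3
        at_codon = int(rng.integers(1, max(n_codons, 2)))
        pos = 3 * at_codon
        return [nt[:pos] + intron + nt[pos:]], {
            "kind": "retained_intron",
            "pos": pos,
            "len": ilen,
            "intron": intron,
        }
    raise ValueError(f"unknown degradation kind {kind!r}")


def generate_pangenome(cfg: SynthConfig) -> tuple[AccessionSet, TruthTable]:
    """Generate a synthetic pan-transcriptome and its ground truth.

    Deterministic under ``cfg.seed``: same config, byte-identical sequences.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_accessions
    accessions = [f"acc{i + 1:02d}" for i in range(n)]
    seqs = AccessionSet(accessions=list(accessions), records={a: [] for a in accessions})

    families: dict[str, FamilyTruth] = {}
    intron_registry: dict[str, tuple[int, int]] = {}
    fragment_registry: dict[str, str] = {}

    specs = (
        [("core", i) for i in range(cfg.n_core)]
        + [("shell", i) for i in range(cfg.n_shell)]
        + [("cloud", i) for i in range(cfg.n_cloud)]
    )
    for fam_index, (label, _) in enumerate(specs):
        fam_id = f"fam{fam_index + 1:04d}"
        lo, hi = cfg.gene_length_range
        length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        ancestor = _random_cds(length, rng)
        if label == "core":
            carriers = list(range(n))
        elif label == "shell":
            occ = int(rng.integers(3, n))  # 3 .. N-1
            carriers = sorted(rng.choice(n, size=occ, replace=False).tolist())
        else:
            occ = int(rng.integers(1, 3))  # 1 or 2
            carriers = sorted(rng.choice(n, size=occ, replace=False).tolist())

        members: dict[str, list[str]] = {}
        tpm: dict[str, float] = {}
        mu, sigma = cfg.expression_law[label]
        for ci in carriers:
            acc = accessions[ci]
            base_id = f"{fam_id}_{acc}"
            copy = mutate_sequence(ancestor, cfg.divergence / 2.0, mode="any", seed=rng)

            r = rng.uniform()
            ids_and_seqs: list[tuple[str, str]] = []
            if r < cfg.fragment_rate:
                pieces, info = degrade_copy(
                    copy, "fragment",
                    {"fraction_range": cfg.fragment_fraction_range}, rng,
                )
                ids_and_seqs.append((base_id + "_frag", pieces[0]))
                fragment_registry[base_id + "_frag"] = "fragment"
            elif r < cfg.fragment_rate + cfg.split_rate and len(carriers) >= 2:
                pieces, info = degrade_copy(copy, "split", None, rng)
                ids_and_seqs.append((base_id + "_p1", pieces[0]))
                ids_and_seqs.append((base_id + "_p2", pieces[1]))
                fragment_registry[base_id + "_p1"] = "split"
                fragment_registry[base_id + "_p2"] = "split"
            elif r < cfg.fragment_rate + cfg.split_rate + cfg.intron_retention_rate:
                pieces, info = degrade_copy(
                    copy, "retained_intron",
                    {"length_range": cfg.intron_length_range}, rng,
                )
                ids_and_seqs.append((base_id, pieces[0]))
                intron_registry[base_id] = (info["pos"], info["len"])
            else:
                ids_and_seqs.append((base_id, copy))

            if rng.uniform() < cfg.isoform_rate:
                # a 3'-truncated redundant isoform of the first piece
                src = ids_and_seqs[0][1]
                keep = max(int(len(src) * rng.uniform(0.6, 0.9)), 60)
                ids_and_seqs.append((base_id + ".i1", src[:keep]))

            members[acc] = []
            base_tpm = float(rng.lognormal(mu, sigma))
            for sid, seq_nt in ids_and_seqs:
                peptide = None
                if len(seq_nt) % 3 == 0:
                    pep = str(Seq(seq_nt).translate())
                    if "*" not in pep[:-1]:
                        peptide = pep.rstrip("*")
                seqs.add(
                    SequenceRecord(seq_id=sid, accession=acc, nt=seq_nt, peptide=peptide)
                )
                members[acc].append(sid)
                tpm[sid] = round(base_tpm * float(rng.uniform(0.8, 1.25)), 3)

        families[fam_id] = FamilyTruth(
            family_id=fam_id,
            label=label,
            members=members,
            occupancy=len(members),
            tpm=tpm,
        )

    truth = TruthTable(
        families=families,
        intron_registry=intron_registry,
        fragment_registry=fragment_registry,
        divergence=cfg.divergence,
    )
    return seqs, truth


def write_truth(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# one row per family\n")
        fh.write("family_id\tclass\toccupancy\tmembers\n")
        for fam in truth.families.values():
            member_ids = ";".join(
                ",".join(ids) for ids in fam.members.values()
            )
            fh.write(f"{fam.family_id}\t{fam.label}\t{fam.occupancy}\t{member_ids}\n")


def write_tpm(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\ttpm\n")
        for fam in truth.families.values():
            for sid, value in fam.tpm.items():
                fh.write(f"{sid}\t{value}\n")
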