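"""Reading and writing per-accession sequence sets and cluster artifacts.

A pan-genome run starts from a folder of nucleotide FASTA files, one file
per accession/genotype, optionally gzip- or bzip2-compressed and optionally
paired with translated-peptide FASTA files sharing the same stem.  The
accession identifier is the file name minus its recognised extensions, since
every downstream structure (pan-genome matrix rows, ANI rows, growth curves)
is keyed by input file.
"""

from __future__ import annotations

import bz2
import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

NT_EXTENSIONS = (".fa", ".fna", ".fasta")
PEP_EXTENSIONS = (".faa", ".pep")
COMPRESSION_SUFFIXES = (".gz", ".bz2")

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass
class SequenceRecord:
    """One nucleotide sequence with its accession of origin."""

    seq_id: str
    accession: str
    nt: str
    peptide: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.nt)

    def __post_init__(self) -> None:
        if not self.nt:
            raise ValueError(f"empty sequence for {self.seq_id!r}")


@dataclass
class AccessionSet:
    """Ordered collection of per-accession sequence records."""

    accessions: list[str] = field(default_factory=list)
    records: dict[str, list[SequenceRecord]] = field(default_factory=dict)
    has_peptides: bool = False

    def __iter__(self) -> Iterable[SequenceRecord]:
        for acc in self.accessions:
            yield from self.records[acc]

    def __len__(self) -> int:
        return sum(len(v) for v in self.records.values())

    def by_id(self) -> dict[str, SequenceRecord]:
        return {rec.seq_id: rec for rec in self}

    def add(self, rec: SequenceRecord) -> None:
        if rec.accession not in self.records:
            self.accessions.append(rec.accession)
            self.records[rec.accession] = []
        self.records[rec.accession].append(rec)


def _open_maybe_compressed(path: Path) -> IO[str]:
    name = path.name
    if name.endswith(".gz"):
        return gzip.open(path, "rt")
    if name.endswith(".bz2"):
        return bz2.open(path, "rt")
    return open(path, "rt")


def _strip_extensions(name: str, extensions: tuple[str, ...]) -> Optional[str]:
    """File stem if ``name`` carries one of ``extensions`` (+- compression)."""
    for comp in COMPRESSION_SUFFIXES:
        if name.endswith(comp):
            name = name[: -len(comp)]
            break
    for ext in extensions:
        if name.endswith(ext):
            return name[: -len(ext)]
    return None


def _normalize_nt(raw: str, seq_id: str) -> str:
    nt = raw.upper().replace("U", "T")
    n_bad = len(_NON_ACGTN.findall(nt))
    if n_bad:
        logger.info("mapped %d non-ACGTN characters to N in %s", n_bad, seq_id)
        nt = _NON_ACGTN.sub("N", nt)
    return nt


def read_sequence_sets(
    folder: str | Path,
    extensions: tuple[str, ...] = NT_EXTENSIONS,
    peptide_extensions: tuple[str, ...] = PEP_EXTENSIONS,
) -> AccessionSet:
    """Read one accession per nucleotide FASTA file found under ``folder``.

    Headers are parsed up to the first whitespace; lowercase bases are
    uppercased and non-ACGTN characters mapped to N.  Duplicate ids across
    accessions are disambiguated by prefixing the accession id.  Peptide
    pairing is all-or-nothing: ``has_peptides`` is true only when every
    nucleotide file has a peptide mate with exactly matching ids.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"input folder {folder} does not exist")

    nt_files: dict[str, Path] = {}
    pep_files: dict[str, Path] = {}
    for path in sorted(folder.iterdir()):
        if not path.is_file():
            continue
        stem = _strip_extensions(path.name, extensions)
        if stem is not None:
            if stem in nt_files:
                raise ValueError(f"two nucleotide files for accession {stem!r}")
            nt_files[stem] = path
            continue
        stem = _strip_extensions(path.name, peptide_extensions)
        if stem is not None:
            pep_files[stem] = path
    if not nt_files:
        raise FileNotFoundError(f"no FASTA files with extensions {extensions} in {folder}")

    seen_ids: dict[str, str] = {}  # raw id -> accession of first occurrence
    out = AccessionSet()
    for accession, path in nt_files.items():
        with _open_maybe_compressed(path) as handle:
            raw_records = list(SeqIO.parse(handle, "fasta"))
        if not raw_records:
            raise ValueError(f"no FASTA entries in {path}")
        peptides: dict[str, str] = {}
        if accession in pep_files:
            with _open_maybe_compressed(pep_files[accession]) as handle:
                peptides = {r.id: str(r.seq).upper() for r in SeqIO.parse(handle, "fasta")}
            nt_ids = {r.id for r in raw_records}
            mismatched = sorted(set(peptides) - nt_ids)
            if mismatched:
                raise ValueError(
                    f"peptide file {pep_files[accession].name} has ids not present "
                    f"in its nucleotide mate: {', '.join(mismatched[:10])}"
                )
        for raw in raw_records:
            seq_id = raw.id
            if seq_id in seen_ids and seen_ids[seq_id] != accession:
                seq_id = f"{accession}|{seq_id}"
                logger.warning("duplicate id %s; prefixed as %s", raw.id, seq_id)
            if seq_id in seen_ids and seen_ids[seq_id] == accession:
                raise ValueError(f"duplicate id {seq_id!r} within accession {accession}")
            if f"{accession}|{raw.id}" in seen_ids:
                raise ValueError(f"id collision after prefixing: {accession}|{raw.id}")
            seen_ids[seq_id] = accession
            out.add(
                SequenceRecord(
                    seq_id=seq_id,
                    accession=accession,
                    nt=_normalize_nt(str(raw.seq), seq_id),
                    peptide=peptides.get(raw.id),
                )
            )
    out.has_peptides = bool(nt_files) and all(
        acc in pep_files
        and all(rec.peptide is not None for rec in out.records[acc])
        for acc in nt_files
    )
    return out


def _write_fasta(records: Iterable[tuple[str, str]], path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sequence_sets(seqs: AccessionSet, outdir: str | Path) -> list[Path]:
    """Write one nucleotide FASTA per accession (plus peptides when present)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for acc in seqs.accessions:
        path = outdir / f"{acc}.fna"
        _write_fasta(((r.seq_id, r.nt) for r in seqs.records[acc]), path)
        written.append(path)
        if all(r.peptide is not None for r in seqs.records[acc]):
            ppath = outdir / f"{acc}.faa"
            _write_fasta(((r.seq_id, r.peptide) for r in seqs.records[acc]), ppath)
            written.append(ppath)
    return written


def write_clusters(clusters, seqs: AccessionSet, outdir: str | Path) -> Path:
    """Write one FASTA per cluster plus a ``cluster_list`` text index.

    Clusters are ordered by descending occupancy then id; members follow the
    accession order of the input set.  Reruns on the same input are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = seqs.by_id()
    acc_rank = {acc: i for i, acc in enumerate(seqs.accessions)}

    ordered = sorted(clusters, key=lambda c: (-c.occupancy, c.cluster_id))
    list_path = outdir / "cluster_list.tsv"
    with open(list_path, "w") as fh:
        fh.write("# one row per cluster\n")
        fh.write("cluster_id\tsize\toccupancy\trepresentative\tmembers\n")
        for cluster in ordered:
            members = sorted(
                cluster.members, key=lambda m: (acc_rank[index[m].accession], m)
            )
            for m in members:
                if m not in index:
                    raise KeyError(f"cluster {cluster.cluster_id} member {m!r} not in input")
            rep = max(members, key=lambda m: (index[m].length, m))
            fh.write(
                f"{cluster.cluster_id}\t{len(members)}\t{cluster.occupancy}\t{rep}\t"
                + ",".join(members)
                + "\n"
            )
            _write_fasta(
                ((m, index[m].nt) for m in members),
                outdir / f"{cluster.cluster_id}_{rep}.fna",
            )
    return list_path
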