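"""TSS table ingestion, quality filtering, and strand-aware flank extraction.

Genomic input coordinates are 1-based inclusive (DBTSS style): ``pos`` is the
genomic coordinate of the first transcribed base.  Extracted flanks live on a
common TSS-relative frame where the +1 base sits at a fixed string offset and
increasing index means downstream of transcription; minus-strand records are
reverse-complemented at extraction time.  Windows overrunning a contig edge
are padded with ``N`` so that every extracted sequence has the same length
(``N`` is excluded from all frequency denominators downstream).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "TssRecord",
    "TssSet",
    "AlignedSeqSet",
    "read_tss_table",
    "read_tss_bed",
    "filter_tss",
    "extract_flanks",
    "reverse_complement",
    "concat_aligned",
    "write_aligned_fasta",
    "read_aligned_fasta",
]

_STRANDS = frozenset({"+", "-"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A=0 C=1 G=2 T=3, anything else (incl. N) = 4
BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_CODES[ord(_b)] = _i
    BASE_CODES[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TssRecord:
    """A single transcription start site anchored on the genome."""

    id: str
    chrom: str
    pos: int  # 1-based coordinate of the first transcribed base
    strand: str
    support: int = 0  # cDNAs mapping to this exact position
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"TSS {self.id!r}: pos must be >= 1, got {self.pos}")
        if self.strand not in _STRANDS:
            raise ValueError(f"TSS {self.id!r}: unknown strand {self.strand!r}")
        if self.support < 0:
            raise ValueError(f"TSS {self.id!r}: support must be >= 0")


@dataclass
class TssSet:
    """An ordered collection of TSS records with unique ids."""

    records: list[TssRecord] = field(default_factory=list)
    genome_id: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), set()
            for i in ids:
                (dup if i in seen else seen).add(i)
            raise ValueError(f"duplicate TSS ids: {sorted(dup)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TssRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> TssRecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass(eq=False)
class AlignedSeqSet:
    """N promoter sequences on a common TSS-relative coordinate frame.

    ``offset_of_tss`` is the 0-based string index of the +1 base in every
    sequence.  All sequences have identical length; minus-strand sources have
    been reverse-complemented so that increasing index = downstream of
    transcription.
    """

    sequences: list[str]
    offset_of_tss: int
    source_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.source_ids):
            raise ValueError("sequences and source_ids differ in length")
        if self.sequences:
            L = len(self.sequences[0])
            if any(len(s) != L for s in self.sequences):
                raise ValueError("all sequences must have identical length")
            if not 0 <= self.offset_of_tss < L:
                raise ValueError("offset_of_tss outside sequence bounds")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @cached_property
    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix, A=0 C=1 G=2 T=3 N/other=4."""
        if not self.sequences:
            return np.empty((0, 0), dtype=np.uint8)
        flat = np.frombuffer("".join(self.sequences).encode("ascii"), dtype=np.uint8)
        return BASE_CODES[flat].reshape(len(self.sequences), self.length)

    def subset(self, index: Sequence[int]) -> "AlignedSeqSet":
        index = np.asarray(index)
        return AlignedSeqSet(
            [self.sequences[i] for i in index],
            self.offset_of_tss,
            [self.source_ids[i] for i in index],
        )


def concat_aligned(sets: Iterable[AlignedSeqSet]) -> AlignedSeqSet:
    sets = list(sets)
    offsets = {s.offset_of_tss for s in sets}
    lengths = {s.length for s in sets}
    if len(offsets) != 1 or len(lengths) != 1:
        raise ValueError("cannot concatenate sets with differing frames")
    seqs: list[str] = []
    ids: list[str] = []
    for s in sets:
        seqs.extend(s.sequences)
        ids.extend(s.source_ids)
    return AlignedSeqSet(seqs, offsets.pop(), ids)


# ---------------------------------------------------------------------------
# Parsing

#: Column order of a plain DBTSS-style table: chrom, pos, strand, support, gene.
DEFAULT_DIALECT: dict[str, int | None] = {
    "chrom": 0,
    "pos": 1,
    "strand": 2,
    "support": 3,
    "gene_id": 4,
    "id": None,
}

_KNOWN_COLUMNS = {"id", "chrom", "pos", "strand", "support", "gene_id"}


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_tss_table(path, dialect: Mapping[str, int | None] | None = None,
                   genome_id: str = "") -> TssSet:
    """Read a tab-separated TSS table into a :class:`TssSet`.

    ``dialect`` maps field names to 0-based column indices (``id`` may be
    ``None``, in which case ids are synthesized as ``chrom:pos:strand``).  A
    header line whose fields name the known columns overrides the dialect;
    otherwise a non-numeric first line is skipped as a header.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    records: list[TssRecord] = []
    with _open_text(path) as fh:
        first_data = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.lstrip("#").split("\t")
            if first_data:
                names = [f.strip().lower() for f in fields]
                if set(names) <= _KNOWN_COLUMNS and "pos" in names:
                    dialect = {k: None for k in _KNOWN_COLUMNS}
                    dialect.update({n: i for i, n in enumerate(names)})
                    first_data = False
                    continue
                try:
                    int(fields[dialect["pos"]])
                except (ValueError, IndexError, TypeError):
                    if line.startswith("#"):
                        continue
                    raise ValueError(
                        f"{path}: line {lineno}: cannot parse position "
                        f"(and line is not a recognizable header)"
                    )
                first_data = False
            records.append(_parse_row(fields, dialect, lineno, path))
    return TssSet(records, genome_id=genome_id)


def _parse_row(fields, dialect, lineno, path) -> TssRecord:
    def get(name, default=None):
        idx = dialect.get(name)
        if idx is None:
            return default
        try:
            return fields[idx]
        except IndexError:
            raise ValueError(f"{path}: line {lineno}: missing column {name!r}")

    try:
        chrom = get("chrom")
        pos = int(get("pos"))
        strand = get("strand")
        support = int(get("support", "0") or 0)
        gene_id = get("gene_id", "") or ""
        rec_id = get("id") or f"{chrom}:{pos}:{strand}"
        return TssRecord(rec_id, chrom, pos, strand, support, gene_id)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: line {lineno}: {exc}") from None


def read_tss_bed(path, genome_id: str = "") -> TssSet:
    """Read TSSs from BED6 (0-based half-open): TSS = start+1 on '+', end on '-'.

    The BED score column is interpreted as cDNA support.
    """
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}: line {lineno}: BED6 requires 6 columns")
            try:
                chrom, start, end, name, score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            pos = start + 1 if strand == "+" else end
            support = int(float(score)) if score not in (".", "") else 0
            records.append(TssRecord(name, chrom, pos, strand, support))
    return TssSet(records, genome_id=genome_id)


# ---------------------------------------------------------------------------
# Filtering

def filter_tss(tss: TssSet, min_support: int = 2, cluster_bp: int = 200) -> TssSet:
    """Apply the support and clustering quality filters.

    Records supported by fewer than ``min_support`` cDNAs are dropped.  Among
    the survivors, same-chromosome records linked transitively by pairwise
    distance <= ``cluster_bp`` (single linkage) are collapsed to the record
    with maximal support; ties break to the smaller genomic coordinate (then
    lexicographically smaller id).  The operation is idempotent: retained
    records from distinct clusters are by construction > ``cluster_bp`` apart.
    """
    survivors = [r for r in tss.records if r.support >= min_support]
    by_chrom: dict[str, list[TssRecord]] = {}
    for r in survivors:
        by_chrom.setdefault(r.chrom, []).append(r)

    keep_ids: set[str] = set()
    for chrom_records in by_chrom.values():
        ordered = sorted(chrom_records, key=lambda r: (r.pos, r.id))
        cluster: list[TssRecord] = []
        for r in ordered:
            if cluster and r.pos - cluster[-1].pos > cluster_bp:
                keep_ids.add(_cluster_representative(cluster).id)
                cluster = []
            cluster.append(r)
        if cluster:
            keep_ids.add(_cluster_representative(cluster).id)

    return TssSet([r for r in tss.records if r.id in keep_ids], genome_id=tss.genome_id)


def _cluster_representative(cluster: list[TssRecord]) -> TssRecord:
    return max(cluster, key=lambda r: (r.support, -r.pos, r.id))


# ---------------------------------------------------------------------------
# Flank extraction

def _contig_names(genome) -> set[str]:
    return set(genome.keys())


def extract_flanks(tss: TssSet, genome, upstream: int = 1000,
                   downstream: int = 1000) -> AlignedSeqSet:
    """Extract TSS-aligned flanking windows from a genome.

    ``genome`` may be a mapping ``{chrom: sequence}``, a :class:`pyfaidx.Fasta`
    handle, or a path to an (indexable) FASTA file.  Each returned sequence
    has length ``upstream + downstream`` with the +1 base at string offset
    ``upstream``.  Minus-strand records are reverse-complemented; windows that
    overrun a contig edge are padded with ``N``.
    """
    if isinstance(genome, (str, Path)):
        import pyfaidx

        genome = pyfaidx.Fasta(str(genome))
    missing = sorted({r.chrom for r in tss} - _contig_names(genome))
    if missing:
        offenders = [r.id for r in tss if r.chrom in set(missing)]
        raise KeyError(
            f"chromosomes {missing} absent from genome (records: {offenders[:10]})"
        )

    seqs: list[str] = []
    for r in tss:
        contig = genome[r.chrom]
        if r.strand == "+":
            g_start, g_end = r.pos - upstream, r.pos + downstream - 1
        else:
            g_start, g_end = r.pos - downstream + 1, r.pos + upstream
        window = _fetch_padded(contig, g_start, g_end)
        seqs.append(window if r.strand == "+" else reverse_complement(window))
    return AlignedSeqSet(seqs, upstream, tss.ids())


def _fetch_padded(contig, g_start: int, g_end: int) -> str:
    """1-based inclusive fetch with N padding outside [1, len(contig)]."""
    n = len(contig)
    left_pad = max(0, 1 - g_start)
    right_pad = max(0, g_end - n)
    a = max(g_start, 1)
    b = min(g_end, n)
    core = str(contig[a - 1 : b]).upper() if b >= a else ""
    return "N" * left_pad + core + "N" * right_pad


# ---------------------------------------------------------------------------
# Aligned-set serialization (offset recorded in FASTA headers)

def write_aligned_fasta(seqs: AlignedSeqSet, path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for sid, seq in zip(seqs.source_ids, seqs.sequences):
            fh.write(f">{sid} offset={seqs.offset_of_tss}\n{seq}\n")


def read_aligned_fasta(path) -> AlignedSeqSet:
    ids: list[str] = []
    seqs: list[str] = []
    offset = None
    with _open_text(path) as fh:
        current: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if current:
                    seqs.append("".join(current))
                    current = []
                head = line[1:].split()
                ids.append(head[0])
                for tok in head[1:]:
                    if tok.startswith("offset="):
                        offset = int(tok.split("=", 1)[1])
            elif line:
                current.append(line)
        if current:
            seqs.append("".join(current))
    if offset is None:
        raise ValueError(f"{path}: no offset= annotation in headers")
    return AlignedSeqSet(seqs, offset, ids)
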