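"""Core domain types and readers/writers for the formats the pipeline touches.

Sequence data move through the pipeline as :class:`QualRead` (a read with
per-base Phred scores), reference databases as :class:`ReferenceDB` (FASTA
plus an 8-rank lineage table in the PR2 style), and count data as
:class:`OtuTable` (OTU x sample integer matrix with centroid sequences and
lineage annotations).  All text formats are plain TSV/FASTA/FASTQ so that
every intermediate is diff-able.

FASTQ is fixed to the Sanger Phred+33 dialect.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

#: The eight PR2-style taxonomic ranks, shallowest first.
RANKS = (
    "kingdom",
    "supergroup",
    "division",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
N_RANKS = len(RANKS)

#: Index (0-based) of the class rank (PR2 level 4), used for cross-marker
#: taxonomy matching.
CLASS_LEVEL = 3

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(slots=True)
class QualRead:
    """A sequence read with per-base Phred quality scores.

    Parameters
    ----------
    id:
        Read identifier (FASTQ header without the leading ``@``).
    seq:
        Nucleotide string over ``{A, C, G, T, N}``.
    quals:
        Integer Phred scores, one per base.
    orientation:
        ``"forward"`` or ``"reverse"``.
    discarded:
        Set by trimming steps when the read can no longer be used.
    reason:
        Why the read was discarded, if it was.
    """

    id: str
    seq: str
    quals: np.ndarray
    orientation: str = "forward"
    discarded: bool = False
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )
        if len(self.quals) and self.quals.min() < 0:
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True, slots=True)
class Lineage:
    """An 8-rank taxonomy path with an assignment depth.

    ``ranks`` always has 8 entries; entries beyond ``depth`` are empty
    strings.  ``depth == 0`` means unclassified.
    """

    ranks: tuple[str, ...]
    depth: int

    def __post_init__(self) -> None:
        if len(self.ranks) != N_RANKS:
            raise ValueError(f"lineage must have {N_RANKS} ranks, got {len(self.ranks)}")
        if not 0 <= self.depth <= N_RANKS:
            raise ValueError(f"depth must be in [0, {N_RANKS}], got {self.depth}")
        for name in self.ranks[self.depth :]:
            if name:
                raise ValueError("ranks beyond the assignment depth must be empty")
        for name in self.ranks[: self.depth]:
            if not name:
                raise ValueError("assigned ranks must be non-empty")

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse a semicolon-joined lineage; trailing empty ranks allowed."""
        parts = [p.strip() for p in text.split(";")] if text.strip() else []
        while parts and not parts[-1]:
            parts.pop()
        if len(parts) > N_RANKS:
            raise FormatError(f"lineage has {len(parts)} ranks, expected <= {N_RANKS}: {text!r}")
        if any(not p for p in parts):
            raise FormatError(f"lineage has an empty internal rank: {text!r}")
        depth = len(parts)
        return cls(tuple(parts) + ("",) * (N_RANKS - depth), depth)

    @classmethod
    def unclassified(cls) -> "Lineage":
        return cls(("",) * N_RANKS, 0)

    def to_string(self) -> str:
        return ";".join(self.ranks[: self.depth])

    def truncate(self, depth: int) -> "Lineage":
        """Return this lineage cut to at most ``depth`` ranks."""
        depth = min(depth, self.depth)
        return Lineage(self.ranks[:depth] + ("",) * (N_RANKS - depth), depth)

    def name_at(self, level: int) -> str:
        """Rank name at 1-based PR2 level; empty if unassigned there."""
        return self.ranks[level - 1]


@dataclasses.dataclass(frozen=True, slots=True)
class RefEntry:
    seq: str
    lineage: Lineage


@dataclasses.dataclass(slots=True)
class ReferenceDB:
    """Reference sequences with fully specified 8-rank lineages."""

    entries: dict[str, RefEntry]

    def __post_init__(self) -> None:
        for rid, entry in self.entries.items():
            if not entry.seq:
                raise ValueError(f"reference {rid!r} has an empty sequence")
            if entry.lineage.depth != N_RANKS:
                raise ValueError(f"reference {rid!r} lineage is not fully specified")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, rid: str) -> bool:
        return rid in self.entries

    def ids(self) -> list[str]:
        return list(self.entries)

    def lineage(self, rid: str) -> Lineage:
        return self.entries[rid].lineage

    def seq(self, rid: str) -> str:
        return self.entries[rid].seq

    def without(self, ids: Iterable[str]) -> "ReferenceDB":
        """A copy with the given ids removed."""
        drop = set(ids)
        return ReferenceDB({k: v for k, v in self.entries.items() if k not in drop})


@dataclasses.dataclass(slots=True)
class OtuTable:
    """OTU x sample count matrix with centroids and lineage annotations."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    centroids: dict[str, str]
    lineages: dict[str, Lineage]
    marker: str
    junctions: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        missing = [o for o in self.otu_ids if o not in self.centroids]
        if missing:
            raise ValueError(f"OTUs without centroid sequence: {missing[:5]}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> dict[str, int]:
        return dict(zip(self.sample_ids, self.counts.sum(axis=0).tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def subset_otus(self, keep: Iterable[str]) -> "OtuTable":
        keep = list(keep)
        idx = [self.otu_ids.index(o) for o in keep]
        return OtuTable(
            otu_ids=keep,
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
            centroids={o: self.centroids[o] for o in keep},
            lineages={o: self.lineages[o] for o in keep if o in self.lineages},
            marker=self.marker,
            junctions={o: self.junctions[o] for o in keep if o in self.junctions},
        )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def parse_fastq(path: str | Path, orientation: str = "forward") -> Iterator[QualRead]:
    """Stream reads from a Sanger (Phred+33) FASTQ file.

    Malformed records raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"{path}:{lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FormatError(
                    f"{path}:{lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            if len(quals) and quals.min() < 0:
                raise FormatError(f"{path}:{lineno}: quality character below '!' (Phred+33)")
            yield QualRead(header[1:].split()[0], seq.upper(), quals, orientation)


def write_fastq(reads: Iterable[QualRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = (read.quals.astype(np.uint8) + 33).tobytes().decode("ascii")
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------


def parse_reference_db(fasta_path: str | Path, taxonomy_path: str | Path) -> ReferenceDB:
    """Load a reference FASTA plus an id -> 8-rank lineage TSV.

    The taxonomy table has two columns (id, semicolon-joined lineage) and
    must cover every FASTA id with exactly eight ranks.
    """
    lineages: dict[str, Lineage] = {}
    with open(taxonomy_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{taxonomy_path}:{lineno}: expected 2 columns, got {len(fields)}")
            rid, lineage_str = fields
            lineage = Lineage.from_string(lineage_str)
            if lineage.depth != N_RANKS:
                raise FormatError(
                    f"{taxonomy_path}:{lineno}: lineage for {rid!r} has "
                    f"{lineage.depth} ranks, expected {N_RANKS}"
                )
            if rid in lineages:
                raise FormatError(f"{taxonomy_path}:{lineno}: duplicate id {rid!r}")
            lineages[rid] = lineage

    entries: dict[str, RefEntry] = {}
    missing: list[str] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in entries:
            raise FormatError(f"{fasta_path}: duplicate FASTA id {record.id!r}")
        if record.id not in lineages:
            missing.append(record.id)
            continue
        entries[record.id] = RefEntry(str(record.seq).upper(), lineages[record.id])
    if missing:
        raise FormatError(
            f"{len(missing)} FASTA ids missing from taxonomy table: {missing[:10]}"
        )
    return ReferenceDB(entries)


def write_reference_db(refdb: ReferenceDB, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for rid, entry in refdb.entries.items():
            fh.write(f">{rid}\n{entry.seq}\n")
    with open(taxonomy_path, "w") as fh:
        for rid, entry in refdb.entries.items():
            fh.write(f"{rid}\t{entry.lineage.to_string()}\n")


# ---------------------------------------------------------------------------
# OTU table TSV
# ---------------------------------------------------------------------------


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Serialize an OTU table as TSV (OTU rows, sample columns, lineage last).

    The marker and per-OTU centroid/junction data are carried in ``#`` header
    lines so that :func:`read_otu_table` round-trips the full object.
    """
    with open(path, "w") as fh:
        fh.write(f"#marker={table.marker}\n")
        for otu in table.otu_ids:
            junction = table.junctions.get(otu)
            extra = f"\tjunction={junction}" if junction is not None else ""
            fh.write(f"#centroid\t{otu}\t{table.centroids[otu]}{extra}\n")
        fh.write("otu_id\t" + "\t".join(table.sample_ids) + "\tlineage\n")
        for i, otu in enumerate(table.otu_ids):
            lineage = table.lineages.get(otu, Lineage.unclassified()).to_string()
            row = "\t".join(str(c) for c in table.counts[i])
            sep = "\t" if table.sample_ids else ""
            fh.write(f"{otu}{sep}{row}\t{lineage}\n")


def read_otu_table(path: str | Path) -> OtuTable:
    """Inverse of :func:`write_otu_table`."""
    marker = ""
    centroids: dict[str, str] = {}
    junctions: dict[str, int] = {}
    header: Optional[list[str]] = None
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    lineages: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#marker="):
                marker = line.split("=", 1)[1]
                continue
            if line.startswith("#centroid\t"):
                fields = line.split("\t")
                centroids[fields[1]] = fields[2]
                for extra in fields[3:]:
                    if extra.startswith("junction="):
                        junctions[fields[1]] = int(extra.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] != "otu_id" or fields[-1] != "lineage":
                    raise FormatError(f"{path}:{lineno}: malformed OTU table header")
                header = fields[1:-1]
                continue
            otu, counts, lineage_str = fields[0], fields[1:-1], fields[-1]
            try:
                row = [int(c) for c in counts]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count") from exc
            if any(c < 0 for c in row):
                raise FormatError(f"{path}:{lineno}: negative count")
            otu_ids.append(otu)
            rows.append(row)
            lineage = Lineage.from_string(lineage_str)
            if lineage.depth:
                lineages[otu] = lineage
    if header is None:
        raise FormatError(f"{path}: missing OTU table header")
    counts = np.array(rows, dtype=np.int64).reshape(len(otu_ids), len(header))
    return OtuTable(otu_ids, header, counts, centroids, lineages, marker, junctions)


def export_centroids_fasta(table: OtuTable, path: str | Path) -> None:
    """Write centroid sequences as FASTA, junction carried in the header."""
    with open(path, "w") as fh:
        for otu in table.otu_ids:
            junction = table.junctions.get(otu)
            extra = f" junction={junction}" if junction is not None else ""
            fh.write(f">{otu}{extra}\n{table.centroids[otu]}\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def parse_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Load a sample metadata TSV into a DataFrame indexed by sample id.

    Requires ``sample_id``, ``salinity`` and ``temperature`` columns; extra
    columns (station, latitude, ...) are preserved as-is.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "salinity", "temperature"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids: {dup}")
    for col in ("salinity", "temperature"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric {col}") from exc
    if (df["salinity"] < 0).any():
        raise FormatError(f"{path}: negative salinity")
    return df.set_index("sample_id", drop=False)


def write_sample_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)
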