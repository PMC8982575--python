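"""DNA-string primitives, coordinate conventions, and record I/O.

All coordinates in this package are 0-based, half-open. Sequences are plain
Python strings over the alphabet {A, C, G, T} wrapped in :class:`DnaSeq`,
which also carries topology (linear or circular). Circular sequences have no
distinguished endpoint: motif searches wrap the origin and report hit offsets
reduced into ``[0, len)``.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")

__all__ = [
    "DnaSeq",
    "MotifHit",
    "AlphabetError",
    "RecordError",
    "revcomp",
    "revcomp_str",
    "find_motif",
    "read_records",
    "write_records",
]


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T}."""


class RecordError(ValueError):
    """A sequence file record is malformed (e.g. empty sequence)."""


def _normalize(bases: str) -> str:
    """Uppercase, convert U->T (RNA paste-in), and validate the alphabet."""
    s = bases.strip().upper()
    if "U" in s:
        logger.warning("U bases converted to T (RNA input normalized to DNA)")
        s = s.replace("U", "T")
    for i, c in enumerate(s):
        if c not in DNA_ALPHABET:
            raise AlphabetError(
                f"invalid character {c!r} at position {i} (alphabet is ACGT)"
            )
    return s


@dataclass(frozen=True)
class DnaSeq:
    """An uppercase DNA string with linear or circular topology."""

    bases: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "bases", _normalize(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence at a forward-strand offset.

    Minus-strand hits are reported at the forward-strand start coordinate of
    the reverse-complemented motif.
    """

    offset: int
    strand: str
    motif: str


def revcomp_str(bases: str) -> str:
    """Reverse complement of a raw DNA string (no topology bookkeeping)."""
    return str(Seq(bases).reverse_complement())


def revcomp(seq: DnaSeq) -> DnaSeq:
    """Reverse complement; topology is preserved.

    An involution: ``revcomp(revcomp(x)) == x``.
    """
    return DnaSeq(revcomp_str(seq.bases), topology=seq.topology)


def _scan(haystack: str, needle: str) -> list[int]:
    """All (overlapping) occurrence offsets of needle in haystack."""
    hits = []
    start = haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def find_motif(seq: DnaSeq, motif: str, both_strands: bool = False) -> list[MotifHit]:
    """Find all occurrences of ``motif`` in ``seq``.

    Circular sequences are searched across the origin: the sequence is
    extended by its first ``len(motif) - 1`` bases and offsets are reduced
    into ``[0, len)``. With ``both_strands`` the reverse complement of the
    motif is also searched on the forward strand; palindromic motifs yield
    the same hit set as a single-strand search (no double counting).

    A motif longer than the sequence yields an empty list.
    """
    motif = _normalize(motif)
    if len(motif) < 4:
        raise ValueError(f"motif must be at least 4 nt, got {len(motif)}")
    n = len(seq)
    if len(motif) > n:
        return []
    text = seq.bases + (seq.bases[: len(motif) - 1] if seq.is_circular else "")
    hits = [MotifHit(off % n, "+", motif) for off in _scan(text, motif)]
    if both_strands:
        rc = revcomp_str(motif)
        if rc != motif:
            hits += [MotifHit(off % n, "-", motif) for off in _scan(text, rc)]
    return sorted(hits, key=lambda h: (h.offset, h.strand))


# ---------------------------------------------------------------------------
# Record I/O: multi-record FASTA (any wrap width) and a simple TSV dialect
# (tab-separated, optional header, columns name/sequence).
# ---------------------------------------------------------------------------


def _dedupe_names(named: list[tuple[str, str]]) -> list[tuple[str, str]]:
    seen: dict[str, int] = {}
    out = []
    for name, seqstr in named:
        if name in seen:
            seen[name] += 1
            new = f"{name}.{seen[name]}"
            warnings.warn(f"duplicate record name {name!r} renamed to {new!r}")
            name = new
        else:
            seen[name] = 1
        out.append((name, seqstr))
    return out


def _looks_like_header(fields: list[str]) -> bool:
    seq_cols = fields[1:]
    return not all(
        set(f.upper()) <= DNA_ALPHABET | {"U"} and f for f in seq_cols
    )


def read_records(
    path: str | Path, format: str = "fasta", topology: str = "linear"
) -> list[tuple[str, DnaSeq]]:
    """Read named sequences from FASTA or two-column TSV.

    Record order is preserved; duplicate names are made unique with a
    ``.2``, ``.3``, ... suffix (with a warning). Empty sequences raise
    :class:`RecordError`. CRLF input parses identically to LF.
    """
    path = Path(path)
    named: list[tuple[str, str]] = []
    if format == "fasta":
        # pearson dialect: tolerates ';' comment lines (our provenance headers)
        for rec in SeqIO.parse(str(path), "fasta-pearson"):
            named.append((rec.id, str(rec.seq)))
    elif format == "tsv":
        with open(path, newline="") as fh:
            rows = [r for r in csv.reader(fh, delimiter="\t") if r and any(r)]
        if rows and _looks_like_header(rows[0]):
            rows = rows[1:]
        for row in rows:
            if len(row) < 2:
                raise RecordError(f"TSV row has fewer than 2 columns: {row!r}")
            named.append((row[0].strip(), row[1]))
    else:
        raise ValueError(f"unknown format {format!r}")
    out = []
    for name, seqstr in _dedupe_names(named):
        if not seqstr.strip():
            raise RecordError(f"record {name!r} has an empty sequence")
        out.append((name, DnaSeq(seqstr, topology=topology)))
    return out


def write_records(
    path: str | Path,
    records: Iterable[tuple[str, DnaSeq]],
    format: str = "fasta",
    header: str | None = None,
) -> None:
    """Write named sequences as FASTA or two-column TSV (inverse of read)."""
    path = Path(path)
    records = list(records)
    if format == "fasta":
        seqrecs = [
            SeqRecord(Seq(seq.bases), id=name, description="")
            for name, seq in records
        ]
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f";{line}\n")
            SeqIO.write(seqrecs, fh, "fasta")
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["name", "sequence"])
            for name, seq in records:
                w.writerow([name, seq.bases])
    else:
        raise ValueError(f"unknown format {format!r}")
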