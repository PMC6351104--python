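"""Insert extraction from raw small-RNA FASTQ reads.

A raw read is barcode + insert + 3' linker + downstream sequence.  The
insert is recovered by stripping the exact sample barcode and locating the
6-nt 3' linker (default CTGTAG) allowing at most one mismatch; the leftmost
qualifying window wins regardless of its mismatch count.  Qualities are
never consulted: the protocol's processing is sequence-only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome import normalize_seq

DEFAULT_LINKER = "CTGTAG"
DEFAULT_MIN_LEN = 15
DEFAULT_MAX_LEN = 30


class ReadRejected(Exception):
    """A read that fails processing; ``reason`` is a tally key."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class FastqFormatError(ValueError):
    """Malformed FASTQ input, identifying the offending record number."""


@dataclass(frozen=True)
class InsertRecord:
    """A processed insert with its linker provenance."""

    read_id: str
    insert: str
    linker_pos: int
    linker_mismatches: int

    @property
    def length(self) -> int:
        return len(self.insert)

    @property
    def first_nt(self) -> str:
        return self.insert[0]


def strip_barcode(read_seq: str, barcode: str) -> str:
    """Remove an exact leading barcode; reject reads with any other prefix."""
    if len(read_seq) < len(barcode):
        raise ReadRejected("too_short")
    if barcode and not read_seq.startswith(barcode):
        raise ReadRejected("barcode_mismatch")
    return read_seq[len(barcode):]


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_linker(seq: str, linker: str = DEFAULT_LINKER):
    """Leftmost position p >= 1 where seq[p:p+6] matches the linker with at
    most one mismatch, scanning full-length windows only.

    Returns (p, n_mismatches) or None when no window qualifies.  p >= 1
    guarantees a non-empty insert.
    """
    k = len(linker)
    for p in range(1, len(seq) - k + 1):
        d = hamming(seq[p : p + k], linker)
        if d <= 1:
            return p, d
    return None


def extract_insert(
    read_id: str,
    read_seq: str,
    barcode: str = "",
    linker: str = DEFAULT_LINKER,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> InsertRecord:
    """strip_barcode + find_linker + length filter; raises ReadRejected."""
    seq = strip_barcode(normalize_seq(read_seq), normalize_seq(barcode))
    hit = find_linker(seq, normalize_seq(linker))
    if hit is None:
        raise ReadRejected("no_linker")
    pos, mism = hit
    if not min_len <= pos <= max_len:
        raise ReadRejected("length_out_of_range")
    return InsertRecord(read_id, seq[:pos], pos, mism)


@dataclass
class ProcessingReport:
    n_input: int
    n_accepted: int
    rejected: Counter

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_accepted": self.n_accepted,
            "rejected": dict(self.rejected),
        }


def process_reads(reads, barcode="", linker=DEFAULT_LINKER,
                  min_len=DEFAULT_MIN_LEN, max_len=DEFAULT_MAX_LEN):
    """Extract inserts from an iterable of (read_id, sequence) pairs.

    Returns (inserts, report); n_accepted plus the per-reason rejection
    tallies always sum to n_input.
    """
    inserts: list[InsertRecord] = []
    rejected: Counter = Counter()
    n = 0
    for read_id, seq in reads:
        n += 1
        try:
            inserts.append(extract_insert(read_id, seq, barcode, linker, min_len, max_len))
        except ReadRejected as exc:
            rejected[exc.reason] += 1
    return inserts, ProcessingReport(n, len(inserts), rejected)


def iter_fastq(path):
    """Yield (read_id, sequence) from a FASTQ file via Biopython."""
    from Bio import SeqIO

    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield rec.id, str(rec.seq)
    except ValueError as exc:
        raise FastqFormatError(str(exc)) from exc


def process_fastq(path, barcode="", linker=DEFAULT_LINKER,
                  min_len=DEFAULT_MIN_LEN, max_len=DEFAULT_MAX_LEN):
    """process_reads over a FASTQ file."""
    return process_reads(iter_fastq(path), barcode, linker, min_len, max_len)


def inserts_to_tsv(inserts, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "read_id": [r.read_id for r in inserts],
            "insert": [r.insert for r in inserts],
            "length": [r.length for r in inserts],
            "first_nt": [r.first_nt for r in inserts],
            "linker_pos": [r.linker_pos for r in inserts],
            "mismatches": [r.linker_mismatches for r in inserts],
        }
    ).to_csv(path, sep="\t", index=False)
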