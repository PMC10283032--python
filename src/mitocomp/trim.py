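"""Sliding-window 3' quality trimming of single-end FASTQ reads.

The rule: while the mean Phred quality of the last ``window_len`` bases
(the whole read when shorter) is below ``qv_threshold``, cut the final
``trim_step`` bases; a read falling below ``min_len`` at any point is
removed outright.  Defaults (window 30, threshold 16, step 15, minimum
length 25) suit Ion Torrent single-end data, whose base quality decays
toward the 3' end.  A mean exactly at the threshold passes.  Only the 3'
end is touched; adapter removal is assumed done upstream.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError, ValidationError

#: Sentinel returned when a read is discarded entirely.
REMOVED = None


@dataclass(frozen=True)
class TrimParams:
    window_len: int = 30
    qv_threshold: float = 16.0
    trim_step: int = 15
    min_len: int = 25
    qv_offset: int = 33

    def __post_init__(self) -> None:
        if min(self.window_len, self.trim_step, self.min_len) <= 0:
            raise ValidationError("trim parameters must be positive")
        if self.trim_step > self.window_len:
            raise ValidationError("trim_step must not exceed window_len")


@dataclass
class QualityRead:
    id: str
    bases: str
    qv: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qv):
            raise ValidationError(
                f"read {self.id!r}: {len(self.bases)} bases vs "
                f"{len(self.qv)} quality values"
            )
        if self.qv and min(self.qv) < 0:
            raise ValidationError(f"read {self.id!r}: negative quality value")


def trim_read(r: QualityRead, p: TrimParams = TrimParams()) -> QualityRead | None:
    """Apply the 3' sliding-window rule to one read.

    Returns the surviving prefix, or :data:`REMOVED` (``None``) when the read
    shrinks below ``min_len``.  The output is always a prefix of the input
    and, when kept, itself satisfies the window criterion (idempotence).
    """
    n = len(r.bases)
    while True:
        if n < p.min_len:
            return REMOVED
        w = min(p.window_len, n)
        if sum(r.qv[n - w : n]) / w >= p.qv_threshold:
            break
        n -= p.trim_step
    if n == len(r.bases):
        return r
    return QualityRead(r.id, r.bases[:n], r.qv[:n])


@dataclass
class TrimSummary:
    reads_in: int = 0
    reads_out: int = 0
    reads_removed: int = 0
    bases_in: int = 0
    bases_out: int = 0
    bases_removed: int = 0
    mean_len_before: float | None = None
    mean_len_after: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _open_maybe_gzip(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def trim_fastq(in_path, out_path, p: TrimParams = TrimParams()) -> TrimSummary:
    """Trim every record of a (possibly gzipped) FASTQ file, streaming.

    Writes surviving reads to ``out_path`` and returns a :class:`TrimSummary`
    with read/base accounting and mean lengths before/after.
    """
    s = TrimSummary()
    with _open_maybe_gzip(in_path, "r") as fin, \
            _open_maybe_gzip(out_path, "w") as fout:
        try:
            for idx, (title, seq, qual) in enumerate(FastqGeneralIterator(fin)):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"FASTQ record {idx} ({title.split()[0]}): "
                        f"sequence/quality length mismatch"
                    )
                qv = [ord(ch) - p.qv_offset for ch in qual]
                read = QualityRead(title, seq, qv)
                s.reads_in += 1
                s.bases_in += len(seq)
                trimmed = trim_read(read, p)
                if trimmed is REMOVED:
                    s.reads_removed += 1
                    continue
                s.reads_out += 1
                s.bases_out += len(trimmed.bases)
                out_qual = "".join(chr(q + p.qv_offset) for q in trimmed.qv)
                fout.write(f"@{trimmed.id}\n{trimmed.bases}\n+\n{out_qual}\n")
        except ValueError as exc:  # malformed FASTQ from the iterator
            raise ParseError(f"malformed FASTQ near record {s.reads_in}: {exc}")
    s.bases_removed = s.bases_in - s.bases_out
    if s.reads_in:
        s.mean_len_before = s.bases_in / s.reads_in
    if s.reads_out:
        s.mean_len_after = s.bases_out / s.reads_out
    return s


def write_summary(summary: TrimSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2)
        fh.write("\n")
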