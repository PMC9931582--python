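"""FASTQ input/output (4-line records, Phred+33, optional gzip)."""
from __future__ import annotations

import gzip
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .chemistry import PhredRead

PathLike = Union[str, "os.PathLike[str]"]


def _open(path: PathLike, mode: str) -> IO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: PathLike) -> Iterator[PhredRead]:
    """Stream reads from a (possibly gzipped) FASTQ file.

    Raises ValueError with the record index on a malformed record.
    """
    with _open(path, "r") as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {i}: {exc}") from exc
            title, seq, qual = rec
            yield PhredRead(title.split()[0], seq, [ord(c) - 33 for c in qual])
            i += 1


def write_fastq(path: PathLike, reads: Iterable[PhredRead]) -> int:
    """Write reads as 4-line FASTQ; returns the number written."""
    n = 0
    with _open(path, "w") as fh:
        for r in reads:
            fh.write(format_record(r))
            n += 1
    return n


def format_record(read: PhredRead) -> str:
    qual = "".join(chr(q + 33) for q in read.quals)
    return f"@{read.id}\n{read.bases}\n+\n{qual}\n"
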