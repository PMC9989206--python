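"""Small-RNA read preprocessing: quality filter, 3'-adapter trim, collapse.

Raw miRNA-seq reads are the mature/isomiR insert followed by the library's
3' adapter (and, for UMI kits, further bases that the adapter trim discards).
Reads failing a mean-quality threshold are dropped, the adapter is located by
a mismatch-tolerant prefix match, inserts outside the miRNA length range are
discarded, and identical inserts are collapsed to unique sequences with
counts to reduce mapping time.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .mirbase_reference import normalize_sequence

log = logging.getLogger(__name__)

PHRED_OFFSET = 33


@dataclass
class ReadParams:
    """Preprocessing parameters (conventional miRNA-seq defaults).

    ``adapter`` has no default: the library kit's 3' adapter must be given.
    """

    adapter: str
    min_mean_quality: float = 20.0
    min_adapter_overlap: int = 8
    max_adapter_mismatch_rate: float = 0.125
    min_len: int = 16
    max_len: int = 30
    keep_untrimmed: bool = False

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter sequence is required")
        self.adapter = normalize_sequence(self.adapter)
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not 0.0 <= self.max_adapter_mismatch_rate <= 1.0:
            raise ValueError("max_adapter_mismatch_rate must be in [0, 1]")


@dataclass(frozen=True)
class CollapsedRead:
    """A unique insert sequence with its multiplicity in one sample."""

    sequence: str
    count: int
    sample_id: str = ""


def mean_phred(quals: str) -> float:
    if not quals:
        return 0.0
    return sum(ord(c) - PHRED_OFFSET for c in quals) / len(quals)


def quality_filter(read: str, quals: str, params: ReadParams) -> bool:
    """Keep a read iff its mean Phred quality is >= the threshold (inclusive)."""
    if len(read) != len(quals):
        raise ValueError("read and quality strings differ in length")
    return mean_phred(quals) >= params.min_mean_quality


def trim_adapter(read: str, params: ReadParams) -> str | None:
    """Trim the 3' adapter; return the insert, or None if no adapter found.

    The leftmost read position where a prefix of the adapter, at least
    ``min_adapter_overlap`` nt long, matches with mismatch rate at most
    ``max_adapter_mismatch_rate`` defines the insert end.
    """
    read = normalize_sequence(read)
    adapter = params.adapter
    n = len(read)
    for j in range(0, n - params.min_adapter_overlap + 1):
        overlap = min(len(adapter), n - j)
        if overlap < params.min_adapter_overlap:
            break
        mism = sum(read[j + i] != adapter[i] for i in range(overlap))
        if mism / overlap <= params.max_adapter_mismatch_rate:
            return read[:j]
    return None


def collapse(
    reads: Iterable[str],
    params: ReadParams,
    sample_id: str = "",
) -> tuple[list[CollapsedRead], int]:
    """Collapse trimmed inserts to unique sequences with counts.

    Inserts outside [min_len, max_len] are discarded (their number is
    returned).  Output is sorted by count descending then sequence
    lexicographic, a total deterministic order.
    """
    counter: Counter[str] = Counter()
    n_length_failed = 0
    for seq in reads:
        if params.min_len <= len(seq) <= params.max_len:
            counter[seq] += 1
        else:
            n_length_failed += 1
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    collapsed = [CollapsedRead(seq, cnt, sample_id) for seq, cnt in ordered]
    return collapsed, n_length_failed


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def preprocess_fastq(
    fastq_path: str | Path,
    params: ReadParams,
    sample_id: str = "",
) -> tuple[list[CollapsedRead], dict]:
    """FASTQ -> collapsed unique inserts, with per-sample accounting stats."""
    stats = {
        "input": 0,
        "quality_failed": 0,
        "untrimmed": 0,
        "length_failed": 0,
        "collapsed_unique": 0,
        "surviving": 0,
    }
    inserts: list[str] = []
    with _open_maybe_gzip(fastq_path) as handle:
        for _title, seq, quals in FastqGeneralIterator(handle):
            stats["input"] += 1
            if not quality_filter(seq, quals, params):
                stats["quality_failed"] += 1
                continue
            insert = trim_adapter(seq, params)
            if insert is None:
                stats["untrimmed"] += 1
                if params.keep_untrimmed:
                    inserts.append(normalize_sequence(seq))
                continue
            inserts.append(insert)
    collapsed, n_length_failed = collapse(inserts, params, sample_id)
    stats["length_failed"] += n_length_failed
    stats["collapsed_unique"] = len(collapsed)
    stats["surviving"] = sum(c.count for c in collapsed)
    return collapsed, stats


def write_collapsed_fasta(collapsed: Sequence[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with ids encoding rank and count."""
    with open(path, "w") as fa:
        for rank, rec in enumerate(collapsed, start=1):
            fa.write(f">seq{rank}_x{rec.count}\n{rec.sequence}\n")


def read_collapsed_fasta(path: str | Path, sample_id: str = "") -> list[CollapsedRead]:
    """Read a collapsed FASTA written by :func:`write_collapsed_fasta`."""
    out: list[CollapsedRead] = []
    with open(path) as fa:
        title = None
        seq_parts: list[str] = []
        for line in fa:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if title is not None:
                    out.append(_collapsed_from(title, "".join(seq_parts), sample_id))
                title = line[1:]
                seq_parts = []
            else:
                seq_parts.append(line)
        if title is not None:
            out.append(_collapsed_from(title, "".join(seq_parts), sample_id))
    return out


def _collapsed_from(title: str, seq: str, sample_id: str) -> CollapsedRead:
    count = 1
    if "_x" in title:
        try:
            count = int(title.rsplit("_x", 1)[1])
        except ValueError:
            pass
    return CollapsedRead(normalize_sequence(seq), count, sample_id)
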