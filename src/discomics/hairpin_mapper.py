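"""Ungapped mismatch-tolerant alignment of collapsed reads to hairpins.

Emulates `-v`-mode short-read mapping semantics: a read aligns at a hairpin
offset iff its full-length Hamming distance there is at most ``v`` (no
indels, no quality weighting, forward strand only).  Among all hits the
minimum-mismatch stratum is taken and ties are broken deterministically by
(hairpin id lexicographic, then smallest offset) so that reruns are
reproducible; the original tool's pseudo-random best-hit choice is not
reproduced.

Candidate offsets come from an exact k-mer seed index.  The pigeonhole
guarantee (some k-mer of the read is error-free) only holds for reads of
length >= (v+1)*k; shorter reads — most miRNA-length reads at the default
k = 10 — fall back to an exhaustive vectorized Hamming scan over all
offsets, so results always equal the brute-force minimum-Hamming search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .mirbase_reference import HairpinRecord
from .smallrna_reads import CollapsedRead

log = logging.getLogger(__name__)


@dataclass
class MapperParams:
    """Mapping parameters; ``v`` is the maximum number of mismatches."""

    v: int = 2

    def __post_init__(self) -> None:
        if self.v < 0:
            raise ValueError("v must be >= 0")


@dataclass(frozen=True)
class Alignment:
    read_sequence: str
    hairpin_id: str
    offset: int
    mismatches: int
    read_count: int = 1

    @property
    def end(self) -> int:
        return self.offset + len(self.read_sequence)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class HairpinIndex:
    """Exact k-mer seed index over hairpin sequences.

    Hairpins shorter than k are indexed by their full sequence so they remain
    findable.  Encoded sequences are kept for Hamming verification and for
    the exhaustive scan used with short reads.
    """

    def __init__(self, hairpins: Sequence[HairpinRecord], k: int = 10) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        # Sort by id so tie-breaking by hairpin id is an index-order scan.
        self.hairpins = sorted(hairpins, key=lambda h: h.id)
        self.ids = [h.id for h in self.hairpins]
        self.seqs = [h.sequence for h in self.hairpins]
        self.arrays = [_encode(s) for s in self.seqs]
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        self.n_indexed_positions = 0
        for hidx, seq in enumerate(self.seqs):
            if len(seq) < k:
                self.kmers.setdefault(seq, []).append((hidx, 0))
                self.n_indexed_positions += 1
                continue
            for pos in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos : pos + k], []).append((hidx, pos))
                self.n_indexed_positions += 1

    def __len__(self) -> int:
        return len(self.hairpins)


def build_index(hairpins: Sequence[HairpinRecord], k: int = 10) -> HairpinIndex:
    """Build the seed index over (de-duplicated) hairpins."""
    return HairpinIndex(hairpins, k=k)


def _best_hit(
    read_arr: np.ndarray,
    index: HairpinIndex,
    v: int,
    candidates: Iterable[tuple[int, int]] | None,
) -> tuple[int, int, int] | None:
    """Return (hidx, offset, mismatches) of the best hit, or None.

    ``candidates=None`` triggers the exhaustive scan.  Tie-break: minimum
    mismatches, then smallest hairpin index (ids are sorted), then offset.
    """
    L = read_arr.size
    best: tuple[int, int, int] | None = None
    n_tied = 0
    if candidates is None:
        for hidx, harr in enumerate(index.arrays):
            if harr.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(harr, L)
            mism = (windows != read_arr).sum(axis=1)
            good = np.flatnonzero(mism <= v)
            if good.size == 0:
                continue
            local_best = int(mism[good].min())
            off = int(good[np.argmax(mism[good] == local_best)])
            cand = (local_best, hidx, off)
            if best is None or cand < (best[2], best[0], best[1]):
                if best is not None and cand[0] == best[2]:
                    n_tied += 1
                best = (cand[1], cand[2], cand[0])
            elif best is not None and cand[0] == best[2]:
                n_tied += 1
    else:
        for hidx, off in sorted(set(candidates)):
            harr = index.arrays[hidx]
            if off < 0 or off + L > harr.size:
                continue
            mism = int((harr[off : off + L] != read_arr).sum())
            if mism > v:
                continue
            cand = (mism, hidx, off)
            if best is None or cand < (best[2], best[0], best[1]):
                best = (hidx, off, mism)
            elif cand[0] == best[2]:
                n_tied += 1
    if best is not None and n_tied:
        log.debug("tie broken among %d equal-mismatch hits", n_tied + 1)
    return best


def map_read(
    read: str,
    index: HairpinIndex,
    params: MapperParams | None = None,
    read_count: int = 1,
) -> Alignment | None:
    """Map one read; return the deterministic best alignment or None."""
    params = params or MapperParams()
    if not read:
        return None
    read_arr = _encode(read)
    L = read_arr.size
    candidates: Iterable[tuple[int, int]] | None
    if L >= (params.v + 1) * index.k:
        # Pigeonhole: some k-mer of the read is exact; enumerate seed hits.
        cand_set: set[tuple[int, int]] = set()
        for i in range(L - index.k + 1):
            for hidx, pos in index.kmers.get(read[i : i + index.k], ()):
                cand_set.add((hidx, pos - i))
        candidates = cand_set
    else:
        candidates = None
    hit = _best_hit(read_arr, index, params.v, candidates)
    if hit is None:
        return None
    hidx, offset, mism = hit
    return Alignment(read, index.ids[hidx], offset, mism, read_count)


def map_reads(
    reads: Sequence[CollapsedRead],
    index: HairpinIndex,
    params: MapperParams | None = None,
) -> tuple[list[Alignment], list[CollapsedRead]]:
    """Map a collapsed read set; returns (alignments, unmapped reads)."""
    params = params or MapperParams()
    aligned: list[Alignment] = []
    unmapped: list[CollapsedRead] = []
    for rec in reads:
        aln = map_read(rec.sequence, index, params, read_count=rec.count)
        if aln is None:
            unmapped.append(rec)
        else:
            aligned.append(aln)
    return aligned, unmapped


def write_sam(
    path: str | Path,
    index: HairpinIndex,
    alignments: Sequence[Alignment],
    unmapped: Sequence[CollapsedRead] = (),
) -> None:
    """Write alignments as SAM against the retained-hairpin reference.

    POS is 1-based per SAM; the NM tag carries the mismatch count.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": hid, "LN": len(seq)} for hid, seq in zip(index.ids, index.seqs)],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, aln in enumerate(alignments):
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = f"seq{i + 1}_x{aln.read_count}"
            rec.query_sequence = aln.read_sequence
            rec.flag = 0
            rec.reference_id = index.ids.index(aln.hairpin_id)
            rec.reference_start = aln.offset
            rec.mapping_quality = 255
            rec.cigarstring = f"{len(aln.read_sequence)}M"
            rec.set_tag("NM", aln.mismatches)
            sam.write(rec)
        for j, miss in enumerate(unmapped):
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = f"unmapped{j + 1}_x{miss.count}"
            rec.query_sequence = miss.sequence
            rec.flag = 4
            rec.reference_id = -1
            rec.reference_start = -1
            rec.mapping_quality = 0
            sam.write(rec)
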