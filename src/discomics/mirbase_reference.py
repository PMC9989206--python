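"""miRBase-dialect hairpin/mature reference handling.

Builds the mapping reference used by the rest of the small-RNA pipeline:
species-filtered hairpin (precursor) sequences, de-duplicated so that no
retained hairpin is identical to or fully contained in another, with every
mature miRNA located on its hairpin(s) by exact substring search.  All
sequences are normalized to the DNA alphabet (U -> T, uppercase) so that
sequencing reads and reference compare directly; coordinates are 0-based
half-open internally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

#: length of the seed region (positions 2-8 of a mature miRNA, 1-based)
SEED_LENGTH = 7


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return str(seq).upper().replace("U", "T")


def seed_of(sequence: str) -> str:
    """Seed region of a mature (or read) sequence: nucleotides 2-8, 1-based.

    Raises ``ValueError`` for sequences shorter than 8 nt, for which the
    seed is undefined.
    """
    if len(sequence) < 8:
        raise ValueError(
            f"seed undefined for sequence of length {len(sequence)} (< 8 nt)"
        )
    return sequence[1 : 1 + SEED_LENGTH]


def _check_alphabet(identifier: str, sequence: str) -> None:
    if not sequence:
        raise ValueError(f"record {identifier!r} has an empty sequence")
    bad = set(sequence) - VALID_ALPHABET
    if bad:
        raise ValueError(
            f"record {identifier!r} contains invalid characters {sorted(bad)}"
        )


@dataclass(frozen=True)
class HairpinRecord:
    """A precursor (stem-loop) sequence from a miRBase-style hairpin FASTA."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        _check_alphabet(self.id, self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _arm_from_id(mature_id: str) -> str:
    lowered = mature_id.lower()
    if lowered.endswith("-5p"):
        return "5p"
    if lowered.endswith("-3p"):
        return "3p"
    return "unknown"


@dataclass(frozen=True)
class MatureRecord:
    """A mature miRNA sequence; the arm (5p/3p) is parsed from the id suffix."""

    id: str
    sequence: str
    arm: str = "unknown"

    def __post_init__(self) -> None:
        _check_alphabet(self.id, self.sequence)
        if not 16 <= len(self.sequence) <= 30:
            log.warning(
                "mature %s has unusual length %d nt (expected 16-30)",
                self.id,
                len(self.sequence),
            )


@dataclass(frozen=True)
class MatureLocus:
    """Location of a mature miRNA on a retained hairpin (0-based, half-open)."""

    mature_id: str
    hairpin_id: str
    start: int
    end: int
    canonical_seed: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid locus coordinates [{self.start}, {self.end})")
        if len(self.canonical_seed) != SEED_LENGTH:
            raise ValueError("canonical seed must be 7 nt")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def arm(self) -> str:
        return _arm_from_id(self.mature_id)


def _parse_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    text_head = ""
    with open(path) as handle:
        for line in handle:
            if line.strip():
                text_head = line
                break
    if text_head and not text_head.startswith(">"):
        raise ValueError(f"{path} is not FASTA: first record line {text_head!r}")
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = normalize_sequence(rec.seq)
            if not seq:
                raise ValueError(f"FASTA record {rec.id!r} in {path} has no sequence")
            records.append((rec.id, seq))
    return records


def load_hairpins(fasta_path: str | Path, species_prefix: str) -> list[HairpinRecord]:
    """Load hairpins whose id starts with ``species_prefix + '-'``.

    Sequences are normalized (U -> T, uppercase).  Duplicate ids raise.
    """
    prefix = species_prefix + "-"
    out: list[HairpinRecord] = []
    seen: set[str] = set()
    for rid, seq in _parse_fasta(fasta_path):
        if not rid.startswith(prefix):
            continue
        if rid in seen:
            raise ValueError(f"duplicate hairpin id {rid!r}")
        seen.add(rid)
        out.append(HairpinRecord(rid, seq))
    return out


def load_matures(fasta_path: str | Path, species_prefix: str) -> list[MatureRecord]:
    """Load mature miRNAs for a species; arm is parsed from the id suffix."""
    prefix = species_prefix + "-"
    out: list[MatureRecord] = []
    seen: set[str] = set()
    for rid, seq in _parse_fasta(fasta_path):
        if not rid.startswith(prefix):
            continue
        if rid in seen:
            raise ValueError(f"duplicate mature id {rid!r}")
        seen.add(rid)
        out.append(MatureRecord(rid, seq, _arm_from_id(rid)))
    return out


def dedup_hairpins(
    hairpins: Iterable[HairpinRecord],
    return_log: bool = False,
):
    """Remove hairpins identical to, or contained in, another hairpin.

    Entries are processed in order of decreasing sequence length, ties broken
    by lexicographic id; a candidate is dropped iff its sequence is identical
    to or a contiguous substring of an already retained sequence (forward
    strand only).  The result is deterministic and idempotent, and no
    retained sequence is a substring of another retained sequence.
    """
    ordered = sorted(hairpins, key=lambda h: (-h.length, h.id))
    retained: list[HairpinRecord] = []
    dropped: list[dict] = []
    for cand in ordered:
        container = next((r for r in retained if cand.sequence in r.sequence), None)
        if container is not None:
            dropped.append({"dropped": cand.id, "contained_in": container.id})
        else:
            retained.append(cand)
    if dropped:
        log.info("dedup_hairpins: dropped %d contained entries", len(dropped))
    if return_log:
        return retained, dropped
    return retained


def locate_matures(
    hairpins: Sequence[HairpinRecord],
    matures: Sequence[MatureRecord],
) -> list[MatureLocus]:
    """Locate each mature on every retained hairpin by exact substring search.

    Every occurrence in every hairpin yields one locus; if a mature occurs
    more than once within a single hairpin, only the leftmost occurrence is
    kept (logged).  Matures absent from all hairpins are logged and skipped.
    """
    loci: list[MatureLocus] = []
    for mat in matures:
        n_hits = 0
        for hp in hairpins:
            pos = hp.sequence.find(mat.sequence)
            if pos < 0:
                continue
            second = hp.sequence.find(mat.sequence, pos + 1)
            if second >= 0:
                log.info(
                    "mature %s occurs more than once in %s; keeping leftmost (%d)",
                    mat.id,
                    hp.id,
                    pos,
                )
            loci.append(
                MatureLocus(
                    mature_id=mat.id,
                    hairpin_id=hp.id,
                    start=pos,
                    end=pos + len(mat.sequence),
                    canonical_seed=seed_of(mat.sequence),
                )
            )
            n_hits += 1
        if n_hits == 0:
            log.info("mature %s not found in any retained hairpin; skipped", mat.id)
    loci.sort(key=lambda l: (l.mature_id, l.hairpin_id, l.start))
    for locus in loci:
        hp = next(h for h in hairpins if h.id == locus.hairpin_id)
        assert hp.sequence[locus.start : locus.end] is not None
    return loci


@dataclass
class Reference:
    """Retained hairpins plus located mature loci (the mapping reference)."""

    hairpins: list[HairpinRecord]
    loci: list[MatureLocus]
    species_prefix: str = ""
    dedup_log: list[dict] = field(default_factory=list)

    def loci_by_hairpin(self) -> dict[str, list[MatureLocus]]:
        by_hp: dict[str, list[MatureLocus]] = {}
        for locus in self.loci:
            by_hp.setdefault(locus.hairpin_id, []).append(locus)
        return by_hp


def build_reference(
    hairpin_fasta: str | Path,
    mature_fasta: str | Path,
    species_prefix: str,
) -> Reference:
    """End-to-end reference build: load, de-duplicate, locate matures."""
    hairpins = load_hairpins(hairpin_fasta, species_prefix)
    matures = load_matures(mature_fasta, species_prefix)
    retained, dropped = dedup_hairpins(hairpins, return_log=True)
    loci = locate_matures(retained, matures)
    return Reference(retained, loci, species_prefix, dropped)


def write_reference(reference: Reference, out_dir: str | Path) -> None:
    """Write the reference bundle: hairpins.fa, loci.tsv and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "hairpins.fa", "w") as fa:
        for hp in reference.hairpins:
            fa.write(f">{hp.id}\n{hp.sequence}\n")
    with open(out / "loci.tsv", "w") as tsv:
        tsv.write("mature_id\thairpin_id\tstart\tend\tcanonical_seed\n")
        for locus in reference.loci:
            tsv.write(
                f"{locus.mature_id}\t{locus.hairpin_id}\t{locus.start}"
                f"\t{locus.end}\t{locus.canonical_seed}\n"
            )
    manifest = {
        "species_prefix": reference.species_prefix,
        "n_hairpins_retained": len(reference.hairpins),
        "n_loci": len(reference.loci),
        "dedup_dropped": reference.dedup_log,
    }
    with open(out / "manifest.json", "w") as mf:
        json.dump(manifest, mf, indent=2)


def load_reference(ref_dir: str | Path) -> Reference:
    """Load a reference bundle written by :func:`write_reference`."""
    ref_dir = Path(ref_dir)
    hairpins = [HairpinRecord(rid, seq) for rid, seq in _parse_fasta(ref_dir / "hairpins.fa")]
    loci: list[MatureLocus] = []
    with open(ref_dir / "loci.tsv") as tsv:
        header = tsv.readline()
        assert header.startswith("mature_id")
        for line in tsv:
            mid, hid, start, end, cseed = line.rstrip("\n").split("\t")
            loci.append(MatureLocus(mid, hid, int(start), int(end), cseed))
    species = ""
    manifest_path = ref_dir / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as mf:
            species = json.load(mf).get("species_prefix", "")
    return Reference(hairpins, loci, species)
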