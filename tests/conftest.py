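import numpy as np
import pytest

from discomics import hairpin_mapper, mirbase_reference, synthetic_data


@pytest.fixture(scope="session")
def small_reference():
    """50 synthetic hairpins with planted mature arms (no decoys)."""
    return synthetic_data.gen_reference(7, n_hairpins=50)


@pytest.fixture(scope="session")
def retained_hairpins(small_reference):
    return mirbase_reference.dedup_hairpins(small_reference.hairpins)


@pytest.fixture(scope="session")
def hairpin_index(retained_hairpins):
    return hairpin_mapper.build_index(retained_hairpins)


@pytest.fixture(scope="session")
def loci_by_hairpin(small_reference):
    by_hp = {}
    for locus in small_reference.loci:
        by_hp.setdefault(locus.hairpin_id, []).append(locus)
    return by_hp


def brute_force_map(read, hairpins, v=2):
    """Independent O(|read| * total hairpin length) minimum-Hamming oracle.

    Returns (mismatches, hairpin_id, offset) of the best hit under the same
    deterministic tie-break, or None.
    """
    best = None
    for hp in sorted(hairpins, key=lambda h: h.id):
        seq = hp.sequence
        for off in range(len(seq) - len(read) + 1):
            mm = sum(a != b for a, b in zip(read, seq[off : off + len(read)]))
            if mm <= v and (best is None or (mm, hp.id, off) < best):
                best = (mm, hp.id, off)
    return best


def random_reads(rng, hairpins, n, mutate_up_to=3):
    """Mix of purely random reads and hairpin substrings with mutations."""
    reads = []
    for _ in range(n):
        if rng.random() < 0.4:
            length = int(rng.integers(16, 31))
            reads.append("".join(rng.choice(list("ACGT"), size=length)))
        else:
            hp = hairpins[int(rng.integers(0, len(hairpins)))]
            length = int(rng.integers(16, min(31, len(hp.sequence))))
            off = int(rng.integers(0, len(hp.sequence) - length + 1))
            chars = list(hp.sequence[off : off + length])
            for _ in range(int(rng.integers(0, mutate_up_to + 1))):
                k = int(rng.integers(0, length))
                chars[k] = str(rng.choice([b for b in "ACGT" if b != chars[k]]))
            reads.append("".join(chars))
    return reads
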