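"""isomiR-aware read counting against located mature miRNA loci.

An alignment is attributed to a mature miRNA locus iff it starts and ends
within the "bleed" window (default +/- 2 nt) of the annotated start and stop.
The counted feature is the pair (mature id, seed of the *read*): 5'-shifted
or seed-mutated variants create distinct features with their own seeds,
whereas 3'-only variants share the canonical seed and are counted together
with the canonical form.  Features are detection-filtered on reads per
million (strict > threshold on the mean across samples by default).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hairpin_mapper import Alignment
from .mirbase_reference import MatureLocus, seed_of

log = logging.getLogger(__name__)

DETECTION_RULES = ("mean", "min", "any")


@dataclass
class QuantParams:
    """bleed: +/- nt tolerance; rpm_threshold: strict > detection cut."""

    bleed: int = 2
    rpm_threshold: float = 10.0
    detection_rule: str = "mean"

    def __post_init__(self) -> None:
        if self.bleed < 0:
            raise ValueError("bleed must be >= 0")
        if self.rpm_threshold < 0:
            raise ValueError("rpm_threshold must be >= 0")
        if self.detection_rule not in DETECTION_RULES:
            raise ValueError(f"detection_rule must be one of {DETECTION_RULES}")


@dataclass(frozen=True)
class IsomiRFeature:
    """Counting unit: one (mature miRNA, observed seed) pair."""

    mature_id: str
    seed: str
    is_canonical_seed: bool

    @property
    def label(self) -> str:
        if self.is_canonical_seed:
            return self.mature_id
        return f"{self.mature_id}|seed={self.seed}"


def _arm_rank(locus: MatureLocus) -> int:
    return {"5p": 0, "3p": 1}.get(locus.arm, 2)


def assign_alignment(
    alignment: Alignment,
    loci_by_hairpin: Mapping[str, Sequence[MatureLocus]],
    params: QuantParams | None = None,
) -> IsomiRFeature | None:
    """Attribute an alignment to a locus within the bleed window, or None.

    If several loci qualify the one minimizing |dstart| + |dend| wins
    (ties: 5p arm first, then mature id).  Reads shorter than 8 nt have no
    seed and are unassigned.
    """
    params = params or QuantParams()
    if len(alignment.read_sequence) < 8:
        log.warning("read shorter than 8 nt cannot carry a seed; unassigned")
        return None
    loci = loci_by_hairpin.get(alignment.hairpin_id, ())
    read_start = alignment.offset
    read_end = alignment.end
    best: tuple[int, int, str, MatureLocus] | None = None
    for locus in loci:
        ds = abs(read_start - locus.start)
        de = abs(read_end - locus.end)
        if ds <= params.bleed and de <= params.bleed:
            key = (ds + de, _arm_rank(locus), locus.mature_id, locus)
            if best is None or key[:3] < best[:3]:
                best = key
    if best is None:
        return None
    locus = best[3]
    read_seed = seed_of(alignment.read_sequence)
    return IsomiRFeature(
        mature_id=locus.mature_id,
        seed=read_seed,
        is_canonical_seed=read_seed == locus.canonical_seed,
    )


@dataclass
class CountMatrix:
    """Integer feature x sample count table with sample groups attached.

    ``library_sizes`` defaults to the per-sample totals of assigned reads,
    which keeps normalization recomputable from the matrix itself.
    """

    counts: pd.DataFrame
    features: pd.DataFrame
    groups: pd.Series | None = None
    library_sizes: pd.Series | None = None
    unassigned: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes, dtype=float)[
                self.counts.columns
            ]
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def rpm(self) -> pd.DataFrame:
        lib = self.library_sizes
        if (lib <= 0).any():
            raise ValueError("library sizes must be positive to compute RPM")
        return self.counts * 1e6 / lib


def quantify_sample(
    alignments: Sequence[Alignment],
    loci_by_hairpin: Mapping[str, Sequence[MatureLocus]],
    params: QuantParams | None = None,
) -> tuple[Counter, int]:
    """Per-sample feature counts; returns (Counter[feature], unassigned reads)."""
    params = params or QuantParams()
    counts: Counter[IsomiRFeature] = Counter()
    unassigned_reads = 0
    for aln in alignments:
        feature = assign_alignment(aln, loci_by_hairpin, params)
        if feature is None:
            unassigned_reads += aln.read_count
        else:
            counts[feature] += aln.read_count
    return counts, unassigned_reads


def count_features(
    sample_counts: Mapping[str, Counter],
    groups: Mapping[str, str] | None = None,
    unassigned: Mapping[str, int] | None = None,
) -> CountMatrix:
    """Combine per-sample feature counters into one CountMatrix.

    Features are ordered by total count descending, then label lexicographic.
    """
    samples = list(sample_counts)
    all_features: set[IsomiRFeature] = set()
    for counter in sample_counts.values():
        all_features.update(counter)
    totals = {
        f: sum(counter.get(f, 0) for counter in sample_counts.values())
        for f in all_features
    }
    ordered = sorted(all_features, key=lambda f: (-totals[f], f.label))
    labels = [f.label for f in ordered]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate feature labels; inconsistent references?")
    data = {
        s: [sample_counts[s].get(f, 0) for f in ordered] for s in samples
    }
    counts = pd.DataFrame(data, index=pd.Index(labels, name="label"), dtype=int)
    features = pd.DataFrame(
        {
            "mature_id": [f.mature_id for f in ordered],
            "seed": [f.seed for f in ordered],
            "is_canonical_seed": [f.is_canonical_seed for f in ordered],
        },
        index=counts.index,
    )
    grp = pd.Series(groups)[samples] if groups is not None else None
    return CountMatrix(
        counts,
        features,
        groups=grp,
        unassigned=dict(unassigned or {}),
    )


def rpm_filter(matrix: CountMatrix, params: QuantParams | None = None) -> CountMatrix:
    """Retain features detected above the RPM threshold (strict >).

    The default rule requires mean RPM across all samples > threshold;
    "min" requires every sample above, "any" at least one.
    """
    params = params or QuantParams()
    rpm = matrix.rpm()
    if params.detection_rule == "mean":
        stat = rpm.mean(axis=1)
    elif params.detection_rule == "min":
        stat = rpm.min(axis=1)
    else:
        stat = rpm.max(axis=1)
    keep = stat > params.rpm_threshold
    return CountMatrix(
        matrix.counts.loc[keep],
        matrix.features.loc[keep],
        groups=matrix.groups,
        library_sizes=matrix.library_sizes,
        unassigned=matrix.unassigned,
    )


def write_count_matrix(matrix: CountMatrix, out_dir: str | Path) -> None:
    """Write counts.tsv (feature metadata + per-sample columns) and summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = matrix.features.join(matrix.counts)
    table.index.name = "label"
    table.to_csv(out / "counts.tsv", sep="\t")
    summary = {
        "n_features": int(matrix.counts.shape[0]),
        "samples": matrix.samples,
        "library_sizes": {s: float(v) for s, v in matrix.library_sizes.items()},
        "unassigned": {k: int(v) for k, v in matrix.unassigned.items()},
    }
    if matrix.groups is not None:
        summary["groups"] = {s: str(g) for s, g in matrix.groups.items()}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def read_count_matrix(path: str | Path, groups: Mapping[str, str] | None = None) -> CountMatrix:
    """Read a counts.tsv written by :func:`write_count_matrix`."""
    table = pd.read_csv(path, sep="\t", index_col="label")
    meta_cols = ["mature_id", "seed", "is_canonical_seed"]
    features = table[meta_cols]
    counts = table.drop(columns=meta_cols).astype(int)
    grp = pd.Series(groups)[counts.columns] if groups is not None else None
    return CountMatrix(counts, features, groups=grp)
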