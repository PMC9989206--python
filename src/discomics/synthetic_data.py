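"""Seeded generators emulating the study's data structures.

Every generator is a pure function of its arguments (seed included), so
reruns are byte-identical, and each emits a ground-truth table sufficient to
score the downstream stage without re-deriving the truth.

Defaults mirror the study conditions: 3 vs 3 libraries (articular
chondrocyte "AC" vs mesenchymal stromal cell "MSC" discs), negative-binomial
feature counts with common dispersion and planted two-fold-plus effects,
reads with planted 5'/3' isomiR offsets, label-free protein tables with
group shifts and missing-not-at-random dropout producing on/off proteins,
and bipartite miRNA -> gene target maps with planted coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mirbase_reference import HairpinRecord, MatureLocus, MatureRecord, seed_of
from .isomir_quant import CountMatrix
from .proteome_de import ProteinTable

BASES = np.array(list("ACGT"))

#: Illumina small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_GROUPS = ("AC", "MSC")

#: default distribution over (dstart, dend) isomiR offsets: mostly canonical,
#: some templated trimming/extension within the +/-2 bleed window
DEFAULT_OFFSET_PROBS: dict[tuple[int, int], float] = {
    (0, 0): 0.55,
    (0, 1): 0.12,
    (0, -1): 0.10,
    (1, 0): 0.08,
    (-1, 0): 0.05,
    (2, 0): 0.03,
    (0, 2): 0.03,
    (-2, -2): 0.02,
    (1, 1): 0.02,
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _sample_names(n_per_group: int, groups: Sequence[str] = DEFAULT_GROUPS) -> dict[str, str]:
    return {f"{g}{i + 1}": g for g in groups for i in range(n_per_group)}


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTruth:
    hairpins: list[HairpinRecord]
    matures: list[MatureRecord]
    loci: list[MatureLocus]
    expected_retained_ids: set[str] = field(default_factory=set)


def gen_reference(
    seed: int,
    n_hairpins: int = 20,
    dup_fraction: float = 0.0,
    substring_fraction: float = 0.0,
    hairpin_length: tuple[int, int] = (70, 100),
    two_arm_fraction: float = 0.8,
) -> ReferenceTruth:
    """Random hairpins with planted mature arms; optional dup/substring decoys.

    Of ``n_hairpins`` entries, round(n * dup_fraction) are exact duplicates
    and round(n * substring_fraction) are contiguous substrings of unique
    base hairpins, so the de-duplication ground truth is the base set.
    """
    rng = np.random.default_rng(seed)
    n_dup = int(round(n_hairpins * dup_fraction))
    n_sub = int(round(n_hairpins * substring_fraction))
    n_unique = n_hairpins - n_dup - n_sub
    if n_unique < 1:
        raise ValueError("dup/substring fractions leave no unique hairpins")
    hairpins: list[HairpinRecord] = []
    matures: list[MatureRecord] = []
    loci: list[MatureLocus] = []
    seen: set[str] = set()
    for i in range(n_unique):
        while True:
            length = int(rng.integers(hairpin_length[0], hairpin_length[1] + 1))
            seq = _random_seq(rng, length)
            if seq not in seen:
                seen.add(seq)
                break
        hid = f"syn-mir-{i:04d}"
        hairpins.append(HairpinRecord(hid, seq))
        arms = ["5p", "3p"] if rng.random() < two_arm_fraction else [rng.choice(["5p", "3p"])]
        for arm in arms:
            mlen = int(rng.integers(20, 24))
            if arm == "5p":
                start = int(rng.integers(3, 8))
            else:
                start = length - mlen - int(rng.integers(3, 8))
            mid = f"syn-miR-{i:04d}-{arm}"
            mseq = seq[start : start + mlen]
            matures.append(MatureRecord(mid, mseq, arm))
            loci.append(MatureLocus(mid, hid, start, start + mlen, seed_of(mseq)))
    base_ids = {h.id for h in hairpins}
    for j in range(n_dup):
        src = hairpins[int(rng.integers(0, n_unique))]
        hairpins.append(HairpinRecord(f"{src.id}-dup{j}", src.sequence))
    for j in range(n_sub):
        src = hairpins[int(rng.integers(0, n_unique))]
        lo = int(rng.integers(0, max(1, len(src.sequence) - 45)))
        hi = lo + int(rng.integers(40, min(60, len(src.sequence) - lo) + 1))
        hairpins.append(HairpinRecord(f"{src.id}-sub{j}", src.sequence[lo:hi]))
    return ReferenceTruth(hairpins, matures, loci, expected_retained_ids=base_ids)


def write_fasta(records: Sequence, path) -> None:
    with open(path, "w") as fa:
        for rec in records:
            fa.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def gen_reads(
    seed: int,
    reference: ReferenceTruth,
    n_reads: int = 2000,
    n_per_group: int = 3,
    offset_probs: Mapping[tuple[int, int], float] | None = None,
    error_rate: float = 0.0,
    adapter: str = DEFAULT_ADAPTER,
    quality_char: str = "?",  # constant Q30
    bleed: int = 2,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Per-sample FASTQ text with planted isomiR offsets, plus a truth table.

    Truth columns: sample, read_id, mature_id, dstart, dend, insert,
    expected_label ("unassignable" for offsets beyond the bleed window).
    Sequencing errors are applied to the insert before the adapter is
    appended; the expected feature seed is derived from the observed insert.
    """
    rng = np.random.default_rng(seed)
    offset_probs = dict(offset_probs or DEFAULT_OFFSET_PROBS)
    offsets = list(offset_probs)
    probs = np.array([offset_probs[o] for o in offsets], dtype=float)
    probs /= probs.sum()
    samples = _sample_names(n_per_group)
    hp_by_id = {h.id: h.sequence for h in reference.hairpins}
    usable = [
        l for l in reference.loci
        if l.start - 3 >= 0 and l.end + 3 <= len(hp_by_id[l.hairpin_id])
    ]
    canonical_seed = {l.mature_id: l.canonical_seed for l in usable}
    fastqs: dict[str, str] = {}
    truth_rows: list[dict] = []
    for sample in samples:
        lines: list[str] = []
        for i in range(n_reads):
            locus = usable[int(rng.integers(0, len(usable)))]
            ds, de = offsets[int(rng.choice(len(offsets), p=probs))]
            start, end = locus.start + ds, locus.end + de
            insert = list(hp_by_id[locus.hairpin_id][start:end])
            if error_rate > 0:
                for k in range(len(insert)):
                    if rng.random() < error_rate:
                        insert[k] = str(rng.choice([b for b in "ACGT" if b != insert[k]]))
            insert_s = "".join(insert)
            if abs(ds) > bleed or abs(de) > bleed:
                expected = "unassignable"
            else:
                obs_seed = seed_of(insert_s)
                expected = (
                    locus.mature_id
                    if obs_seed == canonical_seed[locus.mature_id]
                    else f"{locus.mature_id}|seed={obs_seed}"
                )
            read = insert_s + adapter
            rid = f"{sample}_read{i}"
            lines.append(f"@{rid}\n{read}\n+\n{quality_char * len(read)}")
            truth_rows.append(
                {
                    "sample": sample,
                    "read_id": rid,
                    "mature_id": locus.mature_id,
                    "dstart": ds,
                    "dend": de,
                    "insert": insert_s,
                    "expected_label": expected,
                }
            )
        fastqs[sample] = "\n".join(lines) + "\n"
    return fastqs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def gen_counts(
    seed: int,
    n_features: int = 2000,
    n_per_group: int = 3,
    lib_size_range: tuple[float, float] = (8e5, 1.2e6),
    dispersion: float = 0.1,
    de_fraction: float = 0.0,
    log2fc: float = 2.0,
    abundance_range: tuple[float, float] = (5e-6, 5e-4),
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix (variance mu + phi mu^2) with planted fold changes.

    Feature abundances are log-uniform; a ``de_fraction`` subset of features
    gets the full |log2fc| effect applied to the second group, sign random.
    Truth columns: feature, de, sign (0 for non-DE).
    """
    rng = np.random.default_rng(seed)
    sample_groups = _sample_names(n_per_group, groups)
    samples = list(sample_groups)
    lib = rng.uniform(*lib_size_range, size=len(samples))
    abundance = np.exp(
        rng.uniform(np.log(abundance_range[0]), np.log(abundance_range[1]), size=n_features)
    )
    n_de = int(round(n_features * de_fraction))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    sign = np.zeros(n_features)
    sign[de_idx] = rng.choice([-1.0, 1.0], size=n_de)
    labels = [f"feat{i:05d}" for i in range(n_features)]
    counts = np.zeros((n_features, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = abundance * lib[j]
        if sample_groups[s] == groups[1]:
            mu = mu * 2.0 ** (sign * log2fc)
        if dispersion <= 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=labels, columns=samples)
    features = pd.DataFrame(
        {
            "mature_id": labels,
            "seed": ["NNNNNNN"] * n_features,
            "is_canonical_seed": [True] * n_features,
        },
        index=labels,
    )
    matrix = CountMatrix(counts_df, features, groups=pd.Series(sample_groups))
    truth = pd.DataFrame(
        {"feature": labels, "de": sign != 0, "sign": sign.astype(int)}
    ).set_index("feature")
    return matrix, truth


# ---------------------------------------------------------------------------
# protein tables
# ---------------------------------------------------------------------------

def gen_protein_table(
    seed: int,
    n_proteins: int = 1000,
    n_per_group: int = 3,
    base_mean: float = 6.5,
    base_sd: float = 0.6,
    noise_sd: float = 0.15,
    n_de: int = 0,
    effect_fold: float = 4.0,
    mcar_rate: float = 0.08,
    n_onoff: int = 0,
    n_contaminants: int = 0,
    groups: Sequence[str] = DEFAULT_GROUPS,
) -> tuple[ProteinTable, dict]:
    """Log-normal intensity table with planted shifts, MCAR dropout and
    on/off (missing-not-at-random) proteins.

    Planted DE proteins get a log10(effect_fold) shift in the second group
    (sign random); on/off proteins are fully missing in one group.  Truth:
    {"de": {protein: sign}, "onoff": {protein: detected_group}}.
    """
    rng = np.random.default_rng(seed)
    sample_groups = _sample_names(n_per_group, groups)
    samples = list(sample_groups)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    genes = [f"GENE{i:05d}" for i in range(n_proteins)]
    base = rng.normal(base_mean, base_sd, size=n_proteins)
    logged = base[:, None] + rng.normal(0.0, noise_sd, size=(n_proteins, len(samples)))
    special = rng.choice(n_proteins, size=n_de + n_onoff + n_contaminants, replace=False)
    de_idx = special[:n_de]
    onoff_idx = special[n_de : n_de + n_onoff]
    contam_idx = special[n_de + n_onoff :]
    g2_cols = np.array([j for j, s in enumerate(samples) if sample_groups[s] == groups[1]])
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    for k, idx in enumerate(de_idx):
        logged[idx, g2_cols] += de_sign[k] * np.log10(effect_fold)
    values = 10.0**logged
    missing = rng.random(values.shape) < mcar_rate
    onoff_group = rng.choice(len(groups), size=n_onoff)
    for k, idx in enumerate(onoff_idx):
        dead = [
            j for j, s in enumerate(samples)
            if sample_groups[s] != groups[onoff_group[k]]
        ]
        missing[idx, dead] = True
        live = [j for j in range(len(samples)) if j not in dead]
        missing[idx, live] = False
    values = np.where(missing, np.nan, values)
    intensities = pd.DataFrame(values, index=proteins, columns=samples)
    contaminants = pd.Series(False, index=proteins)
    contaminants.iloc[contam_idx] = True
    table = ProteinTable(
        intensities,
        groups=pd.Series(sample_groups),
        contaminants=contaminants,
        gene_symbols=pd.Series(genes, index=proteins),
    )
    truth = {
        "de": {proteins[i]: int(de_sign[k]) for k, i in enumerate(de_idx)},
        "onoff": {proteins[i]: groups[onoff_group[k]] for k, i in enumerate(onoff_idx)},
        "contaminants": [proteins[i] for i in contam_idx],
    }
    return table, truth


# ---------------------------------------------------------------------------
# target predictions
# ---------------------------------------------------------------------------

def gen_predictions(
    seed: int,
    mirnas: Sequence[str],
    genes: Sequence[str],
    true_edges: set[tuple[str, str]] | None = None,
    edge_density: float = 0.1,
    n_decoys: int = 100,
    prob_min: float = 0.99995,
    mfe_max: float = -15.0,
) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Prediction table whose post-filter graph equals the planted edge set.

    Planted edges pass both thresholds; decoy rows straddle them (low
    probability with strong MFE, high probability with weak MFE, or both
    failing), so threshold filtering must recover exactly the planted graph.
    """
    rng = np.random.default_rng(seed)
    if true_edges is None:
        true_edges = {
            (m, g) for m in mirnas for g in genes if rng.random() < edge_density
        }
    rows = []
    for m, g in sorted(true_edges):
        rows.append(
            {
                "mirna": m,
                "gene": g,
                "probability": float(rng.uniform(prob_min, 1.0)),
                "mfe": float(rng.uniform(-30.0, mfe_max)),
                "site_class": str(rng.choice(["canonical", "non_canonical"])),
            }
        )
    flavors = ["low_prob", "weak_mfe", "both_fail"]
    made = 0
    attempts = 0
    while made < n_decoys and attempts < 50 * n_decoys:
        attempts += 1
        m = str(rng.choice(mirnas))
        g = str(rng.choice(genes))
        if (m, g) in true_edges:
            continue
        flavor = flavors[made % 3]
        prob = (
            float(rng.uniform(0.5, prob_min * 0.99999))
            if flavor in ("low_prob", "both_fail")
            else float(rng.uniform(prob_min, 1.0))
        )
        mfe = (
            float(rng.uniform(mfe_max + 0.5, -1.0))
            if flavor in ("weak_mfe", "both_fail")
            else float(rng.uniform(-30.0, mfe_max))
        )
        rows.append(
            {"mirna": m, "gene": g, "probability": prob, "mfe": mfe, "site_class": "canonical"}
        )
        made += 1
    table = pd.DataFrame(rows, columns=["mirna", "gene", "probability", "mfe", "site_class"])
    return table, true_edges


def gen_coverage_instance(
    seed: int,
    n_proteins: int = 72,
    n_targeted: int = 46,
    n_mirnas: int = 10,
    direction_protein: str = "up_in_AC",
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """A planted coverage instance: DE proteins, top miRNAs, predictions.

    Exactly ``n_targeted`` of the proteins' genes receive at least one
    passing prediction edge from the miRNA panel; the rest get only decoys.
    """
    rng = np.random.default_rng(seed)
    proteins = [f"PROT{i:03d}" for i in range(n_proteins)]
    genes = [f"GENE{i:03d}" for i in range(n_proteins)]
    mirnas = [f"syn-miR-{i:02d}-5p" for i in range(n_mirnas)]
    de_proteins = pd.DataFrame(
        {"gene": genes, "direction": direction_protein}, index=proteins
    )
    targeted = rng.choice(n_proteins, size=n_targeted, replace=False)
    true_edges = set()
    for idx in targeted:
        for m in rng.choice(mirnas, size=int(rng.integers(1, 4)), replace=False):
            true_edges.add((str(m), genes[idx]))
    predictions, _ = gen_predictions(
        int(rng.integers(0, 2**31 - 1)), mirnas, genes, true_edges=true_edges, n_decoys=120
    )
    return de_proteins, mirnas, predictions
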