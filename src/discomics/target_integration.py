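"""miRNA-target / differential-protein integration.

Selects one 3'UTR per gene (transcript-support-level and length rules),
filters external target-prediction tables on prediction probability and
duplex minimum free energy, ranks differentially expressed miRNAs by fold
change per direction, and computes the bipartite coverage graph: the
fraction of differential proteins in one direction that are predicted
targets of at least one of the top-N miRNAs moving the opposite way.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class IntegrationParams:
    """prob_min / mfe_max are inclusive retention bounds; top_n per direction.

    ``literal_mfe`` flips the MFE rule to the literal reading (retain weak
    duplexes, MFE >= mfe_max); the default treats the filter as removing
    weak predictions, the conventional direction for MFE thresholds.
    """

    prob_min: float = 0.99995
    mfe_max: float = -15.0
    top_n: int = 10
    literal_mfe: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.prob_min < 1:
            raise ValueError("prob_min must be in (0, 1)")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def select_utrs(records: pd.DataFrame) -> pd.DataFrame:
    """One 3'UTR per gene.

    Genes with a single annotated UTR keep it as-is.  Genes with several are
    restricted to transcript support level 1 or 2 (gene dropped if none
    qualify), then the longest UTR wins; ties go to the lexicographically
    smallest transcript id.  Output is independent of input order.

    Expects columns: gene, transcript, tsl, utr_length.
    """
    def _tsl_ok(v) -> bool:
        try:
            return int(v) in (1, 2)
        except (TypeError, ValueError):
            return False

    chosen = []
    for gene, grp in records.groupby("gene", sort=True):
        if len(grp) == 1:
            chosen.append(grp.iloc[0])
            continue
        supported = grp[grp["tsl"].map(_tsl_ok)]
        if supported.empty:
            log.info("gene %s dropped: no TSL1/TSL2 transcript among multiple UTRs", gene)
            continue
        best = supported.sort_values(
            ["utr_length", "transcript"], ascending=[False, True]
        ).iloc[0]
        chosen.append(best)
    if not chosen:
        return records.iloc[0:0]
    return pd.DataFrame(chosen).reset_index(drop=True)


def filter_predictions(
    records: pd.DataFrame,
    params: IntegrationParams | None = None,
) -> pd.DataFrame:
    """Retain predictions with probability >= prob_min and MFE <= mfe_max.

    Rows with missing probability or MFE are dropped with a warning.
    Expects columns: mirna, gene, probability, mfe (site_class optional).
    """
    params = params or IntegrationParams()
    complete = records["probability"].notna() & records["mfe"].notna()
    if (~complete).any():
        log.warning("dropping %d predictions with missing probability/MFE", int((~complete).sum()))
    recs = records[complete]
    prob_ok = recs["probability"] >= params.prob_min
    if params.literal_mfe:
        mfe_ok = recs["mfe"] >= params.mfe_max
    else:
        mfe_ok = recs["mfe"] <= params.mfe_max
    return recs[prob_ok & mfe_ok].reset_index(drop=True)


def top_n_mirnas(
    de_table: pd.DataFrame,
    direction: str,
    params: IntegrationParams | None = None,
) -> list[str]:
    """Top-N DE miRNAs in one direction, ranked by |log2FC| descending.

    Ties break by smaller FDR, then label.  Fewer than N DE features in the
    direction returns them all with a warning.
    """
    params = params or IntegrationParams()
    de_mask = de_table["de"] if "de" in de_table.columns else pd.Series(True, index=de_table.index)
    eligible = de_table[de_mask & (de_table["direction"] == direction)]
    ranked = eligible.assign(
        _absfc=eligible["log2FC"].abs(), _lbl=eligible.index
    ).sort_values(["_absfc", "fdr", "_lbl"], ascending=[False, True, True])
    labels = list(ranked.index[: params.top_n])
    if len(labels) < params.top_n:
        log.warning(
            "only %d DE features in direction %s (requested top %d)",
            len(labels), direction, params.top_n,
        )
    return labels


@dataclass
class CoverageReport:
    direction: str
    n_proteins: int
    n_targeted: int
    edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def fraction(self) -> float:
        return self.n_targeted / self.n_proteins

    @property
    def percent(self) -> int:
        # round half up so 63.5 -> 64
        return int(math.floor(self.fraction * 100.0 + 0.5))

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "n_proteins": self.n_proteins,
            "n_targeted": self.n_targeted,
            "fraction": self.fraction,
            "percent": self.percent,
            "edges": [list(e) for e in self.edges],
        }


def coverage(
    de_proteins: pd.DataFrame,
    top_mirnas: Sequence[str],
    predictions: pd.DataFrame,
    gene_map: Mapping[str, str] | None = None,
    direction: str = "",
) -> CoverageReport:
    """Bipartite miRNA -> protein coverage for one direction pairing.

    A protein counts as targeted iff its gene symbol is the target of at
    least one of the given miRNAs in the filtered predictions.  Proteins
    without a mappable gene symbol stay in the denominator as untargeted.

    ``de_proteins`` must be indexed by protein id with an optional ``gene``
    column; ``gene_map`` overrides/supplies protein -> gene mapping.
    """
    if len(de_proteins) == 0:
        raise ValueError("empty differential-protein list")
    mirna_set = set(top_mirnas)
    preds = predictions[predictions["mirna"].isin(mirna_set)]
    targets: dict[str, set[str]] = {}
    for _, row in preds.iterrows():
        targets.setdefault(str(row["gene"]), set()).add(str(row["mirna"]))
    edges: list[tuple[str, str]] = []
    n_targeted = 0
    for prot in de_proteins.index:
        gene = None
        if gene_map is not None and prot in gene_map:
            gene = gene_map[prot]
        elif "gene" in de_proteins.columns:
            gene = de_proteins.at[prot, "gene"]
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            continue
        hit_mirnas = targets.get(str(gene), set())
        if hit_mirnas:
            n_targeted += 1
            edges.extend((m, str(prot)) for m in sorted(hit_mirnas))
    return CoverageReport(
        direction=direction,
        n_proteins=len(de_proteins),
        n_targeted=n_targeted,
        edges=edges,
    )


def integrate(
    mirna_de: pd.DataFrame,
    protein_de: pd.DataFrame,
    predictions: pd.DataFrame,
    params: IntegrationParams | None = None,
    gene_map: Mapping[str, str] | None = None,
) -> dict[str, CoverageReport]:
    """Per-direction coverage: miRNAs up in X vs proteins down in X.

    ``mirna_de`` directions are "up_in_<G>" labels from the count DE table;
    ``protein_de`` carries a "direction" column with the same labels.  For
    each group G, proteins down in G (up in the other group) are paired with
    miRNAs up in G.
    """
    params = params or IntegrationParams()
    filtered = filter_predictions(predictions, params)
    levels = sorted(
        {d.removeprefix("up_in_") for d in mirna_de["direction"].unique() if d != "ns"}
    )
    reports: dict[str, CoverageReport] = {}
    for g in levels:
        other = [x for x in levels if x != g]
        if not other:
            continue
        mirnas = top_n_mirnas(mirna_de, f"up_in_{g}", params)
        down_in_g = protein_de[protein_de["direction"] == f"up_in_{other[0]}"]
        if len(down_in_g) == 0:
            continue
        reports[f"proteins_down_in_{g}"] = coverage(
            down_in_g, mirnas, filtered, gene_map, direction=f"proteins_down_in_{g}"
        )
    return reports


def write_coverage_reports(reports: Mapping[str, CoverageReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: r.to_dict() for k, r in reports.items()}, fh, indent=2)
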