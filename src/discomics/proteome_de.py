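"""Label-free proteome statistics in the Perseus style.

Protein-group intensity tables (MaxQuant-like, one LFQ intensity column per
sample) are cleaned of flagged contaminants, log10-transformed, and filtered
to proteins with enough valid values in at least one group.  Proteins seen
in only one group are "on/off" qualitative differences; for the quantitative
comparison, missing values are imputed from a down-shifted narrow normal
distribution per sample column (missing-not-at-random convention) and a
two-sample t-test is assessed with a permutation-based FDR plus a minimum
fold-change rule.  Targeted (parallel reaction monitoring) tables get a
plain Student t-test per protein.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ProteomeParams:
    """Perseus-default imputation constants; s0 = 0 means a plain t statistic."""

    min_valid: int = 2
    group_size: int = 3
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    s0: float = 0.0
    fold_threshold: float = 2.0
    fdr_threshold: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_valid > self.group_size:
            raise ValueError("min_valid must be <= group_size")
        if self.impute_width <= 0:
            raise ValueError("impute_width must be > 0")


@dataclass
class ProteinTable:
    """Intensities (proteins x samples, NaN = missing) with group labels."""

    intensities: pd.DataFrame
    groups: pd.Series
    contaminants: pd.Series | None = None
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)[self.intensities.columns]
        if self.contaminants is None:
            self.contaminants = pd.Series(False, index=self.intensities.index)
        if (self.intensities.to_numpy() <= 0).any():
            raise ValueError("intensities must be positive where present")


def _group_columns(groups: pd.Series) -> dict[str, pd.Index]:
    return {g: groups[groups == g].index for g in groups.unique()}


def preprocess_table(table: ProteinTable, params: ProteomeParams | None = None) -> pd.DataFrame:
    """Contaminant removal, log10 transform, 2-of-3 valid-value filter.

    A protein is retained iff it has >= ``min_valid`` present values in at
    least one group.
    """
    params = params or ProteomeParams()
    vals = table.intensities.loc[~table.contaminants.astype(bool)]
    logged = np.log10(vals)
    keep = pd.Series(False, index=logged.index)
    for _, cols in _group_columns(table.groups).items():
        keep |= logged[cols].notna().sum(axis=1) >= params.min_valid
    return logged.loc[keep]


def call_on_off(
    logged: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    params: ProteomeParams | None = None,
) -> pd.DataFrame:
    """Proteins with valid values in exactly one group, post-filter.

    Returns a frame with the detected group per protein; by construction the
    detecting group has >= ``min_valid`` valid values.
    """
    params = params or ProteomeParams()
    groups = pd.Series(groups)[logged.columns]
    cols_by_group = _group_columns(groups)
    n_valid = {g: logged[cols].notna().sum(axis=1) for g, cols in cols_by_group.items()}
    levels = list(cols_by_group)
    assert len(levels) == 2, "on/off calling expects two groups"
    a, b = levels
    only_a = (n_valid[a] >= params.min_valid) & (n_valid[b] == 0)
    only_b = (n_valid[b] >= params.min_valid) & (n_valid[a] == 0)
    assert not ((n_valid[a] == 0) & (n_valid[b] == 0)).any(), "all-missing row survived filter"
    out = pd.DataFrame(
        {"direction": np.where(only_a, f"on_in_{a}", f"on_in_{b}")},
        index=logged.index,
    )[only_a | only_b]
    return out


def impute_missing(
    logged: pd.DataFrame,
    params: ProteomeParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Impute missing values column-wise from a down-shifted normal.

    Per sample column, missing values are drawn from
    Normal(mean - downshift * SD, (width * SD)^2) of that column's observed
    values.  Observed values are untouched; results are reproducible for a
    given seed.
    """
    params = params or ProteomeParams()
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    out = logged.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - params.impute_downshift * sd, params.impute_width * sd, n_missing)
        out.loc[out[col].isna(), col] = draws
    return out


def _t_statistics(
    values: np.ndarray, cols1: np.ndarray, cols2: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t (with s0 offset); returns (t, diff)."""
    x1, x2 = values[:, cols1], values[:, cols2]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / (se + s0)
    t[np.isnan(t)] = 0.0
    return t, diff


def _distinct_splits(groups: pd.Series) -> list[np.ndarray]:
    """All distinct balanced label reassignments (complement pairs merged).

    The first sample is pinned to group 1 so each split appears once; for
    3 vs 3 this yields C(6,3)/2 = 10 splits including the observed one.
    """
    n = len(groups)
    n1 = int((groups == groups.unique()[0]).sum())
    splits = []
    for rest in combinations(range(1, n), n1 - 1):
        splits.append(np.array((0,) + rest))
    return splits


def permutation_fdr_ttest(
    complete: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    params: ProteomeParams | None = None,
) -> pd.DataFrame:
    """Two-sample t-test with permutation-estimated FDR and a fold rule.

    The null distribution pools the t statistics of all distinct label
    splits other than the observed one (9 for 3 vs 3).  For a |t| cutoff c,
    estimated FDR(c) = mean permuted exceedances / observed exceedances
    (capped at 1); per-protein q-values are made monotone step-up style.
    Significant proteins satisfy q <= fdr_threshold and
    |mean log10 difference| >= log10(fold_threshold).

    With 3 vs 3 there are only 10 distinct splits, so the per-protein
    permutation p-value (add-one convention over the 9 null splits) cannot
    go below 1/10 — the granularity limit of this design.
    """
    params = params or ProteomeParams()
    groups = pd.Series(groups)[complete.columns]
    levels = list(groups.unique())
    if len(levels) != 2:
        raise ValueError("permutation test requires two groups")
    counts = groups.value_counts()
    if counts[levels[0]] != counts[levels[1]]:
        raise ValueError("groups must be balanced")
    values = complete.to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(complete.columns)}
    obs1 = np.array([col_pos[c] for c in groups[groups == levels[0]].index])
    obs2 = np.array([col_pos[c] for c in groups[groups == levels[1]].index])
    t_obs, diff = _t_statistics(values, obs1, obs2, params.s0)

    all_idx = np.arange(len(groups))
    observed_key = frozenset(obs1.tolist())
    if 0 not in observed_key:
        observed_key = frozenset(obs2.tolist())
    null_t: list[np.ndarray] = []
    for split in _distinct_splits(groups):
        key = frozenset(split.tolist())
        if key == observed_key:
            continue
        other = np.setdiff1d(all_idx, split)
        t_perm, _ = _t_statistics(values, split, other, params.s0)
        null_t.append(np.abs(t_perm))
    n_perm = len(null_t)
    null_abs = np.concatenate(null_t)

    abs_obs = np.abs(t_obs)
    order = np.argsort(-abs_obs)
    sorted_abs = abs_obs[order]
    # exceedances at each observed cutoff
    null_sorted = np.sort(null_abs)
    n_null_ge = null_abs.size - np.searchsorted(null_sorted, sorted_abs, side="left")
    r_obs = np.arange(1, len(sorted_abs) + 1)
    fdr_raw = np.minimum((n_null_ge / n_perm) / r_obs, 1.0)
    q_sorted = np.minimum.accumulate(fdr_raw[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    # per-protein permutation p: add-one convention over the protein's own
    # null splits, so min attainable p = 1/(1 + n_perm) = 1/10 for 3 vs 3
    exceed_per_protein = (np.stack(null_t) >= abs_obs[None, :]).sum(axis=0)
    perm_p = (1.0 + exceed_per_protein) / (1.0 + n_perm)

    fold_ok = np.abs(diff) >= math.log10(params.fold_threshold)
    significant = (q <= params.fdr_threshold) & fold_ok
    out = pd.DataFrame(
        {
            "t": t_obs,
            "log10_diff": diff,
            "q": q,
            "perm_p": np.clip(perm_p, 1.0 / (1 + n_perm), 1.0),
            "fold_ok": fold_ok,
            "significant": significant,
            "direction": np.where(diff > 0, f"up_in_{levels[1]}", f"up_in_{levels[0]}"),
        },
        index=complete.index,
    )
    out.attrs["n_permutations"] = n_perm
    out.attrs["group_levels"] = levels
    return out


def summarize_targeted(
    long_table: pd.DataFrame,
    protein_col: str = "protein",
    peptide_col: str = "peptide",
    sample_col: str = "sample",
    area_col: str = "area",
) -> pd.DataFrame:
    """Fragment areas -> protein x sample values.

    Per (protein, peptide, sample): mean of the 3 most intense ion areas;
    then the mean across peptides of a protein.
    """
    def top3_mean(x: pd.Series) -> float:
        return float(x.nlargest(3).mean())

    per_peptide = (
        long_table.groupby([protein_col, peptide_col, sample_col])[area_col]
        .apply(top3_mean)
        .reset_index()
    )
    per_protein = per_peptide.groupby([protein_col, sample_col])[area_col].mean()
    return per_protein.unstack(sample_col)


def targeted_ttest(
    values: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Plain two-sided equal-variance Student t-test per protein.

    Degenerate rows (zero variance in both groups) get p = 1 when the group
    means are equal and p = 0 otherwise.
    """
    groups = pd.Series(groups)[values.columns]
    levels = list(groups.unique())
    if len(levels) != 2:
        raise ValueError("targeted t-test requires two groups")
    cols1 = groups[groups == levels[0]].index
    cols2 = groups[groups == levels[1]].index
    x1 = values[cols1].to_numpy(dtype=float)
    x2 = values[cols2].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x1, x2, axis=1, equal_var=True)
        t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    degenerate = (x1.var(axis=1) == 0) & (x2.var(axis=1) == 0)
    equal_means = np.isclose(x1.mean(axis=1), x2.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    t = np.where(degenerate, 0.0, t)
    diff = x2.mean(axis=1) - x1.mean(axis=1)
    return pd.DataFrame(
        {
            "t": t,
            "diff": diff,
            "p_value": p,
            "significant": p <= 0.05,
            "direction": np.where(diff > 0, f"up_in_{levels[1]}", f"up_in_{levels[0]}"),
        },
        index=values.index,
    )


def combine_de_proteins(
    on_off: pd.DataFrame | None = None,
    lfq: pd.DataFrame | None = None,
    targeted: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Union of differential proteins with source tags (on_off|lfq_fdr|targeted).

    A protein may appear in more than one source; overlap sizes are stored
    in the frame attrs for the composite accounting.
    """
    sources: dict[str, pd.Index] = {}
    direction: dict[str, str] = {}
    if on_off is not None and len(on_off):
        sources["on_off"] = on_off.index
        for prot, row in on_off.iterrows():
            direction.setdefault(prot, row["direction"].replace("on_in", "up_in"))
    if lfq is not None:
        sig = lfq[lfq["significant"]]
        sources["lfq_fdr"] = sig.index
        for prot, row in sig.iterrows():
            direction.setdefault(prot, row["direction"])
    if targeted is not None:
        sig = targeted[targeted["significant"]]
        sources["targeted"] = sig.index
        for prot, row in sig.iterrows():
            direction.setdefault(prot, row["direction"])
    all_proteins = sorted({p for idx in sources.values() for p in idx})
    rows = []
    for prot in all_proteins:
        tags = [name for name, idx in sources.items() if prot in idx]
        rows.append({"protein": prot, "sources": "|".join(tags), "direction": direction[prot]})
    out = pd.DataFrame(rows).set_index("protein") if rows else pd.DataFrame(
        columns=["sources", "direction"]
    )
    out.attrs["source_sizes"] = {k: len(v) for k, v in sources.items()}
    overlaps = {}
    names = list(sources)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            overlaps[f"{names[i]}&{names[j]}"] = len(
                set(sources[names[i]]) & set(sources[names[j]])
            )
    out.attrs["overlaps"] = overlaps
    return out
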