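"""QC, normalization, clonotype-cluster occupancy, and cross-cohort DEG.

Expression lives in an :class:`anndata.AnnData` with raw counts in ``X``
and per-cell metadata in ``obs`` (sample_id, mouse, group, cohort_id,
compartment, cluster_label, clonotype_key).  The operations here:

* QC: drop cells with fewer than 500 detected features or more than 10%
  mitochondrial counts (both thresholds strict, mitochondrial genes found
  by name prefix);
* normalization: ln(1 + 1e4 * count / cell_total), stored as a layer;
* occupancy: per-sample and per-clonotype percent of cells in each
  activation cluster, compared between groups with a two-sided
  Mann-Whitney U test, plus the A6/A5-style cluster ratio;
* differential expression per cohort (Wilcoxon rank-sum on normalized
  values, Seurat-style ln fold change), consolidated across cohorts by the
  most conservative (maximum) p-value and the mean ln fold change, with
  the signed fold-change transform e^lnFC for lnFC > 0 and -1/e^lnFC for
  lnFC < 0.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps

from .errors import ConsistencyError
from .stats import rank_sum_test

OBS_COLUMNS = [
    "barcode", "sample_id", "mouse", "group", "cohort_id", "compartment",
    "cluster_label", "clonotype_key",
]


def _dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def qc_filter(
    adata,
    min_features: int = 500,
    max_mito: float = 0.10,
    mito_prefix: str = "mt-",
):
    """Remove low-quality cells; returns (filtered AnnData, removal tally).

    A cell is removed when it has fewer than ``min_features`` detected
    genes, or when its mitochondrial count share strictly exceeds
    ``max_mito``.  Cells failing both rules are tallied under
    ``low_features`` (reason priority: features first).  If no gene name
    carries the mitochondrial prefix the mito rule is skipped with a
    warning.
    """
    X = adata.X
    if sparse.issparse(X):
        n_features = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        n_features = (X > 0).sum(axis=1)
        totals = X.sum(axis=1)
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    low = n_features < min_features
    if mito_mask.any():
        if sparse.issparse(X):
            mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
        else:
            mito_counts = X[:, mito_mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
        high = share > max_mito
    else:
        warnings.warn(
            f"no gene names start with {mito_prefix!r}; mitochondrial rule skipped"
        )
        high = np.zeros(adata.n_obs, dtype=bool)
    tally = {
        "kept": int((~low & ~high).sum()),
        "low_features": int(low.sum()),
        "high_mito": int((high & ~low).sum()),
    }
    return adata[~low & ~high].copy(), tally


def normalize(adata, layer: str = "lognorm", target_sum: float = 1e4):
    """Add the ln(1 + target_sum * count / total) layer; returns adata."""
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts; run qc_filter first")
    adata.layers[layer] = np.log1p(target_sum * X / totals[:, None])
    return adata


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------


def cluster_distribution(
    obs: pd.DataFrame,
    sample_col: str = "sample_id",
    cluster_col: str = "cluster_label",
) -> pd.DataFrame:
    """Percent of each sample's cells residing in each cluster (rows sum
    to 100)."""
    counts = pd.crosstab(obs[sample_col], obs[cluster_col])
    return 100.0 * counts.div(counts.sum(axis=1), axis=0)


def clonotype_occupancy(
    obs: pd.DataFrame,
    clonotypes: Iterable[str] | None = None,
    min_cells: int = 1,
    clonotype_col: str = "clonotype_key",
    cluster_col: str = "cluster_label",
) -> pd.DataFrame:
    """Per-clonotype percent of cells in each cluster (rows sum to 100).

    Restricted to ``clonotypes`` when given; clonotypes with fewer than
    ``min_cells`` labeled cells are excluded (with a warning when that
    leaves a requested clonotype out entirely).
    """
    sub = obs[obs[cluster_col].notna()]
    if clonotypes is not None:
        wanted = set(clonotypes)
        sub = sub[sub[clonotype_col].isin(wanted)]
    counts = pd.crosstab(sub[clonotype_col], sub[cluster_col])
    sizes = counts.sum(axis=1)
    dropped = sizes[sizes < min_cells]
    if clonotypes is not None:
        missing = wanted - set(counts.index)
        if missing or len(dropped):
            warnings.warn(
                f"{len(missing) + len(dropped)} clonotype(s) excluded "
                f"(< {min_cells} labeled cells)"
            )
    counts = counts[sizes >= min_cells]
    occ = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    occ.index.name = "clonotype_key"
    return occ


def log10_occupancy(occupancy: pd.DataFrame) -> pd.DataFrame:
    """Display transform: log10 of percent, zero percent -> missing."""
    with np.errstate(divide="ignore"):
        out = np.log10(occupancy.where(occupancy > 0))
    return out


def occupancy_compare(
    occ_r: pd.DataFrame, occ_nr: pd.DataFrame, min_clonotypes: int = 3
) -> pd.DataFrame:
    """Per-cluster two-sided Mann-Whitney U comparison of R vs NR
    clonotype occupancies.  Requires at least ``min_clonotypes`` per side."""
    if len(occ_r) < min_clonotypes or len(occ_nr) < min_clonotypes:
        raise ValueError(
            f"need at least {min_clonotypes} clonotypes per group "
            f"(got {len(occ_r)} and {len(occ_nr)})"
        )
    clusters = occ_r.columns.union(occ_nr.columns)
    rows = []
    for cluster in clusters:
        x = occ_r.get(cluster, pd.Series(0.0, index=occ_r.index)).to_numpy()
        y = occ_nr.get(cluster, pd.Series(0.0, index=occ_nr.index)).to_numpy()
        res = rank_sum_test(x, y)
        rows.append((cluster, res.u, res.p, res.method))
    return pd.DataFrame(
        rows, columns=["cluster", "u", "p", "method"]
    ).set_index("cluster")


def cluster_ratio(
    occupancy: pd.DataFrame, num_cluster: str = "A6", den_cluster: str = "A5"
) -> pd.Series:
    """Per-clonotype percent ratio num/den; NaN where the denominator is 0."""
    num = occupancy.get(num_cluster, pd.Series(0.0, index=occupancy.index))
    den = occupancy.get(den_cluster, pd.Series(0.0, index=occupancy.index))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / den, np.nan)
    return pd.Series(ratio, index=occupancy.index, name=f"{num_cluster}/{den_cluster}")


def shared_clonotype_profile(
    obs: pd.DataFrame,
    shared_keys: Iterable[str],
    min_cells: int = 20,
    group_col: str = "group",
    clonotype_col: str = "clonotype_key",
    cluster_col: str = "cluster_label",
) -> pd.DataFrame:
    """Side-by-side R/NR occupancy vectors for shared clonotypes.

    Only clonotypes with at least ``min_cells`` labeled cells in *each*
    group are profiled; the result is indexed by (clonotype, group) and
    may be empty.
    """
    shared_keys = set(shared_keys)
    sub = obs[
        obs[clonotype_col].isin(shared_keys)
        & obs[cluster_col].notna()
        & obs[group_col].isin(["R", "NR"])
    ]
    frames = []
    for key, block in sub.groupby(clonotype_col, observed=True):
        sizes = block.groupby(group_col, observed=True).size()
        if sizes.get("R", 0) < min_cells or sizes.get("NR", 0) < min_cells:
            continue
        occ = 100.0 * pd.crosstab(
            block[group_col], block[cluster_col], normalize="index"
        )
        occ.index = pd.MultiIndex.from_product(
            [[key], occ.index], names=["clonotype_key", "group"]
        )
        frames.append(occ)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames).fillna(0.0)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def _wilcoxon_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise two-sided Mann-Whitney p-values (tie-corrected normal
    approximation; exact when both arms have <= 8 cells)."""
    if a.shape[0] <= 8 and b.shape[0] <= 8:
        return np.array(
            [rank_sum_test(a[:, j], b[:, j]).p for j in range(a.shape[1])]
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                               method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))


def _seurat_lnfc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """ln[(mean(e^x - 1 over A) + 1) / (mean(e^x - 1 over B) + 1)] on the
    log-normalized scale — the de-logged-mean-plus-pseudocount ratio."""
    ma = np.expm1(a).mean(axis=0)
    mb = np.expm1(b).mean(axis=0)
    return np.log((ma + 1.0) / (mb + 1.0))


def deg_per_cohort(
    adata,
    mask_a,
    mask_b,
    cohort_id,
    layer: str = "lognorm",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DEG between two cell groups of one cohort.

    Returns (gene, cohort_id, ln_fc, p); an empty frame with a warning when
    either arm has fewer than ``min_cells`` cells.
    """
    if layer not in adata.layers:
        raise ValueError(f"layer {layer!r} not found; run normalize() first")
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.sum() < min_cells or mask_b.sum() < min_cells:
        warnings.warn(
            f"cohort {cohort_id}: arm too small "
            f"({int(mask_a.sum())} vs {int(mask_b.sum())} cells); skipped"
        )
        return pd.DataFrame(columns=["gene", "cohort_id", "ln_fc", "p"])
    a = _dense(adata.layers[layer][mask_a])
    b = _dense(adata.layers[layer][mask_b])
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "cohort_id": cohort_id,
            "ln_fc": _seurat_lnfc(a, b),
            "p": _wilcoxon_matrix(a, b),
        }
    )


def fc_transform(ln_fc):
    """Signed fold change: e^lnFC for lnFC > 0, -1/e^lnFC for lnFC < 0,
    1.0 at exactly zero.  Accepts scalars or arrays."""
    arr = np.asarray(ln_fc, dtype=float)
    out = np.where(arr > 0, np.exp(arr), np.where(arr < 0, -np.exp(-arr), 1.0))
    if np.isscalar(ln_fc) or arr.ndim == 0:
        return float(out)
    return out


def consolidate_deg(records: pd.DataFrame) -> pd.DataFrame:
    """Combine per-cohort DEG records per gene: most conservative (maximum)
    p across cohorts, arithmetic-mean lnFC, signed fold change, and a flag
    for genes whose lnFC sign disagrees across cohorts."""
    if records.empty:
        return pd.DataFrame(
            columns=["gene", "ln_fc_mean", "p_conservative", "fold_change",
                     "n_cohorts", "sign_consistent"]
        )
    grouped = records.groupby("gene", observed=True)
    out = pd.DataFrame(
        {
            "ln_fc_mean": grouped["ln_fc"].mean(),
            "p_conservative": grouped["p"].max(),
            "n_cohorts": grouped["p"].size(),
            "sign_consistent": grouped["ln_fc"].agg(
                lambda s: bool((s >= 0).all() or (s <= 0).all())
            ),
        }
    )
    out["fold_change"] = fc_transform(out["ln_fc_mean"].to_numpy())
    out = out.reset_index()[
        ["gene", "ln_fc_mean", "p_conservative", "fold_change",
         "n_cohorts", "sign_consistent"]
    ]
    return out.sort_values("gene", kind="stable").reset_index(drop=True)


def spleen_abundance(obs: pd.DataFrame) -> pd.DataFrame:
    """Percent of each clonotype in each splenic sample (clonotype x sample)."""
    spleen = obs[obs["compartment"] == "spleen"]
    if spleen.empty:
        raise ConsistencyError("no splenic cells in obs")
    counts = pd.crosstab(spleen["clonotype_key"], spleen["sample_id"])
    return 100.0 * counts.div(counts.sum(axis=0), axis=1)


def other_cell_mask(
    obs: pd.DataFrame,
    top_keys: Set[str],
    spleen_threshold: float = 1.0,
    scope: str = "all",
) -> np.ndarray:
    """Cells of "Other" clonotypes: below ``spleen_threshold`` percent in
    every splenic sample (``scope='all'``) or in the cell's own mouse's
    spleen (``scope='own'``), and not in any top set.  Clonotypes absent
    from a spleen count as 0% there.
    """
    ab = spleen_abundance(obs)
    key = obs["clonotype_key"]
    if scope == "all":
        low = set(ab.index[(ab < spleen_threshold).all(axis=1)])
        # clonotypes never seen in any spleen are below threshold everywhere
        unseen = set(key.dropna()) - set(ab.index)
        ok = key.isin(low | unseen)
    elif scope == "own":
        sample_mouse = (
            obs[obs["compartment"] == "spleen"]
            .groupby("sample_id", observed=True)["mouse"]
            .first()
        )
        mouse_of_spleen = {m: s for s, m in sample_mouse.items()}
        ok = np.zeros(len(obs), dtype=bool)
        for i, (k, mouse) in enumerate(zip(key, obs["mouse"])):
            spl = mouse_of_spleen.get(mouse)
            pct = ab.at[k, spl] if (spl is not None and k in ab.index) else 0.0
            ok[i] = pct < spleen_threshold
        ok = pd.Series(ok, index=obs.index)
    else:
        raise ValueError("scope must be 'all' or 'own'")
    return (ok & key.notna() & ~key.isin(top_keys)).to_numpy()


def deg_comparisons(
    adata,
    top_r: Set[str],
    top_nr: Set[str],
    layer: str = "lognorm",
    spleen_threshold: float = 1.0,
    other_scope: str = "all",
    min_cells: int = 3,
) -> Dict[str, pd.DataFrame]:
    """The four consolidated DEG comparisons.

    I:  R top TIL clonotype cells vs "Other" clonotype cells
    II: NR top TIL clonotype cells vs "Other" clonotype cells
    III: R top vs NR top;  IV: NR top vs R top (III with signs negated)

    Each comparison runs per cohort and is consolidated across cohorts.
    """
    obs = adata.obs
    key = obs["clonotype_key"]
    til = (obs["compartment"] == "TIL").to_numpy()
    r_cells = (key.isin(top_r) & (obs["group"] == "R")).to_numpy() & til
    nr_cells = (key.isin(top_nr) & (obs["group"] == "NR")).to_numpy() & til
    other = other_cell_mask(
        obs, top_r | top_nr, spleen_threshold=spleen_threshold, scope=other_scope
    )
    cohorts = sorted(obs["cohort_id"].unique())
    arms = {
        "I": (r_cells, other),
        "II": (nr_cells, other),
        "III": (r_cells, nr_cells),
        "IV": (nr_cells, r_cells),
    }
    out: Dict[str, pd.DataFrame] = {}
    for name, (a, b) in arms.items():
        records = []
        for cohort in cohorts:
            in_cohort = (obs["cohort_id"] == cohort).to_numpy()
            rec = deg_per_cohort(
                adata, a & in_cohort, b & in_cohort, cohort,
                layer=layer, min_cells=min_cells,
            )
            if not rec.empty:
                records.append(rec)
        merged = (
            pd.concat(records, ignore_index=True)
            if records
            else pd.DataFrame(columns=["gene", "cohort_id", "ln_fc", "p"])
        )
        out[name] = consolidate_deg(merged)
    return out


def differential_gene_filter(
    cons_r: pd.DataFrame, cons_nr: pd.DataFrame, min_diff: float = 0.4
) -> pd.DataFrame:
    """Genes whose R and NR signed fold changes differ by at least
    ``min_diff`` (the display filter used for the top-clonotype heatmap)."""
    merged = cons_r.set_index("gene")[["fold_change"]].join(
        cons_nr.set_index("gene")[["fold_change"]],
        lsuffix="_r", rsuffix="_nr", how="inner",
    )
    diff = (merged["fold_change_r"] - merged["fold_change_nr"]).abs()
    return merged[diff >= min_diff].assign(fc_difference=diff[diff >= min_diff])
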