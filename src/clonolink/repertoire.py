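"""Repertoire-level summaries and the R-vs-NR mutual-exclusivity test.

Covers the pairwise overlap-coefficient matrix, binned relative clonal
abundance, V-J gene-segment usage, K-means clustering of samples on TRBV
usage, and a Fisher's-exact contingency test of whether top clonotypes of
one response group are detected in the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .stats import FisherResult, fisher_exact, fisher_exact_p, odds_ratio

# (0, 1]-partitioning proportion bins spanning singleton to hyperexpanded
DEFAULT_ABUNDANCE_BINS: Tuple[Tuple[float, float], ...] = (
    (0.0, 1e-4), (1e-4, 1e-3), (1e-3, 1e-2), (1e-2, 1e-1), (1e-1, 1.0),
)


def overlap_coefficient(a: Set[str], b: Set[str]) -> float:
    """|A n B| / min(|A|, |B|); NaN with a warning when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        warnings.warn("overlap coefficient undefined for two empty sets")
        return float("nan")
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def sample_clonotype_sets(
    tables: Mapping[str, pd.DataFrame]
) -> Dict[str, Set[str]]:
    """Clonotype-key sets (>= 1 cell) per sample from abundance tables."""
    return {
        s: set(t.loc[t["cell_count"] >= 1, "clonotype_key"])
        for s, t in tables.items()
    }


def overlap_matrix(sets: Mapping[str, Set[str]]) -> pd.DataFrame:
    """Symmetric pairwise overlap-coefficient matrix over samples."""
    if len(sets) < 2:
        raise ValueError("need at least two samples")
    ids = list(sets)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, si in enumerate(ids):
            for sj in ids[i:]:
                v = overlap_coefficient(sets[si], sets[sj])
                mat.loc[si, sj] = v
                mat.loc[sj, si] = v
    return mat


def _validate_bins(bins: Sequence[Tuple[float, float]]) -> None:
    bins = list(bins)
    if not bins:
        raise ValueError("bins must be non-empty")
    for lo, hi in bins:
        if not lo < hi:
            raise ValueError(f"bin ({lo}, {hi}] is empty or inverted")
    for (lo1, hi1), (lo2, hi2) in zip(bins, bins[1:]):
        if hi1 > lo2:
            raise ValueError("bins overlap")
        if hi1 < lo2:
            raise ValueError("bins leave a gap; they must partition (0, 1]")
    if bins[0][0] != 0.0 or bins[-1][1] != 1.0:
        raise ValueError("bins must partition (0, 1]")


def relative_clonal_abundance(
    table: pd.DataFrame,
    bins: Sequence[Tuple[float, float]] = DEFAULT_ABUNDANCE_BINS,
) -> pd.DataFrame:
    """Clonotype counts and summed cell share per proportion bin.

    Each clonotype falls in the (lo, hi] bin containing its within-sample
    proportion; shares across bins sum to 1.
    """
    _validate_bins(bins)
    props = table["percent"].to_numpy() / 100.0
    uppers = np.array([hi for _, hi in bins])
    idx = np.searchsorted(uppers, props, side="left")
    labels = [f"({lo:g}, {hi:g}]" for lo, hi in bins]
    out = pd.DataFrame(
        {"n_clonotypes": 0, "cell_share": 0.0},
        index=pd.Index(labels, name="bin"),
    )
    for i, lab in enumerate(labels):
        sel = idx == i
        out.loc[lab, "n_clonotypes"] = int(sel.sum())
        out.loc[lab, "cell_share"] = float(props[sel].sum())
    return out


def vj_usage(cells: pd.DataFrame, chain: str) -> pd.DataFrame:
    """Cell-weighted V x J usage proportions for one sample's cells.

    For TRA, a dual-alpha cell contributes 0.5 per alpha chain so each cell
    has total weight 1; entries sum to 1.
    """
    if chain not in ("TRA", "TRB"):
        raise ValueError("chain must be 'TRA' or 'TRB'")
    if len(cells) == 0:
        raise ValueError("need at least one cell")
    if chain == "TRB":
        long = cells[["trb_v", "trb_j"]].rename(
            columns={"trb_v": "v", "trb_j": "j"}
        )
        long = long.assign(w=1.0)
    else:
        has2 = cells["tra2_cdr3_nt"].notna() if "tra2_cdr3_nt" in cells else pd.Series(False, index=cells.index)
        first = cells[["tra1_v", "tra1_j"]].rename(
            columns={"tra1_v": "v", "tra1_j": "j"}
        )
        first = first.assign(w=np.where(has2, 0.5, 1.0))
        parts = [first]
        if has2.any():
            second = cells.loc[has2, ["tra2_v", "tra2_j"]].rename(
                columns={"tra2_v": "v", "tra2_j": "j"}
            )
            parts.append(second.assign(w=0.5))
        long = pd.concat(parts, ignore_index=True)
    mat = long.pivot_table(index="v", columns="j", values="w", aggfunc="sum",
                           fill_value=0.0)
    return mat / mat.to_numpy().sum()


def trbv_usage_vectors(
    cells_by_sample: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Samples x TRBV matrix of marginal beta-V usage proportions."""
    rows = {}
    for sample, cells in cells_by_sample.items():
        counts = cells["trb_v"].value_counts(normalize=True)
        rows[sample] = counts
    return pd.DataFrame(rows).T.fillna(0.0).sort_index(axis=1)


def kmeans_usage(
    usage: pd.DataFrame, k: int = 2, seed: int | None = None, n_init: int = 25
) -> pd.Series:
    """Cluster samples on usage vectors: Lloyd's algorithm, Euclidean
    distance, best of ``n_init`` random initializations."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(usage):
        raise ValueError(f"k={k} exceeds the number of samples ({len(usage)})")
    km = KMeans(
        n_clusters=k, init="random", n_init=n_init, random_state=seed,
        algorithm="lloyd",
    )
    labels = km.fit_predict(usage.to_numpy())
    return pd.Series(labels, index=usage.index, name="cluster")


@dataclass(frozen=True)
class ExclusivityResult:
    table: np.ndarray  # rows: (R-top, NR-top); cols: (detected in R, in NR)
    odds_ratio: float
    p: float
    unit: str


def _detections(
    keys: Set[str], tables: Mapping[str, pd.DataFrame], unit: str
) -> int:
    sets = sample_clonotype_sets(tables)
    if unit == "events":
        return sum(1 for s in sets.values() for k in keys if k in s)
    if unit == "clonotypes":
        return sum(1 for k in keys if any(k in s for s in sets.values()))
    raise ValueError("unit must be 'events' or 'clonotypes'")


def exclusivity_test(
    top_r: Set[str],
    top_nr: Set[str],
    tables_r: Mapping[str, pd.DataFrame],
    tables_nr: Mapping[str, pd.DataFrame],
    unit: str = "events",
) -> ExclusivityResult:
    """Fisher's exact test of whether R-top clonotypes are detected in R
    samples and NR-top clonotypes in NR samples more than crosswise.

    With ``unit='events'`` (default) each (clonotype, sample) presence is
    one detection, so a clonotype seen in 3 R samples contributes 3; with
    ``unit='clonotypes'`` each clonotype contributes at most one detection
    per group.
    """
    if not top_r or not top_nr:
        raise ValueError("both top sets must be non-empty")
    table = np.array(
        [
            [_detections(top_r, tables_r, unit), _detections(top_r, tables_nr, unit)],
            [_detections(top_nr, tables_r, unit), _detections(top_nr, tables_nr, unit)],
        ],
        dtype=np.int64,
    )
    return ExclusivityResult(
        table=table,
        odds_ratio=odds_ratio(table),
        p=fisher_exact_p(table),
        unit=unit,
    )


__all__ = [
    "overlap_coefficient", "overlap_matrix", "sample_clonotype_sets",
    "relative_clonal_abundance", "vj_usage", "trbv_usage_vectors",
    "kmeans_usage", "exclusivity_test", "ExclusivityResult",
    "fisher_exact", "fisher_exact_p", "DEFAULT_ABUNDANCE_BINS",
]
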