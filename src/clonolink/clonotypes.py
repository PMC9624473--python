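"""Clone and clonotype assignment, percent abundance, top selection, sharing.

A *clone* groups cells by identical nucleotide CDR3 sequences of the beta
and alpha chain(s); a *clonotype* groups by identical amino-acid CDR3s, so
synonymous nucleotide variants collapse into one clonotype and the clone
partition refines the clonotype partition.  Keys are flat strings:

    clone_key     = TRB_cdr3_nt | tra_nt_1[,tra_nt_2]      (alphas sorted)
    clonotype_key = TRB_cdr3_aa | tra_aa_1[,tra_aa_2]      (alphas sorted)

A dual-alpha cell never merges with a single-alpha cell even when one alpha
matches: the sorted alpha tuple is part of the identity.

Percent abundance of a clonotype in a sample is 100 * (cells with that
clonotype) / (total cells in the sample).  "Top" selection is strict:
a clonotype is top for a group iff its percent exceeds the group threshold
in at least one sample of that group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Set

import numpy as np
import pandas as pd

from .errors import ConsistencyError

# threshold presets, in percent: `vdj` for repertoire analyses, `expression`
# for the transcriptome analyses (0.65% in responder samples so both groups
# contribute comparable clonotype numbers)
TOP_THRESHOLDS = {
    "vdj": {"R": 1.0, "NR": 1.0},
    "expression": {"R": 0.65, "NR": 1.0},
}


def _sorted_pair(a: pd.Series, b: pd.Series | None, has2: np.ndarray) -> np.ndarray:
    """Comma-join the sorted (a, b) pair where b is present, else a alone."""
    x1 = a.fillna("").to_numpy(dtype=object)
    if b is None:
        return x1
    x2 = b.fillna("").to_numpy(dtype=object)
    lo = np.where(x1 <= x2, x1, x2)
    hi = np.where(x1 <= x2, x2, x1)
    return np.where(has2, lo + "," + hi, x1)


def add_receptor_keys(cells: pd.DataFrame) -> pd.DataFrame:
    """Add ``clone_key`` and ``clonotype_key`` columns to an assembled-cell
    table (idempotent; returns a copy)."""
    out = cells.copy()
    if "tra2_cdr3_nt" in out:
        has2 = out["tra2_cdr3_nt"].notna().to_numpy()
    else:
        has2 = np.zeros(len(out), dtype=bool)
    tra_nt = _sorted_pair(out["tra1_cdr3_nt"], out.get("tra2_cdr3_nt"), has2)
    tra_aa = _sorted_pair(out["tra1_cdr3_aa"], out.get("tra2_cdr3_aa"), has2)
    out["clone_key"] = out["trb_cdr3_nt"].astype(str) + "|" + tra_nt
    out["clonotype_key"] = out["trb_cdr3_aa"].astype(str) + "|" + tra_aa
    return out


def _ensure_keys(cells: pd.DataFrame) -> pd.DataFrame:
    if "clone_key" not in cells.columns or "clonotype_key" not in cells.columns:
        return add_receptor_keys(cells)
    return cells


def assign_clones(cells: pd.DataFrame) -> pd.DataFrame:
    """Partition cells into clones (nt identity).

    Returns a tidy table (clone_key, sample_id, n_cells) ordered by total
    clone size descending then key; empty input gives an empty table.
    """
    return _partition(cells, "clone_key")


def assign_clonotypes(cells: pd.DataFrame) -> pd.DataFrame:
    """Partition cells into clonotypes (aa identity); see assign_clones."""
    return _partition(cells, "clonotype_key")


def _partition(cells: pd.DataFrame, key: str) -> pd.DataFrame:
    if len(cells) == 0:
        return pd.DataFrame(columns=[key, "sample_id", "n_cells"])
    cells = _ensure_keys(cells)
    tidy = (
        cells.groupby([key, "sample_id"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = tidy.groupby(key, observed=True)["n_cells"].sum()
    order = totals.sort_values(ascending=False).index
    rank = {k: i for i, k in enumerate(
        sorted(order, key=lambda k: (-totals[k], k))
    )}
    tidy["_rank"] = tidy[key].map(rank)
    tidy = tidy.sort_values(["_rank", "sample_id"], kind="stable").drop(columns="_rank")
    return tidy.reset_index(drop=True)


def clone_clonotype_map(cells: pd.DataFrame) -> pd.DataFrame:
    """Unique (clone_key, clonotype_key) pairs; raises if any clone maps to
    two clonotypes (impossible for translation-consistent data)."""
    cells = _ensure_keys(cells)
    pairs = cells[["clone_key", "clonotype_key"]].drop_duplicates()
    dup = pairs["clone_key"].duplicated()
    if dup.any():
        bad = pairs.loc[dup, "clone_key"].iloc[0]
        raise ConsistencyError(
            f"clone {bad!r} maps to more than one clonotype"
        )
    return pairs.sort_values("clone_key", kind="stable").reset_index(drop=True)


def abundance_table(cells: pd.DataFrame, sample_id: str | None = None) -> pd.DataFrame:
    """Per-clonotype cell counts and percent abundance for one sample.

    percent = 100 * count / total cells in the sample; percents sum to 100.
    """
    cells = _ensure_keys(cells)
    if sample_id is not None:
        cells = cells[cells["sample_id"] == sample_id]
    elif cells["sample_id"].nunique() > 1:
        raise ValueError("cells span multiple samples; pass sample_id")
    if len(cells) == 0:
        raise ValueError("cannot build an abundance table for an empty sample")
    total = len(cells)
    counts = cells.groupby("clonotype_key", observed=True).size()
    table = pd.DataFrame(
        {
            "clonotype_key": counts.index,
            "cell_count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total,
        }
    )
    table = table.sort_values(
        ["cell_count", "clonotype_key"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table.attrs["sample_id"] = sample_id or cells["sample_id"].iloc[0]
    table.attrs["total_cells"] = total
    return table


def select_top(
    tables: Mapping[str, pd.DataFrame],
    thresholds: Mapping[str, float],
    sample_groups: Mapping[str, str],
) -> Dict[str, Set[str]]:
    """Top clonotypes per group: percent strictly above the group threshold
    in at least one sample of that group.

    ``thresholds`` maps group -> percent (see TOP_THRESHOLDS presets);
    ``sample_groups`` maps sample id -> group.  Groups that appear on only
    one side of the two maps are an error.
    """
    for g, thr in thresholds.items():
        if thr <= 0:
            raise ValueError(f"threshold for group {g!r} must be positive")
    groups_seen = {sample_groups[s] for s in tables if s in sample_groups}
    missing_samples = [s for s in tables if s not in sample_groups]
    if missing_samples:
        raise ValueError(f"samples without a group: {missing_samples}")
    unknown = groups_seen - set(thresholds)
    if unknown:
        raise ValueError(f"no threshold for group(s): {sorted(unknown)}")
    stale = set(thresholds) - groups_seen
    if stale:
        raise ValueError(f"threshold for unknown group(s): {sorted(stale)}")
    top: Dict[str, Set[str]] = {g: set() for g in thresholds}
    for sample, table in tables.items():
        g = sample_groups[sample]
        hits = table.loc[table["percent"] > thresholds[g], "clonotype_key"]
        top[g].update(hits)
    return top


@dataclass(frozen=True)
class SharingSummary:
    presence: pd.Series  # clonotype_key -> number of mice it was detected in
    multi_mouse_fraction: float


def sharing_summary(
    tables_by_mouse: Mapping[str, pd.DataFrame], top_keys: Iterable[str]
) -> SharingSummary:
    """How many mice each top clonotype was detected in (>= 1 cell), and the
    fraction of top clonotypes present in more than one mouse."""
    if len(tables_by_mouse) < 2:
        raise ValueError("sharing requires at least two mice")
    top_keys = sorted(set(top_keys))
    counts = pd.Series(0, index=pd.Index(top_keys, name="clonotype_key"))
    for table in tables_by_mouse.values():
        seen = set(table.loc[table["cell_count"] >= 1, "clonotype_key"])
        for k in top_keys:
            if k in seen:
                counts[k] += 1
    frac = float((counts > 1).mean()) if len(counts) else float("nan")
    return SharingSummary(presence=counts, multi_mouse_fraction=frac)
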