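"""Ingest 10x-style ``filtered_contig_annotations`` tables into paired cells.

The contract mirrors how the source data were filtered: keep only full
length, productive, high-confidence TRA/TRB contigs with complete V/J calls
and CDR3 sequences, then keep only barcodes carrying exactly one beta chain
and one or two alpha chains (the TCRa locus lacks allelic exclusion, so a
genuine cell may express two alphas).  Everything is kept in pandas
DataFrames: contigs one-row-per-contig, assembled cells one-row-per-cell
with ``trb_*`` / ``tra1_*`` / ``tra2_*`` columns.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError

REQUIRED_COLUMNS = [
    "barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt",
    "full_length", "productive", "high_confidence",
]

CELL_COLUMNS = [
    "sample_id", "barcode",
    "trb_v", "trb_j", "trb_cdr3_nt", "trb_cdr3_aa",
    "tra1_v", "tra1_j", "tra1_cdr3_nt", "tra1_cdr3_aa",
    "tra2_v", "tra2_j", "tra2_cdr3_nt", "tra2_cdr3_aa",
]

_TRUE = {"true", "t", "1", "yes"}
_FALSE = {"false", "f", "0", "no", "none", ""}
_MISSING = {"", "none", "nan", "na"}


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    lowered = series.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(_TRUE | _FALSE)
    if bad.any():
        value = series[bad].iloc[0]
        raise FormatError(
            f"column '{column}' has unrecognized boolean value {value!r}"
        )
    return lowered.isin(_TRUE)


def _clean_text(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip()
    return s.mask(s.str.lower().isin(_MISSING))


def read_contigs(path, sample_id: str) -> pd.DataFrame:
    """Read one contig-annotation CSV into a normalized contig table.

    Chains other than TRA/TRB are retained but flagged ``other``; a CDR3 of
    "None" or empty becomes missing; True/False, true/false and TRUE/FALSE
    boolean dialects are all accepted.  A missing ``umis`` column defaults
    to 1.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise FormatError(f"cannot read contig file {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required columns: {', '.join(missing)}"
        )
    chain = raw["chain"].astype(str).str.strip().str.upper()
    out = pd.DataFrame(
        {
            "barcode": raw["barcode"].astype(str),
            "sample_id": sample_id,
            "chain": chain.where(chain.isin(["TRA", "TRB"]), "other"),
            "v_gene": _clean_text(raw["v_gene"]),
            "d_gene": _clean_text(raw["d_gene"]) if "d_gene" in raw.columns else pd.NA,
            "j_gene": _clean_text(raw["j_gene"]),
            "cdr3_nt": _clean_text(raw["cdr3_nt"]),
            "cdr3_aa": _clean_text(raw["cdr3"]),
            "full_length": _parse_bool(raw["full_length"], "full_length"),
            "productive": _parse_bool(raw["productive"], "productive"),
            "high_confidence": _parse_bool(raw["high_confidence"], "high_confidence"),
        }
    )
    if "umis" in raw.columns:
        out["umis"] = pd.to_numeric(raw["umis"], errors="coerce").fillna(1).astype(int)
    else:
        out["umis"] = 1
    return out


def filter_contigs(contigs: pd.DataFrame) -> pd.DataFrame:
    """Keep full-length, productive, high-confidence TRA/TRB contigs with
    complete V/J calls and CDR3 nt+aa sequences.  Idempotent."""
    mask = (
        contigs["full_length"]
        & contigs["productive"]
        & contigs["high_confidence"]
        & contigs["chain"].isin(["TRA", "TRB"])
        & contigs["cdr3_nt"].notna()
        & contigs["cdr3_aa"].notna()
        & contigs["v_gene"].notna()
        & contigs["j_gene"].notna()
    )
    return contigs.loc[mask].reset_index(drop=True)


def assemble_cells(contigs: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Group filtered contigs by barcode into paired-chain cells.

    A barcode becomes a cell iff it carries exactly 1 TRB and 1-2 TRA
    contigs after collapsing duplicate (barcode, chain, cdr3_nt) rows to
    the highest-UMI copy — two alpha contigs with identical nucleotide CDR3
    are one rearrangement.  Dropped barcodes are tallied by the first
    matching reason (no TRB, multiple TRB, no TRA, more than two TRA).
    """
    tally = {"kept": 0, "no_trb": 0, "multi_trb": 0, "no_tra": 0, "excess_tra": 0}
    if contigs.empty:
        return pd.DataFrame(columns=CELL_COLUMNS), tally
    dedup = (
        contigs.sort_values("umis", ascending=False, kind="stable")
        .drop_duplicates(["sample_id", "barcode", "chain", "cdr3_nt"], keep="first")
    )
    key = ["sample_id", "barcode"]
    counts = (
        dedup.groupby(key + ["chain"], observed=True)
        .size()
        .unstack("chain", fill_value=0)
    )
    n_trb = counts["TRB"] if "TRB" in counts else pd.Series(0, index=counts.index)
    n_tra = counts["TRA"] if "TRA" in counts else pd.Series(0, index=counts.index)
    tally["no_trb"] = int((n_trb == 0).sum())
    tally["multi_trb"] = int((n_trb >= 2).sum())
    remaining = (n_trb == 1)
    tally["no_tra"] = int((remaining & (n_tra == 0)).sum())
    tally["excess_tra"] = int((remaining & (n_tra >= 3)).sum())
    keep = remaining & n_tra.isin([1, 2])
    tally["kept"] = int(keep.sum())

    kept_index = counts.index[keep]
    idx = pd.MultiIndex.from_frame(dedup[key])
    sub = dedup.loc[idx.isin(kept_index)]
    if sub.empty:
        return pd.DataFrame(columns=CELL_COLUMNS), tally

    trb = sub[sub["chain"] == "TRB"].set_index(key)
    tra = sub[sub["chain"] == "TRA"].sort_values(
        key + ["cdr3_nt"], kind="stable"
    )
    tra = tra.assign(rank=tra.groupby(key).cumcount() + 1)
    cells = pd.DataFrame(index=trb.index)
    cells["trb_v"] = trb["v_gene"]
    cells["trb_j"] = trb["j_gene"]
    cells["trb_cdr3_nt"] = trb["cdr3_nt"]
    cells["trb_cdr3_aa"] = trb["cdr3_aa"]
    for rank in (1, 2):
        part = tra[tra["rank"] == rank].set_index(key)
        for col, src in (("v", "v_gene"), ("j", "j_gene"),
                         ("cdr3_nt", "cdr3_nt"), ("cdr3_aa", "cdr3_aa")):
            cells[f"tra{rank}_{col}"] = part[src]
    cells = cells.reset_index()[CELL_COLUMNS].sort_values(
        ["sample_id", "barcode"], kind="stable"
    )
    return cells.reset_index(drop=True), tally


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_cells(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
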