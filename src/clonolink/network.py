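"""CDR3-beta specificity groups and network node metrics.

Nodes are beta-chain CDR3 amino-acid sequences; a node's percent in a
sample is the summed percent of all clonotypes sharing that beta CDR3.
The two per-node metrics follow the source formulas exactly (percents on
the 0-100 scale, averaged over the samples of each group):

    node_size      = 100 * (mean % in R samples + mean % in NR samples)
    relative_ratio = mean % in NR / (mean % in R + mean % in NR)

so a sequence seen only in NR samples scores 1.0 and one seen only in R
samples scores 0.0; the ratio is undefined (NaN) when both means are zero.

Group construction here is a deliberately simplified similarity grouping —
a stand-in with two criteria, equal-length Hamming-distance-<=1 ("global")
edges and shared-enriched-interior-k-mer ("local") edges — and externally
computed group assignments can be imported instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError

Edge = Tuple[str, str, str]  # (seq_a, seq_b, "global" | "local")


@dataclass(frozen=True)
class SpecificityGroup:
    group_id: str
    members: Tuple[str, ...]
    edges: Tuple[Edge, ...]


def node_size(pct_r: Sequence[float], pct_nr: Sequence[float]) -> float:
    """100 * (mean percent across R samples + mean percent across NR
    samples); absent samples enter as zeros in the caller's vectors."""
    r = np.asarray(pct_r, dtype=float)
    nr = np.asarray(pct_nr, dtype=float)
    if np.any(r < 0) or np.any(nr < 0):
        raise ValueError("percents must be non-negative")
    return float(100.0 * (r.mean() + nr.mean()))


def relative_ratio(pct_r: Sequence[float], pct_nr: Sequence[float]) -> float:
    """mean%NR / (mean%R + mean%NR); NaN when both group means are zero."""
    r = float(np.mean(np.asarray(pct_r, dtype=float)))
    nr = float(np.mean(np.asarray(pct_nr, dtype=float)))
    if r < 0 or nr < 0:
        raise ValueError("percents must be non-negative")
    if r + nr == 0:
        return float("nan")
    return nr / (r + nr)


def cdr3b_percents(
    tables: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Beta-CDR3 x sample matrix of percents, summing clonotype percents
    over clonotypes that share the beta chain.  Clonotype keys are the
    ``TRB_aa|TRA_aa...`` strings produced by the clonotyping module."""
    cols = {}
    for sample, table in tables.items():
        trb = table["clonotype_key"].str.split("|").str[0]
        cols[sample] = table.groupby(trb.to_numpy())["percent"].sum()
    return pd.DataFrame(cols).fillna(0.0).sort_index()


def node_metrics(
    tables_r: Mapping[str, pd.DataFrame],
    tables_nr: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """node_size and relative_ratio for every beta CDR3 seen in any sample."""
    pr = cdr3b_percents(tables_r)
    pnr = cdr3b_percents(tables_nr)
    seqs = pr.index.union(pnr.index)
    pr = pr.reindex(seqs, fill_value=0.0)
    pnr = pnr.reindex(seqs, fill_value=0.0)
    out = pd.DataFrame(index=seqs)
    out.index.name = "cdr3b"
    out["node_size"] = 100.0 * (pr.mean(axis=1) + pnr.mean(axis=1))
    denom = pr.mean(axis=1) + pnr.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["relative_ratio"] = np.where(
            denom > 0, pnr.mean(axis=1) / denom, np.nan
        )
    return out


def global_similarity_edges(seqs: Iterable[str]) -> List[Edge]:
    """Edges between distinct equal-length sequences at Hamming distance <= 1."""
    unique = sorted(set(seqs))
    by_len: Dict[int, List[str]] = {}
    for s in unique:
        by_len.setdefault(len(s), []).append(s)
    edges: List[Edge] = []
    for group in by_len.values():
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if sum(x != y for x, y in zip(a, b)) <= 1:
                    edges.append((a, b, "global"))
    return edges


def _interior_kmers(seq: str, k: int) -> Set[str]:
    interior = seq[3:-3]
    return {interior[i : i + k] for i in range(len(interior) - k + 1)}


def enriched_kmers(
    seqs: Sequence[str],
    reference: Sequence[str],
    k: int = 3,
    fold_threshold: float = 10.0,
    min_count: int = 3,
) -> Set[str]:
    """Interior k-mers over-represented in the sample relative to a
    reference multiset (sequence-presence frequencies, CDR3s trimmed by
    three residues at each end)."""
    if len(reference) == 0:
        raise ValueError("reference must be non-empty")
    if k not in (2, 3, 4):
        raise ValueError("k must be 2, 3 or 4")
    seqs = list(seqs)
    sample_counts: Counter = Counter()
    for s in set(seqs):
        sample_counts.update(_interior_kmers(s, k))
    ref_counts: Counter = Counter()
    for s in reference:
        ref_counts.update(_interior_kmers(s, k))
    n_sample = max(1, len(set(seqs)))
    n_ref = len(reference)
    enriched = set()
    for kmer, cnt in sample_counts.items():
        if cnt < min_count:
            continue
        if cnt / n_sample >= fold_threshold * ref_counts.get(kmer, 0) / n_ref:
            enriched.add(kmer)
    return enriched


def local_motif_edges(
    seqs: Sequence[str],
    reference: Sequence[str],
    k: int = 3,
    fold_threshold: float = 10.0,
    min_count: int = 3,
) -> List[Edge]:
    """Edges between sequences sharing at least one enriched interior k-mer."""
    motifs = enriched_kmers(seqs, reference, k, fold_threshold, min_count)
    unique = sorted(set(seqs))
    kmers = {s: _interior_kmers(s, k) & motifs for s in unique}
    edges: List[Edge] = []
    for i, a in enumerate(unique):
        if not kmers[a]:
            continue
        for b in unique[i + 1 :]:
            if kmers[a] & kmers[b]:
                edges.append((a, b, "local"))
    return edges


def build_groups(
    edges: Iterable[Edge],
    node_sizes: Mapping[str, float] | None = None,
) -> List[SpecificityGroup]:
    """Connected components of the similarity graph (singletons excluded),
    ranked by summed node_size (ties by members)."""
    graph = nx.Graph()
    edge_list = list(edges)
    for a, b, kind in edge_list:
        if graph.has_edge(a, b):
            # a pair can satisfy both criteria; "global" wins for display
            if kind == "global":
                graph[a][b]["kind"] = "global"
        else:
            graph.add_edge(a, b, kind=kind)
    comps = [c for c in nx.connected_components(graph) if len(c) >= 2]

    def total_size(comp) -> float:
        if node_sizes is None:
            return float(len(comp))
        return float(sum(node_sizes.get(s, 0.0) for s in comp))

    ordered = sorted(
        comps, key=lambda c: (-total_size(c), tuple(sorted(c)))
    )
    groups = []
    for i, comp in enumerate(ordered, start=1):
        members = tuple(sorted(comp))
        comp_edges = tuple(
            sorted(
                (min(a, b), max(a, b), data["kind"])
                for a, b, data in graph.edges(comp, data=True)
                if a in comp and b in comp
            )
        )
        groups.append(
            SpecificityGroup(group_id=f"G{i}", members=members, edges=comp_edges)
        )
    return groups


def import_groups(path) -> List[SpecificityGroup]:
    """Read externally computed group assignments from a (group_id, cdr3b)
    TSV; duplicate rows collapse, a CDR3 in two groups is an error."""
    assignments: Dict[str, str] = {}
    members: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            gid, cdr3 = (f.strip() for f in fields)
            if lineno == 1 and (gid, cdr3) == ("group_id", "cdr3b"):
                continue
            if cdr3 in assignments and assignments[cdr3] != gid:
                raise FormatError(
                    f"{path}: line {lineno}: CDR3 {cdr3!r} assigned to two "
                    f"groups ({assignments[cdr3]!r} and {gid!r})"
                )
            assignments[cdr3] = gid
            members.setdefault(gid, set()).add(cdr3)
    return [
        SpecificityGroup(group_id=gid, members=tuple(sorted(ms)), edges=())
        for gid, ms in sorted(members.items())
    ]
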