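"""Synthetic paired scTCR-seq / scRNA-seq data with known ground truth.

The generator emulates the structure of a checkpoint-blockade mouse study:
responder (R) and non-responder (NR) mice, each contributing one
tumor-infiltrating-lymphocyte (TIL) and one splenic CD8 T-cell sample, were
profiled with paired 10x-style V(D)J and gene-expression libraries.  The
features it reproduces, with a ground-truth record for every one of them:

* per-mouse *private* clonal expansion — a handful of top clonotypes at
  1-15% abundance over a long Dirichlet tail — against near-uniform splenic
  repertoires;
* disjoint top-clonotype pools between R and NR mice, with an optional
  number of clonotypes injected into both groups (``shared_clonotype_count``)
  or a fully shared pool (``top_pool_shared``) for null calibration;
* the clone / clonotype distinction: a configurable fraction of clonotypes
  carries two synonymous nucleotide variants of the same amino-acid CDR3s;
* clonotype-conditional activation-cluster occupancy (cells of a top
  clonotype draw their cluster label from a group-specific distribution);
* negative-binomial counts with mitochondrial genes, cluster marker genes,
  planted differentially expressed genes, and planted QC violators;
* tumor-volume courses that classify to a requested response class, and
  survival cohorts whose hazard scales with a gene-signature score.

Everything is driven by a single :class:`numpy.random.Generator` seeded by
the caller, so identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import ConfigurationError, ConsistencyError, GenerationError
from .response import (
    NON_RESPONDER,
    RESPONDER,
    SLOW_PROGRESSOR,
    TumorCourse,
    classify_response,
)

# ---------------------------------------------------------------------------
# Gene-segment catalogs (IMGT-like names) and codon machinery
# ---------------------------------------------------------------------------

TRBV_GENES = tuple(f"TRBV{i}" for i in range(1, 21))
TRBJ_GENES = tuple(f"TRBJ{1 + i // 6}-{1 + i % 6}" for i in range(12))
TRAV_GENES = tuple(f"TRAV{i}" for i in range(1, 41))
TRAJ_GENES = tuple(f"TRAJ{i}" for i in range(1, 31))

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

_table = CodonTable.unambiguous_dna_by_id[1]
AA_TO_CODONS: Dict[str, List[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    AA_TO_CODONS.setdefault(aa, []).append(codon)

MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Co3",
    "mt-Atp6", "mt-Cytb", "mt-Nd4", "mt-Nd5", "mt-Rnr1",
)

CONTIG_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "length", "chain",
    "v_gene", "d_gene", "j_gene", "c_gene", "full_length", "productive",
    "cdr3", "cdr3_nt", "reads", "umis", "raw_clonotype_id", "raw_consensus_id",
]

NAIVE_CLUSTERS = tuple(f"N{i}" for i in range(1, 6))
ACTIVATED_CLUSTERS = tuple(f"A{i}" for i in range(1, 8))
DIVIDING_CLUSTERS = ("D1", "D2")
CLUSTER_LABELS = NAIVE_CLUSTERS + ACTIVATED_CLUSTERS + DIVIDING_CLUSTERS


def default_occupancy_probs() -> Dict[str, Dict[str, float]]:
    """Group-conditional cluster occupancy used by the generator.

    ``R`` / ``NR`` apply to cells of top clonotypes in TILs of the
    corresponding group; ``other`` to tail TIL cells; ``spleen`` to splenic
    cells.  The NR skew toward A6 (0.6 vs 0.3 in R) mirrors the differential
    activation-state occupancy the pipeline is built to detect.
    """
    r = {"A1": 0.075, "A2": 0.075, "A3": 0.075, "A4": 0.075,
         "A5": 0.20, "A6": 0.30, "A7": 0.10, "D1": 0.05, "D2": 0.05}
    nr = {"A1": 0.05, "A2": 0.05, "A3": 0.05, "A4": 0.05,
          "A5": 0.08, "A6": 0.60, "A7": 0.04, "D1": 0.04, "D2": 0.04}
    other = {f"A{i}": 0.12 for i in range(1, 8)}
    other.update({"D1": 0.08, "D2": 0.08})
    spleen = {f"N{i}": 0.18 for i in range(1, 6)}
    spleen.update({"A1": 0.04, "A2": 0.03, "A3": 0.03})
    return {"R": r, "NR": nr, "other": other, "spleen": spleen}


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings.

    Defaults encode the emulated study conditions: 4 mice per response group,
    2000 TIL and 1000 splenic cells per mouse, 10 top clonotypes per mouse at
    1-15% abundance over a ~400-clonotype Dirichlet tail, and an NR-vs-R
    occupancy skew in cluster A6 (0.6 vs 0.3).
    """

    n_mice_per_group: int = 4
    n_cells_til: int = 2000
    n_cells_spleen: int = 1000
    n_top_clonotypes: int = 10
    top_abundance_range: Tuple[float, float] = (1.0, 15.0)
    tail_dirichlet_alpha: float = 1.0
    n_tail_clonotypes: int = 400
    spleen_dirichlet_alpha: float = 5.0
    shared_clonotype_count: int = 0
    top_pool_shared: bool = False
    synonymous_variant_fraction: float = 0.2
    dual_tra_fraction: float = 0.3
    contamination_rate: float = 0.0
    max_top_mass: float = 0.85
    occupancy_probs: Dict[str, Dict[str, float]] = field(
        default_factory=default_occupancy_probs
    )
    n_genes: int = 800
    n_mito_genes: int = 10
    mito_fraction_mean: float = 0.03
    nb_dispersion: float = 2.0
    marker_effect: float = 1.0
    n_marker_genes_per_cluster: int = 3
    n_planted_deg: int = 20
    planted_deg_lnfc: float = 0.7
    qc_violation_rate: float = 0.05

    def validate(self) -> None:
        counts = [
            "n_mice_per_group", "n_cells_til", "n_cells_spleen",
            "n_top_clonotypes", "n_tail_clonotypes", "n_genes",
        ]
        for name in counts:
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_mito_genes < 0 or self.n_mito_genes > len(MITO_GENES):
            raise ConfigurationError(
                f"n_mito_genes must be in [0, {len(MITO_GENES)}]"
            )
        if self.n_mito_genes + self.n_planted_deg >= self.n_genes:
            raise ConfigurationError("n_genes too small for mito + planted genes")
        lo, hi = self.top_abundance_range
        if not (0 < lo <= hi <= 100):
            raise ConfigurationError(
                "top_abundance_range must satisfy 0 < low <= high <= 100"
            )
        for name in ("tail_dirichlet_alpha", "spleen_dirichlet_alpha",
                     "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("synonymous_variant_fraction", "dual_tra_fraction",
                     "contamination_rate", "qc_violation_rate",
                     "mito_fraction_mean"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be a proportion in [0, 1]")
        if self.shared_clonotype_count < 0:
            raise ConfigurationError("shared_clonotype_count must be >= 0")
        if self.shared_clonotype_count > self.n_mice_per_group * self.n_top_clonotypes:
            raise ConfigurationError(
                "shared_clonotype_count exceeds the number of top clonotypes"
            )
        if not (0 < self.max_top_mass < 1):
            raise ConfigurationError("max_top_mass must be in (0, 1)")
        for group, probs in self.occupancy_probs.items():
            total = sum(probs.values())
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ConfigurationError(
                    f"occupancy_probs[{group}] has probabilities outside [0, 1]"
                )
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"occupancy_probs[{group}] must sum to 1 (got {total})"
                )

    @property
    def mice(self) -> List[str]:
        n = self.n_mice_per_group
        return [f"R{i}" for i in range(1, n + 1)] + [
            f"NR{i}" for i in range(1, n + 1)
        ]

    @property
    def cluster_labels(self) -> List[str]:
        labels = []
        for probs in self.occupancy_probs.values():
            for lab in probs:
                if lab not in labels:
                    labels.append(lab)
        return labels


@dataclass
class GroundTruth:
    """Everything the generator decided, for downstream recovery checks."""

    clonotype_frequencies: Dict[str, Dict[str, float]]
    clonotype_cluster_probs: Dict[str, Dict]
    planted_deg: Dict[str, float]
    response_class: Dict[str, str]
    r_top: set
    nr_top: set
    shared_top: set
    clone_to_clonotype: Dict[str, str]
    clonotype_defs: Dict[str, dict]
    cells: pd.DataFrame


# ---------------------------------------------------------------------------
# Receptor construction helpers
# ---------------------------------------------------------------------------


def _random_cdr3_aa(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 17))
    middle = "".join(rng.choice(list(_AA20), size=length))
    return "C" + middle + "F"


def _back_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        AA_TO_CODONS[a][int(rng.integers(len(AA_TO_CODONS[a])))] for a in aa
    )


def _synonymous_variant(aa: str, nt: str, rng: np.random.Generator) -> str:
    # Every CDR3 starts with C (2 codons), so a distinct variant always exists.
    for _ in range(100):
        other = _back_translate(aa, rng)
        if other != nt:
            return other
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    alts = [c for c in AA_TO_CODONS[aa[0]] if c != codons[0]]
    codons[0] = alts[0]
    return "".join(codons)


def _make_clonotype(rng: np.random.Generator, config: SyntheticConfig,
                    used_keys: set) -> dict:
    """One clonotype definition: chains, genes and nt variant(s)."""
    while True:
        trb_aa = _random_cdr3_aa(rng)
        n_tra = 2 if rng.random() < config.dual_tra_fraction else 1
        tra_aa = sorted(_random_cdr3_aa(rng) for _ in range(n_tra))
        key = trb_aa + "|" + ",".join(tra_aa)
        if key not in used_keys:
            used_keys.add(key)
            break
    trb_v = str(rng.choice(TRBV_GENES))
    trb_j = str(rng.choice(TRBJ_GENES))
    tra_genes = [
        (str(rng.choice(TRAV_GENES)), str(rng.choice(TRAJ_GENES)))
        for _ in tra_aa
    ]
    n_variants = 2 if rng.random() < config.synonymous_variant_fraction else 1
    variants = []
    trb_nt0 = _back_translate(trb_aa, rng)
    tra_nt0 = [_back_translate(a, rng) for a in tra_aa]
    variants.append((trb_nt0, tuple(tra_nt0)))
    if n_variants == 2:
        variants.append(
            (_synonymous_variant(trb_aa, trb_nt0, rng), tuple(tra_nt0))
        )
    return {
        "key": key,
        "trb_aa": trb_aa,
        "trb_v": trb_v,
        "trb_j": trb_j,
        "tra_aa": tuple(tra_aa),
        "tra_genes": tuple(tra_genes),
        "variants": variants,
    }


def _clone_key(variant: Tuple[str, Tuple[str, ...]]) -> str:
    trb_nt, tra_nts = variant
    return trb_nt + "|" + ",".join(sorted(tra_nts))


_BASES = np.array(list("ACGT"))


def _barcode(index: int) -> str:
    digits = []
    v = index
    for _ in range(16):
        digits.append("ACGT"[v % 4])
        v //= 4
    return "".join(reversed(digits)) + "-1"


# ---------------------------------------------------------------------------
# Repertoire generation
# ---------------------------------------------------------------------------


def generate_repertoire(
    config: SyntheticConfig, seed: int, emit_contigs: bool = True
) -> Tuple[Dict[str, pd.DataFrame], GroundTruth]:
    """Generate one 10x-style contig table per sample plus ground truth.

    Returns a dict mapping sample id (e.g. ``RTIL1``, ``NRSP3``) to a
    DataFrame laid out like a CellRanger ``filtered_contig_annotations.csv``,
    and the :class:`GroundTruth` describing every planted property.

    ``emit_contigs=False`` skips building the contig tables (the returned
    dict is empty) for simulation studies that only consume the cell-level
    ground truth; the realization differs from the ``True`` stream because
    per-contig randomness is not drawn.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_mice_per_group
    used_keys: set = set()

    # --- top-clonotype pools -------------------------------------------------
    top_pools: Dict[str, List[dict]] = {}
    shared_top: set = set()
    if config.top_pool_shared:
        # Group-exchangeable null: one common pool, each clonotype expands
        # in exactly one mouse chosen uniformly regardless of group, and the
        # truth R-top / NR-top labels are a random half partition of the
        # pool.  Detection counts per labeled set then follow the classic
        # two-binomial-proportion design, under which Fisher's exact test
        # is calibrated.
        pool_size = 2 * config.n_mice_per_group * config.n_top_clonotypes
        pool = [_make_clonotype(rng, config, used_keys) for _ in range(pool_size)]
        perm = rng.permutation(pool_size)
        r_top = {pool[i]["key"] for i in perm[: pool_size // 2]}
        nr_top = {pool[i]["key"] for i in perm[pool_size // 2 :]}
        top_pools = {mouse: [] for mouse in config.mice}
        carriers = rng.integers(len(config.mice), size=pool_size)
        for clonotype, carrier in zip(pool, carriers):
            top_pools[config.mice[int(carrier)]].append(clonotype)
    else:
        for mouse in config.mice:
            top_pools[mouse] = [
                _make_clonotype(rng, config, used_keys)
                for _ in range(config.n_top_clonotypes)
            ]
        for s in range(config.shared_clonotype_count):
            c = _make_clonotype(rng, config, used_keys)
            shared_top.add(c["key"])
            i = 1 + (s // config.n_top_clonotypes) % n
            slot = s % config.n_top_clonotypes
            top_pools[f"R{i}"][slot] = c
            top_pools[f"NR{i}"][slot] = c
        r_top = {c["key"] for i in range(1, n + 1) for c in top_pools[f"R{i}"]}
        nr_top = {c["key"] for i in range(1, n + 1) for c in top_pools[f"NR{i}"]}

    tail_pools: Dict[str, List[dict]] = {}
    for mouse in config.mice:
        tail_pools[mouse] = [
            _make_clonotype(rng, config, used_keys)
            for _ in range(config.n_tail_clonotypes)
        ]

    defs: Dict[str, dict] = {}
    for pool in list(top_pools.values()) + list(tail_pools.values()):
        for c in pool:
            defs[c["key"]] = c

    # --- group-conditional occupancy truth ----------------------------------
    cluster_probs: Dict[str, Dict] = {}
    for mouse in config.mice:
        group = "R" if mouse.startswith("R") else "NR"
        for c in top_pools[mouse]:
            key = c["key"]
            if key in shared_top or (key in r_top and key in nr_top):
                cluster_probs[key] = {
                    "R": dict(config.occupancy_probs["R"]),
                    "NR": dict(config.occupancy_probs["NR"]),
                }
            else:
                which = "R" if key in r_top else "NR"
                cluster_probs[key] = dict(config.occupancy_probs[which])

    # --- per-sample frequencies and cell draws -------------------------------
    frequencies: Dict[str, Dict[str, float]] = {}
    tables: Dict[str, pd.DataFrame] = {}
    cell_rows: List[tuple] = []
    clone_to_clonotype: Dict[str, str] = {}
    lo, hi = config.top_abundance_range

    for mouse in config.mice:
        group = "R" if mouse.startswith("R") else "NR"
        cohort = int(mouse[len(group):])
        tops = top_pools[mouse]
        tails = tail_pools[mouse]
        for compartment in ("TIL", "SP"):
            sample = f"{group}{compartment}{cohort}"
            if compartment == "TIL":
                u = rng.uniform(lo, hi, size=len(tops)) / 100.0
                if u.sum() > config.max_top_mass:
                    u *= config.max_top_mass / u.sum()
                tail_mass = 1.0 - u.sum()
                tail_w = rng.dirichlet(
                    np.full(len(tails), config.tail_dirichlet_alpha)
                ) * tail_mass
                freqs = np.concatenate([u, tail_w])
                n_cells = config.n_cells_til
            else:
                freqs = rng.dirichlet(
                    np.full(len(tops) + len(tails), config.spleen_dirichlet_alpha)
                )
                n_cells = config.n_cells_spleen
            members = tops + tails
            frequencies[sample] = {
                c["key"]: float(f) for c, f in zip(members, freqs)
            }
            counts = rng.multinomial(n_cells, freqs)
            contig_rows: List[tuple] = []
            cell_index = 0
            for c, k in zip(members, counts):
                if k == 0:
                    continue
                variant_idx = (
                    rng.integers(len(c["variants"]), size=k)
                    if len(c["variants"]) > 1
                    else np.zeros(k, dtype=int)
                )
                for j in range(k):
                    barcode = _barcode(cell_index)
                    cell_index += 1
                    variant = c["variants"][int(variant_idx[j])]
                    ck = _clone_key(variant)
                    clone_to_clonotype[ck] = c["key"]
                    contaminated = rng.random() < config.contamination_rate
                    cell_rows.append(
                        (barcode, sample, mouse, group, cohort,
                         "TIL" if compartment == "TIL" else "spleen",
                         c["key"], ck, contaminated)
                    )
                    if emit_contigs:
                        contig_rows.extend(
                            _cell_contigs(barcode, c, variant, rng)
                        )
                        if contaminated:
                            contig_rows.extend(
                                _contamination_contigs(barcode, c, variant, defs, rng)
                            )
            if emit_contigs:
                df = pd.DataFrame(contig_rows, columns=CONTIG_COLUMNS)
                df = df.sort_values(["barcode", "contig_id"], kind="stable")
                tables[sample] = df.reset_index(drop=True)

    cells = pd.DataFrame(
        cell_rows,
        columns=[
            "barcode", "sample_id", "mouse", "group", "cohort_id",
            "compartment", "clonotype_key", "clone_key", "contaminated",
        ],
    )
    truth = GroundTruth(
        clonotype_frequencies=frequencies,
        clonotype_cluster_probs=cluster_probs,
        planted_deg={},
        response_class={m: ("R" if m.startswith("R") else "NR") for m in config.mice},
        r_top=set(r_top),
        nr_top=set(nr_top),
        shared_top=shared_top if not config.top_pool_shared else (r_top & nr_top),
        clone_to_clonotype=clone_to_clonotype,
        clonotype_defs=defs,
        cells=cells,
    )
    return tables, truth


def _cell_contigs(barcode: str, c: dict, variant, rng) -> List[tuple]:
    rows = []
    trb_nt, tra_nts = variant
    umis = int(rng.integers(2, 40))
    rows.append(
        (barcode, "True", f"{barcode}_contig_1", "True", len(trb_nt) + 180,
         "TRB", c["trb_v"], "TRBD1", c["trb_j"], "TRBC1", "True", "True",
         c["trb_aa"], trb_nt, umis * 30, umis, "", "")
    )
    for i, (aa, nt, (v, j)) in enumerate(zip(c["tra_aa"], tra_nts, c["tra_genes"])):
        umis = int(rng.integers(1, 25))
        rows.append(
            (barcode, "True", f"{barcode}_contig_{2 + i}", "True",
             len(nt) + 160, "TRA", v, "None", j, "TRAC", "True", "True",
             aa, nt, umis * 30, umis, "", "")
        )
    return rows


def _contamination_contigs(barcode: str, c: dict, variant, defs, rng) -> List[tuple]:
    """Rows that make a cell fail the chain-count or contig filters."""
    keys = sorted(defs)
    other = defs[keys[int(rng.integers(len(keys)))]]
    action = int(rng.integers(3))
    umis = int(rng.integers(1, 10))
    if action == 0:  # extra TRB -> ">= 2 TRB" drop
        v = other["variants"][0]
        return [
            (barcode, "True", f"{barcode}_contig_9", "True",
             len(v[0]) + 180, "TRB", other["trb_v"], "TRBD1", other["trb_j"],
             "TRBC1", "True", "True", other["trb_aa"], v[0],
             umis * 30, umis, "", "")
        ]
    if action == 1:  # two extra distinct TRA -> ">= 3 TRA" drop
        v = other["variants"][0]
        rows = []
        for i, (aa, nt, (tv, tj)) in enumerate(
            zip(other["tra_aa"], v[1], other["tra_genes"])
        ):
            rows.append(
                (barcode, "True", f"{barcode}_contig_{8 + i}", "True",
                 len(nt) + 160, "TRA", tv, "None", tj, "TRAC", "True",
                 "True", aa, nt, umis * 30, umis, "", "")
            )
        # guarantee the cell reaches >= 3 alpha chains even if `other` is single-TRA
        if len(other["tra_aa"]) < 2:
            rows.append(
                (barcode, "True", f"{barcode}_contig_7", "True", 260, "TRA",
                 "TRAV1", "None", "TRAJ1", "TRAC", "True", "True",
                 "CAVSNTGKLIF", "TGTGCTGTGAGCAATACAGGCAAACTAATCTTT",
                 umis * 30, umis, "", "")
            )
        return rows
    # non-TCR junk row; harmless on its own but exercises the chain filter
    return [
        (barcode, "True", f"{barcode}_contig_6", "True", 400, "IGH",
         "IGHV1-1", "IGHD1-1", "IGHJ1", "IGHM", "True", "True",
         "CARGLDYW", "TGTGCGAGAGGCCTGGACTACTGG", umis * 30, umis, "", "")
    ]


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------


def _check_truth_cells(truth: GroundTruth) -> pd.DataFrame:
    required = {"barcode", "sample_id", "mouse", "group", "cohort_id",
                "compartment", "clonotype_key"}
    if not required.issubset(truth.cells.columns):
        missing = sorted(required - set(truth.cells.columns))
        raise ConsistencyError(f"truth.cells is missing columns: {missing}")
    cells = truth.cells.reset_index(drop=True)
    if len(cells) == 0:
        raise ConsistencyError("truth contains no cells")
    return cells


def assign_cluster_labels(
    config: SyntheticConfig, truth: GroundTruth, rng: np.random.Generator
) -> np.ndarray:
    """Draw one activation-cluster label per cell.

    Cells of top clonotypes in TILs use the group-conditional occupancy map
    (``R`` or ``NR``), tail TIL cells the ``other`` map, splenic cells the
    ``spleen`` map.
    """
    cells = _check_truth_cells(truth)
    n_cells = len(cells)
    labels = np.array(config.cluster_labels)
    is_spleen = (cells["compartment"] == "spleen").to_numpy()
    in_top = cells["clonotype_key"].isin(truth.r_top | truth.nr_top).to_numpy()
    group = cells["group"].to_numpy()
    category = np.where(is_spleen, "spleen", np.where(in_top, group, "other"))
    cluster = np.empty(n_cells, dtype=object)
    for cat in ("R", "NR", "other", "spleen"):
        mask = category == cat
        if not mask.any():
            continue
        probs = config.occupancy_probs[cat]
        p = np.array([probs.get(lab, 0.0) for lab in labels])
        p = p / p.sum()
        cluster[mask] = rng.choice(labels, size=int(mask.sum()), p=p)
    return cluster


def generate_expression(config: SyntheticConfig, truth: GroundTruth, seed: int):
    """Negative-binomial count matrix + per-cell metadata as an AnnData.

    Cluster labels are drawn per cell from its clonotype's group-conditional
    occupancy distribution (tail TIL cells use the ``other`` map, splenic
    cells the ``spleen`` map).  Updates ``truth.planted_deg`` with the genes
    that received the planted R-top-specific ln-fold-change.
    """
    import anndata as ad

    config.validate()
    rng = np.random.default_rng(seed)
    cells = _check_truth_cells(truth)
    n_cells = len(cells)
    labels = np.array(config.cluster_labels)
    cluster = assign_cluster_labels(config, truth, rng)
    is_spleen = (cells["compartment"] == "spleen").to_numpy()
    in_r_top = cells["clonotype_key"].isin(truth.r_top).to_numpy()
    group = cells["group"].to_numpy()

    # --- gene universe -------------------------------------------------------
    mito = list(MITO_GENES[: config.n_mito_genes])
    n_other = config.n_genes - len(mito)
    genes = [f"Gene{i:04d}" for i in range(1, n_other + 1)] + mito
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[n_other:] = True

    base_mean = np.empty(config.n_genes)
    base_mean[:n_other] = rng.lognormal(mean=np.log(2.5), sigma=0.5, size=n_other)
    if mito:
        # scale mito means so the expected mitochondrial share is mito_fraction_mean
        nonmito_total = base_mean[:n_other].sum()
        share = config.mito_fraction_mean
        base_mean[n_other:] = share / (1 - share) * nonmito_total / len(mito)

    marker_cluster = np.array([""] * config.n_genes, dtype=object)
    candidates = rng.permutation(n_other)
    pos = 0
    marker_of: Dict[str, np.ndarray] = {}
    for lab in labels:
        take = candidates[pos : pos + config.n_marker_genes_per_cluster]
        pos += config.n_marker_genes_per_cluster
        marker_of[lab] = take
        marker_cluster[take] = lab
    free = candidates[pos:]
    # plant DEG effects on reasonably expressed genes so the effect survives
    # normalization (10^4 * count/total >> 1)
    free_sorted = free[np.argsort(base_mean[free])]
    planted_idx = np.sort(free_sorted[-config.n_planted_deg :])
    planted_lnfc = np.zeros(config.n_genes)
    planted_lnfc[planted_idx] = config.planted_deg_lnfc
    truth.planted_deg.clear()
    truth.planted_deg.update(
        {genes[i]: config.planted_deg_lnfc for i in planted_idx}
    )

    # planted QC violators, half low-feature and half high-mito
    viol = rng.random(n_cells) < config.qc_violation_rate
    viol_reason = np.array([""] * n_cells, dtype=object)
    viol_idx = np.flatnonzero(viol)
    half = len(viol_idx) // 2
    viol_reason[viol_idx[:half]] = "low_features"
    viol_reason[viol_idx[half:]] = "high_mito"

    deg_arm = (in_r_top & (group == "R") & ~is_spleen)

    X = np.empty((n_cells, config.n_genes), dtype=np.int32)
    chunk = 2048
    disp = config.nb_dispersion
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        m = np.tile(base_mean, (stop - start, 1))
        for lab in labels:
            rows = np.flatnonzero(cluster[start:stop] == lab)
            if rows.size:
                m[np.ix_(rows, marker_of[lab])] *= math.exp(config.marker_effect)
        rows = np.flatnonzero(deg_arm[start:stop])
        if rows.size:
            m[np.ix_(rows, planted_idx)] *= math.exp(config.planted_deg_lnfc)
        reason = viol_reason[start:stop]
        rows = np.flatnonzero(reason == "low_features")
        if rows.size:
            m[rows, :] *= 0.08
        rows = np.flatnonzero(reason == "high_mito")
        if rows.size and mito:
            m[np.ix_(rows, np.flatnonzero(mito_mask))] *= 8.0
        lam = rng.gamma(shape=disp, scale=m / disp)
        X[start:stop] = rng.poisson(lam).astype(np.int32)

    obs = cells[
        ["barcode", "sample_id", "mouse", "group", "cohort_id",
         "compartment", "clonotype_key"]
    ].copy()
    obs["cluster_label"] = cluster
    obs["qc_planted"] = viol_reason
    obs.index = (obs["sample_id"] + "_" + obs["barcode"]).to_numpy()
    var = pd.DataFrame(
        {
            "mito": mito_mask,
            "marker_cluster": marker_cluster,
            "planted_lnfc": planted_lnfc,
        },
        index=pd.Index(genes, name="gene"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["mito_prefix"] = "mt-"
    return adata


# ---------------------------------------------------------------------------
# Tumor courses and survival cohorts
# ---------------------------------------------------------------------------

_RCTV_RANGES = {
    RESPONDER: (-0.8, -0.2),
    SLOW_PROGRESSOR: (0.2, 1.3),
    NON_RESPONDER: (2.0, 5.0),
}


def generate_tumor_courses(
    config: SyntheticConfig,
    seed: int,
    target_classes: Optional[Mapping[str, str]] = None,
    days: Sequence[int] = (12, 14, 16, 18, 20),
) -> List[TumorCourse]:
    """Tumor-volume courses whose endpoints classify to the requested class.

    Volumes interpolate geometrically between a baseline of 250-350 mm^3 and
    the endpoint implied by a class-typical RCTV, with mild lognormal jitter
    on interior points so curves look measured rather than computed.
    """
    config.validate()
    if len(days) < 2:
        raise GenerationError("need at least two time points to compute RCTV")
    rng = np.random.default_rng(seed)
    if target_classes is None:
        target_classes = {
            m: ("R" if m.startswith("R") else "NR") for m in config.mice
        }
    courses = []
    for mouse in target_classes:
        cls = target_classes[mouse]
        if cls not in _RCTV_RANGES:
            raise GenerationError(
                f"unknown response class '{cls}' for mouse {mouse}"
            )
        tv0 = rng.uniform(250, 350)
        lo, hi = _RCTV_RANGES[cls]
        target = rng.uniform(lo, hi)
        tvn = tv0 * (1.0 + target)
        t = np.asarray(days, dtype=float)
        frac = (t - t[0]) / (t[-1] - t[0])
        volumes = tv0 * np.exp(frac * np.log(tvn / tv0))
        jitter = np.exp(rng.normal(0.0, 0.05, size=len(t)))
        jitter[0] = jitter[-1] = 1.0
        volumes = np.maximum(volumes * jitter, 1.0)
        course = TumorCourse(
            mouse_id=mouse, days=tuple(int(d) for d in days),
            volumes=tuple(float(v) for v in volumes),
        )
        call = classify_response(course)
        if call.response_class != cls:
            raise GenerationError(
                f"could not realize class {cls} for mouse {mouse}"
            )
        courses.append(course)
    return courses


def generate_survival_cohort(
    n_patients: int,
    signature_genes: Sequence[str],
    hazard_ratio: float,
    censor_rate: float,
    seed: int,
    base_hazard: float = 0.1,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score expression matrix plus exponential survival records.

    Event times are exponential with hazard ``base_hazard * HR**score`` where
    the score is the mean z of the signature genes, i.e. the log hazard is
    linear in the score with slope ln(hazard_ratio) per unit.  Censoring is
    an independent exponential clock whose rate is set so the marginal
    censoring probability is roughly ``censor_rate`` for a null cohort.
    """
    if n_patients < 10:
        raise GenerationError("n_patients must be at least 10")
    if hazard_ratio <= 0:
        raise GenerationError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise GenerationError("censor_rate must be in [0, 1)")
    if len(signature_genes) == 0:
        raise GenerationError("signature_genes must be non-empty")
    rng = np.random.default_rng(seed)
    subjects = [f"S{i:04d}" for i in range(1, n_patients + 1)]
    z = rng.standard_normal((n_patients, len(signature_genes)))
    zmat = pd.DataFrame(z, index=subjects, columns=list(signature_genes))
    score = z.mean(axis=1)
    rate = base_hazard * np.power(hazard_ratio, score)
    times = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        c_rate = base_hazard * censor_rate / (1.0 - censor_rate)
        censor = rng.exponential(1.0 / c_rate, size=n_patients)
        event = times <= censor
        times = np.minimum(times, censor)
    else:
        event = np.ones(n_patients, dtype=bool)
    records = pd.DataFrame(
        {"subject_id": subjects, "time": times, "event": event}
    )
    return zmat, records
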