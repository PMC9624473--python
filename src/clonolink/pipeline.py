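"""End-to-end orchestration: dataset simulation, staged analysis, report.

A dataset is a directory described by a YAML config: per-sample contig
CSVs, an expression matrix (MatrixMarket + genes/barcodes TSVs) with a
cell-metadata table carrying the activation-cluster labels, and optional
tumor-volume courses and a survival cohort.  ``run_pipeline`` executes the
stages in order — ingest, clonotype, stats, network, link, deg, signature,
classify — writing one output bundle per stage plus a JSON manifest; any
stage failure aborts with a stage-named error, preserving earlier outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from . import __version__
from . import clonotypes as ct
from . import expression as xp
from . import network as net
from . import repertoire as rep
from . import survival as surv
from . import synth
from . import vdj
from .errors import ClonolinkError, ConfigurationError, PipelineError
from .response import TumorCourse, classify_response

log = logging.getLogger("clonolink")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    base_dir: Path
    samples: pd.DataFrame  # sample_id, group, compartment, mouse, cohort_id, contig_path
    expression_matrix: Optional[Path] = None
    expression_genes: Optional[Path] = None
    expression_barcodes: Optional[Path] = None
    cell_meta: Optional[Path] = None
    tumor_courses: Optional[Path] = None
    survival_expression: Optional[Path] = None
    survival_records: Optional[Path] = None
    signature_genes: Optional[Path] = None
    survival_prezscored: bool = True
    qc_min_features: int = 500
    qc_max_mito: float = 0.10
    mito_prefix: str = "mt-"
    min_cells_occupancy: int = 40
    min_cells_shared: int = 20
    ratio_clusters: tuple = ("A6", "A5")
    exclusivity_unit: str = "events"
    kmeans_k: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        samples = pd.DataFrame(raw["samples"])
        required = {"sample_id", "group", "compartment", "mouse", "cohort_id",
                    "contig_path"}
        missing = required - set(samples.columns)
        if missing:
            raise ConfigurationError(
                f"samples table missing fields: {sorted(missing)}"
            )

        def p(key):
            v = raw.get(key)
            return (base / v) if v else None

        params = raw.get("params", {})
        cfg = cls(
            base_dir=base,
            samples=samples,
            expression_matrix=p("expression_matrix"),
            expression_genes=p("expression_genes"),
            expression_barcodes=p("expression_barcodes"),
            cell_meta=p("cell_meta"),
            tumor_courses=p("tumor_courses"),
            survival_expression=p("survival_expression"),
            survival_records=p("survival_records"),
            signature_genes=p("signature_genes"),
            survival_prezscored=bool(raw.get("survival_prezscored", True)),
            seed=int(params.get("seed", 0)),
        )
        for key in ("qc_min_features", "qc_max_mito", "min_cells_occupancy",
                    "min_cells_shared", "kmeans_k", "exclusivity_unit",
                    "mito_prefix"):
            if key in params:
                setattr(cfg, key, params[key])
        if "ratio_clusters" in params:
            cfg.ratio_clusters = tuple(params["ratio_clusters"])
        return cfg

    def preflight(self) -> None:
        """Fail before any computation if a referenced input is missing."""
        missing: List[str] = []
        for _, row in self.samples.iterrows():
            path = self.base_dir / row["contig_path"]
            if not path.exists():
                missing.append(str(path))
        for attr in ("expression_matrix", "expression_genes",
                     "expression_barcodes", "cell_meta", "tumor_courses",
                     "survival_expression", "survival_records",
                     "signature_genes"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                missing.append(str(path))
        if missing:
            raise ConfigurationError(
                "missing input file(s): " + ", ".join(missing)
            )


# ---------------------------------------------------------------------------
# Dataset simulation (writes everything run_pipeline reads)
# ---------------------------------------------------------------------------

DEMO_SIGNATURE = [f"SIG{i:02d}" for i in range(1, 22)]


def write_dataset(
    outdir,
    config: Optional[synth.SyntheticConfig] = None,
    seed: int = 0,
    n_patients: int = 300,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.2,
) -> Path:
    """Simulate a full study and write it as a pipeline-readable dataset.

    Returns the path of the dataset YAML.  All randomness derives from
    ``seed``; the same config + seed writes byte-identical files.
    """
    config = config or synth.SyntheticConfig()
    outdir = Path(outdir)
    (outdir / "contigs").mkdir(parents=True, exist_ok=True)
    (outdir / "expression").mkdir(exist_ok=True)

    tables, truth = synth.generate_repertoire(config, seed=seed)
    sample_rows = []
    for sample, table in tables.items():
        rel = f"contigs/{sample}_filtered_contig_annotations.csv"
        table.to_csv(outdir / rel, index=False)
        compartment = "TIL" if "TIL" in sample else "spleen"
        group = "R" if sample.startswith("R") else "NR"
        cohort = int(sample[-1])
        sample_rows.append(
            {
                "sample_id": sample, "group": group, "compartment": compartment,
                "mouse": f"{group}{cohort}", "cohort_id": cohort,
                "contig_path": rel,
            }
        )

    adata = synth.generate_expression(config, truth, seed=seed + 1)
    mat = sparse.csr_matrix(adata.X).T.tocoo()  # genes x cells, 10x-style
    spio.mmwrite(str(outdir / "expression" / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(
        outdir / "expression" / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        outdir / "expression" / "barcodes.tsv", sep="\t", index=False, header=False
    )
    meta = adata.obs[
        ["barcode", "sample_id", "mouse", "group", "cohort_id",
         "compartment", "cluster_label"]
    ]
    meta.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)

    courses = synth.generate_tumor_courses(config, seed=seed + 2)
    rows = [
        {"mouse_id": c.mouse_id, "day": d, "volume": v}
        for c in courses
        for d, v in zip(c.days, c.volumes)
    ]
    pd.DataFrame(rows).to_csv(outdir / "tumor_courses.tsv", sep="\t", index=False)

    zmat, records = synth.generate_survival_cohort(
        n_patients=n_patients, signature_genes=DEMO_SIGNATURE,
        hazard_ratio=hazard_ratio, censor_rate=censor_rate, seed=seed + 3,
    )
    zmat.to_csv(outdir / "survival_expression.tsv", sep="\t")
    records.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    (outdir / "signature_genes.txt").write_text(
        "\n".join(DEMO_SIGNATURE) + "\n"
    )

    dataset = {
        "samples": sample_rows,
        "expression_matrix": "expression/matrix.mtx",
        "expression_genes": "expression/genes.tsv",
        "expression_barcodes": "expression/barcodes.tsv",
        "cell_meta": "cell_meta.tsv",
        "tumor_courses": "tumor_courses.tsv",
        "survival_expression": "survival_expression.tsv",
        "survival_records": "survival.tsv",
        "signature_genes": "signature_genes.txt",
        "survival_prezscored": True,
        "params": {"seed": seed},
    }
    cfg_path = outdir / "dataset.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(dataset, fh, sort_keys=True)
    return cfg_path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.cells: Optional[pd.DataFrame] = None
        self.tables: Dict[str, pd.DataFrame] = {}
        self.top: Dict[str, Dict[str, set]] = {}
        self.adata = None
        self.manifest: Dict = {
            "package": "clonolink",
            "version": __version__,
            "seed": config.seed,
            "stages": {},
            "inputs": {},
            "outputs": [],
        }

    def out(self, name: str) -> Path:
        path = self.outdir / name
        self.manifest["outputs"].append(name)
        return path


def _stage_ingest(run: _Run) -> None:
    cfg = run.config
    frames = []
    tallies = {}
    for _, row in cfg.samples.iterrows():
        path = cfg.base_dir / row["contig_path"]
        run.manifest["inputs"][row["sample_id"]] = _sha256(path)
        contigs = vdj.read_contigs(path, row["sample_id"])
        kept = vdj.filter_contigs(contigs)
        cells, tally = vdj.assemble_cells(kept)
        frames.append(cells)
        tallies[row["sample_id"]] = tally
    cells = pd.concat(frames, ignore_index=True)
    run.cells = ct.add_receptor_keys(cells)
    run.cells.to_csv(run.out("cells.tsv"), sep="\t", index=False)
    _write_json(run.out("assembly_tally.json"), tallies)


def _stage_clonotype(run: _Run) -> None:
    cfg = run.config
    cells = run.cells
    ct.clone_clonotype_map(cells).to_csv(
        run.out("clone_clonotype_map.tsv"), sep="\t", index=False
    )
    tables = {
        s: ct.abundance_table(cells[cells["sample_id"] == s], s)
        for s in cfg.samples["sample_id"]
        if (cells["sample_id"] == s).any()
    }
    run.tables = tables
    long = pd.concat(
        [t.assign(sample_id=s) for s, t in tables.items()], ignore_index=True
    )
    long.to_csv(run.out("abundance.tsv"), sep="\t", index=False)
    sample_groups = dict(
        zip(cfg.samples["sample_id"], cfg.samples["group"])
    )
    til = cfg.samples[cfg.samples["compartment"] == "TIL"]["sample_id"]
    til_tables = {s: tables[s] for s in til if s in tables}
    run.top = {
        preset: ct.select_top(
            til_tables, ct.TOP_THRESHOLDS[preset], sample_groups
        )
        for preset in ("vdj", "expression")
    }
    _write_json(
        run.out("top_clonotypes.json"),
        {
            preset: {g: sorted(keys) for g, keys in groups.items()}
            for preset, groups in run.top.items()
        },
    )


def _stage_stats(run: _Run) -> None:
    cfg = run.config
    cells = run.cells
    sets = rep.sample_clonotype_sets(run.tables)
    rep.overlap_matrix(sets).to_csv(run.out("overlap_matrix.tsv"), sep="\t")

    til = cfg.samples[cfg.samples["compartment"] == "TIL"]
    til_tables = {s: run.tables[s] for s in til["sample_id"] if s in run.tables}

    usage_rows = []
    for s in run.tables:
        sample_cells = cells[cells["sample_id"] == s]
        for chain in ("TRA", "TRB"):
            mat = rep.vj_usage(sample_cells, chain)
            long = mat.stack().rename("proportion").reset_index()
            long.insert(0, "chain", chain)
            long.insert(0, "sample_id", s)
            usage_rows.append(long[long["proportion"] > 0])
    pd.concat(usage_rows, ignore_index=True).to_csv(
        run.out("vj_usage.tsv"), sep="\t", index=False
    )

    by_sample = {s: cells[cells["sample_id"] == s] for s in run.tables}
    usage = rep.trbv_usage_vectors(by_sample)
    labels = rep.kmeans_usage(usage, k=cfg.kmeans_k, seed=cfg.seed)
    labels.rename("kmeans_cluster").to_csv(run.out("kmeans_usage.tsv"), sep="\t")

    rel = pd.concat(
        {s: rep.relative_clonal_abundance(t) for s, t in run.tables.items()},
        names=["sample_id"],
    )
    rel.to_csv(run.out("relative_abundance.tsv"), sep="\t")

    mice_tables = {}
    for mouse, block in til.groupby("mouse"):
        s = block["sample_id"].iloc[0]
        if s in run.tables:
            mice_tables[mouse] = run.tables[s]
    top_vdj = run.top["vdj"]
    share = ct.sharing_summary(
        mice_tables, top_vdj["R"] | top_vdj["NR"]
    )
    _write_json(
        run.out("sharing_summary.json"),
        {
            "multi_mouse_fraction": share.multi_mouse_fraction,
            "n_top_clonotypes": int(len(share.presence)),
            "presence_histogram": share.presence.value_counts().sort_index()
            .to_dict(),
        },
    )

    tr = {s: run.tables[s] for s in til[til["group"] == "R"]["sample_id"] if s in run.tables}
    tnr = {s: run.tables[s] for s in til[til["group"] == "NR"]["sample_id"] if s in run.tables}
    excl = rep.exclusivity_test(
        top_vdj["R"], top_vdj["NR"], tr, tnr, unit=cfg.exclusivity_unit
    )
    _write_json(
        run.out("exclusivity.json"),
        {
            "table": excl.table.tolist(),
            "odds_ratio": excl.odds_ratio,
            "p": excl.p,
            "unit": excl.unit,
        },
    )


def _stage_network(run: _Run) -> None:
    cfg = run.config
    til = cfg.samples[cfg.samples["compartment"] == "TIL"]
    tr = {s: run.tables[s] for s in til[til["group"] == "R"]["sample_id"] if s in run.tables}
    tnr = {s: run.tables[s] for s in til[til["group"] == "NR"]["sample_id"] if s in run.tables}
    nodes = net.node_metrics(tr, tnr)
    top = run.top["vdj"]
    top_trb = {k.split("|")[0] for k in top["R"] | top["NR"]}
    reference = [k.split("|")[0] for t in run.tables.values()
                 for k in t["clonotype_key"]]
    edges = net.global_similarity_edges(top_trb) + net.local_motif_edges(
        sorted(top_trb), reference
    )
    groups = net.build_groups(edges, node_sizes=nodes["node_size"].to_dict())
    gid = {s: g.group_id for g in groups for s in g.members}
    nodes = nodes.assign(group_id=[gid.get(s, "") for s in nodes.index])
    nodes.to_csv(run.out("network_nodes.tsv"), sep="\t")
    pd.DataFrame(
        [(g.group_id, a, b, kind) for g in groups for a, b, kind in g.edges],
        columns=["group_id", "a", "b", "type"],
    ).to_csv(run.out("network_edges.tsv"), sep="\t", index=False)


def _load_expression(cfg: PipelineConfig):
    import anndata as ad

    mat = spio.mmread(str(cfg.expression_matrix)).tocsr().T  # cells x genes
    genes = pd.read_csv(cfg.expression_genes, sep="\t", header=None)[0]
    barcodes = pd.read_csv(cfg.expression_barcodes, sep="\t", header=None)[0]
    meta = pd.read_csv(cfg.cell_meta, sep="\t")
    meta.index = (meta["sample_id"] + "_" + meta["barcode"]).to_numpy()
    meta = meta.loc[barcodes]
    adata = ad.AnnData(
        X=mat.astype(np.int32),
        obs=meta,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata


def _stage_link(run: _Run) -> None:
    cfg = run.config
    adata = _load_expression(cfg)
    # attach clonotype keys from the assembled VDJ cells
    keyed = run.cells.set_index(
        (run.cells["sample_id"] + "_" + run.cells["barcode"]).to_numpy()
    )["clonotype_key"]
    adata.obs["clonotype_key"] = keyed.reindex(adata.obs_names)
    adata, tally = xp.qc_filter(
        adata, min_features=cfg.qc_min_features, max_mito=cfg.qc_max_mito,
        mito_prefix=cfg.mito_prefix,
    )
    _write_json(run.out("qc_tally.json"), tally)
    xp.normalize(adata)
    run.adata = adata

    xp.cluster_distribution(adata.obs).to_csv(
        run.out("cluster_distribution.tsv"), sep="\t"
    )
    top = run.top["expression"]
    obs_til = adata.obs[adata.obs["compartment"] == "TIL"]
    occ_r = xp.clonotype_occupancy(
        obs_til[obs_til["group"] == "R"], top["R"],
        min_cells=cfg.min_cells_occupancy,
    )
    occ_nr = xp.clonotype_occupancy(
        obs_til[obs_til["group"] == "NR"], top["NR"],
        min_cells=cfg.min_cells_occupancy,
    )
    occ_r.assign(group="R").to_csv(run.out("occupancy_r.tsv"), sep="\t")
    occ_nr.assign(group="NR").to_csv(run.out("occupancy_nr.tsv"), sep="\t")
    if len(occ_r) >= 3 and len(occ_nr) >= 3:
        comp = xp.occupancy_compare(occ_r, occ_nr)
        comp.to_csv(run.out("occupancy_compare.tsv"), sep="\t")
    num, den = cfg.ratio_clusters
    ratios = pd.DataFrame(
        {
            "ratio": pd.concat(
                [xp.cluster_ratio(occ_r, num, den),
                 xp.cluster_ratio(occ_nr, num, den)]
            ),
            "group": ["R"] * len(occ_r) + ["NR"] * len(occ_nr),
        }
    )
    ratios.to_csv(run.out("cluster_ratio.tsv"), sep="\t")

    shared = (top["R"] & top["NR"]) | (
        set(occ_r.index) & set(occ_nr.index)
    )
    profile = xp.shared_clonotype_profile(
        obs_til, shared, min_cells=cfg.min_cells_shared
    )
    profile.to_csv(run.out("shared_clonotype_profile.tsv"), sep="\t")


def _stage_deg(run: _Run) -> None:
    cfg = run.config
    top = run.top["expression"]
    results = xp.deg_comparisons(run.adata, top["R"], top["NR"])
    for name, table in results.items():
        table.to_csv(run.out(f"deg_{name}.tsv"), sep="\t", index=False)
    diff = xp.differential_gene_filter(results["I"], results["II"])
    diff.to_csv(run.out("deg_differential_genes.tsv"), sep="\t")


def _stage_signature(run: _Run) -> None:
    cfg = run.config
    expr = pd.read_csv(cfg.survival_expression, sep="\t", index_col=0)
    records = pd.read_csv(cfg.survival_records, sep="\t")
    records["event"] = records["event"].astype(bool)
    genes = [
        g.strip() for g in Path(cfg.signature_genes).read_text().splitlines()
        if g.strip()
    ]
    res = surv.score_and_compare(
        expr, genes, records, prezscored=cfg.survival_prezscored
    )
    pd.DataFrame({"score": res["scores"], "stratum": res["strata"]}).to_csv(
        run.out("signature_scores.tsv"), sep="\t"
    )
    res["km_table"].to_csv(run.out("km_table.tsv"), sep="\t", index=False)
    lr = res["logrank"]
    _write_json(
        run.out("signature_logrank.json"),
        {"statistic": lr.statistic, "p": lr.p,
         "n_high": lr.n_high, "n_low": lr.n_low},
    )


def _stage_classify(run: _Run) -> None:
    cfg = run.config
    courses = pd.read_csv(cfg.tumor_courses, sep="\t")
    calls = []
    for mouse, block in courses.groupby("mouse_id"):
        block = block.sort_values("day")
        course = TumorCourse(
            mouse_id=str(mouse),
            days=tuple(block["day"]),
            volumes=tuple(block["volume"]),
        )
        call = classify_response(course)
        calls.append(
            {"mouse_id": call.mouse_id, "rctv": call.rctv,
             "response_class": call.response_class}
        )
    pd.DataFrame(calls).sort_values("mouse_id").to_csv(
        run.out("response_calls.tsv"), sep="\t", index=False
    )


STAGES = [
    ("ingest", _stage_ingest),
    ("clonotype", _stage_clonotype),
    ("stats", _stage_stats),
    ("network", _stage_network),
    ("link", _stage_link),
    ("deg", _stage_deg),
    ("signature", _stage_signature),
    ("classify", _stage_classify),
]

# stages that only run when their inputs are configured
_OPTIONAL = {
    "link": lambda c: c.expression_matrix is not None,
    "deg": lambda c: c.expression_matrix is not None,
    "signature": lambda c: c.survival_expression is not None,
    "classify": lambda c: c.tumor_courses is not None,
}


def run_pipeline(
    config: PipelineConfig, outdir, stages: Optional[List[str]] = None
) -> Dict:
    """Execute the pipeline stages; returns the manifest dict.

    Pre-flight checks fail before any computation; a stage error is
    re-raised as :class:`PipelineError` naming the stage, with the outputs
    of completed stages preserved on disk.
    """
    config.preflight()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(config, outdir)
    wanted = set(stages) if stages is not None else None
    for name, fn in STAGES:
        if wanted is not None and name not in wanted:
            continue
        gate = _OPTIONAL.get(name)
        if gate is not None and not gate(config):
            run.manifest["stages"][name] = "skipped"
            continue
        t0 = time.monotonic()
        try:
            fn(run)
        except ClonolinkError:
            run.manifest["stages"][name] = "failed"
            _write_json(outdir / "manifest.json", run.manifest)
            raise
        except Exception as exc:
            run.manifest["stages"][name] = "failed"
            _write_json(outdir / "manifest.json", run.manifest)
            raise PipelineError(name, str(exc)) from exc
        run.manifest["stages"][name] = "ok"
        log.info("stage %s finished in %.2fs", name, time.monotonic() - t0)
    _write_json(outdir / "manifest.json", run.manifest)
    make_report(outdir)
    return run.manifest


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def make_report(outdir) -> Path:
    """Write a human-readable markdown summary from the stage outputs.

    Idempotent: reads only files listed in the manifest and overwrites
    report.md in place.
    """
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    lines = ["# clonolink run report", ""]
    lines.append(
        "Stages: "
        + ", ".join(f"{k}={v}" for k, v in manifest["stages"].items())
    )
    lines.append("")

    def have(name):
        return name in manifest["outputs"] and (outdir / name).exists()

    if have("top_clonotypes.json"):
        with open(outdir / "top_clonotypes.json") as fh:
            top = json.load(fh)
        for preset, groups in top.items():
            counts = {g: len(v) for g, v in groups.items()}
            lines.append(f"Top clonotypes ({preset} preset): {counts}")
        lines.append("")
    if have("sharing_summary.json"):
        with open(outdir / "sharing_summary.json") as fh:
            share = json.load(fh)
        lines.append(
            f"Top clonotypes present in >1 mouse: "
            f"{100 * share['multi_mouse_fraction']:.1f}% "
            f"of {share['n_top_clonotypes']}"
        )
        lines.append("")
    if have("exclusivity.json"):
        with open(outdir / "exclusivity.json") as fh:
            excl = json.load(fh)
        lines.append(
            f"Mutual exclusivity (Fisher's exact, unit={excl['unit']}): "
            f"table={excl['table']}, OR={excl['odds_ratio']:.3g}, "
            f"p={excl['p']:.3g}"
        )
        lines.append("")
    if have("overlap_matrix.tsv"):
        lines.append("Overlap-coefficient matrix: overlap_matrix.tsv")
    if have("occupancy_compare.tsv"):
        comp = pd.read_csv(outdir / "occupancy_compare.tsv", sep="\t",
                           index_col=0)
        sig = comp[comp["p"] < 0.05].index.tolist()
        lines.append(
            "Occupancy R-vs-NR clusters with p<0.05: "
            + (", ".join(map(str, sig)) if sig else "none found")
        )
    if have("cluster_ratio.tsv"):
        ratios = pd.read_csv(outdir / "cluster_ratio.tsv", sep="\t",
                             index_col=0)
        means = ratios.groupby("group")["ratio"].mean()
        lines.append(
            "Mean cluster ratio by group: "
            + ", ".join(f"{g}={v:.2f}" for g, v in means.items())
        )
    if have("shared_clonotype_profile.tsv"):
        prof = pd.read_csv(outdir / "shared_clonotype_profile.tsv", sep="\t")
        n = prof["clonotype_key"].nunique() if "clonotype_key" in prof else 0
        lines.append(
            f"Shared clonotypes profiled in both groups: "
            + (str(n) if n else "none found")
        )
    lines.append("")
    for name in ("deg_I", "deg_II", "deg_III", "deg_IV"):
        if have(f"{name}.tsv"):
            table = pd.read_csv(outdir / f"{name}.tsv", sep="\t")
            n_sig = int((table["p_conservative"] < 0.01).sum())
            lines.append(
                f"DEG comparison {name.split('_')[1]}: "
                f"{n_sig} genes with conservative p < 0.01"
            )
    if have("signature_logrank.json"):
        with open(outdir / "signature_logrank.json") as fh:
            lr = json.load(fh)
        lines.append("")
        lines.append(
            f"Signature survival split: log-rank chi2={lr['statistic']:.2f}, "
            f"p={lr['p']:.3g} (high n={lr['n_high']}, low n={lr['n_low']})"
        )
    if have("response_calls.tsv"):
        calls = pd.read_csv(outdir / "response_calls.tsv", sep="\t")
        counts = calls["response_class"].value_counts().to_dict()
        lines.append("")
        lines.append(f"Response classification: {counts}")
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def demo(outdir, seed: int = 0, config: Optional[synth.SyntheticConfig] = None):
    """Simulate a reduced-size dataset and run the full pipeline on it.

    The demo halves the per-sample cell counts relative to the emulated
    study so a laptop run finishes in about a minute; every stage still
    executes.
    """
    outdir = Path(outdir)
    if config is None:
        config = synth.SyntheticConfig(
            n_cells_til=800, n_cells_spleen=400, n_tail_clonotypes=150
        )
    data_dir = outdir / "data"
    cfg_path = write_dataset(data_dir, config, seed=seed)
    cfg = PipelineConfig.from_yaml(cfg_path)
    cfg.seed = seed
    manifest = run_pipeline(cfg, outdir / "results")
    return manifest
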