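"""Per-treatment pipeline orchestration with reproducible seeds and manifests.

Stage order per treatment: counts -> DEG calling -> prizes -> parameter
tuning -> forest solve -> random-terminal runs -> centralities ->
prioritization -> community clustering -> GO enrichment.  Every intermediate
is written to the run directory as plain TSV/SIF/JSON, a manifest records
the configuration hash, derived seed and per-stage row counts, and reruns
with the same configuration and seed are byte-identical.  Treatment runs are
independent; cross-treatment comparisons (logFC correlations, top-50
ranking, node overlaps) are a separate step consuming finished run
directories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import degs, enrichment, interactome, patterns, pcsf, prioritize, simulate
from .errors import InputError

__all__ = ["RunConfig", "simulate_inputs", "run_treatment", "run_all", "compare"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline settings; defaults are the study's stated values."""

    counts: dict = field(default_factory=dict)  # treatment -> counts TSV path
    interactome_path: str = ""
    mapping_path: str | None = None
    annotations_path: str | None = None
    control_label: str = "control"
    treated_label: str = "treated"

    cpm_min: float = 5.0
    bcv: float = 0.045
    logfc_abs_min: float = 2.0
    p_max: float = 0.01
    fdr_max: float = 0.01
    prior_cpm: float = 0.5
    min_conf: float = 0.7
    omega_values: tuple = (1.0, 5.0, 10.0)
    beta_values: tuple = (1.0, 5.0, 10.0)
    mu_values: tuple = (0.01, 0.05)
    min_terminal_frac: float = 0.1
    n_random: int = 100
    freq_max: float = 0.01
    centrality_min: float = 0.001
    random_degree_max: float = 0.001
    go_fdr: float = 0.005
    k_per_treatment: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cpm_min", "bcv", "logfc_abs_min", "p_max", "fdr_max", "prior_cpm",
            "min_conf", "freq_max", "centrality_min", "random_degree_max", "go_fdr",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if len(set(self.counts)) != len(self.counts):
            raise InputError("treatment labels must be unique")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["counts"] = {k: str(v) for k, v in d["counts"].items()}
        for key in ("omega_values", "beta_values", "mu_values"):
            d[key] = list(d[key])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def treatment_seed(self, treatment: str) -> int:
        return int((self.seed * 1009 + zlib.crc32(treatment.encode())) % (2**31))


def _write_tsv(df: pd.DataFrame, path, cfg_hash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g", lineterminator="\n")


def simulate_inputs(
    synth_cfg: simulate.SynthConfig,
    outdir,
    treatments=("ALPHA", "SALPHA"),
    synergy_delta: float = 0.0,
) -> RunConfig:
    """Generate a complete synthetic input set and the matching RunConfig.

    One count matrix is generated per treatment (independent seeds derived
    from the base seed; the planted DE gene identities are shared, so
    cross-treatment logFC panels correlate).  The interactome, annotations
    and dose-response surface come from the base seed.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_paths = {}
    for i, label in enumerate(treatments):
        cfg_i = dataclasses.replace(synth_cfg, seed=synth_cfg.seed + 101 * i)
        cm, labels = simulate.make_counts(cfg_i)
        path = outdir / f"counts_{label}.tsv"
        cm.to_tsv(path)
        counts_paths[label] = str(path)

    net, module, prized = simulate.make_interactome(synth_cfg)
    net.to_tsv(outdir / "interactome.tsv")
    annot, planted_term = simulate.make_annotations(
        synth_cfg, module, background=list(net.graph.nodes)
    )
    annot.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    drm = simulate.make_dose_response(synth_cfg, synergy_delta=synergy_delta)
    drm.to_csv(outdir / "dose_response.csv")

    labels = simulate._truth_labels(synth_cfg)
    truth = {
        "housekeeping": [g for g in labels.index if labels[g] == "housekeeping"],
        "de": [g for g in labels.index if labels[g] in ("de_up", "de_down")],
        "module_nodes": module,
        "prized_module_nodes": prized,
        "planted_term": planted_term,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    return RunConfig(
        counts=counts_paths,
        interactome_path=str(outdir / "interactome.tsv"),
        annotations_path=str(outdir / "annotations.tsv"),
        seed=synth_cfg.seed,
    )


def run_treatment(cfg: RunConfig, treatment: str, outdir) -> dict:
    """Execute the full stage sequence for one treatment.

    Returns the artifact bundle (tables and the forest solution) and writes
    every intermediate plus a manifest to ``outdir``.  An empty DEG list (or
    no prized gene mapping into the interactome) ends the run cleanly with
    status "no terminals".
    """
    if treatment not in cfg.counts:
        raise InputError(f"unknown treatment {treatment!r}")
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash
    seed = cfg.treatment_seed(treatment)
    manifest: dict = {
        "treatment": treatment,
        "config_hash": h,
        "seed": seed,
        "stages": {},
    }
    bundle: dict = {}

    def fail(stage, err):
        raise InputError(f"stage {stage!r} failed for treatment {treatment!r}: {err}")

    # --- differential expression
    try:
        cm = degs.CountMatrix.from_tsv(cfg.counts[treatment])
        model = degs.DispersionModel(bcv=cfg.bcv)
        filt = degs.DEGFilter(
            logfc_abs_min=cfg.logfc_abs_min,
            p_max=cfg.p_max,
            fdr_max=cfg.fdr_max,
            cpm_min=cfg.cpm_min,
            prior_cpm=cfg.prior_cpm,
        )
        deg_table = degs.call_degs(
            cm, model, filt, treated=cfg.treated_label, control=cfg.control_label
        )
    except Exception as err:
        fail("deg", err)
    _write_tsv(deg_table, outdir / "degs.tsv", h)
    manifest["stages"]["deg"] = {"rows": len(deg_table),
                                 "n_called": int((deg_table["call"] != "ns").sum())}
    bundle["degs"] = deg_table

    # --- prizes and interactome
    try:
        net = interactome.load_interactome(
            cfg.interactome_path, cfg.mapping_path, min_conf=cfg.min_conf
        )
        prizes = interactome.build_prizes(deg_table)
        prizes = prizes[prizes.index.isin(net.graph.nodes)]
    except Exception as err:
        fail("network", err)
    manifest["stages"]["network"] = {
        "interactome_nodes": net.n_nodes,
        "interactome_edges": net.n_edges,
        "n_prized": int(len(prizes)),
    }
    bundle["prizes"] = prizes
    if len(prizes) == 0:
        manifest["status"] = "no terminals"
        _write_manifest(manifest, outdir)
        log.info("treatment %s: no terminals; stopping after DEG stage", treatment)
        return bundle

    # --- tune + solve
    try:
        tuned = pcsf.tune(
            net,
            prizes,
            omega_values=cfg.omega_values,
            beta_values=cfg.beta_values,
            mu_values=cfg.mu_values,
            min_terminal_frac=cfg.min_terminal_frac,
        )
    except Exception as err:
        fail("tune", err)
    _write_tsv(tuned.grid, outdir / "tuner_grid.tsv", h)
    sol = tuned.best_solution
    pcsf.write_sif(sol, outdir / "forest.sif")
    logfc_map = deg_table.set_index("gene_id")["logFC"].to_dict()
    pcsf.write_node_attributes(sol, prizes, outdir / "forest_nodes.tsv", logfc=logfc_map)
    manifest["stages"]["forest"] = pcsf.forest_stats(sol, n_prized_total=len(prizes))
    manifest["stages"]["forest"]["params"] = dataclasses.asdict(tuned.best_params)
    bundle["forest"] = sol
    bundle["tuned"] = tuned

    # --- randomization, centralities, prioritization
    try:
        rand = prioritize.randomize(
            net, prizes, tuned.best_params, n=cfg.n_random, seed=seed
        )
        cent = prioritize.centralities(sol)
        priority = prioritize.prioritize(
            cent,
            rand,
            prizes=prizes,
            k_per_treatment=cfg.k_per_treatment,
            freq_max=cfg.freq_max,
            centrality_min=cfg.centrality_min,
            random_degree_max=cfg.random_degree_max,
            treatment=treatment,
        )
    except Exception as err:
        fail("prioritize", err)
    _write_tsv(rand.reset_index(), outdir / "randomization.tsv", h)
    _write_tsv(cent.reset_index(), outdir / "centrality.tsv", h)
    _write_tsv(priority, outdir / "priority.tsv", h)
    manifest["stages"]["prioritize"] = {"rows": len(priority)}
    bundle["randomization"] = rand
    bundle["centrality"] = cent
    bundle["priority"] = priority

    # --- clustering + enrichment
    try:
        clusters = enrichment.cluster_network(sol)
        if cfg.annotations_path:
            annot = pd.read_csv(cfg.annotations_path, sep="\t", comment="#")
            enr = enrichment.enrich_clusters(
                clusters, annot, background=list(net.graph.nodes), q_max=cfg.go_fdr
            )
        else:
            enr = pd.DataFrame(
                columns=["cluster", "term", "k", "K", "n", "N", "p", "q", "significant"]
            )
    except Exception as err:
        fail("enrich", err)
    _write_tsv(clusters.to_frame(), outdir / "clusters.tsv", h)
    _write_tsv(enr, outdir / "enrichment.tsv", h)
    manifest["stages"]["enrich"] = {
        "n_clusters": len(set(clusters.assignments.values())),
        "modularity": clusters.modularity,
        "rows": len(enr),
        "n_significant": int(enr["significant"].sum()) if len(enr) else 0,
    }
    bundle["clusters"] = clusters
    bundle["enrichment"] = enr

    manifest["status"] = "ok"
    _write_manifest(manifest, outdir)
    bundle["manifest"] = manifest
    return bundle


def _write_manifest(manifest: dict, outdir) -> None:
    with open(pathlib.Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_all(cfg: RunConfig, outdir) -> dict:
    """Run every configured treatment, then the cross-treatment comparison."""
    outdir = pathlib.Path(outdir)
    bundles = {}
    for treatment in sorted(cfg.counts):
        bundles[treatment] = run_treatment(cfg, treatment, outdir / treatment)
    comparison = compare([outdir / t for t in sorted(cfg.counts)])
    comp_dir = outdir / "compare"
    comp_dir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash
    _write_tsv(comparison["pearson"].reset_index(), comp_dir / "pearson.tsv", h)
    _write_tsv(comparison["top50"].reset_index(), comp_dir / "top50.tsv", h)
    _write_tsv(comparison["node_overlap"].reset_index(), comp_dir / "node_overlap.tsv", h)
    bundles["compare"] = comparison
    return bundles


def compare(run_dirs) -> dict:
    """Cross-treatment comparison of finished run directories.

    Builds the logFC panel (one column per treatment over the union of
    tested genes), computes pairwise Pearson correlations and the top-50
    genes by summed |logFC|, and counts forest-node overlaps between
    treatments.  Runs with mismatched configuration hashes refuse to
    combine.
    """
    run_dirs = [pathlib.Path(p) for p in run_dirs]
    hashes, panels, node_sets = set(), {}, {}
    for d in run_dirs:
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        hashes.add(manifest["config_hash"])
        label = manifest["treatment"]
        table = pd.read_csv(d / "degs.tsv", sep="\t", comment="#")
        panels[label] = table.set_index("gene_id")["logFC"]
        nodes_path = d / "forest_nodes.tsv"
        if nodes_path.exists():
            nodes = pd.read_csv(nodes_path, sep="\t", comment="#")["gene"]
            node_sets[label] = set(nodes)
        else:
            node_sets[label] = set()
    if len(hashes) > 1:
        raise InputError(
            f"refusing to combine runs with mismatched config hashes: {sorted(hashes)}"
        )
    panel = pd.DataFrame(panels)
    pearson = patterns.pairwise_pearson(panel) if panel.shape[1] >= 2 else pd.DataFrame()
    top50 = patterns.top_k_by_abs_logfc(panel, k=min(50, len(panel)))
    labels = sorted(node_sets)
    overlap = pd.DataFrame(
        [[len(node_sets[a] & node_sets[b]) for b in labels] for a in labels],
        index=pd.Index(labels, name="treatment"),
        columns=labels,
    )
    return {"panel": panel, "pearson": pearson, "top50": top50, "node_overlap": overlap}
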