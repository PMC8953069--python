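"""Synthetic data generators with planted, recoverable structure.

Every downstream stage of the pipeline is exercised on data produced here:

* a two-condition, no-replicate RNA-seq count matrix with planted
  differentially expressed (DE) genes and stable housekeeping genes, drawn
  from a negative binomial with variance mu + bcv^2 * mu^2;
* a scale-free-like interactome carrying a planted connected module whose
  internal edges receive the highest confidence scores, with a designated
  subset of module nodes identified with planted DE genes;
* a gene/term/evidence-code annotation table with one planted enriched term;
* dose-response inhibition surfaces that obey (or deviate from by a planted
  delta) the zero-interaction-potency independence null.

All generators are bit-reproducible under a fixed seed, and every generator
returns the planted truth alongside the data so recovery metrics never need
to re-derive it.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .degs import CountMatrix
from .interactome import Interactome

__all__ = [
    "SynthConfig",
    "make_counts",
    "make_interactome",
    "make_annotations",
    "make_dose_response",
    "logistic4",
]

EXPERIMENTAL_CODES = ("EXP", "IDA", "IEP", "IGI", "IMP", "IPI")


def _two_fold_grid(top: float = 40.0, n: int = 8) -> tuple[float, ...]:
    """Two-fold dilution series of n points ending at `top` (ascending, uM)."""
    return tuple(top / 2**k for k in reversed(range(n)))


@dataclass(frozen=True)
class SynthConfig:
    """Study-level parameters for all synthetic generators.

    Defaults mirror the analyzed study design: no replicates, BCV 0.045,
    ~100 strongly shifted DE genes (|log2 FC| around 3) among 2000, a
    STRING-like interactome of 500 genes at confidences 0.7-0.99 containing
    a 15-gene planted module of which 8 are DE ("prized"), and an 8-point
    two-fold dose dilution series.
    """

    seed: int = 0
    n_genes: int = 2000
    n_housekeeping: int = 200
    n_de: int = 100
    de_logfc_mean: float = 3.0
    bcv_true: float = 0.045
    lib_size: float = 1e7
    n_interactome_nodes: int = 500
    planted_module_size: int = 15
    module_prized: int = 8
    edge_conf_range: tuple[float, float] = (0.7, 0.99)
    n_terms: int = 50
    term_enrichment_factor: float = 10.0
    annotation_rate: float = 0.08
    iea_fraction: float = 0.3
    dose_grid: tuple[float, ...] = field(default_factory=_two_fold_grid)

    def __post_init__(self) -> None:
        def bad(fieldname, msg):
            raise ConfigurationError(f"{fieldname}: {msg}")

        if self.n_genes < 1:
            bad("n_genes", "must be positive")
        if self.n_de < 0 or self.n_housekeeping < 0:
            bad("n_de/n_housekeeping", "must be nonnegative")
        if self.n_de + self.n_housekeeping > self.n_genes:
            bad("n_de", "n_de + n_housekeeping must not exceed n_genes")
        if self.bcv_true <= 0:
            bad("bcv_true", "must be positive")
        if self.lib_size <= 0:
            bad("lib_size", "must be positive")
        if self.planted_module_size > self.n_interactome_nodes:
            bad("planted_module_size", "must not exceed n_interactome_nodes")
        if self.module_prized > self.planted_module_size:
            bad("module_prized", "must not exceed planted_module_size")
        lo, hi = self.edge_conf_range
        if not (0 < lo <= hi <= 1):
            bad("edge_conf_range", "must satisfy 0 < lo <= hi <= 1")
        if any(d <= 0 for d in self.dose_grid):
            bad("dose_grid", "all doses must be positive")
        if not 0 <= self.iea_fraction <= 1:
            bad("iea_fraction", "must be in [0, 1]")
        if not 0 < self.annotation_rate < 1:
            bad("annotation_rate", "must be in (0, 1)")
        if self.term_enrichment_factor <= 0:
            bad("term_enrichment_factor", "must be positive")


def gene_ids(cfg: SynthConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(cfg.n_genes)]


def _truth_labels(cfg: SynthConfig) -> pd.Series:
    """Planted per-gene labels: de_up, de_down, housekeeping, null.

    The first n_de genes are DE (first half up, rest down); the following
    n_housekeeping genes are housekeeping; the remainder are null.
    """
    labels = np.full(cfg.n_genes, "null", dtype=object)
    n_up = cfg.n_de // 2 + cfg.n_de % 2
    labels[:n_up] = "de_up"
    labels[n_up : cfg.n_de] = "de_down"
    labels[cfg.n_de : cfg.n_de + cfg.n_housekeeping] = "housekeeping"
    return pd.Series(labels, index=gene_ids(cfg), name="label")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, bcv: float) -> np.ndarray:
    """NB(mean, variance = mean + bcv^2 mean^2) via the Poisson-gamma mixture."""
    phi = bcv**2
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def make_counts(cfg: SynthConfig) -> tuple[CountMatrix, pd.Series]:
    """Two-sample (control, treated) count matrix with planted DE genes.

    Per-gene base abundances are log-normal, scaled so the expected library
    size equals ``lib_size``.  Planted DE genes have their treated-sample
    mean multiplied by 2^(+/- de_logfc_mean); housekeeping and null genes
    keep identical means in both samples.  Returns the matrix and the truth
    labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    labels = _truth_labels(cfg)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    base *= cfg.lib_size / base.sum()

    fc = np.ones(cfg.n_genes)
    fc[(labels == "de_up").to_numpy()] = 2.0**cfg.de_logfc_mean
    fc[(labels == "de_down").to_numpy()] = 2.0**-cfg.de_logfc_mean

    treated_mean = base * fc
    # rescale so both libraries have the same expected depth; cpm-level fold
    # changes are unaffected (cpm normalizes by the realized library size)
    treated_mean *= cfg.lib_size / treated_mean.sum()

    control = _nb_counts(rng, base, cfg.bcv_true)
    treated = _nb_counts(rng, treated_mean, cfg.bcv_true)
    counts = pd.DataFrame(
        {"control": control, "treated": treated}, index=gene_ids(cfg)
    )
    return CountMatrix(counts), labels


def make_interactome(cfg: SynthConfig) -> tuple[Interactome, list[str], list[str]]:
    """Scale-free interactome with a planted high-confidence connected module.

    A preferential-attachment backbone provides hubs; the planted module is
    wired as a random spanning tree plus ~20% extra internal edges, and its
    internal edges receive confidences from the top decile of the configured
    range.  The first ``module_prized`` module nodes are identified with
    planted DE gene ids so DEG-derived prizes land inside the module.

    Returns (interactome, module_nodes, prized_module_nodes).
    """
    if cfg.planted_module_size < 3:
        raise ConfigurationError("planted_module_size: must be at least 3")
    if cfg.n_interactome_nodes > cfg.n_genes:
        raise ConfigurationError(
            "n_interactome_nodes: must not exceed n_genes (nodes are gene ids)"
        )
    if cfg.module_prized > cfg.n_de:
        raise ConfigurationError(
            "module_prized: must not exceed n_de (prized module nodes are DE genes)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = cfg.n_interactome_nodes
    m = cfg.planted_module_size
    lo, hi = cfg.edge_conf_range

    ids = gene_ids(cfg)
    labels = _truth_labels(cfg)
    de_ids = [g for g in ids if labels[g] in ("de_up", "de_down")]
    other_ids = [g for g in ids if labels[g] == "null"]
    prized = de_ids[: cfg.module_prized]
    n_steiner = m - cfg.module_prized
    module_nodes = prized + other_ids[:n_steiner]
    rest = other_ids[n_steiner:]
    fill = [g for g in rest if g not in module_nodes][: n - m]
    if len(fill) < n - m:
        # fall back on housekeeping ids if null genes run out
        hk = [g for g in ids if labels[g] == "housekeeping"]
        fill = (fill + hk)[: n - m]
    nodes = module_nodes + fill

    backbone = nx.barabasi_albert_graph(n, 2, seed=int(rng.integers(2**31)))
    # module nodes take low-degree (peripheral) backbone positions: a
    # treatment-specific sub-pathway lives in network branches, not among
    # hubs, and must not become a cheap shortcut corridor for unrelated paths
    by_degree = sorted(backbone.nodes, key=lambda v: (backbone.degree[v], v))
    peripheral_pool = by_degree[: max(m, n // 3)]
    module_pos = rng.choice(len(peripheral_pool), size=m, replace=False)
    module_positions = [peripheral_pool[int(i)] for i in module_pos]
    rest_positions = [v for v in by_degree if v not in set(module_positions)]
    rest_perm = rng.permutation(len(rest_positions))
    name = {}
    for i, pos in enumerate(module_positions):
        name[pos] = nodes[i]  # nodes[:m] are the module nodes
    for j, idx in enumerate(rest_perm):
        name[rest_positions[int(idx)]] = nodes[m + j]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in backbone.edges():
        g.add_edge(name[u], name[v], confidence=float(rng.uniform(lo, hi)))

    # plant the module: random spanning tree + 20% extra internal edges,
    # internal confidences in the top decile of the range.  Non-prized
    # members form the tree's internal backbone and prized (DE) genes attach
    # to them, emulating a pathway whose regulated genes are connected
    # through shared intermediates — the nodes the forest must rediscover
    # as Steiner nodes.
    hi_lo = hi - 0.1 * (hi - lo)
    non_prized = [v for v in module_nodes if v not in set(prized)]
    internal = []
    if len(non_prized) >= 2:
        order = [non_prized[i] for i in rng.permutation(len(non_prized))]
        for i in range(1, len(order)):
            j = int(rng.integers(i))
            internal.append((order[i], order[j]))
        for v in prized:
            internal.append((v, non_prized[int(rng.integers(len(non_prized)))]))
    else:
        order = [module_nodes[i] for i in rng.permutation(len(module_nodes))]
        for i in range(1, len(order)):
            j = int(rng.integers(i))
            internal.append((order[i], order[j]))
    extra = max(1, round(0.2 * m))
    candidates = [
        (a, b)
        for a, b in itertools.combinations(sorted(module_nodes), 2)
        if not g.has_edge(a, b) and (a, b) not in internal and (b, a) not in internal
    ]
    if candidates:
        pick = rng.choice(len(candidates), size=min(extra, len(candidates)), replace=False)
        internal += [candidates[int(i)] for i in pick]
    for a, b in internal:
        g.add_edge(a, b, confidence=float(rng.uniform(hi_lo, hi)))

    for _, _, d in g.edges(data=True):
        d["cost"] = -math.log10(d["confidence"])
    return Interactome(g), module_nodes, prized


def make_annotations(
    cfg: SynthConfig, module_nodes, background=None
) -> tuple[pd.DataFrame, str]:
    """GAF-like annotation table with one planted enriched term.

    Each of ``n_terms`` terms annotates background genes independently at
    ``annotation_rate``; the planted term (the first) annotates module genes
    at ``term_enrichment_factor`` times that rate (capped at 1).  A fraction
    ``iea_fraction`` of records carry the electronic IEA code; the rest are
    drawn uniformly from the experimental codes.

    Returns (annotation table, planted term id).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    if background is None:
        background = gene_ids(cfg)
    background = list(background)
    module = set(module_nodes)
    if not module <= set(background):
        raise ConfigurationError("module_nodes: must be a subset of the background")
    q = cfg.annotation_rate
    q_mod = min(1.0, cfg.term_enrichment_factor * q)
    terms = [f"T{i:04d}" for i in range(cfg.n_terms)]
    planted = terms[0]
    records = []
    for t in terms:
        for gene in background:
            rate = q_mod if (t == planted and gene in module) else q
            if rng.random() < rate:
                if rng.random() < cfg.iea_fraction:
                    code = "IEA"
                else:
                    code = EXPERIMENTAL_CODES[int(rng.integers(len(EXPERIMENTAL_CODES)))]
                records.append((gene, t, code))
    table = pd.DataFrame(records, columns=["gene", "term", "evidence_code"])
    return table, planted


def logistic4(dose, ymin: float, ymax: float, ec50: float, hill: float):
    """Four-parameter logistic inhibition curve, increasing in dose."""
    dose = np.asarray(dose, dtype=float)
    return ymin + (ymax - ymin) / (1.0 + (ec50 / dose) ** hill)


#: default monotherapy curves: plateau 0.6 so a planted delta of +0.15 stays
#: below 1 on the whole surface (no clipping region)
DEFAULT_DRUG1 = dict(ymin=0.0, ymax=0.6, ec50=3.5, hill=1.3)
DEFAULT_DRUG2 = dict(ymin=0.0, ymax=0.6, ec50=5.0, hill=1.7)


def make_dose_response(
    cfg: SynthConfig,
    synergy_delta: float = 0.0,
    drug1: dict | None = None,
    drug2: dict | None = None,
):
    """Dose-response inhibition surface obeying the ZIP null up to a planted delta.

    Monotherapy rows follow 4-parameter logistic curves; each combination
    cell is y1 + y2 - y1*y2 + synergy_delta, clipped to [0, 1].  Returns a
    :class:`~prizeforest.synergy.DoseResponseMatrix`.
    """
    from .synergy import DoseResponseMatrix

    d = np.asarray(cfg.dose_grid, dtype=float)
    y1 = logistic4(d, **(drug1 or DEFAULT_DRUG1))
    y2 = logistic4(d, **(drug2 or DEFAULT_DRUG2))
    doses1 = np.concatenate([[0.0], d])
    doses2 = np.concatenate([[0.0], d])
    surface = np.zeros((len(doses1), len(doses2)))
    surface[1:, 0] = y1
    surface[0, 1:] = y2
    zip_null = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]
    surface[1:, 1:] = np.clip(zip_null + synergy_delta, 0.0, 1.0)
    return DoseResponseMatrix(doses1=doses1, doses2=doses2, inhibition=surface)


def random_pcsf_instance(rng: np.random.Generator, max_nodes: int = 12):
    """Small random PCSF benchmark instance: (graph, prizes, params).

    A connected G(n, 0.4) graph (4 <= n <= max_nodes) with confidences in
    (0.5, 0.99), 1..n/2 prized nodes with prizes in (0.2, 3), and parameters
    omega in (0.2, 2), beta in (0.5, 3), mu in (0, 0.1).  Used to compare the
    heuristic solver against the exhaustive one.
    """
    from .pcsf import PCSTParams

    n = int(rng.integers(4, max_nodes + 1))
    while True:
        g0 = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
        if nx.is_connected(g0) and g0.number_of_edges() > 0:
            break
    g = nx.Graph()
    for u, v in g0.edges():
        c = float(rng.uniform(0.5, 0.99))
        g.add_edge(f"N{u:02d}", f"N{v:02d}", confidence=c, cost=-math.log10(c))
    nodes = sorted(g.nodes)
    k = int(rng.integers(1, max(2, n // 2)))
    chosen = rng.choice(len(nodes), size=k, replace=False)
    prizes = {nodes[int(i)]: float(rng.uniform(0.2, 3.0)) for i in chosen}
    params = PCSTParams(
        omega=float(rng.uniform(0.2, 2.0)),
        beta=float(rng.uniform(0.5, 3.0)),
        mu=float(rng.uniform(0.0, 0.1)),
    )
    return g, prizes, params


# ---------------------------------------------------------------------------
# file export (all plain text)

def write_fixture_bundle(cfg: SynthConfig, outdir, synergy_delta: float = 0.0) -> dict:
    """Write every synthetic input (TSV/CSV) plus a JSON truth sidecar.

    Returns the dict of file paths written.
    """
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, labels = make_counts(cfg)
    net, module, prized = make_interactome(cfg)
    annot, planted_term = make_annotations(cfg, module, background=list(net.graph.nodes))
    drm = make_dose_response(cfg, synergy_delta=synergy_delta)

    paths = {
        "counts": outdir / "counts.tsv",
        "interactome": outdir / "interactome.tsv",
        "annotations": outdir / "annotations.tsv",
        "dose_response": outdir / "dose_response.csv",
        "truth": outdir / "truth.json",
    }
    cm.to_tsv(paths["counts"])
    net.to_tsv(paths["interactome"])
    annot.to_csv(paths["annotations"], sep="\t", index=False)
    drm.to_csv(paths["dose_response"])
    truth = {
        "labels": labels.to_dict(),
        "module_nodes": module,
        "prized_module_nodes": prized,
        "planted_term": planted_term,
        "synergy_delta": synergy_delta,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
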