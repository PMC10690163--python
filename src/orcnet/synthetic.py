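"""Synthetic cohorts with planted module structure.

Emulates the statistical structure the downstream analysis assumes: a sparse
connected interaction topology with planted gene modules, per-patient
expression-difference vectors whose within-module correlations arise from a
shared latent factor, survival times whose hazard depends on one module's
score, and RECIST-like response categories associated with that score.
Ground truth (labels, loadings, factors) is retained for recovery tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_topology",
    "generate_delta",
    "generate_clinical",
    "generate_dataset",
    "truth_module_scores",
    "write_dataset",
]

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a 120-gene network with four planted modules
    (within-module edge probability 0.3, between 0.02), a shared-factor
    model with loading a=2 and unit noise (within-module gene-gene
    correlation a^2/(a^2+sigma^2) = 0.8), 100 patients, and a protective
    log-hazard of -1 on the module-1 score with 20% censoring.
    """

    n_genes: int = 120
    n_modules: int = 4
    n_patients: int = 100
    p_within: float = 0.3
    p_between: float = 0.02
    factor_loading: float = 2.0
    noise_sd: float = 1.0
    hazard_beta: float = -1.0
    censor_rate: float = 0.2
    seed: int = 0
    loading_jitter: float = 0.0
    response_noise: float = 0.1
    baseline_hazard: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_modules < 1 or self.n_patients < 1:
            raise ValueError("n_genes, n_modules and n_patients must be positive")
        if not (0.0 <= self.p_between < self.p_within <= 1.0):
            raise ValueError("require 0 <= p_between < p_within <= 1")
        if self.n_genes < self.n_modules:
            raise ValueError("n_genes must be >= n_modules")
        if self.n_genes < 2 * self.n_modules:
            raise ValueError("modules need at least 2 genes each on average")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.factor_loading < 0:
            raise ValueError("factor_loading must be nonnegative")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth used by recovery tests."""

    module_labels: dict[str, int]
    loadings: dict[str, float]
    factors: np.ndarray  # (n_modules, n_patients)
    hazard_beta: float
    patient_ids: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.module_labels)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _patient_ids(n: int) -> list[str]:
    return [f"P{i:03d}" for i in range(1, n + 1)]


def generate_topology(config: SyntheticConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Sample a planted-partition graph and repair connectivity.

    Genes are split into ``n_modules`` near-equal blocks (labels 1..k);
    each within-block pair receives an edge with probability ``p_within``
    and each between-block pair with ``p_between``.  If the sample is
    disconnected, the minimum number of uniform-random cross-component
    edges (preferring between-module pairs, so planted densities are not
    inflated) is added to connect it.  The result is simple and connected.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    sizes = np.full(config.n_modules, config.n_genes // config.n_modules)
    sizes[: config.n_genes % config.n_modules] += 1
    labels = np.repeat(np.arange(1, config.n_modules + 1), sizes)

    iu, ju = np.triu_indices(config.n_genes, k=1)
    same = labels[iu] == labels[ju]
    probs = np.where(same, config.p_within, config.p_between)
    keep = rng.random(len(probs)) < probs

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from((genes[a], genes[b]) for a, b in zip(iu[keep], ju[keep]))

    # connect components pairwise, preferring endpoints in different modules
    label_of = {g: int(l) for g, l in zip(genes, labels)}
    components = [sorted(c) for c in nx.connected_components(graph)]
    while len(components) > 1:
        components.sort(key=len, reverse=True)
        core, other = components[0], components[1]
        pairs = [
            (u, v) for u in core for v in other if label_of[u] != label_of[v]
        ] or [(u, v) for u in core for v in other]
        u, v = pairs[rng.integers(len(pairs))]
        graph.add_edge(u, v)
        components = [sorted(c) for c in nx.connected_components(graph)]

    nx.set_node_attributes(graph, label_of, "module")
    loadings = {
        g: float(config.factor_loading * (1.0 + config.loading_jitter * z))
        for g, z in zip(genes, rng.standard_normal(config.n_genes))
    }
    truth = SyntheticTruth(
        module_labels=label_of,
        loadings=loadings,
        factors=np.empty((config.n_modules, 0)),
        hazard_beta=config.hazard_beta,
        patient_ids=[],
    )
    return graph, truth


def generate_delta(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Draw the gene x patient expression-difference matrix.

    Single shared factor per module: x_gp = a_g * f_{m(g),p} + sigma * eps_gp
    with f, eps iid standard normal, so two genes of one module with common
    loading a correlate at a^2 / (a^2 + sigma^2).  Also fills ``truth.factors``
    and ``truth.patient_ids`` in place.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = truth.genes
    patients = _patient_ids(config.n_patients)
    factors = rng.standard_normal((config.n_modules, config.n_patients))
    noise = rng.standard_normal((len(genes), config.n_patients))
    loadings = np.array([truth.loadings[g] for g in genes])
    rows = np.array([truth.module_labels[g] - 1 for g in genes])
    values = loadings[:, None] * factors[rows, :] + config.noise_sd * noise
    truth.factors = factors
    truth.patient_ids = patients
    return pd.DataFrame(values, index=genes, columns=patients)


def generate_clinical(scores: pd.Series, config: SyntheticConfig) -> pd.DataFrame:
    """Simulate survival and RECIST-like response from per-patient scores.

    Event times are exponential with rate lambda0 * exp(hazard_beta * score);
    censoring times are an independent exponential whose rate is calibrated
    so the expected censored fraction matches ``censor_rate``.  Response is
    assigned by score tertile (top -> CR/PR, middle -> SD, bottom -> PD) and
    then a ``response_noise`` fraction of labels is reassigned at random.
    """
    if scores.nunique() <= 1:
        warnings.warn("all patient scores identical; Cox covariate degenerate",
                      stacklevel=2)
    rng = np.random.default_rng(config.seed + 2)
    s = scores.to_numpy(dtype=float)
    rate = config.baseline_hazard * np.exp(config.hazard_beta * s)
    event_time = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        cens_rate = config.censor_rate / (1 - config.censor_rate) * rate.mean()
        cens_time = rng.exponential(1.0 / cens_rate, size=len(s))
    else:
        cens_time = np.full(len(s), np.inf)
    os_time = np.minimum(event_time, cens_time)
    os_event = (event_time <= cens_time).astype(int)

    order = np.argsort(np.argsort(s, kind="stable"), kind="stable")
    tertile = (order * 3) // len(s)  # 0 = lowest scores
    response = np.where(tertile == 0, "PD", np.where(tertile == 1, "SD", "PR"))
    response = response.astype(object)
    top = np.where(tertile == 2)[0]
    response[top[rng.random(len(top)) < 1 / 3]] = "CR"
    flip = rng.random(len(s)) < config.response_noise
    response[flip] = rng.choice(RESPONSE_CATEGORIES, size=int(flip.sum()))

    return pd.DataFrame(
        {
            "patient_id": scores.index,
            "response": response,
            "os_time": os_time,
            "os_event": os_event,
        }
    ).set_index("patient_id", drop=False)


def truth_module_scores(delta: pd.DataFrame, truth: SyntheticTruth) -> pd.DataFrame:
    """Per-patient mean scaled delta over each planted module (truth scores)."""
    sd = delta.std(axis=1, ddof=1)
    scaled = delta.div(sd.where(sd > 0, 1.0), axis=0)
    groups = pd.Series(truth.module_labels)
    return scaled.groupby(groups).mean().T  # patient x module


def generate_dataset(config: SyntheticConfig):
    """Full synthetic cohort: topology, delta matrix, clinical table, truth.

    The clinical table is driven by the planted module-1 score (mean scaled
    delta over module-1 genes), so hazard_beta acts on that module alone.
    """
    graph, truth = generate_topology(config)
    delta = generate_delta(truth, config)
    scores = truth_module_scores(delta, truth)
    clinical = generate_clinical(scores[1], config)
    return graph, delta, clinical, truth


def write_dataset(outdir: str | Path, config: SyntheticConfig) -> dict[str, Path]:
    """Write delta TSV, edge-list TSV, clinical TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, delta, clinical, truth = generate_dataset(config)

    paths = {
        "delta": outdir / "delta.tsv",
        "edges": outdir / "edges.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    delta.to_csv(paths["delta"], sep="\t", index_label="gene")
    edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in graph.edges()),
                         columns=["geneA", "geneB"])
    edges["confidence"] = 1.0
    edges.to_csv(paths["edges"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    paths["truth"].write_text(
        json.dumps(
            {
                "module_labels": truth.module_labels,
                "loadings": truth.loadings,
                "hazard_beta": truth.hazard_beta,
                "seed": config.seed,
            },
            indent=1,
        )
    )
    return paths
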