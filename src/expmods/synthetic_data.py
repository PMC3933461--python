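"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* :func:`simulate_expression` — gene-level log2 matrices for a two-group
  case/control design (default 7 cases vs 5 controls) in which a chosen set
  of *planted* genes carries a mean shift of ``effect_size`` log2 units in
  the cases.
* :func:`simulate_raw_probes` — a raw-scale probe-level matrix (lognormal
  intensities, background-corrected so some values are negative) with
  detection p-values and a probe->gene map, for exercising the
  preprocessing chain.
* :func:`simulate_interactome` — a background interaction network
  (preferential-attachment by default, uniform-random optionally) with a
  planted dense subnetwork whose internal edge density is guaranteed to be
  at least the requested value.
* :func:`simulate_validation_stats` — a paired "validation" statistic
  vector for a module, with a controlled concordant fraction, emulating an
  independent replication dataset.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import CASE, CONTROL, ExpressionMatrix, ProbeMatrix

__all__ = [
    "SimulationConfig",
    "NetworkSimConfig",
    "simulate_expression",
    "simulate_raw_probes",
    "simulate_interactome",
    "simulate_validation_stats",
    "gene_ids",
]


def gene_ids(n: int) -> list[str]:
    """Stable synthetic gene identifiers G0001, G0002, ..."""
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


@dataclass
class SimulationConfig:
    """Two-group expression simulation on the log2 scale.

    Defaults mirror a small clinical microarray design: 7 cases vs
    5 controls, baseline log2 intensity 8, per-gene noise sd 1 log2 unit.
    ``effect_size`` is the case-minus-control mean shift applied to
    ``planted_genes``.
    """

    n_genes: int = 1000
    n_case: int = 7
    n_control: int = 5
    planted_genes: list[str] = field(default_factory=list)
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    heteroscedastic: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        universe = set(gene_ids(self.n_genes))
        extra = set(self.planted_genes) - universe
        if extra:
            raise ValueError(f"planted genes outside the simulated universe: {sorted(extra)[:5]}")


def simulate_expression(cfg: SimulationConfig) -> ExpressionMatrix:
    """Draw a genes x samples log2 matrix under ``cfg``.

    Every value is normal with sd ``noise_sd`` around ``baseline_mean``;
    planted genes get ``baseline_mean + effect_size`` in the case group.
    With ``heteroscedastic=True`` per-gene sds are scaled by a chi-draw so
    variances differ across genes.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genes = gene_ids(cfg.n_genes)
    n = cfg.n_case + cfg.n_control
    sd = np.full(cfg.n_genes, cfg.noise_sd)
    if cfg.heteroscedastic:
        # scaled inverse-chi-square-ish spread of per-gene sds
        sd = cfg.noise_sd * np.sqrt(rng.chisquare(4, cfg.n_genes) / 4.0)
    x = cfg.baseline_mean + rng.standard_normal((cfg.n_genes, n)) * sd[:, None]
    planted_idx = [genes.index(g) for g in cfg.planted_genes]
    x[planted_idx, : cfg.n_case] += cfg.effect_size
    samples = [f"case_{i + 1}" for i in range(cfg.n_case)] + [
        f"ctrl_{i + 1}" for i in range(cfg.n_control)
    ]
    groups = pd.Series(
        [CASE] * cfg.n_case + [CONTROL] * cfg.n_control, index=samples, name="group"
    )
    return ExpressionMatrix(values=pd.DataFrame(x, index=genes, columns=samples),
                            groups=groups)


def simulate_raw_probes(
    n_genes: int = 200,
    probes_per_gene: int = 2,
    n_case: int = 7,
    n_control: int = 5,
    frac_unexpressed: float = 0.2,
    frac_unannotated: float = 0.1,
    rng_seed: int = 0,
) -> ProbeMatrix:
    """Raw-scale probe matrix with detection p-values for preprocessing tests.

    Expressed probes get lognormal intensities and small detection
    p-values; "unexpressed" probes get background-level intensities (some
    negative, as after background subtraction) and detection p-values near
    uniform.  A ``frac_unannotated`` share of probes carries no gene
    annotation.
    """
    rng = np.random.default_rng(rng_seed)
    genes = gene_ids(n_genes)
    n_probes = n_genes * probes_per_gene
    n_samples = n_case + n_control
    probe_ids = [f"P{i + 1:05d}" for i in range(n_probes)]
    mapping = np.repeat(genes, probes_per_gene)

    unexpressed = rng.random(n_probes) < frac_unexpressed
    base = rng.lognormal(mean=6.0, sigma=1.0, size=(n_probes, n_samples))
    values = np.where(
        unexpressed[:, None],
        rng.normal(0.0, 30.0, size=(n_probes, n_samples)),  # background noise, may be < 0
        base,
    )
    det = np.where(
        unexpressed[:, None],
        rng.uniform(0.0, 1.0, size=(n_probes, n_samples)),
        rng.uniform(0.0, 0.04, size=(n_probes, n_samples)),
    )
    annotated = rng.random(n_probes) >= frac_unannotated
    probe2gene = pd.Series(mapping, index=probe_ids)[annotated]
    samples = [f"case_{i + 1}" for i in range(n_case)] + [f"ctrl_{i + 1}" for i in range(n_control)]
    groups = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=samples, name="group")
    return ProbeMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=samples),
        detection_p=pd.DataFrame(det, index=probe_ids, columns=samples),
        probe2gene=probe2gene,
        groups=groups,
    )


@dataclass
class NetworkSimConfig:
    """Background network with a planted dense subnetwork.

    ``topology`` is ``"preferential_attachment"`` (heavy-tailed, like real
    interactomes) or ``"uniform"`` (Erdos-Renyi).
    ``attachment_or_density`` is the BA attachment count m in the first
    case and the edge probability p in the second.  The planted module is
    placed on the first ``planted_module_size`` gene ids (or on
    ``planted_nodes`` when given) and its internal edge density is
    guaranteed to be >= ``planted_internal_density``.
    """

    n_nodes: int = 300
    topology: str = "preferential_attachment"
    attachment_or_density: float = 3
    planted_module_size: int = 10
    planted_internal_density: float = 0.9
    planted_nodes: list[str] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_module_size > self.n_nodes:
            raise ValueError("planted_module_size exceeds n_nodes")
        if not 0.0 <= self.planted_internal_density <= 1.0:
            raise ValueError("planted_internal_density must be in [0, 1]")
        if self.topology not in ("preferential_attachment", "uniform"):
            raise ValueError(f"unknown topology {self.topology!r}")


def simulate_interactome(cfg: NetworkSimConfig) -> nx.Graph:
    """Simple undirected graph over gene ids with the planted module dense.

    The planted density guarantee is met by adding exactly
    ``ceil(density * n_pairs)`` internal edges chosen uniformly at random
    (on top of whatever the background already placed there).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    ids = gene_ids(cfg.n_nodes)
    if cfg.topology == "preferential_attachment":
        m = int(cfg.attachment_or_density)
        g = nx.barabasi_albert_graph(cfg.n_nodes, m, seed=int(rng.integers(2**31)))
    else:
        g = nx.gnp_random_graph(
            cfg.n_nodes, float(cfg.attachment_or_density), seed=int(rng.integers(2**31))
        )
    # random id assignment decouples gene ids from topology (BA node order
    # correlates with degree, and the planted module must not sit on hubs
    # by construction)
    perm = rng.permutation(cfg.n_nodes)
    g = nx.relabel_nodes(g, {i: ids[perm[i]] for i in range(cfg.n_nodes)})
    g.add_nodes_from(ids)  # keep isolated nodes in the uniform case

    planted = cfg.planted_nodes if cfg.planted_nodes is not None else ids[: cfg.planted_module_size]
    missing = set(planted) - set(ids)
    if missing:
        raise ValueError(f"planted nodes not in the simulated universe: {sorted(missing)[:5]}")
    pairs = list(itertools.combinations(sorted(planted), 2))
    if pairs:
        k = int(np.ceil(cfg.planted_internal_density * len(pairs)))
        chosen = rng.choice(len(pairs), size=k, replace=False)
        g.add_edges_from(pairs[i] for i in chosen)
    g.remove_edges_from(nx.selfloop_edges(g))
    nx.set_edge_attributes(g, 1.0, "weight")
    g.graph["planted"] = sorted(planted)
    return g


def simulate_validation_stats(
    module_genes: list[str],
    discovery_t: pd.Series | dict,
    concordant_frac: float,
    rng_seed: int = 0,
    df: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Validation t-statistics for a module with a known concordant fraction.

    A random ``floor(concordant_frac * len(module))`` subset of module
    genes receives a statistic with the discovery sign and a magnitude
    beyond the two-sided nominal-significance threshold at ``alpha`` for a
    t law with ``df`` degrees of freedom (the default df of 6 matches a
    4 vs 4 validation design).  The remaining genes get small statistics
    near zero.  Returns a DataFrame with columns ``t`` and ``p``.
    """
    module_genes = list(module_genes)
    if not module_genes:
        raise ValueError("empty module")
    if not 0.0 <= concordant_frac <= 1.0:
        raise ValueError("concordant_frac must be in [0, 1]")
    disc = pd.Series(discovery_t)
    missing = [g for g in module_genes if g not in disc.index]
    if missing:
        raise ValueError(f"no discovery statistic for: {missing[:5]}")

    rng = np.random.default_rng(rng_seed)
    n = len(module_genes)
    k = int(np.floor(concordant_frac * n))
    concordant = np.zeros(n, dtype=bool)
    concordant[rng.choice(n, size=k, replace=False)] = True

    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    mags = t_crit * rng.uniform(1.2, 3.0, size=n)
    signs = np.sign(disc.loc[module_genes].to_numpy())
    signs[signs == 0] = 1.0
    t_null = rng.normal(0.0, 0.3, size=n)  # well inside the acceptance region
    t = np.where(concordant, signs * mags, t_null)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"t": t, "p": p}, index=pd.Index(module_genes, name="gene_id"))
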