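"""Synthetic replicated-microbiome data with known variance structure.

The generator emulates a two-tier repeated-measures 16S study: hosts (fish)
drawn from full-sib families nested in populations, each host's gut sampled
several times (either with different DNA-isolation protocols — the
reproducibility arm — or with identical protocol — the precision arm).

Generative model, per taxon t, fish i, replicate library j:

    log lambda_tij = b_t + population/protocol offsets + a_ti + e_tij
    a_ti ~ Normal(0, sigma2_A)      (among-fish, biological)
    e_tij ~ Normal(0, sigma2_W)     (within-fish, technical)

Library counts are a single multinomial draw of `library_depth` reads with
probabilities proportional to lambda_tij — composition is closed at the
sampling step, mirroring relative-abundance 16S data with fixed
(downsampled) totals. Baseline log-abundances b_t are Normal draws
rank-sorted to give a lognormal rank-abundance curve with a rare-taxon tail.

The latent effects are retained and returned so recovery tests can compare
estimates against ground truth without re-deriving it from counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .counts import CountTable, StudyDesign
from .diversity import Phylogeny

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_random_phylogeny",
    "simulate_yields",
    "PROTOCOLS",
]

PROTOCOLS = ("PCP", "PFP", "DEP")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated reproducibility design: 2 populations x 3
    full-sib families x 6 fish x 3 protocol replicates = 108 libraries.
    Variances are on the natural-log scale of expected abundance.
    """

    n_populations: int = 2
    families_per_population: int = 3
    fish_per_family: int = 6
    replicates_per_fish: int = 3
    n_taxa: int = 200
    library_depth: int = 105_000
    sigma2_A: float = 0.5
    sigma2_W: float = 0.05
    baseline_logabundance_spread: float = 2.0
    protocol_offsets: dict | None = None    # taxon id/index -> {protocol: dlog}
    population_offsets: dict | None = None  # taxon id/index -> {population: dlog}
    experiment: str = "reproducibility"     # or "precision"
    seed: int = 0

    def __post_init__(self):
        for name in ("n_populations", "families_per_population",
                     "fish_per_family", "replicates_per_fish", "n_taxa",
                     "library_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sigma2_A < 0 or self.sigma2_W < 0:
            raise ValueError("variance components must be >= 0")
        if self.baseline_logabundance_spread < 0:
            raise ValueError("baseline spread must be >= 0")
        for offsets in (self.protocol_offsets, self.population_offsets):
            if offsets:
                for v in offsets.values():
                    if not all(np.isfinite(list(v.values()))):
                        raise ValueError("offsets must be finite")
        if self.experiment not in ("reproducibility", "precision"):
            raise ValueError("experiment must be reproducibility or precision")

    @property
    def n_fish(self) -> int:
        return self.n_populations * self.families_per_population * self.fish_per_family

    @property
    def n_libraries(self) -> int:
        return self.n_fish * self.replicates_per_fish


@dataclass
class SimulatedDataset:
    """Bundle of simulated data plus retained latent ground truth.

    Unpacks as ``table, design, tree = simulate_dataset(cfg)``; the latent
    arrays stay accessible as attributes.
    """

    table: CountTable
    design: StudyDesign
    tree: Phylogeny
    log_lambda: np.ndarray = field(repr=False, default=None)   # taxa x libraries
    fish_effects: np.ndarray = field(repr=False, default=None)  # taxa x fish
    rep_effects: np.ndarray = field(repr=False, default=None)   # taxa x libraries
    baseline: np.ndarray = field(repr=False, default=None)      # taxa

    def __iter__(self):
        return iter((self.table, self.design, self.tree))


def _taxon_key(offsets, taxon_ids):
    """Resolve offset keys given either taxon ids or integer indices."""
    out = {}
    if not offsets:
        return out
    for key, per_level in offsets.items():
        idx = key if isinstance(key, (int, np.integer)) else taxon_ids.index(key)
        out[idx] = per_level
    return out


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate a count table, design table and phylogeny under `config`.

    In the reproducibility arm each fish's replicates use distinct protocols
    (cycling PCP, PFP, DEP, ...); in the precision arm a fish's replicates all
    share one protocol and protocols cycle across fish.
    """
    rng = np.random.default_rng(config.seed)
    T = config.n_taxa
    taxon_ids = [f"t{k:04d}" for k in range(1, T + 1)]

    # design table
    rows = []
    fish_counter = 0
    for p in range(config.n_populations):
        pop = f"pop{p + 1}"
        for f in range(config.families_per_population):
            fam = f"fam{p + 1}.{f + 1}"
            for _ in range(config.fish_per_family):
                fish_counter += 1
                fish = f"fish{fish_counter:03d}"
                for j in range(config.replicates_per_fish):
                    if config.experiment == "reproducibility":
                        proto = PROTOCOLS[j % len(PROTOCOLS)]
                    else:
                        proto = PROTOCOLS[(fish_counter - 1) % len(PROTOCOLS)]
                    rows.append((f"{fish}.r{j + 1}", fish, fam, pop, proto,
                                 config.experiment))
    design = StudyDesign(pd.DataFrame(
        rows, columns=["library_id", "fish_id", "family_id", "population",
                       "protocol", "experiment"]))
    n_fish = config.n_fish
    n_lib = config.n_libraries

    # latent structure
    baseline = np.sort(rng.normal(0.0, config.baseline_logabundance_spread, T))[::-1]
    fish_effects = rng.normal(0.0, np.sqrt(config.sigma2_A), (T, n_fish))
    rep_effects = rng.normal(0.0, np.sqrt(config.sigma2_W), (T, n_lib))

    fish_idx = np.repeat(np.arange(n_fish), config.replicates_per_fish)
    log_lam = baseline[:, None] + fish_effects[:, fish_idx] + rep_effects

    proto_of = design.table["protocol"].to_numpy()
    pop_of = design.table["population"].to_numpy()
    for t_idx, per_proto in _taxon_key(config.protocol_offsets, taxon_ids).items():
        for lvl, dlog in per_proto.items():
            log_lam[t_idx, proto_of == lvl] += dlog
    for t_idx, per_pop in _taxon_key(config.population_offsets, taxon_ids).items():
        for lvl, dlog in per_pop.items():
            log_lam[t_idx, pop_of == lvl] += dlog

    # closed-composition sequencing: one multinomial draw per library
    lam = np.exp(log_lam - log_lam.max(axis=0, keepdims=True))
    probs = lam / lam.sum(axis=0, keepdims=True)
    counts = np.empty((T, n_lib), dtype=np.int64)
    for j in range(n_lib):
        counts[:, j] = rng.multinomial(config.library_depth, probs[:, j])

    table = CountTable(taxon_ids, design.library_ids, counts)
    tree = simulate_random_phylogeny(T, seed=rng.integers(2**31),
                                     taxon_ids=taxon_ids)
    return SimulatedDataset(table, design, tree, log_lam, fish_effects,
                            rep_effects, baseline)


def simulate_random_phylogeny(n_taxa: int, seed=0, taxon_ids=None) -> Phylogeny:
    """Random rooted binary tree with exponential branch lengths.

    Built by iteratively joining uniformly chosen subtree pairs (a random
    topology) with Exp(1) branch lengths; leaves are labelled to match the
    count-table taxa. Deterministic under the seed.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa for a phylogeny")
    rng = np.random.default_rng(seed)
    if taxon_ids is None:
        taxon_ids = [f"t{k:04d}" for k in range(1, n_taxa + 1)]
    nodes = []
    for name in taxon_ids:
        tip = TreeNode(name=name)
        tip.length = float(rng.exponential(1.0)) + 1e-6
        nodes.append(tip)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(1.0)) + 1e-6
        nodes.append(parent)
    root = TreeNode(children=list(nodes))
    return Phylogeny(root)


def simulate_yields(group_means, group_cvs, group_ns, seed=0) -> pd.DataFrame:
    """Lognormal DNA-yield draws per group with requested population CVs.

    For a lognormal, CV depends only on the log-scale variance:
    sigma^2 = ln(1 + CV^2); the log-mean is set so the arithmetic mean equals
    the requested group mean. CV = 0 degenerates to constant yields. Returns
    a long table (group, yield) suitable for the CV-equality test.
    """
    group_means = np.asarray(group_means, dtype=float)
    group_cvs = np.asarray(group_cvs, dtype=float)
    group_ns = np.asarray(group_ns, dtype=int)
    if not (len(group_means) == len(group_cvs) == len(group_ns)):
        raise ValueError("group parameter sequences must have equal length")
    if np.any(group_means < 0) or np.any(group_cvs < 0):
        raise ValueError("means and CVs must be >= 0")
    if np.any(group_ns < 2):
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(seed)
    frames = []
    for g, (m, cv, n) in enumerate(zip(group_means, group_cvs, group_ns)):
        if cv == 0:
            y = np.full(n, m)
        else:
            s2 = np.log1p(cv**2)
            mu = np.log(m) - s2 / 2.0
            y = rng.lognormal(mu, np.sqrt(s2), n)
        frames.append(pd.DataFrame({"group": f"g{g + 1}", "yield": y}))
    return pd.concat(frames, ignore_index=True)
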