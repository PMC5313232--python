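"""Synthetic data generator.

Emulates the statistical structure of the pipeline's real inputs so
every stage can be exercised end-to-end without external downloads:

* a Yule (pure-birth) phylogeny of genomes, scaled to a fixed depth;
* gene-family presence/absence evolving along the tree as independent
  two-state (gain/loss) Markov chains, with *planted* gene sets whose
  member families share gain/loss events (correlated evolution, so
  clustered functional modules exist to discover);
* a scored link table with dense high-scoring links inside planted
  sets and sparse low-scoring background links, straddling the
  score threshold;
* a binary OTU x sample table generated under habitat filtering: each
  sample draws a latent habitat vector, and a genome's occupancy
  probability is a logistic function of the match between its
  gene-content-derived trait vector and the habitat, scaled by
  ``habitat_effect``. At ``habitat_effect = 0`` occupancy is i.i.d.
  Bernoulli, independent of genome content — the null model.

Every generator is deterministic given the config seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .containers import (
    GeneSetCatalog,
    GenomeGeneContent,
    OtuTable,
    ScoredLinkTable,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "planted_gene_sets",
    "simulate_gene_content",
    "simulate_network",
    "simulate_otu_table",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults give 40 genomes in 200 samples under strong habitat
    filtering (habitat_effect 5), a tree of depth 1 with gain and loss
    rates of 1 per unit branch length, and 30 planted gene sets of
    6-14 families whose members share every gain/loss event
    (set_correlation 1), overlaid with 10% per-genome family-call
    noise (content_noise) emulating strain-level and annotation
    scatter. Module turnover accumulates with phylogenetic distance
    while the noise floor does not, which reproduces the empirical
    behaviour of the pairwise indices: close relatives differ by
    scattered families inside shared modules, distant ones by whole
    modules.
    """

    n_genomes: int = 40
    n_families: int = 400
    # tree
    birth_rate: float = 1.0
    tree_depth: float = 1.0
    # gene content evolution (rates per unit branch length)
    gain_rate: float = 1.0
    loss_rate: float = 1.0
    # planted gene sets
    n_planted_sets: int = 30
    set_size_min: int = 6
    set_size_max: int = 14
    set_correlation: float = 1.0
    driver_rate_scale: float = 1.0
    content_noise: float = 0.1
    # link table
    intra_set_edge_prob: float = 0.9
    background_edge_prob: float = 0.001
    intra_score_range: tuple[int, int] = (600, 1000)
    background_score_range: tuple[int, int] = (276, 450)
    # ecology
    n_samples: int = 200
    habitat_effect: float = 5.0
    n_habitat_dims: int = 5
    base_occupancy: float = 0.3
    occupancy_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intra_set_edge_prob", "background_edge_prob",
                     "set_correlation", "base_occupancy",
                     "occupancy_noise", "content_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("gain_rate", "loss_rate", "habitat_effect",
                     "birth_rate", "tree_depth", "driver_rate_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulatedDataset:
    tree: dendropy.Tree
    content: GenomeGeneContent
    planted_sets: GeneSetCatalog
    links: ScoredLinkTable
    otu_table: OtuTable


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31 - 1) for s in
            np.random.SeedSequence(seed).generate_state(n)]


def simulate_tree(config: SimulationConfig) -> dendropy.Tree:
    """Yule tree with ``n_genomes`` leaves (labels g1..gN), scaled so
    the deepest root-to-leaf distance equals ``tree_depth``
    (``tree_depth = 0`` keeps the raw birth-process branch lengths)."""
    if config.n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    rng = random.Random(_child_seeds(config.seed, 1)[0])
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_genomes,
        rng=rng,
    )
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if depth > 0 and config.tree_depth > 0:
        scale = config.tree_depth / depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    ns = dendropy.TaxonNamespace()
    for k, leaf in enumerate(tree.leaf_node_iter(), 1):
        leaf.taxon = ns.new_taxon(f"g{k}")
    tree.taxon_namespace = ns
    return tree


def planted_gene_sets(config: SimulationConfig) -> GeneSetCatalog:
    """Assign the first families to ``n_planted_sets`` disjoint sets
    with sizes uniform in [set_size_min, set_size_max]; remaining
    families up to ``n_families`` are unclustered background."""
    rng = np.random.default_rng(_child_seeds(config.seed, 2)[1])
    sizes = rng.integers(
        config.set_size_min, config.set_size_max + 1,
        size=config.n_planted_sets,
    )
    if sizes.sum() > config.n_families:
        raise ValueError(
            "planted sets need more families than n_families provides"
        )
    width = len(str(config.n_families))
    fam = iter(f"F{k:0{width}d}" for k in range(1, config.n_families + 1))
    sets = {}
    for k, size in enumerate(sizes, 1):
        sets[f"PS{k:04d}"] = frozenset(next(fam) for _ in range(size))
    return GeneSetCatalog(sets)


def _family_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_families))
    return [f"F{k:0{width}d}" for k in range(1, config.n_families + 1)]


def simulate_gene_content(
    tree: dendropy.Tree,
    planted_sets: GeneSetCatalog,
    config: SimulationConfig,
) -> GenomeGeneContent:
    """Evolve family presence/absence along the tree.

    Each family follows a two-state Markov chain with gain rate g and
    loss rate l per unit branch (root state from the stationary
    distribution pi = g / (g + l)). Each planted set carries a hidden
    per-set "driver" chain; on every branch each member family is
    *coupled* to the driver with probability ``set_correlation``: a
    coupled family experiences exactly the driver's gain/loss event on
    that branch (none, if the driver is quiet), while an uncoupled
    family transitions independently. Shared events produce correlated
    module presence, and a zero-length branch changes nothing.
    """
    rng = np.random.default_rng(_child_seeds(config.seed, 3)[2])
    g, l = config.gain_rate, config.loss_rate
    if g + l == 0:
        raise ValueError("gain_rate + loss_rate must be positive")
    pi = g / (g + l)
    families = _family_ids(config)
    fam_index = {f: k for k, f in enumerate(families)}
    nf = len(families)
    set_of_family = np.full(nf, -1, dtype=int)
    for s, (sid, members) in enumerate(sorted(planted_sets.sets.items())):
        for f in members:
            set_of_family[fam_index[f]] = s
    n_sets = len(planted_sets.sets)
    rho = config.set_correlation
    in_set = set_of_family >= 0

    def transition(parent: np.ndarray, t: float,
                   scale: float = 1.0) -> np.ndarray:
        e = np.exp(-(g + l) * scale * t)
        p_present = np.where(parent, pi + (1 - pi) * e, pi * (1 - e))
        return rng.random(parent.shape) < p_present

    # root states
    driver = rng.random(n_sets) < pi if n_sets else np.zeros(0, dtype=bool)
    states = rng.random(nf) < pi
    if n_sets:
        copy = in_set & (rng.random(nf) < rho)
        states[copy] = driver[set_of_family[copy]]

    leaf_states: dict[str, np.ndarray] = {}
    node_state = {id(tree.seed_node): (states, driver)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        p_states, p_driver = node_state[id(node.parent_node)]
        d = (transition(p_driver, t, config.driver_rate_scale)
             if n_sets else p_driver)
        s = transition(p_states, t)
        if n_sets:
            coupled = in_set & (rng.random(nf) < rho)
            driver_changed = (d != p_driver)[
                np.where(in_set, set_of_family, 0)
            ]
            adopt = coupled & driver_changed
            quiet = coupled & ~driver_changed
            s[adopt] = d[set_of_family[adopt]]
            s[quiet] = p_states[quiet]
        node_state[id(node)] = (s, d)
        if node.is_leaf():
            leaf_states[node.taxon.label] = s

    membership = {}
    fam_arr = np.array(families, dtype=object)
    for label in sorted(leaf_states, key=lambda x: int(x[1:])):
        s = leaf_states[label]
        if config.content_noise > 0:
            flip = rng.random(nf) < config.content_noise
            s = s ^ flip
        fams = frozenset(fam_arr[s])
        if not fams:
            raise ValueError(
                f"genome {label} lost every family; lower loss_rate or "
                "raise gain_rate"
            )
        membership[label] = fams
    return GenomeGeneContent(membership)


def simulate_network(
    planted_sets: GeneSetCatalog, config: SimulationConfig
) -> ScoredLinkTable:
    """Scored links: within-set pairs with ``intra_set_edge_prob`` and
    scores uniform in ``intra_score_range``; all other family pairs
    with ``background_edge_prob`` and scores in
    ``background_score_range`` (straddling the 275 threshold)."""
    rng = np.random.default_rng(_child_seeds(config.seed, 4)[3])
    families = _family_ids(config)
    fam_index = {f: k for k, f in enumerate(families)}
    same_set = np.zeros(len(families), dtype=int) - 1
    for s, (sid, members) in enumerate(sorted(planted_sets.sets.items())):
        for f in members:
            same_set[fam_index[f]] = s
    records = []
    lo_i, hi_i = config.intra_score_range
    lo_b, hi_b = config.background_score_range
    nf = len(families)
    iu, ju = np.triu_indices(nf, k=1)
    intra = (same_set[iu] >= 0) & (same_set[iu] == same_set[ju])
    u = rng.random(iu.size)
    keep = np.where(intra, u < config.intra_set_edge_prob,
                    u < config.background_edge_prob)
    scores = np.where(
        intra,
        rng.integers(lo_i, hi_i + 1, size=iu.size),
        rng.integers(lo_b, hi_b + 1, size=iu.size),
    )
    for i, j, s in zip(iu[keep], ju[keep], scores[keep]):
        records.append((families[i], families[j], int(s)))
    return ScoredLinkTable.from_records(records)


def simulate_otu_table(
    content: GenomeGeneContent,
    tree: dendropy.Tree,
    config: SimulationConfig,
) -> OtuTable:
    """Habitat-filtered occupancy (one OTU per genome).

    Genome trait vectors are standardized random projections of the
    binary gene-content matrix onto ``n_habitat_dims`` fixed
    directions; each sample draws a standard-normal habitat vector h,
    and genome i occupies the sample with probability
    sigmoid(logit(base_occupancy) + habitat_effect * <t_i, h> / sqrt(k)).
    Occupancy states are then flipped with probability
    ``occupancy_noise``. habitat_effect = 0 gives i.i.d. occupancy.
    """
    rng = np.random.default_rng(_child_seeds(config.seed, 5)[4])
    genomes = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    families = sorted(content.all_families())
    fam_index = {f: k for k, f in enumerate(families)}
    m = np.zeros((len(genomes), len(families)))
    for gi, g in enumerate(genomes):
        for f in content.families(g):
            m[gi, fam_index[f]] = 1.0
    k = config.n_habitat_dims
    w = rng.standard_normal((len(families), k))
    traits = m @ w
    sd = traits.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    traits = (traits - traits.mean(axis=0)) / sd

    base = np.log(config.base_occupancy / (1.0 - config.base_occupancy))
    h = rng.standard_normal((k, config.n_samples))
    logits = base + config.habitat_effect * (traits @ h) / np.sqrt(k)
    prob = 1.0 / (1.0 + np.exp(-logits))
    occ = rng.random(prob.shape) < prob
    if config.occupancy_noise > 0:
        flip = rng.random(prob.shape) < config.occupancy_noise
        occ = occ ^ flip
    sample_ids = [f"s{j}" for j in range(1, config.n_samples + 1)]
    return OtuTable(genomes, sample_ids, occ.astype(np.int8))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full coupled dataset: tree, gene content, planted
    sets, link table and OTU table, all from one seed."""
    tree = simulate_tree(config)
    sets = planted_gene_sets(config)
    content = simulate_gene_content(tree, sets, config)
    links = simulate_network(sets, config)
    otu = simulate_otu_table(content, tree, config)
    return SimulatedDataset(
        tree=tree, content=content, planted_sets=sets,
        links=links, otu_table=otu,
    )
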