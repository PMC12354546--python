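"""Forward simulators for every analysis stage, plus study-shaped fixtures.

All simulators draw exact continuous-time Markov chain paths per branch
(Gillespie sampling), so event-level truth — e.g. "at least one change on
this branch" — is available for convergence scenarios, and all are
deterministic given a seed.

The default fixture mirrors the study design at reduced scale: a rooted
tree with a mammal-like clade and an iguanian clade split into
pleurodont-like and acrodont-like groups, the acrodonts further split into
chameleon-like and agamid-like subclades (6/6/3+3 taxa by default,
documented against the study's 12 mammals, 17 pleurodonts and 24
acrodonts).  Generator presets carry the study's printed estimates: the
three-class ω preset (0.33, 0.46, 0.40) for acrodonts/pleurodonts/mammals,
the four-class preset (0.26, 0.42, 0.60, 0.29) for chameleons/agamids/
pleurodonts/mammals, and Type-I θ presets 0.74 and 0.80.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clock_rates import GTRSpec, NUCLEOTIDES, gtr_matrix
from .codon_selection import SENSE_CODONS, CodonModelSpec, _gy94_q
from .convergence_pcoc import (ConvergenceScenario, ProfileSet,
                               profile_substitution_model)
from .functional_divergence import (AMINO_ACIDS, DEFAULT_PROPERTY_PARTITION,
                                    ClusterPair, SiteCountTable)
from .seq_prep import Alignment, CodonAlignment, ProteinAlignment
from .trees import Chronogram, LabeledTree

__all__ = [
    "OMEGA_PRESET_THREE_CLASS",
    "OMEGA_PRESET_FOUR_CLASS",
    "THETA_PRESETS",
    "StudyFixture",
    "make_study_fixture",
    "balanced_clade_tree",
    "simulate_codon_alignment",
    "simulate_type1",
    "simulate_type1_alignment",
    "simulate_type2",
    "simulate_convergent_alignment",
    "simulate_clock_alignment",
]

#: Branch-class ω presets taken from the study's printed estimates
#: (background, acrodont-like, pleurodont-like, mammal-like order varies by
#: use; see make_study_fixture).
OMEGA_PRESET_THREE_CLASS = (0.33, 0.46, 0.40)   # acrodont, pleurodont, mammal
OMEGA_PRESET_FOUR_CLASS = (0.26, 0.42, 0.60, 0.29)  # cham, agamid, pleuro, mammal
THETA_PRESETS = (0.74, 0.80)


# ------------------------------------------------------------- tree shapes


def _balanced_topology(labels: list[str]):
    if len(labels) == 1:
        return labels[0]
    mid = (len(labels) + 1) // 2
    return (_balanced_topology(labels[:mid]), _balanced_topology(labels[mid:]))


def _height(node) -> int:
    if isinstance(node, str):
        return 0
    return 1 + max(_height(node[0]), _height(node[1]))


def _to_newick(node, unit: float, parent_h: int) -> str:
    h = _height(node)
    length = (parent_h - h) * unit
    if isinstance(node, str):
        return f"{node}:{length:.8f}"
    left = _to_newick(node[0], unit, h)
    right = _to_newick(node[1], unit, h)
    return f"({left},{right}):{length:.8f}"


def balanced_clade_tree(labels: list[str], depth: float) -> str:
    """Ultrametric balanced Newick subtree of the given total depth.

    Returned without the trailing branch (caller supplies the stem).
    """
    topo = _balanced_topology(labels)
    h = _height(topo)
    if h == 0:
        return labels[0]
    unit = depth / h
    left = _to_newick(topo[0], unit, h)
    right = _to_newick(topo[1], unit, h)
    return f"({left},{right})"


@dataclass
class StudyFixture:
    """Reduced-scale analogue of the study's clade design."""

    tree2: LabeledTree      # classes: 0 mammal+deep, 1 iguania (all lizards)
    tree3: LabeledTree      # classes: 0 mammal+deep, 1 acrodont, 2 pleurodont
    tree4: LabeledTree      # classes: 0 mammal+deep, 1 cham, 2 agamid, 3 pleuro
    chronogram: Chronogram  # rate classes as tree3
    chronogram4: Chronogram  # rate classes as tree4
    clades: dict[str, list[str]]
    seed: int


def make_study_fixture(
    seed: int = 0,
    n_chameleon: int = 3,
    n_agamid: int = 3,
    n_pleurodont: int = 6,
    n_mammal: int = 6,
    clade_depth: float = 0.5,
    stem: float = 0.25,
) -> StudyFixture:
    """Build the labeled study tree(s) and matching chronogram.

    Branch lengths are expected substitutions per site at the neutral rate;
    the chronogram reuses the topology with ages in MY (amniote root 312,
    iguanian split 160, acrodont split 100, crown clades 60).
    """
    cham = [f"cham{i+1}" for i in range(n_chameleon)]
    agam = [f"agam{i+1}" for i in range(n_agamid)]
    pleu = [f"pleu{i+1}" for i in range(n_pleurodont)]
    mamm = [f"mamm{i+1}" for i in range(n_mammal)]

    def sub(labels, depth):
        return balanced_clade_tree(labels, depth)

    acro_depth = clade_depth * 0.6
    newick = (
        f"((({sub(cham, acro_depth)}:{clade_depth - acro_depth:.6f},"
        f"{sub(agam, acro_depth)}:{clade_depth - acro_depth:.6f})"
        f":{stem:.6f},{sub(pleu, clade_depth)}:{stem:.6f})"
        f":{stem:.6f},{sub(mamm, clade_depth)}:{2 * stem:.6f});"
    )
    clades = {
        "chameleon": cham, "agamid": agam, "acrodont": cham + agam,
        "pleurodont": pleu, "mammal": mamm, "iguania": cham + agam + pleu,
    }
    # k-ratio convention: labeled clades get classes 1..k−1; mammals and the
    # root branches form the background class 0, so a k-ratio model has
    # exactly k omega (or rate) classes.  Labeling the broader clade first
    # and overwriting its subclades keeps the ladder strictly nested: each
    # model's classes partition a coarser model's classes, so warm-started
    # lnL is monotone.  Consequence: the iguanian and acrodont stem branches
    # ride with class 1 (acrodont, then chameleon) in the finer models.
    tree2 = LabeledTree.from_newick(newick)
    tree2.label_clades({"iguania": cham + agam + pleu})
    tree3 = LabeledTree.from_newick(newick)
    tree3.label_clades({"acrodont": cham + agam + pleu, "pleurodont": pleu},
                       class_ids={"acrodont": 1, "pleurodont": 2})
    tree4 = LabeledTree.from_newick(newick)
    tree4.label_clades(
        {"chameleon": cham + agam + pleu, "agamid": agam, "pleurodont": pleu},
        class_ids={"chameleon": 1, "agamid": 2, "pleurodont": 3},
    )

    # Time tree: same topology, clade crowns at 60 MY, splits 100/160/312.
    def timed(labels, crown):
        return balanced_clade_tree(labels, crown)

    chron_newick = (
        f"((({timed(cham, 60)}:40,{timed(agam, 60)}:40):60,"
        f"{timed(pleu, 60)}:100):152,{timed(mamm, 60)}:252);"
    )
    chron = Chronogram.from_newick(chron_newick)
    chron.label_clades({"acrodont": cham + agam + pleu, "pleurodont": pleu},
                       class_ids={"acrodont": 1, "pleurodont": 2})
    chron4 = Chronogram.from_newick(chron_newick)
    chron4.label_clades(
        {"chameleon": cham + agam + pleu, "agamid": agam, "pleurodont": pleu},
        class_ids={"chameleon": 1, "agamid": 2, "pleurodont": 3},
    )
    return StudyFixture(tree2=tree2, tree3=tree3, tree4=tree4,
                        chronogram=chron, chronogram4=chron4,
                        clades=clades, seed=seed)


# --------------------------------------------------------------- CTMC core


def _draw_path(state: int, Q: np.ndarray, t: float, rng,
               force_first: bool = False) -> tuple[int, int]:
    """Exact CTMC endpoint after time t; returns (end state, n_events).

    ``force_first`` conditions the path on at least one event: the first
    waiting time is drawn from Exp(q) truncated to [0, t], the remainder is
    unconditional.
    """
    cur = state
    remaining = t
    events = 0
    first = force_first
    while True:
        q = -Q[cur, cur]
        if q <= 0:
            break
        if first:
            u = rng.random()
            wait = -math.log1p(-u * (1.0 - math.exp(-q * remaining))) / q
            first = False
        else:
            wait = rng.exponential(1.0 / q)
        if wait >= remaining:
            break
        remaining -= wait
        probs = Q[cur].copy()
        probs[cur] = 0.0
        probs /= q
        cur = int(rng.choice(len(probs), p=probs))
        events += 1
    return cur, events


def _simulate_states(
    arrays, Q_of_edge, root_freq, n_sites, rng, forced_edges=None,
    forced_sites=None,
):
    """Evolve n_sites independent characters down the tree.

    Returns (leaf_states (n_leaves, n_sites), events_per_edge dict
    edge → (n_sites,) event counts).
    """
    forced_edges = forced_edges or set()
    if forced_sites is None:
        forced_sites = np.zeros(n_sites, dtype=bool)
    n_states = len(root_freq)
    states = {arrays.root: rng.choice(n_states, size=n_sites, p=root_freq)}
    n_leaves = int((arrays.leaf_index >= 0).sum())
    leaf_states = np.zeros((n_leaves, n_sites), dtype=int)
    events = {}
    for node in arrays.postorder[::-1]:
        if node == arrays.root:
            if arrays.leaf_index[node] >= 0:
                leaf_states[arrays.leaf_index[node]] = states[node]
            continue
        parent_states = states[arrays.parent[node]]
        Q = Q_of_edge(int(node))
        t = arrays.lengths[node]
        out = np.empty(n_sites, dtype=int)
        ev = np.zeros(n_sites, dtype=int)
        force_here = int(node) in forced_edges
        for s in range(n_sites):
            out[s], ev[s] = _draw_path(
                int(parent_states[s]), Q if not callable(Q) else Q(s), t, rng,
                force_first=force_here and forced_sites[s],
            )
        states[node] = out
        events[int(node)] = ev
        if arrays.leaf_index[node] >= 0:
            leaf_states[arrays.leaf_index[node]] = out
    return leaf_states, events


# --------------------------------------------------------------- simulators


def simulate_codon_alignment(
    tree: LabeledTree,
    spec: CodonModelSpec,
    n_codons: int,
    seed: int,
) -> CodonAlignment:
    """Evolve a codon alignment under branch-class-specific ω."""
    arrays = tree.to_arrays()
    rng = np.random.default_rng(seed)
    Qs = [
        _gy94_q(spec.kappa, float(w), spec.codon_frequencies)
        for w in spec.omega_by_class
    ]
    if spec.n_classes > 1 and tree.n_classes != spec.n_classes:
        raise ValueError(
            f"tree has {tree.n_classes} branch classes but spec has "
            f"{spec.n_classes} omega classes"
        )

    def q_of_edge(e):
        return Qs[0] if spec.n_classes == 1 else Qs[arrays.classes[e]]

    leaf_states, _ = _simulate_states(
        arrays, q_of_edge, spec.codon_frequencies, n_codons, rng
    )
    rows = [
        "".join(SENSE_CODONS[s] for s in leaf_states[i])
        for i in range(len(arrays.taxa))
    ]
    return CodonAlignment(list(arrays.taxa), rows)


def simulate_type1(
    n_sites: int,
    theta: float = THETA_PRESETS[0],
    alpha: float = 0.5,
    d1: float = 2.0,
    d2: float = 2.0,
    seed: int = 0,
    n_planted: int = 0,
    planted_rates: tuple[float, float] = (3.0, 0.1),
) -> tuple[SiteCountTable, np.ndarray]:
    """Draw per-site cluster substitution counts from the Type-I model.

    With probability θ a site is state F (independent gamma rates per
    cluster), else state S (shared rate); counts are Poisson(rate × D_k).
    ``n_planted`` sites (labelled "P") instead get fixed fast/slow rates —
    a strong, localizable divergence signal for planted-recovery tests.
    Returns (table, truth labels in {"S","F","P"}).
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = np.where(rng.random(n_sites) < theta, "F", "S").astype(object)
    if n_planted:
        planted = rng.choice(n_sites, size=n_planted, replace=False)
        truth[planted] = "P"
    lam1 = np.empty(n_sites)
    lam2 = np.empty(n_sites)
    for i, state in enumerate(truth):
        if state == "S":
            lam1[i] = lam2[i] = rng.gamma(alpha, 1.0 / alpha)
        elif state == "F":
            lam1[i] = rng.gamma(alpha, 1.0 / alpha)
            lam2[i] = rng.gamma(alpha, 1.0 / alpha)
        else:
            lam1[i], lam2[i] = planted_rates
    c1 = rng.poisson(d1 * lam1)
    c2 = rng.poisson(d2 * lam2)
    table = SiteCountTable(c1, c2, np.arange(n_sites))
    return table, truth.astype(str)


def simulate_type1_alignment(
    tree: LabeledTree,
    cluster_taxa: set[str],
    n_sites: int,
    theta: float = THETA_PRESETS[0],
    alpha: float = 0.5,
    seed: int = 0,
    base_rate: float = 1.0,
) -> tuple[ProteinAlignment, np.ndarray]:
    """Evolve a protein alignment with a Type-I rate shift in one cluster.

    Every site draws a gamma(α, α) rate; a θ fraction of sites (state F)
    additionally draws an independent gamma rate for the branches inside
    ``cluster_taxa``'s subtree, decoupling that cluster's evolutionary rate
    at those sites.  Residues evolve under a uniform-frequency exchange
    process.  Returns (alignment, truth labels in {"S", "F"}).
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    arrays = tree.to_arrays()
    rng = np.random.default_rng(seed)
    mrca = tree.tree.mrca(taxon_labels=sorted(cluster_taxa))
    nodes = list(tree.tree.postorder_node_iter())
    node_id = {id(n): i for i, n in enumerate(nodes)}
    cluster_edges = {node_id[id(n)] for n in mrca.preorder_iter()
                    if n is not mrca}
    cluster_edges.add(node_id[id(mrca)])

    truth = np.where(rng.random(n_sites) < theta, "F", "S")
    lam_shared = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
    lam_cluster = np.where(
        truth == "F", rng.gamma(alpha, 1.0 / alpha, size=n_sites), lam_shared
    )
    Q = profile_substitution_model(np.full(20, 1 / 20))

    n_leaves = int((arrays.leaf_index >= 0).sum())
    leaf_states = np.zeros((n_leaves, n_sites), dtype=int)
    states = {arrays.root: rng.integers(0, 20, size=n_sites)}
    for node in arrays.postorder[::-1]:
        if node == arrays.root:
            continue
        parent_states = states[arrays.parent[node]]
        lam = lam_cluster if int(node) in cluster_edges else lam_shared
        t_e = arrays.lengths[node] * base_rate
        out = np.empty(n_sites, dtype=int)
        for s in range(n_sites):
            out[s], _ = _draw_path(int(parent_states[s]), Q,
                                   t_e * lam[s], rng)
        states[node] = out
        if arrays.leaf_index[node] >= 0:
            leaf_states[arrays.leaf_index[node]] = out
    rows = ["".join(AMINO_ACIDS[s] for s in leaf_states[i])
            for i in range(len(arrays.taxa))]
    return ProteinAlignment(list(arrays.taxa), rows), truth


def simulate_type2(
    n_sites: int,
    theta2: float = 0.2,
    n_taxa_per_cluster: int = 4,
    property_partition: dict[str, str] | None = None,
    seed: int = 0,
    background_fractions: tuple[float, float, float] = (0.55, 0.05, 0.40),
) -> tuple[ProteinAlignment, LabeledTree, ClusterPair, np.ndarray]:
    """Plant conserved-but-different radical sites between two clusters.

    A θ_II fraction of sites is fixed within each cluster for residues from
    different property groups; background sites are fixed-same, fixed at
    two random residues, or freely variable, in the given fractions.
    Returns (alignment, matching tree, cluster pair, truth labels in
    {"T2", "same", "diff", "var"}).
    """
    partition = property_partition or DEFAULT_PROPERTY_PARTITION
    groups = sorted(partition)
    rng = np.random.default_rng(seed)
    n = n_taxa_per_cluster
    taxa1 = [f"one{i+1}" for i in range(n)]
    taxa2 = [f"two{i+1}" for i in range(n)]
    p_same, p_diff, p_var = background_fractions

    cols1, cols2, truth = [], [], []
    for _ in range(n_sites):
        u = rng.random()
        if u < theta2:
            g1, g2 = rng.choice(len(groups), size=2, replace=False)
            r1 = partition[groups[g1]][rng.integers(len(partition[groups[g1]]))]
            r2 = partition[groups[g2]][rng.integers(len(partition[groups[g2]]))]
            cols1.append(r1 * n)
            cols2.append(r2 * n)
            truth.append("T2")
        else:
            v = rng.random()
            if v < p_same:
                r = AMINO_ACIDS[rng.integers(20)]
                cols1.append(r * n)
                cols2.append(r * n)
                truth.append("same")
            elif v < p_same + p_diff:
                i, j = rng.choice(20, size=2, replace=False)
                cols1.append(AMINO_ACIDS[i] * n)
                cols2.append(AMINO_ACIDS[j] * n)
                truth.append("diff")
            else:
                pool = rng.choice(20, size=4, replace=False)
                cols1.append("".join(
                    AMINO_ACIDS[pool[rng.integers(4)]] for _ in range(n)))
                cols2.append("".join(
                    AMINO_ACIDS[pool[rng.integers(4)]] for _ in range(n)))
                truth.append("var")
    rows1 = ["".join(col[i] for col in cols1) for i in range(n)]
    rows2 = ["".join(col[i] for col in cols2) for i in range(n)]
    aln = ProteinAlignment(taxa1 + taxa2, rows1 + rows2)
    newick = (
        f"({balanced_clade_tree(taxa1, 0.3)}:0.2,"
        f"{balanced_clade_tree(taxa2, 0.3)}:0.2);"
    )
    tree = LabeledTree.from_newick(newick)
    pair = ClusterPair("one", set(taxa1), "two", set(taxa2))
    return aln, tree, pair, np.array(truth)


def simulate_convergent_alignment(
    tree: LabeledTree,
    scenario: ConvergenceScenario,
    profiles: ProfileSet,
    fraction_convergent: float,
    n_sites: int,
    seed: int,
    background_profile: int = 8,   # "negative" in the default profile set
    convergent_profile: int = 6,   # "positive"
) -> tuple[ProteinAlignment, np.ndarray]:
    """Evolve a protein alignment with convergent profile shifts.

    Convergent sites use the convergent profile on foreground subtrees with
    a forced (≥1 event) change on each transition branch; the rest evolve
    under the background profile throughout.  Returns (alignment, truth
    boolean array over sites).
    """
    arrays = tree.to_arrays()
    rng = np.random.default_rng(seed)
    truth = rng.random(n_sites) < fraction_convergent
    Qa = profile_substitution_model(profiles.frequencies[background_profile])
    Qc = profile_substitution_model(profiles.frequencies[convergent_profile])
    fg = scenario.foreground_edges | scenario.transition_edges

    def q_of_edge(e):
        if e in fg:
            def per_site(s):
                return Qc if truth[s] else Qa
            return per_site
        return Qa

    leaf_states, _ = _simulate_states(
        arrays, q_of_edge, profiles.frequencies[background_profile], n_sites,
        rng, forced_edges=scenario.transition_edges, forced_sites=truth,
    )
    rows = ["".join(AMINO_ACIDS[s] for s in leaf_states[i])
            for i in range(len(arrays.taxa))]
    return ProteinAlignment(list(arrays.taxa), rows), truth


def simulate_clock_alignment(
    chron: Chronogram,
    rates: np.ndarray,
    gtr: GTRSpec,
    n_sites: int,
    seed: int,
) -> Alignment:
    """Evolve nucleotides on a chronogram with clade-specific clock rates."""
    rates = np.atleast_1d(np.asarray(rates, float))
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    arrays = chron.to_arrays()
    durations = chron.durations()
    rng = np.random.default_rng(seed)
    Q = gtr_matrix(gtr)

    # Scale branch lengths into the arrays so the generic walker applies.
    sim_arrays = chron.to_arrays()
    for e in sim_arrays.edges:
        cls = sim_arrays.classes[e] if len(rates) > 1 else 0
        sim_arrays.lengths[e] = rates[cls] * durations[e]

    leaf_states, _ = _simulate_states(
        sim_arrays, lambda e: Q, gtr.frequencies, n_sites, rng
    )
    rows = ["".join(NUCLEOTIDES[s] for s in leaf_states[i])
            for i in range(len(sim_arrays.taxa))]
    return Alignment(list(sim_arrays.taxa), rows)
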