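"""Convergent amino-acid profile-shift detection (PCOC-style).

Each site evolves under an amino-acid frequency profile via an F81-type
process (rate into state j proportional to π_j, scaled to unit rate).  For
a scenario naming ≥2 independent foreground (putatively convergent) clades,
four models are scored per column:

* null — one profile on every branch, and at least one transition branch
  (the stem of a foreground clade) carries no substitution;
* PC (profile change) — foreground subtrees use a different profile than
  the background, with at least one eventless transition branch;
* OC (one change) — one profile everywhere, but every transition branch
  carries at least one substitution;
* PCOC — profile change and a substitution on every transition branch.

The four models are disjoint path classes, so with equal priors their
joint posteriors (``pp_joint``) sum to 1 per site.  The headline per-model
scores ``pp_PC``, ``pp_OC`` and ``pp_PCOC``, used for detection thresholds,
follow the convergence-detection convention of scoring each model pairwise
against the unconstrained single-profile null (equal prior two-model
Bayes); the joint vector is reported alongside.  The "all transition
branches substituted" likelihood subtracts the zero-event path from the
transition matrix on those branches: P̃_ij(t) = P_ij(t) − δ_ij e^{−q_i t};
the complementary classes subtract it from the unconstrained likelihood.
Likelihoods average over profile assignments (uniform over profiles, and
over ordered pairs c ≠ a when a shift is present).  Gaps and ambiguities
are missing data.  A per-site rate multiplier over a log-spaced grid is
treated as a nuisance and marginalized with a uniform prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pruning import ReversibleEigen
from .functional_divergence import AMINO_ACIDS
from .seq_prep import ProteinAlignment
from .trees import LabeledTree

__all__ = [
    "ProfileSet",
    "ConvergenceScenario",
    "SiteConvergenceResult",
    "default_profiles",
    "profile_substitution_model",
    "site_posteriors",
    "detect_convergent_sites",
    "threshold_summary",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Log-spaced per-site rate multipliers tried for the shared site rate.
RATE_GRID = np.geomspace(0.25, 8.0, 7)


@dataclass
class ProfileSet:
    """K amino-acid frequency vectors (rows of a (K, 20) matrix)."""

    labels: list[str]
    frequencies: np.ndarray

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, float)
        if self.frequencies.shape != (len(self.labels), 20):
            raise ValueError("profile matrix must be (K, 20)")
        if np.any(self.frequencies <= 0):
            raise ValueError("profiles must be strictly positive "
                             "(Dirichlet-smooth upstream)")
        sums = self.frequencies.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-12):
            raise ValueError("each profile must sum to 1")

    @property
    def k(self) -> int:
        return len(self.labels)


#: Physicochemical subgroups behind the default K=10 profile set.  Peaked
#: (rather than mixed) profiles keep the null model from absorbing genuine
#: two-state convergent columns.
PROFILE_SUBGROUPS: dict[str, str] = {
    "aliphatic": "AVLIM",
    "aromatic": "FWY",
    "proline-glycine": "PG",
    "hydroxyl": "ST",
    "cysteine": "C",
    "amide": "NQ",
    "positive": "KR",
    "histidine": "H",
    "negative": "DE",
}


def default_profiles(
    subgroups: dict[str, str] | None = None, pseudocount: float = 0.01
) -> ProfileSet:
    """Default profile set: one peaked profile per physicochemical subgroup
    plus a uniform catch-all, Dirichlet-smoothed with ``pseudocount``."""
    subgroups = subgroups or PROFILE_SUBGROUPS
    labels, rows = [], []
    for name, members in subgroups.items():
        v = np.zeros(20)
        for aa in members:
            v[_AA_INDEX[aa]] = 1.0 / len(members)
        v = v + pseudocount
        labels.append(name)
        rows.append(v / v.sum())
    labels.append("uniform")
    rows.append(np.full(20, 1 / 20))
    return ProfileSet(labels, np.array(rows))


def profile_substitution_model(profile: np.ndarray) -> np.ndarray:
    """F81-style 20×20 generator with stationary distribution = profile."""
    pi = np.asarray(profile, float)
    if np.any(pi <= 0):
        raise ValueError("profile entries must be > 0")
    Q = np.tile(pi, (20, 1))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = 1.0 - float(np.sum(pi**2))
    return Q / scale


@dataclass
class ConvergenceScenario:
    """Foreground clades, their transition (stem) branches, background rest.

    Built against a specific tree: edge ids refer to that tree's postorder
    array form.
    """

    tree: LabeledTree
    foreground_clades: dict[str, set[str]]
    foreground_edges: set[int] = field(default_factory=set)
    transition_edges: set[int] = field(default_factory=set)

    def __post_init__(self):
        clades = {k: set(v) for k, v in self.foreground_clades.items()}
        if len(clades) < 2:
            raise ValueError("convergence needs >= 2 independent foreground "
                             "clades")
        all_fg = [t for s in clades.values() for t in s]
        if len(all_fg) != len(set(all_fg)):
            raise ValueError("foreground clades must be disjoint")
        arrays = self.tree.to_arrays()
        nodes = list(self.tree.tree.postorder_node_iter())
        node_id = {id(n): i for i, n in enumerate(nodes)}
        for name, taxa in clades.items():
            if not self.tree.is_monophyletic(taxa):
                raise ValueError(f"foreground clade {name!r} not monophyletic")
            mrca = self.tree.tree.mrca(taxon_labels=sorted(taxa))
            mid = node_id[id(mrca)]
            if arrays.parent[mid] < 0:
                raise ValueError(f"foreground clade {name!r} is the whole tree")
            self.transition_edges.add(mid)
            for node in mrca.preorder_iter():
                i = node_id[id(node)]
                if i != mid:
                    self.foreground_edges.add(i)
        self.foreground_clades = clades


@dataclass
class SiteConvergenceResult:
    """Per-column convergence scores.

    ``pp_pc``/``pp_oc``/``pp_pcoc`` are each model's posterior against the
    unconstrained null (pairwise, equal priors); ``pp_joint`` is the
    posterior over the four disjoint model classes (sums to 1).
    """

    column: int
    pp_pc: float
    pp_oc: float
    pp_pcoc: float
    pp_joint: tuple[float, float, float, float]  # null, PC, OC, PCOC
    best_profile_pair: tuple[str, str]
    rate: float
    flags: list[str] = field(default_factory=list)


# ------------------------------------------------------------ likelihoods


def _aa_state_matrix(aln: ProteinAlignment) -> np.ndarray:
    out = np.full((aln.n_taxa, aln.n_columns), -1, dtype=int)
    for r, row in enumerate(aln.rows):
        for c, ch in enumerate(row):
            out[r, c] = _AA_INDEX.get(ch, -1)
    return out


def _batched_loglik(arrays, states_cols, P_per_edge, root_freq):
    """Column × hypothesis log-likelihoods.

    ``states_cols``: (n_taxa, C); ``P_per_edge``: edge → (H, 20, 20);
    ``root_freq``: (H, 20).  Returns (C, H).
    """
    C = states_cols.shape[1]
    H = root_freq.shape[0]
    partial: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    for node in arrays.postorder:
        kids = arrays.children[node]
        if not kids:
            s = states_cols[arrays.leaf_index[node]]
            p = np.zeros((C, 1, 20))
            obs = s >= 0
            p[obs, 0, s[obs]] = 1.0
            p[~obs, 0, :] = 1.0
            partial[node] = np.broadcast_to(p, (C, H, 20))
            logscale[node] = np.zeros((C, H))
            continue
        acc = np.ones((C, H, 20))
        sc = np.zeros((C, H))
        for k in kids:
            down = np.einsum("chs,hts->cht", partial[k], P_per_edge[k])
            acc = acc * down
            sc = sc + logscale[k]
            del partial[k], logscale[k]
        m = acc.max(axis=2)
        m = np.where(m > 0, m, 1.0)
        partial[node] = acc / m[:, :, None]
        logscale[node] = sc + np.log(m)
    root = arrays.root
    lik = np.einsum("chs,hs->ch", partial[root], root_freq)
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale[root]


class _ModelBank:
    """Precomputed transition matrices per (profile, edge, rate)."""

    def __init__(self, arrays, profiles: ProfileSet, rates=RATE_GRID):
        self.arrays = arrays
        self.profiles = profiles
        self.rates = np.asarray(rates, float)
        self.eigens = []
        self.qdiag = []
        for k in range(profiles.k):
            Q = profile_substitution_model(profiles.frequencies[k])
            self.eigens.append(
                ReversibleEigen.from_q(Q, profiles.frequencies[k])
            )
            self.qdiag.append(-np.diag(Q))
        # P[r][k][edge] and forced variant
        self.P = {}
        self.P_forced = {}
        for ri, r in enumerate(self.rates):
            for k in range(profiles.k):
                for e in arrays.edges:
                    t = r * arrays.lengths[e]
                    P = self.eigens[k].transition(t)
                    self.P[ri, k, int(e)] = P
                    Pf = P.copy()
                    np.fill_diagonal(
                        Pf, np.diag(P) - np.exp(-self.qdiag[k] * t)
                    )
                    self.P_forced[ri, k, int(e)] = np.clip(Pf, 0.0, None)


def _hypotheses(scenario, profiles: ProfileSet):
    """Rows: (model, background profile, foreground profile or −1)."""
    K = profiles.k
    hyp = []
    for a in range(K):
        hyp.append(("null", a, -1))
    for a in range(K):
        for c in range(K):
            if c != a:
                hyp.append(("PC", a, c))
    for a in range(K):
        hyp.append(("OC", a, -1))
    for a in range(K):
        for c in range(K):
            if c != a:
                hyp.append(("PCOC", a, c))
    return hyp


def _stack_edges(bank: _ModelBank, scenario, hyp, rate_index: int):
    arrays = bank.arrays
    H = len(hyp)
    P_per_edge = {}
    for e in arrays.edges:
        e = int(e)
        fg = e in scenario.foreground_edges
        trans = e in scenario.transition_edges
        mats = np.empty((H, 20, 20))
        for h, (model, a, c) in enumerate(hyp):
            prof = a
            if model in ("PC", "PCOC") and (fg or trans):
                prof = c
            forced = trans and model in ("OC", "PCOC")
            key = (rate_index, prof, e)
            mats[h] = bank.P_forced[key] if forced else bank.P[key]
        P_per_edge[e] = mats
    root_freq = np.array([bank.profiles.frequencies[a] for _, a, _ in hyp])
    return P_per_edge, root_freq


def site_posteriors(
    aln: ProteinAlignment,
    tree: LabeledTree,
    scenario: ConvergenceScenario,
    profiles: ProfileSet | None = None,
    columns: np.ndarray | None = None,
) -> list[SiteConvergenceResult]:
    """Posterior probabilities of {null, PC, OC, PCOC} for each column."""
    profiles = profiles or default_profiles()
    if set(aln.taxa) != set(tree.taxa):
        raise ValueError("alignment and tree taxa differ")
    arrays = tree.to_arrays(taxa_order=aln.taxa)
    states = _aa_state_matrix(aln)
    if columns is None:
        columns = np.arange(aln.n_columns)
    columns = np.asarray(columns, int)
    states = states[:, columns]
    C = states.shape[1]
    bank = _ModelBank(arrays, profiles)
    hyp = _hypotheses(scenario, profiles)
    models = np.array([h[0] for h in hyp])
    null_rows = np.flatnonzero(models == "null")
    pc_rows = np.flatnonzero(models == "PC")
    oc_rows = np.flatnonzero(models == "OC")
    pcoc_rows = np.flatnonzero(models == "PCOC")

    # Per rate on the grid: the four disjoint-model marginals plus the
    # unconstrained single-profile null M0; the rate is a nuisance,
    # marginalized with a uniform prior over the grid.
    n_rates = len(bank.rates)
    model_ll = np.full((C, n_rates, 4), -np.inf)
    m0_ll = np.full((C, n_rates), -np.inf)
    best_pair = np.zeros((C, n_rates), dtype=int)
    for ri in range(n_rates):
        P_per_edge, root_freq = _stack_edges(bank, scenario, hyp, ri)
        ll = _batched_loglik(arrays, states, P_per_edge, root_freq)
        # "Some stem eventless" variants subtract the all-stems-substituted
        # likelihood from the unconstrained one (null/OC rows share profile
        # order a; PC/PCOC rows share pair order (a, c)).
        ll_null = ll[:, null_rows] + _log1mexp(ll[:, oc_rows] - ll[:, null_rows])
        ll_pc = ll[:, pc_rows] + _log1mexp(ll[:, pcoc_rows] - ll[:, pc_rows])
        m0_ll[:, ri] = _logmeanexp(ll[:, null_rows], axis=1)
        model_ll[:, ri, 0] = _logmeanexp(ll_null, axis=1)
        model_ll[:, ri, 1] = _logmeanexp(ll_pc, axis=1)
        model_ll[:, ri, 2] = _logmeanexp(ll[:, oc_rows], axis=1)
        model_ll[:, ri, 3] = _logmeanexp(ll[:, pcoc_rows], axis=1)
        best_pair[:, ri] = pcoc_rows[np.argmax(ll[:, pcoc_rows], axis=1)]

    marg = _logsumexp(model_ll, axis=1) - np.log(n_rates)      # (C, 4)
    m0 = _logsumexp(m0_ll, axis=1) - np.log(n_rates)           # (C,)
    joint = np.exp(marg - _logsumexp(marg, axis=1)[:, None])
    # pairwise-vs-null posteriors (equal priors): sigmoid of the log ratio
    pair_pp = 1.0 / (1.0 + np.exp(np.clip(m0[:, None] - marg[:, 1:], -700, 700)))
    rate_idx = np.argmax(_logsumexp(model_ll, axis=2), axis=1)

    flags_by_clade = _missing_clades(aln, scenario, columns)
    results: list[SiteConvergenceResult] = []
    for ci in range(C):
        ri = int(rate_idx[ci])
        _, a, c = hyp[best_pair[ci, ri]]
        results.append(SiteConvergenceResult(
            column=int(columns[ci]),
            pp_pc=float(pair_pp[ci, 0]),
            pp_oc=float(pair_pp[ci, 1]),
            pp_pcoc=float(pair_pp[ci, 2]),
            pp_joint=tuple(float(v) for v in joint[ci]),
            best_profile_pair=(profiles.labels[a], profiles.labels[c]),
            rate=float(bank.rates[ri]),
            flags=flags_by_clade.get(int(columns[ci]), []),
        ))
    return results


def _log1mexp(x):
    """log(1 − e^x) for x ≤ 0, safe near 0 (clamped to a tiny remainder)."""
    x = np.minimum(x, -1e-12)
    return np.where(x > -0.693, np.log(-np.expm1(x)), np.log1p(-np.exp(x)))


def _logmeanexp(x, axis):
    return _logsumexp(x, axis=axis) - np.log(x.shape[axis])


def _logsumexp(x, axis):
    m = np.max(x, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(x - m), axis=axis, keepdims=True))).squeeze(
        axis
    )


def _missing_clades(aln, scenario, columns):
    """Columns that are entirely gap/ambiguous within a foreground clade."""
    flags: dict[int, list[str]] = {}
    states = _aa_state_matrix(aln)
    taxon_row = {t: i for i, t in enumerate(aln.taxa)}
    for name, taxa in scenario.foreground_clades.items():
        rows = [taxon_row[t] for t in sorted(taxa)]
        empty = np.all(states[rows] < 0, axis=0)
        for c in columns[empty[columns]]:
            flags.setdefault(int(c), []).append(f"no data in {name}")
    return flags


def detect_convergent_sites(
    aln: ProteinAlignment,
    tree: LabeledTree,
    scenario: ConvergenceScenario,
    profiles: ProfileSet | None = None,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-column posteriors with a convergence call at ``threshold``."""
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must be in (0.5, 1)")
    res = site_posteriors(aln, tree, scenario, profiles)
    df = pd.DataFrame(
        {
            "column": [r.column for r in res],
            "pp_PC": [r.pp_pc for r in res],
            "pp_OC": [r.pp_oc for r in res],
            "pp_PCOC": [r.pp_pcoc for r in res],
            "pp_joint_null": [r.pp_joint[0] for r in res],
            "pp_joint_PCOC": [r.pp_joint[3] for r in res],
            "best_background": [r.best_profile_pair[0] for r in res],
            "best_convergent": [r.best_profile_pair[1] for r in res],
            "rate": [r.rate for r in res],
            "flags": [";".join(r.flags) for r in res],
        }
    )
    df["convergent"] = df["pp_PCOC"] >= threshold
    return df


def threshold_summary(
    df: pd.DataFrame, aln: ProteinAlignment, thresholds=(0.8, 0.9, 0.95)
) -> pd.DataFrame:
    """Counts of convergent sites per pp tier, as counts and as percent of
    the average ungapped sequence length."""
    avg_len = float(np.mean([
        sum(ch in AMINO_ACIDS for ch in row) for row in aln.rows
    ]))
    rows = []
    for t in thresholds:
        n = int((df["pp_PCOC"] >= t).sum())
        rows.append({
            "threshold": t,
            "n_sites": n,
            "pct_of_avg_length": 100.0 * n / avg_len if avg_len else np.nan,
        })
    return pd.DataFrame(rows)
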