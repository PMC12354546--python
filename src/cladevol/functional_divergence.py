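"""Type-I and Type-II functional divergence between two monophyletic clusters.

Type-I divergence is a site-specific decoupling of evolutionary rates after
a split: with probability θ a site draws independent gamma rates in the two
clusters, otherwise it shares one rate.  Per-cluster substitution counts per
site (minimum parsimony changes on each cluster's subtree) are modelled as
Poisson mixtures over the gamma rate — negative binomial marginally, with a
closed-form shared-rate bivariate form — and (θ, α, D₁, D₂) are estimated
by maximum likelihood.  θ = 0 is tested by LRT (χ²₁ by default, optional
½χ²₀+½χ²₁ boundary mixture), and per-site posteriors of the independent-rate
state rank candidate divergence-related sites; the empirical posterior
cutoff removes top sites until significance is lost.

Type-II divergence is "conserved but different": sites fixed within each
cluster for physicochemically radical different residues.  The estimator
here is a documented stand-in (not a reimplementation of Gu's 2006 model):
sites are classified into fixed-same / fixed-similar / fixed-radical /
variable, and θ_II is the weight of a point-mass-on-radical component over
a background multinomial whose radical share among fixed-different sites is
pinned to the null expectation from residue frequencies (which makes the
mixture identifiable).  Significance is a Z-test on θ_II/SE.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, norm

from .seq_prep import ProteinAlignment
from .trees import LabeledTree

__all__ = [
    "DEFAULT_PROPERTY_PARTITION",
    "ClusterPair",
    "SiteCountTable",
    "ThetaEstimate",
    "Type2Result",
    "site_substitution_counts",
    "count_table",
    "fit_type1",
    "empirical_pp_cutoff",
    "fit_type2",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Physicochemical property groups used to call radical replacements.
DEFAULT_PROPERTY_PARTITION: dict[str, str] = {
    "nonpolar": "AVLIMFWP",
    "polar": "GSTCYNQ",
    "positive": "KRH",
    "negative": "DE",
}


@dataclass
class ClusterPair:
    """Two disjoint monophyletic taxon sets with their subtrees."""

    name1: str
    taxa1: set[str]
    name2: str
    taxa2: set[str]

    def __post_init__(self):
        self.taxa1, self.taxa2 = set(self.taxa1), set(self.taxa2)
        if self.taxa1 & self.taxa2:
            raise ValueError("clusters must be disjoint")
        for name, taxa in ((self.name1, self.taxa1), (self.name2, self.taxa2)):
            if len(taxa) < 3:
                raise ValueError(
                    f"cluster {name!r} has {len(taxa)} taxa; need >= 3 for "
                    "within-cluster rate signal"
                )

    def validate_monophyly(self, tree: LabeledTree) -> None:
        for name, taxa in ((self.name1, self.taxa1), (self.name2, self.taxa2)):
            if not tree.is_monophyletic(taxa):
                raise ValueError(f"cluster {name!r} is not monophyletic")


@dataclass
class SiteCountTable:
    """Per-site minimum substitution counts for the two clusters.

    ``site_index`` maps rows back to 0-based columns of the original
    alignment (gap columns are excluded before counting).
    """

    counts1: np.ndarray
    counts2: np.ndarray
    site_index: np.ndarray

    def __post_init__(self):
        self.counts1 = np.asarray(self.counts1, dtype=int)
        self.counts2 = np.asarray(self.counts2, dtype=int)
        self.site_index = np.asarray(self.site_index, dtype=int)
        if np.any(self.counts1 < 0) or np.any(self.counts2 < 0):
            raise ValueError("negative substitution count")
        if not len(self.counts1) == len(self.counts2) == len(self.site_index):
            raise ValueError("count/index length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.counts1)

    def drop(self, positions: np.ndarray) -> "SiteCountTable":
        keep = np.setdiff1d(np.arange(self.n_sites), positions)
        return SiteCountTable(
            self.counts1[keep], self.counts2[keep], self.site_index[keep]
        )


@dataclass
class ThetaEstimate:
    """ML estimate of the Type-I coefficient with test and site posteriors."""

    theta: float
    se: float
    alpha: float
    d1: float
    d2: float
    lnl: float
    lnl_null: float
    lrt: float
    p_value: float
    pp: np.ndarray
    site_index: np.ndarray
    converged: bool = True


@dataclass
class Type2Result:
    theta2: float
    se: float
    z: float
    p_value: float
    radical_sites: list[int]
    category_counts: dict[str, int]
    excluded_ties: int = 0


# -------------------------------------------------------- parsimony counts


def _sankoff_min_changes(arrays, states: np.ndarray, n_states: int) -> int:
    """Minimum substitutions for one column (unit-cost Sankoff DP).

    Handles multifurcations exactly; missing states (−1) contribute zero
    cost for any assignment.
    """
    INF = 10**6
    cost = {}
    for node in arrays.postorder:
        kids = arrays.children[node]
        if not kids:
            s = states[arrays.leaf_index[node]]
            c = np.full(n_states, INF if s >= 0 else 0)
            if s >= 0:
                c[s] = 0
            cost[node] = c
            continue
        total = np.zeros(n_states)
        for k in kids:
            ck = cost[k]
            # min over child state: stay (cost ck) or switch (min ck + 1)
            total += np.minimum(ck, ck.min() + 1)
        cost[node] = total
    return int(cost[arrays.root].min())


def _root_states(arrays, states: np.ndarray, n_states: int) -> list[int]:
    """All root states achieving the parsimony minimum (for tie detection)."""
    INF = 10**6
    cost = {}
    for node in arrays.postorder:
        kids = arrays.children[node]
        if not kids:
            s = states[arrays.leaf_index[node]]
            c = np.full(n_states, INF if s >= 0 else 0)
            if s >= 0:
                c[s] = 0
            cost[node] = c
        else:
            total = np.zeros(n_states)
            for k in kids:
                ck = cost[k]
                total += np.minimum(ck, ck.min() + 1)
            cost[node] = total
    c = cost[arrays.root]
    return [int(i) for i in np.flatnonzero(c == c.min())]


def _aa_states(aln: ProteinAlignment) -> np.ndarray:
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    out = np.full((aln.n_taxa, aln.n_columns), -1, dtype=int)
    for r, row in enumerate(aln.rows):
        for c, ch in enumerate(row):
            out[r, c] = idx.get(ch, -1)
    return out


def gap_free_columns(aln: ProteinAlignment, taxa: set[str]) -> np.ndarray:
    """0-based columns with no gap or ambiguity in any of ``taxa``."""
    rows = [aln.row(t) for t in sorted(taxa)]
    ok = []
    for c in range(aln.n_columns):
        col = [r[c] for r in rows]
        if all(ch in AMINO_ACIDS for ch in col):
            ok.append(c)
    return np.array(ok, dtype=int)


def site_substitution_counts(
    aln: ProteinAlignment,
    tree: LabeledTree,
    cluster: set[str],
    columns: np.ndarray | None = None,
) -> np.ndarray:
    """Per-column minimum change counts on the cluster's subtree."""
    if len(cluster) < 3:
        raise ValueError("cluster needs >= 3 taxa")
    sub = tree.subtree(cluster)
    order = sub.taxa
    arrays = sub.to_arrays(taxa_order=order)
    subaln = ProteinAlignment(order, [aln.row(t) for t in order])
    states = _aa_states(subaln)
    if columns is None:
        columns = np.arange(aln.n_columns)
    return np.array(
        [_sankoff_min_changes(arrays, states[:, c], 20) for c in columns],
        dtype=int,
    )


def count_table(
    aln: ProteinAlignment, tree: LabeledTree, pair: ClusterPair
) -> SiteCountTable:
    """Build the two-cluster count table over mutually gap-free columns."""
    pair.validate_monophyly(tree)
    cols = gap_free_columns(aln, pair.taxa1 | pair.taxa2)
    c1 = site_substitution_counts(aln, tree, pair.taxa1, cols)
    c2 = site_substitution_counts(aln, tree, pair.taxa2, cols)
    return SiteCountTable(c1, c2, cols)


# ----------------------------------------------------------- Type-I model


def _log_nb(x: np.ndarray, alpha: float, d: float) -> np.ndarray:
    """log P(X=x) for X|λ ~ Poisson(dλ), λ ~ Gamma(α, α)."""
    return (
        gammaln(alpha + x)
        - gammaln(alpha)
        - gammaln(x + 1.0)
        + alpha * math.log(alpha / (alpha + d))
        + x * math.log(d / (alpha + d))
    )


def _log_shared(x1, x2, alpha: float, d1: float, d2: float) -> np.ndarray:
    """Closed-form joint with a common gamma rate (bivariate NB)."""
    s = alpha + d1 + d2
    return (
        gammaln(alpha + x1 + x2)
        - gammaln(alpha)
        - gammaln(x1 + 1.0)
        - gammaln(x2 + 1.0)
        + alpha * math.log(alpha / s)
        + x1 * math.log(d1 / s)
        + x2 * math.log(d2 / s)
    )


def _type1_loglik(params, x1, x2, free_theta=True):
    if free_theta:
        theta, la, ld1, ld2 = params
    else:
        theta = 0.0
        la, ld1, ld2 = params
    alpha, d1, d2 = np.exp(la), np.exp(ld1), np.exp(ld2)
    logS = _log_shared(x1, x2, alpha, d1, d2)
    if theta <= 0:
        return float(np.sum(logS)), logS, logS
    logF = _log_nb(x1, alpha, d1) + _log_nb(x2, alpha, d2)
    both = np.stack(
        [np.log1p(-theta) + logS, np.log(theta) + logF]
    )
    site = logsumexp(both, axis=0)
    return float(np.sum(site)), logS, logF


def fit_type1(
    counts: SiteCountTable,
    boundary_mixture: bool = False,
    n_starts: int = 4,
    seed: int = 0,
) -> ThetaEstimate:
    """ML fit of the two-state rate-decoupling mixture.

    With probability θ a site's gamma rates are independent between the two
    clusters (state F), otherwise shared (state S).  Counts are Poisson
    given rate × D_k.  Maximizes over (θ, α, D₁, D₂); tests θ=0 by LRT;
    SE(θ) from observed-information curvature; per-site posteriors of F.
    """
    x1 = counts.counts1.astype(float)
    x2 = counts.counts2.astype(float)
    if x1.sum() == 0 or x2.sum() == 0:
        raise ValueError("all counts zero in one cluster: degenerate input")
    if counts.n_sites < 30:
        warnings.warn(f"only {counts.n_sites} sites; theta estimate unstable")

    m1 = max(x1.mean(), 0.05)
    m2 = max(x2.mean(), 0.05)

    def neg(params):
        lnl, _, _ = _type1_loglik(params, x1, x2)
        return -lnl

    def neg0(params):
        lnl, _, _ = _type1_loglik(params, x1, x2, free_theta=False)
        return -lnl

    rng = np.random.default_rng(seed)
    base = np.array([np.log(0.5), np.log(m1), np.log(m2)])
    res0 = minimize(neg0, base, method="Nelder-Mead",
                    options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
    lnl0 = -float(res0.fun)

    starts = [np.concatenate([[0.3], res0.x]),
              np.concatenate([[0.7], res0.x])]
    while len(starts) < n_starts:
        starts.append(np.concatenate([
            [rng.uniform(0.05, 0.95)],
            base + rng.normal(0, 0.5, size=3),
        ]))
    best = None
    bounds = [(1e-6, 1 - 1e-9), (np.log(1e-3), np.log(1e3)),
              (np.log(1e-4), np.log(1e4)), (np.log(1e-4), np.log(1e4))]
    for x0 in starts[:n_starts]:
        r = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                     options={"maxiter": 500, "ftol": 1e-12})
        if best is None or r.fun < best.fun:
            best = r
    theta = float(best.x[0])
    alpha, d1, d2 = np.exp(best.x[1:])
    lnl = -float(best.fun)
    if lnl < lnl0 - 1e-9:
        # the alternative contains the null: fall back to the null optimum
        theta, lnl = 0.0, lnl0
        alpha, d1, d2 = np.exp(res0.x)
        best_x = np.concatenate([[1e-6], res0.x])
    else:
        best_x = best.x

    stat = max(0.0, 2.0 * (lnl - lnl0))
    p = float(chi2.sf(stat, 1))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0

    se = _theta_se(best_x, x1, x2)

    _, logS, logF = _type1_loglik(
        np.concatenate([[max(theta, 1e-12)], np.log([alpha, d1, d2])]), x1, x2
    )
    if theta <= 0:
        pp = np.zeros(counts.n_sites)
    else:
        num = np.log(theta) + logF
        den = np.logaddexp(np.log1p(-theta) + logS, num)
        pp = np.exp(num - den)
    return ThetaEstimate(
        theta=theta, se=se, alpha=float(alpha), d1=float(d1), d2=float(d2),
        lnl=lnl, lnl_null=lnl0, lrt=stat, p_value=p, pp=pp,
        site_index=counts.site_index.copy(),
        converged=bool(best.success or res0.success),
    )


def _theta_se(x_opt, x1, x2, eps: float = 1e-4) -> float:
    """SE(θ) from the observed-information matrix at the optimum."""
    def nll(p):
        return -_type1_loglik(p, x1, x2)[0]

    n = len(x_opt)
    H = np.zeros((n, n))
    x = np.asarray(x_opt, float)
    x[0] = min(max(x[0], 2 * eps), 1 - 2 * eps)  # keep θ interior for FD
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                nll(x + ei + ej) - nll(x + ei - ej)
                - nll(x - ei + ej) + nll(x - ei - ej)
            ) / (4 * eps * eps)
    try:
        cov = np.linalg.inv(H)
        v = cov[0, 0]
        return float(np.sqrt(v)) if v > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")


def empirical_pp_cutoff(
    counts: SiteCountTable,
    alpha_level: float = 0.05,
    boundary_mixture: bool = False,
    fit: ThetaEstimate | None = None,
    max_removals: int | None = None,
) -> tuple[float, list[int]]:
    """Sequential top-posterior removal until θ loses significance.

    Returns ``(cutoff, removed_columns)``: the removed sites (0-based
    original alignment columns, in removal order) are the predicted
    functional-divergence-related (RFD) residues; the cutoff is the pp of
    the last site removed.  An initially non-significant fit removes
    nothing (cutoff NaN).
    """
    current = counts
    removed: list[int] = []
    cutoff = float("nan")
    limit = max_removals if max_removals is not None else counts.n_sites - 2
    est = fit if fit is not None else fit_type1(
        current, boundary_mixture=boundary_mixture
    )
    while est.p_value <= alpha_level and len(removed) < limit:
        top = int(np.argmax(est.pp))
        removed.append(int(current.site_index[top]))
        cutoff = float(est.pp[top])
        current = current.drop(np.array([top]))
        if current.n_sites < 30:
            break
        est = fit_type1(current, boundary_mixture=boundary_mixture)
    return cutoff, removed


# ---------------------------------------------------------- Type-II model


def _property_of(partition: dict[str, str]) -> dict[str, str]:
    prop = {}
    for name, members in partition.items():
        for aa in members:
            prop[aa] = name
    missing = set(AMINO_ACIDS) - set(prop)
    if missing:
        raise ValueError(f"partition misses residues {sorted(missing)}")
    return prop


def _null_radical_fraction(freqs: np.ndarray, prop_of_idx: np.ndarray) -> float:
    """P(different property groups | different residues) for random pairs."""
    p_diff_res = 1.0 - float(np.sum(freqs**2))
    same_group = 0.0
    for g in np.unique(prop_of_idx):
        pg = float(freqs[prop_of_idx == g].sum())
        same_group += pg * pg
    p_same_group_diff_res = same_group - float(np.sum(freqs**2))
    if p_diff_res <= 0:
        return 0.5
    return 1.0 - p_same_group_diff_res / p_diff_res


def fit_type2(
    aln: ProteinAlignment,
    tree: LabeledTree,
    pair: ClusterPair,
    property_partition: dict[str, str] | None = None,
) -> Type2Result:
    """Stand-in estimator of the Type-II ("conserved but different") share.

    Gap-free sites are classified from per-cluster parsimony root states
    (parsimony ties excluded, logged): fixed-same (C0), fixed-different
    within one property group (CC), fixed-different across groups (CR,
    radical), or variable (V).  θ_II is the weight of a point-mass-on-CR
    mixture component over a background multinomial whose CC:CR split is
    pinned to the null radical fraction; fitted by EM, tested by Z = θ̂/SE.
    """
    partition = property_partition or DEFAULT_PROPERTY_PARTITION
    prop = _property_of(partition)
    pair.validate_monophyly(tree)
    cols = gap_free_columns(aln, pair.taxa1 | pair.taxa2)
    if len(cols) == 0:
        raise ValueError("no gap-free columns")

    subs = {}
    for name, taxa in ((pair.name1, pair.taxa1), (pair.name2, pair.taxa2)):
        sub = tree.subtree(taxa)
        order = sub.taxa
        subs[name] = (
            sub.to_arrays(taxa_order=order),
            _aa_states(ProteinAlignment(order, [aln.row(t) for t in order])),
            order,
        )

    categories: list[str] = []
    kept_cols: list[int] = []
    radical_sites: list[int] = []
    ties = 0
    for c in cols:
        reps = []
        fixed = True
        tie = False
        for name in (pair.name1, pair.name2):
            arrays, states, order = subs[name]
            col = states[:, c]
            if len(set(col.tolist())) > 1:
                fixed = False
                break
            # cluster monomorphic: the parsimony root state is that residue
            roots = _root_states(arrays, col, 20)
            if len(roots) > 1:  # unreachable for monomorphic data; kept for
                tie = True      # robustness with partial/missing columns
                break
            reps.append(AMINO_ACIDS[roots[0]])
        if tie:
            ties += 1
            continue
        kept_cols.append(c)
        if not fixed:
            categories.append("V")
        elif reps[0] == reps[1]:
            categories.append("C0")
        elif prop[reps[0]] == prop[reps[1]]:
            categories.append("CC")
        else:
            categories.append("CR")
            radical_sites.append(int(c))
    if ties:
        logger.info("fit_type2: excluded %d parsimony-tie columns", ties)
    if not any(cat.startswith("C") for cat in categories):
        raise ValueError("no fixed sites: Type-II model is undefined")

    n = len(categories)
    n0 = categories.count("C0")
    ncc = categories.count("CC")
    ncr = categories.count("CR")
    nv = categories.count("V")

    # Null radical fraction from observed residue frequencies.
    counts_aa = np.zeros(20)
    aa_idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for t in sorted(pair.taxa1 | pair.taxa2):
        for c in kept_cols:
            ch = aln.row(t)[c]
            if ch in aa_idx:
                counts_aa[aa_idx[ch]] += 1
    freqs = counts_aa / counts_aa.sum()
    groups = sorted(partition)
    prop_idx = np.array(
        [groups.index(prop[a]) for a in AMINO_ACIDS], dtype=int
    )
    r0 = _null_radical_fraction(freqs, prop_idx)

    theta, se = _fit_point_mass_mixture(n0, ncc, ncr, nv, r0)
    z = theta / se if (se and se > 0 and np.isfinite(se)) else 0.0
    p = float(2 * norm.sf(abs(z))) if z else 1.0
    return Type2Result(
        theta2=theta, se=se, z=z, p_value=p,
        radical_sites=radical_sites,
        category_counts={"C0": n0, "CC": ncc, "CR": ncr, "V": nv},
        excluded_ties=ties,
    )


def _fit_point_mass_mixture(
    n0: int, ncc: int, ncr: int, nv: int, r0: float, tol: float = 1e-10
) -> tuple[float, float]:
    """EM for θ_II with background CC:CR ratio pinned at (1−r0):r0."""
    n = n0 + ncc + ncr + nv
    if ncr == 0:
        return 0.0, float("nan")
    if ncr == n:
        return 1.0, float("nan")
    theta = max(ncr / n - 0.05, 0.01)
    for _ in range(500):
        pcd_cur = _pcd_given_theta(n0, ncc, ncr, nv, theta, r0)
        denom = theta + (1 - theta) * r0 * pcd_cur
        w = theta / denom if denom > 0 else 0.0
        new_theta = w * ncr / n
        if abs(new_theta - theta) < tol:
            theta = new_theta
            break
        theta = min(max(new_theta, 0.0), 1 - 1e-9)
    theta = float(min(max(theta, 0.0), 1.0))
    se = _theta2_se(n0, ncc, ncr, nv, r0, theta)
    return theta, se


def _pcd_given_theta(n0, ncc, ncr, nv, theta, r0):
    """Background P(fixed-different) maximizing the constrained likelihood."""
    # Expected background CR count given theta
    n = n0 + ncc + ncr + nv
    # solve by short inner fixed-point
    pcd = max((ncc + ncr) / max(n, 1), 1e-9)
    for _ in range(200):
        denom = theta + (1 - theta) * r0 * pcd
        w = theta / denom if denom > 0 else 0.0
        bg_cr = ncr * (1 - w)
        nb = n0 + ncc + nv + bg_cr
        new = (ncc + bg_cr) / nb if nb > 0 else 0.0
        if abs(new - pcd) < 1e-12:
            pcd = new
            break
        pcd = new
    return max(pcd, 1e-12)


def _type2_loglik(theta, n0, ncc, ncr, nv, r0):
    pcd = _pcd_given_theta(n0, ncc, ncr, nv, theta, r0)
    # background simplex given pcd: p0, pv proportional to counts
    rest = max(1 - pcd, 1e-12)
    n_rest = n0 + nv
    p0 = rest * (n0 / n_rest) if n_rest else 0.0
    pv = rest * (nv / n_rest) if n_rest else 0.0
    ll = 0.0
    if n0:
        ll += n0 * math.log((1 - theta) * max(p0, 1e-300))
    if nv:
        ll += nv * math.log((1 - theta) * max(pv, 1e-300))
    if ncc:
        ll += ncc * math.log((1 - theta) * (1 - r0) * pcd)
    if ncr:
        ll += ncr * math.log(theta + (1 - theta) * r0 * pcd)
    return ll


def _theta2_se(n0, ncc, ncr, nv, r0, theta, eps=1e-4) -> float:
    t = min(max(theta, 2 * eps), 1 - 2 * eps)
    f = lambda th: _type2_loglik(th, n0, ncc, ncr, nv, r0)
    d2 = (f(t + eps) - 2 * f(t) + f(t - eps)) / (eps * eps)
    if d2 >= 0:
        return float("nan")
    return float(1.0 / math.sqrt(-d2))
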