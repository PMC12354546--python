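"""Branch-specific dN/dS under the Goldman–Yang codon model.

The 61-sense-codon substitution process has rate π_j (synonymous
transversion), κπ_j (synonymous transition), ωπ_j (nonsynonymous
transversion) or κωπ_j (nonsynonymous transition) between codons differing
at a single position, zero otherwise, scaled to one expected substitution
per codon per unit branch length.  Branch models give each labeled branch
class its own ω while sharing κ and the codon frequencies; nested models
(one-, two-, three-, four-ratio, free-ratio) are compared with likelihood
ratio tests, 2Δℓ ~ χ² with df equal to the difference in ω-class counts.

By the study convention, the one-ratio model is fitted on the unrooted tree
and multi-ratio models on the rooted tree; under reversible models the two
root-adjacent branch lengths are confounded, so identifiable branch counts
(and hence LRT df) are computed on the unrooted form either way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.optimize import minimize
from scipy.stats import chi2

from ._pruning import MISSING, PruningModel, ReversibleEigen, compress_patterns
from .seq_prep import CodonAlignment
from .trees import LabeledTree, TreeArrays

__all__ = [
    "SENSE_CODONS",
    "CODON_INDEX",
    "CodonModelSpec",
    "ModelFit",
    "LRTResult",
    "f3x4_frequencies",
    "f61_frequencies",
    "gy94_rate_matrix",
    "transition_matrix",
    "codon_log_likelihood",
    "fit_branch_model",
    "likelihood_ratio_test",
    "ladder_table",
]

_NUC = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)

#: The 61 sense codons of the standard genetic code, codeml ordering (TTT first).
SENSE_CODONS: list[str] = [
    a + b + c
    for a in _NUC
    for b in _NUC
    for c in _NUC
    if a + b + c not in _STOPS
]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF_CODON: list[str] = [_TABLE.forward_table[c] for c in SENSE_CODONS]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _pair_features() -> tuple[np.ndarray, np.ndarray]:
    """(is_single_step & is_transition, is_single_step & is_nonsynonymous)."""
    n = len(SENSE_CODONS)
    ts = np.zeros((n, n), dtype=bool)
    single = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = diffs[0] in _TRANSITIONS
            nonsyn[i, j] = AA_OF_CODON[i] != AA_OF_CODON[j]
    return single, ts, nonsyn


_SINGLE, _IS_TS, _IS_NONSYN = _pair_features()


@dataclass
class CodonModelSpec:
    """GY94 parameters: κ, per-class ω, and 61 codon frequencies."""

    kappa: float
    omega_by_class: np.ndarray
    codon_frequencies: np.ndarray
    frequency_mode: str = "F3x4"

    def __post_init__(self):
        self.omega_by_class = np.atleast_1d(np.asarray(self.omega_by_class, float))
        self.codon_frequencies = np.asarray(self.codon_frequencies, float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if np.any(self.omega_by_class < 0):
            raise ValueError("omega must be >= 0")
        pi = self.codon_frequencies
        if pi.shape != (61,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-12:
            raise ValueError("codon frequencies must be a 61-simplex")

    @property
    def n_classes(self) -> int:
        return len(self.omega_by_class)


@dataclass
class ModelFit:
    """A maximized branch-model fit: the unit the LRT ladder compares."""

    model_name: str
    lnl: float
    kappa: float
    omega_by_class: np.ndarray
    #: edge lengths keyed by the edge's child leaf set (topology-stable, so
    #: fits transfer between the rooted and unrooted forms of a topology)
    branch_lengths: dict[frozenset, float]
    n_free_params: int
    converged: bool
    n_iter: int
    frequency_mode: str = "F3x4"
    n_classes: int = 1

    def __post_init__(self):
        if not np.isfinite(self.lnl):
            raise ValueError("non-finite log-likelihood in ModelFit")


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    null_model: str
    alt_model: str


# ------------------------------------------------------------- frequencies


def f3x4_frequencies(aln: CodonAlignment, floor: float = 1e-6) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies.

    π(c1c2c3) ∝ f₁(c1)·f₂(c2)·f₃(c3) over the 61 sense codons.  A small
    floor keeps unobserved nucleotides from zeroing whole codon classes.
    """
    counts = np.zeros((3, 4))
    nuc_idx = {n: k for k, n in enumerate(_NUC)}
    for row in aln.rows:
        for i in range(0, len(row), 3):
            codon = row[i : i + 3]
            if codon == "---":
                continue
            for pos, nt in enumerate(codon):
                if nt in nuc_idx:
                    counts[pos, nuc_idx[nt]] += 1
    f = counts / counts.sum(axis=1, keepdims=True)
    f = np.maximum(f, floor)
    f = f / f.sum(axis=1, keepdims=True)
    pi = np.array(
        [f[0, nuc_idx[c[0]]] * f[1, nuc_idx[c[1]]] * f[2, nuc_idx[c[2]]]
         for c in SENSE_CODONS]
    )
    return pi / pi.sum()


def f61_frequencies(aln: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    counts = np.full(61, pseudocount)
    for row in aln.rows:
        for i in range(0, len(row), 3):
            codon = row[i : i + 3]
            if codon in CODON_INDEX:
                counts[CODON_INDEX[codon]] += 1
    return counts / counts.sum()


# ------------------------------------------------------------ rate matrix


def gy94_rate_matrix(spec: CodonModelSpec, class_id: int = 0) -> np.ndarray:
    """61×61 GY94 generator for one ω class, scaled to unit expected rate."""
    return _gy94_q(spec.kappa, float(spec.omega_by_class[class_id]),
                   spec.codon_frequencies)


def _gy94_q(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    rates = np.where(_SINGLE, pi[None, :], 0.0)
    rates = np.where(_IS_TS, kappa * rates, rates)
    rates = np.where(_IS_NONSYN, omega * rates, rates)
    Q = rates.copy()
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate codon frequencies: zero total rate")
    return Q / scale


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Qt), entries clamped at 0."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite generator")
    from scipy.linalg import expm

    return np.clip(expm(Q * t), 0.0, None)


# ------------------------------------------------------------- likelihood


def codon_states(aln: CodonAlignment) -> np.ndarray:
    """(n_taxa, n_codons) integer state matrix; gaps/ambiguities → −1."""
    out = np.full((aln.n_taxa, aln.n_codons), MISSING, dtype=int)
    for r in range(aln.n_taxa):
        for c in range(aln.n_codons):
            codon = aln.codon(r, c)
            if codon in CODON_INDEX:
                out[r, c] = CODON_INDEX[codon]
            elif codon in _STOPS:
                raise ValueError(
                    f"in-frame stop codon {codon} at column {c} in {aln.taxa[r]}"
                )
    return out


def _eigens_for(kappa: float, omegas: np.ndarray, pi: np.ndarray):
    return [
        ReversibleEigen.from_q(_gy94_q(kappa, float(w), pi), pi) for w in omegas
    ]


def codon_log_likelihood(
    aln: CodonAlignment, tree: LabeledTree, spec: CodonModelSpec
) -> float:
    """Pruning log-likelihood of a codon alignment under a branch model.

    Gap and ambiguous codons are missing data (all-ones tip partials); the
    root uses the stationary codon frequencies.
    """
    if set(aln.taxa) != set(tree.taxa):
        raise ValueError("alignment and tree taxa differ")
    arrays = tree.to_arrays(taxa_order=aln.taxa)
    patterns, weights = compress_patterns(codon_states(aln))
    model = PruningModel(arrays, patterns, weights, n_states=61)
    eigens = _eigens_for(spec.kappa, spec.omega_by_class, spec.codon_frequencies)
    P = {
        int(e): eigens[arrays.classes[e]].transition(arrays.lengths[e])
        for e in arrays.edges
    }
    return model.loglik(P, spec.codon_frequencies)


# ----------------------------------------------------------------- fitting


class _BranchModelObjective:
    """Joint −lnL over (log κ, log ω-vector, log branch lengths).

    Branch-length gradients are analytic (one extra tree sweep); κ/ω
    gradients use forward differences, each costing one pruning pass.
    """

    def __init__(self, model: PruningModel, arrays: TreeArrays,
                 pi: np.ndarray, n_classes: int,
                 fixed_lengths: np.ndarray | None = None):
        self.model = model
        self.arrays = arrays
        self.pi = pi
        self.k = n_classes
        self.edges = arrays.edges
        self.fixed = fixed_lengths

    def unpack(self, x: np.ndarray):
        kappa = float(np.exp(x[0]))
        omegas = np.exp(x[1 : 1 + self.k])
        if self.fixed is None:
            lengths = np.exp(x[1 + self.k :])
        else:
            lengths = self.fixed
        return kappa, omegas, lengths

    def _lnl(self, kappa, omegas, lengths, with_grad: bool):
        eigens = _eigens_for(kappa, omegas, self.pi)
        P, QP = {}, {}
        for pos, e in enumerate(self.edges):
            eg = eigens[self.arrays.classes[e]]
            P[int(e)] = eg.transition(lengths[pos])
            if with_grad:
                QP[int(e)] = eg.qp(lengths[pos])
        if with_grad:
            return self.model.loglik_and_branch_grad(P, QP, self.pi)
        return self.model.loglik(P, self.pi)

    def value(self, x: np.ndarray) -> float:
        return -self._lnl(*self.unpack(x), with_grad=False)

    def value_and_grad(self, x: np.ndarray):
        kappa, omegas, lengths = self.unpack(x)
        lnl, bgrad = self._lnl(kappa, omegas, lengths, with_grad=True)
        if not np.isfinite(lnl):
            return np.inf, np.zeros_like(x)
        grad = np.zeros_like(x)
        eps = 1e-5
        for i in range(1 + self.k):
            xp = x.copy()
            xp[i] += eps
            lp = -self.value(xp)
            grad[i] = -(lp - lnl) / eps
        if self.fixed is None:
            # d(−lnL)/d log t = −t · d lnL/dt
            grad[1 + self.k :] = -lengths * bgrad[self.edges]
        return -lnl, grad


def _identifiable_branch_count(tree: LabeledTree) -> int:
    arrays = tree.to_arrays()
    n_edges = len(arrays.edges)
    # Rooted binary trees: the two root-adjacent lengths are confounded.
    if tree.rooted and len(arrays.children[arrays.root]) == 2:
        return n_edges - 1
    return n_edges


def fit_branch_model(
    aln: CodonAlignment,
    tree: LabeledTree,
    model: int | str = 1,
    frequency_mode: str = "F3x4",
    fix_branch_lengths: "ModelFit | None" = None,
    warm_start: "ModelFit | None" = None,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 300,
) -> ModelFit:
    """Maximize a branch-model likelihood over κ, ω per class, and lengths.

    ``model``: number of ω classes (1 ignores branch labels) or ``"free"``
    (every branch its own class).  ``fix_branch_lengths`` reuses a previous
    fit's lengths for speed; ``warm_start`` seeds the first optimizer start
    (guaranteeing nested fits never fall below their null).
    """
    if model == "free":
        tree = _free_ratio_relabel(tree)
        k = tree.n_classes
        name = "free-ratio"
    else:
        k = int(model)
        if k == 1:
            tree = _single_class(tree)
            name = "one-ratio"
        else:
            if tree.n_classes != k:
                raise ValueError(
                    f"tree has {tree.n_classes} branch classes, model wants {k}"
                )
            name = {2: "two-ratio", 3: "three-ratio", 4: "four-ratio"}.get(
                k, f"{k}-ratio"
            )

    if set(aln.taxa) != set(tree.taxa):
        raise ValueError("alignment and tree taxa differ")
    arrays = tree.to_arrays(taxa_order=aln.taxa)
    patterns, weights = compress_patterns(codon_states(aln))
    pruner = PruningModel(arrays, patterns, weights, n_states=61)
    if frequency_mode == "F3x4":
        pi = f3x4_frequencies(aln)
    elif frequency_mode == "F61":
        pi = f61_frequencies(aln)
    else:
        raise ValueError(f"unknown frequency mode {frequency_mode!r}")

    leafsets = arrays.leafsets()
    all_taxa = frozenset(aln.taxa)

    def _lookup_lengths(fit: "ModelFit", default: np.ndarray) -> np.ndarray:
        # Exact leafset match; a root-adjacent edge whose complement carries
        # the length in an unrooted fit gets epsilon (pulley principle: only
        # the sum of the two root edges is identifiable).
        out = default.copy()
        for pos, e in enumerate(arrays.edges):
            ls = leafsets[e]
            if ls in fit.branch_lengths:
                out[pos] = fit.branch_lengths[ls]
            elif (all_taxa - ls) in fit.branch_lengths:
                out[pos] = 1e-8
        return np.maximum(out, 1e-8)

    fixed = None
    if fix_branch_lengths is not None:
        fixed = _lookup_lengths(
            fix_branch_lengths, np.full(len(arrays.edges), 0.1)
        )
    obj = _BranchModelObjective(pruner, arrays, pi, k, fixed_lengths=fixed)

    t0 = np.maximum(arrays.lengths[arrays.edges], 1e-3)
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if warm_start is not None:
        w = np.full(k, float(np.mean(warm_start.omega_by_class)))
        m = min(len(warm_start.omega_by_class), k)
        w[:m] = warm_start.omega_by_class[:m]
        tl = _lookup_lengths(warm_start, t0)
        starts.append(_pack(warm_start.kappa, w, tl, fixed))
    starts.append(_pack(2.0, np.full(k, 0.5), t0, fixed))
    while len(starts) < max(n_starts, 1):
        starts.append(
            _pack(
                float(np.exp(rng.normal(np.log(2.0), 0.5))),
                np.exp(rng.normal(np.log(0.4), 0.4, size=k)),
                t0 * np.exp(rng.normal(0, 0.3, size=len(t0))),
                fixed,
            )
        )

    bounds = [(np.log(1e-3), np.log(1e3))]            # kappa
    bounds += [(np.log(1e-4), np.log(1e3))] * k       # omegas
    if fixed is None:
        bounds += [(np.log(1e-8), np.log(50.0))] * len(arrays.edges)
    best = None
    for x0 in starts[: max(n_starts, 1)]:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            obj.value_and_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    kappa, omegas, lengths = obj.unpack(best.x)
    if not best.success:
        warnings.warn(f"{name}: optimizer did not report convergence "
                      f"({best.message})")
    n_bl = _identifiable_branch_count(tree)
    return ModelFit(
        model_name=name,
        lnl=-float(best.fun),
        kappa=kappa,
        omega_by_class=omegas,
        branch_lengths={leafsets[e]: float(lengths[pos])
                        for pos, e in enumerate(arrays.edges)},
        n_free_params=n_bl + 1 + k,
        converged=bool(best.success),
        n_iter=int(best.nit),
        frequency_mode=frequency_mode,
        n_classes=k,
    )


def _pack(kappa, omegas, lengths, fixed):
    head = np.concatenate([[np.log(kappa)], np.log(np.maximum(omegas, 1e-6))])
    if fixed is not None:
        return head
    return np.concatenate([head, np.log(np.maximum(lengths, 1e-8))])


def _single_class(tree: LabeledTree) -> LabeledTree:
    clone = LabeledTree(tree.tree.clone(depth=1), rooted=tree.rooted)
    for e in clone.tree.preorder_edge_iter():
        e.class_id = 0
    return clone


def _free_ratio_relabel(tree: LabeledTree) -> LabeledTree:
    clone = LabeledTree(tree.tree.clone(depth=1), rooted=tree.rooted)
    for i, e in enumerate(
        e for e in clone.tree.preorder_edge_iter() if e.head_node.parent_node
    ):
        e.class_id = i
    for e in clone.tree.preorder_edge_iter():
        if e.head_node.parent_node is None:
            e.class_id = 0
    return clone


# ----------------------------------------------------------------- tests


_LADDER_ORDER = ["one-ratio", "two-ratio", "three-ratio", "four-ratio",
                 "free-ratio"]


def likelihood_ratio_test(
    null: ModelFit, alt: ModelFit, boundary_mixture: bool = False
) -> LRTResult:
    """2(ℓ₁ − ℓ₀) against χ² with df = free-parameter difference.

    Negative statistics (optimizer noise in nested fits) are clamped to 0
    with a warning.  ``boundary_mixture`` uses ½χ²₀ + ½χ²_df instead of the
    plain tail.
    """
    if null.model_name in _LADDER_ORDER and alt.model_name in _LADDER_ORDER:
        if _LADDER_ORDER.index(alt.model_name) <= _LADDER_ORDER.index(
            null.model_name
        ):
            raise ValueError(
                f"{alt.model_name} is not an extension of {null.model_name}"
            )
    df = alt.n_classes - null.n_classes
    if df <= 0:
        raise ValueError("alternative must have more omega classes than null")
    stat = 2.0 * (alt.lnl - null.lnl)
    if stat < 0:
        warnings.warn(
            f"negative LRT statistic {stat:.4g} clamped to 0 "
            f"({null.model_name} vs {alt.model_name})"
        )
        stat = 0.0
    p = float(chi2.sf(stat, df))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return LRTResult(stat, df, p, null.model_name, alt.model_name)


def ladder_table(fits: list[ModelFit], boundary_mixture: bool = False) -> pd.DataFrame:
    """Nested-model report: lnL, parameter counts and sequential LRTs."""
    rows = []
    for i, fit in enumerate(fits):
        rec = {
            "model": fit.model_name,
            "lnL": fit.lnl,
            "n_params": fit.n_free_params,
            "kappa": fit.kappa,
            "omega": ",".join(f"{w:.4f}" for w in fit.omega_by_class),
            "converged": fit.converged,
        }
        if i > 0:
            lrt = likelihood_ratio_test(fits[i - 1], fit, boundary_mixture)
            rec.update({"2dlnL": lrt.statistic, "df": lrt.df, "p": lrt.p_value})
        rows.append(rec)
    return pd.DataFrame(rows)
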