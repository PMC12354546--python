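"""Nucleotide substitution rates under global and local clocks.

On a time-calibrated tree (chronogram) the expected substitutions on a
branch equal rate × time span, where the rate is shared within a labeled
branch class: one class is a global (strict) clock, k classes a local
clock.  The substitution process is GTR (REV); exchangeabilities and —
optionally — base frequencies are estimated jointly with the rates.
Nested clock models are compared by LRT with df = difference in the number
of rate classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from ._pruning import MISSING, PruningModel, ReversibleEigen, compress_patterns
from .seq_prep import Alignment
from .trees import Chronogram

__all__ = [
    "NUCLEOTIDES",
    "GTRSpec",
    "ClockFit",
    "gtr_matrix",
    "fit_clock_model",
    "compare_clock_models",
    "rate_standard_errors",
]

NUCLEOTIDES = "ACGT"
_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
# Order of the 6 exchangeabilities: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class GTRSpec:
    """REV model: 6 exchangeabilities (AC, AG, AT, CG, CT, GT) and π."""

    exchangeabilities: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, float)
        self.frequencies = np.asarray(self.frequencies, float)
        if self.exchangeabilities.shape != (6,) or np.any(
            self.exchangeabilities <= 0
        ):
            raise ValueError("need 6 positive exchangeabilities")
        pi = self.frequencies
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-9:
            raise ValueError("frequencies must be a 4-simplex")


@dataclass
class ClockFit:
    """Fitted clock model: per-class rates (subs/site/time unit) and GTR."""

    model_name: str
    lnl: float
    rates: np.ndarray
    gtr: GTRSpec
    n_free_params: int
    converged: bool
    n_iter: int
    n_classes: int

    def __post_init__(self):
        if not np.isfinite(self.lnl):
            raise ValueError("non-finite log-likelihood")
        if np.any(self.rates < 0):
            raise ValueError("negative rate")


def gtr_matrix(spec: GTRSpec) -> np.ndarray:
    """4×4 GTR generator scaled to one expected substitution per unit length."""
    pi = spec.frequencies
    Q = np.zeros((4, 4))
    for (i, j), s in zip(_PAIRS, spec.exchangeabilities):
        if s > 0 and (pi[i] == 0 or pi[j] == 0):
            raise ValueError("zero frequency with nonzero exchangeability")
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate GTR spec")
    return Q / scale


def nucleotide_states(aln: Alignment) -> np.ndarray:
    out = np.full((aln.n_taxa, aln.n_columns), MISSING, dtype=int)
    for r, row in enumerate(aln.rows):
        for c, nt in enumerate(row):
            out[r, c] = _NUC_INDEX.get(nt, MISSING)
    return out


def empirical_frequencies(aln: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    counts = np.full(4, pseudocount)
    for row in aln.rows:
        for nt in row:
            if nt in _NUC_INDEX:
                counts[_NUC_INDEX[nt]] += 1
    return counts / counts.sum()


class _ClockObjective:
    """−lnL over (log rates, log exchangeabilities[1:], freq logits).

    Rate gradients are analytic via branch-length gradients
    (d lnL/d r_c = Σ_{edges in c} τ_e · d lnL/d t_e); GTR parameters use
    forward differences.
    """

    def __init__(self, model, arrays, durations, n_classes,
                 estimate_freqs, fixed_freqs):
        self.model = model
        self.arrays = arrays
        self.durations = durations
        self.k = n_classes
        self.estimate_freqs = estimate_freqs
        self.fixed_freqs = fixed_freqs
        self.edges = arrays.edges

    def unpack(self, x):
        rates = np.exp(x[: self.k])
        exch = np.ones(6)
        exch[:5] = np.exp(x[self.k : self.k + 5])  # GT fixed at 1
        if self.estimate_freqs:
            logits = np.concatenate([x[self.k + 5 :], [0.0]])
            pi = np.exp(logits - logits.max())
            pi = pi / pi.sum()
        else:
            pi = self.fixed_freqs
        return rates, GTRSpec(exch, pi)

    def _lnl(self, rates, spec, with_grad):
        Q = gtr_matrix(spec)
        eig = ReversibleEigen.from_q(Q, spec.frequencies)
        P, QP = {}, {}
        for e in self.edges:
            t = rates[self.arrays.classes[e]] * self.durations[e]
            P[int(e)] = eig.transition(t)
            if with_grad:
                QP[int(e)] = eig.qp(t)
        if with_grad:
            return self.model.loglik_and_branch_grad(P, QP, spec.frequencies)
        return self.model.loglik(P, spec.frequencies)

    def value(self, x):
        return -self._lnl(*self.unpack(x), with_grad=False)

    def value_and_grad(self, x):
        rates, spec = self.unpack(x)
        lnl, bgrad = self._lnl(rates, spec, with_grad=True)
        if not np.isfinite(lnl):
            return np.inf, np.zeros_like(x)
        grad = np.zeros_like(x)
        for c in range(self.k):
            sel = self.edges[self.arrays.classes[self.edges] == c]
            # chain rule through t = r τ and r = exp(x)
            grad[c] = -rates[c] * float(
                np.sum(bgrad[sel] * self.durations[sel])
            )
        eps = 1e-5
        for i in range(self.k, len(x)):
            xp = x.copy()
            xp[i] += eps
            grad[i] = (self.value(xp) - (-lnl)) / eps
        return -lnl, grad


def fit_clock_model(
    aln: Alignment,
    chron: Chronogram,
    k_classes: int = 1,
    estimate_freqs: bool = True,
    rate_init: float = 1e-3,
    maxiter: int = 400,
) -> ClockFit:
    """Maximize the local-clock likelihood over rates and GTR parameters.

    ``k_classes=1`` is the global clock (branch labels ignored); for k>1 the
    chronogram's branch classes must be exactly 0..k−1.
    """
    if set(aln.taxa) != set(chron.taxa):
        raise ValueError("alignment and chronogram taxa differ")
    if k_classes > 1 and chron.n_classes != k_classes:
        raise ValueError(
            f"chronogram has {chron.n_classes} branch classes, model wants "
            f"{k_classes}"
        )
    arrays = chron.to_arrays(taxa_order=aln.taxa)
    if k_classes == 1:
        arrays.classes = np.zeros_like(arrays.classes)
    durations = chron.durations()
    patterns, weights = compress_patterns(nucleotide_states(aln))
    pruner = PruningModel(arrays, patterns, weights, n_states=4)
    emp = empirical_frequencies(aln)
    obj = _ClockObjective(pruner, arrays, durations, k_classes,
                          estimate_freqs, emp)
    x0 = np.concatenate([
        np.full(k_classes, np.log(rate_init)),
        np.zeros(5),
        np.log(np.maximum(emp[:3] / emp[3], 1e-6)) if estimate_freqs else [],
    ])
    res = minimize(obj.value_and_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
    rates, spec = obj.unpack(res.x)
    if not res.success:
        warnings.warn(f"clock fit ({k_classes} classes): {res.message}")
    name = {1: "one-rate", 3: "three-rates", 4: "four-rates"}.get(
        k_classes, f"{k_classes}-rates"
    )
    n_params = k_classes + 5 + (3 if estimate_freqs else 0)
    return ClockFit(
        model_name=name,
        lnl=-float(res.fun),
        rates=rates,
        gtr=spec,
        n_free_params=n_params,
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_classes=k_classes,
    )


def compare_clock_models(fits: list[ClockFit]) -> pd.DataFrame:
    """Sequential LRTs between nested clock fits (df = Δ rate classes)."""
    fits = sorted(fits, key=lambda f: f.n_classes)
    rows = []
    for i, fit in enumerate(fits):
        rec = {
            "model": fit.model_name,
            "lnL": fit.lnl,
            "n_classes": fit.n_classes,
            "rates": ",".join(f"{r:.6g}" for r in fit.rates),
            "converged": fit.converged,
        }
        if i > 0:
            null = fits[i - 1]
            if fit.n_classes <= null.n_classes:
                raise ValueError("clock fits are not nested by refinement")
            stat = max(0.0, 2.0 * (fit.lnl - null.lnl))
            df = fit.n_classes - null.n_classes
            rec.update({
                "null": null.model_name,
                "2dlnL": stat,
                "df": df,
                "p": float(chi2.sf(stat, df)),
            })
        rows.append(rec)
    return pd.DataFrame(rows)


def rate_standard_errors(
    aln: Alignment, chron: Chronogram, fit: ClockFit, eps: float = 1e-4
) -> np.ndarray:
    """Curvature-based SEs of the fitted rates (other parameters held fixed).

    Central-difference Hessian of lnL in log-rate space, mapped back by the
    delta method.  NaN where the information matrix is not positive.
    """
    arrays = chron.to_arrays(taxa_order=aln.taxa)
    if fit.n_classes == 1:
        arrays.classes = np.zeros_like(arrays.classes)
    durations = chron.durations()
    patterns, weights = compress_patterns(nucleotide_states(aln))
    pruner = PruningModel(arrays, patterns, weights, n_states=4)
    eig_pi = fit.gtr.frequencies

    def lnl_of(log_rates):
        rates = np.exp(log_rates)
        Q = gtr_matrix(fit.gtr)
        eig = ReversibleEigen.from_q(Q, eig_pi)
        P = {
            int(e): eig.transition(rates[arrays.classes[e]] * durations[e])
            for e in arrays.edges
        }
        return pruner.loglik(P, eig_pi)

    k = fit.n_classes
    x = np.log(np.maximum(fit.rates, 1e-12))
    H = np.zeros((k, k))
    f0 = lnl_of(x)
    for i in range(k):
        for j in range(i, k):
            xi = np.zeros(k); xi[i] = eps
            xj = np.zeros(k); xj[j] = eps
            H[i, j] = H[j, i] = (
                lnl_of(x + xi + xj) - lnl_of(x + xi - xj)
                - lnl_of(x - xi + xj) + lnl_of(x - xi - xj)
            ) / (4 * eps * eps)
    info = -H
    se = np.full(k, np.nan)
    try:
        cov = np.linalg.inv(info)
        d = np.diag(cov)
        ok = d > 0
        se[ok] = np.sqrt(d[ok]) * fit.rates[ok]  # delta method from log-scale
    except np.linalg.LinAlgError:
        pass
    return se
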