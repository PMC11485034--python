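"""Annotation enrichment: Wakefield Bayes factors and a block hierarchical model.

The model assumes at most one causal variant per block. A block is causal
with probability ``Pi``; within a causal block, variant *j* is causal with
prior weight ``w_j = exp(sum_k beta_k z_jk) / sum_l exp(sum_k beta_k z_lk)``.
Marginalising the causal configuration gives the block likelihood ratio::

    L_block = (1 - Pi) + Pi * sum_j w_j * Lambda_j

where ``Lambda_j`` is the variant's approximate Bayes factor for
association. Maximising the summed log likelihood over ``(Pi, beta)``
yields log-fold enrichment estimates; annotations enter a joint model by
forward selection under a Bonferroni-corrected likelihood-ratio stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit, logsumexp

logger = logging.getLogger(__name__)

DEFAULT_W = 0.04  # prior variance of the (standardised) effect, sd 0.2
_CHI2_95_1DF = stats.chi2.ppf(0.95, 1)  # 3.841; half of it bounds the profile drop


def wakefield_abf(beta, se, prior_var: float = DEFAULT_W):
    """Natural-log approximate Bayes factor for association.

    ``ln Lambda = 0.5 ln(V / (V + W)) + z^2 W / (2 (V + W))`` with
    ``V = se^2`` and ``z = beta / se``; the Bayes factor compares a normal
    effect prior N(0, W) against the point-null. W = 0 gives Lambda = 1.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_var < 0:
        raise ValueError("prior variance W must be non-negative")
    if prior_var == 0:
        return np.zeros_like(beta) if beta.shape else 0.0
    v = se**2
    z2 = (beta / se) ** 2
    ln_bf = 0.5 * np.log(v / (v + prior_var)) + z2 * prior_var / (2.0 * (v + prior_var))
    return ln_bf if ln_bf.shape else float(ln_bf)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test p-value threshold under Bonferroni correction."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


@dataclass
class EnrichmentModel:
    """A fitted joint enrichment model."""

    selected: list[str]
    beta_hat: np.ndarray
    ci95: list[tuple[float, float]]
    block_prior_hat: float
    loglik: float
    n_annotations_tested: int

    def prior_weights(self, z: np.ndarray) -> np.ndarray:
        """Per-variant prior gamma = exp(sum_k beta_hat_k z_k); 1 if empty model."""
        if not self.selected:
            return np.ones(z.shape[0] if z.ndim > 1 else 1)
        return np.exp(np.asarray(z, dtype=float) @ self.beta_hat)


def block_loglik(ln_bfs: np.ndarray, z: np.ndarray, beta: np.ndarray, pi: float) -> float:
    """Log-likelihood contribution of a single block (see module docstring)."""
    ln_bfs = np.asarray(ln_bfs, dtype=float)
    if ln_bfs.size == 0:
        raise ValueError("empty block")
    if not (0 <= pi <= 1):
        raise ValueError("Pi must be a probability")
    z = np.asarray(z, dtype=float).reshape(ln_bfs.size, -1)
    beta = np.asarray(beta, dtype=float)
    score = z @ beta if beta.size else np.zeros(ln_bfs.size)
    ln_w = score - logsumexp(score)
    ln_s = logsumexp(ln_w + ln_bfs)
    return _ln_mixture(ln_s, pi)


def _ln_mixture(ln_s, pi):
    """log((1 - pi) + pi * exp(ln_s)), stable for very large ln_s."""
    ln_s = np.asarray(ln_s, dtype=float)
    if pi == 0:
        return float(np.sum(np.zeros_like(ln_s)))
    if pi == 1:
        return float(np.sum(ln_s))
    a = np.full_like(ln_s, np.log1p(-pi))
    b = np.log(pi) + ln_s
    return float(np.sum(np.logaddexp(a, b)))


class _BlockLikelihood:
    """Vectorised total log-likelihood over many blocks."""

    def __init__(self, ln_bfs: np.ndarray, blocks: np.ndarray, z: np.ndarray | None):
        order = np.argsort(blocks, kind="stable")
        self.ln_bfs = np.asarray(ln_bfs, dtype=float)[order]
        sorted_blocks = np.asarray(blocks)[order]
        self.z = None if z is None else np.asarray(z, dtype=float)[order]
        self.starts = np.flatnonzero(np.r_[True, sorted_blocks[1:] != sorted_blocks[:-1]])
        if self.ln_bfs.size == 0:
            raise ValueError("no variants")

    def _segment_logsumexp(self, x: np.ndarray) -> np.ndarray:
        mx = np.maximum.reduceat(x, self.starts)
        rep = np.diff(np.r_[self.starts, x.size])
        shifted = np.exp(x - np.repeat(mx, rep))
        return mx + np.log(np.add.reduceat(shifted, self.starts))

    def __call__(self, pi: float, beta: np.ndarray) -> float:
        beta = np.asarray(beta, dtype=float)
        if self.z is None or beta.size == 0:
            score = np.zeros_like(self.ln_bfs)
        else:
            score = self.z @ beta
        ln_w = score - np.repeat(
            self._segment_logsumexp(score), np.diff(np.r_[self.starts, score.size])
        )
        ln_s = self._segment_logsumexp(ln_w + self.ln_bfs)
        return _ln_mixture(ln_s, pi)


def _check_identifiable(z: np.ndarray, blocks: np.ndarray, names: list[str]) -> None:
    for k, name in enumerate(names):
        varies = False
        for b in np.unique(blocks):
            col = z[blocks == b, k]
            if col.size and col.min() != col.max():
                varies = True
                break
        if not varies:
            raise ValueError(
                f"annotation {name!r} is constant within every block; "
                "its enrichment is unidentifiable"
            )


def _maximise(lik: _BlockLikelihood, k: int, x0=None) -> tuple[float, float, np.ndarray]:
    def negll(x):
        return -lik(float(expit(x[0])), x[1:])

    if x0 is None:
        x0 = np.r_[logit(0.01), np.zeros(k)]
    res = optimize.minimize(negll, x0, method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-10})
    return -res.fun, float(expit(res.x[0])), res.x[1:].copy()


def fit_enrichment(
    ln_bfs: np.ndarray,
    blocks: np.ndarray,
    z: np.ndarray | None,
    names: list[str] | None = None,
    n_annotations_tested: int | None = None,
    compute_ci: bool = True,
) -> EnrichmentModel:
    """Maximum-likelihood fit of (Pi, beta) for a fixed annotation subset.

    Parameters
    ----------
    ln_bfs
        Per-variant natural-log Bayes factors.
    blocks
        Block index per variant (same length as *ln_bfs*).
    z
        Per-variant indicators of the model annotations (n x k) or None for
        the annotation-free model.
    names
        Annotation names matching the columns of *z*.
    compute_ci
        Profile-likelihood 95% intervals per beta (brentq on the profile).
    """
    names = list(names or [])
    k = 0 if z is None else np.asarray(z).shape[1]
    if k != len(names):
        raise ValueError("names must match annotation columns")
    if k:
        _check_identifiable(np.asarray(z), np.asarray(blocks), names)
    lik = _BlockLikelihood(ln_bfs, blocks, z if k else None)
    ll, pi_hat, beta_hat = _maximise(lik, k)
    cis = []
    if compute_ci and k:
        for j in range(k):
            cis.append(_profile_ci(lik, k, ll, beta_hat, pi_hat, j))
    return EnrichmentModel(
        selected=names,
        beta_hat=beta_hat,
        ci95=cis,
        block_prior_hat=pi_hat,
        loglik=ll,
        n_annotations_tested=n_annotations_tested if n_annotations_tested is not None else k,
    )


def _profile_ci(lik, k, ll_max, beta_hat, pi_hat, j) -> tuple[float, float]:
    target = ll_max - _CHI2_95_1DF / 2.0

    def profile(bj):
        def negll(x):
            beta = np.insert(x[1:], j, bj)
            return -lik(float(expit(x[0])), beta)

        x0 = np.r_[logit(max(min(pi_hat, 0.99), 1e-4)), np.delete(beta_hat, j)]
        res = optimize.minimize(negll, x0, method="L-BFGS-B", options={"ftol": 1e-12})
        return -res.fun - target

    centre = beta_hat[j]
    lo_bracket = centre - 0.5
    while profile(lo_bracket) > 0 and centre - lo_bracket < 50:
        lo_bracket -= max(0.5, centre - lo_bracket)
    hi_bracket = centre + 0.5
    while profile(hi_bracket) > 0 and hi_bracket - centre < 50:
        hi_bracket += max(0.5, hi_bracket - centre)
    try:
        lo = optimize.brentq(profile, lo_bracket, centre, xtol=1e-4)
    except ValueError:
        lo = -np.inf
    try:
        hi = optimize.brentq(profile, centre, hi_bracket, xtol=1e-4)
    except ValueError:
        hi = np.inf
    return (float(lo), float(hi))


def forward_select(
    ln_bfs: np.ndarray,
    blocks: np.ndarray,
    annotations,
    alpha: float = 0.05,
    n_tests: int | None = None,
    compute_ci: bool = True,
) -> EnrichmentModel:
    """Forward selection of a joint enrichment model.

    At each step the candidate annotation maximising the joint
    log-likelihood is provisionally added; it is accepted when its
    likelihood-ratio p-value (chi-square, 1 df) is below
    ``alpha / n_tests`` (Bonferroni over the annotations tested). Ties are
    broken by annotation name. Stops when no candidate is accepted; an
    empty selection is a valid outcome.

    *annotations* is an :class:`~annofine.io.AnnotationMatrix`-like object
    exposing ``names``/``values`` or a (frame-convertible) 2-D array plus
    names via the ``names`` keyword of :func:`fit_enrichment`.
    """
    z_all = np.asarray(annotations.values, dtype=float)
    all_names = list(annotations.names)
    n_tests = n_tests if n_tests is not None else len(all_names)
    threshold = bonferroni_threshold(alpha, n_tests)
    blocks = np.asarray(blocks)

    selected: list[str] = []
    base = fit_enrichment(ln_bfs, blocks, None, [], n_tests, compute_ci=False)
    current_ll = base.loglik
    while True:
        best = None
        for name in sorted(set(all_names) - set(selected)):
            cols = [all_names.index(s) for s in selected] + [all_names.index(name)]
            try:
                fit = fit_enrichment(
                    ln_bfs, blocks, z_all[:, cols], selected + [name], n_tests, compute_ci=False
                )
            except ValueError:
                continue  # unidentifiable in this data
            if best is None or fit.loglik > best[0].loglik + 1e-12:
                best = (fit, name)
        if best is None:
            break
        fit, name = best
        lrt = 2.0 * (fit.loglik - current_ll)
        pval = stats.chi2.sf(max(lrt, 0.0), 1)
        if pval >= threshold:
            break
        selected.append(name)
        current_ll = fit.loglik
        logger.info("selected annotation %s (LRT p = %.3g)", name, pval)

    cols = [all_names.index(s) for s in selected]
    return fit_enrichment(
        ln_bfs,
        blocks,
        z_all[:, cols] if cols else None,
        selected,
        n_tests,
        compute_ci=compute_ci,
    )
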