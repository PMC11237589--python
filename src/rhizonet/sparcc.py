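"""Compositional correlation inference (SparCC / FastSpar algorithm).

Sequencing yields relative, not absolute, abundances, so naive correlations
between taxon fractions are biased by the closure constraint. SparCC
estimates correlations between the latent *basis* (absolute) abundances
from the log-ratio variation matrix

    t_ij = Var_samples[ log(x_i / x_j) ]

under a sparsity assumption: if most pairs are uncorrelated,
t_ij ≈ ω_i + ω_j with ω_i the basis variance of taxon i, giving the linear
system  Σ_{j≠i} t_ij = (D−2)·ω_i + Σ_j ω_j  whose solution yields

    ρ_ij = (ω_i + ω_j − t_ij) / (2·√(ω_i·ω_j)).

Strongly correlated pairs violate the sparsity assumption and are excluded
iteratively (largest |ρ| above a threshold, system re-solved) up to a cap.
The point estimate is the element-wise median over Dirichlet-resampled
fraction draws (counts + 1 pseudocount as posterior concentration); the
two-sided p-value comes from bootstrap datasets in which each taxon's
counts are independently permuted across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

__all__ = ["SparccParams", "CorrelationEstimate", "variation_matrix",
           "basis_correlations", "estimate"]

_OMEGA_FLOOR = 1e-10


@dataclass
class SparccParams:
    """Knobs of the correlation estimator.

    ``n_iterations`` Dirichlet-resampling rounds for the point estimate and
    ``n_bootstraps`` permuted datasets for p-values follow the "50
    iterations of 1,000 bootstraps" convention of the reference tool.
    ``bootstrap_iterations`` (default: same as ``n_iterations``) allows a
    cheaper p-value mode with fewer resampling rounds per bootstrap dataset.
    """

    n_iterations: int = 50
    n_bootstraps: int = 1000
    exclusion_threshold: float = 0.1
    max_exclusions: int | None = None   # None → 10% of taxon pairs
    bootstrap_iterations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.n_bootstraps < 1:
            raise ValueError("n_iterations and n_bootstraps must be >= 1")
        if not 0.0 < self.exclusion_threshold < 1.0:
            raise ValueError("exclusion_threshold must be in (0, 1)")


@dataclass
class CorrelationEstimate:
    """Taxa × taxa correlation matrix with bootstrap p-values."""

    rho: pd.DataFrame
    pvalue: pd.DataFrame
    basis_variance: pd.Series
    variation: pd.DataFrame
    params: SparccParams
    diagnostics: dict = field(default_factory=dict)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rho.index)

    def write(self, rho_path: str | Path,
              pvalue_path: str | Path | None = None) -> None:
        """Square TSVs mirroring the reference tool's output layout."""
        self.rho.to_csv(rho_path, sep="\t", float_format="%.6g")
        if pvalue_path is not None:
            self.pvalue.to_csv(pvalue_path, sep="\t", float_format="%.6g")


def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """Log-ratio variance t_ij = Var over samples of log(x_i/x_j).

    *fractions* is taxa × samples and must be strictly positive (apply a
    pseudocount upstream). Invariant to per-sample rescaling.
    """
    fractions = np.asarray(fractions, dtype=float)
    if (fractions <= 0).any():
        raise ValueError(
            "zero or negative fractions; apply a pseudocount before "
            "computing log-ratio variances")
    L = np.log(fractions)
    V = np.cov(L)                      # taxa × taxa covariance of logs
    V = np.atleast_2d(V)
    d = np.diag(V)
    t = d[:, None] + d[None, :] - 2 * V
    t = np.clip((t + t.T) / 2, 0.0, None)
    np.fill_diagonal(t, 0.0)
    return t


def basis_correlations(variation: np.ndarray,
                       exclusion_threshold: float = 0.1,
                       max_exclusions: int | None = None
                       ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Solve the sparsity approximation for basis variances and correlations.

    Returns ``(rho, omega, diagnostics)``. Iteratively excludes the
    strongest not-yet-excluded pair with |ρ| above *exclusion_threshold*
    (re-solving the linear system each time) until none qualifies or
    *max_exclusions* (default: 10% of pairs) is reached. Negative basis
    variances are floored at 1e-10 and recorded in the diagnostics.
    """
    t = np.asarray(variation, dtype=float)
    D = t.shape[0]
    if D < 4:
        raise ValueError(
            f"SparCC needs at least 4 taxa (got {D}); the basis-variance "
            f"system is underdetermined below that")
    if max_exclusions is None:
        max_exclusions = int(np.ceil(0.1 * D * (D - 1) / 2))

    M = np.ones((D, D))
    np.fill_diagonal(M, D - 1)
    include = np.ones((D, D), dtype=bool)   # pair (i,j) still in the system
    np.fill_diagonal(include, False)

    n_floored_total = 0

    def _solve() -> tuple[np.ndarray, np.ndarray]:
        nonlocal n_floored_total
        rowsum = (t * include).sum(axis=1)
        try:
            omega = np.linalg.solve(M, rowsum)
        except np.linalg.LinAlgError:
            omega = np.linalg.lstsq(M, rowsum, rcond=None)[0]
        n_floored_total += int((omega < _OMEGA_FLOOR).sum())
        omega = np.maximum(omega, _OMEGA_FLOOR)
        rho = (omega[:, None] + omega[None, :] - t) / (
            2 * np.sqrt(np.outer(omega, omega)))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return rho, omega

    rho, omega = _solve()
    excluded: list[tuple[int, int]] = []
    candidate = np.abs(rho.copy())
    np.fill_diagonal(candidate, 0.0)
    while len(excluded) < max_exclusions:
        candidate_masked = np.where(include, candidate, 0.0)
        i, j = np.unravel_index(np.argmax(candidate_masked), candidate.shape)
        if candidate_masked[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
        M[i, i] -= 1
        M[j, j] -= 1
        M[i, j] -= 1
        M[j, i] -= 1
        excluded.append((int(min(i, j)), int(max(i, j))))
        rho, omega = _solve()
        candidate = np.abs(rho.copy())
        np.fill_diagonal(candidate, 0.0)

    diagnostics = {"n_excluded_pairs": len(excluded),
                   "excluded_pairs": excluded,
                   "n_omega_floored": n_floored_total}
    return rho, omega, diagnostics


def _dirichlet_fractions(counts: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """One posterior draw of per-sample fractions, concentration counts+1."""
    g = rng.standard_gamma(counts + 1.0)
    return g / g.sum(axis=0, keepdims=True)


def _median_estimate(counts: np.ndarray, n_iterations: int,
                     exclusion_threshold: float, max_exclusions: int | None,
                     rng: np.random.Generator,
                     collect: bool = False):
    """Element-wise median of basis correlations over resampling rounds."""
    rhos, omegas, ts = [], [], []
    diag = {"n_excluded_pairs": 0, "n_omega_floored": 0}
    for _ in range(n_iterations):
        fracs = _dirichlet_fractions(counts, rng)
        t = variation_matrix(fracs)
        rho, omega, d = basis_correlations(t, exclusion_threshold,
                                           max_exclusions)
        rhos.append(rho)
        diag["n_excluded_pairs"] += d["n_excluded_pairs"]
        diag["n_omega_floored"] += d["n_omega_floored"]
        if collect:
            omegas.append(omega)
            ts.append(t)
    rho_med = np.median(rhos, axis=0)
    np.fill_diagonal(rho_med, 1.0)
    if collect:
        return rho_med, np.median(omegas, axis=0), np.median(ts, axis=0), diag
    return rho_med


def estimate(table: AbundanceTable,
             params: SparccParams | None = None) -> CorrelationEstimate:
    """Full SparCC estimate with bootstrap p-values.

    Point estimate: median over ``n_iterations`` Dirichlet resampling
    rounds. P-values: for each of ``n_bootstraps`` null datasets (each
    taxon's counts permuted independently across samples) the same
    median-of-iterations estimator is run and
    p_ij = (1 + #{|ρ_null| ≥ |ρ_obs|}) / (1 + n_bootstraps). Deterministic
    given ``params.seed``.
    """
    if params is None:
        params = SparccParams()
    counts = table.counts.to_numpy(dtype=float)
    D, n = counts.shape
    if D < 4:
        raise ValueError(f"SparCC needs at least 4 taxa, got {D}")

    ss = np.random.SeedSequence(params.seed)
    seed_point, seed_perm, seed_boot = ss.spawn(3)
    rng_point = np.random.default_rng(seed_point)

    rho, omega, t_med, diag = _median_estimate(
        counts, params.n_iterations, params.exclusion_threshold,
        params.max_exclusions, rng_point, collect=True)

    boot_iters = params.bootstrap_iterations or params.n_iterations
    rng_perm = np.random.default_rng(seed_perm)
    boot_streams = seed_boot.spawn(params.n_bootstraps)
    abs_obs = np.abs(rho)
    exceed = np.zeros((D, D), dtype=np.int64)
    for b in range(params.n_bootstraps):
        null_counts = np.empty_like(counts)
        for i in range(D):
            null_counts[i] = counts[i, rng_perm.permutation(n)]
        rho_null = _median_estimate(
            null_counts, boot_iters, params.exclusion_threshold,
            params.max_exclusions, np.random.default_rng(boot_streams[b]))
        exceed += np.abs(rho_null) >= abs_obs
    pval = (1.0 + exceed) / (1.0 + params.n_bootstraps)
    np.fill_diagonal(pval, 1.0)

    ids = table.taxon_ids
    return CorrelationEstimate(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        pvalue=pd.DataFrame(pval, index=ids, columns=ids),
        basis_variance=pd.Series(omega, index=ids, name="omega"),
        variation=pd.DataFrame(t_med, index=ids, columns=ids),
        params=params,
        diagnostics=diag)
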