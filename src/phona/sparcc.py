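"""Compositionally corrected OTU-OTU correlations (SparCC) with bootstrap
significance.

Sequencing counts are compositional: only relative abundances are observed,
so naive Pearson correlations of proportions are biased (the closure induces
spurious negative correlation).  SparCC works around the closure through
pairwise log-ratio variances.  Writing w_i for the latent absolute abundance
of OTU i, the variance of log(x_i/x_j) decomposes as

    T_ij = Var log(w_i/w_j) = omega_i^2 + omega_j^2 - 2 rho_ij omega_i omega_j

where omega_i^2 is the basis (log-abundance) variance of OTU i and rho_ij the
basis correlation.  Under a sparsity assumption (most rho_ij ~ 0) the
cross terms drop when summing over partners, leaving a linear system for the
basis variances:

    sum_{j != i} (omega_i^2 + omega_j^2) = sum_{j != i} T_ij

Correlations follow as rho_ij = (omega_i^2 + omega_j^2 - T_ij) /
(2 omega_i omega_j).  Strongly correlated pairs violate the sparsity
assumption, so the strongest pair above a threshold is iteratively excluded
from the sums and the system re-solved.  Count-level uncertainty and zeros
are handled by drawing fractions from a Dirichlet(counts + 1) posterior and
averaging the estimate over several draws.

Edge significance comes from a bootstrap null in which each OTU's counts are
resampled over samples independently, destroying inter-OTU association while
preserving marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .io_tables import OtuTable

__all__ = [
    "AssociationResult",
    "dirichlet_fractions",
    "logratio_variances",
    "basis_variances",
    "sparcc_correlations",
    "bootstrap_pvalues",
    "filter_associations",
]

DEFAULT_N_ITERATIONS = 20
DEFAULT_N_BOOTSTRAPS = 500
DEFAULT_EXCLUSION_THRESHOLD = 0.1
DEFAULT_N_EXCLUSION_ROUNDS = 10
DEFAULT_MIN_ABS_RHO = 0.5
DEFAULT_ALPHA = 0.05

_OMEGA_FLOOR = 1e-12


@dataclass(frozen=True)
class AssociationResult:
    """SparCC correlations and bootstrap p-values over one OTU set."""

    rho: pd.DataFrame
    pvals: pd.DataFrame | None
    n_iterations: int
    n_bootstraps: int = 0

    def __post_init__(self) -> None:
        r = self.rho.to_numpy()
        if not np.allclose(r, r.T, atol=1e-10):
            raise DataError("rho must be symmetric")
        if np.abs(r).max(initial=0.0) > 1 + 1e-9:
            raise DataError("rho entries must lie in [-1, 1]")

    @property
    def otu_ids(self) -> list[str]:
        return [str(o) for o in self.rho.index]


def dirichlet_fractions(table: OtuTable,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Per-sample fractions drawn from a Dirichlet(counts + 1) posterior.

    The add-one prior resolves zero counts so log-ratios are defined; rows
    sum to one and are strictly positive.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = table.counts
    fractions = np.empty(counts.shape, dtype=float)
    for i, row in enumerate(counts):
        fractions[i] = rng.dirichlet(row + 1.0)
    # dirichlet can return exact zeros for extreme alphas; clamp defensively
    np.clip(fractions, 1e-300, None, out=fractions)
    fractions /= fractions.sum(axis=1, keepdims=True)
    return fractions


def logratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Matrix T of sample variances of log(f_i / f_j) (unbiased, ddof=1)."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[0] < 2:
        raise DataError("log-ratio variances need at least 2 samples")
    if (fractions <= 0).any():
        raise DataError("fractions must be strictly positive")
    logf = np.log(fractions)
    cov = np.cov(logf, rowvar=False, ddof=1)
    var = np.diag(cov)
    T = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(T, 0.0)
    return np.clip(T, 0.0, None)


def basis_variances(T: np.ndarray,
                    excluded: frozenset[tuple[int, int]] | set[tuple[int, int]] = frozenset(),
                    ) -> np.ndarray:
    """Solve the sparsity-assumption linear system for basis variances.

    ``excluded`` holds unordered OTU index pairs dropped from the sums (pairs
    whose strong correlation breaks the sparsity assumption).  Negative
    solutions are floored at a small positive epsilon and reported by the
    caller as degenerate.
    """
    T = np.asarray(T, dtype=float)
    p = T.shape[0]
    if p < 4:
        raise DataError("SparCC basis variances need at least 4 OTUs")
    M = np.ones((p, p)) + np.eye(p) * (p - 2.0)
    t = T.sum(axis=1).astype(float)
    for i, j in excluded:
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        t[i] -= T[i, j]
        t[j] -= T[i, j]
    try:
        omega2 = np.linalg.solve(M, t)
    except np.linalg.LinAlgError:
        omega2 = np.linalg.lstsq(M, t, rcond=None)[0]
    return omega2


def _rho_from_basis(T: np.ndarray, omega2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix from log-ratio variances and basis variances.

    Returns (rho, degenerate) where ``degenerate`` flags OTUs whose solved
    basis variance was non-positive; their correlations are zeroed.
    """
    degenerate = omega2 <= 0
    w2 = np.clip(omega2, _OMEGA_FLOOR, None)
    w = np.sqrt(w2)
    rho = (w2[:, None] + w2[None, :] - T) / (2.0 * np.outer(w, w))
    rho = np.clip(rho, -1.0, 1.0)
    rho[degenerate, :] = 0.0
    rho[:, degenerate] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho, degenerate


def _sparcc_single(fractions: np.ndarray, exclusion_threshold: float,
                   n_exclusion_rounds: int) -> np.ndarray:
    """One SparCC estimate from a single fraction matrix."""
    T = logratio_variances(fractions)
    p = T.shape[0]
    excluded: set[tuple[int, int]] = set()
    omega2 = basis_variances(T, excluded)
    rho, degen = _rho_from_basis(T, omega2)
    for _ in range(n_exclusion_rounds):
        masked = np.abs(rho.copy())
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        # excluding too many partners leaves a singular system on tiny p
        if len(excluded) >= p * (p - 1) // 2 - p:
            break
        omega2 = basis_variances(T, excluded)
        rho, degen = _rho_from_basis(T, omega2)
    if degen.any():
        warnings.warn(
            f"{int(degen.sum())} OTU(s) had non-positive basis variance; "
            "their correlations were set to 0", RuntimeWarning, stacklevel=3
        )
    return rho


def sparcc_correlations(table: OtuTable,
                        n_iterations: int = DEFAULT_N_ITERATIONS,
                        exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
                        n_exclusion_rounds: int = DEFAULT_N_EXCLUSION_ROUNDS,
                        seed: int | np.random.Generator = 0) -> AssociationResult:
    """SparCC correlation matrix averaged over Dirichlet resampling iterations."""
    n, p = table.shape
    if p < 4:
        raise DataError("SparCC needs at least 4 OTUs")
    if n < 3:
        raise DataError("SparCC needs at least 3 samples")
    if n_iterations < 1:
        raise DataError("n_iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    acc = np.zeros((p, p))
    for _ in range(n_iterations):
        fractions = dirichlet_fractions(table, rng)
        acc += _sparcc_single(fractions, exclusion_threshold, n_exclusion_rounds)
    rho = np.clip(acc / n_iterations, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    ids = table.otu_ids
    return AssociationResult(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        pvals=None,
        n_iterations=n_iterations,
    )


def _null_counts(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample each OTU's counts over samples independently (breaks
    inter-OTU association, keeps per-OTU marginals)."""
    n, p = counts.shape
    idx = rng.integers(0, n, size=(n, p))
    return counts[idx, np.arange(p)]


def bootstrap_pvalues(table: OtuTable, rho_obs: pd.DataFrame | np.ndarray,
                      n_bootstraps: int = DEFAULT_N_BOOTSTRAPS,
                      seed: int | np.random.Generator = 0,
                      n_inner_iterations: int = 1,
                      exclusion_threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
                      n_exclusion_rounds: int = DEFAULT_N_EXCLUSION_ROUNDS,
                      ) -> pd.DataFrame:
    """Two-sided bootstrap p-values for each observed correlation.

    For every bootstrap data set, SparCC is re-run and the null |rho| per pair
    recorded; p_ij = (1 + #{null |rho_ij| >= |rho_obs_ij|}) / (1 + B).  The
    add-one numerator keeps the minimum attainable p at 1/(B+1).
    """
    if n_bootstraps < 1:
        raise DataError("n_bootstraps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho = rho_obs.to_numpy() if isinstance(rho_obs, pd.DataFrame) else np.asarray(rho_obs)
    n, p = table.shape
    abs_obs = np.abs(rho)
    exceed = np.zeros((p, p))
    index = table.data.index
    columns = table.data.columns
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_bootstraps):
            boot = OtuTable(pd.DataFrame(_null_counts(table.counts, rng),
                                         index=index, columns=columns))
            null = sparcc_correlations(
                boot, n_iterations=n_inner_iterations,
                exclusion_threshold=exclusion_threshold,
                n_exclusion_rounds=n_exclusion_rounds, seed=rng,
            ).rho.to_numpy()
            exceed += np.abs(null) >= abs_obs
    pvals = (1.0 + exceed) / (1.0 + n_bootstraps)
    pvals = (pvals + pvals.T) / 2.0
    np.fill_diagonal(pvals, 1.0)
    ids = table.otu_ids
    return pd.DataFrame(pvals, index=ids, columns=ids)


def filter_associations(result: AssociationResult,
                        min_abs_rho: float = DEFAULT_MIN_ABS_RHO,
                        alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Edge set of pairs with |rho| strictly above ``min_abs_rho`` and
    p strictly below ``alpha``.

    Returns a DataFrame with columns source, target, weight, sign; OTUs with
    no retained pair simply do not appear.
    """
    if result.pvals is None:
        raise DataError("AssociationResult has no p-values; run bootstrap_pvalues")
    rho = result.rho.to_numpy()
    pv = result.pvals.to_numpy()
    ids = result.otu_ids
    rows = []
    p = len(ids)
    for i in range(p):
        for j in range(i + 1, p):
            if abs(rho[i, j]) > min_abs_rho and pv[i, j] < alpha:
                rows.append({
                    "source": ids[i],
                    "target": ids[j],
                    "weight": rho[i, j],
                    "sign": "positive" if rho[i, j] > 0 else "negative",
                })
    return pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])


def write_square_matrix(m: pd.DataFrame, path) -> None:
    """Write rho or pvals as a square TSV with OTU ids as header."""
    m.to_csv(path, sep="\t")


def read_square_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
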