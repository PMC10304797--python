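"""Synthetic data with the statistical structure the pipeline assumes.

Counts are generated compositionally: latent absolute (basis) abundances are
multivariate log-normal with a user-planted correlation structure, and each
sample's reads are a multinomial draw of fixed depth on the normalised
basis.  Observing only the closure is precisely what makes naive Pearson
correlations of proportions biased, so this generator exercises the
compositional correction rather than sidestepping it.  A negative-binomial
count mode (per-OTU means scaled by planted per-treatment fold changes, with
a common dispersion) backs the differential-abundance statistics.

Phenotypes are linear in the standardized relative abundances of a planted
OTU subset plus Gaussian noise.  Every generator returns the ground truth
alongside the data; tests treat the generating parameters as the oracle and
never re-derive truth from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .io_tables import OtuTable, PhenotypeVector

__all__ = ["SynthConfig", "generate_counts", "generate_phenotype", "generate_design"]


@dataclass
class SynthConfig:
    """Parameters of one synthetic data set.

    Basis log-abundance means are N(0, 1) offsets and log-sds uniform on
    [0.5, 1.5] (both drawn once from the seed), spanning the couple of orders
    of magnitude of abundance and the strong per-OTU variability typical of
    rarefied amplicon tables.
    """

    n_samples: int = 100
    n_otus: int = 60
    depth: int = 5000
    correlations: list[tuple[int, int, float]] = field(default_factory=list)
    phenotype_betas: list[tuple[int, float]] = field(default_factory=list)
    phenotype_noise_sd: float = 1.0
    treatment_levels: list[str] = field(default_factory=list)
    compartment_levels: list[str] = field(default_factory=list)
    # fold changes: {otu index: {treatment level: linear fold change}}
    fold_changes: dict[int, dict[str, float]] = field(default_factory=dict)
    count_model: str = "multinomial"  # or "negative-binomial"
    nb_dispersion: float = 0.5
    # NB mode pins the fold-change OTUs to this baseline proportion so the
    # planted effect size stays interpretable: enriching dominant taxa mostly
    # perturbs everyone else's relative abundances (compositional dilution),
    # whereas treatment-responsive taxa are typically subdominant.
    fold_change_baseline_prop: float | None = 0.001
    seed: int = 0


def _basis_covariance(cfg: SynthConfig, sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation and covariance matrices from the planted pair spec."""
    p = cfg.n_otus
    corr = np.eye(p)
    for i, j, rho in cfg.correlations:
        if not (0 <= i < p and 0 <= j < p) or i == j:
            raise DataError(f"bad correlation spec ({i}, {j}, {rho})")
        if not -1 < rho < 1:
            raise DataError(f"rho must lie in (-1, 1), got {rho}")
        corr[i, j] = corr[j, i] = rho
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < 1e-8:
        floored = np.clip(eigval, 1e-6, None)
        corr = eigvec @ np.diag(floored) @ eigvec.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        warnings.warn("correlation spec not positive definite; eigenvalues "
                      "floored and matrix renormalised", RuntimeWarning)
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise DataError("correlation spec could not be repaired")
    cov = corr * np.outer(sigma, sigma)
    return corr, cov


def generate_design(cfg: SynthConfig) -> pd.DataFrame:
    """Balanced factorial sample metadata (treatment x compartment).

    Every level combination receives the same number of samples; an
    n_samples that the number of combinations does not divide is an error.
    """
    levels_t = cfg.treatment_levels or ["T1"]
    levels_c = cfg.compartment_levels or ["C1"]
    combos = [(t, c) for t in levels_t for c in levels_c]
    if cfg.n_samples % len(combos):
        raise DataError(
            f"{cfg.n_samples} samples cannot be balanced over {len(combos)} "
            "treatment x compartment combinations"
        )
    reps = cfg.n_samples // len(combos)
    rows = [{"treatment": t, "compartment": c} for t, c in combos for _ in range(reps)]
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(cfg.n_samples)
    df = pd.DataFrame(rows).iloc[order].reset_index(drop=True)
    df.index = [f"S{i:04d}" for i in range(cfg.n_samples)]
    df.index.name = "sample"
    return df


def generate_counts(cfg: SynthConfig,
                    design: pd.DataFrame | None = None) -> tuple[OtuTable, dict]:
    """Count table plus ground truth.

    Multinomial mode: per-sample multinomial(depth, normalised log-normal
    basis), so every row sums exactly to ``depth``.  Negative-binomial mode:
    counts NB(mean = depth * expected proportion, dispersion) for
    differential-abundance testing; rows then vary around ``depth``.
    Planted per-treatment fold changes multiply the basis abundance of the
    designated OTUs before counts are drawn.
    """
    rng = np.random.default_rng(cfg.seed)
    p, n = cfg.n_otus, cfg.n_samples
    mu = rng.normal(0.0, 1.0, size=p)
    sigma = rng.uniform(0.5, 1.5, size=p)
    corr, cov = _basis_covariance(cfg, sigma)
    if cfg.count_model == "negative-binomial":
        # NB mode: expected proportions are fixed per group so that the only
        # between-sample variation is the NB dispersion itself
        if cfg.fold_changes and cfg.fold_change_baseline_prop is not None:
            base = np.exp(mu)
            share = base / base.sum()
            for otu_idx in cfg.fold_changes:
                share[otu_idx] = cfg.fold_change_baseline_prop
            mu = np.log(share / share.sum())
        log_basis = np.tile(mu, (n, 1))
    else:
        log_basis = rng.multivariate_normal(mu, cov, size=n, method="cholesky")

    sample_ids = (list(design.index) if design is not None
                  else [f"S{i:04d}" for i in range(n)])
    if design is not None and len(design) != n:
        raise DataError("design rows must equal n_samples")
    if cfg.fold_changes:
        if design is None:
            raise DataError("fold changes need a design (generate_design first)")
        treatment = design["treatment"].astype(str).to_numpy()
        for otu_idx, per_level in cfg.fold_changes.items():
            for level, fc in per_level.items():
                if fc <= 0:
                    raise DataError(f"fold change must be positive, got {fc}")
                log_basis[treatment == level, otu_idx] += np.log(fc)

    basis = np.exp(log_basis)
    props = basis / basis.sum(axis=1, keepdims=True)
    counts = np.empty((n, p), dtype=np.int64)
    if cfg.count_model == "multinomial":
        for i in range(n):
            counts[i] = rng.multinomial(cfg.depth, props[i])
    elif cfg.count_model == "negative-binomial":
        mean = cfg.depth * props
        if cfg.nb_dispersion <= 0:
            raise DataError("nb_dispersion must be positive")
        r = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape=r, scale=mean / r)
        counts[:] = rng.poisson(lam)
    else:
        raise DataError(f"unknown count_model: {cfg.count_model!r}")

    table = OtuTable(pd.DataFrame(counts, index=sample_ids,
                                  columns=[f"OTU{j:04d}" for j in range(p)]))
    truth = {
        "correlation_matrix": corr,
        "planted_pairs": [(i, j, rho) for i, j, rho in cfg.correlations],
        "mu": mu,
        "sigma": sigma,
        "log_basis": log_basis,
        "fold_changes": cfg.fold_changes,
        "count_model": cfg.count_model,
        "seed": cfg.seed,
    }
    return table, truth


def generate_phenotype(table: OtuTable, cfg: SynthConfig) -> tuple[PhenotypeVector, dict]:
    """Phenotype linear in standardized relative abundances of planted OTUs."""
    rel = table.relative_abundance().to_numpy()
    n, p = rel.shape
    for idx, _ in cfg.phenotype_betas:
        if not 0 <= idx < p:
            raise DataError(f"phenotype OTU index {idx} out of range")
    rng = np.random.default_rng(cfg.seed + 1)
    y = np.zeros(n)
    for idx, beta in cfg.phenotype_betas:
        col = rel[:, idx]
        sd = col.std(ddof=1)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        y += beta * z
    y += rng.normal(0.0, cfg.phenotype_noise_sd, size=n)
    vec = PhenotypeVector(pd.Series(y, index=table.data.index, name="phenotype"),
                          units="arbitrary")
    truth = {
        "betas": {table.otu_ids[idx]: beta for idx, beta in cfg.phenotype_betas},
        "signs": {table.otu_ids[idx]: ("positive" if beta >= 0 else "negative")
                  for idx, beta in cfg.phenotype_betas},
        "noise_sd": cfg.phenotype_noise_sd,
    }
    return vec, truth
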