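"""Supporting community statistics.

Alpha diversity (observed richness, Shannon entropy in nats), Bray-Curtis
dissimilarity with a sequential (type-I) PERMANOVA, and per-OTU negative
binomial differential abundance with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError
from .io_tables import OtuTable

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "permanova",
    "fit_nb_per_otu",
    "bh_adjust",
]

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_FDR_ALPHA = 0.01


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample observed richness and Shannon entropy (nats).

    H = -sum p_i ln p_i over nonzero proportions; an all-zero sample gets
    richness 0 and H = 0.
    """
    counts = table.counts.astype(float)
    richness = (counts > 0).sum(axis=1)
    shannon = np.zeros(len(counts))
    for i, row in enumerate(counts):
        if row.sum() > 0:
            shannon[i] = scipy.stats.entropy(row)  # normalises and uses ln
    return pd.DataFrame({"richness": richness, "shannon": shannon},
                        index=table.data.index)


def bray_curtis(table: OtuTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix, d in [0, 1].

    A pair of all-zero samples has an undefined quotient; it is reported as
    0 with a warning (identical emptiness).
    """
    counts = table.counts.astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(counts, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair(s); distance set to 0", RuntimeWarning)
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=table.data.index, columns=table.data.index)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(d: pd.DataFrame | np.ndarray, design: pd.DataFrame,
              terms: list[str] | None = None,
              n_perm: int = DEFAULT_N_PERMUTATIONS,
              seed: int = 0) -> pd.DataFrame:
    """Sequential (type-I) PERMANOVA on a distance matrix.

    Sums of squares are partitioned term by term via hat matrices on the
    Gower-centered squared distances (the adonis construction); p-values come
    from free permutation of sample labels.  Returns one row per term plus a
    Residual/Total block with df, SS, R2, pseudo-F and p.
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        dm = d.to_numpy(dtype=float)
        design = design.loc[ids]
    else:
        dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    if dm.shape[0] != dm.shape[1]:
        raise DataError("distance matrix must be square")
    if len(design) != n:
        raise DataError("design rows must match distance matrix")
    if terms is None:
        terms = list(design.columns)
    for t in terms:
        if design[t].nunique() < 2:
            raise DataError(f"factor {t!r} has a single level")
    g = _gower_center(dm)
    ss_total = np.trace(g)

    # cumulative hat matrices, intercept first
    hats = [np.full((n, n), 1.0 / n)]
    dfs = []
    x = np.ones((n, 1))
    for t in terms:
        dummies = pd.get_dummies(design[t].astype(str), drop_first=True).to_numpy(float)
        x = np.column_stack([x, dummies])
        h = _hat(x)
        dfs.append(int(round(np.trace(h - hats[-1]))))
        hats.append(h)
    df_resid = n - int(round(np.trace(hats[-1])))
    if df_resid <= 0:
        raise DataError("no residual degrees of freedom")

    def stats(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([np.trace((hats[k + 1] - hats[k]) @ gm)
                             for k in range(len(terms))])
        ss_res = np.trace((np.eye(n) - hats[-1]) @ gm)
        f = (ss_terms / np.array(dfs)) / (ss_res / df_resid)
        return f, ss_res

    f_obs, ss_res = stats(g)
    ss_terms = np.array([np.trace((hats[k + 1] - hats[k]) @ g)
                         for k in range(len(terms))])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_perm, _ = stats(g[np.ix_(perm, perm)])
        exceed += f_perm >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, t in enumerate(terms):
        rows.append({"term": t, "df": dfs[k], "ss": ss_terms[k],
                     "R2": ss_terms[k] / ss_total, "pseudo_F": f_obs[k],
                     "p": pvals[k]})
    rows.append({"term": "Residual", "df": df_resid, "ss": ss_res,
                 "R2": ss_res / ss_total, "pseudo_F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "ss": ss_total, "R2": 1.0,
                 "pseudo_F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_ALPHA_BOUNDS = (1e-6, 50.0)


def _nb_glm(y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: float):
    fam = sm.families.NegativeBinomial(alpha=alpha)
    return sm.GLM(y, x, family=fam, offset=offset).fit()


def _cr_profile(alpha: float, y: np.ndarray, x: np.ndarray,
                offset: np.ndarray) -> tuple[float, object]:
    """Cox-Reid adjusted profile log-likelihood of the NB2 dispersion.

    The -0.5 log det(X'WX) adjustment removes the downward bias of plain
    profile ML that comes from estimating the mean parameters; without it
    small-sample dispersion estimates correlate negatively with the test
    statistic and inflate the deep tail of the null.
    """
    res = _nb_glm(y, x, offset, alpha)
    mu = res.mu
    w = mu / (1.0 + alpha * mu)  # IRLS weights, log link
    _, logdet = np.linalg.slogdet((x * w[:, None]).T @ x)
    return res.llf - 0.5 * logdet, res


def _alpha_moments(y: np.ndarray, x: np.ndarray, offset: np.ndarray) -> float:
    """Fallback: df-corrected Pearson method-of-moments dispersion."""
    n, k = x.shape
    res = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset).fit()
    alpha = 0.0
    for _ in range(8):
        mu = res.mu
        a_new = float(((y - mu) ** 2 - mu).sum() / (mu ** 2).sum() * n / (n - k))
        a_new = min(max(a_new, _ALPHA_BOUNDS[0]), _ALPHA_BOUNDS[1])
        if abs(a_new - alpha) < 1e-6:
            return a_new
        alpha = a_new
        res = _nb_glm(y, x, offset, alpha)
    return alpha


def _fit_nb(y: np.ndarray, x: np.ndarray, offset: np.ndarray):
    """NB2 fit with per-OTU Cox-Reid adjusted ML dispersion.

    Returns (result, alpha) or (None, None) on failure.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")

            def neg(log_a: float) -> float:
                try:
                    return -_cr_profile(float(np.exp(log_a)), y, x, offset)[0]
                except Exception:
                    return np.inf
            opt = scipy.optimize.minimize_scalar(
                neg, bounds=tuple(np.log(_ALPHA_BOUNDS)), method="bounded",
                options={"xatol": 1e-3})
            if np.isfinite(opt.fun):
                alpha = float(np.exp(opt.x))
            else:
                alpha = _alpha_moments(y, x, offset)
            res = _nb_glm(y, x, offset, alpha)
        if not np.isfinite(res.llf):
            return None, None
        return res, alpha
    except Exception:
        return None, None


@dataclass(frozen=True)
class _ContrastSpec:
    level: str
    control: str

    @property
    def name(self) -> str:
        return f"{self.level}_vs_{self.control}"


def fit_nb_per_otu(table: OtuTable, design: pd.DataFrame, group_col: str,
                   contrasts: list[tuple[str, str]],
                   alpha: float = DEFAULT_FDR_ALPHA) -> pd.DataFrame:
    """Per-OTU negative binomial differential abundance.

    For each (level, control) contrast, samples of the two groups are
    modelled as NB counts with a log link, log-library-size offset and
    per-OTU Cox-Reid adjusted ML dispersion; the group effect is tested by
    likelihood ratio against the intercept-only model at that dispersion.  q-values are BH-adjusted within each
    contrast family; status is enriched/depleted at q < ``alpha`` by the sign
    of the log2 fold change.  Non-convergent OTUs are flagged and excluded
    from the BH family.
    """
    groups = design.loc[table.data.index, group_col].astype(str)
    counts = table.counts
    libsize = counts.sum(axis=1).astype(float)
    if (libsize == 0).any():
        raise DataError("samples with zero total count cannot be offset")
    log_lib = np.log(libsize)
    records = []
    for level, control in contrasts:
        spec = _ContrastSpec(str(level), str(control))
        mask = (groups == spec.level) | (groups == spec.control)
        if (groups == spec.level).sum() < 2 or (groups == spec.control).sum() < 2:
            raise DataError(
                f"contrast {spec.name} needs >= 2 samples per level"
            )
        y_all = counts[mask.to_numpy()]
        is_level = (groups[mask] == spec.level).to_numpy(dtype=float)
        x_full = np.column_stack([np.ones(len(is_level)), is_level])
        x_null = np.ones((len(is_level), 1))
        offs = log_lib[mask.to_numpy()]
        for j, otu in enumerate(table.otu_ids):
            y = y_all[:, j].astype(float)
            if y.sum() == 0:
                records.append({"otu": otu, "contrast": spec.name,
                                "log2_fc": 0.0, "lrt_stat": 0.0, "p": 1.0,
                                "converged": True})
                continue
            full, disp_hat = _fit_nb(y, x_full, offs)
            if full is None:
                records.append({"otu": otu, "contrast": spec.name,
                                "log2_fc": np.nan, "lrt_stat": np.nan,
                                "p": np.nan, "converged": False})
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    null = _nb_glm(y, x_null, offs, disp_hat)
            except Exception:
                null = None
            if null is None or not np.isfinite(null.llf):
                records.append({"otu": otu, "contrast": spec.name,
                                "log2_fc": np.nan, "lrt_stat": np.nan,
                                "p": np.nan, "converged": False})
                continue
            lrt = max(0.0, 2.0 * (full.llf - null.llf))
            p = scipy.stats.chi2.sf(lrt, df=1)
            records.append({"otu": otu, "contrast": spec.name,
                            "log2_fc": full.params[1] / np.log(2.0),
                            "lrt_stat": lrt, "p": p, "converged": True})
    out = pd.DataFrame.from_records(records)
    n_bad = int((~out["converged"]).sum())
    if n_bad:
        warnings.warn(f"{n_bad} OTU fits did not converge; excluded from FDR",
                      RuntimeWarning)
    out["q"] = np.nan
    for name, idx in out.groupby("contrast").groups.items():
        sub = out.loc[idx]
        ok = sub["converged"] & sub["p"].notna()
        if ok.any():
            out.loc[sub.index[ok], "q"] = bh_adjust(sub.loc[ok, "p"].to_numpy())
    status = np.where(
        (out["q"] < alpha) & (out["log2_fc"] > 0), "enriched",
        np.where((out["q"] < alpha) & (out["log2_fc"] < 0), "depleted", "ns"),
    )
    out["status"] = np.where(out["converged"], status, "ns")
    return out
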