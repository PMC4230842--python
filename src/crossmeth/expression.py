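"""Negative-binomial GLM differential expression with deviance ANOVA.

Counts are modelled as NB with a log link and library-size offset; the fit
is iteratively reweighted least squares, batched across genes (all genes
share the design matrix). Significance of each factor or interaction term
comes from an analysis-of-deviance: the model is refitted without the
term's columns and the deviance difference is referred to chi-squared with
the term's degrees of freedom -- one simultaneous test per term rather than
per coefficient, which keeps the multiple-testing burden down. Gene-wise
dispersions are estimated by Cox-Reid adjusted profile likelihood and
shrunk toward a mean-dependent trend with a fixed prior weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def build_design(
    design: pd.DataFrame, factors: list[str]
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Full-factorial treatment-coded design matrix with all interactions.

    Returns (X, term_slices) where term_slices maps "Intercept", each main
    effect, and each interaction (e.g. ``"tissue:treatment"``) to its column
    indices. Reference level of each factor = first appearance in the frame.
    """
    cols: list[np.ndarray] = [np.ones(len(design))]
    names: list[str] = ["Intercept"]
    term_slices: dict[str, list[int]] = {"Intercept": [0]}
    level_cols: dict[str, list[tuple[str, np.ndarray]]] = {}
    for f in factors:
        levels = list(pd.unique(design[f]))
        level_cols[f] = [
            (lv, (design[f] == lv).to_numpy(float)) for lv in levels[1:]
        ]
    idx = 1
    for order in range(1, len(factors) + 1):
        for combo in combinations(factors, order):
            term = ":".join(combo)
            term_slices[term] = []
            # product over the chosen factors' non-reference indicator columns
            def expand(i: int, cur: np.ndarray, label: str):
                nonlocal idx
                if i == len(combo):
                    cols.append(cur)
                    names.append(label)
                    term_slices[term].append(idx)
                    idx += 1
                    return
                for lv, col in level_cols[combo[i]]:
                    expand(i + 1, cur * col, f"{label}{'&' if label else ''}{combo[i]}[{lv}]")

            expand(0, np.ones(len(design)), "")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    return X, term_slices


# ---------------------------------------------------------------------------
# RPKM and expression filter
# ---------------------------------------------------------------------------


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM = 1e9 * count / (library_size * gene_length)."""
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return 1e9 * counts.div(lib, axis=1).div(lengths, axis=0)


def species_rpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, sample_species: pd.Series
) -> pd.DataFrame:
    """Species-level RPKM from summed counts and summed library sizes."""
    out = {}
    for sp in pd.unique(sample_species):
        cols = sample_species.index[sample_species == sp]
        pooled = counts[cols].sum(axis=1).to_frame(sp)
        out[sp] = rpkm(pooled, gene_lengths)[sp]
    return pd.DataFrame(out)


def expressed_filter(
    rpkm_matrix: pd.DataFrame, min_rpkm: float = 3.0, min_samples: int = 3
) -> pd.Series:
    """Gene is expressed iff >= min_samples samples reach >= min_rpkm."""
    return (rpkm_matrix >= min_rpkm).sum(axis=1) >= min_samples


# ---------------------------------------------------------------------------
# batched NB GLM
# ---------------------------------------------------------------------------


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB (or Poisson when phi ~ 0) residual deviance."""
    y = np.asarray(y, float)
    mu = np.maximum(mu, 1e-10)
    phi = np.asarray(phi, float).reshape(-1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        r = 1.0 / np.maximum(phi, 1e-12)
        nb_term2 = (y + r) * np.log((y + r) / (mu + r))
        pois_term2 = y - mu
        term2 = np.where(phi > 1e-12, nb_term2, pois_term2)
    return 2.0 * np.sum(term1 - term2, axis=1)


@dataclass
class BatchFit:
    beta: np.ndarray  # genes x p
    mu: np.ndarray  # genes x samples
    deviance: np.ndarray
    converged: np.ndarray


def fit_nb_glm(
    counts: np.ndarray,
    X: np.ndarray,
    phi: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> BatchFit:
    """IRLS NB GLM fit with log link and offset, batched across genes."""
    y = np.asarray(counts, float)
    G, n = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, float), (G,)).copy()
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    dev = nb_deviance(y, mu, phi)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        W = mu / (1.0 + phi[:, None] * mu)  # working weights for log link
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("ni,gn,nj->gij", X, W, X)
        b = np.einsum("ni,gn->gi", X, W * z)
        A[:, np.arange(p), np.arange(p)] += 1e-10  # ridge for numerical safety
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        eta = offset[None, :] + beta @ X.T
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        new_dev = nb_deviance(y, mu, phi)
        delta = np.abs(new_dev - dev) / (np.abs(new_dev) + 1.0)
        converged = delta < tol
        dev = new_dev
        if converged.all():
            break
    return BatchFit(beta=beta, mu=mu, deviance=dev, converged=converged)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood (phi > 0)."""
    r = 1.0 / np.maximum(phi, 1e-12)[:, None]
    mu = np.maximum(mu, 1e-10)
    return np.sum(
        stats.nbinom.logpmf(y, r, r / (r + mu)),
        axis=1,
    )


def _adjusted_profile_loglik(
    y: np.ndarray, X: np.ndarray, phi: np.ndarray, offset: np.ndarray
) -> np.ndarray:
    """Cox-Reid APL: NB loglik at the fitted betas minus 0.5 log det(X'WX)."""
    fit = fit_nb_glm(y, X, phi, offset, max_iter=25)
    W = fit.mu / (1.0 + phi[:, None] * fit.mu)
    A = np.einsum("ni,gn,nj->gij", X, W, X)
    sign, logdet = np.linalg.slogdet(A)
    ll = _nb_loglik(y, fit.mu, phi)
    return ll - 0.5 * logdet


def estimate_dispersion(
    counts: pd.DataFrame | np.ndarray,
    design: pd.DataFrame,
    factors: list[str] | None = None,
    prior_weight: float = 10.0,
    grid: np.ndarray | None = None,
    n_trend_bins: int = 20,
) -> pd.Series | np.ndarray:
    """Gene-wise NB dispersion by adjusted-profile-likelihood maximization.

    The APL is profiled on a log-spaced grid; the per-gene maximizer is
    refined by quadratic interpolation, a mean-dependent trend (binned
    median of the gene-wise estimates) is formed, and the final estimate
    shrinks the gene-wise value toward the trend in log space with weight
    ``prior_weight`` against the gene's residual degrees of freedom.
    All-zero genes get NaN; estimates are floored at 1e-6.
    """
    is_df = isinstance(counts, pd.DataFrame)
    y = counts.to_numpy(float) if is_df else np.asarray(counts, float)
    factors = factors or [
        f for f in ("species", "tissue", "treatment") if f in design and design[f].nunique() > 1
    ]
    X, _ = build_design(design, factors)
    G, n = y.shape
    if n - X.shape[1] < 1:
        raise ValueError("need at least 2 replicates per design cell")
    offset = np.log(np.maximum(y.sum(axis=0), 1.0))
    nonzero = y.sum(axis=1) > 0
    yz = y[nonzero]
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-4), np.log(10.0), 25))
    log_grid = np.log(grid)
    apl = np.empty((len(grid), int(nonzero.sum())))
    for i, phi in enumerate(grid):
        apl[i] = _adjusted_profile_loglik(yz, X, np.full(yz.shape[0], phi), offset)

    # mean-dependent trend: per mean-count bin, the shared APL curve
    mean_count = yz.mean(axis=1)
    order = np.argsort(mean_count)
    bins = np.array_split(order, min(n_trend_bins, max(1, len(order) // 10)))
    bin_curve = np.empty((len(grid), len(bins)))
    bin_of_gene = np.empty(yz.shape[0], dtype=int)
    for bi, b in enumerate(bins):
        bin_curve[:, bi] = apl[:, b].mean(axis=1)
        bin_of_gene[b] = bi

    def _argmax_interp(curve: np.ndarray) -> float:
        i = int(np.argmax(curve))
        if 0 < i < len(curve) - 1:
            y0, y1, y2 = curve[i - 1], curve[i], curve[i + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            shift = float(np.clip(shift, -1.0, 1.0))
            return float(np.exp(log_grid[i] + shift * (log_grid[i + 1] - log_grid[i])))
        return float(grid[i])

    # tagwise: gene APL moderated by the bin's shared curve with fixed weight
    phi_hat = np.empty(yz.shape[0])
    for g in range(yz.shape[0]):
        moderated = apl[:, g] + prior_weight * bin_curve[:, bin_of_gene[g]]
        phi_hat[g] = _argmax_interp(moderated)
    shrunk = np.maximum(phi_hat, DISPERSION_FLOOR)
    out = np.full(G, np.nan)
    out[nonzero] = shrunk
    if is_df:
        return pd.Series(out, index=counts.index, name="dispersion")
    return out


def fit_and_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    dispersions: pd.Series | np.ndarray,
    factors: list[str] | None = None,
    library_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit the factorial NB GLM and test every term by analysis of deviance.

    For each main effect and interaction, the model is refitted without
    that term's columns and p = chi2.sf(dev_reduced - dev_full, df_term).
    Returns a per-gene frame with coefficients, deviance, convergence flag
    and one ``p_<term>`` column per term; all-zero or non-converged genes
    carry NaN p-values.
    """
    factors = factors or [
        f for f in ("species", "tissue", "treatment") if f in design and design[f].nunique() > 1
    ]
    y = counts.to_numpy(float)
    X, term_slices = build_design(design, factors)
    phi = np.asarray(dispersions, float)
    lib = y.sum(axis=0) if library_sizes is None else np.asarray(library_sizes, float)
    offset = np.log(np.maximum(lib, 1.0))
    usable = (y.sum(axis=1) > 0) & np.isfinite(phi)
    yz = y[usable]
    phz = phi[usable]
    full = fit_nb_glm(yz, X, phz, offset)
    out = pd.DataFrame(index=counts.index)
    out["deviance"] = np.nan
    out.loc[usable, "deviance"] = full.deviance
    out["converged"] = False
    out.loc[usable, "converged"] = full.converged
    terms = [t for t in term_slices if t != "Intercept"]
    for term in terms:
        keep = [i for i in range(X.shape[1]) if i not in term_slices[term]]
        red = fit_nb_glm(yz, X[:, keep], phz, offset)
        diff = np.maximum(red.deviance - full.deviance, 0.0)
        df_term = len(term_slices[term])
        p = stats.chi2.sf(diff, df_term)
        p = np.where(full.converged & red.converged, p, np.nan)
        out[f"p_{term}"] = np.nan
        out.loc[usable, f"p_{term}"] = p
    for j, name in enumerate(_column_names(term_slices, X.shape[1])):
        out[f"coef_{name}"] = np.nan
        out.loc[usable, f"coef_{name}"] = full.beta[:, j]
    return out


def _column_names(term_slices: dict[str, list[int]], p: int) -> list[str]:
    names = [""] * p
    for term, cols in term_slices.items():
        for k, c in enumerate(cols):
            names[c] = term if len(cols) == 1 else f"{term}.{k}"
    return names


def log2_fold_change(fits: pd.DataFrame, term: str) -> pd.Series:
    """log2 fold change of a single-column term from the natural-log coef."""
    return fits[f"coef_{term}"] / np.log(2.0)


def methylation_expression_correlation(
    assoc: pd.DataFrame,
    log2fc: pd.Series,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of differential methylation with expression change.

    ``assoc`` has one row per (gene, feature-class) association with a
    ``meth_value`` column: the DMP direction (+-1) or the DMR
    methylation-rate difference. Ties are handled by scipy's midrank
    convention. Classes with fewer than ``min_genes`` distinct genes are
    reported as unavailable (NaN rho).
    """
    rows = []
    for feature, sub in assoc.groupby("feature"):
        sub = sub[sub["gene_id"].isin(log2fc.dropna().index)]
        n = sub["gene_id"].nunique()
        if n < min_genes:
            rows.append({"feature": feature, "n_genes": n, "rho": np.nan, "p": np.nan})
            continue
        x = sub["meth_value"].to_numpy(float)
        yv = log2fc.reindex(sub["gene_id"]).to_numpy(float)
        rho, p = stats.spearmanr(x, yv)
        rows.append({"feature": feature, "n_genes": n, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)
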