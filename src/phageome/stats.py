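"""Statistical layer of the phageome pipeline.

Alpha diversity (Shannon index, natural log), log-transformation of the VRU
table, Pearson-correlation distances, classical PCoA, an adonis-style
PERMANOVA with sequential sums of squares, and the two longitudinal mixed
models: a Gaussian LMM on log abundance and a binomial GLMM on phage
presence, both with a random intercept per infant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from phageome.glmm import fit_logistic_random_intercept

logger = logging.getLogger("phageome")

# indicator encodings of the cohort covariates; the named level codes as 1
_TERM_ENCODINGS = {
    "treatment": ("treatment", "PE"),
    "delivery": ("delivery", "vaginal"),
    "age": ("age_months", 12),
}


@dataclass
class DistanceMatrix:
    """A symmetric distance matrix with a zero diagonal over sample IDs."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-10).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class LmmResult:
    """Fitted mixed model: per-term (estimate, std error, p), intercept SD."""

    coefficients: dict[str, tuple[float, float, float]]
    random_intercept_sd: float
    model_family: str  # "gaussian_log" | "binomial"
    n_obs: int
    converged: bool
    message: str = ""


# ---------------------------------------------------------------------------
# Diversity and distances


def shannon_diversity(abundance_vector: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i in nats."""
    x = np.asarray(abundance_vector, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0:
        raise ValueError("all-zero abundance vector has no diversity")
    return float(entropy(x))  # scipy normalises and uses natural log


def default_pseudocount(table: pd.DataFrame | np.ndarray) -> float:
    """Half the smallest nonzero value of the table."""
    values = np.asarray(table, dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("table has no nonzero entries")
    return float(nonzero.min() / 2.0)


def log_transform(
    table: pd.DataFrame | np.ndarray, pseudocount: float | None = None
) -> pd.DataFrame | np.ndarray:
    """Element-wise ln(x + pseudocount).

    With ``pseudocount=None`` half the smallest nonzero entry is used; an
    explicit 0 is only valid on strictly positive tables.
    """
    values = np.asarray(table, dtype=float)
    if pseudocount is None:
        pseudocount = default_pseudocount(values) if (values == 0).any() else 0.0
    if pseudocount == 0 and (values <= 0).any():
        raise ValueError("zeros present: a positive pseudocount is required")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    out = np.log(values + pseudocount)
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(out, index=table.index, columns=table.columns)
    return out


def pearson_distance(log_table: pd.DataFrame) -> DistanceMatrix:
    """d(i, j) = 1 - Pearson r between the profile rows of samples i and j."""
    X = np.asarray(log_table, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = list(log_table.index[sd == 0])
        raise ValueError(f"zero-variance sample profile(s): {bad}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrise away float noise
    return DistanceMatrix(ids=list(log_table.index), d=d)


# ---------------------------------------------------------------------------
# Ordination


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Classical scaling (principal coordinates analysis).

    Returns ``(coordinates, eigenvalues, proportion_explained)``: axes
    ordered by decreasing eigenvalue; coordinates span the positive
    eigenvalues only; negative eigenvalues (possible for non-Euclidean
    distances such as 1 - r) are reported but excluded from the
    proportion-explained denominator.
    """
    if dist.n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    B = _gower_center(dist.d)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    prop = np.zeros_like(eigvals)
    pos_sum = eigvals[positive].sum()
    if pos_sum > 0:
        prop[positive] = eigvals[positive] / pos_sum
    frame = pd.DataFrame(
        coords,
        index=dist.ids,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return frame, eigvals, prop


# ---------------------------------------------------------------------------
# PERMANOVA (adonis-style, sequential sums of squares)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def _design_columns(series: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
        return series.to_numpy(dtype=float).reshape(-1, 1)
    dummies = pd.get_dummies(series.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def permanova(
    dist: DistanceMatrix,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    Factors are fitted sequentially in column order; sums of squares come
    from the Gower-centred matrix (SS(H) = tr(H G)), F compares each term's
    mean square to the residual, and p-values count permutations of raw
    sample labels with F* >= F, including the observed one:
    p = (1 + #{F* >= F}) / (1 + n_perm).

    Returns a DataFrame indexed by term with columns df, SS, R2, F, p
    plus Residual and Total rows.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    n = dist.n
    factors = factors.loc[dist.ids]
    for col in factors.columns:
        levels = factors[col].nunique()
        if levels < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")
        if levels >= n:
            raise ValueError(f"factor {col!r} is confounded with sample identity")
    G = _gower_center(dist.d)
    ss_total = float(np.trace(G))

    X = np.ones((n, 1))
    hats = [_hat(X)]
    dfs: list[int] = []
    for col in factors.columns:
        X = np.hstack([X, _design_columns(factors[col])])
        H = _hat(X)
        dfs.append(int(round(np.trace(H) - np.trace(hats[-1]))))
        hats.append(H)
    H_full = hats[-1]
    df_res = n - int(round(np.trace(H_full)))
    if df_res <= 0:
        raise ValueError("model saturates the samples; no residual df")
    diffs = [hats[k + 1] - hats[k] for k in range(len(factors.columns))]
    resid_proj = np.eye(n) - H_full

    def _stats(Gp: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([np.sum(Dk * Gp) for Dk in diffs])
        ss_res = float(np.sum(resid_proj * Gp))
        return ss_terms, ss_res

    ss_terms, ss_res = _stats(G)
    ms_terms = ss_terms / np.array(dfs, dtype=float)
    F_obs = ms_terms / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(dfs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_res_p = _stats(Gp)
        F_p = (ss_p / dfs) / (ss_res_p / df_res)
        exceed += F_p >= F_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, col in enumerate(factors.columns):
        rows.append((col, dfs[k], ss_terms[k], ss_terms[k] / ss_total, F_obs[k], pvals[k]))
    rows.append(("Residual", df_res, ss_res, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["term", "df", "SS", "R2", "F", "p"]
    ).set_index("term")


# ---------------------------------------------------------------------------
# Mixed models


def build_design(meta: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Fixed-effect design matrix with explicit indicator coding.

    ``treatment`` codes PE as 1 (control reference), ``delivery`` codes
    vaginal as 1 (cesarean reference), ``age`` codes 12 months as 1.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(meta))}
    for term in terms:
        if term not in _TERM_ENCODINGS:
            raise ValueError(f"unknown model term {term!r}")
        column, one_level = _TERM_ENCODINGS[term]
        cols[f"{term}[{one_level}]"] = (
            (meta[column] == one_level).to_numpy(dtype=float)
        )
    return pd.DataFrame(cols, index=meta.index)


def fit_abundance_lmm(
    log_abundance: pd.Series,
    meta: pd.DataFrame,
    terms: Sequence[str] = ("treatment",),
) -> LmmResult:
    """Gaussian LMM on log abundance with a per-infant random intercept.

    log(Y_ij) = b0 + sum_k b_k x_kij + R_j + e_ij, REML fit, Wald p-values.
    A singular or non-converged fit is flagged, not raised.
    """
    meta = meta.loc[log_abundance.index]
    X = build_design(meta, terms)
    groups = meta["infant_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 infants for a random intercept")
    y = log_abundance.to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM(y, X.to_numpy(), groups=groups)
        result = model.fit(reml=True)
    singular = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    coeffs = {
        name: (
            float(result.fe_params[i]),
            float(result.bse_fe[i]),
            float(result.pvalues[i]),
        )
        for i, name in enumerate(X.columns)
    }
    return LmmResult(
        coefficients=coeffs,
        random_intercept_sd=float(np.sqrt(max(np.asarray(result.cov_re)[0, 0], 0.0))),
        model_family="gaussian_log",
        n_obs=len(y),
        converged=bool(result.converged and not singular),
        message="; ".join(str(w.message) for w in caught) if singular else "",
    )


def fit_presence_glmm(
    presence: pd.Series,
    meta: pd.DataFrame,
    terms: Sequence[str] = ("treatment", "delivery", "age"),
) -> LmmResult:
    """Binomial (logit) mixed model on presence/absence, random intercept per infant.

    logit P(Y_ij = 1) = b0 + sum_k b_k x_kij + R_j, marginal ML via
    Gauss-Hermite quadrature.  Complete separation yields a flagged
    penalized refit rather than an exception; a constant response is an
    error (nothing to model).
    """
    meta = meta.loc[presence.index]
    X = build_design(meta, terms)
    y = presence.to_numpy(dtype=float)
    fit = fit_logistic_random_intercept(
        X.to_numpy(), y, meta["infant_id"].to_numpy(), names=list(X.columns)
    )
    coeffs = {
        name: (float(fit.params[i]), float(fit.se[i]), float(fit.pvalues[i]))
        for i, name in enumerate(fit.names)
    }
    message = fit.message if (fit.penalized or not fit.converged) else ""
    return LmmResult(
        coefficients=coeffs,
        random_intercept_sd=fit.sigma,
        model_family="binomial",
        n_obs=fit.n_obs,
        converged=fit.converged,
        message=message,
    )


def screen_presence_glmm(
    presence: pd.DataFrame,
    meta: pd.DataFrame,
    terms: Sequence[str] = ("treatment", "delivery", "age"),
    min_prevalence: int = 3,
) -> pd.DataFrame:
    """Fit the presence GLMM per phage group and BH-adjust p-values per term.

    Groups observed in fewer than ``min_prevalence`` samples (or missing in
    fewer) are skipped: their models are not identifiable.  Returns a long
    DataFrame (group, term, estimate, se, p, p_bh, converged).
    """
    rows = []
    for group in presence.columns:
        y = presence[group]
        if y.sum() < min_prevalence or (1 - y).sum() < min_prevalence:
            continue
        try:
            res = fit_presence_glmm(y, meta, terms)
        except ValueError:
            continue
        for term, (est, se, p) in res.coefficients.items():
            if term == "Intercept":
                continue
            rows.append((str(group), term, est, se, p, res.converged))
    df = pd.DataFrame(
        rows, columns=["group", "term", "estimate", "se", "p", "converged"]
    )
    if df.empty:
        df["p_bh"] = []
        return df
    df["p_bh"] = np.nan
    for term in df["term"].unique():
        mask = (df["term"] == term) & df["p"].notna()
        if mask.any():
            df.loc[mask, "p_bh"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df
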