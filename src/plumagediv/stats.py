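"""Comparative statistics: pairwise GLS partitions, VIF, PGLS, and FDR.

The pairwise analysis regresses colour distance (JND) for each patch (and
the whole-body average) on three predictors fitted together without
interactions: phylogenetic distance, a geographic predictor, and NDVI niche
overlap.  Three data partitions are analysed: all pairs (geographic
predictor = 0/1 sympatry indicator), sympatric pairs only (range-overlap
fraction), and allopatric pairs only (minimal range distance).

The species-level analysis is a phylogenetic generalized least squares
(PGLS) of each colorimetric variable (segment chroma S1, hue H1, mean
brightness B2) on species mean NDVI, with the error covariance sigma^2 *
C(lambda), run both at fixed lambda = 1 and with lambda estimated by
maximum likelihood on [0, 1].

Benjamini-Hochberg step-up false-discovery-rate correction is applied
within each output table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .geography import PairGeoMetrics
from .niche import NicheOverlap
from .phylo import PhyloCovariance, PhyloDistanceMatrix
from .visual import ColorDistanceMatrix

logger = logging.getLogger(__name__)

PREDICTORS = ("phylo_dist", "geo_predictor", "ndvi_overlap")


class StatsError(ValueError):
    pass


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("cannot z-score a constant column")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Pair table assembly and partitioning


def aggregate_overlap(f1: float, f2: float, how: str = "mean") -> float:
    """Collapse the two directional overlap fractions to one predictor value."""
    if how == "mean":
        return 0.5 * (f1 + f2)
    if how == "max":
        return max(f1, f2)
    if how == "min":
        return min(f1, f2)
    if how == "species1":
        return f1
    raise StatsError(f"unknown overlap aggregation {how!r}")


def assemble_pair_table(
    colour: dict[str, ColorDistanceMatrix],
    phylo: PhyloDistanceMatrix,
    geo: list[PairGeoMetrics],
    ndvi_overlap: list[NicheOverlap],
    all_overlap: list[NicheOverlap] | None = None,
    overlap_aggregation: str = "mean",
) -> pd.DataFrame:
    """One row per unordered species pair with all response and predictor columns.

    Species present in every layer are kept; the rest are dropped with a
    logged count.  Rows are ordered lexicographically by (species1, species2).
    """
    colour_species = set.intersection(*(set(m.species) for m in colour.values()))
    geo_by_pair = {frozenset((g.species1, g.species2)): g for g in geo}
    geo_species = {s for g in geo for s in (g.species1, g.species2)}
    ndvi_by_pair = {frozenset((o.species1, o.species2)): o for o in ndvi_overlap}
    ndvi_species = {s for o in ndvi_overlap for s in (o.species1, o.species2)}
    universe = colour_species & set(phylo.species) & geo_species & ndvi_species
    if not universe:
        raise StatsError("no species shared across colour, phylo, geo and niche layers")
    dropped = (colour_species | set(phylo.species) | geo_species | ndvi_species) - universe
    if dropped:
        logger.warning("%d species missing from some layer, dropped: %s",
                       len(dropped), sorted(dropped))

    all_by_pair = (
        {frozenset((o.species1, o.species2)): o for o in all_overlap}
        if all_overlap is not None
        else None
    )
    rows = []
    for sp1, sp2 in itertools.combinations(sorted(universe), 2):
        key = frozenset((sp1, sp2))
        g = geo_by_pair[key]
        row = {
            "species1": sp1,
            "species2": sp2,
            "phylo_dist": phylo.pair(sp1, sp2),
            "ndvi_overlap": ndvi_by_pair[key].D,
            "sympatric": g.sympatric,
            "overlap_frac": aggregate_overlap(
                g.overlap_frac_1, g.overlap_frac_2, overlap_aggregation
            ),
            "min_distance": g.min_distance,
        }
        if all_by_pair is not None:
            row["all_overlap"] = all_by_pair[key].D
        for patch, matrix in colour.items():
            row[f"jnd_{patch}"] = matrix.pair(sp1, sp2)
        rows.append(row)
    return pd.DataFrame(rows)


def partition_pairs(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split into all / sympatric / allopatric with the substituted predictor.

    The ``geo_predictor`` column is the 0/1 sympatry indicator in the full
    table, the overlap fraction among sympatric pairs, and the minimal range
    distance among allopatric pairs.
    """
    full = table.copy()
    full["geo_predictor"] = full["sympatric"].astype(float)
    symp = table[table["sympatric"]].copy()
    symp["geo_predictor"] = symp["overlap_frac"]
    allo = table[~table["sympatric"]].copy()
    allo["geo_predictor"] = allo["min_distance"]
    for name, part in (("sympatric", symp), ("allopatric", allo)):
        if part.empty:
            logger.warning("%s partition is empty", name)
    assert len(symp) + len(allo) == len(full)
    return {"all": full, "sympatric": symp, "allopatric": allo}


# ---------------------------------------------------------------------------
# GLS on pair partitions


def fit_gls(
    partition: pd.DataFrame,
    response: str,
    geo_categorical: bool = False,
    standardize: str = "predictors",
) -> pd.DataFrame:
    """Linear model ``response ~ phylo_dist + geo_predictor + ndvi_overlap``.

    Fitted with an identity correlation structure (equivalent to OLS; ML and
    least-squares coefficient estimates coincide).  Continuous predictors are
    z-scored so coefficients are standardized effect sizes; the 0/1 sympatry
    indicator is left on its native scale.  ``standardize`` may be
    ``"predictors"`` (default), ``"both"`` or ``"none"``.

    Returns a DataFrame indexed by predictor with columns effect_size,
    std_error, t_value, p_value; the model log-likelihood and n are stored
    in ``DataFrame.attrs``.
    """
    if len(partition) < 10:
        raise StatsError(f"partition has {len(partition)} rows; need at least 10")
    if standardize not in ("predictors", "both", "none"):
        raise StatsError(f"unknown standardization mode {standardize!r}")
    y = partition[response].to_numpy(dtype=float)
    if standardize == "both":
        y = _zscore(y)
    cols = {}
    for name in PREDICTORS:
        x = partition[name].to_numpy(dtype=float)
        if x.std(ddof=1) == 0:
            logger.warning("predictor %s is constant; dropped from the model", name)
            continue
        if standardize != "none" and not (geo_categorical and name == "geo_predictor"):
            x = _zscore(x)
        cols[name] = x
    X = sm.add_constant(pd.DataFrame(cols, index=partition.index))
    model = sm.OLS(y, X).fit()
    result = pd.DataFrame(
        {
            "effect_size": model.params,
            "std_error": model.bse,
            "t_value": model.tvalues,
            "p_value": model.pvalues,
        }
    ).drop(index="const")
    result.attrs["loglik"] = float(model.llf)
    result.attrs["n"] = int(len(partition))
    return result


def vif(partition: pd.DataFrame, predictors: tuple[str, ...] = PREDICTORS) -> dict[str, float]:
    """Variance inflation factor per predictor: 1 / (1 - R_j^2).

    R_j^2 is from regressing predictor j (with intercept) on the others.
    Perfect collinearity yields ``inf``.
    """
    out: dict[str, float] = {}
    for name in predictors:
        others = [p for p in predictors if p != name]
        X = sm.add_constant(partition[others].to_numpy(dtype=float))
        r2 = sm.OLS(partition[name].to_numpy(dtype=float), X).fit().rsquared
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


# ---------------------------------------------------------------------------
# PGLS with Pagel's lambda


@dataclass
class PGLSResult:
    slope: float
    std_error: float
    t_value: float
    p_value: float
    intercept: float
    lam: float
    lambda_mode: str  # "fixed" | "ml"
    loglik: float
    n: int


def _gls_solve(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS estimates for fixed covariance V via Cholesky whitening.

    Returns (beta, weighted RSS, ML log-likelihood, (X' V^-1 X)^-1).
    """
    n = y.size
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise StatsError("singular phylogenetic covariance C(lambda)") from exc
    Xw = scipy.linalg.solve_triangular(L, X, lower=True)
    yw = scipy.linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2_ml) + n + logdet_v)
    return beta, rss, loglik, np.linalg.inv(XtX)


class PGLS:
    """Phylogenetic GLS of one trait on one predictor.

    Error covariance is sigma^2 * C(lambda) with C the phylogenetic
    covariance and lambda Pagel's branch-length multiplier on the
    off-diagonal.  ``lambda_mode="fixed"`` uses ``lam`` (default 1, pure
    Brownian); ``lambda_mode="ml"`` maximizes the profile log-likelihood
    over lambda in [0, 1] by bounded scalar search (tolerance 1e-6), with
    boundary optima reported at the boundary.

    Fitted attributes (trailing underscore) follow the estimator convention:
    ``slope_``, ``intercept_``, ``stderr_``, ``tvalue_``, ``pvalue_``,
    ``lam_``, ``loglik_``.
    """

    def __init__(self, lambda_mode: str = "fixed", lam: float = 1.0):
        if lambda_mode not in ("fixed", "ml"):
            raise StatsError(f"unknown lambda mode {lambda_mode!r}")
        if not 0.0 <= lam <= 1.0:
            raise StatsError("lambda must lie in [0, 1]")
        self.lambda_mode = lambda_mode
        self.lam = lam

    def get_params(self) -> dict:
        return {"lambda_mode": self.lambda_mode, "lam": self.lam}

    def set_params(self, **params) -> "PGLS":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
        V = C * lam
        np.fill_diagonal(V, np.diag(C))
        return V

    def fit(self, y: np.ndarray, x: np.ndarray, cov: PhyloCovariance) -> "PGLS":
        y = np.asarray(y, dtype=float)
        x = np.asarray(x, dtype=float)
        C = cov.C
        n = y.size
        if n < 4:
            raise StatsError("PGLS needs at least 4 species")
        if x.size != n or C.shape != (n, n):
            raise StatsError("trait, predictor and covariance dimensions disagree")
        X = np.column_stack([np.ones(n), x])

        def negloglik(lam: float) -> float:
            return -_gls_solve(y, X, self._lambda_cov(C, lam))[2]

        if self.lambda_mode == "ml":
            res = scipy.optimize.minimize_scalar(
                negloglik, bounds=(0.0, 1.0), method="bounded",
                options={"xatol": 1e-6},
            )
            candidates = [(negloglik(0.0), 0.0), (negloglik(1.0), 1.0), (res.fun, res.x)]
            _, lam_hat = min(candidates, key=lambda t: t[0])
        else:
            lam_hat = self.lam
        V = self._lambda_cov(C, lam_hat)
        beta, rss, loglik, XtX_inv = _gls_solve(y, X, V)
        k = X.shape[1]
        sigma2 = rss / (n - k)
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        t = beta / se
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - k)
        self.intercept_, self.slope_ = float(beta[0]), float(beta[1])
        self.stderr_ = float(se[1])
        self.tvalue_ = float(t[1])
        self.pvalue_ = float(p[1])
        self.lam_ = float(lam_hat)
        self.loglik_ = float(loglik)
        self.n_ = int(n)
        return self

    def result(self) -> PGLSResult:
        return PGLSResult(
            self.slope_, self.stderr_, self.tvalue_, self.pvalue_,
            self.intercept_, self.lam_, self.lambda_mode, self.loglik_, self.n_,
        )


def fit_pgls(
    trait: np.ndarray,
    predictor: np.ndarray,
    cov: PhyloCovariance,
    lambda_mode: str = "fixed",
    lam: float = 1.0,
) -> PGLSResult:
    """Functional wrapper over :class:`PGLS` (species order must align)."""
    return PGLS(lambda_mode=lambda_mode, lam=lam).fit(trait, predictor, cov).result()


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min over j >= i of min(1, p_(j) * m / j) over the ascending
    order statistics, mapped back to the original positions.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise StatsError("p-values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# Mantel-style permutation (robustness flag for pairwise non-independence)


def mantel_correlation(
    d1: np.ndarray, d2: np.ndarray, permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Pearson correlation of two distance matrices with a permutation p.

    Rows/columns of the second matrix are permuted jointly (species-label
    permutation).  Returns (r, two-sided permutation p-value).
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    n = d1.shape[0]
    iu = np.triu_indices(n, 1)
    v1 = d1[iu]
    r_obs = np.corrcoef(v1, d2[iu])[0, 1]
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(permutations):
        perm = rng.permutation(n)
        r = np.corrcoef(v1, d2[np.ix_(perm, perm)][iu])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return float(r_obs), count / (permutations + 1)


# ---------------------------------------------------------------------------
# Full analysis orchestration


def run_gls_tables(
    pair_table: pd.DataFrame,
    patches: list[str],
    sex: str,
    standardize: str = "predictors",
    fdr_family: str = "table",
) -> pd.DataFrame:
    """GLS results for every partition x patch, BH-corrected per partition.

    Returns the long-format table behind the printed per-sex results: one
    row per (partition, patch, predictor).
    """
    parts = partition_pairs(pair_table)
    rows = []
    for part_name, part in parts.items():
        if len(part) < 10:
            logger.warning("partition %s too small (%d rows); skipped", part_name, len(part))
            continue
        for patch in patches:
            fit = fit_gls(
                part, f"jnd_{patch}",
                geo_categorical=(part_name == "all"),
                standardize=standardize,
            )
            for pred, r in fit.iterrows():
                rows.append(
                    {
                        "sex": sex, "partition": part_name, "patch": patch,
                        "predictor": pred, "effect_size": r["effect_size"],
                        "std_error": r["std_error"], "t_value": r["t_value"],
                        "p_value": r["p_value"], "n": fit.attrs["n"],
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    if fdr_family == "global":
        table["p_value_corrected"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["p_value_corrected"] = np.nan
        for part_name, idx in table.groupby("partition").groups.items():
            table.loc[idx, "p_value_corrected"] = bh_adjust(
                table.loc[idx, "p_value"].to_numpy()
            )
    return table


def run_pgls_tables(
    metrics: pd.DataFrame,
    mean_ndvi: pd.Series,
    cov: PhyloCovariance,
    sex: str,
    fdr_family: str = "table",
) -> pd.DataFrame:
    """PGLS of each colour metric on mean NDVI, fixed-lambda and ML-lambda.

    ``metrics`` has a (species, patch) MultiIndex and one column per colour
    metric (S1U..S1R, H1, B2).  BH correction is applied within each
    (lambda-mode, patch) family.
    """
    rows = []
    species = [s for s in cov.species if s in mean_ndvi.index]
    idx = [cov.species.index(s) for s in species]
    sub_cov = PhyloCovariance(species, cov.C[np.ix_(idx, idx)])
    x = mean_ndvi.loc[species].to_numpy(dtype=float)
    for patch in metrics.index.get_level_values("patch").unique():
        block = metrics.xs(patch, level="patch").reindex(species)
        for metric in metrics.columns:
            y = block[metric].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() < 4:
                continue
            sub2 = PhyloCovariance(
                [s for s, k in zip(species, ok) if k],
                sub_cov.C[np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))],
            )
            for mode in ("fixed", "ml"):
                res = fit_pgls(y[ok], x[ok], sub2, lambda_mode=mode)
                rows.append(
                    {
                        "sex": sex, "patch": patch, "metric": metric,
                        "lambda_mode": mode, "lambda": res.lam,
                        "estimate": res.slope, "std_error": res.std_error,
                        "t_value": res.t_value, "p_value": res.p_value,
                        "n": res.n,
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    if fdr_family == "global":
        table["p_value_corrected"] = bh_adjust(table["p_value"].to_numpy())
    else:
        table["p_value_corrected"] = np.nan
        for _, idx2 in table.groupby(["lambda_mode", "patch"]).groups.items():
            table.loc[idx2, "p_value_corrected"] = bh_adjust(
                table.loc[idx2, "p_value"].to_numpy()
            )
    return table
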