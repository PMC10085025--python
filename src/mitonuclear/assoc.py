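"""Genome scan for nuclear main effects and SNP × mitotype interactions.

For every SNP three nested models are fitted to the petite phenotype of the
isonuclear collection replicated across mitotypes::

    M0:  phenotype ~ covariates + mitotype
    M1:  M0 + SNP
    M2:  M1 + SNP : mitotype

The main-effect test compares M0 vs M1 and the interaction test compares
M1 vs M2 with (mitotype levels - 1) numerator degrees of freedom — a
formulation that is invariant to the factor reference coding. The Gaussian
family uses F-tests on strain-mean petite percentages; the binomial family
uses chi-square likelihood-ratio tests on (petite, grande) colony counts.

Also here: PCA covariates from the genotype matrix, multiple-testing
control (Bonferroni, Benjamini-Hochberg, Storey q-values), the
allele-frequency-weighted effect size Delta, and a pairwise nuclear×nuclear
epistasis scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .snp_table import MISSING, SNPTable

__all__ = [
    "ModelSpec",
    "MultipleTestingResult",
    "genotype_pca",
    "scan_mitonuclear",
    "mitonuclear_anova",
    "adjust_pvalues",
    "effect_size_delta",
    "effect_sizes",
    "pairwise_epistasis_scan",
]


@dataclass
class ModelSpec:
    """Configuration of the per-SNP association model.

    ``response`` names the phenotype column for the Gaussian family
    (strain-mean petite percent); the binomial family instead uses
    ``count_cols`` = (successes, totals). ``covariates`` are column names in
    the phenotype table (categorical columns are dummy-coded).
    ``conditioning_snps`` are variant indices whose genotypes are appended
    to the covariates (e.g. a large-effect locus being conditioned out).
    """

    response: str = "petite_pct"
    covariates: list[str] = field(default_factory=list)
    conditioning_snps: list[int] = field(default_factory=list)
    mitotype_col: str = "mitotype"
    family: str = "gaussian"
    count_cols: tuple[str, str] = ("petite_count", "total_count")

    def __post_init__(self) -> None:
        if self.family not in {"gaussian", "binomial"}:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class MultipleTestingResult:
    method: str
    alpha: float
    adjusted: np.ndarray
    threshold: float | None = None  # per-test p threshold (bonferroni)
    pi0: float | None = None  # Storey's null-proportion estimate

    def n_significant(self) -> int:
        return int(np.nansum(self.adjusted <= self.alpha))


# ------------------------------------------------------------- PCA ------


def genotype_pca(
    genotypes: np.ndarray | SNPTable, k: int = 10, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of population structure from the call matrix.

    Operates on unique nuclear genotypes (one row per strain). Missing
    calls are mean-imputed per variant and variants are centered;
    ``scale=True`` additionally standardises each variant by
    ``sqrt(p(1-p))``. Returns per-strain scores for the top ``k`` right
    singular directions (columns ``PC1``..) and the fraction of variance
    each explains. If ``k`` exceeds the matrix rank the extra scores are
    ~0 and a warning is emitted.
    """
    if isinstance(genotypes, SNPTable):
        strains = list(genotypes.strains)
        mat = genotypes.genotypes.T.astype(float)  # strains × variants
        mat[genotypes.genotypes.T == MISSING] = np.nan
    else:
        mat = np.asarray(genotypes, dtype=float)
        strains = [f"S{i + 1:04d}" for i in range(mat.shape[0])]
    n, m = mat.shape
    if n < 2:
        raise ValueError("need at least 2 strains for PCA")
    col_mean = np.nanmean(mat, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(mat))
    mat[inds] = col_mean[inds[1]]
    mat = mat - col_mean
    if scale:
        p = np.clip(col_mean, 1e-8, 1 - 1e-8)
        mat = mat / np.sqrt(p * (1 - p))
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    tol = s.max(initial=0.0) * max(n, m) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if k > rank:
        warnings.warn(
            f"requested {k} PCs but genotype matrix has rank {rank}; "
            "surplus scores are ~0",
            stacklevel=2,
        )
    k_eff = min(k, s.size)
    scores = u[:, :k_eff] * s[:k_eff]
    if k_eff < k:
        scores = np.hstack([scores, np.zeros((n, k - k_eff))])
    total_var = (s**2).sum()
    explained = (s[:k_eff] ** 2 / total_var) if total_var > 0 else np.zeros(k_eff)
    df = pd.DataFrame(scores, index=strains, columns=[f"PC{j + 1}" for j in range(k)])
    df.index.name = "strain_id"
    return df, explained


# -------------------------------------------------- design utilities ----


def _dummy_columns(series: pd.Series, prefix: str) -> pd.DataFrame:
    levels = sorted(series.astype(str).unique())
    return pd.DataFrame(
        {f"{prefix}{lv}": (series.astype(str) == lv).astype(float) for lv in levels[1:]},
        index=series.index,
    )


def _build_base_design(
    phenotype: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Base design X0 (intercept + covariates + mitotype dummies) and the
    mitotype dummy block used to form interaction columns."""
    n = len(phenotype)
    parts = [pd.Series(np.ones(n), index=phenotype.index, name="intercept")]
    for cov in spec.covariates:
        if cov not in phenotype.columns:
            raise ValueError(f"covariate {cov!r} not in phenotype table")
        col = phenotype[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            dums = _dummy_columns(col, f"{cov}_")
            parts.extend(dums[c] for c in dums)
    mito = phenotype[spec.mitotype_col].astype(str)
    levels = sorted(mito.unique())
    zm = _dummy_columns(mito, "mito_")
    parts.extend(zm[c] for c in zm.columns)
    X0 = np.column_stack([np.asarray(p, dtype=float) for p in parts])
    return X0, zm.to_numpy(dtype=float), levels


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int, np.ndarray]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        rss = float(res[0])
    else:
        rss = float(np.sum((y - X @ beta) ** 2))
    return rss, int(rank), beta


def _f_test(
    rss_r: float, rss_f: float, df_num: int, df_den: int, scale_eps: float
) -> tuple[float, float]:
    """Nested-model F-test using the fuller model's error term; degenerate
    (near-zero residual) fits resolve to stat 0 / p 1 when the reduction is
    also ~0, and to an effectively infinite statistic otherwise."""
    if df_num <= 0 or df_den <= 0:
        return np.nan, np.nan
    drss = max(rss_r - rss_f, 0.0)
    if rss_f <= scale_eps:
        if drss <= scale_eps:
            return 0.0, 1.0
        return np.inf, 0.0
    f = (drss / df_num) / (rss_f / df_den)
    return float(f), float(stats.f.sf(f, df_num, df_den))


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def _glm_llf(X: np.ndarray, endog: np.ndarray) -> tuple[float, int]:
    keep = _independent_columns(X)
    model = sm.GLM(endog, X[:, keep], family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    return float(res.llf), keep.size


def _nested_tests_gaussian(
    y: np.ndarray, X0: np.ndarray, g_block: np.ndarray, zm: np.ndarray,
    base: tuple[float, int] | None = None,
) -> dict:
    n = y.size
    eps = 1e-10 * (1.0 + float(y @ y))
    if base is None:
        rss0, rank0, _ = _ols_rss(X0, y)
    else:
        rss0, rank0 = base
    X1 = np.hstack([X0, g_block])
    rss1, rank1, beta1 = _ols_rss(X1, y)
    df_main = rank1 - rank0
    if df_main == 0:
        return {"status": "collinear"}
    inter = np.hstack([g_block[:, [j]] * zm for j in range(g_block.shape[1])])
    X2 = np.hstack([X1, inter])
    rss2, rank2, _ = _ols_rss(X2, y)
    df_int = rank2 - rank1
    stat_main, p_main = _f_test(rss0, rss1, df_main, n - rank1, eps)
    stat_int, p_int = _f_test(rss1, rss2, df_int, n - rank2, eps)
    status = "ok" if df_int == zm.shape[1] * g_block.shape[1] else "reduced_df"
    beta_main = float(beta1[X0.shape[1]]) if g_block.shape[1] == 1 else np.nan
    return {
        "status": status, "beta_main": beta_main,
        "stat_main": stat_main, "p_main": p_main,
        "stat_int": stat_int, "df_int": df_int, "p_int": p_int,
    }


def _nested_tests_binomial(
    endog: np.ndarray, X0: np.ndarray, g_block: np.ndarray, zm: np.ndarray
) -> dict:
    llf0, k0 = _glm_llf(X0, endog)
    X1 = np.hstack([X0, g_block])
    llf1, k1 = _glm_llf(X1, endog)
    df_main = k1 - k0
    if df_main == 0:
        return {"status": "collinear"}
    inter = np.hstack([g_block[:, [j]] * zm for j in range(g_block.shape[1])])
    X2 = np.hstack([X1, inter])
    llf2, k2 = _glm_llf(X2, endog)
    df_int = k2 - k1
    lr_main = max(2.0 * (llf1 - llf0), 0.0)
    lr_int = max(2.0 * (llf2 - llf1), 0.0)
    p_main = float(stats.chi2.sf(lr_main, df_main))
    p_int = float(stats.chi2.sf(lr_int, df_int)) if df_int > 0 else np.nan
    status = "ok" if df_int == zm.shape[1] * g_block.shape[1] else "reduced_df"
    return {
        "status": status, "beta_main": np.nan,
        "stat_main": lr_main, "p_main": p_main,
        "stat_int": lr_int, "df_int": df_int, "p_int": p_int,
    }


def _strain_genotype_rows(
    phenotype: pd.DataFrame, table: SNPTable
) -> np.ndarray:
    index_of = {s: i for i, s in enumerate(table.strains)}
    missing = set(phenotype["strain_id"]) - set(index_of)
    if missing:
        raise ValueError(f"phenotype strains absent from SNP table: {sorted(missing)[:5]}")
    return phenotype["strain_id"].map(index_of).to_numpy()


_EMPTY_RESULT = {
    "beta_main": np.nan, "stat_main": np.nan, "p_main": np.nan,
    "stat_int": np.nan, "df_int": 0, "p_int": np.nan,
}


def scan_mitonuclear(
    phenotype: pd.DataFrame,
    snp_table: SNPTable,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Per-SNP main-effect and SNP×mitotype interaction scan.

    ``phenotype`` has one row per strain × mitotype replicate with columns
    ``strain_id``, the mitotype column, the response (or count columns for
    the binomial family) and any covariate columns named in the spec.
    Strains with a missing call at a SNP are dropped for that SNP
    (complete case). Monomorphic or covariate-collinear SNPs are flagged
    with undefined p-values; when an allele is absent in some mitotype
    group the interaction is tested with reduced degrees of freedom and
    flagged ``reduced_df``.

    Returns a table with one row per variant: coordinates, allele labels,
    ``beta_main``, main-effect and interaction statistics/p-values,
    interaction df, and a status flag.
    """
    spec = spec or ModelSpec()
    row_idx = _strain_genotype_rows(phenotype, snp_table)
    X0_all, zm_all, levels = _build_base_design(phenotype, spec)
    if len(levels) < 2:
        raise ValueError("need >= 2 mitotype levels for interaction testing")
    for v in spec.conditioning_snps:
        g = snp_table.genotypes[v, row_idx].astype(float)
        g[snp_table.genotypes[v, row_idx] == MISSING] = np.nan
        g = np.where(np.isnan(g), np.nanmean(g), g)
        X0_all = np.hstack([X0_all, g[:, None]])

    if spec.family == "gaussian":
        y_all = phenotype[spec.response].to_numpy(dtype=float)
        base_full = _ols_rss(X0_all, y_all)[:2]
    else:
        pet = phenotype[spec.count_cols[0]].to_numpy(dtype=float)
        tot = phenotype[spec.count_cols[1]].to_numpy(dtype=float)
        endog_all = np.column_stack([pet, tot - pet])

    records = []
    for v in range(snp_table.n_variants):
        g_raw = snp_table.genotypes[v, row_idx]
        keep = g_raw != MISSING
        g = g_raw[keep].astype(float)
        rec = dict(_EMPTY_RESULT)
        if g.size == 0 or np.all(g == g[0]):
            rec["status"] = "monomorphic"
        else:
            X0 = X0_all[keep] if not keep.all() else X0_all
            zm = zm_all[keep] if not keep.all() else zm_all
            if spec.family == "gaussian":
                y = y_all[keep] if not keep.all() else y_all
                base = base_full if keep.all() else None
                out = _nested_tests_gaussian(y, X0, g[:, None], zm, base=base)
            else:
                endog = endog_all[keep] if not keep.all() else endog_all
                out = _nested_tests_binomial(endog, X0, g[:, None], zm)
            rec.update(out)
            rec.setdefault("status", "ok")
        rec.update(
            {
                "marker": v,
                "chrom": snp_table.variants.iloc[v]["chrom"],
                "pos": int(snp_table.variants.iloc[v]["pos"]),
                "ref": snp_table.variants.iloc[v]["ref"],
                "alt": snp_table.variants.iloc[v]["alt"],
            }
        )
        records.append(rec)
    cols = [
        "marker", "chrom", "pos", "ref", "alt", "beta_main",
        "stat_main", "p_main", "stat_int", "df_int", "p_int", "status",
    ]
    return pd.DataFrame(records)[cols]


def mitonuclear_anova(
    phenotype: pd.DataFrame,
    nuclear_factor: str,
    spec: ModelSpec | None = None,
) -> pd.Series:
    """Factorial mitonuclear test with a categorical nuclear background.

    Runs the same nested comparison as the genome scan but with a
    categorical nuclear factor (e.g. strain background or knockout
    genotype) in place of a SNP, yielding nuclear main-effect and
    nuclear×mitotype interaction tests.
    """
    spec = spec or ModelSpec()
    X0, zm, levels = _build_base_design(phenotype, spec)
    if len(levels) < 2:
        raise ValueError("need >= 2 mitotype levels for interaction testing")
    block = _dummy_columns(phenotype[nuclear_factor], f"{nuclear_factor}_").to_numpy(float)
    if block.shape[1] == 0:
        raise ValueError(f"nuclear factor {nuclear_factor!r} has a single level")
    if spec.family == "gaussian":
        y = phenotype[spec.response].to_numpy(dtype=float)
        out = _nested_tests_gaussian(y, X0, block, zm)
    else:
        pet = phenotype[spec.count_cols[0]].to_numpy(dtype=float)
        tot = phenotype[spec.count_cols[1]].to_numpy(dtype=float)
        out = _nested_tests_binomial(np.column_stack([pet, tot - pet]), X0, block, zm)
    return pd.Series(out)


# ------------------------------------------- multiple-testing control ----


def _storey_pi0(p: np.ndarray, lambdas: np.ndarray) -> float:
    """Storey's null-proportion estimate: the cubic smoother through
    pi0(lambda) evaluated at lambda = 0.90, clipped into (0, 1]."""
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coefs = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coefs, 0.90))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def adjust_pvalues(
    p_values,
    method: str = "storey",
    alpha: float = 0.05,
    pi0: float | None = None,
) -> MultipleTestingResult:
    """Multiple-testing control: ``bonferroni``, ``bh`` or ``storey``.

    Bonferroni reports the per-test threshold ``alpha/m`` and adjusted
    p-values ``min(1, p*m)``; ``bh`` is the Benjamini-Hochberg step-up;
    ``storey`` computes q-values with the null proportion pi0 estimated by
    a cubic smoother over lambda in {0.05, ..., 0.90} (fixing ``pi0=1``
    makes the q-values identical to BH). NaN p-values (flagged SNPs) are
    passed through as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    ok = ~np.isnan(p)
    if not ok.any():
        raise ValueError("all p-values are NaN")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = pv.size
    adjusted = np.full(p.shape, np.nan)
    threshold = None
    pi0_est = None
    if method == "bonferroni":
        adjusted[ok] = np.minimum(pv * m, 1.0)
        threshold = alpha / m
    elif method in {"bh", "storey"}:
        if method == "bh":
            pi0_est = 1.0
        else:
            lambdas = np.arange(0.05, 0.901, 0.05)
            pi0_est = _storey_pi0(pv, lambdas) if pi0 is None else float(pi0)
            if not 0 < pi0_est <= 1:
                raise ValueError("pi0 must be in (0, 1]")
        order = np.argsort(pv)[::-1]  # descending p
        q = np.empty(m)
        prev = np.inf
        for rank_from_top, idx in enumerate(order):
            i = m - rank_from_top  # rank in ascending order
            prev = min(prev, pi0_est * m * pv[idx] / i)
            q[idx] = min(prev, 1.0)
        adjusted[ok] = q
    else:
        raise ValueError(f"unknown method {method!r}")
    return MultipleTestingResult(
        method=method, alpha=alpha, adjusted=adjusted, threshold=threshold, pi0=pi0_est
    )


# ------------------------------------------------------- effect size ----


def effect_size_delta(snp_calls, strain_petite_means) -> float:
    """Allele-frequency-weighted effect size Delta (percent petite).

    ``Delta = |f_0 * pbar_0 - f_1 * pbar_1|`` where ``f_a`` is the
    frequency of allele ``a`` among strains with non-missing calls and
    ``pbar_a`` the mean strain petite frequency of its carriers. Returns
    NaN for monomorphic SNPs.
    """
    g = np.asarray(snp_calls)
    y = np.asarray(strain_petite_means, dtype=float)
    if g.shape != y.shape:
        raise ValueError("calls and phenotype vectors must align")
    ok = (g != MISSING) & ~np.isnan(y)
    g, y = g[ok], y[ok]
    if g.size == 0 or np.all(g == g[0]):
        return float("nan")
    f1 = float((g == 1).mean())
    f0 = 1.0 - f1
    p0 = float(y[g == 0].mean())
    p1 = float(y[g == 1].mean())
    return abs(f0 * p0 - f1 * p1)


def effect_sizes(table: SNPTable, strain_means: pd.Series) -> np.ndarray:
    """Per-variant Delta over a strain_id -> mean petite percent series."""
    y = strain_means.reindex(table.strains).to_numpy(dtype=float)
    return np.array(
        [effect_size_delta(table.genotypes[v], y) for v in range(table.n_variants)]
    )


# ---------------------------------------------- pairwise epistasis ------


def pairwise_epistasis_scan(
    phenotype: pd.DataFrame,
    snp_table: SNPTable,
    focal_snps: list[int],
    spec: ModelSpec | None = None,
    snps: list[int] | None = None,
) -> pd.DataFrame:
    """Nuclear × nuclear epistasis check against focal SNPs.

    For every (SNP i, focal SNP j) pair, compares the additive model
    ``covariates + g_i + g_j`` against ``... + g_i * g_j`` with an F-test
    (Gaussian response, typically on a single-mitotype collection; the
    mitotype term drops out when only one level is present). Pairs with
    i == j or with the two SNPs in perfect LD are flagged and excluded.
    Benjamini-Hochberg q-values are computed over all tested pairs.
    """
    spec = spec or ModelSpec()
    if spec.family != "gaussian":
        raise NotImplementedError("pairwise scan implemented for the gaussian family")
    row_idx = _strain_genotype_rows(phenotype, snp_table)
    n = len(phenotype)
    parts = [np.ones(n)]
    for cov in spec.covariates:
        col = phenotype[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.to_numpy(dtype=float))
        else:
            parts.extend(
                _dummy_columns(col, f"{cov}_").to_numpy(float).T
            )
    if phenotype[spec.mitotype_col].nunique() > 1:
        parts.extend(_dummy_columns(phenotype[spec.mitotype_col], "mito_").to_numpy(float).T)
    X0 = np.column_stack(parts)
    y = phenotype[spec.response].to_numpy(dtype=float)
    all_snps = snps if snps is not None else list(range(snp_table.n_variants))
    records = []
    for j in focal_snps:
        gj_raw = snp_table.genotypes[j, row_idx]
        for i in all_snps:
            gi_raw = snp_table.genotypes[i, row_idx]
            rec = {"snp": i, "focal": j, "stat": np.nan, "p_int": np.nan}
            if i == j:
                rec["status"] = "self"
                records.append(rec)
                continue
            keep = (gi_raw != MISSING) & (gj_raw != MISSING)
            gi = gi_raw[keep].astype(float)
            gj = gj_raw[keep].astype(float)
            if gi.size == 0 or np.all(gi == gi[0]) or np.all(gj == gj[0]):
                rec["status"] = "monomorphic"
                records.append(rec)
                continue
            corr = abs(float(np.corrcoef(gi, gj)[0, 1]))
            if corr > 1 - 1e-10:
                rec["status"] = "perfect_ld"
                records.append(rec)
                continue
            Xa = np.hstack([X0[keep], gi[:, None], gj[:, None]])
            rss_a, rank_a, _ = _ols_rss(Xa, y[keep])
            Xf = np.hstack([Xa, (gi * gj)[:, None]])
            rss_f, rank_f, _ = _ols_rss(Xf, y[keep])
            eps = 1e-10 * (1.0 + float(y[keep] @ y[keep]))
            stat, p = _f_test(rss_a, rss_f, rank_f - rank_a, gi.size - rank_f, eps)
            rec.update({"stat": stat, "p_int": p, "status": "ok"})
            records.append(rec)
    out = pd.DataFrame(records, columns=["snp", "focal", "stat", "p_int", "status"])
    tested = out["p_int"].notna()
    if tested.any():
        res = adjust_pvalues(out.loc[tested, "p_int"].to_numpy(), method="bh")
        out.loc[tested, "q_int"] = res.adjusted
    else:
        out["q_int"] = np.nan
    return out
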