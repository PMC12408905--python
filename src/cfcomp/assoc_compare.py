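"""Association analyses and their cross-library agreement.

Runs the same association battery on two genotype matrices derived from
the same individuals and quantifies how well the results agree:

* SNP quality-control filters (MAF, exact Hardy-Weinberg test,
  missingness) applied before association testing,
* per-SNP linear GWAS on a rank-based inverse-normal transformed
  quantitative phenotype with variance-standardized covariates
  (age/sex analogues plus top genotype principal components),
* permutation-based cis-eQTL mapping: nominal linear-model P for every
  variant within a window of the transcription start site, a gene-level
  empirical P from phenotype permutations, and Benjamini-Hochberg FDR
  across genes,
* agreement reports: squared Pearson correlation of -log10 P and of
  effect sizes over the variants tested in both datasets.

The quantitative-trait "generalized linear model" is ordinary least
squares with t-tests, matching how quantile-normalized phenotypes are
analysed in practice.  The per-variant scan uses the
Frisch-Waugh-Lovell residualization identity, which reproduces the
full-design OLS coefficient, standard error and t-test for the dosage
term exactly while allowing thousands of variants (and permutations) to
be scanned with matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import MISSING, GenotypeMatrix
from .variant_compare import _pc_scores, _shared_samples

__all__ = [
    "AssocSummary",
    "AgreementReport",
    "inverse_normal_transform",
    "hwe_exact_p",
    "qc_filter",
    "gwas_linear",
    "cis_eqtl",
    "agreement",
]

KEY_COLS = ["chrom", "pos", "ref", "alt"]


@dataclass
class AssocSummary:
    """Per-variant association results plus filter/covariate provenance.

    ``table`` has the variant key columns and beta / se / p / n (and for
    eQTL additionally gene_id); ``genes`` (eQTL only) has the gene-level
    empirical P and q-value.
    """

    table: pd.DataFrame
    filters: dict = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    genes: pd.DataFrame | None = None
    skipped: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def inverse_normal_transform(x: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    Maps values to ``Phi^{-1}((rank - 3/8)/(n + 1/4))`` with average
    ranks for ties; NaNs are preserved and excluded from ranking.
    """
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    n = ok.sum()
    if n == 0:
        return out
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------


def hwe_exact_p(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy-Weinberg test P-value.

    Sums, over all heterozygote counts compatible with the observed
    allele counts, the probabilities of configurations as or less
    probable than the observed one.  Probabilities follow the standard
    conditional distribution of the heterozygote count given allele
    counts; they are evaluated in log space via gammaln.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("at least one genotype required")
    n_alt = n_het + 2 * n_homalt
    n_rare = min(n_alt, 2 * n - n_alt)
    # Heterozygote count shares the parity of the rare allele count.
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-5,
    miss_max: float = 0.10,
) -> tuple[GenotypeMatrix, dict]:
    """Standard pre-association SNP filters.

    Keeps biallelic SNPs with MAF > ``maf_min``, exact HWE P >
    ``hwe_p_min`` and missing rate < ``miss_max``.  The filter log
    reports, for the removed variants, how many failed each rule
    (non-exclusive counts) plus the non-SNP records set aside.
    """
    v = g.variants
    is_snp = ((v["vclass"] == "SNP") & ~v["multiallelic"].astype(bool)).to_numpy()
    maf = g.maf()
    miss = g.missing_rate()
    hwe_p = np.ones(g.n_variants)
    for j in np.flatnonzero(is_snp):
        d = g.dosages[:, j]
        counts = [(d == 0).sum(), (d == 1).sum(), (d == 2).sum()]
        if sum(counts) > 0:
            hwe_p[j] = hwe_exact_p(*counts)

    with np.errstate(invalid="ignore"):
        fail_maf = is_snp & ~(maf > maf_min)
        fail_hwe = is_snp & ~(hwe_p > hwe_p_min)
        fail_miss = is_snp & ~(miss < miss_max)
    keep = is_snp & ~fail_maf & ~fail_hwe & ~fail_miss
    log = {
        "n_input": g.n_variants,
        "n_not_snp": int((~is_snp).sum()),
        "n_fail_maf": int(fail_maf.sum()),
        "n_fail_hwe": int(fail_hwe.sum()),
        "n_fail_missing": int(fail_miss.sum()),
        "n_kept": int(keep.sum()),
        "maf_min": maf_min,
        "hwe_p_min": hwe_p_min,
        "miss_max": miss_max,
    }
    return g.take_variants(np.flatnonzero(keep)), log


# ---------------------------------------------------------------------------
# Linear-model scan core (Frisch-Waugh-Lovell)
# ---------------------------------------------------------------------------


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M on the orthonormal basis Q."""
    return M - Q @ (Q.T @ M)


def _scan(y_r: np.ndarray, X_r: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dosage beta, SE and two-sided P for residualized y and dosages.

    ``df`` is the residual degrees of freedom of the full model
    (n - n_covariate_columns - 1 for the dosage term).
    """
    sxx = np.einsum("ij,ij->j", X_r, X_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (X_r.T @ y_r) / sxx
        rss = float(y_r @ y_r) - beta**2 * sxx
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def _build_covariates(
    g: GenotypeMatrix,
    covariates: pd.DataFrame | None,
    n_pcs: int,
    samples: list[str],
) -> tuple[np.ndarray, list[str]]:
    """Intercept + variance-standardized user covariates + genotype PCs."""
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    if covariates is not None:
        cov = covariates.loc[samples]
        for c in cov.columns:
            col = cov[c].to_numpy(dtype=float)
            sd = col.std()
            cols.append((col - col.mean()) / sd if sd > 0 else np.zeros_like(col))
            names.append(str(c))
    if n_pcs > 0:
        maf = g.maf()
        usable = np.flatnonzero(maf > 0.05)
        if len(usable) >= n_pcs:
            pcs = _pc_scores(g.dosages[:, usable], n_pcs)
            for k in range(n_pcs):
                col = pcs[:, k]
                sd = col.std()
                cols.append((col - col.mean()) / sd if sd > 0 else np.zeros_like(col))
                names.append(f"PC{k + 1}")
    return np.column_stack(cols), names


def gwas_linear(
    g: GenotypeMatrix,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_pcs: int = 5,
) -> AssocSummary:
    """Per-SNP ordinary least squares on an inverse-normal phenotype.

    The phenotype is rank-based inverse-normal transformed; covariates
    (plus the top ``n_pcs`` principal components of this same genotype
    matrix) are standardized to unit variance.  Individuals missing a
    SNP are dropped for that SNP only.  Constant-dosage or collinear
    SNPs are skipped and recorded.
    """
    samples = [s for s in g.samples if s in phenotype.index and not np.isnan(phenotype[s])]
    if len(samples) < 10:
        raise ValueError("need at least 10 complete cases")
    sidx = np.array([g.samples.index(s) for s in samples])
    y = inverse_normal_transform(phenotype.loc[samples].to_numpy(dtype=float))
    C, cov_names = _build_covariates(g, covariates, n_pcs, samples)

    D = g.dosages[sidx, :]
    n_var = g.n_variants
    beta = np.full(n_var, np.nan)
    se = np.full(n_var, np.nan)
    pval = np.full(n_var, np.nan)
    n_used = np.zeros(n_var, dtype=int)
    skipped: list[tuple[int, str]] = []

    complete = D != MISSING
    all_complete = complete.all(axis=0)
    df_full = len(samples) - C.shape[1] - 1
    if df_full < 1:
        raise ValueError("not enough residual degrees of freedom")
    Q_full, _ = np.linalg.qr(C)
    y_r_full = _residualize(y[:, None], Q_full)[:, 0]

    # Fast path: variants with no missing calls share one residualization.
    idx_full = np.flatnonzero(all_complete)
    if len(idx_full):
        X = D[:, idx_full].astype(float)
        var_ok = X.std(axis=0) > 0
        X_r = _residualize(X, Q_full)
        sxx = np.einsum("ij,ij->j", X_r, X_r)
        ok = var_ok & (sxx > 1e-10 * len(samples))
        b, s, p = _scan(y_r_full, X_r[:, ok], df_full)
        sel = idx_full[ok]
        beta[sel], se[sel], pval[sel] = b, s, p
        n_used[idx_full] = len(samples)
        for j in idx_full[~ok]:
            skipped.append((int(j), "zero-variance or collinear dosage"))

    # Per-variant complete cases for variants with missing calls.
    for j in np.flatnonzero(~all_complete):
        mask = complete[:, j]
        nj = int(mask.sum())
        dfj = nj - C.shape[1] - 1
        x = D[mask, j].astype(float)
        if dfj < 1 or x.std() == 0:
            skipped.append((int(j), "insufficient cases or zero-variance dosage"))
            continue
        Qj, _ = np.linalg.qr(C[mask])
        yj = _residualize(y[mask][:, None], Qj)[:, 0]
        xj = _residualize(x[:, None], Qj)
        if float(xj[:, 0] @ xj[:, 0]) <= 1e-10 * nj:
            skipped.append((int(j), "dosage collinear with covariates"))
            continue
        b, s, p = _scan(yj, xj, dfj)
        beta[j], se[j], pval[j] = b[0], s[0], p[0]
        n_used[j] = nj

    table = g.variants[KEY_COLS].copy()
    table["maf"] = g.maf()
    table["beta"] = beta
    table["se"] = se
    table["p"] = pval
    table["n"] = n_used
    table = table[~table["p"].isna()].reset_index(drop=True)
    return AssocSummary(
        table=table,
        filters={"n_samples": len(samples)},
        covariates=cov_names,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# cis-eQTL mapping with permutations
# ---------------------------------------------------------------------------


def cis_eqtl(
    g: GenotypeMatrix,
    expression: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    window: int = 1_000_000,
    maf_min: float = 0.01,
    n_perm: int = 1000,
    fdr: float = 0.05,
    covariates: pd.DataFrame | None = None,
    n_geno_pcs: int = 2,
    n_expr_pcs: int = 5,
    seed: int | None = None,
) -> AssocSummary:
    """Permutation-based cis-eQTL scan.

    For each gene, every SNP with MAF >= ``maf_min`` within ``window``
    bases of the transcription start site is tested with the same linear
    model as the GWAS (inverse-normal expression; covariates = user
    covariates + genotype PCs + top expression PCs standing in for
    latent expression confounders).  The gene-level empirical P is
    ``(1 + #{permutations with max |association| >= observed}) /
    (1 + n_perm)``, permuting expression across individuals; q-values
    are Benjamini-Hochberg across genes, with eGenes declared at
    q <= ``fdr``.  Missing dosages are mean-imputed for this scan.
    """
    samples = [s for s in g.samples if s in expression.columns]
    if len(samples) < 10:
        raise ValueError("need at least 10 shared samples")
    sidx = np.array([g.samples.index(s) for s in samples])

    # Inverse-normal transform each gene's expression across samples.
    expr = expression[samples].to_numpy(dtype=float)
    expr_int = np.vstack([inverse_normal_transform(row) for row in expr])

    cov_frames = []
    if covariates is not None:
        cov_frames.append(covariates.loc[samples])
    if n_expr_pcs > 0 and expr_int.shape[0] > n_expr_pcs:
        z = expr_int - expr_int.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(z.T, full_matrices=False)
        epcs = pd.DataFrame(
            u[:, :n_expr_pcs] * s[:n_expr_pcs],
            index=pd.Index(samples, name="sample"),
            columns=[f"ePC{k + 1}" for k in range(n_expr_pcs)],
        )
        cov_frames.append(epcs)
    cov_df = pd.concat(cov_frames, axis=1) if cov_frames else None
    C, cov_names = _build_covariates(g, cov_df, n_geno_pcs, samples)
    Q, _ = np.linalg.qr(C)
    df = len(samples) - C.shape[1] - 1
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")

    maf = g.maf()
    pos = g.variants["pos"].to_numpy()
    is_snp = (g.variants["vclass"] == "SNP").to_numpy()
    eligible = is_snp & (maf >= maf_min)

    D = g.dosages[sidx, :].astype(float)
    D[D == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(D), np.nan, D), axis=0)
    nan_mask = np.isnan(D)
    D[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    D_r = _residualize(D, Q)

    rng = np.random.default_rng(seed)
    n = len(samples)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)]) if n_perm > 0 else None

    nominal_rows = []
    gene_rows = []
    skipped: list[tuple[str, str]] = []
    ann = gene_annotation.set_index("gene_id")
    for gi, gene in enumerate(expression.index):
        if gene not in ann.index:
            skipped.append((str(gene), "no annotation"))
            continue
        tss = int(ann.loc[gene, "tss"])
        cis = np.flatnonzero(eligible & (np.abs(pos - tss) <= window))
        if len(cis) == 0:
            skipped.append((str(gene), "no cis variants after filters"))
            continue
        y_r = _residualize(expr_int[gi][:, None], Q)[:, 0]
        X_r = D_r[:, cis]
        sxx = np.einsum("ij,ij->j", X_r, X_r)
        ok = sxx > 1e-10 * n
        cis, X_r, sxx = cis[ok], X_r[:, ok], sxx[ok]
        if len(cis) == 0:
            skipped.append((str(gene), "cis variants collinear with covariates"))
            continue
        b, s, p = _scan(y_r, X_r, df)
        sub = g.variants.iloc[cis][KEY_COLS].copy()
        sub.insert(0, "gene_id", gene)
        sub["maf"] = maf[cis]
        sub["beta"] = b
        sub["se"] = s
        sub["p"] = p
        nominal_rows.append(sub)

        best = int(np.argmin(p))
        # Max absolute partial correlation == min nominal P at common df.
        syy = float(y_r @ y_r)
        obs_stat = np.max(np.abs(X_r.T @ y_r) / np.sqrt(sxx)) / np.sqrt(syy)
        if n_perm > 0:
            Yp = y_r[perms]  # (n_perm, n)
            num = np.abs(Yp @ X_r) / np.sqrt(sxx)  # (n_perm, m)
            perm_stat = num.max(axis=1) / np.sqrt(syy)
            emp_p = (1.0 + np.sum(perm_stat >= obs_stat)) / (1.0 + n_perm)
        else:
            emp_p = np.nan
        gene_rows.append(
            {
                "gene_id": gene,
                "n_cis": len(cis),
                "best_chrom": sub["chrom"].iloc[best],
                "best_pos": sub["pos"].iloc[best],
                "best_ref": sub["ref"].iloc[best],
                "best_alt": sub["alt"].iloc[best],
                "beta": float(b[best]),
                "se": float(s[best]),
                "nominal_p": float(p[best]),
                "empirical_p": float(emp_p),
            }
        )

    if not gene_rows:
        raise ValueError("no genes could be tested")
    genes = pd.DataFrame(gene_rows)
    if genes["empirical_p"].notna().all() and n_perm > 0:
        _, qvals, _, _ = multipletests(genes["empirical_p"].to_numpy(), method="fdr_bh")
        genes["q"] = qvals
        genes["significant"] = genes["q"] <= fdr
    table = pd.concat(nominal_rows, ignore_index=True)
    return AssocSummary(
        table=table,
        filters={"window": window, "maf_min": maf_min, "n_perm": n_perm, "fdr": fdr},
        covariates=cov_names,
        genes=genes,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Cross-library agreement
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """Agreement of two association summaries over shared tested variants."""

    n_overlap: int
    n_a_unique: int
    n_b_unique: int
    r2_neglog10_p: float
    r2_beta: float
    n_allele_flipped: int
    mirrored: pd.DataFrame  # key cols + neglog10_p_a/b + beta_a/b
    a_unique: pd.DataFrame
    b_unique: pd.DataFrame


def _squared_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def agreement(resA: AssocSummary, resB: AssocSummary) -> AgreementReport:
    """Join two association summaries on the variant key and correlate.

    Variants whose ref/alt orientation is swapped between the datasets
    are harmonized by flipping the sign of beta (counted in the report).
    R² values are computed over the overlapping tested variants only.
    """
    keys = (["gene_id"] if "gene_id" in resA.table.columns else []) + KEY_COLS
    a = resA.table.copy()
    b = resB.table.copy()
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"), how="inner")

    # Allele-swapped records: same position, ref/alt exchanged.
    swap_keys = [k for k in keys if k not in ("ref", "alt")]
    rest_a = a.loc[~a.set_index(keys).index.isin(merged.set_index(keys).index)].copy()
    b_sw = b.rename(columns={"ref": "alt", "alt": "ref"}).copy()
    b_sw["beta"] = -b_sw["beta"]
    swapped = rest_a.merge(b_sw, on=keys, suffixes=("_a", "_b"), how="inner")
    n_flipped = len(swapped)
    if n_flipped:
        merged = pd.concat([merged, swapped], ignore_index=True)

    if len(merged) == 0:
        raise ValueError("no overlapping tested variants")

    neglog_a = -np.log10(merged["p_a"].to_numpy())
    neglog_b = -np.log10(merged["p_b"].to_numpy())
    mirrored = merged[keys].copy()
    mirrored["neglog10_p_a"] = neglog_a
    mirrored["neglog10_p_b"] = neglog_b
    mirrored["beta_a"] = merged["beta_a"]
    mirrored["beta_b"] = merged["beta_b"]

    matched_keys = merged[keys]
    a_unique = a.loc[~a.set_index(keys).index.isin(matched_keys.set_index(keys).index)]
    # For b, the swapped records were matched under flipped orientation.
    b_matched = pd.concat(
        [
            merged.iloc[: len(merged) - n_flipped][keys] if n_flipped else merged[keys],
            swapped[keys].rename(columns={"ref": "alt", "alt": "ref"}) if n_flipped else pd.DataFrame(columns=keys),
        ]
    )
    b_unique = b.loc[~b.set_index(keys).index.isin(b_matched.set_index(keys).index)]

    return AgreementReport(
        n_overlap=len(merged),
        n_a_unique=len(a_unique),
        n_b_unique=len(b_unique),
        r2_neglog10_p=_squared_pearson(neglog_a, neglog_b),
        r2_beta=_squared_pearson(merged["beta_a"].to_numpy(), merged["beta_b"].to_numpy()),
        n_allele_flipped=n_flipped,
        mirrored=mirrored,
        a_unique=a_unique.reset_index(drop=True),
        b_unique=b_unique.reset_index(drop=True),
    )
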