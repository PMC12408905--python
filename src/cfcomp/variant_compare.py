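"""Genotype-level comparison of two call sets from the same individuals.

Implements the battery used to judge whether two library preparations
(short-insert cell-free DNA vs long-insert genomic DNA) recover the same
genetic information: variant overlap accounting, Ti/Tv and Het/Hom
quality ratios, allele-frequency spectrum correlation, MAF-binned
genotype dosage R², per-individual genotype concordance, and agreement
of principal-component population structure after Procrustes alignment.

All statistics use pairwise-complete observations: a genotype enters a
comparison only when non-missing in both datasets at that site for that
individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .synthetic_data import MISSING, TRANSITIONS, GenotypeMatrix

__all__ = [
    "UndefinedRatioError",
    "ConcordanceReport",
    "MAFBinReport",
    "PCAComparison",
    "overlap_counts",
    "titv",
    "het_hom",
    "af_spectrum_r2",
    "maf_bin_r2",
    "concordance",
    "pca_compare",
]


class UndefinedRatioError(ValueError):
    """A ratio statistic has a zero denominator (e.g. no transversions)."""


# ---------------------------------------------------------------------------
# Alignment of two matrices on shared keys / samples
# ---------------------------------------------------------------------------


def _shared_variants(a: GenotypeMatrix, b: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Positional indices of the key-intersection in each matrix's order."""
    ka, kb = a.keys(), b.keys()
    common = ka.intersection(kb)
    ia = ka.get_indexer(common)
    ib = kb.get_indexer(common)
    return ia, ib


def _shared_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    common = [s for s in a.samples if s in set(b.samples)]
    pos_b = {s: i for i, s in enumerate(b.samples)}
    ia = np.array([a.samples.index(s) for s in common], dtype=int)
    ib = np.array([pos_b[s] for s in common], dtype=int)
    return ia, ib


# ---------------------------------------------------------------------------
# Overlap accounting
# ---------------------------------------------------------------------------


def overlap_counts(a: GenotypeMatrix, b: GenotypeMatrix) -> pd.DataFrame:
    """Variant-count table: records, SNPs, INDELs, multiallelic sites.

    Columns ``a``, ``b`` and ``overlap`` (the (chrom,pos,ref,alt) key
    intersection), mirroring a population-level call-set summary.
    """
    if a.n_variants == 0 or b.n_variants == 0:
        raise ValueError("empty genotype matrix")
    ia, _ = _shared_variants(a, b)
    shared = a.variants.iloc[ia]

    def _row(v: pd.DataFrame) -> dict[str, int]:
        return {
            "records": len(v),
            "snps": int((v["vclass"] == "SNP").sum()),
            "indels": int((v["vclass"] == "INDEL").sum()),
            "multiallelic": int(v["multiallelic"].sum()),
        }

    return pd.DataFrame(
        {"a": _row(a.variants), "b": _row(b.variants), "overlap": _row(shared)}
    )


# ---------------------------------------------------------------------------
# Quality ratios
# ---------------------------------------------------------------------------


def titv(g: GenotypeMatrix) -> float:
    """Transition/transversion ratio over biallelic SNP sites.

    Counted per site (not per genotype), restricted to sites carrying at
    least one non-reference call.  Raises when no transversions exist.
    """
    v = g.variants
    is_snp = (v["vclass"] == "SNP") & ~v["multiallelic"].astype(bool)
    has_alt = (g.dosages > 0).any(axis=0)
    use = is_snp.to_numpy() & has_alt
    pairs = list(zip(v.loc[use, "ref"], v.loc[use, "alt"]))
    ts = sum(1 for p in pairs if p in TRANSITIONS)
    tv = len(pairs) - ts
    if tv == 0:
        raise UndefinedRatioError("no transversions among called SNPs; Ti/Tv undefined")
    return ts / tv


def het_hom(g: GenotypeMatrix) -> pd.Series:
    """Per-individual heterozygous / homozygous-alternate call ratio.

    Individuals with zero homozygous-alternate calls get NaN.
    """
    het = (g.dosages == 1).sum(axis=1).astype(float)
    hom = (g.dosages == 2).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hom > 0, het / hom, np.nan)
    return pd.Series(ratio, index=pd.Index(g.samples, name="sample"), name="het_hom")


# ---------------------------------------------------------------------------
# Allele-frequency agreement
# ---------------------------------------------------------------------------


def af_spectrum_r2(a: GenotypeMatrix, b: GenotypeMatrix) -> float:
    """Squared Pearson correlation of MAFs over shared variants."""
    ia, ib = _shared_variants(a, b)
    if len(ia) < 2:
        raise ValueError("need at least 2 shared variants")
    maf_a = a.maf()[ia]
    maf_b = b.maf()[ib]
    ok = ~np.isnan(maf_a) & ~np.isnan(maf_b)
    maf_a, maf_b = maf_a[ok], maf_b[ok]
    if len(maf_a) < 2 or maf_a.std() == 0 or maf_b.std() == 0:
        raise ValueError("degenerate MAF vectors: zero variance")
    r, _ = stats.pearsonr(maf_a, maf_b)
    return float(r**2)


@dataclass
class MAFBinReport:
    """Mean per-SNP genotype R² within MAF bins of fixed width."""

    bin_width: float
    table: pd.DataFrame  # bin_lo, bin_hi, n_variants, n_used, mean_r2
    overall_mean: float
    per_snp: pd.DataFrame  # key columns + maf_ref + r2


def _pairwise_r2(da: np.ndarray, db: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise complete.

    NaN when fewer than 2 complete pairs or either side is constant.
    """
    ok = (da != MISSING) & (db != MISSING)
    x, y = da[ok].astype(float), db[ok].astype(float)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def maf_bin_r2(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    bin_width: float = 0.01,
    bin_by: str = "b",
) -> MAFBinReport:
    """Genotype dosage R² per shared SNP, averaged within MAF bins.

    Shared SNPs are binned by the reference dataset's MAF (``bin_by`` in
    {"a", "b", "mean"}) into intervals of ``bin_width`` spanning
    [0, 0.5].  SNPs monomorphic in either dataset are counted but
    excluded from bin means; empty bins are reported with NaN and do not
    enter the overall mean.
    """
    ia, ib = _shared_variants(a, b)
    if len(ia) == 0:
        raise ValueError("no shared variants")
    sa, sb = _shared_samples(a, b)
    is_snp = (a.variants["vclass"].to_numpy() == "SNP")[ia]
    ia, ib = ia[is_snp], ib[is_snp]

    maf_a, maf_b = a.maf()[ia], b.maf()[ib]
    if bin_by == "a":
        maf_ref = maf_a
    elif bin_by == "b":
        maf_ref = maf_b
    elif bin_by == "mean":
        maf_ref = (maf_a + maf_b) / 2.0
    else:
        raise ValueError("bin_by must be one of {'a', 'b', 'mean'}")

    da = a.dosages[np.ix_(sa, ia)]
    db = b.dosages[np.ix_(sb, ib)]
    r2 = np.array([_pairwise_r2(da[:, j], db[:, j]) for j in range(da.shape[1])])

    n_bins = int(np.ceil(0.5 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    # Right-closed top bin so MAF == 0.5 lands in the last interval.
    bin_idx = np.clip(np.floor(maf_ref / bin_width).astype(int), 0, n_bins - 1)

    rows = []
    for bi in range(n_bins):
        mask = (bin_idx == bi) & ~np.isnan(maf_ref)
        vals = r2[mask]
        used = vals[~np.isnan(vals)]
        rows.append(
            {
                "bin_lo": edges[bi],
                "bin_hi": edges[bi + 1],
                "n_variants": int(mask.sum()),
                "n_used": len(used),
                "mean_r2": float(used.mean()) if len(used) else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    nonempty = table["mean_r2"].dropna()
    per_snp = a.variants.iloc[ia][["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    per_snp["maf_ref"] = maf_ref
    per_snp["r2"] = r2
    return MAFBinReport(
        bin_width=bin_width,
        table=table,
        overall_mean=float(nonempty.mean()) if len(nonempty) else np.nan,
        per_snp=per_snp,
    )


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    """Per-individual identical-genotype fraction over shared sites."""

    per_individual: pd.Series
    n_sites: pd.Series  # usable (both non-missing) sites per individual

    @property
    def mean(self) -> float:
        return float(self.per_individual.mean())

    @property
    def min(self) -> float:
        return float(self.per_individual.min())

    @property
    def max(self) -> float:
        return float(self.per_individual.max())


def concordance(a: GenotypeMatrix, b: GenotypeMatrix) -> ConcordanceReport:
    """Fraction of shared sites with identical dosage, per individual.

    Only sites non-missing in both datasets count; individuals with zero
    usable sites are reported as NaN.
    """
    ia, ib = _shared_variants(a, b)
    sa, sb = _shared_samples(a, b)
    if len(ia) == 0 or len(sa) == 0:
        raise ValueError("no shared variants or samples")
    da = a.dosages[np.ix_(sa, ia)]
    db = b.dosages[np.ix_(sb, ib)]
    usable = (da != MISSING) & (db != MISSING)
    same = (da == db) & usable
    n_usable = usable.sum(axis=1)
    with np.errstate(invalid="ignore"):
        conc = np.where(n_usable > 0, same.sum(axis=1) / n_usable, np.nan)
    samples = [a.samples[i] for i in sa]
    idx = pd.Index(samples, name="sample")
    return ConcordanceReport(
        per_individual=pd.Series(conc, index=idx, name="concordance"),
        n_sites=pd.Series(n_usable, index=idx, name="n_sites"),
    )


# ---------------------------------------------------------------------------
# Population-structure agreement
# ---------------------------------------------------------------------------


@dataclass
class PCAComparison:
    """Per-individual PC-score displacement after Procrustes alignment."""

    scores_a: np.ndarray
    scores_b_aligned: np.ndarray
    displacement: pd.Series
    mean_displacement: float
    relative_displacement: float  # mean displacement / RMS score norm of a
    n_variants_used: int


def _pc_scores(dosages: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top-PC scores of a standardized dosage matrix (missing -> mean)."""
    d = dosages.astype(float)
    d[dosages == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    sd = np.sqrt(2 * p * (1 - p))
    z = (d - 2 * p) / sd
    z[np.isnan(z)] = 0.0
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def pca_compare(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    n_pcs: int = 5,
    maf_min: float = 0.05,
) -> PCAComparison:
    """Compare population structure recovered from the two call sets.

    Shared variants with MAF > ``maf_min`` in both datasets are
    standardized per variant ((dosage - 2p)/sqrt(2p(1-p))); top PCs come
    from a truncated SVD of each dataset, and dataset b's scores are
    aligned to a's by an orthogonal Procrustes rotation, making the
    comparison invariant to per-PC sign flips and rotations.
    """
    ia, ib = _shared_variants(a, b)
    sa, sb = _shared_samples(a, b)
    if len(sa) <= n_pcs:
        raise ValueError(f"need more than {n_pcs} shared individuals for {n_pcs} PCs")
    maf_a, maf_b = a.maf()[ia], b.maf()[ib]
    ok = (maf_a > maf_min) & (maf_b > maf_min)
    ia, ib = ia[ok], ib[ok]
    if len(ia) < n_pcs:
        raise ValueError("too few shared variants after the MAF filter")
    scores_a = _pc_scores(a.dosages[np.ix_(sa, ia)], n_pcs)
    scores_b = _pc_scores(b.dosages[np.ix_(sb, ib)], n_pcs)
    rotation, _ = linalg.orthogonal_procrustes(scores_b, scores_a)
    aligned = scores_b @ rotation
    disp = np.linalg.norm(scores_a - aligned, axis=1)
    scale = float(np.sqrt(np.mean(np.sum(scores_a**2, axis=1))))
    samples = [a.samples[i] for i in sa]
    return PCAComparison(
        scores_a=scores_a,
        scores_b_aligned=aligned,
        displacement=pd.Series(disp, index=pd.Index(samples, name="sample"), name="displacement"),
        mean_displacement=float(disp.mean()),
        relative_displacement=float(disp.mean() / scale) if scale > 0 else np.nan,
        n_variants_used=len(ia),
    )
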