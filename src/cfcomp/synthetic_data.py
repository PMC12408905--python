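"""Synthetic inputs for the two-library comparison.

Everything the downstream analyses consume is generated here: a labeled
genome (normal / difficult / centromere / gap intervals with per-library
fragment-retention multipliers), a cohort of true genotypes drawn under
Hardy-Weinberg proportions, noisy *observed* genotype matrices for each
library type (variant dropout, missingness, genotype error), and
quantitative phenotypes / expression with planted genetic effects.

The generators emulate the design of a paired cfDNA/gDNA study: two
observed datasets derived from the *same* underlying genomes, differing
only through library-dependent observation processes.  They do not model
linkage disequilibrium, indel realignment artefacts, or sequence content
(GC, mappability) beyond the discrete region labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage_model import LibraryKind

__all__ = [
    "MISSING",
    "REGION_LABELS",
    "GenomeModel",
    "CohortTruth",
    "GenotypeMatrix",
    "KindObservation",
    "ObservationModel",
    "CisConfig",
    "generate_genome",
    "generate_cohort",
    "observe_genotypes",
    "generate_phenotypes",
    "generate_covariates",
    "generate_expression",
    "read_bed",
    "write_bed",
    "write_vcf",
    "read_vcf",
]

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

REGION_LABELS = ("normal", "difficult", "centromere", "gap")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_COMPLEMENTARY = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------


@dataclass
class GenomeModel:
    """A single synthetic chromosome with labeled intervals.

    ``regions`` are 0-based half-open ``(start, end, label)`` triples,
    sorted and non-overlapping.  Unlabeled positions are implicitly
    ``"normal"``.  ``bias`` maps a region label to a per-library-kind
    fragment-retention multiplier in [0, 1]; absent entries default to 1.
    """

    length: int
    regions: list[tuple[int, int, str]] = field(default_factory=list)
    bias: dict[str, dict[str, float]] = field(default_factory=dict)
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be positive")
        regs = sorted((int(s), int(e), str(lab)) for s, e, lab in self.regions)
        prev_end = 0
        for start, end, label in regs:
            if start < 0 or end > self.length or start >= end:
                raise ValueError(f"region ({start}, {end}, {label}) outside [0, {self.length})")
            if start < prev_end:
                raise ValueError(f"overlapping regions at {start}")
            prev_end = end
        self.regions = regs
        for label, kinds in self.bias.items():
            for kind, mult in kinds.items():
                if not 0.0 <= mult <= 1.0:
                    raise ValueError(f"retention bias for ({label}, {kind}) outside [0,1]: {mult}")
        self._starts = np.array([r[0] for r in regs], dtype=np.int64)
        self._ends = np.array([r[1] for r in regs], dtype=np.int64)
        self._labels = np.array([r[2] for r in regs], dtype=object)

    def labels_at(self, positions: np.ndarray) -> np.ndarray:
        """Region label for each position (``"normal"`` when unlabeled)."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, "normal", dtype=object)
        if len(self._starts):
            idx = np.searchsorted(self._starts, positions, side="right") - 1
            ok = idx >= 0
            inside = np.zeros_like(ok)
            inside[ok] = positions[ok] < self._ends[idx[ok]]
            out[inside] = self._labels[idx[inside]]
        return out

    def retention(self, label: str, kind: LibraryKind | str) -> float:
        kind = LibraryKind(kind).value
        return float(self.bias.get(label, {}).get(kind, 1.0))


def generate_genome(
    length: int,
    region_spec: Sequence[tuple[int, int, str]] = (),
    seed: int | None = None,
    bias: Mapping[str, Mapping[str, float]] | None = None,
    chrom: str = "chr1",
) -> GenomeModel:
    """Build a :class:`GenomeModel` from an explicit interval list.

    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators but unused.
    """
    del seed
    return GenomeModel(
        length=length,
        regions=[tuple(r) for r in region_spec],
        bias={k: dict(v) for k, v in (bias or {}).items()},
        chrom=chrom,
    )


def write_bed(genome: GenomeModel, path: str | Path) -> None:
    """Write the labeled intervals as a 4-column BED track."""
    with open(path, "w") as fh:
        for start, end, label in genome.regions:
            fh.write(f"{genome.chrom}\t{start}\t{end}\t{label}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+label track into a DataFrame (chrom, start, end, label)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            label = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    if ((df["end"] <= df["start"]) | (df["start"] < 0)).any():
        raise ValueError("malformed BED: intervals must satisfy 0 <= start < end")
    return df.sort_values(["chrom", "start"], ignore_index=True)


# ---------------------------------------------------------------------------
# Genotype containers
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "vclass", "multiallelic"]


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with a variant table.

    ``dosages`` holds alternate-allele counts 0/1/2 with ``MISSING`` (-1)
    for no-calls, shaped ``(n_samples, n_variants)``.  The variant table
    carries ``chrom, pos, ref, alt, vclass (SNP|INDEL), multiallelic``
    and is keyed uniquely by ``(chrom, pos, ref, alt)``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or MISSING (-1)")
        keys = self.variants[["chrom", "pos", "ref", "alt"]]
        if keys.duplicated().any():
            raise ValueError("variant keys (chrom, pos, ref, alt) must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def keys(self) -> pd.Index:
        v = self.variants
        return pd.MultiIndex.from_arrays(
            [v["chrom"], v["pos"], v["ref"], v["alt"]], names=["chrom", "pos", "ref", "alt"]
        )

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls (NaN if none)."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
        )


@dataclass
class CohortTruth:
    """Ground-truth cohort: genotypes, allele frequencies, ancestry labels."""

    n_individuals: int
    variants: pd.DataFrame  # VARIANT_COLUMNS + "true_af"
    genotypes: np.ndarray  # (n_individuals, n_variants), 0/1/2
    ancestry: np.ndarray  # group label per individual
    samples: list[str]

    def as_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants[VARIANT_COLUMNS].copy(),
            dosages=self.genotypes.copy(),
        )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_alleles(rng: np.random.Generator, n: int, transition_prob: float) -> tuple[np.ndarray, np.ndarray]:
    """Ref/alt pairs for SNPs with the given transition fraction.

    A transition fraction of 2/3 yields the genome-wide expected
    Ti/Tv ~ 2 of high-quality human call sets.
    """
    ref = _BASES[rng.integers(0, 4, size=n)]
    is_ts = rng.random(n) < transition_prob
    alt = np.empty(n, dtype=object)
    for i in range(n):
        if is_ts[i]:
            alt[i] = _COMPLEMENTARY[ref[i]]
        else:
            choices = [b for b in "ACGT" if b != ref[i] and b != _COMPLEMENTARY[ref[i]]]
            alt[i] = choices[rng.integers(0, 2)]
    return ref.astype(object), alt


def generate_cohort(
    n_individuals: int,
    n_variants: int,
    maf_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    ancestry_groups: int = 1,
    seed: int | None = None,
    genome: GenomeModel | None = None,
    genome_length: int = 1_000_000,
    indel_fraction: float = 0.15,
    multiallelic_fraction: float = 0.06,
    transition_prob: float = 2.0 / 3.0,
    ancestry_af_shift: float = 0.1,
) -> CohortTruth:
    """Draw a cohort of true genotypes.

    Allele frequencies come from ``maf_distribution`` (default uniform on
    [0.001, 0.5]); genotypes are Binomial(2, AF) per individual, i.e.
    Hardy-Weinberg proportions.  With ``ancestry_groups > 1`` each
    non-reference group receives Gaussian per-variant AF offsets of scale
    ``ancestry_af_shift`` so principal components separate the groups.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if n_variants < 1:
        raise ValueError("need at least 1 variant")
    if ancestry_groups < 1:
        raise ValueError("ancestry_groups must be >= 1")
    rng = np.random.default_rng(seed)
    length = genome.length if genome is not None else genome_length
    chrom = genome.chrom if genome is not None else "chr1"
    if n_variants > length:
        raise ValueError("more variants than genome positions")

    if maf_distribution is None:
        af = rng.uniform(0.001, 0.5, size=n_variants)
    else:
        af = np.asarray(maf_distribution(rng, n_variants), dtype=float)
        if af.shape != (n_variants,) or np.any(af < 0) or np.any(af > 1):
            raise ValueError("maf_distribution must return n_variants frequencies in [0, 1]")

    pos = np.sort(rng.choice(length, size=n_variants, replace=False))
    vclass = np.where(rng.random(n_variants) < indel_fraction, "INDEL", "SNP")
    multi = rng.random(n_variants) < multiallelic_fraction
    ref, alt = _draw_alleles(rng, n_variants, transition_prob)
    # Indels as 1-bp insertions/deletions relative to the drawn ref base.
    is_indel = vclass == "INDEL"
    for i in np.flatnonzero(is_indel):
        if rng.random() < 0.5:
            alt[i] = ref[i] + str(_BASES[rng.integers(0, 4)])
        else:
            ref[i], alt[i] = ref[i] + str(_BASES[rng.integers(0, 4)]), ref[i]

    groups = rng.integers(0, ancestry_groups, size=n_individuals)
    group_af = np.tile(af, (ancestry_groups, 1))
    if ancestry_groups > 1:
        offsets = rng.normal(0.0, ancestry_af_shift, size=(ancestry_groups, n_variants))
        offsets[0] = 0.0
        group_af = np.clip(group_af + offsets, 1e-4, 1.0 - 1e-4)

    genotypes = rng.binomial(2, group_af[groups, :]).astype(np.int8)

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "vclass": vclass,
            "multiallelic": multi,
            "true_af": af,
        }
    )
    samples = [f"S{i:04d}" for i in range(n_individuals)]
    return CohortTruth(
        n_individuals=n_individuals,
        variants=variants,
        genotypes=genotypes,
        ancestry=groups,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Observation (genotyping) model
# ---------------------------------------------------------------------------


@dataclass
class KindObservation:
    """Observation noise for one library kind.

    ``error_rate``: probability a called genotype differs from truth
    (perturbed uniformly to one of the two other dosages).
    ``missing_rate``: probability a retained genotype is a no-call.
    ``dropout``: probability a variant is absent from the call set,
    either a scalar or a per-region-label mapping.
    """

    error_rate: float = 0.01
    missing_rate: float = 0.01
    dropout: float | Mapping[str, float] = 0.01

    def dropout_for(self, label: str) -> float:
        if isinstance(self.dropout, Mapping):
            return float(self.dropout.get(label, self.dropout.get("normal", 0.0)))
        return float(self.dropout)

    def __post_init__(self) -> None:
        vals = [self.error_rate, self.missing_rate]
        if isinstance(self.dropout, Mapping):
            vals += list(self.dropout.values())
        else:
            vals.append(self.dropout)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("observation rates must lie in [0, 1]")


@dataclass
class ObservationModel:
    """Per-library-kind observation noise (short-insert vs long-insert)."""

    short: KindObservation = field(default_factory=lambda: KindObservation(0.01, 0.01, {"normal": 0.02, "difficult": 0.10, "centromere": 0.15, "gap": 0.5}))
    long: KindObservation = field(default_factory=lambda: KindObservation(0.01, 0.01, {"normal": 0.01, "difficult": 0.05, "centromere": 0.08, "gap": 0.5}))

    def for_kind(self, kind: LibraryKind | str) -> KindObservation:
        return self.short if LibraryKind(kind) is LibraryKind.SHORT_INSERT else self.long


def observe_genotypes(
    truth: CohortTruth,
    model: ObservationModel | KindObservation,
    genome: GenomeModel,
    kind: LibraryKind | str,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Apply dropout, missingness and genotype error to the true cohort.

    Each variant is dropped from the call set with the region-dependent
    dropout probability; retained genotypes are set missing with the
    missing rate, else perturbed with the error rate (uniformly to one of
    the two other dosage values).  Never invents variants absent from
    the truth.
    """
    obs = model.for_kind(kind) if isinstance(model, ObservationModel) else model
    rng = np.random.default_rng(seed)
    pos = truth.variants["pos"].to_numpy()
    if len(pos) and pos.max() >= genome.length:
        raise ValueError("variant positions exceed genome length")
    labels = genome.labels_at(pos)
    drop_p = np.array([obs.dropout_for(lab) for lab in labels])
    keep = rng.random(len(pos)) >= drop_p

    geno = truth.genotypes[:, keep].astype(np.int8).copy()
    shape = geno.shape
    u = rng.random(shape)
    miss = u < obs.missing_rate
    err = (u >= obs.missing_rate) & (u < obs.missing_rate + (1 - obs.missing_rate) * obs.error_rate)
    # Perturb: add 1 or 2 mod 3 moves a dosage uniformly to the other two.
    shift = rng.integers(1, 3, size=shape)
    geno[err] = ((geno[err] + shift[err]) % 3).astype(np.int8)
    geno[miss] = MISSING

    return GenotypeMatrix(
        samples=list(truth.samples),
        variants=truth.variants.loc[keep, VARIANT_COLUMNS].reset_index(drop=True),
        dosages=geno,
    )


# ---------------------------------------------------------------------------
# Phenotypes and covariates
# ---------------------------------------------------------------------------


def generate_phenotypes(
    truth: CohortTruth,
    causal_variants: Sequence[int],
    effect_sizes: Sequence[float],
    heritability: float,
    n_phenotypes: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Quantitative phenotypes with planted additive genetic effects.

    ``phenotype = sum(beta * dosage) + noise`` with the noise standard
    deviation scaled so the *sample* genetic-variance fraction equals
    ``heritability``.  ``causal_variants`` are integer indices into the
    truth variant table.  With ``heritability = 0`` the phenotype is pure
    standard-normal noise.
    """
    if not 0.0 <= heritability < 1.0:
        raise ValueError("heritability must lie in [0, 1)")
    causal = np.asarray(causal_variants, dtype=int)
    beta = np.asarray(effect_sizes, dtype=float)
    if causal.shape != beta.shape:
        raise ValueError("causal_variants and effect_sizes must align")
    if len(causal) and (causal.min() < 0 or causal.max() >= truth.variants.shape[0]):
        raise ValueError("causal variant index out of range")
    rng = np.random.default_rng(seed)
    n = truth.n_individuals
    out = {}
    for j in range(n_phenotypes):
        if heritability == 0.0 or len(causal) == 0:
            y = rng.normal(size=n)
        else:
            g = truth.genotypes[:, causal].astype(float) @ beta
            var_g = g.var()
            if var_g == 0:
                y = rng.normal(size=n)
            else:
                noise = rng.normal(size=n)
                # Orthogonalize to the genetic component so the sample
                # variance fraction equals the target exactly.
                gc = g - g.mean()
                noise = noise - noise.mean()
                noise -= gc * (noise @ gc) / (gc @ gc)
                noise /= noise.std()
                y = g + noise * np.sqrt(var_g * (1 - heritability) / heritability)
        out[f"pheno_{j}"] = y
    return pd.DataFrame(out, index=pd.Index(truth.samples, name="sample"))


def generate_covariates(
    n_individuals: int,
    samples: Sequence[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Age/sex-like nuisance covariates with no phenotype effect.

    These exist so the association design matrix has the same shape as a
    real analysis (age, sex and genotype PCs); they carry no signal.
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index(
        samples if samples is not None else [f"S{i:04d}" for i in range(n_individuals)],
        name="sample",
    )
    return pd.DataFrame(
        {
            "age": rng.integers(20, 70, size=n_individuals).astype(float),
            "sex": rng.integers(0, 2, size=n_individuals).astype(float),
        },
        index=idx,
    )


# ---------------------------------------------------------------------------
# Expression with planted cis effects
# ---------------------------------------------------------------------------


@dataclass
class CisConfig:
    """Planted cis-regulatory architecture for synthetic expression."""

    egene_fraction: float = 0.3
    beta: float = 1.0
    noise_sd: float = 1.0
    window: int = 1_000_000
    max_causal_distance: int | None = None  # defaults to window

    def __post_init__(self) -> None:
        if not 0.0 <= self.egene_fraction <= 1.0:
            raise ValueError("egene_fraction must lie in [0, 1]")
        if self.max_causal_distance is None:
            self.max_causal_distance = self.window
        if self.max_causal_distance > self.window:
            raise ValueError("causal variant would fall outside the cis window")


def generate_expression(
    truth: CohortTruth,
    cis_config: CisConfig,
    n_genes: int,
    seed: int | None = None,
    genome_length: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) plus gene annotation.

    A fraction of genes are eGenes whose expression is
    ``beta * dosage(causal cis variant) + Gaussian noise``; the rest are
    pure noise.  The gene annotation table carries gene id, chromosome,
    transcription start site and strand.
    """
    rng = np.random.default_rng(seed)
    pos = truth.variants["pos"].to_numpy()
    length = genome_length or int(pos.max()) + 1
    chrom = truth.variants["chrom"].iloc[0] if len(truth.variants) else "chr1"
    tss = np.sort(rng.choice(length, size=n_genes, replace=False))
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    is_egene = rng.random(n_genes) < cis_config.egene_fraction

    expr = np.empty((n_genes, truth.n_individuals))
    causal_idx = np.full(n_genes, -1, dtype=int)
    for gi in range(n_genes):
        noise = cis_config.noise_sd * rng.normal(size=truth.n_individuals)
        if is_egene[gi]:
            # plant on SNPs only: the cis scan tests SNP dosages
            near = np.flatnonzero(
                (np.abs(pos - tss[gi]) <= cis_config.max_causal_distance)
                & (truth.variants["vclass"].to_numpy() == "SNP")
            )
            if len(near) == 0:
                is_egene[gi] = False
                expr[gi] = noise
                continue
            ci = int(rng.choice(near))
            causal_idx[gi] = ci
            expr[gi] = cis_config.beta * truth.genotypes[:, ci].astype(float) + noise
        else:
            expr[gi] = noise

    genes = [f"G{g:04d}" for g in range(n_genes)]
    annotation = pd.DataFrame(
        {
            "gene_id": genes,
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
            "is_egene": is_egene,
            "causal_variant": causal_idx,
        }
    )
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=truth.samples)
    return expression, annotation


# ---------------------------------------------------------------------------
# Minimal VCF I/O (GT-only, single chromosome)
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path, contig_length: int | None = None) -> None:
    """Write the matrix as an uncompressed GT-only VCF 4.2 file.

    Positions are converted to 1-based per the format.  The multiallelic
    flag is preserved in INFO as ``MA``.
    """
    v = g.variants
    chroms = v["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MA,Number=0,Type=Flag,Description="Multiallelic site">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            if contig_length is not None:
                fh.write(f"##contig=<ID={c},length={contig_length}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples) + "\n")
        for j in range(g.n_variants):
            row = v.iloc[j]
            info = "MA" if bool(row["multiallelic"]) else "."
            gts = "\t".join(_GT[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only VCF (as written by :func:`write_vcf`) via pysam."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows = []
        dosage_cols = []
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "."
            vclass = "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "INDEL"
            rows.append(
                (
                    rec.chrom,
                    rec.pos - 1,  # back to 0-based
                    rec.ref,
                    alt,
                    vclass,
                    "MA" in rec.info,
                )
            )
            col = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    col[i] = MISSING
                else:
                    col[i] = sum(gt)
            dosage_cols.append(col)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.stack(dosage_cols, axis=1) if dosage_cols else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)
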