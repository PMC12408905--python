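"""Sequencing-library simulation: fragments, PCR duplicates, depth tracks.

Models the mechanics that differ between a cell-free DNA library
(short inserts ~170 bp, heavy PCR amplification) and a sheared genomic
DNA library (long inserts ~350 bp, ~1% duplicates):

* fragment placement uniform over the genome, thinned by region-label
  retention multipliers (repetitive/centromeric placement loss),
* truncated-normal fragment lengths,
* PCR copies per unique fragment distributed 1 + Poisson(lambda),
* coordinate-based duplicate marking keyed on (start, length),
* two rounds of down-sampling (raw copies, then deduplicated fragments)
  to match depths between the two libraries,
* exact per-base depth from paired-end read geometry: reads of length r
  at both fragment ends, overlapping (depth 2) where the insert is
  shorter than 2r.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .coverage_model import LibraryKind
from .synthetic_data import GenomeModel

__all__ = [
    "LibraryModel",
    "FragmentSet",
    "DepthTrack",
    "short_insert_library",
    "long_insert_library",
    "sample_fragments",
    "duplication_rate",
    "dedup",
    "downsample",
    "depth_track",
    "matched_depth_tracks",
]


@dataclass(frozen=True)
class LibraryModel:
    """Library construction parameters for one DNA type."""

    kind: LibraryKind
    mean_insert: float
    sd_insert: float
    read_length: int = 100
    dup_lambda: float = 0.0  # expected extra PCR copies per unique fragment
    min_insert: int = 1
    max_insert: int | None = None

    def __post_init__(self) -> None:
        if self.mean_insert <= 0 or self.sd_insert < 0:
            raise ValueError("insert-length distribution must have positive mean, non-negative sd")
        if self.read_length < 1:
            raise ValueError("read length must be >= 1")
        if self.dup_lambda < 0:
            raise ValueError("duplication intensity must be >= 0")
        if self.min_insert < 1:
            raise ValueError("minimum insert must be >= 1")


def short_insert_library(dup_lambda: float = 0.229, read_length: int = 100) -> LibraryModel:
    """cfDNA-like library: ~170 bp inserts, high PCR duplication.

    The default ``dup_lambda`` of 0.229 gives an expected duplication
    rate lambda/(1+lambda) of ~18.6%, typical of low-input plasma
    libraries.
    """
    return LibraryModel(
        kind=LibraryKind.SHORT_INSERT,
        mean_insert=170.0,
        sd_insert=15.0,
        read_length=read_length,
        dup_lambda=dup_lambda,
    )


def long_insert_library(dup_lambda: float = 0.0115, read_length: int = 100) -> LibraryModel:
    """gDNA-like library: ~350 bp sheared inserts, ~1.1% duplication."""
    return LibraryModel(
        kind=LibraryKind.LONG_INSERT,
        mean_insert=350.0,
        sd_insert=60.0,
        read_length=read_length,
        dup_lambda=dup_lambda,
    )


@dataclass
class FragmentSet:
    """Unique fragments with PCR copy counts for one sample/library."""

    starts: np.ndarray  # int64
    lengths: np.ndarray  # int64
    copies: np.ndarray  # int64, >= 1
    genome_length: int
    kind: LibraryKind
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.copies = np.asarray(self.copies, dtype=np.int64)
        if not (len(self.starts) == len(self.lengths) == len(self.copies)):
            raise ValueError("starts, lengths and copies must align")
        if len(self.starts):
            if self.starts.min() < 0 or (self.starts + self.lengths).max() > self.genome_length:
                raise ValueError("fragments must lie within the genome")
            if self.lengths.min() < 1 or self.copies.min() < 1:
                raise ValueError("lengths and copies must be >= 1")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def total_copies(self) -> int:
        return int(self.copies.sum())

    def read_bases(self, read_length: int) -> int:
        """Total sequenced bases over all copies: 2*min(r, length) each."""
        per_copy = 2 * np.minimum(read_length, self.lengths)
        return int(np.sum(per_copy * self.copies))

    def raw_depth(self, read_length: int) -> float:
        return self.read_bases(read_length) / self.genome_length


@dataclass
class DepthTrack:
    """Per-base integer depth over the genome for one sample/library."""

    depth: np.ndarray
    kind: LibraryKind
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if len(self.depth) and self.depth.min() < 0:
            raise ValueError("depth must be non-negative")

    @property
    def genome_length(self) -> int:
        return len(self.depth)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.sum()) / len(self.depth)


def sample_fragments(
    genome: GenomeModel,
    lib: LibraryModel,
    target_raw_depth: float,
    seed: int | None = None,
    sample_id: str = "sample",
) -> FragmentSet:
    """Draw a fragment set targeting the given raw (copy-counted) depth.

    The unique-fragment count is sized so that expected raw sequenced
    bases (2r per copy, expected 1 + lambda copies per fragment) match
    ``target_raw_depth * genome_length``.  Fragment start positions are
    uniform; each fragment is then retained with the retention
    probability of its midpoint's region label, so a biased genome
    realizes *less* than the target depth in the biased regions.
    """
    if target_raw_depth <= 0:
        raise ValueError("target_raw_depth must be positive")
    r = lib.read_length
    n = genome.length
    region_labels = {reg[2] for reg in genome.regions} | {"normal"}
    retentions = [genome.retention(lab, lib.kind) for lab in region_labels]
    if max(retentions, default=1.0) <= 0.0:
        raise ValueError("target depth unreachable: retention is zero everywhere")

    rng = np.random.default_rng(seed)
    n_unique = int(round(target_raw_depth * n / (2 * r * (1.0 + lib.dup_lambda))))
    if n_unique < 1:
        raise ValueError("target depth too low to place a single fragment")

    hi = lib.max_insert if lib.max_insert is not None else n
    hi = min(hi, n)
    if lib.sd_insert == 0:
        lengths = np.full(n_unique, int(np.clip(round(lib.mean_insert), lib.min_insert, hi)), dtype=np.int64)
    else:
        a = (lib.min_insert - lib.mean_insert) / lib.sd_insert
        b = (hi - lib.mean_insert) / lib.sd_insert
        lengths = (
            stats.truncnorm.rvs(a, b, loc=lib.mean_insert, scale=lib.sd_insert, size=n_unique, random_state=rng)
            .round()
            .astype(np.int64)
        )
        np.clip(lengths, lib.min_insert, hi, out=lengths)

    starts = np.floor(rng.random(n_unique) * (n - lengths + 1)).astype(np.int64)

    midpoints = starts + lengths // 2
    labels = genome.labels_at(midpoints)
    keep_p = np.fromiter(
        (genome.retention(lab, lib.kind) for lab in labels), dtype=float, count=len(labels)
    )
    keep = rng.random(n_unique) < keep_p
    starts, lengths = starts[keep], lengths[keep]
    if len(starts) == 0:
        raise ValueError("target depth unreachable: no fragments survived retention")
    copies = 1 + rng.poisson(lib.dup_lambda, size=len(starts))
    return FragmentSet(
        starts=starts,
        lengths=lengths,
        copies=copies,
        genome_length=n,
        kind=lib.kind,
        sample_id=sample_id,
    )


def duplication_rate(frags: FragmentSet) -> float:
    """Fraction of copies that are duplicates: 1 - unique/(total copies).

    "Unique" counts distinct (start, length) keys, matching
    coordinate-based duplicate-marking semantics.
    """
    if len(frags) == 0:
        raise ValueError("empty fragment set")
    keys = np.stack([frags.starts, frags.lengths], axis=1)
    n_unique = len(np.unique(keys, axis=0))
    return 1.0 - n_unique / frags.total_copies


def dedup(frags: FragmentSet) -> FragmentSet:
    """Collapse identical (start, length) fragments and drop PCR copies."""
    if len(frags) == 0:
        return replace(frags, copies=frags.copies.copy())
    keys = np.stack([frags.starts, frags.lengths], axis=1)
    uniq = np.unique(keys, axis=0)
    return FragmentSet(
        starts=uniq[:, 0],
        lengths=uniq[:, 1],
        copies=np.ones(len(uniq), dtype=np.int64),
        genome_length=frags.genome_length,
        kind=frags.kind,
        sample_id=frags.sample_id,
    )


def downsample(
    frags: FragmentSet,
    target_depth: float,
    count_copies: bool,
    seed: int | None = None,
    read_length: int = 100,
) -> FragmentSet:
    """Binomial thinning to the target depth.

    With ``count_copies=True`` (first round, raw data) each PCR copy is
    retained independently with probability target/current raw depth;
    with ``count_copies=False`` (second round, after deduplication) each
    unique fragment is retained with that probability.  Depth is
    accounted in read bases (``2*min(r, length)`` per copy), matching
    :func:`depth_track` exactly.
    """
    return _thin(frags, target_depth, read_length, count_copies, np.random.default_rng(seed))


def _thin(
    frags: FragmentSet,
    target_depth: float,
    read_length: int,
    count_copies: bool,
    rng: np.random.Generator,
) -> FragmentSet:
    current = frags.read_bases(read_length) / frags.genome_length
    if target_depth > current * (1 + 1e-12):
        raise ValueError(f"target depth {target_depth} exceeds current depth {current:.4f}")
    p = min(1.0, target_depth / current)
    if count_copies:
        kept = rng.binomial(frags.copies, p)
        keep = kept > 0
        return FragmentSet(
            starts=frags.starts[keep],
            lengths=frags.lengths[keep],
            copies=kept[keep],
            genome_length=frags.genome_length,
            kind=frags.kind,
            sample_id=frags.sample_id,
        )
    keep = rng.random(len(frags)) < p
    return FragmentSet(
        starts=frags.starts[keep],
        lengths=frags.lengths[keep],
        copies=frags.copies[keep],
        genome_length=frags.genome_length,
        kind=frags.kind,
        sample_id=frags.sample_id,
    )


def depth_track(frags: FragmentSet, lib: LibraryModel, genome: GenomeModel) -> DepthTrack:
    """Exact per-base depth from paired-end read geometry.

    Each fragment copy contributes a read at each end: [start, start+r)
    and [start+length-r, start+length).  When length < 2r the reads
    overlap and the overlapped bases count twice; when length < r each
    read is truncated to the fragment.
    """
    n = genome.length
    diff = np.zeros(n + 1, dtype=np.int64)
    r = lib.read_length
    s, ln, c = frags.starts, frags.lengths, frags.copies
    rl = np.minimum(r, ln)
    # read 1: [s, s+rl), read 2: [s+ln-rl, s+ln)
    np.add.at(diff, s, c)
    np.subtract.at(diff, s + rl, c)
    np.add.at(diff, s + ln - rl, c)
    np.subtract.at(diff, s + ln, c)
    depth = np.cumsum(diff[:-1])
    return DepthTrack(depth=depth, kind=frags.kind, sample_id=frags.sample_id)


def matched_depth_tracks(
    genome: GenomeModel,
    short_lib: LibraryModel,
    long_lib: LibraryModel,
    target_raw_depth: float,
    seed: int,
    sample_id: str = "sample",
) -> tuple[DepthTrack, DepthTrack, dict]:
    """Run the paired two-round depth-matching pipeline.

    1. Sample both libraries at the same raw depth (first-round match).
    2. Remove PCR duplicates; the high-duplication (short-insert)
       library loses more effective depth.
    3. Second round: down-sample the deeper deduplicated library to the
       shallower one's effective depth.

    Returns the two matched post-dedup depth tracks and a log of
    duplication rates and depths at each stage.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    frags_s = sample_fragments(genome, short_lib, target_raw_depth, seed=int(seeds[0]), sample_id=sample_id)
    frags_l = sample_fragments(genome, long_lib, target_raw_depth, seed=int(seeds[1]), sample_id=sample_id)
    log = {
        "raw_depth_short": frags_s.raw_depth(short_lib.read_length),
        "raw_depth_long": frags_l.raw_depth(long_lib.read_length),
        "duplication_rate_short": duplication_rate(frags_s),
        "duplication_rate_long": duplication_rate(frags_l),
    }
    dd_s, dd_l = dedup(frags_s), dedup(frags_l)
    d_s = dd_s.raw_depth(short_lib.read_length)
    d_l = dd_l.raw_depth(long_lib.read_length)
    log["dedup_depth_short"], log["dedup_depth_long"] = d_s, d_l
    target = min(d_s, d_l)
    if d_s > target:
        dd_s = _thin(dd_s, target, short_lib.read_length, count_copies=False, rng=np.random.default_rng(int(seeds[2])))
    if d_l > target:
        dd_l = _thin(dd_l, target, long_lib.read_length, count_copies=False, rng=np.random.default_rng(int(seeds[3])))
    log["matched_depth_short"] = dd_s.raw_depth(short_lib.read_length)
    log["matched_depth_long"] = dd_l.raw_depth(long_lib.read_length)
    track_s = depth_track(dd_s, short_lib, genome)
    track_l = depth_track(dd_l, long_lib, genome)
    return track_s, track_l, log
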