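"""Copy-number profiling from binned read counts.

The stage chain mirrors standard shallow-WGS practice:

1. ``correct_counts`` — remove GC and mappability bias, drop blacklisted
   and low-mappability bins, and express each bin as a median-centred
   log2 ratio.
2. ``segment_profile`` — circular binary segmentation (CBS): recursively
   find the pair of circular breakpoints maximising a two-sample
   mean-shift statistic and accept the split when a permutation test is
   significant.  Chromosomes are segmented independently.
3. ``call_segments`` — robust thresholding of segment means into
   loss / neutral / gain using ``max(min_abs, k_mad x noise)``, where the
   noise is the scaled MAD of bin-level residuals.  This deliberately
   replaces a mixture-model caller: the calls are used downstream only as
   binary presence evidence, and a mixture model is unidentifiable on a
   single sample.
4. ``cna_detectable`` — a sample shows a copy-number signal when at least
   one non-neutral autosomal segment spans >= 3 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeBins

SEGMENT_COLUMNS = (
    "chrom", "start", "end", "start_bin", "end_bin", "n_bins", "mean_log2", "call"
)


@dataclass(frozen=True)
class CorrectedProfile:
    """Per-bin corrected, median-centred log2 ratios with a validity mask."""

    sample_id: str
    log2: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)
    genome: GenomeBins = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.log2) != self.genome.n_bins or len(self.valid) != self.genome.n_bins:
            raise ValueError("profile length does not match the bin frame")

    def to_frame(self) -> pd.DataFrame:
        t = self.genome.table[["chrom", "start", "end"]].copy()
        t["log2ratio"] = self.log2
        t["valid"] = self.valid
        return t


@dataclass(frozen=True)
class SegmentedProfile:
    """Segments partitioning the valid bins, plus a bin-level noise estimate."""

    profile: CorrectedProfile = field(repr=False)
    segments: pd.DataFrame = field(repr=False)
    noise: float

    def called(self) -> bool:
        return (self.segments["call"] != "").all()


def correct_counts(
    counts: np.ndarray,
    genome: GenomeBins,
    *,
    sample_id: str = "sample",
    min_mappability: float = 0.5,
    gc_bins: int = 20,
    pseudocount: float = 0.5,
) -> CorrectedProfile:
    """GC/mappability correction and log2-ratio transformation.

    Counts get a pseudocount, are divided by a smoothed GC-bias estimate
    (local medians in ``gc_bins`` equal-frequency GC strata, linearly
    interpolated) and by mappability, then log2-scaled against the sample
    median over valid bins.  Blacklisted, low-mappability and non-autosomal
    bins are invalidated (values still computed where possible).
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) != genome.n_bins:
        raise ValueError(
            f"counts length {len(counts)} does not match {genome.n_bins} bins"
        )
    if not np.any(counts > 0):
        raise ValueError("all-zero count vector")
    valid = genome.valid_mask(min_mappability)
    t = genome.table
    gc = t["gc"].to_numpy()
    mapp = np.maximum(t["mappability"].to_numpy(), 1e-6)
    c = counts + pseudocount
    # bias curve fitted on valid bins, evaluated at every bin's GC
    fit_all = _gc_bias_curve(gc, *_fit_knots(c[valid], gc[valid], gc_bins))
    corrected = c / np.maximum(fit_all, 1e-9) / mapp
    med = np.median(corrected[valid])
    log2 = np.log2(np.maximum(corrected, 1e-12) / med)
    log2 = log2 - np.median(log2[valid])
    return CorrectedProfile(sample_id, log2, valid, genome)


def _gc_bias_curve(x: np.ndarray, xp: np.ndarray, fp: np.ndarray, w: np.ndarray):
    """Smooth bias curve through the local-median knots.

    A size-weighted quadratic through the knot medians: equal-frequency
    strata concentrate knots in the dense GC centre, so pure interpolation
    is unstable in the sparse tails where the bias curve is steepest; a
    low-order smoother keeps the fit robust there while the medians keep
    it robust to copy-number structure.  Falls back to the knot median
    when fewer than three knots exist.
    """
    if len(xp) < 3:
        return np.full_like(x, float(np.median(fp)), dtype=float)
    coef = np.polyfit(xp, fp, 2, w=np.sqrt(w))
    y = np.polyval(coef, x)
    return np.maximum(y, 0.05 * float(np.median(fp)))


def _fit_knots(counts: np.ndarray, gc: np.ndarray, n_bins: int):
    """Knot points (gc, median count, stratum size) over equal-frequency
    GC strata."""
    k = min(n_bins, len(np.unique(gc)))
    if k < 2:
        g = np.array([gc.min(), gc.max() + 1e-9])
        m = np.full(2, np.median(counts))
        return g, m, np.ones(2)
    edges = np.quantile(gc, np.linspace(0, 1, k + 1))
    idx = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, k - 1)
    med_gc, med_count, sizes = [], [], []
    for b in range(k):
        sel = idx == b
        if sel.any():
            med_gc.append(np.median(gc[sel]))
            med_count.append(np.median(counts[sel]))
            sizes.append(int(sel.sum()))
    order = np.argsort(med_gc)
    return (
        np.asarray(med_gc)[order],
        np.asarray(med_count)[order],
        np.asarray(sizes, dtype=float)[order],
    )


# -- circular binary segmentation ---------------------------------------


def _arc_pairs(n: int, min_width: int):
    """All circular split pairs (i, j) with both arcs >= min_width bins."""
    i, j = np.triu_indices(n + 1, k=1)
    k = j - i
    keep = (k >= min_width) & (n - k >= min_width)
    return i[keep], j[keep], k[keep]


def _max_arc_stat(x: np.ndarray, i, j, k):
    """Maximum mean-shift statistic over circular arcs.

    For arc x[i:j] of length k the statistic is
    ``|mean_arc - mean_rest| * sqrt(k (n-k) / n)``, the z-numerator of the
    two-sample comparison; the permutation reference makes it scale-free.
    """
    n = x.size
    s = np.concatenate(([0.0], np.cumsum(x)))
    total = s[-1]
    arc = s[j] - s[i]
    stat = np.abs(arc - k * (total / n)) * np.sqrt(n / (k * (n - k)))
    m = int(np.argmax(stat))
    return float(stat[m]), int(i[m]), int(j[m])


def _split_is_significant(
    x: np.ndarray,
    obs_stat: float,
    i,
    j,
    k,
    rng: np.random.Generator,
    alpha: float,
    n_perm: int,
    chunk: int = 100,
) -> bool:
    """Permutation test for the best circular split, with early stopping.

    The exceedance count only grows, so once ``(1+count)/(1+n_perm)``
    reaches alpha the split can be rejected without drawing the remaining
    permutations; the decision is identical to the full test.
    """
    n = x.size
    total = float(x.sum())
    scale = np.sqrt(n / (k * (n - k)))
    thresh = obs_stat * (1.0 - 1e-12)
    count = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm = rng.permuted(np.tile(x, (b, 1)), axis=1)
        s = np.concatenate(
            (np.zeros((b, 1)), np.cumsum(perm, axis=1)), axis=1
        )
        arc = s[:, j] - s[:, i]
        stats = np.abs(arc - k * (total / n)) * scale
        count += int((stats.max(axis=1) >= thresh).sum())
        done += b
        if (1 + count) / (1 + n_perm) >= alpha:
            return False
    return (1 + count) / (1 + n_perm) < alpha


def _segment_region(
    x: np.ndarray,
    lo: int,
    hi: int,
    breakpoints: list[int],
    rng: np.random.Generator,
    alpha: float,
    n_perm: int,
    min_width: int,
) -> None:
    n = hi - lo
    if n < 2 * min_width:
        return
    i, j, k = _arc_pairs(n, min_width)
    stat, bi, bj = _max_arc_stat(x[lo:hi], i, j, k)
    if stat <= 1e-12:
        return
    if not _split_is_significant(x[lo:hi], stat, i, j, k, rng, alpha, n_perm):
        return
    cuts = sorted(c for c in (bi, bj) if 0 < c < n)
    breakpoints.extend(lo + c for c in cuts)
    bounds = [lo] + [lo + c for c in cuts] + [hi]
    for a, b in zip(bounds[:-1], bounds[1:]):
        _segment_region(x, a, b, breakpoints, rng, alpha, n_perm, min_width)


def segment_profile(
    profile: CorrectedProfile,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> SegmentedProfile:
    """Segment each chromosome of a corrected profile by CBS.

    Requires >= ``2 * min_width`` valid bins per chromosome.  Returned
    segments partition the valid bins; the segment mean is the mean of its
    member bins' log2 ratios.  The noise estimate is the scaled MAD
    (1.4826 x median absolute residual) of bin values about their segment
    means.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    t = profile.genome.table
    rows = []
    residuals = []
    for chrom, pos in profile.genome.chrom_indices().items():
        vpos = pos[profile.valid[pos]]
        if len(vpos) == 0:
            continue
        if len(vpos) < 2 * min_width:
            raise ValueError(
                f"{chrom}: {len(vpos)} valid bins < 2*min_width={2 * min_width}"
            )
        x = profile.log2[vpos]
        breakpoints: list[int] = []
        _segment_region(x, 0, len(x), breakpoints, rng, alpha, n_perm, min_width)
        bounds = [0] + sorted(breakpoints) + [len(x)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            member = vpos[a:b]
            mean = float(np.mean(x[a:b]))
            residuals.append(x[a:b] - mean)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(t["start"].iloc[member[0]]),
                    "end": int(t["end"].iloc[member[-1]]),
                    "start_bin": int(member[0]),
                    "end_bin": int(member[-1]) + 1,
                    "n_bins": len(member),
                    "mean_log2": mean,
                    "call": "",
                }
            )
    resid = np.concatenate(residuals) if residuals else np.array([0.0])
    noise = float(1.4826 * np.median(np.abs(resid)))
    return SegmentedProfile(
        profile=profile,
        segments=pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS)),
        noise=noise,
    )


def call_segments(
    seg: SegmentedProfile, k_mad: float = 3.0, min_abs: float = 0.10
) -> SegmentedProfile:
    """Classify segment means as loss / neutral / gain.

    A segment is a gain when its mean exceeds ``max(min_abs, k_mad x
    noise)`` and a loss when it falls below the negated cutoff; the
    absolute floor keeps single-sample calls conservative when the profile
    is extremely quiet.
    """
    cutoff = max(min_abs, k_mad * seg.noise)
    segments = seg.segments.copy()
    mean = segments["mean_log2"].to_numpy()
    call = np.where(mean > cutoff, "gain", np.where(mean < -cutoff, "loss", "neutral"))
    segments["call"] = call
    return replace(seg, segments=segments)


def cna_detectable(seg: SegmentedProfile, min_bins: int = 3) -> bool:
    """A profile carries detectable tumour signal: any non-neutral
    autosomal segment spanning >= ``min_bins`` bins."""
    s = seg.segments
    if (s["call"] == "").any():
        raise ValueError("segments are not called; run call_segments first")
    hit = (s["call"] != "neutral") & (s["n_bins"] >= min_bins)
    return bool(hit.any())


def segment_table(seg: SegmentedProfile) -> pd.DataFrame:
    """Segments as a flat exportable table."""
    return seg.segments.copy()


def count_reads_in_bins(
    alignment_path, genome: GenomeBins, min_mapq: int = 37
) -> np.ndarray:
    """Optional ingestion helper: per-bin read counts from a SAM/BAM/CRAM.

    Counts primary, non-duplicate alignments with mapping quality >=
    ``min_mapq``, assigned to the bin containing the alignment start.
    Requires pysam.
    """
    import pysam

    counts = np.zeros(genome.n_bins, dtype=np.int64)
    width = genome.bin_width
    offsets: dict[str, tuple[int, int]] = {}
    for chrom, pos in genome.chrom_indices().items():
        offsets[chrom] = (int(pos[0]), len(pos))
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as fh:
        for read in fh:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < min_mapq
            ):
                continue
            info = offsets.get(read.reference_name)
            if info is None:
                continue
            first, n = info
            b = read.reference_start // width
            if 0 <= b < n:
                counts[first + b] += 1
    return counts
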