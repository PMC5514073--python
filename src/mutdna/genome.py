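"""Binned reference frame shared by the simulator and the copy-number pipeline.

The genome is represented as equally sized, non-overlapping bins per
chromosome (1 Mb by default, 50 kb optionally), each annotated with GC
content, mappability and a blacklist flag.  Coordinates are 0-based
half-open throughout; a bin's identity is ``(chrom, start)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

REQUIRED_COLUMNS = ("chrom", "start", "end", "gc", "mappability", "blacklisted")

#: Chromosome labels excluded from "autosomal" masks when real data is loaded.
NON_AUTOSOMES = frozenset({"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"})


@dataclass(frozen=True)
class GenomeBins:
    """Immutable table of genomic bins.

    Parameters
    ----------
    table
        DataFrame with columns ``chrom, start, end, gc, mappability,
        blacklisted``.  Bins must be sorted, non-overlapping and of equal
        width within each chromosome.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"bin table is missing columns: {missing}")
        if len(t) == 0:
            raise ValueError("bin table is empty")
        if not ((t["gc"] >= 0) & (t["gc"] <= 1)).all():
            raise ValueError("gc must lie in [0, 1]")
        if not ((t["mappability"] >= 0) & (t["mappability"] <= 1)).all():
            raise ValueError("mappability must lie in [0, 1]")
        for chrom, sub in t.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if not (ends > starts).all():
                raise ValueError(f"{chrom}: empty or inverted bin")
            widths = ends - starts
            if len(np.unique(widths)) != 1:
                raise ValueError(f"{chrom}: bins are not equal width")
            if len(starts) > 1 and not (starts[1:] >= ends[:-1]).all():
                raise ValueError(f"{chrom}: bins overlap or are unsorted")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    # -- basic accessors -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def bin_width(self) -> int:
        t = self.table
        return int((t["end"] - t["start"]).iloc[0])

    def autosomal_mask(self) -> np.ndarray:
        return ~self.table["chrom"].isin(NON_AUTOSOMES).to_numpy()

    def valid_mask(self, min_mappability: float = 0.5) -> np.ndarray:
        """Autosomal bins that are neither blacklisted nor low-mappability."""
        t = self.table
        return (
            self.autosomal_mask()
            & ~t["blacklisted"].to_numpy().astype(bool)
            & (t["mappability"].to_numpy() >= min_mappability)
        )

    def chrom_indices(self) -> dict[str, np.ndarray]:
        """Positional bin indices per chromosome, in genome order."""
        out: dict[str, np.ndarray] = {}
        chrom = self.table["chrom"].to_numpy()
        for c in self.chroms:
            out[c] = np.flatnonzero(chrom == c)
        return out

    # -- I/O -------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeBins":
        t = pd.read_csv(path, sep="\t")
        t["blacklisted"] = t["blacklisted"].astype(bool)
        return cls(t)

    def with_blacklist_bed(self, bed_path) -> "GenomeBins":
        """Return a copy with bins overlapping BED intervals flagged.

        The BED file is read as ``chrom, start, end`` (0-based half-open);
        any bin with a positive-length overlap is marked blacklisted.
        """
        bed = pd.read_csv(
            bed_path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#",
        )
        t = self.table.copy()
        flagged = t["blacklisted"].to_numpy().astype(bool).copy()
        for _, iv in bed.iterrows():
            hit = (
                (t["chrom"] == iv["chrom"])
                & (t["start"] < iv["end"])
                & (t["end"] > iv["start"])
            )
            flagged |= hit.to_numpy()
        t["blacklisted"] = flagged
        return GenomeBins(t)


def make_genome(
    n_chrom: int,
    bin_width: int = 1_000_000,
    bins_per_chrom: int = 50,
    seed: int | None = None,
    *,
    blacklist_rate: float = 0.01,
    gc_centre: float = 0.45,
    gc_sd: float = 0.05,
) -> GenomeBins:
    """Generate a synthetic autosomal bin frame.

    GC content is drawn from a smooth spatially autocorrelated field
    (stationary AR(1) along each chromosome, ρ=0.9) centred at
    ``gc_centre`` and squashed smoothly into (0.3, 0.6).  Mappability is near 1 for
    most bins with a small fraction of low-mappability bins; ~1% of bins
    are flagged blacklisted.  Deterministic for a fixed seed.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if bin_width <= 0 or bins_per_chrom <= 0:
        raise ValueError("bin_width and bins_per_chrom must be positive")
    rng = np.random.default_rng(seed)
    rho = 0.9
    rows = []
    for c in range(1, n_chrom + 1):
        eps = rng.normal(size=bins_per_chrom)
        ar = lfilter([1.0], [1.0, -rho], eps)  # AR(1) innovations filter
        z = gc_sd * np.sqrt(1 - rho**2) * ar
        # smooth squash into (0.3, 0.6): no saturated runs at the bounds
        gc = gc_centre + 0.15 * np.tanh(z / 0.15)
        mapp = rng.beta(50, 2, size=bins_per_chrom)
        low = rng.random(bins_per_chrom) < 0.02
        mapp[low] *= rng.uniform(0.1, 0.5, size=low.sum())
        black = rng.random(bins_per_chrom) < blacklist_rate
        starts = np.arange(bins_per_chrom, dtype=np.int64) * bin_width
        rows.append(
            pd.DataFrame(
                {
                    "chrom": f"chr{c}",
                    "start": starts,
                    "end": starts + bin_width,
                    "gc": gc,
                    "mappability": np.clip(mapp, 0.0, 1.0),
                    "blacklisted": black,
                }
            )
        )
    return GenomeBins(pd.concat(rows, ignore_index=True))
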