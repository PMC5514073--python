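"""Readers and writers for the pipeline's on-disk formats.

Tab-separated tables with BED-style (0-based half-open) intervals for bin
counts and segments; long TSVs for variants and the sample sheet; JSON for
configs, summaries and the ground-truth ledger.  A minimal VCF reader is
provided for variant input from other callers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBins

SAMPLE_SHEET_COLUMNS = (
    "sample_id", "patient", "timepoint", "days", "sample_type",
    "recurrence_days", "recurred", "followup_days",
)
VARIANT_COLUMNS = (
    "sample_id", "patient", "timepoint", "days", "sample_type",
    "variant_id", "gene", "chrom", "pos", "ref", "alt",
    "depth", "alt_reads", "genomic_equivalents",
)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {missing}")
    df["recurred"] = df["recurred"].astype(bool)
    return df


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "depth", "alt_reads", "genomic_equivalents")
               if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path}: missing columns {missing}")
    return df


def read_bin_counts(path, genome: GenomeBins | None = None) -> np.ndarray:
    """Read one sample's bin-count TSV (chrom, start, end, count).

    When a genome is given, the rows must match its bin frame exactly.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end", "count"):
        if col not in df.columns:
            raise ValueError(f"bin-count table {path}: missing column {col!r}")
    if genome is not None:
        t = genome.table
        if len(df) != len(t) or not (
            (df["chrom"].to_numpy() == t["chrom"].to_numpy()).all()
            and (df["start"].to_numpy() == t["start"].to_numpy()).all()
        ):
            raise ValueError(f"bin-count table {path} does not match the bin frame")
    return df["count"].to_numpy()


def write_bin_counts(path, counts: np.ndarray, genome: GenomeBins) -> None:
    df = genome.table[["chrom", "start", "end"]].copy()
    df["count"] = np.asarray(counts)
    df.to_csv(path, sep="\t", index=False)


def read_counts_dir(counts_dir, genome: GenomeBins | None = None) -> dict[str, np.ndarray]:
    """All ``<sample>.counts.tsv`` files in a directory, keyed by sample id."""
    out: dict[str, np.ndarray] = {}
    for p in sorted(Path(counts_dir).glob("*.counts.tsv")):
        out[p.name.removesuffix(".counts.tsv")] = read_bin_counts(p, genome)
    if not out:
        raise ValueError(f"no *.counts.tsv files found in {counts_dir}")
    return out


def read_variants_vcf(path, sample_metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Minimal VCF ingestion: one row per sample x record.

    Requires per-sample FORMAT fields ``DP`` (depth), ``AD`` (ref,alt
    depths) or ``AO`` (alt depth), and ``GE`` (genomic equivalents input
    to the reaction).  ``sample_metadata`` (indexed by sample id with
    patient/timepoint/days/sample_type columns) is merged in when given.
    Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for rec in vcf:
        gene = dict(rec.INFO).get("GENE", rec.ID or f"{rec.CHROM}:{rec.POS}")
        depth = rec.format("DP")
        ad = rec.format("AD")
        ao = rec.format("AO") if ad is None else None
        ge = rec.format("GE")
        if depth is None or ge is None or (ad is None and ao is None):
            raise ValueError(
                f"{path}: records need FORMAT fields DP, GE and AD or AO"
            )
        for si, sid in enumerate(samples):
            alt = int(ad[si][1]) if ad is not None else int(np.ravel(ao[si])[0])
            rows.append(
                {
                    "sample_id": sid,
                    "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.ALT[0]}",
                    "gene": gene,
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": rec.ALT[0],
                    "depth": int(np.ravel(depth[si])[0]),
                    "alt_reads": alt,
                    "genomic_equivalents": float(np.ravel(ge[si])[0]),
                }
            )
    df = pd.DataFrame(rows)
    if sample_metadata is not None:
        df = df.merge(sample_metadata, left_on="sample_id", right_index=True, how="left")
    return df
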