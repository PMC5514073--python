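"""Dual-threshold mutant allele-fraction detection.

A variant observation in a body-fluid sample is called *detected* when its
allele fraction strictly exceeds the higher of

* the technical threshold (0.5% AF, chosen so germline controls are
  uniformly negative), and
* the sample threshold ``1 / genomic equivalents``, the sampling floor set
  by how many amplifiable template molecules entered the reaction.

Allele fractions below threshold are retained — longitudinal kinetics are
interpreted on raw AFs even when individual points are not called.
Per-patient presence at a timepoint means detection of any panel variant in
any available sample type; missing samples never count as negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: AF floor below which a call is never made, regardless of input amount.
TECHNICAL_AF_THRESHOLD = 0.005

FLUID_SAMPLE_TYPES = ("PLS", "UCP", "USN")


def detection_threshold(genomic_equivalents: float) -> float:
    """AF threshold for one reaction: ``max(0.005, 1/GE)``."""
    if genomic_equivalents <= 0:
        raise ValueError("genomic_equivalents must be positive")
    return max(TECHNICAL_AF_THRESHOLD, 1.0 / genomic_equivalents)


@dataclass(frozen=True)
class VariantObservation:
    """One assayed locus in one sample."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    depth: int
    alt_reads: int
    genomic_equivalents: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError("alt_reads must lie in [0, depth]")
        if self.genomic_equivalents <= 0:
            raise ValueError("genomic_equivalents must be positive")

    @property
    def af(self) -> float:
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class DetectionResult:
    detected: bool
    af: float
    threshold_used: float
    technical_threshold: float = TECHNICAL_AF_THRESHOLD
    sample_threshold: float = float("nan")


def call_variant(obs: VariantObservation) -> DetectionResult:
    """Apply the dual-threshold rule to a single observation."""
    sample_thr = 1.0 / obs.genomic_equivalents
    thr = max(TECHNICAL_AF_THRESHOLD, sample_thr)
    return DetectionResult(
        detected=obs.af > thr,
        af=obs.af,
        threshold_used=thr,
        sample_threshold=sample_thr,
    )


def call_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Vectorised detection over a long variant table.

    Requires columns ``depth, alt_reads, genomic_equivalents``; returns a
    copy with ``af``, ``threshold`` and ``detected`` columns added.
    """
    v = variants.copy()
    ge = v["genomic_equivalents"].to_numpy(dtype=float)
    if (ge <= 0).any():
        raise ValueError("genomic_equivalents must be positive")
    depth = v["depth"].to_numpy(dtype=float)
    if (depth <= 0).any():
        raise ValueError("depth must be positive")
    v["af"] = v["alt_reads"].to_numpy(dtype=float) / depth
    v["threshold"] = np.maximum(TECHNICAL_AF_THRESHOLD, 1.0 / ge)
    v["detected"] = v["af"].to_numpy() > v["threshold"].to_numpy()
    return v


class Presence(enum.Enum):
    """Per-patient mutDNA status at one timepoint."""

    PRESENT = "present"
    ABSENT = "absent"
    UNEVALUABLE = "unevaluable"


def patient_presence(
    called: pd.DataFrame, patient: str, timepoint: int
) -> Presence:
    """Presence of mutDNA for ``patient`` at ``timepoint``.

    PRESENT if any variant is detected in any available sample type;
    ABSENT if samples were tested and all were below threshold;
    UNEVALUABLE when no sample row exists at the timepoint (missingness
    is distinguishable from tested-negative).
    """
    sub = called[(called["patient"] == patient) & (called["timepoint"] == timepoint)]
    sub = sub[sub["sample_type"].isin(FLUID_SAMPLE_TYPES)]
    if len(sub) == 0:
        return Presence.UNEVALUABLE
    return Presence.PRESENT if sub["detected"].any() else Presence.ABSENT


def presence_table(called: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Presence status for every patient x fluid timepoint in the sheet."""
    fluids = sample_sheet[sample_sheet["sample_type"].isin(FLUID_SAMPLE_TYPES)]
    rows = []
    for (patient, tp), _ in fluids.groupby(["patient", "timepoint"], sort=True):
        rows.append(
            {
                "patient": patient,
                "timepoint": tp,
                "presence": patient_presence(called, patient, tp).value,
            }
        )
    return pd.DataFrame(rows, columns=["patient", "timepoint", "presence"])


def max_af_per_timepoint(
    called: pd.DataFrame, patient: str, sample_type: str
) -> pd.Series:
    """Maximum AF over panel variants per timepoint for one sample type.

    Timepoints with no observations are simply absent from the series
    (missing stays missing).
    """
    sub = called[
        (called["patient"] == patient) & (called["sample_type"] == sample_type)
    ]
    if len(sub) == 0:
        return pd.Series(dtype=float, name="max_af")
    out = sub.groupby("timepoint")["af"].max()
    out.name = "max_af"
    return out


def detection_grid(
    called: pd.DataFrame, sample_sheet: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Long-format cohort detection grid.

    One row per (patient, variant, timepoint, sample_type) with status in
    ``{detected, tested-negative, missing}``.  When a sample sheet is given,
    the grid is completed over every fluid sample in the sheet crossed with
    the patient's panel, and cells with no observation are marked missing.
    """
    cols = ["patient", "variant_id", "timepoint", "sample_type", "status", "af"]
    if len(called) == 0:
        return pd.DataFrame(columns=cols)
    obs = called.copy()
    obs["status"] = np.where(obs["detected"], "detected", "tested-negative")
    obs = obs[obs["sample_type"].isin(FLUID_SAMPLE_TYPES)]
    if sample_sheet is None:
        return obs[cols].reset_index(drop=True)

    fluids = sample_sheet[sample_sheet["sample_type"].isin(FLUID_SAMPLE_TYPES)]
    panel = obs[["patient", "variant_id"]].drop_duplicates()
    frame = fluids[["patient", "timepoint", "sample_type"]].merge(panel, on="patient")
    grid = frame.merge(
        obs[cols], on=["patient", "variant_id", "timepoint", "sample_type"], how="left"
    )
    grid["status"] = grid["status"].fillna("missing")
    return grid[cols].reset_index(drop=True)


def estimate_tumour_fraction(called: pd.DataFrame) -> pd.Series:
    """Crude per-sample tumour-fraction estimate: ``2 x max AF``.

    Assumes heterozygous variants at copy-neutral loci carried by the
    dominant clone, so AF = tf/2.  Indexed by sample_id.
    """
    out = 2.0 * called.groupby("sample_id")["af"].max()
    out.name = "tf_estimate"
    return out
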