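"""Genome-wide imbalance score and CNA-profile concordance.

The imbalance score quantifies how far a sample's binned copy-number
signal departs from a pooled germline control.  An ordinary least-squares
line is fitted through the test sample's corrected log2 bin values against
the control's (control as predictor); because shallow-WGS bin values are
noisy around baseline, only the 5% most extreme residuals (largest squared
residuals) contribute, and the score is the sum of those squared
residuals.  The score is zero exactly when the test profile is an affine
function of the control on the shared valid bins, and grows with tumour
fraction on a fixed aberration profile.

Profile concordance between two samples is the adjusted R^2 of the OLS
fit of one profile's log ratios on the other's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cna import CorrectedProfile, correct_counts
from .genome import GenomeBins

MIN_SHARED_BINS = 10


@dataclass(frozen=True)
class ControlProfile:
    """Pooled germline control on the same bin frame as the test samples.

    Pooling sums the members' raw bin counts before correction, so the
    result is order-free in the members.
    """

    profile: CorrectedProfile = field(repr=False)
    member_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ImbalanceResult:
    score: float
    n_extreme: int
    n_bins: int
    slope: float
    intercept: float
    residuals: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be non-negative")


def pool_controls(
    counts: Sequence[np.ndarray],
    genome: GenomeBins,
    member_ids: Sequence[str] | None = None,
    **correct_kwargs,
) -> ControlProfile:
    """Sum raw germline bin counts and correct the pool as one sample."""
    if len(counts) == 0:
        raise ValueError("at least one control sample is required")
    pooled = np.sum(np.vstack([np.asarray(c, dtype=float) for c in counts]), axis=0)
    prof = correct_counts(pooled, genome, sample_id="pooled_control", **correct_kwargs)
    ids = tuple(member_ids) if member_ids is not None else ()
    return ControlProfile(profile=prof, member_ids=ids)


def _shared_valid(test: CorrectedProfile, control: CorrectedProfile) -> np.ndarray:
    if test.genome.n_bins != control.genome.n_bins:
        raise ValueError("test and control are on different bin frames")
    shared = test.valid & control.valid
    if shared.sum() < MIN_SHARED_BINS:
        raise ValueError(
            f"only {int(shared.sum())} shared valid bins (need >= {MIN_SHARED_BINS})"
        )
    return shared


def fit_against_control(
    test: CorrectedProfile, control: ControlProfile | CorrectedProfile
) -> tuple[np.ndarray, float, float]:
    """OLS of the test profile on the control profile over shared valid bins.

    Returns ``(residuals, slope, intercept)``; residuals are signed and
    ordered by genome position of the shared bins.
    """
    ctrl = control.profile if isinstance(control, ControlProfile) else control
    shared = _shared_valid(test, ctrl)
    x = ctrl.log2[shared]
    y = test.log2[shared]
    if np.ptp(x) < 1e-12:
        raise ValueError("control profile is constant; the fit is degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return resid, float(slope), float(intercept)


def imbalance_score(
    test: CorrectedProfile,
    control: ControlProfile | CorrectedProfile,
    extreme_fraction: float = 0.05,
) -> ImbalanceResult:
    """Sum of squared residuals over the most extreme ``extreme_fraction``
    of bins (ceil of the fractional count; ties broken by bin order)."""
    if not 0.0 < extreme_fraction <= 1.0:
        raise ValueError("extreme_fraction must lie in (0, 1]")
    resid, slope, intercept = fit_against_control(test, control)
    n = len(resid)
    n_extreme = math.ceil(extreme_fraction * n)
    sq = resid**2
    top = np.argsort(-sq, kind="stable")[:n_extreme]
    return ImbalanceResult(
        score=float(sq[top].sum()),
        n_extreme=n_extreme,
        n_bins=n,
        slope=slope,
        intercept=intercept,
        residuals=resid,
    )


def concordance_r2(
    profile_a: CorrectedProfile, profile_b: CorrectedProfile
) -> tuple[float, int]:
    """Adjusted R^2 of the OLS fit of profile b on profile a.

    ``adj R^2 = 1 - (1 - R^2)(n - 1)/(n - 2)``; slightly negative values
    are possible (and expected) for null fits.
    """
    shared = _shared_valid(profile_b, profile_a)
    x = profile_a.log2[shared]
    y = profile_b.log2[shared]
    if np.ptp(x) < 1e-12:
        raise ValueError("predictor profile is constant; the fit is degenerate")
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(adj), n


def loo_control_threshold(
    counts: Sequence[np.ndarray],
    genome: GenomeBins,
    extreme_fraction: float = 0.05,
    **correct_kwargs,
) -> float:
    """Leave-one-out imbalance threshold from the control members.

    Each germline member is scored against the pool of the remaining
    members; the maximum score observed is returned as a conservative
    positivity threshold.  This is a pragmatic artifact of this pipeline:
    no absolute threshold is inherent to the score itself.
    """
    if len(counts) < 3:
        raise ValueError("need >= 3 control members for a leave-one-out threshold")
    scores = []
    for i, held_out in enumerate(counts):
        rest = [c for j, c in enumerate(counts) if j != i]
        ctrl = pool_controls(rest, genome, **correct_kwargs)
        test = correct_counts(
            np.asarray(held_out, dtype=float), genome,
            sample_id=f"loo_{i}", **correct_kwargs,
        )
        scores.append(imbalance_score(test, ctrl, extreme_fraction).score)
    return float(max(scores))
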