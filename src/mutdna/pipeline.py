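"""End-to-end pipeline: simulate or load a cohort, profile copy number,
detect variants, and compute the outcome statistics.

``run_pipeline`` orchestrates correct -> segment -> call -> score on every
sWGS sample, the dual-threshold SNV detection grid, per-patient presence,
and the recurrence analysis, writing all stage outputs plus a
machine-readable ``summary.json`` and a human-readable ``report.txt``.
The run is deterministic under a fixed config.

``verify_reference_cohort`` recomputes the reference cohort's printed
contingency arithmetic (sensitivity/specificity/PPV/NPV, the exact CI
lower bound, the recurrence median, the pre-NAC detection fractions) from
the underlying counts and checks each against its printed value.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import reference
from .cna import (
    call_segments,
    cna_detectable,
    correct_counts,
    segment_profile,
)
from .detection import (
    FLUID_SAMPLE_TYPES,
    call_variants,
    detection_grid,
    estimate_tumour_fraction,
    presence_table,
)
from .genome import GenomeBins, make_genome
from .imbalance import imbalance_score, pool_controls
from .outcome import (
    chi2_detection_by_timepoint,
    classify_cycle2,
    contingency_metrics,
    km_curve,
    kruskal_dunn,
    ks_af_comparison,
    logrank_test,
    median_time_to_event,
)
from .simulate import default_scenario, simulate_cohort

log = logging.getLogger("mutdna")


class PipelineError(RuntimeError):
    """A structured pipeline failure naming the offending input."""


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serialisable to YAML/JSON.

    Leave the input paths unset to run on a freshly simulated default
    cohort (seeded by ``seed``); set them to analyse external tables.
    """

    seed: int = 0
    # synthetic genome geometry
    n_chrom: int = 22
    bins_per_chrom: int = 50
    bin_width: int = 1_000_000
    # CNA stage
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    cbs_min_width: int = 2
    k_mad: float = 3.0
    min_abs: float = 0.10
    min_mappability: float = 0.5
    gc_bins: int = 20
    extreme_fraction: float = 0.05
    # outcome stage
    confidence: float = 0.95
    cycle2_timepoint: int = 2
    # optional external inputs
    sample_sheet: str | None = None
    variants: str | None = None
    counts_dir: str | None = None
    genome_bins: str | None = None
    blacklist_bed: str | None = None

    def __post_init__(self) -> None:
        for name in ("cbs_alpha", "extreme_fraction", "confidence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise PipelineError(f"config field {name}={v} must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config fields in {path}: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    out_dir: Path
    summary: dict
    detections: pd.DataFrame = field(repr=False)
    cna_table: pd.DataFrame = field(repr=False)


def _require_path(path: str | None, fieldname: str) -> Path:
    if path is None:
        raise PipelineError(f"config field {fieldname!r} is required in load mode")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"config field {fieldname!r}: file not found: {p}")
    return p


def _load_or_simulate(config: PipelineConfig):
    external = any(
        getattr(config, f) is not None
        for f in ("sample_sheet", "variants", "counts_dir", "genome_bins")
    )
    if not external:
        scenario = default_scenario(
            config.seed, n_chrom=config.n_chrom, bins_per_chrom=config.bins_per_chrom
        )
        genome = make_genome(
            config.n_chrom, config.bin_width, config.bins_per_chrom, seed=config.seed
        )
        tables = simulate_cohort(scenario, genome=genome)
        return tables.genome, tables.sample_sheet, tables.variants, \
            tables.bin_counts, tables.truth
    sheet = mio.read_sample_sheet(_require_path(config.sample_sheet, "sample_sheet"))
    variants = mio.read_variants_tsv(_require_path(config.variants, "variants"))
    genome = GenomeBins.from_tsv(_require_path(config.genome_bins, "genome_bins"))
    if config.blacklist_bed is not None:
        genome = genome.with_blacklist_bed(
            _require_path(config.blacklist_bed, "blacklist_bed")
        )
    counts = {}
    if config.counts_dir is not None:
        counts = mio.read_counts_dir(
            _require_path(config.counts_dir, "counts_dir"), genome
        )
    return genome, sheet, variants, counts, None


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Run every stage and write the report bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def emit(name: str, writer) -> Path:
        p = out / name
        writer(p)
        created.append(p)
        return p

    t0 = time.perf_counter()
    try:
        genome, sheet, variants, counts, truth = _load_or_simulate(config)
        log.info("inputs ready (%.1fs)", time.perf_counter() - t0)

        # --- CNA stage -------------------------------------------------
        t1 = time.perf_counter()
        buf_ids = sorted(
            sheet.loc[sheet["sample_type"] == "BUF", "sample_id"]
        )
        control = None
        buf_counts = [counts[s] for s in buf_ids if s in counts]
        if len(buf_counts) >= 1:
            control = pool_controls(
                buf_counts, genome,
                member_ids=[s for s in buf_ids if s in counts],
                min_mappability=config.min_mappability, gc_bins=config.gc_bins,
            )
        cna_rows, seg_frames = [], []
        for sid in sorted(counts):
            prof = correct_counts(
                counts[sid], genome, sample_id=sid,
                min_mappability=config.min_mappability, gc_bins=config.gc_bins,
            )
            seg = call_segments(
                segment_profile(
                    prof, alpha=config.cbs_alpha, n_perm=config.cbs_n_perm,
                    min_width=config.cbs_min_width, seed=config.seed,
                ),
                k_mad=config.k_mad, min_abs=config.min_abs,
            )
            row = {
                "sample_id": sid,
                "cna_detectable": cna_detectable(seg),
                "noise": seg.noise,
                "n_segments": len(seg.segments),
            }
            if control is not None and sid not in buf_ids:
                res = imbalance_score(prof, control, config.extreme_fraction)
                row.update(
                    imbalance_score_value=res.score,
                    imbalance_n_extreme=res.n_extreme,
                )
            cna_rows.append(row)
            sf = seg.segments.copy()
            sf.insert(0, "sample_id", sid)
            seg_frames.append(sf)
        cna_table = pd.DataFrame(cna_rows)
        log.info("CNA stage: %d samples (%.1fs)", len(counts), time.perf_counter() - t1)

        # --- SNV detection ---------------------------------------------
        t2 = time.perf_counter()
        called = call_variants(variants)
        grid = detection_grid(called, sheet)
        presence = presence_table(called, sheet)
        log.info("detection stage (%.1fs)", time.perf_counter() - t2)

        # --- outcome ----------------------------------------------------
        t3 = time.perf_counter()
        cls = classify_cycle2(called, sheet, timepoint=config.cycle2_timepoint)
        evaluable = cls[cls["group"] != "unevaluable"]
        tp_ = int(((evaluable["group"] == "present") & (evaluable["event"] == 1)).sum())
        fp_ = int(((evaluable["group"] == "present") & (evaluable["event"] == 0)).sum())
        fn_ = int(((evaluable["group"] == "absent") & (evaluable["event"] == 1)).sum())
        tn_ = int(((evaluable["group"] == "absent") & (evaluable["event"] == 0)).sum())
        metrics = contingency_metrics(tp_, fp_, fn_, tn_, conf=config.confidence)

        survival_stats: dict = {}
        km = pd.DataFrame(columns=["group", "time", "survival", "at_risk"])
        grp_counts = evaluable["group"].value_counts()
        if grp_counts.get("present", 0) > 0 and grp_counts.get("absent", 0) > 0:
            km = km_curve(evaluable)
            if evaluable["event"].sum() > 0:
                stat, p = logrank_test(evaluable)
                survival_stats = {"logrank_statistic": stat, "logrank_p": p}

        fluids = called[called["sample_type"].isin(FLUID_SAMPLE_TYPES)]
        rec_map = sheet.drop_duplicates("patient").set_index("patient")["recurred"]
        af_rec = fluids.loc[fluids["patient"].map(rec_map).astype(bool), "af"]
        af_non = fluids.loc[~fluids["patient"].map(rec_map).astype(bool), "af"]
        comparisons: dict = {}
        if len(af_rec) and len(af_non):
            ks_stat, ks_p = ks_af_comparison(af_rec, af_non)
            comparisons["ks_af_recur_vs_non"] = {"statistic": ks_stat, "p": ks_p}
        chi2_tab = chi2_detection_by_timepoint(called, sheet)
        comparisons["kruskal_dunn_sample_types"] = kruskal_dunn(
            {st: fluids.loc[fluids["sample_type"] == st, "af"].to_numpy()
             for st in FLUID_SAMPLE_TYPES}
        )
        rec_times = sheet.loc[sheet["recurred"], ["patient", "recurrence_days"]] \
            .drop_duplicates("patient")["recurrence_days"]
        med_days, min_days, max_days = (
            median_time_to_event(rec_times) if len(rec_times) else (0, 0.0, 0.0)
        )

        summary = {
            "config": config.to_dict(),
            "n_patients": int(sheet["patient"].nunique()),
            "n_samples": int(len(sheet)),
            "n_swgs_samples": int(len(counts)),
            "cycle2": {
                "timepoint": config.cycle2_timepoint,
                "groups": cls.groupby("group")["patient"].count().to_dict(),
                "contingency": metrics.to_dict(),
                **survival_stats,
            },
            "recurrence_days": {
                "median": med_days, "min": min_days, "max": max_days,
                "n_events": int(len(rec_times)),
            },
            "patients": {
                patient: dict(
                    zip(sub["timepoint"].astype(str), sub["presence"])
                )
                for patient, sub in presence.groupby("patient")
            },
            "comparisons": comparisons,
            "chi2_by_timepoint": chi2_tab.to_dict(orient="records"),
            "cna_detectable_rate": (
                float(cna_table["cna_detectable"].mean()) if len(cna_table) else None
            ),
        }
        if truth is not None:
            tf_true = pd.Series(
                {s: v["tumour_fraction"] for s, v in truth["samples"].items()}
            )
            tf_est = estimate_tumour_fraction(fluids)
            shared = tf_est.index.intersection(tf_true.index)
            if len(shared) >= 3 and np.ptp(tf_true[shared].to_numpy()) > 0:
                slope = float(
                    np.polyfit(tf_true[shared], tf_est[shared], 1)[0]
                )
                summary["tf_recovery_slope"] = slope
        log.info("outcome stage (%.1fs)", time.perf_counter() - t3)

        # --- outputs ----------------------------------------------------
        emit("config.json", lambda p: p.write_text(
            json.dumps(config.to_dict(), indent=1, sort_keys=True) + "\n"))
        emit("sample_sheet.tsv", lambda p: sheet.to_csv(p, sep="\t", index=False))
        emit("detections.tsv", lambda p: called.to_csv(p, sep="\t", index=False))
        emit("detection_grid.tsv", lambda p: grid.to_csv(p, sep="\t", index=False))
        emit("presence.tsv", lambda p: presence.to_csv(p, sep="\t", index=False))
        emit("cna_summary.tsv", lambda p: cna_table.to_csv(p, sep="\t", index=False))
        if seg_frames:
            segs = pd.concat(seg_frames, ignore_index=True)
            emit("segments.tsv", lambda p: segs.to_csv(p, sep="\t", index=False))
        emit("km_curve.tsv", lambda p: km.to_csv(p, sep="\t", index=False))
        emit("tests_by_timepoint.tsv",
             lambda p: chi2_tab.to_csv(p, sep="\t", index=False))
        emit("summary.json", lambda p: p.write_text(
            json.dumps(summary, indent=1, sort_keys=True, allow_nan=True) + "\n"))
        emit("report.txt", lambda p: p.write_text(_render_report(summary)))
        log.info("pipeline done (%.1fs total)", time.perf_counter() - t0)
        return PipelineResult(
            out_dir=out, summary=summary, detections=called, cna_table=cna_table
        )
    except Exception:
        for p in created:  # leave no partial bundle behind
            try:
                p.unlink()
            except OSError:
                pass
        raise


def _fmt_prop(d: dict) -> str:
    if not d["defined"]:
        return "undefined (zero denominator)"
    lo, hi = d["ci_percent"]
    return f"{d['percent']:.1f}% ({d['k']}/{d['n']}; CI {lo}-{hi}%)"


def _render_report(summary: dict) -> str:
    c = summary["cycle2"]["contingency"]
    lines = [
        "mutDNA cohort report",
        "====================",
        f"patients: {summary['n_patients']}, samples: {summary['n_samples']}"
        f" (sWGS on {summary['n_swgs_samples']})",
        "",
        f"cycle-{summary['cycle2']['timepoint']} presence vs recurrence:",
        f"  groups: {summary['cycle2']['groups']}",
        f"  2x2 table: tp={c['tp']} fp={c['fp']} fn={c['fn']} tn={c['tn']}",
        f"  sensitivity: {_fmt_prop(c['sensitivity'])}",
        f"  specificity: {_fmt_prop(c['specificity'])}",
        f"  PPV:         {_fmt_prop(c['ppv'])}",
        f"  NPV:         {_fmt_prop(c['npv'])}",
    ]
    if "logrank_p" in summary["cycle2"]:
        lines.append(
            f"  log-rank: chi2={summary['cycle2']['logrank_statistic']:.3f}, "
            f"p={summary['cycle2']['logrank_p']:.4g}"
        )
    r = summary["recurrence_days"]
    lines += [
        "",
        f"recurrence: {r['n_events']} events, median {r['median']} days "
        f"(range {r['min']:.0f}-{r['max']:.0f})",
    ]
    if summary.get("cna_detectable_rate") is not None:
        lines.append(f"CNA-detectable fraction of sWGS samples: "
                     f"{summary['cna_detectable_rate']:.2f}")
    if "tf_recovery_slope" in summary:
        lines.append(
            f"tumour-fraction recovery slope (est vs truth): "
            f"{summary['tf_recovery_slope']:.3f}"
        )
    kw = summary["comparisons"].get("kruskal_dunn_sample_types")
    if kw and not kw.get("degenerate"):
        lines.append(f"Kruskal-Wallis across PLS/UCP/USN: H={kw['statistic']:.2f}, "
                     f"p={kw['p']:.3g}")
    return "\n".join(lines) + "\n"


# -- in-cohort verification ----------------------------------------------


def verify_reference_cohort(conf: float = 0.95) -> tuple[list[dict], bool]:
    """Recompute the reference cohort's printed summary numbers.

    Uses only the in-text counts (the 2x2 cycle-2 table, the eight
    recurrence times, the pre-NAC detection counts) and checks each
    derived value against its printed counterpart.  Returns (rows, all_ok).
    """
    rows: list[dict] = []

    def check(name: str, computed, expected) -> None:
        ok = (
            abs(computed - expected) < 1e-9
            if isinstance(expected, float)
            else computed == expected
        )
        rows.append(
            {"quantity": name, "computed": computed, "expected": expected, "ok": ok}
        )

    cc = reference.CYCLE2_COUNTS
    m = contingency_metrics(cc["tp"], cc["fp"], cc["fn"], cc["tn"], conf=conf)
    exp = reference.EXPECTED
    check("sensitivity_percent", m.sensitivity.percent(), exp["sensitivity_percent"])
    check("specificity_percent", m.specificity.percent(), exp["specificity_percent"])
    check("ppv_percent", m.ppv.percent(), exp["ppv_percent"])
    check("npv_percent", m.npv.percent(), exp["npv_percent"])
    check(
        "sensitivity_ci_lower_percent",
        m.sensitivity.ci_percent()[0],
        exp["sensitivity_ci_lower_percent"],
    )
    med, lo, hi = median_time_to_event(reference.RECURRENCE_DAYS)
    check("recurrence_median_days", med, exp["recurrence_median_days"])
    check("recurrence_min_days", int(lo), exp["recurrence_min_days"])
    check("recurrence_max_days", int(hi), exp["recurrence_max_days"])
    for fluid, (k, n) in reference.PRE_NAC_DETECTED.items():
        check(
            f"prenac_{fluid}_percent",
            round(100.0 * k / n, 1),
            exp[f"prenac_{fluid}_percent"],
        )
    return rows, all(r["ok"] for r in rows)
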