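"""Synthetic liquid-biopsy cohort generator.

Emulates the statistical structure of a muscle-invasive bladder cancer
cohort monitored through neoadjuvant chemotherapy (NAC): tumour clones
carrying copy-number events and panel SNVs, compartment-specific tumour
fractions (urine well above plasma), a molecular bottleneck set by the
amplifiable genomic equivalents per reaction, and overdispersed sequencing
counts.  Every downstream pipeline stage can therefore be exercised and
tested without any external data.

The generative model, per sample:

* bin counts — expected count per bin is proportional to
  ``mappability x gc_bias(gc) x (1 + sum_c w_c (cn_c/2 - 1))`` where
  ``w_c = tumour_fraction x clone_fraction_c`` and the remainder of the DNA
  mixture is diploid germline; counts are negative-binomial with dispersion
  ``overdispersion`` (Poisson in the limit 0), scaled to ``total_reads``.
* variant reads — mutant template molecules are Binomial(GE, true AF);
  reads are resampled from that molecule pool at the amplicon depth with a
  symmetric per-base substitution error.
* allele fractions — ``af = tf x clone_fraction / 2`` (heterozygous,
  copy-neutral simplification; see the methods note).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeBins, make_genome
from .detection import VariantObservation

FLUIDS = ("PLS", "UCP", "USN")

# -- domain types --------------------------------------------------------


@dataclass(frozen=True)
class SnvSpec:
    """A panel locus carried by a clone (1-based position)."""

    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class CnaEvent:
    """A copy-number event on one chromosome (bin coordinates)."""

    chrom: str
    start_bin: int
    n_bins: int
    cn: int

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError("copy number must be >= 0")
        if self.n_bins <= 0:
            raise ValueError("event must span at least one bin")


@dataclass(frozen=True)
class CloneSpec:
    """A tumour clone: its CNA events, SNVs and per-timepoint cellular fraction."""

    clone_id: str
    events: tuple[CnaEvent, ...] = ()
    snvs: tuple[SnvSpec, ...] = ()
    fractions: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("clone fractions must lie in [0, 1]")


@dataclass(frozen=True)
class CloneProfile:
    """A clone realised against a bin frame: integer copy number per bin."""

    clone_id: str
    cn: np.ndarray = field(repr=False)
    snvs: tuple[SnvSpec, ...] = ()

    def __post_init__(self) -> None:
        if (self.cn < 0).any():
            raise ValueError("copy numbers must be >= 0")


def build_clone(genome: GenomeBins, spec: CloneSpec) -> CloneProfile:
    """Realise a clone spec as a per-bin copy-number vector (baseline 2)."""
    cn = np.full(genome.n_bins, 2, dtype=np.int64)
    idx = genome.chrom_indices()
    for ev in spec.events:
        if ev.chrom not in idx:
            raise ValueError(f"unknown chromosome {ev.chrom!r}")
        pos = idx[ev.chrom]
        if ev.start_bin + ev.n_bins > len(pos):
            raise ValueError(f"event exceeds {ev.chrom} ({len(pos)} bins)")
        cn[pos[ev.start_bin : ev.start_bin + ev.n_bins]] = ev.cn
    return CloneProfile(spec.clone_id, cn, spec.snvs)


@dataclass(frozen=True)
class SamplingModel:
    """Noise and depth parameters for one sequencing reaction."""

    total_reads: float = 13_600_000.0  # sWGS reads per sample
    variant_depth: int = 7600          # amplicon re-sequencing depth
    genomic_equivalents: float = 10_000.0
    error_rate: float = 1e-4           # symmetric per-base substitution rate
    overdispersion: float = 5e-4       # NB dispersion phi; var = mu + phi mu^2
    gc_curvature: float = 4.0          # strength of the unimodal GC bias

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.variant_depth <= 0 or self.genomic_equivalents <= 0:
            raise ValueError("depth and genomic_equivalents must be positive")


# -- elementary operations ----------------------------------------------


def expected_bin_factor(cn: float, tf: float) -> float:
    """Multiplicative count factor for copy number ``cn`` at tumour fraction ``tf``.

    A mixture of tumour (copy number ``cn``) and diploid germline:
    ``1 + tf * (cn/2 - 1)``.
    """
    if cn < 0:
        raise ValueError("cn must be >= 0")
    if not 0.0 <= tf <= 1.0:
        raise ValueError("tf must lie in [0, 1]")
    return 1.0 + tf * (cn / 2.0 - 1.0)


def gc_bias(gc: np.ndarray, curvature: float = 4.0) -> np.ndarray:
    """Smooth unimodal library bias: quadratic in GC, peaking at GC=0.45."""
    return np.maximum(1.0 - curvature * (np.asarray(gc) - 0.45) ** 2, 1e-3)


def expected_counts(
    genome: GenomeBins,
    clone_mix: Sequence[tuple[CloneProfile, float]],
    model: SamplingModel,
) -> np.ndarray:
    """Analytic expected count per bin (blacklisted bins included)."""
    weights = np.array([w for _, w in clone_mix], dtype=float)
    if (weights < 0).any():
        raise ValueError("clone weights must be >= 0")
    if weights.sum() > 1.0 + 1e-9:
        raise ValueError("clone weights must sum to <= 1")
    factor = np.ones(genome.n_bins)
    for clone, w in clone_mix:
        factor += w * (clone.cn / 2.0 - 1.0)
    t = genome.table
    bias = t["mappability"].to_numpy() * gc_bias(t["gc"].to_numpy(), model.gc_curvature)
    mu = bias * factor
    return mu / mu.sum() * model.total_reads


def simulate_counts(
    genome: GenomeBins,
    clone_mix: Sequence[tuple[CloneProfile, float]],
    model: SamplingModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw overdispersed per-bin raw counts for one sWGS library."""
    mu = expected_counts(genome, clone_mix, model)
    if model.overdispersion <= 1e-12:
        return rng.poisson(mu)
    r = 1.0 / model.overdispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_variant_reads(
    true_af: float,
    model: SamplingModel,
    rng: np.random.Generator,
    *,
    sample_id: str = "sample",
    snv: SnvSpec | None = None,
) -> VariantObservation:
    """Two-stage sampling of one amplicon: molecular bottleneck then reads.

    Mutant template molecules are Binomial(GE, true_af); sequenced reads are
    drawn from the molecule pool at ``variant_depth`` with symmetric
    substitution error, so the per-read alt probability is
    ``m (1-e) + (1-m) e`` for molecular fraction ``m``.
    """
    if not 0.0 <= true_af <= 1.0:
        raise ValueError("true_af must lie in [0, 1]")
    ge = int(round(model.genomic_equivalents))
    if ge <= 0 or model.variant_depth <= 0:
        raise ValueError("depth and genomic equivalents must be positive")
    mutant = rng.binomial(ge, true_af)
    m = mutant / ge
    e = model.error_rate
    p_alt = m * (1.0 - e) + (1.0 - m) * e
    alt = int(rng.binomial(model.variant_depth, p_alt))
    if snv is None:
        snv = SnvSpec("locus", "NA", "chr1", 1, "A", "T")
    return VariantObservation(
        sample_id=sample_id,
        chrom=snv.chrom,
        pos=snv.pos,
        ref=snv.ref,
        alt=snv.alt,
        gene=snv.gene,
        depth=model.variant_depth,
        alt_reads=alt,
        genomic_equivalents=float(ge),
    )


# -- cohort scenarios ----------------------------------------------------

TRAJECTORIES = ("responder-decay", "persistent", "clonal-switch", "mutdna-absent")


@dataclass(frozen=True)
class PatientScenario:
    patient_id: str
    trajectory: str
    tf_fluid: tuple[float, ...]          # urinary-reference tumour fraction per timepoint
    clones: tuple[CloneSpec, ...]
    recurrence_days: float | None        # None = censored
    followup_days: float                 # censoring time (= recurrence time if recurred)
    tumour_tf: float = 0.6               # tumour fraction of the resection specimen

    def __post_init__(self) -> None:
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"unknown trajectory {self.trajectory!r}")
        if self.followup_days <= 0:
            raise ValueError("followup/recurrence time must be positive")
        if self.recurrence_days is not None and self.recurrence_days <= 0:
            raise ValueError("recurrence time must be positive")
        for c in self.clones:
            if len(c.fractions) != len(self.tf_fluid):
                raise ValueError(
                    f"{self.patient_id}/{c.clone_id}: clone fractions do not "
                    "match the timepoint grid"
                )

    @property
    def recurred(self) -> bool:
        return self.recurrence_days is not None


@dataclass(frozen=True)
class CohortScenario:
    """Full study design: patients, visit schedule and sampling parameters."""

    patients: tuple[PatientScenario, ...]
    timepoint_days: tuple[int, ...] = (45, 66, 87, 108, 129, 150)
    compartment_factors: dict = field(
        default_factory=lambda: {"PLS": 0.15, "UCP": 0.8, "USN": 1.0}
    )
    model: SamplingModel = field(default_factory=SamplingModel)
    ge_log10_range: tuple[float, float] = (2.0, 5.0)
    swgs_timepoints: tuple[int, ...] = ()  # defaults to first and last
    seed: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.timepoint_days)
        if not (np.diff(days) > 0).all() or (days <= 0).any():
            raise ValueError("timepoint days must be positive and strictly increasing")
        for p in self.patients:
            if len(p.tf_fluid) != len(self.timepoint_days):
                raise ValueError(
                    f"{p.patient_id}: tumour-fraction trajectory does not "
                    "match the timepoint grid"
                )
        pf = min(self.compartment_factors.get("PLS", 0.0), 1.0)
        for u in ("UCP", "USN"):
            if self.compartment_factors.get(u, 1.0) < pf:
                raise ValueError("urine tumour fractions must be >= plasma")
        if not self.swgs_timepoints:
            object.__setattr__(
                self, "swgs_timepoints", (1, len(self.timepoint_days))
            )

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoint_days)


# Panel of recurrent bladder-cancer loci (nominal GRCh37 coordinates).
PANEL: tuple[SnvSpec, ...] = (
    SnvSpec("TP53_R248Q", "TP53", "chr17", 7577538, "C", "T"),
    SnvSpec("TP53_R273C", "TP53", "chr17", 7577121, "G", "A"),
    SnvSpec("TP53_H193A", "TP53", "chr17", 7578203, "C", "G"),
    SnvSpec("TP53_E285K", "TP53", "chr17", 7577094, "C", "T"),
    SnvSpec("KRAS_G12C", "KRAS", "chr12", 25398285, "C", "A"),
    SnvSpec("PIK3CA_E545K", "PIK3CA", "chr3", 178936091, "G", "A"),
    SnvSpec("BRAF_V600E", "BRAF", "chr7", 140453136, "A", "T"),
    SnvSpec("CTNNB1_S37F", "CTNNB1", "chr3", 41266113, "C", "T"),
    SnvSpec("FGFR3_S249C", "FGFR3", "chr4", 1803568, "C", "G"),
    SnvSpec("NFE2L2_G31A", "NFE2L2", "chr2", 178098817, "C", "G"),
)

_PERSISTENT_SHAPE = (1.0, 0.8, 0.7, 0.6, 0.55, 0.6)
_RESPONDER_SHAPE = (1.0, 0.02, 0.006, 0.002, 0.001, 0.0005)
_SWITCH_TOTAL = (0.15, 0.06, 0.05, 0.08, 0.12, 0.15)
_SWITCH_FRAC_A = (0.9, 0.7, 0.45, 0.25, 0.1, 0.05)


def _random_events(
    rng: np.random.Generator, n_chrom: int, bins_per_chrom: int, n_events: int
) -> tuple[CnaEvent, ...]:
    events = []
    used: set[int] = set()
    for _ in range(n_events):
        for _attempt in range(20):
            c = int(rng.integers(1, n_chrom + 1))
            if c in used:
                continue
            used.add(c)
            lo = min(10, max(2, bins_per_chrom // 4))
            hi = max(lo + 1, min(36, bins_per_chrom))
            width = int(rng.integers(lo, hi))
            start = int(rng.integers(0, bins_per_chrom - width + 1))
            cn = int(rng.choice([1, 1, 3, 3, 4]))
            events.append(CnaEvent(f"chr{c}", start, width, cn))
            break
    return tuple(events)


def default_scenario(
    seed: int = 0,
    *,
    n_chrom: int = 22,
    bins_per_chrom: int = 50,
) -> CohortScenario:
    """The default 17-patient cohort: 8 recurrers, 6 visits, 3 fluids.

    Composition (fixed): 5 persistent recurrers, 1 clonal-switch recurrer,
    1 responder-decay recurrer (the false negative at cycle 2), 1
    mutDNA-absent recurrer; 5 responder-decay and 4 mutDNA-absent
    non-recurrers.  Recurrence times span 264-507 days; censoring times
    span 463-1008 days.
    """
    rng = np.random.default_rng(seed)
    n_tp = 6
    patients: list[PatientScenario] = []

    def snv_pick(k: int) -> tuple[SnvSpec, ...]:
        # TP53-led panels, mirroring the mutation spectrum of this disease
        idx = rng.choice(len(PANEL) - 1, size=k, replace=False)
        chosen = [PANEL[i] for i in sorted(idx)]
        if not any(s.gene == "TP53" for s in chosen):
            chosen[0] = PANEL[int(rng.integers(0, 4))]
        return tuple(dict.fromkeys(chosen))

    plan = (
        [("persistent", t) for t in (264, 269, 283, 293, 378)]
        + [("clonal-switch", 466), ("responder-decay", 472), ("mutdna-absent", 507)]
        + [("responder-decay", -t) for t in (1008, 952, 882, 851, 781)]
        + [("mutdna-absent", -t) for t in (742, 588, 487, 463)]
    )
    for i, (kind, t) in enumerate(plan, start=1):
        pid = f"P{i:02d}"
        recurred = t > 0
        rec_days = float(t) if recurred else None
        follow = float(abs(t))
        if kind == "persistent":
            tf0 = rng.uniform(0.08, 0.20)
            tf = tuple(tf0 * s for s in _PERSISTENT_SHAPE)
            clones = (
                CloneSpec(
                    f"{pid}_c1",
                    events=_random_events(rng, n_chrom, bins_per_chrom, 3),
                    snvs=snv_pick(int(rng.integers(1, 4))),
                    fractions=(1.0,) * n_tp,
                ),
            )
        elif kind == "responder-decay":
            tf0 = rng.uniform(0.06, 0.15)
            tf = tuple(tf0 * s for s in _RESPONDER_SHAPE)
            clones = (
                CloneSpec(
                    f"{pid}_c1",
                    events=_random_events(rng, n_chrom, bins_per_chrom, 3),
                    snvs=snv_pick(int(rng.integers(1, 3))),
                    fractions=(1.0,) * n_tp,
                ),
            )
        elif kind == "clonal-switch":
            tf = _SWITCH_TOTAL
            frac_a = _SWITCH_FRAC_A
            frac_b = tuple(1.0 - f for f in frac_a)
            # distinct chromosomes for the two clones, scaled to the genome
            cs = [f"chr{c}" for c in
                  np.linspace(1, n_chrom, 4).round().astype(int)]
            broad = max(5, bins_per_chrom // 3)
            focal_start = bins_per_chrom // 4
            clone_a = CloneSpec(
                f"{pid}_cA",
                events=(
                    CnaEvent(cs[0], 0, broad, 3),
                    CnaEvent(cs[3], focal_start, 3, 6),  # focal amplification
                ),
                snvs=(PANEL[2],),  # TP53_H193A
                fractions=frac_a,
            )
            clone_b = CloneSpec(
                f"{pid}_cB",
                events=(
                    CnaEvent(cs[1], focal_start, 3, 0),  # focal deletion
                    CnaEvent(cs[1], bins_per_chrom - broad, broad, 3),
                    CnaEvent(cs[2], 0, broad, 1),
                ),
                snvs=(PANEL[1], PANEL[9]),  # TP53_R273C, NFE2L2_G31A
                fractions=frac_b,
            )
            clones = (clone_a, clone_b)
        else:  # mutdna-absent
            tf = (0.0,) * n_tp
            clones = ()
        patients.append(
            PatientScenario(
                patient_id=pid,
                trajectory=kind,
                tf_fluid=tf,
                clones=clones,
                recurrence_days=rec_days,
                followup_days=follow,
            )
        )
    return CohortScenario(patients=tuple(patients), seed=seed)


# -- cohort simulation ---------------------------------------------------


@dataclass
class CohortTables:
    """Everything the pipeline consumes, plus the ground-truth ledger."""

    genome: GenomeBins
    sample_sheet: pd.DataFrame
    variants: pd.DataFrame
    bin_counts: dict[str, np.ndarray]
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genome.to_tsv(out / "genome_bins.tsv")
        self.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
        self.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        counts_dir = out / "counts"
        counts_dir.mkdir(exist_ok=True)
        bed = self.genome.table[["chrom", "start", "end"]]
        for sid in sorted(self.bin_counts):
            df = bed.copy()
            df["count"] = self.bin_counts[sid]
            df.to_csv(counts_dir / f"{sid}.counts.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)

    def content_hash(self) -> str:
        """Hash of all emitted tables; stable iff the simulation is."""
        h = hashlib.sha256()
        h.update(self.genome.table.to_csv(index=False).encode())
        h.update(self.sample_sheet.to_csv(index=False).encode())
        h.update(self.variants.to_csv(index=False).encode())
        for sid in sorted(self.bin_counts):
            h.update(sid.encode())
            h.update(np.ascontiguousarray(self.bin_counts[sid]).tobytes())
        h.update(json.dumps(self.truth, sort_keys=True).encode())
        return h.hexdigest()


def simulate_cohort(
    scenario: CohortScenario,
    genome: GenomeBins | None = None,
    out_dir=None,
) -> CohortTables:
    """Generate all pipeline inputs for a cohort scenario.

    Emits the sample sheet, per-variant read counts for every fluid visit
    plus the resection (TUR) and germline (BUF) samples, sWGS bin counts
    for TUR, BUF and the configured sWGS timepoints, and a ground-truth
    ledger (true tumour fraction and clone fractions per sample) for
    parameter-recovery tests.  Fully deterministic for a fixed scenario.
    """
    rng = np.random.default_rng(scenario.seed)
    if genome is None:
        genome = make_genome(22, 1_000_000, 50, seed=scenario.seed)
    model = scenario.model
    lo10, hi10 = scenario.ge_log10_range

    sheet_rows, var_rows = [], []
    bin_counts: dict[str, np.ndarray] = {}
    truth_samples: dict[str, dict] = {}
    truth_patients: dict[str, dict] = {}

    def draw_ge() -> float:
        return float(10 ** rng.uniform(lo10, hi10))

    for pat in scenario.patients:
        clones = [(spec, build_clone(genome, spec)) for spec in pat.clones]
        panel = [s for spec in pat.clones for s in spec.snvs]
        truth_patients[pat.patient_id] = {
            "trajectory": pat.trajectory,
            "recurred": pat.recurred,
            "recurrence_days": pat.recurrence_days,
            "followup_days": pat.followup_days,
            "clones": {
                spec.clone_id: {
                    "fractions": list(spec.fractions),
                    "snvs": [s.variant_id for s in spec.snvs],
                    "events": [asdict(e) for e in spec.events],
                }
                for spec in pat.clones
            },
        }

        def emit_sample(
            sid: str, stype: str, tp: int, days: float, tf: float,
            fracs: dict[str, float], ge: float, with_swgs: bool,
        ) -> None:
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "patient": pat.patient_id,
                    "timepoint": tp,
                    "days": days,
                    "sample_type": stype,
                    "recurrence_days": pat.recurrence_days,
                    "recurred": pat.recurred,
                    "followup_days": pat.followup_days,
                }
            )
            smodel = SamplingModel(
                total_reads=model.total_reads,
                variant_depth=model.variant_depth,
                genomic_equivalents=ge,
                error_rate=model.error_rate,
                overdispersion=model.overdispersion,
                gc_curvature=model.gc_curvature,
            )
            for snv in panel:
                af_true = sum(
                    tf * fracs[spec.clone_id] / 2.0
                    for spec in pat.clones
                    if snv in spec.snvs
                )
                obs = simulate_variant_reads(
                    af_true, smodel, rng, sample_id=sid, snv=snv
                )
                var_rows.append(
                    {
                        "sample_id": sid,
                        "patient": pat.patient_id,
                        "timepoint": tp,
                        "days": days,
                        "sample_type": stype,
                        "variant_id": snv.variant_id,
                        "gene": snv.gene,
                        "chrom": snv.chrom,
                        "pos": snv.pos,
                        "ref": snv.ref,
                        "alt": snv.alt,
                        "depth": obs.depth,
                        "alt_reads": obs.alt_reads,
                        "genomic_equivalents": obs.genomic_equivalents,
                    }
                )
            if with_swgs:
                mix = [
                    (clone, tf * fracs[spec.clone_id]) for spec, clone in clones
                ]
                bin_counts[sid] = simulate_counts(genome, mix, smodel, rng)
            truth_samples[sid] = {
                "patient": pat.patient_id,
                "sample_type": stype,
                "timepoint": tp,
                "tumour_fraction": tf,
                "clone_fractions": {
                    spec.clone_id: fracs[spec.clone_id] for spec in pat.clones
                },
                "genomic_equivalents": ge,
            }

        frac0 = {spec.clone_id: spec.fractions[0] for spec in pat.clones}
        emit_sample(
            f"{pat.patient_id}_TUR", "TUR", 0, 0.0, pat.tumour_tf,
            frac0, float(10 ** rng.uniform(4, 5)), True,
        )
        emit_sample(
            f"{pat.patient_id}_BUF", "BUF", 0, 0.0, 0.0,
            frac0, float(10 ** rng.uniform(4, 5)), True,
        )
        for tp, days in enumerate(scenario.timepoint_days, start=1):
            fracs = {spec.clone_id: spec.fractions[tp - 1] for spec in pat.clones}
            for stype in FLUIDS:
                tf = pat.tf_fluid[tp - 1] * scenario.compartment_factors[stype]
                emit_sample(
                    f"{pat.patient_id}_T{tp}_{stype}", stype, tp, float(days),
                    tf, fracs, draw_ge(), tp in scenario.swgs_timepoints,
                )

    tables = CohortTables(
        genome=genome,
        sample_sheet=pd.DataFrame(sheet_rows),
        variants=pd.DataFrame(var_rows),
        bin_counts=bin_counts,
        truth={"samples": truth_samples, "patients": truth_patients},
    )
    if out_dir is not None:
        tables.write(out_dir)
    return tables
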