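"""Simulation-based validation experiments.

These run the whole pipeline (simulate -> categorize -> classify) over many
synthetic embryos with known ground truth and summarize recovery rates:
chromosome-level event-class accuracy, BPH vs SPH discrimination, meiosis
stage accuracy, parental-origin accuracy, mosaic-fraction calibration and
the polar-body contamination signature.  Event classes and noise follow the
simulator defaults; problem sizes are arguments.
"""

from __future__ import annotations

import logging

import numpy as np

from .categorize import categorize_frame
from .classify import ClassifierConfig
from .genome import AUTOSOMES, default_genome
from .pipeline import analyze_case
from .simulate import Contamination, IbdRegion, KaryotypeEvent, SimConfig, simulate_biopsy

log = logging.getLogger(__name__)

__all__ = [
    "classifier_recovery",
    "mosaic_calibration",
    "polar_body_experiment",
    "consanguinity_check",
]

EVENT_CLASSES = ("disomy", "gain_BPH_MI", "gain_BPH_MII", "gain_SPH",
                 "monosomy", "deletion", "mosaic")


def _draw_event(rng, chrom: str, cls: str, genome) -> tuple:
    """(events, expected chromosome-level class, origin)."""
    origin = "maternal" if rng.random() < 0.5 else "paternal"
    if cls == "disomy":
        return (), "disomy", None
    if cls in ("gain_BPH_MI", "gain_BPH_MII"):
        return ((KaryotypeEvent(chrom, cls, origin),), "trisomy_BPH", origin)
    if cls == "gain_SPH":
        return ((KaryotypeEvent(chrom, cls, origin),), "trisomy_SPH", origin)
    if cls == "monosomy":
        return ((KaryotypeEvent(chrom, "loss", origin),), "monosomy", origin)
    if cls == "deletion":
        length = genome.length(chrom)
        size = int(rng.uniform(10e6, min(80e6, 0.6 * length)))
        start = int(rng.uniform(1, length - size))
        ev = KaryotypeEvent(chrom, "loss", origin, start_bp=start,
                            end_bp=start + size)
        return ((ev,), "deletion", origin)
    if cls == "mosaic":
        f = float(rng.uniform(0.3, 0.7))
        if rng.random() < 0.5:
            ev = KaryotypeEvent(chrom, "gain_SPH", origin, cell_fraction=f)
            return ((ev,), "trisomy_SPH", origin)
        ev = KaryotypeEvent(chrom, "loss", origin, cell_fraction=f)
        return ((ev,), "monosomy", origin)
    raise ValueError(cls)


def _called_class(calls) -> tuple[str, object]:
    """Dominant call of a chromosome: the widest abnormal segment, else disomy."""
    abnormal = [c for c in calls if c.event not in ("disomy", "no_call")]
    if abnormal:
        top = max(abnormal, key=lambda c: c.end_bp - c.start_bp)
        return top.event, top
    if any(c.event == "disomy" for c in calls):
        return "disomy", None
    return "no_call", None


_GAINS = {"trisomy_BPH", "trisomy_SPH", "segmental_gain_BPH", "segmental_gain_SPH"}


def classifier_recovery(
    n_embryos: int = 200,
    seed: int = 0,
    events_per_embryo: int = 2,
    config: ClassifierConfig = ClassifierConfig(),
) -> dict:
    """Simulate embryos with randomly drawn abnormalities and score recovery.

    Each embryo carries ``events_per_embryo`` classes drawn uniformly from
    disomy, meiosis-I/II BPH trisomy, SPH trisomy, monosomy, segmental
    deletion (10-80 Mb) and 30-70% mosaic (mitotic-type gain or loss), on
    distinct random autosomes, at the simulator's default MDA-like noise.
    """
    rng = np.random.default_rng(seed)
    genome = default_genome()
    n_chrom = n_calls_ok = 0
    gain_tot = gain_ok = 0
    mech_tot = mech_ok = 0
    origin_tot = origin_ok = 0

    for i in range(n_embryos):
        chroms = rng.choice(len(AUTOSOMES), size=events_per_embryo, replace=False)
        chroms = [AUTOSOMES[j] for j in chroms]
        truth_by_chrom = {}
        events = []
        for chrom in chroms:
            cls = EVENT_CLASSES[int(rng.integers(len(EVENT_CLASSES)))]
            evs, expected, origin = _draw_event(rng, chrom, cls, genome)
            events.extend(evs)
            truth_by_chrom[chrom] = (cls, expected, origin)
        sim_seed = int(rng.integers(2 ** 31))
        df, truth = simulate_biopsy(SimConfig(seed=sim_seed, events=tuple(events)))
        report = analyze_case(categorize_frame(df), config)

        for chrom in AUTOSOMES:
            cls, expected, origin = truth_by_chrom.get(chrom, ("disomy", "disomy", None))
            got, top = _called_class(report.per_chromosome[chrom])
            # a segmental call label for a whole-chromosome event (or the
            # reverse) of the right type still identifies the event class
            canon = {"segmental_gain_BPH": "trisomy_BPH",
                     "segmental_gain_SPH": "trisomy_SPH",
                     "deletion": "monosomy" if expected == "monosomy" else "deletion",
                     "monosomy": "deletion" if expected == "deletion" else "monosomy"}
            got_c = canon.get(got, got)
            n_chrom += 1
            hit = got_c == expected
            n_calls_ok += hit
            if expected in _GAINS and got in _GAINS:
                gain_tot += 1
                gain_ok += (got_c == expected)
            if origin is not None and top is not None and hit:
                origin_tot += 1
                origin_ok += (top.origin == origin)
            if cls in ("gain_BPH_MI", "gain_BPH_MII") and got_c == "trisomy_BPH":
                parent = "mother" if origin == "maternal" else "father"
                n_xo = len(truth.crossovers.get((parent, chrom), ())) + \
                    len(truth.crossovers.get((parent + "_extra", chrom), ()))
                if n_xo >= 1 and top.mechanism in ("meiosis_I", "meiosis_II"):
                    mech_tot += 1
                    want = "meiosis_I" if cls == "gain_BPH_MI" else "meiosis_II"
                    mech_ok += (top.mechanism == want)
        if (i + 1) % 50 == 0:
            log.info("recovery: %d/%d embryos", i + 1, n_embryos)

    return {
        "n_embryos": n_embryos,
        "n_chromosomes": n_chrom,
        "event_class_accuracy_percent": 100.0 * n_calls_ok / n_chrom,
        "bph_sph_discrimination_percent": (100.0 * gain_ok / gain_tot
                                           if gain_tot else float("nan")),
        "n_gain_calls": gain_tot,
        "meiosis_stage_accuracy_percent": (100.0 * mech_ok / mech_tot
                                           if mech_tot else float("nan")),
        "n_mechanism_calls": mech_tot,
        "origin_accuracy_percent": (100.0 * origin_ok / origin_tot
                                    if origin_tot else float("nan")),
        "n_origin_calls": origin_tot,
    }


def mosaic_calibration(
    fractions=tuple(np.round(np.arange(0.3, 1.01, 0.1), 2)),
    n_seeds: int = 50,
    seed: int = 0,
    chromosome: str = "2",
    config: ClassifierConfig = ClassifierConfig(),
) -> dict:
    """Bias of the delta-inverted cell-fraction estimate per true fraction.

    Alternates maternal one-dose gains and losses on one large autosome
    (~10k SNPs at default density)."""
    rng = np.random.default_rng(seed)
    biases = {}
    for f in fractions:
        estimates = []
        for s in range(n_seeds):
            kind = "gain_SPH" if s % 2 == 0 else "loss"
            ev = KaryotypeEvent(chromosome, kind, "maternal", cell_fraction=float(f))
            sim_seed = int(rng.integers(2 ** 31))
            df, _ = simulate_biopsy(SimConfig(
                seed=sim_seed, events=(ev,), chromosomes=(chromosome, "X", "Y")))
            report = analyze_case(categorize_frame(df), config)
            est = [c.mosaic.fraction for c in report.per_chromosome[chromosome]
                   if c.mosaic is not None]
            estimates.append(max(est) if est else 0.0)
        biases[float(f)] = float(np.mean(estimates) - f)
    max_bias = max(abs(b) for b in biases.values())
    return {"bias_by_fraction": biases, "max_abs_bias": max_bias,
            "n_seeds": n_seeds}


def polar_body_experiment(
    n_cases: int = 30,
    fraction: float = 0.10,
    seed: int = 0,
    config: ClassifierConfig = ClassifierConfig(),
) -> dict:
    """Second-polar-body contamination detection rate and clean false-positive
    rate of the pericentromeric-gap signature."""
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_cases):
        df, _ = simulate_biopsy(SimConfig(
            seed=int(rng.integers(2 ** 31)),
            contamination=Contamination("second_polar_body", fraction)))
        report = analyze_case(categorize_frame(df), config)
        detected += bool(report.polar_body_signature)
    false_pos = 0
    for _ in range(n_cases):
        df, _ = simulate_biopsy(SimConfig(seed=int(rng.integers(2 ** 31))))
        report = analyze_case(categorize_frame(df), config)
        false_pos += bool(report.polar_body_signature)
    return {
        "n_cases": n_cases,
        "detection_rate_percent": 100.0 * detected / n_cases,
        "false_positive_rate_percent": 100.0 * false_pos / n_cases,
    }


def consanguinity_check(seed: int = 0,
                        config: ClassifierConfig = ClassifierConfig()) -> dict:
    """A shared parental haplotype removes category-1 SNPs; the region must
    come back as an explicit no_call, never as disomy."""
    region = IbdRegion("6", 40_000_000, 110_000_000)
    df, _ = simulate_biopsy(SimConfig(seed=seed, ibd_regions=(region,),
                                      chromosomes=("6", "X", "Y")))
    dfc = categorize_frame(df)
    inside = dfc[(dfc.chromosome == "6")
                 & dfc.position_bp.between(region.start_bp, region.end_bp)]
    n_cat1 = int(inside.subcategory.isin(("1A", "1B")).sum())
    report = analyze_case(dfc, config)
    calls = report.per_chromosome["6"]
    gap_no_call = any(
        c.event == "no_call" and c.start_bp >= region.start_bp - 15e6
        and c.end_bp <= region.end_bp + 15e6 for c in calls)
    disomy_inside = any(
        c.event == "disomy" and c.start_bp >= region.start_bp
        and c.end_bp <= region.end_bp for c in calls)
    return {"n_category1_in_region": n_cat1,
            "gap_reported_no_call": bool(gap_no_call),
            "disomy_inside_region": bool(disomy_inside)}
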