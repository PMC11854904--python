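"""Classifier: BPH detection, mechanism, decision table, segmentation,
sex inference, genome-wide verdicts and contamination QC."""

import numpy as np
import pandas as pd
import pytest

from apcad.cbaf import DeltaBafResult
from apcad.classify import (ClassifierConfig, HomozygosityMask, _classify_interval,
                            call_chromosome, call_genome_wide,
                            classify_trisomy_mechanism, contamination_qc,
                            detect_bph_pattern, infer_sex, segment_chromosome)
from apcad.genome import default_genome
from apcad.pipeline import analyze_case
from apcad.simulate import (Contamination, IbdRegion, KaryotypeEvent, SimConfig,
                            simulate_biopsy)
from apcad.categorize import categorize_frame

from conftest import single_chrom_case

CFG = ClassifierConfig()
GENOME = default_genome()


def _nondisomy(report, chrom):
    return [c for c in report.per_chromosome[chrom]
            if c.event not in ("disomy", "no_call")]


# --- BPH pattern ----------------------------------------------------------

def test_bph_pattern_zero_noise_bph_region():
    """A crossover-free maternal meiotic trisomy pins all maternal-informative
    SNPs away from homozygosity: flag set, no homozygous stretch."""
    df, _ = single_chrom_case(1, (KaryotypeEvent("2", "gain_BPH_MI", "maternal"),),
                              noise=False, crossover_rate=0.0)
    flag, mask = detect_bph_pattern(df, "2", "maternal", CFG)
    assert flag and mask.stretches == ()


def test_bph_pattern_sph_and_disomy_have_homozygous_stretches():
    df, _ = single_chrom_case(2, (KaryotypeEvent("2", "gain_SPH", "maternal"),),
                              noise=False, crossover_rate=0.0)
    flag, mask = detect_bph_pattern(df, "2", "maternal", CFG)
    assert not flag
    covered = sum(e - s for s, e in mask.stretches)
    assert covered > 0.8 * (df[df.chromosome == "2"].position_bp.max())

    df2, _ = single_chrom_case(3, noise=False)
    flag2, mask2 = detect_bph_pattern(df2, "2", "maternal", CFG)
    assert not flag2 and len(mask2.stretches) > 0


def test_mechanism_from_mask_overlap():
    cen = GENOME.centromere("2")
    mask_mi = HomozygosityMask("2", "maternal",
                               ((cen[1] + 20_000_000, cen[1] + 60_000_000),), 500, 400)
    mask_mii = HomozygosityMask("2", "maternal",
                                ((cen[0] - 5_000_000, cen[1] + 8_000_000),), 500, 400)
    empty = HomozygosityMask("2", "maternal", (), 500, 500)
    assert classify_trisomy_mechanism(mask_mi, GENOME, CFG) == "meiosis_I"
    assert classify_trisomy_mechanism(mask_mii, GENOME, CFG) == "meiosis_II"
    assert classify_trisomy_mechanism(empty, GENOME, CFG) == "meiosis_I"
    assert classify_trisomy_mechanism(empty, None, CFG) == "undetermined"


# --- decision table -------------------------------------------------------

def _d(delta, chrom="5", n=200, se=0.01):
    return DeltaBafResult(chrom, 1, 100_000_000, 0.5 - delta / 2, 0.5 + delta / 2,
                          delta, n, n, se)


@pytest.mark.parametrize(
    "delta,l2r,bph_m,bph_p,event,origin",
    [
        (0.00, 0.00, False, False, "disomy", "undetermined"),
        (0.33, 0.58, True, False, "trisomy_BPH", "maternal"),
        (0.33, 0.58, False, False, "trisomy_SPH", "maternal"),
        (-0.33, 0.58, False, True, "trisomy_BPH", "paternal"),
        (-0.98, -1.00, False, False, "monosomy", "maternal"),
        (0.98, -1.00, False, False, "monosomy", "paternal"),
        (0.95, 0.00, True, False, "UPD_hetero", "maternal"),
        (0.95, 0.00, False, False, "UPD_iso", "maternal"),
        (-0.20, 0.25, False, False, "trisomy_SPH", "paternal"),  # mosaic gain
        (0.18, -0.20, False, False, "monosomy", "paternal"),     # mosaic loss
        (-0.98, 0.58, False, False, "no_call", "undetermined"),  # conflict
        (0.00, 0.58, False, False, "no_call", "undetermined"),   # conflict
    ],
)
def test_decision_table(delta, l2r, bph_m, bph_p, event, origin):
    call = _classify_interval(_d(delta), l2r, bph_m, bph_p,
                              HomozygosityMask("5", "maternal", (), 300, 300),
                              HomozygosityMask("5", "paternal", (), 300, 300),
                              CFG, GENOME, whole_chromosome=True)
    assert (call.event, call.origin) == (event, origin)


def test_insufficient_snps_is_no_call_not_exception():
    d = DeltaBafResult("5", 1, 2, np.nan, np.nan, np.nan, 3, 2, np.nan, no_call=True)
    call = _classify_interval(d, 0.0, False, False, None, None, CFG, GENOME, True)
    assert call.event == "no_call"


def test_sph_mechanism_label_and_mosaic_fraction():
    df, _ = single_chrom_case(4, (KaryotypeEvent("2", "gain_SPH", "paternal",
                                                 cell_fraction=0.6),))
    rep = analyze_case(df)
    (c,) = _nondisomy(rep, "2")
    assert c.event == "trisomy_SPH" and c.origin == "paternal"
    assert c.mechanism == "mitotic_or_MII_no_recomb"
    assert c.mosaic.fraction == pytest.approx(0.6, abs=0.1)


def test_bph_call_always_carries_pattern_flag():
    """Structural guarantee: BPH gain calls only exist with the flag set."""
    for seed, kind in ((5, "gain_BPH_MI"), (6, "gain_BPH_MII")):
        df, _ = single_chrom_case(seed, (KaryotypeEvent("2", kind, "maternal"),))
        rep = analyze_case(df)
        for c in rep.per_chromosome["2"]:
            if c.event in ("trisomy_BPH", "segmental_gain_BPH"):
                assert c.bph_flag


# --- segmentation ---------------------------------------------------------

def test_segment_chromosome_uniform_is_single_segment():
    df, _ = single_chrom_case(7)
    calls = call_chromosome(df, "2", CFG, GENOME)
    assert len(calls) == 1 and calls[0].event == "disomy"


def test_deletion_within_mosaic_monosomy_two_calls():
    """A full paternal deletion inside a high-grade mosaic loss of the rest
    of the chromosome yields both calls with sensible breakpoints."""
    evs = (
        KaryotypeEvent("10", "loss", "paternal",
                       start_bp=75_000_000, end_bp=95_000_000),
        KaryotypeEvent("10", "loss", "paternal", start_bp=1, end_bp=74_999_999,
                       cell_fraction=0.7),
        KaryotypeEvent("10", "loss", "paternal", start_bp=95_000_001,
                       end_bp=134_000_000, cell_fraction=0.7),
    )
    df, _ = single_chrom_case(8, evs, chromosome="10")
    rep = analyze_case(df)
    calls = rep.per_chromosome["10"]
    dels = [c for c in calls if c.event == "deletion" and c.origin == "paternal"]
    assert dels
    full = [c for c in dels if c.mosaic.fraction > 0.85]
    assert full, [(c.event, c.start_bp, c.end_bp, c.fraction) for c in calls]
    # breakpoints within one window span (~8 Mb at default density) of truth
    c = full[0]
    assert abs(c.start_bp - 75e6) < 12e6 and abs(c.end_bp - 95e6) < 12e6
    mosaics = [c for c in dels if 0.4 < c.mosaic.fraction < 0.9]
    assert mosaics


def test_segmental_deletion_breakpoint_localization():
    ev = (KaryotypeEvent("1", "loss", "maternal",
                         start_bp=100_000_000, end_bp=160_000_000),)
    df, _ = single_chrom_case(9, ev, chromosome="1")
    rep = analyze_case(df)
    dels = [c for c in rep.per_chromosome["1"] if c.event == "deletion"]
    assert len(dels) == 1 and dels[0].origin == "maternal"
    assert abs(dels[0].start_bp - 100e6) < 12e6
    assert abs(dels[0].end_bp - 160e6) < 12e6


# --- sex inference --------------------------------------------------------

@pytest.mark.parametrize("sex", ["XY", "XX"])
def test_infer_sex(sex):
    df, _ = simulate_biopsy(SimConfig(seed=10, sex=sex,
                                      chromosomes=("1", "X", "Y")))
    assert infer_sex(categorize_frame(df), CFG) == sex


def test_infer_sex_undetermined_without_y_snps(disomy_case):
    df, _ = disomy_case
    assert infer_sex(df[df.chromosome != "Y"], CFG) == "undetermined"


def test_male_x_reported_normal(disomy_case):
    df, truth = disomy_case
    assert truth.sex == "XY"
    rep = analyze_case(df)
    (x_call,) = rep.per_chromosome["X"]
    assert x_call.event == "disomy" and "hemizygous" in x_call.note


# --- genome-wide ----------------------------------------------------------

def test_genome_wide_haploid_and_triploid():
    df, _ = simulate_biopsy(SimConfig(seed=11,
                                      events=(KaryotypeEvent("1", "haploid", "maternal"),)))
    rep = analyze_case(categorize_frame(df))
    assert rep.genome_wide == "haploid_maternal"

    df, _ = simulate_biopsy(SimConfig(seed=12,
                                      events=(KaryotypeEvent("1", "triploid", "maternal"),)))
    rep = analyze_case(categorize_frame(df))
    assert rep.genome_wide == "triploid_extra_maternal"


def test_genome_wide_normal_case(disomy_case):
    df, _ = disomy_case
    rep = analyze_case(df)
    assert rep.genome_wide == "normal" and not rep.polar_body_signature


def test_second_polar_body_contamination_detected():
    df, _ = simulate_biopsy(SimConfig(
        seed=13, contamination=Contamination("second_polar_body", 0.12)))
    rep = analyze_case(categorize_frame(df))
    assert rep.genome_wide == "underrepresented_haplotype_maternal"
    assert rep.polar_body_signature


def test_genome_wide_invariant_to_chromosome_order(disomy_case):
    df, _ = disomy_case
    blocks = [g for _, g in df.groupby("chromosome", sort=False)]
    shuffled = pd.concat(blocks[::-1], ignore_index=True)
    v1 = call_genome_wide(df, {}, CFG, GENOME)
    v2 = call_genome_wide(shuffled, {}, CFG, GENOME)
    assert v1 == v2


def test_consanguinity_region_no_call_not_disomy():
    df, _ = single_chrom_case(14, chromosome="6",
                              ibd_regions=(IbdRegion("6", 40_000_000, 110_000_000),))
    rep = analyze_case(df)
    calls = rep.per_chromosome["6"]
    gap = [c for c in calls if c.event == "no_call"
           and c.start_bp > 35e6 and c.end_bp < 115e6]
    assert gap
    # nothing inside the IBD region is asserted to be disomic
    for c in calls:
        if c.event == "disomy":
            assert c.end_bp <= gap[0].start_bp or c.start_bp >= gap[0].end_bp


# --- contamination QC -----------------------------------------------------

def test_contamination_clean_sample_zero():
    df, _ = single_chrom_case(15, noise=False)
    qc = contamination_qc(df, CFG)
    assert qc.fraction_het_band == 0.0 and not qc.flagged


def test_contamination_all_rail_values_zero():
    df = pd.DataFrame({
        "chromosome": ["1"] * 60, "position_bp": np.arange(1, 61),
        "subcategory": ["4A"] * 30 + ["4B"] * 30,
        "embryo_baf": [1.0] * 30 + [0.0] * 30,
    })
    qc = contamination_qc(df, CFG)
    assert qc.fraction_het_band == 0.0 and qc.dose_estimate == 0.0


def test_contamination_monotone_in_admixture():
    means = []
    for frac in (0.0, 0.1, 0.2, 0.4):
        vals = []
        for s in range(3):
            cont = Contamination("unrelated", frac) if frac else None
            df, _ = single_chrom_case(20 + s, contamination=cont)
            vals.append(contamination_qc(df, CFG).fraction_het_band)
        means.append(np.mean(vals))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_contamination_too_few_snps_flagged():
    df = pd.DataFrame({
        "chromosome": ["1"] * 4, "position_bp": [1, 2, 3, 4],
        "subcategory": ["4A"] * 4, "embryo_baf": [1.0] * 4,
    })
    assert contamination_qc(df, CFG).flagged
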