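"""Per-chromosome, segmental and genome-wide calls from cBAF evidence.

The caller combines three signals per interval:

* ``delta_BAF`` from category-1 SNPs — magnitude and sign of the parental
  imbalance (positive = maternal excess);
* mean Log2R — copy-number direction (gain vs loss vs normal);
* the BPH pattern on the informative parent's category-2/3 SNPs — whether
  both of that parent's haplotypes are present (a long run of informative
  SNPs pinned away from homozygosity), the hallmark of a meiotic-origin gain.

Meiosis I vs meiosis II is resolved from where homozygous stretches fall:
a gain with two different parental homologs at the centromere (no
homozygous stretch pericentromerically) arose in meiosis I; identical
centromeric copies (a pericentromeric homozygous stretch) indicate
meiosis II.  An SPH gain (single homolog duplicated) is reported as
mitotic or meiosis-II-without-recombination, which cannot be told apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cbaf import (DeltaBafResult, MosaicEstimate, delta_baf,
                   estimate_mosaic_fraction, trimmed_stats as _trimmed_stats)
from .genome import AUTOSOMES, CentromereTable, default_genome
from .segment import binary_segmentation

log = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "HomozygosityMask",
    "SegmentCall",
    "ContaminationQC",
    "CaseReport",
    "detect_bph_pattern",
    "classify_trisomy_mechanism",
    "call_chromosome",
    "segment_chromosome",
    "infer_sex",
    "call_genome_wide",
    "contamination_qc",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds.  Defaults calibrated on the built-in simulator."""

    # delta_BAF bands
    d_disomy: float = 0.08          # |delta| below this is balanced
    upd_delta: float = 0.80         # |delta| above this with normal Log2R -> UPD / full absence
    # Log2R bands (array baseline 0 for the modal copy number)
    log2r_gain: float = 0.10
    log2r_loss: float = -0.12
    # homozygosity / BPH pattern detection
    low_thr: float = 0.15
    high_thr: float = 0.85
    min_run: int = 10               # SNPs per homozygous stretch
    bph_min_run: int = 20           # informative SNPs with no homozygote -> BPH evidence
    pericentromere_margin_bp: int = 5_000_000
    mechanism_margin_bp: int = 0        # MI/MII test: overlap with the centromere interval
    dose_tol: float = 0.25          # slack on f<=1 when choosing extra doses
    # windows / segmentation (windows counted in category-1 SNPs)
    min_snps: int = 20
    window_snps: int = 16
    seg_penalty: float = 12.0
    min_seg_windows: int = 2
    max_cat1_gap_bp: int = 12_000_000   # larger category-1 gaps become explicit no_call
    # mosaic / dose model
    full_fraction: float = 0.80
    max_extra_doses: int = 3
    # genome-wide verdicts
    underrep_band: tuple = (0.04, 0.20)
    genome_frac: float = 0.80
    bph_frac_triploid: float = 0.50
    # polar-body signature (hom-deviation of category-2 SNPs)
    pb_window: int = 25
    pb_dev_hi: float = 0.05
    pb_dev_lo: float = 0.03
    pb_chrom_frac: float = 0.50
    # contamination QC on category-4 SNPs
    het_band: tuple = (0.20, 0.80)
    contaminant_het_rate: float = 0.5
    # sex inference
    y_present_log2r: float = -2.0
    trim: float = 0.05


@dataclass(frozen=True)
class HomozygosityMask:
    chromosome: str
    parent: str                     # 'maternal' or 'paternal'
    stretches: tuple                # ((start_bp, end_bp), ...)
    n_informative: int
    longest_nonhom_run: int

    def overlaps(self, start_bp: int, end_bp: int) -> bool:
        return any(s <= end_bp and e >= start_bp for s, e in self.stretches)


@dataclass(frozen=True)
class SegmentCall:
    chromosome: str
    start_bp: int
    end_bp: int
    event: str          # disomy | trisomy_BPH | trisomy_SPH | segmental_gain_BPH |
                        # segmental_gain_SPH | monosomy | deletion | UPD_hetero | UPD_iso | no_call
    origin: str         # maternal | paternal | undetermined
    mechanism: str      # meiosis_I | meiosis_II | mitotic_or_MII_no_recomb | not_applicable
    extra_doses: int = 0
    mosaic: MosaicEstimate | None = None
    delta_baf: float = np.nan
    se_delta: float = np.nan
    mean_log2r: float = np.nan
    bph_flag: bool = False
    note: str = ""

    @property
    def fraction(self) -> float:
        return self.mosaic.fraction if self.mosaic is not None else np.nan


@dataclass(frozen=True)
class ContaminationQC:
    fraction_het_band: float
    dose_estimate: float
    n_snps: int
    flagged: bool = False


@dataclass
class CaseReport:
    sex: str                                 # XX | XY | undetermined
    genome_wide: str
    polar_body_signature: bool
    contamination: ContaminationQC
    per_chromosome: dict = field(default_factory=dict)  # chrom -> list[SegmentCall]
    qc: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# BPH pattern & mechanism
# ---------------------------------------------------------------------------

_INFORMATIVE = {"maternal": ("2A", "2B"), "paternal": ("3A", "3B")}


def _informative_arrays(df, chromosome, parent, start_bp=None, end_bp=None):
    cats = _INFORMATIVE[parent]
    sel = (df["chromosome"] == str(chromosome)) & df["subcategory"].isin(cats) \
        & df["embryo_baf"].notna()
    if start_bp is not None:
        sel &= df["position_bp"] >= start_bp
    if end_bp is not None:
        sel &= df["position_bp"] <= end_bp
    sub = df.loc[sel]
    return sub["position_bp"].to_numpy(np.int64), sub["embryo_baf"].to_numpy(float)


def detect_bph_pattern(
    df: pd.DataFrame,
    chromosome: str,
    parent: str,
    config: ClassifierConfig = ClassifierConfig(),
    start_bp: int | None = None,
    end_bp: int | None = None,
) -> tuple[bool, HomozygosityMask]:
    """BPH evidence and homozygous stretches for one parent over an interval.

    The informative SNPs are the ones heterozygous in that parent and
    homozygous in the other (categories 2A/2B for the mother, 3A/3B for the
    father).  Where both of the parent's haplotypes are present, no
    informative SNP can be homozygous in the embryo, so a run of
    ``bph_min_run`` consecutive informative SNPs outside the homozygous BAF
    bands is strong BPH evidence (under disomy or SPH roughly half of them
    are homozygous, making such runs vanishingly unlikely).  Homozygous
    stretches (rolling homozygote fraction >= 0.3 over ``min_run`` SNPs) are
    recorded for meiosis-stage calling.
    """
    pos, baf = _informative_arrays(df, chromosome, parent, start_bp, end_bp)
    n = len(pos)
    hom = (baf <= config.low_thr) | (baf >= config.high_thr)

    hom_idx = np.flatnonzero(hom)
    gaps = np.diff(np.concatenate(([-1], hom_idx, [n]))) - 1
    longest = int(gaps.max()) if len(gaps) else n
    flag = n >= config.min_snps and longest >= config.bph_min_run

    stretches: list[tuple[int, int]] = []
    w = config.min_run
    if n >= w:
        frac = np.convolve(hom.astype(float), np.ones(w) / w, mode="valid")
        dense = frac >= 0.30
        i = 0
        while i < len(dense):
            if dense[i]:
                j = i
                while j + 1 < len(dense) and dense[j + 1]:
                    j += 1
                lo_i, hi_i = i, j + w - 1
                inside = lo_i + np.flatnonzero(hom[lo_i: hi_i + 1])
                # trim to the actual homozygous SNPs so stretch bounds do not
                # overshoot into adjacent heterozygous territory
                if len(inside) >= config.min_run:
                    stretches.append((int(pos[inside[0]]), int(pos[inside[-1]])))
                i = j + 1
            else:
                i += 1
    merged: list[list[int]] = []
    for s, e in stretches:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    mask = HomozygosityMask(
        chromosome=str(chromosome),
        parent=parent,
        stretches=tuple((s, e) for s, e in merged),
        n_informative=n,
        longest_nonhom_run=longest,
    )
    return flag, mask


def classify_trisomy_mechanism(
    mask: HomozygosityMask,
    centromeres: CentromereTable | None,
    config: ClassifierConfig = ClassifierConfig(),
) -> str:
    """Meiosis stage of a BPH gain from pericentromeric homozygosity.

    meiosis_I when no homozygous stretch overlaps the centromere interval
    padded by the configured margin (the two centromeric copies differ);
    meiosis_II when one does.
    """
    if centromeres is None or mask.chromosome not in centromeres:
        return "undetermined"
    lo, hi = centromeres.pericentromeric(mask.chromosome, config.mechanism_margin_bp)
    return "meiosis_II" if mask.overlaps(lo, hi) else "meiosis_I"


# ---------------------------------------------------------------------------
# Interval decision table
# ---------------------------------------------------------------------------


def _pick_extra_doses(d_mag: float, log2r: float, config: ClassifierConfig) -> int:
    """Smallest number of extra doses k whose implied cell fraction is <= 1.

    A gain of k doses in a fraction f of cells and one of 2k doses in f/2
    are indistinguishable from (delta, Log2R) alone, so the parsimonious k
    is chosen: k is only raised when delta exceeds what a single extra dose
    present in every cell could produce (plus noise slack)."""
    if d_mag >= 1.0:
        return config.max_extra_doses
    for k in range(1, config.max_extra_doses + 1):
        f = 2.0 * d_mag / (k * (1.0 - d_mag))
        if f <= 1.0 + config.dose_tol:
            return k
    return config.max_extra_doses


def _classify_interval(
    d: DeltaBafResult,
    mean_log2r: float,
    bph_mat: bool,
    bph_pat: bool,
    mask_mat: HomozygosityMask | None,
    mask_pat: HomozygosityMask | None,
    config: ClassifierConfig,
    centromeres: CentromereTable | None,
    whole_chromosome: bool,
) -> SegmentCall:
    chrom, lo, hi = d.interval
    base = dict(chromosome=chrom, start_bp=lo, end_bp=hi,
                delta_baf=d.delta_baf, se_delta=d.se_delta, mean_log2r=mean_log2r)

    def call(event, origin="undetermined", mechanism="not_applicable",
             k=0, mosaic=None, bph=False, note=""):
        return SegmentCall(event=event, origin=origin, mechanism=mechanism,
                           extra_doses=k, mosaic=mosaic, bph_flag=bph, note=note, **base)

    if d.no_call:
        return call("no_call", note=f"insufficient category-1 SNPs (n={d.n_1A}/{d.n_1B})")

    dv = d.delta_baf
    mag = abs(dv)
    maternal_excess = dv > 0
    L = mean_log2r
    gain_L = np.isfinite(L) and L >= config.log2r_gain
    loss_L = np.isfinite(L) and L <= config.log2r_loss
    balanced = mag <= config.d_disomy

    def gain_call(origin: str) -> SegmentCall:
        bph = bph_mat if origin == "maternal" else bph_pat
        mask = mask_mat if origin == "maternal" else mask_pat
        k = _pick_extra_doses(mag, L, config) if gain_L else 1
        mosaic = estimate_mosaic_fraction(d, "gain", k)
        if bph:
            event = "trisomy_BPH" if whole_chromosome else "segmental_gain_BPH"
            mech = classify_trisomy_mechanism(mask, centromeres, config) \
                if mask is not None else "undetermined"
        else:
            event = "trisomy_SPH" if whole_chromosome else "segmental_gain_SPH"
            mech = "mitotic_or_MII_no_recomb"
        return call(event, origin, mech, k=k, mosaic=mosaic, bph=bph)

    def loss_call(origin: str) -> SegmentCall:
        mosaic = estimate_mosaic_fraction(d, "loss")
        event = "monosomy" if whole_chromosome else "deletion"
        return call(event, origin, "not_applicable", mosaic=mosaic)

    if gain_L:
        if balanced:
            return call("no_call", note="elevated Log2R without parental imbalance")
        if mag >= config.upd_delta:
            # near-total absence of one parent cannot coexist with a gain
            return call("no_call", note="parental imbalance inconsistent with gain")
        return gain_call("maternal" if maternal_excess else "paternal")
    if loss_L:
        if balanced:
            return call("no_call", note="reduced Log2R without parental imbalance")
        # excess of one parent with reduced copy number = loss of the other
        return loss_call("paternal" if maternal_excess else "maternal")
    # normal Log2R
    if balanced:
        return call("disomy")
    if mag >= config.upd_delta:
        origin = "maternal" if maternal_excess else "paternal"
        bph = bph_mat if origin == "maternal" else bph_pat
        if whole_chromosome:
            return call("UPD_hetero" if bph else "UPD_iso", origin, bph=bph)
        # a segmental full one-parent absence at normal Log2R is reported as
        # segmental UPD-like imbalance
        return call("UPD_hetero" if bph else "UPD_iso", origin, bph=bph,
                    note="segmental")
    # intermediate imbalance at normal Log2R: low-grade BPH gain if the
    # excess parent shows the BPH pattern, otherwise ambiguous
    if maternal_excess and bph_mat:
        return gain_call("maternal")
    if (not maternal_excess) and bph_pat:
        return gain_call("paternal")
    return call("no_call", note="parental imbalance without copy-number support")


# ---------------------------------------------------------------------------
# Chromosome-level analysis
# ---------------------------------------------------------------------------


def _window_stats(df: pd.DataFrame, chromosome: str, config: ClassifierConfig):
    """Non-overlapping windows of category-1 SNPs with (delta, mean log2r)."""
    chrom_df = df[df["chromosome"] == str(chromosome)]
    cat1 = chrom_df[chrom_df["subcategory"].isin(("1A", "1B")) & chrom_df["embryo_baf"].notna()]
    pos1 = cat1["position_bp"].to_numpy(np.int64)
    baf1 = cat1["embryo_baf"].to_numpy(float)
    is_a = (cat1["subcategory"] == "1A").to_numpy()
    all_pos = chrom_df["position_bp"].to_numpy(np.int64)
    all_l2r = chrom_df["embryo_log2r"].to_numpy(float)
    w = config.window_snps
    n = len(pos1)
    windows = []
    if n == 0:
        return windows
    edges = list(range(0, n, w))
    if len(edges) > 1 and n - edges[-1] < w // 2:
        edges.pop()  # fold a short tail into the previous window
    min_w = max(2, w // 4)
    for i, s in enumerate(edges):
        e = edges[i + 1] - 1 if i + 1 < len(edges) else n - 1
        lo, hi = int(pos1[s]), int(pos1[e])
        a_vals = baf1[s:e + 1][is_a[s:e + 1]]
        b_vals = baf1[s:e + 1][~is_a[s:e + 1]]
        if len(a_vals) < min_w or len(b_vals) < min_w:
            dres = DeltaBafResult(str(chromosome), lo, hi, np.nan, np.nan, np.nan,
                                  len(a_vals), len(b_vals), np.nan, no_call=True)
        else:
            ma, va = _trimmed_stats(a_vals, config.trim)
            mb, vb = _trimmed_stats(b_vals, config.trim)
            dres = DeltaBafResult(str(chromosome), lo, hi, ma, mb, mb - ma,
                                  len(a_vals), len(b_vals), float(np.sqrt(va + vb)))
        a, b = np.searchsorted(all_pos, lo), np.searchsorted(all_pos, hi, side="right")
        l2r = all_l2r[a:b]
        l2r = l2r[np.isfinite(l2r)]
        windows.append((lo, hi, dres, float(np.mean(l2r)) if len(l2r) else np.nan))
    return windows


def segment_chromosome(windows, config: ClassifierConfig = ClassifierConfig()):
    """Changepoint segmentation of the joint (delta_BAF, Log2R) window series.

    Returns a list of (start_bp, end_bp) intervals covering the windowed span.
    """
    usable = [(lo, hi, d, l) for lo, hi, d, l in windows
              if not d.no_call and np.isfinite(l)]
    if len(usable) < 2 * config.min_seg_windows:
        if not windows:
            return []
        return [(windows[0][0], windows[-1][1])]
    series = np.column_stack([
        [d.delta_baf for _, _, d, _ in usable],
        [l for _, _, _, l in usable],
    ])
    # standardize dimensions so delta and Log2R carry comparable weight
    scale = np.maximum(np.std(series, axis=0), 1e-6)
    cps = binary_segmentation(series / scale, penalty=config.seg_penalty,
                              min_size=config.min_seg_windows)
    bounds = [0] + cps + [len(usable)]
    segments = []
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1] - 1
        lo = usable[s][0] if s > 0 else windows[0][0]
        hi = usable[e][1] if e < len(usable) - 1 else windows[-1][1]
        if i > 0:
            # boundary at the midpoint between adjacent windows
            prev_hi = usable[s - 1][1]
            lo = (prev_hi + usable[s][0]) // 2 + 1
            segments[-1] = (segments[-1][0], lo - 1)
        segments.append((lo, hi))
    return segments


def _cat1_gaps(df, chromosome, config):
    """Long internal intervals devoid of category-1 SNPs but covered by
    other SNPs (e.g. a parental IBD region) -> explicit no_call intervals."""
    chrom_df = df[df["chromosome"] == str(chromosome)]
    pos1 = chrom_df.loc[chrom_df["subcategory"].isin(("1A", "1B")),
                        "position_bp"].to_numpy(np.int64)
    all_pos = chrom_df["position_bp"].to_numpy(np.int64)
    gaps = []
    if len(pos1) < 2:
        return gaps
    d = np.diff(pos1)
    for i in np.nonzero(d > config.max_cat1_gap_bp)[0]:
        lo, hi = int(pos1[i]) + 1, int(pos1[i + 1]) - 1
        inside = np.count_nonzero((all_pos > lo) & (all_pos < hi))
        if inside >= config.min_snps:
            gaps.append((lo, hi))
    return gaps


def call_chromosome(
    df: pd.DataFrame,
    chromosome: str,
    config: ClassifierConfig = ClassifierConfig(),
    centromeres: CentromereTable | None = None,
    sex: str = "undetermined",
) -> list[SegmentCall]:
    """Segment one chromosome and classify every segment.

    Returns one call for a uniform chromosome, several for segmental events.
    Regions without category-1 information (consanguinity) yield explicit
    ``no_call`` entries.
    """
    chromosome = str(chromosome)
    if centromeres is None:
        centromeres = default_genome()
    chrom_df = df[df["chromosome"] == chromosome]
    df = chrom_df  # all downstream selections are within this chromosome
    windows = _window_stats(chrom_df, chromosome, config)

    if not windows:
        l2r = chrom_df["embryo_log2r"].to_numpy(float)
        l2r = l2r[np.isfinite(l2r)]
        lo = int(chrom_df["position_bp"].min()) if len(chrom_df) else 0
        hi = int(chrom_df["position_bp"].max()) if len(chrom_df) else 0
        d = delta_baf(df, chromosome, min_snps=config.min_snps, trim=config.trim)
        return [_classify_interval(
            d, float(np.mean(l2r)) if len(l2r) else np.nan,
            False, False, None, None, config, centromeres, True)]

    segments = segment_chromosome(windows, config)
    gaps = _cat1_gaps(df, chromosome, config)
    whole = len(segments) == 1 and not gaps

    calls: list[SegmentCall] = []
    for lo, hi in segments:
        d = delta_baf(df, chromosome, lo if not whole else None,
                      hi if not whole else None,
                      min_snps=config.min_snps, trim=config.trim)
        sel = (chrom_df["position_bp"] >= lo) & (chrom_df["position_bp"] <= hi)
        l2r = chrom_df.loc[sel, "embryo_log2r"].to_numpy(float)
        l2r = l2r[np.isfinite(l2r)]
        L = float(np.mean(l2r)) if len(l2r) else np.nan
        bph_m, mask_m = detect_bph_pattern(df, chromosome, "maternal", config,
                                           None if whole else lo, None if whole else hi)
        bph_p, mask_p = detect_bph_pattern(df, chromosome, "paternal", config,
                                           None if whole else lo, None if whole else hi)
        calls.append(_classify_interval(d, L, bph_m, bph_p, mask_m, mask_p,
                                        config, centromeres, whole))

    # merge adjacent segments with the same verdict at the same evidence
    # level (a full deletion stays separate from a mosaic loss next to it)
    def _same_level(a: SegmentCall, b: SegmentCall) -> bool:
        if (a.event, a.origin, a.mechanism) != (b.event, b.origin, b.mechanism):
            return False
        if np.isfinite(a.delta_baf) and np.isfinite(b.delta_baf):
            if abs(a.delta_baf - b.delta_baf) > config.d_disomy:
                return False
        if np.isfinite(a.mean_log2r) and np.isfinite(b.mean_log2r):
            if abs(a.mean_log2r - b.mean_log2r) > 0.2:
                return False
        return True

    merged: list[SegmentCall] = []
    for c in calls:
        if merged and _same_level(merged[-1], c):
            prev = merged.pop()
            redo = delta_baf(df, chromosome, prev.start_bp, c.end_bp,
                             min_snps=config.min_snps, trim=config.trim)
            sel = (chrom_df["position_bp"] >= prev.start_bp) & \
                  (chrom_df["position_bp"] <= c.end_bp)
            l2r = chrom_df.loc[sel, "embryo_log2r"].to_numpy(float)
            l2r = l2r[np.isfinite(l2r)]
            L = float(np.mean(l2r)) if len(l2r) else np.nan
            bph_m, mask_m = detect_bph_pattern(df, chromosome, "maternal", config,
                                               prev.start_bp, c.end_bp)
            bph_p, mask_p = detect_bph_pattern(df, chromosome, "paternal", config,
                                               prev.start_bp, c.end_bp)
            whole2 = (prev.start_bp == calls[0].start_bp
                      and c.end_bp == calls[-1].end_bp and not gaps)
            merged.append(_classify_interval(redo, L, bph_m, bph_p, mask_m, mask_p,
                                             config, centromeres, whole2))
        else:
            merged.append(c)
    calls = merged

    # carve category-1 gaps out of the classified intervals: nothing can be
    # asserted there, so the gap itself is reported no_call
    for lo, hi in gaps:
        carved: list[SegmentCall] = []
        for c in calls:
            if c.end_bp < lo or c.start_bp > hi:
                carved.append(c)
                continue
            if c.start_bp < lo:
                carved.append(replace(c, end_bp=lo - 1))
            if c.end_bp > hi:
                carved.append(replace(c, start_bp=hi + 1))
        calls = carved
        calls.append(SegmentCall(
            chromosome=chromosome, start_bp=lo, end_bp=hi, event="no_call",
            origin="undetermined", mechanism="not_applicable",
            note="no category-1 SNPs (possible shared parental haplotype)"))
    calls.sort(key=lambda c: c.start_bp)

    # sex-chromosome context: a hemizygous X/Y in a male embryo is normal
    if sex == "XY" and chromosome == "X":
        adjusted = []
        for c in calls:
            if c.event == "monosomy" and c.origin == "paternal":
                adjusted.append(replace(c, event="disomy", origin="undetermined",
                                        mosaic=None, note="hemizygous X (XY)"))
            else:
                adjusted.append(c)
        calls = adjusted
    return calls


# ---------------------------------------------------------------------------
# Sex, genome-wide verdicts, contamination
# ---------------------------------------------------------------------------


def infer_sex(df: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()) -> str:
    """XY when Y-rule category-1 SNPs show concordant paternal signal; XX when
    the Y is silent and the X carries both parents; undetermined otherwise."""
    y = df[(df["chromosome"] == "Y") & df["subcategory"].isin(("1A", "1B"))]
    n_y = len(y)
    if n_y < config.min_snps // 2:
        return "undetermined"
    l2r = y["embryo_log2r"].to_numpy(float)
    present = np.isfinite(l2r) & (l2r > config.y_present_log2r)
    frac_present = float(np.mean(present)) if n_y else 0.0
    d_x = delta_baf(df, "X", min_snps=config.min_snps, trim=config.trim)
    if frac_present >= 0.5:
        baf = y["embryo_baf"].to_numpy(float)
        is_1a = (y["subcategory"] == "1A").to_numpy()
        ok = np.where(is_1a, baf >= 0.8, baf <= 0.2)
        conc = float(np.mean(ok[present])) if present.any() else 0.0
        if conc >= 0.8:
            return "XY"
        return "undetermined"
    if frac_present <= 0.2 and not d_x.no_call and abs(d_x.delta_baf) <= 0.6:
        return "XX"
    return "undetermined"


def _pb_chromosome_signature(df, chromosome, centromeres, config):
    """Hom-deviation contrast: polar-body contamination shifts distal (but not
    pericentromeric) homozygous category-2 SNPs away from the 0/1 rails."""
    sel = (df["chromosome"] == str(chromosome)) & df["subcategory"].isin(("2A", "2B")) \
        & df["embryo_baf"].notna()
    sub = df.loc[sel]
    pos = sub["position_bp"].to_numpy(np.int64)
    baf = sub["embryo_baf"].to_numpy(float)
    is_2a = (sub["subcategory"] == "2A").to_numpy()
    dev = np.where(is_2a, 1.0 - baf, baf)          # distance from the hom rail
    near_hom = np.where(is_2a, baf >= 0.70, baf <= 0.30)
    w = config.pb_window
    if len(pos) < 3 * w or str(chromosome) not in centromeres:
        return None
    lo_c, hi_c = centromeres.pericentromeric(str(chromosome),
                                             config.pericentromere_margin_bp)
    peri_devs, distal_devs = [], []
    for s in range(0, len(pos) - w + 1, w):
        idx = slice(s, s + w)
        hom_idx = near_hom[idx]
        if hom_idx.sum() < 5:
            continue
        wdev = float(np.mean(dev[idx][hom_idx]))
        mid = (pos[s] + pos[s + w - 1]) / 2
        if lo_c <= mid <= hi_c:
            peri_devs.append(wdev)
        else:
            distal_devs.append(wdev)
    if not distal_devs:
        return None
    peri = float(np.mean(peri_devs)) if peri_devs else 0.0
    distal_max = float(np.max(distal_devs))
    return distal_max >= config.pb_dev_hi and peri <= config.pb_dev_lo


def call_genome_wide(
    df: pd.DataFrame,
    per_chromosome: dict,
    config: ClassifierConfig = ClassifierConfig(),
    centromeres: CentromereTable | None = None,
) -> tuple[str, bool]:
    """Genome-wide ploidy/haplotype verdict plus the polar-body signature.

    Verdicts are driven by the autosome-wide delta_BAF distribution and BPH
    flags, not by Log2R (array normalization can mask whole-ploidy shifts):
    near-total one-parent absence on almost all autosomes means haploidy, a
    genome-wide +1/3-type excess with BPH patterns means triploidy, and a
    consistent low-grade excess means an underrepresented extra haplotype.
    """
    if centromeres is None:
        centromeres = default_genome()
    by_chrom = {str(c): g for c, g in df.groupby("chromosome", sort=False)}
    deltas, bph_flags = {}, {}
    for chrom in AUTOSOMES:
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        d = delta_baf(sub, chrom, min_snps=config.min_snps, trim=config.trim)
        if d.no_call:
            continue
        deltas[chrom] = d.delta_baf
        flag, _ = detect_bph_pattern(sub, chrom, "maternal", config)
        flag_p, _ = detect_bph_pattern(sub, chrom, "paternal", config)
        bph_flags[chrom] = (flag, flag_p)
    if not deltas:
        return "normal", False
    dv = np.array(list(deltas.values()))
    n = len(dv)
    frac = config.genome_frac
    lo_u, hi_u = config.underrep_band

    verdict = "normal"
    for sign, side in ((1.0, "maternal"), (-1.0, "paternal")):
        s = sign * dv
        if np.mean(s >= config.upd_delta) >= frac:
            verdict = f"haploid_{side}"
            break
        in_tri = (s >= 0.20) & (s <= 0.50)
        bph_n = np.mean([bph_flags[c][0 if side == "maternal" else 1]
                         for c in deltas])
        if np.mean(in_tri) >= frac and bph_n >= config.bph_frac_triploid:
            verdict = f"triploid_extra_{side}"
            break
        if np.mean((s >= lo_u) & (s < 0.20)) >= frac:
            verdict = f"underrepresented_haplotype_{side}"
            break

    signature = False
    if verdict.startswith("underrepresented_haplotype") or (
            float(np.median(dv)) >= lo_u and verdict == "normal"):
        results = [_pb_chromosome_signature(by_chrom[c], c, centromeres, config)
                   for c in AUTOSOMES if c in by_chrom]
        results = [r for r in results if r is not None]
        if results:
            signature = float(np.mean(results)) >= config.pb_chrom_frac
    return verdict, signature


def contamination_qc(
    df: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()
) -> ContaminationQC:
    """External contamination from obligate-homozygous (category-4) SNPs.

    Reports the fraction of category-4 SNPs in the open heterozygous BAF band
    and a rough DNA-dose estimate from the mean deviation off the homozygous
    rails, assuming the contaminant carries the opposite allele at the
    configured rate.
    """
    cat4 = df[df["subcategory"].isin(("4A", "4B")) & df["embryo_baf"].notna()]
    n = len(cat4)
    if n < config.min_snps:
        return ContaminationQC(np.nan, np.nan, n, flagged=True)
    baf = cat4["embryo_baf"].to_numpy(float)
    is_4a = (cat4["subcategory"] == "4A").to_numpy()
    lo, hi = config.het_band
    frac = float(np.mean((baf > lo) & (baf < hi)))
    dev = np.where(is_4a, 1.0 - baf, baf)
    mean_dev = float(np.mean(np.clip(dev, 0.0, 1.0)))
    r = config.contaminant_het_rate
    if mean_dev >= r:
        dose = 1.0
    else:
        g = 2.0 * mean_dev / (r - mean_dev) if r > mean_dev else np.inf
        dose = float(np.clip(g / (2.0 + g), 0.0, 1.0))
    return ContaminationQC(frac, dose, n)
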