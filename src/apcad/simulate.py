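"""Synthetic trio + embryo SNP-array cases with known ground truth.

The generator emulates the data regime of an MDA-amplified trophectoderm
biopsy genotyped with its parents on a SNP array:

* phased diploid parents drawn per-SNP from Hardy-Weinberg at a population
  B-allele frequency (optionally sharing an IBD haplotype region);
* meiosis with Poisson crossovers per chromosome arm; copy-number events are
  built mechanistically — a meiosis-I gain transmits two chromatids with
  different centromeric homologs, a meiosis-II gain two sister chromatids
  (identical pericentromerically, diverging beyond crossovers), an SPH gain
  two identical copies;
* mosaicism as a dose mixture of euploid and aneuploid cell populations;
* contamination from a second/first polar body (derived from the actual
  non-transmitted maternal chromatids of the simulated meiosis, so the
  pericentromeric gap in the extra-haplotype signal emerges mechanistically),
  cumulus cells, or an unrelated individual;
* measurement noise: allele dropout at the allele level, truncated-normal
  BAF jitter (wider at heterozygous clusters), Gaussian Log2R noise.

Expected BAF is the dose-weighted B-allele proportion and Log2R is
log2(total dose / 2) plus noise.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import AUTOSOMES, CentromereTable, default_genome

__all__ = [
    "NoiseModel",
    "KaryotypeEvent",
    "Contamination",
    "IbdRegion",
    "SimConfig",
    "GroundTruth",
    "simulate_parents",
    "simulate_meiosis",
    "simulate_biopsy",
]

EVENT_KINDS = ("gain_BPH_MI", "gain_BPH_MII", "gain_SPH", "loss",
               "UPD_hetero", "UPD_iso", "haploid", "triploid")


@dataclass(frozen=True)
class NoiseModel:
    baf_sd_hom: float = 0.03
    baf_sd_het: float = 0.07
    ado_rate: float = 0.05
    log2r_sd: float = 0.30
    parent_log2r_sd: float = 0.10


@dataclass(frozen=True)
class KaryotypeEvent:
    chromosome: str
    kind: str
    origin: str = "maternal"
    start_bp: int | None = None       # None = whole chromosome
    end_bp: int | None = None
    cell_fraction: float = 1.0
    extra_doses: int = 1

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.origin not in ("maternal", "paternal"):
            raise ValueError(f"origin must be maternal/paternal, got {self.origin!r}")
        if not 0.0 < self.cell_fraction <= 1.0:
            raise ValueError("cell_fraction must be in (0, 1]")
        if self.extra_doses < 1:
            raise ValueError("extra_doses must be >= 1")


@dataclass(frozen=True)
class Contamination:
    source: str                       # second_polar_body | first_polar_body | cumulus | unrelated
    fraction: float

    def __post_init__(self) -> None:
        if self.source not in ("second_polar_body", "first_polar_body",
                               "cumulus", "unrelated"):
            raise ValueError(f"unknown contamination source {self.source!r}")
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("fraction must be in [0, 1)")


@dataclass(frozen=True)
class IbdRegion:
    chromosome: str
    start_bp: int
    end_bp: int


@dataclass(frozen=True)
class SimConfig:
    snps_per_mb: float = 40.0
    allele_freq_range: tuple = (0.05, 0.95)
    crossover_rate: float = 1.0       # expected crossovers per chromosome arm
    noise: NoiseModel = field(default_factory=NoiseModel)
    events: tuple = ()
    contamination: Contamination | None = None
    sex: str = "random"               # XX | XY | random
    chromosomes: tuple | None = None  # default: all 22 autosomes + X + Y
    ibd_regions: tuple = ()
    parental_nc_rate: float = 0.002
    call_thresholds: tuple = (0.20, 0.80)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("XX", "XY", "random"):
            raise ValueError("sex must be XX, XY or random")
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "ibd_regions", tuple(self.ibd_regions))


@dataclass
class GroundTruth:
    sex: str
    events: list
    genome_wide: str                  # normal | haploid_* | triploid_extra_*
    crossovers: dict                  # (parent, chromosome) -> tuple of bp
    transmitted_start_hap: dict       # (parent, chromosome) -> int
    contamination: Contamination | None
    ibd_regions: tuple
    n_snps: int = 0


_ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0)


def zero_noise(config: SimConfig) -> SimConfig:
    """Convenience: the same configuration with all noise switched off."""
    return replace(config, noise=_ZERO_NOISE, parental_nc_rate=0.0)


# ---------------------------------------------------------------------------
# parents & meiosis
# ---------------------------------------------------------------------------


def simulate_parents(rng, n: int, freq: np.ndarray, share_ibd: np.ndarray | None = None):
    """Two phased diploid parents at Hardy-Weinberg equilibrium.

    Returns ((f0, f1), (m0, m1)) haplotype B-allele indicator arrays.  Where
    ``share_ibd`` is true, the mother's first haplotype is replaced by the
    father's first haplotype (an identical-by-descent segment), which
    removes all category-1 SNPs there by construction.
    """
    f0, f1, m0, m1 = (rng.random((4, n)) < freq).astype(np.int8)
    if share_ibd is not None and share_ibd.any():
        m0 = m0.copy()
        m0[share_ibd] = f0[share_ibd]
    return (f0, f1), (m0, m1)


def _crossover_positions(rng, arms, rate: float) -> np.ndarray:
    pts = []
    for lo, hi in arms:
        if hi <= lo:
            continue
        k = rng.poisson(rate)
        if k:
            pts.append(rng.integers(lo, hi + 1, size=k))
    if not pts:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(pts).astype(np.int64))


def _chromatid_alleles(h0, h1, positions, cen_mid, breakpoints, start_hap):
    """Allele array of a recombined chromatid whose centromere comes from
    haplotype ``start_hap``."""
    if len(breakpoints) == 0:
        src = np.full(len(positions), start_hap, dtype=np.int8)
    else:
        parity = (np.searchsorted(breakpoints, positions)
                  - np.searchsorted(breakpoints, cen_mid)) % 2
        src = (start_hap + parity) % 2
    return np.where(src == 0, h0, h1)


def simulate_meiosis(rng, haps, positions, arms, cen_mid, rate: float,
                     mode: str = "disomic", start_hap: int | None = None):
    """Transmitted chromatid(s) for one parent and chromosome.

    mode: ``disomic`` (one chromatid), ``gain_BPH_MI`` (two chromatids with
    different centromeric homologs), ``gain_BPH_MII`` (two sister chromatids:
    same centromeric homolog, independent crossovers), ``gain_SPH`` (one
    chromatid duplicated).  Returns (list of allele arrays, info dict).
    """
    h0, h1 = haps
    s = int(rng.integers(0, 2)) if start_hap is None else int(start_hap)
    bk1 = _crossover_positions(rng, arms, rate)
    first = _chromatid_alleles(h0, h1, positions, cen_mid, bk1, s)
    info = {"start_hap": s, "crossovers": tuple(int(b) for b in bk1)}
    if mode == "disomic":
        return [first], info
    if mode == "gain_SPH":
        return [first, first.copy()], info
    if mode == "gain_BPH_MI":
        bk2 = _crossover_positions(rng, arms, rate)
        second = _chromatid_alleles(h0, h1, positions, cen_mid, bk2, 1 - s)
        info["crossovers_extra"] = tuple(int(b) for b in bk2)
        return [first, second], info
    if mode == "gain_BPH_MII":
        # the two retained sisters must carry distinct haplotype content
        # (an MII error without any recombination divergence is an SPH event)
        for _ in range(50):
            bk2 = _crossover_positions(rng, arms, rate)
            second = _chromatid_alleles(h0, h1, positions, cen_mid, bk2, s)
            if np.any(second != first):
                break
        info["crossovers_extra"] = tuple(int(b) for b in bk2)
        return [first, second], info
    raise ValueError(f"unknown meiosis mode {mode!r}")


# ---------------------------------------------------------------------------
# biopsy
# ---------------------------------------------------------------------------


def _expand_events(config: SimConfig, chroms):
    """Split genome-wide events into per-chromosome ones; validate overlaps."""
    per_chrom: dict[str, list[KaryotypeEvent]] = {c: [] for c in chroms}
    genome_wide = "normal"
    for ev in config.events:
        if ev.kind == "haploid":
            if len(config.events) > 1:
                raise ValueError("haploid cannot be combined with other events")
            genome_wide = f"haploid_{ev.origin}"
            gone = "paternal" if ev.origin == "maternal" else "maternal"
            for c in chroms:
                per_chrom[c].append(KaryotypeEvent(c, "loss", gone))
        elif ev.kind == "triploid":
            if len(config.events) > 1:
                raise ValueError("triploid cannot be combined with other events")
            genome_wide = f"triploid_extra_{ev.origin}"
            for c in chroms:
                if c != "Y":
                    per_chrom[c].append(KaryotypeEvent(c, "gain_BPH_MII", ev.origin))
        else:
            if ev.chromosome not in per_chrom:
                raise ValueError(f"event on chromosome {ev.chromosome!r} "
                                 "not in the simulated set")
            per_chrom[ev.chromosome].append(ev)
    for c, evs in per_chrom.items():
        ivs = sorted((e.start_bp or 0, e.end_bp or np.inf) for e in evs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping events on chromosome {c}")
    return per_chrom, genome_wide


def _geno_str(dose_b: np.ndarray, ploidy: int = 2) -> np.ndarray:
    out = np.full(len(dose_b), "AB", dtype="U2")
    out[dose_b == 0] = "AA"
    out[dose_b == ploidy] = "BB"
    return out


def simulate_biopsy(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one trio case table plus its ground truth.

    The returned DataFrame has the native case-table columns (snp_id,
    chromosome, position_bp, pat_call, mat_call, mat_log2r, embryo_call,
    embryo_baf, embryo_log2r) sorted by genome position, ready for
    :func:`apcad.categorize.categorize_frame`.
    """
    rng = np.random.default_rng(config.seed)
    genome = default_genome()
    chroms = tuple(config.chromosomes) if config.chromosomes else tuple(genome.rows)
    noise = config.noise
    sex = config.sex if config.sex != "random" else ("XY" if rng.random() < 0.5 else "XX")

    per_chrom_events, genome_wide = _expand_events(config, chroms)
    contam = config.contamination
    g_dose = 0.0
    if contam is not None and contam.fraction > 0:
        g_dose = 2.0 * contam.fraction / (1.0 - contam.fraction)

    ibd_by_chrom: dict[str, list[IbdRegion]] = {}
    for reg in config.ibd_regions:
        ibd_by_chrom.setdefault(str(reg.chromosome), []).append(reg)

    crossovers: dict = {}
    start_haps: dict = {}
    frames = []

    for chrom in chroms:
        cs, ce, length = genome.rows[chrom]
        cen_mid = (cs + ce) // 2
        arms = genome.arms(chrom)
        n = max(10, int(round(length / 1e6 * config.snps_per_mb)))
        positions = np.unique(rng.integers(1, length + 1, size=n))
        n = len(positions)
        lo_f, hi_f = config.allele_freq_range
        freq = rng.uniform(lo_f, hi_f, size=n)

        share = None
        if chrom in ibd_by_chrom:
            share = np.zeros(n, dtype=bool)
            for reg in ibd_by_chrom[chrom]:
                share |= (positions >= reg.start_bp) & (positions <= reg.end_bp)
        (f0, f1), (m0, m1) = simulate_parents(rng, n, freq, share)

        # --- parental genotype calls -----------------------------------
        if chrom == "Y":
            pat_call = np.where(f0 == 1, "BB", "AA").astype("U2")
            mat_call = np.full(n, "NC", dtype="U2")
            mat_log2r = (np.full(n, -5.0) if noise.parent_log2r_sd == 0
                         else rng.normal(-5.0, 0.3, size=n))
        elif chrom == "X":
            pat_call = np.where(f0 == 1, "BB", "AA").astype("U2")
            mat_call = _geno_str(m0 + m1)
            mat_log2r = rng.normal(0.0, noise.parent_log2r_sd, size=n)
        else:
            pat_call = _geno_str(f0 + f1)
            mat_call = _geno_str(m0 + m1)
            mat_log2r = rng.normal(0.0, noise.parent_log2r_sd, size=n)
        if config.parental_nc_rate > 0 and chrom != "Y":
            nc = rng.random(n) < config.parental_nc_rate
            pat_call = pat_call.copy(); pat_call[nc] = "NC"
            nc2 = rng.random(n) < config.parental_nc_rate
            mat_call = mat_call.copy(); mat_call[nc2] = "NC"

        # --- transmission ----------------------------------------------
        events = per_chrom_events[chrom]
        mat_mode = "disomic"
        for ev in events:
            if ev.origin == "maternal" and ev.kind in ("gain_BPH_MI", "gain_BPH_MII",
                                                       "gain_SPH", "UPD_hetero", "UPD_iso"):
                mat_mode = {"UPD_hetero": "gain_BPH_MI", "UPD_iso": "gain_SPH"}.get(ev.kind, ev.kind)

        if chrom == "Y":
            mat_chromatids, mat_info = [], {"start_hap": -1, "crossovers": ()}
        else:
            mat_chromatids, mat_info = simulate_meiosis(
                rng, (m0, m1), positions, arms, cen_mid, config.crossover_rate, mat_mode)
        crossovers[("mother", chrom)] = mat_info["crossovers"]
        if "crossovers_extra" in mat_info:
            crossovers[("mother_extra", chrom)] = mat_info["crossovers_extra"]
        start_haps[("mother", chrom)] = mat_info["start_hap"]

        pat_mode = "disomic"
        for ev in events:
            if ev.origin == "paternal" and ev.kind in ("gain_BPH_MI", "gain_BPH_MII",
                                                       "gain_SPH", "UPD_hetero", "UPD_iso"):
                pat_mode = {"UPD_hetero": "gain_BPH_MI", "UPD_iso": "gain_SPH"}.get(ev.kind, ev.kind)

        if chrom == "Y":
            pat_chromatids = [f0] if sex == "XY" else []
            pat_info = {"start_hap": 0, "crossovers": ()}
        elif chrom == "X":
            pat_chromatids = [f0] if sex == "XX" else []
            pat_info = {"start_hap": 0, "crossovers": ()}
        else:
            pat_chromatids, pat_info = simulate_meiosis(
                rng, (f0, f1), positions, arms, cen_mid, config.crossover_rate, pat_mode)
        crossovers[("father", chrom)] = pat_info["crossovers"]
        if "crossovers_extra" in pat_info:
            crossovers[("father_extra", chrom)] = pat_info["crossovers_extra"]
        start_haps[("father", chrom)] = pat_info["start_hap"]

        # --- dose bookkeeping ------------------------------------------
        base_mat = mat_chromatids[:1]
        base_pat = pat_chromatids[:1]
        B = np.zeros(n); T = np.zeros(n)
        for arr in base_mat + base_pat:
            B += arr; T += 1.0

        for ev in events:
            mask = np.ones(n, dtype=bool)
            if ev.start_bp is not None:
                mask &= positions >= ev.start_bp
            if ev.end_bp is not None:
                mask &= positions <= ev.end_bp
            f = ev.cell_fraction
            own = mat_chromatids if ev.origin == "maternal" else pat_chromatids
            other = base_pat if ev.origin == "maternal" else base_mat
            if ev.kind in ("gain_BPH_MI", "gain_BPH_MII", "gain_SPH"):
                extra = own[1] if len(own) > 1 else own[0]
                k = ev.extra_doses
                B[mask] += f * k * extra[mask]; T[mask] += f * k
            elif ev.kind == "loss":
                if own:
                    B[mask] -= f * own[0][mask]; T[mask] -= f
            elif ev.kind in ("UPD_hetero", "UPD_iso"):
                extra = own[1] if len(own) > 1 else own[0]
                B[mask] += f * extra[mask]; T[mask] += f
                if other:
                    B[mask] -= f * other[0][mask]; T[mask] -= f

        # --- contamination ---------------------------------------------
        if g_dose > 0 and chrom != "Y":
            if contam.source == "second_polar_body":
                bk = _crossover_positions(rng, arms, config.crossover_rate)
                sister = _chromatid_alleles(m0, m1, positions, cen_mid, bk,
                                            mat_info["start_hap"])
                B += g_dose * sister; T += g_dose
            elif contam.source == "first_polar_body":
                s_other = 1 - max(mat_info["start_hap"], 0)
                for _ in range(2):
                    bk = _crossover_positions(rng, arms, config.crossover_rate)
                    arr = _chromatid_alleles(m0, m1, positions, cen_mid, bk, s_other)
                    B += 0.5 * g_dose * arr; T += 0.5 * g_dose
            elif contam.source == "cumulus":
                B += 0.5 * g_dose * (m0 + m1); T += g_dose
            elif contam.source == "unrelated":
                u = (rng.random((2, n)) < freq).astype(np.int8)
                B += 0.5 * g_dose * (u[0] + u[1]); T += g_dose

        # --- expected signal -> noise ----------------------------------
        present = T > 1e-9
        baf = np.full(n, np.nan)
        baf[present] = B[present] / T[present]
        log2r_true = np.full(n, -5.0)
        log2r_true[present] = np.log2(T[present] / 2.0)

        if noise.ado_rate > 0:
            het = present & (baf > 1e-9) & (baf < 1 - 1e-9)
            ado = het & (rng.random(n) < noise.ado_rate)
            baf[ado] = (rng.random(int(ado.sum())) < 0.5).astype(float)
        if noise.baf_sd_hom > 0 or noise.baf_sd_het > 0:
            centered = np.abs(2.0 * np.nan_to_num(baf, nan=0.5) - 1.0)
            sd = noise.baf_sd_hom + (noise.baf_sd_het - noise.baf_sd_hom) * (1.0 - centered)
            baf = np.clip(baf + rng.normal(0.0, 1.0, n) * sd, 0.0, 1.0)
        if (~present).any():
            baf[~present] = np.clip(rng.normal(0.5, 0.2, int((~present).sum())), 0, 1)
        log2r = log2r_true + (rng.normal(0.0, noise.log2r_sd, n)
                              if noise.log2r_sd > 0 else 0.0)

        lo_t, hi_t = config.call_thresholds
        call = np.full(n, "AB", dtype="U2")
        call[baf <= lo_t] = "AA"
        call[baf >= hi_t] = "BB"
        call[log2r < -4.0] = "NC"

        frames.append(pd.DataFrame({
            "snp_id": [f"snp_{chrom}_{i}" for i in range(n)],
            "chromosome": chrom,
            "position_bp": positions,
            "pat_call": pat_call,
            "mat_call": mat_call,
            "mat_log2r": mat_log2r,
            "embryo_call": call,
            "embryo_baf": baf,
            "embryo_log2r": log2r,
        }))

    df = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        sex=sex,
        events=[ev for evs in per_chrom_events.values() for ev in evs],
        genome_wide=genome_wide,
        crossovers=crossovers,
        transmitted_start_hap=start_haps,
        contamination=contam,
        ibd_regions=config.ibd_regions,
        n_snps=len(df),
    )
    return df, truth
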