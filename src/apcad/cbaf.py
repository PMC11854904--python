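"""Categorized-BAF tracks, the delta_BAF statistic, and mosaic-fraction estimates.

delta_BAF is the difference between the mean embryo BAF of subcategory-1B
SNPs (both parents homozygous, mother carrying the B allele — so the BAF
measures the maternal contribution) and subcategory-1A SNPs (father carrying
the B allele — paternal contribution):

    delta_BAF = mean BAF(1B) - mean BAF(1A) = (m - p) / (m + p)

where m and p are the maternal and paternal chromosomal doses.  Disomy gives
0, a full maternal trisomy +1/3, a full maternal loss -1; the sign is
positive for maternal excess.

Under a mixture in which a fraction ``f`` of cells carries the event with
``k`` extra (or one missing) chromatid doses:

    gain:  d = +/- k f / (2 + k f)   =>  f = 2|d| / (k (1 - |d|))
    loss:  d = -/+   f / (2 - f)     =>  f = 2|d| / (1 + |d|)

which this module inverts to estimate the aneuploid-cell fraction
independently of Log2R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProfileTrack",
    "DeltaBafResult",
    "MosaicEstimate",
    "build_tracks",
    "delta_baf",
    "windowed_delta",
    "estimate_mosaic_fraction",
    "gain_delta",
    "loss_delta",
]


@dataclass(frozen=True)
class ProfileTrack:
    """Ordered per-chromosome BAF values for one subcategory."""

    chromosome: str
    subcategory: str
    positions_bp: np.ndarray
    baf: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions_bp) != len(self.baf):
            raise ValueError("positions and baf must have equal length")
        if len(self.positions_bp) > 1 and not np.all(np.diff(self.positions_bp) > 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions_bp)


@dataclass(frozen=True)
class DeltaBafResult:
    chromosome: str
    start_bp: int
    end_bp: int
    mean_baf_1A: float
    mean_baf_1B: float
    delta_baf: float
    n_1A: int
    n_1B: int
    se_delta: float
    no_call: bool = False

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chromosome, self.start_bp, self.end_bp)


@dataclass(frozen=True)
class MosaicEstimate:
    direction: str  # maternal_gain | maternal_loss | paternal_gain | paternal_loss
    fraction: float
    ci_low: float
    ci_high: float
    extra_doses: int = 1
    clamped: bool = False


def gain_delta(f: float, k: int = 1) -> float:
    """Expected delta_BAF magnitude for a gain of ``k`` doses in fraction f of cells."""
    return k * f / (2.0 + k * f)


def loss_delta(f: float) -> float:
    """Expected delta_BAF magnitude for a one-dose loss in fraction f of cells."""
    return f / (2.0 - f)


def build_tracks(df: pd.DataFrame) -> list[ProfileTrack]:
    """One ProfileTrack per (chromosome, subcategory) with at least one SNP.

    Excluded SNPs and SNPs with missing BAF are omitted.  Input must be a
    categorized case table (see :func:`apcad.categorize.categorize_frame`).
    """
    sub = df[(df["subcategory"] != "EXCLUDED") & df["embryo_baf"].notna()]
    tracks = []
    for (chrom, cat), grp in sub.groupby(["chromosome", "subcategory"], sort=False):
        tracks.append(
            ProfileTrack(
                chromosome=str(chrom),
                subcategory=str(cat),
                positions_bp=grp["position_bp"].to_numpy(dtype=np.int64),
                baf=grp["embryo_baf"].to_numpy(dtype=float),
            )
        )
    return tracks


def trimmed_stats(x: np.ndarray, trim: float) -> tuple[float, float]:
    """Trimmed mean and the variance of the trimmed sample (resists WGA outliers)."""
    if trim > 0 and len(x) >= 3:
        mean = float(stats.trim_mean(x, trim))
        lo, hi = np.quantile(x, [trim, 1 - trim])
        kept = x[(x >= lo) & (x <= hi)]
        var = float(np.var(kept, ddof=1)) if len(kept) > 1 else 0.0
        n_eff = max(len(kept), 1)
    else:
        mean = float(np.mean(x))
        var = float(np.var(x, ddof=1)) if len(x) > 1 else 0.0
        n_eff = len(x)
    return mean, var / n_eff


def delta_baf(
    df: pd.DataFrame,
    chromosome: str | None = None,
    start_bp: int | None = None,
    end_bp: int | None = None,
    *,
    min_snps: int = 20,
    trim: float = 0.05,
) -> DeltaBafResult:
    """delta_BAF over an interval (default: whole chromosome / whole table).

    Requires at least ``min_snps`` category-1 SNPs of each subcategory with a
    measured BAF; below that the result is flagged ``no_call`` rather than
    raising.
    """
    sel = df["subcategory"].isin(("1A", "1B")) & df["embryo_baf"].notna()
    if chromosome is not None:
        sel &= df["chromosome"] == str(chromosome)
    if start_bp is not None:
        sel &= df["position_bp"] >= start_bp
    if end_bp is not None:
        sel &= df["position_bp"] <= end_bp
    cat1 = df.loc[sel]
    a = cat1.loc[cat1["subcategory"] == "1A", "embryo_baf"].to_numpy(dtype=float)
    b = cat1.loc[cat1["subcategory"] == "1B", "embryo_baf"].to_numpy(dtype=float)

    chrom = str(chromosome) if chromosome is not None else "*"
    lo = int(start_bp) if start_bp is not None else (
        int(cat1["position_bp"].min()) if len(cat1) else 0)
    hi = int(end_bp) if end_bp is not None else (
        int(cat1["position_bp"].max()) if len(cat1) else 0)

    if len(a) < min_snps or len(b) < min_snps:
        return DeltaBafResult(chrom, lo, hi, np.nan, np.nan, np.nan,
                              len(a), len(b), np.nan, no_call=True)

    mean_a, sev_a = trimmed_stats(a, trim)
    mean_b, sev_b = trimmed_stats(b, trim)
    d = mean_b - mean_a
    se = float(np.sqrt(sev_a + sev_b))
    return DeltaBafResult(chrom, lo, hi, mean_a, mean_b, d, len(a), len(b), se)


def windowed_delta(
    df: pd.DataFrame,
    chromosome: str,
    window_snps: int = 40,
    step_snps: int = 10,
    *,
    min_snps: int = 20,
    trim: float = 0.05,
) -> list[DeltaBafResult]:
    """Overlapping windows of ``window_snps`` category-1 SNPs tiling a chromosome.

    Windows are defined on the category-1 SNP index so each window carries a
    comparable amount of information regardless of SNP density.  A chromosome
    with fewer category-1 SNPs than one window yields a single
    whole-chromosome result.
    """
    if window_snps < 2 * min_snps:
        min_snps = max(2, window_snps // 4)
    chrom_df = df[(df["chromosome"] == str(chromosome))
                  & df["subcategory"].isin(("1A", "1B")) & df["embryo_baf"].notna()]
    pos = chrom_df["position_bp"].to_numpy(dtype=np.int64)
    n = len(pos)
    if n <= window_snps:
        return [delta_baf(df, chromosome, min_snps=min_snps, trim=trim)]
    starts = list(range(0, n - window_snps + 1, step_snps))
    if starts[-1] != n - window_snps:
        starts.append(n - window_snps)
    out = []
    for s in starts:
        out.append(
            delta_baf(
                df, chromosome, int(pos[s]), int(pos[s + window_snps - 1]),
                min_snps=min_snps, trim=trim,
            )
        )
    return out


def estimate_mosaic_fraction(
    d: DeltaBafResult | float,
    event: str = "gain",
    extra_doses: int = 1,
    *,
    se: float | None = None,
    log2r_reduced: bool | None = None,
) -> MosaicEstimate:
    """Invert delta_BAF into an aneuploid-cell fraction.

    ``event`` is ``"gain"`` or ``"loss"`` (normally resolved by the classifier
    from Log2R).  Direction follows the delta sign: positive means maternal
    excess (maternal gain or paternal loss), negative the mirror.  Values
    outside the invertible range after noise are clamped to the boundary and
    flagged.  The confidence interval propagates the delta standard error
    through the inversion (delta method, 95%).
    """
    if isinstance(d, DeltaBafResult):
        dv, dse = d.delta_baf, d.se_delta
    else:
        dv, dse = float(d), (se if se is not None else 0.0)
    if event not in ("gain", "loss"):
        raise ValueError("event must be 'gain' or 'loss'")
    k = int(extra_doses)
    if k < 1:
        raise ValueError("extra_doses must be >= 1")
    mag = abs(dv)
    maternal_excess = dv >= 0
    if event == "gain":
        direction = "maternal_gain" if maternal_excess else "paternal_gain"
        d_max = k / (2.0 + k)
        clamped = mag > d_max
        mag_c = min(mag, d_max)
        f = 2.0 * mag_c / (k * (1.0 - mag_c)) if mag_c < 1 else 1.0
        deriv = 2.0 / (k * (1.0 - mag_c) ** 2)
    else:
        direction = "paternal_loss" if maternal_excess else "maternal_loss"
        clamped = mag > 1.0
        mag_c = min(mag, 1.0)
        f = 2.0 * mag_c / (1.0 + mag_c)
        deriv = 2.0 / (1.0 + mag_c) ** 2
    f = min(max(f, 0.0), 1.0)
    half = 1.96 * deriv * (dse if np.isfinite(dse) else 0.0)
    return MosaicEstimate(
        direction=direction,
        fraction=f,
        ci_low=max(0.0, f - half),
        ci_high=min(1.0, f + half),
        extra_doses=k,
        clamped=bool(clamped),
    )
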