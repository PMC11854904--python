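"""SNP categorization by parental genotype combination.

Each SNP of a father/mother/embryo trio is assigned to one of eight
subcategories (or excluded) as a total, deterministic function of the two
parental genotype calls, the chromosome, and — on the Y chromosome only —
the maternal log2R intensity:

========  ===============  ===============  ==========================
subcat    paternal call    maternal call    remark
========  ===============  ===============  ==========================
1A        BB               AA               embryo BAF = paternal proportion
1A        BB               NC / low log2R   Y chromosome only
1B        AA               BB               embryo BAF = maternal proportion
1B        AA               NC / low log2R   Y chromosome only
2A        BB               AB               maternal informative, not phased
2B        AA               AB               maternal informative, not phased
3A        AB               BB               paternal informative, not phased
3B        AB               AA               paternal informative, not phased
4A        BB               BB               obligate homozygous (QC)
4B        AA               AA               obligate homozygous (QC)
========  ===============  ===============  ==========================

Any other combination (AB x AB, or a parental no-call outside the Y rule)
is excluded.  Hemizygous A/- and B/- calls are encoded AA and BB, as
hemizygosity and homozygosity cannot be distinguished on an array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .genome import CHROMOSOMES, chromosome_sort_key

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "Subcategory",
    "SnpLocus",
    "TrioSnpRecord",
    "CategorizedSnp",
    "categorize_snp",
    "categorize_case",
    "categorize_frame",
    "Y_LOW_INTENSITY_LOG2R",
    "SUBCATEGORIES",
    "CATEGORY_OF",
]

#: maternal log2R below this counts as "very low signal intensity" in the Y rule
Y_LOW_INTENSITY_LOG2R = -4.0

SUBCATEGORIES = ("1A", "1B", "2A", "2B", "3A", "3B", "4A", "4B")
EXCLUDED = "EXCLUDED"

#: subcategory -> category number (1..4)
CATEGORY_OF = {s: int(s[0]) for s in SUBCATEGORIES}


class GenotypeCall(str, Enum):
    AA = "AA"
    AB = "AB"
    BB = "BB"
    NC = "NC"


class Subcategory(str, Enum):
    S1A = "1A"
    S1B = "1B"
    S2A = "2A"
    S2B = "2B"
    S3A = "3A"
    S3B = "3B"
    S4A = "4A"
    S4B = "4B"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class SnpLocus:
    snp_id: str
    chromosome: str
    position_bp: int

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"invalid chromosome {self.chromosome!r}")
        if self.position_bp < 1:
            raise ValueError("position_bp must be >= 1 (1-based)")


@dataclass(frozen=True)
class TrioSnpRecord:
    locus: SnpLocus
    pat_call: GenotypeCall
    mat_call: GenotypeCall
    mat_log2r: float
    embryo_baf: float | None
    embryo_log2r: float | None
    embryo_call: GenotypeCall

    def __post_init__(self) -> None:
        if self.embryo_baf is not None and not np.isnan(self.embryo_baf):
            if not 0.0 <= self.embryo_baf <= 1.0:
                raise ValueError("embryo_baf must be in [0, 1]")


@dataclass(frozen=True)
class CategorizedSnp:
    record: TrioSnpRecord
    subcategory: Subcategory


# (pat, mat) -> subcategory, chromosome-independent rows
_TABLE = {
    ("BB", "AA"): "1A",
    ("AA", "BB"): "1B",
    ("BB", "AB"): "2A",
    ("AA", "AB"): "2B",
    ("AB", "BB"): "3A",
    ("AB", "AA"): "3B",
    ("BB", "BB"): "4A",
    ("AA", "AA"): "4B",
}


def categorize_snp(
    pat_call: str | GenotypeCall,
    mat_call: str | GenotypeCall,
    chromosome: str,
    mat_log2r: float = 0.0,
) -> Subcategory:
    """Assign one SNP to its subcategory.

    On the Y chromosome a homozygous father combined with a maternal no-call
    *or* very low maternal signal intensity (log2R < -4) joins category 1,
    since the mother carries no Y; everywhere else a parental no-call
    excludes the SNP.
    """
    chromosome = str(chromosome)
    if chromosome not in CHROMOSOMES:
        raise ValueError(f"invalid chromosome {chromosome!r}")
    pat = GenotypeCall(pat_call).value
    mat = GenotypeCall(mat_call).value

    if chromosome == "Y" and pat in ("AA", "BB"):
        if mat == "NC" or (mat_log2r is not None and mat_log2r < Y_LOW_INTENSITY_LOG2R):
            return Subcategory("1A" if pat == "BB" else "1B")
    return Subcategory(_TABLE.get((pat, mat), EXCLUDED))


def categorize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized categorization of a case table.

    Parameters
    ----------
    df : DataFrame with columns ``chromosome, position_bp, pat_call,
        mat_call, mat_log2r`` (genotype calls as AA/AB/BB/NC strings).

    Returns a copy sorted by (chromosome, position) with a ``subcategory``
    column added.  Rows on chromosomes outside 1..22/X/Y are dropped with a
    warning.
    """
    if len(df) == 0:
        raise ValueError("empty case table")
    df = df.copy()
    df["chromosome"] = df["chromosome"].astype(str)
    known = df["chromosome"].isin(CHROMOSOMES)
    if not known.all():
        dropped = (~known).sum()
        log.warning("dropping %d SNPs on unsupported contigs: %s",
                    dropped, sorted(df.loc[~known, "chromosome"].unique())[:10])
        df = df.loc[known]
        if len(df) == 0:
            raise ValueError("no SNPs on supported chromosomes")
    order = df["chromosome"].map(chromosome_sort_key)
    df = df.assign(_ord=order).sort_values(["_ord", "position_bp"], kind="mergesort")
    df = df.drop(columns="_ord").reset_index(drop=True)

    pat = df["pat_call"].to_numpy(dtype="U2")
    mat = df["mat_call"].to_numpy(dtype="U2")
    sub = np.full(len(df), EXCLUDED, dtype="U8")
    for (p, m), s in _TABLE.items():
        sub[(pat == p) & (mat == m)] = s

    on_y = df["chromosome"].to_numpy() == "Y"
    if on_y.any():
        mat_l2r = df["mat_log2r"].to_numpy(dtype=float)
        mother_silent = (mat == "NC") | (mat_l2r < Y_LOW_INTENSITY_LOG2R)
        sub[on_y & (pat == "BB") & mother_silent] = "1A"
        sub[on_y & (pat == "AA") & mother_silent] = "1B"

    df["subcategory"] = sub
    counts = pd.Series(sub).value_counts()
    log.info("categorized %d SNPs: %s", len(df), counts.to_dict())
    return df


def categorize_case(records: list[TrioSnpRecord]) -> list[CategorizedSnp]:
    """Categorize a list of records, preserving order after genomic sorting."""
    if not records:
        raise ValueError("empty record list")
    ordered = sorted(
        records, key=lambda r: (chromosome_sort_key(r.locus.chromosome), r.locus.position_bp)
    )
    return [
        CategorizedSnp(
            record=r,
            subcategory=categorize_snp(
                r.pat_call, r.mat_call, r.locus.chromosome, r.mat_log2r
            ),
        )
        for r in ordered
    ]
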