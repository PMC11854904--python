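"""Genome model: chromosome lengths, centromere positions, sort order.

The package works on an abstract genome so that no reference download is
needed.  The default model is human-scaled (approximate metacentric /
acrocentric layout in Mb); real array-manifest coordinates can be supplied
through a BED-like annotation file instead (see :func:`read_centromere_table`).
All internal coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CHROMOSOMES",
    "AUTOSOMES",
    "CentromereTable",
    "default_genome",
    "read_centromere_table",
    "write_centromere_table",
    "chromosome_sort_key",
]

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")

_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}

# chrom: (length_mb, cen_start_mb, cen_end_mb) -- human-scaled defaults
_DEFAULT_MB = {
    "1": (249, 121, 126), "2": (242, 92, 95), "3": (198, 90, 94),
    "4": (190, 49, 52), "5": (182, 46, 50), "6": (171, 58, 61),
    "7": (159, 58, 62), "8": (145, 43, 47), "9": (138, 43, 46),
    "10": (134, 39, 42), "11": (135, 51, 55), "12": (133, 34, 38),
    "13": (114, 16, 19), "14": (107, 16, 18), "15": (102, 17, 20),
    "16": (90, 36, 39), "17": (83, 23, 27), "18": (80, 15, 21),
    "19": (59, 24, 28), "20": (64, 26, 30), "21": (47, 11, 13),
    "22": (51, 14, 16), "X": (156, 59, 63), "Y": (57, 10, 11),
}


def chromosome_sort_key(chrom: str) -> int:
    """Natural chromosome order 1..22, X, Y (not lexicographic)."""
    try:
        return _CHROM_ORDER[str(chrom)]
    except KeyError:
        raise ValueError(f"unknown chromosome {chrom!r}") from None


@dataclass(frozen=True)
class CentromereTable:
    """Per-chromosome centromere interval and chromosome length (1-based bp)."""

    rows: dict  # chrom -> (cen_start_bp, cen_end_bp, length_bp)

    def __post_init__(self) -> None:
        for chrom, (cs, ce, ln) in self.rows.items():
            if chrom not in _CHROM_ORDER:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if not (1 <= cs <= ce <= ln):
                raise ValueError(f"centromere interval outside chromosome {chrom}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.rows

    def length(self, chrom: str) -> int:
        return self.rows[chrom][2]

    def centromere(self, chrom: str) -> tuple[int, int]:
        cs, ce, _ = self.rows[chrom]
        return cs, ce

    def arms(self, chrom: str) -> tuple[tuple[int, int], tuple[int, int]]:
        """(p-arm, q-arm) as 1-based inclusive intervals."""
        cs, ce, ln = self.rows[chrom]
        return (1, cs - 1), (ce + 1, ln)

    def pericentromeric(self, chrom: str, margin_bp: int) -> tuple[int, int]:
        cs, ce, ln = self.rows[chrom]
        return max(1, cs - margin_bp), min(ln, ce + margin_bp)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (c, cs, ce, ln)
            for c, (cs, ce, ln) in sorted(
                self.rows.items(), key=lambda kv: chromosome_sort_key(kv[0])
            )
        ]
        return pd.DataFrame(recs, columns=["chromosome", "cen_start_bp", "cen_end_bp", "length_bp"])


def default_genome() -> CentromereTable:
    mb = 1_000_000
    return CentromereTable(
        {c: (cs * mb + 1, ce * mb, ln * mb) for c, (ln, cs, ce) in _DEFAULT_MB.items()}
    )


def read_centromere_table(path) -> CentromereTable:
    """Read a BED-like annotation: chromosome, cen_start_bp, cen_end_bp, length_bp.

    Coordinates in the file are 1-based inclusive (array-manifest convention),
    tab-delimited with a header.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"chromosome", "cen_start_bp", "cen_end_bp", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"centromere table missing columns: {sorted(missing)}")
    return CentromereTable(
        {
            str(r.chromosome): (int(r.cen_start_bp), int(r.cen_end_bp), int(r.length_bp))
            for r in df.itertuples()
        }
    )


def write_centromere_table(table: CentromereTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
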