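"""Reading and writing case tables, ground truth and reports.

The native case table is tab-delimited with a header::

    snp_id  chromosome  position_bp  pat_call  mat_call  mat_log2r
    embryo_call  embryo_baf  embryo_log2r

A ``column_map`` translates exports with other headers (e.g. a genotyping
final report) onto the native names.  Genotype strings are normalized
(``NoCall``/``--``/``NN`` -> ``NC``, ``BA`` -> ``AB``).  Internally all
coordinates are 1-based inclusive; the BED export is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import pandas as pd

from .classify import CaseReport, SegmentCall
from .genome import CHROMOSOMES, chromosome_sort_key

log = logging.getLogger(__name__)

__all__ = [
    "read_case",
    "write_case",
    "write_truth",
    "write_report",
    "to_bed_interval",
    "from_bed_interval",
]

MANDATORY = ("snp_id", "chromosome", "position_bp", "pat_call", "mat_call", "embryo_baf")
OPTIONAL_DEFAULTS = {"mat_log2r": 0.0, "embryo_log2r": np.nan, "embryo_call": "NC"}

_GENO_NORM = {
    "AA": "AA", "AB": "AB", "BA": "AB", "BB": "BB",
    "NC": "NC", "NOCALL": "NC", "NO CALL": "NC", "--": "NC", "NN": "NC",
    "A": "AA", "B": "BB", "A/-": "AA", "B/-": "BB",
}


def _normalize_calls(col: pd.Series) -> pd.Series:
    return col.astype(str).str.strip().str.upper().map(_GENO_NORM).fillna("NC")


def read_case(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load and validate a case table; malformed rows are skipped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"case table missing mandatory column(s): {missing}")
    for col, default in OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default

    n0 = len(df)
    df["chromosome"] = df["chromosome"].astype(str).str.strip().str.replace(
        "^chr", "", regex=True)
    df["position_bp"] = pd.to_numeric(df["position_bp"], errors="coerce")
    for col in ("mat_log2r", "embryo_baf", "embryo_log2r"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("pat_call", "mat_call", "embryo_call"):
        df[col] = _normalize_calls(df[col])

    ok = (
        df["chromosome"].isin(CHROMOSOMES)
        & df["position_bp"].notna() & (df["position_bp"] >= 1)
        & (df["embryo_baf"].isna() | df["embryo_baf"].between(0.0, 1.0))
    )
    if not ok.all():
        for _, row in df.loc[~ok].head(20).iterrows():
            log.warning("skipping malformed row: snp_id=%s chromosome=%s position=%s",
                        row.get("snp_id"), row.get("chromosome"), row.get("position_bp"))
        log.warning("skipped %d malformed row(s) of %d", int((~ok).sum()), n0)
        df = df.loc[ok]
    if len(df) == 0:
        raise ValueError("no valid rows in case table")

    df["position_bp"] = df["position_bp"].astype(np.int64)
    order = df["chromosome"].map(chromosome_sort_key)
    df = df.assign(_ord=order).sort_values(["_ord", "position_bp"], kind="mergesort")
    cols = ["snp_id", "chromosome", "position_bp", "pat_call", "mat_call",
            "mat_log2r", "embryo_call", "embryo_baf", "embryo_log2r"]
    return df[cols].reset_index(drop=True)


def write_case(df: pd.DataFrame, path) -> None:
    cols = ["snp_id", "chromosome", "position_bp", "pat_call", "mat_call",
            "mat_log2r", "embryo_call", "embryo_baf", "embryo_log2r"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_truth(truth, path) -> None:
    """Ground-truth sidecar as JSON (simulator output)."""
    d = dataclasses.asdict(truth)
    d["crossovers"] = {f"{p}:{c}": list(v) for (p, c), v in d["crossovers"].items()}
    d["transmitted_start_hap"] = {f"{p}:{c}": v for (p, c), v
                                  in d["transmitted_start_hap"].items()}
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1, sort_keys=True, default=str)


def to_bed_interval(start_bp: int, end_bp: int) -> tuple[int, int]:
    """Internal 1-based inclusive -> BED 0-based half-open."""
    return start_bp - 1, end_bp


def from_bed_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    return bed_start + 1, bed_end


def _call_row(c: SegmentCall) -> dict:
    return {
        "chromosome": c.chromosome,
        "start_bp": c.start_bp,
        "end_bp": c.end_bp,
        "event": c.event,
        "origin": c.origin,
        "mechanism": c.mechanism,
        "extra_doses": c.extra_doses,
        "cell_fraction": round(c.fraction, 4) if np.isfinite(c.fraction) else "",
        "fraction_ci_low": round(c.mosaic.ci_low, 4) if c.mosaic else "",
        "fraction_ci_high": round(c.mosaic.ci_high, 4) if c.mosaic else "",
        "delta_baf": round(c.delta_baf, 4) if np.isfinite(c.delta_baf) else "",
        "mean_log2r": round(c.mean_log2r, 4) if np.isfinite(c.mean_log2r) else "",
        "bph_pattern": int(c.bph_flag),
        "note": c.note,
    }


def write_report(report: CaseReport, out_dir) -> dict:
    """Write the three report files; returns their paths.

    ``chromosome_calls.tsv`` — one row per segment call (1-based inclusive);
    ``segments.bed`` — abnormal segments, BED 0-based half-open;
    ``summary.json`` — sex, genome-wide verdict, contamination and QC.
    Field order and rounding are fixed so reruns are byte-identical.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [_call_row(c) for chrom in CHROMOSOMES
            for c in report.per_chromosome.get(chrom, [])]
    calls_path = out / "chromosome_calls.tsv"
    pd.DataFrame(rows).to_csv(calls_path, sep="\t", index=False)

    bed_path = out / "segments.bed"
    with open(bed_path, "w") as fh:
        for row in rows:
            if row["event"] in ("disomy", "no_call"):
                continue
            b0, b1 = to_bed_interval(row["start_bp"], row["end_bp"])
            name = f"{row['event']};{row['origin']};{row['mechanism']}"
            frac = row["cell_fraction"]
            score = int(round(1000 * frac)) if frac != "" else 0
            fh.write(f"{row['chromosome']}\t{b0}\t{b1}\t{name}\t{score}\t.\n")

    summary = {
        "sex": report.sex,
        "genome_wide": report.genome_wide,
        "polar_body_signature": bool(report.polar_body_signature),
        "contamination": {
            "fraction_het_band": (round(report.contamination.fraction_het_band, 4)
                                  if np.isfinite(report.contamination.fraction_het_band)
                                  else None),
            "dose_estimate": (round(report.contamination.dose_estimate, 4)
                              if np.isfinite(report.contamination.dose_estimate)
                              else None),
            "n_snps": report.contamination.n_snps,
            "flagged": bool(report.contamination.flagged),
        },
        "qc": {k: (round(v, 6) if isinstance(v, float) else v)
               for k, v in report.qc.items()},
    }
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return {"calls": calls_path, "bed": bed_path, "summary": summary_path}
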