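"""End-to-end case analysis: categorize, call every chromosome, summarize."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .categorize import categorize_frame
from .cbaf import build_tracks
from .classify import (CaseReport, ClassifierConfig, SegmentCall, call_chromosome,
                       call_genome_wide, contamination_qc, infer_sex)
from .genome import CHROMOSOMES, CentromereTable, default_genome

log = logging.getLogger(__name__)

__all__ = ["analyze_case"]


def _y_status_call(df: pd.DataFrame, sex: str) -> SegmentCall:
    y = df[df["chromosome"] == "Y"]
    lo = int(y["position_bp"].min()) if len(y) else 0
    hi = int(y["position_bp"].max()) if len(y) else 0
    if sex == "XY":
        return SegmentCall("Y", lo, hi, "disomy", "paternal", "not_applicable",
                           note="Y present (hemizygous)")
    if sex == "XX":
        return SegmentCall("Y", lo, hi, "no_call", "undetermined", "not_applicable",
                           note="Y absent")
    return SegmentCall("Y", lo, hi, "no_call", "undetermined", "not_applicable",
                       note="Y status undetermined")


def analyze_case(
    df: pd.DataFrame,
    config: ClassifierConfig = ClassifierConfig(),
    centromeres: CentromereTable | None = None,
) -> CaseReport:
    """Full analysis of one trio case table.

    Accepts either a raw case table or one already carrying a
    ``subcategory`` column.  Returns a :class:`~apcad.classify.CaseReport`
    with per-chromosome segment calls, the genome-wide verdict, the
    polar-body contamination signature, contamination QC and noise metrics.
    """
    if centromeres is None:
        centromeres = default_genome()
    if "subcategory" not in df.columns:
        df = categorize_frame(df)

    sex = infer_sex(df, config)
    per_chromosome: dict[str, list[SegmentCall]] = {}
    present = set(df["chromosome"].unique())
    for chrom in CHROMOSOMES:
        if chrom not in present:
            continue
        if chrom == "Y":
            per_chromosome[chrom] = [_y_status_call(df, sex)]
            continue
        per_chromosome[chrom] = call_chromosome(df, chrom, config, centromeres, sex)

    genome_wide, pb_signature = call_genome_wide(df, per_chromosome, config, centromeres)
    contamination = contamination_qc(df, config)

    cat4 = df[df["subcategory"].isin(("4A", "4B")) & df["embryo_baf"].notna()]
    rail_dev = np.where(cat4["subcategory"] == "4A",
                        1.0 - cat4["embryo_baf"], cat4["embryo_baf"])
    qc = {
        "n_snps": int(len(df)),
        "embryo_call_rate": float((df["embryo_call"] != "NC").mean()),
        "cat4_rail_sd": float(np.std(rail_dev)) if len(cat4) else np.nan,
        "subcategory_counts": df["subcategory"].value_counts().to_dict(),
    }
    report = CaseReport(
        sex=sex,
        genome_wide=genome_wide,
        polar_body_signature=pb_signature,
        contamination=contamination,
        per_chromosome=per_chromosome,
        qc=qc,
    )
    log.info("case analyzed: sex=%s genome_wide=%s polar_body=%s",
             sex, genome_wide, pb_signature)
    return report
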