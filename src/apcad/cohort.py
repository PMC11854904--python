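"""Cohort-level summary arithmetic and the bundled validation-cohort tallies.

The package ships the chromosome-level event tallies from the method's
359-embryo clinical validation cohort (benchmarked against a haplotyping
reference) as plain TSV inputs.  The functions here recompute the headline
accuracy figures from those counts: per-chromosome sensitivity and
specificity of detecting meiotic-origin (BPH) copy-number gains and full
copy-number losses > 5 Mb, and the rate of samples with an extra
underrepresented genome-wide haplotype.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_cohort_events",
    "load_cohort_summary",
    "bph_gain_total",
    "full_loss_total",
    "confusion_summary",
    "proportion_percent",
    "reference_confusion",
]


def _data_path(name: str):
    return resources.files("apcad.data").joinpath(name)


def load_cohort_events() -> pd.DataFrame:
    """Per-event-type tallies (maternal/paternal counts and concordance flags)."""
    with resources.as_file(_data_path("cohort_events.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_cohort_summary() -> dict:
    with resources.as_file(_data_path("cohort_summary.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["key"], df["value"].astype(int)))


def bph_gain_total(events: pd.DataFrame) -> int:
    """Total chromosomes with a concordant BPH copy-number gain."""
    rows = events[events["concordant_gain"] == 1]
    return int((rows["n_maternal"] + rows["n_paternal"]).sum())


def full_loss_total(events: pd.DataFrame) -> int:
    """Total chromosomes with a concordant full copy-number loss > 5 Mb."""
    rows = events[events["concordant_loss"] == 1]
    return int((rows["n_maternal"] + rows["n_paternal"]).sum())


def confusion_summary(tp: int, fn: int, tn: int, fp: int) -> dict:
    """Sensitivity/specificity (in percent) from a 2x2 confusion matrix."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be non-negative")
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity_percent": sens,
        "specificity_percent": spec,
    }


def proportion_percent(k: int, n: int) -> float:
    if n <= 0:
        raise ValueError("n must be positive")
    return 100.0 * k / n


def reference_confusion() -> dict:
    """Recompute the cohort confusion matrix from the bundled tallies.

    True positives are the concordant BPH gains plus concordant full losses
    (a chromosome carrying both a gain and a loss contributes to both
    tallies); false positives are the events seen only by this method;
    true/false negatives come from the cohort summary counts.
    """
    events = load_cohort_events()
    summary = load_cohort_summary()
    tp = bph_gain_total(events) + full_loss_total(events)
    fp = int(events["apcad_only"].sum())
    out = confusion_summary(tp, summary["false_negatives"],
                            summary["true_negatives"], fp)
    out["bph_gain_total"] = bph_gain_total(events)
    out["full_loss_total"] = full_loss_total(events)
    out["underrepresented_haplotype_rate_percent"] = proportion_percent(
        summary["embryos_underrepresented_haplotype"],
        summary["samples_screened_for_underrepresentation"],
    )
    return out
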