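"""Run configuration: YAML loading with validation for the classifier and
simulator blocks.  All defaults are overridable; the effective configuration
is echoed to the log on load."""

from __future__ import annotations

import dataclasses
import logging

import yaml

from .classify import ClassifierConfig
from .simulate import Contamination, IbdRegion, KaryotypeEvent, NoiseModel, SimConfig

log = logging.getLogger(__name__)

__all__ = ["load_classifier_config", "load_sim_config", "load_run_config"]


def _build(cls, mapping: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown {name} option(s): {sorted(unknown)}")
    coerced = {}
    for k, v in mapping.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_classifier_config(mapping: dict | None) -> ClassifierConfig:
    return _build(ClassifierConfig, mapping or {}, "classifier")


def load_sim_config(mapping: dict | None) -> SimConfig:
    mapping = dict(mapping or {})
    if "noise" in mapping:
        mapping["noise"] = _build(NoiseModel, mapping["noise"], "noise")
    if "events" in mapping:
        mapping["events"] = tuple(
            _build(KaryotypeEvent, {**e, "chromosome": str(e.get("chromosome", ""))},
                   "event")
            for e in mapping["events"]
        )
    if "contamination" in mapping and mapping["contamination"] is not None:
        mapping["contamination"] = _build(Contamination, mapping["contamination"],
                                          "contamination")
    if "ibd_regions" in mapping:
        mapping["ibd_regions"] = tuple(
            _build(IbdRegion, {**r, "chromosome": str(r.get("chromosome", ""))},
                   "ibd_region")
            for r in mapping["ibd_regions"]
        )
    return _build(SimConfig, mapping, "simulator")


def load_run_config(path) -> tuple[ClassifierConfig, SimConfig]:
    """Read a YAML file with optional ``classifier:`` and ``simulator:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"classifier", "simulator"}
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")
    classifier = load_classifier_config(raw.get("classifier"))
    simulator = load_sim_config(raw.get("simulator"))
    log.info("effective classifier config: %s", dataclasses.asdict(classifier))
    log.info("effective simulator config: %s", dataclasses.asdict(simulator))
    return classifier, simulator
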