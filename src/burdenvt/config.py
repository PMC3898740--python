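"""YAML configuration schema.

One file can hold up to three top-level sections::

    burden:                       # BurdenConfig + QualificationRule fields
      thresholds: [0.005, 0.001, 0.0005]
      model: dominant             # dominant | additive
      n_permutations: 10000
      seed: 0
      control_subset: all         # all | normal_weight
      bmi_cutoff: 30.0
      classes_included: [frameshift, nonsense, missense]
      maf_reference: pooled       # pooled | controls_only
      region: null                # region_name, resolved against the regions file

    plans:                        # optional list of analysis-grid cells
      - {sample: original, control_set: all, region: null, model: dominant}

    sim:                          # SimConfig fields
      n_cases: 2101
      n_controls: 1536
      n_sites: 15
      odds_ratio: 2.0
      seed: 0
      cohort_label: original
      maf_spectrum: {kind: point_mixture,
                     components: [[0.0001, 0.6], [0.0003, 0.3], [0.002, 0.1]]}
      class_probs: {frameshift: 0.08, nonsense: 0.07, missense: 0.65,
                    synonymous: 0.20}

Unknown keys raise :class:`ConfigError` naming the key.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Any, Optional

import yaml

from .burden import AnalysisPlan, BurdenConfig, ControlSubset, GeneticModel
from .errors import ConfigError
from .filters import MafReference, QualificationRule
from .model import FuncClass, RegionAnnotation
from .simulate import FixedMaf, PointMixtureMaf, SimConfig, UniformMaf


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from None
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    return doc


def _reject_unknown(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")


_BURDEN_KEYS = {
    "thresholds", "model", "n_permutations", "seed", "control_subset",
    "bmi_cutoff", "classes_included", "maf_reference", "region",
}


def burden_config_from_dict(
    data: Optional[dict],
    regions: Optional[dict[str, RegionAnnotation]] = None,
) -> BurdenConfig:
    data = dict(data or {})
    _reject_unknown("burden", data, _BURDEN_KEYS)
    region_name = data.pop("region", None)
    region = None
    if region_name:
        regions = regions or {}
        if region_name not in regions:
            raise ConfigError(
                f"burden.region names unknown region {region_name!r}; "
                "provide a regions file defining it"
            )
        region = regions[region_name]
    rule_kwargs: dict[str, Any] = {"region": region}
    if "classes_included" in data:
        try:
            rule_kwargs["classes_included"] = frozenset(
                FuncClass(c) for c in data.pop("classes_included")
            )
        except ValueError as exc:
            raise ConfigError(f"burden.classes_included: {exc}") from None
    if "maf_reference" in data:
        try:
            rule_kwargs["maf_reference"] = MafReference(data.pop("maf_reference"))
        except ValueError as exc:
            raise ConfigError(f"burden.maf_reference: {exc}") from None
    try:
        rule = QualificationRule(**rule_kwargs)
        return BurdenConfig(rule_template=rule, **data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"burden section: {exc}") from None


_PLAN_KEYS = {"sample", "control_set", "region", "model"}


def plans_from_list(
    data: Optional[list],
    burden: BurdenConfig,
) -> list[AnalysisPlan]:
    if not data:
        return [
            AnalysisPlan(
                model=burden.model, control_set=burden.control_subset, burden=burden
            )
        ]
    plans = []
    for i, cell in enumerate(data):
        if not isinstance(cell, dict):
            raise ConfigError(f"plans[{i}] must be a mapping")
        _reject_unknown(f"plans[{i}]", cell, _PLAN_KEYS)
        try:
            plans.append(
                AnalysisPlan(
                    sample=cell.get("sample", "original"),
                    control_set=ControlSubset(cell.get("control_set", "all")),
                    region=cell.get("region"),
                    model=GeneticModel(cell.get("model", burden.model)),
                    burden=burden,
                )
            )
        except ValueError as exc:
            raise ConfigError(f"plans[{i}]: {exc}") from None
    return plans


_SIM_KEYS = {
    "n_cases", "n_controls", "n_sites", "odds_ratio", "seed", "cohort_label",
    "maf_spectrum", "class_probs",
}


def _spectrum_from_dict(data: dict):
    kind = data.get("kind")
    if kind == "fixed":
        return FixedMaf(float(data["value"]))
    if kind == "uniform":
        return UniformMaf(float(data["lo"]), float(data["hi"]))
    if kind == "point_mixture":
        return PointMixtureMaf(
            tuple((float(m), float(w)) for m, w in data["components"])
        )
    raise ConfigError(
        f"sim.maf_spectrum.kind must be fixed|uniform|point_mixture, got {kind!r}"
    )


def sim_config_from_dict(data: Optional[dict]) -> SimConfig:
    data = dict(data or {})
    _reject_unknown("sim", data, _SIM_KEYS)
    kwargs: dict[str, Any] = {}
    if "maf_spectrum" in data:
        spec = data.pop("maf_spectrum")
        if not isinstance(spec, dict):
            raise ConfigError("sim.maf_spectrum must be a mapping with a 'kind'")
        try:
            kwargs["maf_spectrum"] = _spectrum_from_dict(spec)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"sim.maf_spectrum: {exc}") from None
    if "class_probs" in data:
        try:
            kwargs["class_probs"] = {
                FuncClass(k): float(v) for k, v in data.pop("class_probs").items()
            }
        except (ValueError, AttributeError) as exc:
            raise ConfigError(f"sim.class_probs: {exc}") from None
    try:
        return SimConfig(**kwargs, **data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"sim section: {exc}") from None


def apply_overrides(config: BurdenConfig, **overrides: Any) -> BurdenConfig:
    """Apply non-None CLI flag overrides onto a loaded BurdenConfig."""
    updates = {k: v for k, v in overrides.items() if v is not None}
    if not updates:
        return config
    rule = config.rule_template
    if "maf_reference" in updates:
        rule = replace(rule, maf_reference=MafReference(updates.pop("maf_reference")))
    try:
        return replace(config, rule_template=rule, **updates)
    except ValueError as exc:
        raise ConfigError(str(exc)) from None
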