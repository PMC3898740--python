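"""Serialization of burden results with provenance.

JSON carries full precision plus provenance (schema version, package
version, resolved config, seed, input digests); the flat TSV rounds
p-values to 4 significant figures and carrier percentages to one decimal,
the precision at which such results are conventionally printed.  Raw
fractions always remain available in the JSON.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Optional

from . import __version__
from .burden import BurdenResult, GeneticModel

REPORT_SCHEMA_VERSION = "1.0"


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, enum.Enum):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(_jsonable(k)): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        out = [_jsonable(v) for v in obj]
        return sorted(out) if isinstance(obj, (set, frozenset)) else out
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def input_digests(paths: Mapping[str, Optional[str]]) -> dict[str, Optional[str]]:
    out: dict[str, Optional[str]] = {}
    for name, p in paths.items():
        if p is None:
            out[name] = None
            continue
        p = Path(p)
        if p.is_dir():
            parts = sorted(f for f in p.iterdir() if f.is_file())
            out[name] = hashlib.sha256(
                b"".join(file_digest(f).encode() for f in parts)
            ).hexdigest()
        else:
            out[name] = file_digest(p)
    return out


def carrier_percentages(result: BurdenResult, model: GeneticModel) -> dict[str, float]:
    """Case/control carrier percentages at the widest threshold (one decimal),
    with the raw fractions.  Under the additive model the 'units' are alleles,
    so the percentage is an allele frequency x 100."""
    table = result.per_threshold[0].table
    case_frac = table.a / table.case_units if table.case_units else 0.0
    ctrl_frac = table.c / table.control_units if table.control_units else 0.0
    return {
        "case_carrier_fraction": case_frac,
        "control_carrier_fraction": ctrl_frac,
        "case_carrier_pct": round(100.0 * case_frac, 1),
        "control_carrier_pct": round(100.0 * ctrl_frac, 1),
    }


def build_report(
    results: Mapping[str, BurdenResult],
    config: Any,
    seed: Optional[int],
    inputs: Optional[Mapping[str, Optional[str]]] = None,
) -> dict:
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package": "burdenvt",
        "version": __version__,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": _jsonable(config),
        "input_digests": input_digests(inputs) if inputs else {},
        "results": {},
    }
    for key, result in results.items():
        model = GeneticModel(key.rsplit("/", 1)[-1]) if "/" in key else GeneticModel.DOMINANT
        entry = result.to_dict()
        entry.update(carrier_percentages(result, model))
        report["results"][key] = entry
    return report


def write_report_json(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path


def _sig4(p: float) -> str:
    return f"{p:.4g}"


def write_report_tsv(results: Mapping[str, BurdenResult], path) -> Path:
    """One row per (plan cell, threshold): counts, table, p-values."""
    path = Path(path)
    header = [
        "plan", "threshold", "n_qualifying", "a", "b", "c", "d",
        "case_carrier_pct", "control_carrier_pct",
        "fisher_p", "min_p", "min_p_threshold", "adjusted_p",
    ]
    lines = ["\t".join(header)]
    for key, result in sorted(results.items()):
        for row in result.per_threshold:
            t = row.table
            case_pct = round(100.0 * t.a / t.case_units, 1) if t.case_units else 0.0
            ctrl_pct = round(100.0 * t.c / t.control_units, 1) if t.control_units else 0.0
            adj = _sig4(result.adjusted_p) if result.adjusted_p is not None else "NA"
            lines.append(
                "\t".join(
                    (
                        key, f"{row.threshold:g}", str(row.n_qualifying),
                        str(t.a), str(t.b), str(t.c), str(t.d),
                        f"{case_pct:.1f}", f"{ctrl_pct:.1f}",
                        _sig4(row.fisher_p), _sig4(result.min_p),
                        f"{result.min_p_threshold:g}", adj,
                    )
                )
            )
    path.write_text("\n".join(lines) + "\n")
    return path
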