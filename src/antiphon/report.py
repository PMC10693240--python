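"""Analysis-report assembly and schema validation.

The report is a single JSON document tying every reported statistic back to
the stage outputs it came from: input digests, stage row counts, the fitted
GLMs, the randomization block, warnings, seeds and the tool version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .model import PlaybackExchangeResults

__all__ = ["assemble_report", "validate_report", "write_report", "file_digest"]

#: top-level keys every report must carry
REPORT_REQUIRED_KEYS = (
    "tool",
    "version",
    "seed",
    "inputs",
    "stages",
    "models",
    "warnings",
)


def file_digest(path: str | Path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


def assemble_report(
    results: PlaybackExchangeResults, inputs: dict[str, str] | None = None
) -> dict:
    """Build the JSON-serializable analysis report from fitted results."""
    models = {}
    for name, res in (
        ("latency_phase", results.latency_phase_model),
        ("counter_call", results.counter_call_model),
        ("match", results.match_model),
        ("discrepancy", results.discrepancy_model),
        ("amplitude", results.amplitude_model),
    ):
        models[name] = res.to_dict() if res is not None else None
    if results.randomization is not None:
        models["randomization"] = results.randomization.to_dict()

    stages = {
        "latency_records": len(results.latency_data),
        "counter_calls": int(results.latency_data["is_counter_call"].fillna(False).sum()),
        "pairs_et": len(results.pairs_et),
        "pairs_te": len(results.pairs_te),
        "match_counts": (
            results.match_counts.to_dict(orient="records")
            if results.match_counts is not None
            else []
        ),
    }
    report = {
        "tool": "antiphon",
        "version": __version__,
        "seed": results.seed,
        "inputs": inputs or {},
        "stages": stages,
        "models": models,
        "warnings": list(results.warnings),
    }
    validate_report(report)
    return report


def validate_report(report: dict) -> None:
    """Structural schema check; raises ValueError on a malformed report."""
    for key in REPORT_REQUIRED_KEYS:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    if not isinstance(report["stages"], dict) or not isinstance(report["models"], dict):
        raise ValueError("report stages/models must be objects")
    for req in ("latency_records", "pairs_et", "pairs_te"):
        if req not in report["stages"]:
            raise ValueError(f"report stages missing {req!r}")
    json.dumps(report)  # must be serializable


def write_report(report: dict, path: str | Path) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
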