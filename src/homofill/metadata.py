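"""JSON provenance metadata for filled models.

One metadata document per filled model: the query id, a timestamp, the
configuration echo, and one record per transplant in placement order with
provenance (donor entry/chain/copy, E-value, identity) and quality scores
(global/local r.m.s.d., TCS, confidence labels).

A JSON-schema description of the format ships with the package
(``data/metadata.schema.json``); :func:`validate_metadata` enforces the same
constraints with a small built-in structural checker.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .engine import FillConfig, FillResult, TransplantRecord

__all__ = [
    "FillMetadata",
    "MetadataError",
    "build_metadata",
    "write_metadata",
    "read_metadata",
    "validate_metadata",
    "filter_by_identity",
    "default_identity_cutoff",
    "STANDARD_IDENTITY_LEVELS",
]

STANDARD_IDENTITY_LEVELS = (0.70, 0.60, 0.50, 0.40, 0.30, 0.25)


class MetadataError(ValueError):
    """Metadata document violates the shipped schema."""


@dataclass
class FillMetadata:
    model_id: str
    timestamp: str
    config: dict
    transplants: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _record_dict(rec: TransplantRecord) -> dict:
    return {
        "compound": rec.comp_id,
        "original_compound": rec.original_comp_id,
        "donor_entry": rec.donor_entry,
        "donor_chain": rec.donor_chain,
        "donor_copy": rec.donor_copy,
        "evalue": rec.evalue,
        "identity_fraction": round(rec.identity_fraction, 6),
        "alignment_length": rec.alignment_length,
        "global_rmsd": round(rec.global_rmsd, 4),
        "local_rmsd": round(rec.local_rmsd, 4),
        "tcs": round(rec.tcs, 4),
        "confidence_local": rec.confidence_local,
        "confidence_tcs": rec.confidence_tcs,
        "placed_chain": rec.placed_chain_id,
        "mono_atomic": rec.mono_atomic,
    }


def build_metadata(
    result: FillResult, config: FillConfig, timestamp: str = "1970-01-01T00:00:00Z"
) -> FillMetadata:
    """Assemble the metadata document; transplant order equals placement order.

    ``timestamp`` is caller-supplied so that repeat runs on identical inputs
    can produce byte-identical documents.
    """
    cfg = dataclasses.asdict(config)
    cfg["thresholds"] = dataclasses.asdict(config.thresholds)
    return FillMetadata(
        model_id=result.model.entry_id,
        timestamp=timestamp,
        config=cfg,
        transplants=[_record_dict(r) for r in result.transplants],
    )


def write_metadata(meta: FillMetadata, path: str | Path) -> None:
    Path(path).write_text(json.dumps(meta.to_dict(), indent=1, sort_keys=True) + "\n")


def read_metadata(path: str | Path) -> FillMetadata:
    data = json.loads(Path(path).read_text())
    validate_metadata(data)
    return FillMetadata(**data)


_RECORD_FIELDS: dict[str, type | tuple[type, ...]] = {
    "compound": str, "original_compound": str, "donor_entry": str,
    "donor_chain": str, "donor_copy": int, "evalue": (int, float),
    "identity_fraction": (int, float), "alignment_length": int,
    "global_rmsd": (int, float), "local_rmsd": (int, float),
    "tcs": (int, float), "confidence_local": str, "confidence_tcs": str,
    "placed_chain": str, "mono_atomic": bool,
}


def schema() -> dict:
    return json.loads(resources.files("homofill.data").joinpath("metadata.schema.json").read_text())


def validate_metadata(data: dict) -> None:
    """Structural validation mirroring the shipped JSON schema."""
    for key, typ in (("model_id", str), ("timestamp", str), ("config", dict), ("transplants", list)):
        if key not in data:
            raise MetadataError(f"missing required field {key!r}")
        if not isinstance(data[key], typ):
            raise MetadataError(f"field {key!r} must be {typ.__name__}")
    for i, rec in enumerate(data["transplants"]):
        if not isinstance(rec, dict):
            raise MetadataError(f"transplant {i} is not an object")
        for key, typ in _RECORD_FIELDS.items():
            if key not in rec:
                raise MetadataError(f"transplant {i}: missing field {key!r}")
            value = rec[key]
            if isinstance(value, bool) and typ is not bool:
                raise MetadataError(f"transplant {i}: field {key!r} has wrong type")
            if not isinstance(value, typ):
                raise MetadataError(f"transplant {i}: field {key!r} has wrong type")
        for key in ("confidence_local", "confidence_tcs"):
            if rec[key] not in ("high", "medium", "low"):
                raise MetadataError(f"transplant {i}: {key} must be high/medium/low")
        if not (0.0 <= rec["identity_fraction"] <= 1.0):
            raise MetadataError(f"transplant {i}: identity_fraction outside [0, 1]")


def filter_by_identity(meta: FillMetadata, cutoff: float) -> FillMetadata:
    """View retaining transplants with identity_fraction >= cutoff."""
    return FillMetadata(
        model_id=meta.model_id,
        timestamp=meta.timestamp,
        config=meta.config,
        transplants=[t for t in meta.transplants if t["identity_fraction"] >= cutoff],
    )


def default_identity_cutoff(meta: FillMetadata) -> float:
    """Highest standard identity level that still leaves >= 1 transplant
    (0 when the transplant list is empty)."""
    for level in STANDARD_IDENTITY_LEVELS:
        if any(t["identity_fraction"] >= level for t in meta.transplants):
            return level
    return 0.0
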