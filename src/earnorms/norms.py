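"""Published EAR norms as a versioned, checksummed resource.

The package ships the published adjustment constants and Equivalent Score
thresholds for both indices as a JSON resource.  The loader verifies a
SHA-256 checksum over the canonical payload so that a silently edited
norms file cannot masquerade as the published version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .adjustment import AdjustmentModel
from .limits import EquivalentScoreBands

__all__ = [
    "PublishedNorms",
    "NormsIntegrityError",
    "load_published_norms",
    "canonical_checksum",
    "write_norms",
]

_DEFAULT_RESOURCE = "ear_norms_v1.json"


class NormsIntegrityError(ValueError):
    """Norms file checksum does not match its payload."""


@dataclass(frozen=True)
class PublishedNorms:
    version: str
    citation: str
    er_model: AdjustmentModel
    ea_model: AdjustmentModel
    er_bands: EquivalentScoreBands
    ea_bands: EquivalentScoreBands
    er_itl: float
    ea_itl: float
    n: int

    def model(self, index_name: str) -> AdjustmentModel:
        return {"ER": self.er_model, "EA": self.ea_model}[index_name]

    def bands(self, index_name: str) -> EquivalentScoreBands:
        return {"ER": self.er_bands, "EA": self.ea_bands}[index_name]


def canonical_checksum(norms_payload: dict) -> str:
    canon = json.dumps(norms_payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def _parse(payload: dict) -> PublishedNorms:
    if payload.get("checksum") != canonical_checksum(payload["norms"]):
        raise NormsIntegrityError(
            "norms payload does not match its checksum; the file was edited "
            "or corrupted"
        )
    norms = payload["norms"]

    def _model(key: str) -> AdjustmentModel:
        m = norms[key]["adjustment"]
        return AdjustmentModel(
            index_name=key,
            beta_age2=m["beta_age2"],
            centering_c=m["centering_c"],
            sex_offset=m["sex_offset"],
            validity_age_range=tuple(norms[key]["validity_age_range"]),
        )

    def _bands(key: str) -> EquivalentScoreBands:
        return EquivalentScoreBands(
            thresholds=tuple(norms[key]["es_thresholds"]), method="published"
        )

    return PublishedNorms(
        version=payload["version"],
        citation=payload["citation"],
        er_model=_model("ER"),
        ea_model=_model("EA"),
        er_bands=_bands("ER"),
        ea_bands=_bands("EA"),
        er_itl=norms["ER"]["iTL"],
        ea_itl=norms["EA"]["iTL"],
        n=norms["n"],
    )


def load_published_norms(path: str | Path | None = None) -> PublishedNorms:
    """Load the shipped published norms, or a user-supplied norms JSON."""
    if path is None:
        text = (
            resources.files("earnorms").joinpath("data", _DEFAULT_RESOURCE)
        ).read_text()
    else:
        text = Path(path).read_text()
    return _parse(json.loads(text))


def write_norms(payload_norms: dict, version: str, citation: str,
                path: str | Path) -> None:
    """Write a norms JSON with its canonical checksum."""
    payload = {
        "version": version,
        "citation": citation,
        "norms": payload_norms,
        "checksum": canonical_checksum(payload_norms),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
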