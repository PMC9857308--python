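"""Channel montage and region schemes.

Two aggregation schemes are shipped for the default 62-channel 10-10
layout:

* ``regions5`` — frontal (F), left temporal (LT), parietal (P), right
  temporal (RT), occipital (O); used for within-region functional
  connectivity.
* ``regions8`` — lateralized frontal/temporal/parietal/occipital regions
  (LF, RF, LT, RT, LP, RP, LO, RO) with the four homologous
  cross-hemisphere pairs; used for transhemispheric functional
  connectivity and for the region-averaged signals that feed the MVAR /
  DTF stage.

The shipped channel→region assignment is a documented best-effort 10-10
layout; supply your own JSON scheme file to override it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "RegionScheme",
    "STANDARD_62_CHANNELS",
    "load_region_scheme",
    "region_scheme_from_dict",
    "region_scheme_to_dict",
    "save_region_scheme",
    "default_scheme",
]

#: The 62-channel 10-10 montage used by default (61 standard 10-10 sites
#: plus Iz).
STANDARD_62_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

_VALID_KINDS = ("within", "transhemispheric")


@dataclass(frozen=True)
class RegionScheme:
    """A named mapping of channels to brain regions.

    Parameters
    ----------
    name : str
        Scheme identifier.
    kind : {"within", "transhemispheric"}
        Whether the scheme is meant for within-region aggregation or for
        cross-hemisphere (region-pair) analyses.
    regions : mapping of str to tuple of str
        Ordered region label → channel labels.  Every channel belongs to
        at most one region; channels absent from all regions are simply
        excluded from aggregation.
    pairs : tuple of (str, str)
        Homologous cross-hemisphere region pairs (transhemispheric
        schemes only).
    """

    name: str
    kind: str
    regions: Mapping[str, tuple[str, ...]]
    pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}; expected one of {_VALID_KINDS}")
        if not self.regions:
            raise ValueError("region scheme has no regions")
        object.__setattr__(
            self, "regions",
            {str(r): tuple(chs) for r, chs in self.regions.items()},
        )
        seen: dict[str, str] = {}
        for region, channels in self.regions.items():
            if not channels:
                raise ValueError(f"region {region!r} has no channels")
            for ch in channels:
                if ch in seen:
                    raise ValueError(
                        f"channel {ch!r} assigned to both {seen[ch]!r} and {region!r}"
                    )
                seen[ch] = region
        object.__setattr__(self, "pairs", tuple((str(a), str(b)) for a, b in self.pairs))
        for a, b in self.pairs:
            for lab in (a, b):
                if lab not in self.regions:
                    raise ValueError(f"pair references unknown region {lab!r}")

    @property
    def region_labels(self) -> tuple[str, ...]:
        return tuple(self.regions)

    @property
    def channels(self) -> tuple[str, ...]:
        """All assigned channels, in region order."""
        return tuple(ch for chs in self.regions.values() for ch in chs)

    def channels_of(self, region: str) -> tuple[str, ...]:
        try:
            return self.regions[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r} in scheme {self.name!r}") from None


def region_scheme_from_dict(doc: Mapping) -> RegionScheme:
    """Validate and build a :class:`RegionScheme` from a parsed JSON document."""
    for key in ("name", "kind", "regions"):
        if key not in doc:
            raise ValueError(f"region scheme document missing required field {key!r}")
    regions: dict[str, tuple[str, ...]] = {}
    for entry in doc["regions"]:
        if "label" not in entry or "channels" not in entry:
            raise ValueError("each region entry needs 'label' and 'channels'")
        label = str(entry["label"])
        if label in regions:
            raise ValueError(f"duplicate region label {label!r}")
        regions[label] = tuple(str(c) for c in entry["channels"])
    pairs = tuple((str(a), str(b)) for a, b in doc.get("pairs", []))
    return RegionScheme(name=str(doc["name"]), kind=str(doc["kind"]),
                        regions=regions, pairs=pairs)


def region_scheme_to_dict(scheme: RegionScheme) -> dict:
    """Serialize a scheme to the JSON document layout (round-trips)."""
    doc: dict = {
        "name": scheme.name,
        "kind": scheme.kind,
        "regions": [{"label": r, "channels": list(chs)}
                    for r, chs in scheme.regions.items()],
    }
    if scheme.pairs:
        doc["pairs"] = [list(p) for p in scheme.pairs]
    return doc


def save_region_scheme(scheme: RegionScheme, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(region_scheme_to_dict(scheme), fh, indent=1)


def load_region_scheme(path: str | Path) -> RegionScheme:
    """Load and validate a region scheme from a JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"invalid region scheme JSON in {path}: {exc}") from exc
    return region_scheme_from_dict(doc)


def default_scheme(name: str) -> RegionScheme:
    """Return a shipped scheme: ``"regions5"`` or ``"regions8"``."""
    if name not in ("regions5", "regions8"):
        raise KeyError(f"no shipped scheme named {name!r}")
    ref = resources.files("eegconn.data").joinpath(f"{name}.json")
    return region_scheme_from_dict(json.loads(ref.read_text(encoding="utf-8")))
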