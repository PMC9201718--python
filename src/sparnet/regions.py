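"""Brain-region channel maps and region-wise slicing of feature tensors.

Five scalp regions are used throughout: central (C), frontal (F), occipital
(O), parietal (P) and temporal (T), each an ordered list of 128-channel
geodesic-net labels (E1..E128).  Two shipped variants exist: ``initial``
(12 channels per region) and ``final`` (frontal expanded to 25 channels,
73 channels in total).  Channels are always addressed by montage name, never
by storage index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .spectra import SpectralFeatures

__all__ = ["REGION_ORDER", "RegionMap", "load_region_map", "slice_by_region"]

REGION_ORDER = ("C", "F", "O", "P", "T")
MONTAGE = frozenset(f"E{i}" for i in range(1, 129))

EXPECTED_COUNTS = {
    "initial": {r: 12 for r in REGION_ORDER},
    "final": {"C": 12, "F": 25, "O": 12, "P": 12, "T": 12},
}


class RegionMapError(ValueError):
    """Raised when a region configuration violates the map invariants."""


@dataclass(frozen=True)
class RegionMap:
    """Validated mapping region name -> ordered channel list."""

    variant: str
    regions: dict
    substitutions: tuple = ()

    @property
    def all_channels(self) -> list:
        return [ch for r in REGION_ORDER for ch in self.regions[r]]

    @property
    def n_channels(self) -> int:
        return len(self.all_channels)

    def counts(self) -> dict:
        return {r: len(self.regions[r]) for r in REGION_ORDER}


def _validate(variant: str, regions: dict) -> None:
    problems = []
    missing = [r for r in REGION_ORDER if r not in regions]
    if missing:
        raise RegionMapError(f"missing regions: {missing}")
    seen: dict[str, str] = {}
    for r in REGION_ORDER:
        for ch in regions[r]:
            if ch not in MONTAGE:
                problems.append(f"unknown montage label {ch!r} in region {r}")
            if ch in seen:
                problems.append(f"channel {ch} appears in both {seen[ch]} and {r}")
            else:
                seen[ch] = r
    if variant in EXPECTED_COUNTS:
        for r, want in EXPECTED_COUNTS[variant].items():
            got = len(regions[r])
            if got != want:
                problems.append(
                    f"region {r} has {got} channels, variant {variant!r} requires {want}"
                )
    if problems:
        raise RegionMapError("; ".join(problems))


def load_region_map(source: str | Path = "final") -> RegionMap:
    """Load and validate a region map.

    ``source`` is either a shipped variant name (``"initial"`` / ``"final"``)
    or a path to a JSON config with the same schema.
    """
    if source in ("initial", "final"):
        cfg = json.loads(
            resources.files("sparnet.data")
            .joinpath(f"regions_{source}.json")
            .read_text()
        )
    else:
        path = Path(source)
        cfg = json.loads(path.read_text())
    variant = cfg.get("variant", "custom")
    regions = {r: list(chs) for r, chs in cfg["regions"].items()}
    _validate(variant, regions)
    return RegionMap(
        variant=variant,
        regions=regions,
        substitutions=tuple(
            tuple(sorted(s.items())) if isinstance(s, dict) else s
            for s in cfg.get("substitutions", [])
        ),
    )


def slice_by_region(sf: SpectralFeatures, rm: RegionMap) -> list[np.ndarray]:
    """Slice a feature tensor into the five region tensors, in canonical order.

    Channel lookup is by name, so the result is independent of how the
    feature tensor stores its channels; channels outside the map are dropped.
    """
    index = {name: i for i, name in enumerate(sf.channel_names)}
    out = []
    for r in REGION_ORDER:
        missing = [ch for ch in rm.regions[r] if ch not in index]
        if missing:
            raise KeyError(
                f"region {r} channels missing from features: {missing}"
            )
        rows = [index[ch] for ch in rm.regions[r]]
        out.append(np.ascontiguousarray(sf.amplitudes[:, rows, :]))
    return out
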