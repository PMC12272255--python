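"""Region tables for lateralized brain atlases.

The package ships a 95-region atlas of lateralized visuospatial-attention
areas (66 right-hemisphere, 29 left-hemisphere), each carrying its anatomical
name, hemisphere, intrinsic-network assignment, and MNI center-of-mass
coordinates in millimetres.  Region tables are plain tab-separated files so
that they can be diffed, versioned and edited by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "NETWORKS",
    "HEMISPHERES",
    "AtlasRegion",
    "RegionSet",
    "load_region_table",
    "write_region_table",
    "load_packaged_atlas",
    "summarize_region_set",
]

#: The five intrinsic networks of the packaged atlas.
NETWORKS = (
    "Visu",
    "Somato-motor",
    "Posterior-medial",
    "Temporo-frontal",
    "Parieto-frontal",
)

HEMISPHERES = ("Left", "Right")

#: Token written for an unassigned network in the TSV dialect.
NA_TOKEN = "NA"

_COLUMNS = ["network", "abbreviation", "region", "hemisphere", "x", "y", "z"]


@dataclass(frozen=True)
class AtlasRegion:
    """One atlas region: a functionally defined area in one hemisphere."""

    abbreviation: str
    full_name: str
    hemisphere: str
    network: str | None
    mni_x: int
    mni_y: int
    mni_z: int

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"unknown hemisphere {self.hemisphere!r} for region "
                f"{self.abbreviation!r}; expected one of {HEMISPHERES}"
            )
        if self.network is not None and self.network not in NETWORKS:
            raise ValueError(
                f"unknown network label {self.network!r} for region "
                f"{self.abbreviation!r}; expected one of {NETWORKS} or None"
            )


@dataclass(frozen=True)
class RegionSet:
    """An ordered collection of atlas regions.

    ``(abbreviation, hemisphere)`` must be unique within the set.
    """

    regions: tuple[AtlasRegion, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("no regions: a RegionSet cannot be empty")
        keys = [(r.abbreviation, r.hemisphere) for r in self.regions]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, str]] = set()
            dupes = sorted({k for k in keys if k in seen or seen.add(k)})
            raise ValueError(f"duplicate (abbreviation, hemisphere): {dupes}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[AtlasRegion]:
        return iter(self.regions)

    @property
    def abbreviations(self) -> tuple[str, ...]:
        return tuple(r.abbreviation for r in self.regions)

    def filter_network(self, network: str) -> "RegionSet":
        """Sub-set to the regions assigned to ``network``."""
        kept = tuple(r for r in self.regions if r.network == network)
        if not kept:
            raise ValueError(f"no regions in network {network!r}")
        return RegionSet(kept, provenance=f"{self.provenance} [network={network}]")

    def network_members(self) -> dict[str, tuple[str, ...]]:
        """Mapping network -> member abbreviations, in table order."""
        out: dict[str, list[str]] = {}
        for r in self.regions:
            if r.network is not None:
                out.setdefault(r.network, []).append(r.abbreviation)
        return {k: tuple(v) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "network": [r.network if r.network is not None else NA_TOKEN for r in self.regions],
                "abbreviation": [r.abbreviation for r in self.regions],
                "region": [r.full_name for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "x": [r.mni_x for r in self.regions],
                "y": [r.mni_y for r in self.regions],
                "z": [r.mni_z for r in self.regions],
            }
        )


def _regions_from_frame(df: pd.DataFrame, provenance: str) -> RegionSet:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region table is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("no regions: region table has no data rows")
    regions = []
    for row in df.itertuples(index=False):
        network = None if str(row.network) == NA_TOKEN else str(row.network)
        try:
            x, y, z = int(row.x), int(row.y), int(row.z)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"non-numeric MNI coordinates for region {row.abbreviation!r}"
            ) from exc
        regions.append(
            AtlasRegion(
                abbreviation=str(row.abbreviation),
                full_name=str(row.region),
                hemisphere=str(row.hemisphere),
                network=network,
                mni_x=x,
                mni_y=y,
                mni_z=z,
            )
        )
    return RegionSet(tuple(regions), provenance=provenance)


def load_region_table(path: str | Path) -> RegionSet:
    """Read a region table from a tab-separated file.

    The table must have a single header row with columns
    ``network, abbreviation, region, hemisphere, x, y, z``; row order is
    preserved.  ``NA`` in the network column means unassigned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _regions_from_frame(df, provenance=str(path))


def write_region_table(region_set: RegionSet, path: str | Path) -> None:
    """Write a region table as TSV; ``load_region_table`` round-trips it."""
    region_set.to_frame().to_csv(path, sep="\t", index=False)


def load_packaged_atlas() -> RegionSet:
    """The packaged 95-region lateralized visuospatial-attention atlas."""
    with resources.as_file(
        resources.files("alans").joinpath("data/alans_regions.tsv")
    ) as p:
        rs = load_region_table(p)
    return replace(rs, provenance="packaged ALANs region table")


def summarize_region_set(region_set: RegionSet) -> dict[str, dict[str, int]]:
    """Counts by hemisphere and by network; each group sums to the total."""
    by_hemi: dict[str, int] = {}
    by_net: dict[str, int] = {}
    for r in region_set:
        by_hemi[r.hemisphere] = by_hemi.get(r.hemisphere, 0) + 1
        key = r.network if r.network is not None else NA_TOKEN
        by_net[key] = by_net.get(key, 0) + 1
    return {"total": {"regions": len(region_set)}, "hemisphere": by_hemi, "network": by_net}
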