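"""Synthetic occurrence-set generator for tests and demonstrations.

Emulates the point patterns a conservation assessor actually meets:
either records scattered uniformly over a lat/lon box, or a few Gaussian
clusters of collections around population centres (herbarium data is
strongly clustered around localities).  Optional defect injection —
swapped lat/lon pairs, missing coordinates, exact duplicates — produces
the georeferencing mistakes the validator is built to catch, at stated
rates.  Everything is driven by a seeded generator, so a fixture is fully
reproducible from (n, pattern, extent, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .occurrences import Occurrence, OccurrenceSet

#: default geographic window: a 2x2 degree box in the tropics, the scale of
#: a narrowly distributed species for which criterion B is relevant
DEFAULT_EXTENT = (-1.0, 30.0, 1.0, 32.0)  # (min_lat, min_lon, max_lat, max_lon)


@dataclass(frozen=True)
class DefectRates:
    """Fraction of records given each injected georeferencing defect."""

    swap: float = 0.0        # lat/lon transposed
    missing: float = 0.0     # coordinates blanked
    duplicate: float = 0.0   # exact copy of an earlier record


def generate_fixture(n: int, pattern: str = "gaussian_clusters",
                     extent: tuple = DEFAULT_EXTENT, seed: int = 0,
                     n_clusters: int = 3, cluster_sd_deg: float = 0.05,
                     defects: DefectRates = DefectRates(),
                     taxon_name: str = "Synthetica exemplaris") -> OccurrenceSet:
    """Generate a reproducible synthetic occurrence set.

    ``uniform_box`` draws points uniformly over the extent;
    ``gaussian_clusters`` draws cluster centres uniformly, then points
    normally around them with ``cluster_sd_deg`` spread (clipped to valid
    coordinates).  Defect counts are binomial draws at the stated rates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if pattern not in ("uniform_box", "gaussian_clusters"):
        raise ValueError(f"unknown pattern {pattern!r}")
    min_lat, min_lon, max_lat, max_lon = extent
    rng = np.random.default_rng(seed)

    if pattern == "uniform_box":
        lats = rng.uniform(min_lat, max_lat, n)
        lons = rng.uniform(min_lon, max_lon, n)
    else:
        centres_lat = rng.uniform(min_lat, max_lat, n_clusters)
        centres_lon = rng.uniform(min_lon, max_lon, n_clusters)
        which = rng.integers(0, n_clusters, n)
        lats = np.clip(centres_lat[which] + rng.normal(0, cluster_sd_deg, n), -90, 90)
        lons = np.clip(centres_lon[which] + rng.normal(0, cluster_sd_deg, n), -180, 180)

    occurrences = []
    for i in range(n):
        occurrences.append(Occurrence(
            id=f"syn-{i + 1}", lat=round(float(lats[i]), 6), lon=round(float(lons[i]), 6),
            source="csv",
            coordinate_uncertainty_m=float(rng.choice([100.0, 1000.0, 5000.0])),
            metadata={"collector": f"Collector {int(rng.integers(1, 6))}"},
        ))

    # defect injection, each on an independent seeded subset
    idx = np.arange(n)
    if defects.swap > 0:
        for i in idx[rng.random(n) < defects.swap]:
            o = occurrences[i]
            o.lat, o.lon = o.lon, o.lat
    if defects.missing > 0:
        for i in idx[rng.random(n) < defects.missing]:
            occurrences[i].lat = float("nan")
            occurrences[i].lon = float("nan")
    if defects.duplicate > 0 and n > 1:
        for i in idx[rng.random(n) < defects.duplicate]:
            src = occurrences[int(rng.integers(0, n))]
            occurrences[i].lat = src.lat
            occurrences[i].lon = src.lon

    return OccurrenceSet(
        taxon_name=taxon_name,
        occurrences=occurrences,
        provenance={"generator": pattern, "seed": str(seed), "n": str(n)},
    )
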