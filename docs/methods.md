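# Methods

## The two range metrics

Criterion B of the IUCN Red List rates restricted-range taxa from two
measures of geographic range, both computed here from the visible subset
of a set of occurrence records.

**Extent of occurrence (B1).** The area of the convex hull of the
occurrence sites — the smallest polygon with no internal angle over 180°
containing all of them. The hull is computed with quickhull: take the two
x-extreme points as a chord, recurse on the point farthest from the chord
on each side, keeping only points strictly outside the running hull.
The implementation deduplicates input first, sorts it lexicographically so
farthest-point ties resolve to the lowest index (deterministic output),
excludes collinear boundary points from the vertex list (a *strict* hull;
the area is unchanged and the output canonical), and returns vertices
counter-clockwise starting from the lowest-x, then lowest-y vertex. The
area is the shoelace sum ½|Σ(xᵢyᵢ₊₁ − xᵢ₊₁yᵢ)|. Sets with fewer than
three non-collinear distinct points are degenerate: EOO = 0 and the flag
is passed to the rating step. Collinearity uses a 1e-9 km² signed-area
tolerance.

**Area of occupancy (B2).** Overlay a square grid of width *w* anchored at
the projected origin; each point belongs to the half-open cell
[kw, (k+1)w) × [mw, (m+1)w) found by true floor division (so a point at
x = −0.1 km is in cell −1, not 0, and a point exactly on a boundary belongs
to the higher cell). AOO = (number of occupied cells) · w², and per-cell
point counts are kept as a collection-density signal. Because the grid is
anchored at the data-centred projection origin, AOO depends on the
projection parameters; these are stored in the `.geocat` file so any result
can be reproduced exactly.

**Cell width.** Three rules: the default 2 km (the 2×2 km grid the IUCN
guidelines recommend; note AOO thresholds assume a comparable scale), a
user-supplied width, and one tenth of the maximum pairwise distance
between points. The factor of 10 mirrors the 10:1 ratio between the EOO
and AOO thresholds in the criteria and scales the grid to the species'
extent. The maximum distance is the O(n²) brute-force maximum in the
projected plane. If all points coincide the auto rule falls back to 2 km
with a warning.

## Projection

Planar km coordinates come from a cylindrical equal-area projection of the
authalic sphere (R = 6371.0072 km, the sphere with Earth's surface area):

    x = R · radians(λ − λ₀) · cos(φₜₛ)
    y = R · sin(φ) / cos(φₜₛ)

The map's Jacobian is identically 1, so planar polygon areas equal
spherical areas exactly — the property both metrics rely on. Per dataset,
λ₀ is the midpoint of the longitude range and φₜₛ the mean latitude of the
visible points, minimising shape distortion where the data are. Longitudes
are first wrapped to [−180, 180) and, if the set straddles the ±180° seam,
rotated through the largest empty gap; adding 360° to every longitude
therefore changes nothing. Sets spanning ≥ 180° of longitude are refused
rather than given a misleading planar hull, as are sets whose mean
latitude is within 0.001° of a pole. Forward∘inverse is identity to well
below 1e-9°.

Distortion note: a cylindrical equal-area frame preserves areas exactly
but stretches shapes away from the standard parallel, so hull *vertices*
(and hence which points are on the boundary) are projection-dependent for
near-degenerate configurations; areas are not.

## Rating

Strict less-than lookups against the v3.1 criterion-B thresholds
(EOO: 100 / 5,000 / 20,000 km²; AOO: 10 / 500 / 2,000 km²); at or above
the VU bound the combined label "LC or NT" is emitted, since the data
cannot distinguish the two. The single preliminary category is the more
threatened of B1 and B2. A degenerate EOO is rated "not applicable
(<3 points)" and the preliminary category comes from AOO alone; the
opt-in `eoo_floor_aoo` flag instead applies the IUCN convention that EOO
is never smaller than AOO, raising EOO to the AOO value before rating
(off by default, because a two-point record is an extent of zero unless
the assessor chooses the convention). Every report carries the fixed
caveat that subcriteria must also be met.

## Data handling

Validation flags (and hides) records with missing or out-of-range
coordinates and suspected latitude/longitude swaps (|lat| in (90, 180] is
an impossible latitude that looks like a longitude); swaps are never
auto-corrected — the workflow is manual review and an explicit `move`
edit, which is the only coordinate-mutating operation and always marks the
record `edited`. Exact coordinate duplicates are reported as pair counts
but stay visible: they are real records. Bounding-box filters use
boundary-inclusive containment so hide-inside and hide-outside of the same
box partition the record set. The precision filter hides records whose
stated uncertainty exceeds the threshold; records without the field pass,
since typical herbarium data lacks it and silently dropping it would be
destructive. Hidden records are excluded from every analysis step but kept
in all files and exports (KML gives them a distinct grey style).

CSV import recognises `latitude`/`longitude` and Darwin Core
`decimalLatitude`/`decimalLongitude` headers case-insensitively, with
tab/comma auto-detection for GBIF downloads. Per-source display caps
(GBIF 500, Flickr 250, others unlimited) are applied by file position:
rows past the cap load as hidden, so no data is lost. All writers are
deterministic — fixed key order, degrees at 6 decimal places (~0.1 m),
areas at 4 — so identical inputs give byte-identical `.geocat`, CSV and
KML files, and rewriting a read project is byte-stable.

## Synthetic data

The fixture generator emulates the two point patterns an assessor meets:
uniform scatter over a lat/lon box, and Gaussian clusters (default 3
clusters, sd 0.05°) around uniformly drawn centres inside a 2°×2° tropical
window — the scale of a narrow-range species for which criterion B
matters, and the clustered shape of real collection data. Optional defect
injection (swapped pairs, blanked coordinates, exact duplicates) happens at
stated per-record rates from the same seeded generator, so defect counts
are reproducible from the seed. What it does not emulate: spatial sampling
bias along roads and rivers, date/collector structure, datum errors other
than swaps, or non-stationary cluster sizes — so passing tests show the
algorithms are correct on realistic geometries, not that real GBIF data
needs no further cleaning.

Test and script problem sizes (hull oracle on 1,000 sets of ≤ 50 points,
grid oracle on 500 sets, 1,000-point projection round trips, 100–150-point
pipeline fixtures) were chosen to exercise every code path and tie-break
while keeping the whole suite in seconds.

## Design choices and limitations

- "2 km²" default cell size is read as cell *width* 2 km (cell area
  4 km²), matching the IUCN guidelines grid; the constant lives in one
  place (`aoo.DEFAULT_CELL_WIDTH_KM`).
- The projection is this package's own choice; the historical web tool's
  planar frame was never published, so agreement with its outputs is
  approximate, not bit-exact. Parameters are serialized for exact
  reproducibility of *this* package's numbers.
- Subcriteria (a)–(c), α-hulls, scale-area curves and live GBIF/Flickr
  queries are out of scope; the `.geocat` schema is versioned and
  forward-compatible (unknown top-level keys survive round trips) so such
  extensions can be added.
- Batch mode projects each species independently; EOO/AOO values of
  different species in one table are therefore each in their own optimal
  frame, which is what per-species assessment wants but means cell grids
  do not align across species.
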