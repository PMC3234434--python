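# geocat — offline geospatial conservation assessment

`geocat` computes the two range-size metrics at the heart of IUCN Red List
criterion B from georeferenced species occurrence records, and reports the
preliminary threat category they imply:

- **Extent of occurrence (EOO, criterion B1)** — the area of the smallest
  convex polygon containing all occurrence sites, computed with a quickhull
  convex hull and the shoelace formula.
- **Area of occupancy (AOO, criterion B2)** — the summed area of occupied
  grid cells, with each point snapped to its cell's lower-left corner by
  `floor(coord / width) · width`. Cell width is the 2 km IUCN-guidelines
  default, a user-chosen width, or 1/10 of the maximum pairwise distance
  between points.

Areas are measured in a per-dataset cylindrical equal-area projection on
the authalic sphere (R = 6371.0072 km), so km² values are metrically
meaningful. The EOO and AOO areas are then compared against the criterion-B
thresholds of the IUCN (2001) v3.1 standard (EOO: CR < 100, EN < 5,000,
VU < 20,000 km²; AOO: CR < 10, EN < 500, VU < 2,000 km²) and the more
threatened of the two becomes the preliminary rating — *preliminary*
because a full listing also requires the criterion-B subcriteria
(fragmentation, locations, decline) that range areas alone cannot show.

The package is aimed at assessors and biodiversity informaticians who want
these numbers reproducibly from the command line or from Python: it reads
generic and GBIF-download CSVs (with the 500/250 GBIF/Flickr display caps
applied as load-but-hide), supports the usual data-cleaning moves (hide,
move, delete points; bounding-box and coordinate-precision filters;
swapped-coordinate and duplicate screening), saves everything to a
versioned `.geocat` JSON project file, and exports CSV and KML.

## Worked example

Generate a reproducible synthetic occurrence set (three Gaussian clusters
of collections, as clustered as real herbarium data) and analyse it:

```sh
geocat fixture --n 100 --pattern gaussian_clusters --seed 42 --out demo.csv
geocat analyze demo.csv --taxon "Synthetica exemplaris" \
    --out demo.geocat --kml demo.kml --report demo_report.txt
```

which prints:

```
Taxon: Synthetica exemplaris
EOO: 6126.515 km2 -> VU
AOO: 316.0 km2 (79 cells at 2.0 km) -> EN
Preliminary rating: EN
```

The convex hull of the 100 points encloses 6,126.5 km² (below the 20,000
km² VU bound for EOO), the points occupy 79 cells of the 2-km grid for an
AOO of 316 km² (below the 500 km² EN bound), and the preliminary category
is the more threatened of the two, EN. `demo.geocat` holds the records,
parameters and results; `demo.kml` shows the points, hull and occupied
cells in Google Earth. Multi-species files run through `geocat batch
input.csv --taxon-column taxon`.

The same pipeline is available as a library:

```python
from geocat import GeoCatProject, generate_fixture, run_analysis

occ = generate_fixture(100, pattern="gaussian_clusters", seed=42)
project = run_analysis(GeoCatProject(taxon_name=occ.taxon_name, occurrence_set=occ))
print(project.results["rating"]["preliminary"])
```

## Layout

- `src/geocat/occurrences.py` — records, editing, filters, validation
- `src/geocat/projection.py` — cylindrical equal-area km frame
- `src/geocat/eoo.py`, `src/geocat/aoo.py` — the two range metrics
- `src/geocat/rating.py` — criterion-B thresholds and consolidation
- `src/geocat/io.py` — CSV, `.geocat` JSON, KML
- `src/geocat/analysis.py` — pipeline, report, batch mode
- `src/geocat/synthetic.py` — seeded fixture generator
- `src/geocat/cli.py` — `geocat analyze | batch | fixture`

See `docs/methods.md` for the model, parameter and design details.
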