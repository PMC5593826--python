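"""Known-polymorphism annotation and cohort-level summaries.

Polymorphism recognition uses a packaged snapshot of MITOMAP / dbSNP /
HAPMAP records (no live database access); annotation adds status columns
only and never alters filter flags or plasmy classes.  The summary
functions reproduce the two standard cohort views: the substitution
spectrum collapsed to strand-symmetric transition classes, and the
distribution of calls across annotated genome regions (the D-LOOP, which
wraps the origin, is handled wrap-aware).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from .reference import MtRegion, substitution_class

logger = logging.getLogger(__name__)

DB_COLUMNS = ["position", "ref", "alt", "source", "disease_flag", "note"]
DB_SOURCES = {"MITOMAP", "dbSNP", "HAPMAP"}

SPECTRUM_CLASSES = ["T>C/A>G", "G>A/C>T", "other"]


def packaged_polymorphism_db_path() -> Path:
    return Path(str(resources.files("mtlineage").joinpath("data/mito_polymorphisms.tsv")))


def load_polymorphism_db(path: str | Path | None = None) -> pd.DataFrame:
    """Load the polymorphism snapshot TSV; malformed rows are skipped with a warning."""
    path = Path(path) if path is not None else packaged_polymorphism_db_path()
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("position\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                logger.warning("skipping malformed db row %d in %s", lineno, path)
                continue
            pos, ref, alt, source, disease, note = parts
            try:
                rows.append(dict(position=int(pos), ref=ref, alt=alt, source=source,
                                 disease_flag=bool(int(disease)), note=note))
            except ValueError:
                logger.warning("skipping malformed db row %d in %s", lineno, path)
    db = pd.DataFrame(rows, columns=DB_COLUMNS)
    dup = db.duplicated(["position", "ref", "alt", "source"])
    if dup.any():
        logger.warning("dropping %d duplicate db rows", int(dup.sum()))
        db = db[~dup]
    return db.reset_index(drop=True)


def annotate_polymorphisms(calls: pd.DataFrame, db: pd.DataFrame) -> pd.DataFrame:
    """Mark calls matching a db record by (position, ref, alt).

    Adds ``known_polymorphism`` (bool), ``poly_sources`` (';'-joined) and
    ``disease_flag`` (bool).  Idempotent; never touches filter or plasmy
    columns.
    """
    out = calls.copy()
    grouped = db.groupby(["position", "ref", "alt"]).agg(
        poly_sources=("source", lambda s: ";".join(sorted(set(s)))),
        disease_flag=("disease_flag", "any"),
    )
    keys = list(zip(out["position"], out["ref"], out["alt"]))
    known, sources, disease = [], [], []
    for key in keys:
        if key in grouped.index:
            rec = grouped.loc[key]
            known.append(True)
            sources.append(rec["poly_sources"])
            disease.append(bool(rec["disease_flag"]))
        else:
            known.append(False)
            sources.append("")
            disease.append(False)
    out["known_polymorphism"] = known
    out["poly_sources"] = sources
    out["disease_flag"] = disease
    return out


def spectrum_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of the spectrum classes; indels count as 'other'.

    Fractions are exact count ratios and sum to 1 for non-empty input.
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["class", "count", "fraction"])
    classes = []
    for row in calls.itertuples():
        if row.ref and row.alt and len(row.ref) == 1 and len(row.alt) == 1:
            classes.append(substitution_class(row.ref, row.alt))
        else:
            classes.append("other")
    counts = pd.Series(classes).value_counts()
    total = int(counts.sum())
    rows = [
        dict(**{"class": c}, count=int(counts.get(c, 0)),
             fraction=int(counts.get(c, 0)) / total)
        for c in SPECTRUM_CLASSES
        if counts.get(c, 0) > 0
    ]
    return pd.DataFrame(rows, columns=["class", "count", "fraction"])


def region_distribution(
    calls: pd.DataFrame,
    region_map: list[MtRegion],
    genome_length: int,
) -> pd.DataFrame:
    """Per-region-category call counts and fractions of total calls.

    A call in several categories (e.g. a microsatellite inside the D-LOOP)
    counts once per category; the denominator is always the total number of
    calls, so fractions can exceed 1 in sum.  Calls outside every region are
    reported as ``intergenic``; attributed + intergenic == total calls holds
    category-wise for the ``intergenic`` complement.
    """
    total = len(calls)
    counts: dict[str, int] = {}
    intergenic = 0
    for row in calls.itertuples():
        cats = {r.category for r in region_map if r.contains(int(row.position), genome_length)}
        if not cats:
            intergenic += 1
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
    rows = [dict(category=c, count=n, fraction=(n / total if total else 0.0))
            for c, n in sorted(counts.items())]
    rows.append(dict(category="intergenic", count=intergenic,
                     fraction=(intergenic / total if total else 0.0)))
    return pd.DataFrame(rows, columns=["category", "count", "fraction"])
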