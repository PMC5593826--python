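"""Circular mitochondrial reference model: sequence, annotated regions, variant naming.

The human mitochondrial genome is a 16,569 bp circular molecule (rCRS,
accession NC_012920) carrying 37 genes plus the non-coding control region
(D-LOOP), which spans the origin of the circular map.  All coordinates in
this package are 1-based inclusive; a region whose ``start`` exceeds its
``end`` wraps through the origin (e.g. the control region, 16024-576).
BED exports convert to 0-based half-open at the I/O boundary only.

Variant labels follow the compact dialect used in the mitochondrial
literature: ``G3036A`` for substitutions, ``66 del-G`` for deletions
(anchored on the first deleted base) and ``12384^12385-ins C`` for
insertions (anchored on the 5' flanking position).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

RCRS_LENGTH = 16569
RCRS_ACCESSION = "NC_012920"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REGION_CATEGORIES = frozenset(
    {"protein_gene", "rRNA", "tRNA", "control_region", "microsatellite"}
)


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceError(ValueError):
    """Raised for malformed reference inputs or out-of-range coordinates."""


@dataclass(frozen=True)
class MtReference:
    """A circular mitochondrial reference sequence."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ReferenceError(f"non-DNA characters in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position; positions beyond the length wrap."""
        if position < 1:
            raise ReferenceError(f"position outside genome: {position}")
        return self.sequence[(position - 1) % self.length]

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval [start, end], wrap-aware.

        ``start > end`` means the interval crosses the origin.
        """
        L = self.length
        if not (1 <= start <= L and 1 <= end <= L):
            raise ReferenceError(f"position outside genome: {start}-{end}")
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ReferenceError("wrapping interval on a linear reference")
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass(frozen=True)
class MtRegion:
    """An annotated interval on the circle; start > end wraps the origin."""

    label: str
    start: int
    end: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in REGION_CATEGORIES:
            raise ReferenceError(f"unknown region category: {self.category!r}")
        if self.start < 1 or self.end < 1:
            raise ReferenceError("region coordinates must be positive")

    def contains(self, position: int, genome_length: int) -> bool:
        if not 1 <= position <= genome_length:
            raise ReferenceError(f"position outside genome: {position}")
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end

    def span(self, genome_length: int) -> int:
        """Number of positions covered, wrap-aware."""
        return (self.end - self.start) % genome_length + 1


@dataclass(frozen=True)
class VariantDescriptor:
    """A variant in mt-coordinate space.

    For insertions ``position`` is the 5' flanking base and ``ref`` is empty;
    for deletions ``position`` is the first deleted base and ``alt`` is empty.
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == "" and self.alt == "":
            raise ReferenceError("variant needs at least one allele")
        if self.var_type == "SNV" and self.ref == self.alt:
            raise ReferenceError("not a substitution")

    @property
    def var_type(self) -> str:
        if self.ref and self.alt:
            return "SNV"
        return "deletion" if self.alt == "" else "insertion"

    def label(self, genome_length: int = RCRS_LENGTH) -> str:
        """Canonical text label in the field's dialect."""
        if self.var_type == "SNV":
            return f"{self.ref}{self.position}{self.alt}"
        if self.var_type == "deletion":
            return f"{self.position} del-{self.ref}"
        nxt = self.position % genome_length + 1
        return f"{self.position}^{nxt}-ins {self.alt}"


_SNV_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_DEL_RE = re.compile(r"^(\d+)\s*del-([ACGT]+)$")
_INS_RE = re.compile(r"^(\d+)\^(\d+)-ins\s*([ACGT]+)$")


def parse_variant_label(label: str, genome_length: int = RCRS_LENGTH) -> VariantDescriptor:
    """Parse an SNV / deletion / insertion label into a descriptor.

    Raises :class:`ReferenceError` for unrecognised strings, and for
    insertion anchors that are not adjacent on the circle.
    """
    label = label.strip()
    if m := _SNV_RE.match(label):
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if ref == alt:
            raise ReferenceError(f"not a substitution: {label!r}")
        return VariantDescriptor(pos, ref, alt)
    if m := _DEL_RE.match(label):
        return VariantDescriptor(int(m.group(1)), m.group(2), "")
    if m := _INS_RE.match(label):
        p1, p2, ins = int(m.group(1)), int(m.group(2)), m.group(3)
        if p2 != p1 % genome_length + 1:
            raise ReferenceError(f"non-adjacent insertion anchor: {label!r}")
        return VariantDescriptor(p1, "", ins)
    raise ReferenceError(f"unrecognised variant label: {label!r}")


def substitution_class(ref: str, alt: str) -> str:
    """Collapse a substitution into the strand-symmetric spectrum classes.

    ``{T>C, A>G}`` -> ``"T>C/A>G"``; ``{G>A, C>T}`` -> ``"G>A/C>T"``;
    every transversion -> ``"other"``.  Invariant under complementing both
    alleles.
    """
    if ref == alt:
        raise ReferenceError("not a substitution")
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ReferenceError(f"not a single-base substitution: {ref}>{alt}")
    pair = (ref, alt)
    if pair in {("T", "C"), ("A", "G")}:
        return "T>C/A>G"
    if pair in {("G", "A"), ("C", "T")}:
        return "G>A/C>T"
    return "other"


def load_reference(fasta_path: str | Path) -> MtReference:
    """Load a single-record FASTA as a circular reference (uppercased)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) == 0:
        raise ReferenceError(f"no sequence in {fasta_path}")
    if len(records) > 1:
        raise ReferenceError(f"ambiguous reference: {len(records)} records in {fasta_path}")
    rec = records[0]
    return MtReference(name=rec.id, sequence=str(rec.seq).upper())


def packaged_reference_path() -> Path:
    """Path of the packaged synthetic rCRS-scale reference FASTA."""
    return Path(str(resources.files("mtlineage").joinpath("data/rcrs_synthetic.fa")))


def packaged_region_table_path() -> Path:
    return Path(str(resources.files("mtlineage").joinpath("data/regions_rcrs.tsv")))


def load_packaged_reference() -> MtReference:
    return load_reference(packaged_reference_path())


def load_regions(path: str | Path | None = None) -> list[MtRegion]:
    """Load the region-annotation table (label, start, end, category TSV)."""
    path = Path(path) if path is not None else packaged_region_table_path()
    regions: list[MtRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            label, start, end, category = line.split("\t")
            if label == "label":  # header row
                continue
            regions.append(MtRegion(label, int(start), int(end), category))
    return regions


def region_of(position: int, region_map: Sequence[MtRegion],
              genome_length: int = RCRS_LENGTH) -> list[str]:
    """Labels of every region containing a position (wrap-aware); [] if intergenic."""
    if not 1 <= position <= genome_length:
        raise ReferenceError(f"position outside genome: {position}")
    return [r.label for r in region_map if r.contains(position, genome_length)]


def write_regions_bed(region_map: Iterable[MtRegion], path: str | Path,
                      genome_length: int = RCRS_LENGTH,
                      chrom: str = "chrM") -> None:
    """Export regions as BED (0-based half-open); wrapping regions split in two."""
    with open(path, "w") as out:
        for r in region_map:
            if r.start <= r.end:
                out.write(f"{chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")
            else:
                out.write(f"{chrom}\t{r.start - 1}\t{genome_length}\t{r.label}\n")
                out.write(f"{chrom}\t0\t{r.end}\t{r.label}\n")
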