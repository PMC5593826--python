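"""Amplicon panel design on the circular mt-genome.

Multiplex PCR enrichment of FFPE-grade mtDNA works on short fragments, so
the genome is tiled with small overlapping amplicons (inserts of 60-200 bp,
~160 bp on average).  Overlapping amplicons must not share a PCR reaction —
a primer of one would sit inside the insert of its neighbour — so the panel
is partitioned into pools such that no two amplicons in a pool overlap.

The tiling is a uniform-step walk around the circle: insert starts are
placed at ``round(i * L / n)`` so the steps differ by at most 1 bp and the
last insert wraps through the origin to close the circle.  Consecutive
inserts overlap by ``min_overlap`` bp.  Primer binding sites are the
``primer_length`` bases flanking each insert; the forward primer is the
reference top strand 5' of the insert, the reverse primer the reverse
complement of the 3' flank.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from .reference import MtReference, revcomp

MIN_INSERT = 60
MAX_INSERT = 200


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class Amplicon:
    """One tiled amplicon; insert coordinates are 1-based inclusive, wrap-aware."""

    id: int
    insert_start: int
    insert_end: int
    fwd_primer: str
    rev_primer: str
    pool: int | None = None

    def insert_length(self, genome_length: int) -> int:
        return (self.insert_end - self.insert_start) % genome_length + 1

    def insert_positions(self, genome_length: int) -> range | list[int]:
        """1-based positions covered by the insert, unrolled through the origin."""
        if self.insert_start <= self.insert_end:
            return range(self.insert_start, self.insert_end + 1)
        return list(range(self.insert_start, genome_length + 1)) + list(
            range(1, self.insert_end + 1)
        )

    def covers(self, position: int, genome_length: int) -> bool:
        if self.insert_start <= self.insert_end:
            return self.insert_start <= position <= self.insert_end
        return position >= self.insert_start or position <= self.insert_end

    def boundary_distance(self, position: int, genome_length: int) -> int:
        """Distance (bp) from a covered position to the nearer insert edge."""
        off = (position - self.insert_start) % genome_length
        return min(off, self.insert_length(genome_length) - 1 - off)


@dataclass
class Panel:
    """An ordered circular chain of amplicons over one reference."""

    amplicons: list[Amplicon]
    reference: MtReference
    n_pools: int | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return (
            self.amplicons == other.amplicons
            and self.n_pools == other.n_pools
            and self.reference.sequence == other.reference.sequence
        )

    @property
    def primer_length(self) -> int:
        return len(self.amplicons[0].fwd_primer)

    def overlaps(self, a: Amplicon, b: Amplicon) -> bool:
        """Whether two inserts share at least one position on the circle."""
        L = self.reference.length
        pa = set(a.insert_positions(L))
        return any(p in pa for p in b.insert_positions(L))

    def covering(self, position: int) -> list[Amplicon]:
        L = self.reference.length
        return [a for a in self.amplicons if a.covers(position, L)]

    def primer_footprint_positions(self) -> set[int]:
        """All 1-based positions under any primer binding site."""
        L = self.reference.length
        k = self.primer_length
        out: set[int] = set()
        for a in self.amplicons:
            for d in range(1, k + 1):
                out.add((a.insert_start - 1 - (d - 1)) % L or L)
                out.add((a.insert_end - 1 + d) % L + 1)
        return out

    def insert_sequence(self, amp: Amplicon) -> str:
        return self.reference.fetch(amp.insert_start, amp.insert_end)


def design_panel(
    reference: MtReference,
    n_amplicons: int = 108,
    mean_length: int = 160,
    min_overlap: int = 6,
    primer_length: int = 22,
) -> Panel:
    """Tile the circular reference with ``n_amplicons`` overlapping inserts.

    Insert ``i`` runs from start ``round(i*L/n)+1`` to ``min_overlap`` bases
    past the next start, so consecutive inserts overlap by exactly
    ``min_overlap`` bp and the union covers the whole circle.

    Raises :class:`PanelError` when the requested geometry cannot cover the
    circle or falls outside the 60-200 bp insert range.
    """
    L = reference.length
    if not MIN_INSERT <= mean_length <= MAX_INSERT:
        raise PanelError(f"amplicon size out of design range: {mean_length}")
    if n_amplicons * (mean_length - min_overlap) < L:
        raise PanelError(
            f"cannot tile circle: {n_amplicons} amplicons of mean {mean_length} bp "
            f"with {min_overlap} bp overlap cover < {L} bp"
        )
    starts = [round(i * L / n_amplicons) + 1 for i in range(n_amplicons)]
    if len(set(starts)) != n_amplicons:
        raise PanelError("cannot tile circle: more amplicons than distinct start positions")
    amplicons = []
    for i, start in enumerate(starts):
        nxt = starts[(i + 1) % n_amplicons]
        end = (nxt - 1 + min_overlap - 1) % L + 1  # min_overlap bases past next start
        amp_len = (end - start) % L + 1
        if not MIN_INSERT <= amp_len <= MAX_INSERT:
            raise PanelError(
                f"cannot tile circle: amplicon {i} insert length {amp_len} outside "
                f"[{MIN_INSERT}, {MAX_INSERT}]"
            )
        fwd_start = (start - 1 - primer_length) % L + 1
        fwd_end = (start - 2) % L + 1
        rev_start = end % L + 1
        rev_end = (end - 1 + primer_length) % L + 1
        fwd = reference.fetch(fwd_start, fwd_end)
        rev = revcomp(reference.fetch(rev_start, rev_end))
        amplicons.append(Amplicon(i, start, end, fwd, rev))
    mean = sum(a.insert_length(L) for a in amplicons) / n_amplicons
    if abs(mean - mean_length) > 10:
        raise PanelError(f"cannot tile circle: achieved mean insert {mean:.1f} bp")
    return Panel(amplicons, reference)


def assign_pools(panel: Panel, n_pools: int = 4) -> Panel:
    """Partition amplicons into pools so overlapping amplicons never share one.

    Round-robin by amplicon ordinal, then greedy repair of residual
    conflicts; deterministic and balanced (pool sizes differ by at most 1)
    for chain tilings.  Raises :class:`PanelError` when the overlap graph is
    not ``n_pools``-colourable under the balanced round-robin scheme.
    """
    n = len(panel.amplicons)
    if n_pools < 1:
        raise PanelError("need at least one pool")
    L = panel.reference.length
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if panel.overlaps(panel.amplicons[i], panel.amplicons[j]):
                adj[i].add(j)
                adj[j].add(i)
    if n_pools == 1 and any(adj.values()):
        raise PanelError("pool constraint unsatisfiable: overlapping amplicons with one pool")
    pool_of = {i: i % n_pools for i in range(n)}
    # greedy repair: move conflicted amplicons to the least-loaded conflict-free pool
    for _ in range(n):
        conflicts = [i for i in range(n) if any(pool_of[j] == pool_of[i] for j in adj[i])]
        if not conflicts:
            break
        i = conflicts[0]
        sizes = {p: sum(1 for v in pool_of.values() if v == p) for p in range(n_pools)}
        candidates = [
            p for p in range(n_pools) if all(pool_of[j] != p for j in adj[i])
        ]
        if not candidates:
            raise PanelError("pool constraint unsatisfiable")
        pool_of[i] = min(candidates, key=lambda p: (sizes[p], p))
    else:
        raise PanelError("pool constraint unsatisfiable")
    sizes = [sum(1 for v in pool_of.values() if v == p) for p in range(n_pools)]
    if max(sizes) - min(sizes) > 1:
        raise PanelError("pool constraint unsatisfiable: cannot balance pools")
    amps = [replace(a, pool=pool_of[a.id] + 1) for a in panel.amplicons]
    return Panel(amps, panel.reference, n_pools=n_pools)


def write_panel(panel: Panel, out_dir: str | Path, chrom: str = "chrM") -> None:
    """Write the panel as a BED of inserts plus a tab-separated primer sheet.

    Wrapping inserts become two BED records with the same name.  The primer
    sheet (``primers.tsv``) round-trips through :func:`read_panel`.
    """
    if any(a.pool is None for a in panel.amplicons):
        raise PanelError("assign pools first")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = panel.reference.length
    with open(out_dir / "inserts.bed", "w") as bed:
        for a in panel.amplicons:
            name = f"amp{a.id:03d}"
            if a.insert_start <= a.insert_end:
                bed.write(f"{chrom}\t{a.insert_start - 1}\t{a.insert_end}\t{name}\n")
            else:
                bed.write(f"{chrom}\t{a.insert_start - 1}\t{L}\t{name}\n")
                bed.write(f"{chrom}\t0\t{a.insert_end}\t{name}\n")
    with open(out_dir / "primers.tsv", "w") as sheet:
        sheet.write("id\tfwd_primer\trev_primer\tinsert_start\tinsert_end\tpool\n")
        for a in panel.amplicons:
            sheet.write(
                f"{a.id}\t{a.fwd_primer}\t{a.rev_primer}\t"
                f"{a.insert_start}\t{a.insert_end}\t{a.pool}\n"
            )


def read_panel(out_dir: str | Path, reference: MtReference) -> Panel:
    """Reconstruct a panel from a primer sheet written by :func:`write_panel`."""
    out_dir = Path(out_dir)
    amps = []
    with open(out_dir / "primers.tsv") as sheet:
        header = sheet.readline()
        if not header.startswith("id\t"):
            raise PanelError(f"not a primer sheet: {out_dir / 'primers.tsv'}")
        for line in sheet:
            aid, fwd, rev, start, end, pool = line.rstrip("\n").split("\t")
            amps.append(Amplicon(int(aid), int(start), int(end), fwd, rev, int(pool)))
    n_pools = max(a.pool for a in amps) if amps else None
    return Panel(amps, reference, n_pools=n_pools)
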