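"""Amplicon read assignment, strand-aware pileups and threshold variant calling.

Reads are assigned to the unique amplicon whose forward primer prefixes
read 1 (the simulator keeps primer bases error-free, so assignment is
exact); pairs matching no primer count as off-target.  Each pair
contributes one forward-strand observation (read 1) and one reverse-strand
observation (read 2) of every insert position.

Calling applies three documented predicates per (position, alternate
allele): minimum read depth 30, minimum variant allele fraction 5%, and a
balanced forward/reverse performance — operationalised as the minor-strand
fraction of alt-supporting reads — strictly above 0.2.  Sites passing depth
and VAF but failing strand balance are emitted flagged ``strand_imbalance``
rather than dropped, so downstream review keeps the audit trail.  Calls at
or above 95% VAF are classified homoplasmic, otherwise heteroplasmic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import Panel
from .reference import MtReference, VariantDescriptor, revcomp

DEFAULT_MIN_DEPTH = 30
DEFAULT_MIN_VAF = 0.05
DEFAULT_MIN_STRAND_BALANCE = 0.2
DEFAULT_HOMOPLASMY_VAF = 0.95

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_IDX_BASE = "ACGTN"
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class CallingError(ValueError):
    pass


@dataclass
class PileupColumn:
    """Strand-split allele counts at one 1-based position.

    ``base_counts`` is a (2, 5) array (rows fwd/rev, columns A,C,G,T,N);
    ``gap`` counts reads spanning the column with the base deleted;
    ``dels``/``inss`` key indel events by their allele string — deletions
    anchored on their first deleted base, insertions on the 5' flank.
    Depth is the number of spanning reads: bases plus gaps (insertion
    observations ride on a based read, so they are not added again).
    """

    position: int
    ref_base: str
    base_counts: np.ndarray
    gap: np.ndarray
    dels: dict[str, np.ndarray] = field(default_factory=dict)
    inss: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return int(self.base_counts.sum() + self.gap.sum())


@dataclass(frozen=True)
class VariantCall:
    descriptor: VariantDescriptor
    vaf: float
    depth: int
    fwd_alt: int
    rev_alt: int
    filter_flags: frozenset[str] = frozenset()
    plasmy: str | None = None

    @property
    def strand_balance(self) -> float:
        total = self.fwd_alt + self.rev_alt
        return min(self.fwd_alt, self.rev_alt) / total if total else 0.0

    @property
    def is_pass(self) -> bool:
        return not self.filter_flags


@dataclass
class RunMetrics:
    total_reads: int
    mapped_mt_reads: int
    covered_fraction: float      # % of mt positions at depth >= 30
    mean_depth_per_100bp: float  # mean reads overlapping a 100 bp window

    @property
    def specificity(self) -> float:
        return 100.0 * self.mapped_mt_reads / self.total_reads if self.total_reads else 0.0


class Pileup:
    """Genome-wide strand-aware pileup backed by dense count arrays."""

    def __init__(self, reference: MtReference):
        self.reference = reference
        L = reference.length
        # [strand, position(0-based), base]
        self.base_counts = np.zeros((2, L, 5), dtype=np.int64)
        self.gap = np.zeros((2, L), dtype=np.int64)
        self.dels: dict[tuple[int, str], np.ndarray] = {}
        self.inss: dict[tuple[int, str], np.ndarray] = {}

    def depth_array(self) -> np.ndarray:
        return self.base_counts.sum(axis=(0, 2)) + self.gap.sum(axis=0)

    def column(self, position: int) -> PileupColumn:
        i = position - 1
        return PileupColumn(
            position=position,
            ref_base=self.reference.base(position),
            base_counts=self.base_counts[:, i, :].copy(),
            gap=self.gap[:, i].copy(),
            dels={allele: counts.copy() for (p, allele), counts in self.dels.items() if p == position},
            inss={allele: counts.copy() for (p, allele), counts in self.inss.items() if p == position},
        )

    def columns(self) -> list[PileupColumn]:
        covered = np.nonzero(self.depth_array() > 0)[0]
        return [self.column(int(i) + 1) for i in covered]

    def _count_event(self, store: dict, position: int, allele: str, strand: int) -> None:
        key = (position, allele)
        if key not in store:
            store[key] = np.zeros(2, dtype=np.int64)
        store[key][strand] += 1

    def add_matrix(self, rows: Sequence[str], positions: Sequence[int], strand: int) -> None:
        """Count equal-length reads over the given genome positions at once."""
        if not rows:
            return
        m = len(positions)
        arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), m)
        idx = np.array([p - 1 for p in positions])
        for base, b_idx in _BASE_IDX.items():
            hits = (arr == ord(base)).sum(axis=0)
            self.base_counts[strand, idx, b_idx] += hits

    def add_aligned(self, read: str, ref_insert: str, positions: Sequence[int], strand: int) -> None:
        """Count one length-changed read via edlib alignment to its insert."""
        res = edlib.align(read, ref_insert, task="path", mode="NW")
        qi = ti = 0
        for n_s, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(n_s)
            if op in "=XM":
                for j in range(n):
                    pos = positions[ti + j]
                    b = read[qi + j]
                    self.base_counts[strand, pos - 1, _BASE_IDX.get(b, 4)] += 1
                qi += n
                ti += n
            elif op == "D":  # bases present in reference, absent in read
                first = positions[ti]
                allele = ref_insert[ti: ti + n]
                self._count_event(self.dels, first, allele, strand)
                for j in range(n):
                    self.gap[strand, positions[ti + j] - 1] += 1
                ti += n
            elif op == "I":  # extra read bases after the previous reference base
                anchor = positions[ti - 1] if ti > 0 else positions[0]
                self._count_event(self.inss, anchor, read[qi: qi + n], strand)
                qi += n


def assign_and_pileup(
    r1_path: str | Path,
    r2_path: str | Path,
    panel: Panel,
    reference: MtReference,
) -> tuple[Pileup, RunMetrics]:
    """Assign read pairs to amplicons by forward-primer prefix and pile up.

    Read 1 contributes forward-strand counts, read 2 reverse-strand counts.
    Raises :class:`CallingError` when no pair is assignable.
    """
    k = panel.primer_length
    L = reference.length
    by_primer = {a.fwd_primer: a for a in panel.amplicons}
    amp_info = {
        a.id: (panel.insert_sequence(a), list(a.insert_positions(L)))
        for a in panel.amplicons
    }
    # buckets[amp_id][strand] -> (equal-length rows, odd-length rows)
    buckets: dict[int, list[list[str]]] = {a.id: [[], [], [], []] for a in panel.amplicons}
    pair_counts: dict[int, int] = {a.id: 0 for a in panel.amplicons}
    total_pairs = 0
    on_pairs = 0
    with open(r1_path) as fh1, open(r2_path) as fh2:
        for (t1, s1, _), (t2, s2, _) in zip(
            FastqGeneralIterator(fh1), FastqGeneralIterator(fh2)
        ):
            total_pairs += 1
            amp = by_primer.get(s1[:k])
            if amp is None:
                continue
            on_pairs += 1
            pair_counts[amp.id] += 1
            m = len(amp_info[amp.id][1])
            ins1 = s1[k: len(s1) - k]
            ins2 = revcomp(s2)[k: len(s2) - k]
            b = buckets[amp.id]
            (b[0] if len(ins1) == m else b[1]).append(ins1)
            (b[2] if len(ins2) == m else b[3]).append(ins2)
    if on_pairs == 0:
        raise CallingError("no on-target data")

    pileup = Pileup(reference)
    for amp_id, (ref_insert, positions) in amp_info.items():
        eq_f, odd_f, eq_r, odd_r = buckets[amp_id]
        pileup.add_matrix(eq_f, positions, strand=0)
        pileup.add_matrix(eq_r, positions, strand=1)
        for row in odd_f:
            pileup.add_aligned(row, ref_insert, positions, strand=0)
        for row in odd_r:
            pileup.add_aligned(row, ref_insert, positions, strand=1)

    depth = pileup.depth_array()
    covered = 100.0 * float((depth >= DEFAULT_MIN_DEPTH).mean())
    mean_window = _mean_reads_per_window(panel, pair_counts, L, window=100)
    metrics = RunMetrics(
        total_reads=2 * total_pairs,
        mapped_mt_reads=2 * on_pairs,
        covered_fraction=covered,
        mean_depth_per_100bp=mean_window,
    )
    return pileup, metrics


def _mean_reads_per_window(panel: Panel, pair_counts: dict[int, int],
                           genome_length: int, window: int = 100) -> float:
    """Mean number of reads whose insert overlaps a 100 bp genome window."""
    n_windows = -(-genome_length // window)
    counts = np.zeros(n_windows, dtype=np.int64)
    for a in panel.amplicons:
        reads = 2 * pair_counts.get(a.id, 0)
        if reads == 0:
            continue
        touched = {(p - 1) // window for p in a.insert_positions(genome_length)}
        for w in touched:
            counts[w] += reads
    return float(counts.mean())


def call_variants(
    pileup: Pileup | Iterable[PileupColumn],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_vaf: float = DEFAULT_MIN_VAF,
    min_strand_balance: float = DEFAULT_MIN_STRAND_BALANCE,
) -> list[VariantCall]:
    """Threshold calling per (position, alt allele).

    A PASS call needs depth >= ``min_depth``, alt fraction >= ``min_vaf``
    and minor-strand alt fraction strictly > ``min_strand_balance``;
    strand-imbalanced sites are emitted with the ``strand_imbalance`` flag.
    Output is ordered by (position, alt representation).
    """
    columns = pileup.columns() if isinstance(pileup, Pileup) else list(pileup)
    calls: list[VariantCall] = []
    for col in sorted(columns, key=lambda c: c.position):
        depth = col.depth
        if depth < min_depth:
            continue
        candidates: list[tuple[VariantDescriptor, int, int]] = []
        ref_idx = _BASE_IDX.get(col.ref_base, 4)
        for b_idx in range(4):
            if b_idx == ref_idx:
                continue
            f, r = int(col.base_counts[0, b_idx]), int(col.base_counts[1, b_idx])
            if f + r:
                candidates.append(
                    (VariantDescriptor(col.position, col.ref_base, _IDX_BASE[b_idx]), f, r)
                )
        for allele, counts in sorted(col.dels.items()):
            candidates.append((VariantDescriptor(col.position, allele, ""),
                               int(counts[0]), int(counts[1])))
        for allele, counts in sorted(col.inss.items()):
            candidates.append((VariantDescriptor(col.position, "", allele),
                               int(counts[0]), int(counts[1])))
        for desc, f, r in sorted(candidates, key=lambda c: (c[0].ref, c[0].alt)):
            vaf = (f + r) / depth
            if vaf < min_vaf:
                continue
            balance = min(f, r) / (f + r)
            flags = frozenset() if balance > min_strand_balance else frozenset({"strand_imbalance"})
            calls.append(VariantCall(desc, vaf=vaf, depth=depth,
                                     fwd_alt=f, rev_alt=r, filter_flags=flags))
    return calls


def classify_plasmy(call: VariantCall, homoplasmy_vaf: float = DEFAULT_HOMOPLASMY_VAF) -> VariantCall:
    """Homoplasmic iff VAF >= threshold (boundary inclusive), else heteroplasmic."""
    plasmy = "homoplasmic" if call.vaf >= homoplasmy_vaf else "heteroplasmic"
    return replace(call, plasmy=plasmy)


def calls_to_frame(calls: Sequence[VariantCall], patient: str, lesion: str,
                   genome_length: int) -> pd.DataFrame:
    """Flatten calls into the cohort table layout used by the filter stage."""
    rows = []
    for c in calls:
        d = c.descriptor
        rows.append(dict(
            patient=patient, lesion=lesion, position=d.position, ref=d.ref,
            alt=d.alt, var_type=d.var_type, label=d.label(genome_length),
            vaf=c.vaf, depth=c.depth, fwd_alt=c.fwd_alt, rev_alt=c.rev_alt,
            strand_balance=c.strand_balance, plasmy=c.plasmy,
            flags=";".join(sorted(c.filter_flags)),
        ))
    return pd.DataFrame(rows, columns=[
        "patient", "lesion", "position", "ref", "alt", "var_type", "label",
        "vaf", "depth", "fwd_alt", "rev_alt", "strand_balance", "plasmy", "flags",
    ])


def run_metrics_report(metrics: dict[str, RunMetrics], path: str | Path) -> None:
    """One TSV row per sample: specificity, coverage, windowed depth."""
    with open(path, "w") as out:
        out.write("sample\ttotal_reads\tmapped_mt_reads\tspecificity\t"
                  "covered_fraction\tmean_depth_per_100bp\n")
        for sample in sorted(metrics):
            m = metrics[sample]
            out.write(f"{sample}\t{m.total_reads}\t{m.mapped_mt_reads}\t"
                      f"{m.specificity:.4f}\t{m.covered_fraction:.4f}\t"
                      f"{m.mean_depth_per_100bp:.2f}\n")


# ---------------------------------------------------------------------------
# VCF I/O (left-anchored representation at the boundary only)


def _vcf_header(reference: MtReference, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(reference.name, length=reference.length)
    header.info.add("VAF", number=1, type="Float", description="Variant allele fraction")
    header.info.add("DP", number=1, type="Integer", description="Read depth")
    header.info.add("SB", number=1, type="Float", description="Minor-strand alt fraction")
    header.info.add("PLASMY", number=1, type="String",
                    description="homoplasmic or heteroplasmic")
    for flag, desc in (
        ("strand_imbalance", "Minor-strand alt fraction at or below threshold"),
        ("recurrent_similar_vaf", "Similar VAF across unrelated patients"),
        ("amplicon_end", "Within the end margin of every covering amplicon"),
        ("repetitive_region", "Microsatellite / repetitive region"),
        ("noisy_region", "High cross-sample background noise"),
    ):
        header.filters.add(flag, None, None, desc)
    header.add_sample(sample)
    return header


def write_vcf(calls: Sequence[VariantCall], reference: MtReference,
              path: str | Path, sample: str) -> None:
    """One VCF per lesion; indels are left-anchored on the previous base."""
    header = _vcf_header(reference, sample)
    # htslib grumbles that a field named SB conventionally has Number=4;
    # ours is the scalar minor-strand fraction, so silence the sanity check
    verbosity = pysam.set_verbosity(0)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: (c.descriptor.position, c.descriptor.alt)):
            d = c.descriptor
            if d.var_type == "SNV":
                pos, ref, alt = d.position, d.ref, d.alt
            elif d.var_type == "deletion":
                anchor_pos = d.position - 1 if d.position > 1 else reference.length
                anchor = reference.base(anchor_pos)
                pos, ref, alt = max(d.position - 1, 1), anchor + d.ref, anchor
            else:
                anchor = reference.base(d.position)
                pos, ref, alt = d.position, anchor, anchor + d.alt
            rec = vcf.new_record(contig=reference.name, start=pos - 1,
                                 alleles=(ref, alt))
            rec.info["VAF"] = float(c.vaf)
            rec.info["DP"] = int(c.depth)
            rec.info["SB"] = float(c.strand_balance)
            if c.plasmy:
                rec.info["PLASMY"] = c.plasmy
            if c.filter_flags:
                for f in sorted(c.filter_flags):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            vcf.write(rec)
    pysam.set_verbosity(verbosity)


def read_vcf_calls(path: str | Path, reference: MtReference) -> list[VariantCall]:
    """Inverse of :func:`write_vcf` (descriptor-level round trip)."""
    calls = []
    verbosity = pysam.set_verbosity(0)
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref, alt = rec.alleles[0], rec.alleles[1]
            if len(ref) == 1 and len(alt) == 1:
                d = VariantDescriptor(rec.pos, ref, alt)
            elif len(ref) > len(alt):
                d = VariantDescriptor(rec.pos + 1, ref[1:], "")
            else:
                d = VariantDescriptor(rec.pos, "", alt[1:])
            flags = frozenset(f for f in rec.filter.keys() if f != "PASS")
            sb = float(rec.info["SB"])
            depth = int(rec.info["DP"])
            vaf = float(rec.info["VAF"])
            alt_total = round(vaf * depth)
            minor = round(sb * alt_total)
            calls.append(VariantCall(
                d, vaf=vaf, depth=depth, fwd_alt=alt_total - minor, rev_alt=minor,
                filter_flags=flags, plasmy=rec.info.get("PLASMY"),
            ))
    pysam.set_verbosity(verbosity)
    return calls
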