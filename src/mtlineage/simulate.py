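"""Synthetic multi-lesion FFPE mtDNA cohorts with ground truth.

Each simulated patient is a rooted clonal tree whose leaves are tumour
lesions.  Variants are planted on tree edges: homoplasmic germline
polymorphisms (drawn from the packaged polymorphism snapshot) and trunk
variants sit above the root and appear in every lesion; branch variants sit
on internal edges and appear in a proper subset; private variants sit on
leaf edges.  Heteroplasmic allele fractions are drawn from a truncated
Beta, bimodal toward the extremes, reflecting the observation that tumour
mt-variants are mostly homoplasmic or highly heteroplasmic.

Reads emulate the amplicon protocol: every fragment spans its full insert
plus both primer binding sites (inserts are at most 200 bp, reads 2x300 bp),
so each read pair contributes one forward- and one reverse-strand
observation of every insert position.  FFPE deamination artifacts are
injected as independent low-fraction (<5%) C>T / G>A sites, the mechanism by
which formalin fixation corrupts PCR: the default caller threshold is
expected to suppress them.  A configurable fraction of read pairs is drawn
from a scrambled decoy and labelled off-target.  Primer bases are simulated
error-free so that amplicon assignment by primer prefix is exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import load_polymorphism_db
from .panel import Panel, PanelError
from .reference import MtReference, VariantDescriptor, revcomp

TRUTH_COLUMNS = [
    "patient", "lesion", "label", "position", "ref", "alt",
    "var_type", "true_vaf", "origin",
]

_BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
# code -> index in ACGT (255 = not a base)
_CODE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TO_IDX[_b] = _i


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic cohort generator.

    ``lesions_per_patient`` may be a fixed count or an inclusive (lo, hi)
    range sampled per patient.  ``deamination_rate`` is the per-vulnerable-
    site (C or G on the reference top strand) probability that a lesion
    acquires a low-fraction deamination artifact there.  Depth per amplicon
    is negative binomial with mean ``depth_mean`` and shape
    ``depth_dispersion``.
    """

    n_patients: int = 3
    lesions_per_patient: int | tuple[int, int] = (2, 4)
    n_germline: int = 10
    n_trunk: int = 3
    n_branch: int = 2
    n_private: int = 2
    vaf_alpha: float = 0.8
    vaf_beta: float = 0.8
    vaf_min: float = 0.05
    somatic_homoplasmic_fraction: float = 0.2
    clonal_drift: float = 1.0
    indel_fraction: float = 0.1
    spectrum_weights: tuple[float, float, float] = (0.45, 0.35, 0.20)
    deamination_rate: float = 0.005
    artifact_vaf_max: float = 0.01
    sequencing_error_rate: float = 0.001
    off_target_fraction: float = 0.025
    depth_mean: float = 2000.0
    depth_dispersion: float = 20.0
    read_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deamination_rate", "sequencing_error_rate",
                     "off_target_fraction", "vaf_min", "artifact_vaf_max",
                     "somatic_homoplasmic_fraction", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_patients", "n_germline", "n_trunk", "n_branch", "n_private"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


@dataclass
class CloneTree:
    """Rooted clonal tree; lesions are leaves, variants live on edges.

    An edge is identified by its child node; the synthetic root's own
    "edge" carries germline and trunk variants (present in every leaf).
    """

    parent: dict[str, str | None]           # child -> parent (root maps to None)
    leaves: list[str]
    variant_placement: dict[str, str] = field(default_factory=dict)  # label -> node

    @property
    def root(self) -> str:
        return next(n for n, p in self.parent.items() if p is None)

    def children(self, node: str) -> list[str]:
        return sorted(n for n, p in self.parent.items() if p == node)

    def clade(self, node: str) -> frozenset[str]:
        """Leaves below (and including) a node."""
        if node in self.leaves:
            return frozenset([node])
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            kids = self.children(n)
            if not kids and n in self.leaves:
                out.add(n)
            stack.extend(kids)
        return frozenset(out)

    def carriers(self, label: str) -> frozenset[str]:
        return self.clade(self.variant_placement[label])

    def clades(self) -> set[frozenset[str]]:
        """All leaf sets induced by edges carrying at least one variant."""
        return {self.carriers(lab) for lab in self.variant_placement}


def _sample_tree(lesions: list[str], n_branch: int, rng: np.random.Generator) -> CloneTree:
    """One or two nested internal nodes when branch variants are requested."""
    parent: dict[str, str | None] = {"ROOT": None}
    for leaf in lesions:
        parent[leaf] = "ROOT"
    k = len(lesions)
    if n_branch > 0 and k >= 3:
        size = int(rng.integers(2, k))  # 2 .. k-1
        subset = sorted(rng.choice(lesions, size=size, replace=False))
        parent["INT1"] = "ROOT"
        for leaf in subset:
            parent[leaf] = "INT1"
        if n_branch >= 2 and len(subset) >= 3:
            size2 = int(rng.integers(2, len(subset)))
            subset2 = sorted(rng.choice(subset, size=size2, replace=False))
            parent["INT2"] = "INT1"
            for leaf in subset2:
                parent[leaf] = "INT2"
    return CloneTree(parent=parent, leaves=list(lesions))


def _allowed_positions(reference: MtReference, panel: Panel | None) -> np.ndarray:
    """1-based positions outside every primer footprint."""
    L = reference.length
    blocked = panel.primer_footprint_positions() if panel is not None else set()
    return np.array([p for p in range(1, L + 1) if p not in blocked], dtype=np.int64)


def _truncated_beta(cfg: SimConfig, rng: np.random.Generator) -> float:
    if rng.random() < cfg.somatic_homoplasmic_fraction:
        return 1.0
    for _ in range(1000):
        v = float(rng.beta(cfg.vaf_alpha, cfg.vaf_beta))
        if v >= cfg.vaf_min:
            return round(v, 4)
    return cfg.vaf_min


def _draw_snv(reference: MtReference, allowed: list[int], used: set[int],
              cfg: SimConfig, rng: np.random.Generator) -> VariantDescriptor:
    w = np.asarray(cfg.spectrum_weights, dtype=float)
    cls = rng.choice(3, p=w / w.sum())
    for _ in range(10000):
        pos = int(rng.choice(allowed))
        if pos in used:
            continue
        ref = reference.base(pos)
        if cls == 0 and ref in "TA":          # T>C / A>G transitions
            alt = "C" if ref == "T" else "G"
        elif cls == 1 and ref in "GC":        # G>A / C>T transitions
            alt = "A" if ref == "G" else "T"
        elif cls == 2:                        # transversions
            alt = str(rng.choice([b for b in _BASES if b not in (ref, _transition(ref))]))
        else:
            continue
        return VariantDescriptor(pos, ref, alt)
    raise SimulationError("could not place SNV without collision")


def _transition(base: str) -> str:
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[base]


def _draw_indel(reference: MtReference, allowed: list[int], used: set[int],
                rng: np.random.Generator) -> VariantDescriptor:
    """Single-base indel at an unambiguous (non-homopolymer) site."""
    L = reference.length
    for _ in range(10000):
        pos = int(rng.choice(allowed))
        if pos in used or pos + 1 in used or pos - 1 in used:
            continue
        here = reference.base(pos)
        before, after = reference.base(pos - 1 if pos > 1 else L), reference.base(pos + 1)
        if rng.random() < 0.5:
            if here != before and here != after:  # canonical placement is unique
                return VariantDescriptor(pos, here, "")
        else:
            choices = [b for b in _BASES if b != here and b != after]
            if choices:
                return VariantDescriptor(pos, "", str(rng.choice(choices)))
    raise SimulationError("could not place indel without collision")


def simulate_patient(
    config: SimConfig,
    panel: Panel | None,
    reference: MtReference,
    patient_id: str,
    rng: np.random.Generator,
    n_lesions: int | None = None,
) -> tuple[CloneTree, pd.DataFrame]:
    """Plant a clonal tree of variants for one patient; returns (tree, truth).

    Germline polymorphisms are homoplasmic in every lesion and drawn from
    the packaged database snapshot where possible, so downstream annotation
    recognises them.  Branch variants need an internal edge (>=3 lesions);
    with 2 lesions they are re-allocated alternately to trunk and private.
    Planted positions avoid primer footprints and never collide.
    """
    if n_lesions is None:
        lp = config.lesions_per_patient
        n_lesions = lp if isinstance(lp, int) else int(rng.integers(lp[0], lp[1] + 1))
    if n_lesions < 1:
        raise SimulationError("lesions_per_patient must be >= 1")
    lesions = [f"TN{i + 1}" for i in range(n_lesions)]

    n_trunk, n_branch, n_private = config.n_trunk, config.n_branch, config.n_private
    if n_branch > 0 and n_lesions < 3:
        # no internal edge exists: re-allocate alternately to trunk / private
        extra_trunk = (n_branch + 1) // 2
        n_trunk, n_private, n_branch = n_trunk + extra_trunk, n_private + n_branch - extra_trunk, 0
    tree = _sample_tree(lesions, n_branch, rng)
    internal = [n for n in tree.parent if n.startswith("INT")]

    allowed = _allowed_positions(reference, panel)
    allowed_set = set(int(p) for p in allowed)
    used: set[int] = set()
    rows: list[dict] = []

    # -- germline: homoplasmic database polymorphisms shared by all lesions
    db = load_polymorphism_db()
    db_sites = db[[p in allowed_set and reference.base(p) == r
                   for p, r in zip(db["position"], db["ref"])]]
    db_sites = db_sites.drop_duplicates("position").sort_values("position")
    take = min(config.n_germline, len(db_sites))
    picked = db_sites.iloc[sorted(rng.choice(len(db_sites), size=take, replace=False))]
    germline: list[VariantDescriptor] = []
    for _, row in picked.iterrows():
        germline.append(VariantDescriptor(int(row["position"]), row["ref"], row["alt"]))
        used.add(int(row["position"]))
    while len(germline) < config.n_germline:  # top up with novel homoplasmic sites
        d = _draw_snv(reference, allowed, used, config, rng)
        used.add(d.position)
        germline.append(d)

    def _new_somatic() -> VariantDescriptor:
        if rng.random() < config.indel_fraction:
            d = _draw_indel(reference, allowed, used, rng)
        else:
            d = _draw_snv(reference, allowed, used, config, rng)
        used.add(d.position)
        return d

    placements: list[tuple[VariantDescriptor, str, str]] = []  # (descriptor, node, origin)
    for _ in range(n_trunk):
        placements.append((_new_somatic(), "ROOT", "trunk"))
    for i in range(n_branch):
        placements.append((_new_somatic(), internal[i % len(internal)], "branch"))
    for i in range(n_private):
        placements.append((_new_somatic(), lesions[i % n_lesions], "private"))

    L = reference.length
    for d in germline:
        tree.variant_placement[d.label(L)] = "ROOT"
        for lesion in lesions:
            rows.append(dict(patient=patient_id, lesion=lesion, label=d.label(L),
                             position=d.position, ref=d.ref, alt=d.alt,
                             var_type=d.var_type, true_vaf=1.0, origin="germline"))
    for d, node, origin in placements:
        tree.variant_placement[d.label(L)] = node
        base_vaf = _truncated_beta(config, rng)
        carriers = sorted(tree.clade(node))
        for j, lesion in enumerate(carriers):
            vaf = min(1.0, round(base_vaf * config.clonal_drift ** j, 4))
            rows.append(dict(patient=patient_id, lesion=lesion, label=d.label(L),
                             position=d.position, ref=d.ref, alt=d.alt,
                             var_type=d.var_type, true_vaf=vaf, origin=origin))

    # -- FFPE deamination artifacts: independent per lesion, low VAF
    if config.deamination_rate > 0:
        seq = np.frombuffer(reference.sequence.encode(), dtype=np.uint8)
        vulnerable = np.nonzero((seq == ord("C")) | (seq == ord("G")))[0] + 1
        vulnerable = vulnerable[np.isin(vulnerable, allowed)]
        vulnerable = np.array([p for p in vulnerable if p not in used])
        for lesion in lesions:
            hits = vulnerable[rng.random(len(vulnerable)) < config.deamination_rate]
            for pos in hits:
                ref = reference.base(int(pos))
                alt = "T" if ref == "C" else "A"
                vaf = round(float(rng.uniform(0.002, config.artifact_vaf_max)), 4)
                d = VariantDescriptor(int(pos), ref, alt)
                rows.append(dict(patient=patient_id, lesion=lesion, label=d.label(L),
                                 position=d.position, ref=d.ref, alt=d.alt,
                                 var_type="SNV", true_vaf=vaf, origin="artifact"))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["lesion", "position", "alt"], kind="stable").reset_index(drop=True)
    return tree, truth


# ---------------------------------------------------------------------------
# read simulation


def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """In-place per-base substitution errors: rotate to one of the 3 other bases."""
    if rate <= 0:
        return
    mask = rng.random(mat.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return
    shifts = rng.integers(1, 4, size=n_err)
    idx = _CODE_TO_IDX[mat[mask]]
    idx = np.where(idx == 255, 0, idx)  # N errors become A-cycle; negligible
    mat[mask] = _BASE_CODES[(idx + shifts) % 4]


def _edit_string(s: str, edits: list[tuple[int, VariantDescriptor]]) -> str:
    """Apply indel/SNV descriptors at 0-based insert offsets, right to left."""
    for off, d in sorted(edits, key=lambda e: -e[0]):
        if d.var_type == "SNV":
            s = s[:off] + d.alt + s[off + 1:]
        elif d.var_type == "deletion":
            s = s[:off] + s[off + len(d.ref):]
        else:  # insertion after the anchor base
            s = s[: off + 1] + d.alt + s[off + 1:]
    return s


def simulate_reads(
    truth: pd.DataFrame,
    panel: Panel,
    config: SimConfig,
    lesion: str,
    rng: np.random.Generator,
    r1_path: str | Path,
    r2_path: str | Path,
    patient_id: str | None = None,
) -> dict:
    """Write paired FASTQ for one lesion; headers carry amplicon id and
    on/off-target origin for truth-aware evaluation.

    Returns a summary dict (pair counts).  Raises
    :class:`SimulationError` if reads cannot span the largest amplicon.
    """
    if any(a.pool is None for a in panel.amplicons):
        raise PanelError("assign pools first")
    ref = panel.reference
    L = ref.length
    k = panel.primer_length
    longest = max(a.insert_length(L) for a in panel.amplicons) + 2 * k
    if config.read_length < longest:
        raise SimulationError(
            f"read cannot span amplicon: read_length {config.read_length} < {longest}"
        )
    sub = truth[truth["lesion"] == lesion]
    if patient_id is not None:
        sub = sub[sub["patient"] == patient_id]
    variants = [
        (VariantDescriptor(int(r.position), r.ref, r.alt), float(r.true_vaf))
        for r in sub.itertuples()
    ]

    p_nb = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    qual = "I"
    pair_n = 0
    n_on = 0
    r1_buf, r2_buf = io.StringIO(), io.StringIO()

    for amp in panel.amplicons:
        m = amp.insert_length(L)
        positions = list(amp.insert_positions(L))
        pos_to_off = {p: i for i, p in enumerate(positions)}
        insert = panel.insert_sequence(amp)
        n = int(rng.negative_binomial(config.depth_dispersion, p_nb))
        if n == 0:
            continue
        # which reads carry which variants (template-level, so both mates agree)
        snv_edits: list[tuple[np.ndarray, int, int]] = []  # (mask, offset, alt code)
        indel_edits: list[tuple[np.ndarray, int, VariantDescriptor]] = []
        for d, vaf in variants:
            if d.var_type == "insertion":
                ok = d.position in pos_to_off and (d.position % L + 1) in pos_to_off
            elif d.var_type == "deletion":
                ok = all(((d.position - 1 + i) % L) + 1 in pos_to_off
                         for i in range(len(d.ref)))
            else:
                ok = d.position in pos_to_off
            if not ok:
                continue
            mask = rng.random(n) < vaf
            off = pos_to_off[d.position]
            if d.var_type == "SNV":
                snv_edits.append((mask, off, ord(d.alt)))
            else:
                indel_edits.append((mask, off, d))

        template = np.frombuffer(insert.encode(), dtype=np.uint8)
        mat = np.tile(template, (n, 1))
        for mask, off, code in snv_edits:
            mat[mask, off] = code
        indel_rows = np.zeros(n, dtype=bool)
        for mask, _, _ in indel_edits:
            indel_rows |= mask
        plain = ~indel_rows

        # independent sequencing errors on each mate's insert copy
        mat1 = mat.copy()
        _apply_errors(mat1, config.sequencing_error_rate, rng)
        _apply_errors(mat, config.sequencing_error_rate, rng)
        b1, b2 = mat1.tobytes(), mat.tobytes()
        rc_rev = revcomp(amp.rev_primer)
        for i in range(n):
            if plain[i]:
                ins1 = b1[i * m:(i + 1) * m].decode()
                ins2 = b2[i * m:(i + 1) * m].decode()
            else:
                edits = [(off, d) for mask, off, d in indel_edits if mask[i]]
                base1 = b1[i * m:(i + 1) * m].decode()
                base2 = b2[i * m:(i + 1) * m].decode()
                ins1 = _edit_string(base1, edits)
                ins2 = _edit_string(base2, edits)
            name = f"{lesion}:amp={amp.id}:n={pair_n}:target=on"
            frag1 = amp.fwd_primer + ins1 + rc_rev
            frag2 = amp.fwd_primer + ins2 + rc_rev
            r1_buf.write(f"@{name}/1\n{frag1}\n+\n{qual * len(frag1)}\n")
            rc = revcomp(frag2)
            r2_buf.write(f"@{name}/2\n{rc}\n+\n{qual * len(rc)}\n")
            pair_n += 1
            n_on += 1

    # -- off-target reads from a scrambled decoy
    f = config.off_target_fraction
    n_off = int(rng.binomial(n_on, f / (1.0 - f))) if f > 0 and n_on > 0 else 0
    if n_off:
        decoy_len = max(4 * config.read_length, 2000)
        decoy = "".join(rng.choice(list(_BASES), size=decoy_len))
        starts = rng.integers(0, decoy_len - config.read_length, size=n_off)
        for s in starts:
            frag = decoy[s: s + config.read_length]
            name = f"{lesion}:amp=NA:n={pair_n}:target=off"
            r1_buf.write(f"@{name}/1\n{frag}\n+\n{qual * len(frag)}\n")
            rc = revcomp(frag)
            r2_buf.write(f"@{name}/2\n{rc}\n+\n{qual * len(rc)}\n")
            pair_n += 1

    Path(r1_path).write_text(r1_buf.getvalue())
    Path(r2_path).write_text(r2_buf.getvalue())
    return {"pairs": pair_n, "on_target_pairs": n_on, "off_target_pairs": n_off}


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Truth table as TSV, one row per (lesion, variant), fixed column order."""
    truth.to_csv(path, sep="\t", index=False, columns=TRUTH_COLUMNS)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    for col in ("ref", "alt"):
        df[col] = df[col].fillna("")
    return df[TRUTH_COLUMNS]


def make_sample_sheet(patients: dict[str, list[str]], rng: np.random.Generator) -> pd.DataFrame:
    """Sample sheet (patient, lesion, histology in {AD, SQ}, grade)."""
    rows = []
    for pid in sorted(patients):
        for lesion in patients[pid]:
            rows.append(dict(patient=pid, lesion=lesion,
                             histology=str(rng.choice(["AD", "SQ"])),
                             grade=str(rng.choice(["G2", "G3"]))))
    return pd.DataFrame(rows, columns=["patient", "lesion", "histology", "grade"])


def patient_05_like(
    reference: MtReference,
    panel: Panel | None = None,
    patient_id: str = "P05",
) -> tuple[CloneTree, pd.DataFrame]:
    """Three-lesion preset: a trunk set plus three branch variants confined
    to lesions TN2 and TN3 with VAFs increasing along the subclone edge,
    mirroring a nested-subclone expansion pattern.

    Branch positions sit near 215, 2268 and 11711 (shifted off any primer
    footprint of the supplied panel); alleles are transitions from the
    packaged reference base, so labels depend on the reference build.
    """
    lesions = ["TN1", "TN2", "TN3"]
    parent = {"ROOT": None, "TN1": "ROOT", "INT1": "ROOT", "TN2": "INT1", "TN3": "INT1"}
    tree = CloneTree(parent=parent, leaves=lesions)
    blocked = panel.primer_footprint_positions() if panel is not None else set()

    def _usable(pos: int) -> int:
        while pos in blocked:
            pos += 1
        return pos

    def _snv_at(pos: int) -> VariantDescriptor:
        ref = reference.base(pos)
        return VariantDescriptor(pos, ref, _transition(ref))

    L = reference.length
    rows = []
    trunk = [_snv_at(_usable(p)) for p in (1005, 5105, 9005)]
    branch = [_snv_at(_usable(p)) for p in (215, 2268, 11711)]
    private = [_snv_at(_usable(3500))]
    for d in trunk:
        tree.variant_placement[d.label(L)] = "ROOT"
        for lesion in lesions:
            rows.append(dict(patient=patient_id, lesion=lesion, label=d.label(L),
                             position=d.position, ref=d.ref, alt=d.alt,
                             var_type="SNV", true_vaf=0.9, origin="trunk"))
    for d, vafs in zip(branch, ({"TN2": 0.25, "TN3": 0.45},
                                {"TN2": 0.30, "TN3": 0.50},
                                {"TN2": 0.35, "TN3": 0.55})):
        tree.variant_placement[d.label(L)] = "INT1"
        for lesion, vaf in vafs.items():
            rows.append(dict(patient=patient_id, lesion=lesion, label=d.label(L),
                             position=d.position, ref=d.ref, alt=d.alt,
                             var_type="SNV", true_vaf=vaf, origin="branch"))
    for d in private:
        tree.variant_placement[d.label(L)] = "TN1"
        rows.append(dict(patient=patient_id, lesion="TN1", label=d.label(L),
                         position=d.position, ref=d.ref, alt=d.alt,
                         var_type="SNV", true_vaf=0.4, origin="private"))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["lesion", "position", "alt"], kind="stable").reset_index(drop=True)
    return tree, truth
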