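"""Trunk/branch/private classification and clonal-tree reconstruction.

For a patient with several tumour lesions, each somatic variant's carrier
set (the lesions where it is present) places it in exactly one category:
trunk (all lesions — evidence of a common cell of origin), branch (a proper
subset of >= 2 lesions) or private (one lesion).  If the family of carrier
sets is laminar — any two nested or disjoint — it is exactly the set of
clades of a rooted tree, which is reconstructed with variants attached to
edges.  Non-laminar families (possible with real data) are resolved to a
maximal laminar subfamily greedily, and the crossing pairs are reported
rather than hidden.

Without matched normal tissue, somatic status is heuristic: a call
annotated as a known population polymorphism and homoplasmic in every
lesion of the patient is treated as germline; everything else is a somatic
candidate.

The per-patient verdict follows the carrier evidence: ``untrackable`` when
only shared homoplasmic polymorphisms remain (no somatic variant to track),
``monoclonal`` when at least one somatic variant is shared by two or more
lesions (trunk, or branch — either proves a common progenitor of its
carriers), and ``independent`` when somatic variants exist but no two
lesions share any.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .simulate import CloneTree


class ClonalityError(ValueError):
    pass


@dataclass
class ClonalAssignment:
    patient: str
    lesions: list[str]
    somatic: pd.DataFrame     # label, position, ref, alt, category, carriers, vafs
    polymorphisms: pd.DataFrame  # germline-annotated rows (label, carriers, vafs)

    def category_counts(self) -> dict[str, int]:
        counts = self.somatic["category"].value_counts().to_dict()
        return {c: int(counts.get(c, 0)) for c in ("trunk", "branch", "private")}


@dataclass
class ClonalVerdict:
    patient: str
    verdict: str  # monoclonal | untrackable | independent
    n_trunk: int
    n_branch: int
    n_private: int
    n_polymorphisms: int
    tree: CloneTree | None = None
    conflicts: list[tuple[frozenset, frozenset]] = field(default_factory=list)


def classify_trunk_branch_private(
    patient_calls: pd.DataFrame,
    lesions: list[str],
    presence_min_vaf: float = 0.05,
) -> ClonalAssignment:
    """Partition a patient's somatic variants by carrier set.

    ``patient_calls`` holds one row per (lesion, variant) PASS call with at
    least columns lesion/position/ref/alt/label/vaf/plasmy and (optionally)
    ``known_polymorphism``.  Presence in a lesion means a PASS call with
    VAF >= ``presence_min_vaf`` there.  Raises for single-lesion patients.
    """
    if len(lesions) < 2:
        raise ClonalityError("clonality undefined for one lesion")
    if len(patient_calls) and patient_calls["patient"].nunique() > 1:
        raise ClonalityError("calls from more than one patient")
    all_lesions = frozenset(lesions)
    som_rows, poly_rows = [], []
    if len(patient_calls) == 0:
        grouped = []
    else:
        grouped = patient_calls.groupby(["position", "ref", "alt"], sort=True)
    for (pos, ref, alt), sub in grouped:
        present = sub[sub["vaf"] >= presence_min_vaf]
        carriers = frozenset(present["lesion"])
        if not carriers:
            continue
        vafs = dict(zip(present["lesion"], present["vaf"]))
        label = sub["label"].iloc[0]
        known = bool(sub.get("known_polymorphism", pd.Series([False])).all())
        germline = (
            known
            and carriers == all_lesions
            and (present["plasmy"] == "homoplasmic").all()
        )
        row = dict(label=label, position=int(pos), ref=ref, alt=alt,
                   carriers=carriers, vafs=vafs)
        if germline:
            poly_rows.append(row)
            continue
        if carriers == all_lesions:
            row["category"] = "trunk"
        elif len(carriers) == 1:
            row["category"] = "private"
        else:
            row["category"] = "branch"
        som_rows.append(row)
    som = pd.DataFrame(som_rows, columns=["label", "position", "ref", "alt",
                                          "category", "carriers", "vafs"])
    poly = pd.DataFrame(poly_rows, columns=["label", "position", "ref", "alt",
                                            "carriers", "vafs"])
    som = som.sort_values("position", kind="stable").reset_index(drop=True)
    patient = patient_calls["patient"].iloc[0] if len(patient_calls) else ""
    return ClonalAssignment(patient=patient, lesions=list(lesions),
                            somatic=som, polymorphisms=poly)


def _laminar(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def build_clonal_tree(
    assignment: ClonalAssignment,
) -> tuple[CloneTree | None, list[tuple[frozenset, frozenset]]]:
    """Reconstruct the clonal tree from carrier sets.

    Distinct carrier sets are candidate clades.  Crossing pairs (neither
    nested nor disjoint) are reported; a maximal laminar subfamily is kept
    greedily — by descending variant support, then larger set, then smaller
    minimum variant position.  Returns (None, []) with no somatic variants.
    """
    som = assignment.somatic
    if len(som) == 0:
        return None, []
    support: dict[frozenset, list] = {}
    for row in som.itertuples():
        support.setdefault(row.carriers, []).append(row)
    sets = list(support)
    conflicts = [
        (a, b) for i, a in enumerate(sets) for b in sets[i + 1:] if not _laminar(a, b)
    ]
    order = sorted(
        sets,
        key=lambda s: (-len(support[s]), -len(s), min(r.position for r in support[s])),
    )
    kept: list[frozenset] = []
    for s in order:
        if all(_laminar(s, t) for t in kept):
            kept.append(s)

    all_lesions = frozenset(assignment.lesions)
    # nodes: the root clade plus every kept set; leaves attach to the
    # smallest containing clade
    clades = sorted(set(kept) | {all_lesions}, key=lambda s: (-len(s), sorted(s)))
    name_of: dict[frozenset, str] = {}
    for s in clades:
        name_of[s] = "ROOT" if s == all_lesions else "|".join(sorted(s))
    parent: dict[str, str | None] = {"ROOT": None}
    for s in clades:
        if s == all_lesions:
            continue
        supersets = [t for t in clades if s < t]
        direct = min(supersets, key=len)
        parent[name_of[s]] = name_of[direct]
    for leaf in assignment.lesions:
        containing = [s for s in clades if leaf in s and len(s) > 1]
        host = min(containing, key=len) if containing else all_lesions
        if frozenset([leaf]) in name_of and name_of[frozenset([leaf])] == leaf:
            continue  # leaf already a node via a private-variant clade
        parent[leaf] = name_of[host]
    tree = CloneTree(parent=parent, leaves=list(assignment.lesions))
    for row in som.itertuples():
        if row.carriers in name_of:
            tree.variant_placement[row.label] = name_of[row.carriers]
    return tree, conflicts


def clonal_verdict(
    assignment: ClonalAssignment,
    tree: CloneTree | None = None,
    conflicts: list | None = None,
) -> ClonalVerdict:
    """Patient-level verdict from the trunk/branch/private evidence."""
    counts = assignment.category_counts()
    n_som = int(len(assignment.somatic))
    if n_som == 0:
        verdict = "untrackable"
    elif counts["trunk"] > 0 or counts["branch"] > 0:
        verdict = "monoclonal"
    else:
        verdict = "independent"
    return ClonalVerdict(
        patient=assignment.patient,
        verdict=verdict,
        n_trunk=counts["trunk"],
        n_branch=counts["branch"],
        n_private=counts["private"],
        n_polymorphisms=int(len(assignment.polymorphisms)),
        tree=tree,
        conflicts=list(conflicts or []),
    )


def venn_summary(assignment: ClonalAssignment) -> pd.DataFrame:
    """Variant counts per carried lesion subset (somatic + polymorphisms).

    Subset counts sum to the total number of distinct variants; trunk and
    shared polymorphisms land in the full-intersection cell.
    """
    counts: dict[tuple[str, ...], int] = {}
    for df in (assignment.somatic, assignment.polymorphisms):
        for row in df.itertuples():
            key = tuple(sorted(row.carriers))
            counts[key] = counts.get(key, 0) + 1
    rows = [dict(lesions=",".join(k), n_lesions=len(k), count=v)
            for k, v in sorted(counts.items(), key=lambda kv: (-len(kv[0]), kv[0]))]
    return pd.DataFrame(rows, columns=["lesions", "n_lesions", "count"])


def to_newick(tree: CloneTree) -> str:
    """Newick with lesions as leaves; edge comments list supporting variants."""
    by_node: dict[str, list[str]] = {}
    for label, node in tree.variant_placement.items():
        by_node.setdefault(node, []).append(label)

    def comment(node: str) -> str:
        labels = sorted(by_node.get(node, []))
        return f"[&variants={'|'.join(labels)}]" if labels else ""

    def render(node: str) -> str:
        kids = tree.children(node)
        if not kids:
            return f"{node}{comment(node)}"
        inner = ",".join(render(k) for k in kids)
        name = "" if node == tree.root else node.replace("|", "_")
        return f"({inner}){name}{comment(node)}"

    return render(tree.root) + ";"


def write_clonality_report(assignment: ClonalAssignment, verdict: ClonalVerdict,
                           path: str | Path) -> None:
    """Per-patient TSV: one row per variant with category, carriers and VAFs."""
    with open(path, "w") as out:
        out.write(f"# patient={assignment.patient}\tverdict={verdict.verdict}\t"
                  f"trunk={verdict.n_trunk}\tbranch={verdict.n_branch}\t"
                  f"private={verdict.n_private}\tpolymorphisms={verdict.n_polymorphisms}\n")
        out.write("label\tposition\tcategory\tcarriers\tvafs\n")
        for row in assignment.somatic.itertuples():
            vafs = ",".join(f"{l}:{row.vafs[l]:.4f}" for l in sorted(row.vafs))
            out.write(f"{row.label}\t{row.position}\t{row.category}\t"
                      f"{','.join(sorted(row.carriers))}\t{vafs}\n")
        for row in assignment.polymorphisms.itertuples():
            vafs = ",".join(f"{l}:{row.vafs[l]:.4f}" for l in sorted(row.vafs))
            out.write(f"{row.label}\t{row.position}\tpolymorphism\t"
                      f"{','.join(sorted(row.carriers))}\t{vafs}\n")
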