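"""Cohort-level false-variant heuristics and the review/pass partition.

Four heuristics mark putative artifacts: recurrence across unrelated
patients at near-identical allele fraction (multiplex PCR artifacts strike
the same site at the same rate in every library), proximity to amplicon
ends, location in repetitive microsatellite regions, and location in
positions whose cross-sample background noise is extreme.

No heuristic deletes a call.  Flagged calls are routed to a review table
with full flag provenance and a ``needs_orthogonal_confirmation`` marker
(the analogue of re-assessing candidates by Sanger sequencing); unflagged
calls pass.  All heuristics are pure functions of the cohort snapshot, so
they commute and the pass/review split is a deterministic partition.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .calling import Pileup
from .panel import Panel
from .reference import MtRegion

FLAG_RECURRENT = "recurrent_similar_vaf"
FLAG_AMPLICON_END = "amplicon_end"
FLAG_REPETITIVE = "repetitive_region"
FLAG_NOISY = "noisy_region"


class FilterError(ValueError):
    pass


def _add_flag(flags: str, new: str) -> str:
    current = set(flags.split(";")) - {""}
    current.add(new)
    return ";".join(sorted(current))


def cross_sample_filter(
    table: pd.DataFrame,
    vaf_tolerance: float = 0.05,
    min_patients: int = 3,
) -> pd.DataFrame:
    """Flag (position, alt) seen in >= ``min_patients`` patients with a VAF
    spread (max - min) <= ``vaf_tolerance``.

    Known homoplasmic polymorphisms are exempt: genuinely shared germline
    alleles recur across patients at VAF ~1 by nature.  A single-patient
    table is returned unchanged with a warning.
    """
    out = table.copy()
    if out["patient"].nunique() < 2:
        warnings.warn("cross-sample filter needs >= 2 patients; no-op")
        return out
    for (_, _, _), idx in out.groupby(["position", "ref", "alt"]).groups.items():
        sub = out.loc[idx]
        if sub["patient"].nunique() < min_patients:
            continue
        if sub["vaf"].max() - sub["vaf"].min() > vaf_tolerance:
            continue
        known = "known_polymorphism" in sub.columns and sub["known_polymorphism"].all()
        if known and (sub["plasmy"] == "homoplasmic").all():
            continue
        out.loc[idx, "flags"] = [_add_flag(f, FLAG_RECURRENT) for f in sub["flags"]]
    return out


def amplicon_end_filter(
    table: pd.DataFrame,
    panel: Panel,
    end_margin: int = 5,
) -> pd.DataFrame:
    """Flag positions lying within ``end_margin`` bp of an insert boundary of
    *every* covering amplicon; a position interior to any overlapping
    neighbour is exempt.  A position covered by no amplicon is an error.
    """
    out = table.copy()
    L = panel.reference.length
    cache: dict[int, bool] = {}
    for pos in out["position"].unique():
        pos = int(pos)
        covering = panel.covering(pos)
        if not covering:
            raise FilterError(f"position off-panel: {pos}")
        cache[pos] = all(a.boundary_distance(pos, L) < end_margin for a in covering)
    hit = out["position"].map(cache)
    out.loc[hit, "flags"] = [_add_flag(f, FLAG_AMPLICON_END) for f in out.loc[hit, "flags"]]
    return out


def region_filter(table: pd.DataFrame, region_map: list[MtRegion],
                  genome_length: int) -> pd.DataFrame:
    """Flag calls inside microsatellite-category regions (e.g. the polyC
    stretches at 302-315 and 16184-16193)."""
    out = table.copy()
    micro = [r for r in region_map if r.category == "microsatellite"]
    hit = out["position"].map(
        lambda p: any(r.contains(int(p), genome_length) for r in micro)
    )
    out.loc[hit, "flags"] = [_add_flag(f, FLAG_REPETITIVE) for f in out.loc[hit, "flags"]]
    return out


def noise_filter(
    table: pd.DataFrame,
    pileups: Mapping[tuple[str, str], Pileup],
    noise_quantile: float = 0.99,
) -> pd.DataFrame:
    """Flag calls at positions of extreme cross-sample background noise.

    Per position, noise is the mean non-reference allele fraction across
    the samples *not* carrying a call there (carriers are excluded so true
    variants never inflate their own background).  Positions above the
    cohort ``noise_quantile`` of that statistic flag their calls.  Needs
    pileups from >= 3 samples, else a warned no-op.
    """
    out = table.copy()
    samples = sorted(pileups)
    if len(samples) < 3:
        warnings.warn("noise filter needs >= 3 samples; no-op")
        return out
    any_pileup = pileups[samples[0]]
    L = any_pileup.reference.length
    ref_idx = np.array(
        [{"A": 0, "C": 1, "G": 2, "T": 3}.get(b, 4) for b in any_pileup.reference.sequence]
    )
    nonref = np.zeros((len(samples), L))
    has_depth = np.zeros((len(samples), L), dtype=bool)
    for si, key in enumerate(samples):
        p = pileups[key]
        depth = p.depth_array().astype(float)
        ref_counts = p.base_counts.sum(axis=0)[np.arange(L), ref_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, 1.0 - ref_counts / depth, 0.0)
        nonref[si] = frac
        has_depth[si] = depth > 0
    carrier = np.zeros((len(samples), L), dtype=bool)
    key_of = {key: i for i, key in enumerate(samples)}
    for row in out.itertuples():
        key = (row.patient, row.lesion)
        if key in key_of:
            carrier[key_of[key], row.position - 1] = True
    usable = has_depth & ~carrier
    with np.errstate(invalid="ignore"):
        noise = np.where(usable.sum(axis=0) > 0,
                         (nonref * usable).sum(axis=0) / np.maximum(usable.sum(axis=0), 1),
                         0.0)
    threshold = float(np.quantile(noise[has_depth.any(axis=0)], noise_quantile))
    noisy_positions = set((np.nonzero(noise > threshold)[0] + 1).tolist())
    hit = out["position"].isin(noisy_positions)
    out.loc[hit, "flags"] = [_add_flag(f, FLAG_NOISY) for f in out.loc[hit, "flags"]]
    return out


def apply_filters(
    table: pd.DataFrame,
    panel: Panel,
    region_map: list[MtRegion],
    pileups: Mapping[tuple[str, str], Pileup] | None = None,
    vaf_tolerance: float = 0.05,
    min_patients: int = 3,
    end_margin: int = 5,
    noise_quantile: float = 0.99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every applicable heuristic and split calls into (pass, review).

    Flags accumulate (union semantics); rows are never dropped, so the two
    tables partition the input.  Review rows gain
    ``needs_orthogonal_confirmation=True``.
    """
    out = table.copy()
    if out["patient"].nunique() >= 2:
        out = cross_sample_filter(out, vaf_tolerance, min_patients)
    out = amplicon_end_filter(out, panel, end_margin)
    out = region_filter(out, region_map, panel.reference.length)
    if pileups is not None and len(pileups) >= 3:
        out = noise_filter(out, pileups, noise_quantile)
    flagged = out["flags"] != ""
    pass_table = out[~flagged].reset_index(drop=True)
    review = out[flagged].reset_index(drop=True)
    review = review.assign(needs_orthogonal_confirmation=True)
    return pass_table, review
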