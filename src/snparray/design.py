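"""Candidate filtering, ranking and greedy probeset selection.

Implements the array-design flow: drop unacceptable probesets (keeping
previously validated SNPs with at least one buildable probeset), rank
transcripts and probesets-within-transcripts, then fill the array by
cycling through transcripts in rank order so genome coverage is maximized
before any transcript contributes a second SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "buildable",
    "filter_candidates",
    "rank_transcripts",
    "rank_probesets",
    "select_array",
    "hit_category",
]

HIGH_TIER = "high"
_AT_CG = ({"A", "T"}, {"C", "G"})
_HIT_ORDER = {"one": 0, "gt1": 1, "zero": 2}
_PERFECT_ORDER = {1: 0, 2: 1, 0: 2}


def _variants(spec) -> list[tuple[int, str]]:
    if not spec or (isinstance(spec, float) and math.isnan(spec)):
        return []
    out = []
    for item in str(spec).split(";"):
        pos_s, tier = item.split(":")
        pos = int(pos_s)
        if pos == 36:
            raise ValueError("position 36 is the target SNP, not a flanking variant")
        if not 1 <= pos <= 71:
            raise ValueError(f"flanking variant position {pos} outside 1..71")
        out.append((pos, tier))
    return out


def buildable(flanking_variants, direction: str) -> bool:
    """Whether one 35-nt flank is free of high-confidence variants.

    Forward probesets use positions 1-35, reverse probesets 37-71; a
    direction is buildable iff no high-tier variant falls in its flank.
    ``flanking_variants`` is a list of ``(position, tier)`` pairs or the
    serialized ``"pos:tier;..."`` string.
    """
    variants = (
        flanking_variants
        if isinstance(flanking_variants, list)
        else _variants(flanking_variants)
    )
    for pos, tier in variants:
        if pos == 36:
            raise ValueError("position 36 is the target SNP, not a flanking variant")
        if tier != HIGH_TIER:
            continue
        if direction == "forward" and pos <= 35:
            return False
        if direction == "reverse" and pos >= 37:
            return False
    return True


def _is_at_cg(allele_a: str, allele_b: str) -> bool:
    return {allele_a, allele_b} in _AT_CG


def filter_candidates(
    candidates: pd.DataFrame,
    probesets: pd.DataFrame,
    drop_at_cg: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove unacceptable probesets; return (retained, rejection log).

    A probeset is unacceptable if (1) its SNP sequence has no genome
    match, (2) high-confidence variants block both flanks, or (3) its
    recommendation is not_recommended / not_possible.  SNPs already
    validated on the earlier platform are exempt from rules (1) and (3)
    as long as the probeset direction is buildable.  A/T and C/G SNPs are
    dropped entirely unless validated.
    """
    unknown = set(probesets["snp_id"]) - set(candidates["snp_id"])
    if unknown:
        raise ValueError(f"probesets reference unknown SNPs: {sorted(unknown)[:5]}")
    cand = candidates.set_index("snp_id")
    kept_rows, rejected = [], []
    for row in probesets.itertuples():
        snp = cand.loc[row.snp_id]
        infinium = bool(snp["infinium_success"])
        variants = _variants(snp["flanking_variants"])
        is_buildable = buildable(variants, row.direction)
        reason = None
        if drop_at_cg and _is_at_cg(snp["allele_a"], snp["allele_b"]) and not infinium:
            reason = "at_cg"
        elif row.recommendation == "not_possible":
            reason = "not_possible"
        elif not buildable(variants, "forward") and not buildable(variants, "reverse"):
            reason = "flanking_variants_both_flanks"
        elif not is_buildable:
            reason = "flanking_variant_in_flank"
        elif row.n_scaffold_hits_v05 == 0 and not infinium:
            reason = "no_genome_match"
        elif row.recommendation == "not_recommended" and not infinium:
            reason = "not_recommended"
        if reason is None:
            kept_rows.append(row.Index)
        else:
            rejected.append(
                {
                    "probeset_id": row.probeset_id,
                    "snp_id": row.snp_id,
                    "reason": reason,
                }
            )
    retained = probesets.loc[kept_rows].reset_index(drop=True)
    return retained, pd.DataFrame(rejected, columns=["probeset_id", "snp_id", "reason"])


def hit_category(mean_hits: float) -> str:
    """Categorize a transcript's mean scaffold-hit count: one / gt1 / zero."""
    if mean_hits == 0:
        return "zero"
    if mean_hits <= 1:
        return "one"
    return "gt1"


def rank_transcripts(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Total order over transcripts.

    Keys, best first: scaffold-hit category (one > gt1 > zero), then
    confidence score ascending (transcripts without a score sort after
    scored ones within the same hit category), then SNP count descending,
    then transcript_id.  Expects columns ``transcript_id, hit_category,
    confidence_score, n_snps``.
    """
    df = transcripts.copy()
    df.index = pd.RangeIndex(len(df))
    df["_hit"] = df["hit_category"].map(_HIT_ORDER)
    if df["_hit"].isna().any():
        bad = df.loc[df["_hit"].isna(), "hit_category"].unique()
        raise ValueError(f"unknown hit category: {bad}")
    df["_conf"] = df["confidence_score"].fillna(float("inf"))
    df = df.sort_values(
        ["_hit", "_conf", "n_snps", "transcript_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop(columns=["_hit", "_conf"])
    df["combined_rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def _probeset_key(row, cand) -> tuple:
    snp = cand.loc[row.snp_id]
    if snp["source"] == "OSU":
        evidence = float(snp["target_snp_prob"])  # smaller is better
    else:
        evidence = -float(snp["n_detect_programs"])  # more programs better
    return (
        0 if bool(snp["infinium_success"]) else 1,
        int(row.flanking_rank),
        _PERFECT_ORDER[int(row.n_perfect_alleles)],
        -float(row.pconvert),
        evidence,
        str(row.probeset_id),
    )


def rank_probesets(
    probesets: pd.DataFrame, candidates: pd.DataFrame
) -> pd.DataFrame:
    """Order probesets of one transcript best-first.

    Keys: previously validated SNPs first; flanking rank 1 < 2 < 3;
    perfect-allele count in the order 1, 2, 0; pConvert descending;
    target-SNP evidence (probability ascending for OSU, program count
    descending for UH); probeset_id as the final tie-break.
    """
    cand = candidates.set_index("snp_id")
    keys = {row.Index: _probeset_key(row, cand) for row in probesets.itertuples()}
    order = sorted(keys, key=keys.get)
    out = probesets.loc[order].reset_index(drop=True)
    out["within_rank"] = range(1, len(out) + 1)
    return out


@dataclass
class _TranscriptState:
    ranked: pd.DataFrame  # probesets best-first
    next_idx: int = 0


def select_array(
    candidates: pd.DataFrame,
    probesets: pd.DataFrame,
    transcripts: pd.DataFrame,
    capacity: int,
    allow_second_probeset: bool = True,
) -> pd.DataFrame:
    """Greedy coverage-first selection of probesets up to ``capacity``.

    Cycles through transcripts in rank order; each pass takes the best
    not-yet-selected probeset of a not-yet-covered SNP in that transcript.
    Once all of a transcript's SNPs are covered, a second
    (opposite-direction) probeset of an already covered SNP may be taken
    if ``allow_second_probeset``.  A/T and C/G SNPs cost two capacity
    units (they need two probesets to assay); an item that does not fit
    the remaining capacity is skipped.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    cand = candidates.set_index("snp_id")
    ranked_tr = rank_transcripts(transcripts)
    states: list[_TranscriptState] = []
    for tr in ranked_tr["transcript_id"]:
        ps = probesets[probesets["snp_id"].map(
            cand["transcript_id"].to_dict()
        ) == tr]
        if len(ps):
            states.append(_TranscriptState(rank_probesets(ps, candidates)))

    covered: set[str] = set()
    selected_ids: set[str] = set()
    remaining = capacity
    out_rows = []
    progress = True
    while remaining > 0 and progress:
        progress = False
        for state in states:
            if remaining <= 0:
                break
            pick = _next_pick(
                state, covered, selected_ids, cand, allow_second_probeset
            )
            if pick is None:
                continue
            row, cost = pick
            if cost > remaining:
                continue
            remaining -= cost
            covered.add(row.snp_id)
            selected_ids.add(row.probeset_id)
            out_rows.append(
                {
                    "probeset_id": row.probeset_id,
                    "snp_id": row.snp_id,
                    "transcript_id": cand.loc[row.snp_id, "transcript_id"],
                }
            )
            progress = True
    out = pd.DataFrame(
        out_rows, columns=["probeset_id", "snp_id", "transcript_id"]
    )
    out["final_rank"] = range(1, len(out) + 1)
    return out


def _next_pick(state, covered, selected_ids, cand, allow_second):
    ranked = state.ranked
    # first choice: best probeset of an uncovered SNP
    for row in ranked.itertuples():
        if row.probeset_id in selected_ids or row.snp_id in covered:
            continue
        return row, _cost(row.snp_id, cand)
    if not allow_second:
        return None
    # all SNPs covered: opposite-direction probeset of the top-ranked SNP
    taken_dirs: dict[str, set] = {}
    for row in ranked.itertuples():
        if row.probeset_id in selected_ids:
            taken_dirs.setdefault(row.snp_id, set()).add(row.direction)
    for row in ranked.itertuples():
        if row.probeset_id in selected_ids:
            continue
        dirs = taken_dirs.get(row.snp_id, set())
        if dirs and row.direction not in dirs:
            return row, _cost(row.snp_id, cand)
    return None


def _cost(snp_id: str, cand: pd.DataFrame) -> int:
    snp = cand.loc[snp_id]
    return 2 if _is_at_cg(snp["allele_a"], snp["allele_b"]) else 1
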