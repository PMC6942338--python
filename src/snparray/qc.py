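"""Sample/plate QC, SNP category classification, and rescue protocols.

A run proceeds in up to two phases: phase 1 applies sample-level and
plate-level thresholds and classifies every probeset into one of six
categories (OTV, Other, CallRateBelowThreshold, NoMinorHom,
MonoHighResolution, PolyHighResolution); phase 2 optionally re-thresholds
the Other and CallRateBelowThreshold probesets at a stricter confidence
score and a lowered call-rate cutoff, moving qualifying probesets into a
seventh Rescued category.  Successful probesets are the polymorphic,
reliably called ones: PolyHighResolution plus Rescued.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calling import NOCALL

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "QcThresholds",
    "PROTOCOLS",
    "sample_plate_qc",
    "genotype_counts",
    "classify_snp",
    "classify_all",
    "rescue_snps",
    "summarize_categories",
    "run_protocol",
    "run_protocol_populations",
    "duplicate_accuracy",
]

CATEGORIES = (
    "OTV",
    "Other",
    "CallRateBelowThreshold",
    "NoMinorHom",
    "MonoHighResolution",
    "PolyHighResolution",
    "Rescued",
)
SUCCESS_CATEGORIES = ("PolyHighResolution", "Rescued")
CONVERTED_CATEGORIES = (
    "PolyHighResolution",
    "NoMinorHom",
    "MonoHighResolution",
    "Rescued",
)


@dataclass(frozen=True)
class QcThresholds:
    """QC thresholds; call rates are fractions in [0, 1]."""

    protocol_name: str = "default"
    dqc_min: float = 0.82
    sample_cr_min: float = 0.97
    plate_pass_fraction_min: float = 0.95
    plate_cr_min: float = 0.985
    snp_cr_cutoff: float = 0.97
    confidence_threshold: float = 0.15
    rescue_cr_cutoff: float | None = None
    rescue_confidence_threshold: float = 0.10
    otv_min_fraction: float = 0.05
    count_monomorphic_rescues: bool = False
    #: probesets used for sample/plate call rates: resolved clusters with
    #: at least this overall call rate (mimics QC on a known-good panel)
    panel_cr_min: float = 0.95

    def __post_init__(self):
        for name in (
            "dqc_min",
            "sample_cr_min",
            "plate_pass_fraction_min",
            "plate_cr_min",
            "snp_cr_cutoff",
            "confidence_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rescue_cr_cutoff is not None:
            if not 0.0 <= self.rescue_cr_cutoff <= 1.0:
                raise ValueError("rescue_cr_cutoff outside [0, 1]")
            if self.rescue_cr_cutoff > self.snp_cr_cutoff:
                raise ValueError("rescue_cr_cutoff must be <= snp_cr_cutoff")


_DEFAULT = QcThresholds()
_MODIFIED = QcThresholds(
    protocol_name="modified",
    dqc_min=0.50,
    sample_cr_min=0.80,
    plate_pass_fraction_min=0.80,
    plate_cr_min=0.90,
    snp_cr_cutoff=0.95,
    rescue_cr_cutoff=0.80,
)

PROTOCOLS: dict[str, QcThresholds] = {
    "default": _DEFAULT,
    "rescue90": replace(_DEFAULT, protocol_name="rescue90", rescue_cr_cutoff=0.90),
    "rescue80": replace(_DEFAULT, protocol_name="rescue80", rescue_cr_cutoff=0.80),
    "rescue70": replace(_DEFAULT, protocol_name="rescue70", rescue_cr_cutoff=0.70),
    "rescue60": replace(_DEFAULT, protocol_name="rescue60", rescue_cr_cutoff=0.60),
    "modified": _MODIFIED,
}


# ---------------------------------------------------------------------------
# sample / plate QC
# ---------------------------------------------------------------------------


def qc_panel(
    calls: pd.DataFrame,
    diagnostics: pd.DataFrame | None,
    thresholds: QcThresholds,
) -> list:
    """Probesets used for sample/plate call-rate QC.

    Sample call rates are meaningful only over probesets that genotype
    reliably, so the panel is restricted to resolved probesets whose
    overall call rate reaches ``thresholds.panel_cr_min``.  Without
    diagnostics, all probesets qualify on call rate alone.
    """
    cr = (calls != NOCALL).mean(axis=0)
    ok = cr >= thresholds.panel_cr_min
    if diagnostics is not None and len(diagnostics):
        resolved = diagnostics.set_index("probeset_id")["resolved"]
        ok &= calls.columns.map(lambda c: bool(resolved.get(c, True)))
    panel = list(calls.columns[ok])
    return panel if panel else list(calls.columns)


def sample_plate_qc(
    samples: pd.DataFrame,
    calls: pd.DataFrame,
    thresholds: QcThresholds,
    panel: list | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply per-sample then per-plate QC.

    ``samples`` needs columns ``sample_id, plate_id, dqc``; ``calls`` is
    samples x probesets.  Samples fail on Dish-QC or sample call rate
    (computed over ``panel`` probesets if given); whole plates fail on
    passing-sample fraction or plate call rate (the mean sample call rate
    of its passing samples).  Returns the surviving sample ids and a
    per-plate report.
    """
    req = {"sample_id", "plate_id", "dqc"}
    if not req <= set(samples.columns):
        raise ValueError(f"samples table must have columns {sorted(req)}")
    sub = calls.loc[samples["sample_id"], panel] if panel else calls.loc[
        samples["sample_id"]
    ]
    sample_cr = (sub != NOCALL).mean(axis=1)
    meta = samples.set_index("sample_id")
    passing = (meta["dqc"] >= thresholds.dqc_min) & (
        sample_cr >= thresholds.sample_cr_min
    )

    plate_rows = []
    kept: list[str] = []
    for plate, ids in meta.groupby("plate_id").groups.items():
        ids = list(ids)
        ok = passing.loc[ids]
        frac = float(ok.mean())
        plate_cr = float(sample_cr.loc[ids][ok].mean()) if ok.any() else float("nan")
        plate_pass = (
            ok.any()
            and frac >= thresholds.plate_pass_fraction_min
            and plate_cr >= thresholds.plate_cr_min
        )
        if not ok.any():
            log.warning("plate %s: no passing samples", plate)
        plate_rows.append(
            {
                "plate_id": plate,
                "n_samples": len(ids),
                "n_passing_samples": int(ok.sum()),
                "fraction_passing": frac,
                "plate_call_rate": plate_cr,
                "plate_pass": bool(plate_pass),
            }
        )
        if plate_pass:
            kept.extend(s for s in ids if passing.loc[s])
    return kept, pd.DataFrame(plate_rows)


# ---------------------------------------------------------------------------
# SNP classification
# ---------------------------------------------------------------------------


def genotype_counts(calls: np.ndarray) -> dict[str, int]:
    calls = np.asarray(calls, dtype=object)
    return {
        "n_aa": int((calls == "AA").sum()),
        "n_ab": int((calls == "AB").sum()),
        "n_bb": int((calls == "BB").sum()),
        "n_nc": int((calls == NOCALL).sum()),
    }


def _category_from_counts(
    counts: dict[str, int],
    otv_fraction: float,
    resolved: bool,
    thresholds: QcThresholds,
) -> str:
    n_called = counts["n_aa"] + counts["n_ab"] + counts["n_bb"]
    total = n_called + counts["n_nc"]
    cr = n_called / total if total else 0.0
    if otv_fraction >= thresholds.otv_min_fraction:
        return "OTV"
    if not resolved:
        return "Other"
    if cr < thresholds.snp_cr_cutoff:
        return "CallRateBelowThreshold"
    n_classes = sum(counts[k] > 0 for k in ("n_aa", "n_ab", "n_bb"))
    if n_classes <= 1:
        return "MonoHighResolution"
    if counts["n_aa"] == 0 or counts["n_bb"] == 0:
        return "NoMinorHom"
    return "PolyHighResolution"


def classify_snp(
    calls: np.ndarray,
    otv_fraction: float,
    resolved: bool,
    thresholds: QcThresholds,
    probeset_id: str = "",
) -> dict:
    """Classify one probeset from its (sample-QC'ed) calls.

    Decision order: OTV, then Other (unresolved clusters), then
    CallRateBelowThreshold, then MonoHighResolution, NoMinorHom,
    PolyHighResolution.
    """
    counts = genotype_counts(calls)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"probeset {probeset_id}: zero passing samples")
    n_called = total - counts["n_nc"]
    category = _category_from_counts(counts, otv_fraction, resolved, thresholds)
    return {
        "probeset_id": probeset_id,
        "category": category,
        "call_rate": n_called / total,
        **counts,
        "successful": category in SUCCESS_CATEGORIES,
    }


def classify_all(
    calls: pd.DataFrame,
    diagnostics: pd.DataFrame,
    thresholds: QcThresholds,
) -> pd.DataFrame:
    """Phase-1 classification of every probeset column in ``calls``."""
    diag = diagnostics.set_index("probeset_id")
    rows = []
    for ps in calls.columns:
        if ps in diag.index:
            otv_frac = float(diag.loc[ps, "otv_fraction"])
            resolved = bool(diag.loc[ps, "resolved"])
        else:
            otv_frac, resolved = 0.0, True
        if len(calls[ps]) == 0:
            log.warning("probeset %s skipped: zero passing samples", ps)
            continue
        rows.append(
            classify_snp(
                calls[ps].to_numpy(), otv_frac, resolved, thresholds, str(ps)
            )
        )
    return pd.DataFrame(rows)


def rescue_snps(
    classifications: pd.DataFrame,
    calls: pd.DataFrame,
    confidences: pd.DataFrame,
    thresholds: QcThresholds,
) -> pd.DataFrame:
    """Phase-2 rescue of Other and CallRateBelowThreshold probesets.

    Calls are re-thresholded at the stricter rescue confidence score
    (genotype labels are unchanged; only extra NoCalls appear), the call
    rate recomputed, and the probeset reclassified as Rescued iff the new
    call rate reaches ``rescue_cr_cutoff`` and at least two genotype
    classes remain.  Monomorphic rescue candidates are recorded in the
    ``rescued_monomorphic`` column and only counted as Rescued when
    ``thresholds.count_monomorphic_rescues`` is set.
    """
    if thresholds.rescue_cr_cutoff is None:
        raise ValueError("rescue requested but rescue_cr_cutoff is not set")
    out = classifications.copy()
    out["rescued_monomorphic"] = False
    eligible = out["category"].isin(["Other", "CallRateBelowThreshold"])
    for idx in out.index[eligible]:
        ps = out.at[idx, "probeset_id"]
        vec = calls[ps].to_numpy(dtype=object).copy()
        conf = confidences[ps].to_numpy()
        vec[conf > thresholds.rescue_confidence_threshold] = NOCALL
        counts = genotype_counts(vec)
        total = sum(counts.values())
        n_called = total - counts["n_nc"]
        cr = n_called / total if total else 0.0
        if cr < thresholds.rescue_cr_cutoff:
            continue
        n_classes = sum(counts[k] > 0 for k in ("n_aa", "n_ab", "n_bb"))
        polymorphic = n_classes >= 2
        if polymorphic or thresholds.count_monomorphic_rescues:
            out.at[idx, "category"] = "Rescued"
            out.at[idx, "call_rate"] = cr
            for k, v in counts.items():
                out.at[idx, k] = v
            out.at[idx, "successful"] = polymorphic
            out.at[idx, "rescued_monomorphic"] = not polymorphic
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_categories(counts: dict[str, int]) -> dict:
    """Category counts -> converted / successful totals and percentages.

    Converted = PolyHighResolution + NoMinorHom + MonoHighResolution +
    Rescued; successful = PolyHighResolution + Rescued.  Percentages are
    of the total and rounded to one decimal.
    """
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classified probesets")
    converted = sum(counts.get(c, 0) for c in CONVERTED_CATEGORIES)
    successful = sum(counts.get(c, 0) for c in SUCCESS_CATEGORIES)
    pct = lambda x: round(100.0 * x / total, 1)  # noqa: E731
    return {
        "total": total,
        "counts": {c: counts.get(c, 0) for c in CATEGORIES},
        "percent": {c: pct(counts.get(c, 0)) for c in CATEGORIES},
        "converted": converted,
        "percent_converted": pct(converted),
        "successful": successful,
        "percent_successful": pct(successful),
    }


def run_protocol(
    calls: pd.DataFrame,
    confidences: pd.DataFrame,
    diagnostics: pd.DataFrame,
    samples: pd.DataFrame,
    protocol_name: str,
) -> dict:
    """Run one QC protocol end to end on one population of samples.

    Returns a summary dict with the per-category breakdown, the passing
    samples, the plate report and the full classification table.
    """
    if protocol_name not in PROTOCOLS:
        raise ValueError(
            f"unknown protocol {protocol_name!r}; choose from {sorted(PROTOCOLS)}"
        )
    thresholds = PROTOCOLS[protocol_name]
    panel = qc_panel(calls.loc[samples["sample_id"]], diagnostics, thresholds)
    kept, plate_report = sample_plate_qc(samples, calls, thresholds, panel)
    if not kept:
        raise ValueError("no samples passed QC")
    sub_calls = calls.loc[kept]
    sub_conf = confidences.loc[kept]
    classes = classify_all(sub_calls, diagnostics, thresholds)
    if thresholds.rescue_cr_cutoff is not None:
        classes = rescue_snps(classes, sub_calls, sub_conf, thresholds)
    counts = classes["category"].value_counts().to_dict()
    summary = summarize_categories(counts)
    summary.update(
        {
            "protocol": protocol_name,
            "n_samples_passing": len(kept),
            "n_samples_total": len(samples),
        }
    )
    return {
        "summary": summary,
        "passing_samples": kept,
        "plate_report": plate_report,
        "classifications": classes,
    }


def run_protocol_populations(
    calls: pd.DataFrame,
    confidences: pd.DataFrame,
    diagnostics: pd.DataFrame,
    samples: pd.DataFrame,
    protocol_name: str,
) -> dict:
    """Run a protocol separately per population and combine.

    Mirrors the reporting convention of analysing populations separately:
    per-population summaries plus the across-population average and the
    sum of per-population successful sets (a SNP counts once if successful
    in at least one population).
    """
    per_pop, success_sets = {}, {}
    for pop, grp in samples.groupby("population_id"):
        res = run_protocol(calls, confidences, diagnostics, grp, protocol_name)
        per_pop[pop] = res
        cls = res["classifications"]
        success_sets[pop] = set(cls.loc[cls["successful"], "probeset_id"])
    n_success = [res["summary"]["successful"] for res in per_pop.values()]
    union = set().union(*success_sets.values())
    return {
        "per_population": per_pop,
        "successful_average": float(np.mean(n_success)),
        "successful_sum": len(union),
        "successful_union": union,
    }


# ---------------------------------------------------------------------------
# duplicate-sample accuracy
# ---------------------------------------------------------------------------

_ALLELES = {"AA": (2, 0), "AB": (1, 1), "BB": (0, 2)}


def duplicate_accuracy(
    calls: pd.DataFrame, samples: pd.DataFrame
) -> dict[str, float]:
    """Concordance between duplicate samples of the same tree.

    Over all within-tree sample pairs and SNPs where both calls are
    present: ``genotype_accuracy`` is the concordant fraction,
    ``allele_accuracy`` the shared-allele fraction (AA vs AB share one of
    two alleles, AA vs BB none), and ``missing_fraction`` the fraction of
    pairs excluded because either call was missing.
    """
    groups = samples.groupby("tree_id")["sample_id"].apply(list)
    pairs = [
        (ids[i], ids[j])
        for ids in groups
        if len(ids) >= 2
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    ]
    if not pairs:
        raise ValueError("no tree has duplicate samples")
    total = compared = concordant = shared = 0
    for s1, s2 in pairs:
        a = calls.loc[s1].to_numpy(dtype=object)
        b = calls.loc[s2].to_numpy(dtype=object)
        both = (a != NOCALL) & (b != NOCALL)
        total += len(a)
        compared += int(both.sum())
        concordant += int((a[both] == b[both]).sum())
        for g1, g2 in zip(a[both], b[both]):
            x, y = _ALLELES[g1], _ALLELES[g2]
            shared += min(x[0], y[0]) + min(x[1], y[1])
    if compared == 0:
        raise ValueError("all duplicate pairs were missing")
    return {
        "genotype_accuracy": concordant / compared,
        "allele_accuracy": shared / (2 * compared),
        "missing_fraction": (total - compared) / total,
        "n_pairs": len(pairs),
        "n_compared": compared,
    }
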