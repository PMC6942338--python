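"""Transparent stand-in genotype caller for two-channel array intensities.

Intensities are mapped to Axiom-convention coordinates (contrast =
log2(A/B), size = mean log2 signal) and genotypes are called per probeset
by fitting 1-, 2- and 3-component Gaussian mixtures on contrast, selecting
the component count by information criterion, and labelling components by
the sign of their mean (negative -> BB, near zero -> AB, positive -> AA).
Per-call confidence is ``1 - max posterior`` (lower is better), so
standard confidence thresholds such as 0.15 and 0.10 apply directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "ClusterDiagnostics",
    "transform_intensities",
    "call_probeset",
    "call_genotypes",
    "apply_confidence_threshold",
    "detect_otv",
]

NOCALL = "NC"
GENOTYPES = ("AA", "AB", "BB")


@dataclass
class CallerConfig:
    """Tunable thresholds of the mixture-model caller.

    These cluster-geometry defaults are stand-ins chosen for the synthetic
    intensity model; they are deliberately configurable and make no claim
    of equivalence with any proprietary caller.
    """

    max_components: int = 3
    ab_halfwidth: float = 0.6  # |mean| below this labels a component AB
    confidence_threshold: float = 0.15
    min_samples: int = 20
    separation_min: float = 3.6  # min |dmu|/pooled SD to count as resolved
    mono_sd_max: float = 0.5  # 1-component fits wider than this are unresolved
    reg_covar: float = 1e-4
    criterion: str = "bic"
    otv_size_offset: float = 1.0  # log2 units below main-cluster median size
    otv_min_fraction: float = 0.05
    max_iter: int = 200


@dataclass
class ClusterDiagnostics:
    """Per-probeset mixture fit summary."""

    probeset_id: str
    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    separation: float
    resolved: bool
    otv_fraction: float = 0.0
    n_used: int = 0

    def as_record(self) -> dict:
        return {
            "probeset_id": self.probeset_id,
            "n_components": self.n_components,
            "means": ",".join(f"{m:.4f}" for m in self.means),
            "sds": ",".join(f"{s:.4f}" for s in self.sds),
            "weights": ",".join(f"{w:.4f}" for w in self.weights),
            "separation": self.separation,
            "resolved": self.resolved,
            "otv_fraction": self.otv_fraction,
            "n_used": self.n_used,
        }


def transform_intensities(signal_a, signal_b):
    """Map channel signals to (contrast, size) coordinates.

    ``contrast = log2(A/B)``, ``size = (log2 A + log2 B) / 2``.  Entries
    with a non-positive signal are returned as NaN (missing), not raised.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    ok = (a > 0) & (b > 0)
    contrast = np.full(a.shape, np.nan)
    size = np.full(a.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        la = np.log2(a, where=ok, out=np.full(a.shape, np.nan))
        lb = np.log2(b, where=ok, out=np.full(b.shape, np.nan))
    contrast[ok] = la[ok] - lb[ok]
    size[ok] = (la[ok] + lb[ok]) / 2.0
    return contrast, size


def _fit_mixture(x: np.ndarray, k: int, cfg: CallerConfig) -> GaussianMixture:
    """Fit a k-component mixture with deterministic, sign-equivariant inits.

    Two starts are tried -- means spread over the data range, and means at
    evenly spaced quantiles -- and the higher-likelihood fit wins.  Both
    inits negate under a channel swap, so calls swap AA/BB symmetrically.
    """
    qs = (2 * np.arange(k) + 1) / (2 * k)
    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1e-3)
    inits = [
        np.linspace(lo + span / (2 * k), hi - span / (2 * k), k),
        np.quantile(x, qs),
    ]
    var_small = max((span / (3 * k)) ** 2, cfg.reg_covar)
    best = None
    for means in inits:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            reg_covar=cfg.reg_covar,
            max_iter=cfg.max_iter,
            n_init=1,
            means_init=means.reshape(-1, 1),
            weights_init=np.full(k, 1.0 / k),
            precisions_init=np.full(k, 1.0 / var_small),
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(x.reshape(-1, 1))
        score = gm.score(x.reshape(-1, 1))
        if best is None or score > best[0] + 1e-12:
            best = (score, gm)
    return best[1]


def _label_components(means: np.ndarray, cfg: CallerConfig) -> list[str]:
    labels = []
    for m in means:
        if m < -cfg.ab_halfwidth:
            labels.append("BB")
        elif m > cfg.ab_halfwidth:
            labels.append("AA")
        else:
            labels.append("AB")
    return labels


def call_probeset(
    contrast: np.ndarray,
    size: np.ndarray,
    cfg: CallerConfig | None = None,
    probeset_id: str = "",
) -> tuple[np.ndarray, np.ndarray, ClusterDiagnostics]:
    """Call genotypes for one probeset.

    Returns ``(calls, confidences, diagnostics)`` where calls are already
    thresholded at ``cfg.confidence_threshold`` (confidence above it gives
    NoCall).  Probesets with fewer than ``cfg.min_samples`` usable samples
    are marked unresolved and all-NoCall.
    """
    cfg = cfg or CallerConfig()
    contrast = np.asarray(contrast, dtype=float)
    size = np.asarray(size, dtype=float)
    n = len(contrast)
    calls = np.full(n, NOCALL, dtype=object)
    conf = np.ones(n)
    ok = np.isfinite(contrast)
    x = contrast[ok]
    if ok.sum() < cfg.min_samples:
        diag = ClusterDiagnostics(
            probeset_id, 0, np.array([]), np.array([]), np.array([]),
            0.0, False, n_used=int(ok.sum()),
        )
        return calls, conf, diag

    best, best_ic = None, np.inf
    for k in range(1, cfg.max_components + 1):
        if len(np.unique(x)) < k:
            break
        gm = _fit_mixture(x, k, cfg)
        ic = gm.bic(x.reshape(-1, 1)) if cfg.criterion == "bic" else gm.aic(
            x.reshape(-1, 1)
        )
        if ic < best_ic - 1e-9:
            best, best_ic = gm, ic
    if best is None:  # all samples identical contrast
        calls[ok] = "AA" if x[0] > cfg.ab_halfwidth else (
            "BB" if x[0] < -cfg.ab_halfwidth else "AB"
        )
        conf[ok] = 0.0
        diag = ClusterDiagnostics(
            probeset_id, 1, np.array([x[0]]), np.array([0.0]),
            np.array([1.0]), np.inf, True, n_used=int(ok.sum()),
        )
        return calls, conf, diag

    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    sds = np.sqrt(best.covariances_.ravel()[order])
    if (sds < np.sqrt(cfg.reg_covar) * 1.01).any():
        log.info("probeset %s: degenerate variance floored", probeset_id)
    weights = best.weights_[order]
    labels = _label_components(means, cfg)

    post = best.predict_proba(x.reshape(-1, 1))[:, order]
    comp = np.argmax(post, axis=1)
    conf_ok = 1.0 - post[np.arange(len(x)), comp]
    geno = np.array(labels, dtype=object)[comp]
    geno[conf_ok > cfg.confidence_threshold] = NOCALL
    calls[ok] = geno
    conf[ok] = conf_ok

    k = len(means)
    if k == 1:
        separation = np.inf
        resolved = sds[0] <= cfg.mono_sd_max
    else:
        seps = [
            abs(means[j] - means[i]) / np.sqrt((sds[i] ** 2 + sds[j] ** 2) / 2)
            for i in range(k)
            for j in range(i + 1, k)
        ]
        separation = float(min(seps))
        resolved = separation >= cfg.separation_min
    diag = ClusterDiagnostics(
        probeset_id, k, means, sds, weights, separation, resolved,
        n_used=int(ok.sum()),
    )
    diag.otv_fraction, _ = detect_otv(size, calls, cfg)
    return calls, conf, diag


def call_genotypes(
    contrast: pd.DataFrame,
    size: pd.DataFrame,
    cfg: CallerConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Call genotypes over a samples x probesets (contrast, size) matrix.

    Returns ``(calls, confidences, diagnostics)``; diagnostics has one row
    per probeset.
    """
    cfg = cfg or CallerConfig()
    calls = pd.DataFrame(index=contrast.index, columns=contrast.columns, dtype=object)
    conf = pd.DataFrame(index=contrast.index, columns=contrast.columns, dtype=float)
    diags = []
    for ps in contrast.columns:
        c, q, d = call_probeset(
            contrast[ps].to_numpy(), size[ps].to_numpy(), cfg, probeset_id=str(ps)
        )
        calls[ps] = c
        conf[ps] = q
        diags.append(d.as_record())
    return calls, conf, pd.DataFrame(diags)


def apply_confidence_threshold(calls, conf, threshold: float):
    """Convert calls whose confidence exceeds ``threshold`` to NoCall."""
    out = calls.copy()
    if isinstance(out, pd.DataFrame):
        out[conf > threshold] = NOCALL
    else:
        out = np.where(np.asarray(conf) > threshold, NOCALL, out)
    return out


def detect_otv(
    size: np.ndarray,
    calls: np.ndarray,
    cfg: CallerConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Flag samples in a low-size (off-target) cluster.

    A sample is flagged when its size falls more than
    ``cfg.otv_size_offset`` below the median size of called samples.
    Returns ``(otv_fraction, flags)`` over samples with finite size.
    """
    cfg = cfg or CallerConfig()
    size = np.asarray(size, dtype=float)
    calls = np.asarray(calls, dtype=object)
    ok = np.isfinite(size)
    flags = np.zeros(len(size), dtype=bool)
    called = ok & (calls != NOCALL)
    ref = size[called] if called.any() else size[ok]
    if len(ref) == 0:
        return 0.0, flags
    threshold = np.median(ref) - cfg.otv_size_offset
    flags[ok] = size[ok] < threshold
    return float(flags[ok].mean()), flags
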