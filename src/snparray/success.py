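"""Predicting assay success from design and alignment features.

Covers: feature engineering from BLAST tabular output (hit counts, percent
identities, perfect-allele counts), univariate association tests
(likelihood-ratio chi-square, Welch t, Monte-Carlo Wilcoxon), stepwise
logistic regression with cross-validated ROC, and the marker-detection
sample-size calculator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _trapz_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

import statsmodels.api as sm

__all__ = [
    "BLAST_COLUMNS",
    "read_blast_tabular",
    "design_hit_features",
    "perfect_allele_counts",
    "pid_features",
    "bin_hit_count",
    "g2_test",
    "group_compare",
    "association_table",
    "StepwiseResult",
    "stepwise_logistic_roc",
    "detection_sample_size",
]

#: Standard 12-column BLAST tabular (``-outfmt 6``) column names.
BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

_NUMERIC = {
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
}


def read_blast_tabular(path) -> pd.DataFrame:
    """Read a standard 12-column BLAST tabular file.

    Malformed rows are skipped; the number skipped is recorded in
    ``df.attrs["n_skipped"]`` and reported via a warning.
    """
    rows, skipped = [], 0
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                skipped += 1
                continue
            try:
                rec = dict(zip(BLAST_COLUMNS, parts))
                for key, cast in _NUMERIC.items():
                    rec[key] = cast(rec[key])
            except ValueError:
                skipped += 1
                continue
            rows.append(rec)
    if skipped:
        warnings.warn(f"skipped {skipped} malformed BLAST rows", stacklevel=2)
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    df.attrs["n_skipped"] = skipped
    return df


def bin_hit_count(n: int) -> str:
    """Bin a hit count into the three-level category one / gt1 / zero."""
    if n == 1:
        return "one"
    if n > 1:
        return "gt1"
    return "zero"


def design_hit_features(
    hits: pd.DataFrame,
    queries,
    min_length: int = 65,
) -> pd.DataFrame:
    """Design-time (v0.5 style) hit counts per query.

    One hit is counted per alignment of at least ``min_length`` nt of the
    71-nt query.  Queries without any such hit get a count of 0.
    """
    good = hits[hits["length"] >= min_length]
    counts = good.groupby("qseqid").size()
    out = pd.DataFrame({"qseqid": list(queries)})
    out["n_hits"] = out["qseqid"].map(counts).fillna(0).astype(int)
    out["hit_bin"] = out["n_hits"].map(bin_hit_count)
    return out


def perfect_allele_counts(
    hits: pd.DataFrame,
    snp_ids,
    allele_sep: str = "|",
    probe_length: int = 71,
) -> pd.Series:
    """Number of allele sequences per SNP with a perfect genome match.

    Queries are allele sequences named ``<snp_id><sep><allele>``; a perfect
    match is full-length (``length == probe_length``) at 100% identity.
    Returns a Series indexed by snp_id with values in {0, 1, 2}.
    """
    perfect = hits[(hits["pident"] == 100.0) & (hits["length"] == probe_length)]
    snp_of = perfect["qseqid"].str.rsplit(allele_sep, n=1).str[0]
    n = (
        pd.DataFrame({"snp": snp_of, "q": perfect["qseqid"]})
        .drop_duplicates()
        .groupby("snp")
        .size()
    )
    out = pd.Series(0, index=pd.Index(list(snp_ids), name="snp_id"))
    out.update(n)
    return out.astype(int).clip(upper=2)


def pid_features(
    hits: pd.DataFrame,
    queries,
    pid_floor: float = 80.0,
    hit_pid_cutoff: float = 90.0,
) -> pd.DataFrame:
    """Post-hoc (v1.0 style) percent-identity features per query.

    Extracts the best and second-best hit PID (missing hits floored at
    ``pid_floor``), the three-level best/second pair category, and the
    number of hits above ``hit_pid_cutoff`` binned one / gt1 / zero.
    """
    out = pd.DataFrame({"qseqid": list(queries)})
    ranked = hits.sort_values(
        ["qseqid", "pident"], ascending=[True, False], kind="mergesort"
    ).copy()
    ranked["_rank"] = ranked.groupby("qseqid").cumcount()
    best = ranked[ranked["_rank"] == 0].set_index("qseqid")["pident"]
    second = ranked[ranked["_rank"] == 1].set_index("qseqid")["pident"]
    out["pid_best"] = out["qseqid"].map(best).fillna(pid_floor)
    out["pid_second"] = out["qseqid"].map(second).fillna(pid_floor)
    out["pid_second"] = out[["pid_best", "pid_second"]].min(axis=1)

    def _cat(row):
        b = row["pid_best"] > pid_floor
        s = row["pid_second"] > pid_floor
        if b and s:
            return "both_gt80"
        if b:
            return "best_gt80_second_le80"
        return "both_le80"

    out["pid_pair_category"] = out.apply(_cat, axis=1)
    n90 = hits[hits["pident"] > hit_pid_cutoff].groupby("qseqid").size()
    out["n_hits_gt90"] = out["qseqid"].map(n90).fillna(0).astype(int)
    out["hit_bin"] = out["n_hits_gt90"].map(bin_hit_count)
    return out


# ---------------------------------------------------------------------------
# univariate association tests
# ---------------------------------------------------------------------------


def g2_test(table) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square (G-squared) test of independence.

    ``G2 = 2 * sum O * ln(O / E)`` over non-zero cells of a 2 x k table;
    df = (rows-1) * (cols-1) counted over non-degenerate rows/columns.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total <= 0:
        raise ValueError("empty table")
    nz_rows = int((row.ravel() > 0).sum())
    nz_cols = int((col.ravel() > 0).sum())
    if nz_rows < obs.shape[0] or nz_cols < obs.shape[1]:
        warnings.warn("degenerate row/column; df reduced", stacklevel=2)
    df = max((nz_rows - 1) * (nz_cols - 1), 0)
    expected = row @ col / total
    mask = obs > 0
    g2 = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    p = float(sps.chi2.sf(g2, df)) if df > 0 else 1.0
    return g2, df, p


def group_compare(
    values,
    labels,
    test: str = "welch_t",
    n_perms: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-group comparison: Welch t or Monte-Carlo Wilcoxon rank-sum.

    ``labels`` must contain exactly two distinct values.  The Monte-Carlo
    p-value uses the add-one estimator ``(exceedances + 1) / (perms + 1)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("group_compare needs exactly two groups")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if test == "welch_t":
        if np.ptp(values) == 0:
            raise ValueError("all values constant: statistic undefined")
        res = sps.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon_mc":
        if np.ptp(values) == 0:
            raise ValueError("all values constant: statistic undefined")
        rng = np.random.default_rng(seed)
        ranks = sps.rankdata(values)
        n_a = len(a)
        w_obs = float(ranks[labels == uniq[0]].sum())
        mu = n_a * (len(values) + 1) / 2.0
        exceed = 0
        for _ in range(n_perms):
            perm = rng.permutation(ranks)
            if abs(perm[:n_a].sum() - mu) >= abs(w_obs - mu) - 1e-12:
                exceed += 1
        return w_obs, (exceed + 1) / (n_perms + 1)
    raise ValueError(f"unknown test {test!r}")


def association_table(category_counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Success/failure report for one categorical variable.

    ``category_counts`` maps category -> (n_success, n_fail).  Percentages
    are reported to one decimal; the table-level G-squared test is attached
    in ``df.attrs``.
    """
    rows = []
    for cat, (n_s, n_f) in category_counts.items():
        total = n_s + n_f
        rows.append(
            {
                "category": cat,
                "n_success": n_s,
                "n_fail": n_f,
                "percent_success": round(100.0 * n_s / total, 1),
                "percent_fail": round(100.0 * n_f / total, 1),
            }
        )
    df = pd.DataFrame(rows)
    table = df[["n_success", "n_fail"]].to_numpy().T
    if table.shape[1] >= 2:
        g2, dof, p = g2_test(table)
        df.attrs.update({"g2": g2, "df": dof, "p": p})
    return df


# ---------------------------------------------------------------------------
# stepwise logistic regression + cross-validated ROC
# ---------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    """Outcome of stepwise logistic selection and cross-validated ROC."""

    steps: list[dict] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    auc: float = float("nan")
    roc_fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    roc_tpr: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_probs: np.ndarray = field(default_factory=lambda: np.array([]))
    separation_flagged: bool = False

    def operating_point(self, threshold: float = 0.5) -> tuple[float, float]:
        """(TPR, FPR) when predicting success at P >= threshold."""
        y = self._y
        pred = self.cv_probs >= threshold
        tpr = float(pred[y == 1].mean()) if (y == 1).any() else float("nan")
        fpr = float(pred[y == 0].mean()) if (y == 0).any() else float("nan")
        return tpr, fpr

    def step_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _fit_logit(y, X):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return sm.Logit(y, X).fit(disp=0, maxiter=200, method="bfgs")


def _score_test(y, X_base, fit_base, Z):
    """Rao score chi-square for adding columns Z to a fitted logit model."""
    p = fit_base.predict(X_base)
    w = p * (1.0 - p)
    resid = y - p
    U = Z.T @ resid
    XtWX = X_base.T @ (X_base * w[:, None])
    XtWZ = X_base.T @ (Z * w[:, None])
    ZtWZ = Z.T @ (Z * w[:, None])
    try:
        V = ZtWZ - XtWZ.T @ np.linalg.solve(XtWX, XtWZ)
        stat = float(U @ np.linalg.solve(V, U))
    except np.linalg.LinAlgError:
        return 0.0, len(U), 1.0
    if stat < 0:  # numerical collinearity
        stat = 0.0
    df = Z.shape[1]
    return stat, df, float(sps.chi2.sf(stat, df))


def stepwise_logistic_roc(
    features: pd.DataFrame,
    label,
    variables: dict[str, list[str]] | None = None,
    sle: float = 0.05,
    sls: float = 0.05,
    folds: int = 10,
    seed: int = 0,
    coef_cap: float = 25.0,
) -> StepwiseResult:
    """Stepwise logistic regression with cross-validated ROC.

    Forward steps enter the candidate variable with the best score
    chi-square if its p-value is <= ``sle``; after each entry, variables
    whose likelihood-ratio p-value exceeds ``sls`` are removed.  Predicted
    probabilities come from stratified ``folds``-fold cross-validation of
    the final model and are pooled into a single ROC curve (trapezoidal
    AUC).

    ``variables`` maps variable name -> feature columns (multi-column for
    categorical dummies); by default every column is its own variable.
    """
    y = np.asarray(label, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("label must be binary 0/1")
    if variables is None:
        variables = {c: [c] for c in features.columns}
    if len(variables) < 2:
        raise ValueError("need at least two candidate variables")
    Xall = {v: features[cols].to_numpy(dtype=float) for v, cols in variables.items()}

    result = StepwiseResult()
    included: list[str] = []
    step_no = 0
    seen_states: set[frozenset] = set()
    while True:
        state = frozenset(included)
        if state in seen_states:  # entry/removal cycle: stop, SAS-style
            break
        seen_states.add(state)
        X_base = np.column_stack(
            [np.ones(len(y))] + [Xall[v] for v in included]
        )
        fit_base = _fit_logit(y, X_base)
        # forward: best score chi-square among excluded variables
        best = None
        for v in variables:
            if v in included:
                continue
            stat, df, p = _score_test(y, X_base, fit_base, Xall[v])
            if p <= sle and (best is None or stat > best[1]):
                best = (v, stat, df, p)
        if best is None:
            break
        step_no += 1
        included.append(best[0])
        result.steps.append(
            {
                "step": step_no,
                "variable": best[0],
                "chi_square": best[1],
                "df": best[2],
                "p": best[3],
            }
        )
        # backward: LR test for each included variable
        removed = True
        while removed and len(included) > 0:
            removed = False
            X_full = np.column_stack(
                [np.ones(len(y))] + [Xall[v] for v in included]
            )
            fit_full = _fit_logit(y, X_full)
            worst = None
            for v in included:
                rest = [u for u in included if u != v]
                X_red = np.column_stack(
                    [np.ones(len(y))] + [Xall[u] for u in rest]
                )
                fit_red = _fit_logit(y, X_red)
                lr = 2.0 * (fit_full.llf - fit_red.llf)
                df = Xall[v].shape[1]
                p = float(sps.chi2.sf(max(lr, 0.0), df))
                if p > sls and (worst is None or p > worst[1]):
                    worst = (v, p)
            if worst is not None and worst[0] != included[-1]:
                included.remove(worst[0])
                removed = True

    result.selected = list(included)
    # cross-validated predicted probabilities of the final model
    cols = [c for v in included for c in variables[v]]
    if cols:
        X = features[cols].to_numpy(dtype=float)
    else:
        X = np.zeros((len(y), 0))
    X = np.column_stack([np.ones(len(y)), X])
    probs = np.empty(len(y))
    n_splits = min(folds, int((y == 1).sum()), int((y == 0).sum()))
    def _cv_fit_predict(y_tr, X_tr, X_te):
        # light ridge keeps separated folds finite; near-MLE otherwise
        clf = LogisticRegression(C=1e4, max_iter=2000, fit_intercept=False)
        clf.fit(X_tr, y_tr)
        params = clf.coef_.ravel()
        if np.abs(params).max() > coef_cap:
            result.separation_flagged = True
        return clf.predict_proba(X_te)[:, 1]

    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for train, test in skf.split(X, y):
            probs[test] = _cv_fit_predict(y[train], X[train], X[test])
    else:
        probs[:] = _cv_fit_predict(y, X, X)
    result.cv_probs = probs
    result._y = y
    fpr, tpr, _ = _roc_curve(y, probs)
    result.roc_fpr, result.roc_tpr = fpr, tpr
    result.auc = float(_trapz_auc(fpr, tpr))
    return result


# ---------------------------------------------------------------------------
# detection sample size
# ---------------------------------------------------------------------------


def detection_sample_size(maf: float, success_rate: float) -> int:
    """Minimum trees needed to observe a minor allele at least once.

    Under the one-informative-allele-per-tree model the probability of
    missing the minor allele in ``n`` trees is ``(1 - maf) ** n``; the
    result is the smallest integer ``n`` with
    ``(1 - maf) ** n <= 1 - success_rate``.
    """
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must be in (0, 1)")
    if not 0.0 < success_rate < 1.0:
        raise ValueError("success_rate must be in (0, 1)")
    miss = 1.0 - success_rate
    n = max(1, math.ceil(math.log(miss) / math.log(1.0 - maf)))
    while n > 1 and (1.0 - maf) ** (n - 1) <= miss:
        n -= 1
    while (1.0 - maf) ** n > miss:
        n += 1
    return n
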