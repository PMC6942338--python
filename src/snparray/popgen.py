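"""Per-SNP, per-population genetic statistics and cross-population summaries.

Statistics are computed from genotype counts of biallelic SNPs: call rate
(CR), minor allele frequency (MAF), observed and expected heterozygosity,
polymorphic information content (PIC, biallelic Botstein form), and a
Hardy-Weinberg equilibrium (HWE) chi-square goodness-of-fit test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SnpPopStats",
    "snp_stats",
    "hwe_test",
    "hwe_exact_test",
    "stats_table",
    "population_summary",
    "maf_histogram",
]


@dataclass(frozen=True)
class SnpPopStats:
    """Population-genetic statistics for one SNP in one population."""

    probeset_id: str
    population_id: str
    cr: float
    maf: float
    het_obs: float
    het_exp: float
    pic: float
    hwe_chi2: float
    hwe_p: float
    n_called: int

    @property
    def polymorphic(self) -> bool:
        return self.maf > 0.0


def snp_stats(
    n_aa: int,
    n_ab: int,
    n_bb: int,
    n_nc: int = 0,
    *,
    probeset_id: str = "",
    population_id: str = "",
) -> SnpPopStats:
    """Compute per-SNP statistics from genotype counts.

    ``n_aa``/``n_ab``/``n_bb`` are called genotype counts and ``n_nc`` the
    number of missing (no-call) samples.  The A allele frequency is
    ``p = (2*n_aa + n_ab) / (2*n)``; MAF is ``min(p, 1-p)``; expected
    heterozygosity is the plain ``2pq`` estimator (no small-sample
    correction); PIC is ``1 - (p^2 + q^2) - 2 p^2 q^2``.

    Raises
    ------
    ValueError
        If no genotype was called (all NoCall) or a count is negative.
    """
    for v in (n_aa, n_ab, n_bb, n_nc):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("all calls missing: statistics undefined")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    maf = min(p, q)
    cr = n / (n + n_nc)
    het_obs = n_ab / n
    het_exp = 2.0 * p * q
    pic = 1.0 - (p * p + q * q) - 2.0 * p * p * q * q
    if maf == 0.0:
        chi2, pval = 0.0, 1.0
    else:
        chi2, pval = hwe_test(n_aa, n_ab, n_bb)
    return SnpPopStats(
        probeset_id=probeset_id,
        population_id=population_id,
        cr=cr,
        maf=maf,
        het_obs=het_obs,
        het_exp=het_exp,
        pic=max(pic, 0.0),
        hwe_chi2=chi2,
        hwe_p=pval,
        n_called=n,
    )


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """Pearson chi-square goodness-of-fit test against HWE proportions.

    Expected counts are ``n*p^2``, ``2*n*p*q``, ``n*q^2`` with ``p``
    estimated from the data; df = 1, no continuity correction.  Monomorphic
    input returns ``(0.0, 1.0)`` by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one called genotype")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    pval = float(sps.chi2.sf(chi2, df=1))
    return chi2, pval


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test p-value (Wigginton et al. style enumeration).

    Provided as an alternative to the chi-square test; not used by default.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_minor = min(n_a, 2 * n - n_a)
    # log-probability of each possible heterozygote count, same parity
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = []
    for h in hets:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        lp = (
            h * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_minor + 1)
            - math.lgamma(hom_major + 1)
            + math.lgamma(n_minor + 1)
            + math.lgamma(2 * n - n_minor + 1)
            - math.lgamma(2 * n + 1)
        )
        logp.append(lp)
    prob = np.exp(np.array(logp))
    prob /= prob.sum()
    obs_het = n_ab
    p_obs = prob[hets == obs_het][0]
    return float(prob[prob <= p_obs + 1e-12].sum())


def stats_table(
    counts: pd.DataFrame,
    population_id: str = "",
) -> pd.DataFrame:
    """Vectorized :func:`snp_stats` over a counts table.

    ``counts`` needs columns ``probeset_id, n_aa, n_ab, n_bb, n_nc``.
    SNPs with zero called genotypes are dropped.
    """
    df = counts.copy()
    n = df["n_aa"] + df["n_ab"] + df["n_bb"]
    df = df[n > 0].copy()
    n = n[n > 0]
    p = (2 * df["n_aa"] + df["n_ab"]) / (2 * n)
    q = 1.0 - p
    out = pd.DataFrame(
        {
            "probeset_id": df["probeset_id"],
            "population_id": population_id,
            "cr": n / (n + df["n_nc"]),
            "maf": np.minimum(p, q),
            "het_obs": df["n_ab"] / n,
            "het_exp": 2 * p * q,
            "pic": (1.0 - (p**2 + q**2) - 2 * p**2 * q**2).clip(lower=0.0),
            "n_called": n,
        }
    )
    exp_aa = n * p * p
    exp_ab = 2 * n * p * q
    exp_bb = n * q * q
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (
            (df["n_aa"] - exp_aa) ** 2 / exp_aa
            + (df["n_ab"] - exp_ab) ** 2 / exp_ab
            + (df["n_bb"] - exp_bb) ** 2 / exp_bb
        )
    poly = out["maf"].to_numpy() > 0
    chi2 = chi2.to_numpy()
    chi2[~poly] = 0.0
    out["hwe_chi2"] = chi2
    out["hwe_p"] = np.where(poly, sps.chi2.sf(chi2, df=1), 1.0)
    return out.reset_index(drop=True)


def population_summary(
    pop_stats: dict[str, pd.DataFrame],
    hwe_alpha: float = 0.01,
) -> dict:
    """Cross-population medians for polymorphic SNPs in HWE.

    For each population the SNPs are filtered to polymorphic with HWE
    p >= ``hwe_alpha``; medians of cr, maf, het_obs, het_exp and pic are
    computed, then averaged arithmetically across populations.
    """
    per_pop = {}
    fields = ["cr", "maf", "het_obs", "het_exp", "pic"]
    for pop, df in pop_stats.items():
        keep = df[(df["maf"] > 0) & (df["hwe_p"] >= hwe_alpha)]
        if keep.empty:
            raise ValueError(
                f"population {pop!r}: no SNP is polymorphic and in HWE "
                f"(p >= {hwe_alpha})"
            )
        per_pop[pop] = {f: float(keep[f].median()) for f in fields}
        per_pop[pop]["n_snps"] = int(len(keep))
    averaged = {
        f: float(np.mean([per_pop[p][f] for p in per_pop])) for f in fields
    }
    averaged["n_snps"] = float(np.mean([per_pop[p]["n_snps"] for p in per_pop]))
    return {"per_population": per_pop, "averaged_medians": averaged}


def maf_histogram(
    stats_df: pd.DataFrame,
    hwe_alpha: float = 0.01,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """MAF histogram counts for all polymorphic SNPs and the HWE subset.

    Returns one row per bin with ``bin_low``, ``bin_high``, ``n_all`` and
    ``n_hwe`` columns; bins cover (0, 0.5].
    """
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    poly = stats_df[stats_df["maf"] > 0]
    hwe = poly[poly["hwe_p"] >= hwe_alpha]
    n_all, _ = np.histogram(poly["maf"], bins=edges)
    n_hwe, _ = np.histogram(hwe["maf"], bins=edges)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "n_all": n_all,
            "n_hwe": n_hwe,
        }
    )
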