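"""Synthetic candidate, genotype-truth, intensity and feature generator.

Emulates the statistical structure a SNP genotyping array pipeline
consumes: candidate SNPs with 71-nt probe contexts and tiered flanking
variants, per-SNP latent quality classes, HWE genotypes across one or two
populations with duplicate samples per tree, two-channel log-normal
intensities, per-sample Dish-QC and plate structure, and a feature table
with a planted logistic success signal.

Each logical entity class (SNPs, samples, intensities, features) draws
from its own seeded stream, so enlarging one dimension does not perturb
draws in another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LATENT_CLASSES",
    "SimConfig",
    "TruthTable",
    "gen_candidates",
    "gen_genotype_truth",
    "gen_intensity_data",
    "gen_design_features",
]

LATENT_CLASSES = (
    "poly_resolved",
    "no_minor_hom",
    "monomorphic",
    "low_cr",
    "otv",
    "unresolvable",
)

#: loosely calibrated to observed category percentages of a conifer array;
#: user-overridable via SimConfig.class_proportions
DEFAULT_CLASS_PROPORTIONS = {
    "poly_resolved": 0.32,
    "no_minor_hom": 0.13,
    "monomorphic": 0.16,
    "low_cr": 0.08,
    "otv": 0.01,
    "unresolvable": 0.30,
}

_BASES = np.array(list("ACGT"))
_TIERS = ("low", "medium", "high")


@dataclass
class SimConfig:
    n_snps: int = 200
    n_samples_per_pop: int = 100
    n_pops: int = 2
    maf_distribution: tuple[str, dict] = ("uniform", {"low": 0.01, "high": 0.5})
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    duplicate_fraction: float = 0.05
    dqc_distribution: tuple[str, dict] = ("beta", {"a": 40.0, "b": 2.0})
    plate_size: int = 96
    seed: int = 0
    # candidate/design extras
    uh_fraction: float = 0.1
    infinium_fraction: float = 0.05
    mean_snps_per_transcript: float = 3.0
    # intensity model
    contrast_center: float = 1.5
    contrast_sd: float = 0.15
    size_mean: float = 3.0
    size_sd: float = 0.15
    unresolvable_sd_factor: float = 6.0
    otv_sample_fraction: float = 0.3
    otv_size_shift: float = 2.0
    low_cr_frac_range: tuple[float, float] = (0.05, 0.45)
    # planted success model for the feature table
    success_intercept: float = 0.0
    success_coefs: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_snps < 1 or self.n_samples_per_pop < 1:
            raise ValueError("n_snps and n_samples_per_pop must be positive")
        if self.n_pops not in (1, 2):
            raise ValueError("n_pops must be 1 or 2")
        if set(self.class_proportions) != set(LATENT_CLASSES):
            raise ValueError(
                f"class_proportions must have exactly the keys {LATENT_CLASSES}"
            )
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, expected 1")
        for name, frac in [
            ("duplicate_fraction", self.duplicate_fraction),
            ("uh_fraction", self.uh_fraction),
            ("infinium_fraction", self.infinium_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.plate_size < 1:
            raise ValueError("plate_size must be positive")
        _check_distribution(*self.maf_distribution)
        _check_distribution(*self.dqc_distribution)


def _check_distribution(name: str, params: dict) -> None:
    if name == "uniform":
        if not 0 <= params["low"] < params["high"]:
            raise ValueError("uniform distribution needs 0 <= low < high")
    elif name == "beta":
        if params["a"] <= 0 or params["b"] <= 0:
            raise ValueError("beta distribution needs positive a, b")
    else:
        raise ValueError(f"unknown distribution {name!r}")


def _draw(rng: np.random.Generator, name: str, params: dict, size: int):
    if name == "uniform":
        return rng.uniform(params["low"], params["high"], size)
    if name == "beta":
        return rng.beta(params["a"], params["b"], size)
    raise ValueError(f"unknown distribution {name!r}")


def _rng(seed: int, *key: str) -> np.random.Generator:
    token = zlib.crc32("/".join(key).encode())
    return np.random.default_rng(np.random.SeedSequence([seed, token]))


# ---------------------------------------------------------------------------
# candidates + probesets
# ---------------------------------------------------------------------------


def gen_candidates(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a candidate-SNP table and its probeset-design table.

    Each candidate carries a 71-nt context with the variant at 1-based
    position 36, tiered flanking variants, source-specific target-SNP
    evidence, and an Infinium-validation flag.  Probesets are generated
    for both strand directions with pConvert, Repetitive, hit-count and
    flanking-rank fields.
    """
    config.validate()
    rng = _rng(config.seed, "candidates")
    n = config.n_snps

    snp_ids = np.array([f"snp{i:06d}" for i in range(n)])
    source = np.where(rng.random(n) < config.uh_fraction, "UH", "OSU")
    n_transcripts = max(1, int(round(n / config.mean_snps_per_transcript)))
    transcript = np.array(
        [f"tr{t:05d}" for t in rng.integers(0, n_transcripts, n)]
    )

    allele_a = rng.choice(_BASES, n)
    # pick a distinct alt allele; A/T and C/G pairs arise naturally
    alt_offset = rng.integers(1, 4, n)
    allele_b = _BASES[(np.searchsorted(_BASES, allele_a) + alt_offset) % 4]

    contexts = rng.choice(_BASES, (n, 71))
    contexts[:, 35] = allele_a  # variant base at 1-based position 36
    context_seq = ["".join(row) for row in contexts]

    infinium = (source == "OSU") & (rng.random(n) < config.infinium_fraction)
    p_s = np.where(source == "OSU", 10.0 ** rng.uniform(-8, -3, n), np.nan)
    n_programs = np.where(source == "UH", rng.integers(1, 4, n), 0)

    flank_lists = []
    for i in range(n):
        k = rng.poisson(0.8)
        positions = [int(p) for p in rng.choice(70, size=min(k, 70), replace=False)]
        entries = []
        for p in positions:
            pos = p + 1 if p < 35 else p + 2  # skip position 36
            entries.append(f"{pos}:{_TIERS[rng.integers(0, 3)]}")
        flank_lists.append(";".join(sorted(entries, key=lambda e: int(e.split(':')[0]))))

    candidates = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "source": source,
            "transcript_id": transcript,
            "allele_a": allele_a,
            "allele_b": allele_b,
            "context_seq": context_seq,
            "target_snp_prob": p_s,
            "n_detect_programs": n_programs,
            "flanking_variants": flank_lists,
            "infinium_success": infinium,
        }
    )

    rows = []
    for i in range(n):
        variants = _parse_variants(flank_lists[i])
        for direction in ("forward", "reverse"):
            flank = (
                [t for p, t in variants if p <= 35]
                if direction == "forward"
                else [t for p, t in variants if p >= 37]
            )
            if not flank:
                flanking_rank = 1
            elif all(t == "low" for t in flank):
                flanking_rank = 2
            else:
                flanking_rank = 3
            repetitive = rng.random() < 0.03
            pconvert = 0.0 if repetitive else float(rng.beta(6, 4))
            if rng.random() < 0.02:
                recommendation = "not_possible"
            elif pconvert >= 0.6:
                recommendation = "recommended"
            elif pconvert >= 0.4:
                recommendation = "neutral"
            else:
                recommendation = "not_recommended"
            hits = int(rng.choice([0, 1, 2, 3], p=[0.06, 0.64, 0.2, 0.1]))
            rows.append(
                {
                    "probeset_id": f"{snp_ids[i]}_{direction[0].upper()}",
                    "snp_id": snp_ids[i],
                    "direction": direction,
                    "repetitive": repetitive,
                    "pconvert": pconvert,
                    "recommendation": recommendation,
                    "n_scaffold_hits_v05": hits,
                    "n_perfect_alleles": int(
                        rng.choice([0, 1, 2], p=[0.1, 0.75, 0.15])
                    ),
                    "flanking_rank": flanking_rank,
                }
            )
    return candidates, pd.DataFrame(rows)


def _parse_variants(spec: str) -> list[tuple[int, str]]:
    if not spec:
        return []
    out = []
    for item in spec.split(";"):
        pos, tier = item.split(":")
        out.append((int(pos), tier))
    return out


# ---------------------------------------------------------------------------
# genotype truth
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Ground truth: latent classes, per-population MAF and genotypes.

    ``genotypes`` holds minor-allele (B) dosage 0/1/2 with shape
    (n_samples, n_snps); ``samples`` carries tree-of-origin, population,
    plate and Dish-QC; ``snps`` carries the latent class and per-population
    true MAF.
    """

    snps: pd.DataFrame
    samples: pd.DataFrame
    genotypes: np.ndarray
    config: SimConfig

    GENO_STR = np.array(["AA", "AB", "BB"])

    def genotype_calls(self) -> pd.DataFrame:
        """Genotypes as AA/AB/BB strings, samples x SNPs."""
        return pd.DataFrame(
            self.GENO_STR[self.genotypes],
            index=self.samples["sample_id"].to_numpy(),
            columns=self.snps["snp_id"].to_numpy(),
        )


def gen_genotype_truth(config: SimConfig) -> TruthTable:
    """Draw latent classes, sample structure and true genotypes.

    Genotypes of ``poly_resolved`` (and intensity-corrupted) SNPs follow
    HWE at the SNP's population MAF; ``monomorphic`` SNPs are fixed for
    the major allele; ``no_minor_hom`` SNPs are drawn from HWE conditioned
    on the absence of minor homozygotes.  Duplicate samples copy the
    tree's genotype vector exactly.
    """
    config.validate()
    rng_snp = _rng(config.seed, "snps")
    rng_smp = _rng(config.seed, "samples")

    classes = rng_snp.choice(
        LATENT_CLASSES,
        size=config.n_snps,
        p=[config.class_proportions[c] for c in LATENT_CLASSES],
    )
    name, params = config.maf_distribution
    mafs = {
        pop: _draw(rng_snp, name, params, config.n_snps)
        for pop in range(config.n_pops)
    }
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(config.n_snps)],
            "latent_class": classes,
        }
    )
    for pop in range(config.n_pops):
        maf = mafs[pop].copy()
        maf[classes == "monomorphic"] = 0.0
        snps[f"maf_pop{pop + 1}"] = maf

    # samples: trees, duplicates, plates, dish-QC
    recs = []
    for pop in range(1, config.n_pops + 1):
        for t in range(config.n_samples_per_pop):
            tree = f"pop{pop}_t{t:05d}"
            recs.append({"tree_id": tree, "population_id": f"pop{pop}"})
    trees = pd.DataFrame(recs)
    is_dup = rng_smp.random(len(trees)) < config.duplicate_fraction
    rows = []
    for idx, rec in trees.iterrows():
        rows.append({**rec, "replicate": 1})
        if is_dup[idx]:
            rows.append({**rec, "replicate": 2})
    samples = pd.DataFrame(rows)
    samples["sample_id"] = [
        f"{r.tree_id}_r{r.replicate}" for r in samples.itertuples()
    ]
    samples["plate_id"] = [
        f"plate{i // config.plate_size:03d}" for i in range(len(samples))
    ]
    dname, dparams = config.dqc_distribution
    samples["dqc"] = np.clip(_draw(rng_smp, dname, dparams, len(samples)), 0, 1)
    samples = samples[
        ["sample_id", "tree_id", "population_id", "replicate", "plate_id", "dqc"]
    ]

    # per-tree genotypes, then copy to duplicate samples
    geno_tree = np.zeros((len(trees), config.n_snps), dtype=np.int8)
    rng_geno = _rng(config.seed, "genotypes")
    for pop in range(1, config.n_pops + 1):
        sel = (trees["population_id"] == f"pop{pop}").to_numpy()
        maf = snps[f"maf_pop{pop}"].to_numpy()
        n_trees = int(sel.sum())
        hwe = rng_geno.binomial(2, np.broadcast_to(maf, (n_trees, config.n_snps)))
        # condition no_minor_hom SNPs on genotype != BB
        nmh = classes == "no_minor_hom"
        if nmh.any():
            p_ab = np.zeros(config.n_snps)
            q = maf[nmh]
            denom = (1 - q) ** 2 + 2 * q * (1 - q)
            with np.errstate(invalid="ignore", divide="ignore"):
                p_ab[nmh] = np.where(denom > 0, 2 * q * (1 - q) / denom, 0.0)
            cond = rng_geno.random((n_trees, config.n_snps)) < p_ab
            hwe[:, nmh] = cond[:, nmh].astype(np.int8)
        geno_tree[sel] = hwe.astype(np.int8)

    tree_index = {t: i for i, t in enumerate(trees["tree_id"])}
    geno = geno_tree[[tree_index[t] for t in samples["tree_id"]]]
    return TruthTable(snps=snps, samples=samples, genotypes=geno, config=config)


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------


def gen_intensity_data(
    truth: TruthTable, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-channel log-normal intensities implied by the latent classes.

    Returns ``(signal_a, signal_b)`` DataFrames (samples x SNPs).  The
    genotype sets the contrast-cluster center (+c / 0 / -c for AA/AB/BB);
    ``unresolvable`` SNPs inflate the contrast SD, ``otv`` SNPs shift a
    subset of samples to low size, and ``low_cr`` SNPs zero out a
    per-SNP fraction of samples (missing signals).
    """
    config = config or truth.config
    rng = _rng(config.seed, "intensities")
    n_smp, n_snp = truth.genotypes.shape
    classes = truth.snps["latent_class"].to_numpy()

    # contrast centered by genotype: dosage of B 0/1/2 -> +c, 0, -c
    centers = config.contrast_center * (1 - truth.genotypes.astype(float))
    sd = np.full(n_snp, config.contrast_sd)
    sd[classes == "unresolvable"] *= config.unresolvable_sd_factor
    contrast = centers + rng.normal(0.0, 1.0, (n_smp, n_snp)) * sd
    size = config.size_mean + rng.normal(0.0, config.size_sd, (n_smp, n_snp))

    otv_cols = np.flatnonzero(classes == "otv")
    for j in otv_cols:
        pick = rng.random(n_smp) < config.otv_sample_fraction
        size[pick, j] -= config.otv_size_shift
        contrast[pick, j] = rng.normal(0.0, config.contrast_sd, int(pick.sum()))

    lo, hi = config.low_cr_frac_range
    zero_mask = np.zeros((n_smp, n_snp), dtype=bool)
    for j in np.flatnonzero(classes == "low_cr"):
        frac = rng.uniform(lo, hi)
        zero_mask[:, j] = rng.random(n_smp) < frac

    signal_a = np.power(2.0, size + contrast / 2.0)
    signal_b = np.power(2.0, size - contrast / 2.0)
    signal_a[zero_mask] = 0.0
    signal_b[zero_mask] = 0.0

    index = truth.samples["sample_id"].to_numpy()
    columns = truth.snps["snp_id"].to_numpy()
    return (
        pd.DataFrame(signal_a, index=index, columns=columns),
        pd.DataFrame(signal_b, index=index, columns=columns),
    )


# ---------------------------------------------------------------------------
# feature table with planted success signal
# ---------------------------------------------------------------------------


def gen_design_features(
    candidates: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Fabricate a per-SNP feature table with a logistic success label.

    The label is Bernoulli with ``logit P(success) = intercept +
    sum(coef * feature)`` over ``config.success_coefs``; with all
    coefficients zero the empirical success rate converges to the
    inverse-logit of the intercept.
    """
    config.validate()
    rng = _rng(config.seed, "features")
    n = len(candidates)
    feats = pd.DataFrame({"snp_id": candidates["snp_id"].to_numpy()})
    # best/second-best PID: point mass at 100/80 plus a continuous tail
    best_kind = rng.random(n)
    feats["pid_best"] = np.where(
        best_kind < 0.6, 100.0,
        np.where(best_kind < 0.9, rng.uniform(81, 100, n), 80.0),
    )
    feats["pid_second"] = np.minimum(
        feats["pid_best"],
        np.where(rng.random(n) < 0.5, 80.0, rng.uniform(80, 100, n)),
    )
    feats["n_hits_scaffold"] = rng.choice([0, 1, 2, 3], n, p=[0.15, 0.6, 0.15, 0.1])
    feats["pconvert"] = rng.beta(6, 4, n)
    feats["target_snp_prob"] = 10.0 ** rng.uniform(-8, -3, n)
    feats["neg_log10_target_prob"] = -np.log10(feats["target_snp_prob"])
    feats["infinium"] = (rng.random(n) < config.infinium_fraction).astype(int)

    eta = np.full(n, config.success_intercept, dtype=float)
    for var, coef in config.success_coefs.items():
        if var not in feats.columns:
            raise ValueError(f"success_coefs references unknown feature {var!r}")
        eta += coef * feats[var].to_numpy(dtype=float)
    prob = 1.0 / (1.0 + np.exp(-eta))
    feats["success"] = (rng.random(n) < prob).astype(int)
    return feats
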