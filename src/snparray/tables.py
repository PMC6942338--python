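"""Validated TSV readers/writers, FASTA output and the run manifest.

All tables are UTF-8, tab-separated, Unix newlines, with a mandatory
header row.  Schemas are strict: missing or unknown columns and invalid
genotype symbols raise :class:`SchemaError` naming the offender and row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .calling import GENOTYPES, NOCALL

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "read_table",
    "write_table",
    "calls_to_wide",
    "wide_to_long",
    "intensities_to_wide",
    "write_fasta",
    "write_manifest",
]

VALID_CALLS = set(GENOTYPES) | {NOCALL}

#: table name -> {column: dtype}
SCHEMAS: dict[str, dict[str, type]] = {
    "candidates": {
        "snp_id": str,
        "source": str,
        "transcript_id": str,
        "allele_a": str,
        "allele_b": str,
        "context_seq": str,
        "target_snp_prob": float,
        "n_detect_programs": int,
        "flanking_variants": str,
        "infinium_success": bool,
    },
    "probesets": {
        "probeset_id": str,
        "snp_id": str,
        "direction": str,
        "repetitive": bool,
        "pconvert": float,
        "recommendation": str,
        "n_scaffold_hits_v05": int,
        "n_perfect_alleles": int,
        "flanking_rank": int,
    },
    "intensities": {
        "sample_id": str,
        "probeset_id": str,
        "signal_a": float,
        "signal_b": float,
    },
    "calls": {
        "sample_id": str,
        "probeset_id": str,
        "call": str,
        "confidence": float,
    },
    "samples": {
        "sample_id": str,
        "tree_id": str,
        "population_id": str,
        "replicate": int,
        "plate_id": str,
        "dqc": float,
    },
    "features": {},  # free-form numeric feature table; only snp_id required
}


class SchemaError(ValueError):
    """A table violated its declared schema."""


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if schema == "features":
        if "snp_id" not in df.columns:
            raise SchemaError(f"{path}: features table missing column 'snp_id'")
        for col in df.columns:
            if col != "snp_id":
                df[col] = pd.to_numeric(df[col])
        return df
    missing = set(spec) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column {sorted(missing)[0]!r}")
    unknown = set(df.columns) - set(spec)
    if unknown:
        raise SchemaError(f"{path}: unknown column {sorted(unknown)[0]!r}")
    for col, typ in spec.items():
        if typ is bool:
            bad = ~df[col].isin(["True", "False", "true", "false", "1", "0"])
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based incl. header
                raise SchemaError(f"{path}: bad boolean in {col!r} at row {row}")
            df[col] = df[col].isin(["True", "true", "1"])
        elif typ in (int, float):
            blank = df[col] == ""
            try:
                vals = pd.to_numeric(df[col].where(~blank))
            except ValueError as exc:
                raise SchemaError(f"{path}: non-numeric value in {col!r}: {exc}")
            df[col] = vals if typ is float else vals.fillna(0).astype(int)
    if schema == "calls":
        bad = ~df["call"].isin(VALID_CALLS)
        if bad.any():
            row = int(bad.idxmax()) + 2
            sym = df.loc[bad.idxmax(), "call"]
            raise SchemaError(
                f"{path}: invalid genotype symbol {sym!r} in 'call' at row {row}"
            )
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with Unix newlines and a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def calls_to_wide(calls_long: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long calls table -> (calls, confidence) samples x probesets frames."""
    calls = calls_long.pivot(
        index="sample_id", columns="probeset_id", values="call"
    )
    conf = calls_long.pivot(
        index="sample_id", columns="probeset_id", values="confidence"
    )
    return calls, conf


def wide_to_long(calls: pd.DataFrame, conf: pd.DataFrame) -> pd.DataFrame:
    long = calls.stack().rename("call").reset_index()
    long.columns = ["sample_id", "probeset_id", "call"]
    long["confidence"] = conf.stack().to_numpy()
    return long


def intensities_to_wide(
    intens_long: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    a = intens_long.pivot(
        index="sample_id", columns="probeset_id", values="signal_a"
    )
    b = intens_long.pivot(
        index="sample_id", columns="probeset_id", values="signal_b"
    )
    return a, b


def write_fasta(records: dict[str, str], path, width: int = 80) -> None:
    """Write id -> sequence records as FASTA."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_manifest(path, *, inputs: dict, thresholds: dict, seed: int) -> None:
    """Machine-readable record of a run: inputs, thresholds and seed."""
    from . import __version__

    payload = {
        "version": __version__,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "thresholds": thresholds,
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
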