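"""VCF v4.2 export of a genotype call matrix."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .calling import NOCALL

__all__ = ["vcf_export"]

_GT = {"AA": "0/0", "AB": "0/1", "BB": "1/1", NOCALL: "./."}
_BASES = set("ACGT")

#: variant offset within the 71-nt probe context (1-based)
CONTEXT_SNP_POS = 36


def vcf_export(
    calls: pd.DataFrame,
    snp_meta: pd.DataFrame,
    path,
    coordinates: pd.DataFrame | None = None,
    source: str = "snparray",
    protocol: str | None = None,
) -> None:
    """Write calls (samples x SNPs) as a VCF v4.2 file.

    ``snp_meta`` needs ``snp_id, allele_a, allele_b`` and, for unplaced
    SNPs, ``transcript_id``; A is REF and B is ALT.  With no
    ``coordinates`` table (``snp_id, chrom, pos``), records are emitted
    with contig = transcript_id and pos = the in-context SNP offset.
    """
    meta = snp_meta.set_index("snp_id")
    coords = coordinates.set_index("snp_id") if coordinates is not None else None
    samples = list(calls.index)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}" + (f" protocol={protocol}" if protocol else ""),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for snp_id in calls.columns:
        if snp_id not in meta.index:
            raise ValueError(f"no allele metadata for SNP {snp_id!r}")
        ref = str(meta.loc[snp_id, "allele_a"])
        alt = str(meta.loc[snp_id, "allele_b"])
        if ref not in _BASES or alt not in _BASES or ref == alt:
            raise ValueError(
                f"SNP {snp_id!r}: invalid allele pair {ref!r}/{alt!r}"
            )
        if coords is not None and snp_id in coords.index:
            chrom = str(coords.loc[snp_id, "chrom"])
            pos = int(coords.loc[snp_id, "pos"])
        else:
            chrom = str(meta.loc[snp_id, "transcript_id"])
            pos = CONTEXT_SNP_POS
        gts = []
        for s in samples:
            call = calls.at[s, snp_id]
            if call not in _GT:
                raise ValueError(
                    f"SNP {snp_id!r}, sample {s!r}: unknown call {call!r}"
                )
            gts.append(_GT[call])
        lines.append(
            f"{chrom}\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
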