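"""Readers and writers for the pipeline's on-disk formats.

Formats: per-sample VCF 4.2 (one tissue or blood sample per file), BED
target regions (0-based half-open), germline-blacklist TSV, gene x sample
raw count TSV, sample sheet TSV, and GMT gene sets.  VCF reading goes
through cyvcf2; coordinates stay 1-based in memory, and multi-allelic
records are split into one call per ALT with AD/AF matched positionally.

VCF key map: FORMAT DP -> coverage, AD -> variant-supporting count,
AF (fraction) -> frequency in percent; INFO GENE / CCHANGE / PCHANGE /
NONSYN (flag) / Q (variant-allele quality); the QUAL column is the call
quality.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .triage import Locus, VariantCall

VCF_HEADER_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CCHANGE,Number=1,Type=String,Description="HGVS coding change">',
    '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="HGVS protein change">',
    '##INFO=<ID=NONSYN,Number=0,Type=Flag,Description="Non-synonymous variant">',
    '##INFO=<ID=Q,Number=1,Type=Float,Description="Variant-allele quality (phred)">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=A,Type=Integer,Description="Variant-supporting reads per ALT">',
    '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Variant-allele fraction per ALT">',
]

REQUIRED_SHEET_COLUMNS = ("sample_id", "tissue", "blood_id", "sex", "uacr")
TISSUE_CLASSES = ("healthy", "BCC", "SCC")


def _chrom_key(chrom: str):
    digits = chrom.replace("chr", "")
    return (0, int(digits)) if digits.isdigit() else (1, digits)


def write_vcf(
    path: str | Path,
    sample_id: str,
    calls: Sequence[VariantCall],
    *,
    contigs: Sequence[str] | None = None,
) -> None:
    """Write one sample's calls as a sorted single-sample VCF 4.2 file."""
    if contigs is None:
        contigs = sorted({c.chrom for c in calls}, key=_chrom_key)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += VCF_HEADER_LINES
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for c in sorted(calls, key=lambda v: (_chrom_key(v.chrom), v.pos, v.ref, v.alt)):
        info = []
        if c.gene:
            info.append(f"GENE={c.gene}")
        if c.coding_change:
            info.append(f"CCHANGE={c.coding_change}")
        if c.aa_change:
            info.append(f"PCHANGE={c.aa_change}")
        if c.nonsynonymous:
            info.append("NONSYN")
        info.append(f"Q={c.q_score:.2f}")
        qual = "." if c.qual is None else f"{c.qual:g}"
        af = c.count / c.coverage if c.coverage else 0.0
        lines.append(
            "\t".join(
                [
                    c.chrom,
                    str(c.pos),
                    ".",
                    c.ref,
                    c.alt,
                    qual,
                    "PASS",
                    ";".join(info),
                    "DP:AD:AF",
                    f"{c.coverage}:{c.count}:{af:.6f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, sample_id: str | None = None) -> list[VariantCall]:
    """Read a single-sample VCF into VariantCall records (1-based positions).

    Multi-allelic records are split into one call per ALT; AD and AF are
    matched positionally.  Missing DP/AD/Q raise an error naming the file
    and key.
    """
    path = str(path)
    vcf = VCF(path)
    if not vcf.samples:
        raise ValueError(f"{path}: VCF has no sample column")
    sid = sample_id or vcf.samples[0]
    calls = []
    for rec in vcf:
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if dp is None:
            raise ValueError(f"{path}: missing required FORMAT key DP")
        if ad is None:
            raise ValueError(f"{path}: missing required FORMAT key AD")
        q = rec.INFO.get("Q")
        if q is None:
            raise ValueError(f"{path}: missing required INFO key Q")
        coverage = int(dp[0][0])
        gene = rec.INFO.get("GENE") or ""
        cchange = rec.INFO.get("CCHANGE") or ""
        pchange = rec.INFO.get("PCHANGE") or ""
        nonsyn = bool(rec.INFO.get("NONSYN"))
        for i, alt in enumerate(rec.ALT):
            calls.append(
                VariantCall(
                    sample_id=sid,
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    coverage=coverage,
                    count=int(np.atleast_1d(ad[0])[i]),
                    frequency=None,  # recomputed from count/coverage
                    q_score=float(q),
                    qual=None if rec.QUAL is None else float(rec.QUAL),
                    gene=gene,
                    coding_change=cchange,
                    aa_change=pchange,
                    nonsynonymous=nonsyn,
                )
            )
    return calls


def read_variant_tables(
    vcf_paths: Mapping[str, str | Path],
) -> dict[str, list[VariantCall]]:
    """Read several per-sample VCFs, keyed by sample id."""
    return {sid: read_vcf(p, sample_id=sid) for sid, p in vcf_paths.items()}


def write_bed(path: str | Path, regions: Sequence[tuple[str, int, int]]) -> None:
    rows = sorted(regions, key=lambda r: (_chrom_key(r[0]), r[1]))
    Path(path).write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in rows)
    )


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED (0-based half-open)."""
    regions = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{line_no}: BED line needs >=3 columns")
        regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions


def write_blacklist(path: str | Path, blacklist: Iterable[Locus]) -> None:
    rows = sorted(blacklist, key=lambda l: (_chrom_key(l[0]), l[1], l[2], l[3]))
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


def read_blacklist(path: str | Path) -> frozenset[Locus]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: blacklist missing column(s) {sorted(missing)}")
    return frozenset(
        (r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples()
    )


def write_gmt(path: str | Path, sets: Mapping[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT (tab-delimited: name, description, member genes)."""
    sets: dict[str, list[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{line_no}: GMT line needs name, description, >=1 gene"
            )
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{line_no}: duplicate set name {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets


def write_counts(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_sample_sheet(path: str | Path, sheet: pd.DataFrame) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(
    path: str | Path, *, known_blood_ids: Iterable[str] | None = None
) -> pd.DataFrame:
    """Read and validate the sample sheet.

    Requires columns sample_id, tissue, blood_id, sex, uacr; tissue must be
    healthy/BCC/SCC; sample ids unique; UACR numeric.  When
    ``known_blood_ids`` is given, every row's blood pairing must resolve.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "blood_id": str})
    missing = set(REQUIRED_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    dup = df["sample_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 2  # 1-based, after header
        raise ValueError(f"{path}: duplicate sample id at row {row}")
    bad = ~df["tissue"].isin(TISSUE_CLASSES)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: tissue must be one of {TISSUE_CLASSES} at row {row}"
        )
    try:
        df["uacr"] = pd.to_numeric(df["uacr"])
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: non-numeric uacr value: {err}") from err
    if known_blood_ids is not None:
        known = set(known_blood_ids)
        dangling = ~df["blood_id"].isin(known)
        if dangling.any():
            row = int(dangling.idxmax()) + 2
            raise ValueError(
                f"{path}: blood id {df['blood_id'][dangling.idxmax()]!r} "
                f"at row {row} has no matching sample"
            )
    return df.set_index("sample_id")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    header_comment: str | None = None,
    index: bool = True,
    float_format: str = "%.6g",
) -> None:
    """Write a report TSV with stable column order and an optional comment."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
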