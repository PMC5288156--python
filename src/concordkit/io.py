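"""File formats: VCF call sets, BED+depth coverage, SEG, expression and
fusion TSVs, YAML configs.

Conventions: variants are 1-based (VCF); intervals are 0-based half-open
(BED).  All conversions between the two live here.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .cnv import CopySegment, TargetInterval
from .coverage import CoverageProfile
from .transcriptome import FusionCall
from .variants import VariantCall

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_variant_tsv",
    "read_variant_tsv",
    "read_variants",
    "write_coverage",
    "read_coverage",
    "write_bed",
    "read_bed",
    "write_seg",
    "read_seg",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_fusion_tsv",
    "read_fusion_tsv",
    "read_panel",
    "write_truth_config",
    "read_truth_config",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AR,Number=1,Type=Integer,Description="Alt-supporting reads">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">
##INFO=<ID=NSYN,Number=0,Type=Flag,Description="Nonsynonymous">
"""


def write_vcf(calls: Sequence[VariantCall], path: str | os.PathLike,
              contigs: Sequence[str] | None = None) -> None:
    """Write a somatic call set as sites-only VCF 4.2."""
    if contigs is None:
        contigs = sorted({c.chrom for c in calls})
    lines = [_VCF_HEADER.rstrip("\n")]
    for contig in contigs:
        lines.append(f"##contig=<ID={contig}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(calls, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        info = f"DP={c.depth};AR={c.alt_reads};VC={c.var_class}"
        if c.gene:
            info += f";GENE={c.gene}"
        if c.nonsynonymous:
            info += ";NSYN"
        lines.append(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike) -> list[VariantCall]:
    """Read a VCF into VariantCalls (via cyvcf2), splitting multiallelics."""
    from cyvcf2 import VCF

    calls: list[VariantCall] = []
    vcf = VCF(str(path))
    for rec in vcf:
        depth = rec.INFO.get("DP") or 0
        alt_reads = rec.INFO.get("AR")
        if alt_reads is None:
            alt_reads = 0
        gene = rec.INFO.get("GENE")
        var_class = rec.INFO.get("VC")
        nsyn = rec.INFO.get("NSYN") is not None
        for alt in rec.ALT:
            calls.append(
                VariantCall(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    alt_reads=int(alt_reads),
                    depth=int(depth),
                    gene=gene,
                    nonsynonymous=nsyn,
                    var_class=var_class if var_class in
                    ("SNV", "insertion", "deletion", "MNV") else None,
                )
            )
    vcf.close()
    return calls


_VARIANT_COLS = ["chrom", "pos", "ref", "alt", "alt_reads", "depth", "gene",
                 "nonsynonymous", "var_class"]


def write_variant_tsv(calls: Sequence[VariantCall], path) -> None:
    rows = [
        {
            "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "alt_reads": c.alt_reads, "depth": c.depth, "gene": c.gene or "",
            "nonsynonymous": int(c.nonsynonymous), "var_class": c.var_class,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLS).to_csv(path, sep="\t", index=False)


def read_variant_tsv(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    calls = []
    for row in df.itertuples(index=False):
        gene = getattr(row, "gene", None)
        if gene is not None and (pd.isna(gene) or gene == ""):
            gene = None
        vc = getattr(row, "var_class", None)
        calls.append(
            VariantCall(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                alt_reads=int(getattr(row, "alt_reads", 0) or 0),
                depth=int(getattr(row, "depth", 0) or 0),
                gene=gene,
                nonsynonymous=bool(int(getattr(row, "nonsynonymous", 1))),
                var_class=vc if isinstance(vc, str) else None,
            )
        )
    return calls


def read_variants(path) -> list[VariantCall]:
    """Dispatch on extension: .vcf -> VCF, anything else -> TSV."""
    if str(path).endswith(".vcf"):
        return read_vcf(path)
    return read_variant_tsv(path)


def write_coverage(profile: CoverageProfile, path) -> None:
    """Depth TSV: chrom, start, end, id, mean_depth (BED-style intervals)."""
    pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in profile.intervals],
            "start": [iv.start for iv in profile.intervals],
            "end": [iv.end for iv in profile.intervals],
            "id": [iv.id for iv in profile.intervals],
            "mean_depth": profile.depths,
        }
    ).to_csv(path, sep="\t", index=False)


def read_coverage(path) -> CoverageProfile:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "start", "end", "mean_depth"} - set(df.columns)
    if missing:
        raise ValueError(f"coverage TSV missing columns: {sorted(missing)}")
    intervals = [
        TargetInterval(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            id=str(getattr(r, "id", "")),
        )
        for r in df.itertuples(index=False)
    ]
    return CoverageProfile(intervals=intervals,
                           depths=df["mean_depth"].to_numpy(dtype=float))


def write_bed(intervals: Sequence[TargetInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


def read_bed(path) -> list[TargetInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(
                TargetInterval(
                    chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                    id=parts[3] if len(parts) > 3 else "",
                )
            )
    return out


def write_seg(segments: Sequence[CopySegment], path, sample: str = "sample") -> None:
    """SEG-style TSV: sample, chrom, start, end, n_targets, seg_mean."""
    pd.DataFrame(
        {
            "sample": sample,
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_targets": [s.n_targets for s in segments],
            "seg_mean": [s.seg_mean for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_seg(path) -> list[CopySegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CopySegment(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                    n_targets=int(r.n_targets), seg_mean=float(r.seg_mean))
        for r in df.itertuples(index=False)
    ]


def write_expression_tsv(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("gene", "length_bp", "count", "rpkm") if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "length_bp", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"expression TSV missing columns: {sorted(missing)}")
    return df


def write_fusion_tsv(calls: Sequence[FusionCall], path) -> None:
    pd.DataFrame(
        {
            "gene5": [c.gene5 for c in calls],
            "gene3": [c.gene3 for c in calls],
            "caller": [c.caller for c in calls],
            "center": [c.center for c in calls],
            "junction_reads": [c.junction_reads for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fusion_tsv(path) -> list[FusionCall]:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene5", "gene3"} - set(df.columns)
    if missing:
        raise ValueError(f"fusion TSV missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        jr = getattr(r, "junction_reads", None)
        out.append(
            FusionCall(
                gene5=str(r.gene5), gene3=str(r.gene3),
                caller=str(getattr(r, "caller", "")),
                center=str(getattr(r, "center", "")),
                junction_reads=None if jr is None or pd.isna(jr) else int(jr),
            )
        )
    return out


def read_panel(path) -> list[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_truth_config(config, path) -> None:
    from dataclasses import asdict

    d = asdict(config)
    d["cn_segments"] = [list(s) for s in d["cn_segments"]]
    d["fusion_truth"] = [list(p) for p in d["fusion_truth"]]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_truth_config(path):
    from .synthetic import TruthConfig

    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("cn_segments"):
        d["cn_segments"] = tuple(tuple(s) for s in d["cn_segments"])
    if d.get("fusion_truth"):
        d["fusion_truth"] = tuple(tuple(p) for p in d["fusion_truth"])
    return TruthConfig(**d)
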