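"""Two-center comparative pipeline.

Reads a YAML manifest naming each center's files (variant calls, coverage,
copy-number inputs, expression, fusion tables) plus shared resources (gene
model, panels, stage parameters), runs every concordance stage, and emits a
comparative event report: per-event rows with each center's finding and an
agreement flag, plus the global metrics (cross-validation rates in both
directions, indel fractions among well-supported private calls, expression
r^2, fusion validation rates, panel coverage audits).

A stage that fails is recorded as failed in the report and the remaining
stages still run; the process exit is then non-zero.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as ckio
from .cnv import CnaThresholds, call_gene_cna, cbs_segment, cna_concordance, copy_ratio
from .coverage import acmg_audit
from .power import PowerParams, TumorContext
from .purity import InsufficientSitesError, AFObservation, estimate_purity
from .transcriptome import (
    compute_rpkm,
    dual_caller_fusions,
    expression_concordance,
    fusion_cross_validation,
)
from .variants import (
    classify_discordant,
    match_callsets,
    normalize_variant,
    panel_concordance,
    powered_cross_validation,
)

__all__ = ["CenterManifest", "run_pipeline", "render_report", "load_manifest"]

CENTERS = ("A", "B")


@dataclass
class CenterManifest:
    """Validated file manifest for a two-center comparison."""

    variants: dict[str, str]
    coverage: dict[str, str] = field(default_factory=dict)
    tumor_cn_coverage: dict[str, str] = field(default_factory=dict)
    normal_cn_coverage: dict[str, list[str]] = field(default_factory=dict)
    expression: dict[str, str] = field(default_factory=dict)
    fusions: dict[str, list[str]] = field(default_factory=dict)
    germline_coverage: dict[str, str] = field(default_factory=dict)
    gene_model_bed: str | None = None
    panel: str | None = None
    purity_override: dict[str, float] = field(default_factory=dict)
    power: dict[str, Any] = field(default_factory=dict)
    cbs: dict[str, Any] = field(default_factory=dict)
    cna_thresholds: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for center in CENTERS:
            if center not in self.variants:
                raise ValueError(f"manifest must name variants for center {center}")
        for attr in (
            "variants", "coverage", "tumor_cn_coverage", "expression",
            "germline_coverage",
        ):
            for center, path in getattr(self, attr).items():
                if not os.path.exists(path):
                    raise FileNotFoundError(f"{attr}[{center}]: {path}")
        for center, paths in {**self.normal_cn_coverage, **self.fusions}.items():
            for path in paths:
                if not os.path.exists(path):
                    raise FileNotFoundError(f"file for center {center}: {path}")


def load_manifest(path: str | os.PathLike) -> CenterManifest:
    base = Path(path).parent
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def resolve(p):
        return str((base / p)) if not os.path.isabs(p) else p

    centers = raw.get("centers", {})
    fields: dict[str, Any] = {
        "variants": {}, "coverage": {}, "tumor_cn_coverage": {},
        "normal_cn_coverage": {}, "expression": {}, "fusions": {},
        "germline_coverage": {},
    }
    for center, files in centers.items():
        for key, dest in (
            ("variants", "variants"), ("coverage", "coverage"),
            ("tumor_cn_coverage", "tumor_cn_coverage"),
            ("expression", "expression"), ("germline_coverage", "germline_coverage"),
        ):
            if key in files:
                fields[dest][center] = resolve(files[key])
        if "normal_cn_coverage" in files:
            fields["normal_cn_coverage"][center] = [
                resolve(p) for p in files["normal_cn_coverage"]
            ]
        if "fusions" in files:
            fields["fusions"][center] = [resolve(p) for p in files["fusions"]]
    shared = raw.get("shared", {})
    return CenterManifest(
        **fields,
        gene_model_bed=resolve(shared["gene_model"]) if "gene_model" in shared else None,
        panel=resolve(shared["panel"]) if "panel" in shared else None,
        purity_override=raw.get("purity", {}).get("override", {}),
        power=raw.get("power", {}),
        cbs=raw.get("cbs", {}),
        cna_thresholds=raw.get("cna_thresholds", {}),
        seed=int(raw.get("seed", 0)),
    )


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _gene_model(manifest: CenterManifest):
    if manifest.gene_model_bed is None:
        return None
    model: dict[str, list] = {}
    for iv in ckio.read_bed(manifest.gene_model_bed):
        model.setdefault(iv.id, []).append(iv)
    return model


def run_pipeline(manifest: CenterManifest, timestamp: bool = False) -> dict:
    """Execute all stages; returns the comparative report as a dict."""
    report: dict[str, Any] = {
        "metadata": {
            "seed": manifest.seed,
            "power_params": dict(manifest.power),
            "cbs_params": dict(manifest.cbs),
            "powered_partition_context": "evaluating (other) center's purity",
            "input_checksums": {},
            "stages_failed": [],
        },
        "stages": {},
    }
    if timestamp:
        import datetime

        report["metadata"]["timestamp"] = datetime.datetime.now().isoformat()
    for center, path in manifest.variants.items():
        report["metadata"]["input_checksums"][f"variants_{center}"] = _checksum(path)

    power_params = PowerParams(**manifest.power) if manifest.power else PowerParams()
    gene_model = _gene_model(manifest)
    panel = ckio.read_panel(manifest.panel) if manifest.panel else None

    calls: dict[str, list] = {}
    coverage: dict[str, Any] = {}
    purity: dict[str, float] = {}

    # --- load + normalize variants, load coverage
    try:
        for center in CENTERS:
            calls[center] = [
                normalize_variant(c) for c in ckio.read_variants(manifest.variants[center])
            ]
            if center in manifest.coverage:
                coverage[center] = ckio.read_coverage(manifest.coverage[center])
        report["stages"]["inputs"] = {
            "status": "ok",
            "n_calls": {c: len(calls[c]) for c in CENTERS},
        }
    except Exception as exc:  # pragma: no cover - defensive
        report["stages"]["inputs"] = {"status": "failed", "error": str(exc)}
        report["metadata"]["stages_failed"].append("inputs")
        return report

    # --- copy number (first: its segments feed copy-neutral site selection)
    gene_calls: dict[str, dict[str, Any]] = {}
    seg_by_center: dict[str, list] = {}
    if manifest.tumor_cn_coverage and gene_model:
        try:
            thresholds = CnaThresholds(**manifest.cna_thresholds) \
                if manifest.cna_thresholds else CnaThresholds()
            tracks = {}
            for center in CENTERS:
                if center not in manifest.tumor_cn_coverage:
                    continue
                tumor = ckio.read_coverage(manifest.tumor_cn_coverage[center])
                normals = [
                    ckio.read_coverage(p).depths
                    for p in manifest.normal_cn_coverage.get(center, [])
                ]
                if not normals:
                    raise ValueError(f"no normal coverage for center {center}")
                track = copy_ratio(tumor.depths, normals, tumor.intervals)
                tracks[center] = track
                segs = cbs_segment(track, seed=manifest.seed, **manifest.cbs)
                seg_by_center[center] = segs
                gene_calls[center] = {
                    c.gene: {"call": c.call, "seg_mean": c.seg_mean}
                    for c in call_gene_cna(segs, gene_model, thresholds)
                }
            conc = None
            if len(gene_calls) == 2:
                from .cnv import GeneCnaCall

                conc = cna_concordance(
                    [GeneCnaCall(g, v["call"], v["seg_mean"])
                     for g, v in gene_calls["A"].items()],
                    [GeneCnaCall(g, v["call"], v["seg_mean"])
                     for g, v in gene_calls["B"].items()],
                    tracks.get("A"), tracks.get("B"),
                )
            report["stages"]["copy_number"] = {
                "status": "ok",
                "n_segments": {c: len(s) for c, s in seg_by_center.items()},
                "gene_calls": gene_calls,
                "concordance": conc,
            }
        except Exception as exc:
            report["stages"]["copy_number"] = {"status": "failed", "error": str(exc)}
            report["metadata"]["stages_failed"].append("copy_number")
    else:
        report["stages"]["copy_number"] = {"status": "skipped"}

    # --- purity per center (copy-neutral sites only, when segments exist)
    stage: dict[str, Any] = {"status": "ok", "estimates": {}}
    for center in CENTERS:
        if center in manifest.purity_override:
            purity[center] = float(manifest.purity_override[center])
            stage["estimates"][center] = {"alpha": purity[center], "source": "override"}
            continue
        try:
            neutral = _copy_neutral_fn(seg_by_center.get(center))
            obs = [
                AFObservation(alt_reads=c.alt_reads, depth=c.depth,
                              chrom=c.chrom, pos=c.pos,
                              copy_neutral=neutral(c.chrom, c.pos))
                for c in calls[center]
                if c.depth > 0 and c.var_class == "SNV"
            ]
            est = estimate_purity(obs, seed=manifest.seed)
            purity[center] = est.alpha
            stage["estimates"][center] = {
                "alpha": est.alpha,
                "component_means": est.component_means,
                "component_weights": est.component_weights,
                "n_used": est.n_used,
                "n_components": est.n_components,
                "source": "binomial_mixture_em",
            }
        except (InsufficientSitesError, ValueError) as exc:
            purity[center] = 1.0
            stage["estimates"][center] = {
                "alpha": None, "error": str(exc), "source": "failed"
            }
            stage["status"] = "partial"
    report["stages"]["purity"] = stage

    # --- powered cross-validation both directions
    try:
        xval: dict[str, Any] = {}
        for origin, other in (("A", "B"), ("B", "A")):
            if other not in coverage:
                xval[f"{origin}_to_{other}"] = {"status": "no coverage for " + other}
                continue
            ctx = TumorContext(purity=purity[other])
            res = powered_cross_validation(
                calls[origin], calls[other], coverage[other], ctx, power_params
            )
            xval[f"{origin}_to_{other}"] = {
                "n_concordant": res.n_concordant,
                "n_powered_missed": res.n_powered_missed,
                "n_underpowered": res.n_underpowered,
                "n_unassessable": res.n_unassessable,
                "cross_validation_rate": res.cross_validation_rate,
            }
        report["stages"]["powered_cross_validation"] = {"status": "ok", **xval}
    except Exception as exc:
        report["stages"]["powered_cross_validation"] = {
            "status": "failed", "error": str(exc)
        }
        report["metadata"]["stages_failed"].append("powered_cross_validation")

    # --- match table, discordant breakdown, panel agreement
    match = None
    try:
        match = match_callsets(calls["A"], calls["B"])
        breakdown = {
            "A_private": classify_discordant(match.a_private),
            "B_private": classify_discordant(match.b_private),
        }
        stage = {
            "status": "ok",
            "n_concordant": match.n_concordant,
            "n_A_private": len(match.a_private),
            "n_B_private": len(match.b_private),
            "discordant_breakdown": breakdown,
        }
        if panel:
            stage["panel"] = panel_concordance(match, panel)
        report["stages"]["match"] = stage
    except Exception as exc:
        report["stages"]["match"] = {"status": "failed", "error": str(exc)}
        report["metadata"]["stages_failed"].append("match")

    # --- expression
    if len(manifest.expression) == 2:
        try:
            tables = {
                c: compute_rpkm(ckio.read_expression_tsv(manifest.expression[c]))
                for c in CENTERS
            }
            report["stages"]["expression"] = {
                "status": "ok",
                **expression_concordance(tables["A"], tables["B"]),
            }
        except Exception as exc:
            report["stages"]["expression"] = {"status": "failed", "error": str(exc)}
            report["metadata"]["stages_failed"].append("expression")
    else:
        report["stages"]["expression"] = {"status": "skipped"}

    # --- fusions
    if len(manifest.fusions) == 2:
        try:
            by_center = {
                c: [ckio.read_fusion_tsv(p) for p in manifest.fusions[c]]
                for c in CENTERS
            }
            dual = {}
            pooled = {}
            for c in CENTERS:
                tables = by_center[c]
                if len(tables) < 2:
                    raise ValueError(f"center {c} needs two caller tables")
                dual[c] = dual_caller_fusions(tables[0], tables[1])
                pooled[c] = [f for t in tables for f in t]
            stage = {"status": "ok"}
            for origin, other in (("A", "B"), ("B", "A")):
                stage[f"{origin}_to_{other}"] = fusion_cross_validation(
                    dual[origin], pooled[other]
                )
            report["stages"]["fusions"] = stage
        except Exception as exc:
            report["stages"]["fusions"] = {"status": "failed", "error": str(exc)}
            report["metadata"]["stages_failed"].append("fusions")
    else:
        report["stages"]["fusions"] = {"status": "skipped"}

    # --- germline coverage audit
    if manifest.germline_coverage and gene_model:
        try:
            audits = {}
            for center, path in manifest.germline_coverage.items():
                profile = ckio.read_coverage(path)
                rep = acmg_audit(profile, gene_model,
                                 panel=panel if panel else None)
                audits[center] = {
                    "percent_genes_passing_30x": rep.percent_genes_passing_threshold,
                    "all_genes_ge_30x": rep.all_genes_ge_threshold,
                    "genes_below_50x_mtc": rep.genes_below_mtc_flag,
                    "missing_genes": rep.missing_genes,
                }
            report["stages"]["germline_audit"] = {"status": "ok", **audits}
        except Exception as exc:
            report["stages"]["germline_audit"] = {"status": "failed", "error": str(exc)}
            report["metadata"]["stages_failed"].append("germline_audit")
    else:
        report["stages"]["germline_audit"] = {"status": "skipped"}

    # --- comparative event rows
    report["events"] = _event_rows(report, match, gene_calls, panel)
    return report


def _copy_neutral_fn(segments, max_abs_seg_mean: float = 0.2):
    """Locus -> copy-neutral flag from a center's segmentation.

    Without segments every site counts as copy-neutral (and the purity fit
    leans on the mixture to absorb CN-shifted clusters).
    """
    if not segments:
        return lambda chrom, pos: True

    def neutral(chrom: str, pos: int) -> bool:
        for seg in segments:
            if seg.chrom == chrom and seg.start < pos <= seg.end:
                return abs(seg.seg_mean) <= max_abs_seg_mean
        return True

    return neutral


def _event_rows(report, match, gene_calls, panel) -> list[dict]:
    """Table-style rows: one per notable event, with both centers' findings."""
    rows: list[dict] = []
    # copy-number events: any gene not neutral at either center
    if gene_calls and len(gene_calls) == 2:
        for gene in sorted(gene_calls["A"]):
            a = gene_calls["A"][gene]["call"]
            b = gene_calls["B"].get(gene, {}).get("call", "not_assessable")
            if a == b == "neutral":
                continue
            rows.append(
                {
                    "event_class": "gene copy number",
                    "gene": gene,
                    "center_A": a,
                    "center_B": b,
                    "agreement": a == b,
                }
            )
    # mutation events (panel genes if a panel is given, else all discordant)
    if match is not None:
        def label(call):
            if call.var_class == "SNV":
                return f"{call.chrom}:{call.pos} {call.ref}>{call.alt}"
            return f"{call.chrom}:{call.pos} {call.var_class}"

        for pair in match.concordant:
            c = pair[0]
            if panel and c.gene in panel:
                rows.append(
                    {
                        "event_class": "mutation",
                        "gene": c.gene or "",
                        "center_A": label(c),
                        "center_B": label(pair[1]),
                        "agreement": True,
                    }
                )
        for c in match.a_private:
            if not panel or c.gene in panel:
                rows.append(
                    {
                        "event_class": "mutation",
                        "gene": c.gene or "",
                        "center_A": label(c),
                        "center_B": "N.D.",
                        "agreement": False,
                    }
                )
        for c in match.b_private:
            if not panel or c.gene in panel:
                rows.append(
                    {
                        "event_class": "mutation",
                        "gene": c.gene or "",
                        "center_A": "N.D.",
                        "center_B": label(c),
                        "agreement": False,
                    }
                )
    return rows


def render_report(report: dict, path: str | os.PathLike, format: str = "json") -> None:
    """Serialize a report: json (lossless), markdown or tsv (event table)."""
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
    elif format in ("markdown", "md"):
        lines = ["| Event | Gene | Center A | Center B | Agreement |",
                 "|---|---|---|---|---|"]
        for row in report.get("events", []):
            lines.append(
                "| {event_class} | {gene} | {center_A} | {center_B} | {agr} |".format(
                    agr="yes" if row["agreement"] else "no", **row
                )
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif format == "tsv":
        import pandas as pd

        pd.DataFrame(report.get("events", [])).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(
            f"unknown format {format!r}; supported: json, markdown, tsv"
        )


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
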