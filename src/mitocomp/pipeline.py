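"""End-to-end comparative pipeline over labelled genome groups.

``run_pipeline`` takes a manifest mapping GenBank files to group labels
(plus a reference genome for Ka/Ks), runs every analysis stage, and writes
a bundle of TSV tables plus one JSON summary of the headline statistics:
per-partition composition and group tests, pooled RSCU per group, the
ENC-GC3 table with the expected-under-mutation curve, the neutrality fit
and its mutation/selection partition per group, per-gene Ka/Ks per group,
and the gene-order breakpoint matrix.  Every number in the summary is
recomputable from the stage TSVs.
"""

from __future__ import annotations

import json
import logging
import math
import shutil
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import (
    codon_usage,
    composition,
    gene_order,
    mito_io,
    neutrality,
    selection_rates,
)
from .genes import PCGS

logger = logging.getLogger("mitocomp")


@dataclass
class GroupManifest:
    """Map of genome files to group labels, plus the Ka/Ks reference path."""

    groups: dict[str, str]  # path -> label
    reference: str | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("manifest needs at least one genome")
        if any(not lbl for lbl in self.groups.values()):
            raise ValueError("group labels must be non-empty")

    @classmethod
    def from_tsv(cls, path, reference: str | None = None) -> "GroupManifest":
        """Two-column TSV: genome path <tab> group label."""
        groups = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"manifest line not 'path<TAB>label': {line!r}")
            groups[fields[0]] = fields[1]
        return cls(groups, reference)

    @property
    def labels(self) -> list[str]:
        seen = []
        for lbl in self.groups.values():
            if lbl not in seen:
                seen.append(lbl)
        return seen


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _composition_stage(records_by_group, outdir: Path) -> tuple[pd.DataFrame, dict]:
    rows = []
    for label, records in records_by_group.items():
        for rec in records:
            for part in mito_io.PARTITIONS:
                s = composition.composition_summary(rec, part)
                rows.append({
                    "record": rec.id, "group": label, "partition": part,
                    "length_bp": s.length_bp,
                    "frac_A": s.frac_A, "frac_T": s.frac_T,
                    "frac_G": s.frac_G, "frac_C": s.frac_C,
                    "at_content": s.at_content,
                    "at_skew": s.at_skew, "gc_skew": s.gc_skew,
                })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "composition.tsv", sep="\t", index=False, float_format="%.6f")

    tests = []
    labels = list(records_by_group)
    summary: dict = {"per_group": {}}
    for label in labels:
        sub = df[(df.group == label) & (df.partition == "whole")]
        summary["per_group"][label] = {
            "n": int(sub.shape[0]),
            "mean_at_content": float(sub.at_content.mean()),
            "mean_length_bp": float(sub.length_bp.mean()),
        }
    if len(labels) == 2:
        a, b = labels
        for part in mito_io.PARTITIONS:
            for metric in ("at_content", "length_bp", "at_skew", "gc_skew"):
                xa = df[(df.group == a) & (df.partition == part)][metric].dropna()
                xb = df[(df.group == b) & (df.partition == part)][metric].dropna()
                if xa.empty or xb.empty:
                    continue
                cmp = composition.group_compare(list(xa), list(xb), metric=metric)
                tests.append({
                    "partition": part, "metric": metric,
                    "n_a": cmp.n_a, "n_b": cmp.n_b,
                    "median_a": cmp.median_a, "median_b": cmp.median_b,
                    "U": cmp.statistic, "p_value": cmp.p_value, "tier": cmp.tier,
                })
        pd.DataFrame(tests).to_csv(outdir / "composition_tests.tsv",
                                   sep="\t", index=False, float_format="%.6g")
        summary["group_tests"] = {
            f"{t['partition']}:{t['metric']}": {"p": t["p_value"], "tier": t["tier"]}
            for t in tests
        }
    return df, summary


def _codon_stage(records_by_group, outdir: Path) -> dict:
    summary: dict = {}
    for label, records in records_by_group.items():
        pooled: list[str] = []
        for rec in records:
            pooled.extend(seq for _, seq in mito_io.extract_partition(rec, "PCG"))
        s = codon_usage.count_codons(pooled)
        values = codon_usage.rscu(s)
        classes = codon_usage.classify_rscu(s)
        rows = [{
            "codon": c,
            "aa": s.code.forward[c],
            "count": s.count(c),
            "rscu": values[c],
            "class": classes[c],
        } for c in s.code.sense_codons]
        pd.DataFrame(rows).to_csv(outdir / f"rscu_{label}.tsv", sep="\t",
                                  index=False, float_format="%.4f")
        report = codon_usage.rscu_class_report(s)
        summary[label] = {
            "n_codons": s.n_codons,
            "n_overrepresented": report["overrepresented"]["count"],
            "mean_rscu_overrepresented": report["overrepresented"]["mean_rscu"],
            "n_underrepresented": report["underrepresented"]["count"],
            "mean_rscu_underrepresented": report["underrepresented"]["mean_rscu"],
            "n_unused": report["unused"]["count"],
        }
    return summary


def _enc_neutrality_stage(records_by_group, outdir: Path) -> dict:
    rows = []
    summary: dict = {}
    for label, records in records_by_group.items():
        enc_pts = neutrality.enc_gc3_points(records)
        neu_pts = neutrality.neutrality_points(records)
        for rec, (gc3, enc_v), (_, gc12) in zip(records, enc_pts, neu_pts):
            rows.append({
                "record": rec.id, "group": label,
                "gc3": gc3, "gc12": gc12, "enc": enc_v,
                "enc_expected": codon_usage.enc_expected(gc3),
            })
        group_summary: dict = {
            "mean_enc": float(pd.Series([e for _, e in enc_pts]).mean()),
        }
        if len(neu_pts) >= 3 and len({x for x, _ in neu_pts}) > 1:
            fit = neutrality.ols_fit(neu_pts)
            part = neutrality.neutrality_partition(fit)
            group_summary["neutrality"] = {
                "slope": fit.slope, "intercept": fit.intercept,
                "r": fit.r, "F": fit.F_stat, "p": fit.p_value,
                "mutation_pct": part.mutation_pct,
                "selection_pct": part.selection_pct,
            }
        if len(enc_pts) >= 3 and len({x for x, _ in enc_pts}) > 1:
            fit_enc = neutrality.ols_fit(enc_pts)
            group_summary["enc_gc3_fit"] = {
                "slope": fit_enc.slope, "F": fit_enc.F_stat, "p": fit_enc.p_value,
            }
        summary[label] = group_summary
    pd.DataFrame(rows).to_csv(outdir / "enc_gc3.tsv", sep="\t",
                              index=False, float_format="%.6f")
    return summary


def _kaks_stage(records_by_group, reference, outdir: Path) -> dict:
    rows = []
    summary: dict = {}
    for label, records in records_by_group.items():
        res = selection_rates.group_kaks(records, reference, genes=PCGS)
        gene_means = {}
        for gene, bundle in res.items():
            for r in bundle["results"]:
                rows.append({
                    "group": label, "gene": gene,
                    "Ka": r.Ka, "Ks": r.Ks, "ratio": r.ratio, "regime": r.regime,
                })
            gene_means[gene] = {
                "mean_ratio": bundle["mean_ratio"],
                "n_defined": bundle["n_defined"],
                "n_undefined": bundle["n_undefined"],
                "regime": selection_rates.classify_ratio(bundle["mean_ratio"]),
            }
        summary[label] = gene_means
    pd.DataFrame(rows).to_csv(outdir / "kaks.tsv", sep="\t",
                              index=False, float_format="%.6f")
    return summary


def _gene_order_stage(records_by_group, reference, outdir: Path) -> dict:
    orders = []
    for records in records_by_group.values():
        orders.extend(gene_order.extract_order(r) for r in records)
    if reference is not None:
        orders.append(gene_order.extract_order(reference))
    dist, freq = gene_order.order_matrix(orders)
    dist.to_csv(outdir / "gene_order_matrix.tsv", sep="\t")
    freq.to_csv(outdir / "adjacency_freq.tsv", sep="\t", index=False,
                float_format="%.4f")
    (outdir / "gene_orders.txt").write_text(
        "".join(f"{o.record_id}\t{gene_order.order_to_string(o)}\n" for o in orders)
    )
    return {
        "n_orders": len(orders),
        "max_breakpoint_distance": int(dist.values.max()),
        "n_universal_adjacencies": int((freq.frequency == 1.0).sum()),
    }


def run_pipeline(manifest: GroupManifest, outdir) -> dict:
    """Run every comparative stage and write the report bundle to ``outdir``.

    Returns the summary dict (also written as ``summary.json``).  Any stage
    failure removes the partially written bundle and re-raises with a
    stage-tagged message.
    """
    outdir = Path(outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)

    counter = _WarningCounter()
    logger.addHandler(counter)
    stage = "parse"
    try:
        records_by_group: dict[str, list] = {}
        for path, label in manifest.groups.items():
            records_by_group.setdefault(label, []).append(mito_io.read_genbank(path))
        reference = (
            mito_io.read_genbank(manifest.reference) if manifest.reference else None
        )

        summary: dict = {"groups": {
            lbl: [r.id for r in recs] for lbl, recs in records_by_group.items()
        }}
        stage = "composition"
        _, summary["composition"] = _composition_stage(records_by_group, outdir)
        stage = "codon_usage"
        summary["rscu"] = _codon_stage(records_by_group, outdir)
        stage = "enc_neutrality"
        summary["enc_neutrality"] = _enc_neutrality_stage(records_by_group, outdir)
        if reference is not None:
            stage = "kaks"
            summary["kaks"] = _kaks_stage(records_by_group, reference, outdir)
        stage = "gene_order"
        summary["gene_order"] = _gene_order_stage(records_by_group, reference, outdir)

        summary["warnings"] = {"count": len(counter.messages)}
        stage = "summary"
        summary = _sanitize(summary)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, allow_nan=False) + "\n"
        )
        (outdir / "warnings.log").write_text(
            "".join(m + "\n" for m in counter.messages)
        )
        return summary
    except Exception as exc:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        logger.removeHandler(counter)


def _sanitize(obj):
    """Make a summary JSON-safe: NaN/inf -> None, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


__all__ = ["GroupManifest", "run_pipeline"]
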