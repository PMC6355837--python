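"""Stratification of concordance results by genomic and functional context.

Groups per-CpG correlation records by genic class (promoter/genic/
intergenic), regulatory status (any of TFBS, enhancer, open chromatin — or
per feature), mQTL status, or user-supplied gene sets, recomputing both
correlation frameworks within each group.  Also provides the local
region/gene/probe lookup that powers browser-style queries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import (
    ConcordanceSummary,
    CorrelationRecord,
    across_subject_correlation,
    summarize,
)

GROUPINGS = ("genic_class", "regulatory_any", "regulatory_feature", "mqtl", "gene_set")
REGULATORY_FLAGS = ("tfbs", "enhancer", "open_chromatin")


@dataclass
class StratifiedSummary:
    group_label: str
    group_size: int
    summary: ConcordanceSummary | None  # None when the group is too small


def _gene_index(annotation: pd.DataFrame) -> pd.Series:
    """probe -> set of upper-cased gene symbols (semicolon-separated field)."""
    return annotation["genes"].fillna("").map(
        lambda g: {s.strip().upper() for s in str(g).split(";") if s.strip()}
    )


def _groups_for(
    annotation: pd.DataFrame, grouping: str, gene_sets: dict[str, list[str]] | None = None
) -> dict[str, pd.Index]:
    ann = annotation
    if grouping == "genic_class":
        return {
            cls: ann.index[ann["genic_class"] == cls]
            for cls in ("promoter", "genic", "intergenic")
        }
    if grouping == "regulatory_any":
        reg = ann[list(REGULATORY_FLAGS)].any(axis=1)
        return {"regulatory": ann.index[reg], "non_regulatory": ann.index[~reg]}
    if grouping == "regulatory_feature":
        # per-feature groups overlap; not a partition
        return {flag: ann.index[ann[flag]] for flag in REGULATORY_FLAGS}
    if grouping == "mqtl":
        return {"mqtl": ann.index[ann["mqtl"]], "non_mqtl": ann.index[~ann["mqtl"]]}
    if grouping == "gene_set":
        if not gene_sets:
            raise ValueError("grouping 'gene_set' requires gene_sets")
        genes = _gene_index(ann)
        out = {}
        for label, symbols in gene_sets.items():
            wanted = {s.upper() for s in symbols}
            out[label] = ann.index[genes.map(lambda g: bool(g & wanted))]
        return out
    raise ValueError(f"unknown grouping key: {grouping!r}")


def stratified_concordance(
    records: list[CorrelationRecord],
    annotation: pd.DataFrame,
    grouping: str,
    profile_a: pd.Series | None = None,
    profile_b: pd.Series | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    restrict_variable: str | None = None,
    tissue_pair: tuple[str, str] = ("a", "b"),
) -> list[StratifiedSummary]:
    """Concordance summaries per annotation-defined group.

    When mean profiles are supplied the across-subject Pearson correlation is
    recomputed on each group's probes.  Groups with fewer than 3 probes are
    emitted with a null summary and their size.
    """
    rec_by_probe = {r.probe_id: r for r in records}
    groups = _groups_for(annotation, grouping, gene_sets)
    out = []
    for label, probes in groups.items():
        grp_records = [rec_by_probe[p] for p in probes if p in rec_by_probe]
        if len(grp_records) < 3:
            out.append(StratifiedSummary(label, len(grp_records), None))
            continue
        across = None
        if profile_a is not None and profile_b is not None:
            try:
                across, _ = across_subject_correlation(profile_a, profile_b, probes)
            except ValueError:
                across = None
        try:
            summary = summarize(
                grp_records,
                restrict_variable=restrict_variable,
                tissue_pair=tissue_pair,
                across_subject_rho=across,
            )
        except ValueError:
            summary = None
        out.append(StratifiedSummary(label, len(grp_records), summary))
    return out


def gene_set_concordance(
    records: list[CorrelationRecord],
    annotation: pd.DataFrame,
    gene_list: list[str],
    require_variable_in: set[str] | None = None,
    profile_a: pd.Series | None = None,
    profile_b: pd.Series | None = None,
    nominal_alpha: float = 0.05,
    tissue_pair: tuple[str, str] = ("a", "b"),
) -> tuple[ConcordanceSummary, pd.DataFrame]:
    """Concordance within a gene set plus a per-gene breakdown.

    require_variable_in: subset of {'a', 'b'} restricting to records variable
    in the reference tissue ('a'), the peripheral tissue ('b'), or both.
    The per-gene table carries CpG count, nominally correlated count, and
    max |rho| per listed gene.
    """
    if not gene_list:
        raise ValueError("gene_list is empty")
    wanted = {g.upper() for g in gene_list}
    genes = _gene_index(annotation)
    in_set = genes.map(lambda g: bool(g & wanted))
    set_probes = set(annotation.index[in_set])
    matched_symbols = set().union(*genes[in_set]) & wanted if in_set.any() else set()
    if not set_probes:
        raise ValueError(f"no probes map to the gene list; unmatched genes: {sorted(wanted)}")

    recs = [r for r in records if r.probe_id in set_probes]
    if require_variable_in:
        if not set(require_variable_in) <= {"a", "b"}:
            raise ValueError("require_variable_in must be a subset of {'a', 'b'}")
        if "a" in require_variable_in:
            recs = [r for r in recs if r.variable_in_a]
        if "b" in require_variable_in:
            recs = [r for r in recs if r.variable_in_b]
    across = None
    if profile_a is not None and profile_b is not None:
        try:
            across, _ = across_subject_correlation(profile_a, profile_b, sorted(set_probes))
        except ValueError:
            across = None
    summary = summarize(recs, tissue_pair=tissue_pair, across_subject_rho=across)

    rows = []
    rec_by_probe = {r.probe_id: r for r in recs}
    for gene in sorted(matched_symbols):
        probes = [p for p in annotation.index[genes.map(lambda g: gene in g)] if p in rec_by_probe]
        if not probes:
            continue
        rhos = np.array([rec_by_probe[p].rho for p in probes])
        ps = np.array([rec_by_probe[p].p_value for p in probes])
        ok = np.isfinite(rhos) & np.isfinite(ps)
        rows.append(
            {
                "gene": gene,
                "n_cpgs": len(probes),
                "n_nominal": int(np.sum(ps[ok] < nominal_alpha)),
                "max_abs_rho": float(np.max(np.abs(rhos[ok]))) if ok.any() else np.nan,
            }
        )
    per_gene = pd.DataFrame(rows, columns=["gene", "n_cpgs", "n_nominal", "max_abs_rho"])
    return summary, per_gene


# ---------------------------------------------------------------------------
# region / gene / probe query

_INTERVAL_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_interval(text: str) -> tuple[str, int, int]:
    """Parse 'chr:start-end' (1-based inclusive) to 0-based half-open."""
    m = _INTERVAL_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed interval: {text!r} (expected chr:start-end)")
    start, end = int(m["start"]), int(m["end"])
    if start > end:
        raise ValueError(f"malformed interval: start {start} > end {end}")
    return m["chrom"], start - 1, end


def region_query(
    records: list[CorrelationRecord],
    annotation: pd.DataFrame,
    betas: dict[str, pd.DataFrame],
    probe_ids: list[str] | None = None,
    gene: str | None = None,
    interval: str | tuple[str, int, int] | None = None,
) -> tuple[pd.DataFrame, str | None]:
    """Look up methylation level and cross-tissue concordance for a locus.

    Exactly one of probe_ids, gene, or interval must be given.  Intervals as
    strings are 1-based inclusive ('chr1:100-200'); tuple intervals are
    0-based half-open.  Returns (table, warning); an empty match is a warning
    rather than an error.
    """
    selectors = [probe_ids is not None, gene is not None, interval is not None]
    if sum(selectors) != 1:
        raise ValueError("provide exactly one of probe_ids, gene, or interval")

    if probe_ids is not None:
        probes = [str(p) for p in probe_ids if str(p) in annotation.index]
        missing = [str(p) for p in probe_ids if str(p) not in annotation.index]
        warning = f"unknown probes: {missing}" if missing else None
    elif gene is not None:
        genes = _gene_index(annotation)
        probes = list(annotation.index[genes.map(lambda g: gene.upper() in g)])
        warning = None if probes else f"gene {gene!r} not found in annotation"
    else:
        chrom, start0, end0 = parse_interval(interval) if isinstance(interval, str) else interval
        mask = (
            (annotation["chrom"] == chrom)
            & (annotation["pos"] - 1 >= start0)
            & (annotation["pos"] - 1 < end0)
        )
        probes = list(annotation.index[mask])
        warning = None if probes else f"no probes in interval {interval!r}"

    rec_by_probe = {r.probe_id: r for r in records}
    rows = []
    for p in probes:
        row = {
            "probe_id": p,
            "chrom": annotation.loc[p, "chrom"],
            "pos": int(annotation.loc[p, "pos"]),
            "genes": annotation.loc[p, "genes"],
        }
        for tissue, mat in betas.items():
            row[f"mean_beta_{tissue}"] = float(mat.loc[p].mean()) if p in mat.index else np.nan
        rec = rec_by_probe.get(p)
        row["rho"] = rec.rho if rec else np.nan
        row["p"] = rec.p_value if rec else np.nan
        row["variable_a"] = rec.variable_in_a if rec else False
        row["variable_b"] = rec.variable_in_b if rec else False
        rows.append(row)
    cols = ["probe_id", "chrom", "pos", "genes"] + [f"mean_beta_{t}" for t in betas] + [
        "rho",
        "p",
        "variable_a",
        "variable_b",
    ]
    return pd.DataFrame(rows, columns=cols), warning
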