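"""End-to-end pipeline: QC -> identity -> concordance -> stratification ->
ordination -> optional cell-composition adjustment.

`run_pipeline` drives the analysis from a YAML config of file paths;
`run_bundle` is the in-memory engine it delegates to (also used directly on
synthetic cohorts).  All outputs are TSV/JSON under the output directory,
and a manifest records every parameter so a rerun with identical config and
inputs is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as mio
from . import celladjust, concordance, probe_qc, stratify, structure

log = logging.getLogger("methconcord")


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class RunConfig:
    betas: dict[str, str]  # tissue -> path
    sample_sheet: str
    annotation: str
    detection_p: dict[str, str] = field(default_factory=dict)
    snp_probes: str | None = None
    reference_tissue: str = "brain"
    tissue_pairs: list[tuple[str, str]] = field(default_factory=list)
    filter_rules: tuple[str, ...] = probe_qc.FILTER_RULES
    detection_threshold: float = 0.01
    greedycut_stop: float = 0.05
    trim: float = 0.10
    min_range: float = 0.05
    nominal_alpha: float = 0.05
    moderate_rho: float = 0.5
    groupings: tuple[str, ...] = ("genic_class", "regulatory_any", "mqtl")
    gene_set_paths: dict[str, str] = field(default_factory=dict)
    mds_metric: str = "euclidean"
    adjust: bool = False
    reference_profiles: str | None = None  # required when adjust=True
    outdir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissue_pairs:
            self.tissue_pairs = [
                (self.reference_tissue, t) for t in self.betas if t != self.reference_tissue
            ]
        if not self.tissue_pairs:
            raise ValueError("no tissue pairs to compare")
        if not any(self.reference_tissue in pair for pair in self.tissue_pairs):
            raise ValueError(
                f"at least one tissue pair must include the reference tissue "
                f"'{self.reference_tissue}'"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "tissue_pairs" in raw:
            raw["tissue_pairs"] = [tuple(p) for p in raw["tissue_pairs"]]
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Load the input bundle from disk and run the full analysis."""
    betas = {t: mio.read_beta_matrix(p) for t, p in config.betas.items()}
    sheet = mio.read_sample_sheet(config.sample_sheet)
    annotation = mio.read_annotation(config.annotation)
    detection = {t: mio.read_beta_matrix(p) for t, p in config.detection_p.items()}
    snp = mio.read_beta_matrix(config.snp_probes) if config.snp_probes else None
    gene_sets = {
        label: mio.read_gene_list(path) for label, path in config.gene_set_paths.items()
    }
    reference = None
    if config.adjust:
        if not config.reference_profiles:
            raise ValueError("adjust=True requires reference_profiles")
        reference = celladjust.ReferenceProfiles(mio.read_beta_matrix(config.reference_profiles))
    return run_bundle(
        betas,
        sheet,
        annotation,
        detection_p=detection,
        snp_betas=snp,
        config=config,
        gene_sets=gene_sets,
        reference=reference,
    )


def run_bundle(
    betas: dict[str, pd.DataFrame],
    sample_sheet: pd.DataFrame,
    annotation: pd.DataFrame,
    detection_p: dict[str, pd.DataFrame] | None = None,
    snp_betas: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    reference: celladjust.ReferenceProfiles | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs; write artifacts under outdir."""
    if config is None:
        config = RunConfig(betas={t: "" for t in betas}, sample_sheet="", annotation="")
    out = Path(config.outdir)
    for sub in ("qc", "concordance", "stratified", "mds", "adjusted", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    probe_sets = {t: tuple(b.index) for t, b in betas.items()}
    if len(set(probe_sets.values())) != 1:
        raise PipelineError("input: probe sets differ across tissues")

    results: dict = {}

    # ---- stage: QC -------------------------------------------------------
    stage = "qc"
    try:
        unreliable_probes: set[str] = set()
        removed_samples: list[str] = []
        if detection_p:
            all_dp = pd.concat([detection_p[t] for t in sorted(detection_p)], axis=1)
            flags = probe_qc.flag_unreliable(all_dp, config.detection_threshold)
            gc_probes, gc_samples, trace = probe_qc.greedycut(flags, config.greedycut_stop)
            # after greedy-cut, any probe still failing detection anywhere is unreliable
            rest = flags.drop(index=gc_probes, columns=gc_samples)
            unreliable_probes = set(gc_probes) | set(rest.index[rest.any(axis=1)].astype(str))
            removed_samples = gc_samples
        report = probe_qc.filter_probes(annotation, unreliable_probes, config.filter_rules)
        report.samples_removed = removed_samples
        kept = [p for p in report.kept_probes if p in next(iter(betas.values())).index]
        betas = {
            t: b.loc[kept].drop(columns=[s for s in removed_samples if s in b.columns])
            for t, b in betas.items()
        }
        mio.write_json(report.as_dict(), out / "qc" / "filter_report.json")
        log.info("stage=qc kept=%d removed=%d", len(kept), len(report.removed_probes))
        results["qc"] = report
    except Exception as exc:  # noqa: BLE001
        _abort(out, stage, exc)

    # ---- stage: identity -------------------------------------------------
    stage = "identity"
    try:
        if snp_betas is not None:
            identity = probe_qc.verify_sample_identity(snp_betas, sample_sheet)
            mio.write_json(
                {
                    "n_same_subject_pairs": len(identity.expected_same_subject_pairs),
                    "flagged_mismatches": [list(map(str, f)) for f in identity.flagged_mismatches],
                    "unevaluable_samples": identity.unevaluable_samples,
                },
                out / "qc" / "identity_report.json",
            )
            results["identity"] = identity
    except Exception as exc:  # noqa: BLE001
        _abort(out, stage, exc)

    # ---- stage: concordance ---------------------------------------------
    stage = "concordance"
    try:
        profiles = {t: concordance.mean_profile(b) for t, b in betas.items()}
        variable = {t: concordance.classify_variable(b, config.trim, config.min_range) for t, b in betas.items()}
        pair_results = {}
        table1_rows = []
        for ta, tb in config.tissue_pairs:
            across, n_probes = concordance.across_subject_correlation(profiles[ta], profiles[tb])
            records = concordance.within_subject_correlations(
                betas[ta], betas[tb], sample_sheet,
                variable_a=variable[ta], variable_b=variable[tb],
            )
            summary = concordance.summarize(
                records, tissue_pair=(ta, tb),
                nominal_alpha=config.nominal_alpha, moderate_rho=config.moderate_rho,
                across_subject_rho=across,
            )
            variable_probes = [p for p in betas[ta].index if variable[ta][p] and variable[tb][p]]
            across_var = None
            if len(variable_probes) >= 3:
                try:
                    across_var, _ = concordance.across_subject_correlation(
                        profiles[ta], profiles[tb], variable_probes
                    )
                except ValueError:
                    pass
            summary_var = concordance.summarize(
                records, restrict_variable="b", tissue_pair=(ta, tb),
                nominal_alpha=config.nominal_alpha, moderate_rho=config.moderate_rho,
                across_subject_rho=across_var,
            )
            pair_results[(ta, tb)] = {
                "records": records, "summary": summary, "summary_variable": summary_var,
            }
            concordance.records_frame(records).to_csv(
                out / "concordance" / f"records_{ta}_{tb}.tsv", sep="\t", index=False
            )
            table1_rows.append(
                {
                    "tissue_a": ta, "tissue_b": tb,
                    "overall_rho": round(across, 4),
                    "variable_cpg_rho": None if across_var is None else round(across_var, 4),
                    "prop_nominal": round(summary.prop_nominal, 4),
                    "prop_moderate": round(summary.prop_moderate, 4),
                    "mean_within_rho": round(summary.mean_rho, 4),
                }
            )
            log.info("stage=concordance pair=%s-%s n=%d rho=%.3f", ta, tb, n_probes, across)
        table1 = pd.DataFrame(table1_rows)
        table1.to_csv(out / "concordance" / "correlation_matrix.tsv", sep="\t", index=False)
        mio.write_json(
            {f"{ta}-{tb}": res["summary"].as_dict() for (ta, tb), res in pair_results.items()},
            out / "concordance" / "summaries.json",
        )
        results["concordance"] = pair_results
        results["table1"] = table1
        results["profiles"] = profiles
        results["variable"] = variable
    except Exception as exc:  # noqa: BLE001
        _abort(out, stage, exc)

    # ---- stage: stratified ----------------------------------------------
    stage = "stratified"
    try:
        strat_out = {}
        for (ta, tb), res in results["concordance"].items():
            for grouping in config.groupings:
                strata = stratify.stratified_concordance(
                    res["records"], annotation.loc[annotation.index.intersection(betas[ta].index)],
                    grouping,
                    profile_a=results["profiles"][ta], profile_b=results["profiles"][tb],
                    gene_sets=gene_sets, tissue_pair=(ta, tb),
                )
                strat_out[f"{ta}-{tb}:{grouping}"] = [
                    {
                        "group": s.group_label,
                        "size": s.group_size,
                        "summary": s.summary.as_dict() if s.summary else None,
                    }
                    for s in strata
                ]
        mio.write_json(strat_out, out / "stratified" / "stratified_summaries.json")
        results["stratified"] = strat_out
    except Exception as exc:  # noqa: BLE001
        _abort(out, stage, exc)

    # ---- stage: mds ------------------------------------------------------
    stage = "mds"
    try:
        combined = pd.concat([betas[t] for t in sorted(betas)], axis=1)
        distances = structure.sample_distances(combined, metric=config.mds_metric)
        mds = structure.classical_mds(distances, k=2)
        coords = mds.coordinates.join(sample_sheet.set_index("sample")[["subject", "tissue"]])
        coords.to_csv(out / "mds" / "coordinates.tsv", sep="\t", index_label="sample")
        structure.plot_mds(mds, sample_sheet, str(out / "mds" / "mds_plot.png"))
        distances.to_csv(out / "mds" / "distances.tsv", sep="\t", index_label="sample")
        per_subject = {}
        regressions = {}
        ref = config.reference_tissue
        for ta, tb in config.tissue_pairs:
            if ta != ref and tb != ref:
                continue
            periph = tb if ta == ref else ta
            rho_by_subject, warn = structure.per_subject_concordance(
                betas[ref], betas[periph], sample_sheet
            )
            per_subject[periph] = rho_by_subject
            for w in warn:
                log.warning("stage=mds %s", w)
            dist = structure.paired_mds_distances(distances, sample_sheet, ref, periph)
            try:
                regressions[periph] = structure.paired_distance_vs_correlation(
                    dist, rho_by_subject
                )
            except ValueError as exc:
                log.warning("stage=mds regression skipped for %s: %s", periph, exc)
        if per_subject:
            pd.DataFrame(per_subject).to_csv(
                out / "mds" / "per_subject_concordance.tsv", sep="\t", index_label="subject"
            )
        mio.write_json(
            {
                "metric": config.mds_metric,
                "goodness_of_fit": mds.goodness_of_fit,
                "regressions": {
                    t: dict(slope=r.slope, intercept=r.intercept, r_squared=r.r_squared,
                            f_stat=r.f_stat, p_value=r.p_value, n=r.n)
                    for t, r in regressions.items()
                },
            },
            out / "mds" / "mds_summary.json",
        )
        results["mds"] = mds
        results["distances"] = distances
        results["per_subject"] = per_subject
        results["regressions"] = regressions
    except Exception as exc:  # noqa: BLE001
        _abort(out, stage, exc)

    # ---- stage: adjusted -------------------------------------------------
    stage = "adjusted"
    if config.adjust and reference is not None:
        try:
            adj_results = {}
            ref_t = config.reference_tissue
            for ta, tb in config.tissue_pairs:
                if ta != ref_t:
                    continue
                adj_pair = {}
                adj_betas = {}
                for t in (ta, tb):
                    est = celladjust.estimate_proportions(betas[t], reference)
                    adj, rep = celladjust.adjust_for_composition(betas[t], est)
                    adj_betas[t] = adj
                    est.proportions.to_csv(
                        out / "adjusted" / f"proportions_{t}.tsv", sep="\t", index_label="sample"
                    )
                    adj_pair[t] = {"estimate": est, "report": rep}
                rec_adj = concordance.within_subject_correlations(
                    adj_betas[ta], adj_betas[tb], sample_sheet
                )
                comparison = celladjust.compare_adjusted_concordance(
                    results["concordance"][(ta, tb)]["records"], rec_adj
                )
                adj_results[(ta, tb)] = {"comparison": comparison, "records": rec_adj}
                mio.write_json(
                    {k: v for k, v in comparison.items() if not isinstance(v, pd.Series)},
                    out / "adjusted" / f"comparison_{ta}_{tb}.json",
                )
            results["adjusted"] = adj_results
        except Exception as exc:  # noqa: BLE001
            _abort(out, stage, exc)

    # ---- manifest --------------------------------------------------------
    manifest = {
        "version": __version__,
        "parameters": {
            "reference_tissue": config.reference_tissue,
            "tissue_pairs": [list(p) for p in config.tissue_pairs],
            "filter_rules": list(config.filter_rules),
            "detection_threshold": config.detection_threshold,
            "greedycut_stop": config.greedycut_stop,
            "trim": config.trim,
            "min_range": config.min_range,
            "nominal_alpha": config.nominal_alpha,
            "moderate_rho": config.moderate_rho,
            "groupings": list(config.groupings),
            "mds_metric": config.mds_metric,
            "adjust": config.adjust,
            "seed": config.seed,
        },
        "n_probes_kept": len(next(iter(betas.values())).index),
        "tissues": sorted(betas),
    }
    mio.write_json(manifest, out / "report" / "manifest.json")
    results["manifest"] = manifest
    return results


def _abort(out: Path, stage: str, exc: Exception) -> None:
    (out / "report").mkdir(parents=True, exist_ok=True)
    (out / "report" / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
    raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
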