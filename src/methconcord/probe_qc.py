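"""Probe-level quality control and sample-identity verification.

Three filter rules mirror the standard array preprocessing sequence: probes
within 5 bp of a SNP, probes with unreliable detection (detection p > 0.01 or
removed by an iterative greedy-cut over the unreliable-call matrix), and
context-specific (non-CpG) probes.  Sample identity within subjects is
checked by correlating the genotyping control (SNP) probes, whose trimodal
betas act as a genetic fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

FILTER_RULES = ("snp_within_5bp", "unreliable", "context_specific")


@dataclass
class FilterReport:
    counts_removed_per_rule: dict[str, int]
    kept_probes: list[str]
    removed_probes: dict[str, str]  # probe -> first rule it failed
    samples_removed: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "counts_removed_per_rule": self.counts_removed_per_rule,
            "n_kept": len(self.kept_probes),
            "n_removed": len(self.removed_probes),
            "samples_removed": self.samples_removed,
        }


@dataclass
class IdentityReport:
    pairwise_similarity: pd.DataFrame
    expected_same_subject_pairs: list[tuple[str, str]]
    flagged_mismatches: list[tuple[str, str, float, str]]  # (s1, s2, r, reason)
    unevaluable_samples: list[str]


def flag_unreliable(detection_p: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Boolean matrix: True where detection p exceeds the threshold (strict >)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    vals = detection_p.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("detection p-values must lie in [0, 1]")
    return detection_p > threshold


def greedycut(
    unreliable: pd.DataFrame, stop_fraction: float = 0.05
) -> tuple[list[str], list[str], list[dict]]:
    """Iteratively remove the worst probe row or sample column.

    At each step the row or column with the highest fraction of unreliable
    entries is dropped (ties: rows before columns, then lexicographic
    identifier) until the worst remaining fraction is <= stop_fraction.
    Returns (removed_probes, removed_samples, trace).
    """
    if not 0.0 <= stop_fraction <= 1.0:
        raise ValueError("stop_fraction must be in [0, 1]")
    if unreliable.size == 0:
        raise ValueError("unreliable matrix is empty")
    mat = unreliable.to_numpy(dtype=bool).copy()
    rows = list(map(str, unreliable.index))
    cols = list(map(str, unreliable.columns))
    row_alive = np.ones(len(rows), dtype=bool)
    col_alive = np.ones(len(cols), dtype=bool)
    removed_rows: list[str] = []
    removed_cols: list[str] = []
    trace: list[dict] = []

    while row_alive.any() and col_alive.any():
        sub = mat[np.ix_(row_alive, col_alive)]
        row_frac = sub.mean(axis=1)
        col_frac = sub.mean(axis=0)
        best_row = row_frac.max() if len(row_frac) else 0.0
        best_col = col_frac.max() if len(col_frac) else 0.0
        worst = max(best_row, best_col)
        if worst <= stop_fraction:
            break
        alive_rows = [r for r, a in zip(rows, row_alive) if a]
        alive_cols = [c for c, a in zip(cols, col_alive) if a]
        if best_row >= best_col:  # row preferred on ties
            cands = [alive_rows[i] for i in np.flatnonzero(row_frac == best_row)]
            victim = min(cands)
            row_alive[rows.index(victim)] = False
            removed_rows.append(victim)
            trace.append({"kind": "probe", "id": victim, "fraction": float(best_row)})
        else:
            cands = [alive_cols[i] for i in np.flatnonzero(col_frac == best_col)]
            victim = min(cands)
            col_alive[cols.index(victim)] = False
            removed_cols.append(victim)
            trace.append({"kind": "sample", "id": victim, "fraction": float(best_col)})
    return removed_rows, removed_cols, trace


def filter_probes(
    annotation: pd.DataFrame,
    unreliable_rows: set[str] | list[str],
    rules: tuple[str, ...] = FILTER_RULES,
) -> FilterReport:
    """Apply the ordered filter rules; attribute each removal to the first rule hit.

    Rules: 'snp_within_5bp' and 'context_specific' read the annotation flags;
    'unreliable' removes probes in unreliable_rows (detection-p failures plus
    greedy-cut removals).  The kept set preserves input probe order and does
    not depend on rule order (only attribution does).
    """
    for rule in rules:
        if rule not in FILTER_RULES:
            raise ValueError(f"unknown filter rule: {rule!r}")
    unreliable_rows = set(map(str, unreliable_rows))
    probe_ids = [str(p) for p in annotation["probe_id"]]

    fails: dict[str, np.ndarray] = {}
    if "snp_within_5bp" in rules:
        fails["snp_within_5bp"] = annotation["snp_within_5bp"].to_numpy(dtype=bool)
    if "unreliable" in rules:
        fails["unreliable"] = np.array([p in unreliable_rows for p in probe_ids])
    if "context_specific" in rules:
        fails["context_specific"] = annotation["context_specific"].to_numpy(dtype=bool)

    counts = {rule: 0 for rule in rules}
    kept: list[str] = []
    removed: dict[str, str] = {}
    for i, probe in enumerate(probe_ids):
        hit = next((rule for rule in rules if fails[rule][i]), None)
        if hit is None:
            kept.append(probe)
        else:
            removed[probe] = hit
            counts[hit] += 1
    return FilterReport(counts_removed_per_rule=counts, kept_probes=kept, removed_probes=removed)


def verify_sample_identity(
    snp_betas: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    same_threshold: float = 0.9,
    diff_threshold: float = 0.8,
) -> IdentityReport:
    """Check that samples labelled as the same subject genetically match.

    Similarity is the Pearson correlation over SNP probes.  A same-subject
    pair below same_threshold, or a different-subject pair above
    diff_threshold, is flagged.  Zero-variance SNP vectors make a sample
    unevaluable (reported, not an exception).
    """
    if snp_betas.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if snp_betas.shape[0] < 10:
        raise ValueError("need at least 10 SNP probes")
    samples = list(map(str, snp_betas.columns))
    vals = snp_betas.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    unevaluable = [s for s, v in zip(samples, sd) if v == 0]

    with np.errstate(invalid="ignore"):
        sim = np.corrcoef(vals.T)
    np.fill_diagonal(sim, 1.0)
    sim_df = pd.DataFrame(sim, index=samples, columns=samples)

    subj = sample_sheet.set_index("sample")["subject"]
    same_pairs = []
    flags = []
    for s1, s2 in combinations(samples, 2):
        if s1 in unevaluable or s2 in unevaluable:
            continue
        if s1 not in subj.index or s2 not in subj.index:
            continue
        r = float(sim_df.loc[s1, s2])
        if subj[s1] == subj[s2]:
            same_pairs.append((s1, s2))
            if r < same_threshold:
                flags.append((s1, s2, r, "same_subject_below_threshold"))
        elif r > diff_threshold:
            flags.append((s1, s2, r, "different_subject_above_threshold"))
    return IdentityReport(
        pairwise_similarity=sim_df,
        expected_same_subject_pairs=same_pairs,
        flagged_mismatches=flags,
        unevaluable_samples=unevaluable,
    )
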