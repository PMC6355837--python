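"""Cross-tissue concordance statistics.

Two complementary frameworks:

* **across-subject** — Pearson correlation, over probes, between two tissues'
  subject-averaged methylation profiles (a global similarity measure);
* **within-subject** — per-CpG Spearman correlation over subject-paired
  values (which CpGs track the reference tissue in individuals), with exact
  permutation p-values at small n and a t approximation above that.

Also houses the interpercentile-range "variable CpG" classifier, Bonferroni
family-wise thresholding, and the Steiger/Meng-Rosenthal-Rubin z test for
comparing two dependent correlations that share a variable (e.g. brain-saliva
vs brain-blood).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

#: fewest complete subject pairs for which a correlation is reported
MIN_PAIRS = 5
#: largest n for which the exact permutation null is enumerated (n! grows fast)
EXACT_CUTOFF = 7

_TINY = np.nextafter(0.0, 1.0)


@dataclass
class CorrelationRecord:
    probe_id: str
    rho: float  # NaN when not evaluable
    p_value: float  # NaN when not evaluable
    n_pairs: int
    variable_in_a: bool = False
    variable_in_b: bool = False

    @property
    def evaluable(self) -> bool:
        return not math.isnan(self.rho)


@dataclass
class ConcordanceSummary:
    tissue_pair: tuple[str, str]
    n_cpgs: int  # evaluable records
    n_total: int  # records supplied (after any restriction)
    prop_nominal: float
    prop_moderate: float
    mean_rho: float
    median_rho: float
    n_bonferroni: int
    restricted_to_variable: str | None
    across_subject_rho: float | None = None

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["tissue_pair"] = list(self.tissue_pair)
        return d


# ---------------------------------------------------------------------------
# across-subject framework


def mean_profile(betas: pd.DataFrame) -> pd.Series:
    """Per-probe mean beta over non-missing samples."""
    if betas.shape[1] < 1:
        raise ValueError("beta matrix must have at least one sample")
    return betas.mean(axis=1, skipna=True)


def across_subject_correlation(
    profile_a: pd.Series, profile_b: pd.Series, probe_subset=None
) -> tuple[float, int]:
    """Pearson correlation between two mean methylation profiles.

    probe_subset restricts the calculation (the stratified analyses); pairs
    with a missing value in either profile are dropped.
    """
    a, b = profile_a.align(profile_b, join="inner")
    if probe_subset is not None:
        keep = a.index.intersection(pd.Index(probe_subset))
        a, b = a.loc[keep], b.loc[keep]
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError(f"need >= 3 complete probes, have {len(a)}")
    if np.isclose(a.std(ddof=0), 0.0):
        raise ValueError("zero variance in profile_a")
    if np.isclose(b.std(ddof=0), 0.0):
        raise ValueError("zero variance in profile_b")
    r = float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
    return r, int(len(a))


# ---------------------------------------------------------------------------
# within-subject framework


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p-value.

    Enumerates all n! pairings of the (average) ranks of y against x; p is
    the fraction of permutations whose |rho| >= |rho_observed| (observed
    included by construction).  Ties are handled by average ranks; the
    permutation distribution conditions on the observed tie pattern.
    """
    ra = stats.rankdata(x)
    rb = stats.rankdata(y)
    a = ra - ra.mean()
    b = rb - rb.mean()
    na, nb = np.sqrt((a**2).sum()), np.sqrt((b**2).sum())
    if na == 0 or nb == 0:
        return np.nan, np.nan
    rho = float((a * b).sum() / (na * nb))
    perms = _perm_matrix(len(x))
    rho_all = (b[perms] @ a) / (na * nb)
    p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    return rho, p


def spearman_approx(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation with df = n-2."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.where(np.isnan(rho), np.nan, np.clip(p, 0.0, 1.0))


def _paired_matrices(
    betas_a: pd.DataFrame, betas_b: pd.DataFrame, sample_sheet: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, pd.Index, list[str]]:
    """Align the two tissue matrices by subject (one sample per subject per tissue)."""
    by_sample = sample_sheet.set_index("sample")["subject"]
    sub_a = {by_sample[s]: s for s in betas_a.columns if s in by_sample.index}
    sub_b = {by_sample[s]: s for s in betas_b.columns if s in by_sample.index}
    subjects = sorted(set(sub_a) & set(sub_b))
    probes = betas_a.index.intersection(betas_b.index)
    a = betas_a.loc[probes, [sub_a[s] for s in subjects]].to_numpy(dtype=float)
    b = betas_b.loc[probes, [sub_b[s] for s in subjects]].to_numpy(dtype=float)
    return a, b, probes, subjects


def within_subject_correlations(
    betas_a: pd.DataFrame,
    betas_b: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_pairs: int = MIN_PAIRS,
    exact_cutoff: int = EXACT_CUTOFF,
    variable_a: pd.Series | None = None,
    variable_b: pd.Series | None = None,
) -> list[CorrelationRecord]:
    """Per-probe Spearman correlation over subject-paired tissue values.

    Uses pairwise-complete subjects per probe.  For probes with n <=
    exact_cutoff complete pairs the p-value is the exact enumeration p;
    above, the t approximation.  Probes with fewer than min_pairs complete
    pairs or a constant vector yield a null (NaN) record with n recorded.
    """
    a, b, probes, subjects = _paired_matrices(betas_a, betas_b, sample_sheet)
    n_sub = len(subjects)
    if n_sub < min_pairs:
        raise ValueError(f"only {n_sub} subjects shared between tissues; need >= {min_pairs}")

    complete = np.isfinite(a) & np.isfinite(b)
    all_complete = complete.all(axis=1)

    rho = np.full(len(probes), np.nan)
    pval = np.full(len(probes), np.nan)
    npairs = complete.sum(axis=1)

    # fast path: probes complete in every subject, n > exact_cutoff
    if n_sub > exact_cutoff and all_complete.any():
        idx = np.where(all_complete)[0]
        ra = stats.rankdata(a[idx], axis=1)
        rb = stats.rankdata(b[idx], axis=1)
        ra -= ra.mean(axis=1, keepdims=True)
        rb -= rb.mean(axis=1, keepdims=True)
        denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
        ok = denom > 0
        r = np.full(len(idx), np.nan)
        r[ok] = (ra * rb).sum(axis=1)[ok] / denom[ok]
        rho[idx] = r
        pval[idx] = spearman_approx(r, n_sub)
        rest = np.where(~all_complete)[0]
    else:
        rest = np.arange(len(probes))

    for i in rest:
        mask = complete[i]
        n = int(mask.sum())
        if n < min_pairs:
            continue
        x, y = a[i, mask], b[i, mask]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        if n <= exact_cutoff:
            rho[i], pval[i] = spearman_exact(x, y)
        else:
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            r = float(np.corrcoef(rx, ry)[0, 1])
            rho[i] = r
            pval[i] = float(spearman_approx(np.array([r]), n)[0])

    va = variable_a.reindex(probes).fillna(False) if variable_a is not None else None
    vb = variable_b.reindex(probes).fillna(False) if variable_b is not None else None
    records = []
    for i, probe in enumerate(probes):
        records.append(
            CorrelationRecord(
                probe_id=str(probe),
                rho=float(rho[i]),
                p_value=float(pval[i]),
                n_pairs=int(npairs[i]),
                variable_in_a=bool(va.iloc[i]) if va is not None else False,
                variable_in_b=bool(vb.iloc[i]) if vb is not None else False,
            )
        )
    return records


def records_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """CorrelationRecord list -> tidy DataFrame (probe_id index preserved as column)."""
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "rho": [r.rho for r in records],
            "p": [r.p_value for r in records],
            "n_pairs": [r.n_pairs for r in records],
            "variable_a": [r.variable_in_a for r in records],
            "variable_b": [r.variable_in_b for r in records],
        }
    )


# ---------------------------------------------------------------------------
# variability classifier


def classify_variable(
    betas: pd.DataFrame, trim: float = 0.10, min_range: float = 0.05
) -> pd.Series:
    """Interpercentile-range variability flag per probe.

    Drops values outside the [trim, 1-trim] quantiles (linear-interpolation
    quantiles), then flags the probe if the range of the remaining values is
    at least min_range on the beta scale (boundary inclusive).  Probes with
    fewer than 3 non-missing values are flagged False.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    vals = betas.to_numpy(dtype=float)
    n_ok = np.isfinite(vals).sum(axis=1)
    lo = np.nanquantile(vals, trim, axis=1)
    hi = np.nanquantile(vals, 1.0 - trim, axis=1)
    with np.errstate(invalid="ignore"):
        inside = (vals >= lo[:, None]) & (vals <= hi[:, None])
    kept = np.where(inside, vals, np.nan)
    rng = np.nanmax(kept, axis=1) - np.nanmin(kept, axis=1)
    flag = (rng >= min_range) & (n_ok >= 3)
    return pd.Series(flag, index=betas.index)


# ---------------------------------------------------------------------------
# thresholds & summaries


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def summarize(
    records: list[CorrelationRecord],
    restrict_variable: str | None = None,
    tissue_pair: tuple[str, str] = ("a", "b"),
    nominal_alpha: float = 0.05,
    moderate_rho: float = 0.5,
    bonferroni_m: int | None = None,
    across_subject_rho: float | None = None,
) -> ConcordanceSummary:
    """Summarise a set of per-CpG correlation records.

    restrict_variable: None (all), 'a', 'b', or 'both' — limit to records
    flagged variable in that tissue (the variable-CpG analyses, where tissue
    'b' is conventionally the peripheral one).  Proportions are over
    evaluable records; the Bonferroni count uses alpha / bonferroni_m with m
    defaulting to the number of evaluable records.
    """
    if not records:
        raise ValueError("record list is empty")
    if restrict_variable not in (None, "a", "b", "both"):
        raise ValueError(f"unknown restrict_variable: {restrict_variable!r}")
    if restrict_variable == "a":
        records = [r for r in records if r.variable_in_a]
    elif restrict_variable == "b":
        records = [r for r in records if r.variable_in_b]
    elif restrict_variable == "both":
        records = [r for r in records if r.variable_in_a and r.variable_in_b]
    rho = np.array([r.rho for r in records])
    p = np.array([r.p_value for r in records])
    ok = np.isfinite(rho) & np.isfinite(p)
    n_eval = int(ok.sum())
    if n_eval == 0:
        raise ValueError("no evaluable records")
    rho, p = rho[ok], p[ok]
    m = bonferroni_m if bonferroni_m is not None else n_eval
    thresh = bonferroni_threshold(nominal_alpha, m)
    return ConcordanceSummary(
        tissue_pair=tissue_pair,
        n_cpgs=n_eval,
        n_total=len(records),
        prop_nominal=float(np.mean(p < nominal_alpha)),
        prop_moderate=float(np.mean(rho > moderate_rho)),
        mean_rho=float(np.mean(rho)),
        median_rho=float(np.median(rho)),
        n_bonferroni=int(np.sum(p < thresh)),
        restricted_to_variable=restrict_variable,
        across_subject_rho=across_subject_rho,
    )


# ---------------------------------------------------------------------------
# dependent (overlapping) correlation comparison


def compare_dependent_correlations(
    r_common_a: float, r_common_b: float, r_ab: float, n: int
) -> tuple[float, float]:
    """Steiger z test for two correlations sharing one variable.

    Compares r(common, a) with r(common, b) given r(a, b), for correlations
    estimated on the same n observations, via Fisher z-transforms with the
    Meng-Rosenthal-Rubin covariance correction.  Returns (z, two-sided p);
    p is floored at the smallest positive float, in which case it is an
    upper bound.
    """
    for name, r in (("r_common_a", r_common_a), ("r_common_b", r_common_b), ("r_ab", r_ab)):
        if abs(r) >= 1.0:
            raise ValueError(f"{name} must satisfy |r| < 1 (Fisher z undefined at |r|=1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    z1 = np.arctanh(r_common_a)
    z2 = np.arctanh(r_common_b)
    r2bar = (r_common_a**2 + r_common_b**2) / 2.0
    f = min((1.0 - r_ab) / (2.0 * (1.0 - r2bar)), 1.0)
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    z = (z1 - z2) * math.sqrt((n - 3) / (2.0 * (1.0 - r_ab) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(max(p, _TINY))
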