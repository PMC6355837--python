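"""Sample-level structure: distances, classical MDS, per-subject concordance.

Classical (Torgerson) multidimensional scaling embeds all samples from their
pairwise distances over the methylome, recovering the tissue-level geometry
(brain apart from peripheral tissues; saliva between blood and buccal, as
expected from its mixed cellular composition).  Per-subject concordance and
the distance-vs-correlation regression quantify how a subject's peripheral
sample position relates to how well it tracks that subject's brain profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class MDSResult:
    coordinates: pd.DataFrame  # sample x k
    eigenvalues: np.ndarray  # all eigenvalues, descending
    goodness_of_fit: float  # retained positive eigenvalue mass


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int


def sample_distances(
    betas: pd.DataFrame, probe_subset=None, metric: str = "euclidean"
) -> pd.DataFrame:
    """Pairwise sample distances over probes.

    betas: probes x samples (all tissues concatenated column-wise).
    metric: 'euclidean' or 'one_minus_r' (1 - Pearson correlation).
    """
    if betas.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = betas if probe_subset is None else betas.loc[betas.index.intersection(probe_subset)]
    x = mat.to_numpy(dtype=float).T  # samples x probes
    if metric == "euclidean":
        sq = (x**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
        d = np.sqrt(np.clip(d2, 0.0, None))
    elif metric == "one_minus_r":
        d = 1.0 - np.corrcoef(x)
        np.clip(d, 0.0, None, out=d)
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(d, index=mat.columns, columns=mat.columns)


def classical_mds(distances: pd.DataFrame, k: int = 2) -> MDSResult:
    """Torgerson metric MDS: double-center squared distances, eigendecompose.

    Coordinates are the top-k eigenvectors scaled by sqrt(eigenvalue); the
    goodness of fit is the retained share of positive eigenvalue mass.  Axis
    signs are fixed by making each axis's largest-magnitude loading positive.
    """
    n = distances.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}")
    d2 = distances.to_numpy(dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(vals[0]), 1.0)
    n_pos = int(np.sum(vals > tol))
    if k > n_pos:
        raise ValueError(f"k={k} exceeds positive-eigenvalue count {n_pos}")
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    gof = float(vals[:k].sum() / vals[:n_pos].sum())
    return MDSResult(
        coordinates=pd.DataFrame(
            coords, index=distances.index, columns=[f"MDS{i + 1}" for i in range(k)]
        ),
        eigenvalues=vals,
        goodness_of_fit=gof,
    )


def full_rank_embedding(distances: pd.DataFrame) -> pd.DataFrame:
    """Embedding on all positive eigenvalues (used for paired distances)."""
    n = distances.shape[0]
    d2 = distances.to_numpy(dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(vals[0]), 1.0)
    n_pos = int(np.sum(vals > tol))
    coords = vecs[:, :n_pos] * np.sqrt(vals[:n_pos])
    return pd.DataFrame(coords, index=distances.index)


def paired_mds_distances(
    distances: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
) -> pd.Series:
    """Per-subject distance between their tissue_a and tissue_b samples.

    Computed in the full-rank MDS embedding (all positive eigenvalues), so no
    low-dimensional projection artifacts enter.
    """
    emb = full_rank_embedding(distances)
    sheet = sample_sheet.set_index("sample")
    out = {}
    for subject, grp in sheet.groupby("subject"):
        sa = grp.index[grp["tissue"] == tissue_a]
        sb = grp.index[grp["tissue"] == tissue_b]
        if len(sa) == 1 and len(sb) == 1 and sa[0] in emb.index and sb[0] in emb.index:
            out[subject] = float(
                np.linalg.norm(emb.loc[sa[0]].to_numpy() - emb.loc[sb[0]].to_numpy())
            )
    return pd.Series(out, name=f"dist_{tissue_a}_{tissue_b}")


def per_subject_concordance(
    betas_a: pd.DataFrame,
    betas_b: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> tuple[pd.Series, list[str]]:
    """Spearman correlation across all probes, per subject, between two tissues.

    Returns (subject -> rho, warnings for subjects missing a tissue).
    """
    sheet = sample_sheet.set_index("sample")
    warnings: list[str] = []
    out = {}
    for subject, grp in sheet.groupby("subject"):
        cols_a = [s for s in betas_a.columns if s in grp.index]
        cols_b = [s for s in betas_b.columns if s in grp.index]
        if not cols_a or not cols_b:
            warnings.append(f"subject {subject} missing a tissue; omitted")
            continue
        probes = betas_a.index.intersection(betas_b.index)
        va = betas_a.loc[probes, cols_a[0]].to_numpy(dtype=float)
        vb = betas_b.loc[probes, cols_b[0]].to_numpy(dtype=float)
        mask = np.isfinite(va) & np.isfinite(vb)
        rho = stats.spearmanr(va[mask], vb[mask]).statistic
        out[subject] = float(rho)
    return pd.Series(out, name="rho"), warnings


def plot_mds(
    result: MDSResult, sample_sheet: pd.DataFrame, path: str, title: str = "MDS of all samples"
) -> None:
    """Scatter the first two MDS axes, colored by tissue (SVG/PNG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = result.coordinates
    tissue = sample_sheet.set_index("sample")["tissue"].reindex(coords.index)
    fig, ax = plt.subplots(figsize=(6, 5))
    for t in sorted(tissue.dropna().unique()):
        sub = coords[tissue == t]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=t, s=24, alpha=0.8)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def paired_distance_vs_correlation(
    distances: pd.Series, correlations: pd.Series
) -> RegressionResult:
    """OLS of per-subject correlation on per-subject MDS distance.

    Reports slope, intercept, r-squared, and the F test (df 1, n-2) of the
    regression.
    """
    d, c = distances.align(correlations, join="inner")
    mask = d.notna() & c.notna()
    d, c = d[mask], c[mask]
    if len(d) < 3:
        raise ValueError(f"need >= 3 subjects with both values, have {len(d)}")
    if np.ptp(d.to_numpy()) == 0:
        raise ValueError("zero-variance predictor (all distances equal)")
    x = sm.add_constant(d.to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):  # exact fits: F = inf, p = 0
        fit = sm.OLS(c.to_numpy(), x).fit()
        f_stat, f_p = float(fit.fvalue), float(fit.f_pvalue)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_stat=f_stat,
        p_value=0.0 if np.isnan(f_p) and np.isinf(f_stat) else f_p,
        n=int(len(d)),
    )
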