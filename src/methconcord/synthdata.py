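"""Synthetic multi-tissue methylation cohort generator.

Emulates a paired-tissue DNA methylation array study: each subject contributes
one sample per tissue (e.g. brain, blood, saliva, buccal), each bulk sample is
a mixture of latent cell types, and cross-tissue concordance at a CpG arises
from a subject-level random effect shared across that subject's tissues.

Model, per probe j, subject i, tissue t:

    logit(beta_ijt) = logit( sum_c w_itc * expit(mu_j + delta_cj) )
                      + s_j * u_ij + s_j * e_ijt

where mu_j is a bimodal probe-level base mean (hypo/hyper-methylated modes),
delta_cj a cell-type-specific deviation, w_it. the sample's Dirichlet-drawn
cell mixture, u_ij ~ N(0, sigma_u^2) the shared subject effect, e_ijt
~ N(0, sigma_e^2) tissue-specific noise, and s_j a per-probe spread multiplier
(large for the "variable" probe fraction, small otherwise).  Mixing of cell
types happens on the beta scale (bulk methylation is linear in cell
proportions); subject effects and noise act on the logit scale.

The latent cross-tissue correlation of a probe is
sigma_u^2 / (sigma_u^2 + sigma_e^2); a requested ``target_rho`` is converted
to sigma_u with sigma_e fixed by ``noise_sd``.  Every random draw comes from a
named substream of the root seed, drawn in fixed-size probe blocks, so the
bundle is bit-reproducible and extending ``n_probes`` does not perturb
earlier probes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as mio

_BLOCK = 4096
BETA_EPS = 1e-6

#: spread multiplier for probes flagged variable vs. the rest
_VARIABLE_SCALE = 1.0
_STABLE_SCALE = 0.1


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


@dataclass
class SynthConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults encode the emulated study conditions: 21 subjects, four tissues,
    saliva a ~70/30 leukocyte/epithelial mixture with the widest
    sample-to-sample spread, blood nearly pure leukocyte, buccal predominantly
    epithelial, brain a glia-dominated glia/neuron mixture.
    """

    n_subjects: int = 21
    n_probes: int = 10_000
    tissues: tuple[str, ...] = ("brain", "blood", "saliva", "buccal")
    cell_types: tuple[str, ...] = ("leukocyte", "epithelial", "glia", "neuron")
    # Dirichlet concentrations per tissue over a subset of cell_types; the
    # mean mixture is the normalised vector, the sum sets the spread.
    tissue_mixture_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "brain": {"glia": 49.0, "neuron": 21.0},
            "blood": {"leukocyte": 95.0, "epithelial": 5.0},
            "saliva": {"leukocyte": 14.0, "epithelial": 6.0},
            "buccal": {"leukocyte": 8.0, "epithelial": 32.0},
        }
    )
    subject_effect_sd: float = 0.5
    noise_sd: float = 0.5
    target_rho: float | None = None
    variable_fraction: float = 0.5
    cell_profile_sd: float = 1.2
    # per-cell-type multiplier on cell_profile_sd: epithelial methylomes
    # diverge more from the shared baseline than leukocyte or neural lineages,
    # which is what makes predominantly-epithelial buccal track brain worst
    # while the mixed saliva tracks it best
    cell_divergence: dict[str, float] = field(
        default_factory=lambda: {"epithelial": 1.5}
    )
    detection_fail_rate: float = 0.002
    snp_maf: float = 0.3
    snp_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.n_probes < 1:
            raise ConfigError("n_probes must be >= 1")
        if not self.tissues:
            raise ConfigError("tissues must be nonempty")
        if len(set(self.tissues)) != len(self.tissues):
            raise ConfigError("tissues must be unique")
        for sd_name in ("subject_effect_sd", "noise_sd", "cell_profile_sd", "snp_noise_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigError(f"{sd_name} must be >= 0")
        if not 0.0 <= self.variable_fraction <= 1.0:
            raise ConfigError("variable_fraction must be in [0, 1]")
        if not 0.0 <= self.detection_fail_rate <= 1.0:
            raise ConfigError("detection_fail_rate must be in [0, 1]")
        if not 0.0 < self.snp_maf <= 0.5:
            raise ConfigError("snp_maf must be in (0, 0.5]")
        for cell, mult in self.cell_divergence.items():
            if mult <= 0:
                raise ConfigError(f"cell_divergence multiplier for '{cell}' must be > 0")
        if self.target_rho is not None:
            if not 0.0 <= self.target_rho <= 1.0:
                raise ConfigError("target_rho must be in [0, 1]")
            if self.target_rho == 1.0 and self.noise_sd > 0:
                raise ConfigError("target_rho=1 is unattainable with noise_sd > 0")
        for tissue in self.tissues:
            if tissue not in self.tissue_mixture_params:
                raise ConfigError(f"tissue_mixture_params missing tissue '{tissue}'")
            params = self.tissue_mixture_params[tissue]
            for cell, conc in params.items():
                if cell not in self.cell_types:
                    raise ConfigError(f"tissue_mixture_params: unknown cell type '{cell}'")
                if conc <= 0:
                    raise ConfigError(
                        f"tissue_mixture_params: concentration for {tissue}/{cell} must be > 0"
                    )

    def subject_sd(self) -> float:
        """Subject-effect SD implied by target_rho (or the configured SD)."""
        if self.target_rho is None:
            return self.subject_effect_sd
        rho = self.target_rho
        if rho == 0.0:
            return 0.0
        if rho == 1.0:
            # only reachable with noise_sd == 0; any positive SD gives rho=1
            return self.subject_effect_sd if self.subject_effect_sd > 0 else 1.0
        return self.noise_sd * np.sqrt(rho / (1.0 - rho))


@dataclass
class SynthTruth:
    """Generator ground truth recorded alongside a cohort."""

    cell_profiles: pd.DataFrame  # cell type x probe, logit scale
    mixture_proportions: pd.DataFrame  # sample x cell type
    subject_effects: pd.DataFrame  # subject x probe (unscaled by spread)
    realized_rho: pd.Series  # per probe, latent corr between first two tissues
    variable_probes: pd.Series  # per probe, spread-flag ground truth
    seed: int


@dataclass
class CohortBundle:
    betas: dict[str, pd.DataFrame]  # tissue -> probes x samples
    sample_sheet: pd.DataFrame
    annotation: pd.DataFrame
    detection_p: dict[str, pd.DataFrame]
    snp_betas: pd.DataFrame  # 65 SNP probes x all samples
    snp_genotypes: pd.DataFrame  # SNP probe x subject, values in {0, 1, 2}
    truth: SynthTruth


# ---------------------------------------------------------------------------
# seeded substreams


def _stream(seed: int, *key) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _draw_blocked(seed: int, key: tuple, n_probes: int, sampler) -> np.ndarray:
    """Draw a (..., n_probes) array in fixed blocks along the probe axis.

    sampler(rng, m) must return an array whose last axis has length m.
    """
    parts = []
    for b in range(0, n_probes, _BLOCK):
        m = min(_BLOCK, n_probes - b)
        rng = _stream(seed, *key, b // _BLOCK)
        # always draw a full block so a partial final block does not shift
        # the stream: the first k probes are identical for any n >= k
        parts.append(sampler(rng, _BLOCK)[..., :m])
    return np.concatenate(parts, axis=-1)


# ---------------------------------------------------------------------------
# component operations


def simulate_mixture_sample(
    cell_profiles: np.ndarray,
    proportions: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mix cell-type beta profiles into one bulk sample.

    cell_profiles are logit-scale means (cell type x probe); mixing is done on
    the beta scale, then optional logit-normal noise is applied.
    """
    profiles = np.asarray(cell_profiles, dtype=float)
    w = np.asarray(proportions, dtype=float)
    if w.ndim != 1 or w.shape[0] != profiles.shape[0]:
        raise ValueError("proportions length must match number of cell profiles")
    if np.any(w < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1 (got {w.sum()!r})")
    beta = w @ expit(profiles)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        beta = expit(logit(np.clip(beta, BETA_EPS, 1 - BETA_EPS)) + rng.normal(0, noise_sd, beta.shape))
    return np.clip(beta, BETA_EPS, 1 - BETA_EPS)


def spike_snp_probes(
    n_subjects: int,
    n_probes: int = 65,
    maf: float = 0.3,
    noise_sd: float = 0.02,
    seed: int = 0,
    samples_per_subject: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate genotyping control probes with trimodal beta values.

    Genotypes are drawn once per subject under Hardy-Weinberg equilibrium and
    reused for every sample of that subject; betas sit near 0, 0.5, 1 with
    beta-scale Gaussian noise.

    Returns (betas, genotypes): betas is (n_probes, n_subjects *
    samples_per_subject) with columns subject-major, genotypes is
    (n_probes, n_subjects) with allele counts in {0, 1, 2}.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    rng = _stream(seed, "snp")
    genotypes = rng.binomial(2, maf, size=(n_probes, n_subjects))
    base = genotypes / 2.0
    expanded = np.repeat(base, samples_per_subject, axis=1)
    if noise_sd > 0:
        expanded = expanded + rng.normal(0, noise_sd, expanded.shape)
    return np.clip(expanded, 0.0, 1.0), genotypes


def generate_detection_p(
    shape: tuple[int, int], fail_rate: float, seed: int = 0
) -> np.ndarray:
    """Detection p-value matrix: passing entries U(0, 0.005), failures U(0.02, 1)."""
    if not 0.0 <= fail_rate <= 1.0:
        raise ValueError("fail_rate must be in [0, 1]")
    rng = _stream(seed, "detp")
    fails = rng.random(shape) < fail_rate
    p = rng.uniform(0.0, 0.005, shape)
    p[fails] = rng.uniform(0.02, 1.0, int(fails.sum()))
    return p


# ---------------------------------------------------------------------------
# annotation


_GENIC_CLASSES = np.array(["promoter", "genic", "intergenic"])
_GENIC_PROBS = np.array([0.25, 0.45, 0.30])


def _make_annotation(config: SynthConfig, probe_ids: np.ndarray) -> pd.DataFrame:
    n = config.n_probes
    seed = config.seed

    genic = _draw_blocked(seed, ("ann", "genic"), n, lambda r, m: r.choice(3, size=m, p=_GENIC_PROBS))
    tfbs = _draw_blocked(seed, ("ann", "tfbs"), n, lambda r, m: r.random(m) < 0.15)
    enh = _draw_blocked(seed, ("ann", "enh"), n, lambda r, m: r.random(m) < 0.18)
    oc = _draw_blocked(seed, ("ann", "oc"), n, lambda r, m: r.random(m) < 0.15)
    mqtl = _draw_blocked(seed, ("ann", "mqtl"), n, lambda r, m: r.random(m) < 0.06)
    snp5 = _draw_blocked(seed, ("ann", "snp5"), n, lambda r, m: r.random(m) < 0.03)
    ctx = _draw_blocked(seed, ("ann", "ctx"), n, lambda r, m: r.random(m) < 0.005)

    idx = np.arange(n)
    chrom = np.array([f"chr{(i % 22) + 1}" for i in idx])
    pos = 1000 + (idx // 22) * 500 + (idx % 22)  # unique, increasing per chromosome
    genes = np.array([f"G{(i // 10) + 1:04d}" for i in idx], dtype=object)
    genes[genic == 2] = ""  # intergenic probes carry no gene symbol

    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chrom,
            "pos": pos,
            "genes": genes,
            "genic_class": _GENIC_CLASSES[genic],
            "tfbs": tfbs,
            "enhancer": enh,
            "open_chromatin": oc,
            "mqtl": mqtl,
            "snp_within_5bp": snp5,
            "context_specific": ctx,
        },
        index=pd.Index(probe_ids, name=None),
    )


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(config: SynthConfig) -> CohortBundle:
    """Generate a full multi-tissue cohort with recorded ground truth.

    Deterministic for a fixed config (including seed); the first k probes of
    an n-probe cohort equal the k-probe cohort generated from the same seed.
    """
    n, n_sub = config.n_probes, config.n_subjects
    seed = config.seed
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
    subjects = [f"S{i + 1:02d}" for i in range(n_sub)]

    # probe base means: bimodal on the logit scale (hypo/hyper-methylated)
    def _mu(rng, m):
        hyper = rng.random(m) < 0.5
        return np.where(hyper, 2.5, -2.5) + rng.normal(0, 1.0, m)

    mu = _draw_blocked(seed, ("mu",), n, _mu)

    # cell-type deviations
    profiles = {}
    for cell in config.cell_types:
        sd_c = config.cell_profile_sd * config.cell_divergence.get(cell, 1.0)
        delta = _draw_blocked(seed, ("cell", cell), n, lambda r, m: r.normal(0, sd_c, m))
        profiles[cell] = mu + delta
    cell_profiles = pd.DataFrame(profiles, index=probe_ids).T  # cell x probe, logits
    beta_profiles = expit(cell_profiles.to_numpy())

    # per-probe spread: a 'variable' fraction gets full spread, the rest is shrunk
    variable = _draw_blocked(
        seed, ("variable",), n, lambda r, m: r.random(m) < config.variable_fraction
    )
    scale = np.where(variable, _VARIABLE_SCALE, _STABLE_SCALE)

    sigma_u = config.subject_sd()
    sigma_e = config.noise_sd
    u = _draw_blocked(
        seed, ("subject",), n, lambda r, m: r.normal(0, 1.0, (n_sub, m))
    )  # standard normal; scaled below

    # mixture proportions per sample
    cell_index = {c: k for k, c in enumerate(config.cell_types)}
    sample_rows = []
    mixture_rows = {}
    betas: dict[str, pd.DataFrame] = {}
    detection: dict[str, pd.DataFrame] = {}
    latent_noise = {}  # tissue -> (n_sub, n) latent u+e, for realized_rho

    for tissue in config.tissues:
        params = config.tissue_mixture_params[tissue]
        cells = list(params)
        conc = np.array([params[c] for c in cells])
        mrng = _stream(seed, "mixture", tissue)
        w_sub = mrng.dirichlet(conc, size=n_sub)  # n_sub x len(cells)
        w_full = np.zeros((n_sub, len(config.cell_types)))
        for k, c in enumerate(cells):
            w_full[:, cell_index[c]] = w_sub[:, k]

        e = _draw_blocked(
            seed, ("noise", tissue), n, lambda r, m: r.normal(0, 1.0, (n_sub, m))
        )
        latent = scale * (sigma_u * u + sigma_e * e)
        latent_noise[tissue] = latent

        mix_beta = w_full @ beta_profiles  # n_sub x n, beta scale
        vals = expit(logit(np.clip(mix_beta, BETA_EPS, 1 - BETA_EPS)) + latent)
        vals = np.clip(vals, BETA_EPS, 1 - BETA_EPS)

        sample_ids = [f"{s}_{tissue}" for s in subjects]
        betas[tissue] = pd.DataFrame(vals.T, index=probe_ids, columns=sample_ids)

        day = 0 if tissue in ("brain", "blood") else 2
        for s, sid in zip(subjects, sample_ids):
            sample_rows.append({"sample": sid, "subject": s, "tissue": tissue, "day_offset": day})
        for sid, w in zip(sample_ids, w_full):
            mixture_rows[sid] = w

        dp = generate_detection_p(
            (n, n_sub),
            config.detection_fail_rate,
            seed=_stream(seed, "detp-seed", tissue).integers(2**31),
        )
        detection[tissue] = pd.DataFrame(dp, index=probe_ids, columns=sample_ids)

    sheet = pd.DataFrame(sample_rows, columns=mio.SAMPLE_SHEET_COLUMNS)
    mixtures = pd.DataFrame.from_dict(
        mixture_rows, orient="index", columns=list(config.cell_types)
    )

    # realized latent correlation between the first two tissues (per probe)
    if len(config.tissues) >= 2:
        a = latent_noise[config.tissues[0]]
        b = latent_noise[config.tissues[1]]
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, (ac * bc).sum(axis=0) / denom, np.nan)
    else:
        rho = np.full(n, np.nan)
    realized_rho = pd.Series(rho, index=probe_ids).clip(-1.0, 1.0)

    annotation = _make_annotation(config, probe_ids)

    snp_vals, genotypes = spike_snp_probes(
        n_sub,
        65,
        maf=config.snp_maf,
        noise_sd=config.snp_noise_sd,
        seed=_stream(seed, "snp-seed").integers(2**31),
        samples_per_subject=len(config.tissues),
    )
    snp_ids = [f"rs{i:05d}" for i in range(65)]
    snp_cols = [f"{s}_{t}" for s in subjects for t in config.tissues]
    snp_betas = pd.DataFrame(snp_vals, index=snp_ids, columns=snp_cols)
    snp_geno = pd.DataFrame(genotypes, index=snp_ids, columns=subjects)

    truth = SynthTruth(
        cell_profiles=cell_profiles,
        mixture_proportions=mixtures,
        subject_effects=pd.DataFrame(sigma_u * u, index=subjects, columns=probe_ids),
        realized_rho=realized_rho,
        variable_probes=pd.Series(variable, index=probe_ids),
        seed=seed,
    )
    return CohortBundle(
        betas=betas,
        sample_sheet=sheet,
        annotation=annotation,
        detection_p=detection,
        snp_betas=snp_betas,
        snp_genotypes=snp_geno,
        truth=truth,
    )


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write a cohort bundle as TSV files plus a JSON ground-truth record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for tissue, df in bundle.betas.items():
        mio.write_beta_matrix(df, out / f"betas_{tissue}.tsv")
    for tissue, df in bundle.detection_p.items():
        mio.write_beta_matrix(df, out / f"detection_p_{tissue}.tsv")
    mio.write_sample_sheet(bundle.sample_sheet, out / "sample_sheet.tsv")
    mio.write_annotation(bundle.annotation.reset_index(drop=True), out / "annotation.tsv")
    mio.write_beta_matrix(bundle.snp_betas, out / "snp_probes.tsv")
    truth = bundle.truth
    mio.write_json(
        {
            "seed": truth.seed,
            "mixture_proportions": {
                s: [float(x) for x in row]
                for s, row in truth.mixture_proportions.iterrows()
            },
            "cell_types": list(truth.mixture_proportions.columns),
            "realized_rho": [None if np.isnan(x) else float(x) for x in truth.realized_rho],
            "variable_probes": [bool(v) for v in truth.variable_probes],
        },
        out / "truth.json",
    )
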