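"""Synthetic cohorts and textured slides for end-to-end pipeline testing.

No public dataset carries per-patient Gleason pattern pairs, PSA, 5-year
biochemical-recurrence labels *and* patch-level histology, so the package
ships a generator that emulates that structure at desk scale:

* a cohort table (Gleason pair drawn over the nine clinically occurring
  combinations, log-normal PSA, binary BCR outcome) together with
* per-patient patch cluster counts whose Dirichlet-multinomial weights carry
  a hidden prognostic signal partially independent of the Gleason grade, and
* optional rendered slides: a grid of per-cluster procedural textures
  (oriented band-limited gratings under a two-stain colour map) with a
  ground-truth patch table.

The outcome model is logistic in the reasoning base grade, log-PSA and the
hidden signal; an "external institution" mode perturbs the marginal
composition and stain statistics (concentration multiplier, weight and
stain offsets) while leaving the outcome mechanism untouched, so a
well-specified pipeline should transfer across the shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .reasoning import GLEASON_PAIRS, base_score

__all__ = [
    "DEFAULT_GLEASON_PROBS",
    "DomainShift",
    "CohortConfig",
    "TextureParams",
    "generate_cohort",
    "generate_slide",
    "default_impact_loadings",
    "default_grade_loadings",
    "default_texture_params",
    "counts_to_fractions",
    "cluster_columns",
]

# Default frequencies of the nine pattern combinations, in the base-grade
# order of GLEASON_PAIRS.  Per-combination frequencies are free parameters
# of the generator; these defaults reflect a contemporary surgical cohort
# dominated by Gleason 6-7 disease.
DEFAULT_GLEASON_PROBS: tuple[float, ...] = (
    0.28,  # 3+3
    0.25,  # 3+4
    0.17,  # 4+3
    0.10,  # 4+4
    0.04,  # 3+5
    0.08,  # 4+5
    0.02,  # 5+3
    0.04,  # 5+4
    0.02,  # 5+5
)


def default_impact_loadings(k: int, amplitude: float = 0.7) -> np.ndarray:
    """Loadings linking the hidden signal to composition log-weights.

    The first fifth of the clusters is up-weighted and the last fifth
    down-weighted by the hidden signal; the middle is untouched.
    """
    load = np.zeros(k)
    m = max(1, k // 5)
    load[:m] = amplitude
    load[k - m:] = -amplitude
    return load


def default_grade_loadings(k: int, amplitude: float = 0.7) -> np.ndarray:
    """Loadings linking the (centred) grade to composition log-weights.

    Occupies cluster blocks disjoint from :func:`default_impact_loadings`
    so the two signals are only partially confounded in composition space.
    """
    load = np.zeros(k)
    m = max(1, k // 5)
    load[m:min(2 * m, k)] = amplitude
    load[max(0, k - 2 * m):k - m] = -amplitude
    return load


def default_weight_offset(k: int, scale: float = 0.15) -> np.ndarray:
    """Centred log-weight offset used as the institutional composition shift."""
    off = np.zeros(k)
    off[::3] = scale
    return off - off.mean()


@dataclass(frozen=True)
class DomainShift:
    """Institutional domain shift: marginal statistics move, mechanism doesn't.

    ``conc_multiplier`` scales the Dirichlet concentration (lower = noisier
    compositions); ``weight_offset_scale`` sets the amplitude of a fixed,
    centred offset pattern added to the composition log-weights;
    ``stain_offset`` shifts the rendered RGB channels (int8 range).
    """

    conc_multiplier: float = 1.0
    weight_offset_scale: float = 0.0
    stain_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)


#: Shift used for external-institution cohorts in the headline experiment.
DEFAULT_EXTERNAL_SHIFT = DomainShift(
    conc_multiplier=0.7, weight_offset_scale=0.15, stain_offset=(12.0, -8.0, 6.0)
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    The outcome model is
    ``BCR ~ Bernoulli(logistic(beta0 + beta_grade*base + beta_psa*log(psa)
    + beta_hidden*hidden))`` with ``base`` the reasoning base grade (2-10)
    of the drawn Gleason pair and ``hidden ~ N(0, hidden_sd)``.  When
    ``beta0`` is None it is solved so the population prevalence is
    ``target_prevalence`` at the mean covariates.  Cluster counts are drawn
    ``Multinomial(N_i, p_i)`` with
    ``p_i ~ Dirichlet(conc * softmax(hidden_i*impact_loadings +
    grade_i*grade_loadings + offset))``.
    """

    n_patients: int = 170
    cohort: str = "internal"
    gleason_probs: tuple[float, ...] = DEFAULT_GLEASON_PROBS
    psa_mu: float = float(np.log(9.0))   # log-scale location, ng/mL
    psa_sigma: float = 0.55
    beta0: float | None = None
    beta_grade: float = 0.3
    beta_psa: float = 0.7
    beta_hidden: float = 1.6
    hidden_sd: float = 1.0
    target_prevalence: float = 0.45
    n_clusters: int = 100
    patches_per_sample: tuple[int, int] = (500, 1000)
    dirichlet_conc: float = 500.0
    impact_loadings: tuple[float, ...] | None = None
    grade_loadings: tuple[float, ...] | None = None
    shift: DomainShift = field(default_factory=DomainShift)
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.gleason_probs, dtype=float)
        if p.shape != (9,):
            raise ValueError("gleason_probs must have nine entries")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("gleason_probs must be nonnegative and sum to 1")
        if self.psa_sigma <= 0:
            raise ValueError("psa_sigma must be positive")
        if self.hidden_sd < 0:
            raise ValueError("hidden_sd must be nonnegative")
        if self.dirichlet_conc <= 0:
            raise ValueError("dirichlet_conc must be positive")
        if self.n_patients < 1 or self.n_clusters < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.patches_per_sample
        if not 1 <= lo <= hi:
            raise ValueError("patches_per_sample must be an increasing range >= 1")
        for name in ("beta_grade", "beta_psa", "beta_hidden"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.beta0 is not None and not np.isfinite(self.beta0):
            raise ValueError("beta0 must be finite")

    def resolved_beta0(self) -> float:
        """Intercept making prevalence ~= target_prevalence at mean covariates."""
        if self.beta0 is not None:
            return float(self.beta0)
        probs = np.asarray(self.gleason_probs, dtype=float)
        mean_base = float(probs @ np.arange(2, 11))
        pi = self.target_prevalence
        return float(np.log(pi / (1 - pi))
                     - self.beta_grade * mean_base - self.beta_psa * self.psa_mu)

    def resolved_loadings(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.n_clusters
        imp = (np.asarray(self.impact_loadings, dtype=float)
               if self.impact_loadings is not None else default_impact_loadings(k))
        grd = (np.asarray(self.grade_loadings, dtype=float)
               if self.grade_loadings is not None else default_grade_loadings(k))
        if imp.shape != (k,) or grd.shape != (k,):
            raise ValueError("loadings must have n_clusters entries")
        return imp, grd


def cluster_columns(k: int) -> list[str]:
    """Column names c000..c0NN for a counts/composition matrix."""
    width = max(3, len(str(k - 1)))
    return [f"c{i:0{width}d}" for i in range(k)]


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic cohort.

    Returns ``(patients, counts)``: a patient table with columns
    ``patient_id, cohort, gleason_primary, gleason_secondary, gleason_score,
    psa, bcr, hidden, base_grade`` and a (patients x clusters) integer count
    matrix indexed by patient_id with columns ``c000..``.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    k = config.n_clusters
    n = config.n_patients
    rng = child_rng(config.seed, "cohort", config.cohort)

    pair_idx = rng.choice(9, size=n, p=np.asarray(config.gleason_probs, float))
    pairs = [GLEASON_PAIRS[i] for i in pair_idx]
    primary = np.array([p for p, _ in pairs])
    secondary = np.array([s for _, s in pairs])
    score = primary + secondary
    base = np.array([base_score(sc, p, s)
                     for sc, p, s in zip(score, primary, secondary)])

    log_psa = rng.normal(config.psa_mu, config.psa_sigma, size=n)
    psa = np.exp(log_psa)
    hidden = rng.normal(0.0, config.hidden_sd, size=n)

    beta0 = config.resolved_beta0()
    logit = (beta0 + config.beta_grade * base
             + config.beta_psa * log_psa + config.beta_hidden * hidden)
    prob = 1.0 / (1.0 + np.exp(-logit))
    bcr = rng.binomial(1, prob)

    imp, grd = config.resolved_loadings()
    offset = default_weight_offset(k, config.shift.weight_offset_scale)
    grade_centred = (base - 4.0) / 2.0
    logw = (hidden[:, None] * imp[None, :]
            + grade_centred[:, None] * grd[None, :] + offset[None, :])
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)

    conc = config.dirichlet_conc * config.shift.conc_multiplier
    lo, hi = config.patches_per_sample
    totals = rng.integers(lo, hi + 1, size=n)
    counts = np.empty((n, k), dtype=int)
    for i in range(n):
        p_i = rng.dirichlet(conc * w[i])
        counts[i] = rng.multinomial(totals[i], p_i)

    ids = [f"{config.cohort}-{i:04d}" for i in range(n)]
    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "cohort": config.cohort,
            "gleason_primary": primary,
            "gleason_secondary": secondary,
            "gleason_score": score,
            "psa": psa,
            "bcr": bcr,
            "hidden": hidden,
            "base_grade": base,
        }
    )
    counts_df = pd.DataFrame(counts, columns=cluster_columns(k), index=ids)
    counts_df.index.name = "patient_id"
    return patients, counts_df


def counts_to_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise a counts matrix into composition fractions."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every sample needs at least one patch")
    return counts.div(totals, axis=0)


# ---------------------------------------------------------------------------
# slide rendering


@dataclass(frozen=True)
class TextureParams:
    """Procedural texture family per cluster.

    Each cluster renders as an oriented sinusoidal grating (frequency in
    cycles per patch, orientation in radians) whose intensity interpolates
    between two stain-like colours; families are placed on an
    orientation x frequency x colour-mix grid so a simple descriptor can
    tell them apart.  ``background`` is the slide background colour.
    """

    patch_px: int = 32
    frequencies: tuple[float, ...] = ()
    orientations: tuple[float, ...] = ()
    colour_mixes: tuple[float, ...] = ()
    stain_dark: tuple[float, float, float] = (110.0, 60.0, 140.0)   # haematoxylin-like
    stain_light: tuple[float, float, float] = (235.0, 150.0, 180.0)  # eosin-like
    background: tuple[float, float, float] = (255.0, 255.0, 255.0)
    noise_sd: float = 4.0

    @property
    def n_families(self) -> int:
        return len(self.frequencies)


def default_texture_params(k: int, patch_px: int = 32) -> TextureParams:
    """Distinguishable texture families for ``k`` clusters."""
    n_orient = 4
    n_freq = int(np.ceil(k / (n_orient * 2))) + 1
    freqs, orients, mixes = [], [], []
    for c in range(k):
        orients.append(np.pi * (c % n_orient) / n_orient)
        freqs.append(2.0 + 2.5 * ((c // n_orient) % n_freq))
        mixes.append((c % 10) / 9.0 if k > 1 else 0.5)
    return TextureParams(
        patch_px=patch_px,
        frequencies=tuple(freqs),
        orientations=tuple(orients),
        colour_mixes=tuple(mixes),
    )


def _render_patch(cluster: int, params: TextureParams,
                  rng: np.random.Generator,
                  stain_offset: tuple[float, float, float]) -> np.ndarray:
    n = params.patch_px
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    f = params.frequencies[cluster]
    th = params.orientations[cluster]
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * f * (xx * np.cos(th) + yy * np.sin(th)) / n + phase)
    inten = 0.5 + 0.45 * wave  # 0..1
    mix = params.colour_mixes[cluster]
    dark = np.asarray(params.stain_dark)
    light = np.asarray(params.stain_light)
    base_col = mix * dark + (1 - mix) * light
    white = np.asarray([250.0, 250.0, 250.0])
    img = inten[..., None] * base_col[None, None, :] \
        + (1 - inten[..., None]) * white[None, None, :]
    img = img + rng.normal(0, params.noise_sd, img.shape)
    img = img + np.asarray(stain_offset)[None, None, :]
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_slide(
    counts,
    texture_params: TextureParams | None = None,
    seed: int = 0,
    margin: int = 0,
    stain_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic slide from a per-cluster patch count vector.

    Patches are laid on a near-square grid in randomised order; cells beyond
    the patch total are background.  Returns the RGB uint8 image and a
    ground-truth table with 0-based half-open pixel intervals
    ``x0,y0,x1,y1,cluster``.  Deterministic given ``seed``.
    """
    counts = np.asarray(counts, dtype=int)
    total = int(counts.sum())
    if total <= 0:
        raise ValueError("counts must sum to a positive patch total")
    if texture_params is None:
        texture_params = default_texture_params(len(counts))
    if texture_params.n_families < len(counts):
        raise ValueError(
            f"{texture_params.n_families} texture families for "
            f"{len(counts)} clusters"
        )
    rng = child_rng(seed, "slide")
    labels = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(labels)

    px = texture_params.patch_px
    ncol = int(np.ceil(np.sqrt(total)))
    nrow = int(np.ceil(total / ncol))
    width = ncol * px + 2 * margin
    height = nrow * px + 2 * margin
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = np.asarray(texture_params.background, dtype=np.uint8)

    records = []
    for idx, cluster in enumerate(labels):
        r, c = divmod(idx, ncol)
        y0 = margin + r * px
        x0 = margin + c * px
        img[y0:y0 + px, x0:x0 + px] = _render_patch(
            int(cluster), texture_params, rng, stain_offset)
        records.append((x0, y0, x0 + px, y0 + px, int(cluster)))
    truth = pd.DataFrame(records, columns=["x0", "y0", "x1", "y1", "cluster"])
    return img, truth
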