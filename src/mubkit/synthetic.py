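"""Synthetic paired-tendon B-mode simulator with known ground truth.

No image archive accompanies the reference cohort, so every downstream
stage is exercised against rendered stand-ins.  The simulator states a
simple physical world:

* a tendon band (longitudinal plane) or flattened-oval cross-section
  (transverse plane) of known thickness sits in a 2-cm-deep field of
  view over a hypoechoic background;
* within the tendon, the fibrillar architecture appears as periodic
  striations across depth (longitudinal) or isotropic micro-texture
  (transverse) of amplitude ``fibril_contrast`` — organised collagen is
  striated, degenerate collagen is smooth;
* multiplicative speckle modulates everything:
  ``1 + speckle_scale * (R/E[R] - 1)`` with ``R ~ Rayleigh``, so
  ``speckle_scale = 0`` is exactly noise-free and ``1`` is fully
  developed mean-normalised Rayleigh speckle.

A symptomatic tendon is thicker (multiplicative factor), darker
(additive echogenicity drop) and smoother (fibril-contrast drop), each
scaled by a per-subject latent severity that also drives the clinical
measures linearly — the simplest structure with tunable biomarker–clinic
correlations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import reference
from .errors import InvalidParameterError
from .geometry import (
    LONGITUDINAL,
    PLANES,
    TRANSVERSE,
    BoundaryCurves,
    CalibratedImage,
)

SIDES = ("asympt", "sympt")
_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)  # mean of Rayleigh(scale=1)

#: default probe footprint width (mm) fixing horizontal calibration
FOOTPRINT_MM = 50.0


@dataclass(frozen=True)
class TendonImageParams:
    """Generative parameters of one rendered tendon image."""

    thickness_mm: float = 5.15
    mean_echo: float = 77.0
    fibril_contrast: float = 8.0
    fibril_period_mm: float = 0.8
    speckle_scale: float = 0.5
    depth_mm: float = 20.0
    plane: str = LONGITUDINAL
    superior_margin_mm: float = 4.0
    background_echo: float = 35.0
    transverse_semiwidth_mm: float = 7.5
    psf_mm: float = 0.3

    def __post_init__(self):
        if min(self.thickness_mm, self.fibril_period_mm, self.depth_mm,
               self.superior_margin_mm, self.transverse_semiwidth_mm) <= 0:
            raise InvalidParameterError("lengths must be positive")
        if not 0 <= self.mean_echo <= 255 or not 0 <= self.background_echo <= 255:
            raise InvalidParameterError("echo levels must lie in [0, 255]")
        if self.fibril_contrast < 0 or self.speckle_scale < 0 or self.psf_mm < 0:
            raise InvalidParameterError("contrast, speckle scale and PSF width "
                                        "must be >= 0")
        if self.plane not in PLANES:
            raise InvalidParameterError(f"unknown plane {self.plane!r}")
        if self.thickness_mm + self.superior_margin_mm >= self.depth_mm:
            raise InvalidParameterError(
                f"tendon band ({self.superior_margin_mm:g} + {self.thickness_mm:g} mm) "
                f"exceeds the {self.depth_mm:g} mm field of view")


@dataclass(frozen=True)
class SymptomaticEffects:
    """Symptomatic-side parameter shifts (thicker, darker, smoother)."""

    thickening_factor: float = 1.0
    echo_drop: float = 0.0
    contrast_drop: float = 0.0

    def __post_init__(self):
        if not all(np.isfinite([self.thickening_factor, self.echo_drop,
                                self.contrast_drop])):
            raise InvalidParameterError("effects must be finite")

    def scaled(self, severity: float) -> "SymptomaticEffects":
        """Effects modulated by a latent severity (severity 1 = nominal)."""
        return SymptomaticEffects(
            thickening_factor=1.0 + (self.thickening_factor - 1.0) * severity,
            echo_drop=self.echo_drop * severity,
            contrast_drop=self.contrast_drop * severity,
        )


def apply_symptomatic_effects(params: TendonImageParams,
                              effects: SymptomaticEffects) -> TendonImageParams:
    """Shift generative parameters to their symptomatic-side values.

    Thickness is multiplied by the thickening factor; echogenicity and
    fibril contrast are reduced by their drops.  The resulting parameter
    set is re-validated (an over-large band or negative contrast raises
    :class:`InvalidParameterError`).
    """
    return dataclasses.replace(
        params,
        thickness_mm=params.thickness_mm * effects.thickening_factor,
        mean_echo=params.mean_echo - effects.echo_drop,
        fibril_contrast=params.fibril_contrast - effects.contrast_drop,
    )


def render_tendon_image(params: TendonImageParams, rows: int, cols: int,
                        rng_seed: int,
                        col_spacing_mm: float | None = None,
                        side: str | None = None,
                        image_index: int | None = None,
                        ) -> tuple[CalibratedImage, BoundaryCurves]:
    """Render one calibrated B-mode frame plus its ground-truth boundaries.

    Vertical pixel spacing is ``depth_mm / rows``; horizontal spacing
    defaults to a 5-cm probe footprint divided across the columns.  A
    pixel at row r images depth ``r * row_spacing``; it belongs to the
    tendon when that depth lies in the half-open band
    ``[superior_margin, superior_margin + thickness)`` (longitudinal) or
    inside the flattened-oval cross-section (transverse).  The striation
    / micro-texture field is demeaned per column inside the tendon, so
    the noise-free intra-tendon column means equal ``mean_echo`` exactly.
    """
    if rows < 32 or cols < 32:
        raise InvalidParameterError("raster must be at least 32 x 32")
    rs = params.depth_mm / rows
    cs = col_spacing_mm if col_spacing_mm is not None else FOOTPRINT_MM / cols
    if cs <= 0:
        raise InvalidParameterError("column spacing must be positive")
    rng = np.random.default_rng(rng_seed)

    z = np.arange(rows)[:, None] * rs          # depth at each pixel centre
    echo = np.full((rows, cols), params.background_echo, dtype=float)

    if params.plane == LONGITUDINAL:
        inside = (z >= params.superior_margin_mm) & \
                 (z < params.superior_margin_mm + params.thickness_mm)
        inside = np.broadcast_to(inside, (rows, cols)).copy()
        texture = params.fibril_contrast * np.sin(
            2.0 * np.pi * (z - params.superior_margin_mm) / params.fibril_period_mm)
        texture = np.broadcast_to(texture, (rows, cols)).copy()
    else:
        x = (np.arange(cols) - (cols - 1) / 2.0) * cs
        xa = np.clip(np.abs(x) / params.transverse_semiwidth_mm, 0.0, 1.0)
        # flattened oval: superellipse chord, exponent 4
        half = (params.thickness_mm / 2.0) * (1.0 - xa ** 4) ** 0.25
        half[np.abs(x) >= params.transverse_semiwidth_mm] = 0.0
        zc = params.superior_margin_mm + params.thickness_mm / 2.0
        inside = (z >= zc - half[None, :]) & (z < zc + half[None, :])
        if params.fibril_contrast > 0:
            # fibril cross-sections are sub-resolution dots imaged at the
            # system PSF scale, so the micro-texture decorrelates at psf_mm
            sigma_px = (max(params.psf_mm / 2.355 / rs, 0.35),
                        max(params.psf_mm / 2.355 / cs, 0.35))
            noise = gaussian_filter(rng.standard_normal((rows, cols)), sigma_px,
                                    mode="reflect")
            sd = noise.std()
            # RMS-match the longitudinal sinusoid (amplitude / sqrt(2))
            texture = noise / (sd if sd > 0 else 1.0) * \
                params.fibril_contrast / np.sqrt(2.0)
        else:
            texture = np.zeros((rows, cols))

    if not inside.any():
        raise InvalidParameterError("tendon band covers no pixel at this raster")

    # per-column demeaning keeps intra-tendon column means at mean_echo
    tex = np.where(inside, texture, 0.0)
    n_in = inside.sum(axis=0)
    col_mean = np.divide(tex.sum(axis=0), n_in, out=np.zeros(cols), where=n_in > 0)
    echo[inside] = (params.mean_echo + texture - col_mean[None, :])[inside]

    if params.speckle_scale > 0:
        # fully developed speckle has a fixed coefficient of variation
        # (~0.523 for Rayleigh); the system PSF correlates it spatially.
        cv = np.sqrt(4.0 / np.pi - 1.0)
        noise = rng.rayleigh(1.0, size=(rows, cols)) / _RAYLEIGH_MEAN - 1.0
        if params.psf_mm > 0:
            sigma = (params.psf_mm / 2.355 / rs, params.psf_mm / 2.355 / cs)
            noise = gaussian_filter(noise, sigma, mode="reflect")
            sd = noise.std()
            if sd > 0:
                noise *= cv / sd
        echo *= 1.0 + params.speckle_scale * noise

    pixels = np.clip(np.rint(echo), 0, 255).astype(np.uint8)
    image = CalibratedImage(pixels=pixels, row_spacing_mm=rs, col_spacing_mm=cs,
                            plane=params.plane, side=side, image_index=image_index)

    col_has = inside.any(axis=0)
    bcols = np.flatnonzero(col_has)
    sup = np.argmax(inside[:, bcols], axis=0)
    inf = rows - 1 - np.argmax(inside[::-1, bcols], axis=0)
    boundaries = BoundaryCurves(cols=bcols, superior=sup, inferior=inf)
    return image, boundaries


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalLink:
    """Latent-severity regression for one clinical outcome.

    ``value = mean + coef * (severity - 1) + Normal(0, resid_sd)``,
    then rounded (if integer-valued) and clipped to the instrument range.
    """

    mean: float
    resid_sd: float
    coef: float = 0.0
    lo: float = 0.0
    hi: float = float("inf")
    integer: bool = False

    def __post_init__(self):
        if self.resid_sd < 0:
            raise InvalidParameterError("residual SD must be >= 0")

    def draw(self, severity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = self.mean + self.coef * (severity - 1.0) + \
            rng.normal(0.0, self.resid_sd, size=severity.shape)
        if self.integer:
            y = np.rint(y)
        return np.clip(y, self.lo, self.hi)


@dataclass(frozen=True)
class PairedClinicalLink:
    """Per-side clinical outcome with a severity-scaled side asymmetry.

    ``asympt = base + e_a``; ``sympt = base * (1 + di_frac * severity) + e_s``
    with ``base ~ Normal(mean, between_sd)`` and independent per-side
    measurement residuals — so at ``di_frac = 0`` the two sides are
    exchangeable (the null world used for calibration checks).
    """

    mean: float
    between_sd: float
    di_frac: float = 0.0
    resid_sd: float = 0.0
    lo: float = 0.0

    def draw(self, severity: np.ndarray, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
        base = rng.normal(self.mean, self.between_sd, size=severity.shape)
        e_a = rng.normal(0.0, self.resid_sd, size=severity.shape)
        e_s = rng.normal(0.0, self.resid_sd, size=severity.shape)
        asympt = np.clip(base + e_a, self.lo, None)
        sympt = np.clip(base * (1.0 + self.di_frac * severity) + e_s, self.lo, None)
        return asympt, sympt


def _default_asympt_params() -> dict[str, TendonImageParams]:
    m = reference.SIDE_MEANS
    return {
        LONGITUDINAL: TendonImageParams(
            thickness_mm=m["thickness_longitudinal_mm"][0],
            mean_echo=m["echogenicity_longitudinal"][0],
            plane=LONGITUDINAL),
        TRANSVERSE: TendonImageParams(
            thickness_mm=m["thickness_transverse_mm"][0],
            mean_echo=m["echogenicity_transverse"][0],
            plane=TRANSVERSE),
    }


def _default_between_sd() -> dict[str, dict[str, float]]:
    m = reference.SIDE_MEANS
    return {
        LONGITUDINAL: {"thickness": m["thickness_longitudinal_mm"][1],
                       "echo": m["echogenicity_longitudinal"][1], "contrast": 1.5},
        TRANSVERSE: {"thickness": m["thickness_transverse_mm"][1],
                     "echo": m["echogenicity_transverse"][1], "contrast": 1.5},
    }


def _default_effects() -> dict[str, SymptomaticEffects]:
    m = reference.SIDE_MEANS
    return {
        LONGITUDINAL: SymptomaticEffects(
            thickening_factor=m["thickness_longitudinal_mm"][2]
            / m["thickness_longitudinal_mm"][0],
            echo_drop=m["echogenicity_longitudinal"][0]
            - m["echogenicity_longitudinal"][2],
            contrast_drop=0.8),
        TRANSVERSE: SymptomaticEffects(
            thickening_factor=m["thickness_transverse_mm"][2]
            / m["thickness_transverse_mm"][0],
            echo_drop=m["echogenicity_transverse"][0]
            - m["echogenicity_transverse"][2],
            contrast_drop=1.6),
    }


def _default_clinical_links() -> dict[str, ClinicalLink]:
    links = {}
    for name, (mean, sd, lo, hi) in reference.CLINICAL_MEANS.items():
        coef = -5.0 if name in ("visa_q8", "lefs") else -2.0
        links[name] = ClinicalLink(mean=mean, resid_sd=sd, coef=coef,
                                   lo=lo, hi=hi, integer=True)
    return links


def _default_paired_clinical() -> dict[str, PairedClinicalLink]:
    m = reference.SIDE_MEANS
    spec = {  # (di_frac at severity 1, per-side measurement residual SD)
        "soleus_lunge_cm": (-0.073, 1.0),
        "gastroc_lunge_cm": (-0.029, 2.0),
        "plantarflexion_nm": (-0.037, 8.0),
        "dorsiflexion_nm": (-0.025, 3.0),
    }
    out = {}
    for name, (di_frac, resid) in spec.items():
        mean, sd = m[name][0], m[name][1]
        between = np.sqrt(max(sd ** 2 - resid ** 2, (0.1 * sd) ** 2))
        out[name] = PairedClinicalLink(mean=mean, between_sd=float(between),
                                       di_frac=di_frac, resid_sd=resid)
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Stated world for one simulated cohort."""

    n_subjects: int = reference.N_GROUP
    seed: int = 0
    asympt_params: dict = field(default_factory=_default_asympt_params)
    between_sd: dict = field(default_factory=_default_between_sd)
    sympt_effects: dict = field(default_factory=_default_effects)
    clinical_links: dict = field(default_factory=_default_clinical_links)
    paired_clinical: dict = field(default_factory=_default_paired_clinical)
    severity_mean: float = 1.0
    severity_sd: float = 0.35
    subgroup_size: int = reference.N_SUBGROUP
    images_per_plane: int = 3

    def __post_init__(self):
        if self.n_subjects < 3:
            raise InvalidParameterError("need at least 3 subjects")
        if self.severity_sd < 0:
            raise InvalidParameterError("severity SD must be >= 0")
        if not 0 <= self.subgroup_size <= self.n_subjects:
            raise InvalidParameterError("subgroup size must be within the cohort")
        if not 1 <= self.images_per_plane <= 3:
            raise InvalidParameterError("images_per_plane must be 1..3")


def null_config(n_subjects: int = reference.N_GROUP, seed: int = 0) -> CohortConfig:
    """A cohort with no side asymmetry and no biomarker–clinic links."""
    effects = {p: SymptomaticEffects() for p in PLANES}
    links = {k: dataclasses.replace(v, coef=0.0)
             for k, v in _default_clinical_links().items()}
    paired = {k: dataclasses.replace(v, di_frac=0.0)
              for k, v in _default_paired_clinical().items()}
    return CohortConfig(n_subjects=n_subjects, seed=seed, sympt_effects=effects,
                        clinical_links=links, paired_clinical=paired)


def residual_sd_for_r(coef: float, severity_sd: float, target_r: float) -> float:
    """Residual SD making the population correlation between an outcome
    ``mean + coef*(severity-1) + e`` and any severity-proportional
    biomarker (e.g. the thickness Difference Index) equal ``target_r``."""
    if not 0 < abs(target_r) < 1:
        raise InvalidParameterError("target_r must lie strictly between 0 and 1")
    return abs(coef) * severity_sd * float(np.sqrt(1.0 / target_r ** 2 - 1.0))


def _subject_params(config: CohortConfig, severity: np.ndarray,
                    rng: np.random.Generator) -> dict[str, dict[str, np.ndarray]]:
    """Per-subject generative tendon parameters, both sides, both planes."""
    n = config.n_subjects
    out: dict[str, dict[str, np.ndarray]] = {}
    for plane in PLANES:
        base = config.asympt_params[plane]
        sd = config.between_sd[plane]
        thick = np.clip(rng.normal(base.thickness_mm, sd["thickness"], n), 2.0, 9.0)
        echo = np.clip(rng.normal(base.mean_echo, sd["echo"], n), 30.0, 200.0)
        contrast = np.clip(rng.normal(base.fibril_contrast, sd["contrast"], n),
                           2.0, 50.0)
        eff = config.sympt_effects[plane]
        factors = np.array([eff.scaled(s).thickening_factor for s in severity])
        drops = np.array([eff.scaled(s).echo_drop for s in severity])
        cdrops = np.array([eff.scaled(s).contrast_drop for s in severity])
        out[plane] = {
            "thickness_asympt": thick,
            "thickness_sympt": thick * factors,
            "echo_asympt": echo,
            "echo_sympt": np.clip(echo - drops, 10.0, 255.0),
            "contrast_asympt": contrast,
            "contrast_sympt": np.clip(contrast - cdrops, 0.0, None),
        }
    return out


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw the cohort table: latent severity, per-subject generative
    tendon parameters for both sides and planes, and clinical measures.

    One row per subject.  Subgroup-only measures (isometric strength,
    LEFS) are missing (NaN) outside the last ``subgroup_size`` subjects.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    n = config.n_subjects
    # all participants are clinically symptomatic, so severity is bounded
    # away from zero
    severity = np.clip(rng.normal(config.severity_mean, config.severity_sd, n),
                       0.2, 2.5)
    data: dict[str, np.ndarray] = {
        "subject": np.arange(1, n + 1),
        "severity": severity,
        "in_subgroup": np.arange(n) >= n - config.subgroup_size,
    }
    params = _subject_params(config, severity, rng)
    for plane in PLANES:
        for key, vals in params[plane].items():
            stem, side = key.rsplit("_", 1)
            name = {"thickness": "thickness", "echo": "echogenicity",
                    "contrast": "fibril_contrast"}[stem]
            data[f"true_{name}_{plane}_{side}"] = vals

    for name, link in config.paired_clinical.items():
        asympt, sympt = link.draw(severity, rng)
        stem, unit = name.rsplit("_", 1)
        data[f"{stem}_asympt_{unit}"] = asympt
        data[f"{stem}_sympt_{unit}"] = sympt

    for name, link in config.clinical_links.items():
        data[name] = link.draw(severity, rng)

    df = pd.DataFrame(data)
    df["visa_total"] = df[list(reference.VISA_ITEMS)].sum(axis=1)

    sub = df["in_subgroup"].to_numpy()
    for col in ["plantarflexion_asympt_nm", "plantarflexion_sympt_nm",
                "dorsiflexion_asympt_nm", "dorsiflexion_sympt_nm", "lefs"]:
        df.loc[~sub, col] = np.nan
    return df


@dataclass(frozen=True)
class ImageRecord:
    """One rendered frame of a simulated cohort."""

    subject: int
    side: str            # "asympt" | "sympt"
    plane: str
    image_index: int     # 1..images_per_plane
    image: CalibratedImage
    boundaries: BoundaryCurves


def image_seed(config_seed: int, subject: int, side: str, plane: str,
               image_index: int) -> int:
    """Stable per-frame RNG seed derived from the cohort seed."""
    ss = np.random.SeedSequence((config_seed, 2, subject, SIDES.index(side),
                                 PLANES.index(plane), image_index))
    return int(ss.generate_state(1)[0])


def subject_image_params(config: CohortConfig, cohort: pd.DataFrame,
                         subject: int, side: str, plane: str) -> TendonImageParams:
    """Generative parameters of one subject/side/plane, read off the cohort."""
    row = cohort.loc[cohort["subject"] == subject].iloc[0]
    return dataclasses.replace(
        config.asympt_params[plane],
        thickness_mm=float(row[f"true_thickness_{plane}_{side}"]),
        mean_echo=float(row[f"true_echogenicity_{plane}_{side}"]),
        fibril_contrast=float(row[f"true_fibril_contrast_{plane}_{side}"]),
    )


def iter_cohort_images(config: CohortConfig, cohort: pd.DataFrame,
                       rows: int = 128, cols: int = 128) -> Iterator[ImageRecord]:
    """Render every frame of the cohort (3 per plane per side by default),
    each with its own speckle realisation, lazily."""
    full_side = {"asympt": "asymptomatic", "sympt": "symptomatic"}
    for subject in cohort["subject"].astype(int):
        for side in SIDES:
            for plane in PLANES:
                p = subject_image_params(config, cohort, subject, side, plane)
                for k in range(1, config.images_per_plane + 1):
                    img, bounds = render_tendon_image(
                        p, rows, cols,
                        rng_seed=image_seed(config.seed, subject, side, plane, k),
                        side=full_side[side], image_index=k)
                    yield ImageRecord(subject=int(subject), side=side, plane=plane,
                                      image_index=k, image=img, boundaries=bounds)
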