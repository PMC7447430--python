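"""Synthetic ground-truth generators for every pipeline stage.

Four generators emulate the raw inputs of the downstream analyses:

* GUV time-lapses: vesicles drawn as Gaussian-cross-section rings in a
  membrane channel, with a protein channel whose ring signal follows a
  recruitment kinetics model R(t) on top of lumen/exterior backgrounds.
* Bead images: flat inside/outside two-level images with known outlines.
* HDX uptake tables: per-residue exponential exchange aggregated into
  peptide centroid masses, with unexchanged and maximally-labeled controls
  and a uniform back-exchange retention factor.
* Isotope envelopes: binomial deuteration envelopes convolved with Gaussian
  peaks on an m/z grid.
* Filaments: tubes of Gaussian cross-section along parametric curves (line,
  circular arc, sinusoid) whose arc length is known in closed form.

Every generator is deterministic under its seed and reports the exact ground
truth alongside the simulated data, so parameter-recovery tests need no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.spatial import cKDTree
from scipy.special import ellipeinc
from scipy.stats import binom

from .bead_quant import BeadOutline
from .guv_quant import TimelapseStack
from .hdx_diff import DEUTERON_MASS_SHIFT_DA, PROTON_MASS_DA, UNEXCHANGED_LABEL

__all__ = [
    "RecruitmentKinetics",
    "GuvSimSpec",
    "GuvSimResult",
    "simulate_guv_timelapse",
    "BeadSimResult",
    "disc_outlines",
    "simulate_bead_image",
    "HdxPeptide",
    "HdxSimSpec",
    "HdxSimResult",
    "simulate_hdx_experiment",
    "EnvelopeResult",
    "simulate_isotope_envelope",
    "LineCurve",
    "ArcCurve",
    "SinusoidCurve",
    "FilamentSimSpec",
    "FilamentSimResult",
    "simulate_filament",
]


# --------------------------------------------------------------------------
# GUV time-lapse
# --------------------------------------------------------------------------

class RecruitmentKinetics(BaseModel):
    """Recruitment fraction R(t) on the vesicle ring, R in [0, 1].

    Models: ``constant`` (R = value), ``exponential_rise``
    (R = 1 - exp(-k t)), ``logistic`` (R = 1 / (1 + exp(-k (t - t_half)))).
    Times are minutes from the start of the reaction.
    """

    model_config = ConfigDict(extra="forbid")

    model: Literal["constant", "exponential_rise", "logistic"] = "exponential_rise"
    value: float = Field(default=1.0, ge=0.0, le=1.0)
    rate_per_min: float = Field(default=0.1, ge=0.0)
    t_half_min: float = 10.0

    def fraction(self, times_min: np.ndarray) -> np.ndarray:
        t = np.asarray(times_min, dtype=float)
        if self.model == "constant":
            r = np.full_like(t, self.value)
        elif self.model == "exponential_rise":
            r = 1.0 - np.exp(-self.rate_per_min * t)
        else:
            r = 1.0 / (1.0 + np.exp(-self.rate_per_min * (t - self.t_half_min)))
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError("recruitment fraction R(t) left [0, 1]")
        return r


class GuvSimSpec(BaseModel):
    """Parameters of a simulated two-channel GUV time-lapse.

    Vesicles are (center_row, center_col, radius_px) triples; the membrane is
    a Gaussian ring of width ``membrane_sigma`` px.  The default geometry
    (radius 20 px, sigma 3 px at 0.1 um/px) emulates a ~4 um GUV imaged with a
    membrane cross-section a few pixels wide.
    """

    model_config = ConfigDict(extra="forbid")

    image_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = Field(default=0.1, gt=0)
    vesicles: list[tuple[float, float, float]] = [(64.0, 64.0, 20.0)]
    membrane_sigma: float = Field(default=3.5, gt=0)
    membrane_amplitude: float = Field(default=100.0, gt=0)
    protein_amplitude: float = Field(default=100.0, gt=0)
    kinetics: RecruitmentKinetics = RecruitmentKinetics()
    lumen_background: float = Field(default=2.0, ge=0)
    exterior_background: float = Field(default=6.0, ge=0)
    noise_sigma: float = Field(default=5.0, ge=0)
    frame_times_min: list[float] = [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0]
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GuvSimSpec":
        if not self.vesicles:
            raise ValueError("at least one vesicle is required")
        for row, col, radius in self.vesicles:
            if radius < 3 * self.membrane_sigma:
                raise ValueError(
                    f"vesicle radius {radius} < 3 * membrane_sigma "
                    f"({3 * self.membrane_sigma}); ring would fill its own lumen"
                )
        for i, (r1, c1, a1) in enumerate(self.vesicles):
            for r2, c2, a2 in self.vesicles[i + 1 :]:
                dist = float(np.hypot(r1 - r2, c1 - c2))
                if dist <= a1 + a2 + 6 * self.membrane_sigma:
                    raise ValueError(
                        f"vesicles at ({r1}, {c1}) and ({r2}, {c2}) overlap: "
                        f"center distance {dist:.1f} <= "
                        f"{a1 + a2 + 6 * self.membrane_sigma:.1f}"
                    )
        t = np.asarray(self.frame_times_min)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("frame_times_min must be non-empty and strictly increasing")
        self.kinetics.fraction(t)  # rejects R(t) outside [0, 1]
        return self


@dataclass
class GuvSimResult:
    """Simulated stack plus exact ground truth.

    ``truth`` has columns (vesicle_id, frame, time_min, truth_value) where
    truth_value is the mean of the noiseless protein channel over the
    vesicle's true ring mask (|d - radius| <= 2 sigma) minus the average of
    the two backgrounds.  ``ring_labels`` is the labeled true ring mask.
    """

    stack: TimelapseStack
    truth: pd.DataFrame
    ring_labels: np.ndarray
    spec: GuvSimSpec


def simulate_guv_timelapse(spec: GuvSimSpec) -> GuvSimResult:
    """Render a two-channel GUV time-lapse with known per-vesicle truth."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    rr, cc = np.indices(shape)
    sigma = spec.membrane_sigma

    ring_unit = np.zeros(shape, dtype=float)
    ring_labels = np.zeros(shape, dtype=np.int32)
    inside = np.zeros(shape, dtype=bool)
    for vid, (r0, c0, radius) in enumerate(spec.vesicles, start=1):
        d = np.hypot(rr - r0, cc - c0)
        ring_unit += np.exp(-((d - radius) ** 2) / (2 * sigma**2))
        ring_labels[np.abs(d - radius) <= 2 * sigma] = vid
        inside |= d < radius

    background = np.where(inside, spec.lumen_background, spec.exterior_background)
    times = np.asarray(spec.frame_times_min, dtype=float)
    fractions = spec.kinetics.fraction(times)
    bg_mean = 0.5 * (spec.lumen_background + spec.exterior_background)

    membrane_clean = spec.membrane_amplitude * ring_unit
    n_frames = len(times)
    membrane = np.empty((n_frames,) + shape)
    protein = np.empty((n_frames,) + shape)
    truth_rows = []
    for t in range(n_frames):
        protein_clean = spec.protein_amplitude * fractions[t] * ring_unit + background
        if spec.noise_sigma > 0:
            membrane[t] = membrane_clean + rng.normal(0, spec.noise_sigma, shape)
            protein[t] = protein_clean + rng.normal(0, spec.noise_sigma, shape)
        else:
            membrane[t] = membrane_clean
            protein[t] = protein_clean
        for vid in range(1, len(spec.vesicles) + 1):
            ring = ring_labels == vid
            truth_rows.append(
                {
                    "vesicle_id": vid,
                    "frame": t,
                    "time_min": times[t],
                    "truth_value": float(protein_clean[ring].mean()) - bg_mean,
                }
            )

    stack = TimelapseStack(membrane, protein, spec.pixel_size_um, times)
    return GuvSimResult(stack, pd.DataFrame(truth_rows), ring_labels, spec)


# --------------------------------------------------------------------------
# Bead images
# --------------------------------------------------------------------------

@dataclass
class BeadSimResult:
    image: np.ndarray
    outlines: list[BeadOutline]
    true_means: dict[int, float]
    degenerate: bool


def disc_outlines(
    centers: list[tuple[float, float]],
    radius_px: float,
    image_shape: tuple[int, int],
) -> list[BeadOutline]:
    """Circular bead outlines (disk masks) at the given centers."""
    rr, cc = np.indices(image_shape)
    outlines = []
    for bead_id, (r0, c0) in enumerate(centers, start=1):
        if not (
            radius_px <= r0 <= image_shape[0] - 1 - radius_px
            and radius_px <= c0 <= image_shape[1] - 1 - radius_px
        ):
            raise ValueError(f"bead at ({r0}, {c0}) extends beyond the image")
        mask = np.hypot(rr - r0, cc - c0) <= radius_px
        outlines.append(BeadOutline(bead_id, mask))
    return outlines


def simulate_bead_image(
    inside_value: float,
    outside_value: float,
    outlines: list[BeadOutline],
    image_shape: tuple[int, int],
    *,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> BeadSimResult:
    """Two-level bead image: inside_value within outlines, outside elsewhere.

    The result carries a ``degenerate`` flag when the two levels coincide
    (no contrast for downstream thresholding).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    image = np.full(image_shape, float(outside_value))
    seen = np.zeros(image_shape, dtype=bool)
    for outline in outlines:
        if outline.mask.shape != tuple(image_shape):
            raise ValueError(
                f"bead {outline.bead_id}: mask shape {outline.mask.shape} does not "
                f"match image shape {tuple(image_shape)}"
            )
        if (outline.mask & seen).any():
            raise ValueError(f"bead {outline.bead_id} overlaps another bead")
        seen |= outline.mask
        image[outline.mask] = float(inside_value)
    if noise_sigma > 0:
        image = image + np.random.default_rng(seed).normal(0, noise_sigma, image_shape)
    return BeadSimResult(
        image=image,
        outlines=outlines,
        true_means={o.bead_id: float(inside_value) for o in outlines},
        degenerate=inside_value == outside_value,
    )


# --------------------------------------------------------------------------
# HDX uptake tables
# --------------------------------------------------------------------------

class HdxPeptide(BaseModel):
    """One peptide: 1-based inclusive residue span and exchange bookkeeping."""

    model_config = ConfigDict(extra="forbid")

    protein: str
    start: int = Field(ge=1)
    end: int
    n_sites: int = Field(ge=1)
    base_mass_da: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "HdxPeptide":
        if self.end < self.start:
            raise ValueError("end must be >= start")
        return self


class HdxSimSpec(BaseModel):
    """Parameters of a simulated differential HDX experiment.

    ``site_rates`` maps each condition label to one entry per peptide: either
    a scalar rate (1/s, applied to every exchangeable site) or a list of
    per-site rates.  Timepoints follow the standard 6/60/600/60000 s series;
    the 60000 s sample is the maximally-labeled control and must be present.
    ``retention`` is the uniform fraction of label surviving back-exchange.
    """

    model_config = ConfigDict(extra="forbid")

    peptides: list[HdxPeptide]
    site_rates: dict[str, list[Union[float, list[float]]]]
    retention: float = Field(default=0.7, gt=0, le=1.0)
    timepoints_s: list[float] = [6.0, 60.0, 600.0, 60000.0]
    maxlabel_timepoint_s: float = 60000.0
    replicate_noise_sigma_da: float = Field(default=0.05, ge=0)
    n_replicates: int = Field(default=3, ge=2)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "HdxSimSpec":
        if not self.peptides:
            raise ValueError("at least one peptide is required")
        if UNEXCHANGED_LABEL in self.site_rates:
            raise ValueError(
                f"condition label {UNEXCHANGED_LABEL!r} is reserved for the control"
            )
        if self.maxlabel_timepoint_s not in self.timepoints_s:
            raise ValueError(
                "timepoints_s must include the maximally-labeled control time "
                f"({self.maxlabel_timepoint_s} s)"
            )
        for condition, rates in self.site_rates.items():
            if len(rates) != len(self.peptides):
                raise ValueError(
                    f"condition {condition!r}: {len(rates)} rate entries for "
                    f"{len(self.peptides)} peptides"
                )
            for pep, entry in zip(self.peptides, rates):
                ks = np.atleast_1d(np.asarray(entry, dtype=float))
                if np.any(ks <= 0):
                    raise ValueError(f"condition {condition!r}: rates must be > 0")
                if ks.size not in (1, pep.n_sites):
                    raise ValueError(
                        f"condition {condition!r}, peptide {pep.protein} "
                        f"{pep.start}-{pep.end}: expected 1 or {pep.n_sites} rates"
                    )
        return self

    def rates_for(self, condition: str, peptide_index: int) -> np.ndarray:
        pep = self.peptides[peptide_index]
        ks = np.atleast_1d(
            np.asarray(self.site_rates[condition][peptide_index], dtype=float)
        )
        if ks.size == 1:
            ks = np.full(pep.n_sites, ks[0])
        return ks


def uptake_fraction(site_rates: np.ndarray, t_s: float) -> float:
    """Mean per-site labeling fraction (1/N) sum_i (1 - exp(-k_i t))."""
    ks = np.asarray(site_rates, dtype=float)
    return float(np.mean(1.0 - np.exp(-ks * t_s)))


@dataclass
class HdxSimResult:
    """Replicate uptake table plus exact ground truth.

    ``records`` is the long-format uptake table (including unexchanged and
    maximally-labeled control rows); ``truth`` holds the noise-free %D per
    peptide, condition, and timepoint; ``true_delta`` the pairwise condition
    differences of those values.
    """

    records: pd.DataFrame
    truth: pd.DataFrame
    spec: HdxSimSpec

    def true_delta(self, condition: str, reference: str) -> pd.DataFrame:
        key = ["protein", "start", "end", "timepoint_s"]
        c = self.truth[self.truth["condition"] == condition].set_index(key)
        r = self.truth[self.truth["condition"] == reference].set_index(key)
        out = pd.DataFrame(index=c.index).reset_index()
        out["delta_percentD_true"] = (
            c["percentD_true"].to_numpy() - r["percentD_true"].to_numpy()
        )
        return out


def simulate_hdx_experiment(spec: HdxSimSpec) -> HdxSimResult:
    """Simulate replicate centroid masses for every condition and timepoint.

    Centroid mass at time t is ``base + f(t) * N * retention * shift`` plus
    replicate Gaussian noise; the maximally-labeled control is fully labeled
    (``f = 1``) by construction, and the unexchanged control sits at the base
    mass.  Ground-truth %D is ``100 * f(t)``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    shift = DEUTERON_MASS_SHIFT_DA

    def noise() -> float:
        if spec.replicate_noise_sigma_da == 0:
            return 0.0
        return float(rng.normal(0, spec.replicate_noise_sigma_da))

    for condition in spec.site_rates:
        for i, pep in enumerate(spec.peptides):
            ks = spec.rates_for(condition, i)
            full_label = pep.n_sites * spec.retention * shift
            for t in spec.timepoints_s:
                if t == spec.maxlabel_timepoint_s:
                    f = 1.0
                else:
                    f = uptake_fraction(ks, t)
                clean = pep.base_mass_da + f * full_label
                truth_rows.append(
                    {
                        "protein": pep.protein,
                        "start": pep.start,
                        "end": pep.end,
                        "condition": condition,
                        "timepoint_s": t,
                        "percentD_true": 100.0 * f,
                    }
                )
                for rep in range(1, spec.n_replicates + 1):
                    rows.append(
                        {
                            "protein": pep.protein,
                            "start": pep.start,
                            "end": pep.end,
                            "condition": condition,
                            "timepoint_s": t,
                            "replicate": rep,
                            "centroid_mass_da": clean + noise(),
                        }
                    )
    for i, pep in enumerate(spec.peptides):
        for rep in range(1, spec.n_replicates + 1):
            rows.append(
                {
                    "protein": pep.protein,
                    "start": pep.start,
                    "end": pep.end,
                    "condition": UNEXCHANGED_LABEL,
                    "timepoint_s": 0.0,
                    "replicate": rep,
                    "centroid_mass_da": pep.base_mass_da + noise(),
                }
            )
    return HdxSimResult(pd.DataFrame(rows), pd.DataFrame(truth_rows), spec)


# --------------------------------------------------------------------------
# Isotope envelopes
# --------------------------------------------------------------------------

@dataclass
class EnvelopeResult:
    mz_grid: np.ndarray
    intensities: np.ndarray
    weights: np.ndarray
    true_centroid_mass_da: float


def simulate_isotope_envelope(
    base_mass_da: float,
    n_sites: int,
    p_incorporation: float,
    *,
    charge: int = 1,
    peak_sigma_mz: float = 0.02,
    grid_step_mz: float | None = None,
) -> EnvelopeResult:
    """Binomial deuteration envelope convolved with Gaussian peaks.

    Peak j (j deuterons, binomial weight) sits at neutral mass
    ``base + j * shift`` and m/z ``(mass + z * proton) / z``.  The true
    centroid mass is the binomial mean ``base + n * p * shift``.
    """
    if not 0 <= p_incorporation <= 1:
        raise ValueError("p_incorporation must be in [0, 1]")
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if peak_sigma_mz <= 0:
        raise ValueError("peak_sigma_mz must be positive")
    j = np.arange(n_sites + 1)
    weights = binom.pmf(j, n_sites, p_incorporation)
    masses = base_mass_da + j * DEUTERON_MASS_SHIFT_DA
    peak_mz = (masses + charge * PROTON_MASS_DA) / charge
    step = grid_step_mz if grid_step_mz is not None else peak_sigma_mz / 20.0
    grid = np.arange(
        peak_mz.min() - 6 * peak_sigma_mz, peak_mz.max() + 6 * peak_sigma_mz, step
    )
    intensities = np.zeros_like(grid)
    for w, mu in zip(weights, peak_mz):
        if w > 0:
            intensities += w * np.exp(-((grid - mu) ** 2) / (2 * peak_sigma_mz**2))
    return EnvelopeResult(
        mz_grid=grid,
        intensities=intensities,
        weights=weights,
        true_centroid_mass_da=base_mass_da
        + n_sites * p_incorporation * DEUTERON_MASS_SHIFT_DA,
    )


# --------------------------------------------------------------------------
# Filaments
# --------------------------------------------------------------------------

class LineCurve(BaseModel):
    model_config = ConfigDict(extra="forbid")
    model: Literal["line"] = "line"
    start: tuple[float, float]
    end: tuple[float, float]

    def arc_length_px(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    def points(self, ds: float) -> np.ndarray:
        n = max(2, int(np.ceil(self.arc_length_px() / ds)) + 1)
        t = np.linspace(0.0, 1.0, n)
        p0 = np.asarray(self.start)
        p1 = np.asarray(self.end)
        return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


class ArcCurve(BaseModel):
    model_config = ConfigDict(extra="forbid")
    model: Literal["arc"] = "arc"
    center: tuple[float, float]
    radius: float = Field(gt=0)
    theta_start: float = 0.0
    theta_end: float = np.pi

    def arc_length_px(self) -> float:
        return float(self.radius * abs(self.theta_end - self.theta_start))

    def points(self, ds: float) -> np.ndarray:
        n = max(2, int(np.ceil(self.arc_length_px() / ds)) + 1)
        theta = np.linspace(self.theta_start, self.theta_end, n)
        return np.column_stack(
            [
                self.center[0] + self.radius * np.sin(theta),
                self.center[1] + self.radius * np.cos(theta),
            ]
        )


class SinusoidCurve(BaseModel):
    """Sinusoid row = A sin(2 pi x / wavelength) along the column axis.

    Arc length has the closed form
    ``(lambda / 2 pi) sqrt(1 + c^2) E(2 pi L / lambda | m)`` with
    ``c = 2 pi A / lambda`` and ``m = c^2 / (1 + c^2)`` (incomplete elliptic
    integral of the second kind).
    """

    model_config = ConfigDict(extra="forbid")
    model: Literal["sinusoid"] = "sinusoid"
    origin: tuple[float, float]
    amplitude_px: float = Field(gt=0)
    wavelength_px: float = Field(gt=0)
    span_px: float = Field(gt=0)

    def arc_length_px(self) -> float:
        c = 2 * np.pi * self.amplitude_px / self.wavelength_px
        m = c**2 / (1 + c**2)
        phi = 2 * np.pi * self.span_px / self.wavelength_px
        return float(self.wavelength_px / (2 * np.pi) * np.sqrt(1 + c**2) * ellipeinc(phi, m))

    def points(self, ds: float) -> np.ndarray:
        n = max(2, int(np.ceil(self.arc_length_px() / ds)) + 1)
        x = np.linspace(0.0, self.span_px, n)
        return np.column_stack(
            [
                self.origin[0]
                + self.amplitude_px * np.sin(2 * np.pi * x / self.wavelength_px),
                self.origin[1] + x,
            ]
        )


Curve = Union[LineCurve, ArcCurve, SinusoidCurve]


class FilamentSimSpec(BaseModel):
    """Parameters of a simulated filament (tube of Gaussian cross-section)."""

    model_config = ConfigDict(extra="forbid")

    curve: Curve = Field(discriminator="model")
    tube_sigma: float = Field(default=2.0, gt=0)
    amplitude: float = Field(default=100.0, gt=0)
    image_shape: tuple[int, int] = (128, 128)
    pixel_size_nm: float = Field(default=0.88, gt=0)
    noise_sigma: float = Field(default=0.0, ge=0)
    seed: int = 0


@dataclass
class FilamentSimResult:
    image: np.ndarray
    centerline_px: np.ndarray
    arc_length_nm: float
    end_to_end_nm: float
    spec: FilamentSimSpec


def simulate_filament(spec: FilamentSimSpec) -> FilamentSimResult:
    """Render a filament image with analytically known contour length."""
    pts = spec.curve.points(0.2)
    margin = 3 * spec.tube_sigma
    if (
        pts[:, 0].min() < margin
        or pts[:, 1].min() < margin
        or pts[:, 0].max() > spec.image_shape[0] - 1 - margin
        or pts[:, 1].max() > spec.image_shape[1] - 1 - margin
    ):
        raise ValueError(
            f"curve does not fit inside the image with a {margin:.1f} px margin"
        )
    rr, cc = np.indices(spec.image_shape)
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d, _ = cKDTree(pts).query(pix, workers=-1)
    d = d.reshape(spec.image_shape)
    image = spec.amplitude * np.exp(-(d**2) / (2 * spec.tube_sigma**2))
    if spec.noise_sigma > 0:
        image = image + np.random.default_rng(spec.seed).normal(
            0, spec.noise_sigma, spec.image_shape
        )
    return FilamentSimResult(
        image=image,
        centerline_px=spec.curve.points(0.5),
        arc_length_nm=spec.curve.arc_length_px() * spec.pixel_size_nm,
        end_to_end_nm=float(np.linalg.norm(pts[-1] - pts[0]) * spec.pixel_size_nm),
        spec=spec,
    )
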