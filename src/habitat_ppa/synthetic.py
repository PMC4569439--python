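"""Synthetic cohort generator.

Emulates the data structure of a two-channel MR glioblastoma study: per
patient a T1 post-contrast slice and a co-registered T2-FLAIR slice, a
binary tumor ROI, and a clinical record (overall survival, event flag,
12-month class, molecular subtype, demographics).

Within the ROI each channel is a two-component Gaussian mixture whose
low/high labels are spatially coherent (a smoothed Gaussian random field
thresholded at the quantile matching the configured high fraction).
Survival is exponential with a log-linear link to a spatial summary of the
generator-truth habitat pattern, so planted effects are recoverable by the
downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

SUBTYPES = ("classical", "mesenchymal", "neural", "proneural")


@dataclass(frozen=True)
class ChannelMixture:
    """Two-component intensity mixture for one MR channel (gray levels)."""

    low_mean: float
    high_mean: float
    low_sd: float
    high_sd: float
    high_fraction: float

    def validate(self, name: str = "channel") -> None:
        if not (self.low_mean < self.high_mean):
            raise ValueError(f"{name}: low_mean must be < high_mean "
                             f"({self.low_mean} vs {self.high_mean})")
        if self.low_sd <= 0 or self.high_sd <= 0:
            raise ValueError(f"{name}: component sds must be positive")
        if not (0.0 <= self.high_fraction <= 1.0):
            raise ValueError(f"{name}: high_fraction must lie in [0,1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generator settings.

    Defaults follow the study design this generator emulates: 74 patients,
    256-gray-level images, a 12-month-scale exponential survival time
    (baseline hazard 0.06/month gives mean OS ~16.7 months, close to the
    cohort mean of 16.9 months), and four equally likely molecular
    subtypes.
    """

    n_patients: int = 74
    image_side: int = 128
    roi_radius_range: tuple[int, int] = (10, 20)
    t1: ChannelMixture = field(
        default_factory=lambda: ChannelMixture(70.0, 170.0, 15.0, 15.0, 0.40))
    t2: ChannelMixture = field(
        default_factory=lambda: ChannelMixture(90.0, 190.0, 15.0, 15.0, 0.50))
    spatial_smoothness: float = 4.0
    #: per-patient sd of the jitter applied to each channel's high fraction;
    #: this is the dominant between-patient source of spatial-feature variance
    fraction_jitter_sd: float = 0.15
    hazard_coefficient: float = 0.0
    baseline_hazard: float = 0.06
    censor_rate: float = 0.2
    subtype_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    #: which truth-side spatial summary drives the hazard
    hazard_feature: str = "Simpson index"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.roi_radius_range
        if not (0 < lo <= hi):
            raise ValueError("roi_radius_range must satisfy 0 < min <= max")
        self.t1.validate("t1")
        self.t2.validate("t2")
        if self.spatial_smoothness < 0:
            raise ValueError("spatial_smoothness must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must lie in [0,1]")
        p = np.asarray(self.subtype_probs, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("subtype_probs must be 4 nonnegative values "
                             "summing to 1")


@dataclass
class TumorSlicePair:
    """Two co-registered 2D gray-level slices plus one binary ROI mask."""

    t1: np.ndarray
    t2: np.ndarray
    mask: np.ndarray

    def validate(self) -> None:
        if not (self.t1.shape == self.t2.shape == self.mask.shape):
            raise ValueError("t1, t2 and mask must share one shape")
        n_fg = int(self.mask.sum())
        if n_fg < 64:
            raise ValueError(f"ROI has {n_fg} foreground pixels; need >= 64")
        _, n_cc = ndimage.label(self.mask)
        if n_cc != 1:
            raise ValueError(f"ROI must be a single connected component "
                             f"(found {n_cc})")


@dataclass
class ClinicalRecord:
    patient_id: str
    os_months: float
    event: int
    os_class: str  # "le12" iff os_months <= 12 else "gt12"
    subtype: str
    age_years: float
    sex: str


# ---------------------------------------------------------------------------
# ROI mask

def generate_roi_mask(image_side: int, radius: int, seed: int) -> np.ndarray:
    """Connected, roughly elliptical blob with a perturbed boundary.

    The blob is an area-preserving random ellipse whose radius is modulated
    by a few low-order angular harmonics; holes are filled and the largest
    connected component kept.
    """
    if 2 * radius + 2 >= image_side:
        raise ValueError(
            f"ROI radius {radius} too large for image side {image_side} "
            f"(need 2*radius + 2 < image_side)")
    rng = np.random.default_rng(seed)
    c = (image_side - 1) / 2.0
    ecc = rng.uniform(0.7, 1.0)
    a, b = radius / math.sqrt(ecc), radius * math.sqrt(ecc)
    theta = rng.uniform(0.0, math.pi)
    amps = rng.normal(0.0, 0.04, size=4)   # harmonics k = 2..5
    phases = rng.uniform(0.0, 2 * math.pi, size=4)

    rows, cols = np.mgrid[0:image_side, 0:image_side]
    dy, dx = rows - c, cols - c
    du = dx * math.cos(theta) + dy * math.sin(theta)
    dv = -dx * math.sin(theta) + dy * math.cos(theta)
    rho = np.hypot(du / a, dv / b)
    phi = np.arctan2(dv / b, du / a)
    pert = np.zeros_like(phi)
    for k, amp, ph in zip(range(2, 6), amps, phases):
        pert += amp * np.cos(k * phi + ph)
    mask = rho <= 1.0 + np.clip(pert, -0.25, 0.25)

    mask = ndimage.binary_fill_holes(mask)
    labels, n_cc = ndimage.label(mask)
    if n_cc > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_cc + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    area = int(mask.sum())
    if area < 64:
        raise ValueError(f"generated ROI too small ({area} px); "
                         f"increase radius (got {radius})")
    return mask.astype(bool)


# ---------------------------------------------------------------------------
# Channel intensities

def generate_channel(mask: np.ndarray, mixture: ChannelMixture,
                     smoothness: float, seed: int,
                     return_labels: bool = False):
    """Draw one channel's gray levels inside the ROI.

    A Gaussian random field (white noise smoothed with sd ``smoothness``
    pixels) is thresholded at the quantile matching ``high_fraction``; each
    pixel then draws from its component's Gaussian, clipped to [0, 255] and
    rounded to integer gray levels. Background outside the mask is 0.
    """
    mixture.validate()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(mask.shape)
    fld = ndimage.gaussian_filter(noise, smoothness) if smoothness > 0 else noise

    inside = fld[mask]
    hf = mixture.high_fraction
    if hf <= 0.0:
        high = np.zeros(inside.shape, dtype=bool)
    elif hf >= 1.0:
        high = np.ones(inside.shape, dtype=bool)
    else:
        thr = np.quantile(inside, 1.0 - hf)
        high = inside >= thr

    vals = np.where(
        high,
        rng.normal(mixture.high_mean, mixture.high_sd, size=inside.shape),
        rng.normal(mixture.low_mean, mixture.low_sd, size=inside.shape),
    )
    vals = np.clip(np.rint(vals), 0, 255)

    image = np.zeros(mask.shape, dtype=np.uint8)
    image[mask] = vals.astype(np.uint8)
    if return_labels:
        high_mask = np.zeros(mask.shape, dtype=bool)
        high_mask[mask] = high
        return image, high_mask
    return image


# ---------------------------------------------------------------------------
# Survival

def generate_survival(spatial_summary: float, config: SyntheticConfig,
                      seed: int) -> tuple[float, int]:
    """Exponential survival time with a log-linear planted effect.

    ``spatial_summary`` is the standardized spatial summary z; the event
    time is Exp(rate) with rate = baseline_hazard * exp(hazard_coefficient
    * z). Censoring is independent: with probability ``censor_rate`` the
    subject is censored uniformly before the event time.
    """
    if config.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    rng = np.random.default_rng(seed)
    rate = config.baseline_hazard * math.exp(
        config.hazard_coefficient * spatial_summary)
    t = rng.exponential(1.0 / rate)
    if rng.uniform() < config.censor_rate:
        return float(t * rng.uniform()), 0
    return float(t), 1


# ---------------------------------------------------------------------------
# Cohort assembly

def _truth_spatial_summary(mask, t1_high, t2_high, config) -> float:
    """Spatial summary of the generator-truth habitat layout.

    Uses the same grid-centroid point pattern the analysis builds, computed
    from the true (noise-free) habitat labels.
    """
    from .spatial_map import make_grid, build_point_pattern
    from .segmentation import HabitatMaskSet
    from . import features as ppf

    habitats = HabitatMaskSet(
        t1_low=mask & ~t1_high, t1_high=t1_high,
        t2_low=mask & ~t2_high, t2_high=t2_high,
        thresholds={"t1": float("nan"), "t2": float("nan")})
    pattern = build_point_pattern(habitats, make_grid(mask, box_size=8))
    if config.hazard_feature == "Simpson index":
        return ppf.global_simpson(pattern)
    if config.hazard_feature == "Shannon index":
        return ppf.global_shannon(pattern)
    if config.hazard_feature == "t1_high_fraction":
        return float(t1_high.sum()) / float(mask.sum())
    raise ValueError(f"unknown hazard_feature {config.hazard_feature!r}")


def generate_cohort(config: SyntheticConfig, return_truth: bool = False):
    """Generate ``config.n_patients`` image pairs and clinical records.

    Fully reproducible from ``config.seed``: per-patient randomness uses
    seeds spawned from one root SeedSequence. With ``return_truth`` a third
    element carries per-patient generator truth (habitat label masks,
    realized high fractions, the hazard-driving summary z).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    # low 31 bits keep spawned seeds in int range for the per-op seed APIs
    patient_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
                     for s in root.spawn(config.n_patients)]
    rng = np.random.default_rng(root.spawn(1)[0])

    pairs: list[TumorSlicePair] = []
    truth: list[dict] = []
    summaries = np.empty(config.n_patients)
    lo, hi = config.roi_radius_range
    for i, pseed in enumerate(patient_seeds):
        prng = np.random.default_rng(pseed)
        radius = int(prng.integers(lo, hi + 1))
        mask = generate_roi_mask(config.image_side, radius,
                                 seed=int(prng.integers(2**31)))
        chans, highs, hfs = [], [], []
        for mix in (config.t1, config.t2):
            hf = mix.high_fraction
            if config.fraction_jitter_sd > 0:
                hf = float(np.clip(prng.normal(hf, config.fraction_jitter_sd),
                                   0.05, 0.95))
            jmix = ChannelMixture(mix.low_mean, mix.high_mean,
                                  mix.low_sd, mix.high_sd, hf)
            img, high = generate_channel(mask, jmix, config.spatial_smoothness,
                                         seed=int(prng.integers(2**31)),
                                         return_labels=True)
            chans.append(img)
            highs.append(high)
            hfs.append(hf)
        pair = TumorSlicePair(t1=chans[0], t2=chans[1], mask=mask)
        pair.validate()
        pairs.append(pair)
        summaries[i] = _truth_spatial_summary(mask, highs[0], highs[1], config)
        truth.append({"t1_high": highs[0], "t2_high": highs[1],
                      "t1_high_fraction": hfs[0], "t2_high_fraction": hfs[1],
                      "radius": radius})

    sd = summaries.std(ddof=0)
    z = (summaries - summaries.mean()) / sd if sd > 0 else np.zeros_like(summaries)

    records: list[ClinicalRecord] = []
    for i, pseed in enumerate(patient_seeds):
        os_months, event = generate_survival(float(z[i]), config,
                                             seed=pseed ^ 0x5A5A5A5)
        subtype = SUBTYPES[rng.choice(4, p=np.asarray(config.subtype_probs))]
        records.append(ClinicalRecord(
            patient_id=f"SYN-{i:03d}",
            os_months=round(os_months, 3),
            event=event,
            os_class="le12" if os_months <= 12 else "gt12",
            subtype=subtype,
            age_years=round(float(np.clip(rng.normal(57.5, 15.7), 18, 90)), 1),
            sex="M" if rng.uniform() < 49 / 74 else "F",
        ))
        truth[i]["z"] = float(z[i])

    if return_truth:
        return pairs, records, truth
    return pairs, records


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records],
                        columns=["patient_id", "os_months", "event",
                                 "os_class", "subtype", "age_years", "sex"])


def write_cohort(out_dir, pairs: list[TumorSlicePair],
                 records: list[ClinicalRecord]) -> Path:
    """Write NIfTI image/mask files (single-slice volumes) and clinical.csv."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for pair, rec in zip(pairs, records):
        for name, arr in (("t1", pair.t1), ("t2", pair.t2),
                          ("mask", pair.mask.astype(np.uint8))):
            img = nib.Nifti1Image(arr[:, :, None].astype(np.uint8), affine)
            nib.save(img, out / f"{rec.patient_id}_{name}.nii.gz")
    clinical_frame(records).to_csv(out / "clinical.csv", index=False)
    return out
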