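"""Synthetic cohorts and stained images with known ground truth.

Two generators:

* :func:`generate_cohort` builds per-patient tile-feature bags with a planted
  minority of "high-risk" tiles, survival times from a proportional-hazards
  model with independent right censoring, and an MRD label linked to the
  latent risk class through a sensitivity/specificity channel. Every hidden
  quantity (latent class, true event/censoring times, per-tile labels) is
  returned, so downstream estimators can be checked against the exact
  data-generating process.

* :func:`generate_stained_image` renders small H&E-like RGB images from a
  two-stain Beer-Lambert optical-density mixing model with known stain
  directions and smooth random concentration fields, for testing stain
  estimation and normalization.

The survival model is Weibull with shape defaulting to 1 (exponential), so
the data-generating hazard ratio exp(log_hr_per_risk_unit) is available in
closed form as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .bags import FeatureBag

__all__ = [
    "SynthCohortSpec",
    "SynthStainSpec",
    "SynthCohort",
    "generate_cohort",
    "generate_stained_image",
    "render_stains",
]


def _require_finite(name, *values):
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v}")


@dataclass(frozen=True)
class SynthCohortSpec:
    """Parameters of the synthetic study population.

    ``signal_shift`` is the Euclidean distance between the background and
    high-risk tile clusters in feature space; ``signal_fraction`` the share
    of a high-risk patient's tiles drawn from the shifted cluster. Hazards
    and censoring are per-month rates.
    """

    n_patients: int = 200
    tiles_per_patient_range: tuple = (40, 80)
    feature_dim: int = 1024
    signal_fraction: float = 0.3
    signal_shift: float = 3.0
    baseline_hazard: float = 0.02
    log_hr_per_risk_unit: float = 1.5
    censoring_rate: float = 0.015
    weibull_shape: float = 1.0
    mrd_sensitivity: float = 0.8
    mrd_specificity: float = 0.9
    mrd_missing_rate: float = 0.0
    high_risk_fraction: float = 0.5
    latent_risk: str = "binary"   # "binary": z in {0,1}; "continuous": z ~ N(0,1)
    seed: int = 0

    def __post_init__(self):
        _require_finite("spec fields", self.signal_fraction, self.signal_shift,
                        self.baseline_hazard, self.log_hr_per_risk_unit,
                        self.censoring_rate, self.weibull_shape,
                        self.mrd_sensitivity, self.mrd_specificity,
                        self.mrd_missing_rate, self.high_risk_fraction)
        lo, hi = self.tiles_per_patient_range
        if not (1 <= lo <= hi):
            raise ValueError("tiles_per_patient_range must satisfy 1 <= min <= max")
        for name in ("signal_fraction", "mrd_sensitivity", "mrd_specificity",
                     "mrd_missing_rate", "high_risk_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0 or self.weibull_shape <= 0:
            raise ValueError("rates and shape must be > 0")
        if self.n_patients < 1 or self.feature_dim < 1:
            raise ValueError("n_patients and feature_dim must be >= 1")
        if self.latent_risk not in ("binary", "continuous"):
            raise ValueError("latent_risk must be 'binary' or 'continuous'")


@dataclass(frozen=True)
class SynthStainSpec:
    """Two-stain optical-density image model.

    ``stain_matrix`` rows are the unit OD directions of the hematoxylin- and
    eosin-like stains; pixel intensity is
    ``background_intensity * 10**-(c @ stain_matrix)``.
    """

    stain_matrix: tuple = (
        (0.60036032, 0.68040837, 0.42025223),   # hematoxylin-like
        (0.21005252, 0.95023759, 0.23005752),   # eosin-like
    )
    max_concentrations: tuple = (1.4, 1.1)
    background_intensity: int = 255
    image_size: int = 128
    smoothness: float = 8.0
    seed: int = 0

    def __post_init__(self):
        m = np.asarray(self.stain_matrix, dtype=float)
        _require_finite("stain_matrix", m)
        if m.shape != (2, 3):
            raise ValueError("stain_matrix must be 2x3")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain_matrix rows must have unit norm")
        if np.linalg.matrix_rank(m) < 2:
            raise ValueError("stain_matrix rows must be linearly independent")
        if any(c < 0 for c in self.max_concentrations):
            raise ValueError("max_concentrations must be >= 0")
        if not (0 < self.background_intensity <= 255):
            raise ValueError("background_intensity must be in (0, 255]")
        if self.image_size < 4:
            raise ValueError("image_size too small")


@dataclass
class SynthCohort:
    """Bags + clinical table + full ground truth of one simulated cohort."""

    bags: list
    clinical: pd.DataFrame
    truth: pd.DataFrame
    tile_labels: dict = field(default_factory=dict)


def generate_cohort(spec: SynthCohortSpec) -> SynthCohort:
    """Simulate feature bags, DFS outcomes and MRD labels.

    High-risk patients (latent z=1) receive ``round(signal_fraction * n)``
    tiles (at least one when the fraction is positive) from a Gaussian
    cluster shifted by ``signal_shift`` along a fixed seeded unit direction;
    all other tiles come from the standard-normal background cluster.
    Event times are Weibull-PH with hazard
    ``baseline_hazard * exp(log_hr_per_risk_unit * z)``, censoring is an
    independent exponential clock.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.feature_dim
    direction = rng.normal(size=d)
    direction /= np.linalg.norm(direction)

    n = spec.n_patients
    if spec.latent_risk == "binary":
        z = (rng.random(n) < spec.high_risk_fraction).astype(float)
    else:
        z = rng.normal(size=n)
    z_high = z > 0  # MRD channel and group analyses binarize continuous risk at 0

    rate_evt = spec.baseline_hazard * np.exp(spec.log_hr_per_risk_unit * z)
    # Weibull-PH: S(t) = exp(-rate * t^k); k=1 is exponential
    e = rng.exponential(1.0, size=n)
    t_event = (e / rate_evt) ** (1.0 / spec.weibull_shape)
    t_cens = rng.exponential(1.0 / spec.censoring_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    u = rng.random(n)
    mrd_pos = np.where(z_high, u < spec.mrd_sensitivity, u < 1.0 - spec.mrd_specificity)
    mrd = np.where(mrd_pos, "positive", "negative").astype(object)
    if spec.mrd_missing_rate > 0:
        mrd[rng.random(n) < spec.mrd_missing_rate] = "missing"

    lo, hi = spec.tiles_per_patient_range
    bags, tile_labels = [], {}
    for i in range(n):
        pid = f"P{i:04d}"
        n_tiles = int(rng.integers(lo, hi + 1))
        feats = rng.normal(size=(n_tiles, d))
        labels = np.zeros(n_tiles, dtype=bool)
        # binary: high-risk bags get a planted cluster shifted by signal_shift;
        # continuous: the shift magnitude scales with the patient's latent risk
        if spec.signal_fraction > 0 and z[i] != 0:
            k = max(1, round(spec.signal_fraction * n_tiles))
            idx = rng.choice(n_tiles, size=k, replace=False)
            feats[idx] += spec.signal_shift * z[i] * direction
            labels[idx] = True
        coords = np.stack([rng.integers(0, 50_000, n_tiles),
                           rng.integers(0, 50_000, n_tiles)], axis=1).astype(np.int32)
        bags.append(FeatureBag(slide_id=f"{pid}-S1", patient_id=pid,
                               feats=feats.astype(np.float32), coords=coords))
        tile_labels[pid] = labels

    pids = [f"P{i:04d}" for i in range(n)]
    clinical = pd.DataFrame({
        "patient_id": pids,
        "dfs_months": time,
        "dfs_event": event,
        "mrd_status": mrd,
        "age": rng.integers(35, 90, n),
        "sex": rng.choice(["female", "male"], n),
        "pT": rng.integers(1, 5, n),
        "pN": rng.integers(0, 3, n),
        "pM": (rng.random(n) < 0.1).astype(int),
        "act": (rng.random(n) < 0.4).astype(int),
        "msi": (rng.random(n) < 0.15).astype(int),
    })
    truth = pd.DataFrame({
        "patient_id": pids,
        "z": z,
        "t_event": t_event,
        "t_censor": t_cens,
    })
    return SynthCohort(bags=bags, clinical=clinical, truth=truth, tile_labels=tile_labels)


def render_stains(conc: np.ndarray, stain_matrix, background_intensity: int = 255) -> np.ndarray:
    """Beer-Lambert rendering: (H,W,2) concentrations -> 8-bit RGB image."""
    m = np.asarray(stain_matrix, dtype=float)
    od = conc @ m                                     # (H, W, 3)
    img = background_intensity * np.power(10.0, -od)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_stained_image(spec: SynthStainSpec):
    """Smooth random two-stain image; returns (rgb uint8, concentrations).

    Concentration fields are independent Gaussian noise per stain, smoothed
    with a Gaussian filter, clipped at zero, and scaled so the per-stain
    maximum equals ``max_concentrations``; many pixels end up nearly
    single-stain, which is what percentile-extreme stain estimators rely on.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    conc = np.zeros((s, s, 2))
    for j, cmax in enumerate(spec.max_concentrations):
        if cmax <= 0:
            continue
        fld = gaussian_filter(rng.normal(size=(s, s)), sigma=spec.smoothness)
        fld = np.clip(fld, 0.0, None)
        peak = fld.max()
        if peak > 0:
            fld *= cmax / peak
        conc[:, :, j] = fld
    img = render_stains(conc, spec.stain_matrix, spec.background_intensity)
    return img, conc
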