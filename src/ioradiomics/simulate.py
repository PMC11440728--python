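"""Synthetic phantom cohorts with known ground truth.

Every downstream stage is validated against this module: CT-like phantom
volumes with a heterogeneous bright tumour and a peritumoral vessel tree of
controllable tortuosity (analytic helical centerlines with closed-form Frenet
curvature and torsion), a clinical covariate table matching a published
advanced-lung-cancer cohort's marginal frequencies, and progression-free
survival times from a Weibull proportional-hazards model whose log-hazard
depends on the known phantom parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_core import ImageVolume

# Marginal frequencies of the reference cohort (206 advanced-LC patients
# receiving immune-checkpoint inhibitors).
DEFAULT_CLINICAL_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.316, "male": 0.684},
    "smoking": {"smoker": 0.568, "non_smoker": 0.432},
    "stage": {"II": 0.005, "III": 0.024, "IVA": 0.384, "IVB": 0.587},
    "histology": {"adenocarcinoma": 0.713, "squamous": 0.131,
                  "small_cell": 0.073, "other": 0.083},
    "total_protein": {"high": 0.981, "normal": 0.019},
    "mcv": {"high": 0.034, "normal": 0.913, "low": 0.053},
}
#: Age: median 62.2 years, IQR 12.8 -> normal(62.2, 12.8/1.349)
AGE_MEDIAN, AGE_IQR = 62.2, 12.8

#: Default true log-hazard weights on standardized phantom parameters / labs.
DEFAULT_HAZARD_COEFFICIENTS: dict[str, float] = {
    "tumor_radius_mm": 0.7,
    "heterogeneity": 0.5,
    "vessel_tortuosity": 0.7,
    "total_protein_normal": 0.7,
    "mcv_high": 0.7,
}


@dataclass
class PhantomSpec:
    """Parameters of one phantom volume (lengths in mm)."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_radius_mm: float = 10.0
    heterogeneity: float = 0.3
    n_branches: int = 6
    tortuosity: float = 0.2  # helical turn rate (1/mm): curvature = torsion = t/2
    vessel_radius_mm: float = 1.5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_center_mm is None:
            self.tumor_center_mm = tuple(
                n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm))
        if self.vessel_radius_mm <= 0:
            raise ValueError("vessel_radius_mm must be positive")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be nonnegative")
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)
        c = np.asarray(self.tumor_center_mm)
        if np.any(c - self.tumor_radius_mm < 0) or np.any(c + self.tumor_radius_mm > extent):
            raise ValueError("tumor exceeds grid bounds")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort (tabular ground truth + outcomes)."""

    n_subjects: int = 206
    hazard_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_COEFFICIENTS))
    baseline_shape: float = 1.2
    baseline_scale: float = 4.48  # median PFS 3.3 months at zero log-hazard
    censoring_rate: float = 0.25
    clinical_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLINICAL_MARGINALS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        for var, levels in self.clinical_marginals.items():
            total = sum(levels.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"marginals for {var} sum to {total}, not 1")


@dataclass
class GroundTruth:
    """Per-phantom analytic geometry and per-subject true linear predictors."""

    centerlines: list[np.ndarray] = field(default_factory=list)
    curvature_per_branch: list[float] = field(default_factory=list)
    torsion_per_branch: list[float] = field(default_factory=list)
    linear_predictor: float | None = None

    def to_json(self) -> str:
        return json.dumps({
            "centerlines": [c.tolist() for c in self.centerlines],
            "curvature_per_branch": self.curvature_per_branch,
            "torsion_per_branch": self.torsion_per_branch,
            "linear_predictor": self.linear_predictor,
        })


# ---------------------------------------------------------------------------
# analytic vessel branches
# ---------------------------------------------------------------------------

def generate_vessel_branch(start, direction, length_mm: float,
                           helix_radius_mm: float, helix_pitch_mm: float,
                           seed: int = 0, step_mm: float = 0.4) -> np.ndarray:
    """Sample a circular-helix centerline at <= 0.5 mm arc steps.

    For helix radius a > 0 and pitch parameter b the curve has constant
    curvature a/(a^2+b^2) and torsion b/(a^2+b^2); a = 0 gives a straight
    segment. The helical phase is randomized by ``seed``.
    """
    if length_mm <= 0:
        raise ValueError("length must be positive")
    a = float(helix_radius_mm)
    b = float(helix_pitch_mm)
    if a < 0:
        raise ValueError("helix radius must be nonnegative")
    if a > 0 and b <= 0:
        raise ValueError("helix pitch must be positive when radius > 0")
    start = np.asarray(start, dtype=np.float64)
    w = np.asarray(direction, dtype=np.float64)
    w = w / np.linalg.norm(w)
    n_steps = max(int(np.ceil(length_mm / min(step_mm, 0.5))), 2)
    s = np.linspace(0.0, length_mm, n_steps + 1)
    if a == 0:
        return start[None, :] + s[:, None] * w[None, :]
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    # orthonormal frame perpendicular to the axis w
    ref = np.array([1.0, 0.0, 0.0])
    if abs(w @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, ref)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    c = np.sqrt(a**2 + b**2)
    theta = s / c + phase
    pts = (start[None, :]
           + a * (np.cos(theta) - np.cos(phase))[:, None] * u[None, :]
           + a * (np.sin(theta) - np.sin(phase))[:, None] * v[None, :]
           + (b * (theta - phase))[:, None] * w[None, :])
    return pts


def helix_curvature_torsion(helix_radius_mm: float, helix_pitch_mm: float) -> tuple[float, float]:
    """Closed-form Frenet curvature and torsion of a circular helix (1/mm)."""
    a, b = float(helix_radius_mm), float(helix_pitch_mm)
    if a == 0:
        return 0.0, 0.0
    c2 = a**2 + b**2
    return a / c2, b / c2


# ---------------------------------------------------------------------------
# phantom volumes
# ---------------------------------------------------------------------------

def _band_limited_noise(rng: np.random.Generator, shape, smooth_vox: float = 2.0) -> np.ndarray:
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, smooth_vox)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_phantom(spec: PhantomSpec):
    """Build one phantom volume with tumour, lung and vessel ground truth.

    Returns ``(volume, tumor_mask, lung_mask, vessel_mask, ground_truth)``.
    Intensity model: body background 0, lung parenchyma -1, tumour blob at +1
    with additive band-limited texture scaled by ``heterogeneity``, vessel
    tubes at +1, plus white noise of SD ``noise_sd``.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=np.float64)
    rng = np.random.default_rng(spec.seed)

    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    phys = grid * spacing  # voxel centre coordinates, mm
    center = np.asarray(spec.tumor_center_mm)
    dist_tumor = np.linalg.norm(phys - center, axis=-1)
    tumor = dist_tumor <= spec.tumor_radius_mm

    extent = np.asarray(shape) * spacing
    # lung: large ellipsoid around the grid centre
    lung_c = extent / 2.0
    lung_r = extent * 0.47
    lung = (((phys - lung_c) / lung_r) ** 2).sum(axis=-1) <= 1.0

    # vessel tree: branches radiating outward from just off the tumour surface.
    # tortuosity is a helical turn rate: a 45-degree helix with radius = pitch
    # = 1/tortuosity has curvature = torsion = tortuosity/2, so both grow
    # monotonically with the parameter.
    centerlines, curvatures, torsions = [], [], []
    helix_a = 1.0 / spec.tortuosity if spec.tortuosity > 0 else 0.0
    helix_b = helix_a if helix_a > 0 else 1.0
    for i in range(spec.n_branches):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        start = center + u * (spec.tumor_radius_mm + spec.vessel_radius_mm + 2.0)
        length = float(rng.uniform(15.0, 22.0))
        branch_seed = int(rng.integers(0, 2**31 - 1))
        pts = generate_vessel_branch(start, u, length, helix_a, helix_b,
                                     seed=branch_seed)
        # clip to grid bounds
        inside = np.all((pts >= 0) & (pts <= extent - spacing), axis=1)
        pts = pts[inside]
        if len(pts) < 2:
            continue
        centerlines.append(pts)
        k, t = helix_curvature_torsion(helix_a, helix_b)
        curvatures.append(k)
        torsions.append(t)

    vessel = np.zeros(shape, dtype=bool)
    if centerlines:
        seeds = np.zeros(shape, dtype=bool)
        allpts = np.concatenate(centerlines)
        idx = np.clip(np.round(allpts / spacing).astype(int), 0,
                      np.asarray(shape) - 1)
        seeds[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        d = ndimage.distance_transform_edt(~seeds, sampling=spacing)
        vessel = d <= spec.vessel_radius_mm
    vessel &= ~tumor

    values = np.zeros(shape, dtype=np.float64)
    values[lung] = -1.0
    tumor_mean = 1.0
    values[tumor] = tumor_mean
    if spec.heterogeneity > 0:
        texture = _band_limited_noise(rng, shape)
        values[tumor] += spec.heterogeneity * tumor_mean * texture[tumor]
    else:
        rng.standard_normal(shape)  # keep the stream aligned across specs
    values[vessel] = 1.0
    if spec.noise_sd > 0:
        values += spec.noise_sd * rng.standard_normal(shape)

    lung_full = lung | tumor | vessel
    gt = GroundTruth(centerlines=centerlines, curvature_per_branch=curvatures,
                     torsion_per_branch=torsions)
    vol = ImageVolume(values, tuple(spacing), (0.0, 0.0, 0.0))
    return vol, tumor, lung_full, vessel, gt


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def generate_clinical_table(spec: CohortSpec) -> pd.DataFrame:
    """Sample a clinical covariate table from the configured marginals."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    data: dict[str, np.ndarray] = {
        "age": np.round(rng.normal(AGE_MEDIAN, AGE_IQR / 1.349, size=n), 1)
    }
    for var, levels in spec.clinical_marginals.items():
        names = list(levels.keys())
        probs = np.asarray([levels[k] for k in names], dtype=np.float64)
        probs = probs / probs.sum()
        data[var] = rng.choice(names, size=n, p=probs)
    df = pd.DataFrame(data)
    df.index.name = "subject"
    return df


# ---------------------------------------------------------------------------
# survival outcomes
# ---------------------------------------------------------------------------

def generate_survival(linear_predictor, baseline_shape: float, baseline_scale: float,
                      censoring_rate: float, seed: int = 0) -> pd.DataFrame:
    """Weibull proportional-hazards event times with independent uniform censoring.

    Event times follow S(t|x) = exp(-(t/scale)^shape * exp(lp)). Censoring
    times are uniform on [0, c_max] with c_max calibrated (bisection) so the
    expected event fraction equals 1 - censoring_rate; recorded time is the
    minimum, event the indicator.
    """
    lp = np.asarray(linear_predictor, dtype=np.float64)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")
    if not 0.0 <= censoring_rate <= 1.0:
        raise ValueError("censoring_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=lp.shape)
    t_event = baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / baseline_shape)

    if censoring_rate == 0:
        time, event = t_event, np.ones_like(t_event, dtype=int)
    elif censoring_rate == 1:
        time, event = np.zeros_like(t_event), np.zeros_like(t_event, dtype=int)
    else:
        # expected censored fraction with C ~ U(0, c): mean(min(T/c, 1))
        def cens_frac(c):
            return float(np.minimum(t_event / c, 1.0).mean())

        lo, hi = 1e-6, float(t_event.max()) * 2
        while cens_frac(hi) > censoring_rate:
            hi *= 2
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if cens_frac(mid) > censoring_rate:
                lo = mid
            else:
                hi = mid
        c_max = 0.5 * (lo + hi)
        t_cens = rng.uniform(0, c_max, size=lp.shape)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    df = pd.DataFrame({"time": time, "event": event})
    df.index.name = "subject"
    return df


def to_structured(outcome: pd.DataFrame) -> np.ndarray:
    """Convert a (time, event) table to the scikit-survival structured array."""
    return np.array(
        list(zip(outcome["event"].astype(bool), outcome["time"].astype(float))),
        dtype=[("event", "?"), ("time", "<f8")],
    )


# ---------------------------------------------------------------------------
# tabular cohort (parameters as features, known hazard)
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, n_noise_features: int = 10):
    """Generate a tabular cohort with known proportional-hazards structure.

    Continuous phantom parameters (tumour radius, heterogeneity, vessel
    tortuosity) are drawn per subject, combined with the lab covariates from
    the clinical table, standardized, weighted by ``hazard_coefficients`` to
    form the true log-hazard, and fed to the Weibull generator. Pure-noise
    continuous features are appended so screening has something to reject.

    Returns ``(features, clinical, outcome, truth)`` where ``truth`` carries
    the per-subject linear predictor.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    clinical = generate_clinical_table(
        CohortSpec(n_subjects=n, clinical_marginals=spec.clinical_marginals,
                   seed=int(rng.integers(2**31 - 1))))

    params = pd.DataFrame({
        "tumor_radius_mm": rng.uniform(6.0, 16.0, size=n),
        "heterogeneity": rng.uniform(0.05, 0.6, size=n),
        "vessel_tortuosity": rng.uniform(0.0, 0.35, size=n),
    }, index=clinical.index)
    params["total_protein_normal"] = (clinical["total_protein"] == "normal").astype(float)
    params["mcv_high"] = (clinical["mcv"] == "high").astype(float)

    lp = np.zeros(n)
    for name, beta in spec.hazard_coefficients.items():
        col = params[name].to_numpy(dtype=np.float64)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else col * 0.0
        lp += beta * z
    outcome = generate_survival(lp, spec.baseline_shape, spec.baseline_scale,
                                spec.censoring_rate,
                                seed=int(rng.integers(2**31 - 1)))
    features = params.copy()
    for j in range(n_noise_features):
        features[f"noise_{j:02d}"] = rng.standard_normal(n)
    truth = GroundTruth(linear_predictor=None)
    truth_lp = pd.Series(lp, index=clinical.index, name="linear_predictor")
    return features, clinical, outcome, truth_lp


def generate_image_cohort(n_subjects: int, seed: int = 0,
                          grid_shape=(72, 72, 72),
                          cohort_spec: CohortSpec | None = None):
    """Generate phantom images whose parameters drive the survival hazard.

    Returns ``(phantoms, clinical, outcome, truth_lp)`` with ``phantoms`` a
    list of per-subject dicts (volume, masks, spec, ground truth). Intended
    for small-n end-to-end runs of the imaging pipeline.
    """
    base = cohort_spec or CohortSpec(n_subjects=n_subjects, seed=seed)
    rng = np.random.default_rng(seed)
    clinical = generate_clinical_table(
        CohortSpec(n_subjects=n_subjects, clinical_marginals=base.clinical_marginals,
                   seed=int(rng.integers(2**31 - 1))))
    radius = rng.uniform(7.0, 13.0, size=n_subjects)
    heterogeneity = rng.uniform(0.05, 0.6, size=n_subjects)
    tortuosity = rng.uniform(0.0, 0.35, size=n_subjects)

    phantoms = []
    for i in range(n_subjects):
        spec = PhantomSpec(grid_shape=grid_shape,
                           tumor_radius_mm=float(radius[i]),
                           heterogeneity=float(heterogeneity[i]),
                           tortuosity=float(tortuosity[i]),
                           seed=int(rng.integers(2**31 - 1)))
        vol, tumor, lung, vessel, gt = generate_phantom(spec)
        phantoms.append({"volume": vol, "tumor_mask": tumor, "lung_mask": lung,
                         "vessel_mask": vessel, "spec": spec, "truth": gt})

    params = pd.DataFrame({
        "tumor_radius_mm": radius,
        "heterogeneity": heterogeneity,
        "vessel_tortuosity": tortuosity,
        "total_protein_normal": (clinical["total_protein"] == "normal").astype(float),
        "mcv_high": (clinical["mcv"] == "high").astype(float),
    }, index=clinical.index)
    lp = np.zeros(n_subjects)
    for name, beta in base.hazard_coefficients.items():
        col = params[name].to_numpy(dtype=np.float64)
        sd = col.std()
        lp += beta * ((col - col.mean()) / sd if sd > 0 else col * 0.0)
    outcome = generate_survival(lp, base.baseline_shape, base.baseline_scale,
                                base.censoring_rate,
                                seed=int(rng.integers(2**31 - 1)))
    truth_lp = pd.Series(lp, index=clinical.index, name="linear_predictor")
    return phantoms, clinical, outcome, truth_lp
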