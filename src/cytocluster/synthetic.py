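"""Synthetic cytology fields and cohorts.

Real liquid-based endometrial cytology images are not publicly
deposited, so this module generates data with the statistical structure
the analysis assumes:

* **Cluster shapes.** A cell cluster is a star-convex blob whose radius
  is a random Fourier perturbation of an ellipse,
  ``r(theta) = R * (1 + a * sum_k k**(-beta) * (u_k cos k theta + v_k sin k theta))``
  with standard-normal ``u_k, v_k``.  The amplitude ``a`` controls how
  irregular/protruding the boundary is (benign clusters: small ``a``,
  smooth and compact; malignant clusters: large ``a``, rough boundary
  with a higher box-counting dimension); ``beta`` controls the spectral
  decay and hence the fine-scale raggedness.

* **Reference shapes** with known box-counting dimension (line, disk,
  filled square, Sierpinski carpet and triangle, Koch island boundary)
  used to validate the fractal-dimension estimator.

* **Fields.** Five fields per specimen; each field places several
  non-overlapping clusters as dark objects on a bright background.

* **Cohorts.** Patient records with class-conditional age, a three-tier
  cytology category, seven histology classes, and exponential survival
  whose log-hazard is linear in the standardized specimen morphometry.
  Defaults are calibrated to a published 200-patient endometrial
  cytology case series (class sizes, per-class age means/SDs, and the
  cytology-by-histology cross-tabulation).

A second, purely tabular generator draws specimen features directly
from class-conditional Gaussians; its class separation (e.g. the AUC of
a feature) is then known in closed form, which the statistical recovery
tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm
from skimage.draw import polygon as _draw_polygon

from . import morphometry
from .prep import label_clusters

__all__ = [
    "ClusterShapeParams",
    "ShapeRange",
    "CohortConfig",
    "FieldSample",
    "HISTOLOGY_CLASSES",
    "CYTOLOGY_LEVELS",
    "generate_cluster_mask",
    "ReferenceShape",
    "generate_reference_shape",
    "generate_field",
    "generate_cohort",
    "sample_survival",
    "sample_feature_cohort",
    "binormal_auc",
    "binormal_shift",
    "default_cohort_config",
]

HISTOLOGY_CLASSES = ("Normal", "EH", "AEH", "EM_G1", "EM_G2", "EM_G3", "Others")
CYTOLOGY_LEVELS = ("negative", "suspicious_positive", "positive")


@dataclass(frozen=True)
class ClusterShapeParams:
    """Parameters of one synthetic cluster boundary.

    ``roughness_amplitude = 0`` gives an exact ellipse (a disk when the
    eccentricity is also 0).  The radial perturbation must keep
    ``r(theta) > 0``; overly large amplitudes raise at generation time.
    """

    base_radius: float
    eccentricity: float = 0.0
    roughness_amplitude: float = 0.0
    roughness_exponent: float = 1.5
    n_harmonics: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must be in [0, 1)")
        if self.roughness_amplitude < 0:
            raise ValueError("roughness_amplitude must be >= 0")
        if self.roughness_exponent <= 0:
            raise ValueError("roughness_exponent must be > 0")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")


def _radial_profile(params: ClusterShapeParams, n_theta: int = 720) -> np.ndarray:
    """r(theta)/R on a uniform theta grid; raises if it dips <= 0."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    r = np.ones(n_theta)
    if params.roughness_amplitude > 0 and params.n_harmonics > 0:
        rng = np.random.default_rng(params.seed)
        k = np.arange(1, params.n_harmonics + 1)
        u = rng.standard_normal(params.n_harmonics)
        v = rng.standard_normal(params.n_harmonics)
        w = k.astype(float) ** (-params.roughness_exponent)
        pert = (w * u) @ np.cos(np.outer(k, theta)) + (w * v) @ np.sin(np.outer(k, theta))
        r = r + params.roughness_amplitude * pert
    if np.any(r <= 0):
        raise ValueError(
            "roughness_amplitude too large for base_radius: r(theta) <= 0")
    return r


def generate_cluster_mask(
    params: ClusterShapeParams,
    canvas: tuple[int, int] | None = None,
) -> np.ndarray:
    """Rasterize one cluster as a boolean mask.

    The boundary polygon is sampled at 720 angles and filled; the shape
    is star-convex by construction, so the result is one 8-connected
    component.  Deterministic for a fixed ``params.seed``.  When
    ``canvas`` is omitted, a canvas just large enough is used.
    """
    prof = _radial_profile(params)
    theta = np.linspace(0.0, 2.0 * math.pi, prof.size, endpoint=False)
    ax = params.base_radius / (1.0 - params.eccentricity**2) ** 0.25
    ay = params.base_radius * (1.0 - params.eccentricity**2) ** 0.25
    x = prof * ax * np.cos(theta)
    y = prof * ay * np.sin(theta)
    rmax = float(np.hypot(x, y).max())
    if canvas is None:
        side = 2 * int(math.ceil(rmax)) + 5
        canvas = (side, side)
    h, w = canvas
    cy, cx = h / 2.0, w / 2.0
    if rmax >= min(cy, cx, h - cy, w - cx):
        raise ValueError("canvas too small to contain the cluster")
    rr, cc = _draw_polygon(y + cy, x + cx, shape=canvas)
    mask = np.zeros(canvas, bool)
    mask[rr, cc] = True
    return mask


@dataclass(frozen=True)
class ReferenceShape:
    """A deterministic validation mask with known box-counting dimension."""

    name: str
    mask: np.ndarray
    dimension: float
    depth: int


def _sierpinski_carpet(depth: int) -> np.ndarray:
    cell = np.ones((1, 1), bool)
    for _ in range(depth):
        z = np.zeros_like(cell)
        row1 = np.concatenate([cell, cell, cell], axis=1)
        row2 = np.concatenate([cell, z, cell], axis=1)
        cell = np.concatenate([row1, row2, row1], axis=0)
    return cell


def _sierpinski_triangle(depth: int) -> np.ndarray:
    n = 2**depth
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (i & j) == 0          # Pascal-triangle mod 2 pattern


def _koch_island(depth: int, size: int) -> np.ndarray:
    # Koch snowflake boundary drawn as a polygon outline
    def refine(pts: np.ndarray) -> np.ndarray:
        out = []
        for a, b in zip(pts, np.roll(pts, -1, axis=0)):
            d = b - a
            p1 = a + d / 3.0
            p2 = a + 2.0 * d / 3.0
            # outward bump: +60 degree rotation (the vertex coordinates
            # are in screen orientation, which mirrors the polygon)
            rot = np.array([[0.5, -math.sqrt(3) / 2], [math.sqrt(3) / 2, 0.5]])
            peak = p1 + rot @ (d / 3.0)
            out.extend([a, p1, peak, p2])
        return np.asarray(out)

    r = size * 0.31
    c = size / 2.0
    ang = np.array([math.pi / 2, math.pi / 2 + 2 * math.pi / 3,
                    math.pi / 2 + 4 * math.pi / 3])
    pts = np.column_stack([c + r * np.cos(ang), c - r * np.sin(ang)])
    for _ in range(depth):
        pts = refine(pts)
    mask = np.zeros((size, size), bool)
    from skimage.draw import line as _draw_line
    for a, b in zip(pts, np.roll(pts, -1, axis=0)):
        rr, cc = _draw_line(int(round(a[1])), int(round(a[0])),
                            int(round(b[1])), int(round(b[0])))
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        mask[rr[keep], cc[keep]] = True
    return mask


def generate_reference_shape(name: str, depth: int, size: int) -> ReferenceShape:
    """Deterministic analytic fixture for the fractal-dimension estimator.

    Supported shapes and their analytic box-counting dimensions:
    ``line`` (1), ``disk`` (2), ``square`` (2),
    ``sierpinski_carpet`` (log 8 / log 3), ``sierpinski_triangle``
    (log 3 / log 2), ``koch_island`` boundary (log 4 / log 3).
    The carpet requires ``size`` divisible by 3**depth and the triangle
    ``size`` divisible by 2**depth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if name == "line":
        mask = np.zeros((size, size), bool)
        mask[size // 2, :] = True
        return ReferenceShape(name, mask, 1.0, depth)
    if name == "square":
        return ReferenceShape(name, np.ones((size, size), bool), 2.0, depth)
    if name == "disk":
        yy, xx = np.mgrid[:size, :size]
        r = size * 0.45
        mask = (yy - size / 2) ** 2 + (xx - size / 2) ** 2 <= r * r
        return ReferenceShape(name, mask, 2.0, depth)
    if name == "sierpinski_carpet":
        unit = 3**depth
        if size % unit != 0:
            raise ValueError(f"size must be a multiple of 3**depth = {unit}")
        cell = _sierpinski_carpet(depth)
        mask = np.kron(cell, np.ones((size // unit, size // unit), bool))
        return ReferenceShape(name, mask, math.log(8) / math.log(3), depth)
    if name == "sierpinski_triangle":
        unit = 2**depth
        if size % unit != 0:
            raise ValueError(f"size must be a multiple of 2**depth = {unit}")
        cell = _sierpinski_triangle(depth)
        mask = np.kron(cell, np.ones((size // unit, size // unit), bool))
        return ReferenceShape(name, mask, math.log(3) / math.log(2), depth)
    if name == "koch_island":
        return ReferenceShape(name, _koch_island(depth, size),
                              math.log(4) / math.log(3), depth)
    raise ValueError(f"unknown reference shape {name!r}")


@dataclass(frozen=True)
class ShapeRange:
    """Uniform sampling ranges for per-class cluster shape parameters."""

    radius: tuple[float, float] = (14.0, 24.0)
    eccentricity: tuple[float, float] = (0.0, 0.5)
    roughness_amplitude: tuple[float, float] = (0.04, 0.14)
    roughness_exponent: float = 1.5
    n_harmonics: int = 12

    def sample(self, rng: np.random.Generator) -> ClusterShapeParams:
        return ClusterShapeParams(
            base_radius=rng.uniform(*self.radius),
            eccentricity=rng.uniform(*self.eccentricity),
            roughness_amplitude=rng.uniform(*self.roughness_amplitude),
            roughness_exponent=self.roughness_exponent,
            n_harmonics=self.n_harmonics,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    def sample_patient(self, rng: np.random.Generator) -> "ShapeRange":
        """Draw one patient's narrower parameter range within this class.

        Specimens differ: a patient's clusters share that patient's
        morphology and only jitter around it.  Without this hierarchy
        the specimen-level five-field averages would concentrate on the
        class mean and every class would separate perfectly, which real
        cytology cohorts do not do.
        """
        def around(lo_hi, rel):
            c = rng.uniform(*lo_hi)
            return (max(lo_hi[0] * 0.5, c * (1 - rel)), c * (1 + rel))

        ecc_c = rng.uniform(*self.eccentricity)
        return ShapeRange(
            radius=around(self.radius, 0.15),
            eccentricity=(max(0.0, ecc_c - 0.1), min(0.95, ecc_c + 0.1)),
            roughness_amplitude=around(self.roughness_amplitude, 0.25),
            roughness_exponent=self.roughness_exponent,
            n_harmonics=self.n_harmonics,
        )


# Class sizes, ages, and the cytology cross-tabulation follow the
# 200-patient case series the defaults are calibrated to; shape ranges
# encode smooth/compact benign clusters versus irregular malignant ones,
# with roughness increasing by grade.
_DEFAULT_COUNTS = {"Normal": 92, "EH": 13, "AEH": 17, "EM_G1": 43,
                   "EM_G2": 18, "EM_G3": 10, "Others": 7}
_DEFAULT_AGES = {"Normal": (49.9, 12.2), "EH": (45.9, 6.9), "AEH": (46.2, 10.6),
                 "EM_G1": (59.2, 10.6), "EM_G2": (63.1, 13.8),
                 "EM_G3": (60.3, 8.0), "Others": (63.4, 13.6)}
_DEFAULT_CYTOLOGY = {
    "Normal": (25 / 92, 57 / 92, 10 / 92),
    "EH": (1 / 13, 9 / 13, 3 / 13),
    "AEH": (0.0, 11 / 17, 6 / 17),
    "EM_G1": (0.0, 11 / 43, 32 / 43),
    "EM_G2": (0.0, 3 / 18, 15 / 18),
    "EM_G3": (0.0, 0.0, 1.0),
    "Others": (0.0, 0.0, 1.0),
}
# Benign clusters: small, smooth, compact.  Malignant clusters: larger
# (multilayered, invasive growth) with rougher, protruding boundaries,
# increasing with grade.  Size is what moves the field-level box-count
# dimension; roughness is what moves circularity/solidity.
_BENIGN_SHAPES = ShapeRange()
_DEFAULT_SHAPES = {
    "Normal": _BENIGN_SHAPES,
    "EH": _BENIGN_SHAPES,
    "AEH": ShapeRange(radius=(16.0, 28.0), roughness_amplitude=(0.08, 0.18),
                      roughness_exponent=1.3, n_harmonics=14),
    "EM_G1": ShapeRange(radius=(18.0, 30.0), roughness_amplitude=(0.12, 0.24),
                        roughness_exponent=1.2, eccentricity=(0.0, 0.6),
                        n_harmonics=16),
    "EM_G2": ShapeRange(radius=(20.0, 33.0), roughness_amplitude=(0.16, 0.28),
                        roughness_exponent=1.1, eccentricity=(0.0, 0.6),
                        n_harmonics=16),
    "EM_G3": ShapeRange(radius=(22.0, 36.0), roughness_amplitude=(0.20, 0.30),
                        roughness_exponent=1.1, eccentricity=(0.0, 0.7),
                        n_harmonics=16),
    "Others": ShapeRange(radius=(20.0, 34.0), roughness_amplitude=(0.18, 0.30),
                         roughness_exponent=1.1, eccentricity=(0.0, 0.7),
                         n_harmonics=16),
}


@dataclass
class CohortConfig:
    """Full configuration of the synthetic cohort generator.

    Survival is exponential with log-hazard linear in the cohort-
    standardized specimen features named in ``survival_betas``;
    censoring is an independent exponential whose rate is set from
    ``censoring_rate`` (the approximate censored fraction under a null
    hazard), plus administrative censoring at ``max_followup`` months.
    """

    counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_AGES))
    cytology_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CYTOLOGY))
    shape_ranges: dict[str, ShapeRange] = field(
        default_factory=lambda: dict(_DEFAULT_SHAPES))
    clusters_per_field_mean: float = 6.0
    clusters_per_field_max: int = 12
    field_size: int = 384
    fields_per_patient: int = 5
    background_level: int = 220
    foreground_level: int = 60
    noise_sd: float = 8.0
    survival_betas: dict[str, float] = field(default_factory=lambda: {
        "circularity": -0.7, "solidity": -0.7, "fractal_dimension": 0.7})
    baseline_hazard: float = math.log(2) / 60.0   # per month
    censoring_rate: float = 0.6
    max_followup: float = 120.0                   # months
    seed: int = 0

    def validate(self) -> None:
        for cls in self.counts:
            if cls not in HISTOLOGY_CLASSES:
                raise ValueError(f"unknown histology class {cls!r}")
            if self.counts[cls] < 0:
                raise ValueError("counts must be >= 0")
            p = self.cytology_probs[cls]
            if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError(f"cytology probabilities for {cls} must sum to 1")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


def default_cohort_config(**overrides) -> CohortConfig:
    """The default study configuration, optionally with field overrides."""
    cfg = CohortConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class FieldSample:
    """One generated field: grayscale image plus ground truth."""

    image: np.ndarray                 # uint8 (field_size, field_size)
    mask: np.ndarray                  # bool union of cluster masks
    cluster_masks: list[np.ndarray]   # full-size bool mask per cluster
    n_clusters: int


def _sample_cluster(shape_range: ShapeRange, rng: np.random.Generator,
                    max_tries: int = 20) -> np.ndarray:
    """Draw shape parameters and rasterize, redrawing if r(theta) <= 0."""
    for _ in range(max_tries):
        try:
            return generate_cluster_mask(shape_range.sample(rng))
        except ValueError:
            continue
    raise RuntimeError("could not draw a valid cluster shape")


def generate_field(
    config: CohortConfig,
    histology: str,
    rng: np.random.Generator,
    n_clusters: int | None = None,
    max_place_tries: int = 200,
    shape_range: ShapeRange | None = None,
) -> FieldSample:
    """Compose one field of non-overlapping clusters.

    The cluster count is Poisson unless given explicitly.  Clusters are
    placed uniformly at random subject to disjointness (with a 2-pixel
    separation so 8-connected labeling recovers them individually);
    placement fails after ``max_place_tries`` rejected positions.
    ``shape_range`` overrides the class default, e.g. with one
    patient's individual parameter range.
    """
    size = config.field_size
    if n_clusters is None:
        n_clusters = int(min(rng.poisson(config.clusters_per_field_mean),
                             config.clusters_per_field_max))
    if shape_range is None:
        shape_range = config.shape_ranges[histology]
    occupancy = np.zeros((size, size), bool)
    cluster_masks: list[np.ndarray] = []
    tries = 0
    placed = 0
    while placed < n_clusters:
        blob = _sample_cluster(shape_range, rng)
        bh, bw = blob.shape
        if bh + 4 >= size or bw + 4 >= size:
            raise ValueError("cluster larger than field")
        # dilate-by-margin via padded slicing when testing overlap
        while True:
            tries += 1
            if tries > max_place_tries:
                raise RuntimeError(
                    f"could not place {n_clusters} clusters in a "
                    f"{size}x{size} field without overlap")
            r0 = int(rng.integers(2, size - bh - 2))
            c0 = int(rng.integers(2, size - bw - 2))
            region = occupancy[r0 - 2: r0 + bh + 2, c0 - 2: c0 + bw + 2]
            pad = np.zeros_like(region, bool)
            pad[2: 2 + bh, 2: 2 + bw] = blob
            if not (region & _dilate2(pad)).any():
                break
        full = np.zeros((size, size), bool)
        full[r0: r0 + bh, c0: c0 + bw] = blob
        occupancy |= full
        cluster_masks.append(full)
        placed += 1

    img = np.full((size, size), float(config.background_level))
    img[occupancy] = float(config.foreground_level)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FieldSample(image=image, mask=occupancy,
                       cluster_masks=cluster_masks, n_clusters=n_clusters)


def _dilate2(mask: np.ndarray) -> np.ndarray:
    """Binary dilation by a 5x5 square (2-pixel margin), via shifts."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    for dr in range(-2, 3):
        for dc in range(-2, 3):
            out[max(0, dr): h + min(0, dr), max(0, dc): w + min(0, dc)] |= \
                mask[max(0, -dr): h + min(0, -dr), max(0, -dc): w + min(0, -dc)]
    return out


def sample_survival(
    X: np.ndarray,
    beta: np.ndarray,
    baseline_hazard: float,
    censoring_rate: float,
    rng: np.random.Generator,
    max_followup: float = math.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with linear log-hazard, independent censoring.

    ``X`` is (n, p) of covariates (standardize before calling if hazard
    ratios per SD are wanted); event time T ~ Exp(h0 * exp(X beta)),
    censor time C ~ Exp(h0 * c/(1-c)) for censored fraction ~c, plus an
    administrative cap.  Returns (time, event).
    """
    X = np.atleast_2d(np.asarray(X, float))
    beta = np.asarray(beta, float)
    n = X.shape[0]
    rate = baseline_hazard * np.exp(X @ beta)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        c_rate = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, math.inf)
    t_cens = np.minimum(t_cens, max_followup)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return time, event


def _truncated_normal_age(mean: float, sd: float, n: int,
                          rng: np.random.Generator, lo: float = 18.0) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = out < lo
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < lo
    return out


def generate_cohort(
    config: CohortConfig | None = None,
    images: bool = False,
) -> tuple[pd.DataFrame, dict[str, list[FieldSample]]]:
    """Generate a full synthetic cohort.

    Each patient gets an age (class-conditional truncated normal), a
    cytology category (class-conditional categorical), five fields of
    clusters, specimen-level morphometry measured from the ground-truth
    masks with the package's own estimators, and exponential survival
    driven by the standardized features.  Fully deterministic given
    ``config.seed``.

    Returns the patient table and, when ``images`` is true, the per-
    patient field samples (keyed by patient id); with ``images=False``
    the fields dict is empty and only the measured features are kept,
    which is considerably cheaper.
    """
    if config is None:
        config = default_cohort_config()
    config.validate()
    master = np.random.SeedSequence(config.seed)
    rows: list[dict] = []
    field_store: dict[str, list[FieldSample]] = {}
    order = [cls for cls in HISTOLOGY_CLASSES if config.counts.get(cls, 0) > 0]
    seeds = master.spawn(sum(config.counts[c] for c in order))
    idx = 0
    for cls in order:
        for _ in range(config.counts[cls]):
            rng = np.random.default_rng(seeds[idx])
            pid = f"P{idx + 1:04d}"
            idx += 1
            age = float(_truncated_normal_age(*config.age_mean_sd[cls], 1, rng)[0])
            cytology = str(rng.choice(CYTOLOGY_LEVELS,
                                      p=config.cytology_probs[cls]))
            patient_range = config.shape_ranges[cls].sample_patient(rng)
            fields: list[morphometry.FieldFeatures] = []
            samples: list[FieldSample] = []
            for _f in range(config.fields_per_patient):
                # an unlucky dense draw can be unplaceable; redraw the
                # field (count included) a few times before giving up
                for attempt in range(5):
                    try:
                        fs = generate_field(config, cls, rng,
                                            shape_range=patient_range)
                        break
                    except RuntimeError:
                        if attempt == 4:
                            raise
                feats = [morphometry.measure_clusters(m.astype(int))[0]
                         for m in fs.cluster_masks]
                fd = (morphometry.boxcount_fd(fs.mask)
                      if fs.mask.any() else float("nan"))
                fields.append(morphometry.summarize_field(feats, fd))
                if images:
                    samples.append(fs)
            spec = morphometry.summarize_specimen(
                fields, expected_fields=config.fields_per_patient)
            row = {"patient_id": pid, "age": age, "cytology": cytology,
                   "histology": cls}
            row.update(spec.as_dict())
            rows.append(row)
            if images:
                field_store[pid] = samples
    df = pd.DataFrame(rows)

    feat_names = list(config.survival_betas)
    Z = df[feat_names].to_numpy(float)
    sd = Z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (Z - Z.mean(axis=0)) / sd
    surv_rng = np.random.default_rng(master.spawn(1)[0])
    time, event = sample_survival(
        Z, np.array([config.survival_betas[f] for f in feat_names]),
        config.baseline_hazard, config.censoring_rate, surv_rng,
        max_followup=config.max_followup)
    df["time_months"] = time
    df["event"] = event
    return df, field_store


def binormal_auc(mu0: float, sd0: float, mu1: float, sd1: float) -> float:
    """AUC of a Gaussian score: P(X1 > X0) for independent normals."""
    return float(norm.cdf((mu1 - mu0) / math.hypot(sd0, sd1)))


def binormal_shift(auc: float, sd0: float = 1.0, sd1: float = 1.0) -> float:
    """Mean shift mu1 - mu0 giving a target binormal AUC at unit means."""
    if not 0.0 < auc < 1.0:
        raise ValueError("auc must be in (0, 1)")
    return float(norm.ppf(auc) * math.hypot(sd0, sd1))


def sample_feature_cohort(
    n_negative: int,
    n_positive: int,
    rng: np.random.Generator,
    feature_effects: dict[str, float] | None = None,
    cytology_sens: float = 0.85,
    cytology_spec: float = 0.70,
    survival_betas: dict[str, float] | None = None,
    baseline_hazard: float = math.log(2) / 60.0,
    censoring_rate: float = 0.5,
) -> pd.DataFrame:
    """Tabular cohort with analytically known class separation.

    Features are unit-variance Gaussians whose positive-class mean is
    shifted by the value in ``feature_effects`` (so the binormal AUC of
    feature f is ``norm.cdf(shift / sqrt(2))``).  The cytology flag is
    Bernoulli with the given sensitivity/specificity.  Survival, when
    requested, is exponential in the standardized features as in the
    image-based generator.  Intended for statistical recovery tests
    where the ground truth must be known in closed form.
    """
    if feature_effects is None:
        feature_effects = {"fractal_dimension": binormal_shift(0.85)}
    label = np.concatenate([np.zeros(n_negative, bool), np.ones(n_positive, bool)])
    n = label.size
    df = pd.DataFrame({"positive": label})
    for name, shift in feature_effects.items():
        df[name] = rng.standard_normal(n) + shift * label
    p_flag = np.where(label, cytology_sens, 1.0 - cytology_spec)
    df["cytology_flag"] = rng.random(n) < p_flag
    if survival_betas:
        feats = list(survival_betas)
        Z = df[feats].to_numpy(float)
        Z = (Z - Z.mean(0)) / Z.std(0, ddof=0)
        time, event = sample_survival(
            Z, np.array([survival_betas[f] for f in feats]),
            baseline_hazard, censoring_rate, rng)
        df["time_months"] = time
        df["event"] = event
    return df
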