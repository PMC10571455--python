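"""Synthetic pulmonary-nodule phantoms with controllable semantic characteristics.

Each phantom is a star-convex shape drawn on a noisy parenchyma-like
background. The boundary radius function r(theta) composes:

* a sphericity term — an axis-ratio stretch that shrinks as the
  sphericity level rises (level 5 = circular);
* a lobulation term — 2-4 wide, low-frequency sinusoidal bumps whose
  amplitude grows with the lobulation level;
* a spiculation term — narrow, high-amplitude Gaussian spikes whose
  count and amplitude grow with the spiculation level.

Interior contrast over the background encodes subtlety, boundary blur
width encodes margin (wider blur = lower level), and bright interior
speckles encode calcification (level 6 = no calcification = none).
Internal structure and texture are generated as ratings only; the
grading models never target them, but the correlation ranking needs all
eight characteristics.

Three consecutive slices are emulated by re-rendering the same shape
with the radius scaled by 1.0, 0.9 and 0.8. Reader contours are the
truth contour perturbed by smooth, clipped radial noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .ratings import ReaderRatingRecord, SC_NAMES, SC_SCALE_MAX

N_CONTOUR_POINTS = 180
SLICE_SCALES = (1.0, 0.9, 0.8)


class RangeError(ValueError):
    """A semantic-characteristic level outside its rating scale."""


class GeometryError(ValueError):
    """Requested nodule geometry does not fit the image."""


@dataclass(frozen=True)
class SCGenParams:
    """Generating levels and geometry for one phantom nodule.

    Levels follow the LIDC rating scales: 1-5 for subtlety, sphericity,
    margin, lobulation and spiculation; 1-6 for calcification (6 =
    absent). ``reader_jitter`` is the radial standard deviation (pixels)
    of the smooth noise separating simulated readers' contours.
    """

    spiculation_level: int = 1
    lobulation_level: int = 1
    sphericity_level: int = 5
    margin_level: int = 5
    subtlety_level: int = 5
    calcification_level: int = 6
    base_radius: float = 12.0
    image_size: int = 64
    n_readers: int = 4
    reader_jitter: float = 1.5
    seed: int = 0
    # ratings-only characteristics (no image encoding) and the malignancy
    # rating; malignancy defaults to mirroring spiculation, its strongest
    # correlate.
    internal_structure_level: int = 1
    texture_level: int = 5
    malignancy_level: int | None = None

    def __post_init__(self):
        checks = [
            ("spiculation_level", self.spiculation_level, 5),
            ("lobulation_level", self.lobulation_level, 5),
            ("sphericity_level", self.sphericity_level, 5),
            ("margin_level", self.margin_level, 5),
            ("subtlety_level", self.subtlety_level, 5),
            ("calcification_level", self.calcification_level, 6),
            ("internal_structure_level", self.internal_structure_level, 4),
            ("texture_level", self.texture_level, 5),
        ]
        for name, val, hi in checks:
            if not 1 <= val <= hi:
                raise RangeError(f"{name}={val} outside 1-{hi}")
        if self.malignancy_level is not None and not 1 <= self.malignancy_level <= 5:
            raise RangeError(f"malignancy_level={self.malignancy_level} outside 1-5")
        if not 1 <= self.n_readers <= 4:
            raise RangeError(f"n_readers={self.n_readers} outside 1-4")
        if self.base_radius < 4:
            raise GeometryError(f"base_radius must be >= 4 px, got {self.base_radius}")
        if self.image_size < 4 * self.base_radius:
            raise GeometryError(
                f"image_size {self.image_size} < 4 x base_radius {self.base_radius}"
            )


@dataclass
class PhantomCase:
    """One synthetic nodule: 3 consecutive slices with annotations."""

    case_id: str
    slices: list            # 3 float arrays (image_size, image_size) in [0, 1]
    reader_contours: list   # [reader][slice] -> (K, 2) float array of (x, y)
    ratings: list           # one ReaderRatingRecord per reader
    truth_mask: np.ndarray  # (3, image_size, image_size) bool
    malignancy_label: int
    params: SCGenParams


def _radius_function(params: SCGenParams, rng: np.random.Generator):
    """Build r(theta) for the central slice; returns a callable."""
    base = params.base_radius
    # Level-to-geometry mappings are monotone and steepest across the 2 -> 3
    # boundary, where the rating semantics switch from "none/low" to
    # "marked/high": level 2 lobulation or spiculation is barely present,
    # level 3 clearly visible to a reader.
    # sphericity: axis ratio k shrinks to 1 as the level rises
    k = (1.60, 1.45, 1.25, 1.10, 1.00)[params.sphericity_level - 1]
    a, b = base * k, base / k
    phi = rng.uniform(0, np.pi)

    # lobulation: few wide bumps
    n_lobes = int(rng.integers(2, 5))
    lob_amp = base * (0.0, 0.03, 0.14, 0.20, 0.27)[params.lobulation_level - 1]
    lob_phase = rng.uniform(0, 2 * np.pi)

    # spiculation: narrow tall spikes, conspicuous enough to survive margin
    # blur and patch resampling (marked spiculation is obvious to a reader)
    lvl = params.spiculation_level
    n_spikes = (0, 2, 6, 8, 10)[lvl - 1]
    spike_amp = base * (0.0, 0.10, 0.32, 0.45, 0.58)[lvl - 1]
    spike_width = 0.20  # radians
    spike_angles = rng.uniform(0, 2 * np.pi, size=n_spikes)

    def r_of_theta(theta: np.ndarray) -> np.ndarray:
        t = theta - phi
        r = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
        r = r + lob_amp * np.sin(n_lobes * theta + lob_phase)
        if n_spikes:
            d = theta[..., None] - spike_angles[None, :]
            d = (d + np.pi) % (2 * np.pi) - np.pi  # wrap-around angular distance
            r = r + spike_amp * np.exp(-0.5 * (d / spike_width) ** 2).sum(axis=-1)
        return np.maximum(r, 2.0)

    return r_of_theta


def _rasterize_star(r_fn, scale, center, size) -> np.ndarray:
    """Binary mask of {p : |p - c| <= scale * r(theta_p)}, largest 4-CC, filled."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center[0]
    dx = xx - center[1]
    theta = np.arctan2(dy, dx) % (2 * np.pi)
    mask = np.hypot(dy, dx) <= scale * r_fn(theta)
    # keep a single 4-connected component and fill holes
    lab, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def _smooth_periodic_noise(rng, n, sigma, n_harmonics=6) -> np.ndarray:
    """Smooth zero-mean periodic noise over n angular samples, std ~ sigma."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    out = np.zeros(n)
    for h in range(1, n_harmonics + 1):
        out += rng.normal() * np.cos(h * theta) + rng.normal() * np.sin(h * theta)
    out *= sigma / np.sqrt(n_harmonics)  # each harmonic pair has variance 1 per sample
    return np.clip(out, -sigma, sigma)


def _ratings_record(params: SCGenParams, case_id: str, reader_id: int,
                    malignancy_level: int) -> ReaderRatingRecord:
    return ReaderRatingRecord(
        case_id=case_id,
        reader_id=reader_id,
        ratings={
            "subtlety": params.subtlety_level,
            "internal_structure": params.internal_structure_level,
            "calcification": params.calcification_level,
            "sphericity": params.sphericity_level,
            "margin": params.margin_level,
            "lobulation": params.lobulation_level,
            "spiculation": params.spiculation_level,
            "texture": params.texture_level,
            "malignancy": malignancy_level,
        },
    )


def generate_nodule_phantom(params: SCGenParams, case_id: str = "case_0") -> PhantomCase:
    """Render one phantom nodule; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    center = size / 2.0 - 0.5 + rng.uniform(-2, 2, size=2)
    r_fn = _radius_function(params, rng)

    # cap radius so every contour stays inside the image
    max_r = size / 2.0 - 3.0 - params.reader_jitter

    def r_capped(theta):
        return np.minimum(r_fn(theta), max_r)

    bg_mean, bg_std = 0.30, 0.05
    # contrast over background in background SDs, linear in the level;
    # even level 1 stays above the noise floor, as for a human reader
    contrast_sd = 2.0 + 1.3 * (params.subtlety_level - 1)
    nodule_mean = bg_mean + contrast_sd * bg_std
    blur_sigma = (2.6, 2.0, 1.0, 0.7, 0.4)[params.margin_level - 1]

    theta_c = np.linspace(0, 2 * np.pi, N_CONTOUR_POINTS, endpoint=False)
    truth_r = r_capped(theta_c)

    slices, masks = [], np.zeros((3, size, size), dtype=bool)
    reader_contours: list[list[np.ndarray]] = [[] for _ in range(params.n_readers)]

    # one smooth radial-noise field per reader, shared across slices
    reader_noise = [
        _smooth_periodic_noise(rng, N_CONTOUR_POINTS, params.reader_jitter)
        if r > 0 else np.zeros(N_CONTOUR_POINTS)
        for r in range(params.n_readers)
    ]

    # calcification speckles (slice-shared positions, polar coordinates)
    n_speckles = 0 if params.calcification_level == 6 else 2 * (6 - params.calcification_level)
    speckle_r = rng.uniform(0.1, 0.6, size=n_speckles)
    speckle_t = rng.uniform(0, 2 * np.pi, size=n_speckles)

    for s, scale in enumerate(SLICE_SCALES):
        mask = _rasterize_star(r_capped, scale, center, size)
        masks[s] = mask
        bg = rng.normal(bg_mean, bg_std, size=(size, size))
        interior = nodule_mean + rng.normal(0, 0.02, size=(size, size))
        alpha = ndimage.gaussian_filter(mask.astype(float), blur_sigma)
        img = bg * (1 - alpha) + interior * alpha
        # calcification: bright speckles inside the nodule
        if n_speckles:
            yy, xx = np.mgrid[0:size, 0:size]
            for rr, tt in zip(speckle_r, speckle_t):
                rad = rr * scale * params.base_radius
                cy = center[0] + rad * np.sin(tt)
                cx = center[1] + rad * np.cos(tt)
                spot = (yy - cy) ** 2 + (xx - cx) ** 2 <= 1.5 ** 2
                img = np.where(spot & mask, 0.95, img)
        slices.append(np.clip(img, 0.0, 1.0))

        for r in range(params.n_readers):
            rad = np.maximum(scale * truth_r + reader_noise[r], 1.0)
            rad = np.minimum(rad, size / 2.0 - 1.5)
            xs = center[1] + rad * np.cos(theta_c)
            ys = center[0] + rad * np.sin(theta_c)
            reader_contours[r].append(np.column_stack([xs, ys]))

    mal = params.malignancy_level if params.malignancy_level is not None else params.spiculation_level
    ratings = [
        _ratings_record(params, case_id, r + 1, mal) for r in range(params.n_readers)
    ]
    return PhantomCase(
        case_id=case_id,
        slices=slices,
        reader_contours=reader_contours,
        ratings=ratings,
        truth_mask=masks,
        malignancy_label=int(mal >= 3),
        params=params,
    )


# --- cohort generation -------------------------------------------------------

#: Empirical rating frequencies of a large multi-reader screening cohort
#: (counts per level 1..T); used as the marginal distribution of
#: non-target characteristics so phantom cohorts share the field's
#: typical composition (mostly sharp margins, conspicuous nodules,
#: unspiculated shapes) instead of a uniform one.
RATING_MARGINALS = {
    "subtlety": (129, 174, 597, 672, 1519),
    "internal_structure": (3075, 1, 11, 4),
    "calcification": (0, 10, 148, 184, 62, 2687),
    "sphericity": (13, 218, 986, 928, 946),
    "margin": (135, 241, 450, 937, 1328),
    "lobulation": (1401, 800, 423, 365, 102),
    "spiculation": (1677, 528, 406, 220, 260),
    "texture": (149, 38, 129, 267, 2508),
}


def _draw_marginal(rng, sc: str) -> int:
    counts = np.asarray(RATING_MARGINALS[sc], dtype=float)
    return int(rng.choice(np.arange(1, len(counts) + 1), p=counts / counts.sum()))


#: Default monotone link strengths |link| in [0, 1] between each SC and the
#: malignancy label, ordered so spiculation is the strongest correlate,
#: followed by lobulation, calcification, subtlety, margin, sphericity,
#: internal structure and texture.
DEFAULT_CORRELATION_PROFILE = {
    "spiculation": 0.90,
    "lobulation": 0.70,
    "calcification": 0.60,
    "subtlety": 0.50,
    "margin": 0.40,
    "sphericity": 0.30,
    "internal_structure": 0.15,
    "texture": 0.05,
}

#: Direction of each link: sphericity and margin decrease with malignancy.
LINK_SIGN = {sc: (-1.0 if sc in ("sphericity", "margin") else 1.0)
             for sc in DEFAULT_CORRELATION_PROFILE}


class ConfigError(ValueError):
    pass


def _draw_level(rng, label: int, link: float, sign: float, lo: int, hi: int) -> int:
    """Integer level on [lo, hi] whose mean shifts with label * link."""
    mid = (lo + hi) / 2.0
    effect = 0.45 * (hi - lo) * link * sign
    latent = rng.normal(mid + effect * (2 * label - 1), 1.1)
    return int(np.clip(np.rint(latent), lo, hi))


def sample_sc_levels(rng, label: int, profile: dict) -> dict:
    """Draw one nodule's SC levels given its malignancy label."""
    levels = {}
    for sc, link in profile.items():
        hi = SC_SCALE_MAX[sc]
        levels[sc] = _draw_level(rng, label, link, LINK_SIGN[sc], 1, hi)
    # malignancy rating consistent with the label (>= 3 rule)
    levels["malignancy"] = _draw_level(rng, label, 1.0, 1.0, 1, 5)
    if label == 1:
        levels["malignancy"] = max(levels["malignancy"], 3)
    else:
        levels["malignancy"] = min(levels["malignancy"], 2)
    return levels


def generate_cohort(
    n_nodules: int,
    correlation_profile: dict | None = None,
    seed: int = 0,
    image_size: int = 64,
    base_radius: float = 12.0,
    n_readers: int = 4,
    render: bool = True,
) -> tuple[list[PhantomCase], pd.DataFrame]:
    """Cohort of phantoms with SC levels linked to a Bernoulli(0.5) label.

    Returns the cases (empty image payloads when ``render=False``) and a
    flat per-reader ratings table with columns case_id, reader_id,
    C1..C9. The default ``correlation_profile`` makes spiculation the
    strongest malignancy correlate.
    """
    if n_nodules < 10:
        raise ValueError("n_nodules must be >= 10")
    profile = dict(DEFAULT_CORRELATION_PROFILE if correlation_profile is None else correlation_profile)
    for sc, link in profile.items():
        if sc not in SC_SCALE_MAX:
            raise ConfigError(f"unknown SC {sc!r} in correlation profile")
        if not 0.0 <= link <= 1.0:
            raise ConfigError(f"link strength for {sc} must lie in [0, 1], got {link}")

    rng = np.random.default_rng(seed)
    cases, rows = [], []
    for i in range(n_nodules):
        label = int(rng.integers(0, 2))
        levels = sample_sc_levels(rng, label, profile)
        params = SCGenParams(
            spiculation_level=levels["spiculation"],
            lobulation_level=levels["lobulation"],
            sphericity_level=levels["sphericity"],
            margin_level=levels["margin"],
            subtlety_level=levels["subtlety"],
            calcification_level=levels["calcification"],
            internal_structure_level=levels["internal_structure"],
            texture_level=levels["texture"],
            malignancy_level=levels["malignancy"],
            base_radius=base_radius,
            image_size=image_size,
            n_readers=n_readers,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case_id = f"case_{i:04d}"
        if render:
            case = generate_nodule_phantom(params, case_id=case_id)
        else:
            case = PhantomCase(
                case_id=case_id, slices=[], reader_contours=[],
                ratings=[_ratings_record(params, case_id, r + 1, levels["malignancy"])
                         for r in range(n_readers)],
                truth_mask=np.zeros((3, 0, 0), dtype=bool),
                malignancy_label=label, params=params,
            )
        cases.append(case)
        for rec in case.ratings:
            row = {"case_id": case_id, "reader_id": rec.reader_id}
            for code, name in SC_NAMES.items():
                row[code] = rec.ratings[name]
            rows.append(row)
    return cases, pd.DataFrame(rows)


def generate_grading_task(
    n_nodules: int,
    sc: str = "spiculation",
    seed: int = 0,
    image_size: int = 64,
    base_radius: float = 12.0,
    n_readers: int = 4,
) -> tuple[list[PhantomCase], np.ndarray]:
    """Balanced binary low/high grading task for one characteristic.

    Half the nodules get a low level (1-2) of ``sc``, half a high level
    (3-5); every other characteristic is drawn from the empirical rating
    marginals (:data:`RATING_MARGINALS`). Returns the rendered cases and
    the 0/1 labels.
    """
    if sc not in SC_SCALE_MAX or sc == "malignancy":
        raise ConfigError(f"cannot build a grading task for {sc!r}")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_nodules, dtype=int)
    labels[: n_nodules // 2] = 1
    rng.shuffle(labels)
    cases = []
    for i, lab in enumerate(labels):
        levels = {name: _draw_marginal(rng, name) for name in DEFAULT_CORRELATION_PROFILE}
        if sc == "calcification":
            # high = 6 (absent), low = 1-5 (present)
            levels[sc] = 6 if lab else int(rng.integers(1, 6))
        else:
            levels[sc] = int(rng.integers(3, SC_SCALE_MAX[sc] + 1)) if lab else int(rng.integers(1, 3))
        params = SCGenParams(
            spiculation_level=levels["spiculation"],
            lobulation_level=levels["lobulation"],
            sphericity_level=levels["sphericity"],
            margin_level=levels["margin"],
            subtlety_level=levels["subtlety"],
            calcification_level=levels["calcification"],
            internal_structure_level=levels["internal_structure"],
            texture_level=levels["texture"],
            base_radius=base_radius,
            image_size=image_size,
            n_readers=n_readers,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(generate_nodule_phantom(params, case_id=f"task_{i:04d}"))
    return cases, labels
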