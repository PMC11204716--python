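"""Synthetic Gd-phantom XRF images and the dose/bin-width degradation protocol.

The generator emulates a benchtop X-ray fluorescence CT study object: a
water-filled hexagonal container (flat-top regular hexagon, maximum
diameter 50 mm) holding circular gadolinium tube inserts (8 mm
diameter) at tracer concentrations between 0 and 3.1 mg/mL (0 to
0.31 wt%).  A reconstructed XRF slice is modeled as an expected
photon-count image: diffuse Compton-scatter background over the whole
field, a water-scatter level inside the hexagon, and per-tube XRF
signal proportional to Gd concentration, blurred by a Gaussian system
PSF.

Dose and energy-bin degradation follow counting statistics exactly:

* the full-dose image is a per-pixel Poisson draw whose mean scales
  with the energy-bin width (0.5 keV is the reference bin, so a
  0.05 keV bin collects 10x fewer photons per bin);
* "noise level L%" means L% of photons removed, realized as per-pixel
  binomial thinning with keep fraction 1 - L/100 (thinning a Poisson
  image is again Poisson, so this is the physically faithful low-dose
  simulation).

``build_dataset`` assembles (noisy, clean) float pairs over the
(bin width x noise level) grid, applies the 90/180/270 degree rotation
augmentation, and draws a stratified 80/20 phantom-level hold-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "TubeSpec", "PhantomSpec", "CleanImage", "CountImage", "PairMeta",
    "ImagePair", "DatasetSplit", "GD_CONCENTRATIONS_WT",
    "hexagon_mask", "render_phantom", "sample_counts", "thin_counts",
    "counts_to_float", "augment_rotations", "build_dataset",
    "default_phantom_spec", "random_phantom_spec", "child_rng",
    "NOISE_LEVELS", "BIN_WIDTHS_KEV", "REFERENCE_BIN_KEV",
]

#: Gd weight fractions used in the benchtop phantoms (0 to 0.31 wt%).
GD_CONCENTRATIONS_WT = (0.0, 0.00031, 0.001, 0.002, 0.0031)

#: Default dose-reduction grid: fraction of photons REMOVED.
NOISE_LEVELS = (0.25, 0.5, 0.75)

#: Detector energy-bin widths (keV); 0.5 keV is the reference bin.
BIN_WIDTHS_KEV = (0.05, 0.1, 0.5)
REFERENCE_BIN_KEV = 0.5


def child_rng(master_seed: int, *indices: int) -> np.random.Generator:
    """Derive an independent generator from the master seed.

    Children are keyed by a tuple of small integers (stage, item, ...);
    the same key always yields the same stream, so any single pipeline
    stage is independently reproducible.
    """
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed),) + tuple(int(i) for i in indices)))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeSpec:
    """A circular Gd insert: center (row, col) px, radius px, weight fraction."""
    center: tuple[float, float]
    radius: float
    concentration: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("tube radius must be positive")
        if self.concentration < 0:
            raise ValueError("tube concentration must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and expected-count intensities of one phantom slice."""
    image_size: tuple[int, int] = (256, 256)
    hexagon_circumradius: float = 115.0
    water_level: float = 3.0
    compton_level: float = 5.0
    signal_gain: float = 10000.0
    psf_sigma: float = 1.5
    pixel_size_mm: float = 0.217
    tubes: tuple[TubeSpec, ...] = ()

    def __post_init__(self):
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image must be at least 32x32")
        if min(self.water_level, self.compton_level, self.signal_gain) < 0:
            raise ValueError("intensity levels must be non-negative")
        if 2 * self.hexagon_circumradius > min(h, w):
            raise ValueError("hexagon does not fit inside the image")
        for i, t in enumerate(self.tubes):
            r, c = t.center
            if not (t.radius <= r <= h - 1 - t.radius
                    and t.radius <= c <= w - 1 - t.radius):
                raise ValueError(f"tube {i} disc extends outside the image")


@dataclass(frozen=True)
class CleanImage:
    """Noise-free expected-count image (the 0% noise reference)."""
    pixels: np.ndarray
    pixel_size_mm: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("clean image must be finite and non-negative")


@dataclass(frozen=True)
class CountImage:
    """Integer photon-count image with dose/bin metadata."""
    counts: np.ndarray
    dose_fraction: float
    bin_width_keV: float
    seed: int

    def __post_init__(self):
        # dose_fraction 0 only arises from thinning with keep_fraction 0
        if not (0 <= self.dose_fraction <= 1):
            raise ValueError("dose_fraction must lie in [0, 1]")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class PairMeta:
    noise_level: float          # fraction of photons removed (0.25 = "25%")
    bin_width_keV: float
    augmentation_tag: str
    phantom_id: int


@dataclass(frozen=True)
class ImagePair:
    """(noisy input, clean target) in [0, 1] with provenance metadata."""
    noisy: np.ndarray
    clean: np.ndarray
    meta: PairMeta

    def __post_init__(self):
        if self.noisy.shape != self.clean.shape:
            raise ValueError("noisy/clean shape mismatch")


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    test_fraction: float

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train/test ids overlap")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def hexagon_mask(image_size: tuple[int, int], circumradius: float) -> np.ndarray:
    """Boolean mask of a centered flat-top regular hexagon.

    Membership is decided at pixel centers (no sub-pixel weighting): the
    hexagon is the intersection of three strips |dy| <= a,
    |(sqrt3 dx + dy)/2| <= a, |(sqrt3 dx - dy)/2| <= a with apothem
    a = sqrt(3)/2 * circumradius.
    """
    h, w = image_size
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - (h - 1) / 2.0
    dx = cc - (w - 1) / 2.0
    a = np.sqrt(3.0) / 2.0 * circumradius
    return ((np.abs(dy) <= a)
            & (np.abs(np.sqrt(3.0) * dx + dy) / 2.0 <= a)
            & (np.abs(np.sqrt(3.0) * dx - dy) / 2.0 <= a))


def _disc_mask(image_size: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    h, w = image_size
    rr, cc = np.mgrid[0:h, 0:w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def render_phantom(spec: PhantomSpec) -> CleanImage:
    """Render the deterministic expected-count image of a phantom slice.

    The value map is ``compton_level`` everywhere, plus ``water_level``
    inside the hexagon, plus ``signal_gain * concentration`` inside each
    tube disc, blurred by a Gaussian of ``psf_sigma`` pixels.  A tube
    whose disc leaves the hexagon raises an error naming the tube.
    """
    hexm = hexagon_mask(spec.image_size, spec.hexagon_circumradius)
    img = np.full(spec.image_size, float(spec.compton_level))
    img[hexm] += spec.water_level
    for i, tube in enumerate(spec.tubes):
        disc = _disc_mask(spec.image_size, tube.center, tube.radius)
        if np.any(disc & ~hexm):
            raise ValueError(f"tube {i} lies (partly) outside the hexagon")
        img[disc] += spec.signal_gain * tube.concentration
    if spec.psf_sigma > 0:
        img = gaussian_filter(img, spec.psf_sigma)
    return CleanImage(pixels=np.maximum(img, 0.0),
                      pixel_size_mm=spec.pixel_size_mm)


# ---------------------------------------------------------------------------
# counting statistics
# ---------------------------------------------------------------------------

def sample_counts(clean: CleanImage, bin_width_keV: float,
                  exposure_scale: float, seed: int) -> CountImage:
    """Poisson-sample a full-dose count image at a given energy-bin width.

    Expected counts are ``clean * exposure_scale * bin_width / 0.5``:
    the bin width acts purely as a multiplicative expected-count factor
    relative to the 0.5 keV reference bin.
    """
    if exposure_scale <= 0:
        raise ValueError("exposure_scale must be positive")
    if not np.all(np.isfinite(clean.pixels)):
        raise ValueError("clean image contains non-finite pixels")
    lam = clean.pixels * exposure_scale * (bin_width_keV / REFERENCE_BIN_KEV)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return CountImage(counts=counts, dose_fraction=1.0,
                      bin_width_keV=bin_width_keV, seed=seed)


def thin_counts(img: CountImage, keep_fraction: float, seed: int) -> CountImage:
    """Binomially thin a count image: each photon survives w.p. keep_fraction.

    The conventional "noise level L%" label maps to ``keep_fraction = 1 - L/100``.
    Thinning a Poisson(lam) image yields Poisson(keep * lam).
    """
    if not (0.0 <= keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in [0, 1]")
    if keep_fraction == 1.0:
        return replace(img, seed=seed)
    rng = np.random.default_rng(seed)
    if keep_fraction == 0.0:
        counts = np.zeros_like(img.counts)
    else:
        counts = rng.binomial(img.counts, keep_fraction)
    return CountImage(counts=counts,
                      dose_fraction=img.dose_fraction * keep_fraction,
                      bin_width_keV=img.bin_width_keV, seed=seed)


def counts_to_float(img: CountImage, norm="per_image_max") -> np.ndarray:
    """Monotone rescaling of counts into [0, 1].

    ``norm`` is either the string ``"per_image_max"`` (divide by the
    image maximum) or a positive float ``cmax`` (fixed-range mode:
    divide by cmax and clip to [0, 1]).  Fixed-range with a cmax shared
    across dose levels keeps dose reduction visible as darkening.
    """
    counts = img.counts.astype(np.float64)
    if isinstance(norm, str):
        if norm != "per_image_max":
            raise ValueError(f"unknown normalization {norm!r}")
        m = counts.max()
        if m == 0:
            warnings.warn("all-zero count image under per_image_max "
                          "normalization; returning zeros")
            return counts
        return counts / m
    cmax = float(norm)
    if cmax <= 0:
        raise ValueError("fixed-range cmax must be positive")
    return np.clip(counts / cmax, 0.0, 1.0)


# ---------------------------------------------------------------------------
# augmentation and dataset assembly
# ---------------------------------------------------------------------------

_ROT_TAGS = ("r0", "r90", "r180", "r270")


def augment_rotations(pairs: Sequence[ImagePair]) -> list[ImagePair]:
    """Original + counter-clockwise 90/180/270 degree rotations (4x pairs)."""
    out: list[ImagePair] = []
    for pair in pairs:
        h, w = pair.noisy.shape
        if h != w:
            raise ValueError("rotation augmentation requires square images")
        for k, tag in enumerate(_ROT_TAGS):
            out.append(ImagePair(
                noisy=np.ascontiguousarray(np.rot90(pair.noisy, k)),
                clean=np.ascontiguousarray(np.rot90(pair.clean, k)),
                meta=replace(pair.meta, augmentation_tag=tag)))
    return out


def default_phantom_spec(image_size: tuple[int, int] = (256, 256),
                         concentrations: Sequence[float] = (0.0031, 0.002,
                                                            0.001, 0.00031),
                         **overrides) -> PhantomSpec:
    """A phantom with tubes on a ring, mirroring the benchtop layout.

    Geometry scales with the image: the hexagon max diameter (2x
    circumradius) corresponds to 50 mm, and the 8 mm tubes scale
    accordingly (radius = 4/25 of the hexagon circumradius).
    """
    h, w = image_size
    circum = 0.45 * min(h, w)
    tube_r = circum * (4.0 / 25.0)
    ring = 0.5 * circum
    tubes = []
    for i, conc in enumerate(concentrations):
        ang = 2 * np.pi * i / len(concentrations) + np.pi / 6
        tubes.append(TubeSpec(
            center=((h - 1) / 2.0 + ring * np.sin(ang),
                    (w - 1) / 2.0 + ring * np.cos(ang)),
            radius=tube_r, concentration=conc))
    kw = dict(image_size=image_size, hexagon_circumradius=circum,
              pixel_size_mm=50.0 / (2 * circum), tubes=tuple(tubes))
    kw.update(overrides)
    return PhantomSpec(**kw)


def random_phantom_spec(image_size: tuple[int, int],
                        rng: np.random.Generator,
                        n_tubes: tuple[int, int] = (2, 4),
                        **overrides) -> PhantomSpec:
    """Random non-overlapping tube layout with benchtop concentrations."""
    h, w = image_size
    circum = 0.45 * min(h, w)
    tube_r = circum * (4.0 / 25.0)
    max_ring = np.sqrt(3.0) / 2.0 * circum - tube_r - 1.5
    k = int(rng.integers(n_tubes[0], n_tubes[1] + 1))
    centers: list[tuple[float, float]] = []
    tubes: list[TubeSpec] = []
    attempts = 0
    while len(tubes) < k and attempts < 200:
        attempts += 1
        rad = rng.uniform(0, max_ring - tube_r)
        ang = rng.uniform(0, 2 * np.pi)
        cr = (h - 1) / 2.0 + rad * np.sin(ang)
        cc = (w - 1) / 2.0 + rad * np.cos(ang)
        if any((cr - r0) ** 2 + (cc - c0) ** 2 < (2.2 * tube_r) ** 2
               for r0, c0 in centers):
            continue
        conc = float(rng.choice(GD_CONCENTRATIONS_WT))
        centers.append((cr, cc))
        tubes.append(TubeSpec(center=(cr, cc), radius=tube_r,
                              concentration=conc))
    kw = dict(image_size=image_size, hexagon_circumradius=circum,
              pixel_size_mm=50.0 / (2 * circum), tubes=tuple(tubes))
    kw.update(overrides)
    return PhantomSpec(**kw)


def build_dataset(specs: Sequence[PhantomSpec],
                  noise_levels: Iterable[float] = NOISE_LEVELS,
                  bin_widths: Iterable[float] = BIN_WIDTHS_KEV,
                  seed: int = 0,
                  exposure_scale: float = 1.0,
                  test_fraction: float = 0.2,
                  norm: str = "fixed_range",
                  cmax_percentile: float = 99.5,
                  dose_compensate: bool = False,
                  ) -> tuple[list[ImagePair], DatasetSplit]:
    """Assemble the augmented (noisy, clean) dataset over the full grid.

    For every phantom x bin width, one full-dose Poisson image is drawn;
    each noise level thins it binomially.  The clean target is the
    normalized full-dose image of the same phantom/bin.  Normalization
    is fixed-range per bin width with cmax the ``cmax_percentile``-th
    percentile of the full-dose images of the *training* phantoms (or
    per-image max when ``norm='per_image_max'``).  Rotation augmentation
    (4x) is applied after pairing.  With ``dose_compensate`` the noisy
    image is additionally divided by its keep fraction (exposure-matched
    brightness; by default dose reduction visibly darkens the input).
    The 20% hold-out is a seeded
    phantom-level split shared across categories, so every
    (bin, level) category contains round(test_fraction * n_specs) * 4
    test pairs and rotated copies never straddle the split.

    All randomness derives from ``seed`` via a documented child-seed
    scheme; the function is pure in (specs, grids, seed).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("empty phantom spec list")
    noise_levels = tuple(noise_levels)
    bin_widths = tuple(bin_widths)

    # phantom-level hold-out, shared across categories
    n_test = int(round(test_fraction * len(specs)))
    perm = child_rng(seed, 0).permutation(len(specs))
    test_specs = set(int(i) for i in perm[:n_test])

    cleans = [render_phantom(s) for s in specs]
    full_dose: dict[tuple[int, int], CountImage] = {}
    for si in range(len(specs)):
        for bi, bw in enumerate(bin_widths):
            cseed = int(child_rng(seed, 1, si, bi).integers(2 ** 31))
            full_dose[(si, bi)] = sample_counts(cleans[si], bw,
                                                exposure_scale, cseed)

    cmax_per_bin: dict[int, float] = {}
    if norm == "fixed_range":
        for bi in range(len(bin_widths)):
            train_imgs = [full_dose[(si, bi)].counts
                          for si in range(len(specs)) if si not in test_specs]
            if not train_imgs:       # degenerate: everything in test
                train_imgs = [full_dose[(si, bi)].counts
                              for si in range(len(specs))]
            cmax = float(np.percentile(np.concatenate(
                [im.ravel() for im in train_imgs]), cmax_percentile))
            cmax_per_bin[bi] = max(cmax, 1.0)
    elif norm != "per_image_max":
        raise ValueError(f"unknown normalization {norm!r}")

    pairs: list[ImagePair] = []
    train_ids: list[int] = []
    test_ids: list[int] = []
    for si in range(len(specs)):
        for bi, bw in enumerate(bin_widths):
            full = full_dose[(si, bi)]
            nrm = cmax_per_bin[bi] if norm == "fixed_range" else "per_image_max"
            clean_f = counts_to_float(full, nrm)
            for li, level in enumerate(noise_levels):
                tseed = int(child_rng(seed, 2, si, bi, li).integers(2 ** 31))
                keep = 1.0 - level
                noisy = thin_counts(full, keep, tseed)
                if dose_compensate and not isinstance(nrm, str) and keep > 0:
                    noisy_f = counts_to_float(noisy, nrm * keep)
                else:
                    noisy_f = counts_to_float(noisy, nrm)
                base = ImagePair(noisy=noisy_f, clean=clean_f,
                                 meta=PairMeta(noise_level=level,
                                               bin_width_keV=bw,
                                               augmentation_tag="r0",
                                               phantom_id=si))
                for aug in augment_rotations([base]):
                    idx = len(pairs)
                    pairs.append(aug)
                    (test_ids if si in test_specs else train_ids).append(idx)
    split = DatasetSplit(train_ids=tuple(train_ids), test_ids=tuple(test_ids),
                         test_fraction=test_fraction)
    return pairs, split
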