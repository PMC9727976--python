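"""Dataset handling: a synthetic fundus generator, the augmentation scheme,
mask file encoding, and directory/split helpers.

The synthetic generator emulates the structure of disc-centred fundus
photographs: a reddish textured background with uneven illumination and dark
curved vessels, a bright elliptical optic disc with a Gaussian-blurred rim,
and a smaller, brighter, blurrier optic cup strictly inside the disc, with a
controllable vertical cup-to-disc ratio.  Ground-truth masks use labels
0 (background), 1 (disc), 2 (cup); on disk masks are 8-bit PNGs with values
0 / 128 / 255.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import binary_dilation, gaussian_filter, rotate as nd_rotate
from skimage.transform import resize as sk_resize

from .metrics import VALID_LABELS

__all__ = [
    "SyntheticFundusParams",
    "AugmentationSpec",
    "generate_synthetic_fundus",
    "generate_dataset",
    "augment",
    "read_mask",
    "write_mask",
    "save_dataset",
    "load_dataset",
    "write_split",
    "read_split",
]

_MASK_ENCODING = {0: 0, 1: 128, 2: 255}
_MASK_DECODING = {v: k for k, v in _MASK_ENCODING.items()}


@dataclass
class SyntheticFundusParams:
    """Generator settings.  Radii and blurs in pixels, noise in intensity
    units; ``cdr_range`` is the target vertical cup-to-disc ratio interval."""

    image_size: int = 128
    disc_radius_range: tuple = (28, 40)
    cdr_range: tuple = (0.3, 0.8)
    disc_eccentricity_range: tuple = (0.75, 1.0)
    vessel_count_range: tuple = (2, 8)
    illumination_gradient_strength: float = 0.25
    noise_sigma: float = 4.0
    blur_sigma_disc: float = 1.5
    blur_sigma_cup: float = 2.5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.cdr_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("cdr_range must lie strictly inside (0, 1)")
        if self.disc_radius_range[1] * 2 + 8 > self.image_size:
            raise ValueError("disc does not fit inside the image")


def _ellipse_mask(shape, cx, cy, ra, rb):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return ((xx - cx) / ra) ** 2 + ((yy - cy) / rb) ** 2 <= 1.0


def _draw_vessels(canvas, rng, count, size):
    """Dark curved strokes: quadratic Bezier curves painted then dilated."""
    stroke = np.zeros(canvas.shape[:2], dtype=bool)
    for _ in range(count):
        pts = rng.uniform(0, size - 1, size=(3, 2))
        t = np.linspace(0.0, 1.0, 4 * size)[:, None]
        curve = ((1 - t) ** 2 * pts[0] + 2 * (1 - t) * t * pts[1]
                 + t ** 2 * pts[2])
        ij = np.clip(np.rint(curve).astype(int), 0, size - 1)
        stroke[ij[:, 1], ij[:, 0]] = True
    stroke = binary_dilation(stroke, iterations=1)
    alpha = gaussian_filter(stroke.astype(float), 0.8)[..., None]
    vessel_color = np.array([95.0, 32.0, 28.0])
    canvas *= 1 - 0.7 * alpha
    canvas += 0.7 * alpha * vessel_color
    return canvas


def generate_synthetic_fundus(params: SyntheticFundusParams | None = None):
    """Render one synthetic fundus image.

    Returns ``(image, mask, center)`` with an H x W x 3 uint8 image, an
    H x W int mask over {0, 1, 2} (cup strictly inside disc) and the disc
    centroid as (cx, cy).  Deterministic in ``params.seed``.
    """
    params = params or SyntheticFundusParams()
    rng = np.random.default_rng(params.seed)
    size = params.image_size

    # background: reddish base, low-frequency texture, illumination ramp
    base = np.array([165.0, 85.0, 60.0]) + rng.uniform(-12, 12, size=3)
    canvas = np.ones((size, size, 3)) * base
    texture = gaussian_filter(rng.normal(0, 1, (size, size)), size / 10.0)
    texture /= max(np.abs(texture).max(), 1e-9)
    canvas += 12.0 * texture[..., None]
    phi = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    ramp = ((xx - size / 2) * np.cos(phi) + (yy - size / 2) * np.sin(phi))
    ramp /= max(np.abs(ramp).max(), 1e-9)
    canvas *= 1.0 + params.illumination_gradient_strength * ramp[..., None]

    canvas = _draw_vessels(canvas, rng,
                           int(rng.integers(params.vessel_count_range[0],
                                            params.vessel_count_range[1] + 1)),
                           size)

    # disc geometry: integer centre and integer vertical semi-axis so the
    # rasterised vertical extents (hence the CDR) are exact
    rb = int(rng.integers(params.disc_radius_range[0],
                          params.disc_radius_range[1] + 1))
    ecc = rng.uniform(*params.disc_eccentricity_range)
    ra = max(rb * ecc, 2.0)
    margin = int(np.ceil(max(ra, rb))) + 3
    if margin >= size // 2:
        raise ValueError("disc does not fit inside the image")
    cx = int(rng.integers(margin, size - margin))
    cy = int(rng.integers(margin, size - margin))

    cdr = rng.uniform(*params.cdr_range)
    cup_rb = int(round((cdr * (2 * rb + 1) - 1) / 2))
    if cup_rb < 1 or cup_rb >= rb:
        raise ValueError(f"cup of CDR {cdr:.2f} cannot fit in disc radius {rb}")
    cup_ra = max(cup_rb * rng.uniform(0.85, 1.0), 1.0)

    # lateral cup offset (integer, so the extreme rows/columns of the cup
    # ellipse rasterise exactly), shrunk until the cup sits strictly inside
    dx = int(rng.uniform(-0.3, 0.3) * (ra - cup_ra))
    dy = int(rng.uniform(-0.3, 0.3) * (rb - cup_rb))
    phi_grid = np.linspace(0, 2 * np.pi, 256)
    for _ in range(8):
        px = dx + cup_ra * np.cos(phi_grid)
        py = dy + cup_rb * np.sin(phi_grid)
        if np.all((px / ra) ** 2 + (py / rb) ** 2 < 0.96):
            break
        dx = int(dx * 0.5)
        dy = int(dy * 0.5)
    else:
        dx, dy = 0, 0

    disc = _ellipse_mask((size, size), cx, cy, ra, rb)
    cup = _ellipse_mask((size, size), cx + dx, cy + dy, cup_ra, cup_rb)
    cup &= disc  # guaranteed by construction; enforce anyway

    disc_alpha = gaussian_filter(disc.astype(float),
                                 params.blur_sigma_disc)[..., None]
    cup_alpha = gaussian_filter(cup.astype(float),
                                params.blur_sigma_cup)[..., None]
    disc_color = np.array([222.0, 185.0, 120.0]) + rng.uniform(-8, 8, 3)
    cup_color = np.array([250.0, 232.0, 160.0]) + rng.uniform(-5, 5, 3)
    canvas = canvas * (1 - disc_alpha) + disc_alpha * disc_color
    canvas = canvas * (1 - cup_alpha) + cup_alpha * cup_color

    canvas += rng.normal(0, params.noise_sigma, canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    mask = np.zeros((size, size), dtype=np.uint8)
    mask[disc] = 1
    mask[cup] = 2
    ys, xs = np.nonzero(mask >= 1)
    center = (float(xs.mean()), float(ys.mean()))
    return image, mask, center


def generate_dataset(n: int, params: SyntheticFundusParams | None = None,
                     seed: int | None = None):
    """Generate ``n`` images with per-image seeds derived from ``seed``
    (or from ``params.seed``).  Returns (images, masks, centers)."""
    params = params or SyntheticFundusParams()
    base_seed = params.seed if seed is None else seed
    images, masks, centers = [], [], []
    child_seeds = np.random.SeedSequence(base_seed).generate_state(n)
    for s in child_seeds:
        p = SyntheticFundusParams(**{**vars(params), "seed": int(s % (2 ** 31))})
        img, mask, center = generate_synthetic_fundus(p)
        images.append(img)
        masks.append(mask)
        centers.append(center)
    return images, masks, centers


@dataclass
class AugmentationSpec:
    """Disc-centred multi-size crops, random flips, full-circle rotation and
    a resize to the network input size."""

    crop_sizes: tuple = tuple(range(400, 901, 50))
    hflip: float = 0.5
    vflip: float = 0.5
    rotation_range: tuple = (0.0, 360.0)
    output_size: int = 512

    def __post_init__(self):
        if any(c <= 0 for c in self.crop_sizes):
            raise ValueError("crop sizes must be positive")
        lo, hi = self.rotation_range
        if not (0.0 <= lo <= hi <= 360.0):
            raise ValueError("rotation range must lie within [0, 360]")


def _centered_crop(arr, cx, cy, size, fill=0):
    """Crop a size x size window centred at (cx, cy), zero-padded."""
    half = size // 2
    out_shape = (size, size) + arr.shape[2:]
    out = np.full(out_shape, fill, dtype=arr.dtype)
    y0, x0 = int(round(cy)) - half, int(round(cx)) - half
    ys0, xs0 = max(y0, 0), max(x0, 0)
    ys1 = min(y0 + size, arr.shape[0])
    xs1 = min(x0 + size, arr.shape[1])
    if ys1 > ys0 and xs1 > xs0:
        out[ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0] = arr[ys0:ys1, xs0:xs1]
    return out


def augment(image, mask, spec: AugmentationSpec | None = None,
            rng_seed: int = 0):
    """One augmentation draw: sample a crop size, crop centred on the disc
    centroid, flip/rotate image and mask with identical geometry (bilinear
    for the image, nearest for the mask) and resize to ``output_size``."""
    spec = spec or AugmentationSpec()
    rng = np.random.default_rng(rng_seed)
    image = np.asarray(image)
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask >= 1)
    if ys.size == 0:
        raise ValueError("mask contains no disc pixels; cannot centre crop")
    cx, cy = xs.mean(), ys.mean()

    size = int(rng.choice(np.asarray(spec.crop_sizes)))
    img = _centered_crop(image, cx, cy, size)
    msk = _centered_crop(mask, cx, cy, size)
    if rng.random() < spec.hflip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < spec.vflip:
        img, msk = img[::-1], msk[::-1]
    angle = rng.uniform(*spec.rotation_range)
    if angle % 360.0 != 0.0:
        img = nd_rotate(img.astype(float), angle, reshape=False, order=1,
                        mode="constant", cval=0.0)
        msk = nd_rotate(msk, angle, reshape=False, order=0, mode="constant",
                        cval=0)
    out = spec.output_size
    if out != size:
        img = sk_resize(img.astype(float), (out, out), order=1,
                        preserve_range=True, anti_aliasing=True)
        msk = sk_resize(msk, (out, out), order=0, preserve_range=True,
                        anti_aliasing=False)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, np.ascontiguousarray(msk).astype(np.uint8)


# ---------------------------------------------------------------------------
# mask and dataset I/O
# ---------------------------------------------------------------------------

def write_mask(mask, path) -> None:
    """Write a {0,1,2} label mask as an 8-bit PNG with values 0/128/255."""
    arr = np.asarray(mask)
    bad = set(np.unique(arr)) - VALID_LABELS
    if bad:
        raise ValueError(f"mask contains labels outside {{0,1,2}}: "
                         f"{sorted(bad)}")
    encoded = np.zeros(arr.shape, dtype=np.uint8)
    for label, value in _MASK_ENCODING.items():
        encoded[arr == label] = value
    Image.fromarray(encoded, mode="L").save(path)


def read_mask(path) -> np.ndarray:
    """Read a mask PNG back to labels {0, 1, 2}; any other pixel value is a
    format error naming the offending values."""
    encoded = np.asarray(Image.open(path).convert("L"))
    values = set(int(v) for v in np.unique(encoded))
    bad = values - set(_MASK_DECODING)
    if bad:
        raise ValueError(f"mask file {path} contains unexpected pixel values "
                         f"{sorted(bad)}; expected 0 (background), 128 (disc)"
                         ", 255 (cup)")
    mask = np.zeros(encoded.shape, dtype=np.uint8)
    for value, label in _MASK_DECODING.items():
        mask[encoded == value] = label
    return mask


def save_dataset(images, masks, out_dir, stems=None) -> list:
    """Write images/<stem>.png and masks/<stem>.png; returns the stems."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    if stems is None:
        stems = [f"img_{i:04d}" for i in range(len(images))]
    for stem, img, mask in zip(stems, images, masks):
        Image.fromarray(np.asarray(img)).save(out_dir / "images" / f"{stem}.png")
        write_mask(mask, out_dir / "masks" / f"{stem}.png")
    return list(stems)


def load_dataset(data_dir):
    """Load matching images/*.png and masks/*.png; returns
    (stems, images, masks)."""
    data_dir = Path(data_dir)
    image_paths = sorted((data_dir / "images").glob("*.png"))
    if not image_paths:
        raise FileNotFoundError(f"no images under {data_dir}/images")
    stems, images, masks = [], [], []
    for p in image_paths:
        mask_path = data_dir / "masks" / p.name
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for {p.stem}")
        stems.append(p.stem)
        images.append(np.asarray(Image.open(p).convert("RGB")))
        masks.append(read_mask(mask_path))
    return stems, images, masks


def write_split(split: dict, path) -> None:
    """Plain-text manifest: one "<split> <stem>" line per image."""
    with open(path, "w") as fh:
        for name, stems in split.items():
            for stem in stems:
                fh.write(f"{name} {stem}\n")


def read_split(path) -> dict:
    split: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, stem = line.split()
                split.setdefault(name, []).append(stem)
    return split
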