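"""Synthetic retina phantoms with ground-truth lesion annotations.

Two modalities are emulated at desk scale:

* ``fundus`` — colour fundus photographs: a circular field of view with a
  radial background gradient, a bright optic disc, a dark branching vessel
  tree (per-subject identity), and grade-dependent lesions: dark
  microaneurysm dots, larger dark hemorrhage blobs and bright exudates.
  Five ordinal grades (healthy, mild, moderate, severe, proliferative)
  with lesion-count distributions that are monotone in severity.
* ``oct`` — OCT B-scans: horizontal retinal bands with smooth per-subject
  boundary curves.  Disease classes: drusen (bumpy RPE), DME (dark
  intraretinal cavities), CNV (subretinal membrane with RPE disruption).

The generator is fully deterministic given ``(seed, subject_id, grade,
instance)``; anatomy (vessel tree, disc position, band curves) depends only
on ``(seed, subject_id)`` so the same subject can be rendered at every
grade with an identical retinal "identity".

``lesion_oracle`` is a blob/dot detector (morphological top-hats and a
layer-trace for OCT) calibrated so that on generator output it recovers
the ground-truth lesion counts exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter
from scipy.signal import find_peaks
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import (black_tophat, dilation, disk, opening,
                                white_tophat)

FUNDUS_GRADES = ("healthy", "mild", "moderate", "severe", "proliferative")
OCT_CLASSES = ("normal", "CNV", "drusen", "DME")
LESION_TYPES = {
    "fundus": ("microaneurysm", "hemorrhage", "exudate"),
    "oct": ("drusen", "cavity", "cnv"),
}

# per-type count law (mean, min, max) and dot radius range at 32-px scale
_FUNDUS_COUNTS = {
    "healthy": {"microaneurysm": (0, 0, 0), "hemorrhage": (0, 0, 0), "exudate": (0, 0, 0)},
    "mild": {"microaneurysm": (1.5, 1, 2), "hemorrhage": (0, 0, 0), "exudate": (0, 0, 0)},
    "moderate": {"microaneurysm": (4.0, 3, 6), "hemorrhage": (1.5, 1, 3), "exudate": (0.8, 0, 2)},
    "severe": {"microaneurysm": (5.0, 3, 7), "hemorrhage": (2.5, 2, 4), "exudate": (1.5, 1, 3)},
    "proliferative": {"microaneurysm": (6.0, 4, 8), "hemorrhage": (3.5, 2, 5), "exudate": (2.0, 1, 3)},
}
_FUNDUS_RADII = {
    "microaneurysm": (0.9, 1.3),
    "hemorrhage": (1.9, 2.6),
    "exudate": (1.3, 1.9),
}
_OCT_COUNTS = {
    "normal": {"drusen": (0, 0, 0), "cavity": (0, 0, 0), "cnv": (0, 0, 0)},
    "CNV": {"drusen": (0, 0, 0), "cavity": (0, 0, 0), "cnv": (1, 1, 1)},
    "drusen": {"drusen": (3.5, 2, 5), "cavity": (0, 0, 0), "cnv": (0, 0, 0)},
    "DME": {"drusen": (0, 0, 0), "cavity": (2.0, 1, 3), "cnv": (0, 0, 0)},
}


@dataclass
class PhantomConfig:
    """Configuration of a single phantom image."""

    modality: str = "fundus"
    image_size: int = 64
    grade: str = "healthy"
    subject_id: int = 0
    instance: int = 0
    seed: int = 0
    vessel_branches: int = 5
    vessel_wiggle: float = 0.22
    lesion_counts_table: dict = field(default_factory=dict)  # overrides

    def __post_init__(self):
        if self.modality not in ("fundus", "oct"):
            raise ValueError(f"unknown modality {self.modality!r}")
        valid = FUNDUS_GRADES if self.modality == "fundus" else OCT_CLASSES
        if self.grade not in valid:
            raise ValueError(f"unknown grade {self.grade!r} for modality {self.modality!r}; "
                             f"expected one of {valid}")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")

    def count_law(self) -> dict:
        base = _FUNDUS_COUNTS if self.modality == "fundus" else _OCT_COUNTS
        law = {k: dict(v) for k, v in base.items()}
        for g, d in self.lesion_counts_table.items():
            law.setdefault(g, {}).update(d)
        return law


@dataclass
class LabeledImage:
    """A phantom image with its ground-truth annotations."""

    pixels: np.ndarray          # (C,H,W) float32 in [0,1]
    label: int
    grade: str
    modality: str
    lesion_masks: dict          # type -> (H,W) bool
    lesion_counts: dict         # type -> int
    subject_id: int
    meta: dict = field(default_factory=dict)

    @property
    def total_lesions(self) -> int:
        return int(sum(self.lesion_counts.values()))


@dataclass
class PhantomDataset:
    images: list
    splits: list                # aligned with images; "train" | "val" | "test"

    def subset(self, split: str) -> list:
        return [im for im, s in zip(self.images, self.splits) if s == split]

    def subjects(self, split: str) -> set:
        return {im.subject_id for im, s in zip(self.images, self.splits) if s == split}

    def class_counts(self, split: str | None = None) -> dict:
        counts: dict[int, int] = {}
        for im, s in zip(self.images, self.splits):
            if split is None or s == split:
                counts[im.label] = counts.get(im.label, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# helpers

def _draw_counts(rng: np.random.Generator, law: dict) -> dict:
    out = {}
    for typ, (mean, lo, hi) in law.items():
        if hi <= 0:
            out[typ] = 0
        else:
            c = lo + rng.poisson(max(mean - lo, 0.0))
            out[typ] = int(min(hi, c))
    return out


def _stamp(img: np.ndarray, mask: np.ndarray, cy: float, cx: float, r: float,
           color: tuple, alpha_max: float = 0.95) -> None:
    """Blend a Gaussian-profile dot into (C,H,W) image and set its mask."""
    h, w = img.shape[1:]
    core = 0.85 * r
    edge = 0.55
    y0, y1 = max(0, int(cy - 3 * r)), min(h, int(cy + 3 * r) + 1)
    x0, x1 = max(0, int(cx - 3 * r)), min(w, int(cx + 3 * r) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    a = alpha_max * np.exp(-np.maximum(d - core, 0.0) ** 2 / (2 * edge * edge))
    for c in range(img.shape[0]):
        img[c, y0:y1, x0:x1] = (1 - a) * img[c, y0:y1, x0:x1] + a * color[c]
    mask[y0:y1, x0:x1] |= a > 0.5 * alpha_max


# ---------------------------------------------------------------------------
# fundus

def _fundus_anatomy(cfg: PhantomConfig):
    """Vessel tree point cloud + disc position; identical for all grades of a
    subject under the same seed."""
    s = cfg.image_size
    rng = np.random.default_rng([cfg.seed, cfg.subject_id, 11])
    ctr = s / 2.0
    fov_r = 0.47 * s
    disc_ang = rng.uniform(0, 2 * math.pi)
    disc_d = 0.52 * fov_r
    disc = (ctr + disc_d * math.sin(disc_ang), ctr + disc_d * math.cos(disc_ang))
    disc_r = 0.17 * s / 2.0 * 2.0  # radius 0.17*s
    pts = []
    n_steps = int(2.2 * s)
    for b in range(cfg.vessel_branches):
        ang = math.atan2(ctr - disc[0], ctr - disc[1]) + rng.normal(0, 1.1) \
            + (b - cfg.vessel_branches / 2) * 0.9
        y, x = disc
        for _ in range(n_steps):
            ang += rng.normal(0.0, cfg.vessel_wiggle)
            y += 0.5 * math.sin(ang)
            x += 0.5 * math.cos(ang)
            if (y - ctr) ** 2 + (x - ctr) ** 2 > (0.93 * fov_r) ** 2:
                break
            pts.append((y, x))
    tint = rng.uniform(-0.03, 0.03, size=3)
    return disc, disc_r, np.array(pts) if pts else np.zeros((0, 2)), tint, fov_r


def generate_fundus_phantom(config: PhantomConfig) -> LabeledImage:
    if config.modality != "fundus":
        raise ValueError("config.modality must be 'fundus'")
    s = config.image_size
    scale = s / 32.0
    disc, disc_r, vessel_pts, tint, fov_r = _fundus_anatomy(config)
    ctr = s / 2.0

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    rad = np.sqrt((yy - ctr) ** 2 + (xx - ctr) ** 2)
    fov = rad <= fov_r
    fall = 1.0 - 0.25 * (rad / fov_r) ** 2
    base = np.array([0.72, 0.42, 0.13], dtype=np.float32) + tint.astype(np.float32)
    img = np.zeros((3, s, s), dtype=np.float32)
    for c in range(3):
        img[c] = base[c] * fall * fov

    # vessels (drawn first; the disc is painted on top so it stays a clean
    # bright blob and vessels appear to emerge from its rim)
    vmask = np.zeros((s, s), dtype=bool)
    vw = max(1, int(round(0.8 * scale)))
    for (py, px) in vessel_pts:
        iy, ix = int(round(py)), int(round(px))
        vmask[max(0, iy - vw + 1):iy + vw, max(0, ix - vw + 1):ix + vw] = True
    vmask &= fov
    vcol = (0.38, 0.13, 0.10)
    for c in range(3):
        img[c][vmask] = 0.25 * img[c][vmask] + 0.75 * vcol[c]

    # optic disc
    dd = np.sqrt((yy - disc[0]) ** 2 + (xx - disc[1]) ** 2)
    da = np.clip(1.0 - (dd / disc_r) ** 4, 0, 1) * fov
    disc_col = (0.95, 0.82, 0.45)
    for c in range(3):
        img[c] = (1 - da) * img[c] + da * disc_col[c]

    # lesions
    law = config.count_law()[config.grade]
    rng = np.random.default_rng([config.seed, config.subject_id,
                                 FUNDUS_GRADES.index(config.grade), config.instance, 7])
    want = _draw_counts(rng, law)
    masks = {t: np.zeros((s, s), dtype=bool) for t in LESION_TYPES["fundus"]}
    counts = {t: 0 for t in LESION_TYPES["fundus"]}
    placed: list[tuple[float, float, float]] = []
    colors = {"microaneurysm": (0.26, 0.045, 0.03),
              "hemorrhage": (0.28, 0.05, 0.035),
              "exudate": (0.97, 0.92, 0.45)}
    rmul = 1.0
    for typ in LESION_TYPES["fundus"]:
        lo_r, hi_r = _FUNDUS_RADII[typ]
        for _ in range(want[typ]):
            r0 = rng.uniform(lo_r, hi_r) * scale * (rmul if typ == "hemorrhage" else 1.0)
            ok = False
            for _try in range(600):
                r = r0 if _try < 300 else max(lo_r * scale, 0.8 * r0)
                u = math.sqrt(rng.uniform()) * (0.86 * fov_r - r - 1)
                th = rng.uniform(0, 2 * math.pi)
                cy, cx = ctr + u * math.sin(th), ctr + u * math.cos(th)
                if math.hypot(cy - disc[0], cx - disc[1]) < disc_r + r + 1.5 * scale:
                    continue
                if len(vessel_pts) and np.min((vessel_pts[:, 0] - cy) ** 2
                                              + (vessel_pts[:, 1] - cx) ** 2) < (r + 1.2 * scale) ** 2:
                    continue
                if any(math.hypot(cy - py, cx - px) < r + pr + 2.4 * scale for py, px, pr in placed):
                    continue
                ok = True
                break
            if not ok:
                continue
            _stamp(img, masks[typ], cy, cx, r, colors[typ])
            placed.append((cy, cx, r))
            counts[typ] += 1

    np.clip(img, 0.0, 1.0, out=img)
    return LabeledImage(pixels=img, label=FUNDUS_GRADES.index(config.grade),
                        grade=config.grade, modality="fundus", lesion_masks=masks,
                        lesion_counts=counts, subject_id=config.subject_id,
                        meta={"disc": disc, "fov_radius": fov_r})


# ---------------------------------------------------------------------------
# OCT

def _oct_boundaries(cfg: PhantomConfig, s: int):
    """Smooth per-subject layer boundary curves (row index per column)."""
    rng = np.random.default_rng([cfg.seed, cfg.subject_id, 23])
    x = np.arange(s, dtype=np.float32)
    fracs = (0.22, 0.38, 0.55, 0.70, 0.76)
    curves = []
    for i, f in enumerate(fracs):
        c = np.full(s, f * s, dtype=np.float32)
        for k in (1, 2, 3):
            amp = 0.010 * s * rng.uniform(0.3, 1.0) / k
            c += amp * np.sin(2 * math.pi * k * x / s + rng.uniform(0, 2 * math.pi))
        curves.append(c)
    return curves


def generate_oct_phantom(config: PhantomConfig) -> LabeledImage:
    if config.modality != "oct":
        raise ValueError("config.modality must be 'oct'")
    s = config.image_size
    scale = s / 32.0
    curves = _oct_boundaries(config, s)
    b0, b1, b2, b3, b4 = [c.copy() for c in curves]
    law = config.count_law()[config.grade]
    rng = np.random.default_rng([config.seed, config.subject_id,
                                 OCT_CLASSES.index(config.grade), config.instance, 7])
    want = _draw_counts(rng, law)
    masks = {t: np.zeros((s, s), dtype=bool) for t in LESION_TYPES["oct"]}
    counts = {t: 0 for t in LESION_TYPES["oct"]}

    # drusen: Gaussian bumps lifting the RPE top boundary
    x = np.arange(s, dtype=np.float32)
    bump_total = np.zeros(s, dtype=np.float32)
    centers: list[float] = []
    for _ in range(want["drusen"]):
        for _try in range(200):
            cx = rng.uniform(0.17 * s, 0.83 * s)
            if all(abs(cx - c) > 9.0 * scale for c in centers):
                break
        else:
            continue
        h = rng.uniform(3.0, 4.0) * scale
        sig = rng.uniform(1.1, 1.5) * scale
        bump = h * np.exp(-((x - cx) ** 2) / (2 * sig * sig))
        bump_total += bump
        centers.append(cx)
        counts["drusen"] += 1
    b3 = b3 - bump_total

    yy = np.arange(s, dtype=np.float32)[:, None]
    img2 = np.select(
        [yy < b0[None, :], yy < b1[None, :], yy < b2[None, :],
         yy < b3[None, :], yy < b4[None, :]],
        [0.05, 0.55, 0.35, 0.58, 0.92], default=0.15).astype(np.float32)
    for c in centers:  # drusen mask: lifted RPE region
        lift = bump_total > 0.8
        band = (yy >= b3[None, :]) & (yy < curves[3][None, :])
        masks["drusen"] |= band & lift[None, :]

    img = gaussian_filter(img2, 0.6)[None, :, :].astype(np.float32)

    # DME cavities: dark ellipses in the inner retina
    cav_placed: list[tuple[float, float, float]] = []
    for _ in range(want["cavity"]):
        ok = False
        for _try in range(200):
            cx = rng.uniform(0.15 * s, 0.85 * s)
            cy = (b1[int(cx)] + b2[int(cx)]) / 2 + rng.uniform(-1, 1) * scale
            r = rng.uniform(2.0, 2.9) * scale
            if all(math.hypot(cy - py, cx - px) > r + pr + 2.5 for py, px, pr in cav_placed):
                ok = True
                break
        if not ok:
            continue
        _stamp(img, masks["cavity"], cy, cx, r, (0.06,))
        cav_placed.append((cy, cx, r))
        counts["cavity"] += 1

    # CNV: bright subretinal membrane below a disrupted RPE; the RPE gap is
    # wider than the membrane so the two bright structures never touch
    for _ in range(want["cnv"]):
        cx = rng.uniform(0.25 * s, 0.75 * s)
        cy = b4[int(cx)] + 3.6 * scale
        r = rng.uniform(2.8, 3.4) * scale
        gap = np.abs(x - cx) < 3.0 * scale
        band = (yy >= b3[None, :] - 0.5) & (yy < b4[None, :] + 0.5) & gap[None, :]
        img[0][band] = 0.35
        _stamp(img, masks["cnv"], cy, cx, r, (0.70,))
        counts["cnv"] += 1

    np.clip(img, 0.0, 1.0, out=img)
    return LabeledImage(pixels=img, label=OCT_CLASSES.index(config.grade),
                        grade=config.grade, modality="oct", lesion_masks=masks,
                        lesion_counts=counts, subject_id=config.subject_id,
                        meta={"boundaries": [b0, b1, b2, b3, b4],
                              "boundaries_base": curves})


def generate_phantom(config: PhantomConfig) -> LabeledImage:
    if config.modality == "fundus":
        return generate_fundus_phantom(config)
    return generate_oct_phantom(config)


# ---------------------------------------------------------------------------
# datasets

def generate_dataset(n_per_class: int, images_per_subject: int = 1,
                     split_fractions=(0.75, 0.15, 0.10), seed: int = 0,
                     modality: str = "fundus", image_size: int = 64,
                     classes=None) -> PhantomDataset:
    """Subject-wise split phantom dataset with ``n_per_class`` images per class."""
    if abs(sum(split_fractions) - 1.0) > 1e-8:
        raise ValueError("split fractions must sum to 1")
    classes = tuple(classes) if classes is not None else (
        FUNDUS_GRADES if modality == "fundus" else OCT_CLASSES)
    rng = np.random.default_rng([seed, 1234])
    images, splits = [], []
    for ci, grade in enumerate(classes):
        n_subj = math.ceil(n_per_class / images_per_subject)
        subj_ids = [ci * 100000 + i for i in range(n_subj)]
        perm = rng.permutation(n_subj)
        n_tr = int(round(split_fractions[0] * n_subj))
        n_va = int(round(split_fractions[1] * n_subj))
        assign = {}
        for j, pi in enumerate(perm):
            assign[subj_ids[pi]] = ("train" if j < n_tr else
                                    "val" if j < n_tr + n_va else "test")
        made = 0
        for sid in subj_ids:
            for inst in range(images_per_subject):
                if made >= n_per_class:
                    break
                cfg = PhantomConfig(modality=modality, image_size=image_size,
                                    grade=grade, subject_id=sid, instance=inst,
                                    seed=seed)
                images.append(generate_phantom(cfg))
                splits.append(assign[sid])
                made += 1
    return PhantomDataset(images=images, splits=splits)


def balance_by_oversampling(dataset: PhantomDataset) -> PhantomDataset:
    """Equalize train-split class sizes by cyclically repeating entries;
    val/test are untouched."""
    by_class: dict[int, list] = {}
    rest_images, rest_splits = [], []
    for im, s in zip(dataset.images, dataset.splits):
        if s == "train":
            by_class.setdefault(im.label, []).append(im)
        else:
            rest_images.append(im)
            rest_splits.append(s)
    if not by_class:
        return PhantomDataset(images=list(dataset.images), splits=list(dataset.splits))
    target = max(len(v) for v in by_class.values())
    images, splits = [], []
    for lab in sorted(by_class):
        group = by_class[lab]
        for i in range(target):
            images.append(group[i % len(group)])
            splits.append("train")
    images += rest_images
    splits += rest_splits
    return PhantomDataset(images=images, splits=splits)


# ---------------------------------------------------------------------------
# lesion oracle

@dataclass
class OracleConfig:
    """Detection thresholds, calibrated on the generator output."""

    dark_contrast: float = 0.24
    bright_contrast: float = 0.34
    dark_core_level: float = 0.15   # a dark blob must reach below this
    bright_core_level: float = 0.65  # a bright blob must reach above this
    dark_min_area: float = 2.0
    split_area: float = 9.5        # microaneurysm vs hemorrhage
    dark_max_area: float = 60.0
    bright_min_area: float = 3.0
    bright_max_area: float = 40.0
    max_elongation: float = 2.6
    selem_radius: int = 4
    # oct
    oct_bump_lo: float = 0.9
    oct_bump_hi: float = 10.0
    oct_cav_contrast: float = 0.33
    oct_cav_core: float = 0.16
    oct_cav_min_area: float = 4.0
    oct_cav_max_area: float = 70.0
    oct_cnv_level: float = 0.58
    oct_cnv_min_area: float = 6.0


def _blob_components(resp: np.ndarray, thresh: float, min_area: float,
                     max_area: float, max_elong: float, region: np.ndarray,
                     intensity: np.ndarray | None = None,
                     core_below: float | None = None,
                     core_above: float | None = None):
    """Connected components of a top-hat response passing size/shape checks.

    ``core_below``/``core_above`` additionally require the component to
    contain at least one genuinely dark (resp. bright) pixel, which rejects
    top-hat halos cast by neighbouring structures of opposite polarity.
    """
    lab = cc_label((resp > thresh) & region, connectivity=2)
    keep = []
    for p in regionprops(lab):
        if not (min_area <= p.area <= max_area):
            continue
        if p.axis_minor_length > 1e-6 and \
                p.axis_major_length / p.axis_minor_length > max_elong:
            continue
        if intensity is not None:
            vals = intensity[tuple(p.coords.T)]
            if core_below is not None and vals.min() > core_below:
                continue
            if core_above is not None and vals.max() < core_above:
                continue
        keep.append(p)
    return keep


def lesion_oracle(pixels: np.ndarray, modality: str,
                  config: OracleConfig | None = None) -> dict:
    """Count lesions per type from pixels alone.

    Calibrated to reproduce the generator's ground truth exactly on phantom
    output; on arbitrary images it counts compact connected components that
    pass fixed size/contrast/shape thresholds.
    """
    cfg = config or OracleConfig()
    pixels = np.asarray(pixels, dtype=np.float32)
    if modality == "fundus":
        if pixels.ndim != 3 or pixels.shape[0] != 3:
            raise ValueError("fundus oracle expects (3,H,W) pixels")
        g = pixels[1]
        s = g.shape[0]
        scale = s / 32.0
        yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
        ctr, fov_r = s / 2.0, 0.47 * s
        region = np.sqrt((yy - ctr) ** 2 + (xx - ctr) ** 2) < 0.88 * fov_r
        se = disk(max(3, int(round(cfg.selem_radius * scale))))
        a2 = scale * scale
        # the optic disc is the one large bright structure that survives a
        # grey opening; exclude a dilated neighbourhood of it
        disc_mask = opening(g, se) > 0.60
        disc_mask = dilation(disc_mask, disk(max(2, int(2 * scale))))
        region &= ~disc_mask
        dark = black_tophat(g, se)
        bright = white_tophat(g, se)
        dark_props = _blob_components(dark, cfg.dark_contrast, cfg.dark_min_area * a2,
                                      cfg.dark_max_area * a2, cfg.max_elongation, region,
                                      intensity=g, core_below=cfg.dark_core_level)
        ma = sum(1 for p in dark_props if p.area <= cfg.split_area * a2)
        hem = len(dark_props) - ma
        ex = len(_blob_components(bright, cfg.bright_contrast, cfg.bright_min_area * a2,
                                  cfg.bright_max_area * a2, cfg.max_elongation, region,
                                  intensity=g, core_above=cfg.bright_core_level))
        return {"microaneurysm": ma, "hemorrhage": hem, "exudate": ex}

    if modality == "oct":
        if pixels.ndim != 3 or pixels.shape[0] != 1:
            raise ValueError("oct oracle expects (1,H,W) pixels")
        img = pixels[0]
        s = img.shape[0]
        scale = s / 32.0
        # RPE trace: first row from the top brighter than the RPE level
        bright_cols = (img > 0.75).any(axis=0)
        rpe = np.argmax(img > 0.75, axis=0).astype(np.float32)
        cols = np.arange(s)
        if bright_cols.any() and not bright_cols.all():
            # columns with a disrupted RPE: interpolate across neighbours
            rpe[~bright_cols] = np.interp(cols[~bright_cols], cols[bright_cols],
                                          rpe[bright_cols])
        elif not bright_cols.any():
            rpe[:] = s - 1.0
        baseline = median_filter(rpe, size=max(9, int(9 * scale)), mode="nearest")
        lift = baseline - rpe  # positive = elevated RPE
        lift_s = gaussian_filter(lift, 1.0 * scale)
        peaks, _ = find_peaks(lift_s, height=(cfg.oct_bump_lo * scale,
                                              cfg.oct_bump_hi * scale),
                              distance=4 * scale, prominence=0.7 * scale)
        drusen = int(len(peaks))
        # cavities: dark compact blobs above the RPE, below the vitreous
        se = disk(max(3, int(round(cfg.selem_radius * scale))))
        darkresp = black_tophat(img, se)
        yy = np.arange(s, dtype=np.float32)[:, None]
        inner = (yy > 0.26 * s) & (yy < rpe[None, :] - 2 * scale)
        cav = len(_blob_components(darkresp, cfg.oct_cav_contrast,
                                   cfg.oct_cav_min_area * scale * scale,
                                   cfg.oct_cav_max_area * scale * scale,
                                   cfg.max_elongation, inner,
                                   intensity=img, core_below=cfg.oct_cav_core))
        # CNV membrane: a compact bright component whose centroid lies well
        # below the RPE baseline (the RPE band itself is elongated; the inner
        # bands are dimmer than the level threshold)
        lab = cc_label(img > cfg.oct_cnv_level, connectivity=2)
        cnv = 0
        for p in regionprops(lab):
            if p.area < cfg.oct_cnv_min_area * scale * scale:
                continue
            if p.axis_minor_length > 1e-6 and \
                    p.axis_major_length / p.axis_minor_length > 3.0:
                continue
            cy, cx = p.centroid
            if cy > baseline[int(round(cx))] + 3.5 * scale:
                cnv += 1
        return {"drusen": drusen, "cavity": cav, "cnv": int(cnv)}

    raise ValueError(f"unknown modality {modality!r}")
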