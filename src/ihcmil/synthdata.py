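"""Synthetic IHC-like slides with ground-truth TPS/CPS and linked clinical tables.

Emulates the appearance that matters for a PD-L1 pipeline without attempting
photorealism: tumor cells are rendered as large textured discs whose membrane
rings carry DAB-brown chromogen on a controllable fraction (the tumor
proportion score, TPS); immune aggregates are dense small hematoxylin-blue
dots, an independent fraction of which also stain brown (the CPS confound);
background is near-white; a fraction of tissue regions is Gaussian-blurred to
simulate focus artifacts.  Every generator is a pure function of its spec and
seed.

Three generators are provided:

* :func:`generate_slide` — one slide plus pixel-accurate ground-truth masks;
* :func:`generate_cohort` — a cohort of slide specs with a clinical table
  (TPS/CPS, tumor type, PFS with a planted hazard ratio, best response);
* :func:`generate_feature_bags` — a fast Gaussian MIL benchmark that bypasses
  imaging entirely for testing the bag classifier in isolation.

Survival times are exponential (constant hazard per group), so planted
hazard ratios translate into closed-form median ratios, and censoring times
are exponential with the rate chosen so the requested censoring probability
holds exactly and independently of the event process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SyntheticSlideSpec",
    "GroundTruth",
    "SyntheticCohort",
    "MILBags",
    "generate_slide",
    "generate_cohort",
    "generate_feature_bags",
]

# Rendering palette (8-bit RGB).  Only the stain contrast matters: DAB brown
# has red > blue, hematoxylin blue has blue > red.
DAB_RGB = np.array([140, 90, 40], dtype=float)
HEMATOXYLIN_RGB = np.array([60, 60, 140], dtype=float)
CYTOPLASM_RGB = np.array([225, 218, 228], dtype=float)
NEG_MEMBRANE_RGB = np.array([185, 180, 205], dtype=float)
STROMA_RGB = np.array([235, 210, 218], dtype=float)
BACKGROUND = 248.0


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic slide; identical spec + seed => identical image."""

    slide_id: str
    width_px: int
    height_px: int
    mpp: float = 0.46
    true_tps: float = 0.0
    true_cps_extra: float = 0.0
    tumor_fraction: float = 0.5
    immune_fraction: float = 0.2
    blank_fraction: float = 0.1
    blur_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        for name in ("true_tps", "true_cps_extra", "tumor_fraction",
                     "immune_fraction", "blank_fraction", "blur_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tumor_fraction + self.immune_fraction > 1.0 + 1e-12:
            raise ValueError("tumor_fraction + immune_fraction must be <= 1")


@dataclass
class GroundTruth:
    """Pixel masks and realized scores for one rendered slide."""

    tumor_mask: np.ndarray          # bool, pixels belonging to tumor cells
    immune_mask: np.ndarray         # bool, pixels belonging to immune cells
    positive_cell_mask: np.ndarray  # bool, pixels of DAB-positive cells
    n_tumor_cells: int
    n_positive_tumor_cells: int
    n_immune_cells: int
    n_positive_immune_cells: int
    no_tumor: bool = False

    @property
    def realized_tps(self) -> float:
        if self.n_tumor_cells == 0:
            return 0.0
        return self.n_positive_tumor_cells / self.n_tumor_cells

    @property
    def realized_cps(self) -> float:
        if self.n_tumor_cells == 0:
            return 0.0
        return (self.n_positive_tumor_cells + self.n_positive_immune_cells) / self.n_tumor_cells


def _draw_disc(img, masks, r0, c0, radius, fill, ring=None, ring_width=2):
    """Paint a disc (optionally with a membrane ring) into img; update masks."""
    h, w = img.shape[:2]
    rr0, rr1 = max(0, r0 - radius), min(h, r0 + radius + 1)
    cc0, cc1 = max(0, c0 - radius), min(w, c0 + radius + 1)
    if rr0 >= rr1 or cc0 >= cc1:
        return None
    yy, xx = np.ogrid[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0]
    d2 = yy * yy + xx * xx
    disc = d2 <= radius * radius
    patch = img[rr0:rr1, cc0:cc1]
    patch[disc] = fill
    if ring is not None:
        inner = (radius - ring_width) ** 2
        ring_px = disc & (d2 > inner)
        patch[ring_px] = ring
    for m in masks:
        m[rr0:rr1, cc0:cc1][disc] = True
    return disc


def generate_slide(spec: SyntheticSlideSpec):
    """Render one synthetic IHC slide and its ground truth.

    The slide is partitioned into tile-sized (224 px) blocks assigned to
    blank / tumor / immune / stroma compartments in the spec's proportions;
    cells are then drawn per block.  Positive-cell assignment is i.i.d.
    Bernoulli(true_tps) over tumor cells, so the realized TPS is a binomial
    statistic around the requested one.

    Returns ``(slide, ground_truth)`` where ``slide`` is a
    :class:`~ihcmil.wsi_prep.SlideImage`.
    """
    from .wsi_prep import SlideImage  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    img = np.full((h, w, 3), BACKGROUND, dtype=float)
    img += rng.normal(0.0, 1.0, size=(h, w, 3))

    tumor_mask = np.zeros((h, w), dtype=bool)
    immune_mask = np.zeros((h, w), dtype=bool)
    positive_mask = np.zeros((h, w), dtype=bool)

    block = 224
    nbr, nbc = max(1, h // block), max(1, w // block)
    blocks = [(i, j) for i in range(nbr) for j in range(nbc)]
    rng.shuffle(blocks)
    nb = len(blocks)
    n_blank = int(round(spec.blank_fraction * nb))
    tissue = blocks[n_blank:]
    nt = len(tissue)
    n_tumor = int(round(spec.tumor_fraction * nt))
    n_immune = int(round(spec.immune_fraction * nt))
    tumor_blocks = tissue[:n_tumor]
    immune_blocks = tissue[n_tumor:n_tumor + n_immune]
    stroma_blocks = tissue[n_tumor + n_immune:]

    counts = dict(tumor=0, tumor_pos=0, immune=0, immune_pos=0)

    def jitter(color):
        return np.clip(color * (1.0 + rng.uniform(-0.1, 0.1, size=3)), 0, 255)

    for (bi, bj) in tumor_blocks:
        r_off, c_off = bi * block, bj * block
        bh = min(block, h - r_off)
        bw = min(block, w - c_off)
        n_cells = max(1, int(30 * (bh * bw) / (block * block)))
        for _ in range(n_cells):
            radius = int(rng.integers(4, 9))
            r0 = r_off + int(rng.integers(radius, max(radius + 1, bh - radius)))
            c0 = c_off + int(rng.integers(radius, max(radius + 1, bw - radius)))
            positive = rng.random() < spec.true_tps
            ring = jitter(DAB_RGB) if positive else jitter(NEG_MEMBRANE_RGB)
            masks = [tumor_mask] + ([positive_mask] if positive else [])
            _draw_disc(img, masks, r0, c0, radius, jitter(CYTOPLASM_RGB),
                       ring=ring, ring_width=2)
            # nucleus
            _draw_disc(img, [], r0, c0, max(1, radius // 3), jitter(HEMATOXYLIN_RGB))
            counts["tumor"] += 1
            counts["tumor_pos"] += int(positive)

    for (bi, bj) in immune_blocks:
        r_off, c_off = bi * block, bj * block
        bh = min(block, h - r_off)
        bw = min(block, w - c_off)
        n_cells = max(1, int(200 * (bh * bw) / (block * block)))
        for _ in range(n_cells):
            radius = int(rng.integers(2, 4))
            r0 = r_off + int(rng.integers(0, bh))
            c0 = c_off + int(rng.integers(0, bw))
            positive = rng.random() < spec.true_cps_extra
            color = jitter(DAB_RGB) if positive else jitter(HEMATOXYLIN_RGB)
            masks = [immune_mask] + ([positive_mask] if positive else [])
            _draw_disc(img, masks, r0, c0, radius, color)
            counts["immune"] += 1
            counts["immune_pos"] += int(positive)

    for (bi, bj) in stroma_blocks:
        r_off, c_off = bi * block, bj * block
        bh = min(block, h - r_off)
        bw = min(block, w - c_off)
        # fibrous texture: short dark strands on a pale pink field
        img[r_off:r_off + bh, c_off:c_off + bw] = (
            STROMA_RGB + rng.normal(0, 3, size=(bh, bw, 3)))
        n_fibers = int(60 * (bh * bw) / (block * block))
        for _ in range(n_fibers):
            rr = int(rng.integers(0, bh))
            cc = int(rng.integers(0, max(1, bw - 40)))
            length = int(rng.integers(15, 40))
            thick = int(rng.integers(1, 3))
            shade = rng.uniform(0.55, 0.8)
            img[r_off + rr:r_off + rr + thick,
                c_off + cc:c_off + cc + min(length, bw - cc)] *= shade

    # blur a fraction of tissue blocks to emulate out-of-focus regions
    n_blur = int(round(spec.blur_fraction * nt))
    for (bi, bj) in tissue[:n_blur]:
        r_off, c_off = bi * block, bj * block
        bh = min(block, h - r_off)
        bw = min(block, w - c_off)
        for ch in range(3):
            img[r_off:r_off + bh, c_off:c_off + bw, ch] = gaussian_filter(
                img[r_off:r_off + bh, c_off:c_off + bw, ch], sigma=6.0)

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    slide = SlideImage(pixels=pixels, mpp=spec.mpp, slide_id=spec.slide_id)
    gt = GroundTruth(
        tumor_mask=tumor_mask,
        immune_mask=immune_mask,
        positive_cell_mask=positive_mask,
        n_tumor_cells=counts["tumor"],
        n_positive_tumor_cells=counts["tumor_pos"],
        n_immune_cells=counts["immune"],
        n_positive_immune_cells=counts["immune_pos"],
        no_tumor=counts["tumor"] == 0,
    )
    return slide, gt


TUMOR_TYPES = ("NSCLC", "melanoma", "gastrointestinal", "head_and_neck", "other")

CLINICAL_COLUMNS = ["patient_id", "slide_id", "tumor_type", "tps", "cps",
                    "pfs_months", "event", "best_response", "is_baseline"]


@dataclass
class SyntheticCohort:
    """A simulated cohort: slide specs, high/low labels, and a clinical table."""

    slide_specs: list
    labels: np.ndarray                 # 1 = PD-L1 high (TPS >= 1%), per slide
    clinical: pd.DataFrame             # CLINICAL_COLUMNS schema

    def iter_slides(self) -> Iterator[tuple]:
        """Yield (SlideImage, GroundTruth, label) per slide, rendering lazily."""
        for spec, lab in zip(self.slide_specs, self.labels):
            slide, gt = generate_slide(spec)
            yield slide, gt, int(lab)

    def write(self, out_dir) -> None:
        """Write slides as PNG and the clinical table as CSV."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for slide, _, _ in self.iter_slides():
            iio.imwrite(out / f"{slide.slide_id}.png", slide.pixels)
        self.clinical.to_csv(out / "clinical.csv", index=False)


def generate_cohort(n_slides: int,
                    class_balance: float = 0.5,
                    tps_range_high=(0.05, 0.60),
                    tps_range_low=(0.0, 0.005),
                    hazard_ratio: float = 1.5,
                    median_pfs_low: float = 2.7,
                    censor_rate: float = 0.2,
                    seed: int = 0,
                    *,
                    n_patients: int | None = None,
                    slide_px: int = 1344,
                    mpp: float = 256 / 224,
                    blur_fraction: float = 0.05,
                    cps_extra_range=(0.0, 0.30),
                    response_rate_high: float = 0.30,
                    response_rate_low: float = 0.15) -> SyntheticCohort:
    """Simulate a cohort of slides with linked clinical outcomes.

    Labels are exactly balanced by construction: ``round(class_balance *
    n_slides)`` slides are PD-L1 high with TPS drawn from ``tps_range_high``,
    the rest low from ``tps_range_low``.  PFS is exponential with hazard
    ``log(2)/median_pfs_low`` in the low group and that divided by
    ``hazard_ratio`` in the high group, so the high-group median is
    ``median_pfs_low * hazard_ratio``.  Censoring is exponential with rate
    chosen per group so the censoring probability equals ``censor_rate``
    exactly while remaining independent of the event time.

    If ``n_patients`` is smaller than ``n_slides``, the surplus slides are
    assigned as additional (non-baseline) biopsies of randomly chosen
    patients, mirroring cohorts where some patients contribute more than one
    slide; exactly one slide per patient carries ``is_baseline=True``.
    """
    if n_slides < 2:
        raise ValueError("n_slides must be >= 2")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must be in (0, 1)")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    if n_patients is None:
        n_patients = n_slides
    if n_patients > n_slides:
        raise ValueError("n_patients cannot exceed n_slides")

    rng = np.random.default_rng(seed)
    n_high = int(round(class_balance * n_patients))
    patient_labels = np.zeros(n_patients, dtype=int)
    patient_labels[:n_high] = 1
    rng.shuffle(patient_labels)

    lam_low = np.log(2.0) / median_pfs_low
    lam_high = lam_low / hazard_ratio

    rows = []
    slide_specs = []
    slide_labels = []
    extra = n_slides - n_patients
    extra_owner = rng.choice(n_patients, size=extra, replace=False) if extra else []
    extra_per_patient = np.bincount(extra_owner, minlength=n_patients)

    slide_counter = 0
    for p in range(n_patients):
        lab = int(patient_labels[p])
        lo, hi = (tps_range_high if lab else tps_range_low)
        tps = float(rng.uniform(lo, hi))
        cps_extra = float(rng.uniform(*cps_extra_range))
        cps = min(1.0, tps + cps_extra)
        tumor_type = TUMOR_TYPES[int(rng.integers(0, len(TUMOR_TYPES)))]

        lam = lam_high if lab else lam_low
        t_event = rng.exponential(1.0 / lam)
        if censor_rate > 0:
            mu = lam * censor_rate / (1.0 - censor_rate)
            t_cens = rng.exponential(1.0 / mu)
        else:
            t_cens = np.inf
        pfs = max(1e-3, min(t_event, t_cens))
        event = int(t_event <= t_cens)
        resp_p = response_rate_high if lab else response_rate_low
        responder = rng.random() < resp_p
        best_response = ("CR" if rng.random() < 0.25 else "PR") if responder \
            else ("SD" if rng.random() < 0.5 else "PD")

        n_slides_p = 1 + int(extra_per_patient[p])
        for s in range(n_slides_p):
            sid = f"S{slide_counter:04d}"
            slide_counter += 1
            spec = SyntheticSlideSpec(
                slide_id=sid, width_px=slide_px, height_px=slide_px, mpp=mpp,
                true_tps=tps, true_cps_extra=cps_extra,
                tumor_fraction=0.45, immune_fraction=0.2,
                blank_fraction=0.15, blur_fraction=blur_fraction,
                seed=int(rng.integers(0, 2**31 - 1)))
            slide_specs.append(spec)
            slide_labels.append(lab)
            rows.append(dict(patient_id=f"P{p:04d}", slide_id=sid,
                             tumor_type=tumor_type, tps=tps, cps=cps,
                             pfs_months=pfs, event=event,
                             best_response=best_response,
                             is_baseline=(s == 0)))

    clinical = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    return SyntheticCohort(slide_specs=slide_specs,
                           labels=np.asarray(slide_labels),
                           clinical=clinical)


@dataclass
class MILBags:
    """A Gaussian multiple-instance benchmark: bags, bag labels, instance labels."""

    bags: list                      # each bag_size x dim float array
    labels: np.ndarray              # bag labels, 1 = positive
    instance_labels: list           # per-bag boolean arrays, True = signal instance


def generate_feature_bags(n_bags: int, bag_size: int = 50, dim: int = 64,
                          positive_instance_fraction: float = 0.1,
                          separation: float = 6.0, seed: int = 0) -> MILBags:
    """Two-Gaussian MIL benchmark.

    Background instances are N(0, I); signal instances are shifted by
    ``separation`` along axis 0.  Positive bags carry
    ``max(1, Binomial(bag_size, positive_instance_fraction))`` signal
    instances; negative bags carry none.  Bag labels are balanced.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not 0.0 < positive_instance_fraction <= 1.0:
        raise ValueError("positive_instance_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if n_bags == 0:
        return MILBags(bags=[], labels=np.zeros(0, dtype=int), instance_labels=[])

    labels = np.zeros(n_bags, dtype=int)
    labels[: n_bags // 2] = 1
    rng.shuffle(labels)

    bags = []
    inst_labels = []
    for lab in labels:
        x = rng.normal(size=(bag_size, dim))
        mask = np.zeros(bag_size, dtype=bool)
        if lab == 1:
            n_pos = max(1, rng.binomial(bag_size, positive_instance_fraction))
            idx = rng.choice(bag_size, size=min(n_pos, bag_size), replace=False)
            mask[idx] = True
            x[mask, 0] += separation
        bags.append(x.astype(np.float32))
        inst_labels.append(mask)
    return MILBags(bags=bags, labels=labels, instance_labels=inst_labels)
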