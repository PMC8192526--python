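"""Synthetic smear-evidence and tile-image generators.

Real slide corpora for this problem are proprietary clinical data.  The
generators here emulate the *statistical shape* of that evidence so every
downstream stage (feature aggregation, decision engine, QC gate) is
trainable and testable at desk scale:

* :func:`simulate_slide` draws a per-target record stream for a slide
  with a chosen TBS ground truth.  Lesion slides plant counts of their
  characteristic annotation classes (Poisson) with high classifier
  probabilities (Beta); every slide carries normal-cell background and,
  optionally, low-probability false-positive detections.  Nucleus
  morphometry and patch true/false evidence are attached exactly where
  the pipeline expects them (SC/ASC_L_S/ASC_H_S, squamous classes).
* :func:`simulate_tile` renders a cartoon smear tile — dark nuclei +
  pale cytoplasm blobs on a bright-field background — with controllable
  defocus blur, stain contrast, and planted cell coverage, under four
  quality presets (qualified / defocus / low-cellularity / poor-stain).
* :func:`make_corpus` builds a stratified labelled corpus with a
  manifest sufficient for byte-identical regeneration.

All randomness flows from one integer seed through per-item
``numpy.random.SeedSequence`` spawning, so corpora are reproducible
piecewise.  Class mixes mirror clinical screening reality: mostly
negative, common squamous lesions, rare glandular/endometrial findings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .records import BoundingBox, NucleusStats, TargetRecord, sigmoid
from .taxonomy import default_taxonomy

__all__ = [
    "ClassBurden", "SlideSimConfig", "ImageSimConfig", "SlideCorpus",
    "DEFAULT_CLASS_MIX", "QUALITY_PRESETS",
    "simulate_slide", "simulate_tile", "make_corpus", "make_qc_corpus",
    "allocate_counts",
]

_SLIDE_SIDE = 40_000  # simulated slide extent in pixels

#: Patch label planted per refined squamous class (true-lesion evidence).
_TRUE_PATCH = {3: "True_LSIL", 4: "True_LSIL", 5: "True_LSIL",
               6: "True_HSIL", 7: "True_HSIL", 8: "True_HSIL",
               9: "True_HSIL", 10: "True_HSIL"}
_FALSE_PATCH = {3: "False_LSIL", 4: "False_LSIL", 5: "False_LSIL",
                6: "False_HSIL", 7: "False_HSIL", 8: "False_HSIL",
                9: "False_HSIL", 10: "False_HSIL"}

#: Nucleus gray (mean, sd on 0-255) and pixel-area (mean, sd) per refined
#: class with morphometry.  Lesion nuclei are larger and darker
#: (hyperchromatic) than normal small cells.
_NUCLEUS_PARAMS = {
    12: {"gray": (120.0, 12.0), "area_px": (560, 120)},   # SC: small, mid-gray
    3: {"gray": (100.0, 12.0), "area_px": (1400, 300)},   # ASC_L_S: enlarged
    8: {"gray": (70.0, 12.0), "area_px": (1000, 250)},    # ASC_H_S: dark, high N/C
}


@dataclass(frozen=True)
class ClassBurden:
    """Poisson count and Beta probability parameters for one planted class."""

    class_index: int
    mean_count: float
    beta_a: float = 8.0
    beta_b: float = 2.0


@dataclass(frozen=True)
class SlideSimConfig:
    """Composition of simulated slides per TBS truth class.

    ``lesion_burdens`` maps a TBS truth code to the annotation classes it
    plants.  ``background_mean`` is the Poisson mean of normal SC records
    on every slide; ``fp_rate`` the Poisson mean of low-probability
    false-positive lesion detections (0 on pristine negatives).
    """

    lesion_burdens: Mapping[str, tuple[ClassBurden, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_BURDENS))
    background_mean: float = 15.0
    fp_rate: float = 1.5
    fp_beta: tuple[float, float] = (1.5, 8.0)


_DEFAULT_BURDENS: dict[str, tuple[ClassBurden, ...]] = {
    "NILM": (),
    "ASCUS": (ClassBurden(3, 4.0, 5.0, 3.0), ClassBurden(8, 3.0, 5.0, 3.0)),
    "LSIL": (ClassBurden(4, 8.0), ClassBurden(3, 3.0), ClassBurden(5, 3.0)),
    "ASCH": (ClassBurden(6, 3.0, 6.0, 2.5), ClassBurden(7, 3.0, 6.0, 2.5),
             ClassBurden(8, 4.0, 6.0, 2.5)),
    "HSIL": (ClassBurden(6, 6.0), ClassBurden(7, 5.0), ClassBurden(8, 5.0)),
    "SCC": (ClassBurden(9, 6.0), ClassBurden(10, 5.0), ClassBurden(8, 3.0)),
    "AGC": (ClassBurden(1, 4.0), ClassBurden(2, 2.0)),
    "EMC": (ClassBurden(15, 5.0),),
    "TRI": (ClassBurden(16, 6.0),),
    "CAN": (ClassBurden(17, 6.0),),
    "HSV": (ClassBurden(18, 4.0),),
    "ACTINO": (ClassBurden(19, 6.0),),
    "CC": (ClassBurden(20, 6.0),),
}

#: Screening-shaped default class mix: mostly negative, squamous lesions
#: common, glandular/endometrial/infectious findings rare.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "NILM": 0.50, "ASCUS": 0.08, "LSIL": 0.10, "ASCH": 0.06, "HSIL": 0.10,
    "SCC": 0.06, "AGC": 0.03, "EMC": 0.02, "TRI": 0.02, "CAN": 0.01,
    "HSV": 0.005, "ACTINO": 0.005, "CC": 0.01,
}


def _random_box(rng: np.random.Generator) -> BoundingBox:
    w = int(rng.integers(40, 400))
    h = int(rng.integers(40, 400))
    x = int(rng.integers(0, _SLIDE_SIDE - w))
    y = int(rng.integers(0, _SLIDE_SIDE - h))
    return BoundingBox(x, y, w, h)


def _clip01(p: float) -> float:
    return float(min(max(p, 0.0), 1.0))


def _make_record(rng: np.random.Generator, slide_id: str, class_index: int,
                 beta_a: float, beta_b: float, true_lesion: bool) -> TargetRecord:
    tax = default_taxonomy()
    prob = float(rng.beta(beta_a, beta_b))
    det_prob = _clip01(prob + float(rng.normal(0.0, 0.08)))
    patch_label = patch_prob = None
    if 3 <= class_index <= 10:
        patch_label = (_TRUE_PATCH if true_lesion else _FALSE_PATCH)[class_index]
        patch_prob = float(rng.beta(8.0, 2.0))
    nucleus = None
    if class_index in _NUCLEUS_PARAMS:
        par = _NUCLEUS_PARAMS[class_index]
        gray = float(np.clip(rng.normal(*par["gray"]), 0.0, 255.0))
        area_px = max(1, int(round(rng.normal(*par["area_px"]))))
        nucleus = NucleusStats(mean_gray=gray, area_px=area_px,
                               area_um2=area_px * 0.0625)
    det = tax.detection_class_of(class_index)
    return TargetRecord(
        slide_id=slide_id, box=_random_box(rng),
        det_class=det if det != "excluded" else 0,
        det_prob=det_prob, refined_class=class_index, refined_prob=prob,
        patch_label=patch_label, patch_prob=patch_prob, nucleus=nucleus,
        raw_score=float(math.log(prob / (1.0 - prob))) if 0 < prob < 1 else None,
    )


def simulate_slide(config: SlideSimConfig, tbs_truth: str,
                   seed: int | np.random.Generator = 0,
                   slide_id: str = "slide") -> tuple[list[TargetRecord], str]:
    """Draw one slide's record stream for a given TBS ground truth."""
    if tbs_truth not in config.lesion_burdens:
        raise ValueError(f"unknown truth class {tbs_truth!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    records: list[TargetRecord] = []
    for burden in config.lesion_burdens[tbs_truth]:
        for _ in range(int(rng.poisson(burden.mean_count))):
            records.append(_make_record(rng, slide_id, burden.class_index,
                                        burden.beta_a, burden.beta_b, True))
    for _ in range(int(rng.poisson(config.background_mean))):
        records.append(_make_record(rng, slide_id, 12, 6.0, 2.0, False))
    fp_classes = (3, 4, 5, 6, 7, 8, 9, 10, 15, 16, 17, 18, 19, 20)
    for _ in range(int(rng.poisson(config.fp_rate))):
        cls = int(rng.choice(fp_classes))
        records.append(_make_record(rng, slide_id, cls,
                                    *config.fp_beta, False))
    return records, tbs_truth


def allocate_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` slides to a class mix."""
    total = sum(mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"class mix sums to {total}, expected 1")
    quotas = {c: n * p for c, p in mix.items()}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = n - sum(counts.values())
    remainders = sorted(mix, key=lambda c: (-(quotas[c] - counts[c]), c))
    for c in remainders[:short]:
        counts[c] += 1
    return counts


@dataclass
class SlideCorpus:
    """Labelled record corpus plus the manifest to regenerate it."""

    slides: list[tuple[str, str, list[TargetRecord]]]  # (id, truth, records)
    manifest: dict

    def __len__(self) -> int:
        return len(self.slides)

    @property
    def truths(self) -> list[str]:
        return [t for _, t, _ in self.slides]

    def records_by_slide(self) -> dict[str, list[TargetRecord]]:
        return {sid: recs for sid, _, recs in self.slides}


def make_corpus(n_slides: int, class_mix: Mapping[str, float] | None = None,
                seed: int = 0, config: SlideSimConfig | None = None,
                prefix: str = "S") -> SlideCorpus:
    """Stratified labelled corpus of simulated slides.

    Slide ``i`` is generated from ``SeedSequence([seed, i])``, so any
    slide can be regenerated in isolation and two runs with one seed are
    identical.  The manifest records everything needed for regeneration.
    """
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    config = config or SlideSimConfig()
    counts = allocate_counts(n_slides, mix) if n_slides else {c: 0 for c in mix}
    truths = [c for c in sorted(counts) for _ in range(counts[c])]
    order_rng = np.random.default_rng(np.random.SeedSequence([seed, 2**30]))
    order_rng.shuffle(truths)
    slides = []
    for i, truth in enumerate(truths):
        sid = f"{prefix}{i:05d}"
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        recs, _ = simulate_slide(config, truth, rng, slide_id=sid)
        slides.append((sid, truth, recs))
    manifest = {
        "seed": seed, "n_slides": n_slides, "class_mix": mix,
        "counts": counts, "prefix": prefix,
        "slides": [{"slide_id": sid, "truth": t} for sid, t, _ in slides],
    }
    return SlideCorpus(slides=slides, manifest=manifest)


# --------------------------------------------------------------------------
# Tile image simulation


@dataclass(frozen=True)
class ImageSimConfig:
    """Rendering parameters for synthetic smear tiles.

    ``coverage`` is the planted cell-area fraction; ``palette`` selects an
    EA-36-like (pink) or EA-50-like (cyan-green) cytoplasm hue;
    ``blur_sigma`` models defocus; ``contrast`` scales stain contrast
    around the background; ``noise_sd`` is additive sensor noise.
    """

    tile_size: int = 192
    coverage: tuple[float, float] = (0.25, 0.50)
    radius_mean: float = 7.0
    palette: str = "EA36"
    blur_sigma: float = 0.0
    contrast: float = 1.0
    noise_sd: float = 3.0


#: The four quality presets: "qualified" and three single-factor
#: degradations.
QUALITY_PRESETS: dict[str, dict] = {
    "qualified": {},
    "defocus": {"blur_sigma": 6.0},
    "low-cellularity": {"coverage": (0.0, 0.03)},
    "poor-stain": {"contrast": 0.22},
}

_PALETTES = {
    "EA36": {"cyto": (205, 150, 185), "nucleus": (95, 55, 120)},
    "EA50": {"cyto": (150, 195, 190), "nucleus": (70, 80, 130)},
}
_BACKGROUND = (242, 238, 240)


def simulate_tile(config: ImageSimConfig | None = None,
                  quality_label: str = "qualified",
                  seed: int | np.random.Generator = 0,
                  coverage: float | None = None) -> np.ndarray:
    """Render one synthetic smear tile (uint8 RGB).

    ``quality_label`` picks a preset; an explicit ``coverage`` overrides
    the preset's coverage range (useful for planted-fraction checks).
    """
    base = config or ImageSimConfig()
    if quality_label not in QUALITY_PRESETS:
        raise ValueError(f"unknown quality preset {quality_label!r}")
    cfg = replace(base, **QUALITY_PRESETS[quality_label])
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    n = cfg.tile_size
    img = np.empty((n, n, 3), dtype=float)
    img[..., :] = _BACKGROUND
    pal = _PALETTES[cfg.palette]

    target = (coverage if coverage is not None
              else float(rng.uniform(*cfg.coverage)))
    mask = np.zeros((n, n), dtype=bool)
    yy, xx = np.mgrid[0:n, 0:n]
    # paint cells until the planted coverage is reached
    guard = 0
    while mask.mean() < target and guard < 20_000:
        guard += 1
        r = max(2.0, rng.normal(cfg.radius_mean, cfg.radius_mean / 3.0))
        cx, cy = rng.uniform(0, n, size=2)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        cell = d2 <= r * r
        nucleus = d2 <= (0.45 * r) ** 2
        for c in range(3):
            img[..., c][cell] = pal["cyto"][c] + rng.normal(0, 4)
            img[..., c][nucleus] = pal["nucleus"][c] + rng.normal(0, 4)
        mask |= cell

    bg = np.array(_BACKGROUND, dtype=float)
    img = bg + cfg.contrast * (img - bg)          # stain contrast
    if cfg.blur_sigma > 0:
        img = gaussian_filter(img, sigma=(cfg.blur_sigma, cfg.blur_sigma, 0))
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_qc_corpus(n_tiles: int, seed: int = 0,
                   config: ImageSimConfig | None = None,
                   presets: Sequence[str] = tuple(QUALITY_PRESETS)
                   ) -> list[tuple[np.ndarray, str, int]]:
    """Balanced tile corpus over the quality presets.

    Returns ``(image, preset, qualified)`` triples; ``qualified`` is 1
    only for the "qualified" preset.  Tile ``i`` derives its generator
    from ``SeedSequence([seed, i])``.
    """
    out = []
    for i in range(n_tiles):
        preset = presets[i % len(presets)]
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        img = simulate_tile(config, preset, rng)
        out.append((img, preset, int(preset == "qualified")))
    return out
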