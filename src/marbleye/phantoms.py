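"""Synthetic rib-eye phantoms with exact ground truth.

A phantom is a reddish elliptical "steak" on a neutral gray presentation
board, carrying anti-aliased bright disks for intramuscular fat flecks.
The generator records the exact beef mask, per-fleck pixel areas and the
true feature vector, so every stage of the measurement pipeline can be
checked against known truth.  A cohort emulates a 3-breed study design:
breeds × animals × replicates meat samples, each photographed on two faces
with a duplicate shot per face (4 images/sample); duplicate images share a
sample's geometry exactly and differ only in pixel noise.  Synthetic
sensory scores on the 1-7 scale are a linear function of the standardized
MR, SMN and SMA truth features plus Gaussian panel noise, clipped to the
scale — so fleck-rich breeds score high by construction.

Design notes baked into the defaults:

* canvas 500 px at 4 px/mm puts the beef face at roughly 7 000-10 000 mm²,
  a realistic rib-eye cross-section;
* small-fleck areas are log-normal truncated to [1.3, 45] mm² and large to
  [55, 130] mm², keeping every fleck safely away from the 1 and 50 mm²
  class boundaries so pixelation cannot flip a truth class label;
* flecks are placed with a minimum edge gap so connected-component truth
  is unambiguous;
* the six predictors are definitionally linked (TMN contains SMN, MR is
  TMA over area, ...), so for driver-recovery tests to be meaningful each
  score driver must carry variance of its own.  Two realistic sources
  provide it: beef faces vary in cross-section area (ellipse axes jittered
  per sample), giving MR and F variance that no area-free feature shares,
  and marbling coarseness (the mean small-fleck size) varies between
  steaks independently of the fleck count, separating SMA from SMN.
  Large-fleck counts are drawn independently of small-fleck abundance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import InvalidInputError, PlacementError
from .features import (
    Fleck,
    FleckPartition,
    MarblingFeatureVector,
    compute_features,
    partition_flecks,
)
from .segmentation import RibEyeImage

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "BreedParams",
    "ScoreModel",
    "CohortDesign",
    "Cohort",
    "render_phantom",
    "generate_cohort",
    "assign_scores",
    "DEFAULT_DESIGN",
]

BOARD_RGB = (120.0, 120.0, 120.0)
LEAN_RGB = (150.0, 62.0, 58.0)
FAT_RGB = (235.0, 210.0, 185.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, photometry and fleck statistics for one phantom image."""

    size_px: int = 500
    px_per_mm: float = 4.0
    board_rgb: tuple[float, float, float] = BOARD_RGB
    lean_rgb: tuple[float, float, float] = LEAN_RGB
    fat_rgb: tuple[float, float, float] = FAT_RGB
    # beef ellipse, in px, centered on the canvas
    semi_axis_a: float = 215.0
    semi_axis_b: float = 175.0
    angle_rad: float = 0.0
    # fleck model
    n_small: int = 30
    n_large: int = 1
    small_area_range: tuple[float, float] = (1.3, 45.0)  # mm²
    large_area_range: tuple[float, float] = (55.0, 130.0)  # mm²
    small_log_mu: float = np.log(4.0)
    small_log_sigma: float = 0.7
    large_log_mu: float = np.log(75.0)
    large_log_sigma: float = 0.25
    min_gap_px: float = 2.0
    edge_margin_px: float = 6.0
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 32:
            raise InvalidInputError("size_px must be >= 32")
        if not self.px_per_mm > 0:
            raise InvalidInputError("px_per_mm must be positive")
        if self.n_small < 0 or self.n_large < 0:
            raise InvalidInputError("fleck counts must be nonnegative")


@dataclass
class PhantomTruth:
    """Exact ground truth for a rendered phantom."""

    beef_mask: np.ndarray
    fleck_mask: np.ndarray
    flecks: list[Fleck]
    partition: FleckPartition
    features: MarblingFeatureVector
    score: float | None = None


@dataclass(frozen=True)
class BreedParams:
    """Breed-level fleck abundance (means of Poisson counts per image)."""

    name: str
    small_count_mean: float
    large_count_mean: float


@dataclass(frozen=True)
class ScoreModel:
    """Synthetic sensory score: clip(b0 + b·z(MR,SMN,SMA) + N(0,σ), 1, 7)."""

    b0: float = 3.2
    b_mr: float = 0.45
    b_smn: float = 0.35
    b_sma: float = 0.25
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError("score noise sigma must be >= 0")


#: Fleck-rich Boran-like vs fleck-poor Sheko/Senga-like groups, matching the
#: observed breed ordering of panel marbling scores.
DEFAULT_BREEDS = (
    BreedParams("Boran", small_count_mean=46.0, large_count_mean=2.2),
    BreedParams("Senga", small_count_mean=22.0, large_count_mean=1.0),
    BreedParams("Sheko", small_count_mean=19.0, large_count_mean=0.8),
)


@dataclass(frozen=True)
class CohortDesign:
    """The acquisition design: breeds × animals × replicates samples,
    ``images_per_sample`` shots each (two faces × duplicate)."""

    breeds: tuple[BreedParams, ...] = DEFAULT_BREEDS
    animals_per_breed: int = 4
    replicates_per_animal: int = 8
    images_per_sample: int = 4
    canvas_px: int = 500
    px_per_mm: float = 4.0
    axis_jitter: float = 0.15
    fleck_size_sigma: float = 0.35
    animal_effect_sigma: float = 0.12
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.animals_per_breed, self.replicates_per_animal, self.images_per_sample) < 1:
            raise InvalidInputError("all design counts must be >= 1")
        if len(self.breeds) < 1:
            raise InvalidInputError("need at least one breed")

    @property
    def n_samples(self) -> int:
        return len(self.breeds) * self.animals_per_breed * self.replicates_per_animal

    @property
    def n_images(self) -> int:
        return self.n_samples * self.images_per_sample


DEFAULT_DESIGN = CohortDesign()


def _truncated_lognormal(rng, mu, sigma, lo, hi, n) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        if filled == n:
            break
        draw = rng.lognormal(mu, sigma, size=n - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    else:
        out[filled:] = np.clip(rng.lognormal(mu, sigma, size=n - filled), lo, hi)
    return out


def _place_disks(rng, spec: PhantomSpec, radii: np.ndarray) -> np.ndarray:
    """Rejection-sample non-overlapping disk centers inside the beef ellipse.

    Disks are placed largest-first; each must keep ``min_gap_px`` (plus the
    1 px anti-alias band) clear of every other disk and ``edge_margin_px``
    clear of the ellipse boundary.
    """
    c = spec.size_px / 2.0
    cos_t, sin_t = np.cos(spec.angle_rad), np.sin(spec.angle_rad)
    order = np.argsort(-radii)
    centers = np.zeros((len(radii), 2))
    placed: list[int] = []
    for idx in order:
        r = radii[idx]
        a_eff = spec.semi_axis_a - r - spec.edge_margin_px
        b_eff = spec.semi_axis_b - r - spec.edge_margin_px
        if a_eff <= 0 or b_eff <= 0:
            raise PlacementError(
                f"fleck radius {r:.1f}px does not fit inside the beef ellipse"
            )
        for _ in range(400):
            u = rng.uniform(-a_eff, a_eff)
            v = rng.uniform(-b_eff, b_eff)
            if (u / a_eff) ** 2 + (v / b_eff) ** 2 > 1.0:
                continue
            y = c + u * sin_t + v * cos_t
            x = c + u * cos_t - v * sin_t
            ok = True
            for j in placed:
                dy = y - centers[j, 0]
                dx = x - centers[j, 1]
                if np.hypot(dy, dx) < r + radii[j] + spec.min_gap_px + 1.0:
                    ok = False
                    break
            if ok:
                centers[idx] = (y, x)
                placed.append(idx)
                break
        else:
            raise PlacementError(
                f"could not place {len(radii)} flecks without overlap "
                f"(stuck after {len(placed)})"
            )
    return centers


def _render_clean(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Noise-free float canvas plus exact truth. Deterministic in spec.seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    c = n / 2.0
    cos_t, sin_t = np.cos(spec.angle_rad), np.sin(spec.angle_rad)
    u = (xx - c) * cos_t + (yy - c) * sin_t
    v = -(xx - c) * sin_t + (yy - c) * cos_t
    rho = np.sqrt((u / spec.semi_axis_a) ** 2 + (v / spec.semi_axis_b) ** 2)
    beef_mask = rho <= 1.0
    # ~1 px anti-alias band at the ellipse boundary
    alpha_beef = np.clip((1.0 - rho) * min(spec.semi_axis_a, spec.semi_axis_b) + 0.5, 0.0, 1.0)

    canvas = np.empty((n, n, 3))
    canvas[:] = spec.board_rgb
    canvas = canvas * (1 - alpha_beef[..., None]) + np.asarray(spec.lean_rgb) * alpha_beef[..., None]

    small_areas = _truncated_lognormal(
        rng, spec.small_log_mu, spec.small_log_sigma, *spec.small_area_range, spec.n_small
    )
    large_areas = _truncated_lognormal(
        rng, spec.large_log_mu, spec.large_log_sigma, *spec.large_area_range, spec.n_large
    )
    areas = np.concatenate([small_areas, large_areas])
    radii = np.sqrt(areas / np.pi) * spec.px_per_mm
    fleck_mask = np.zeros((n, n), bool)
    flecks: list[Fleck] = []
    if len(radii):
        centers = _place_disks(rng, spec, radii)
        fat = np.asarray(spec.fat_rgb)
        for i, (r, (cy, cx)) in enumerate(zip(radii, centers)):
            lo_y = max(0, int(np.floor(cy - r - 2)))
            hi_y = min(n, int(np.ceil(cy + r + 3)))
            lo_x = max(0, int(np.floor(cx - r - 2)))
            hi_x = min(n, int(np.ceil(cx + r + 3)))
            d = np.hypot(yy[lo_y:hi_y, lo_x:hi_x] - cy, xx[lo_y:hi_y, lo_x:hi_x] - cx)
            alpha = np.clip(r + 0.5 - d, 0.0, 1.0)
            canvas[lo_y:hi_y, lo_x:hi_x] = (
                canvas[lo_y:hi_y, lo_x:hi_x] * (1 - alpha[..., None]) + fat * alpha[..., None]
            )
            disk = d <= r
            fleck_mask[lo_y:hi_y, lo_x:hi_x] |= disk
            npx = int(disk.sum())
            flecks.append(
                Fleck(
                    label=i + 1,
                    pixel_count=npx,
                    area_mm2=npx / spec.px_per_mm**2,
                    centroid=(float(cy), float(cx)),
                )
            )
    partition = partition_flecks(flecks)
    beef_area = float(beef_mask.sum()) / spec.px_per_mm**2
    features = compute_features(partition, beef_area)
    truth = PhantomTruth(
        beef_mask=beef_mask,
        fleck_mask=fleck_mask,
        flecks=flecks,
        partition=partition,
        features=features,
    )
    return canvas, truth


def render_phantom(
    spec: PhantomSpec,
    noise_seed: int | None = None,
    sample_id: str = "",
    side: str = "A",
    duplicate_index: int = 1,
) -> tuple[RibEyeImage, PhantomTruth]:
    """Render one phantom image and its exact truth.

    Geometry (ellipse, fleck areas and positions) is drawn from
    ``spec.seed``; pixel noise from ``noise_seed`` (defaulting to a stream
    derived from ``spec.seed``), so duplicate shots of the same steak face
    re-use ``spec`` with different noise seeds.  Identical arguments yield
    byte-identical images.
    """
    canvas, truth = _render_clean(spec)
    nrng = np.random.default_rng(
        [spec.seed, 0] if noise_seed is None else [spec.seed, 1, int(noise_seed)]
    )
    noisy = canvas + nrng.normal(0.0, spec.noise_sigma, canvas.shape)
    pixels = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    image = RibEyeImage(
        pixels=pixels,
        px_per_mm=spec.px_per_mm,
        sample_id=sample_id,
        side=side,
        duplicate_index=duplicate_index,
    )
    return image, truth


def assign_scores(
    features: pd.DataFrame, model: ScoreModel, rng: np.random.Generator
) -> np.ndarray:
    """Synthetic panel scores from truth features.

    ``features`` needs columns MR, SMN, SMA (one row per sample).  Each is
    standardized across the table (zero std maps to a zero z-score), then
    score = clip(b0 + b_mr·z(MR) + b_smn·z(SMN) + b_sma·z(SMA) + ε, 1, 7)
    with ε ~ N(0, σ); σ = 0 gives deterministic scores.
    """

    def z(col: str) -> np.ndarray:
        x = features[col].to_numpy(float)
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    raw = (
        model.b0
        + model.b_mr * z("MR")
        + model.b_smn * z("SMN")
        + model.b_sma * z("SMA")
        + rng.normal(0.0, model.sigma, size=len(features))
    )
    return np.clip(raw, 1.0, 7.0)


@dataclass
class _SampleRecord:
    sample_id: str
    breed: str
    spec: PhantomSpec


class Cohort:
    """A generated study cohort: manifest, per-sample specs, lazy truth.

    ``manifest`` has one row per image (image_id, sample_id, breed, side,
    duplicate_index, score).  Truth is computed lazily (one clean render per
    sample, cached) because many uses only need the design arithmetic.
    """

    def __init__(self, design: CohortDesign, samples: list[_SampleRecord], score_seed: int):
        self.design = design
        self.samples = samples
        self._score_seed = score_seed
        self._truths: list[PhantomTruth] | None = None
        self._scores: np.ndarray | None = None
        rows = []
        for s in samples:
            for k in range(design.images_per_sample):
                side = "AB"[(2 * k) // design.images_per_sample] if design.images_per_sample > 1 else "A"
                dup = k % 2 + 1 if design.images_per_sample > 1 else 1
                rows.append(
                    {
                        "image_id": f"{s.sample_id}_{side}{dup}",
                        "sample_id": s.sample_id,
                        "breed": s.breed,
                        "side": side,
                        "duplicate_index": dup,
                    }
                )
        self.manifest = pd.DataFrame(rows)

    @property
    def truths(self) -> list[PhantomTruth]:
        """Per-sample ground truth (computed on first access)."""
        if self._truths is None:
            self._truths = [_render_clean(s.spec)[1] for s in self.samples]
            feats = pd.DataFrame([t.features.as_dict() for t in self._truths])
            rng = np.random.default_rng(self._score_seed)
            self._scores = assign_scores(feats, self.design.score_model, rng)
            for t, sc in zip(self._truths, self._scores):
                t.score = float(sc)
        return self._truths

    @property
    def scores(self) -> np.ndarray:
        self.truths
        return self._scores

    def truth_feature_table(self) -> pd.DataFrame:
        """Image-level table of truth features + scores (the model's input
        schema), replicating each sample's truth across its images."""
        truths = self.truths
        by_id = {s.sample_id: t for s, t in zip(self.samples, truths)}
        rows = []
        for _, m in self.manifest.iterrows():
            t = by_id[m["sample_id"]]
            row = dict(m)
            row.update(t.features.as_dict())
            row["score"] = t.score
            rows.append(row)
        return pd.DataFrame(rows)

    def iter_images(self) -> Iterator[tuple[pd.Series, RibEyeImage, PhantomTruth]]:
        """Yield (manifest row, rendered image, sample truth) per image.

        Images of one sample share geometry/truth and differ in pixel noise.
        """
        truths = self.truths
        by_id = {s.sample_id: (s, t) for s, t in zip(self.samples, truths)}
        for i, m in self.manifest.iterrows():
            s, t = by_id[m["sample_id"]]
            img, _ = render_phantom(
                s.spec,
                noise_seed=int(i),
                sample_id=m["sample_id"],
                side=m["side"],
                duplicate_index=int(m["duplicate_index"]),
            )
            yield m, img, t

    def write(self, outdir: str | Path) -> pd.DataFrame:
        """Write PNG images, manifest CSV, per-sample truth JSON and the
        truth-features CSV. Returns the manifest with image paths."""
        from PIL import Image

        outdir = Path(outdir)
        (outdir / "images").mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        score_of = dict(zip((s.sample_id for s in self.samples), map(float, self.scores)))
        manifest["score"] = [score_of[sid] for sid in manifest["sample_id"]]
        paths = []
        for m, img, _ in self.iter_images():
            p = outdir / "images" / f"{m['image_id']}.png"
            Image.fromarray(img.pixels).save(p)
            paths.append(str(p.relative_to(outdir)))
        manifest["image_path"] = paths
        manifest.to_csv(outdir / "manifest.csv", index=False)
        truth_rows = self.truth_feature_table()
        truth_rows.to_csv(outdir / "truth_features.csv", index=False)
        truth_json = {
            s.sample_id: {
                "score": float(t.score),
                "beef_area_mm2": t.features.beef_area_mm2,
                "features": t.features.as_dict(),
                "fleck_areas_mm2": [f.area_mm2 for f in t.flecks],
            }
            for s, t in zip(self.samples, self.truths)
        }
        (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
        (outdir / "design.json").write_text(json.dumps(asdict(self.design), indent=1))
        return manifest


def generate_cohort(design: CohortDesign = DEFAULT_DESIGN) -> Cohort:
    """Draw per-sample phantom specs for the full study design.

    Per-animal multiplicative random effects shift fleck abundance within a
    breed; per-sample jitter varies the beef ellipse.  Everything is
    reproducible bit-for-bit from ``design.seed``.
    """
    ss = np.random.SeedSequence(design.seed)
    master = np.random.default_rng(ss)
    scale = design.canvas_px / 500.0
    samples: list[_SampleRecord] = []
    for breed in design.breeds:
        animal_fx = np.exp(
            master.normal(0.0, design.animal_effect_sigma, design.animals_per_breed)
        )
        for a in range(design.animals_per_breed):
            for r in range(design.replicates_per_animal):
                n_small = max(2, int(master.poisson(breed.small_count_mean * animal_fx[a])))
                n_large = int(master.poisson(breed.large_count_mean))
                ja = master.uniform(1 - design.axis_jitter, 1 + design.axis_jitter)
                jb = master.uniform(1 - design.axis_jitter, 1 + design.axis_jitter)
                # per-sample marbling coarseness: mean fleck size varies
                # between steaks independently of fleck count
                mu = np.log(4.0) + float(
                    np.clip(master.normal(0.0, design.fleck_size_sigma), -0.7, 0.7)
                )
                spec = PhantomSpec(
                    size_px=design.canvas_px,
                    px_per_mm=design.px_per_mm,
                    semi_axis_a=215.0 * scale * ja,
                    semi_axis_b=175.0 * scale * jb,
                    angle_rad=master.uniform(0, np.pi),
                    n_small=n_small,
                    n_large=n_large,
                    small_log_mu=mu,
                    seed=int(master.integers(0, 2**31 - 1)),
                )
                samples.append(
                    _SampleRecord(
                        sample_id=f"{breed.name}-A{a + 1}-R{r + 1}",
                        breed=breed.name,
                        spec=spec,
                    )
                )
    score_seed = int(master.integers(0, 2**31 - 1))
    return Cohort(design, samples, score_seed)
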