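"""Synthetic brightfield galleries and phylogenetic fixtures with known truth.

The renderer emulates what the imaging cytometer's brightfield camera sees:
one dark object per frame on a bright background.  An ideal binary profile
(antialiased by 4x4 subpixel coverage) is attenuated against the background,
blurred with an isotropic Gaussian standing in for the optical PSF, and
corrupted with additive Gaussian noise clipped to the valid range.  Every
rendered object carries a ground-truth record, so segmentation, feature
extraction and gating can be scored exactly.

Shape classes
-------------
bead
    Perfect disk; the calibration standard (certified latex beads).
spheroid
    Disk with a small-amplitude radial roughness emulating pollen sculpture.
oblate_polar / oblate_equatorial
    An oblate grain seen pole-on (near-circular outline of the equatorial
    diameter, the grain's longest dimension) or side-on (ellipse of aspect
    ``aspect``); the longest visible dimension equals ``size_um`` in both
    views.
elongated
    High-aspect capsule (rectangle with semicircular caps).
saccate
    Corpus disk of diameter ``d`` with two air sacs of diameter ``0.6 d``
    centred at ``+-0.55 d`` along one axis (Pinaceae-like silhouette);
    ``size_um`` is the union's longest dimension, so ``d = size_um / 1.7``.
debris
    Small irregular low-contrast blob (strong radial roughness).
doublet
    Two touching grains (disks of radius ``size_um / 3.8`` with centres
    ``1.8`` radii apart; the union's longest dimension is ``size_um``).
cropped
    A grain intersecting the frame border.

Radially parameterised shapes are rescaled after roughness is applied so
that their true longest dimension equals ``size_um`` exactly.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .masking import ObjectImage

SHAPE_CLASSES = (
    "bead",
    "spheroid",
    "oblate_polar",
    "oblate_equatorial",
    "elongated",
    "saccate",
    "debris",
    "doublet",
    "cropped",
)

#: shape classes that represent a single measurable pollen grain
SINGLE_POLLEN_CLASSES = ("spheroid", "oblate_polar", "oblate_equatorial",
                         "elongated", "saccate")

_SUPERSAMPLE = 4
_FRAME_FACTOR = 1.8  # frame side relative to the object's longest dimension


@dataclass
class SyntheticObjectSpec:
    """Parameters of one rendered object.

    ``size_um`` is the true longest dimension of the silhouette;
    ``aspect`` (>= 1) is the axis ratio for anisotropic classes;
    ``contrast`` is the object-to-background intensity difference
    (brightfield: object intensity = background - contrast);
    ``roughness`` is the relative standard deviation of the radial
    boundary perturbation (pollen sculpture; 0 for beads).
    """

    shape_class: str
    size_um: float
    aspect: float = 1.0
    psf_sigma_um: float = 0.5
    noise_sd: float = 0.01
    background_level: float = 0.8
    contrast: float = 0.5
    roughness: float = 0.0

    def validate(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape_class {self.shape_class!r}")
        if not self.size_um > 0:
            raise ValueError("size_um must be positive")
        if self.aspect < 1:
            raise ValueError("aspect must be >= 1")
        for name in ("psf_sigma_um", "noise_sd", "roughness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.background_level <= 1:
            raise ValueError("background_level must be in (0, 1]")
        if not 0 < self.contrast <= self.background_level:
            raise ValueError("contrast must be in (0, background_level]")


@dataclass
class GroundTruthRecord:
    """Exact truth for one rendered object (one record per object)."""

    object_id: str
    shape_class: str
    true_length_um: float
    true_area_um2: float
    true_view: str  # polar | equatorial | none
    species_label: str = ""
    individual_label: str = ""
    year_label: str = ""


# ---------------------------------------------------------------------------
# silhouette geometry
# ---------------------------------------------------------------------------

def _roughness_fn(rng: np.random.Generator, sd: float):
    """Low-order Fourier radial perturbation with std ~= sd."""
    if sd <= 0:
        return lambda theta: np.zeros_like(theta)
    ks = np.arange(2, 7)
    amps = rng.normal(0.0, sd * math.sqrt(2.0 / len(ks)), size=len(ks))
    phases = rng.uniform(0, 2 * math.pi, size=len(ks))

    def h(theta):
        out = np.zeros_like(theta)
        for k, a, p in zip(ks, amps, phases):
            out = out + a * np.cos(k * theta + p)
        return out

    return h


def _normalised_radial(base_r, rough, size_um):
    """Scale a radial function so its longest across-centre extent is size_um."""
    grid = np.linspace(0.0, math.pi, 721)

    def raw(theta):
        return base_r(theta) * (1.0 + rough(theta))

    extent = raw(grid) + raw(grid + math.pi)
    scale = size_um / float(extent.max())

    def r(theta):
        return raw(theta) * scale

    return r


def _make_silhouette(spec: SyntheticObjectSpec, rng: np.random.Generator):
    """Return (inside_fn, rotation) for the spec.

    ``inside_fn(X, Y)`` takes object-centred coordinates in micrometres
    (already rotated) and returns a boolean array.
    """
    S = spec.size_um
    cls = spec.shape_class
    rough = _roughness_fn(rng, spec.roughness)

    if cls in ("bead", "spheroid", "oblate_polar", "cropped"):
        r = _normalised_radial(lambda th: np.full_like(th, S / 2.0), rough, S)

        def inside(X, Y):
            rho = np.hypot(X, Y)
            return rho <= r(np.arctan2(Y, X))

        return inside

    if cls == "oblate_equatorial":
        a, b = S / 2.0, S / (2.0 * spec.aspect)

        def ellipse_r(th):
            return a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)

        r = _normalised_radial(ellipse_r, rough, S)

        def inside(X, Y):
            rho = np.hypot(X, Y)
            return rho <= r(np.arctan2(Y, X))

        return inside

    if cls == "debris":
        base = _roughness_fn(rng, 0.25)
        r = _normalised_radial(
            lambda th: np.full_like(th, S / 2.0), base, S
        )

        def inside(X, Y):
            rho = np.hypot(X, Y)
            return rho <= np.maximum(r(np.arctan2(Y, X)), 0.15 * S)

        return inside

    if cls == "elongated":
        w = S / spec.aspect
        half = S / 2.0 - w / 2.0  # half-length of the rectangular core

        def inside(X, Y):
            dx = np.maximum(np.abs(X) - half, 0.0)
            return np.hypot(dx, Y) <= w / 2.0

        return inside

    if cls == "saccate":
        d = S / 1.7  # corpus diameter such that the union spans size_um
        rc, rs, off = d / 2.0, 0.3 * d, 0.55 * d

        def inside(X, Y):
            corpus = np.hypot(X, Y) <= rc
            s1 = np.hypot(X - off, Y) <= rs
            s2 = np.hypot(X + off, Y) <= rs
            return corpus | s1 | s2

        return inside

    if cls == "doublet":
        # two grains of radius R with centres 1.8 R apart: union spans 3.8 R
        R = S / 3.8
        off = 0.9 * R

        def inside(X, Y):
            return (np.hypot(X - off, Y) <= R) | (np.hypot(X + off, Y) <= R)

        return inside

    raise ValueError(f"unknown shape_class {cls!r}")


_TRUE_VIEW = {"oblate_polar": "polar", "oblate_equatorial": "equatorial"}

_ANISOTROPIC = ("oblate_equatorial", "elongated", "saccate", "doublet", "debris")


def render_object(
    spec: SyntheticObjectSpec,
    pixel_size_um: float,
    seed,
    object_id: str = "obj00000",
    species_label: str = "",
    individual_label: str = "",
    year_label: str = "",
) -> Tuple[ObjectImage, GroundTruthRecord]:
    """Render one object and its ground-truth record.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.  Rendering
    is fully deterministic given the seed.  The frame side is 1.8x the
    object's longest dimension (so only the ``cropped`` class touches the
    border); an object that would not fit is accommodated automatically
    because the frame is derived from its size.
    """
    spec.validate()
    if spec.size_um < 3 * pixel_size_um:
        raise ValueError(
            f"size {spec.size_um} um is below the resolution floor "
            f"(3 px at {pixel_size_um} um/px)"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    inside = _make_silhouette(spec, rng)
    theta = rng.uniform(0.0, math.pi) if spec.shape_class in _ANISOTROPIC else 0.0
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    if spec.shape_class == "cropped":
        n = max(int(math.ceil(1.4 * spec.size_um / pixel_size_um)), 16)
        cx_px = 0.25 * spec.size_um / pixel_size_um  # grain centre near the left border
        cy_px = (n - 1) / 2.0
    else:
        n = max(int(math.ceil(_FRAME_FACTOR * spec.size_um / pixel_size_um)), 16)
        cy_px = (n - 1) / 2.0 + rng.uniform(-0.5, 0.5)
        cx_px = (n - 1) / 2.0 + rng.uniform(-0.5, 0.5)

    ss = _SUPERSAMPLE
    sub = (np.arange(n * ss) + 0.5) / ss - 0.5  # subpixel coords in pixel units
    Xp, Yp = np.meshgrid(sub - cx_px, sub - cy_px)
    X = (Xp * cos_t + Yp * sin_t) * pixel_size_um
    Y = (-Xp * sin_t + Yp * cos_t) * pixel_size_um
    hit = inside(X, Y).astype(float)
    coverage = hit.reshape(n, ss, n, ss).mean(axis=(1, 3))

    clean = spec.background_level - spec.contrast * coverage
    if spec.psf_sigma_um > 0:
        clean = ndi.gaussian_filter(clean, spec.psf_sigma_um / pixel_size_um,
                                    mode="nearest")
    if spec.noise_sd > 0:
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    pixels = np.clip(clean, 0.0, 1.0)

    true_area = float(coverage.sum()) * pixel_size_um ** 2
    record = GroundTruthRecord(
        object_id=object_id,
        shape_class=spec.shape_class,
        true_length_um=float(spec.size_um),
        true_area_um2=true_area,
        true_view=_TRUE_VIEW.get(spec.shape_class, "none"),
        species_label=species_label,
        individual_label=individual_label,
        year_label=year_label,
    )
    return ObjectImage(pixels=pixels, pixel_size_um=pixel_size_um), record


def render_bead(
    diameter_um: float,
    pixel_size_um: float,
    psf_sigma_um: float = 0.5,
    noise_sd: float = 0.01,
    seed=0,
    object_id: str = "bead00000",
) -> Tuple[ObjectImage, GroundTruthRecord]:
    """Render one calibration bead (perfect disk, no surface roughness)."""
    spec = SyntheticObjectSpec(
        shape_class="bead",
        size_um=diameter_um,
        psf_sigma_um=psf_sigma_um,
        noise_sd=noise_sd,
    )
    return render_object(spec, pixel_size_um, seed, object_id=object_id)


def render_pollen(
    spec: SyntheticObjectSpec,
    pixel_size_um: float,
    seed=0,
    object_id: str = "obj00000",
    **labels,
) -> Tuple[ObjectImage, GroundTruthRecord]:
    """Render one pollen-like object (any shape class)."""
    return render_object(spec, pixel_size_um, seed, object_id=object_id, **labels)


# ---------------------------------------------------------------------------
# galleries
# ---------------------------------------------------------------------------

@dataclass
class SpeciesDesign:
    """Sampling design for pollen-class objects in one gallery.

    Per-individual and per-year size effects are drawn once (seeded) and are
    recoverable through :func:`design_effects`, so hierarchical summaries can
    be scored against the configured effect sizes.  Sizes are in micrometres.
    """

    species_label: str = "Synthetica demo"
    n_individuals: int = 1
    years: Sequence[int] = (2021,)
    mean_size_um: float = 32.0
    sd_between_individuals: float = 1.0
    sd_between_years: float = 0.5
    sd_within: float = 2.0
    aspect: float = 1.6  # used by oblate classes


def design_effects(design: SpeciesDesign, seed: int) -> pd.DataFrame:
    """The per-individual x year mean sizes implied by a design and seed."""
    rng = np.random.default_rng([int(seed), 17])
    ind_eff = rng.normal(0.0, design.sd_between_individuals, design.n_individuals)
    year_eff = rng.normal(0.0, design.sd_between_years, len(design.years))
    rows = []
    for i in range(design.n_individuals):
        for j, year in enumerate(design.years):
            rows.append({
                "individual_label": f"ind{i + 1:02d}",
                "year_label": str(year),
                "mean_size_um": design.mean_size_um + ind_eff[i] + year_eff[j],
            })
    return pd.DataFrame(rows)


#: default composition of the mixed demonstration gallery
DEMO_COMPOSITION: Dict[str, float] = {
    "spheroid": 0.45,
    "oblate_polar": 0.125,
    "oblate_equatorial": 0.125,
    "debris": 0.10,
    "doublet": 0.10,
    "cropped": 0.10,
}

#: per-class size and appearance defaults (micrometres; study conditions)
CLASS_DEFAULTS: Dict[str, dict] = {
    "bead": dict(size=(19.98, 0.0), contrast=0.5, roughness=0.0, aspect=1.0),
    "spheroid": dict(size=(32.0, 2.5), contrast=0.5, roughness=0.02, aspect=1.0),
    "oblate_polar": dict(size=(34.0, 2.5), contrast=0.5, roughness=0.02, aspect=1.6),
    "oblate_equatorial": dict(size=(34.0, 2.5), contrast=0.5, roughness=0.02, aspect=1.6),
    "elongated": dict(size=(60.0, 4.0), contrast=0.5, roughness=0.0, aspect=3.0),
    "saccate": dict(size=(68.0, 6.0), contrast=0.5, roughness=0.0, aspect=1.0),
    "debris": dict(size=(6.0, 1.5), contrast=0.25, roughness=0.25, aspect=1.0),
    "doublet": dict(size=(60.8, 4.75), contrast=0.5, roughness=0.0, aspect=1.0),
    "cropped": dict(size=(32.0, 2.5), contrast=0.5, roughness=0.02, aspect=1.0),
}

DEFAULT_PARTICLE_LIMIT = 5000


def render_gallery(
    out_dir,
    n_objects: int,
    composition: Dict[str, float],
    pixel_size_um: float = 0.5,
    seed: int = 0,
    species_design: Optional[SpeciesDesign] = None,
    particle_limit: int = DEFAULT_PARTICLE_LIMIT,
    image_format: str = "tiff",
    psf_sigma_um: float = 0.5,
    noise_sd: float = 0.01,
) -> pd.DataFrame:
    """Render a gallery directory (one image per object) plus a truth table.

    Class counts are a seeded multinomial draw from ``composition`` (which
    must sum to 1).  The gallery is capped at ``particle_limit`` objects
    (default 5000, mirroring the acquisition stop).  Images are written as
    16-bit grayscale TIFF (``image_format="tiff"``) or 8-bit PNG, named
    ``<object_id>.<ext>``; the truth table is ``truth.csv``.

    Returns the truth table as a DataFrame.
    """
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    fractions = np.array(list(composition.values()), dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError("composition fractions must sum to 1")
    for cls in composition:
        if cls not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape_class {cls!r} in composition")
    if image_format not in ("tiff", "png"):
        raise ValueError("image_format must be 'tiff' or 'png'")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(int(seed))
    n = min(int(n_objects), int(particle_limit))
    classes = list(composition.keys())
    counts = rng.multinomial(n, fractions)
    class_seq = np.repeat(classes, counts)
    rng.shuffle(class_seq)

    design = species_design
    effects = design_effects(design, seed) if design is not None else None

    records = []
    for i, cls in enumerate(class_seq):
        object_id = f"obj{i:05d}"
        defaults = CLASS_DEFAULTS[cls]
        labels = dict(species_label="", individual_label="", year_label="")
        if design is not None and cls not in ("bead", "debris"):
            row = effects.iloc[rng.integers(len(effects))]
            base = float(row["mean_size_um"])
            size = rng.normal(base, design.sd_within)
            if cls == "doublet":
                size = 1.9 * size
            labels = dict(
                species_label=design.species_label,
                individual_label=row["individual_label"],
                year_label=row["year_label"],
            )
            aspect = design.aspect if cls.startswith("oblate") else defaults["aspect"]
        else:
            mu, sd = defaults["size"]
            size = rng.normal(mu, sd) if sd > 0 else mu
            aspect = defaults["aspect"]
        size = max(size, 3.5 * pixel_size_um)
        spec = SyntheticObjectSpec(
            shape_class=cls,
            size_um=float(size),
            aspect=float(aspect),
            psf_sigma_um=psf_sigma_um,
            noise_sd=noise_sd,
            contrast=defaults["contrast"],
            roughness=defaults["roughness"],
        )
        image, truth = render_object(
            spec, pixel_size_um, rng, object_id=object_id, **labels
        )
        _write_image(image, out_dir, object_id, image_format)
        rec = truth.__dict__.copy()
        rec["pixel_size_um"] = pixel_size_um
        records.append(rec)

    table = pd.DataFrame(records)
    table.to_csv(out_dir / "truth.csv", index=False)
    return table


def _write_image(image: ObjectImage, out_dir: Path, object_id: str, fmt: str) -> None:
    if fmt == "tiff":
        import tifffile

        data = np.round(image.pixels * 65535).astype(np.uint16)
        tifffile.imwrite(out_dir / f"{object_id}.tif", data)
    else:
        import imageio.v3 as iio

        data = np.round(image.pixels * 255).astype(np.uint8)
        iio.imwrite(out_dir / f"{object_id}.png", data)


# ---------------------------------------------------------------------------
# phylogenetic fixtures
# ---------------------------------------------------------------------------

def simulate_bm_trait(tree: dendropy.Tree, sigma2: float, seed=0) -> pd.Series:
    """Brownian-motion trait on a tree: root state 0, increment variance
    ``sigma2`` per unit branch length.  ``sigma2 = 0`` returns the root
    state at every tip.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
            continue
        el = node.edge.length
        if el is None or el < 0:
            raise ValueError("tree must have nonnegative branch lengths")
        step = rng.normal(0.0, math.sqrt(sigma2 * el)) if sigma2 > 0 and el > 0 else 0.0
        values[node] = values[node.parent_node] + step
    tips = {lf.taxon.label: values[lf] for lf in tree.leaf_node_iter()}
    return pd.Series(tips, name="trait")


def random_ultrametric_tree(n_tips: int, seed: int = 0, depth: float = 1.0) -> dendropy.Tree:
    """Seeded random ultrametric tree (Kingman coalescent topology)
    rescaled to the given root depth.

    Coalescent waiting times are continuous, so all branch lengths are
    strictly positive and the phylogenetic covariance matrix is
    well-conditioned.  Convenience fixture for signal-recovery simulations;
    tip labels are ``T1 .. Tn``.
    """
    from dendropy.simulate import treesim

    ns = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(int(n_tips))])
    tree = treesim.pure_kingman_tree(
        taxon_namespace=ns,
        pop_size=1.0,
        rng=random.Random(int(seed)),
    )
    tree.is_rooted = True
    current = max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )
    factor = depth / current
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree
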