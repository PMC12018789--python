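"""Shared fixtures: rendered galleries and analytic masks.

Galleries are rendered once per session (synthetic data is the test
fixture; nothing is stored on disk in the repository).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from pollenflow import GateConfig, SpeciesDesign, apply_gates, render_gallery
from pollenflow.io import load_truth, read_gallery
from pollenflow.masking import Mask
from pollenflow.morphometry import features_table

MIXED_SEED = 7
MIXED_N = 600

#: mixed torture gallery: single pollen (spheroid + both oblate views),
#: debris, doublets and cropped objects, one synthetic species with a
#: 3-individual x 2-year design
MIXED_COMPOSITION = {
    "spheroid": 0.45,
    "oblate_polar": 0.125,
    "oblate_equatorial": 0.125,
    "debris": 0.10,
    "doublet": 0.10,
    "cropped": 0.10,
}

SPECIES = "Synthetica demo"


def render_and_extract(tmpdir, n, composition, seed, design=None,
                       pixel_size=0.5):
    render_gallery(tmpdir, n_objects=n, composition=composition,
                   pixel_size_um=pixel_size, seed=seed, species_design=design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feats = features_table(read_gallery(tmpdir))
    truth = load_truth(tmpdir)
    feats = feats.merge(
        truth[["object_id", "species_label", "individual_label", "year_label"]],
        on="object_id", how="left")
    return feats, truth


@pytest.fixture(scope="session")
def mixed_gallery(tmp_path_factory):
    """(features, truth) for the seeded mixed gallery."""
    gal = tmp_path_factory.mktemp("mixed_gallery")
    design = SpeciesDesign(species_label=SPECIES, n_individuals=3,
                           years=(2021, 2022))
    return render_and_extract(gal, MIXED_N, MIXED_COMPOSITION, MIXED_SEED,
                              design=design)


@pytest.fixture(scope="session")
def mixed_gates(mixed_gallery):
    feats, _ = mixed_gallery
    cfg = GateConfig(nonspherical_species=(SPECIES,))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return apply_gates(feats, cfg)


@pytest.fixture(scope="session")
def mixed_scored(mixed_gallery, mixed_gates):
    """Features joined with gate labels and ground truth."""
    feats, truth = mixed_gallery
    return feats.merge(
        mixed_gates[["object_id", "label", "view"]], on="object_id"
    ).merge(
        truth[["object_id", "shape_class", "true_length_um", "true_area_um2",
               "true_view"]],
        on="object_id")


@pytest.fixture(scope="session")
def clean_gallery(tmp_path_factory):
    """Singles-only gallery (spheroids + both oblate views), for
    idempotence and zero-outlier checks."""
    gal = tmp_path_factory.mktemp("clean_gallery")
    comp = {"spheroid": 0.5, "oblate_polar": 0.25, "oblate_equatorial": 0.25}
    design = SpeciesDesign(species_label=SPECIES, n_individuals=2)
    return render_and_extract(gal, 120, comp, 11, design=design)


# ---------------------------------------------------------------------------
# analytic masks (no rendering)
# ---------------------------------------------------------------------------

def disk_mask(radius_px: float, pad: int = 4) -> Mask:
    n = int(np.ceil(2 * radius_px)) + 2 * pad + 1
    c = (n - 1) / 2
    yy, xx = np.mgrid[:n, :n]
    return Mask(bits=np.hypot(yy - c, xx - c) <= radius_px, kind="object")


def ellipse_mask(a_px: float, b_px: float, pad: int = 4) -> Mask:
    n = int(np.ceil(2 * max(a_px, b_px))) + 2 * pad + 1
    c = (n - 1) / 2
    yy, xx = np.mgrid[:n, :n]
    return Mask(bits=((xx - c) / a_px) ** 2 + ((yy - c) / b_px) ** 2 <= 1.0,
                kind="object")


def rect_mask(h_px: int, w_px: int, pad: int = 4) -> Mask:
    bits = np.zeros((h_px + 2 * pad, w_px + 2 * pad), dtype=bool)
    bits[pad:pad + h_px, pad:pad + w_px] = True
    return Mask(bits=bits, kind="object")


def horseshoe_mask(r_in: float = 9.0, r_out: float = 15.0, pad: int = 4) -> Mask:
    """Half annulus (open side down): a folded object whose geodesic
    diameter exceeds its Feret diameter."""
    n = int(np.ceil(2 * r_out)) + 2 * pad + 1
    c = (n - 1) / 2
    yy, xx = np.mgrid[:n, :n]
    rho = np.hypot(yy - c, xx - c)
    bits = (rho >= r_in) & (rho <= r_out) & (yy <= c)
    return Mask(bits=bits, kind="object")


def random_blob_mask(seed: int, pad: int = 4) -> Mask:
    """Union of a few overlapping disks; always 8-connected."""
    rng = np.random.default_rng(seed)
    n = 64
    yy, xx = np.mgrid[:n, :n]
    bits = np.zeros((n, n), dtype=bool)
    cy, cx = 32.0, 32.0
    for _ in range(rng.integers(2, 5)):
        r = rng.uniform(5, 12)
        bits |= np.hypot(yy - cy, xx - cx) <= r
        ang = rng.uniform(0, 2 * np.pi)
        step = rng.uniform(3, 0.9 * r)
        cy += step * np.sin(ang)
        cx += step * np.cos(ang)
        cy, cx = np.clip(cy, 14, 50), np.clip(cx, 14, 50)
    from scipy import ndimage as ndi

    labels, num = ndi.label(bits, structure=np.ones((3, 3), bool))
    if num > 1:
        counts = np.bincount(labels.ravel()); counts[0] = 0
        bits = labels == np.argmax(counts)
    return Mask(bits=bits, kind="object")
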