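"""Sequential gating of per-object feature records and size summaries.

The cascade isolates high-quality (HQ) single pollen: debris removal on
brightfield intensities, singlet selection on circularity, cropped-object
and statistical-outlier flags, and polar/equatorial view sorting for
nonspherical species.  Every input object receives exactly one terminal
label (``debris``, ``multiple``, ``cropped``, ``outlier`` or
``hq_single``), so labels partition the input and counts are conserved.

All automatic thresholds (Otsu, KDE valleys) can be overridden from the
run configuration, making gates reproducible and auditable.  Outlier
flagging is stratified by species and view so that the median/MAD rule is
applied to homogeneous populations (a polar/equatorial mixture is bimodal
in elongatedness and would otherwise be shredded by the MAD rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu

GATE_LABELS = ("debris", "multiple", "cropped", "outlier", "hq_single")

#: a touching pair of convex grains has boundary-radius spread ratio below
#: this, while single convex profiles up to ~2:1 aspect sit above it
MULTIPLET_CIRCULARITY_CEILING = 4.5

MODIFIED_Z_CUTOFF = 3.5
_MAD_CONSTANT = 0.6745  # scales MAD to sigma for normal data


# ---------------------------------------------------------------------------
# density helpers
# ---------------------------------------------------------------------------

def _kde_profile(values: np.ndarray, grid_size: int = 512,
                 bw_scale: float = 0.5):
    """KDE density on a regular grid spanning the data (plus 3 bandwidths).

    The Scott bandwidth is halved by default: Scott's rule targets unimodal
    densities and oversmooths the well-separated clusters that the gates
    hunt for; spurious wiggles from the narrower bandwidth are harmless
    because the gates only act when the low mode is physically plausible.
    """
    kde = gaussian_kde(values, bw_method=lambda k: bw_scale * k.scotts_factor())
    bw = kde.factor * values.std(ddof=1)
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    return grid, kde(grid)


def _modes(grid: np.ndarray, dens: np.ndarray,
           min_prominence: float = 0.02) -> np.ndarray:
    """Indices of local density maxima with modest relative prominence."""
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    idx = np.where(interior)[0] + 1
    if dens[0] > dens[1]:
        idx = np.r_[0, idx]
    if dens[-1] > dens[-2]:
        idx = np.r_[idx, len(dens) - 1]
    floor = min_prominence * dens.max()
    return idx[dens[idx] > floor]


def _merged_modes(grid: np.ndarray, dens: np.ndarray, idx: np.ndarray,
                  min_sep: float) -> np.ndarray:
    """Merge modes closer than ``min_sep`` on the grid scale, keeping the
    densest one of each group (tight quantized clusters otherwise produce
    spurious micro-modes)."""
    if len(idx) == 0:
        return idx
    groups = [[idx[0]]]
    for i in idx[1:]:
        if grid[i] - grid[groups[-1][-1]] < min_sep:
            groups[-1].append(i)
        else:
            groups.append([i])
    return np.array([g[int(np.argmax(dens[g]))] for g in groups])


def _valley_between(grid, dens, i_lo, i_hi) -> float:
    """Location of the density minimum strictly between two mode indices."""
    segment = slice(i_lo, i_hi + 1)
    j = int(np.argmin(dens[segment])) + i_lo
    return float(grid[j])


def _snap_to_gap(values: np.ndarray, threshold: float,
                 window: float = 1.0) -> Tuple[float, float]:
    """Move a threshold to the midpoint of the widest empty interval near it.

    Otsu's between-class variance is flat across an empty gap, so the
    returned threshold can sit at the edge of (or just inside) a cluster;
    snapping to the widest inter-point gap whose interval overlaps
    ``[threshold - window, threshold + window]`` recovers the natural
    split.  Returns (snapped threshold, gap width).  A threshold that
    bisects a continuous unimodal population keeps a near-zero gap
    (adjacent order statistics are ~sigma/n apart), while a genuine
    debris/pollen split leaves a wide empty band.
    """
    v = np.sort(values[np.isfinite(values)])
    if len(v) < 2:
        return threshold, 0.0
    gaps = np.diff(v)
    lo, hi = threshold - window, threshold + window
    overlapping = (v[1:] >= lo) & (v[:-1] <= hi)
    if not overlapping.any():
        return threshold, 0.0
    idx = np.flatnonzero(overlapping)
    best = idx[np.argmax(gaps[idx])]
    return float((v[best] + v[best + 1]) / 2.0), float(gaps[best])


# ---------------------------------------------------------------------------
# gates
# ---------------------------------------------------------------------------

def gate_debris(
    records: pd.DataFrame,
    thresholds: Optional[Dict[str, float]] = None,
    channels: Sequence[str] = ("intensity_ch01", "intensity_ch09"),
    min_gap: float = 0.3,
) -> Tuple[pd.Series, Dict[str, float]]:
    """Debris flag from brightfield image intensities.

    Two-camera mode: per-channel Otsu threshold on ``log10(1 + intensity)``;
    debris is below threshold on *both* channels.  With a single camera the
    1-D histogram of the available channel is used instead.  Explicit
    ``thresholds`` (on the log scale, keyed by channel) override Otsu.

    An automatic threshold is only applied when it leaves an empty margin
    of at least ``min_gap`` (log10 units; default 0.3, a factor 2 in
    intensity) between the classes: debris is at least an order of
    magnitude dimmer than pollen, whereas on a debris-free sample Otsu
    would bisect the continuous pollen population, where gaps are tiny.

    Returns the boolean flag (indexed like ``records``) and the thresholds
    used.
    """
    present = [c for c in channels if c in records.columns
               and records[c].notna().any()]
    if not present:
        raise ValueError("no intensity channel available for debris gating")
    used: Dict[str, float] = {}
    below = pd.DataFrame(index=records.index)
    for ch in present:
        logs = np.log10(1.0 + records[ch].to_numpy(dtype=float))
        if thresholds is not None and ch in thresholds:
            thr = float(thresholds[ch])
        else:
            if np.ptp(logs) == 0:
                warnings.warn(f"constant intensity on {ch}; no debris gate applied")
                below[ch] = False
                used[ch] = float("-inf")
                continue
            thr, gap = _snap_to_gap(logs, float(threshold_otsu(logs)))
            if gap < min_gap:
                warnings.warn(
                    f"no effective intensity split on {ch}; no debris gate applied")
                below[ch] = False
                used[ch] = float("-inf")
                continue
        used[ch] = thr
        below[ch] = logs < thr
    flag = below.all(axis=1)
    if flag.all() or not flag.any():
        warnings.warn("degenerate debris split (all or none flagged)")
    return flag, used


def gate_singlets(
    records: pd.DataFrame,
    threshold: Optional[float] = None,
    circ_ceiling: float = MULTIPLET_CIRCULARITY_CEILING,
) -> Tuple[pd.Series, Optional[float]]:
    """Multiple-object flag from the circularity feature.

    Multiplets (touching grains) form the lowest circularity mode; the gate
    cuts at the KDE valley separating that mode from the next one, provided
    the lowest mode lies below ``circ_ceiling`` (the radial-spread ratio of
    a touching convex pair is scale-invariantly below ~4.5, while single
    convex profiles sit above).  A unimodal density, or no mode below the
    ceiling, labels everything single.  ``threshold`` overrides the
    automatic gate exactly.
    """
    circ = records["circularity"].to_numpy(dtype=float)
    valid = np.isfinite(circ)
    if threshold is not None:
        flag = pd.Series(valid & (circ < threshold), index=records.index)
        return flag, float(threshold)
    x = np.log10(np.clip(circ[valid], 1e-3, None))
    if len(x) < 8 or np.ptp(x) == 0:
        warnings.warn("too few or constant circularity values; all labeled single")
        return pd.Series(False, index=records.index), None
    grid, dens = _kde_profile(x)
    modes = _merged_modes(grid, dens, _modes(grid, dens), min_sep=0.15)
    if len(modes) < 2:
        warnings.warn("unimodal circularity density; all labeled single")
        return pd.Series(False, index=records.index), None
    if grid[modes[0]] > np.log10(circ_ceiling):
        return pd.Series(False, index=records.index), None
    cut_log = _valley_between(grid, dens, modes[0], modes[1])
    thr = 10.0 ** cut_log
    flag = pd.Series(valid & (circ < thr), index=records.index)
    return flag, float(thr)


def _modified_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return _MAD_CONSTANT * (x - med) / mad


def flag_quality(
    records: pd.DataFrame,
    z_cutoff: float = MODIFIED_Z_CUTOFF,
    group_keys: Sequence[str] = ("species_label", "view"),
) -> pd.DataFrame:
    """Cropped and outlier flags.

    ``cropped`` is the border-touch flag.  ``outlier`` is a modified
    z-score (median/MAD) above ``z_cutoff`` on log area or on
    elongatedness, evaluated within species x view strata (whichever of
    ``group_keys`` are present); strata of fewer than 8 records skip the
    outlier stage with a warning.
    """
    out = pd.DataFrame(index=records.index)
    out["cropped"] = records["border_touch"].fillna(False).astype(bool)
    out["outlier"] = False
    eligible = records.loc[~out["cropped"]]
    keys = [k for k in group_keys if k in records.columns]
    groups = eligible.groupby(keys, dropna=False) if keys else [(None, eligible)]
    for _, grp in groups:
        if len(grp) < 8:
            warnings.warn("fewer than 8 records in stratum; outlier stage skipped")
            continue
        z_area = _modified_z(np.log(grp["area_um2"].to_numpy(dtype=float)))
        z_elon = _modified_z(grp["elongatedness"].to_numpy(dtype=float))
        flag = (np.abs(z_area) > z_cutoff) | (np.abs(z_elon) > z_cutoff)
        out.loc[grp.index[flag], "outlier"] = True
    return out


def sort_views(
    records: pd.DataFrame,
    threshold: Optional[float] = None,
) -> Tuple[pd.Series, Optional[float]]:
    """Polar/equatorial view labels from the elongatedness histogram.

    The threshold is the deepest KDE valley between the lowest and highest
    elongatedness modes; objects above are labeled ``equatorial`` (the
    elongated profile exposing the grain's longest dimension), objects
    below ``polar``.  A unimodal density (spherical species) labels
    everything polar with a warning.  ``threshold`` overrides the gate.
    """
    elon = records["elongatedness"].to_numpy(dtype=float)
    if threshold is None:
        valid = elon[np.isfinite(elon)]
        if len(valid) < 8 or np.ptp(valid) == 0:
            warnings.warn("too few elongatedness values; all labeled polar")
            return pd.Series("polar", index=records.index), None
        grid, dens = _kde_profile(valid)
        modes = _merged_modes(grid, dens, _modes(grid, dens), min_sep=0.15)
        if len(modes) < 2:
            warnings.warn("unimodal elongatedness density; all labeled polar")
            return pd.Series("polar", index=records.index), None
        candidates = [
            _valley_between(grid, dens, modes[k], modes[k + 1])
            for k in range(len(modes) - 1)
        ]
        dens_at = [dens[np.searchsorted(grid, c)] for c in candidates]
        threshold = candidates[int(np.argmin(dens_at))]
    view = np.where(elon > threshold, "equatorial", "polar")
    return pd.Series(view, index=records.index), float(threshold)


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@dataclass
class GateConfig:
    """Thresholds and overrides for the gating cascade."""

    debris_thresholds: Optional[Dict[str, float]] = None
    singlet_threshold: Optional[float] = None
    multiplet_circ_ceiling: float = MULTIPLET_CIRCULARITY_CEILING
    outlier_z: float = MODIFIED_Z_CUTOFF
    nonspherical_species: Sequence[str] = ()
    view_thresholds: Dict[str, float] = field(default_factory=dict)


def apply_gates(
    records: pd.DataFrame,
    config: Optional[GateConfig] = None,
) -> pd.DataFrame:
    """Run the full cascade; returns one row per object with columns
    ``object_id``, ``stage``, ``label`` and ``view``.

    Stages run in order: debris -> singlets -> cropped -> view sorting
    (per nonspherical species) -> outliers (within species x view).
    Records whose feature status is not "ok" are labeled at the stage that
    failed (as debris — they produced no measurable object).
    """
    cfg = config or GateConfig()
    df = records.reset_index(drop=True).copy()
    label = pd.Series("", index=df.index, dtype=object)
    stage = pd.Series("", index=df.index, dtype=object)
    view = pd.Series("", index=df.index, dtype=object)

    failed = df["status"].ne("ok") if "status" in df.columns else pd.Series(False, index=df.index)
    label[failed] = "debris"
    stage[failed] = "extraction"

    live = ~failed
    debris_flag, _ = gate_debris(df.loc[live], thresholds=cfg.debris_thresholds)
    hit = debris_flag[debris_flag].index
    label[hit] = "debris"
    stage[hit] = "debris_gate"
    live &= label.eq("")

    multi_flag, _ = gate_singlets(
        df.loc[live],
        threshold=cfg.singlet_threshold,
        circ_ceiling=cfg.multiplet_circ_ceiling,
    )
    hit = multi_flag[multi_flag].index
    label[hit] = "multiple"
    stage[hit] = "singlet_gate"
    live &= label.eq("")

    cropped = df.loc[live, "border_touch"].fillna(False).astype(bool)
    hit = cropped[cropped].index
    label[hit] = "cropped"
    stage[hit] = "quality_gate"
    live &= label.eq("")

    if "species_label" in df.columns:
        for sp in cfg.nonspherical_species:
            sel = live & df["species_label"].eq(sp)
            if not sel.any():
                continue
            v, _ = sort_views(df.loc[sel],
                              threshold=cfg.view_thresholds.get(sp))
            view[sel] = v

    working = df.loc[live].copy()
    working["view"] = view[live]
    quality = flag_quality(working, z_cutoff=cfg.outlier_z)
    hit = quality.index[quality["outlier"]]
    label[hit] = "outlier"
    stage[hit] = "quality_gate"
    live &= label.eq("")

    label[live] = "hq_single"
    stage[live] = "final"

    return pd.DataFrame({
        "object_id": df["object_id"],
        "stage": stage,
        "label": label,
        "view": view,
    })


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(
    records: pd.DataFrame,
    value: str = "length_um",
    species_col: str = "species_label",
    individual_col: str = "individual_label",
) -> pd.DataFrame:
    """Two-level species size summaries.

    ``pooled_pollen``: mean/SD over all pollen of a species.
    ``individual_means``: mean/SD over per-individual mean sizes (equal
    weight per individual plant), which de-biases species means under
    uneven per-individual sampling.  A species with a single individual has
    no SD at that level (reported as NaN).
    """
    if records.empty:
        raise ValueError("no records to summarize")
    rows = []
    for sp, grp in records.groupby(species_col):
        vals = grp[value].to_numpy(dtype=float)
        ind_means = grp.groupby(individual_col)[value].mean()
        rows.append({
            "species_label": sp, "level": "pooled_pollen",
            "n_individuals": int(ind_means.size), "n_pollen": int(len(vals)),
            "mean_um": float(vals.mean()),
            "sd_um": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
        })
        rows.append({
            "species_label": sp, "level": "individual_means",
            "n_individuals": int(ind_means.size), "n_pollen": int(len(vals)),
            "mean_um": float(ind_means.mean()),
            "sd_um": float(ind_means.std(ddof=1)) if ind_means.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def modal_size(values: Iterable[float], bin_width_um: float) -> float:
    """Histogram mode with bins of one pixel width anchored at zero;
    ties resolve to the lowest bin.  Warns below n = 30."""
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no finite values")
    if len(vals) < 30:
        warnings.warn("fewer than 30 values; modal size is unstable")
    idx = np.floor(vals / bin_width_um).astype(int)
    counts = np.bincount(idx)
    return (int(np.argmax(counts)) + 0.5) * bin_width_um
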