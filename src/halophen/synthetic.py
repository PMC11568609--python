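"""Synthetic data emulating salinity-treated branched succulent plants.

Everything the analysis layers consume can be generated here with known
ground truth:

* :func:`render_plant` — a procedurally branched shoot (main stem plus
  recursive secondary shoots) rasterized at a physical pixel scale on a
  light background, coloured in Lab around a group mean, with the true
  mask, projected area, height, stem diameter and mean Lab recorded by the
  rasterizer itself.
* :func:`generate_feature_table` — per-plant trait tables with the
  4-treatment × 2-population factorial structure (0/200/400/1000 mM NaCl;
  lower/higher salt-tolerant), 12 replicates per cell for the 96-plant
  trial layout and 3 for the 24-plant validation layout.
* :func:`generate_from_model` — parameter-recovery datasets: predictors
  drawn from stated ranges, response from a fixed linear model plus
  Gaussian noise.
* :func:`generate_cross_section` — concentric-annulus stem cross-section
  phantoms with requested tissue proportions.

Group trait means default to mid-points of reported ranges for the two
populations and are config-overridable approximations, not measured data.
All generators are deterministic under a fixed integer seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as _skcolor
from skimage import draw as _skdraw

from . import published
from .colorimetry import WHITE_STANDARD, chroma, delta_e, hue_angle

__all__ = [
    "GroupParams",
    "GroundTruth",
    "DEFAULT_GROUPS",
    "render_plant",
    "generate_feature_table",
    "trial_table",
    "validation_table",
    "generate_from_model",
    "generate_cross_section",
]


@dataclasses.dataclass(frozen=True)
class GroupParams:
    """Trait distribution of one (population, treatment) cell."""

    population: str
    treatment: str
    lab_mean: tuple[float, float, float]
    lab_sd: tuple[float, float, float] = (0.8, 0.4, 0.6)
    height_cm: float = 12.0
    height_sd: float = 1.0
    diameter_cm: float = 0.25
    diameter_sd: float = 0.015
    pa_cm2: float = 150.0
    pa_sd: float = 12.0
    fd: float = 1.6
    fd_sd: float = 0.04
    branch_depth: int = 2
    branch_angle_deg: float = 35.0
    replicates: int = 12

    def __post_init__(self):
        spreads = (*self.lab_sd, self.height_sd, self.diameter_sd, self.pa_sd, self.fd_sd)
        if any(s <= 0 for s in spreads):
            raise ValueError("all trait spreads must be positive")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Rasterizer-recorded truth for one rendered plant."""

    mask: np.ndarray
    pa_cm2: float
    ht_cm: float
    sd_cm: float
    mean_lab: tuple[float, float, float]
    group: str
    sal_s: int


def _make_default_groups() -> dict[tuple[str, str], GroupParams]:
    # Mid-points of the reported per-treatment ranges: L* rises with salinity
    # (more for the lower-tolerant population), a* falls (−6 → −10 lower,
    # −6 → −7 higher), b* rises to ~19 at severe salinity for the lower
    # population and stays ~10.5 for the higher; shoot diameter 0.20–0.35 cm.
    rows = {
        # population, treatment: L*, a*, b*, Ht, Sd, PA, FD
        ("lower", "NO-S"): (27.0, -6.0, 10.5, 10.0, 0.20, 130.0, 1.55),
        ("lower", "L-OS"): (29.0, -7.5, 13.0, 14.0, 0.25, 180.0, 1.65),
        ("lower", "H-OS"): (31.0, -9.0, 16.0, 14.0, 0.25, 175.0, 1.65),
        ("lower", "SS"): (36.0, -10.0, 19.0, 6.0, 0.23, 60.0, 1.35),
        ("higher", "NO-S"): (25.0, -6.0, 10.5, 10.0, 0.20, 130.0, 1.60),
        ("higher", "L-OS"): (26.0, -6.3, 10.5, 14.0, 0.25, 210.0, 1.70),
        ("higher", "H-OS"): (27.0, -6.6, 10.5, 16.0, 0.25, 250.0, 1.75),
        ("higher", "SS"): (28.0, -7.0, 10.5, 12.0, 0.35, 150.0, 1.70),
    }
    return {
        key: GroupParams(
            population=key[0],
            treatment=key[1],
            lab_mean=(L, a, b),
            height_cm=ht,
            diameter_cm=sd,
            pa_cm2=pa,
            fd=fd,
        )
        for key, (L, a, b, ht, sd, pa, fd) in rows.items()
    }


#: The 8 factorial cells of the default study layout.
DEFAULT_GROUPS: dict[tuple[str, str], GroupParams] = _make_default_groups()


def _branch_segments(
    x0: float,
    y0: float,
    angle: float,
    length: float,
    radius: float,
    depth: int,
    apex_y: float,
    rng: np.random.Generator,
    out: list,
) -> None:
    """Recursive shoot geometry in up-positive coordinates (y grows upward)."""
    x1 = x0 + length * math.sin(angle)
    y1 = y0 + length * math.cos(angle)
    out.append((x0, y0, x1, y1, radius))
    if depth <= 0:
        return
    n_children = int(rng.integers(2, 4))
    for _ in range(n_children):
        frac = float(rng.uniform(0.60, 0.92))
        side = 1.0 if rng.random() < 0.5 else -1.0
        child_angle = angle + side * math.radians(
            35.0 + float(rng.normal(0.0, 5.0))
        )
        bx = x0 + frac * length * math.sin(angle)
        by = y0 + frac * length * math.cos(angle)
        child_len = 0.45 * length * float(rng.uniform(0.8, 1.2))
        # keep branch tips at or below the main apex so the silhouette height
        # equals the stem length
        headroom = apex_y - by - radius
        cos_c = max(math.cos(child_angle), 0.05)
        child_len = min(child_len, max(headroom, 0.0) / cos_c * 0.95)
        if child_len < 3 * radius:
            continue
        _branch_segments(
            bx, by, child_angle, child_len, radius * 0.6, depth - 1, apex_y, rng, out
        )


def _paint_segment(lab_canvas, mask, x0, y0, x1, y1, radius, lab):
    h, w = mask.shape
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    if norm == 0:
        return
    px, py = -dy / norm * radius, dx / norm * radius
    poly_r = np.array([y0 + py, y1 + py, y1 - py, y0 - py])
    poly_c = np.array([x0 + px, x1 + px, x1 - px, x0 - px])
    rr, cc = _skdraw.polygon(poly_r, poly_c, shape=mask.shape)
    for ex, ey in ((x0, y0), (x1, y1)):
        dr, dc = _skdraw.disk((ey, ex), radius, shape=mask.shape)
        rr = np.concatenate([rr, dr])
        cc = np.concatenate([cc, dc])
    mask[rr, cc] = True
    lab_canvas[rr, cc] = lab


_BACKGROUND_RGB = (250, 250, 250)


def render_plant(
    params: GroupParams,
    seed: int,
    pixel_scale: float = 0.1,
    view: str = "front",
) -> tuple[np.ndarray, GroundTruth]:
    """Render one branched plant; returns (8-bit RGB image, GroundTruth).

    The front view grows a main vertical shoot with recursive secondary
    shoots; the canopy view radiates shoots from the pot centre.  Each
    segment is coloured by a small Lab jitter around the group mean; the
    truth (mask, area, height, stem diameter, mean Lab) is recorded from the
    rasterizer, before 8-bit quantization of the image.
    """
    rng = np.random.default_rng(seed)
    height_cm = max(float(rng.normal(params.height_cm, params.height_sd)), 1.0)
    diam_cm = max(float(rng.normal(params.diameter_cm, params.diameter_sd)), 0.05)
    h_px = height_cm * 10.0 / pixel_scale
    radius_px = diam_cm * 10.0 / pixel_scale / 2.0

    segments: list[tuple[float, float, float, float, float]] = []
    if view == "front":
        margin = 0.08 * h_px + 4 * radius_px
        base = (0.0, 0.0)
        _branch_segments(
            base[0], base[1], 0.0, h_px, radius_px, params.branch_depth, h_px, rng, segments
        )
        xs = [v for s in segments for v in (s[0], s[2])]
        half_w = max(max(map(abs, xs)) + margin, h_px * 0.4)
        shape = (int(h_px + 2 * margin), int(2 * half_w))
        # up-positive model coords -> raster rows (origin top-left)
        def to_raster(x, y):
            return x + half_w, (h_px + margin) - y
    elif view == "canopy":
        arm = h_px / 2.0
        n_arms = int(rng.integers(5, 9))
        for k in range(n_arms):
            ang = 2 * math.pi * k / n_arms + float(rng.normal(0.0, 0.15))
            sub: list = []
            _branch_segments(0.0, 0.0, ang, arm * float(rng.uniform(0.7, 1.0)),
                             radius_px, max(params.branch_depth - 1, 0), 10 * arm, rng, sub)
            segments.extend(sub)
        extent = max(max(abs(v) for s in segments for v in (s[0], s[2])),
                     max(abs(v) for s in segments for v in (s[1], s[3])))
        half_w = extent + 4 * radius_px + 8
        shape = (int(2 * half_w), int(2 * half_w))

        def to_raster(x, y):
            return x + half_w, half_w - y
    else:
        raise ValueError(f"unknown view {view!r}")

    if shape[0] > 6000 or shape[1] > 6000:
        raise ValueError("plant geometry exceeds the rendering canvas")

    mask = np.zeros(shape, dtype=bool)
    lab_canvas = np.zeros((*shape, 3), dtype=float)
    for (x0, y0, x1, y1, r) in segments:
        c0, r0 = to_raster(x0, y0)
        c1, r1 = to_raster(x1, y1)
        lab = np.asarray(params.lab_mean) + rng.normal(0.0, 1.0, size=3)
        _paint_segment(lab_canvas, mask, c0, r0, c1, r1, r, lab)

    if not mask.any():
        raise ValueError("degenerate geometry: nothing was rasterized")

    # crossing shoots enclose background pockets; treat those as fleshy
    # overlap and paint them, so the silhouette is hole-free by construction
    filled = ndimage.binary_fill_holes(mask)
    pockets = filled & ~mask
    if pockets.any():
        lab_canvas[pockets] = np.asarray(params.lab_mean, dtype=float)
        mask = filled

    mean_lab = tuple(float(v) for v in lab_canvas[mask].mean(axis=0))
    rgb = np.empty((*shape, 3), dtype=float)
    rgb[:] = np.asarray(_BACKGROUND_RGB, dtype=float) / 255.0
    rgb[mask] = _skcolor.lab2rgb(lab_canvas[mask][None, :, :])[0]
    image = np.round(np.clip(rgb, 0, 1) * 255.0).astype(np.uint8)

    rows = np.flatnonzero(mask.any(axis=1))
    truth = GroundTruth(
        mask=mask,
        pa_cm2=float(mask.sum()) * pixel_scale**2 / 100.0,
        ht_cm=(int(rows[-1]) - int(rows[0]) + 1) * pixel_scale / 10.0,
        sd_cm=2.0 * radius_px * pixel_scale / 10.0,
        mean_lab=mean_lab,
        group=published.assign_class(params.population, params.treatment),
        sal_s=published.TREATMENT_SALINITY[params.treatment],
    )
    return image, truth


def generate_feature_table(
    groups: Mapping[tuple[str, str], GroupParams] | None = None,
    seed: int = 0,
    replicates: int | None = None,
    include_destructive: bool = False,
) -> pd.DataFrame:
    """Draw a per-plant trait table from per-group Gaussian distributions.

    Columns: population, treatment, Sal.s., class, PA, CPA, Sd, Ht, FD, L,
    a, b, S, Hue, dE1, dE2 (ASCII names for L*, a*, b*, S*, ΔE1, ΔE2).  The
    ΔE2 baseline is the per-population mean Lab of the drawn NO-S rows.
    With the default 8 groups and 12 replicates this is the 96-plant trial
    layout; ``replicates=3`` gives the 24-plant validation layout.
    """
    groups = dict(groups if groups is not None else DEFAULT_GROUPS)
    rng = np.random.default_rng(seed)
    records = []
    for (pop, treat), g in groups.items():
        n = replicates if replicates is not None else g.replicates
        if n < 1:
            raise ValueError("replicate count must be >= 1")
        for _ in range(n):
            L = rng.normal(g.lab_mean[0], g.lab_sd[0])
            a = rng.normal(g.lab_mean[1], g.lab_sd[1])
            b = rng.normal(g.lab_mean[2], g.lab_sd[2])
            pa = max(rng.normal(g.pa_cm2, g.pa_sd), 1.0)
            records.append(
                {
                    "population": pop,
                    "treatment": treat,
                    "Sal.s.": published.TREATMENT_SALINITY[treat],
                    "class": published.assign_class(pop, treat),
                    "PA": pa,
                    "CPA": max(rng.normal(0.85 * g.pa_cm2, g.pa_sd), 1.0),
                    "Sd": max(rng.normal(g.diameter_cm, g.diameter_sd), 0.02),
                    "Ht": max(rng.normal(g.height_cm, g.height_sd), 0.5),
                    "FD": rng.normal(g.fd, g.fd_sd),
                    "L": L,
                    "a": a,
                    "b": b,
                }
            )
    table = pd.DataFrame.from_records(records)
    table["S"] = chroma(table["a"].to_numpy(), table["b"].to_numpy())
    table["Hue"] = hue_angle(table["a"].to_numpy(), table["b"].to_numpy())
    lab = table[["L", "a", "b"]].to_numpy()
    table["dE1"] = np.sqrt(((lab - WHITE_STANDARD.as_array()) ** 2).sum(axis=1))
    de2 = np.empty(len(table))
    for pop in table["population"].unique():
        in_pop = table["population"] == pop
        nos = in_pop & (table["treatment"] == "NO-S")
        if not nos.any():
            raise ValueError(f"population {pop!r} has no NO-S rows for the ΔE2 baseline")
        baseline = lab[nos.to_numpy()].mean(axis=0)
        de2[in_pop.to_numpy()] = np.sqrt(
            ((lab[in_pop.to_numpy()] - baseline) ** 2).sum(axis=1)
        )
    table["dE2"] = de2
    if include_destructive:
        table = _add_destructive(table, rng)
    return table


def _add_destructive(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Optional destructive covariates with simple monotone salinity trends.

    FW/DW follow the published per-population biomass–area calibrations plus
    noise; the biochemical columns are plausibility-only approximations.
    """
    t = table.copy()
    fw = np.empty(len(t))
    dw = np.empty(len(t))
    for pop in ("lower", "higher"):
        m = t["population"] == pop
        fw[m.to_numpy()] = np.polyval(
            published.BIOMASS_CALIBRATIONS[(pop, "FW")], t.loc[m, "PA"].to_numpy()
        )
        dw[m.to_numpy()] = np.polyval(
            published.BIOMASS_CALIBRATIONS[(pop, "DW")], t.loc[m, "PA"].to_numpy()
        )
    t["FW"] = np.clip(fw + rng.normal(0, 0.5, len(t)), 0.1, None)
    t["DW"] = np.clip(dw + rng.normal(0, 0.05, len(t)), 0.01, None)
    sal = t["Sal.s."].to_numpy(dtype=float)
    tol = np.where(t["population"] == "higher", 1.3, 1.0)
    t["Prol"] = 15.0 + 0.05 * sal * tol + rng.normal(0, 3.0, len(t))
    t["HP"] = 8.0 + 0.004 * sal / tol + rng.normal(0, 0.6, len(t))
    cha = np.clip(1.2 - 0.0007 * sal / tol + rng.normal(0, 0.05, len(t)), 0.05, None)
    chb = np.clip(0.5 - 0.0003 * sal / tol + rng.normal(0, 0.03, len(t)), 0.02, None)
    t["Cha"], t["Chb"], t["TCh"] = cha, chb, cha + chb
    t["Car"] = np.clip(0.4 - 0.0002 * sal / tol + rng.normal(0, 0.02, len(t)), 0.01, None)
    t["ACS"] = t["Sd"].to_numpy() * 1e4 + rng.normal(0, 100.0, len(t))
    return t


def trial_table(seed: int = 0, **kwargs) -> pd.DataFrame:
    """The default 96-plant trial layout (4 treatments × 2 populations × 12)."""
    return generate_feature_table(seed=seed, replicates=12, **kwargs)


def validation_table(seed: int = 1, **kwargs) -> pd.DataFrame:
    """The default 24-plant validation layout (4 × 2 × 3)."""
    return generate_feature_table(seed=seed, replicates=3, **kwargs)


def generate_from_model(
    model: Mapping[str, float],
    predictor_ranges: Mapping[str, Sequence[float] | tuple[float, float]],
    noise_sd: float,
    n: int,
    seed: int,
    response: str = "y",
) -> pd.DataFrame:
    """Dataset for coefficient recovery: predictors ~ stated ranges, response
    = linear model + Gaussian noise.

    ``model`` maps predictor names to coefficients, with ``"const"`` the
    intercept.  A 2-tuple range draws uniformly on [lo, hi]; a longer
    sequence draws uniformly from its discrete values.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    names = [k for k in model if k != "const"]
    if n <= len(model) + 1:
        raise ValueError("n must exceed the number of coefficients + 1")
    widths = []
    for name in names:
        if name not in predictor_ranges:
            raise ValueError(f"no range given for predictor {name!r}")
        r = predictor_ranges[name]
        widths.append(
            (max(r) - min(r)) if len(r) > 2 else (float(r[1]) - float(r[0]))
        )
    if all(w == 0 for w in widths):
        raise ValueError("degenerate ranges: zero width on all predictors")
    rng = np.random.default_rng(seed)
    data = {}
    for name in names:
        r = predictor_ranges[name]
        if isinstance(r, tuple) and len(r) == 2:
            data[name] = rng.uniform(float(r[0]), float(r[1]), size=n)
        else:
            data[name] = rng.choice(np.asarray(r, dtype=float), size=n)
    table = pd.DataFrame(data)
    y = float(model["const"]) + sum(
        float(model[name]) * table[name].to_numpy() for name in names
    )
    table[response] = y + rng.normal(0.0, noise_sd, size=n)
    return table


def generate_cross_section(
    proportions: Sequence[float], radius_px: int = 200, seed: int = 0
) -> np.ndarray:
    """Concentric-annulus stem cross-section phantom.

    ``proportions`` are the target pixel shares of (epidermis, palisade,
    water-storage parenchyma, vascular+sclerenchyma, pith), outermost first,
    summing to 1.  Annulus radii are sized so realized shares match the
    request within ~0.5 percentage points at the default radius.  The
    construction is deterministic; ``seed`` is accepted for interface
    uniformity with the other generators.
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (5,):
        raise ValueError("exactly 5 tissue proportions are required")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must be non-negative and sum to 1")
    # cumulative area fractions from the centre outward: pith innermost
    inner_fracs = np.cumsum(p[::-1])  # pith, +vascular, +water, +palisade, all
    radii = radius_px * np.sqrt(inner_fracs)
    size = 2 * radius_px + 1
    yy, xx = np.mgrid[:size, :size]
    dist = np.hypot(yy - radius_px, xx - radius_px)
    section = np.zeros((size, size), dtype=np.uint8)
    labels_in_to_out = (5, 4, 3, 2, 1)
    prev = 0.0
    for lab, r in zip(labels_in_to_out, radii):
        section[(dist >= prev) & (dist < r)] = lab
        prev = r
    return section
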