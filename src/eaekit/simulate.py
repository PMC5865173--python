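"""Synthetic-data generators emulating the study's three data modalities.

* Cytometry: per-event log-normal marker intensities drawn population by
  population from the packaged composition profiles, with an exact Jurkat
  spike-in, viability flagging, fluorescent-protein co-expression, and a
  bone-marrow chimera mode (CD45.1 host / CD45.2 donor origin channels).
* Histology: spinal-cord slice records — a cord-shaped boundary polygon
  (ellipse with a dorsal median indentation), plaque-clustered white-matter
  point patterns with a ventro-lateral bias, diffuse cells per compartment,
  and immunostain flags.
* Intravital imaging: cell masks of the three morphology classes with
  optional phagocytic inclusions; per-mouse density time courses; image
  stacks with known integer drifts.

All generators draw from a single numpy Generator seeded explicitly, so a
fixed seed reproduces every sample bit for bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter

from . import profiles_io
from .datatypes import (
    FP_CHANNELS,
    PANEL,
    CompositionProfile,
    MorphSimConfig,
    PopulationProfile,
    SliceRecord,
    SliceSimConfig,
    ValidationError,
)
from .morphology import CellMask
from .spatial import ray_boundary_distance

FP_LABELS = ("EGFP", "EYFP", "double", "none")


# ---------------------------------------------------------------------------
# cytometry

def _draw_population(
    prof: PopulationProfile, n: int, rng: np.random.Generator,
    fp_levels: tuple[float, float], log_sd: float,
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for marker in PANEL:
        spec = prof.marker_specs[marker]
        cols[marker] = 10.0 ** rng.normal(spec.log_mean, spec.log_sd, n)
    p_e, p_y, p_d = prof.fp_probs
    cat = rng.choice(4, size=n, p=[p_e, p_y, p_d, 1.0 - p_e - p_y - p_d])
    neg_mean, pos_mean = fp_levels
    egfp_on = (cat == 0) | (cat == 2)
    eyfp_on = (cat == 1) | (cat == 2)
    cols["EGFP"] = 10.0 ** rng.normal(np.where(egfp_on, pos_mean, neg_mean), log_sd)
    cols["EYFP"] = 10.0 ** rng.normal(np.where(eyfp_on, pos_mean, neg_mean), log_sd)
    df = pd.DataFrame(cols)
    df["true_label"] = prof.label
    df["true_fp"] = np.asarray(FP_LABELS, dtype=object)[cat]
    return df


def simulate_cytometry_sample(
    profiles: dict[str, PopulationProfile],
    composition: CompositionProfile,
    n_events: int,
    n_jurkat_spike: int = 0,
    dead_fraction: float = 0.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Synthetic cytometry event table for one composition profile.

    ``n_events`` CD45+ infiltrate events are split multinomially across the
    composition; exactly ``n_jurkat_spike`` Jurkat (hCD3+ CD45-) events are
    appended, emulating the fixed-count spike-in used for absolute count
    calibration.  Every event is independently flagged dead (viability-dye
    positive) with probability ``dead_fraction``.
    """
    if n_events <= 0:
        raise ValidationError("n_events must be > 0")
    unknown = set(composition.fractions) - set(profiles)
    if unknown:
        raise ValidationError(f"composition refers to unknown populations {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    model = profiles_io.marker_model()
    fp_levels = (model["levels"]["neg"], model["levels"]["pos"])
    log_sd = model["log_sd"]

    pops = sorted(composition.fractions)
    counts = rng.multinomial(n_events, [composition.fractions[p] for p in pops])
    blocks = [
        _draw_population(profiles[p], int(k), rng, fp_levels, log_sd)
        for p, k in zip(pops, counts) if k > 0
    ]
    if n_jurkat_spike > 0:
        blocks.append(_draw_population(profiles["Jurkat"], n_jurkat_spike, rng,
                                       fp_levels, log_sd))
    events = pd.concat(blocks, ignore_index=True)
    events = events.iloc[rng.permutation(len(events))].reset_index(drop=True)
    events["dead"] = rng.random(len(events)) < dead_fraction
    events.attrs.update(
        condition=composition.condition, tissue=composition.tissue,
        day=composition.day, n_jurkat_spike=n_jurkat_spike,
    )
    return events


def simulate_chimera_sample(
    profiles: dict[str, PopulationProfile],
    composition: CompositionProfile,
    n_events: int,
    seed: int | None = 0,
    n_jurkat_spike: int = 0,
) -> pd.DataFrame:
    """Bone-marrow chimera sample with a CD45.1 (host) / CD45.2 (donor) origin.

    Each event's origin is Bernoulli(``origin_prob_donor``) of its
    population: microglia are forced host origin, CD44+ monocyte-derived
    populations are fully donor derived, CD44- macrophages 91% donor.
    Human Jurkat spike-in events (when requested) carry neither congenic
    marker.
    """
    events = simulate_cytometry_sample(
        profiles, composition, n_events, n_jurkat_spike, 0.0, seed)
    rng = np.random.default_rng(None if seed is None else seed + 0x5EED)
    model = profiles_io.marker_model()
    neg, pos = model["levels"]["neg"], model["levels"]["pos"]
    log_sd = model["log_sd"]
    p_donor = events["true_label"].map(
        {k: v.origin_prob_donor for k, v in profiles.items()}
    ).to_numpy(dtype=float)
    donor = rng.random(len(events)) < p_donor
    human = (events["true_label"] == "Jurkat").to_numpy()
    events["CD45_1"] = 10.0 ** rng.normal(np.where(donor | human, neg, pos), log_sd)
    events["CD45_2"] = 10.0 ** rng.normal(np.where(donor & ~human, pos, neg), log_sd)
    events["true_origin"] = np.where(human, "none", np.where(donor, "donor", "host"))
    return events


# ---------------------------------------------------------------------------
# histology slices

def cord_boundary(
    radius_um: float = 500.0, n_vertices: int = 180,
    aspect: float = 1.3, notch_depth: float = 0.22, notch_width: float = 0.18,
) -> np.ndarray:
    """Cord-like boundary polygon: ellipse (a = aspect * b, horizontal major
    axis) with a dorsal median indentation; +y is dorsal."""
    phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    a, b = aspect * radius_um, radius_um
    r_ell = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    notch = 1.0 - notch_depth * np.exp(-((phi - np.pi / 2) / notch_width) ** 2)
    r = r_ell * notch
    return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)


def _place(center, boundary, r, theta):
    """Map normalized polar coordinates back to µm via the boundary rays."""
    R = ray_boundary_distance(center, theta, boundary)
    x = center[0] + r * R * np.cos(theta)
    y = center[1] + r * R * np.sin(theta)
    return x, y


def _sector_theta(rng, sector: str, n: int) -> np.ndarray:
    if sector == "dorsal":
        return rng.uniform(np.pi / 4, 3 * np.pi / 4, n)
    # ventro-lateral: the 270-degree complement of the dorsal sector
    t = rng.uniform(0.0, 1.5 * np.pi, n)
    return np.mod(t + 3 * np.pi / 4, 2 * np.pi)


def simulate_slice(cfg: SliceSimConfig, seed: int | None = 0) -> SliceRecord:
    """One synthetic slice: boundary, plaque clusters and diffuse cells.

    Plaque counts are Poisson per sector; centers are uniform over the
    white-matter annulus of their sector with a minimum pairwise separation
    so plaques remain distinct countable lesions; member cells are
    isotropic Gaussians (sd ``plaque_radius``) around the centers.  Diffuse
    cells are uniform over their compartment.  Ground truth (plaque id,
    sector) is stored in the cell table and metadata.
    """
    rng = np.random.default_rng(seed)
    boundary = cord_boundary(cfg.boundary_radius_um)
    from shapely.geometry import Polygon  # local import: cheap, avoids cycle

    poly = Polygon(boundary)
    center = (poly.centroid.x, poly.centroid.y)
    r_in, r_out = cfg.white_matter_annulus

    # plaque centers per sector, in normalized cartesian coordinates
    centers, sectors = [], []
    for sector, mean in zip(("dorsal", "ventro_lateral"), cfg.plaque_count_mean):
        for _ in range(rng.poisson(mean)):
            for _try in range(300):
                th = float(_sector_theta(rng, sector, 1)[0])
                rr = float(np.sqrt(rng.uniform(r_in**2, r_out**2)))
                p = np.array([rr * np.cos(th), rr * np.sin(th)])
                if all(np.hypot(*(p - q)) >= cfg.plaque_min_separation
                       for q in centers):
                    break
            centers.append(p)
            sectors.append(sector)

    rows: list[pd.DataFrame] = []
    for pid, (p, sector) in enumerate(zip(centers, sectors)):
        k = rng.poisson(cfg.plaque_cells_mean)
        if k == 0:
            continue
        mix = cfg.plaque_channel_mix or {"EGFP": 1.0}
        chans = rng.choice(list(mix), size=k, p=np.asarray(list(mix.values())) /
                           sum(mix.values()))
        xy = p + rng.normal(0.0, cfg.plaque_radius, (k, 2))
        rr = np.hypot(xy[:, 0], xy[:, 1])
        clip = rr > 0.995
        xy[clip] *= (0.995 / rr[clip])[:, None]
        rows.append(pd.DataFrame({
            "r": np.hypot(xy[:, 0], xy[:, 1]),
            "theta": np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2 * np.pi),
            "channel": chans, "plaque_id": pid,
        }))

    for channel, n in cfg.n_cells.items():
        if n <= 0:
            continue
        compartment = cfg.diffuse_compartment.get(channel, "all")
        lo, hi = (r_in, r_out) if compartment == "white" else (0.0, 0.998)
        rr = np.sqrt(rng.uniform(lo**2, hi**2, n))
        th = rng.uniform(0.0, 2 * np.pi, n)
        rows.append(pd.DataFrame({
            "r": rr, "theta": th, "channel": channel, "plaque_id": -1,
        }))

    cells = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["r", "theta", "channel", "plaque_id"]))
    # immunostain flags per channel
    for flag in sorted({f for fl in cfg.flag_probs.values() for f in fl}):
        p = cells["channel"].map(
            {c: fl.get(flag, 0.0) for c, fl in cfg.flag_probs.items()}
        ).fillna(0.0).to_numpy(dtype=float)
        cells[flag] = rng.random(len(cells)) < p

    x, y = _place(center, boundary,
                  cells["r"].to_numpy(float), cells["theta"].to_numpy(float))
    cells.insert(0, "x", x)
    cells.insert(1, "y", y)
    cells = cells.drop(columns=["r", "theta"])

    meta = {
        "center": center,
        "n_plaques_true": {
            "dorsal": sectors.count("dorsal"),
            "ventro_lateral": sectors.count("ventro_lateral"),
        },
        "plaque_centers": [tuple(map(float, p)) for p in centers],
        "plaque_sectors": list(sectors),
        "seed": seed,
    }
    return SliceRecord(boundary=boundary, cells=cells, metadata=meta)


# ---------------------------------------------------------------------------
# cell masks

def _raster_capsule(size, c0, c1, radius):
    yy, xx = np.mgrid[0:size, 0:size]
    p = np.stack([xx, yy], axis=-1).astype(float)
    d = np.asarray(c1) - np.asarray(c0)
    L2 = float(d @ d)
    t = 0.0 if L2 == 0 else np.clip(((p - c0) @ d) / L2, 0.0, 1.0)
    closest = np.asarray(c0) + t[..., None] * d
    return np.hypot(*(p - closest).transpose(2, 0, 1)) <= radius


def _mask_ameboid(size, rng):
    c = size / 2 + rng.uniform(-3, 3, 2)
    a = rng.uniform(9.0, 14.0)
    q = rng.uniform(1.0, 1.5)
    b = a / q
    phi = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - c[0]) * np.cos(phi) + (yy - c[1]) * np.sin(phi)
    v = -(xx - c[0]) * np.sin(phi) + (yy - c[1]) * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _mask_elongated(size, rng):
    c = np.array([size / 2, size / 2]) + rng.uniform(-3, 3, 2)
    phi = rng.uniform(0, np.pi)
    L = rng.uniform(16.0, 24.0)
    w = rng.uniform(3.5, 5.5)
    d = np.array([np.cos(phi), np.sin(phi)])
    return _raster_capsule(size, c - L * d, c + L * d, w)


def _mask_ramified(size, rng):
    c = np.array([size / 2, size / 2]) + rng.uniform(-2, 2, 2)
    rho = rng.uniform(6.0, 9.0)
    yy, xx = np.mgrid[0:size, 0:size]
    m = np.hypot(xx - c[0], yy - c[1]) <= rho
    k = rng.integers(3, 7)
    base = rng.uniform(0, 2 * np.pi)
    for i in range(k):
        ang = base + 2 * np.pi * i / k + rng.uniform(-0.35, 0.35)
        length = rng.uniform(15.0, 28.0)
        width = rng.uniform(1.2, 1.6)
        d = np.array([np.cos(ang), np.sin(ang)])
        m |= _raster_capsule(size, c, c + length * d, width)
    return m


_MASK_FACTORIES = {
    "ameboid": _mask_ameboid, "elongated": _mask_elongated,
    "ramified": _mask_ramified,
}


def simulate_cell_masks(
    cfg: MorphSimConfig, n: int = 100, seed: int | None = 0
) -> list[tuple[CellMask, str, bool]]:
    """Synthetic cell masks with ground-truth class and phagocytic flag.

    Ameboid cells are near-convex elliptical blobs, elongated cells
    high-aspect capsules, ramified cells a central body with 3-6 thin
    processes.  Phagocytic cells carry 1-3 dark intensity inclusions fully
    inside the central body.
    """
    rng = np.random.default_rng(seed)
    size = cfg.mask_size
    classes = sorted(cfg.class_fractions)
    probs = np.asarray([cfg.class_fractions[c] for c in classes])
    out: list[tuple[CellMask, str, bool]] = []
    for cls in rng.choice(classes, size=n, p=probs):
        mask = _MASK_FACTORIES[cls](size, rng)
        inten = np.where(mask, 1.0 + rng.normal(0.0, 0.04, mask.shape), 0.0)
        phag = bool(rng.random() < cfg.phagocytic_fraction.get(cls, 0.0))
        if phag:
            # inclusions must sit strictly inside the cell body
            dt = ndimage.distance_transform_edt(mask)
            yy, xx = np.mgrid[0:size, 0:size]
            for _ in range(rng.integers(1, 4)):
                rad = rng.uniform(2.0, 3.2)
                cand = np.argwhere(dt >= rad + 2.0)
                if len(cand) == 0:
                    rad = 2.0
                    cand = np.argwhere(dt >= rad + 2.0)
                cy, cx = cand[rng.integers(len(cand))]
                hole = np.hypot(xx - cx, yy - cy) <= rad
                inten[hole & mask] = 0.15
        out.append((CellMask(mask=mask, intensity=inten), cls, phag))
    return out


# ---------------------------------------------------------------------------
# time courses and image stacks

def simulate_timecourse(
    n_mice: int = 9,
    days: list[int] | None = None,
    effect_profile: dict | None = None,
    seed: int | None = 0,
    condition: str = "MOG.CFA.PTX",
) -> pd.DataFrame:
    """Per-mouse, per-day cell densities, axon counts and clinical scores.

    Densities are baseline x day-effect x log-normal mouse effect x
    log-normal measurement noise; axon counts are Poisson around their
    profile; scores are the profile plus Gaussian noise clipped to the
    clinical scale.  A profile of all-ones effects yields a null time
    course statistically flat across days.
    """
    prof = effect_profile if effect_profile is not None \
        else profiles_io.load_timecourse_profile()
    days = list(days) if days is not None else list(prof["days"])
    if 0 not in days:
        raise ValidationError("schedule must include day 0 (induction baseline)")
    rng = np.random.default_rng(seed)
    rows = []
    for mouse in range(n_mice):
        m_eff = {ch: rng.lognormal(0.0, prof["mouse_log_sd"])
                 for ch in ("EGFP", "EYFP", "double", "axon")}
        for day in days:
            row = {"mouse": f"m{mouse:02d}", "day": day, "condition": condition}
            for ch in ("EGFP", "EYFP", "double"):
                mu = prof["baseline_per_fov"][ch] * prof["effects"][ch][day] * m_eff[ch]
                row[ch] = mu * rng.lognormal(0.0, prof["noise_log_sd"])
            row["axons"] = rng.poisson(
                prof["baseline_axons"] * prof["effects"]["axon"][day] * m_eff["axon"])
            score = prof["score"][day] + rng.normal(0.0, prof["score_sd"])
            row["score"] = float(np.clip(score, 0.0, prof["score_max"]))
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_cell_depths(
    n_cells: int, day: int, seed: int | None = 0,
    meningeal_scale_um: float = 15.0, infiltration_day: int = 13,
    deep_scale_um: float = 45.0,
) -> np.ndarray:
    """Depths (µm below the dura) with a top-down infiltration gradient.

    Early in disease, cells accumulate in the meninges (exponential depth
    profile with a short scale); from ``infiltration_day`` on they move
    into the parenchyma (longer scale), so the meningeal fraction at a
    fixed boundary decreases between early and late time points.
    """
    rng = np.random.default_rng(seed)
    scale = meningeal_scale_um if day < infiltration_day else deep_scale_um
    return rng.exponential(scale, n_cells)


def null_effect_profile() -> dict:
    """All-ones effect profile (no disease): for null-model checks."""
    prof = {k: (dict(v) if isinstance(v, dict) else v)
            for k, v in profiles_io.load_timecourse_profile().items()}
    for ch in prof["effects"]:
        prof["effects"][ch] = {d: 1.0 for d in prof["days"]}
    prof["score"] = {d: 0.0 for d in prof["days"]}
    return prof


def simulate_drifting_stack(
    n_frames: int = 8,
    shape: tuple[int, int] = (128, 128),
    max_drift: int = 5,
    noise_sd: float = 0.0,
    drifts: list[tuple[int, int]] | None = None,
    seed: int | None = 0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Image stack whose frames are integer-shifted copies of frame 0.

    Returns (stack, ground-truth drifts); drift (dy, dx) means frame i is
    the reference translated by that amount (zero-filled borders).  The
    reference frame's drift is (0, 0).
    """
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.random(shape), 3.0)
    for _ in range(25):  # bright punctate cells on a smooth background
        cy, cx = rng.integers(10, shape[0] - 10), rng.integers(10, shape[1] - 10)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        base += 2.0 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / 8.0))
    if drifts is None:
        drifts = [(0, 0)] + [tuple(rng.integers(-max_drift, max_drift + 1, 2))
                             for _ in range(n_frames - 1)]
    stack = np.empty((len(drifts),) + shape)
    for i, (dy, dx) in enumerate(drifts):
        frame = np.zeros(shape)
        src = base[
            max(0, -dy): shape[0] - max(0, dy),
            max(0, -dx): shape[1] - max(0, dx),
        ]
        frame[
            max(0, dy): shape[0] - max(0, -dy),
            max(0, dx): shape[1] - max(0, -dx),
        ] = src
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, shape)
        stack[i] = frame
    return stack, [tuple(map(int, d)) for d in drifts]
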