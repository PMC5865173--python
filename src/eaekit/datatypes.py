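"""Core data containers shared across the toolkit.

Conventions
-----------
* Cytometry event tables are plain :class:`pandas.DataFrame` objects with one
  row per event and one column per marker / fluorescent-protein channel, plus
  a boolean ``dead`` viability column (True = viability-dye positive).
  Optional ground-truth columns (``true_label``, ``true_fp``, ``true_origin``)
  are carried by synthetic samples for recovery tests.
* Slice coordinates are micrometres, 0-based image coordinates with +y dorsal.
  Standardized coordinates are (r, theta) on the unit disk, theta measured
  counterclockwise from +x in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Marker expression levels in increasing order of fluorescence.
LEVELS = ("neg", "dim", "int", "pos", "high")

#: Terminal population labels of the gating tree.
POPULATIONS = (
    "Jurkat", "Bc", "NKc", "Tc_CD8", "Tc_CD4", "Ne",
    "Mi_rest", "Mi_act", "cDC1", "cDC2",
    "P1_mono", "P2_moDC", "P3_moDC", "P4_mac", "P5_mac",
)

#: Antibody panel (surface markers) carried by every event table.
PANEL = (
    "CD45", "CD19", "CD161", "MHCII", "TCRb", "CD5", "CD8a", "CD11b",
    "Ly6G", "CD11c", "Ly6C", "CD64", "CD44", "F4_80", "hCD3",
    "CD45_1", "CD45_2",
)

#: Fluorescent-protein channels.
FP_CHANNELS = ("EGFP", "EYFP")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class MarkerLevelSpec:
    """Log-normal intensity model for one marker at one expression level."""

    marker: str
    level: str
    log_mean: float  # log10 arbitrary fluorescence units
    log_sd: float    # log10 units

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown level {self.level!r}")
        if not self.log_sd > 0:
            raise ValidationError("log_sd must be > 0")


@dataclass
class PopulationProfile:
    """Marker-level and fluorescent-protein model for one population.

    ``fp_probs`` holds probabilities of (EGFP-only, EYFP-only, double);
    the remainder is unlabeled.  ``origin_prob_donor`` is the probability
    that an event is of donor (CD45.2) bone-marrow origin in chimera mode.
    """

    label: str
    marker_specs: dict[str, MarkerLevelSpec]
    fp_probs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    origin_prob_donor: float = 1.0

    def __post_init__(self) -> None:
        missing = set(PANEL) - set(self.marker_specs)
        if missing:
            raise ValidationError(f"{self.label}: missing marker specs {sorted(missing)}")
        if not all(0.0 <= p <= 1.0 for p in self.fp_probs) or sum(self.fp_probs) > 1.0 + 1e-9:
            raise ValidationError(f"{self.label}: invalid fp_probs {self.fp_probs}")
        if not 0.0 <= self.origin_prob_donor <= 1.0:
            raise ValidationError(f"{self.label}: invalid origin_prob_donor")


@dataclass
class CompositionProfile:
    """Population fractions of CD45+ events for one (condition, tissue, day)."""

    condition: str
    tissue: str
    day: int
    fractions: dict[str, float]
    approx: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.fractions.values()), dtype=float)
        if (vals < 0).any():
            raise ValidationError("composition fractions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.condition}/{self.tissue}/d{self.day}: fractions sum to {vals.sum():.12f}"
            )
        unknown = set(self.fractions) - set(POPULATIONS)
        if unknown:
            raise ValidationError(f"unknown populations {sorted(unknown)}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.condition, self.tissue, self.day)


@dataclass
class SliceSimConfig:
    """Parameters of the synthetic spinal-cord slice generator.

    Cell counts are per channel; plaque counts are Poisson means per sector
    (dorsal, ventro-lateral).  Radii are in normalized (standardized disk)
    units.
    """

    n_cells: dict[str, int] = field(default_factory=dict)
    diffuse_compartment: dict[str, str] = field(default_factory=dict)  # 'white' | 'all'
    plaque_count_mean: tuple[float, float] = (1.0, 4.0)  # (dorsal, ventro-lateral)
    plaque_cells_mean: float = 40.0
    plaque_channel_mix: dict[str, float] = field(default_factory=dict)
    plaque_radius: float = 0.04
    plaque_min_separation: float = 0.2
    white_matter_annulus: tuple[float, float] = (0.55, 0.95)
    flag_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    boundary_radius_um: float = 500.0  # semi-minor axis of the cord ellipse

    def __post_init__(self) -> None:
        r_in, r_out = self.white_matter_annulus
        if not (0.0 <= r_in < r_out <= 1.0):
            raise ValidationError("white_matter_annulus must satisfy 0 <= r_in < r_out <= 1")
        if any(m < 0 for m in self.plaque_count_mean):
            raise ValidationError("plaque count means must be >= 0")


@dataclass
class MorphSimConfig:
    """Parameters of the synthetic cell-mask generator."""

    class_fractions: dict[str, float]
    phagocytic_fraction: dict[str, float] = field(default_factory=dict)
    mask_size: int = 96

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class fractions sum to {total}")
        if self.mask_size < 32:
            raise ValidationError("mask size must be >= 32 px")


@dataclass
class ThresholdSet:
    """Per-marker cutpoints on the asinh-transformed scale.

    ``pos`` maps marker -> negative/positive cutpoint.  Tri-level markers
    additionally carry ``dim_int`` and ``int_high`` cutpoints (for CD45 the
    ``pos`` entry separates negative from dim).
    """

    pos: dict[str, float]
    dim_int: dict[str, float] = field(default_factory=dict)
    int_high: dict[str, float] = field(default_factory=dict)
    cofactor: float = 150.0

    def __post_init__(self) -> None:
        for marker in self.dim_int:
            cuts = [self.pos[marker], self.dim_int[marker]]
            if marker in self.int_high:
                cuts.append(self.int_high[marker])
            if not all(a < b for a, b in zip(cuts, cuts[1:])):
                raise ValidationError(f"{marker}: cutpoints not strictly increasing: {cuts}")


@dataclass
class GateResult:
    """Outcome of hierarchical gating: per-event labels, paths and counts."""

    labels: pd.Series              # terminal label per event ('dead' for excluded)
    paths: dict[str, tuple[str, ...]]  # label -> ordered gate path
    counts: pd.Series              # terminal label -> live single event count

    @property
    def n_live(self) -> int:
        return int(self.counts.sum())


@dataclass
class SliceRecord:
    """One spinal-cord slice: boundary polygon plus detected cell points."""

    boundary: np.ndarray           # (V, 2) closed polygon vertices, µm
    cells: pd.DataFrame            # columns x, y, channel, optional flag cols
    metadata: dict = field(default_factory=dict)


@dataclass
class StandardizedSlice:
    """Slice mapped onto the unit disk by boundary-relative polar scaling."""

    cells: pd.DataFrame            # columns r, theta, channel, flags
    center: tuple[float, float]
    metadata: dict = field(default_factory=dict)
    flagged: np.ndarray | None = None  # indices of cells the transform could not place


@dataclass
class DensityMap:
    """Gridded average cell density over the standardized disk.

    ``grid`` is an (N, N) float array in cells per unit normalized area,
    NaN outside the unit disk.  The integral over the disk equals the mean
    cell count per slice.
    """

    grid: np.ndarray
    n_slices: int
    channel: str | None = None

    @property
    def grid_n(self) -> int:
        return self.grid.shape[0]


@dataclass
class BandProfile:
    """Densities in K equal-area concentric bands of the unit disk."""

    edges: np.ndarray              # K+1 radii, sqrt(k/K)
    counts: np.ndarray             # mean cell count per band (per slice)
    densities: np.ndarray          # counts / (pi / K)
    n_slices: int = 1

    @property
    def n_bands(self) -> int:
        return len(self.counts)


@dataclass
class PlaqueSet:
    """Detected plaques (dense cell clusters) of one standardized slice."""

    members: list[np.ndarray]      # per plaque: indices into the cell table
    centroids: np.ndarray          # (P, 2) centroid (r, theta)
    sectors: list[str]

    @property
    def n_plaques(self) -> int:
        return len(self.members)
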