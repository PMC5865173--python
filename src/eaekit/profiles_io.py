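"""Loading of the packaged plain-text profile files.

The package ships its study conditions as YAML under ``eaekit/profiles``:
marker-level models and per-population assignments (``markers.yaml``),
CD45+ composition per condition/tissue/day (``compositions.yaml``), slice
simulation profiles (``slices.yaml``), morphology class mixtures
(``morphology.yaml``) and the longitudinal effect profile
(``timecourse.yaml``).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .datatypes import (
    PANEL,
    CompositionProfile,
    MarkerLevelSpec,
    MorphSimConfig,
    PopulationProfile,
    SliceSimConfig,
    ValidationError,
)


def _read_yaml(name: str) -> dict:
    ref = resources.files("eaekit.profiles").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def marker_model() -> dict:
    """Raw marker model: level means, log_sd, tri-level channels."""
    raw = _read_yaml("markers.yaml")
    return {
        "levels": raw["levels"],
        "log_sd": float(raw["log_sd"]),
        "tri_level": raw.get("tri_level", {}),
    }


def load_population_profiles(path: str | None = None) -> dict[str, PopulationProfile]:
    """Build :class:`PopulationProfile` objects for all 15 populations."""
    raw = _read_yaml("markers.yaml") if path is None else yaml.safe_load(open(path))
    levels = raw["levels"]
    log_sd = float(raw["log_sd"])
    profiles: dict[str, PopulationProfile] = {}
    for label, spec in raw["populations"].items():
        marker_specs = {}
        for marker in PANEL:
            level = spec["markers"].get(marker, "neg")
            if level not in levels:
                raise ValidationError(f"{label}/{marker}: unknown level {level!r}")
            marker_specs[marker] = MarkerLevelSpec(
                marker=marker, level=level,
                log_mean=float(levels[level]), log_sd=log_sd,
            )
        profiles[label] = PopulationProfile(
            label=label,
            marker_specs=marker_specs,
            fp_probs=tuple(float(p) for p in spec.get("fp", (0, 0, 0))),
            origin_prob_donor=float(spec.get("origin_prob_donor", 1.0)),
        )
    return profiles


def load_composition_profiles(path: str | None = None) -> dict[tuple, CompositionProfile]:
    """Composition profiles keyed by (condition, tissue, day)."""
    raw = _read_yaml("compositions.yaml") if path is None else yaml.safe_load(open(path))
    out: dict[tuple, CompositionProfile] = {}
    for entry in raw["compositions"]:
        prof = CompositionProfile(
            condition=entry["condition"],
            tissue=entry["tissue"],
            day=int(entry["day"]),
            fractions={k: float(v) for k, v in entry["fractions"].items()},
            approx=bool(entry.get("approx", False)),
        )
        out[prof.key] = prof
    return out


def default_profiles() -> tuple[dict[str, PopulationProfile], dict[tuple, CompositionProfile]]:
    """The packaged population and composition profiles."""
    return load_population_profiles(), load_composition_profiles()


def load_slice_profiles(path: str | None = None) -> dict[tuple[str, int], SliceSimConfig]:
    """Slice simulation profiles keyed by (condition, day)."""
    raw = _read_yaml("slices.yaml") if path is None else yaml.safe_load(open(path))
    d = raw["defaults"]
    out: dict[tuple[str, int], SliceSimConfig] = {}
    for entry in raw["slices"]:
        cfg = SliceSimConfig(
            n_cells={k: int(v) for k, v in entry["n_cells"].items()},
            diffuse_compartment=dict(d["diffuse_compartment"]),
            plaque_count_mean=tuple(float(v) for v in entry["plaque_count_mean"]),
            plaque_cells_mean=float(d["plaque_cells_mean"]),
            plaque_channel_mix={k: float(v) for k, v in entry["plaque_channel_mix"].items()},
            plaque_radius=float(d["plaque_radius"]),
            plaque_min_separation=float(d["plaque_min_separation"]),
            white_matter_annulus=tuple(float(v) for v in d["white_matter_annulus"]),
            flag_probs={c: {f: float(p) for f, p in fl.items()}
                        for c, fl in entry.get("flag_probs", {}).items()},
            boundary_radius_um=float(d["boundary_radius_um"]),
        )
        out[(entry["condition"], int(entry["day"]))] = cfg
    return out


def load_morphology_profiles(path: str | None = None) -> dict[str, MorphSimConfig]:
    """Morphology class mixtures per fluorescence channel.

    Printed class percentages are renormalized to sum to one.
    """
    raw = _read_yaml("morphology.yaml") if path is None else yaml.safe_load(open(path))
    size = int(raw.get("mask_size", 96))
    out: dict[str, MorphSimConfig] = {}
    for channel, entry in raw["channels"].items():
        fr = {k: float(v) for k, v in entry["class_fractions"].items()}
        total = sum(fr.values())
        fr = {k: v / total for k, v in fr.items()}
        out[channel] = MorphSimConfig(
            class_fractions=fr,
            phagocytic_fraction={k: float(v) for k, v in
                                 entry.get("phagocytic_fraction", {}).items()},
            mask_size=size,
        )
    return out


@lru_cache(maxsize=None)
def load_timecourse_profile() -> dict:
    """Longitudinal effect profile (per-day multipliers, noise scales)."""
    raw = _read_yaml("timecourse.yaml")
    raw["days"] = [int(d) for d in raw["days"]]
    return raw
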