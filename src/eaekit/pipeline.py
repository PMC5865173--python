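"""End-to-end reproduction pipeline.

``headline_measurements`` regenerates every synthetic dataset from the
packaged profiles and pushes it through the analysis stages (gating with
automatic thresholds, fluorescent-protein and origin classification,
standardized-disk plaque mapping, mask morphometry, inclusion detection),
returning the recovered headline quantities.  ``run_pipeline`` wraps it
with configuration validation, file output and a report that pairs each
estimate with the value implied by the generating profiles.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gating, io, morphology, profiles_io, simulate, spatial, timecourse
from .datatypes import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_events: int = 50_000
    n_jurkat_spike: int = 2_500
    dead_fraction: float = 0.05
    n_masks: int = 2_000
    n_slices_plaque: int = 200
    n_slices_flags: int = 20
    band_k: int = 20
    grid_n: int = 64
    eps: float = 0.03
    min_cells: int = 10
    out_dir: str | None = None

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ValidationError("n_events must be > 0")
        if self.n_masks <= 0 or self.n_slices_plaque <= 0:
            raise ValidationError("sample sizes must be > 0")
        if self.eps <= 0 or self.min_cells < 3 or self.band_k < 1:
            raise ValidationError("invalid spatial parameters")


@dataclass
class RunReport:
    comparisons: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    seed: int
    versions: dict[str, str]
    timings_s: dict[str, float] = field(default_factory=dict)


def _seed_stream(seed: int):
    """Independent child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    while True:
        (child,) = ss.spawn(1)
        ss = child
        yield int(child.generate_state(1)[0] % (2**31))


def headline_measurements(
    seed: int = 0,
    n_events: int = 50_000,
    n_jurkat_spike: int = 2_500,
    dead_fraction: float = 0.05,
    n_masks: int = 2_000,
    n_slices_plaque: int = 200,
    n_slices_flags: int = 20,
    eps: float = 0.03,
    min_cells: int = 10,
) -> dict[str, dict[str, float]]:
    """Recover the study's headline percentages from fresh synthetic data.

    Returns a mapping of measurement name to ``{"value": v, "n": n}`` where
    ``n`` is the denominator (events, masks or slices) behind the value.
    Percentages are on the 0-100 scale.
    """
    seeds = _seed_stream(seed)
    pops, comps = profiles_io.default_profiles()
    out: dict[str, dict[str, float]] = {}

    def put(name, value, n):
        out[name] = {"value": float(value), "n": int(n)}

    # --- cytometry: day-17 spinal cord ------------------------------------
    ev17 = simulate.simulate_cytometry_sample(
        pops, comps[("MOG.CFA.PTX", "SC", 17)], n_events,
        n_jurkat_spike=n_jurkat_spike, dead_fraction=dead_fraction,
        seed=next(seeds),
    )
    thr17 = gating.derive_thresholds(ev17, random_state=next(seeds))
    res17 = gating.gate_events(ev17, thr17)
    fp17 = gating.classify_fp(ev17, thr17)
    t = gating.transform(ev17, thr17.cofactor)
    live = (res17.labels != "dead").to_numpy()
    cd45 = live & (t["CD45"].to_numpy(float) > thr17.pos["CD45"])
    egfp_any = fp17.isin(["EGFP", "double"]).to_numpy()
    put("pct_cd45_egfp_day17_sc", 100.0 * (cd45 & egfp_any).sum() / cd45.sum(),
        cd45.sum())

    eyfp_only = cd45 & (fp17 == "EYFP").to_numpy()
    mi = res17.labels.isin(["Mi_rest", "Mi_act"]).to_numpy()
    put("pct_eyfp_microglia_day17_sc",
        100.0 * (eyfp_only & mi).sum() / eyfp_only.sum(), eyfp_only.sum())

    n_p2 = res17.counts["P2_moDC"]
    n_p3 = res17.counts["P3_moDC"]
    put("pct_p3_of_modc_day17_sc", 100.0 * n_p3 / (n_p2 + n_p3), n_p2 + n_p3)

    # --- cytometry: early (day-8) spinal cord -----------------------------
    ev8 = simulate.simulate_cytometry_sample(
        pops, comps[("MOG.CFA.PTX", "SC", 8)], n_events,
        n_jurkat_spike=n_jurkat_spike, dead_fraction=dead_fraction,
        seed=next(seeds),
    )
    thr8 = gating.derive_thresholds(ev8, random_state=next(seeds))
    res8 = gating.gate_events(ev8, thr8)
    fp8 = gating.classify_fp(ev8, thr8)
    t8 = gating.transform(ev8, thr8.cofactor)
    live8 = (res8.labels != "dead").to_numpy()
    cd45_8 = live8 & (t8["CD45"].to_numpy(float) > thr8.pos["CD45"])
    egfp8 = cd45_8 & fp8.isin(["EGFP", "double"]).to_numpy()
    ne8 = (res8.labels == "Ne").to_numpy()
    put("pct_egfp_neutrophil_day8_sc",
        100.0 * (egfp8 & ne8).sum() / egfp8.sum(), egfp8.sum())

    # --- chimera: disease-onset brain -------------------------------------
    evc = simulate.simulate_chimera_sample(
        pops, comps[("MOG.CFA.PTX", "brain", 15)], n_events, seed=next(seeds),
        n_jurkat_spike=n_jurkat_spike)
    thrc = gating.derive_thresholds(evc, random_state=next(seeds))
    resc = gating.gate_events(evc, thrc)
    orig = gating.classify_origin(evc, thrc)
    mac = resc.labels.isin(["P4_mac", "P5_mac"]).to_numpy()
    put("pct_donor_p4p5_chimera",
        100.0 * ((orig == "donor").to_numpy() & mac).sum() / mac.sum(), mac.sum())

    # --- morphology -------------------------------------------------------
    morph_profiles = profiles_io.load_morphology_profiles()
    clf = morphology.MorphologyClassifier()
    masks_e = simulate.simulate_cell_masks(morph_profiles["EGFP"], n_masks,
                                           seed=next(seeds))
    recs_e = [morphology.measure(m) for m, _, _ in masks_e]
    cls_e = clf.predict(np.array([[r.solidity, r.eccentricity] for r in recs_e]))
    put("pct_ameboid_egfp_masks", 100.0 * (cls_e == "ameboid").mean(), n_masks)
    put("pct_ramified_egfp_masks", 100.0 * (cls_e == "ramified").mean(), n_masks)

    masks_y = simulate.simulate_cell_masks(morph_profiles["EYFP"], n_masks,
                                           seed=next(seeds))
    recs_y = [morphology.measure(m) for m, _, _ in masks_y]
    cls_y = clf.predict(np.array([[r.solidity, r.eccentricity] for r in recs_y]))
    put("pct_ramified_eyfp_masks", 100.0 * (cls_y == "ramified").mean(), n_masks)
    flagged = [morphology.detect_inclusions(m)[1] for m, _, _ in masks_y]
    put("pct_phagocytic_eyfp_masks", 100.0 * np.mean(flagged), n_masks)

    # --- slices: plaques and immunostain flags ----------------------------
    slice_profiles = profiles_io.load_slice_profiles()
    cfg14 = slice_profiles[("MOG.CFA.PTX", 14)]
    vl_counts, ly6g_pos, ly6g_n = [], 0, 0
    for _ in range(n_slices_plaque):
        rec = simulate.simulate_slice(cfg14, seed=next(seeds))
        std = spatial.standardize(rec)
        plq = spatial.detect_plaques(std, channel=None, eps=eps, min_cells=min_cells)
        vl_counts.append(plq.sectors.count("ventro_lateral"))
        is_egfp = std.cells["channel"] == "EGFP"
        ly6g_pos += int((is_egfp & std.cells["Ly6G"]).sum())
        ly6g_n += int(is_egfp.sum())
    put("mean_ventrolateral_plaques_day14", float(np.mean(vl_counts)),
        n_slices_plaque)
    put("pct_ly6g_egfp_day14_slices", 100.0 * ly6g_pos / ly6g_n, ly6g_n)

    cfg17 = slice_profiles[("MOG.CFA.PTX", 17)]
    hi_pos, hi_n = 0, 0
    for _ in range(n_slices_flags):
        rec = simulate.simulate_slice(cfg17, seed=next(seeds))
        dbl = rec.cells[rec.cells["channel"] == "double"]
        hi_pos += int(dbl["MHCII_hi"].sum())
        hi_n += len(dbl)
    put("pct_mhcii_hi_double_day17_slices", 100.0 * hi_pos / hi_n, hi_n)

    return out


def profile_implied_targets() -> dict[str, float]:
    """Headline values implied analytically by the packaged profiles."""
    pops, comps = profiles_io.default_profiles()
    morph = profiles_io.load_morphology_profiles()
    slices = profiles_io.load_slice_profiles()

    def fp(pop):
        return pops[pop].fp_probs

    c17 = comps[("MOG.CFA.PTX", "SC", 17)].fractions
    c8 = comps[("MOG.CFA.PTX", "SC", 8)].fractions
    egfp17 = sum(f * (fp(p)[0] + fp(p)[2]) for p, f in c17.items())
    eyfp17 = {p: f * fp(p)[1] for p, f in c17.items()}
    egfp8 = {p: f * (fp(p)[0] + fp(p)[2]) for p, f in c8.items()}
    mi_eyfp = sum(v for p, v in eyfp17.items() if p.startswith("Mi_"))
    ram_e = morph["EGFP"].class_fractions["ramified"]
    fr_y = morph["EYFP"].class_fractions
    phag_y = sum(fr_y[c] * morph["EYFP"].phagocytic_fraction.get(c, 0.0)
                 for c in fr_y)
    return {
        "pct_cd45_egfp_day17_sc": 100.0 * egfp17,
        "pct_egfp_neutrophil_day8_sc": 100.0 * egfp8["Ne"] / sum(egfp8.values()),
        "pct_eyfp_microglia_day17_sc": 100.0 * mi_eyfp / sum(eyfp17.values()),
        "pct_p3_of_modc_day17_sc":
            100.0 * c17["P3_moDC"] / (c17["P2_moDC"] + c17["P3_moDC"]),
        "pct_donor_p4p5_chimera": 100.0 * pops["P4_mac"].origin_prob_donor,
        "pct_ameboid_egfp_masks": 100.0 * morph["EGFP"].class_fractions["ameboid"],
        "pct_ramified_egfp_masks": 100.0 * ram_e,
        "pct_ramified_eyfp_masks": 100.0 * fr_y["ramified"],
        "pct_phagocytic_eyfp_masks": 100.0 * phag_y,
        "mean_ventrolateral_plaques_day14":
            slices[("MOG.CFA.PTX", 14)].plaque_count_mean[1],
        "pct_mhcii_hi_double_day17_slices":
            100.0 * slices[("MOG.CFA.PTX", 17)].flag_probs["double"]["MHCII_hi"],
        "pct_ly6g_egfp_day14_slices":
            100.0 * slices[("MOG.CFA.PTX", 14)].flag_probs["EGFP"]["Ly6G"],
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Full reproduction run: generate, analyze, compare, optionally save."""
    config.validate()
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    measured = headline_measurements(
        seed=config.seed, n_events=config.n_events,
        n_jurkat_spike=config.n_jurkat_spike,
        dead_fraction=config.dead_fraction, n_masks=config.n_masks,
        n_slices_plaque=config.n_slices_plaque,
        n_slices_flags=config.n_slices_flags,
        eps=config.eps, min_cells=config.min_cells,
    )
    timings["headline"] = time.perf_counter() - t0
    implied = profile_implied_targets()
    comparisons = pd.DataFrame([
        {"measurement": k, "target": implied[k],
         "estimate": v["value"], "n": v["n"]}
        for k, v in measured.items()
    ])

    # longitudinal stage: relative densities and the study's tests
    t1 = time.perf_counter()
    seeds = _seed_stream(config.seed + 1)
    tc = simulate.simulate_timecourse(seed=next(seeds))
    rel = timecourse.normalize_densities(tc)
    d0 = tc[tc["day"] == 0]["EGFP"]
    d13 = tc[tc["day"] == 13]["EGFP"]
    u_mw, p_mw = timecourse.mann_whitney(d0, d13)
    groups = [g["EGFP"].to_numpy() for _, g in tc.groupby("day")]
    h, p_kw = timecourse.kruskal_wallis(groups)
    late = tc[tc["day"] >= 10]
    rho, p_rho = timecourse.score_axon_correlation(late, seed=next(seeds))
    stats_table = pd.DataFrame([
        {"test": "mann_whitney_egfp_d0_vs_d13", "statistic": u_mw, "p": p_mw},
        {"test": "kruskal_wallis_egfp_across_days", "statistic": h, "p": p_kw},
        {"test": "spearman_score_axons", "statistic": rho, "p": p_rho},
    ])
    timings["timecourse"] = time.perf_counter() - t1

    import eaekit

    tables = {"relative_densities": rel, "stats": stats_table, "timecourse": tc}
    report = RunReport(
        comparisons=comparisons, tables=tables, seed=config.seed,
        versions={"eaekit": eaekit.__version__, "numpy": np.__version__,
                  "pandas": pd.__version__},
        timings_s=timings,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_table(comparisons, out / "comparisons.csv")
        for name, table in tables.items():
            io.write_table(table, out / f"{name}.csv")
        logger.info("report written to %s", out)
    return report
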