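"""Hierarchical gating of cytometry event tables.

The gating tree reproduces a 15-marker myeloid-focused strategy: live
events are split into CD45+ hematopoietic cells (R1) and CD45- events (R2,
containing the hCD3+ Jurkat spike-in); B and NK cells are excluded, then
TCRb+CD5+ T cells (R3, CD8+/CD8-), CD11b+Ly6G+ neutrophils (R4); the
remainder (R5) is split by CD45 level into resting (dim) and activated
(int) microglia versus blood-derived CD45-high cells (R6).  R6 resolves
into CD11b- CD11c+ cDC1 (R8) and CD11b+ cells (R7), from which CD11c+
MHCII-high CD64- cDC2 are carved before the Ly6C/CD64 monocyte-macrophage
gate (R9).  R9 splits on CD44: CD44+ (R11) into Ly6C+MHCII- monocytes (P1)
and Ly6C+/- MHCII+ moDCs (P2, P3); CD44- (R12) into Ly6C- MHCII-/hi
macrophages (P4, P5).  Events matching no terminal predicate are labeled
``other``, never dropped.

Thresholds are derived automatically from a control sample: per channel
the modes of the asinh-transformed intensity distribution are located on
a smoothed histogram and cutpoints are placed at the density valleys
between adjacent modes, with a negative-population percentile fallback
for channels without a positive mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, ClassifierMixin
from statsmodels.stats.proportion import proportion_confint

from . import profiles_io
from .datatypes import (
    FP_CHANNELS,
    PANEL,
    POPULATIONS,
    GateResult,
    ThresholdSet,
    ValidationError,
)

DEFAULT_COFACTOR = 150.0

GATE_PATHS: dict[str, tuple[str, ...]] = {
    "Jurkat": ("live", "R2", "Jurkat"),
    "Bc": ("live", "R1", "Bc"),
    "NKc": ("live", "R1", "NKc"),
    "Tc_CD8": ("live", "R1", "R3", "Tc_CD8"),
    "Tc_CD4": ("live", "R1", "R3", "Tc_CD4"),
    "Ne": ("live", "R1", "R4"),
    "Mi_rest": ("live", "R1", "R5", "Mi_rest"),
    "Mi_act": ("live", "R1", "R5", "Mi_act"),
    "cDC1": ("live", "R1", "R5", "R6", "R8"),
    "cDC2": ("live", "R1", "R5", "R6", "R7", "R10"),
    "P1_mono": ("live", "R1", "R5", "R6", "R7", "R9", "R11", "P1"),
    "P2_moDC": ("live", "R1", "R5", "R6", "R7", "R9", "R11", "P2"),
    "P3_moDC": ("live", "R1", "R5", "R6", "R7", "R9", "R11", "P3"),
    "P4_mac": ("live", "R1", "R5", "R6", "R7", "R9", "R12", "P4"),
    "P5_mac": ("live", "R1", "R5", "R6", "R7", "R9", "R12", "P5"),
    "other": ("live", "other"),
}

#: Populations counted as CD45+ (everything but the human spike-in).
CD45_POPULATIONS = tuple(p for p in POPULATIONS if p != "Jurkat")


def transform(events: pd.DataFrame, cofactor: float = DEFAULT_COFACTOR) -> pd.DataFrame:
    """Inverse-hyperbolic-sine transform of all intensity channels."""
    if cofactor <= 0:
        raise ValidationError("cofactor must be > 0")
    out = events.copy()
    channels = [c for c in (*PANEL, *FP_CHANNELS) if c in out.columns]
    vals = out[channels].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("non-finite intensities in event table")
    out[channels] = np.arcsinh(vals / cofactor)
    out.attrs.update(events.attrs, asinh_cofactor=cofactor)
    return out


def _mixture_cuts(
    values: np.ndarray, n_levels: int, rng: np.random.Generator,
    valley_ratio: float = 0.75, fallback_quantile: float = 0.995,
) -> list[float]:
    """Cutpoints between the ``n_levels`` intensity modes of one channel.

    Modes are found on a smoothed histogram of the transformed
    intensities: local maxima are accepted in descending height order, a
    candidate counting as a separate mode only when the density valley
    towards each accepted neighbour drops below ``valley_ratio`` of the
    candidate's own height; modes with negligible mass are then absorbed
    into their neighbours.  This is robust to extremely unequal mode
    weights (a 0.5% positive mode next to a 90% negative mode), where a
    fixed-size mixture fit is not.  Cutpoints are the valley positions
    (middle of a flat valley) between the retained modes.  A bi-level
    channel with a single mode falls back to the negative-population
    ``fallback_quantile`` percentile; a multi-level channel with missing
    modes raises.
    """
    if len(values) > 20000:
        values = rng.choice(values, 20000, replace=False)
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-9:
        if n_levels == 2:
            return [float(np.quantile(values, fallback_quantile))]
        raise ValidationError("constant channel cannot carry multiple levels")

    nbins = 512
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sm = gaussian_filter1d(hist.astype(float), 3.0, mode="constant")

    all_peaks, _ = find_peaks(np.pad(sm, 1))
    all_peaks = all_peaks - 1
    # accept peaks as modes in descending height order; a candidate is a
    # separate mode only when the density valley towards every accepted
    # neighbour drops below valley_ratio of the candidate's own height —
    # this absorbs Poisson ripples inside a cluster and low bumps bridging
    # two modes, regardless of how unequal the mode weights are
    peaks: list[int] = []
    for p in sorted(all_peaks, key=lambda q: -sm[q]):
        separated = True
        for q in peaks:
            lo_b, hi_b = (q, p) if q < p else (p, q)
            between = [r for r in peaks if lo_b < r < hi_b]
            if between:
                continue  # not an adjacent accepted mode
            if sm[lo_b:hi_b + 1].min() > valley_ratio * sm[p]:
                separated = False
                break
        if separated:
            peaks.append(int(p))
    peaks = sorted(peaks)
    if len(peaks) == 0:
        peaks = [int(np.argmax(sm))]

    def valley_bin(a: int, b: int) -> int:
        seg = sm[a:b + 1]
        vmin = seg.min()
        flat = np.flatnonzero(seg <= vmin + 1e-12)
        return a + int(flat[len(flat) // 2])

    modes: list[list[int]] = [[int(p)] for p in peaks]

    def boundaries(ms):
        return [valley_bin(a[-1], b[0]) for a, b in zip(ms[:-1], ms[1:])]

    def masses(ms):
        cuts_b = [0, *boundaries(ms), nbins]
        return [hist[s:e].sum() for s, e in zip(cuts_b[:-1], cuts_b[1:])]

    def absorb(ms, k):
        """Merge mode k into the neighbour separated by the shallower valley."""
        if k == 0:
            j = 1
        elif k == len(ms) - 1:
            j = k - 1
        else:
            r_left = sm[valley_bin(ms[k - 1][-1], ms[k][0])] / \
                max(min(sm[ms[k - 1][-1]], sm[ms[k][0]]), 1e-12)
            r_right = sm[valley_bin(ms[k][-1], ms[k + 1][0])] / \
                max(min(sm[ms[k][-1]], sm[ms[k + 1][0]]), 1e-12)
            j = k - 1 if r_left >= r_right else k + 1
        ms[min(j, k)] = sorted(ms[j] + ms[k])
        del ms[max(j, k)]

    # absorb modes with negligible mass (stray tail bumps)
    min_mass = max(20.0, 5e-4 * len(values))
    while len(modes) > 1:
        m = masses(modes)
        k = int(np.argmin(m))
        if m[k] >= min_mass:
            break
        absorb(modes, k)
    # reduce to the expected number of modes
    while len(modes) > n_levels:
        absorb(modes, int(np.argmin(masses(modes))))

    if len(modes) < n_levels:
        if n_levels == 2:
            return [float(np.quantile(values, fallback_quantile))]
        raise ValidationError(
            f"resolved {len(modes)} intensity modes, expected {n_levels}"
        )
    return [float(centers[b]) for b in boundaries(modes)]


def derive_thresholds(
    control: pd.DataFrame,
    cofactor: float = DEFAULT_COFACTOR,
    random_state: int = 0,
    valley_ratio: float = 0.75,
    fallback_quantile: float = 0.995,
    pre_transformed: bool = False,
) -> ThresholdSet:
    """Automatic per-marker cutpoints from a control event table.

    The control must contain negative events for every marker and, for the
    tri-level channels (CD45, MHCII), events at each expression level —
    e.g. a sample carrying microglia, leukocytes and a Jurkat spike.
    """
    t = control if pre_transformed else transform(control, cofactor)
    tri = profiles_io.marker_model()["tri_level"]
    rng = np.random.default_rng(random_state)
    pos: dict[str, float] = {}
    dim_int: dict[str, float] = {}
    int_high: dict[str, float] = {}
    for channel in (*PANEL, *FP_CHANNELS):
        if channel not in t.columns:
            continue
        n_levels = len(tri.get(channel, ("neg", "pos")))
        cuts = _mixture_cuts(
            t[channel].to_numpy(dtype=float), n_levels, rng,
            valley_ratio, fallback_quantile,
        )
        pos[channel] = cuts[0]
        if n_levels >= 3:
            dim_int[channel] = cuts[1]
        if n_levels >= 4:
            int_high[channel] = cuts[2]
    return ThresholdSet(pos=pos, dim_int=dim_int, int_high=int_high, cofactor=cofactor)


def gate_events(
    events: pd.DataFrame,
    thresholds: ThresholdSet,
    cdc2_before_r9: bool = True,
    pre_transformed: bool = False,
) -> GateResult:
    """Assign every live event a terminal population label.

    Sequential exclusion in the order the tree lists populations; events
    matching no terminal predicate are labeled ``other``.  Dead
    (viability-positive) events are labeled ``dead`` and excluded from
    counts.  Set ``cdc2_before_r9=False`` to form the Ly6C/CD64 gate before
    carving cDC2 from R7.
    """
    t = events if pre_transformed else transform(events, thresholds.cofactor)
    missing = [c for c in PANEL if c not in t.columns]
    if missing:
        raise ValidationError(f"event table lacks channels {missing}")

    def hi(ch):  # positive at the first (neg/pos) cutpoint
        return t[ch].to_numpy(dtype=float) > thresholds.pos[ch]

    cd45 = t["CD45"].to_numpy(dtype=float)
    live = ~t["dead"].to_numpy(dtype=bool) if "dead" in t.columns \
        else np.ones(len(t), dtype=bool)

    labels = np.full(len(t), "other", dtype=object)
    labels[~live] = "dead"
    unassigned = live.copy()

    def take(mask, label):
        sel = unassigned & mask
        labels[sel] = label
        unassigned[sel] = False
        return sel

    r1 = live & hi("CD45")
    take(~r1 & hi("hCD3"), "Jurkat")          # R2 = CD45-, Jurkat therein
    unassigned &= r1                          # remaining CD45- events: other
    mhc = t["MHCII"].to_numpy(dtype=float)
    mhc_pos = mhc > thresholds.pos["MHCII"]
    mhc_hi = mhc > thresholds.dim_int["MHCII"]
    take(hi("CD19") & mhc_pos, "Bc")
    take(hi("CD161") & ~mhc_pos, "NKc")
    tc = hi("TCRb") & hi("CD5")
    take(tc & hi("CD8a"), "Tc_CD8")
    take(tc, "Tc_CD4")
    take(hi("CD11b") & hi("Ly6G"), "Ne")      # R4
    # R5: split by CD45 level
    take(cd45 <= thresholds.dim_int["CD45"], "Mi_rest")
    take(cd45 <= thresholds.int_high["CD45"], "Mi_act")
    r6 = unassigned.copy()                    # CD45-high remainder
    take(r6 & ~hi("CD11b") & hi("CD11c"), "cDC1")       # R8
    unassigned &= hi("CD11b")                 # R7; CD11b-CD11c- -> other
    cdc2_pred = hi("CD11c") & mhc_hi & ~hi("CD64")
    r9_pred = hi("Ly6C") | hi("CD64")
    if cdc2_before_r9:
        take(cdc2_pred, "cDC2")
        unassigned &= r9_pred                 # R9
    else:
        r9 = unassigned & r9_pred             # R9 formed first
        take(~r9 & cdc2_pred, "cDC2")
        unassigned &= r9
    ly6c = hi("Ly6C")
    cd44 = hi("CD44")
    take(cd44 & ly6c & ~mhc_pos, "P1_mono")   # R11
    take(cd44 & ly6c & mhc_pos, "P2_moDC")
    take(cd44 & ~ly6c & mhc_pos, "P3_moDC")
    take(~cd44 & ~ly6c & ~mhc_pos, "P4_mac")  # R12
    take(~cd44 & ~ly6c & mhc_hi, "P5_mac")

    label_s = pd.Series(labels, index=t.index, name="label")
    counts = (
        label_s[live].value_counts()
        .reindex([*POPULATIONS, "other"], fill_value=0)
        .astype(int)
    )
    return GateResult(labels=label_s, paths=dict(GATE_PATHS), counts=counts)


class GatingModel(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style wrapper: fit thresholds on a control, predict labels.

    Parameters mirror :func:`derive_thresholds` and :func:`gate_events`.
    After ``fit``, ``thresholds_`` holds the derived ThresholdSet.
    """

    def __init__(
        self,
        cofactor: float = DEFAULT_COFACTOR,
        cdc2_before_r9: bool = True,
        random_state: int = 0,
        valley_ratio: float = 0.75,
        fallback_quantile: float = 0.995,
    ):
        self.cofactor = cofactor
        self.cdc2_before_r9 = cdc2_before_r9
        self.random_state = random_state
        self.valley_ratio = valley_ratio
        self.fallback_quantile = fallback_quantile

    def fit(self, X: pd.DataFrame, y=None) -> "GatingModel":
        self.thresholds_ = derive_thresholds(
            X, cofactor=self.cofactor, random_state=self.random_state,
            valley_ratio=self.valley_ratio,
            fallback_quantile=self.fallback_quantile,
        )
        self.classes_ = np.asarray([*POPULATIONS, "other", "dead"])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.gate(X).labels.to_numpy()

    def gate(self, X: pd.DataFrame) -> GateResult:
        return gate_events(X, self.thresholds_, cdc2_before_r9=self.cdc2_before_r9)


def calibrate_counts(result: GateResult, n_spiked: int) -> pd.DataFrame:
    """Spike-in calibrated absolute counts per population.

    absolute_count = count * n_spiked / detected Jurkat events; the ratio
    of spiked to detected Jurkat cells estimates the acquisition yield.
    ``pct_of_CD45`` is each population's share of CD45+ events.
    """
    if n_spiked <= 0:
        raise ValidationError("n_spiked must be > 0")
    n_jurkat = int(result.counts.get("Jurkat", 0))
    if n_jurkat == 0:
        raise ValidationError("no Jurkat events detected; cannot calibrate")
    scale = n_spiked / n_jurkat
    counts = result.counts.loc[list(CD45_POPULATIONS)]
    total_cd45 = counts.sum()
    out = pd.DataFrame({
        "count": counts,
        "absolute_count": counts * scale,
        "pct_of_CD45": 100.0 * counts / max(total_cd45, 1),
    })
    out.attrs["jurkat_detected"] = n_jurkat
    out.attrs["jurkat_spiked"] = n_spiked
    return out


def composition_table(
    result: GateResult,
    events: pd.DataFrame,
    thresholds: ThresholdSet,
    n_spiked: int | None = None,
    include_origin: bool = False,
) -> pd.DataFrame:
    """Per-population summary: counts, CD45+ share, FP and origin fractions.

    Fluorescent-protein percentages are computed within each population;
    origin percentages (chimera mode) require the congenic CD45.1/CD45.2
    channels to be informative.  Absolute counts are added when the spike
    size is given.
    """
    fp = classify_fp(events, thresholds)
    rows = []
    scale = None
    if n_spiked is not None:
        n_jurkat = int(result.counts.get("Jurkat", 0))
        if n_jurkat == 0:
            raise ValidationError("no Jurkat events detected; cannot calibrate")
        scale = n_spiked / n_jurkat
    origin = classify_origin(events, thresholds) if include_origin else None
    total_cd45 = int(result.counts.loc[list(CD45_POPULATIONS)].sum())
    for pop in CD45_POPULATIONS:
        sel = (result.labels == pop).to_numpy()
        n = int(sel.sum())
        row = {
            "population": pop, "count": n,
            "pct_of_CD45": 100.0 * n / max(total_cd45, 1),
        }
        if scale is not None:
            row["absolute_count"] = n * scale
        for lab, col in (("EGFP", "pct_egfp"), ("EYFP", "pct_eyfp"),
                         ("double", "pct_double")):
            row[col] = 100.0 * float((fp[sel] == lab).mean()) if n else 0.0
        if origin is not None:
            row["pct_donor"] = (100.0 * float((origin[sel] == "donor").mean())
                                if n else 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def classify_fp(
    events: pd.DataFrame, thresholds: ThresholdSet, pre_transformed: bool = False
) -> pd.Series:
    """Per-event fluorescent-protein label: EGFP, EYFP, double or none."""
    for ch in FP_CHANNELS:
        if ch not in events.columns:
            raise ValidationError(f"missing fluorescent-protein channel {ch}")
    t = events if pre_transformed else transform(events, thresholds.cofactor)
    egfp = t["EGFP"].to_numpy(dtype=float) > thresholds.pos["EGFP"]
    eyfp = t["EYFP"].to_numpy(dtype=float) > thresholds.pos["EYFP"]
    lab = np.where(
        egfp & eyfp, "double",
        np.where(egfp, "EGFP", np.where(eyfp, "EYFP", "none")),
    )
    return pd.Series(lab, index=events.index, name="fp_label")


def classify_origin(
    events: pd.DataFrame, thresholds: ThresholdSet, pre_transformed: bool = False
) -> pd.Series:
    """Chimera origin per event: donor (CD45.2+), host (CD45.1+) or unresolved."""
    t = events if pre_transformed else transform(events, thresholds.cofactor)
    h1 = t["CD45_1"].to_numpy(dtype=float) > thresholds.pos["CD45_1"]
    h2 = t["CD45_2"].to_numpy(dtype=float) > thresholds.pos["CD45_2"]
    lab = np.where(h2 & ~h1, "donor", np.where(h1 & ~h2, "host", "unresolved"))
    return pd.Series(lab, index=events.index, name="origin")


def microglia_activation(
    result: GateResult,
    events: pd.DataFrame,
    thresholds: ThresholdSet,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fractions of microglia positive for CD11c, MHCII and EYFP.

    Returns one row per marker with the positive fraction among all gated
    microglia (resting + activated) and its Wilson confidence interval.
    """
    mi = result.labels.isin(["Mi_rest", "Mi_act"]).to_numpy()
    n = int(mi.sum())
    if n == 0:
        raise ValidationError("no microglia events gated")
    t = transform(events, thresholds.cofactor)
    rows = []
    for marker in ("CD11c", "MHCII", "EYFP"):
        k = int((t.loc[mi, marker].to_numpy(dtype=float) > thresholds.pos[marker]).sum())
        lo, hi_ = proportion_confint(k, n, alpha=alpha, method="wilson")
        rows.append({"marker": marker, "n_microglia": n, "fraction": k / n,
                     "ci_low": lo, "ci_high": hi_})
    return pd.DataFrame(rows)
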