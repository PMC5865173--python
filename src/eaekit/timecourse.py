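"""Longitudinal analysis: stack registration, density normalization, tests.

Image stacks acquired in vivo drift by a few pixels between frames
(animal breathing); registration recovers the integer shift of each frame
against the reference frame by exhaustive cross-correlation.  Cell
densities are binned over two-day windows and expressed relative to the
density on the day of induction.  Group comparisons follow the study's
statistics: Mann-Whitney, Kruskal-Wallis, uncorrected one-way ANOVA, and
a permutation-based Spearman correlation of clinical scores with axon
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .datatypes import ValidationError

#: Two-day bins used for relative densities (day 0 is the baseline).
DEFAULT_BINS: tuple[tuple[int, ...], ...] = (
    (8, 9), (10, 11), (13, 14), (15, 16), (17, 18), (21, 22), (23, 24),
)


@dataclass
class RegisteredStack:
    frames: np.ndarray                     # (F, H, W) registered frames
    shifts: list[tuple[int, int]]          # per-frame (dy, dx) drift removed
    reference: int = 0

    def __post_init__(self) -> None:
        if self.shifts[self.reference] != (0, 0):
            raise ValidationError("reference frame must have zero shift")


def _translate(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero padding."""
    h, w = frame.shape
    out = np.zeros_like(frame)
    src = frame[max(0, -dy): h - max(0, dy), max(0, -dx): w - max(0, dx)]
    out[max(0, dy): h - max(0, -dy), max(0, dx): w - max(0, -dx)] = src
    return out


def register(
    stack: np.ndarray, max_shift: int = 10, reference: int = 0
) -> RegisteredStack:
    """Remove integer-pixel drifts by cross-correlation with the reference.

    For each frame the zero-mean cross-correlation with the reference frame
    is evaluated exhaustively over shifts in [-max_shift, max_shift]^2 (via
    FFT) and the maximizing shift is undone.  Raises on blank
    (zero-variance) frames.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValidationError("stack must be (frames >= 2, H, W)")
    ref = stack[reference]
    if ref.std() == 0:
        raise ValidationError("blank reference frame (zero variance)")
    ref0 = ref - ref.mean()
    h, w = ref.shape
    frames = np.empty_like(stack)
    shifts: list[tuple[int, int]] = []
    for i, frame in enumerate(stack):
        if i == reference:
            frames[i] = frame
            shifts.append((0, 0))
            continue
        if frame.std() == 0:
            raise ValidationError(f"blank frame {i} (zero variance)")
        corr = signal.fftconvolve(frame - frame.mean(), ref0[::-1, ::-1], mode="full")
        # correlation lag (dy, dx): frame ~ reference translated by (dy, dx)
        cy, cx = h - 1, w - 1
        win = corr[
            max(0, cy - max_shift): cy + max_shift + 1,
            max(0, cx - max_shift): cx + max_shift + 1,
        ]
        iy, ix = np.unravel_index(np.argmax(win), win.shape)
        dy = iy + max(0, cy - max_shift) - cy
        dx = ix + max(0, cx - max_shift) - cx
        frames[i] = _translate(frame, -dy, -dx)
        shifts.append((int(dy), int(dx)))
    return RegisteredStack(frames=frames, shifts=shifts, reference=reference)


class StackRegistrar:
    """Estimator-style wrapper around :func:`register`."""

    def __init__(self, max_shift: int = 10, reference: int = 0):
        self.max_shift = max_shift
        self.reference = reference

    def fit(self, stack: np.ndarray, y=None) -> "StackRegistrar":
        self.result_ = register(stack, self.max_shift, self.reference)
        self.shifts_ = self.result_.shifts
        return self

    def transform(self, stack: np.ndarray) -> np.ndarray:
        return self.result_.frames

    def fit_transform(self, stack: np.ndarray, y=None) -> np.ndarray:
        return self.fit(stack).result_.frames

    def get_params(self, deep: bool = True) -> dict:
        return {"max_shift": self.max_shift, "reference": self.reference}

    def set_params(self, **params) -> "StackRegistrar":
        for k, v in params.items():
            setattr(self, k, v)
        return self


def normalize_densities(
    tc: pd.DataFrame,
    bins: tuple[tuple[int, ...], ...] = DEFAULT_BINS,
    channels: tuple[str, ...] = ("EGFP", "EYFP", "double"),
    baseline_day: int = 0,
) -> pd.DataFrame:
    """Two-day-binned densities relative to the induction-day baseline.

    For each mouse and channel the mean density within each bin is divided
    by the mouse's day-``baseline_day`` density.  Mice with a zero baseline
    in any channel are excluded with a warning column rather than silently
    dropped rows.
    """
    rows = []
    for mouse, g in tc.groupby("mouse"):
        base = g[g["day"] == baseline_day]
        if base.empty:
            raise ValidationError(f"mouse {mouse} lacks day-{baseline_day} baseline")
        base = base.iloc[0]
        if any(base[ch] <= 0 for ch in channels):
            rows.append({"mouse": mouse, "bin": None, "excluded": True})
            continue
        for b in bins:
            sel = g[g["day"].isin(b)]
            if sel.empty:
                continue
            row = {"mouse": mouse, "bin": "-".join(map(str, b)), "excluded": False}
            for ch in channels:
                row[ch] = float(sel[ch].mean() / base[ch])
            rows.append(row)
    out = pd.DataFrame(rows)
    excluded = out[out["excluded"]]
    if not excluded.empty:
        import logging

        logging.getLogger(__name__).warning(
            "excluded %d mice with zero baseline density", excluded["mouse"].nunique()
        )
    return out[~out["excluded"]].drop(columns=["excluded"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# statistics

def mann_whitney(
    x, y, alternative: str = "two-sided", exact_max_n: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U test (midrank ties).

    Exact p by enumeration when n + m <= ``exact_max_n`` and the data are
    tie-free; otherwise the normal approximation with tie correction.
    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty sample")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction, chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0   # all observations identical: H = 0 by definition
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups) -> tuple[float, float]:
    """Classical uncorrected one-way ANOVA F test."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    n_total, k = sum(map(len, groups)), len(groups)
    if n_total <= k:
        raise ValidationError("need total n > number of groups")
    grand = np.concatenate(groups)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within == 0:
        if all(np.isclose(g.mean(), grand.mean()) for g in groups):
            raise ValidationError("zero within-group variance with equal means")
        return float("inf"), 0.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def spearman_permutation(
    x, y, n_perm: int = 10_000, seed: int | None = 0
) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with a permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValidationError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    for i in range(n_perm):
        perm[i] = (rxc[rng.permutation(len(rx))] * ryc).sum() / denom
    p = (1 + np.sum(np.abs(perm) >= abs(rho) - 1e-12)) / (n_perm + 1)
    return rho, float(p)


def score_axon_correlation(
    tc: pd.DataFrame, n_perm: int = 10_000, seed: int | None = 0
) -> tuple[float, float]:
    """Spearman correlation of clinical scores with axon counts."""
    return spearman_permutation(
        tc["score"].to_numpy(), tc["axons"].to_numpy(), n_perm=n_perm, seed=seed
    )


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values.

    The study reports uncorrected tests; this option is therefore off by
    default everywhere and provided for users who want family-wise error
    control over a battery of comparisons.
    """
    from statsmodels.stats.multitest import multipletests

    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValidationError("no p-values to adjust")
    return multipletests(pvalues, method="holm")[1]


def depth_partition(depths, d_meningeal: float = 30.0) -> tuple[int, int]:
    """Split cells into meningeal (depth <= d_meningeal µm) vs parenchymal."""
    depths = np.asarray(depths, dtype=float)
    if d_meningeal <= 0:
        raise ValidationError("d_meningeal must be > 0")
    if (depths < 0).any():
        raise ValidationError("negative depths")
    men = int((depths <= d_meningeal).sum())
    return men, len(depths) - men
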