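"""Cell-mask morphometry and ameboid / elongated / ramified classification.

Measurements follow the standard region-property definitions: area is the
foreground pixel count times the pixel area, solidity is area divided by
the area of the convex hull of the pixel-corner polygon (corner points
avoid zero-thickness degeneracies for one-pixel-wide shapes), and
eccentricity is sqrt(1 - l2/l1) of the eigenvalues l1 >= l2 of the
foreground pixel coordinate covariance.  Classification is a fixed rule
cascade: low solidity -> ramified, else high eccentricity -> elongated,
else ameboid.  Phagocytic activity is flagged from dark intensity
inclusions fully enclosed by the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportion_confint

from .datatypes import ValidationError

MORPH_CLASSES = ("ameboid", "elongated", "ramified")


@dataclass
class CellMask:
    """Binary mask of a single cell, optionally with an intensity image."""

    mask: np.ndarray                 # 2-D bool
    intensity: np.ndarray | None = None
    scale_um: float = 1.0            # isotropic µm per pixel


@dataclass
class MorphometryRecord:
    area_um2: float
    solidity: float
    eccentricity: float
    morph_class: str | None = None
    phagocytic: bool | None = None
    n_inclusions: int | None = None


def _foreground(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValidationError("mask must be 2-D")
    if not m.any():
        raise ValidationError("empty mask")
    _, n = ndimage.label(m)
    if n != 1:
        raise ValidationError(f"mask has {n} connected components, expected 1")
    return m

def _hull_area(rows: np.ndarray, cols: np.ndarray) -> float:
    # convex hull over the 4 corners of every foreground pixel
    corners = np.concatenate([
        np.stack([rows + dr, cols + dc], axis=1)
        for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)
    ])
    return float(ConvexHull(corners).volume)   # 2-D hull "volume" is area


def measure(cell: CellMask | np.ndarray) -> MorphometryRecord:
    """Area, solidity and eccentricity of one cell mask (class unset)."""
    if isinstance(cell, np.ndarray):
        cell = CellMask(mask=cell)
    m = _foreground(cell.mask)
    rows, cols = np.nonzero(m)
    area_px = float(len(rows))
    solidity = area_px / _hull_area(rows, cols)
    coords = np.stack([rows, cols], axis=1).astype(float)
    if len(coords) == 1:
        ecc = 0.0
    else:
        cov = np.cov(coords.T, bias=True)
        l2, l1 = np.sort(np.linalg.eigvalsh(cov))
        ecc = 0.0 if l1 <= 0 else float(np.sqrt(max(0.0, 1.0 - l2 / l1)))
    return MorphometryRecord(
        area_um2=area_px * cell.scale_um**2,
        solidity=float(solidity),
        eccentricity=ecc,
    )


class MorphologyClassifier(BaseEstimator):
    """Rule-based morphology classifier.

    Rules are applied in order: ramified if solidity < ``s_ramified``;
    else elongated if eccentricity >= ``e_elongated``; else ameboid.
    Thresholds default to s_ramified=0.75 and e_elongated=0.90, calibrated
    on the synthetic mask generator (see scripts/calibrate_morphology.py).
    The classifier is stateless; ``fit`` only validates parameters.
    """

    def __init__(self, s_ramified: float = 0.75, e_elongated: float = 0.90):
        self.s_ramified = s_ramified
        self.e_elongated = e_elongated

    def fit(self, X=None, y=None) -> "MorphologyClassifier":
        if not (0 < self.s_ramified <= 1) or not (0 <= self.e_elongated < 1):
            raise ValidationError("invalid classification thresholds")
        self.classes_ = np.asarray(MORPH_CLASSES)
        return self

    def predict(self, X) -> np.ndarray:
        """Classify records; X is a DataFrame with solidity/eccentricity columns,
        an iterable of MorphometryRecord, or an (n, 2) array [solidity, ecc]."""
        self.fit()
        if isinstance(X, pd.DataFrame):
            sol = X["solidity"].to_numpy(dtype=float)
            ecc = X["eccentricity"].to_numpy(dtype=float)
        elif isinstance(X, np.ndarray):
            sol, ecc = X[:, 0], X[:, 1]
        else:
            sol = np.asarray([r.solidity for r in X], dtype=float)
            ecc = np.asarray([r.eccentricity for r in X], dtype=float)
        out = np.where(
            sol < self.s_ramified, "ramified",
            np.where(ecc >= self.e_elongated, "elongated", "ameboid"),
        )
        return out.astype(object)


def classify(rec: MorphometryRecord, rules: MorphologyClassifier | None = None) -> str:
    """Morphology class of a measured record (deterministic and total)."""
    clf = rules if rules is not None else MorphologyClassifier()
    label = clf.predict(np.array([[rec.solidity, rec.eccentricity]]))[0]
    rec.morph_class = label
    return label


def detect_inclusions(
    cell: CellMask, f: float = 0.5, a_min: int = 4
) -> tuple[int, bool]:
    """Count dark phagocytic inclusions fully inside the cell.

    An inclusion is a connected component of foreground pixels whose
    intensity is below ``f`` times the median foreground intensity, of area
    at least ``a_min`` px, and not touching the cell border.  Returns
    (inclusion count, phagocytic flag).
    """
    if cell.intensity is None:
        raise ValidationError("intensity image required for inclusion detection")
    m = _foreground(cell.mask)
    inten = np.asarray(cell.intensity, dtype=float)
    med = float(np.median(inten[m]))
    dark = m & (inten < f * med)
    labels, n = ndimage.label(dark)
    interior = ndimage.binary_erosion(m)
    count = 0
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() >= a_min and not (comp & ~interior).any():
            count += 1
    return count, count >= 1


def distribution(
    records: pd.DataFrame,
    by: list[str] | None = None,
    class_col: str = "morph_class",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group morphology class fractions with Wilson confidence intervals."""
    if records.empty:
        raise ValidationError("no records")
    by = by or []
    groups = records.groupby(by) if by else [((), records)]
    rows = []
    for key, g in groups:
        n = len(g)
        if n == 0:
            raise ValidationError(f"empty group {key}")
        for cls in MORPH_CLASSES:
            k = int((g[class_col] == cls).sum())
            lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
            row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
            row.update({"morph_class": cls, "n": n, "fraction": k / n,
                        "ci_low": lo, "ci_high": hi})
            rows.append(row)
    return pd.DataFrame(rows)
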