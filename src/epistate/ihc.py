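"""Positive-pixel-count quantification of immunohistochemistry and cohort tests.

Stained-tissue images are quantified the way slide scanners do it: every
analyzable 8-bit pixel is assigned to an intensity band (strong / positive /
weak / negative staining — darker pixels carry more chromogen, so *lower*
intensity means *stronger* staining), and each sample receives a positivity
score defined as 256 minus the mean pixel intensity, so that darker staining
scores higher.  Per-cohort score vectors (e.g. ER-positive vs triple-negative
tumors) are then compared with an unpaired two-sided t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

from .errors import EpistateError

__all__ = [
    "IntensityImage",
    "PixelClassConfig",
    "PixelClassReport",
    "CohortComparison",
    "load_image",
    "classify_pixels",
    "score_cohort",
    "compare_cohorts",
]

# ITU-R BT.601 luminosity weights for reducing RGB to intensity.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class IntensityImage:
    """An 8-bit intensity image (0 = darkest / strongest stain) with an optional
    mask of analyzable pixels (e.g. the pathologist's tumor-area selection)."""

    pixels: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise EpistateError("intensity image must be a 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise EpistateError("pixel intensities must lie in 0-255")
            self.pixels = self.pixels.astype(np.uint8)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise EpistateError("mask shape must match the image shape")

    def analyzed(self) -> np.ndarray:
        vals = self.pixels[self.mask] if self.mask is not None else self.pixels.ravel()
        if vals.size == 0:
            raise EpistateError("no analyzable pixels (empty mask)")
        return vals


def load_image(path, mask_path=None) -> IntensityImage:
    """Read a PNG/TIFF image (grayscale, or RGB reduced by luminosity) and an
    optional same-shape binary mask image (non-zero = analyzable)."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = np.rint(arr[..., :3].astype(float) @ _LUMA).clip(0, 255).astype(np.uint8)
    mask = None
    if mask_path is not None:
        marr = np.asarray(Image.open(mask_path).convert("L"))
        mask = marr > 0
    return IntensityImage(pixels=arr, mask=mask)


@dataclass(frozen=True)
class PixelClassConfig:
    """Intensity cut points of the positive-pixel-count bands.

    With the default cut points (100, 175, 220) the bands are, in intensity
    units: strong [0,100), positive [100,175), weak [175,220], negative
    (220,255].  The darkest band is the strongest staining.
    """

    boundaries: tuple[int, int, int] = (100, 175, 220)
    names: tuple[str, str, str, str] = ("strong", "positive", "weak", "negative")

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (0 < b[0] < b[1] < b[2] < 255):
            raise EpistateError("cut points must be strictly increasing within (0, 255)")


@dataclass
class PixelClassReport:
    counts: dict[str, int]
    total: int
    positivity_score: float  # 256 - mean analyzed intensity

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise EpistateError("class counts must sum to the analyzed-pixel total")


def classify_pixels(img: IntensityImage, cfg: PixelClassConfig | None = None) -> PixelClassReport:
    """Assign every analyzable pixel to an intensity band and score the image.

    Bands are half-open upward except the top cut point, which closes the weak
    band (see :class:`PixelClassConfig`).  The positivity score is
    ``256 - mean(intensity)`` over analyzed pixels, so darker (stronger)
    staining scores higher.
    """
    cfg = cfg or PixelClassConfig()
    vals = img.analyzed()
    c1, c2, c3 = cfg.boundaries
    idx = np.digitize(vals, [c1, c2, c3 + 1], right=False)
    binned = np.bincount(idx, minlength=4)
    counts = {name: int(n) for name, n in zip(cfg.names, binned)}
    score = 256.0 - float(vals.mean(dtype=np.float64))
    return PixelClassReport(counts=counts, total=int(vals.size), positivity_score=score)


def score_cohort(
    images: list[tuple[str, str, IntensityImage]],
    cfg: PixelClassConfig | None = None,
) -> pd.DataFrame:
    """Score a set of labelled sample images into a cohort table.

    ``images`` is a list of ``(sample_id, cohort_label, IntensityImage)``.
    Returns a DataFrame with columns ``sample_id, cohort, score`` plus the
    per-class pixel counts; sample ids must be unique and every label must
    appear at least once.
    """
    if not images:
        raise EpistateError("no images to score")
    ids = [sid for sid, _, _ in images]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise EpistateError(f"duplicate sample ids: {', '.join(dupes)}")
    cfg = cfg or PixelClassConfig()
    rows = []
    for sid, label, img in images:
        rep = classify_pixels(img, cfg)
        row = {"sample_id": sid, "cohort": label, "score": rep.positivity_score,
               "n_pixels": rep.total}
        row.update({f"n_{name}": rep.counts[name] for name in cfg.names})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortComparison:
    t_statistic: float
    p_value: float
    df: float
    groups: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    equal_var: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cohort": g, "n": n, "mean": m, "sd": s}
            for g, n, m, s in zip(self.groups, self.ns, self.means, self.sds)
        ]
        df = pd.DataFrame(rows)
        df["t"] = self.t_statistic
        df["p_two_sided"] = self.p_value
        return df


def compare_cohorts(table: pd.DataFrame, equal_var: bool = True) -> CohortComparison:
    """Unpaired two-sided t-test between the two cohorts of a score table.

    Student's equal-variance test by default; set ``equal_var=False`` for
    Welch.  Cohorts are taken in sorted label order, so the sign of t refers
    to ``mean(first label) - mean(second label)``.  Degenerate zero-variance
    input is reported as t = ±inf (p = 0) when the means differ.
    """
    labels = sorted(table["cohort"].unique())
    if len(labels) != 2:
        raise EpistateError(f"expected exactly 2 cohorts, found {len(labels)}")
    x = table.loc[table["cohort"] == labels[0], "score"].to_numpy(dtype=float)
    y = table.loc[table["cohort"] == labels[1], "score"].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise EpistateError("each cohort needs at least two samples")

    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        diff = x.mean() - y.mean()
        t = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
        p = 1.0 if diff == 0 else 0.0
        df = float(len(x) + len(y) - 2)
    else:
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return CohortComparison(
        t_statistic=t,
        p_value=p,
        df=df,
        groups=(labels[0], labels[1]),
        means=(float(x.mean()), float(y.mean())),
        sds=(float(x.std(ddof=1)), float(y.std(ddof=1))),
        ns=(len(x), len(y)),
        equal_var=equal_var,
    )

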