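"""Image standardization and classical fluorescence statistics.

Mirrors the conventional quantification workflow for immunofluorescence
micrographs: crop each neuropil to its mask, resize to the kind's standard
resolution, take the mean relative-fluorescence value, then compare cohorts
with ANOVA plus Tukey's HSD and correlate neuropil size with head width.

Tukey's test is computed directly from the studentized-range distribution
(with the Tukey–Kramer unequal-n correction) so the q statistic is exposed;
a two-way (cohort × neuropil) ANOVA mode is available through statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize as _sk_resize

from .synthgen import NeuropilImage, NeuropilKind

__all__ = [
    "FluorescenceRecord",
    "PairwiseComparison",
    "CohortComparisonResult",
    "crop_to_mask",
    "resize_to_standard",
    "mean_fluorescence",
    "quantify_images",
    "compare_cohorts",
    "compare_cohorts_twoway",
    "correlate_size",
]


@dataclass(frozen=True)
class FluorescenceRecord:
    """Mean relative fluorescence of one neuropil image."""

    animal_id: str
    cohort: str
    kind: str
    side_index: int
    mean_rfu: float

    def __post_init__(self):
        if not 0.0 <= self.mean_rfu <= 255.0:
            raise ValueError(f"mean_rfu {self.mean_rfu} outside [0, 255]")


@dataclass(frozen=True)
class PairwiseComparison:
    """One Tukey HSD contrast between two cohorts."""

    group_a: str
    group_b: str
    mean_diff: float
    q_stat: float
    p_adj: float
    significant: bool


@dataclass
class CohortComparisonResult:
    """One-way ANOVA table plus all Tukey pairwise contrasts."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    comparisons: list[PairwiseComparison]
    alpha: float
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.comparisons])


# ---------------------------------------------------------------------------
# Standardization


def crop_to_mask(image: NeuropilImage) -> NeuropilImage:
    """Crop pixels and mask to the tight bounding box of true mask pixels."""
    rows = np.flatnonzero(image.mask.any(axis=1))
    cols = np.flatnonzero(image.mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask")
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return replace(
        image,
        pixels=image.pixels[r0:r1, c0:c1].copy(),
        mask=image.mask[r0:r1, c0:c1].copy(),
    )


def resize_to_standard(image: NeuropilImage) -> NeuropilImage:
    """Bilinear resize to the kind's standard resolution.

    Images already at standard resolution pass through pixel-identical.  The
    mask is resized with nearest-neighbour interpolation to stay boolean.
    """
    target = image.kind.standard_shape
    if image.pixels.shape == target:
        return replace(image, pixels=image.pixels.copy(), mask=image.mask.copy())
    pixels = _sk_resize(
        image.pixels.astype(np.float64),
        target,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    mask = _sk_resize(
        image.mask.astype(np.float64),
        target,
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return replace(
        image,
        pixels=np.clip(pixels, 0, 255).astype(np.float32),
        mask=mask > 0.5,
    )


def mean_fluorescence(image: NeuropilImage) -> float:
    """Arithmetic mean intensity over all pixels of a standardized image."""
    if image.pixels.size == 0:
        raise ValueError("empty image")
    return float(image.pixels.mean())


def quantify_images(images: list[NeuropilImage]) -> pd.DataFrame:
    """Crop, resize and measure every image; one FluorescenceRecord per row."""
    records = []
    for img in images:
        std = resize_to_standard(crop_to_mask(img))
        records.append(
            FluorescenceRecord(
                animal_id=img.animal_id,
                cohort=img.cohort,
                kind=img.kind.value,
                side_index=img.side_index,
                mean_rfu=mean_fluorescence(std),
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# Statistics


def _tukey_pairs(groups: dict[str, np.ndarray], alpha: float) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD via the studentized range distribution, with the
    Tukey–Kramer correction for unequal group sizes."""
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    df_within = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    mse = sse / df_within
    out = []
    for a, b in combinations(sorted(groups), 2):
        va, vb = groups[a], groups[b]
        diff = float(vb.mean() - va.mean())
        se = np.sqrt(mse / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_within))
        p = min(max(p, 0.0), 1.0)
        out.append(
            PairwiseComparison(
                group_a=a,
                group_b=b,
                mean_diff=diff,
                q_stat=float(q),
                p_adj=p,
                significant=bool(p < alpha),
            )
        )
    return out


def compare_cohorts(
    records: pd.DataFrame,
    response: str = "mean_rfu",
    alpha: float = 0.05,
) -> CohortComparisonResult | dict[str, CohortComparisonResult]:
    """One-way ANOVA across cohorts followed by Tukey HSD for all pairs.

    If ``records`` spans several neuropil kinds the analysis is run per kind
    and a dict keyed by kind is returned.  Zero within-group variance with
    identical means is reported explicitly as an undefined F (NaN + note).
    """
    if records["kind"].nunique() > 1:
        return {
            kind: compare_cohorts(sub, response=response, alpha=alpha)
            for kind, sub in records.groupby("kind", sort=True)
        }
    groups = {
        str(c): np.asarray(sub[response], dtype=float)
        for c, sub in records.groupby("cohort", sort=True)
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 cohorts")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 records per cohort")
    k = len(groups)
    n_total = sum(len(v) for v in groups.values())
    values = list(groups.values())
    sse = sum(((v - v.mean()) ** 2).sum() for v in values)
    note = ""
    if sse == 0 and len({v.mean() for v in values}) == 1:
        f, p = np.nan, np.nan
        note = "F undefined: zero within-group variance with identical means"
    else:
        f, p = stats.f_oneway(*values)
        f, p = float(f), float(p)
    return CohortComparisonResult(
        f_stat=f,
        df_between=k - 1,
        df_within=n_total - k,
        p_value=p,
        comparisons=_tukey_pairs(groups, alpha),
        alpha=alpha,
        note=note,
    )


def compare_cohorts_twoway(
    records: pd.DataFrame, response: str = "mean_rfu"
) -> pd.DataFrame:
    """Two-way ANOVA with cohort and neuropil kind as crossed factors
    (type-II sums of squares); returns the statsmodels ANOVA table."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = records.rename(columns={response: "response"})
    model = smf.ols("response ~ C(cohort) * C(kind)", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)


def correlate_size(
    covariates: pd.DataFrame,
    x: str = "head_width_um",
    y: str = "area_px",
) -> tuple[float, float]:
    """Pearson correlation between head width and neuropil area (r, p)."""
    xs = np.asarray(covariates[x], dtype=float)
    ys = np.asarray(covariates[y], dtype=float)
    if len(xs) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)
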