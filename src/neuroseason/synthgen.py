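"""Synthetic serotonin-immunofluorescence (SI) micrograph generator.

Real optic-lobe micrographs for this kind of study are rarely deposited, so
the package ships a generator that emulates their statistical structure: one
8-bit grayscale image per neuropil (lamina, medulla or lobula) at the standard
post-crop resolution, containing SI "profiles" rendered as thresholded
smoothed noise on a dim background, plus per-animal covariates (head width,
neuropil area).  Cohort differences are *planted* through
:func:`plant_effect`, which scales mean intensity and/or texture density, so
downstream inference stages can be calibrated against a known ground truth.

The generator is exactly mean-calibrated: foreground and background levels
are solved so that the expected within-mask mean equals ``mean_intensity``
(before noise clipping, which is negligible away from the 0/255 rails).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "NeuropilKind",
    "CohortSpec",
    "NeuropilImage",
    "generate_neuropil_image",
    "generate_cohort",
    "plant_effect",
    "cohort_presets",
    "write_cohort",
    "read_manifest",
    "STANDARD_SHAPES",
]

#: Standard (rows, cols) resolution per neuropil after crop + resize.
STANDARD_SHAPES: dict[str, tuple[int, int]] = {
    "lamina": (500, 100),
    "medulla": (800, 400),
    "lobula": (250, 400),
}

#: Fraction of the distal-proximal (row) axis occupied by the medulla's
#: central SI band; the outermost layers stay background-only.
MEDULLA_BAND_FRACTION = 0.6


class NeuropilKind(str, enum.Enum):
    """Optic-lobe neuropil identity, carrying its standard resolution."""

    LAMINA = "lamina"
    MEDULLA = "medulla"
    LOBULA = "lobula"

    @property
    def standard_shape(self) -> tuple[int, int]:
        """(rows, cols) of the standardized image."""
        return STANDARD_SHAPES[self.value]

    @property
    def standard_rows(self) -> int:
        return self.standard_shape[0]

    @property
    def standard_cols(self) -> int:
        return self.standard_shape[1]


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of one cohort for one neuropil.

    Parameters
    ----------
    label : str
        Cohort tag, conventionally "H" (hibernating), "A" (active) or
        "O" (outside), but arbitrary strings are accepted.
    mean_intensity : float
        Expected within-mask mean SI level, 8-bit units (0-255).
    texture_density : float
        Fraction of the mask covered by SI profiles (0-1).  For the medulla
        the profiles live inside the central band, so the density cannot
        exceed the band fraction.
    texture_scale : float
        Characteristic profile size in pixels (smoothing sigma of the
        thresholded-noise texture).
    noise_sd : float
        Additive pixel noise standard deviation, 8-bit units.
    head_width_mean, head_width_sd : float
        Per-animal head width distribution, µm.
    area_scale : float
        Relative multiplier on the neuropil area covariate.
    background_fraction : float
        Background level as a fraction of ``mean_intensity``; the foreground
        level is solved from it so the within-mask mean is exact.
    noise_model : str
        "gaussian" (default) or "poisson".
    """

    label: str
    mean_intensity: float
    texture_density: float
    texture_scale: float = 2.0
    noise_sd: float = 10.0
    head_width_mean: float = 685.0
    head_width_sd: float = 15.0
    area_scale: float = 1.0
    background_fraction: float = 0.25
    noise_model: str = "gaussian"

    def __post_init__(self):
        if not 0.0 <= self.mean_intensity <= 255.0:
            raise ValueError(f"mean_intensity {self.mean_intensity} outside [0, 255]")
        if not 0.0 <= self.texture_density <= 1.0:
            raise ValueError(f"texture_density {self.texture_density} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.head_width_mean <= 0:
            raise ValueError("head_width_mean must be > 0")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def levels(self) -> tuple[float, float]:
        """(background, foreground) intensities solving
        d*fg + (1-d)*bg = mean_intensity."""
        bg = self.background_fraction * self.mean_intensity
        d = self.texture_density
        if d == 0.0:
            return self.mean_intensity, self.mean_intensity
        fg = (self.mean_intensity - (1.0 - d) * bg) / d
        if fg > 255.0:
            raise ValueError(
                f"cohort {self.label!r}: foreground level {fg:.1f} exceeds 255; "
                "raise texture_density or background_fraction, or lower "
                "mean_intensity"
            )
        return bg, fg


@dataclass
class NeuropilImage:
    """One single-channel neuropil micrograph with its mask and metadata."""

    pixels: np.ndarray
    mask: np.ndarray
    animal_id: str
    cohort: str
    kind: NeuropilKind
    side_index: int = 1

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels {self.pixels.shape} and mask {self.mask.shape} differ"
            )
        if not self.mask.any():
            raise ValueError("mask has no true pixel")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities outside [0, 255]")
        self.kind = NeuropilKind(self.kind)
        if self.side_index not in (1, 2):
            raise ValueError("side_index must be 1 or 2")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _texture_region(kind: NeuropilKind, shape: tuple[int, int]) -> np.ndarray:
    """Boolean map of where SI profiles are allowed to appear."""
    allowed = np.ones(shape, dtype=bool)
    if kind is NeuropilKind.MEDULLA:
        rows = shape[0]
        margin = (1.0 - MEDULLA_BAND_FRACTION) / 2.0
        lo = int(round(margin * rows))
        hi = int(round((1.0 - margin) * rows))
        allowed[:] = False
        allowed[lo:hi, :] = True
    return allowed


def generate_neuropil_image(
    kind: NeuropilKind | str,
    spec: CohortSpec,
    seed: int | np.random.SeedSequence,
    animal_id: str = "synthetic",
    cohort: str | None = None,
    side_index: int = 1,
) -> NeuropilImage:
    """Render one synthetic SI micrograph at the kind's standard resolution.

    The texture follows the qualitative anatomy of each neuropil: the lamina
    is filled by a dense meshwork across the whole mask, the medulla's SI is
    confined to a central band along the distal-proximal (row) axis, and the
    lobula carries sparse, roughly homogeneous blobs.  Identical
    (kind, spec, seed) triples give bit-identical images.
    """
    kind = NeuropilKind(kind)
    rng = np.random.default_rng(seed)
    shape = kind.standard_shape
    bg, fg = spec.levels()

    img = np.full(shape, bg, dtype=np.float64)
    allowed = _texture_region(kind, shape)
    n_texture = int(round(spec.texture_density * img.size))
    if n_texture > allowed.sum():
        raise ValueError(
            f"texture_density {spec.texture_density} exceeds the allowed "
            f"region fraction {allowed.mean():.2f} for {kind.value}"
        )
    if n_texture > 0:
        # profiles = top-k pixels of smoothed noise within the allowed band;
        # exactly k pixels guarantees the mean calibration
        field_noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(field_noise, sigma=spec.texture_scale)
        smooth = np.where(allowed, smooth, -np.inf)
        flat = smooth.ravel()
        top = np.argpartition(flat, -n_texture)[-n_texture:]
        img.ravel()[top] = fg

    if spec.noise_model == "poisson":
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    elif spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(img, 0.0, 255.0)

    return NeuropilImage(
        pixels=img.astype(np.float32),
        mask=np.ones(shape, dtype=bool),
        animal_id=animal_id,
        cohort=spec.label if cohort is None else cohort,
        kind=kind,
        side_index=side_index,
    )


def generate_cohort(
    n_animals: int,
    kind: NeuropilKind | str,
    spec: CohortSpec,
    neuropils_per_animal: int = 1,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[NeuropilImage], pd.DataFrame]:
    """Generate a cohort: images plus a one-row-per-animal covariate table.

    Head width is drawn Normal(head_width_mean, head_width_sd); neuropil
    area grows with the square of head width (isometric scaling of a planar
    section) times ``area_scale``, with mild lognormal jitter, giving the
    positive size-width coupling seen in real colonies.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if neuropils_per_animal not in (1, 2):
        raise ValueError("neuropils_per_animal must be 1 or 2")
    kind = NeuropilKind(kind)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cov_ss, *img_ss = ss.spawn(1 + n_animals * neuropils_per_animal)
    rng = np.random.default_rng(cov_ss)

    head_widths = rng.normal(spec.head_width_mean, spec.head_width_sd, size=n_animals)
    head_widths = np.clip(head_widths, 1.0, None)
    # planar section area ~ (head width)^2; the lognormal jitter (sigma 0.04)
    # stays below the squared head-width spread so the size-width coupling
    # remains clearly positive even within low-variance laboratory cohorts
    jitter = rng.lognormal(mean=0.0, sigma=0.04, size=n_animals)
    areas = 0.25 * head_widths**2 * spec.area_scale * jitter

    images: list[NeuropilImage] = []
    k = 0
    for a in range(n_animals):
        animal_id = f"{spec.label}{a + 1:03d}"
        for side in range(1, neuropils_per_animal + 1):
            images.append(
                generate_neuropil_image(
                    kind, spec, img_ss[k], animal_id=animal_id, side_index=side
                )
            )
            k += 1

    covariates = pd.DataFrame(
        {
            "animal_id": [f"{spec.label}{a + 1:03d}" for a in range(n_animals)],
            "cohort": spec.label,
            "kind": kind.value,
            "head_width_um": head_widths,
            "area_px": areas,
        }
    )
    return images, covariates


def plant_effect(
    base: CohortSpec,
    delta_intensity: float = 0.0,
    delta_density: float = 0.0,
    label: str | None = None,
) -> CohortSpec:
    """Copy ``base`` with mean intensity and/or texture density scaled by
    (1 + delta); all other fields unchanged.  Raises if a scaled value
    leaves its valid range."""
    new = replace(
        base,
        mean_intensity=base.mean_intensity * (1.0 + delta_intensity),
        texture_density=base.texture_density * (1.0 + delta_density),
        label=base.label if label is None else label,
    )
    new.levels()  # validate renderability of the scaled parameters
    return new


def cohort_presets(kind: NeuropilKind | str) -> dict[str, CohortSpec]:
    """Default H/A/O cohort parameters per neuropil.

    The presets encode the direction of the observed seasonal contrasts, not
    their magnitudes: hibernating lamina SI ~25% below active, outside
    medulla SI ~10% above the laboratory cohorts, outside head width ~40%
    above the (small, young) laboratory colonies, with little head-width
    variation inside laboratory cohorts.
    """
    kind = NeuropilKind(kind)
    lab_hw = dict(head_width_mean=685.0, head_width_sd=15.0)
    out_hw = dict(head_width_mean=946.0, head_width_sd=40.0, area_scale=1.0)
    if kind is NeuropilKind.LAMINA:
        base = dict(texture_density=0.5, texture_scale=1.5, noise_sd=10.0)
        a = CohortSpec("A", mean_intensity=100.0, **base, **lab_hw)
        return {
            "A": a,
            "H": plant_effect(a, delta_intensity=-0.25, label="H"),
            "O": CohortSpec("O", mean_intensity=100.0, **base, **out_hw),
        }
    if kind is NeuropilKind.MEDULLA:
        base = dict(texture_density=0.4, texture_scale=2.5, noise_sd=10.0)
        a = CohortSpec("A", mean_intensity=80.0, **base, **lab_hw)
        return {
            "A": a,
            "H": replace(a, label="H"),
            "O": CohortSpec("O", mean_intensity=88.0, **base, **out_hw),
        }
    base = dict(
        texture_density=0.15, texture_scale=3.0, noise_sd=10.0,
        background_fraction=0.5,
    )
    a = CohortSpec("A", mean_intensity=45.0, **base, **lab_hw)
    return {
        "A": a,
        "H": replace(a, label="H"),
        "O": CohortSpec("O", mean_intensity=45.0, **base, **out_hw),
    }


# ---------------------------------------------------------------------------
# I/O: 8-bit grayscale PNGs plus a CSV manifest


def write_cohort(
    images: list[NeuropilImage],
    covariates: pd.DataFrame,
    out_dir: str | Path,
    write_masks: bool = True,
) -> pd.DataFrame:
    """Write images (8-bit PNG), masks and a manifest CSV; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        stem = f"{img.animal_id}_{img.kind.value}_{img.side_index}"
        path = out_dir / f"{stem}.png"
        iio.imwrite(path, np.round(img.pixels).astype(np.uint8))
        mask_path = ""
        if write_masks:
            mask_path = str(out_dir / f"{stem}_mask.png")
            iio.imwrite(mask_path, (img.mask * 255).astype(np.uint8))
        cov = covariates.loc[covariates["animal_id"] == img.animal_id]
        rows.append(
            {
                "animal_id": img.animal_id,
                "cohort": img.cohort,
                "kind": img.kind.value,
                "side_index": img.side_index,
                "head_width_um": float(cov["head_width_um"].iloc[0]) if len(cov) else np.nan,
                "area_px": float(cov["area_px"].iloc[0]) if len(cov) else np.nan,
                "file_path": str(path),
                "mask_path": mask_path,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(manifest_path: str | Path) -> tuple[list[NeuropilImage], pd.DataFrame]:
    """Load images referenced by a manifest CSV back into NeuropilImage objects."""
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    images = []
    for _, row in manifest.iterrows():
        pixels = iio.imread(row["file_path"]).astype(np.float32)
        if row.get("mask_path", ""):
            mask = iio.imread(row["mask_path"]) > 127
        else:
            mask = np.ones(pixels.shape, dtype=bool)
        images.append(
            NeuropilImage(
                pixels=pixels,
                mask=mask,
                animal_id=str(row["animal_id"]),
                cohort=str(row["cohort"]),
                kind=NeuropilKind(row["kind"]),
                side_index=int(row["side_index"]),
            )
        )
    return images, manifest
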