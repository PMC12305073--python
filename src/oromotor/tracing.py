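"""Anatomical tracing quantification.

Anterograde side: synaptophysin-labelled bouton density per motor-nucleus
subdivision (Mo5, Acc5, Mo7 subdivisions, dorsal/ventral Mo12) as the mean
thresholded pixel intensity within hand-drawn ROIs, averaged across sections
and animals, with assumption-gated paired comparisons between nuclei.
Retrograde side: per-region counts of monosynaptically traced input neurons
(mCherry single-positive), excluding detections outside the brain, in fiber
tracts or in ventricles, expressed as proportions of total input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, PairingError, ParameterError
from .stats import TestReport, gated_group_comparison

__all__ = [
    "RoiIntensity",
    "roi_bouton_intensity",
    "aggregate_intensities",
    "pairwise_intensity_tests",
    "input_proportion_table",
    "simulate_bouton_image",
    "EXCLUDED_COMPARTMENTS",
]

EXCLUDED_COMPARTMENTS = ("off_brain", "fiber_tract", "ventricle")


@dataclass
class RoiIntensity:
    """Mean thresholded pixel intensity in one ROI of one section."""

    roi_label: str
    section_id: str
    animal_id: str
    mean_intensity: float
    n_pixels: int
    threshold: float


def roi_bouton_intensity(
    image: np.ndarray,
    roi_mask: np.ndarray,
    threshold: float,
    roi_label: str = "",
    section_id: str = "",
    animal_id: str = "",
) -> RoiIntensity:
    """Mean bouton intensity in an ROI after background thresholding.

    Pixels below ``threshold`` are set to zero (background removal that
    preserves boutons), remaining intensities inside the mask are summed and
    divided by the total pixel count of the mask.
    """
    image = np.asarray(image, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if image.shape != roi_mask.shape:
        raise ParameterError(
            f"image shape {image.shape} != mask shape {roi_mask.shape}"
        )
    n = int(roi_mask.sum())
    if n == 0:
        raise ParameterError("empty ROI mask")
    vals = image[roi_mask]
    vals = np.where(vals >= threshold, vals, 0.0)
    return RoiIntensity(
        roi_label=roi_label,
        section_id=section_id,
        animal_id=animal_id,
        mean_intensity=float(vals.sum() / n),
        n_pixels=n,
        threshold=float(threshold),
    )


def aggregate_intensities(intensities: list[RoiIntensity] | pd.DataFrame) -> pd.DataFrame:
    """Average per-section intensities to per-animal, then grand means per ROI.

    Returns a tidy frame with one row per (roi_label, animal_id) holding the
    across-section mean, plus the grand mean per ROI in ``grand_mean``.
    """
    if isinstance(intensities, pd.DataFrame):
        df = intensities.copy()
    else:
        df = pd.DataFrame(
            {
                "roi_label": [r.roi_label for r in intensities],
                "animal_id": [r.animal_id for r in intensities],
                "section_id": [r.section_id for r in intensities],
                "mean_intensity": [r.mean_intensity for r in intensities],
            }
        )
    per_animal = (
        df.groupby(["roi_label", "animal_id"], as_index=False)["mean_intensity"]
        .mean()
        .rename(columns={"mean_intensity": "animal_mean"})
    )
    grand = per_animal.groupby("roi_label")["animal_mean"].mean().rename("grand_mean")
    return per_animal.merge(grand, on="roi_label")


def pairwise_intensity_tests(
    intensities: list[RoiIntensity] | pd.DataFrame,
    unit: str = "animal_section",
) -> pd.DataFrame:
    """Assumption-gated paired tests between every pair of nuclei.

    Intensity values are matched across nuclei by observation unit
    (``'animal_section'``: each section of each animal is a pair member;
    ``'animal'``: per-animal means are paired).  For each nucleus pair the
    paired differences are gated through Shapiro-Wilk, then compared with a
    paired t test or a Wilcoxon signed-rank test, two-sided at alpha 0.05.
    """
    if isinstance(intensities, pd.DataFrame):
        df = intensities.copy()
    else:
        df = pd.DataFrame(
            {
                "roi_label": [r.roi_label for r in intensities],
                "animal_id": [r.animal_id for r in intensities],
                "section_id": [r.section_id for r in intensities],
                "mean_intensity": [r.mean_intensity for r in intensities],
            }
        )
    if unit == "animal":
        df = (
            df.groupby(["roi_label", "animal_id"], as_index=False)["mean_intensity"]
            .mean()
            .assign(unit=lambda d: d["animal_id"])
        )
    elif unit == "animal_section":
        df = df.assign(unit=df["animal_id"].astype(str) + "/" + df["section_id"].astype(str))
    else:
        raise ParameterError(f"unit must be 'animal' or 'animal_section', got {unit!r}")
    wide = df.pivot_table(index="unit", columns="roi_label", values="mean_intensity")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise PairingError(f"unmatched observations for nuclei {missing}")
    rois = list(wide.columns)
    rows = []
    for i, a in enumerate(rois):
        for b in rois[i + 1 :]:
            rep = gated_group_comparison(wide[a].to_numpy(), wide[b].to_numpy(), paired=True)
            rows.append(
                {
                    "roi_a": a,
                    "roi_b": b,
                    "method": rep.method,
                    "statistic": rep.statistic,
                    "pvalue": rep.pvalue,
                    "mean_diff": rep.estimate,
                    "significant": rep.significant,
                    "n_pairs": rep.n,
                }
            )
    return pd.DataFrame(rows)


def input_proportion_table(
    detections: pd.DataFrame,
    omit_below: float = 0.003,
    region_col: str = "region",
    seed_col: str = "is_seed",
    compartment_col: str = "compartment",
) -> pd.DataFrame:
    """Per-region input-cell counts and proportions of total input.

    Seed cells (double-positive starters) are not inputs and are dropped;
    detections in excluded compartments (off-brain, fiber tracts,
    ventricles) are eliminated from both counts and totals.  Regions whose
    proportion falls below ``omit_below`` are flagged ``omitted`` (for
    display) but still counted in the total.
    """
    df = detections.copy()
    if region_col not in df.columns:
        raise ParameterError(f"detections lack a {region_col!r} column")
    if seed_col in df.columns:
        df = df[~df[seed_col].astype(bool)]
    if compartment_col in df.columns:
        df = df[~df[compartment_col].isin(EXCLUDED_COMPARTMENTS)]
    if len(df) == 0:
        raise InsufficientDataError("no input cells remain after exclusions")
    counts = df.groupby(region_col).size().rename("count").reset_index()
    total = int(counts["count"].sum())
    counts["proportion"] = counts["count"] / total
    counts["omitted"] = counts["proportion"] < omit_below
    return counts.sort_values("proportion", ascending=False, ignore_index=True)


def simulate_bouton_image(
    shape: tuple[int, int],
    n_boutons: int,
    rng: np.random.Generator,
    amplitude: float = 100.0,
    radius_px: float = 1.5,
    background_sd: float = 2.0,
) -> np.ndarray:
    """Synthetic bouton-like image: punctate Gaussian blobs on noisy background.

    Stand-in for a fluorescence section; used to exercise the intensity
    quantification at configurable bouton density (e.g. the severalfold
    density contrast between antagonist motor pools).
    """
    from scipy.ndimage import gaussian_filter

    img = np.zeros(shape)
    ys = rng.integers(0, shape[0], n_boutons)
    xs = rng.integers(0, shape[1], n_boutons)
    np.add.at(img, (ys, xs), amplitude * (2 * np.pi * radius_px**2))
    img = gaussian_filter(img, radius_px)
    img += np.abs(rng.normal(0.0, background_sd, shape))
    return img
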