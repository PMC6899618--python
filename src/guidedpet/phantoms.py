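"""Paired PET/MR digital brain phantom with PET-unique lesions.

The phantom is procedural: a sinusoidally perturbed annular cortex (gray
matter) wrapped around a white-matter interior with a central CSF
ventricle.  The PET activity and the MR guidance image share exactly the
same label boundaries but carry different contrasts (FDG-like GM > WM for
PET, T1-like WM > GM > CSF for MR), and four tumors are inserted into the
PET activity only — the configuration every guided-reconstruction
evaluation here depends on: shared boundaries, discrepant lesions.

Activity conventions: gray:white = 4:1 with gray matter at 0.1 arbitrary
units by default; CSF is cold (0).  Smoothed uniform random structure
theta * (1 + H*(2*G(rand, sigma_sm) - 1)) breaks the piecewise-constant
tissue plateaus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .images import VoxelImage

__all__ = [
    "TumorSpec",
    "PhantomSpec",
    "PhantomBundle",
    "make_brain_phantom",
    "add_random_structure",
    "insert_tumors",
    "default_tumors",
]

# label codes
BG, CSF, WM, GM = 0, 1, 2, 3

MASK_NAMES = (
    "whole_brain",
    "wm_full",
    "gm_full",
    "csf_full",
    "wm_eroded",
    "tumor_A",
    "tumor_B",
    "tumor_C",
    "tumor_D",
)


@dataclass
class TumorSpec:
    """One PET-unique lesion.

    ``multiplier`` is relative to the gray-matter activity; ``profile`` is
    ``"hard"`` (set voxels inside the radius) or ``"gaussian"`` (smooth
    falloff with sigma = radius/2, blended into the surrounding activity).
    """

    name: str
    center_mm: tuple[float, ...]  # offset from the grid center, mm
    radius_mm: float
    multiplier: float
    profile: str = "hard"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if self.profile not in ("hard", "gaussian"):
            raise ValueError(f"unknown tumor profile {self.profile!r}")


@dataclass
class PhantomSpec:
    """Parameters of the procedural brain phantom."""

    shape: tuple[int, ...] = (128, 128)
    spacing: float | tuple[float, ...] = 1.0
    csf_activity: float = 0.0
    wm_activity: float = 0.025
    gm_wm_ratio: float = 4.0
    mr_values: dict = field(
        default_factory=lambda: {"csf": 0.2, "wm": 1.0, "gm": 0.6, "bg": 0.0}
    )
    structure_amplitude: float = 0.1  # H
    structure_sigma: float = 2.0  # sigma_sm, voxels
    tumors: list[TumorSpec] | None = None  # None -> default four-lesion layout
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * len(self.shape)
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
        if self.gm_wm_ratio <= 0:
            raise ValueError("gm_wm_ratio must be positive")
        if self.structure_amplitude < 0:
            raise ValueError("structure amplitude H must be >= 0")
        if self.structure_sigma <= 0:
            raise ValueError("structure sigma must be positive")

    @property
    def gm_activity(self) -> float:
        return self.wm_activity * self.gm_wm_ratio

    # -- config round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "csf_activity": self.csf_activity,
            "wm_activity": self.wm_activity,
            "gm_wm_ratio": self.gm_wm_ratio,
            "mr_values": dict(self.mr_values),
            "structure_amplitude": self.structure_amplitude,
            "structure_sigma": self.structure_sigma,
            "seed": self.seed,
        }
        if self.tumors is not None:
            d["tumors"] = [
                {
                    "name": t.name,
                    "center_mm": list(t.center_mm),
                    "radius_mm": t.radius_mm,
                    "multiplier": t.multiplier,
                    "profile": t.profile,
                }
                for t in self.tumors
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "tumors" in d and d["tumors"] is not None:
            d["tumors"] = [
                TumorSpec(
                    name=t["name"],
                    center_mm=tuple(t["center_mm"]),
                    radius_mm=t["radius_mm"],
                    multiplier=t["multiplier"],
                    profile=t.get("profile", "hard"),
                )
                for t in d["tumors"]
            ]
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "spacing" in d and not np.isscalar(d["spacing"]):
            d["spacing"] = tuple(d["spacing"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PhantomBundle:
    """Phantom outputs: ground-truth activity, MR guidance, labels, ROI masks."""

    pet_ground_truth: VoxelImage
    mr_image: VoxelImage
    label_map: VoxelImage
    roi_masks: dict[str, VoxelImage]
    spec: PhantomSpec

    def save(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.pet_ground_truth.to_nifti(os.path.join(outdir, "pet_ground_truth.nii.gz"))
        self.mr_image.to_nifti(os.path.join(outdir, "mr_image.nii.gz"))
        self.label_map.to_nifti(os.path.join(outdir, "label_map.nii.gz"))
        for name, mask in self.roi_masks.items():
            mask.to_nifti(os.path.join(outdir, f"{name}.nii.gz"))


# ---------------------------------------------------------------------------


def _brain_geometry(spec: PhantomSpec):
    """Normalized elliptical radius rho and in-plane polar angle phi."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(spec.shape, spec.spacing)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    semi = [0.42 * n * s for n, s in zip(spec.shape, spec.spacing)]
    if min(semi) < 8.0 * max(spec.spacing):
        raise ValueError(
            f"grid {spec.shape} too small to contain the phantom structures"
        )
    rho = np.sqrt(sum((g / r) ** 2 for g, r in zip(grids, semi)))
    phi = np.arctan2(grids[1], grids[0])
    return rho, phi, min(semi)


def _make_labels(spec: PhantomSpec) -> np.ndarray:
    """Nested structures: background, CSF ventricle, WM, folded GM ribbon."""
    rho, phi, _ = _brain_geometry(spec)
    outer = 1.0 + 0.05 * np.sin(5 * phi + 0.7)
    gm_inner = outer - 0.12 * (1.0 + 0.4 * np.sin(7 * phi + 0.3))
    csf_edge = 0.18 * (1.0 + 0.35 * np.sin(3 * phi + 1.2))

    labels = np.full(spec.shape, BG, dtype=np.int16)
    labels[rho <= outer] = GM
    labels[rho <= gm_inner] = WM
    labels[rho <= csf_edge] = CSF
    if not (labels == WM).any() or not (labels == GM).any():
        raise ValueError("grid too small: tissue classes not resolved")
    return labels


def default_tumors(spec: PhantomSpec) -> list[TumorSpec]:
    """Four-lesion layout: small low-contrast A (Gaussian) and C (hard edge)
    inside white matter; larger B (Gaussian, 2x GM) and D (hard, 3x GM)
    straddling the WM/GM boundary.  C and D sit at three times the
    gray-matter intensity."""
    _, _, rmin = _brain_geometry(spec)

    def polar(frac, ang_deg):
        a = math.radians(ang_deg)
        c = [frac * rmin * math.cos(a), frac * rmin * math.sin(a)]
        return tuple(c + [0.0] * (len(spec.shape) - 2))

    return [
        TumorSpec("tumor_A", polar(0.47, 230.0), 0.065 * rmin, 1.5, "gaussian"),
        TumorSpec("tumor_B", polar(0.78, 90.0), 0.12 * rmin, 2.0, "gaussian"),
        TumorSpec("tumor_C", polar(0.47, 315.0), 0.065 * rmin, 3.0, "hard"),
        TumorSpec("tumor_D", polar(0.78, 160.0), 0.12 * rmin, 3.0, "hard"),
    ]


def add_random_structure(
    image: VoxelImage,
    H: float,
    sigma_sm: float,
    rng: np.random.Generator,
    rand_field: np.ndarray | None = None,
) -> VoxelImage:
    """Multiply by 1 + H*(2*G(rand, sigma_sm) - 1) with rand ~ U(0, 1).

    ``rand_field`` overrides the uniform draw (test injection hook).  The
    smoothed field has mean 1/2 so the multiplier is mean-one; the output is
    clipped at zero in case H is large enough to drive it negative.
    """
    if H < 0:
        raise ValueError("H must be >= 0")
    if sigma_sm <= 0:
        raise ValueError("sigma_sm must be positive")
    vals = image.values
    if H == 0:
        return image.copy()
    if rand_field is None:
        rand_field = rng.uniform(0.0, 1.0, size=vals.shape)
    smooth = ndimage.gaussian_filter(rand_field, sigma_sm, mode="nearest")
    out = vals * (1.0 + H * (2.0 * smooth - 1.0))
    return image.with_values(np.clip(out, 0.0, None))


def insert_tumors(bundle: PhantomBundle, descriptors: list[TumorSpec]) -> PhantomBundle:
    """Add PET-unique lesions: the activity image changes, the MR does not.

    Lesion voxels are set to ``multiplier * GM activity`` (hard profile) or
    blended in with a Gaussian falloff; the lesion masks are recorded.
    Tumors must lie inside the brain and must not overlap.
    """
    pet = bundle.pet_ground_truth.values.copy()
    img = bundle.pet_ground_truth
    brain = bundle.roi_masks["whole_brain"].values
    gm_act = bundle.spec.gm_activity
    grids = img.centered_grids()

    masks: dict[str, np.ndarray] = {}
    for t in descriptors:
        d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, t.center_mm)))
        mask = d <= t.radius_mm
        if not mask.any():
            raise ValueError(f"{t.name}: radius below voxel size, empty mask")
        if not brain[mask].all():
            raise ValueError(f"{t.name} extends outside the brain")
        for other, m in masks.items():
            if (mask & m).any():
                raise ValueError(f"{t.name} overlaps {other}")
        masks[t.name] = mask

        target = t.multiplier * gm_act
        if t.profile == "hard":
            pet[mask] = target
        else:
            g = np.exp(-(d**2) / (2.0 * (t.radius_mm / 2.0) ** 2))
            blend = brain & (d <= 2.5 * t.radius_mm)
            pet[blend] = pet[blend] * (1.0 - g[blend]) + target * g[blend]

    roi = dict(bundle.roi_masks)
    for name, m in masks.items():
        roi[name] = img.with_values(m)
    # tissue masks exclude lesion voxels; wm_eroded recomputed accordingly
    if masks:
        union = np.zeros(img.shape, dtype=bool)
        for m in masks.values():
            union |= m
        for tname in ("wm_full", "gm_full", "csf_full"):
            roi[tname] = img.with_values(roi[tname].values & ~union)
        roi["wm_eroded"] = img.with_values(_erode(roi["wm_full"].values))
    return PhantomBundle(
        pet_ground_truth=img.with_values(pet),
        mr_image=bundle.mr_image,
        label_map=bundle.label_map,
        roi_masks=roi,
        spec=bundle.spec,
    )


def _erode(mask: np.ndarray) -> np.ndarray:
    struct = np.ones((3,) * mask.ndim, dtype=bool)
    return ndimage.binary_erosion(mask, structure=struct)


def make_brain_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the paired PET/MR phantom with ROI masks.

    Pipeline: labels -> per-tissue PET activity (GM = ratio x WM) and
    T1-like MR contrast -> smoothed random structure on the PET activity ->
    PET-unique tumors -> ROI masks (tissue masks exclude lesion voxels so
    the eroded-WM noise proxy stays lesion-free).
    """
    rng = np.random.default_rng(spec.seed)
    labels = _make_labels(spec)

    act = np.zeros(4)
    act[CSF] = spec.csf_activity
    act[WM] = spec.wm_activity
    act[GM] = spec.gm_activity
    mrv = np.zeros(4)
    mrv[BG] = spec.mr_values.get("bg", 0.0)
    mrv[CSF] = spec.mr_values["csf"]
    mrv[WM] = spec.mr_values["wm"]
    mrv[GM] = spec.mr_values["gm"]

    pet = VoxelImage(act[labels], spec.spacing)
    mr = VoxelImage(mrv[labels], spec.spacing)
    label_img = VoxelImage(labels, spec.spacing)

    pet = add_random_structure(pet, spec.structure_amplitude, spec.structure_sigma, rng)

    roi = {
        "whole_brain": VoxelImage(labels > BG, spec.spacing),
        "wm_full": VoxelImage(labels == WM, spec.spacing),
        "gm_full": VoxelImage(labels == GM, spec.spacing),
        "csf_full": VoxelImage(labels == CSF, spec.spacing),
    }
    roi["wm_eroded"] = VoxelImage(_erode(roi["wm_full"].values), spec.spacing)

    bundle = PhantomBundle(pet, mr, label_img, roi, spec)
    tumors = default_tumors(spec) if spec.tumors is None else spec.tumors
    if tumors:
        bundle = insert_tumors(bundle, tumors)
    return bundle
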