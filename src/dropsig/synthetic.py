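"""Synthetic dried-blood-droplet study generator.

Real dried blood droplets show a red deposit with a darker peripheral rim
(the coffee-ring), radial cracks in the corona and disordered short cracks
near the centre; cracks dry out near-white.  This module renders droplets
with that morphology from a small set of phenotype parameters, arranges
them into a participants x conditions x replicates study with known
ground-truth labels, and draws a matching blood-chemistry table, so the
whole analysis chain can be exercised without any photograph downloads.

The physiological condition signal is carried by the angular structure of
the pattern: the dominant angular frequency of the rim modulation
(``angular_mode``, cycles per revolution) and the radial crack count.
Per-participant offsets, per-image random rotation, crack jitter and pixel
noise emulate the nuisance variation the rotation-invariant features and
replicate averaging are designed to defeat.

All randomness flows from a single master seed through a documented
per-cell seed derivation (participant, condition, replicate), so studies
are reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "DropletPhenotype",
    "PhenotypeEffect",
    "DropletRender",
    "StudyImage",
    "SyntheticStudy",
    "render_droplet",
    "generate_droplet_image",
    "generate_study",
    "generate_chemistry_table",
    "DEFAULT_CONDITIONS",
]

DEFAULT_CONDITIONS = ("baseline", "peak", "rec2", "rec4", "rec6")

_BACKGROUND = np.array([208.0, 196.0, 188.0])  # pale warm grey, backlit-slide look
_DEPOSIT = np.array([165.0, 60.0, 50.0])  # red-dominated deposit body
_CRACK = np.array([250.0, 250.0, 250.0])  # near-white dried crack

#: soft-edge width (px) of the sigmoid transitions in the render
_EDGE = 1.5
#: Gaussian cross-section width (px) of rendered cracks
_CRACK_W = 0.8
#: blend fraction above which a pixel counts as ground-truth crack core
_CRACK_CORE = 0.8


@dataclass(frozen=True)
class StudyDesign:
    """Cohort geometry: who is imaged, how often, and at what scale."""

    n_participants: int = 30
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    images_per_cell: tuple[int, int] = (10, 12)  # inclusive range per cell
    image_size_px: int = 144
    droplet_radius_px: float = 64.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if len(self.conditions) == 0:
            raise ValueError("conditions list is empty")
        lo, hi = self.images_per_cell
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid images_per_cell range {self.images_per_cell}")
        margin = self.image_size_px / 2.0 - self.droplet_radius_px
        if margin < 5:
            raise ValueError(
                f"droplet radius {self.droplet_radius_px} leaves margin {margin:.1f} px "
                "inside the image; need >= 5"
            )


@dataclass(frozen=True)
class DropletPhenotype:
    """Morphology knobs for one droplet render.

    ``angular_mode`` is the dominant angular frequency of the rim intensity
    modulation in cycles per revolution; ``rim_mod_depth`` its relative
    amplitude.  ``central_crack_density`` is short cracks per px^2 over the
    central disc (r < 0.35 R).
    """

    n_radial_cracks: int = 10
    central_crack_density: float = 0.004
    rim_width_frac: float = 0.16
    rim_darkening: float = 0.62
    angular_mode: float = 10.0
    rim_mod_depth: float = 0.25
    noise_sd: float = 3.0
    crack_angle_jitter: float = 0.05  # radians, per crack per image

    def __post_init__(self) -> None:
        for name in (
            "n_radial_cracks",
            "central_crack_density",
            "rim_darkening",
            "angular_mode",
            "rim_mod_depth",
            "noise_sd",
            "crack_angle_jitter",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not 0.0 < self.rim_width_frac < 0.5:
            raise ValueError(f"rim_width_frac must lie in (0, 0.5), got {self.rim_width_frac}")
        if self.angular_mode >= 51.5:  # half the 103-sample angular grid
            raise ValueError(
                f"angular_mode {self.angular_mode} at or above the angular Nyquist (51.5)"
            )


@dataclass(frozen=True)
class PhenotypeEffect:
    """Additive phenotype shift attached to one condition."""

    d_angular_mode: float = 0.0
    d_n_radial_cracks: float = 0.0
    d_rim_darkening: float = 0.0
    d_rim_mod_depth: float = 0.0
    d_central_density: float = 0.0

    def apply(self, p: DropletPhenotype) -> DropletPhenotype:
        return replace(
            p,
            angular_mode=p.angular_mode + self.d_angular_mode,
            n_radial_cracks=int(round(p.n_radial_cracks + self.d_n_radial_cracks)),
            rim_darkening=float(np.clip(p.rim_darkening + self.d_rim_darkening, 0.05, 0.98)),
            rim_mod_depth=float(np.clip(p.rim_mod_depth + self.d_rim_mod_depth, 0.0, 0.45)),
            central_crack_density=max(0.0, p.central_crack_density + self.d_central_density),
        )


@dataclass
class DropletRender:
    """One rendered droplet plus its ground-truth crack raster."""

    image: np.ndarray  # (S, S, 3) uint8
    crack_mask: np.ndarray  # boolean, True on crack cores
    centre: tuple[float, float]
    radius: float


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def render_droplet(
    design: StudyDesign,
    phenotype: DropletPhenotype,
    rotation: float = 0.0,
    seed: int = 0,
) -> DropletRender:
    """Render one droplet; deterministic given (design, phenotype, rotation, seed).

    Crack jitter and central-crack placement are drawn in a
    rotation-independent frame and then rotated, so two renders from the
    same seed that differ only in ``rotation`` depict the same droplet at
    two orientations (up to the fixed, un-rotated pixel noise field).
    """
    rng = np.random.default_rng(seed)
    S = design.image_size_px
    R = design.droplet_radius_px
    c0 = (S - 1) / 2.0

    rows, cols = np.mgrid[0:S, 0:S].astype(float)
    dy, dx = rows - c0, cols - c0
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    inside = _sigmoid((R - r) / _EDGE)  # 1 in deposit, 0 outside
    img = _BACKGROUND[None, None, :] + inside[:, :, None] * (_DEPOSIT - _BACKGROUND)

    # darker rim annulus with angular intensity modulation at angular_mode
    rim_in = R * (1.0 - phenotype.rim_width_frac)
    rim_win = _sigmoid((r - rim_in) / _EDGE) * _sigmoid((R - r) / _EDGE)
    mod = 1.0 + phenotype.rim_mod_depth * np.cos(
        phenotype.angular_mode * (theta - rotation)
    )
    darken = np.clip((1.0 - phenotype.rim_darkening) * mod, 0.0, 0.95)
    img *= (1.0 - rim_win * darken)[:, :, None]

    # radial corona cracks: near-white lines at jittered, rotation-shifted angles
    crack_field = np.zeros((S, S))
    n_cr = int(phenotype.n_radial_cracks)
    if n_cr > 0:
        jitter = rng.normal(0.0, phenotype.crack_angle_jitter, size=n_cr)
        angles = rotation + 2.0 * np.pi * np.arange(n_cr) / n_cr + jitter
        radial_win = _sigmoid((r - 0.45 * R) / _EDGE) * _sigmoid((0.97 * R - r) / _EDGE)
        for a in angles:
            d_ang = np.angle(np.exp(1j * (theta - a)))  # wrapped to (-pi, pi]
            d_perp = np.abs(r * d_ang)
            line = np.exp(-(d_perp**2) / (2.0 * _CRACK_W**2))
            crack_field = np.maximum(crack_field, line * radial_win)

    # disordered short cracks in the centre
    n_central = rng.poisson(phenotype.central_crack_density * np.pi * (0.35 * R) ** 2)
    if n_central > 0:
        rc = 0.35 * R * np.sqrt(rng.uniform(size=n_central))
        ac = rng.uniform(0.0, 2.0 * np.pi, size=n_central) + rotation
        seg_dir = rng.uniform(0.0, np.pi, size=n_central) + rotation
        half_len = rng.uniform(2.0, 5.0, size=n_central)
        px = c0 + rc * np.cos(ac)
        py = c0 + rc * np.sin(ac)
        for x0, y0, ang, hl in zip(px, py, seg_dir, half_len):
            ux, uy = np.cos(ang), np.sin(ang)
            t = np.clip((dx - (x0 - c0)) * ux + (dy - (y0 - c0)) * uy, -hl, hl)
            ddx = dx - (x0 - c0) - t * ux
            ddy = dy - (y0 - c0) - t * uy
            d2 = ddx**2 + ddy**2
            crack_field = np.maximum(crack_field, np.exp(-d2 / (2.0 * _CRACK_W**2)))

    crack_field = crack_field * _sigmoid((R - r) / _EDGE)
    img = img * (1.0 - crack_field[:, :, None]) + crack_field[:, :, None] * _CRACK[None, None, :]
    mask = crack_field > _CRACK_CORE

    if phenotype.noise_sd > 0:
        img = img + rng.normal(0.0, phenotype.noise_sd, size=img.shape)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return DropletRender(image=image, crack_mask=mask, centre=(c0, c0), radius=R)


def generate_droplet_image(
    design: StudyDesign,
    phenotype: DropletPhenotype,
    rotation: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Convenience wrapper returning just the uint8 RGB raster."""
    return render_droplet(design, phenotype, rotation=rotation, seed=seed).image


def cell_seed(master_seed: int, participant: int, condition_idx: int, replicate: int) -> int:
    """Deterministic per-image seed from the master seed and cell indices."""
    ss = np.random.SeedSequence([int(master_seed), participant, condition_idx, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class StudyImage:
    participant: int
    condition: str
    replicate: int
    seed: int
    rotation: float
    phenotype: DropletPhenotype
    image: np.ndarray


@dataclass
class SyntheticStudy:
    """Labelled image collection indexed by (participant, condition, replicate)."""

    design: StudyDesign
    images: list[StudyImage] = field(default_factory=list)

    def cell(self, participant: int, condition: str) -> list[StudyImage]:
        out = [
            im
            for im in self.images
            if im.participant == participant and im.condition == condition
        ]
        return sorted(out, key=lambda im: im.replicate)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "participant": im.participant,
                "condition": im.condition,
                "replicate": im.replicate,
                "seed": im.seed,
                "rotation": im.rotation,
                "angular_mode": im.phenotype.angular_mode,
                "n_radial_cracks": im.phenotype.n_radial_cracks,
            }
            for im in self.images
        ]
        return pd.DataFrame(rows)


#: per-participant between-subject SDs on the continuous phenotype knobs
_PARTICIPANT_SD = {"rim_darkening": 0.02, "rim_mod_depth": 0.02}
#: per-image within-cell SD on the rim modulation depth
_IMAGE_SD_MOD_DEPTH = 0.04
#: per-image SD of the radial crack count (each replicate is a distinct
#: physical droplet; crack counts vary between droplets of the same blood)
_IMAGE_SD_CRACKS = 1.0


def generate_study(
    design: StudyDesign,
    class_effect: Mapping[str, PhenotypeEffect],
    base_phenotype: DropletPhenotype | None = None,
    conditions: Sequence[str] | None = None,
) -> SyntheticStudy:
    """Generate the full labelled study.

    Each condition's phenotype is the base phenotype plus that condition's
    ``PhenotypeEffect`` plus a per-participant normal offset on rim
    darkening and modulation depth; each image additionally gets a uniform
    random rotation and a small modulation-depth jitter.
    """
    conditions = tuple(conditions if conditions is not None else design.conditions)
    if not conditions:
        raise ValueError("conditions list is empty")
    missing = [c for c in conditions if c not in class_effect]
    if missing:
        raise ValueError(f"class_effect missing conditions: {missing}")
    base = base_phenotype if base_phenotype is not None else DropletPhenotype()

    master = np.random.default_rng(np.random.SeedSequence([design.master_seed, 983]))
    # between-subject offsets, one draw per participant, condition-independent
    offs_dark = master.normal(0.0, _PARTICIPANT_SD["rim_darkening"], design.n_participants)
    offs_mod = master.normal(0.0, _PARTICIPANT_SD["rim_mod_depth"], design.n_participants)

    study = SyntheticStudy(design=design)
    lo, hi = design.images_per_cell
    for p in range(design.n_participants):
        for ci, cond in enumerate(conditions):
            pheno_cond = class_effect[cond].apply(base)
            pheno_part = replace(
                pheno_cond,
                rim_darkening=float(np.clip(pheno_cond.rim_darkening + offs_dark[p], 0.05, 0.98)),
                rim_mod_depth=float(np.clip(pheno_cond.rim_mod_depth + offs_mod[p], 0.0, 0.45)),
            )
            cell_rng = np.random.default_rng(
                np.random.SeedSequence([design.master_seed, 57, p, ci])
            )
            n_img = int(cell_rng.integers(lo, hi + 1))
            for k in range(n_img):
                seed = cell_seed(design.master_seed, p, ci, k)
                img_rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
                rotation = float(img_rng.uniform(0.0, 2.0 * np.pi))
                pheno_img = replace(
                    pheno_part,
                    rim_mod_depth=float(
                        np.clip(
                            pheno_part.rim_mod_depth
                            + img_rng.normal(0.0, _IMAGE_SD_MOD_DEPTH),
                            0.0,
                            0.45,
                        )
                    ),
                    n_radial_cracks=max(
                        0,
                        pheno_part.n_radial_cracks
                        + int(round(img_rng.normal(0.0, _IMAGE_SD_CRACKS))),
                    ),
                )
                image = generate_droplet_image(design, pheno_img, rotation=rotation, seed=seed)
                study.images.append(
                    StudyImage(
                        participant=p,
                        condition=cond,
                        replicate=k,
                        seed=seed,
                        rotation=rotation,
                        phenotype=pheno_img,
                        image=image,
                    )
                )
    return study


def write_study(study: SyntheticStudy, root) -> pd.DataFrame:
    """Write PNGs as participant_<i>/<condition>/img_<k>.png plus a manifest CSV."""
    import imageio.v3 as iio
    from pathlib import Path

    root = Path(root)
    paths = []
    for im in study.images:
        d = root / f"participant_{im.participant}" / im.condition
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"img_{im.replicate}.png"
        iio.imwrite(path, im.image)
        paths.append(str(path.relative_to(root)))
    manifest = study.manifest()
    manifest["path"] = paths
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest


def generate_chemistry_table(design: StudyDesign, seed: int | None = None) -> pd.DataFrame:
    """Draw a per-participant, per-condition blood-chemistry panel.

    Delegates to :func:`dropsig.chemistry.sample_panel`, which holds the
    published per-condition means and SDs.
    """
    from .chemistry import sample_panel

    if seed is None:
        seed = design.master_seed
    return sample_panel(
        n_participants=design.n_participants,
        conditions=design.conditions,
        seed=seed,
    )
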