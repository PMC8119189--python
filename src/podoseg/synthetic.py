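"""Seeded synthetic cohorts of glomeruli for end-to-end testing.

The truth model is deliberately simple and fully known: a glomerulus is a
sphere containing non-overlapping spherical nuclei; podocyte nuclei carry
DNA + WT1 + DACH1 signal, other intraglomerular nuclei (mesangial and
endothelial stand-ins) and extraglomerular nuclei (tubular stand-ins)
carry DNA only, so the DNA channel alone cannot solve the segmentation
task. A 2-D optical section of thickness t is rendered by cutting every
sphere with the section slab, painting analytic disk cross-sections and
then applying Gaussian blur and noise *after* the ground-truth masks are
generated. Sections are drawn near the equator (|z| <= section_z_frac * R),
emulating the operator selecting the maximal glomerular profile, one
glomerulus per frame.

Disease cohorts apply multiplicative effects (podocyte depletion, nuclear
hypertrophy) and render a fraction of glomeruli with focal lesions in
which most podocytes in a spherical cap have disappeared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import MaskPair, MultiChannelImage, SegSample

__all__ = [
    "SceneParams", "Scene3D", "CohortSpec", "DomainShift",
    "sample_scene", "render_section", "simulate_cohort", "apply_domain_shift",
    "PackingError",
]


class PackingError(RuntimeError):
    """Raised when non-overlapping nuclei cannot be packed into the volume."""


# ----------------------------------------------------------------------
@dataclass
class SceneParams:
    """Distribution parameters for one glomerular scene."""

    glom_radius_mean_um: float = 85.0
    glom_radius_sd_um: float = 10.0
    podocyte_count_mean: float = 550.0
    podocyte_count_sd: float = 120.0
    podocyte_count_dist: str = "normal"      # or "poisson"
    nuclear_radius_mean_um: float = 3.5
    nuclear_radius_sd_um: float = 0.25
    other_nuclei_ratio: float = 1.5          # intraglomerular non-podocytes
    outside_nuclei_per_1e4um2: float = 4.0   # tubular nuclei per field area
    section_z_frac: float = 0.3              # |z| <= frac * R
    section_thickness_um: float = 1.0
    min_separation_factor: float = 0.9


@dataclass
class Scene3D:
    glom_radius_um: float
    podocyte_centers_um: np.ndarray          # (n, 3)
    podocyte_nuclear_radius_um: np.ndarray   # (n,)
    other_nuclei_centers_um: np.ndarray      # (m, 3)
    other_nuclei_radius_um: np.ndarray       # (m,)
    section_z_um: float
    section_thickness_um: float
    lesion: bool = False

    @property
    def n_podocytes(self) -> int:
        return int(len(self.podocyte_centers_um))


@dataclass
class DomainShift:
    """Microscope/operator appearance shift: per-channel affine intensity
    transform plus blur and additive noise, always clipped back to [0, 1]."""

    gain: tuple = (1.0, 1.0, 1.0)
    offset: tuple = (0.0, 0.0, 0.0)
    blur_sigma_px: float = 0.0
    noise_sd: float = 0.0


@dataclass
class CohortSpec:
    """Two-group cohort: control distributions plus disease multipliers."""

    n_subjects_per_group: int = 20
    glomeruli_per_subject: tuple = (5, 8)     # inclusive range
    scene: SceneParams = field(default_factory=SceneParams)
    disease_count_multiplier: float = 0.6
    disease_nuclear_radius_multiplier: float = 1.1402  # nuclear area x 1.3
    disease_glom_radius_multiplier: float = 1.0
    lesion_fraction: float = 0.3
    lesion_count_multiplier: float = 0.15
    image_size: int = 256
    pixel_size_um: float = 1.0
    psf_sigma_px: float = 1.0
    noise_sd: float = 0.04
    subject_gain_sd: float = 0.05             # per-subject illumination jitter
    wt1_ring_px: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        for m in (self.disease_count_multiplier,
                  self.disease_nuclear_radius_multiplier,
                  self.disease_glom_radius_multiplier):
            if m <= 0:
                raise ValueError("multipliers must be positive")


# ----------------------------------------------------------------------
# scene sampling
# ----------------------------------------------------------------------
def _uniform_in_sphere(rng, radius: float) -> np.ndarray:
    while True:
        p = rng.uniform(-radius, radius, size=3)
        if p @ p <= radius * radius:
            return p


def _pack(rng, radii, sampler, existing_centers, existing_radii,
          min_factor=0.9, max_tries=200):
    """Sequentially place spheres with pairwise center distance
    >= min_factor * (r_i + r_j), using a uniform grid for neighbor lookup."""
    all_r = list(existing_radii)
    centers = list(existing_centers)
    cell = 2.0 * max(float(np.max(radii, initial=1.0)),
                     float(np.max(existing_radii, initial=1.0)))
    grid: dict = {}
    for idx, c in enumerate(centers):
        grid.setdefault(tuple((np.floor(c / cell)).astype(int)), []).append(idx)
    out = []
    for r in radii:
        for _ in range(max_tries):
            p = sampler(rng)
            key = np.floor(p / cell).astype(int)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        for j in grid.get((key[0] + dx, key[1] + dy,
                                           key[2] + dz), ()):
                            d = p - centers[j]
                            lim = min_factor * (r + all_r[j])
                            if d @ d < lim * lim:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault(tuple(key), []).append(len(centers))
                centers.append(p)
                all_r.append(r)
                out.append(p)
                break
        else:
            raise PackingError(
                f"could not place sphere of radius {r:.2f} after {max_tries} tries")
    return np.array(out).reshape(-1, 3)


def sample_scene(params: SceneParams, seed, field_um: float | None = None,
                 with_other_nuclei: bool = True, lesion: bool = False,
                 lesion_count_multiplier: float = 0.15) -> Scene3D:
    """Draw one 3-D glomerular scene; deterministic given (params, seed)."""
    rng = np.random.default_rng(seed)
    R = max(float(rng.normal(params.glom_radius_mean_um,
                             params.glom_radius_sd_um)),
            4.0 * params.nuclear_radius_mean_um)
    if params.podocyte_count_dist == "poisson":
        n_pod = int(rng.poisson(params.podocyte_count_mean))
    elif params.podocyte_count_dist == "uniform":
        half = np.sqrt(3.0) * params.podocyte_count_sd
        n_pod = max(int(round(rng.uniform(params.podocyte_count_mean - half,
                                          params.podocyte_count_mean + half))), 0)
    else:
        n_pod = max(int(round(rng.normal(params.podocyte_count_mean,
                                         params.podocyte_count_sd))), 0)
    pod_r = np.clip(rng.normal(params.nuclear_radius_mean_um,
                               params.nuclear_radius_sd_um, size=n_pod),
                    0.3 * params.nuclear_radius_mean_um, None)
    inner_sampler = lambda g: _uniform_in_sphere(
        g, R - params.nuclear_radius_mean_um - params.nuclear_radius_sd_um)
    pod_c = _pack(rng, pod_r, inner_sampler, [], [],
                  params.min_separation_factor)

    if lesion and n_pod:
        # focal lesion: podocytes vanish from a random spherical cap,
        # keeping roughly lesion_count_multiplier of the original count
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        proj = pod_c @ u
        keep_n = max(int(round(lesion_count_multiplier * n_pod)), 0)
        order = np.argsort(proj)            # keep the cap farthest from u
        keep = order[:keep_n]
        pod_c, pod_r = pod_c[keep], pod_r[keep]

    z = float(rng.uniform(-params.section_z_frac * R,
                          params.section_z_frac * R))

    if with_other_nuclei:
        n_other_in = int(round(params.other_nuclei_ratio * n_pod))
        other_r_in = np.clip(rng.normal(0.9 * params.nuclear_radius_mean_um,
                                        params.nuclear_radius_sd_um,
                                        size=n_other_in),
                             0.3 * params.nuclear_radius_mean_um, None)
        other_in = _pack(rng, other_r_in, inner_sampler, pod_c, pod_r,
                         params.min_separation_factor)
        half = 0.5 * (field_um if field_um else 3.2 * R)
        margin = R + params.nuclear_radius_mean_um
        n_out = int(round(params.outside_nuclei_per_1e4um2
                          * (2 * half)**2 / 1e4))

        def outside_sampler(g):
            while True:
                p = np.array([g.uniform(-half, half), g.uniform(-half, half),
                              g.uniform(-R, R)])
                if p @ p > margin * margin:
                    return p

        other_r_out = np.clip(rng.normal(0.9 * params.nuclear_radius_mean_um,
                                         params.nuclear_radius_sd_um,
                                         size=n_out),
                              0.3 * params.nuclear_radius_mean_um, None)
        other_out = _pack(rng, other_r_out, outside_sampler, [], [],
                          params.min_separation_factor)
        other_c = np.vstack([other_in, other_out])
        other_r = np.concatenate([other_r_in, other_r_out])
    else:
        other_c = np.zeros((0, 3))
        other_r = np.zeros(0)

    return Scene3D(R, pod_c, pod_r, other_c, other_r, z,
                   params.section_thickness_um, lesion=lesion)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------
def _paint_disks(canvas, centers_px, radii_px, values):
    """Paint filled disks (max blend) onto a 2-D canvas; returns nothing."""
    H, W = canvas.shape
    for (cy, cx), r, v in zip(centers_px, radii_px, values):
        if r <= 0:
            continue
        y0, y1 = max(int(np.floor(cy - r)), 0), min(int(np.ceil(cy + r)) + 1, H)
        x0, x1 = max(int(np.floor(cx - r)), 0), min(int(np.ceil(cx + r)) + 1, W)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (yy - cy)**2 + (xx - cx)**2 <= r * r
        region = canvas[y0:y1, x0:x1]
        np.maximum(region, np.where(disk, v, 0.0), out=region)


def _slab_profiles(centers, radii, z, thickness):
    """Cross-section disks of spheres intersecting the slab [z-t/2, z+t/2].

    Returns (xy centers, profile radii) of every sphere whose surface
    reaches the slab; the profile is the sphere's largest cross-section
    inside the slab.
    """
    dz = np.abs(centers[:, 2] - z) if len(centers) else np.zeros(0)
    hit = dz <= radii + 0.5 * thickness
    eff = np.maximum(dz[hit] - 0.5 * thickness, 0.0)
    prof_r = np.sqrt(np.maximum(radii[hit]**2 - eff**2, 0.0))
    return centers[hit][:, :2], prof_r


def render_section(scene: Scene3D, pixel_size_um: float = 1.0,
                   image_size: int = 256, psf_sigma_px: float = 1.0,
                   noise_sd: float = 0.04, seed=0, wt1_ring_px: int = 3,
                   channel_gain=(1.0, 1.0, 1.0), render_image: bool = True,
                   subject_id: str = "s0", glomerulus_id: str = "g0",
                   group: str = "control") -> SegSample:
    """Render one optical section of a scene into a SegSample.

    The DNA channel shows every nucleus intersecting the slab, DACH1 only
    podocyte nuclei, and WT1 an annular cytoplasmic rim around each
    podocyte nucleus plus a faint diffuse tuft signal. Ground-truth masks
    are rasterized before blur and noise are applied.
    """
    if abs(scene.section_z_um) >= scene.glom_radius_um:
        raise ValueError("section plane lies outside the glomerular sphere")
    rng = np.random.default_rng(seed)
    H = W = int(image_size)
    ps = float(pixel_size_um)
    center = np.array([H / 2.0, W / 2.0])

    def to_px(xy_um):
        return center + xy_um[:, ::-1] / ps if len(xy_um) else xy_um.reshape(0, 2)

    glom_prof_r = np.sqrt(scene.glom_radius_um**2 - scene.section_z_um**2) / ps
    pod_xy, pod_r = _slab_profiles(scene.podocyte_centers_um,
                                   scene.podocyte_nuclear_radius_um,
                                   scene.section_z_um,
                                   scene.section_thickness_um)
    oth_xy, oth_r = _slab_profiles(scene.other_nuclei_centers_um,
                                   scene.other_nuclei_radius_um,
                                   scene.section_z_um,
                                   scene.section_thickness_um)
    pod_px, pod_rpx = to_px(pod_xy), pod_r / ps
    oth_px, oth_rpx = to_px(oth_xy), oth_r / ps

    glom_mask = np.zeros((H, W), dtype=np.float32)
    _paint_disks(glom_mask, [tuple(center)], [glom_prof_r], [1.0])
    podo_mask = np.zeros((H, W), dtype=np.float32)
    _paint_disks(podo_mask, pod_px, pod_rpx, np.ones(len(pod_px)))
    masks = MaskPair(glom_mask > 0.5, podo_mask > 0.5, ps)

    lesion_flag = "lesion" if scene.lesion else "normal"
    if not render_image:
        pixels = np.zeros((H, W, 3), dtype=np.float32)
        image = MultiChannelImage(pixels, pixel_size_um=ps,
                                  source_id=glomerulus_id)
        return SegSample(image, masks, subject_id, glomerulus_id, group,
                         lesion_flag)

    bright = lambda n: rng.uniform(0.75, 1.0, size=n)
    dna = np.full((H, W), 0.03, dtype=np.float32)
    _paint_disks(dna, oth_px, oth_rpx, bright(len(oth_px)))
    pod_v = bright(len(pod_px))
    _paint_disks(dna, pod_px, pod_rpx, pod_v)

    dach1 = np.full((H, W), 0.03, dtype=np.float32)
    _paint_disks(dach1, pod_px, pod_rpx, pod_v * rng.uniform(0.85, 1.0,
                                                             len(pod_px)))

    wt1 = np.full((H, W), 0.03, dtype=np.float32)
    _paint_disks(wt1, [tuple(center)], [glom_prof_r], [0.12])  # diffuse tuft
    ring = np.zeros((H, W), dtype=np.float32)
    _paint_disks(ring, pod_px, pod_rpx + wt1_ring_px,
                 0.6 * np.ones(len(pod_px)))
    inner = np.zeros((H, W), dtype=np.float32)
    _paint_disks(inner, pod_px, pod_rpx, np.ones(len(pod_px)))
    np.maximum(wt1, np.where(inner > 0, 0.25, ring), out=wt1)

    chans = []
    for c, g in zip((dna, wt1, dach1), channel_gain):
        c = c * g
        if psf_sigma_px > 0:
            c = gaussian_filter(c, psf_sigma_px)
        if noise_sd > 0:
            c = c + rng.normal(0.0, noise_sd, size=c.shape)
        chans.append(np.clip(c, 0.0, 1.0))
    pixels = np.stack(chans, axis=-1).astype(np.float32)
    image = MultiChannelImage(pixels, pixel_size_um=ps,
                              source_id=glomerulus_id)
    return SegSample(image, masks, subject_id, glomerulus_id, group,
                     lesion_flag)


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------
def _disease_params(spec: CohortSpec) -> SceneParams:
    s = spec.scene
    return replace(
        s,
        podocyte_count_mean=s.podocyte_count_mean * spec.disease_count_multiplier,
        podocyte_count_sd=s.podocyte_count_sd * spec.disease_count_multiplier,
        nuclear_radius_mean_um=(s.nuclear_radius_mean_um
                                * spec.disease_nuclear_radius_multiplier),
        glom_radius_mean_um=(s.glom_radius_mean_um
                             * spec.disease_glom_radius_multiplier),
    )


def simulate_cohort(spec: CohortSpec, images: bool = True):
    """Simulate a two-group cohort; returns (samples, truth table).

    The truth table records per-glomerulus ground truth: the 3-D podocyte
    count, the number of nuclear profiles in the rendered section, radii
    and the section offset. Bit-identical for identical (spec, seed).
    """
    root = np.random.SeedSequence(spec.seed)
    samples, rows = [], []
    field_um = spec.image_size * spec.pixel_size_um
    for gi, group in enumerate(("control", "disease")):
        params = spec.scene if group == "control" else _disease_params(spec)
        for si in range(spec.n_subjects_per_group):
            sid = f"{group[0]}{si:03d}"
            sseq = np.random.SeedSequence((spec.seed, gi, si))
            srng = np.random.default_rng(sseq)
            gain = np.clip(1.0 + srng.normal(0.0, spec.subject_gain_sd, 3),
                           0.2, None)
            lo, hi = spec.glomeruli_per_subject
            n_glom = int(srng.integers(lo, hi + 1))
            for ki in range(n_glom):
                lesion = (group == "disease"
                          and srng.random() < spec.lesion_fraction)
                scene_seed = np.random.SeedSequence((spec.seed, gi, si, ki, 1))
                scene = sample_scene(params, scene_seed, field_um=field_um,
                                     with_other_nuclei=images, lesion=lesion,
                                     lesion_count_multiplier=spec.lesion_count_multiplier)
                gid = f"{sid}_g{ki:02d}"
                sample = render_section(
                    scene, spec.pixel_size_um, spec.image_size,
                    spec.psf_sigma_px, spec.noise_sd,
                    seed=np.random.SeedSequence((spec.seed, gi, si, ki, 2)),
                    wt1_ring_px=spec.wt1_ring_px, channel_gain=tuple(gain),
                    render_image=images, subject_id=sid, glomerulus_id=gid,
                    group=group)
                n_prof = len(_slab_profiles(scene.podocyte_centers_um,
                                            scene.podocyte_nuclear_radius_um,
                                            scene.section_z_um,
                                            scene.section_thickness_um)[1])
                rows.append(dict(
                    subject_id=sid, glomerulus_id=gid, group=group,
                    lesion=int(lesion), true_count=scene.n_podocytes,
                    n_section_profiles=n_prof,
                    glom_radius_um=scene.glom_radius_um,
                    nuclear_radius_um=float(
                        scene.podocyte_nuclear_radius_um.mean())
                    if scene.n_podocytes else np.nan,
                    section_z_um=scene.section_z_um))
                samples.append(sample)
    truth = pd.DataFrame(rows)
    return samples, truth


def apply_domain_shift(image: MultiChannelImage, shift: DomainShift,
                       seed=0) -> MultiChannelImage:
    """Apply a microscope/operator appearance shift to an image (masks are
    never touched); output clipped to [0, 1]."""
    rng = np.random.default_rng(seed)
    out = image.pixels.copy()
    for c in range(3):
        out[:, :, c] = out[:, :, c] * shift.gain[c] + shift.offset[c]
    if shift.blur_sigma_px > 0:
        for c in range(3):
            out[:, :, c] = gaussian_filter(out[:, :, c], shift.blur_sigma_px)
    if shift.noise_sd > 0:
        out = out + rng.normal(0.0, shift.noise_sd, size=out.shape)
    out = np.clip(out, 0.0, 1.0).astype(np.float32)
    return MultiChannelImage(out, image.channel_roles, image.pixel_size_um,
                             image.source_id)
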