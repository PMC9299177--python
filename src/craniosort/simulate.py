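"""Synthetic study data at three levels of the pipeline.

No skeletal-collection data is distributable, so every pipeline stage is
exercised on generated stand-ins:

1. **Measurement level** — per-individual tables of the 16 linear
   distances, drawn so that each measurement matches the published
   population mean/SD and each occipital/atlas pairing matches its
   published Pearson correlation.  Cross-measurement correlation is
   induced by a shared per-individual size factor.
2. **RMS level** — match and mismatch superimposition outcomes drawn from
   a truncated lognormal (or truncated normal) moment-matched to the
   published group mean/SD and clipped to the published range; the match
   calibration by construction never exceeds the 0.53 mm threshold.
3. **Mesh level** — paired articular-surface patches: each occipital
   condyle is a convex elliptical dome, the matching atlas facet is its
   congruent concave counterpart plus a smooth "articular congruency"
   deformation of amplitude sigma_c; a mismatching facet comes from an
   independent individual.  This level is validated by ordering and
   recovery properties, not by moment calibration — the published numbers
   constrain RMS moments, not surface-noise physics.

All generators take explicit integer seeds; none touches global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy import stats

from .osteometry import C1_MEASUREMENTS, OC_MEASUREMENTS, MeasurementSet
from .registration import FACETS, LandmarkSet, RigidTransform, RoiMesh

__all__ = [
    "MeasurementGeneratorParams",
    "RmsGroupParams",
    "RmsGeneratorParams",
    "SurfaceGeneratorParams",
    "simulate_measurements",
    "simulate_rms",
    "simulate_surface_pair",
]

# Published population calibration: mean, SD (mm) per measurement, and the
# Pearson correlation of each occipital/atlas pairing.
OC_MEANS = (10.5, 10.9, 22.6, 22.6, 31.0, 28.8, 50.5, 16.0)
OC_SDS = (1.3, 1.3, 2.3, 2.3, 2.8, 3.4, 4.7, 2.2)
C1_MEANS = (11.3, 11.2, 23.3, 23.4, 35.4, 30.3, 50.0, 16.0)
C1_SDS = (1.6, 1.6, 2.8, 2.7, 2.8, 2.4, 4.1, 2.1)
PAIR_CORRELATIONS = (0.514, 0.481, 0.650, 0.622, 0.671, 0.591, 0.606, 0.402)

#: Study sex composition: 83 of 150 individuals male.
MALE_FRACTION = 83.0 / 150.0


@dataclass(frozen=True)
class MeasurementGeneratorParams:
    """Calibration of the linear-measurement generator (all mm)."""

    oc_means: tuple[float, ...] = OC_MEANS
    oc_sds: tuple[float, ...] = OC_SDS
    c1_means: tuple[float, ...] = C1_MEANS
    c1_sds: tuple[float, ...] = C1_SDS
    correlations: tuple[float, ...] = PAIR_CORRELATIONS
    male_fraction: float = MALE_FRACTION
    min_value: float = 0.1

    def __post_init__(self) -> None:
        for name in ("oc_means", "oc_sds", "c1_means", "c1_sds", "correlations"):
            if len(getattr(self, name)) != 8:
                raise ValueError(f"{name} must have 8 entries")
        if any(s <= 0 for s in self.oc_sds + self.c1_sds):
            raise ValueError("SDs must be positive")
        if any(not (0 <= r < 1) for r in self.correlations):
            raise ValueError("pair correlations must lie in [0, 1)")


def simulate_measurements(params: MeasurementGeneratorParams | None = None,
                          n: int = 150, seed: int = 0) -> list[MeasurementSet]:
    """Draw ``n`` individuals' 16 linear distances.

    For pairing i the occipital and atlas values share a per-individual
    standard-normal size factor s::

        m_OC,i = mu_OC,i + sigma_OC,i * (sqrt(r_i) s + sqrt(1-r_i) e1)
        m_C1,i = mu_C1,i + sigma_C1,i * (sqrt(r_i) s + sqrt(1-r_i) e2)

    with e1, e2 independent standard normals, so corr(m_OC,i, m_C1,i) =
    r_i in expectation while s also induces realistic cross-measurement
    size correlation.  Draws below ``min_value`` mm are resampled.
    """
    if params is None:
        params = MeasurementGeneratorParams()
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    r = np.asarray(params.correlations)
    sqrt_r, sqrt_1mr = np.sqrt(r), np.sqrt(1.0 - r)
    oc_mu, oc_sd = np.asarray(params.oc_means), np.asarray(params.oc_sds)
    c1_mu, c1_sd = np.asarray(params.c1_means), np.asarray(params.c1_sds)

    out: list[MeasurementSet] = []
    width = max(3, len(str(max(n, 1))))
    for i in range(n):
        sex = "male" if rng.random() < params.male_fraction else "female"
        s = rng.standard_normal()
        oc_vals = np.empty(8)
        c1_vals = np.empty(8)
        for j in range(8):
            for vals, mu, sd in ((oc_vals, oc_mu, oc_sd), (c1_vals, c1_mu, c1_sd)):
                while True:
                    e = rng.standard_normal()
                    v = mu[j] + sd[j] * (sqrt_r[j] * s + sqrt_1mr[j] * e)
                    if v >= params.min_value:
                        vals[j] = v
                        break
        out.append(MeasurementSet(
            individual_id=f"ind{i + 1:0{width}d}",
            sex=sex,
            oc=dict(zip(OC_MEASUREMENTS, oc_vals)),
            c1=dict(zip(C1_MEASUREMENTS, c1_vals)),
        ))
    return out


@dataclass(frozen=True)
class RmsGroupParams:
    """Target moments and range of one RMS group (mm)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ValueError("lower bound must be below upper bound")
        if not (self.lower < self.mean < self.upper):
            raise ValueError("mean must lie strictly inside the bounds")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


# Published RMS calibration (total rows): match and mismatch groups, with
# the sex-specific rows available for sex-structured simulations.
MATCH_TOTAL = RmsGroupParams(mean=0.29, sd=0.09, lower=0.15, upper=0.53)
MISMATCH_TOTAL = RmsGroupParams(mean=0.46, sd=0.20, lower=0.14, upper=1.49)
MATCH_BY_SEX = {
    "male": RmsGroupParams(mean=0.28, sd=0.08, lower=0.16, upper=0.51),
    "female": RmsGroupParams(mean=0.31, sd=0.11, lower=0.15, upper=0.51),
}
MISMATCH_BY_SEX = {
    "male": RmsGroupParams(mean=0.51, sd=0.22, lower=0.18, upper=1.49),
    "female": RmsGroupParams(mean=0.41, sd=0.17, lower=0.14, upper=1.01),
}


@dataclass(frozen=True)
class RmsGeneratorParams:
    """Calibration of the superimposition-outcome (RMS) generator."""

    match: RmsGroupParams = MATCH_TOTAL
    mismatch: RmsGroupParams = MISMATCH_TOTAL
    family: str = "truncated_lognormal"
    match_male_fraction: float = 20.0 / 46.0
    mismatch_male_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ("truncated_lognormal", "truncated_normal"):
            raise ValueError(f"unknown family {self.family!r}")


def _truncated_draws(group: RmsGroupParams, family: str, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Moment-matched parent distribution, sampled on the truncated range.

    The parent (lognormal or normal) is fitted to the target mean/SD, then
    sampled by inverse CDF restricted to [lower, upper], so no draw ever
    leaves the published range.
    """
    if family == "truncated_lognormal":
        sigma2 = np.log1p((group.sd / group.mean) ** 2)
        sigma = float(np.sqrt(sigma2))
        mu = float(np.log(group.mean) - 0.5 * sigma2)
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    else:
        dist = stats.norm(loc=group.mean, scale=group.sd)
    f_lo, f_hi = dist.cdf(group.lower), dist.cdf(group.upper)
    if not (f_hi > f_lo):
        raise ValueError("moment/bound combination leaves no probability mass in range")
    u = rng.uniform(f_lo, f_hi, size=n)
    draws = dist.ppf(u)
    return np.clip(draws, group.lower, group.upper)  # guard against ppf float fuzz


def simulate_rms(params: RmsGeneratorParams | None = None,
                 n_match: int = 46, n_mismatch: int = 260,
                 seed: int = 0) -> pd.DataFrame:
    """Draw labelled superimposition outcomes.

    Returns a frame with columns ``rms`` (mm), ``group`` (match/mismatch)
    and ``sex``; sex labels are assigned at the configured fractions so
    the group-statistics stage (two-way ANOVA) can run on the output.
    Under the default calibration no match draw can exceed 0.53 mm.
    """
    if params is None:
        params = RmsGeneratorParams()
    if n_match < 0 or n_mismatch < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for group_name, group, n, male_frac in (
        ("match", params.match, n_match, params.match_male_fraction),
        ("mismatch", params.mismatch, n_mismatch, params.mismatch_male_fraction),
    ):
        if n == 0:
            continue
        rms = _truncated_draws(group, params.family, n, rng)
        n_male = int(round(n * male_frac))
        sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
        rng.shuffle(sex)
        frames.append(pd.DataFrame({"rms": rms, "group": group_name, "sex": sex}))
    if not frames:
        return pd.DataFrame(columns=["rms", "group", "sex"])
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SurfaceGeneratorParams:
    """Geometry and noise calibration of the articular-surface generator.

    Facet anteroposterior length and dome height scale with the condyle
    length distribution; the bilateral placement uses the medial facet
    separation.  ``sigma_c`` is the articular-congruency noise: the RMS
    amplitude (mm) of the smooth deformation separating a matching atlas
    facet from the exact congruent counterpart of its condyle.  It is a
    free model parameter, not a published value.
    """

    length_mean: float = 22.6
    length_sd: float = 2.3
    width_mean: float = 10.5
    width_sd: float = 1.3
    medial_separation_mean: float = 16.0
    medial_separation_sd: float = 2.2
    dome_height_fraction: float = 0.18
    sigma_c: float = 0.3
    n_rings: int = 6
    n_theta: int = 18
    pose_rotation_deg: float = 15.0
    pose_translation_mm: float = 8.0

    def __post_init__(self) -> None:
        for name in ("length_mean", "length_sd", "width_mean", "width_sd",
                     "medial_separation_mean", "medial_separation_sd",
                     "dome_height_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be non-negative")
        if self.n_rings < 2 or self.n_theta < 3:
            raise ValueError("mesh resolution too coarse: need >= 3x3 vertices per facet")


def _facet_grid(n_rings: int, n_theta: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-disc parametrisation (r, theta) and its fan triangulation."""
    rs = [0.0]
    ths = [0.0]
    for j in range(1, n_rings + 1):
        r = j / n_rings
        for k in range(n_theta):
            rs.append(r)
            ths.append(2.0 * np.pi * k / n_theta)
    r = np.asarray(rs)
    th = np.asarray(ths)

    faces = []
    # innermost fan
    for k in range(n_theta):
        faces.append([0, 1 + k, 1 + (k + 1) % n_theta])
    # quad rings split into triangles
    for j in range(1, n_rings):
        a0 = 1 + (j - 1) * n_theta
        b0 = 1 + j * n_theta
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            faces.append([a0 + k, b0 + k, b0 + k2])
            faces.append([a0 + k, b0 + k2, a0 + k2])
    return r, th, np.asarray(faces, dtype=int)


def _smooth_field(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                  n_modes: int = 4) -> np.ndarray:
    """Smooth random surface field with unit RMS over the query points."""
    span = max(np.ptp(x), np.ptp(y), 1.0)
    field = np.zeros_like(x)
    for _ in range(n_modes):
        kx, ky = rng.uniform(0.5, 2.0, size=2) * 2.0 * np.pi / span
        phase = rng.uniform(0, 2.0 * np.pi, size=2)
        amp = rng.standard_normal()
        field += amp * np.sin(kx * x + phase[0]) * np.sin(ky * y + phase[1])
    rms = np.sqrt(np.mean(field**2))
    return field / rms if rms > 0 else field


def _random_pose(rng: np.random.Generator, max_deg: float, max_mm: float) -> RigidTransform:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_deg, max_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_mm, max_mm, size=3)
    return RigidTransform(R, t)


def _individual_geometry(params: SurfaceGeneratorParams, seed: int) -> dict:
    """Per-individual facet sizes and placement, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    geom = {"msep": max(4.0, rng.normal(params.medial_separation_mean,
                                        params.medial_separation_sd))}
    for side in FACETS:
        length = max(8.0, rng.normal(params.length_mean, params.length_sd))
        width = max(4.0, rng.normal(params.width_mean, params.width_sd))
        geom[side] = {"length": length, "width": width,
                      "height": params.dome_height_fraction * length}
    return geom


def _build_patch(geom: dict, params: SurfaceGeneratorParams,
                 concave: bool, deform_rng: np.random.Generator | None,
                 sigma_c: float, provenance: str) -> tuple[RoiMesh, LandmarkSet]:
    """Bilateral dome patch + its four extremal edge landmarks per facet."""
    r, th, faces = _facet_grid(params.n_rings, params.n_theta)
    n_per = len(r)
    all_v, all_f, labels = [], [], []
    landmarks: dict[str, dict[str, list[float]]] = {}
    for fi, side in enumerate(FACETS):
        g = geom[side]
        sgn = -1.0 if side == "left" else 1.0
        a = g["length"] / 2.0   # anteroposterior semi-axis (y)
        b = g["width"] / 2.0    # mediolateral semi-axis (x)
        cx = sgn * (geom["msep"] / 2.0 + b)
        x = cx + b * r * np.cos(th)
        y = a * r * np.sin(th)
        # Both bones share the articulating interface surface: the condyle
        # dome is convex seen from the skull, the facet that moulds onto it
        # is concave seen from the atlas, but in articulated position the
        # two surfaces coincide (up to the congruency noise).
        z = g["height"] * (1.0 - r**2)
        if deform_rng is not None and sigma_c > 0:
            z = z + sigma_c * _smooth_field(x, y, deform_rng)
        all_v.append(np.column_stack([x, y, z]))
        f = faces[:, ::-1] if concave else faces  # opposing surface normals
        all_f.append(f + fi * n_per)
        labels.extend([side] * n_per)

        boundary = np.flatnonzero(r == 1.0)
        bx, by = x[boundary], y[boundary]
        pts = np.column_stack([x, y, z])[boundary]
        landmarks[side] = {
            "anterior": pts[np.argmax(by)].tolist(),
            "posterior": pts[np.argmin(by)].tolist(),
            "lateral": pts[np.argmax(sgn * bx)].tolist(),
            "medial": pts[np.argmin(sgn * bx)].tolist(),
        }
    mesh = trimesh.Trimesh(vertices=np.vstack(all_v), faces=np.vstack(all_f),
                           process=False)
    return (RoiMesh(mesh, side_labels=np.asarray(labels), provenance=provenance),
            LandmarkSet(landmarks))


def simulate_surface_pair(
    params: SurfaceGeneratorParams | None = None,
    individual_seed: int = 0,
    matched: bool = True,
    partner_seed: int | None = None,
) -> tuple[RoiMesh, RoiMesh, LandmarkSet, LandmarkSet]:
    """Generate one occipital-condyle / atlas-facet ROI pair with landmarks.

    The condyle patch is a bilateral pair of convex elliptical domes whose
    sizes and separation are drawn from ``individual_seed``.  A matched
    atlas patch is the congruent concave counterpart of that same
    geometry plus a smooth deformation of RMS amplitude ``sigma_c``; an
    unmatched one is built from ``partner_seed`` (defaults to a fixed
    offset of ``individual_seed``).  The atlas patch and its landmarks
    are emitted in a random pose so registration has real work to do.

    Returns ``(oc, c1, oc_landmarks, c1_landmarks)``; identical inputs
    give bitwise-identical meshes.
    """
    if params is None:
        params = SurfaceGeneratorParams()
    geom_oc = _individual_geometry(params, individual_seed)
    oc, oc_lm = _build_patch(geom_oc, params, concave=False, deform_rng=None,
                             sigma_c=0.0, provenance="occipital_condyles")

    if matched:
        geom_c1 = geom_oc
        noise_seed = individual_seed
    else:
        if partner_seed is None:
            partner_seed = individual_seed + 1_000_003
        if partner_seed == individual_seed:
            raise ValueError("partner_seed must differ from individual_seed for a mismatch")
        geom_c1 = _individual_geometry(params, partner_seed)
        noise_seed = partner_seed
    deform_rng = np.random.default_rng((noise_seed, 7919))
    c1, c1_lm = _build_patch(geom_c1, params, concave=True, deform_rng=deform_rng,
                             sigma_c=params.sigma_c, provenance="atlas_facets")

    pose = _random_pose(np.random.default_rng((noise_seed, 104729)),
                        params.pose_rotation_deg, params.pose_translation_mm)
    c1 = c1.transformed(pose)
    c1_lm = c1_lm.transformed(pose)
    return oc, c1, oc_lm, c1_lm
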