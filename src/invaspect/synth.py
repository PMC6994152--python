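"""Synthetic boundaries, images and populations with known ground truth.

Every statistical module in the package is exercised against data whose
generating parameters are known exactly:

* **Boundaries** are perturbed circles r(θ) = r0·(1 + Σ_m a_m cos(mθ + φ_m))
  traced at equal angles.  Radial harmonics give analytically controllable
  spectral content, so the harmonic amplitude acts as a monotone
  "invasiveness" dial the phenotype must track.
* **Intensity images** place a known uniform level (plus optional noise)
  inside the rasterized boundary, and return brute-force expected sums for
  oracle tests of the intensity module.
* **Populations** realize the variance-components model: tumor means
  μ_t ~ Norm(μ0, σB²), organoid deviations ε_ti ~ Norm(0, σW²), and a paired
  factor x with separate between- and within-tumor components so that
  between- and within-tumor effect sizes can be set independently:

      y_ti = μ_t + β_B·xb_t + β_W·xw_ti + ε_ti,   x_ti = xb_t + xw_ti.

The paper-scale preset reflects the study this emulates: T = 52 tumors,
16 organoids per tumor, total log10-phenotype variance 0.2344 split
0.278 : 0.722 between : within (σB² = 0.0652, σW² = 0.1692).

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from invaspect.io import RawBoundary, write_boundary_csv

__all__ = [
    "ShapeSpec",
    "PopulationSpec",
    "gen_boundary",
    "gen_population",
    "gen_intensity_image",
    "gen_cohort_boundaries",
    "beta_for_r2",
    "paper_scale_spec",
    "write_synthetic_cohort",
    "point_in_polygon_slow",
]

# paper-scale population defaults (log10 phenotype scale)
PAPER_T = 52
PAPER_N_PER_TUMOR = 16
PAPER_SIGMA0_SQ = 0.2344
PAPER_SIGMAB_SQ = 0.0652
PAPER_SIGMAW_SQ = PAPER_SIGMA0_SQ - PAPER_SIGMAB_SQ  # 0.1692
PAPER_MU0 = 1.0


@dataclass(frozen=True)
class ShapeSpec:
    """A perturbed-circle boundary: r(θ) = r0·(1 + Σ a_m·cos(mθ + φ_m))."""

    r0: float = 100.0
    harmonics: tuple = ()  # (m, a_m, phi_m) triples
    n_vertices: int = 512
    jitter_sd: float = 0.0  # isotropic vertex noise, px
    center: tuple = (0.0, 0.0)
    rotation: float = 0.0  # radians, about the center

    def __post_init__(self) -> None:
        if self.n_vertices < 64:
            raise ValueError("need at least 64 trace vertices")
        if sum(abs(a) for _, a, _ in self.harmonics) >= 1.0:
            raise ValueError("Σ|a_m| must be < 1 (self-intersecting radial profile)")


def gen_boundary(spec: ShapeSpec, seed: int | None = None,
                 tumor_id: str = "", organoid_id: str = "") -> RawBoundary:
    """Trace the radial profile of ``spec`` at equal angles, with optional jitter."""
    rng = np.random.default_rng(seed)
    theta = 2.0 * np.pi * np.arange(spec.n_vertices) / spec.n_vertices
    r = np.full_like(theta, spec.r0)
    for m, a, phi in spec.harmonics:
        r = r + spec.r0 * a * np.cos(m * theta + phi)
    ang = theta + spec.rotation
    x = spec.center[0] + r * np.cos(ang)
    y = spec.center[1] + r * np.sin(ang)
    if spec.jitter_sd > 0:
        x = x + rng.normal(0.0, spec.jitter_sd, size=x.shape)
        y = y + rng.normal(0.0, spec.jitter_sd, size=y.shape)
    return RawBoundary(np.column_stack([x, y]), tumor_id=tumor_id, organoid_id=organoid_id)


@dataclass(frozen=True)
class PopulationSpec:
    """Ground-truth parameters of a structured (tumor, organoid) population."""

    t: int = PAPER_T
    n_per_tumor: int = PAPER_N_PER_TUMOR
    mu0: float = PAPER_MU0
    sigmaB_sq: float = PAPER_SIGMAB_SQ
    sigmaW_sq: float = PAPER_SIGMAW_SQ
    beta_b: float = 0.0  # between-tumor factor effect
    beta_w: float = 0.0  # within-tumor factor effect
    x_between_sd: float = 1.0  # tumor-level spread of the factor
    x_within_sd: float = 1.0  # organoid-level spread of the factor

    def __post_init__(self) -> None:
        if self.sigmaB_sq < 0 or self.sigmaW_sq < 0:
            raise ValueError("variances must be non-negative")


def paper_scale_spec(**overrides) -> PopulationSpec:
    """The default preset: 52 tumors × 16 organoids, 0.278:0.722 variance split."""
    return PopulationSpec(**overrides)


def gen_population(spec: PopulationSpec, seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate the mixed-effects population; returns (long table, ground truth).

    The table has columns tumor_id, organoid_id, y, x.  Ground truth records
    the spec parameters plus the realized tumor means.
    """
    rng = np.random.default_rng(seed)
    mu_t = rng.normal(spec.mu0, math.sqrt(spec.sigmaB_sq), size=spec.t)
    xb = rng.normal(0.0, spec.x_between_sd, size=spec.t)
    rows = []
    for t in range(spec.t):
        xw = rng.normal(0.0, spec.x_within_sd, size=spec.n_per_tumor)
        eps = rng.normal(0.0, math.sqrt(spec.sigmaW_sq), size=spec.n_per_tumor)
        x = xb[t] + xw
        y = mu_t[t] + spec.beta_b * xb[t] + spec.beta_w * xw + eps
        for i in range(spec.n_per_tumor):
            rows.append((f"T{t + 1:03d}", f"O{i + 1:03d}", y[i], x[i]))
    table = pd.DataFrame(rows, columns=["tumor_id", "organoid_id", "y", "x"])
    truth = {
        "mu0": spec.mu0, "sigmaB_sq": spec.sigmaB_sq, "sigmaW_sq": spec.sigmaW_sq,
        "beta_b": spec.beta_b, "beta_w": spec.beta_w, "mu_t": mu_t, "seed": seed,
    }
    return table, truth


def beta_for_r2(r_sq: float, noise_var: float, x_var: float = 1.0) -> float:
    """Slope giving fraction-of-variance-explained R² at the stated noise level.

    From R² = β²σx²/(β²σx² + σ²): β = sqrt(R²/(1−R²) · σ²/σx²).
    """
    if not 0 < r_sq < 1:
        raise ValueError("R² must be in (0, 1)")
    return math.sqrt(r_sq / (1.0 - r_sq) * noise_var / x_var)


def point_in_polygon_slow(px: float, py: float, vertices: np.ndarray) -> bool:
    """Even-odd point-in-polygon by explicit edge walk (independent oracle)."""
    inside = False
    v = np.asarray(vertices, float)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_at:
                inside = not inside
    return inside


def gen_intensity_image(
    boundary: RawBoundary,
    shape: tuple[int, int],
    base: float = 0.0,
    inside_level: float = 255.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """A synthetic intensity frame with known in-mask sums.

    In-mask pixels (by the brute-force even-odd oracle at pixel centers) take
    ``inside_level`` plus optional Gaussian noise, background takes ``base``;
    everything is rounded and clipped to [0, 255].  Returns the uint8 image
    and a dict of expected total/mean intensity and mask area computed by
    brute force from the finished pixel values, usable directly as a test
    oracle for the intensity module.
    """
    if not (0 <= base <= 255 and 0 <= inside_level <= 255):
        raise ValueError("levels must be within [0, 255]")
    height, width = shape
    rng = np.random.default_rng(seed)
    img = np.full((height, width), float(base))
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            mask[r, c] = point_in_polygon_slow(c + 0.5, r + 0.5, boundary.vertices)
    img[mask] = inside_level
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    scaled_sum = float(img[mask].astype(float).sum() / 255.0)
    expected = {
        "mask_area_px": int(mask.sum()),
        "total_k14": scaled_sum / img.size,
        "mean_k14": scaled_sum / int(mask.sum()),
        "mask": mask,
    }
    return img, expected


def gen_cohort_boundaries(
    t: int = PAPER_T,
    n_per_tumor: int = PAPER_N_PER_TUMOR,
    seed: int | None = None,
    r0: float = 100.0,
    n_vertices: int = 512,
) -> list[RawBoundary]:
    """Boundary cohort whose invasiveness carries tumor structure.

    Each tumor gets a baseline harmonic amplitude (log-normal across tumors)
    and each organoid perturbs it (log-normal within tumor), so the spectral
    phenotype of the cohort shows both between- and within-tumor variation.
    """
    rng = np.random.default_rng(seed)
    boundaries = []
    log_amp_t = rng.normal(np.log(0.05), 0.4, size=t)
    for ti in range(t):
        for oi in range(n_per_tumor):
            amp = float(np.exp(log_amp_t[ti] + rng.normal(0.0, 0.5)))
            amp = min(amp, 0.35)
            m_hi = int(rng.integers(5, 12))
            harmonics = ((2, 0.3 * amp, float(rng.uniform(0, 2 * np.pi))),
                         (m_hi, amp, float(rng.uniform(0, 2 * np.pi))))
            spec = ShapeSpec(
                r0=r0, harmonics=harmonics, n_vertices=n_vertices,
                center=(float(rng.uniform(200, 500)), float(rng.uniform(200, 500))),
                rotation=float(rng.uniform(0, 2 * np.pi)),
            )
            boundaries.append(gen_boundary(
                spec, seed=int(rng.integers(2**31)),
                tumor_id=f"T{ti + 1:03d}", organoid_id=f"O{oi + 1:03d}",
            ))
    return boundaries


def write_synthetic_cohort(
    outdir: str | Path,
    t: int = PAPER_T,
    n_per_tumor: int = PAPER_N_PER_TUMOR,
    seed: int | None = None,
) -> Path:
    """Write a boundary cohort as CSV traces plus a TSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    bdir = outdir / "boundaries"
    bdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in gen_cohort_boundaries(t=t, n_per_tumor=n_per_tumor, seed=seed):
        fname = f"{b.tumor_id}_{b.organoid_id}.csv"
        write_boundary_csv(b, bdir / fname)
        rows.append((b.tumor_id, b.organoid_id, f"boundaries/{fname}"))
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=["tumor_id", "organoid_id", "boundary_path"]).to_csv(
        manifest, sep="\t", index=False)
    return manifest
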