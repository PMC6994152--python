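"""Analytic power and design calculators for tumor/organoid association tests.

The tests regress a phenotype y on a factor x either across tumor means
(between-tumor) or across organoid deviations from their tumor mean
(within-tumor).  Under the normal approximation, the squared test statistic
is non-central χ²₁ with non-centrality Q² = (d.f.)·R²/(1−R²), and the design
identity

    Q² = (z_I − z_II)²

links the effect size R² to the two-tailed type-I quantile
z_I = Φ⁻¹(1 − ε_I/2) and the type-II quantile z_II = Φ⁻¹(ε_II).  Degrees of
freedom are T−1 for the between-tumor test and N−T−1 for the within-tumor
test; a pooled extreme-tails design multiplies the within-tumor
non-centrality by its efficiency f_P.

Pooling efficiency under an additive normal model has the closed form
E(f) = 2·φ(Φ⁻¹(1−f))²/f for symmetric tail fraction f — the squared
non-centrality of a pooled-tails mean-difference test relative to
individual-level regression.  It is maximized at f = 0.27 where E ≈ 0.81:
pooling the extreme 27% tails has power equivalent to individually
measuring ~80% of the cohort.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

__all__ = [
    "quantiles",
    "noncentrality_between",
    "noncentrality_within",
    "required_tumors",
    "critical_r2_between",
    "critical_r2_within",
    "pooling_efficiency",
    "optimal_tail_fraction",
    "round_significant",
    "critical_r2_grid",
]

GENOME_WIDE_ALPHA = 0.05 / 20_000  # two-tailed, 20,000 gene-based tests


def quantiles(eps_I: float, eps_II: float) -> tuple[float, float]:
    """Normal quantiles (z_I, z_II) for two-tailed type-I and type-II rates."""
    if not (0 < eps_I < 1 and 0 < eps_II < 1):
        raise ValueError("error rates must be in (0, 1)")
    return float(norm.ppf(1 - eps_I / 2)), float(norm.ppf(eps_II))


def _check_r2(r_sq: float) -> None:
    if not 0 < r_sq < 1:
        raise ValueError("R² must be in the open interval (0, 1)")


def noncentrality_between(t: int, r_sq: float) -> float:
    """Non-centrality (T−1)·R²/(1−R²) of the between-tumor test."""
    _check_r2(r_sq)
    return (t - 1) * r_sq / (1 - r_sq)


def noncentrality_within(n: int, t: int, r_sq: float, f_p: float = 1.0) -> float:
    """Non-centrality f_P·(N−T−1)·R²/(1−R²) of the (optionally pooled) within-tumor test."""
    _check_r2(r_sq)
    return f_p * (n - t - 1) * r_sq / (1 - r_sq)


def required_tumors(r_sq: float, z_I: float, z_II: float) -> int:
    """Smallest T whose between-tumor non-centrality reaches (z_I − z_II)²."""
    _check_r2(r_sq)
    target = (z_I - z_II) ** 2
    return max(2, math.ceil(target * (1 - r_sq) / r_sq) + 1)


def critical_r2_between(
    t: int, n_per_tumor: float, var_ratio: float, z_I: float, z_II: float
) -> float:
    """Critical between-tumor R² for a design of T tumors, N_t organoids each.

    ``var_ratio`` is σW²/σB²; tumor-mean noise inflates the required effect
    by the factor 1 + σW²/(N_t·σB²).  With var_ratio = 0 this reduces to the
    plain non-centrality inversion.
    """
    q = (z_I - z_II) ** 2 / (t - 1)
    return (1 + var_ratio / n_per_tumor) * q / (1 + q)


def critical_r2_within(n: int, t: int, f_p: float, z_I: float, z_II: float) -> float:
    """Critical within-tumor R² for N organoids over T tumors at pooling efficiency f_P."""
    q = (z_I - z_II) ** 2 / (f_p * (n - t - 1))
    return q / (1 + q)


def pooling_efficiency(f: float) -> float:
    """Relative efficiency E(f) = 2·φ(Φ⁻¹(1−f))²/f of symmetric-tails pooling.

    f is the fraction pooled in each tail; f = 0.5 (a median split) gives the
    classic dichotomization efficiency 2/π, and E peaks near f = 0.27.
    """
    if not 0 < f <= 0.5:
        raise ValueError("tail fraction must be in (0, 0.5]")
    z = norm.ppf(1 - f)
    return float(2.0 * norm.pdf(z) ** 2 / f)


def optimal_tail_fraction(step: float = 0.01) -> tuple[float, float]:
    """(argmax f, E(f)) of the pooling efficiency over the grid step … 0.5."""
    grid = np.round(np.arange(step, 0.5 + step / 2, step), 10)
    eff = np.array([pooling_efficiency(f) for f in grid])
    best = int(np.argmax(eff))
    return float(grid[best]), float(eff[best])


def round_significant(value: float, sig_figs: int) -> float:
    """Round to a number of significant figures (presentation helper)."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return round(value, sig_figs - 1 - exponent)


def critical_r2_grid(
    tumors: np.ndarray,
    organoids_per_tumor: np.ndarray,
    mode: str,
    eps_I: float = 2.5e-6,
    eps_II: float = 0.2,
    var_ratio: float = 2.6,
    f_p: float = 0.8,
):
    """Critical-R² surface over a T × N_t design grid for contour plots.

    Returns an array of shape (len(organoids_per_tumor), len(tumors)).
    """
    z_i, z_ii = quantiles(eps_I, eps_II)
    out = np.empty((len(organoids_per_tumor), len(tumors)))
    for i, npt in enumerate(organoids_per_tumor):
        for j, t in enumerate(tumors):
            if mode == "between":
                out[i, j] = critical_r2_between(int(t), float(npt), var_ratio, z_i, z_ii)
            elif mode == "within":
                out[i, j] = critical_r2_within(int(t * npt), int(t), f_p, z_i, z_ii)
            else:
                raise ValueError("mode must be 'between' or 'within'")
    return out
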