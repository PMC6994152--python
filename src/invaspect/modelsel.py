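"""Bootstrapped Bayesian model selection for structured organoid phenotypes.

Three nested generative models describe a phenotype y_ti (organoid i of
tumor t) on either the arithmetic or the log10 scale:

* M0 — one mean and one variance shared by every tumor;
* M1 — a mean per tumor, one shared within-tumor variance;
* M2 — a mean and a variance per tumor.

Each model is scored by its maximized Gaussian log-likelihood penalized in
the Schwarz (BIC) asymptotic form

    S_M = ln L(Θ̃) − (1/2) Σ_θ ln n_θ,

where n_θ is the number of observations informing parameter θ: grand-level
parameters (μ0, σ0², the shared σW²) use N, per-tumor parameters (μ_t, σ_t²)
use N_t.  Maximum-likelihood variances divide by n, not n−1.  With a uniform
prior over the three models, posteriors are a softmax of the scores, computed
relative to the best score to avoid underflow.

Because normal-model selection is noisy for small groups, posteriors are
averaged over bootstrap replicates that resample *tumors* uniformly with
replacement (organoids within a drawn tumor are kept intact; a tumor drawn
twice contributes twice under independent group labels).  A minimum
organoids-per-tumor threshold can be applied before resampling to guard
against poorly estimated within-tumor variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from invaspect.exceptions import DegenerateFitError

__all__ = [
    "GroupedData",
    "ModelFit",
    "BootstrapSelection",
    "fit_model",
    "model_posteriors",
    "bootstrap_model_selection",
]

MODELS = ("M0", "M1", "M2")


@dataclass(frozen=True)
class GroupedData:
    """A phenotype vector with tumor group labels.

    ``values`` is the phenotype y_ti (length N); ``groups`` the parallel
    tumor labels.  ``scale`` records whether values are raw (arithmetic) or
    log10-transformed, which is bookkeeping only — fitting is scale-agnostic.
    """

    values: np.ndarray
    groups: np.ndarray
    scale: str = "log10"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        g = np.asarray(self.groups)
        if v.ndim != 1 or g.shape != v.shape:
            raise ValueError("values and groups must be parallel 1-D arrays")
        if not np.all(np.isfinite(v)):
            raise ValueError("phenotype values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "groups", g)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str, group_col: str = "tumor_id",
                       scale: str = "log10") -> "GroupedData":
        return cls(df[value_col].to_numpy(float), df[group_col].to_numpy(), scale=scale)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def tumor_ids(self) -> np.ndarray:
        # first-appearance order
        _, idx = np.unique(self.groups, return_index=True)
        return self.groups[np.sort(idx)]

    @property
    def n_tumors(self) -> int:
        return len(self.tumor_ids)

    def group_sizes(self) -> dict:
        ids, counts = np.unique(self.groups, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def split(self) -> list[np.ndarray]:
        """Per-tumor value arrays in first-appearance order."""
        return [self.values[self.groups == t] for t in self.tumor_ids]

    def filtered(self, min_organoids: int) -> "GroupedData":
        """Keep only tumors with at least ``min_organoids`` organoids."""
        sizes = self.group_sizes()
        keep = np.array([sizes[g] >= min_organoids for g in self.groups])
        return GroupedData(self.values[keep], self.groups[keep], scale=self.scale)


@dataclass(frozen=True)
class ModelFit:
    """Maximum-likelihood fit of one model: parameters, log-likelihood, score."""

    model: str
    params: dict
    log_likelihood: float
    penalty: float  # (1/2) Σ_θ ln n_θ

    @property
    def score(self) -> float:
        return self.log_likelihood - self.penalty


def _gauss_loglik(n: int, var: float) -> float:
    """Maximized Gaussian log-likelihood of n points with MLE variance var."""
    return -0.5 * n * (np.log(2.0 * np.pi * var) + 1.0)


def fit_model(data: GroupedData, model: str) -> ModelFit:
    """Fit M0, M1 or M2 by maximum likelihood and compute its BIC-style score."""
    y = data.values
    n = data.n
    per_tumor = data.split()
    sizes = np.array([len(g) for g in per_tumor])

    if model == "M0":
        mu0 = float(y.mean())
        var0 = float(np.mean((y - mu0) ** 2))
        if var0 <= 0:
            raise DegenerateFitError("M0: zero MLE variance")
        loglik = _gauss_loglik(n, var0)
        penalty = 0.5 * (np.log(n) + np.log(n))  # μ0 and σ0² each use N
        params = {"mu0": mu0, "sigma0_sq": var0}
    elif model == "M1":
        if n < data.n_tumors + 1:
            raise DegenerateFitError("M1: need more observations than tumors")
        mus = np.array([g.mean() for g in per_tumor])
        ss = sum(float(((g - g.mean()) ** 2).sum()) for g in per_tumor)
        var_w = ss / n
        if var_w <= 0:
            raise DegenerateFitError("M1: zero MLE within-tumor variance")
        loglik = _gauss_loglik(n, var_w)
        penalty = 0.5 * (np.sum(np.log(sizes)) + np.log(n))  # each μ_t: N_t; σW²: N
        params = {"mu_t": dict(zip(data.tumor_ids.tolist(), mus.tolist())),
                  "sigmaW_sq": float(var_w)}
    elif model == "M2":
        if np.any(sizes < 2):
            raise DegenerateFitError("M2: every tumor needs at least 2 organoids")
        mus = np.array([g.mean() for g in per_tumor])
        vars_t = np.array([np.mean((g - g.mean()) ** 2) for g in per_tumor])
        if np.any(vars_t <= 0):
            raise DegenerateFitError("M2: zero MLE variance in some tumor")
        loglik = float(sum(_gauss_loglik(nt, vt) for nt, vt in zip(sizes, vars_t)))
        penalty = float(0.5 * (2 * np.sum(np.log(sizes))))  # μ_t and σ_t² each: N_t
        params = {"mu_t": dict(zip(data.tumor_ids.tolist(), mus.tolist())),
                  "sigma_t_sq": dict(zip(data.tumor_ids.tolist(), vars_t.tolist()))}
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return ModelFit(model=model, params=params, log_likelihood=float(loglik),
                    penalty=float(penalty))


def model_posteriors(fits) -> dict:
    """Posterior probability of each fitted model under a uniform prior.

    Softmax of the scores relative to the best one, so the result is exact
    even when scores are hugely negative.
    """
    if isinstance(fits, dict):
        fits = list(fits.values())
    scores = np.array([f.score for f in fits])
    delta = scores - scores.max()
    weights = np.exp(delta)
    post = weights / weights.sum()
    return {f.model: float(p) for f, p in zip(fits, post)}


def _posteriors_for(data: GroupedData) -> dict:
    fits = [fit_model(data, m) for m in MODELS]
    return model_posteriors(fits)


@dataclass(frozen=True)
class BootstrapSelection:
    """Bootstrap-averaged model posteriors plus the filtered-cohort summary."""

    mean_posterior: dict
    replicates: pd.DataFrame = field(repr=False)  # one row per replicate
    n_tumors: int
    mean_organoids_per_tumor: float
    min_organoids: int
    n_reps: int
    seed: int | None


def bootstrap_model_selection(
    data: GroupedData,
    min_organoids: int = 1,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> BootstrapSelection:
    """Average model posteriors over bootstrap resamples of whole tumors.

    Tumors with fewer than ``min_organoids`` organoids are dropped first;
    each replicate then draws T' tumors uniformly with replacement from the
    filtered set (T' = filtered tumor count) and records the three-model
    posterior of the resampled data.
    """
    filtered = data.filtered(min_organoids)
    tumors = filtered.tumor_ids
    t_prime = len(tumors)
    if t_prime < 2:
        raise ValueError("fewer than 2 tumors remain after filtering")
    groups = {t: filtered.values[filtered.groups == t] for t in tumors}
    rng = np.random.default_rng(seed)
    rows = np.empty((n_reps, 3))
    for rep in range(n_reps):
        draw = rng.integers(0, t_prime, size=t_prime)
        values = np.concatenate([groups[tumors[d]] for d in draw])
        labels = np.repeat(np.arange(t_prime), [len(groups[tumors[d]]) for d in draw])
        post = _posteriors_for(GroupedData(values, labels, scale=filtered.scale))
        rows[rep] = [post[m] for m in MODELS]
    reps = pd.DataFrame(rows, columns=list(MODELS))
    return BootstrapSelection(
        mean_posterior={m: float(reps[m].mean()) for m in MODELS},
        replicates=reps,
        n_tumors=t_prime,
        mean_organoids_per_tumor=float(filtered.n / t_prime),
        min_organoids=min_organoids,
        n_reps=n_reps,
        seed=seed,
    )
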