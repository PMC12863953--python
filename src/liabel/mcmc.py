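"""Single-trait linear and threshold animal models fitted by Gibbs sampling.

Both models share the mixed-model structure

    y = X beta + Z a + e          (linear, observed 0/1 response)
    l = X beta + Z a + e          (threshold, latent liability)

with contemporary-group effects ``beta`` under a vague normal prior,
additive genetic effects ``a ~ N(0, H sigma2_a)`` where ``H`` combines
pedigree and genomic relationships, and i.i.d. residuals. The threshold
model observes only the category (defect present/absent) and augments
the latent liability by sampling it from its truncated normal full
conditional; its residual variance is fixed at 1 and the threshold at 0
(the location is absorbed by the CG effects), the standard
identification for a single threshold.

``solve_mme`` provides the deterministic mixed-model-equation solution
used as an oracle for the sampler at fixed variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gibbs import gibbs_kernel
from .containers import GEBVTable
from .diagnostics import hpd
from .relationships import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "ModelDesign",
    "MCMCChain",
    "PosteriorSummary",
    "build_design",
    "run_gibbs",
    "solve_mme",
    "summarize",
]


@dataclass(frozen=True)
class ModelSpec:
    """Sampler settings.

    Defaults are desk-scale (50K iterations, 10K burn-in, thinning 50);
    production analyses of this kind run 300K-1M iterations with
    30K-500K burn-in, which the fields accept unchanged. Variance priors
    are scaled inverse chi-square with ``nu = -2`` and scale 0, i.e.
    flat on the variances.
    """

    model_type: str = "threshold"
    n_iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 50
    seed: int = 0
    cg_prior_var: float = 1e10
    nu_a: float = -2.0
    scale_a: float = 0.0
    nu_e: float = -2.0
    scale_e: float = 0.0
    fix_variances: bool = False
    # None = data-scaled: half the response variance each (linear), or
    # 0.5 additive with the fixed unit residual (threshold)
    sigma2_a_init: float | None = None
    sigma2_e_init: float | None = None

    def __post_init__(self) -> None:
        if self.model_type not in ("linear", "threshold"):
            raise ValueError(f"model_type must be 'linear' or 'threshold', got {self.model_type!r}")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.cg_prior_var <= 0:
            raise ValueError("cg_prior_var must be positive")
        for name in ("sigma2_a_init", "sigma2_e_init"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelDesign:
    """Records mapped to CG and animal indices, plus the H^-1 prior."""

    y: np.ndarray              # 0/1 per record
    rec_animal: np.ndarray     # index into animal_ids
    rec_cg: np.ndarray         # index into cg_labels
    animal_ids: pd.Index
    cg_labels: pd.Index
    hinv: np.ndarray

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_cgs(self) -> int:
        return len(self.cg_labels)


@dataclass
class MCMCChain:
    """Retained Gibbs draws after burn-in and thinning."""

    sigma2_a: np.ndarray
    sigma2_e: np.ndarray
    a: np.ndarray              # n_kept x n_animals
    animal_ids: pd.Index
    model_type: str
    spec: ModelSpec

    @property
    def n_kept(self) -> int:
        return len(self.sigma2_a)

    def h2(self) -> np.ndarray:
        """Per-draw heritability sigma2_a / (sigma2_a + sigma2_e).

        Liability scale for the threshold model (sigma2_e == 1),
        observed scale for the linear model.
        """
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


@dataclass
class PosteriorSummary:
    """Posterior means and 95% HPD intervals."""

    model_type: str
    sigma2_a: float
    sigma2_e: float
    h2: float
    h2_scale: str
    sigma2_a_hpd: tuple[float, float]
    sigma2_e_hpd: tuple[float, float]
    h2_hpd: tuple[float, float]
    gebv: GEBVTable
    n_kept: int
    warnings: list = field(default_factory=list)


def build_design(
    phenotypes: pd.DataFrame, hinv: RelationshipMatrix
) -> ModelDesign:
    """Map records (columns animal, cg, y) onto the H^-1 animal index."""
    missing = set(phenotypes["animal"]) - set(hinv.ids)
    if missing:
        raise ValueError(
            f"{len(missing)} phenotyped animals absent from the relationship "
            f"matrix, e.g. {sorted(missing)[:5]}"
        )
    y = phenotypes["y"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("phenotypes must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("response has no variability (all 0 or all 1)")
    apos = {a: k for k, a in enumerate(hinv.ids)}
    rec_animal = np.array([apos[a] for a in phenotypes["animal"]], dtype=np.int64)
    cg_labels = pd.Index(dict.fromkeys(phenotypes["cg"]))
    cpos = {c: j for j, c in enumerate(cg_labels)}
    rec_cg = np.array([cpos[c] for c in phenotypes["cg"]], dtype=np.int64)
    return ModelDesign(
        y=y,
        rec_animal=rec_animal,
        rec_cg=rec_cg,
        animal_ids=hinv.ids,
        cg_labels=cg_labels,
        hinv=np.ascontiguousarray(hinv.values),
    )


def run_gibbs(design: ModelDesign, spec: ModelSpec) -> MCMCChain:
    """Run the single-site Gibbs sampler. Deterministic given spec.seed."""
    if design.n_animals < 3:
        raise ValueError("need at least 3 animals for variance sampling")
    if spec.model_type == "threshold":
        s2a_init = spec.sigma2_a_init if spec.sigma2_a_init is not None else 0.5
        s2e_init = 1.0
    else:
        vy = float(np.var(design.y))
        s2a_init = spec.sigma2_a_init if spec.sigma2_a_init is not None else max(vy / 2, 1e-8)
        s2e_init = spec.sigma2_e_init if spec.sigma2_e_init is not None else max(vy / 2, 1e-8)
    s2a, s2e, a = gibbs_kernel(
        design.y,
        design.rec_animal,
        design.rec_cg,
        design.hinv,
        design.n_cgs,
        spec.n_iterations,
        spec.burn_in,
        spec.thin,
        spec.model_type == "threshold",
        spec.fix_variances,
        s2a_init,
        s2e_init,
        spec.cg_prior_var,
        spec.nu_a,
        spec.scale_a,
        spec.nu_e,
        spec.scale_e,
        spec.seed,
    )
    if not (np.isfinite(s2a).all() and np.isfinite(a).all()):
        raise FloatingPointError("non-finite draws in the chain; check H^-1 conditioning")
    return MCMCChain(
        sigma2_a=s2a,
        sigma2_e=s2e,
        a=a,
        animal_ids=design.animal_ids,
        model_type=spec.model_type,
        spec=spec,
    )


def solve_mme(
    design: ModelDesign, sigma2_a: float, sigma2_e: float, cg_prior_var: float = 1e10
) -> tuple[pd.Series, pd.Series]:
    """Henderson's mixed-model equations at fixed variance components.

    Returns ``(beta_hat, a_hat)``. The joint posterior mean of the Gibbs
    sampler with fixed variances coincides with this solution, which
    makes it the deterministic oracle for sampler validation.
    """
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise ValueError("variances must be positive")
    n_rec, p, q = design.n_records, design.n_cgs, design.n_animals
    X = np.zeros((n_rec, p))
    X[np.arange(n_rec), design.rec_cg] = 1.0
    Z = np.zeros((n_rec, q))
    Z[np.arange(n_rec), design.rec_animal] = 1.0
    lam = sigma2_e / sigma2_a
    top = np.hstack([X.T @ X + (sigma2_e / cg_prior_var) * np.eye(p), X.T @ Z])
    bot = np.hstack([Z.T @ X, Z.T @ Z + lam * design.hinv])
    C = np.vstack([top, bot])
    rhs = np.concatenate([X.T @ design.y, Z.T @ design.y])
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular mixed-model equations: confounded CG effects or a "
            "singular H^-1 (check for empty CGs / unblended G)"
        ) from exc
    beta_hat = pd.Series(sol[:p], index=design.cg_labels, name="beta")
    a_hat = pd.Series(sol[p:], index=design.animal_ids, name="a")
    return beta_hat, a_hat


def summarize(chain: MCMCChain, mass: float = 0.95) -> PosteriorSummary:
    """Posterior means and shortest 95% HPD intervals for the chain."""
    if chain.n_kept == 0:
        raise ValueError("empty chain")
    warns = []
    if chain.n_kept < 50:
        warns.append(f"only {chain.n_kept} retained draws; summaries are noisy")
        warnings.warn(warns[-1])
    h2_draws = chain.h2()
    scale = "liability" if chain.model_type == "threshold" else "observed"
    gebv = GEBVTable(
        pd.Series(chain.a.mean(axis=0), index=chain.animal_ids),
        scale=scale,
        model=chain.model_type,
        meta={"n_kept": chain.n_kept, "seed": chain.spec.seed},
    )
    return PosteriorSummary(
        model_type=chain.model_type,
        sigma2_a=float(chain.sigma2_a.mean()),
        sigma2_e=float(chain.sigma2_e.mean()),
        h2=float(h2_draws.mean()),
        h2_scale=scale,
        sigma2_a_hpd=hpd(chain.sigma2_a, mass),
        sigma2_e_hpd=hpd(chain.sigma2_e, mass),
        h2_hpd=hpd(h2_draws, mass),
        gebv=gebv,
        n_kept=chain.n_kept,
        warnings=warns,
    )
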