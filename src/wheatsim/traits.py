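"""Three correlated traits: QTL effects, breeding values and phenotypes.

The simulated program selects on three traits:

* **BVP** — breeder's visual preference, a low-heritability single-plant
  score used in early generations (h2 = 0.1 at the plant level);
* **PYT** — yield in the un-replicated preliminary yield trial (plot
  heritability 0.2 at 50 plants per plot);
* **AYT** — yield in the advanced yield trial, the breeding goal (plot
  heritability 0.3 at 1500 plants per plot).

Each trait is purely additive: the true breeding value (TBV) of a line is
the sum of its QTL allelic effects, dosage-centred at the base-population
allele frequencies so that the base mean is ~0.  QTL effects are drawn from
a zero-mean multivariate normal with the scenario's genetic correlation
structure and then rescaled so the base-population TBV variance is exactly
1 per trait (standardized genetic units).  Phenotypes are ``y = g + e`` with
independent normal residuals; residual variances are calibrated so realized
plot heritabilities hit their targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TRAITS = ("BVP", "PYT", "AYT")
BVP, PYT, AYT = 0, 1, 2


class InvalidCovarianceError(ValueError):
    pass


class DegenerateArchitectureError(ValueError):
    pass


class InfeasibleHeritabilityError(ValueError):
    pass


def genetic_correlation_matrix(corr_pyt_ayt: float,
                               corr_bvp: float = 0.1) -> np.ndarray:
    """3x3 genetic correlation matrix for (BVP, PYT, AYT)."""
    return np.array([
        [1.0, corr_bvp, corr_bvp],
        [corr_bvp, 1.0, corr_pyt_ayt],
        [corr_bvp, corr_pyt_ayt, 1.0],
    ])


@dataclass
class TraitModel:
    """Scaled QTL effects plus the variance parameters of the three traits."""

    qtl_idx: np.ndarray        # (nQ,) locus indices of the QTL
    effects: np.ndarray        # (nQ, 3) additive substitution effects
    qtl_base_freq: np.ndarray  # (nQ,) base-population allele frequencies
    G0: np.ndarray             # (3, 3) genetic covariance, unit diagonal
    sigma_e2: dict             # per-trait per-PLANT residual variance

    def tbv(self, haps: np.ndarray) -> np.ndarray:
        """True breeding values, shape (n, 3), for haplotypes (n, 2, L)."""
        return true_breeding_values(haps, self)


def sample_qtl_effects(n_qtl: int, genetic_correlations: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw raw per-QTL effect 3-vectors i.i.d. from N(0, correlation)."""
    C = np.asarray(genetic_correlations, dtype=float)
    if C.shape != (3, 3) or not np.allclose(C, C.T):
        raise InvalidCovarianceError("correlation matrix must be symmetric 3x3")
    if not np.allclose(np.diag(C), 1.0):
        raise InvalidCovarianceError("correlation matrix must have unit diagonal")
    try:
        L = np.linalg.cholesky(C + 1e-12 * np.eye(3))
    except np.linalg.LinAlgError as exc:
        raise InvalidCovarianceError("correlation matrix not PSD") from exc
    return rng.standard_normal((n_qtl, 3)) @ L.T


def _qtl_dosage(haps: np.ndarray, qtl_idx: np.ndarray) -> np.ndarray:
    if haps.ndim == 2:  # already a dosage matrix (n, L)
        return haps[:, qtl_idx].astype(np.float64)
    return haps[:, :, qtl_idx].sum(axis=1).astype(np.float64)


def scale_qtl_effects(raw_effects: np.ndarray, base_haps: np.ndarray,
                      qtl_idx: np.ndarray, target_variance: float = 1.0,
                      mode: str = "empirical",
                      target_correlation: np.ndarray | None = None):
    """Rescale raw QTL effects so base-population TBV variance hits target.

    ``mode="empirical"`` (default) divides each trait's effects by the
    realized TBV standard deviation over the base lines, making the base
    variance exactly ``target_variance``.  ``mode="empirical_cov"``
    additionally rotates the effect matrix so that the base-population TBV
    covariance equals ``target_variance * target_correlation`` exactly
    (linkage disequilibrium among QTL otherwise perturbs the realized trait
    correlations away from the scenario values).  ``mode="analytic"``
    divides by
    ``sqrt(sum_k 2 p_k (1-p_k) a_k'^2 / sigma2_qtl)``, the Hardy-Weinberg
    expectation, with ``sigma2_qtl = target_variance``.

    Returns ``(effects, base_freq)``.
    """
    raw = np.asarray(raw_effects, dtype=np.float64)
    D = _qtl_dosage(base_haps, qtl_idx)
    p = D.mean(axis=0) / 2.0
    if target_variance == 0.0:
        return np.zeros_like(raw), p
    if mode == "empirical_cov":
        C = (np.eye(raw.shape[1]) if target_correlation is None
             else np.asarray(target_correlation, dtype=np.float64))
        tbv_raw = (D - 2.0 * p) @ raw
        S = np.cov(tbv_raw.T, ddof=1)
        try:
            Ls = np.linalg.cholesky(S)
            Lt = np.linalg.cholesky(target_variance * C)
        except np.linalg.LinAlgError as exc:
            raise DegenerateArchitectureError(
                "degenerate raw TBV covariance in base population") from exc
        M = np.linalg.solve(Ls.T, Lt.T)  # maps realized cov onto the target
        return raw @ M, p
    if mode == "empirical":
        tbv_raw = (D - 2.0 * p) @ raw
        sd = tbv_raw.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise DegenerateArchitectureError(
                "zero raw TBV variance in base population")
        scale = np.sqrt(target_variance) / sd
    elif mode == "analytic":
        denom = np.sqrt(((2.0 * p * (1.0 - p))[:, None] * raw ** 2).sum(axis=0)
                        / target_variance)
        if np.any(denom <= 0):
            raise DegenerateArchitectureError(
                "zero expected TBV variance under HWE scaling")
        scale = 1.0 / denom
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return raw * scale[None, :], p


def true_breeding_values(haps: np.ndarray, model: TraitModel) -> np.ndarray:
    """TBV per trait: sum over QTL of (dosage - 2 p_base) x effect."""
    D = _qtl_dosage(haps, model.qtl_idx)
    return (D - 2.0 * model.qtl_base_freq) @ model.effects


def build_trait_model(layout, base_haps: np.ndarray, corr_pyt_ayt: float,
                      rng: np.random.Generator, *, corr_bvp: float = 0.1,
                      h2_bvp: float = 0.1, h2_pyt: float = 0.2,
                      h2_ayt: float = 0.3, n_plants: dict | None = None,
                      scaling_mode: str = "empirical_cov",
                      residual_mode: str = "empirical") -> TraitModel:
    """Sample, scale and calibrate a full trait model for one replicate."""
    n_plants = {"PYT": 50, "AYT": 1500} if n_plants is None else n_plants
    G0 = genetic_correlation_matrix(corr_pyt_ayt, corr_bvp)
    raw = sample_qtl_effects(layout.n_qtl, G0, rng)
    effects, p = scale_qtl_effects(raw, base_haps, layout.qtl_idx,
                                   target_variance=1.0, mode=scaling_mode,
                                   target_correlation=G0)
    # H enters the printed calibration formula as the expected homozygosity
    # at the generation where the trait is first measured (PYT at F5, AYT at
    # F6); the empirical mode treats plots as clonal and does not use H.
    H_pyt = 1.0 - 0.5 ** 4
    H_ayt = 1.0 - 0.5 ** 5
    sigma_e2 = {
        # single-plant BVP: h2 = sg2 / (sg2 + se2)  ->  se2 = sg2 (1-h2)/h2
        "BVP": (1.0 - h2_bvp) / h2_bvp,
        "PYT": calibrate_residual_variance(h2_pyt, n_plants["PYT"], H=H_pyt,
                                           mode=residual_mode, rng=rng),
        "AYT": calibrate_residual_variance(h2_ayt, n_plants["AYT"], H=H_ayt,
                                           mode=residual_mode, rng=rng),
    }
    return TraitModel(qtl_idx=layout.qtl_idx, effects=effects,
                      qtl_base_freq=p, G0=G0, sigma_e2=sigma_e2)


# ---------------------------------------------------------------------------
# residual-variance calibration
# ---------------------------------------------------------------------------

def calibrate_residual_variance(h2_plot: float, n_plants: int,
                                H: float = 1.0, sigma_g2: float = 1.0,
                                mode: str = "empirical",
                                rng: np.random.Generator | None = None,
                                n_sim: int = 200_000,
                                tol: float = 0.005) -> float:
    """Per-plant residual variance achieving the target plot heritability.

    ``mode="analytic"`` evaluates the closed form
    ``se2 = 2 Np H sg2 (1 - h2) / h2 - (1 - H) sg2`` (H is the expected
    homozygosity of the generation).  ``mode="empirical"`` simulates plot
    phenotypes of clonal plots (``y = g + mean of Np plant residuals``) and
    bisects the per-plant residual variance until the realized plot
    heritability is within ``tol`` of the target; common random numbers make
    the realized heritability a smooth monotone function of the candidate
    variance, so the bisection converges reliably.
    """
    if not 0.0 < h2_plot < 1.0:
        raise InfeasibleHeritabilityError("plot heritability must be in (0, 1)")
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    if not 0.0 <= H <= 1.0:
        raise ValueError("H must be in [0, 1]")

    if mode == "analytic":
        se2 = (2.0 * n_plants * H * sigma_g2 * (1.0 - h2_plot) / h2_plot
               - (1.0 - H) * sigma_g2)
        if se2 <= 0:
            raise InfeasibleHeritabilityError(
                f"computed residual variance {se2:.4g} is not positive")
        return float(se2)
    if mode != "empirical":
        raise ValueError(f"unknown calibration mode {mode!r}")

    rng = np.random.default_rng() if rng is None else rng
    g = rng.normal(0.0, np.sqrt(sigma_g2), n_sim)
    z = rng.standard_normal(n_sim)
    var_g = g.var(ddof=1)

    def realized_h2(se2: float) -> float:
        y = g + z * np.sqrt(se2 / n_plants)
        return var_g / y.var(ddof=1)

    lo, hi = 1e-10, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisection on log scale
        h2 = realized_h2(mid)
        if abs(h2 - h2_plot) <= tol * 0.2:
            break
        if h2 > h2_plot:
            lo = mid
        else:
            hi = mid
    return float(mid)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

@dataclass
class PlotRecord:
    """One phenotype observation on a plot (or a single plant)."""

    line_ids: np.ndarray
    trait: str
    stage: str
    year: int
    replicate: int
    n_plants: int
    value: float
    location: str = "loc1"


def simulate_plot_phenotype(plant_tbvs: np.ndarray, trait: str,
                            n_plants: int, model: TraitModel,
                            rng: np.random.Generator) -> float:
    """Plot value: mean over the plot's plants of (TBV + plant residual).

    ``plant_tbvs`` holds the TBVs (for the given trait) of the distinct
    genotypes in the plot.  A seed-multiplied inbred line contributes a
    single TBV shared by all plants; a family mixture plot passes one TBV
    per family member, and plants are drawn from them with replacement.
    """
    g = np.asarray(plant_tbvs, dtype=float).ravel()
    if g.size == 0:
        raise ValueError("empty plot")
    if g.size == 1:
        g_plot = g[0]
    else:
        g_plot = g[rng.integers(0, g.size, size=n_plants)].mean()
    se2 = model.sigma_e2[trait]
    return float(g_plot + rng.normal(0.0, np.sqrt(se2 / n_plants)))


def plot_values_batch(line_tbvs: np.ndarray, trait: str, n_plants: int,
                      model: TraitModel, rng: np.random.Generator,
                      n_replicates: int = 1) -> np.ndarray:
    """Plot phenotypes for many clonal lines at once.

    Returns shape ``(n_lines,)`` if ``n_replicates == 1`` else
    ``(n_lines, n_replicates)``; each replicate is an independent plot.
    """
    g = np.asarray(line_tbvs, dtype=float)
    se_plot = np.sqrt(model.sigma_e2[trait] / n_plants)
    shape = (g.size, n_replicates)
    y = g[:, None] + rng.normal(0.0, se_plot, size=shape)
    return y[:, 0] if n_replicates == 1 else y


def simulate_plant_phenotype(tbv_bvp, model: TraitModel,
                             rng: np.random.Generator):
    """Single-plant BVP phenotype: TBV + N(0, sigma_e2(BVP))."""
    g = np.asarray(tbv_bvp, dtype=float)
    return g + rng.normal(0.0, np.sqrt(model.sigma_e2["BVP"]), size=g.shape)
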