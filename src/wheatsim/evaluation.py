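"""Selection criteria: genomic relationship matrices, multi-trait GBLUP and
phenotype-based criteria, plus selection accuracy.

The genomic model treats variance components as known (the true simulated
genetic covariance ``G0`` and the calibrated residual variances), so GEBVs
are best linear unbiased predictions given the genomic relationship matrix.
Two algebraically equivalent solvers are provided: the mixed-model equations
(``method="mme"``, a direct dense solve, preferred for small problems and
used to cross-check) and the generalized-least-squares / conditional-mean
form (``method="gls"``), which factorizes only an N x N matrix in the number
of phenotype records and is what the breeding-scheme engine uses at scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .traits import TRAITS


class MissingDataError(ValueError):
    pass


class IndexingError(KeyError):
    pass


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrix:
    """Genomic relationship matrix over an ordered set of lines."""

    entries: np.ndarray              # (n, n) symmetric
    reference_frequencies: np.ndarray
    blend: float = 0.0
    n_markers_excluded: int = 0
    kind: str = "GENOMIC"

    @property
    def n_lines(self) -> int:
        return self.entries.shape[0]


def build_grm(genotypes: np.ndarray, reference_frequencies: np.ndarray,
              blend: float = 0.01) -> RelationshipMatrix:
    """Centred cross-product genomic relationship matrix.

    ``G = Zc Zc' / sum(2 p (1-p))`` with ``Zc = dosage - 2p`` and ``p`` the
    reference (base-population) allele frequencies, then blended with the
    identity: ``(1 - blend) G + blend I`` for guaranteed invertibility.
    Markers monomorphic at the reference frequencies are excluded (their
    count is recorded on the result).
    """
    M = np.asarray(genotypes, dtype=np.float64)
    p = np.asarray(reference_frequencies, dtype=np.float64)
    keep = (p > 0.0) & (p < 1.0)
    n_excluded = int((~keep).sum())
    M, p = M[:, keep], p[keep]
    Zc = M - 2.0 * p
    denom = np.sum(2.0 * p * (1.0 - p))
    G = (Zc @ Zc.T) / denom
    if blend > 0.0:
        G = (1.0 - blend) * G + blend * np.eye(G.shape[0])
    return RelationshipMatrix(entries=G, reference_frequencies=p,
                              blend=blend, n_markers_excluded=n_excluded)


# ---------------------------------------------------------------------------
# multi-trait GBLUP
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Per-line, per-trait selection criteria."""

    line_index: np.ndarray     # indices of lines (into the GRM ordering)
    scores: np.ndarray         # (n, n_traits) criterion values
    model_kind: str            # PS_PHENOTYPE or GS_GBLUP
    trait_names: tuple = TRAITS
    means: np.ndarray | None = None  # fitted trait means (GBLUP only)

    def criterion(self, trait: str) -> np.ndarray:
        return self.scores[:, self.trait_names.index(trait)]


def _records_arrays(records):
    """Normalize records to (line_index, trait_index, value, resid_var)."""
    if isinstance(records, pd.DataFrame):
        li = records["line_index"].to_numpy(dtype=np.int64)
        tr = records["trait"]
        if tr.dtype == object:
            ti = np.array([TRAITS.index(t) for t in tr], dtype=np.int64)
        else:
            ti = tr.to_numpy(dtype=np.int64)
        y = records["value"].to_numpy(dtype=np.float64)
        rv = records["resid_var"].to_numpy(dtype=np.float64)
        return li, ti, y, rv
    li, ti, y, rv = records
    return (np.asarray(li, dtype=np.int64), np.asarray(ti, dtype=np.int64),
            np.asarray(y, dtype=np.float64), np.asarray(rv, dtype=np.float64))


def solve_multitrait_gblup(records, grm, G0: np.ndarray,
                           candidates: np.ndarray | None = None,
                           method: str = "auto") -> EvaluationResult:
    """Solve the multi-trait GBLUP model and return GEBVs for all lines.

    The model per trait ``t`` is ``y_t = 1 mu_t + Z_t a_t + e_t`` with
    ``var(a) = G (x) G0`` and independent residuals (traits are recorded on
    different plots, so residual covariances are zero).  Records are tuples
    or a DataFrame with ``line_index`` (row in the GRM), ``trait`` (name or
    index), ``value`` and ``resid_var`` (the record's residual variance;
    repeated plots may enter either as repeated records or pre-averaged with
    a correspondingly reduced residual variance).

    Fixed effects are one overall mean per trait that has records.  GEBVs
    are returned for every line indexed by the GRM, including unphenotyped
    candidates, which are predicted through genomic relationships.
    """
    G = grm.entries if isinstance(grm, RelationshipMatrix) else np.asarray(grm)
    G0 = np.asarray(G0, dtype=np.float64)
    li, ti, y, rv = _records_arrays(records)
    n = G.shape[0]
    if li.size == 0:
        raise MissingDataError("no phenotype records supplied")
    if li.min() < 0 or li.max() >= n:
        raise IndexingError("record line_index outside the GRM ordering")
    n_traits = G0.shape[0]

    if method == "auto":
        method = "mme" if 3 * n <= 900 else "gls"

    obs_traits = np.unique(ti)
    X = np.zeros((y.size, obs_traits.size))
    for j, t in enumerate(obs_traits):
        X[ti == t, j] = 1.0

    if method == "gls":
        # V = Sigma_g + D with Sigma_g[r, s] = G0[t_r, t_s] * G[i_r, i_s]
        V = G0[np.ix_(ti, ti)] * G[np.ix_(li, li)]
        V[np.diag_indices_from(V)] += rv
        cf = cho_factor(V, lower=True, check_finite=False)
        Vi_X = cho_solve(cf, X, check_finite=False)
        XtViX = X.T @ Vi_X
        mu = np.linalg.solve(XtViX, Vi_X.T @ y)
        w = cho_solve(cf, y - X @ mu, check_finite=False)
        K = G[:, li]  # (n, N)
        scores = np.empty((n, n_traits))
        for t in range(n_traits):
            scores[:, t] = K @ (G0[t, ti] * w)
        means = np.zeros(n_traits)
        means[obs_traits] = mu
    elif method == "mme":
        # unknowns: means for observed traits, then a (line-major, trait-fast)
        Ginv = np.linalg.inv(G)
        G0inv = np.linalg.inv(G0)
        slot = li * n_traits + ti
        Z = np.zeros((y.size, n * n_traits))
        Z[np.arange(y.size), slot] = 1.0
        Rinv = 1.0 / rv
        XtRX = X.T * Rinv @ X
        XtRZ = X.T * Rinv @ Z
        ZtRZ = Z.T * Rinv @ Z
        C = np.block([[XtRX, XtRZ],
                      [XtRZ.T, ZtRZ + np.kron(Ginv, G0inv)]])
        rhs = np.concatenate([X.T @ (Rinv * y), Z.T @ (Rinv * y)])
        sol = np.linalg.solve(C, rhs)
        resid = C @ sol - rhs
        if np.linalg.norm(resid) > 1e-8 * max(1.0, np.linalg.norm(rhs)):
            raise np.linalg.LinAlgError(
                f"MME solve residual too large (cond ~ {np.linalg.cond(C):.2e})")
        nf = obs_traits.size
        scores = sol[nf:].reshape(n, n_traits)
        means = np.zeros(n_traits)
        means[obs_traits] = sol[:nf]
    else:
        raise ValueError(f"unknown method {method!r}")

    idx = np.arange(n) if candidates is None else np.asarray(candidates)
    return EvaluationResult(line_index=idx, scores=scores[idx],
                            model_kind="GS_GBLUP", means=means)


# ---------------------------------------------------------------------------
# phenotype criterion and accuracy
# ---------------------------------------------------------------------------

def phenotype_criterion(records, candidates: np.ndarray,
                        trait: str | int) -> EvaluationResult:
    """Phenotypic-selection criterion: per-line mean of its plot values."""
    li, ti, y, _ = _records_arrays(records)
    t = TRAITS.index(trait) if isinstance(trait, str) else int(trait)
    candidates = np.asarray(candidates, dtype=np.int64)
    mask = ti == t
    li, y = li[mask], y[mask]
    sums = np.bincount(li, weights=y, minlength=int(candidates.max()) + 1)
    counts = np.bincount(li, minlength=int(candidates.max()) + 1)
    if np.any(counts[candidates] == 0):
        missing = candidates[counts[candidates] == 0]
        raise MissingDataError(
            f"{missing.size} candidate(s) have no records for trait {trait}")
    scores = np.full((candidates.size, len(TRAITS)), np.nan)
    scores[:, t] = sums[candidates] / counts[candidates]
    return EvaluationResult(line_index=candidates, scores=scores,
                            model_kind="PS_PHENOTYPE")


def selection_accuracy(criterion: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between a selection criterion and true values.

    Returns NaN (an "undefined accuracy" signal, not an exception) when
    either vector has zero variance or fewer than 3 lines are given.
    """
    c = np.asarray(criterion, dtype=float)
    g = np.asarray(tbv, dtype=float)
    if c.size < 3 or c.std() == 0.0 or g.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(c, g)[0, 1])
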