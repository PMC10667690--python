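"""Linear mixed models for alpha-lattice screening trials.

The engine fits the two model layers used in donor screening:

* single-experiment analysis (SEA), one experiment and one condition::

      y = b0 + b1*replication + block(replication) + u + e

* multi-environment analysis (MEA), both conditions::

      y = b0 + b1*environment + b2*replication + b3*block + u + e

with the genotype effect ``u`` random — covariance either the identity
(phenotypic BLUP) or a genomic relationship matrix (GBLUP) — and everything
else fixed.  An ``across`` scope joins the two calendar experiments of one
condition, with replications and blocks nested inside experiments.

Variance components are estimated by EM-REML through Henderson's mixed-model
equations (MME): with M the coefficient matrix, C = sigma2_e * M^-1 and
q genotypes,

    sigma2_g <- (u' K^-1 u + tr(K^-1 C_uu)) / q
    sigma2_e <- (y'y - b'X'y - u'Z'y) / (n - rank(X)),

which never leaves the parameter space and yields a monotone restricted
likelihood.  The restricted log-likelihood is evaluated each iteration from
MME byproducts via ln|V| + ln|X'V^-1 X| = ln|R| + ln|G| + ln|M / sigma2_e|.

BLUPs, prediction error variances (PEV, the u-block of C), plot-basis
heritability sigma2_g / (sigma2_g + sigma2_e) and reliabilities
1 - PEV/sigma2_g all come from the same solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .exceptions import InputDataError, NumericalError
from .markers import GenomicRelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrices",
    "VarianceComponents",
    "FitResult",
    "build_design",
    "reml_fit",
    "solve_mme",
    "heritability",
    "reliability",
    "reml_loglik_dense",
    "MixedModel",
]

SCOPES = ("sea", "across", "mea")

VAR_FLOOR = 1e-10


# ---------------------------------------------------------------------- #
# design construction
# ---------------------------------------------------------------------- #
def _nested_dummies(df: pd.DataFrame, factor: str, within: tuple[str, ...]
                    ) -> tuple[list[np.ndarray], list[str]]:
    """Treatment-coded dummies for ``factor``, dropping the first sorted level
    within each combination of ``within`` (reference-level coding)."""
    fac = df[factor].astype(str)
    if within:
        key = df[list(within)].astype(str).agg(":".join, axis=1)
    else:
        key = pd.Series("", index=df.index)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for grp in sorted(key.unique()):
        in_grp = (key == grp).to_numpy()
        levels = sorted(fac[in_grp].unique())
        for lev in levels[1:]:
            cols.append((in_grp & (fac == lev).to_numpy()).astype(float))
            label = f"{factor}[{grp}:{lev}]" if grp else f"{factor}[{lev}]"
            names.append(label)
    return cols, names


_SCOPE_TERMS = {
    "sea": [("replication", ()), ("block", ("replication",))],
    "across": [
        ("experiment", ()),
        ("replication", ("experiment",)),
        ("block", ("experiment", "replication")),
    ],
    "mea": [
        ("condition", ()),
        ("experiment", ("condition",)),
        ("replication", ("condition", "experiment")),
        ("block", ("condition", "experiment", "replication")),
    ],
}


@dataclass
class DesignMatrices:
    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    fixed_names: list[str]
    genotype_ids: list[str]
    n_dropped: int
    Z_blocks: np.ndarray | None = None
    block_ids: list[str] | None = None
    n_obs_per_genotype: np.ndarray | None = None


def build_design(table: pd.DataFrame, scope: str = "sea",
                 genotype_ids: list[str] | None = None,
                 blocks: str = "fixed") -> DesignMatrices:
    """Build (X, Z, y) for one trait's records.

    ``table`` must hold a single trait; SEA additionally requires a single
    (experiment, condition) cell and ``across`` a single condition.  Rows
    with a missing response are dropped and counted.  Fixed factors with one
    level contribute no columns (they are confounded with the intercept);
    any residual collinearity is removed by rank-revealing QR with a warning.

    With ``blocks="random"`` the block term moves out of X into an indicator
    matrix ``Z_blocks`` with i.i.d. effects.
    """
    if scope not in SCOPES:
        raise InputDataError(f"scope must be one of {SCOPES}, got {scope!r}")
    if blocks not in ("fixed", "random", "none"):
        raise InputDataError("blocks must be 'fixed', 'random' or 'none'")
    if table["trait"].nunique() > 1:
        raise InputDataError("build_design expects records for exactly one trait")
    if scope == "sea":
        cells = table[["experiment", "condition"]].drop_duplicates()
        if len(cells) > 1:
            raise InputDataError("SEA expects a single (experiment, condition) cell")
    elif scope == "across" and table["condition"].nunique() > 1:
        raise InputDataError("'across' scope expects a single condition")

    data = table.dropna(subset=["value"]).copy()
    n_dropped = len(table) - len(data)
    if n_dropped:
        logger.info("dropped %d records with missing response", n_dropped)
    n = len(data)
    if n == 0:
        raise InputDataError("no observations left after dropping missing responses")

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    z_blocks = None
    block_ids = None
    for factor, within in _SCOPE_TERMS[scope]:
        if factor not in data.columns or data[factor].isna().all():
            continue
        if factor == "block" and blocks != "fixed":
            if blocks == "random":
                key = data[list(within) + ["block"]].astype(str).agg(":".join, axis=1)
                block_ids = sorted(key.unique())
                z_blocks = (key.to_numpy()[:, None] == np.array(block_ids)).astype(float)
            continue
        fac_cols, fac_names = _nested_dummies(data, factor, within)
        if not fac_cols and factor in ("replication", "condition", "experiment"):
            logger.warning("fixed factor %r has a single level; term dropped", factor)
        cols.extend(fac_cols)
        names.extend(fac_names)
    X = np.column_stack(cols)

    # rank-revealing QR: drop linearly dependent columns
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = [names[j] for j in piv[rank:]]
        logger.warning("dropping %d collinear fixed columns: %s", len(dropped), dropped[:5])
        X = X[:, keep]
        names = [names[j] for j in keep]

    gen = data["genotype"].astype(str)
    if genotype_ids is None:
        genotype_ids = sorted(gen.unique())
    else:
        missing = set(gen.unique()) - set(genotype_ids)
        if missing:
            raise InputDataError(
                f"{len(missing)} phenotyped genotypes absent from the covariance panel: "
                f"{sorted(missing)[:5]}"
            )
    Z = (gen.to_numpy()[:, None] == np.array(genotype_ids)).astype(float)
    y = data["value"].to_numpy(dtype=float)
    return DesignMatrices(
        X=X, Z=Z, y=y, fixed_names=names, genotype_ids=list(genotype_ids),
        n_dropped=n_dropped, Z_blocks=z_blocks, block_ids=block_ids,
        n_obs_per_genotype=Z.sum(axis=0),
    )


# ---------------------------------------------------------------------- #
# variance components
# ---------------------------------------------------------------------- #
@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    sigma2_blocks: float | None = None
    converged: bool = False
    boundary: bool = False
    n_iterations: int = 0
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def total(self) -> float:
        extra = self.sigma2_blocks or 0.0
        return self.sigma2_g + extra + self.sigma2_e


@dataclass
class FitResult:
    fixed_effects: pd.Series
    blups: pd.Series
    pev: pd.Series
    varcomp: VarianceComponents
    n_obs: int
    n_dropped: int = 0
    intercept: float = 0.0  # population-average fitted fixed part
    block_blups: pd.Series | None = None


def _reduce_covariance(K: np.ndarray | None, Z: np.ndarray,
                       rtol: float = 1e-12
                       ) -> tuple[np.ndarray, np.ndarray, float, np.ndarray | None]:
    """Represent the random term in the eigenspace of its covariance.

    Returns ``(Z_t, Kinv_t, logdet_t, T)`` where ``Z_t = Z T`` and the
    effect in original coordinates is ``u = T u_t``.  Eigenvectors with
    (near-)zero eigenvalue are dropped, which handles exactly singular
    kinships — the VanRaden GRM always has a null direction from centring —
    without a ridge and keeps the GBLUP/RR-BLUP equivalence exact.  For
    ``K=None`` (identity covariance) the term is left untouched.
    """
    q = Z.shape[1]
    if K is None:
        return Z, np.eye(q), 0.0, None
    K = np.asarray(K, dtype=float)
    if K.shape != (q, q):
        raise InputDataError(f"covariance must be {q}x{q}, got {K.shape}")
    w, v = np.linalg.eigh(K)
    keep = w > rtol * max(w.max(), 0.0)
    if not keep.any():
        raise NumericalError("genotype covariance has no positive eigenvalues")
    w = w[keep]
    T = v[:, keep]
    return Z @ T, np.diag(1.0 / w), float(np.sum(np.log(w))), T


def _assemble(X, y, terms):
    """Precompute cross-products for A = [X, Z_1, ..., Z_k]."""
    A = np.hstack([X] + [Z for Z, _, _ in terms])
    AtA = A.T @ A
    Aty = A.T @ y
    return AtA, Aty, float(y @ y)


def _mme_solve(AtA, Aty, yty, n, p, terms, sigma2s, sigma2_e):
    """One MME solve; returns solution, full inverse, restricted loglik."""
    M = AtA.copy()
    offset = p
    for (Z, Kinv, _), s2 in zip(terms, sigma2s):
        q = Z.shape[1]
        lam = sigma2_e / max(s2, VAR_FLOOR)
        M[offset:offset + q, offset:offset + q] += lam * Kinv
        offset += q
    try:
        cho = linalg.cho_factor(M, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-8 * np.trace(M) / M.shape[0]
        try:
            cho = linalg.cho_factor(M + jitter * np.eye(M.shape[0]), lower=True)
        except linalg.LinAlgError as err:
            raise NumericalError(
                "mixed-model coefficient matrix is singular "
                f"(condition number ~{np.linalg.cond(M):.3g})"
            ) from err
    sol = linalg.cho_solve(cho, Aty)
    Minv = linalg.cho_solve(cho, np.eye(M.shape[0]))
    logdet_M = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))

    # restricted loglik from MME byproducts
    q_tot = sum(Z.shape[1] for Z, _, _ in terms)
    ln_R = n * np.log(sigma2_e)
    ln_G = sum(
        Z.shape[1] * np.log(max(s2, VAR_FLOOR)) + logdetK
        for (Z, _, logdetK), s2 in zip(terms, sigma2s)
    )
    ln_Cfull = logdet_M - (p + q_tot) * np.log(sigma2_e)
    ypy = (yty - sol @ Aty) / sigma2_e
    minus2l = ln_R + ln_G + ln_Cfull + ypy
    loglik = -0.5 * (minus2l + (n - p) * np.log(2.0 * np.pi))
    return sol, Minv, float(loglik)


def reml_fit(X: np.ndarray, Z: np.ndarray, y: np.ndarray,
             K: np.ndarray | None = None, Z_blocks: np.ndarray | None = None,
             tol: float = 1e-8, max_iter: int = 500) -> VarianceComponents:
    """EM-REML for y ~ N(Xb, sigma2_g ZKZ' [+ sigma2_b Z_b Z_b'] + sigma2_e I).

    Iterates Henderson-based EM updates until the largest relative parameter
    change falls below ``tol`` (or ``max_iter``); variances are floored at
    1e-10 and a fit finishing on the floor is flagged as boundary
    convergence.  The returned trace of restricted log-likelihoods is
    nondecreasing, as EM guarantees.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n <= p + 1:
        raise InputDataError(
            f"need more observations ({n}) than fixed-effect rank + 1 ({p + 1})"
        )
    Z_t, Kinv, logdetK, _ = _reduce_covariance(K, Z)
    terms = [(Z_t, Kinv, logdetK)]
    if Z_blocks is not None:
        qb = Z_blocks.shape[1]
        terms.append((np.asarray(Z_blocks, float), np.eye(qb), 0.0))

    AtA, Aty, yty = _assemble(X, y, terms)
    vary = float(np.var(y))
    start = max(vary / (len(terms) + 1), VAR_FLOOR)
    sigma2s = [start] * len(terms)
    sigma2_e = start

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sol, Minv, loglik = _mme_solve(AtA, Aty, yty, n, p, terms, sigma2s, sigma2_e)
        trace.append(loglik)
        # EM is monotone in the restricted likelihood, so a vanishing
        # increment is a sound stopping rule (it also catches the slow
        # geometric crawl toward a zero-variance boundary)
        if it > 1 and trace[-1] - trace[-2] < tol * max(1.0, abs(loglik)):
            converged = True
            break
        new_sigma2s = []
        offset = p
        for (Zi, Kinv_i, _), s2 in zip(terms, sigma2s):
            qi = Zi.shape[1]
            u = sol[offset:offset + qi]
            Cii = Minv[offset:offset + qi, offset:offset + qi]
            s2_new = (u @ Kinv_i @ u + sigma2_e * np.trace(Kinv_i @ Cii)) / qi
            new_sigma2s.append(max(float(s2_new), VAR_FLOOR))
            offset += qi
        s2e_new = max(float((yty - sol @ Aty) / (n - p)), VAR_FLOOR)
        rel = max(
            [abs(a - b) / max(b, VAR_FLOOR) for a, b in zip(new_sigma2s, sigma2s)]
            + [abs(s2e_new - sigma2_e) / max(sigma2_e, VAR_FLOOR)]
        )
        sigma2s, sigma2_e = new_sigma2s, s2e_new
        if rel < tol:
            converged = True
            break

    boundary = sigma2_e <= VAR_FLOOR or any(s2 <= VAR_FLOOR for s2 in sigma2s)
    if not converged:
        logger.warning("EM-REML stopped at max_iter=%d without converging", max_iter)
    return VarianceComponents(
        sigma2_g=sigma2s[0],
        sigma2_e=sigma2_e,
        sigma2_blocks=sigma2s[1] if len(sigma2s) > 1 else None,
        converged=converged,
        boundary=boundary,
        n_iterations=it,
        loglik_trace=trace,
    )


def solve_mme(X: np.ndarray, Z: np.ndarray, y: np.ndarray,
              K: np.ndarray | None, varcomp: VarianceComponents,
              Z_blocks: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Solve Henderson's equations at fixed variance components.

    Returns ``(beta, u, pev, u_blocks)`` where ``pev`` is the genotype block
    of sigma2_e * M^-1 (the prediction error variances).
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    n, p = X.shape
    Z_t, Kinv, logdetK, T = _reduce_covariance(K, Z)
    q_t = Z_t.shape[1]
    terms = [(Z_t, Kinv, logdetK)]
    sigma2s = [varcomp.sigma2_g]
    if Z_blocks is not None:
        if varcomp.sigma2_blocks is None:
            raise InputDataError("varcomp lacks a block variance for Z_blocks")
        qb = Z_blocks.shape[1]
        terms.append((np.asarray(Z_blocks, float), np.eye(qb), 0.0))
        sigma2s.append(varcomp.sigma2_blocks)
    AtA, Aty, yty = _assemble(X, y, terms)
    sol, Minv, _ = _mme_solve(AtA, Aty, yty, n, p, terms, sigma2s, varcomp.sigma2_e)
    beta = sol[:p]
    u_t = sol[p:p + q_t]
    C_uu = Minv[p:p + q_t, p:p + q_t]
    if T is None:
        u = u_t
        pev = varcomp.sigma2_e * np.diag(C_uu).copy()
    else:
        u = T @ u_t
        pev = varcomp.sigma2_e * np.einsum("ij,jk,ik->i", T, C_uu, T)
    u_blocks = sol[p + q_t:] if Z_blocks is not None else None
    return beta, u, pev, u_blocks


def heritability(varcomp: VarianceComponents) -> float:
    """Broad-sense heritability on a plot basis: genetic / total variance.

    Undefined (NaN) when every component converged to the boundary floor.
    """
    if varcomp.sigma2_g <= VAR_FLOOR and varcomp.sigma2_e <= VAR_FLOOR:
        logger.warning("heritability undefined: all variance components at boundary")
        return float("nan")
    return varcomp.sigma2_g / varcomp.total


def reliability(pev: np.ndarray | pd.Series, sigma2_g: float
                ) -> np.ndarray | pd.Series:
    """Per-genotype BLUP reliability 1 - PEV/sigma2_g, clipped to [0, 1].

    With no genetic variance the reliability is reported as 0.
    """
    if sigma2_g <= VAR_FLOOR:
        logger.warning("reliability undefined at sigma2_g=0; reporting zeros")
        return pev * 0.0
    return np.clip(1.0 - pev / sigma2_g, 0.0, 1.0)


def reml_loglik_dense(X: np.ndarray, y: np.ndarray, V: np.ndarray) -> float:
    """Restricted log-likelihood via the dense covariance V (reference path).

    Kept deliberately independent of the MME route so tests can use it as an
    oracle for the EM objective.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    cv = linalg.cho_factor(V, lower=True)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cv[0]))))
    Vi_X = linalg.cho_solve(cv, X)
    Vi_y = linalg.cho_solve(cv, y)
    XtViX = X.T @ Vi_X
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    yPy = float(r @ linalg.cho_solve(cv, r))
    return -0.5 * (logdet_V + logdet_XtViX + yPy + (n - p) * np.log(2.0 * np.pi))


# ---------------------------------------------------------------------- #
# estimator
# ---------------------------------------------------------------------- #
class MixedModel(BaseEstimator):
    """Genotype-BLUP mixed model for one trait of a screening trial.

    Parameters
    ----------
    scope : {"sea", "across", "mea"}
        Which model layer to fit: one experiment+condition, the joined
        experiments of one condition, or everything with an environment
        (condition) contrast.
    kinship : GenomicRelationshipMatrix, DataFrame or None
        Genotype covariance; ``None`` means identity (phenotypic BLUPs),
        a GRM turns the fit into GBLUP and extends predictions to every
        genotype in the panel.
    blocks : {"fixed", "random", "none"}
        Incomplete blocks as fixed effects (default, matching the screening
        model), as an extra i.i.d. random term, or omitted.
    tol, max_iter : EM-REML convergence controls.

    Fitted attributes (per scikit-learn convention) include ``varcomp_``,
    ``blups_``, ``pev_``, ``heritability_``, ``reliabilities_``,
    ``reliability_`` (mean over phenotyped genotypes), ``fixed_effects_``
    and ``intercept_`` (the population-average fitted fixed part used to
    recentre predictions onto the trait scale).
    """

    def __init__(self, scope: str = "sea", kinship=None, blocks: str = "fixed",
                 tol: float = 1e-8, max_iter: int = 500):
        self.scope = scope
        self.kinship = kinship
        self.blocks = blocks
        self.tol = tol
        self.max_iter = max_iter

    def _kinship_parts(self):
        if self.kinship is None:
            return None, None
        if isinstance(self.kinship, GenomicRelationshipMatrix):
            return list(self.kinship.genotype_ids), self.kinship.values
        if isinstance(self.kinship, pd.DataFrame):
            return [str(g) for g in self.kinship.index], self.kinship.to_numpy(float)
        raise InputDataError("kinship must be a GenomicRelationshipMatrix or DataFrame")

    def fit(self, table: pd.DataFrame, y=None) -> "MixedModel":
        kin_ids, K = self._kinship_parts()
        design = build_design(
            table, scope=self.scope, genotype_ids=kin_ids, blocks=self.blocks
        )
        varcomp = reml_fit(
            design.X, design.Z, design.y, K=K, Z_blocks=design.Z_blocks,
            tol=self.tol, max_iter=self.max_iter,
        )
        beta, u, pev, u_blocks = solve_mme(
            design.X, design.Z, design.y, K, varcomp, Z_blocks=design.Z_blocks
        )
        gids = design.genotype_ids
        self.design_ = design
        self.varcomp_ = varcomp
        self.fixed_effects_ = pd.Series(beta, index=design.fixed_names)
        self.blups_ = pd.Series(u, index=gids, name="blup")
        self.pev_ = pd.Series(pev, index=gids, name="pev")
        self.block_blups_ = (
            pd.Series(u_blocks, index=design.block_ids) if u_blocks is not None else None
        )
        self.intercept_ = float(np.mean(design.X @ beta))
        self.heritability_ = heritability(varcomp)
        rel = reliability(self.pev_, varcomp.sigma2_g)
        self.reliabilities_ = rel
        observed = design.n_obs_per_genotype > 0
        self.reliability_ = float(rel[observed].mean()) if observed.any() else float("nan")
        self.n_obs_ = len(design.y)
        self.n_dropped_ = design.n_dropped
        self.converged_ = varcomp.converged
        self.loglik_trace_ = varcomp.loglik_trace
        self.genotype_ids_ = gids
        return self

    def predict(self, genotype_ids=None) -> pd.Series:
        """Genotype merit on the trait scale: intercept + BLUP."""
        values = self.intercept_ + self.blups_
        if genotype_ids is not None:
            values = values.reindex([str(g) for g in genotype_ids])
        return values

    def fit_report(self) -> pd.DataFrame:
        """One row per genotype: BLUP, PEV, reliability, prediction."""
        return pd.DataFrame(
            {
                "blup": self.blups_,
                "pev": self.pev_,
                "reliability": self.reliabilities_,
                "predicted_value": self.predict(),
            }
        ).rename_axis("genotype")
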