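"""GBLUP genomic prediction: REML variance components and mixed-model
equations for the model

    y = Xb + Zg + Ww + Z1 Q q + e,

with g ~ N(0, G sigma2_g) structured by a genomic relationship matrix,
maternal effects w ~ N(0, I sigma2_w), breed effects q ~ N(0, I sigma2_q)
entering through breed proportions Q, and residuals e ~ N(0, I sigma2_e).

`GenomicMixedModel` follows the statsmodels convention: construct from
data (``from_dataframes`` builds the design), ``fit()`` runs AI-REML
(average-information updates with EM fallback when an update leaves the
parameter space) and returns a `GenomicMixedModelResults` carrying the
variance components, fixed-effect solutions, GEBVs and a ``summary()``
table. When the model has a single genomic term the REML iterations run
in the eigenbasis of ZGZ', which gives identical estimates at a fraction
of the cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import GRM

__all__ = [
    "RandomTerm",
    "MixedModelSpec",
    "VarianceComponents",
    "GenomicMixedModel",
    "GenomicMixedModelResults",
    "build_design",
    "solve_mme",
    "gebv_accuracy",
    "matrix_correlation",
]


@dataclass
class RandomTerm:
    """One random effect: u ~ N(0, K sigma2), entering as Z u."""

    name: str
    Z: np.ndarray          # (n, q) incidence / covariate matrix
    K: np.ndarray | None   # (q, q) covariance structure; None = identity
    labels: list           # length q, names of the effect levels

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]

    def ZKZt(self) -> np.ndarray:
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


@dataclass
class MixedModelSpec:
    y: np.ndarray
    X: np.ndarray
    x_names: list
    terms: list  # of RandomTerm

    def __post_init__(self):
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match y")
        for t in self.terms:
            if t.Z.shape[0] != n:
                raise ValueError(f"term {t.name}: Z row count does not match y")


@dataclass
class VarianceComponents:
    components: dict            # name -> sigma2 (includes "residual")
    converged: bool
    loglik: float
    n_iter: int
    boundary: list = field(default_factory=list)

    def __getitem__(self, name):
        return self.components[name]


# ---------------------------------------------------------------------------
# design construction

CLASS_FACTORS = ("birth_type", "rearing_type", "sex")
COVARIATES = ("age", "weight")


def _full_rank(X: np.ndarray, names: list) -> tuple[np.ndarray, list]:
    """Drop linearly dependent columns (QR with column pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    return X[:, keep], [names[i] for i in keep]


def build_design(
    phenotypes: pd.DataFrame,
    grm: GRM,
    pedigree: pd.DataFrame | None = None,
    include_maternal: bool = False,
    include_breed: str = "auto",
) -> MixedModelSpec:
    """Build y, X and the random-effect structure from tidy tables.

    Fixed effects: intercept, birth type, rearing type, sex and
    contemporary group (flock x birth year x management group) as class
    factors with reference-level coding, age and weight as centered
    covariates; the design is reduced to full column rank. The additive
    term relates each phenotype row to its animal in the GRM. The breed
    term uses breed-proportion columns ``prop_*`` of ``pedigree`` and is
    fitted only when more than one breed is represented (``include_breed
    = "auto"``); the maternal term uses known dams.
    """
    df = phenotypes.reset_index(drop=True)
    missing = [c for c in ("id", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    n = len(df)
    y = df["y"].to_numpy(dtype=float)

    cols = [np.ones(n)]
    names = ["intercept"]
    cg = (
        df["flock"].astype(str)
        + "_"
        + df["birth_year"].astype(str)
        + "_"
        + df.get("mgmt_group", pd.Series(["1"] * n)).astype(str)
    )
    factors = {f: df[f] for f in CLASS_FACTORS if f in df.columns}
    factors["contemporary_group"] = cg
    for fac, series in factors.items():
        levels = sorted(pd.unique(series.astype(str)))
        for lv in levels[1:]:  # reference coding: first level absorbed
            cols.append((series.astype(str) == lv).to_numpy(dtype=float))
            names.append(f"{fac}[{lv}]")
    for cov in COVARIATES:
        if cov in df.columns:
            v = df[cov].to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(cov)
    X = np.column_stack(cols)
    X, names = _full_rank(X, names)

    g_ids = list(grm.ids)
    pos = {v: i for i, v in enumerate(g_ids)}
    unknown = [i for i in df["id"] if i not in pos]
    if unknown:
        raise ValueError(f"phenotyped animals missing from the GRM: {unknown[:5]}")
    Z = np.zeros((n, len(g_ids)))
    for r_, ident in enumerate(df["id"]):
        Z[r_, pos[ident]] = 1.0
    terms = [RandomTerm("additive", Z, grm.values, g_ids)]

    if include_maternal:
        dams = df.get("dam_id")
        if dams is None or dams.isna().all():
            warnings.warn("no dam information: maternal term dropped")
        else:
            known = sorted({d for d in dams if d is not None and not pd.isna(d)})
            W = np.zeros((n, len(known)))
            dpos = {d: j for j, d in enumerate(known)}
            for r_, d in enumerate(dams):
                if d is not None and not pd.isna(d):
                    W[r_, dpos[d]] = 1.0
            terms.append(RandomTerm("maternal", W, None, known))

    if include_breed in ("auto", True) and pedigree is not None:
        prop_cols = [c for c in pedigree.columns if c.startswith("prop_")]
        ped = pedigree.set_index("id")
        Q = np.array(
            [[float(ped.loc[i, c]) for c in prop_cols] for i in df["id"]]
        )
        varying = Q.std(axis=0) > 0
        if varying.sum() >= 2 or include_breed is True:
            Q = Q[:, varying] if varying.any() else Q
            kept = [c[5:] for c, v in zip(prop_cols, varying) if v] or [
                c[5:] for c in prop_cols
            ]
            terms.append(RandomTerm("breed", Q, None, kept))
        # single-breed data: Z1Q is constant and confounded with the intercept

    return MixedModelSpec(y, X, names, terms)


# ---------------------------------------------------------------------------
# REML

_FLOOR_FRAC = 1e-8


def _em_update(theta, q_sizes, ypvpy, trpv):
    new = theta.copy()
    for i in range(len(theta)):
        new[i] = theta[i] + (theta[i] ** 2 / q_sizes[i]) * (ypvpy[i] - trpv[i])
    return new


def _reml_dense(y, X, Vs, q_sizes, theta0, floor, maxiter, tol):
    """AI-REML on explicit covariance contributions Vs (last one = I)."""
    n, p = X.shape
    theta = np.array(theta0, dtype=float)
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        V = sum(t * Vi for t, Vi in zip(theta, Vs))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            V = V + np.eye(n) * (np.trace(V) / n * 1e-8)
            L = np.linalg.cholesky(V)
        Vinv = np.linalg.inv(V)
        XtVinv = X.T @ Vinv
        XtVinvX = XtVinv @ X
        Cinv = np.linalg.inv(XtVinvX)
        P = Vinv - XtVinv.T @ Cinv @ XtVinv
        Py = P @ y
        new_ll = -0.5 * (
            2 * np.sum(np.log(np.diag(L)))
            + np.linalg.slogdet(XtVinvX)[1]
            + float(y @ Py)
        )
        ypvpy = np.array([float(Py @ Vi @ Py) for Vi in Vs])
        trpv = np.array([float(np.sum(P * Vi)) for Vi in Vs])
        score = 0.5 * (ypvpy - trpv)
        t_vecs = [Vi @ Py for Vi in Vs]
        Pt = [P @ tv for tv in t_vecs]
        k = len(theta)
        ai = np.empty((k, k))
        for a in range(k):
            for b in range(k):
                ai[a, b] = 0.5 * float(t_vecs[a] @ Pt[b])
        try:
            cand = theta + np.linalg.solve(ai, score)
            if not np.all(np.isfinite(cand)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cand = _em_update(theta, q_sizes, ypvpy, trpv)
        # components the update drives out of the parameter space are
        # pinned at the boundary floor (and flagged by the caller)
        cand = np.maximum(cand, floor)
        rel = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
        theta = cand
        loglik = new_ll
        if rel < tol:
            converged = True
            break
    return theta, loglik, converged, it


def _reml_spectral(y, X, A, floor, maxiter, tol):
    """AI-REML for V = theta_g * A + theta_e * I in the eigenbasis of A."""
    d, U = np.linalg.eigh(A)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ X
    n, p = Xt.shape
    vy = float(np.var(y))
    theta = np.array([vy / 2, vy / 2])
    loglik = -np.inf
    converged = False
    it = 0
    d_list = [d, np.ones(n)]
    q_sizes = [n, n]
    for it in range(1, maxiter + 1):
        w = 1.0 / (theta[0] * d + theta[1])
        XtW = Xt * w[:, None]
        C = Xt.T @ XtW
        beta = np.linalg.solve(C, XtW.T @ yt)
        r = yt - Xt @ beta
        Py = w * r
        new_ll = -0.5 * (
            -np.sum(np.log(w)) + np.linalg.slogdet(C)[1] + float(r @ Py)
        )

        def P_apply(v):
            return w * v - XtW @ np.linalg.solve(C, XtW.T @ v)

        ypvpy = np.array([float(Py @ (dv * Py)) for dv in d_list])
        trpv = []
        Cinv = np.linalg.inv(C)
        for dv in d_list:
            tr = float(np.sum(w * dv)) - float(np.sum(Cinv * (XtW.T @ (dv[:, None] * XtW))))
            trpv.append(tr)
        trpv = np.array(trpv)
        score = 0.5 * (ypvpy - trpv)
        t_vecs = [dv * Py for dv in d_list]
        ai = np.empty((2, 2))
        for a in range(2):
            pa = P_apply(t_vecs[a])
            for b in range(2):
                ai[a, b] = 0.5 * float(t_vecs[b] @ pa)
        try:
            cand = theta + np.linalg.solve(ai, score)
            if not np.all(np.isfinite(cand)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cand = _em_update(theta, q_sizes, ypvpy, trpv)
        cand = np.maximum(cand, floor)
        rel = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
        theta = cand
        loglik = new_ll
        if rel < tol:
            converged = True
            break
    return theta, loglik, converged, it


def reml_estimate(
    spec: MixedModelSpec, maxiter: int = 200, tol: float = 1e-6
) -> VarianceComponents:
    """Estimate variance components by AI-REML.

    Average-information updates; an EM-REML step is substituted when the
    AI system is singular, and components an update drives out of the
    parameter space are pinned at the lower boundary (1e-8 of the
    phenotypic variance) and flagged. Convergence: max relative parameter
    change below ``tol`` (default 1e-6) or ``maxiter`` rounds;
    non-convergence is flagged, never silent.
    """
    n, p = spec.X.shape
    if n <= p:
        raise ValueError("more fixed-effect columns than records")
    vy = float(np.var(spec.y))
    floor = _FLOOR_FRAC * vy
    names = [t.name for t in spec.terms] + ["residual"]
    if len(spec.terms) == 1:
        A = spec.terms[0].ZKZt()
        theta, ll, conv, it = _reml_spectral(spec.y, spec.X, A, floor, maxiter, tol)
    else:
        Vs = [t.ZKZt() for t in spec.terms] + [np.eye(n)]
        k = len(Vs)
        theta0 = np.full(k, vy / k)
        q_sizes = [t.n_levels for t in spec.terms] + [n]
        theta, ll, conv, it = _reml_dense(
            spec.y, spec.X, Vs, q_sizes, theta0, floor, maxiter, tol
        )
    if not conv:
        warnings.warn(f"REML did not converge in {maxiter} iterations")
    boundary = [nm for nm, t in zip(names, theta) if t <= floor * (1 + 1e-6)]
    return VarianceComponents(dict(zip(names, theta)), conv, float(ll), it, boundary)


# ---------------------------------------------------------------------------
# mixed-model equations

def solve_mme(
    spec: MixedModelSpec, components: VarianceComponents
) -> tuple[pd.Series, dict]:
    """Solve Henderson's mixed-model equations.

    Returns the fixed-effect solutions and a dict of random-effect
    solution Series per term (the additive term's solutions are the
    GEBVs). Terms whose variance sits on the boundary are dropped.
    """
    sig_e = components["residual"]
    active = [
        t for t in spec.terms if components[t.name] > 0 and t.name not in components.boundary
    ]
    X = spec.X
    blocks = [X] + [t.Z for t in active]
    C = np.block(
        [[a.T @ b for b in blocks] for a in blocks]
    )
    rhs = np.concatenate([b.T @ spec.y for b in blocks])
    off = X.shape[1]
    for t in active:
        lam = sig_e / components[t.name]
        q = t.n_levels
        if t.K is None:
            Kinv = np.eye(q)
        else:
            try:
                np.linalg.cholesky(t.K)
                Kinv = np.linalg.inv(t.K)
            except np.linalg.LinAlgError:
                # singular covariance: ridge just enough to invert
                K = t.K + np.eye(q) * 1e-8 * np.trace(t.K) / q
                Kinv = np.linalg.inv(K)
        C[off : off + q, off : off + q] += Kinv * lam
        off += q
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError:
        rank = np.linalg.matrix_rank(C)
        raise np.linalg.LinAlgError(
            f"singular MME coefficient matrix (rank {rank} of {C.shape[0]})"
        )
    fixed = pd.Series(sol[: X.shape[1]], index=spec.x_names, name="estimate")
    out = {}
    off = X.shape[1]
    for t in active:
        out[t.name] = pd.Series(sol[off : off + t.n_levels], index=t.labels, name=t.name)
        off += t.n_levels
    return fixed, out


# ---------------------------------------------------------------------------
# model / results objects

class GenomicMixedModel:
    """GBLUP mixed model; construct via ``from_dataframes`` or from a spec."""

    def __init__(self, spec: MixedModelSpec):
        self.spec = spec

    @classmethod
    def from_dataframes(
        cls,
        phenotypes: pd.DataFrame,
        grm: GRM,
        pedigree: pd.DataFrame | None = None,
        include_maternal: bool = False,
        include_breed: str = "auto",
    ) -> "GenomicMixedModel":
        return cls(
            build_design(phenotypes, grm, pedigree, include_maternal, include_breed)
        )

    def fit(self, maxiter: int = 200, tol: float = 1e-6) -> "GenomicMixedModelResults":
        comps = reml_estimate(self.spec, maxiter=maxiter, tol=tol)
        fixed, random_sol = solve_mme(self.spec, comps)
        return GenomicMixedModelResults(self, comps, fixed, random_sol)


@dataclass
class GenomicMixedModelResults:
    model: GenomicMixedModel
    varcomp: VarianceComponents
    fixed_effects: pd.Series
    random_solutions: dict

    @property
    def gebv(self) -> pd.Series:
        """Genomic estimated breeding values (additive-term solutions).

        When the additive variance sits on the boundary the term is
        dropped from the equations and the GEBVs are all zero (the
        complete-shrinkage limit)."""
        if "additive" in self.random_solutions:
            return self.random_solutions["additive"]
        term = next(t for t in self.model.spec.terms if t.name == "additive")
        return pd.Series(np.zeros(term.n_levels), index=term.labels, name="additive")

    @property
    def heritability(self) -> float:
        c = self.varcomp.components
        return c.get("additive", 0.0) / sum(c.values())

    def summary(self) -> str:
        lines = ["Genomic mixed model (GBLUP) — REML", "=" * 44]
        lines.append(f"records: {len(self.model.spec.y)}  "
                     f"fixed-effect columns: {self.model.spec.X.shape[1]}")
        lines.append(f"converged: {self.varcomp.converged}  "
                     f"iterations: {self.varcomp.n_iter}  "
                     f"logL: {self.varcomp.loglik:.3f}")
        lines.append("-" * 44)
        lines.append(f"{'variance component':<26}{'estimate':>12}")
        for name, v in self.varcomp.components.items():
            flag = " (boundary)" if name in self.varcomp.boundary else ""
            lines.append(f"{name:<26}{v:>12.5f}{flag}")
        lines.append(f"{'h2 (additive / total)':<26}{self.heritability:>12.4f}")
        lines.append("-" * 44)
        lines.append(f"{'fixed effect':<26}{'estimate':>12}")
        for name, v in self.fixed_effects.items():
            lines.append(f"{name:<26}{v:>12.5f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# evaluation statistics

def gebv_accuracy(gebv: pd.Series, validation_ebvs: list) -> tuple[float, int]:
    """Pearson r between GEBVs and progeny-test EBVs on the validation
    intersection; returns (r, intersection size)."""
    reported = {r.id: r.reported_ebv for r in validation_ebvs}
    common = [i for i in gebv.index if i in reported]
    if len(common) < 3:
        raise ValueError("need at least three validation animals with both values")
    a = gebv.loc[common].to_numpy(dtype=float)
    b = np.array([reported[i] for i in common])
    return float(np.corrcoef(a, b)[0, 1]), len(common)


def matrix_correlation(a, b) -> float:
    """Pearson correlation between two GRMs (vectorised upper triangle,
    diagonal included) or two aligned GEBV Series."""
    if isinstance(a, GRM) and isinstance(b, GRM):
        if list(a.ids) != list(b.ids):
            raise ValueError("GRM id sets/order differ")
        iu = np.triu_indices(len(a.ids))
        va, vb = a.values[iu], b.values[iu]
    elif isinstance(a, pd.Series) and isinstance(b, pd.Series):
        if list(a.index) != list(b.index):
            raise ValueError("GEBV id sets/order differ")
        va, vb = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    else:
        raise TypeError("arguments must be two GRMs or two GEBV Series")
    return float(np.corrcoef(va, vb)[0, 1])
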