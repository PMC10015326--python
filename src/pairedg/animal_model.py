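"""Multivariate mixed-model REML with pedigree-based additive effects.

The model for the stacked (trait-major) phenotype vector is

    y = X b + Z_v v + Z_a u + e

with var(u) = G (x) A over pedigree individuals, var(v) = V (x) I over vials
and var(e) = R (x) I over records, where A is the numerator relationship
matrix.  Because every phenotyped individual carries a complete trait vector,
the marginal covariance collapses to

    var(y) = G (x) A_mm  +  V (x) W  +  R (x) I_n

with ``A_mm`` the measured-individual block of A and ``W`` the same-vial
indicator.  Estimation is average-information REML on the covariance-element
("G-") scale: AI quasi-Newton steps with an Armijo line search (the restricted
log-likelihood never decreases), leaving individual component matrices free to
wander as long as var(y) stays positive-definite.  If the unconstrained
optimum has a component outside the PSD cone, the fit is re-polished by
quasi-Newton on Cholesky-style factors, which enforces the constraint exactly.
The AI matrix at the optimum (on the covariance scale) is returned for
downstream REML-MVN sampling.

Reduced-rank fits reparameterize G = Lambda Lambda' with a lower-triangular
t x r factor and maximize the same restricted likelihood with the factor-scale
driver, for likelihood-ratio tests of matrix rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "GEstimate",
    "RankLRT",
    "REMLError",
    "ConvergenceError",
    "fit_reml",
    "fit_reduced_rank",
    "rank_lrt",
    "g_param_count",
]


class REMLError(RuntimeError):
    pass


class ConvergenceError(REMLError):
    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: traits, fixed factors, random terms and data subset."""

    traits: tuple[str, ...]
    fixed: tuple[str, ...] = ("generation", "observer")
    include_vial: bool = True
    vial_diagonal: bool = False
    arm: str | None = None
    tol: float = 1e-8
    max_iter: int = 200

    def __post_init__(self) -> None:
        if len(self.traits) < 1:
            raise ValueError("at least one trait required")


@dataclass
class GEstimate:
    """REML estimates with the average-information matrix at the optimum.

    ``manifest`` lists, in order, the (component, row, col) identity of every
    element of the stacked parameter vector that the AI matrix refers to;
    components are 'G', 'V', 'R'.
    """

    G: np.ndarray
    V: np.ndarray | None
    R: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    ai: np.ndarray
    manifest: list[tuple[str, int, int]]
    traits: list[str]
    n_records: int
    rank: int | None = None
    history: list[float] = field(default_factory=list)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_params_g(self) -> int:
        t = self.n_traits
        r = self.rank if self.rank is not None else t
        return g_param_count(t, r)

    def theta(self) -> np.ndarray:
        """Stacked covariance parameters in manifest order."""
        mats = {"G": self.G, "V": self.V, "R": self.R}
        return np.array([mats[c][i, j] for c, i, j in self.manifest])

    def ai_inverse(self) -> np.ndarray:
        """Approximate sampling covariance of the parameter estimates."""
        try:
            return np.linalg.inv(self.ai)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise REMLError(
                "AI matrix is singular (estimate may sit on a boundary); "
                "consider a ridge or a reduced model"
            ) from exc

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "G": self.G.tolist(),
            "V": None if self.V is None else self.V.tolist(),
            "R": self.R.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_records": self.n_records,
            "rank": self.rank,
            "ai": self.ai.tolist(),
            "manifest": [list(m) for m in self.manifest],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GEstimate":
        return cls(
            G=np.array(d["G"]),
            V=None if d["V"] is None else np.array(d["V"]),
            R=np.array(d["R"]),
            loglik=d["loglik"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            ai=np.array(d["ai"]),
            manifest=[tuple(m) for m in d["manifest"]],
            traits=list(d["traits"]),
            n_records=d["n_records"],
            rank=d.get("rank"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def matrices_to_csv(self, directory: str | Path, prefix: str = "") -> None:
        """Write G/V/R as trait-labelled CSV files into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, C in (("G", self.G), ("V", self.V), ("R", self.R)):
            if C is None:
                continue
            pd.DataFrame(C, index=self.traits, columns=self.traits).to_csv(
                directory / f"{prefix}{name}.csv"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GEstimate":
        return cls.from_dict(json.loads(Path(path).read_text()))


def g_param_count(t: int, r: int) -> int:
    """Free parameters of a rank-r factor-analytic t x t covariance."""
    if r > t:
        raise ValueError(f"rank {r} exceeds trait count {t}")
    return t * r - r * (r - 1) // 2


# ---------------------------------------------------------------------------
# data preparation


def _design_matrix(df: pd.DataFrame, fixed: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for factor in fixed:
        if factor not in df.columns:
            continue
        levels = pd.Categorical(df[factor].astype(str))
        if len(levels.categories) < 2:
            continue
        dummies = pd.get_dummies(levels, drop_first=True, dtype=float)
        for lv in dummies.columns:
            cols.append(dummies[lv].to_numpy())
            names.append(f"{factor}[{lv}]")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, _, piv = linalg.qr(x, mode="economic", pivoting=True)
        aliased = sorted(names[k] for k in piv[rank:])
        raise REMLError(f"singular fixed-effects design; aliased levels: {aliased}")
    return x, names


class _Problem:
    """Marginal-likelihood machinery shared by full- and reduced-rank fits."""

    def __init__(
        self,
        phenotypes: pd.DataFrame,
        A: RelationshipMatrix,
        spec: ModelSpec,
    ):
        df = phenotypes
        if spec.arm is not None:
            df = df[df["arm"] == spec.arm]
        df = df.reset_index(drop=True)
        if df.empty:
            raise REMLError("no phenotype records after arm filtering")
        if df["id"].duplicated().any():
            raise REMLError("one phenotype record per individual is required")
        for tr in spec.traits:
            if tr not in df.columns:
                raise REMLError(f"trait column {tr!r} missing from phenotype table")
        Y = df[list(spec.traits)].to_numpy(dtype=float)
        if not np.all(np.isfinite(Y)):
            raise REMLError("missing or non-finite trait values are not supported")

        self.spec = spec
        self.t = len(spec.traits)
        self.n = len(df)
        self.Y = Y
        self.y = Y.T.reshape(-1)  # trait-major stack
        self.X0, self.fixed_names = _design_matrix(df, spec.fixed)
        ids = df["id"].astype(str).tolist()
        try:
            A_mm = A.submatrix(ids)
        except KeyError as exc:
            raise REMLError(f"phenotyped individual missing from A: {exc}") from exc

        self.terms: list[tuple[str, np.ndarray]] = [("G", A_mm)]
        if spec.include_vial:
            if "vial" not in df.columns:
                raise REMLError("include_vial=True but no 'vial' column present")
            codes = pd.Categorical(df["vial"].astype(str)).codes
            W = (codes[:, None] == codes[None, :]).astype(float)
            self.terms.append(("V", W))
        self.terms.append(("R", np.eye(self.n)))

        # manifest: which covariance elements are free parameters
        self.manifest: list[tuple[str, int, int]] = []
        for name, _ in self.terms:
            diag_only = name == "V" and spec.vial_diagonal
            for i in range(self.t):
                for j in range(i, self.t):
                    if diag_only and i != j:
                        continue
                    self.manifest.append((name, i, j))

        self.X = np.kron(np.eye(self.t), self.X0)
        # scale for PSD floors and convergence heuristics
        resid = Y - self.X0 @ np.linalg.lstsq(self.X0, Y, rcond=None)[0]
        self.S0 = np.atleast_2d(np.cov(resid, rowvar=False))
        self.scale = float(np.mean(np.diag(self.S0)))
        self.floor = 1e-9 * self.scale

    # -- matrices <-> parameter vector ---------------------------------

    def start_values(self) -> dict[str, np.ndarray]:
        S = self.S0
        if self.spec.include_vial:
            V0 = np.diag(np.diag(S)) / 6.0 if self.spec.vial_diagonal else S / 6.0
            return {"G": S / 3.0, "V": V0, "R": S / 2.0}
        return {"G": S / 3.0, "R": 2.0 * S / 3.0}

    def project_psd(self, C: np.ndarray) -> np.ndarray:
        C = 0.5 * (C + C.T)
        w, v = np.linalg.eigh(C)
        if w.min() >= self.floor:
            return C
        w = np.clip(w, self.floor, None)
        return (v * w) @ v.T

    def assemble(self, mats: dict[str, np.ndarray]) -> np.ndarray:
        t, n = self.t, self.n
        Vy = np.zeros((t * n, t * n))
        for name, M in self.terms:
            C = mats[name]
            for r in range(t):
                for s in range(r, t):
                    c = C[r, s]
                    if c == 0.0:
                        continue
                    Vy[r * n : (r + 1) * n, s * n : (s + 1) * n] += c * M
        # mirror upper blocks to lower
        for r in range(t):
            for s in range(r + 1, t):
                Vy[s * n : (s + 1) * n, r * n : (r + 1) * n] = Vy[
                    r * n : (r + 1) * n, s * n : (s + 1) * n
                ].T
        return Vy

    # -- likelihood, gradient, AI --------------------------------------

    def evaluate(self, mats: dict[str, np.ndarray], want_ai: bool = True):
        t, n = self.t, self.n
        Vy = self.assemble(mats)
        cho = linalg.cho_factor(Vy, lower=True, overwrite_a=True, check_finite=False)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        ViX = linalg.cho_solve(cho, self.X, check_finite=False)
        XtViX = self.X.T @ ViX
        choX = linalg.cho_factor(XtViX, lower=True, check_finite=False)
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(choX[0]))))
        Viy = linalg.cho_solve(cho, self.y, check_finite=False)
        XtViy = self.X.T @ Viy
        b = linalg.cho_solve(choX, XtViy, check_finite=False)
        Py = Viy - ViX @ b
        loglik = -0.5 * (logdet_v + logdet_x + float(self.y @ Py))

        Vinv = linalg.cho_solve(cho, np.eye(t * n), check_finite=False)
        P = Vinv - ViX @ linalg.cho_solve(choX, ViX.T, check_finite=False)
        U = Py.reshape(t, n)

        S_grads: dict[str, np.ndarray] = {}
        MU: dict[str, np.ndarray] = {}
        for name, M in self.terms:
            mu = U @ M  # (t, n); M symmetric
            MU[name] = mu
            Q = mu @ U.T
            TP = np.empty((t, t))
            for r in range(t):
                for s in range(t):
                    TP[r, s] = np.sum(P[r * n : (r + 1) * n, s * n : (s + 1) * n] * M)
            TPs = 0.5 * (TP + TP.T)
            S_grads[name] = -0.5 * (TPs - 0.5 * (Q + Q.T))

        grad = np.array(
            [
                S_grads[c][i, j] if i == j else 2.0 * S_grads[c][i, j]
                for c, i, j in self.manifest
            ]
        )

        ai = None
        if want_ai:
            K = len(self.manifest)
            F = np.zeros((t * n, K))
            for k, (c, i, j) in enumerate(self.manifest):
                F[i * n : (i + 1) * n, k] += MU[c][j]
                if i != j:
                    F[j * n : (j + 1) * n, k] += MU[c][i]
            PF = P @ F
            ai = 0.5 * (F.T @ PF)
            ai = 0.5 * (ai + ai.T)
        return loglik, grad, ai, S_grads

    def apply_delta(
        self, mats: dict[str, np.ndarray], delta: np.ndarray, step: float
    ) -> dict[str, np.ndarray]:
        new = {name: mats[name].copy() for name in mats}
        for k, (c, i, j) in enumerate(self.manifest):
            new[c][i, j] += step * delta[k]
            if i != j:
                new[c][j, i] += step * delta[k]
        return new


def _lower_tri_indices(t: int, r: int) -> list[tuple[int, int]]:
    return [(i, j) for j in range(r) for i in range(j, t)]


class _FactorParam:
    """Covariance component parameterized as L L' with a patterned factor L."""

    def __init__(self, name: str, t: int, rank: int, diagonal: bool = False):
        self.name = name
        self.t = t
        self.rank = rank
        self.diagonal = diagonal
        self.idx = [(i, i) for i in range(t)] if diagonal else _lower_tri_indices(t, rank)

    def unpack(self, x: np.ndarray) -> np.ndarray:
        L = np.zeros((self.t, self.rank))
        for k, (i, j) in enumerate(self.idx):
            L[i, j] = x[k]
        return L

    def pack(self, L: np.ndarray) -> np.ndarray:
        return np.array([L[i, j] for i, j in self.idx])

    def grad(self, S: np.ndarray, L: np.ndarray) -> np.ndarray:
        """d loglik / d factor params via the chain rule, given matrix gradient S."""
        GL = 2.0 * S @ L
        return np.array([GL[i, j] for i, j in self.idx])


def _factor_from_cov(C: np.ndarray, rank: int, floor: float, diagonal: bool = False) -> np.ndarray:
    if diagonal:
        return np.diag(np.sqrt(np.clip(np.diag(C), floor, None)))
    w, v = np.linalg.eigh(0.5 * (C + C.T))
    order = np.argsort(w)[::-1][:rank]
    B = v[:, order] * np.sqrt(np.clip(w[order], floor, None))
    # rotate to lower-triangular via LQ so the pattern constraint holds
    _, Rq = np.linalg.qr(B.T)
    lam = Rq.T
    for q in range(lam.shape[1]):  # fix column signs for determinism
        if lam[q, q] < 0:
            lam[:, q] = -lam[:, q]
    return lam


def _fit_unconstrained(prob: _Problem, tol: float, max_iter: int):
    """AI-Newton iteration directly on the covariance elements.

    Individual component matrices may wander outside the PSD cone (only the
    overall phenotypic covariance must stay positive-definite); an Armijo line
    search with step halving keeps the log-likelihood strictly non-decreasing.
    """
    mats = prob.start_values()
    loglik, grad, ai, _ = prob.evaluate(mats)
    history = [loglik]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        K = len(grad)
        reg = ai + (1e-10 * max(np.trace(ai) / K, 1.0)) * np.eye(K)
        try:
            delta = np.linalg.solve(reg, grad)
        except np.linalg.LinAlgError:
            delta = grad / max(np.max(np.abs(grad)), 1e-300)
        if float(delta @ grad) <= 0.0:
            delta = grad / max(np.max(np.abs(grad)), 1e-300)
        accepted = None
        for direction in (delta, grad * (1e-3 * prob.scale / max(np.max(np.abs(grad)), 1e-300))):
            slope = float(direction @ grad)
            if slope <= 0.0:
                continue
            step = 1.0
            for _ in range(40):
                cand = prob.apply_delta(mats, direction, step)
                try:
                    out = prob.evaluate(cand)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if out[0] >= loglik + 1e-4 * step * slope - 1e-12:
                    accepted = (cand, out)
                    break
                step *= 0.5
            if accepted is not None:
                break
        if accepted is None:
            return mats, loglik, ai, history, n_iter, True  # flat/boundary: stop
        mats, (new_loglik, grad, ai, _) = accepted
        history.append(new_loglik)
        if abs(new_loglik - loglik) < tol * (1.0 + abs(loglik)):
            return mats, new_loglik, ai, history, n_iter, True
        loglik = new_loglik
    raise ConvergenceError(
        f"REML did not converge in {max_iter} iterations "
        f"(last log-likelihood change {history[-1] - history[-2]:.3g})",
        history,
    )


def _fit_factor_lbfgs(prob: _Problem, g_rank: int, init_mats: dict):
    """Constrained (PSD) maximization via quasi-Newton on Cholesky-style factors.

    Used when the unconstrained optimum leaves the PSD cone, and for
    reduced-rank (factor-analytic) fits of G.
    """
    t = prob.t
    params = [
        _FactorParam(
            name, t,
            g_rank if name == "G" else t,
            diagonal=(name == "V" and prob.spec.vial_diagonal),
        )
        for name, _ in prob.terms
    ]
    factors0 = {
        p.name: _factor_from_cov(init_mats[p.name], p.rank, prob.floor, diagonal=p.diagonal)
        for p in params
    }
    x0 = np.concatenate([p.pack(factors0[p.name]) for p in params])

    def unpack_all(x):
        fs = {}
        pos = 0
        for p in params:
            fs[p.name] = p.unpack(x[pos : pos + len(p.idx)])
            pos += len(p.idx)
        return fs

    def objective(x):
        fs = unpack_all(x)
        mats = {n: L @ L.T for n, L in fs.items()}
        try:
            loglik, _, _, S_grads = prob.evaluate(mats, want_ai=False)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)
        gx = np.concatenate([-p.grad(S_grads[p.name], fs[p.name]) for p in params])
        return -loglik, gx

    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 3000, "maxfun": 6000, "ftol": 1e-13, "gtol": 1e-7},
    )
    fs = unpack_all(res.x)
    mats = {n: L @ L.T for n, L in fs.items()}
    return mats, int(res.nit)


def _min_component_eig(mats: dict[str, np.ndarray]) -> float:
    return min(float(np.linalg.eigvalsh(C).min()) for C in mats.values())


def fit_reml(
    phenotypes: pd.DataFrame,
    A: RelationshipMatrix,
    spec: ModelSpec,
) -> GEstimate:
    """Average-information REML fit of the multivariate animal model.

    Primary path: AI (quasi-Newton) steps on the covariance scale with an
    Armijo line search, so the restricted log-likelihood never decreases.  If
    the unconstrained optimum has a component matrix outside the PSD cone, the
    fit is re-polished on the factor (Cholesky) scale, which enforces the
    constraint exactly.  The AI matrix is evaluated at the optimum on the
    covariance scale for downstream REML-MVN sampling.
    """
    prob = _Problem(phenotypes, A, spec)
    mats, loglik, ai, history, n_iter, _ = _fit_unconstrained(prob, spec.tol, spec.max_iter)
    if _min_component_eig(mats) < -1e-7 * prob.scale:
        # boundary solution: redo under the PSD constraint
        mats, extra = _fit_factor_lbfgs(prob, prob.t, mats)
        n_iter += extra
        loglik, _, ai, _ = prob.evaluate(mats)
        history.append(loglik)
    else:
        clipped = {n: prob.project_psd(C) for n, C in mats.items()}
        if any(not np.array_equal(clipped[n], mats[n]) for n in mats):
            mats = clipped
            loglik, _, ai, _ = prob.evaluate(mats)
    return GEstimate(
        G=mats["G"],
        V=mats.get("V"),
        R=mats["R"],
        loglik=loglik,
        converged=True,
        n_iter=n_iter,
        ai=ai,
        manifest=list(prob.manifest),
        traits=list(spec.traits),
        n_records=prob.n,
        history=history,
    )


def fit_reduced_rank(
    phenotypes: pd.DataFrame,
    A: RelationshipMatrix,
    spec: ModelSpec,
    rank: int,
    init: GEstimate | None = None,
) -> GEstimate:
    """REML with the additive covariance constrained to G = Lambda Lambda' of given rank.

    Lambda is lower-triangular t x rank (``t*rank - rank*(rank-1)/2`` free
    parameters); vial and residual covariances stay unstructured.  Fitted by
    quasi-Newton on the factor scale, initialized from the full-rank fit.
    """
    t = len(spec.traits)
    if not 1 <= rank <= t:
        raise ValueError(f"rank must be in 1..{t}, got {rank}")
    prob = _Problem(phenotypes, A, spec)
    if init is None:
        init = fit_reml(phenotypes, A, spec)
    init_mats = {"G": init.G, "R": init.R}
    if init.V is not None:
        init_mats["V"] = init.V
    mats, n_iter = _fit_factor_lbfgs(prob, rank, init_mats)
    loglik, _, ai, _ = prob.evaluate(mats)
    return GEstimate(
        G=mats["G"],
        V=mats.get("V"),
        R=mats["R"],
        loglik=loglik,
        converged=True,
        n_iter=n_iter,
        ai=ai,
        manifest=list(prob.manifest),
        traits=list(spec.traits),
        n_records=prob.n,
        rank=rank,
    )


@dataclass(frozen=True)
class RankLRT:
    chi2: float
    df: int
    p: float


def rank_lrt(full: GEstimate, reduced: GEstimate) -> RankLRT:
    """Likelihood-ratio test of G-matrix rank between two nested fits."""
    if list(full.traits) != list(reduced.traits):
        raise ValueError("fits are not nested: different trait sets")
    if full.n_records != reduced.n_records:
        raise ValueError("fits are not nested: different data")
    df = full.n_params_g - reduced.n_params_g
    if df < 0:
        raise ValueError("fits are not nested: reduced model has more G parameters")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        p = 1.0 if chi2 <= 1e-8 else 0.0
    else:
        p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return RankLRT(chi2=chi2, df=df, p=p)
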