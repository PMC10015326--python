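"""Comparison of two additive genetic covariance matrices with sampling uncertainty.

Uncertainty is propagated by REML-MVN sampling: covariance parameters are
drawn from a multivariate normal centred at the REML estimates with covariance
equal to the inverse of the average-information matrix.  Samples are
unconstrained (individual draws may be non-positive-definite by design).
Comparisons pair samples from the two fits by index: variance ratios, variance
projected along eigenvectors, dot products between eigenvector sets, and the
difference matrix C = G_O - G_I whose eigenvectors identify the trait
combinations diverging most between the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .animal_model import GEstimate
from .pedigree import Pedigree

__all__ = [
    "MVNSampleSet",
    "RatioCI",
    "EigenReport",
    "EigentensorReport",
    "sample_mvn",
    "variance_ratio_ci",
    "per_trait_ratio_cis",
    "project",
    "eigen_with_ci",
    "dot_products",
    "eigentensor",
    "inbreeding_depression",
]


@dataclass
class MVNSampleSet:
    """Draws of the stacked covariance parameters for one fit."""

    theta: np.ndarray  # (n_samples, K)
    manifest: list[tuple[str, int, int]]
    traits: list[str]
    seed: int | None
    mu: np.ndarray  # point estimates, length K

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]

    def _component(self, which: str, source: np.ndarray) -> np.ndarray:
        t = len(self.traits)
        idx = [(k, i, j) for k, (c, i, j) in enumerate(self.manifest) if c == which]
        if not idx:
            raise ValueError(f"component {which!r} not present in manifest")
        out = np.zeros(source.shape[:-1] + (t, t))
        for k, i, j in idx:
            out[..., i, j] = source[..., k]
            out[..., j, i] = source[..., k]
        return out

    @property
    def G(self) -> np.ndarray:
        """G-block samples reshaped to symmetric matrices, (n_samples, t, t)."""
        return self._component("G", self.theta)

    @property
    def G_point(self) -> np.ndarray:
        return self._component("G", self.mu)


def sample_mvn(
    estimate: GEstimate,
    n: int = 10000,
    seed: int | None = None,
    sigma: np.ndarray | None = None,
) -> MVNSampleSet:
    """REML-MVN sampling on the covariance ("G-") scale.

    Draws ``n`` parameter vectors from N(mu, Sigma) with ``mu`` the REML point
    estimates and ``Sigma`` the inverse AI matrix (or an explicit override,
    e.g. zeros as a degenerate test hook).  Sampling uses the eigendecomposition
    of Sigma so positive semi-definite (including zero) covariances are legal.
    """
    mu = estimate.theta()
    if sigma is None:
        sigma = estimate.ai_inverse()
    sigma = 0.5 * (sigma + np.asarray(sigma, dtype=float).T)
    w, v = np.linalg.eigh(sigma)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError("inverse AI matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(mu)))
    draws = mu + (z * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    return MVNSampleSet(
        theta=draws,
        manifest=list(estimate.manifest),
        traits=list(estimate.traits),
        seed=seed,
        mu=mu,
    )


@dataclass(frozen=True)
class RatioCI:
    """Paired-sample ratio with equal-tail percentile confidence interval.

    ``point`` is the ratio of the two REML point estimates; ``median`` the
    median of the per-pair ratios (reported alongside because published
    summaries may use either convention).
    """

    name: str
    point: float
    median: float
    lo: float
    hi: float
    level: float
    n_dropped: int
    excludes_one: bool

    def as_row(self) -> dict:
        return self.__dict__.copy()


def _quantity(G: np.ndarray, which: str, index: int | None, vector: np.ndarray | None):
    if which == "trace":
        return np.trace(G, axis1=-2, axis2=-1)
    if which == "trait":
        return G[..., index, index]
    if which == "vector":
        return project(vector, G)
    raise ValueError(f"unknown quantity {which!r}")


def variance_ratio_ci(
    samples_o: MVNSampleSet,
    samples_i: MVNSampleSet,
    which: str = "trace",
    index: int | None = None,
    vector: np.ndarray | None = None,
    level: float = 0.95,
    name: str | None = None,
) -> RatioCI:
    """CI for a variance ratio (outbred over inbred) from paired MVN samples.

    ``which`` selects the quantity: 'trace' (total variance), 'trait' (diagonal
    element ``index``) or 'vector' (variance projected on ``vector``).  Pairs
    whose denominator is non-positive are dropped, with the count reported.
    """
    if samples_o.n_samples != samples_i.n_samples:
        raise ValueError("sample sets must have equal size for pairing")
    num = _quantity(samples_o.G, which, index, vector)
    den = _quantity(samples_i.G, which, index, vector)
    ok = den > 0
    n_dropped = int((~ok).sum())
    ratios = num[ok] / den[ok]
    if ratios.size == 0:
        raise ValueError("all paired denominators were non-positive")
    point_num = float(_quantity(samples_o.G_point, which, index, vector))
    point_den = float(_quantity(samples_i.G_point, which, index, vector))
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(ratios, [a, 1.0 - a])
    if name is None:
        name = which if which != "trait" else samples_o.traits[index]
    return RatioCI(
        name=name,
        point=point_num / point_den,
        median=float(np.median(ratios)),
        lo=float(lo),
        hi=float(hi),
        level=level,
        n_dropped=n_dropped,
        excludes_one=bool(lo > 1.0 or hi < 1.0),
    )


def per_trait_ratio_cis(
    samples_o: MVNSampleSet, samples_i: MVNSampleSet, level: float = 0.95
) -> pd.DataFrame:
    rows = [
        variance_ratio_ci(samples_o, samples_i, "trait", index=k, level=level).as_row()
        for k in range(len(samples_o.traits))
    ]
    return pd.DataFrame(rows)


def project(vector: np.ndarray, matrix: np.ndarray) -> np.ndarray | float:
    """Variance along a unit trait combination: the quadratic form e' S e.

    ``matrix`` may be a single t x t matrix or a batch (..., t, t).
    """
    v = np.asarray(vector, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot project through a zero vector")
    if abs(norm - 1.0) > 1e-8:
        raise ValueError("projection vector must be normalized")
    m = np.asarray(matrix, dtype=float)
    out = np.einsum("i,...ij,j->...", v, m, v)
    return float(out) if out.ndim == 0 else out


@dataclass
class EigenReport:
    values: np.ndarray  # descending
    vectors: np.ndarray  # columns, matched to values
    lo: np.ndarray
    hi: np.ndarray
    level: float
    proportion: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        tr = self.values.sum()
        self.proportion = self.values / tr if tr != 0 else np.full_like(self.values, np.nan)

    def as_frame(self, traits: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "eigenvalue": self.values,
                "lo": self.lo,
                "hi": self.hi,
                "proportion": self.proportion,
            }
        )
        df.index.name = "rank"
        return df


def _eigh_desc(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    w, v = np.linalg.eigh(0.5 * (G + G.T))
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def eigen_with_ci(
    G: np.ndarray, samples: MVNSampleSet | np.ndarray, level: float = 0.95
) -> EigenReport:
    """Eigendecomposition with percentile CIs from eigenvector projection.

    The CI for eigenvalue ``i`` comes from projecting the *point-estimate*
    eigenvector through every sampled matrix (the eigenvectors are held fixed,
    so sign ambiguity is irrelevant: the projection is a quadratic form).
    """
    values, vectors = _eigh_desc(np.asarray(G, dtype=float))
    gs = samples.G if isinstance(samples, MVNSampleSet) else np.asarray(samples)
    a = (1.0 - level) / 2.0
    lo = np.empty_like(values)
    hi = np.empty_like(values)
    for k in range(len(values)):
        proj = project(vectors[:, k], gs)
        lo[k], hi[k] = np.quantile(proj, [a, 1.0 - a])
    return EigenReport(values=values, vectors=vectors, lo=lo, hi=hi, level=level)


def dot_products(G_o: np.ndarray, G_i: np.ndarray) -> np.ndarray:
    """Absolute dot products of like-ranked eigenvectors of the two matrices."""
    G_o = np.asarray(G_o, dtype=float)
    G_i = np.asarray(G_i, dtype=float)
    if G_o.shape != G_i.shape:
        raise ValueError("matrices must have matching dimensions")
    _, eo = _eigh_desc(G_o)
    _, ei = _eigh_desc(G_i)
    return np.abs(np.einsum("ij,ij->j", eo, ei))


@dataclass
class EigentensorReport:
    C: np.ndarray
    values: np.ndarray  # signed, descending
    vectors: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float
    excludes_zero: np.ndarray
    index_most_positive: int
    index_most_negative: int

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "eigenvalue": self.values,
                "lo": self.lo,
                "hi": self.hi,
                "excludes_zero": self.excludes_zero,
            }
        )
        df.index.name = "rank"
        return df


def eigentensor(
    G_o: np.ndarray,
    G_i: np.ndarray,
    samples_o: MVNSampleSet,
    samples_i: MVNSampleSet,
    level: float = 0.95,
) -> EigentensorReport:
    """Difference matrix C = G_O - G_I and its eigenstructure with paired CIs.

    Per paired sample j, C_j = S_Oj - S_Ij; the CI for each eigenvalue comes
    from projecting the point-estimate eigenvector of C through all C_j.
    Eigenvalues are ordered by signed value (most positive first); a CI
    excluding zero flags a trait combination departing from the additive
    expectation.
    """
    if samples_o.n_samples != samples_i.n_samples:
        raise ValueError("sample sets must have equal size for pairing")
    G_o = np.asarray(G_o, dtype=float)
    G_i = np.asarray(G_i, dtype=float)
    if G_o.shape != G_i.shape:
        raise ValueError("matrices must have matching trait sets")
    C = G_o - G_i
    values, vectors = _eigh_desc(C)
    Cs = samples_o.G - samples_i.G
    a = (1.0 - level) / 2.0
    lo = np.empty_like(values)
    hi = np.empty_like(values)
    for k in range(len(values)):
        proj = project(vectors[:, k], Cs)
        lo[k], hi[k] = np.quantile(proj, [a, 1.0 - a])
    excludes = (lo > 0) | (hi < 0)
    return EigentensorReport(
        C=C,
        values=values,
        vectors=vectors,
        lo=lo,
        hi=hi,
        level=level,
        excludes_zero=excludes,
        index_most_positive=0,
        index_most_negative=len(values) - 1,
    )


def inbreeding_depression(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    traits: list[str] | None = None,
    f_inbred: float = 0.25,
    level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sire inbreeding depression with linear extrapolation to full inbreeding.

    For each sire with measured sons in both arms, the inbred-son mean is
    extrapolated from the observed coefficient ``f_inbred`` to F = 1,

        z_I = z_O + (z_obs - z_O) / f_inbred,

    and depression is reported as a percentage, ID = 100 (1 - z_I / z_O).
    Returns (per-sire frame, per-trait summary).  The summary contains both the
    percentile interval of the per-sire distribution and the CI of the mean,
    which answer different questions and are labelled accordingly.
    """
    if traits is None:
        traits = [c for c in phenotypes.columns if c.startswith("trait")]
    df = phenotypes
    if "sire" not in df.columns:
        parent = pedigree.parents_of()
        df = df.copy()
        df["sire"] = df["id"].map(lambda i: parent.get(str(i), (None, None))[0])
    means = df.groupby(["sire", "arm"], observed=True)[traits].mean()
    wide_o = means.xs("outbred", level="arm")
    wide_i = means.xs("inbred", level="arm")
    common = wide_o.index.intersection(wide_i.index)
    if len(common) == 0:
        raise ValueError("no sire has measured offspring in both arms")
    z_o = wide_o.loc[common]
    z_obs = wide_i.loc[common]
    if (z_o == 0).any().any():
        bad = [
            (s, tr)
            for tr in traits
            for s in z_o.index[z_o[tr] == 0]
        ]
        raise ZeroDivisionError(f"outbred mean is zero for sire/trait pairs: {bad[:5]}")
    z_full = z_o + (z_obs - z_o) / f_inbred
    id_pct = 100.0 * (1.0 - z_full / z_o)
    id_pct.index.name = "sire"

    a = (1.0 - level) / 2.0
    n = len(id_pct)
    summary = pd.DataFrame(
        {
            "mean": id_pct.mean(),
            "percentile_lo": id_pct.quantile(a),
            "percentile_hi": id_pct.quantile(1.0 - a),
            "mean_ci_lo": id_pct.mean() - 1.959963984540054 * id_pct.std(ddof=1) / np.sqrt(n),
            "mean_ci_hi": id_pct.mean() + 1.959963984540054 * id_pct.std(ddof=1) / np.sqrt(n),
            "n_sires": n,
        }
    )
    summary.index.name = "trait"
    return id_pct, summary
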