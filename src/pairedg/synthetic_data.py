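"""Simulation of paired-pedigree breeding designs with explicit multilocus genetics.

The generator emulates a middle-class-neighbourhood (MCN) design: every
generation, each mated pair contributes exactly one focal son and one focal
daughter to propagate the population.  Focal males are mated both to an
unrelated focal female (outbred arm, F ~ 0) and to their own full sister
(inbred arm, F = 0.25); up to five sons per cross arm are "measured".
Genotypes are realized by gene dropping through the pedigree, and phenotypes
add vial, observer, generation and residual effects on top of the summed
genotypic values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "DesignParams",
    "Locus",
    "LocusSet",
    "FixedEffectSpec",
    "simulate_mcn_pedigree",
    "gene_drop",
    "simulate_phenotypes",
    "inject_outliers",
    "simulate_dataset",
    "measured_vial",
]

MEASURED_ARMS = ("outbred", "inbred")


@dataclass(frozen=True)
class DesignParams:
    """Size and shape of the simulated breeding design.

    ``n_generations`` counts generations of focal crosses that produce measured
    offspring; the founder generation sits above the first of these.
    """

    n_pairs: int
    n_generations: int = 1
    outbred_per_cross: int = 5
    inbred_per_cross: int = 5
    n_traits: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2 to avoid brother-sister outbred pairings")
        for k in (self.outbred_per_cross, self.inbred_per_cross):
            if not 0 <= k <= 5:
                raise ValueError("offspring measured per cross arm must be in [0, 5]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")


@dataclass(frozen=True)
class Locus:
    """One biallelic locus: frequency ``q`` of the increasing allele, genotypic
    values (-a, d, +a) for 0/1/2 copies, and a per-trait loading vector."""

    q: float
    a: float
    d: float
    loadings: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"allele frequency q={self.q} must be in the open interval (0, 1)")
        if not np.all(np.isfinite(self.loadings)):
            raise ValueError("locus loadings must be finite")


@dataclass
class LocusSet:
    loci: list[Locus]

    @property
    def n_traits(self) -> int:
        return len(self.loci[0].loadings)

    @property
    def q(self) -> np.ndarray:
        return np.array([l.q for l in self.loci])

    @classmethod
    def additive(
        cls,
        n_loci: int,
        n_traits: int,
        q: float = 0.5,
        a: float = 1.0,
        seed: int | None = None,
        loading_scale: float = 1.0,
    ) -> "LocusSet":
        """Purely additive loci (d = 0) with random Gaussian trait loadings."""
        rng = np.random.default_rng(seed)
        loci = [
            Locus(q, a, 0.0, tuple(rng.normal(0.0, loading_scale, n_traits)))
            for _ in range(n_loci)
        ]
        return cls(loci)

    @classmethod
    def paired_dominance(
        cls,
        n_pairs: int,
        n_traits: int,
        q: float = 0.05,
        a: float = 1.0,
        d: float = 1.0,
        seed: int | None = None,
        loading_scale: float = 1.0,
    ) -> "LocusSet":
        """Loci in (+d, -d) pairs so that directional dominance cancels exactly.

        Both members of a pair share one loading vector: their heterozygote
        effects on every trait are equal and opposite, so E[d] = 0 holds per
        trait by construction, not just in expectation.
        """
        rng = np.random.default_rng(seed)
        loci = []
        for _ in range(n_pairs):
            loadings = tuple(rng.normal(0.0, loading_scale, n_traits))
            for sign in (1.0, -1.0):
                loci.append(Locus(q, a, sign * d, loadings))
        return cls(loci)


def _sib_avoiding_permutation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation with no fixed points (a fixed point would pair full sibs)."""
    if n < 2:
        raise ValueError("need at least two pairs to avoid sib matings")
    perm = rng.permutation(n)
    for _ in range(100):
        fixed = np.flatnonzero(perm == np.arange(n))
        if fixed.size == 0:
            return perm
        if fixed.size > 1:
            perm[fixed] = perm[np.roll(fixed, 1)]
        else:
            j = int(fixed[0])
            k = int(rng.integers(n - 1))
            k += k >= j
            perm[j], perm[k] = perm[k], perm[j]
    raise RuntimeError("failed to construct a derangement")  # pragma: no cover


def simulate_mcn_pedigree(params: DesignParams) -> Pedigree:
    """Generate the MCN paired pedigree.

    Founders (generation 0) are unrelated pairs.  Each focal generation ``g``
    mates focal son ``j`` with a non-sister focal daughter (outbred cross,
    continuing the line) and with his own full sister (inbred cross); measured
    sons are drawn from both crosses and labelled with arm 'outbred'/'inbred'.
    """
    rng = np.random.default_rng(params.seed)
    rows: list[dict] = []
    n = params.n_pairs

    def add(id_, sire, dam, sex, gen, arm):
        rows.append({"id": id_, "sire": sire, "dam": dam, "sex": sex, "generation": gen, "arm": arm})

    # founder pairs: (male j, female j) already mated
    males = [f"G0M{j}" for j in range(n)]
    females = [f"G0F{j}" for j in range(n)]
    for j in range(n):
        add(males[j], None, None, "M", 0, "parent")
        add(females[j], None, None, "F", 0, "parent")
    # crosses[j] = (sire, dam) of pair j in the current generation
    crosses = list(zip(males, females))

    for g in range(1, params.n_generations + 1):
        sons = [f"G{g}M{j}" for j in range(n)]
        daughters = [f"G{g}F{j}" for j in range(n)]
        for j, (s, d) in enumerate(crosses):
            add(sons[j], s, d, "M", g, "parent")
            add(daughters[j], s, d, "F", g, "parent")
        perm = _sib_avoiding_permutation(n, rng)
        next_crosses = []
        for j in range(n):
            sire = sons[j]
            out_dam = daughters[int(perm[j])]
            inb_dam = daughters[j]  # full sister
            for k in range(params.outbred_per_cross):
                add(f"G{g}O{j}.{k}", sire, out_dam, "M", g, "outbred")
            for k in range(params.inbred_per_cross):
                add(f"G{g}I{j}.{k}", sire, inb_dam, "M", g, "inbred")
            next_crosses.append((sire, out_dam))
        crosses = next_crosses

    return Pedigree.from_records(rows).validate()


def measured_vial(row) -> str:
    """Rearing-vial label: all measured brothers of one cross arm share a vial."""
    return f"v{row.generation}:{row.sire}:{row.arm}"


def gene_drop(
    pedigree: Pedigree, loci: LocusSet, seed: int | None = None
) -> pd.DataFrame:
    """Drop alleles through the pedigree; returns counts (0/1/2) of the increasing allele.

    Founder genotypes are Hardy-Weinberg draws at each locus' frequency ``q``;
    each meiosis transmits one of the parent's two alleles with a fair coin.
    Loci are unlinked.
    """
    if not pedigree.validated:
        raise ValueError("pedigree must be validated")
    rng = np.random.default_rng(seed)
    df = pedigree.df
    ids = df["id"].tolist()
    index = {i: k for k, i in enumerate(ids)}
    nl = len(loci.loci)
    q = loci.q
    alleles = np.zeros((len(ids), nl, 2), dtype=np.int8)
    for i, r in enumerate(df.itertuples(index=False)):
        for slot, parent in enumerate((r.sire, r.dam)):
            if parent is None:
                alleles[i, :, slot] = rng.random(nl) < q
            else:
                p = index[parent]
                pick = rng.integers(0, 2, nl)
                alleles[i, :, slot] = alleles[p, np.arange(nl), pick]
    counts = alleles.sum(axis=2)
    return pd.DataFrame(counts, index=ids, columns=[f"locus{k}" for k in range(nl)])


@dataclass(frozen=True)
class FixedEffectSpec:
    """Additive per-trait shifts for the fixed part of the phenotype model."""

    trait_means: tuple[float, ...] = ()
    generation_effects: dict | None = None  # generation label -> length-t array
    observer_effects: dict | None = None  # observer label -> length-t array
    n_observers: int = 6

    def observer_names(self) -> list[str]:
        return [f"obs{i + 1}" for i in range(self.n_observers)]


def _check_psd(name: str, cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T):
        raise ValueError(f"{name} covariance is not symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -1e-10 * max(1.0, w.max()):
        raise ValueError(f"{name} covariance is not positive semi-definite")
    return cov


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: pd.DataFrame,
    loci: LocusSet,
    vial_cov: np.ndarray,
    residual_cov: np.ndarray,
    fixed: FixedEffectSpec | None = None,
    seed: int | None = None,
    trait_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Phenotype table for measured (outbred/inbred-arm) individuals.

    The genotypic value at each locus maps 0/1/2 copies to (-a, d, +a), is
    multiplied by the locus' trait-loading vector and summed over loci; a vial
    effect (one multivariate draw per vial), observer and generation shifts and
    a residual draw are added.
    """
    t = loci.n_traits
    fixed = fixed or FixedEffectSpec()
    vial_cov = _check_psd("vial", vial_cov)
    residual_cov = _check_psd("residual", residual_cov)
    if vial_cov.shape != (t, t) or residual_cov.shape != (t, t):
        raise ValueError("covariance matrices must be n_traits x n_traits")
    rng = np.random.default_rng(seed)
    if trait_names is None:
        trait_names = [f"trait{i + 1}" for i in range(t)]

    meas = pedigree.df[pedigree.df["arm"].isin(MEASURED_ARMS)].copy()
    g = genotypes.loc[meas["id"]].to_numpy()
    # per-locus genotypic values
    a = np.array([l.a for l in loci.loci])
    d = np.array([l.d for l in loci.loci])
    values = np.where(g == 0, -a, np.where(g == 1, d, a))
    loadings = np.array([l.loadings for l in loci.loci])  # (n_loci, t)
    genetic = values @ loadings  # (n_meas, t)

    vials = meas.apply(measured_vial, axis=1).tolist()
    uniq_vials = sorted(set(vials))
    vial_draws = rng.multivariate_normal(np.zeros(t), vial_cov, size=len(uniq_vials))
    vial_effect = dict(zip(uniq_vials, vial_draws))
    observers = fixed.observer_names()
    vial_observer = {v: observers[k % len(observers)] for k, v in enumerate(uniq_vials)}

    y = genetic + np.array([vial_effect[v] for v in vials])
    y += rng.multivariate_normal(np.zeros(t), residual_cov, size=len(meas))
    if fixed.trait_means:
        y += np.asarray(fixed.trait_means)
    gen_fx = fixed.generation_effects or {}
    obs_fx = fixed.observer_effects or {}
    obs_labels = [vial_observer[v] for v in vials]
    for i, (gen, obs) in enumerate(zip(meas["generation"], obs_labels)):
        if gen in gen_fx:
            y[i] += np.asarray(gen_fx[gen])
        if obs in obs_fx:
            y[i] += np.asarray(obs_fx[obs])

    out = pd.DataFrame(
        {
            "id": meas["id"].to_numpy(),
            "arm": meas["arm"].to_numpy(),
            "vial": vials,
            "observer": obs_labels,
            "generation": meas["generation"].to_numpy(),
            "sire": meas["sire"].to_numpy(),
        }
    )
    for k, name in enumerate(trait_names):
        out[name] = y[:, k]
    return out.reset_index(drop=True)


def inject_outliers(
    table: pd.DataFrame,
    fraction: float,
    magnitude: float,
    seed: int | None = None,
    trait_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Perturb a random fraction of records along a random trait-space direction.

    Each selected record moves ``magnitude`` trait standard deviations along a
    random unit direction; truth flags are kept in an ``is_outlier`` column.
    """
    if not 0.0 <= fraction < 0.1:
        raise ValueError("outlier fraction must be in [0, 0.1)")
    out = table.copy()
    if trait_names is None:
        trait_names = [c for c in table.columns if c.startswith("trait")]
    out["is_outlier"] = False
    if fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n = len(out)
    chosen = rng.random(n) < fraction
    sd = out[list(trait_names)].std(ddof=1).to_numpy()
    idx = np.flatnonzero(chosen)
    for i in idx:
        direction = rng.normal(size=len(trait_names))
        direction /= np.linalg.norm(direction)
        out.loc[out.index[i], list(trait_names)] += magnitude * sd * direction
    out.loc[out.index[idx], "is_outlier"] = True
    return out


#: A plausible mean 9-landmark wing configuration (arbitrary units).
BASE_WING = np.array(
    [
        [0.0, 0.0], [2.0, 0.5], [3.5, 1.2], [4.0, 2.5], [3.0, 3.5],
        [1.8, 3.2], [0.8, 2.5], [0.3, 1.5], [1.5, 1.8],
    ]
)


def simulate_landmarks(
    n_specimens: int,
    seed: int | None = None,
    jitter: float = 0.05,
    size_cv: float = 0.1,
) -> tuple[np.ndarray, list[str]]:
    """Synthetic 9-landmark wing configurations for morphometrics testing.

    Each specimen is the base wing shape with Gaussian landmark jitter, a
    log-normal size factor, and a random rotation + translation, so the full
    Procrustes pipeline is exercised.  Returns (configs (n, 9, 2), ids).
    """
    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(n_specimens):
        shape = BASE_WING + rng.normal(0.0, jitter, BASE_WING.shape)
        shape = shape * np.exp(rng.normal(0.0, size_cv))
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        configs.append(shape @ rot.T + rng.normal(0.0, 2.0, 2))
    ids = [f"specimen{k + 1}" for k in range(n_specimens)]
    return np.stack(configs), ids


def simulate_dataset(
    params: DesignParams,
    loci: LocusSet,
    vial_cov: np.ndarray,
    residual_cov: np.ndarray,
    fixed: FixedEffectSpec | None = None,
    outlier_fraction: float = 0.0,
    outlier_magnitude: float = 10.0,
) -> tuple[Pedigree, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: pedigree + genotypes + phenotypes from one master seed."""
    ss = np.random.SeedSequence(params.seed)
    s_ped, s_geno, s_phen, s_out = [int(c.generate_state(1)[0]) for c in ss.spawn(4)]
    ped = simulate_mcn_pedigree(
        DesignParams(
            params.n_pairs,
            params.n_generations,
            params.outbred_per_cross,
            params.inbred_per_cross,
            params.n_traits,
            seed=s_ped,
        )
    )
    geno = gene_drop(ped, loci, seed=s_geno)
    phen = simulate_phenotypes(ped, geno, loci, vial_cov, residual_cov, fixed, seed=s_phen)
    if outlier_fraction > 0:
        phen = inject_outliers(phen, outlier_fraction, outlier_magnitude, seed=s_out)
    return ped, geno, phen
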