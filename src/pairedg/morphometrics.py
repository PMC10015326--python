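"""Wing-trait construction and data cleaning.

Stages: generalized Procrustes alignment of 9-landmark configurations,
centroid size, inter-landmark distances on the unit-centroid-size aligned
coordinates (hence "in units of CS"), trait scaling, Mahalanobis outlier
rejection within observer x generation strata, and the paired-sire filter that
keeps only records whose sire contributed measured offspring to both mating
arms.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

__all__ = [
    "N_LANDMARKS",
    "DEFAULT_PAIRS",
    "centroid_size",
    "procrustes_align",
    "interlandmark_distances",
    "wing_traits",
    "scale_traits",
    "unscale_traits",
    "mahalanobis_filter",
    "paired_sire_filter",
    "read_tps",
    "write_tps",
    "ild_name",
]

N_LANDMARKS = 9

#: Default 10 landmark pairs (1-based) used as inter-landmark distance traits.
DEFAULT_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 5),
    (1, 9),
    (2, 5),
    (2, 8),
    (3, 7),
    (3, 9),
    (4, 6),
    (4, 8),
    (5, 9),
    (6, 8),
)

ILD_SCALE = 1000.0
CS_SCALE = 200.0


def ild_name(pair: tuple[int, int]) -> str:
    return f"ILD{pair[0]}.{pair[1]}"


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared landmark distances from their centroid."""
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[1] != 2:
        raise ValueError("configuration must be (k, 2)")
    if not np.all(np.isfinite(config)):
        raise ValueError("non-finite landmark coordinates")
    centred = config - config.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise ValueError("all landmarks coincident: centroid size is zero")
    return cs


def _rotation_to(target: np.ndarray, config: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1, no reflection) minimizing ||config @ R - target||."""
    h = config.T @ target
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, sign]) @ vt


def procrustes_align(
    configs: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized (full) Procrustes alignment.

    Each configuration is centred, scaled to unit centroid size and rotated to
    the iteratively re-estimated mean shape; iteration stops when the mean
    shape moves by less than ``tol``.  Returns (aligned (n,k,2), centroid sizes
    (n,)).  Rotations are proper (determinant +1): reflections are not allowed.
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 3 or configs.shape[2] != 2:
        raise ValueError("configs must be (n, k, 2)")
    if configs.shape[0] < 2:
        raise ValueError("need at least two configurations to align")
    cs = np.array([centroid_size(c) for c in configs])
    x = configs - configs.mean(axis=1, keepdims=True)
    x = x / cs[:, None, None]

    mean = x[0].copy()
    for _ in range(max_iter):
        aligned = np.array([c @ _rotation_to(mean, c) for c in x])
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        norm = np.sqrt((new_mean**2).sum())
        if norm == 0.0:
            raise ValueError("degenerate configuration set: mean shape collapsed")
        new_mean /= norm
        change = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if change < tol:
            return aligned, cs
    raise RuntimeError(f"Procrustes alignment did not converge in {max_iter} iterations")


def interlandmark_distances(
    aligned: np.ndarray, pairs: Sequence[tuple[int, int]] = DEFAULT_PAIRS
) -> np.ndarray:
    """Euclidean distances between 1-based landmark pairs of aligned configurations."""
    aligned = np.asarray(aligned, dtype=float)
    k = aligned.shape[-2]
    for i, j in pairs:
        if not (1 <= i <= k and 1 <= j <= k):
            raise ValueError(f"landmark pair ({i}, {j}) outside 1..{k}")
    single = aligned.ndim == 2
    if single:
        aligned = aligned[None]
    out = np.stack(
        [np.linalg.norm(aligned[:, i - 1] - aligned[:, j - 1], axis=1) for i, j in pairs],
        axis=1,
    )
    return out[0] if single else out


def wing_traits(
    configs: np.ndarray,
    meta: pd.DataFrame | None = None,
    pairs: Sequence[tuple[int, int]] = DEFAULT_PAIRS,
) -> pd.DataFrame:
    """Full trait construction: align, then CS plus the 10 ILD traits.

    ``meta`` (optional) supplies per-specimen columns (id, observer,
    generation, ...) to carry through.
    """
    aligned, cs = procrustes_align(configs)
    ilds = interlandmark_distances(aligned, pairs)
    out = pd.DataFrame(ilds, columns=[ild_name(p) for p in pairs])
    out.insert(0, "CS", cs)
    if meta is not None:
        out = pd.concat([meta.reset_index(drop=True), out], axis=1)
    return out


def scale_traits(
    traits: pd.DataFrame, ild_scale: float = ILD_SCALE, cs_scale: float = CS_SCALE
) -> pd.DataFrame:
    """Multiply ILD columns by ``ild_scale`` and CS by ``cs_scale`` (convergence aid).

    The constants are recorded in ``DataFrame.attrs['scaling']``.
    """
    out = traits.copy()
    for col in out.columns:
        if col.startswith("ILD"):
            out[col] = out[col] * ild_scale
        elif col == "CS":
            out[col] = out[col] * cs_scale
    out.attrs["scaling"] = {"ild": ild_scale, "cs": cs_scale}
    return out


def unscale_traits(traits: pd.DataFrame) -> pd.DataFrame:
    scaling = traits.attrs.get("scaling", {"ild": ILD_SCALE, "cs": CS_SCALE})
    out = traits.copy()
    for col in out.columns:
        if col.startswith("ILD"):
            out[col] = out[col] / scaling["ild"]
        elif col == "CS":
            out[col] = out[col] / scaling["cs"]
    out.attrs["scaling"] = {"ild": 1.0, "cs": 1.0}
    return out


def mahalanobis_filter(
    traits: pd.DataFrame,
    trait_names: Sequence[str],
    alpha: float = 0.001,
    df: int | None = None,
    strata: Sequence[str] = ("observer", "generation"),
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """One-pass multivariate outlier rejection.

    Observations are centred per trait within each stratum (by default observer
    x generation); squared Mahalanobis distances of the centred vectors are
    computed against their pooled covariance and records beyond the chi-square
    critical value for ``alpha`` at ``df`` degrees of freedom (default: the
    number of traits) are removed.  Returns (retained, removed, D2).
    """
    trait_names = list(trait_names)
    if df is None:
        df = len(trait_names)
    strata = [s for s in strata if s in traits.columns]
    x = traits[trait_names].astype(float)
    if strata:
        centred = x - traits.groupby(strata, observed=True)[trait_names].transform("mean")
    else:
        centred = x - x.mean()
    z = centred.to_numpy()
    cov = np.cov(z, rowvar=False)
    cov = np.atleast_2d(cov)
    w, v = np.linalg.eigh(cov)
    if w.min() <= 1e-12 * max(w.max(), 1.0):
        null = v[:, 0]
        involved = [trait_names[i] for i in np.argsort(-np.abs(null))[:3]]
        raise ValueError(
            f"singular pooled covariance; near-collinear traits involve {involved}"
        )
    d2 = np.einsum("ij,ij->i", z, np.linalg.solve(cov, z.T).T)
    crit = stats.chi2.ppf(1.0 - alpha, df)
    keep = d2 <= crit
    return traits[keep].copy(), traits[~keep].copy(), d2


def paired_sire_filter(
    traits: pd.DataFrame, pedigree: Pedigree, arm_col: str = "arm", id_col: str = "id"
) -> pd.DataFrame:
    """Retain only records whose sire has measured offspring in both mating arms.

    A male's phenotype is kept iff, within the supplied (already
    outlier-filtered) table, his sire contributed at least one record to the
    outbred arm and at least one to the inbred arm.
    """
    out = traits.copy()
    if "sire" in out.columns:
        sires = out["sire"]
    else:
        parent = pedigree.parents_of()
        sires = out[id_col].map(lambda i: parent.get(str(i), (None, None))[0])
    arms_by_sire = pd.DataFrame({"sire": sires, "arm": out[arm_col]}).groupby("sire")["arm"].agg(set)
    good = {s for s, arms in arms_by_sire.items() if {"outbred", "inbred"} <= arms}
    return out[sires.isin(good)].copy()


# ---------------------------------------------------------------------------
# TPS landmark file IO


def read_tps(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a TPS landmark file; returns (configs (n,k,2), specimen ids)."""
    configs: list[np.ndarray] = []
    ids: list[str] = []
    current: list[list[float]] = []
    expected = 0

    def flush():
        nonlocal current, expected
        if expected:
            if len(current) != expected:
                raise ValueError(
                    f"TPS record has {len(current)} coordinate lines, expected {expected}"
                )
            configs.append(np.array(current))
            if len(ids) < len(configs):
                ids.append(f"specimen{len(configs)}")
        current, expected = [], 0

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            flush()
            expected = int(line.split("=", 1)[1])
        elif upper.startswith("ID="):
            ids.append(line.split("=", 1)[1].strip())
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            continue  # IMAGE=, SCALE=, ... ignored
        else:
            current.append([float(tok) for tok in line.split()])
    flush()
    if not configs:
        raise ValueError(f"no landmark records found in {path}")
    return np.stack(configs), ids


def write_tps(path: str | Path, configs: np.ndarray, ids: Sequence[str]) -> None:
    lines = []
    for config, id_ in zip(configs, ids):
        lines.append(f"LM={len(config)}")
        for x, y in config:
            lines.append(f"{x:.6f} {y:.6f}")
        lines.append(f"ID={id_}")
    Path(path).write_text("\n".join(lines) + "\n")
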