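"""Pedigree validation, inbreeding coefficients and the numerator relationship matrix.

The relationship matrix **A** is built by the tabular method: processing
individuals parents-before-offspring,

    A(i, i) = 1 + 0.5 * A(sire_i, dam_i)
    A(i, j) = 0.5 * [A(j, sire_i) + A(j, dam_i)]   for j processed before i

with an unknown parent contributing zero.  Diagonals therefore equal ``1 + F``,
where ``F`` is the classical inbreeding coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "PedigreeError",
    "CycleError",
    "read_pedigree",
    "build_A",
    "inbreeding_coefficients",
]

#: CSV tokens interpreted as an unknown parent.
UNKNOWN_TOKENS = {"", "0", "na", "nan", "none", ".", "unknown"}

COLUMNS = ["id", "sire", "dam", "sex", "generation", "arm"]


class PedigreeError(ValueError):
    """Structural problem in a pedigree table."""


class CycleError(PedigreeError):
    """The parent graph contains a cycle (an individual is its own ancestor)."""


def _clean_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s.lower() in UNKNOWN_TOKENS else s


@dataclass
class Pedigree:
    """A pedigree table; construct via :meth:`from_frame`/:meth:`read_csv` then :meth:`validate`.

    ``df`` holds columns id, sire, dam, sex, generation, arm with opaque string
    ids and ``None`` for unknown parents.  After validation rows are in
    topological (parents-first) order and ``warnings`` lists any
    founder-promotions applied.
    """

    df: pd.DataFrame
    validated: bool = False
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        df = df.copy()
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = None if col in ("sire", "dam") else ""
        df = df[COLUMNS]
        df["id"] = df["id"].astype(str)
        for col in ("sire", "dam"):
            df[col] = df[col].map(_clean_parent)
        return cls(df.reset_index(drop=True))

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "Pedigree":
        return cls.from_frame(pd.DataFrame(list(records)))

    @classmethod
    def read_csv(cls, path: str | Path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        for col in ("sire", "dam"):
            out[col] = out[col].fillna("0")
        out.to_csv(path, index=False)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    def parents_of(self) -> dict[str, tuple[str | None, str | None]]:
        return {
            r.id: (r.sire, r.dam)
            for r in self.df.itertuples(index=False)
        }

    def validate(self) -> "Pedigree":
        """Return a topologically sorted copy; see module docstring for the rules.

        Parent ids absent from the table are promoted to founders with a
        warning.  Duplicate ids and cycles raise :class:`PedigreeError`.
        """
        df = self.df
        dup = df["id"][df["id"].duplicated()].unique()
        if len(dup):
            raise PedigreeError(f"duplicate individual ids: {sorted(dup)}")

        known = set(df["id"])
        warnings: list[str] = []
        promoted = []
        for col in ("sire", "dam"):
            missing = sorted({p for p in df[col] if p is not None and p not in known})
            for pid in missing:
                if pid in {r["id"] for r in promoted}:
                    continue
                promoted.append(
                    {"id": pid, "sire": None, "dam": None, "sex": "", "generation": "", "arm": "parent"}
                )
                warnings.append(f"parent {pid!r} absent from table; promoted to founder")
                known.add(pid)
        if promoted:
            df = pd.concat([pd.DataFrame(promoted), df], ignore_index=True)

        for r in df.itertuples(index=False):
            if r.sire == r.id or r.dam == r.id:
                raise CycleError(f"individual {r.id!r} listed as its own parent")

        # Kahn's algorithm, stable in input order.
        order = _topological_order(df)
        out = df.iloc[order].reset_index(drop=True)
        return Pedigree(out, validated=True, warnings=warnings)


def _topological_order(df: pd.DataFrame) -> list[int]:
    idx = {i: k for k, i in enumerate(df["id"])}
    n = len(df)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for k, r in enumerate(df.itertuples(index=False)):
        for p in (r.sire, r.dam):
            if p is not None:
                children[idx[p]].append(k)
                indeg[k] += 1
    queue = [k for k in range(n) if indeg[k] == 0]
    order: list[int] = []
    head = 0
    while head < len(queue):
        k = queue[head]
        head += 1
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        stuck = sorted(df["id"].iloc[[k for k in range(n) if indeg[k] > 0]])
        raise CycleError(f"pedigree contains a cycle involving: {stuck}")
    return order


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix indexed by individual id."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {i: k for k, i in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        rows = [self._index[i] for i in ids]
        return self.values[np.ix_(rows, rows)]

    @property
    def inbreeding(self) -> pd.Series:
        return pd.Series(np.diag(self.values) - 1.0, index=self.ids, name="F")

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_triplets(self, tol: float = 0.0) -> pd.DataFrame:
        """Sparse upper-triangle export as (id_i, id_j, value) rows."""
        iu, ju = np.triu_indices(len(self.ids))
        vals = self.values[iu, ju]
        keep = np.abs(vals) > tol
        return pd.DataFrame(
            {
                "id_i": np.asarray(self.ids)[iu[keep]],
                "id_j": np.asarray(self.ids)[ju[keep]],
                "value": vals[keep],
            }
        )


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix via the tabular method.

    Requires a validated (topologically sorted) pedigree.
    """
    if not pedigree.validated:
        raise PedigreeError("pedigree must be validated before building A")
    df = pedigree.df
    ids = df["id"].tolist()
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = [index[s] if s is not None else -1 for s in df["sire"]]
    dams = [index[d] if d is not None else -1 for d in df["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
            if i:
                A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
        elif s >= 0 or d >= 0:
            k = s if s >= 0 else d
            A[i, i] = 1.0
            if i:
                A[i, :i] = 0.5 * A[k, :i]
        else:
            A[i, i] = 1.0
        if i:
            A[:i, i] = A[i, :i]
    return RelationshipMatrix(ids, A)


def inbreeding_coefficients(pedigree: Pedigree) -> pd.Series:
    """Per-individual inbreeding coefficients, F = diag(A) - 1."""
    return build_A(pedigree).inbreeding


def read_pedigree(path: str | Path) -> Pedigree:
    """Read and validate a pedigree CSV (columns id, sire, dam, sex, generation, arm)."""
    return Pedigree.read_csv(path).validate()
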