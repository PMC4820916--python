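"""Pedigrees and pairwise genetic-relationship matrices.

The relationship matrix feeds the survival and liability models as the
covariance structure of the polygenic random effect.  Coefficients are
reported on the doubled-kinship scale (numerator relationship matrix):
self and monozygotic twins are 1, parent-offspring and full siblings 0.5,
grandparent-grandchild / avuncular / half-siblings / double first cousins
0.25, first cousins 0.125.  Internally the classical kinship coefficient
phi (self = 0.5 for a non-inbred individual) is computed by the standard
founder-down recursion and doubled for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (cycles, unknown parents, bad sexes)."""


@dataclass
class Pedigree:
    """A set of (individual, father, mother, sex) records.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``id``, ``father``, ``mother``, ``sex``.  Missing parents
        are encoded as ``None``/NaN/``"0"``/``0``.  ``sex`` uses the PED
        convention 1 = male, 2 = female (0/unknown tolerated).
    """

    records: pd.DataFrame
    _order: list = field(init=False, repr=False)
    _parents: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.records.copy()
        required = {"id", "father", "mother", "sex"}
        missing = required - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
        df["id"] = df["id"].astype(str)
        for col in ("father", "mother"):
            df[col] = df[col].apply(_norm_parent)
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise PedigreeError(f"duplicate individual ids: {dupes}")
        ids = set(df["id"])
        parents: dict[str, tuple[str | None, str | None]] = {}
        sex = dict(zip(df["id"], df["sex"]))
        for _, row in df.iterrows():
            fa, mo = row["father"], row["mother"]
            for p in (fa, mo):
                if p is not None and p not in ids:
                    raise PedigreeError(f"unknown parent id {p!r} for individual {row['id']!r}")
            if fa is not None and sex.get(fa) == 2:
                raise PedigreeError(f"father {fa!r} recorded as female")
            if mo is not None and sex.get(mo) == 1:
                raise PedigreeError(f"mother {mo!r} recorded as male")
            parents[row["id"]] = (fa, mo)
        self._parents = parents
        self._order = _topological_order(parents)
        self.records = df

    @property
    def ids(self) -> list:
        return list(self.records["id"])

    @property
    def founders(self) -> list:
        return [i for i, (f, m) in self._parents.items() if f is None and m is None]

    def parents_of(self, individual: str) -> tuple:
        return self._parents[str(individual)]

    @classmethod
    def from_ped(cls, path) -> "Pedigree":
        """Read a PED-style whitespace-delimited file.

        Accepts either 4 columns (id, father, mother, sex) or the 6-column
        LINKAGE layout (family, id, father, mother, sex, phenotype); the
        family and phenotype columns are ignored for relationship purposes.
        """
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
        if df.shape[1] >= 6:
            df = df.iloc[:, 1:5]
        elif df.shape[1] < 4:
            raise PedigreeError("PED file needs at least 4 columns")
        df = df.iloc[:, :4]
        df.columns = ["id", "father", "mother", "sex"]
        df["sex"] = pd.to_numeric(df["sex"], errors="coerce").fillna(0).astype(int)
        return cls(df)

    def to_ped(self, path) -> None:
        out = self.records[["id", "father", "mother", "sex"]].copy()
        out["father"] = out["father"].fillna("0")
        out["mother"] = out["mother"].fillna("0")
        out.to_csv(path, sep=" ", header=False, index=False)


def _norm_parent(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "0", "0.0", "nan", "None", "NA", "."):
        return None
    return s


def _topological_order(parents: dict) -> list:
    """Founder-down ordering; raises on pedigree cycles."""
    order: list = []
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    def visit(node, stack):
        st = state.get(node)
        if st == 1:
            return
        if st == 0:
            raise PedigreeError(f"pedigree cycle involving {node!r}")
        state[node] = 0
        for p in parents[node]:
            if p is not None:
                visit(p, stack)
        state[node] = 1
        order.append(node)

    for individual in parents:
        visit(individual, [])
    return order


def kinship_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Classical kinship coefficients phi (self = 0.5 when non-inbred).

    Recursion, parents processed before offspring:
    phi(i,i) = 0.5 * (1 + phi(f_i, m_i)),
    phi(i,j) = 0.5 * (phi(f_i, j) + phi(m_i, j))   for j already placed,
    with phi(f, .) = 0 contributions for unknown parents.
    """
    order = pedigree._order
    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for i, ind in enumerate(order):
        fa, mo = pedigree.parents_of(ind)
        fi = idx[fa] if fa is not None else None
        mi = idx[mo] if mo is not None else None
        if fi is not None and mi is not None:
            phi[i, i] = 0.5 * (1.0 + phi[fi, mi])
        else:
            phi[i, i] = 0.5
        for j in range(i):
            val = 0.0
            if fi is not None:
                val += 0.5 * phi[fi, j]
            if mi is not None:
                val += 0.5 * phi[mi, j]
            phi[i, j] = phi[j, i] = val
    # restore the input record order
    perm = [idx[i] for i in pedigree.ids]
    phi = phi[np.ix_(perm, perm)]
    return pd.DataFrame(phi, index=pedigree.ids, columns=pedigree.ids)


def build_relationship_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Relationship (doubled kinship, 2*phi) matrix aligned to pedigree ids.

    Diagonal is 1 + F (F the inbreeding coefficient); entries are symmetric,
    in [0, diagonal], and the matrix is positive semi-definite.
    """
    return 2.0 * kinship_matrix(pedigree)


def relationship_of(pedigree: Pedigree, a, b) -> float:
    """Relationship coefficient (2*phi scale) between two individuals."""
    a, b = str(a), str(b)
    known = set(pedigree.ids)
    for x in (a, b):
        if x not in known:
            raise KeyError(f"unknown individual id {x!r}")
    rel = build_relationship_matrix(pedigree)
    return float(rel.loc[a, b])


def write_relationship_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="id")


def read_relationship_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
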