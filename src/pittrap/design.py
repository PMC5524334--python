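"""Regression designs built from small formula strings.

Formulas are restricted to what randomized-blocks analyses need: main
effects and interactions of categorical (or numeric pass-through)
covariates, written ``"block+treatment"``, ``"block*treatment"`` or
``"block:treatment"``.  Categorical covariates are coded with treatment
contrasts: the first (sorted) level is the reference, and every effect
column indexed by a reference level is dropped, which is the usual
identifiability constraint for models of the form

    log mu_ijk = a0 + a_i + b_k + g_ik,   a_1 = b_1 = g_1k = g_i1 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignSpec"]


def _parse_formula(formula: str) -> list[str]:
    """Expand a formula string into an ordered list of term labels."""
    terms: list[str] = []

    def add(t: str) -> None:
        if t and t != "1" and t not in terms:
            terms.append(t)

    for chunk in formula.replace(" ", "").split("+"):
        if not chunk:
            continue
        if "*" in chunk:
            parts = chunk.split("*")
            if len(parts) != 2:
                raise ValueError(f"only two-way crosses are supported: {chunk!r}")
            a, b = parts
            add(a)
            add(b)
            add(f"{a}:{b}")
        else:
            add(chunk)
    return terms


@dataclass
class DesignSpec:
    """An encoded model matrix plus the term structure that produced it.

    Parameters
    ----------
    data : pandas.DataFrame
        Covariate table, one row per observation.
    formula : str
        Terms joined by ``+``; ``a*b`` expands to ``a + b + a:b``.
    categorical : sequence of str, optional
        Columns to force categorical.  Object/category/bool columns are
        treated as categorical automatically.
    levels : dict, optional
        Mapping column -> level order.  Used internally so that row
        subsets (case resampling) keep the coding of the parent design.
    """

    data: pd.DataFrame
    formula: str
    categorical: tuple[str, ...] | None = None
    levels: dict[str, list] | None = None

    matrix: np.ndarray = field(init=False, repr=False)
    columns: list[str] = field(init=False, repr=False)
    terms: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data).reset_index(drop=True)
        term_labels = _parse_formula(self.formula)
        if self.levels is None:
            self.levels = {}
            for name in self.data.columns:
                if self._is_categorical(name):
                    self.levels[name] = sorted(pd.unique(self.data[name]).tolist())
        cols: list[np.ndarray] = [np.ones(len(self.data))]
        names: list[str] = ["Intercept"]
        terms: dict[str, list[int]] = {"Intercept": [0]}
        for term in term_labels:
            block, block_names = self._encode_term(term)
            idx = list(range(len(names), len(names) + len(block_names)))
            terms[term] = idx
            cols.extend(block)
            names.extend(block_names)
        self.matrix = np.column_stack(cols) if cols else np.empty((len(self.data), 0))
        self.columns = names
        self.terms = terms

    # -- encoding -----------------------------------------------------------

    def _is_categorical(self, name: str) -> bool:
        if name not in self.data.columns:
            raise KeyError(f"covariate {name!r} not in design table")
        if self.categorical and name in self.categorical:
            return True
        dt = self.data[name].dtype
        return dt == object or isinstance(dt, pd.CategoricalDtype) or dt == bool

    def _dummies(self, name: str) -> tuple[list[np.ndarray], list[str]]:
        lv = self.levels.get(name)
        if lv is None:  # numeric pass-through
            return [self.data[name].to_numpy(dtype=float)], [name]
        vals = self.data[name].to_numpy()
        unknown = set(np.unique(vals)) - set(lv)
        if unknown:
            raise ValueError(f"unseen level(s) {unknown} in covariate {name!r}")
        return (
            [(vals == l).astype(float) for l in lv[1:]],
            [f"{name}[{l}]" for l in lv[1:]],
        )

    def _encode_term(self, term: str) -> tuple[list[np.ndarray], list[str]]:
        parts = term.split(":")
        if len(parts) == 1:
            return self._dummies(parts[0])
        if len(parts) != 2:
            raise ValueError(f"only two-way interactions are supported: {term!r}")
        a_cols, a_names = self._dummies(parts[0])
        b_cols, b_names = self._dummies(parts[1])
        cols, names = [], []
        for ac, an in zip(a_cols, a_names):
            for bc, bn in zip(b_cols, b_names):
                cols.append(ac * bc)
                names.append(f"{an}:{bn}")
        return cols, names

    # -- queries ------------------------------------------------------------

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def full_rank(self) -> bool:
        return np.linalg.matrix_rank(self.matrix) == self.k

    def tested_term_columns(self, null: "DesignSpec") -> list[int]:
        """Column indices of terms present here but absent from ``null``."""
        missing = set(null.terms) - set(self.terms)
        if missing:
            raise ValueError(f"null terms {missing} not nested in alternative")
        idx: list[int] = []
        for term, cols in self.terms.items():
            if term not in null.terms:
                idx.extend(cols)
        if not idx:
            raise ValueError("designs are identical; no tested terms")
        return idx

    def tested_matrix(self, null: "DesignSpec") -> np.ndarray:
        return self.matrix[:, self.tested_term_columns(null)]

    def subset(self, rows) -> "DesignSpec":
        """Row subset keeping the level coding of the parent design."""
        return DesignSpec(
            self.data.iloc[np.asarray(rows)],
            self.formula,
            categorical=self.categorical,
            levels=self.levels,
        )
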