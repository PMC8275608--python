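"""Transition-probability design matrices.

Each off-diagonal transition logit is a linear predictor over a shared design
matrix built from per-step covariates.  The column layout is fixed:

    intercept | colony | main effects ... | colony interactions ...

The ``colony`` column is the binary indicator of the non-reference colony.
Every other term can carry a colony interaction (term x colony), so "excluding
a covariate's interaction" or "excluding all its terms" is a column drop.

The time-of-day term is expanded into K harmonic pairs
``sin(2*pi*k*h/24), cos(2*pi*k*h/24)`` so the diel cycle enters the logit
periodically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOUR_TERM = "hour"
COLONY_TERM = "colony"


@dataclass(frozen=True)
class Term:
    """One covariate term of the transition formula."""

    name: str
    interact_colony: bool = True


@dataclass
class DesignInfo:
    """Column layout of a built design matrix.

    ``term_columns`` maps each covariate name to the indices of its main-effect
    columns and its colony-interaction columns, which is what the exclusion
    ladder drops.
    """

    columns: list[str]
    term_columns: dict[str, dict[str, list[int]]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def signature(self) -> str:
        return "|".join(self.columns)

    def drop(self, names: list[str]) -> "DesignInfo":
        """Layout after removing the named columns (for reduced models)."""
        keep = [c for c in self.columns if c not in set(names)]
        info = DesignInfo(columns=keep)
        # term_columns indices are rebuilt lazily by build_design on refit
        return info


def _harmonic_columns(hours: np.ndarray, harmonics: int) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for k in range(1, harmonics + 1):
        w = 2.0 * np.pi * k * hours / 24.0
        cols.append(np.sin(w))
        cols.append(np.cos(w))
        names.append(f"hour_sin{k}")
        names.append(f"hour_cos{k}")
    return np.column_stack(cols), names


def build_design(
    df: pd.DataFrame,
    terms: list[Term],
    harmonics: int = 1,
) -> tuple[np.ndarray, DesignInfo]:
    """Build the transition design matrix from a per-step covariate table.

    Parameters
    ----------
    df
        One row per step.  Must contain a column per term name; ``hour`` holds
        the raw hour of day in [0, 24) and is trig-expanded; ``colony`` is the
        0/1 indicator of the non-reference colony.
    terms
        Ordered covariate terms.  A ``colony`` term contributes the indicator
        column; its ``interact_colony`` flag is ignored.
    harmonics
        Number of harmonic pairs for the time-of-day expansion (K >= 1).

    Returns
    -------
    X : (n, p) float array
    info : DesignInfo
    """
    if harmonics < 1:
        raise ValueError("harmonics must be >= 1")
    n = len(df)
    names = [t.name for t in terms]
    for name in names:
        if name not in df.columns and name != HOUR_TERM:
            raise KeyError(f"covariate column {name!r} missing from data")
    if HOUR_TERM in names and HOUR_TERM not in df.columns:
        raise KeyError("time-of-day term requires an 'hour' column")

    has_colony = COLONY_TERM in names
    colony = None
    if has_colony:
        colony = np.asarray(df[COLONY_TERM], dtype=float)
        bad = ~np.isin(colony[np.isfinite(colony)], (0.0, 1.0))
        if bad.any():
            raise ValueError("colony indicator must be 0/1")

    cols: list[np.ndarray] = [np.ones(n)]
    colnames: list[str] = ["intercept"]
    term_cols: dict[str, dict[str, list[int]]] = {}

    if has_colony:
        cols.append(colony)
        colnames.append(COLONY_TERM)
        term_cols[COLONY_TERM] = {"main": [1], "interaction": []}

    main_blocks: dict[str, tuple[np.ndarray, list[str]]] = {}
    for t in terms:
        if t.name == COLONY_TERM:
            continue
        if t.name == HOUR_TERM:
            block, bnames = _harmonic_columns(np.asarray(df[HOUR_TERM], dtype=float), harmonics)
        else:
            block = np.asarray(df[t.name], dtype=float)[:, None]
            bnames = [t.name]
        main_blocks[t.name] = (block, bnames)
        idx0 = len(colnames)
        cols.extend(block.T)
        colnames.extend(bnames)
        term_cols[t.name] = {"main": list(range(idx0, idx0 + block.shape[1])), "interaction": []}

    for t in terms:
        if t.name == COLONY_TERM or not t.interact_colony:
            continue
        if not has_colony:
            raise ValueError(f"term {t.name!r} requests a colony interaction but no colony term is present")
        block, bnames = main_blocks[t.name]
        idx0 = len(colnames)
        cols.extend((block * colony[:, None]).T)
        colnames.extend([f"{b}:colony" for b in bnames])
        term_cols[t.name]["interaction"] = list(range(idx0, idx0 + block.shape[1]))

    # colony's "interaction" set, for the ladder, is every interaction column
    if has_colony:
        all_inter = [i for tc in term_cols.values() for i in tc["interaction"]]
        term_cols[COLONY_TERM]["interaction"] = sorted(all_inter)

    X = np.column_stack(cols)
    return X, DesignInfo(columns=colnames, term_columns=term_cols)
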