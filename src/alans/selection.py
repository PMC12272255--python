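"""Conjunction selection of lateralized task-involved regions.

A homotopic pair of regions (one per hemisphere) contributes at most one
region to the atlas.  A hemisphere's region is retained when, across
participants, (1) its task contrast is significantly positive and (2) it is
significantly larger than the contrast of its mirror region, both at the
Bonferroni-corrected per-test level ``alpha_family / n_pairs``.  The overall
level of the conjunction is the square of the per-test level: with the
default 0.05 family rate over 185 pairs the per-test level is
0.05/185 ~= 2.7e-4 and the conjunction level ~= 7.3e-8.

Significance convention: the default reads "significantly positive" as a
two-sided p below the per-test level together with a positive t (equivalent
to a one-sided test at half the level); set ``two_sided=False`` for the
one-sided reading at the full level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ContrastTable",
    "SelectionResult",
    "activation_test",
    "asymmetry_test",
    "conjunction_select",
    "ConjunctionSelector",
]

_SIDES = ("Left", "Right")


@dataclass(frozen=True)
class ContrastTable:
    """Per-participant task contrasts for homotopic region pairs.

    ``values`` has shape (participants, pairs, 2) with the last axis ordered
    (Left, Right), in arbitrary task units.
    """

    values: np.ndarray
    participant_ids: tuple[str, ...]
    pair_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != 2:
            raise ValueError("values must have shape (participants, pairs, 2)")
        if v.shape[0] != len(self.participant_ids) or v.shape[1] != len(self.pair_ids):
            raise ValueError("id lists do not match the values array shape")
        if not np.all(np.isfinite(v)):
            raise ValueError("contrast values must be finite: every (participant, pair) "
                             "needs both a left and a right value")
        object.__setattr__(self, "values", v)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]

    def left(self) -> np.ndarray:
        return self.values[:, :, 0]

    def right(self) -> np.ndarray:
        return self.values[:, :, 1]

    def drop_pairs(self, pair_ids) -> "ContrastTable":
        """Mask out pairs (e.g. susceptibility-artifact exclusions)."""
        drop = set(pair_ids)
        unknown = drop - set(self.pair_ids)
        if unknown:
            raise ValueError(f"unknown pair ids: {sorted(unknown)}")
        keep = [i for i, p in enumerate(self.pair_ids) if p not in drop]
        return ContrastTable(
            self.values[:, keep, :],
            self.participant_ids,
            tuple(self.pair_ids[i] for i in keep),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV: participant, pair_id, hemisphere, value."""
        n_p, n_q, _ = self.values.shape
        df = pd.DataFrame(
            {
                "participant": np.repeat(self.participant_ids, n_q * 2),
                "pair_id": np.tile(np.repeat(self.pair_ids, 2), n_p),
                "hemisphere": np.tile(_SIDES, n_p * n_q),
                "value": self.values.reshape(-1),
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContrastTable":
        df = pd.read_csv(path, sep="\t", dtype={"participant": str, "pair_id": str},
                         float_precision="round_trip")
        participants = tuple(pd.unique(df["participant"]))
        pairs = tuple(pd.unique(df["pair_id"]))
        values = np.full((len(participants), len(pairs), 2), np.nan)
        p_idx = {p: i for i, p in enumerate(participants)}
        q_idx = {q: i for i, q in enumerate(pairs)}
        s_idx = {s: i for i, s in enumerate(_SIDES)}
        values[
            df["participant"].map(p_idx),
            df["pair_id"].map(q_idx),
            df["hemisphere"].map(s_idx),
        ] = df["value"].to_numpy()
        return cls(values, participants, pairs)


def activation_test(values: np.ndarray) -> tuple[float, float]:
    """One-sample t of the mean against zero, with its two-sided p.

    ``values`` are one region's contrasts across participants (>= 3).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("need a 1-d array of >= 3 participant values")
    if np.ptp(values) == 0.0:
        raise ValueError("zero variance across participants: t undefined")
    res = stats.ttest_1samp(values, 0.0)
    return float(res.statistic), float(res.pvalue)


def asymmetry_test(left: np.ndarray, right: np.ndarray) -> tuple[float, float]:
    """Paired t on (left - right); the sign of t encodes the direction."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1 or left.size < 3:
        raise ValueError("need paired 1-d arrays of >= 3 participant values")
    diff = left - right
    if np.ptp(diff) == 0.0:
        raise ValueError("zero variance of paired differences: t undefined")
    res = stats.ttest_rel(left, right)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class SelectionResult:
    """Per-pair conjunction outcome plus the run-level thresholds."""

    table: pd.DataFrame
    per_test_alpha: float
    conjunction_alpha: float
    alpha_family: float
    n_pairs_corrected: int

    @property
    def selected_regions(self) -> tuple[tuple[str, str], ...]:
        """(pair_id, hemisphere) for each selected region, in table order."""
        sel = self.table[self.table["selected"]]
        return tuple(zip(sel["pair_id"], sel["hemisphere"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _vector_tests(table: ContrastTable, two_sided: bool) -> pd.DataFrame:
    """Vectorized per-pair activation and asymmetry t-tests."""
    left, right = table.left(), table.right()
    t_l, p_l = stats.ttest_1samp(left, 0.0, axis=0)
    t_r, p_r = stats.ttest_1samp(right, 0.0, axis=0)
    t_a, p_a = stats.ttest_rel(left, right, axis=0)
    if not two_sided:
        # one-sided reading: halve the p on the favored side
        p_l = np.where(t_l > 0, p_l / 2, 1 - p_l / 2)
        p_r = np.where(t_r > 0, p_r / 2, 1 - p_r / 2)
        p_a = p_a / 2  # direction applied downstream via the sign of t_a
    return pd.DataFrame(
        {
            "pair_id": table.pair_ids,
            "act_t_left": t_l,
            "act_p_left": p_l,
            "act_t_right": t_r,
            "act_p_right": p_r,
            "asym_t": t_a,
            "asym_p": p_a,
        }
    )


def conjunction_select(
    table: ContrastTable,
    alpha_family: float = 0.05,
    n_pairs: int | None = None,
    two_sided: bool = True,
) -> SelectionResult:
    """Apply the activation-and-asymmetry conjunction to every pair.

    ``n_pairs`` sets the Bonferroni correction (defaults to the number of
    pairs in the table).  A pair contributes one selected region, on the
    hemisphere favored by a significant asymmetry, provided that
    hemisphere's activation is significantly positive at the same per-test
    level.
    """
    if n_pairs is None:
        n_pairs = table.n_pairs
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    per_test_alpha = alpha_family / n_pairs
    conjunction_alpha = per_test_alpha**2

    df = _vector_tests(table, two_sided)
    favored = np.where(df["asym_t"] > 0, "Left", "Right")
    act_t_fav = np.where(favored == "Left", df["act_t_left"], df["act_t_right"])
    act_p_fav = np.where(favored == "Left", df["act_p_left"], df["act_p_right"])
    selected = (
        (df["asym_p"].to_numpy() < per_test_alpha)
        & (act_p_fav < per_test_alpha)
        & (act_t_fav > 0)
    )
    df["selected"] = selected
    df["hemisphere"] = np.where(selected, favored, "")
    return SelectionResult(
        table=df,
        per_test_alpha=per_test_alpha,
        conjunction_alpha=conjunction_alpha,
        alpha_family=alpha_family,
        n_pairs_corrected=n_pairs,
    )


class ConjunctionSelector(BaseEstimator):
    """Sklearn-style estimator wrapping the conjunction selection.

    Parameters
    ----------
    alpha_family : float, default 0.05
        Family-wise error rate before Bonferroni correction.
    n_pairs : int or None, default None
        Number of pairs for the correction; None uses the fitted table's
        pair count.
    two_sided : bool, default True
        Significance convention (see module docstring).

    Attributes (after ``fit``)
    --------------------------
    result_ : SelectionResult
    per_test_alpha_, conjunction_alpha_ : float
    selected_pairs_ : tuple of (pair_id, hemisphere)
    n_selected_ : int
    """

    def __init__(self, alpha_family: float = 0.05, n_pairs: int | None = None,
                 two_sided: bool = True):
        self.alpha_family = alpha_family
        self.n_pairs = n_pairs
        self.two_sided = two_sided

    def fit(self, X: ContrastTable, y=None) -> "ConjunctionSelector":
        if not isinstance(X, ContrastTable):
            X = ContrastTable(
                np.asarray(X),
                tuple(f"p{i:03d}" for i in range(np.asarray(X).shape[0])),
                tuple(f"pair{i:03d}" for i in range(np.asarray(X).shape[1])),
            )
        self.result_ = conjunction_select(
            X, alpha_family=self.alpha_family, n_pairs=self.n_pairs,
            two_sided=self.two_sided,
        )
        self.per_test_alpha_ = self.result_.per_test_alpha
        self.conjunction_alpha_ = self.result_.conjunction_alpha
        self.selected_pairs_ = self.result_.selected_regions
        self.n_selected_ = len(self.selected_pairs_)
        return self

    def get_support(self) -> np.ndarray:
        """Boolean mask over pairs, True where a region was selected."""
        return self.result_.table["selected"].to_numpy()
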