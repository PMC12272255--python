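"""Inter-network coupling and its exact sign test.

For every unordered pair of networks, each participant contributes the
arithmetic mean of the pairwise correlations between the two networks'
regions; the group value is the plain mean of those per-participant means
(deliberately not Fisher-averaged — the group connectivity matrix and the
inter-network summary follow two different reported conventions).  The sign
of the coupling is tested with an exact binomial sign test at 1/2, two-sided
by doubling the smaller tail and capping at 1; exact zeros are dropped.
Significance is Bonferroni-adjusted over the C(n_networks, 2) pairs — with
five networks, 10 comparisons and an adjusted level of 0.005.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .connectivity import ConnectivityStack

__all__ = [
    "participant_pair_mean",
    "sign_test",
    "adjusted_alpha",
    "SignTestResult",
    "InterNetworkSignTest",
]


def _members_index(region_ids, members) -> np.ndarray:
    idx = {r: i for i, r in enumerate(region_ids)}
    missing = [m for m in members if m not in idx]
    if missing:
        raise ValueError(f"regions not in stack: {missing}")
    return np.array([idx[m] for m in members], dtype=int)


def participant_pair_mean(
    stack: ConnectivityStack, members_a, members_b
) -> np.ndarray:
    """Per-participant mean correlation over all (A-region, B-region) pairs."""
    if len(members_a) == 0 or len(members_b) == 0:
        raise ValueError("empty network")
    ia = _members_index(stack.region_ids, members_a)
    ib = _members_index(stack.region_ids, members_b)
    if set(ia) & set(ib):
        raise ValueError("networks overlap")
    block = stack.matrices[:, ia][:, :, ib]
    return block.mean(axis=(1, 2))


@dataclass(frozen=True)
class SignTestResult:
    n_pos: int
    n_neg: int
    n_zero: int
    p_value: float


def sign_test(values: np.ndarray) -> SignTestResult:
    """Exact two-sided binomial sign test at success probability 1/2.

    Exact zeros are dropped; p = min(1, 2 * min(P(X <= n_pos), P(X >= n_pos)))
    with X ~ Binomial(n_pos + n_neg, 1/2) — the smaller observed tail,
    doubled and capped at 1.
    """
    values = np.asarray(values, dtype=float)
    n_pos = int(np.sum(values > 0))
    n_neg = int(np.sum(values < 0))
    n_zero = int(np.sum(values == 0))
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("all values exactly zero: sign test undefined")
    lower = stats.binom.cdf(n_pos, n, 0.5)     # P(X <= n_pos)
    upper = stats.binom.sf(n_pos - 1, n, 0.5)  # P(X >= n_pos)
    p = min(1.0, 2.0 * min(lower, upper))
    return SignTestResult(n_pos=n_pos, n_neg=n_neg, n_zero=n_zero, p_value=float(p))


def adjusted_alpha(n_networks: int, alpha_family: float = 0.05) -> float:
    """Bonferroni level over the C(n_networks, 2) unordered network pairs."""
    if n_networks < 2:
        raise ValueError("need >= 2 networks")
    return alpha_family / comb(n_networks, 2)


class InterNetworkSignTest(BaseEstimator):
    """Estimator testing the sign of every inter-network coupling.

    Parameters
    ----------
    alpha_family : float, default 0.05
        Family-wise level, Bonferroni-divided by the number of network pairs.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame with one row per unordered network pair
        (network_a, network_b, group_r, n_pos, n_neg, n_zero, p_value,
        significant).
    adjusted_alpha_ : float
    """

    def __init__(self, alpha_family: float = 0.05):
        self.alpha_family = alpha_family

    def fit(self, X: ConnectivityStack, y: dict | None = None) -> "InterNetworkSignTest":
        """``X`` is the connectivity stack; ``y`` maps network -> member ids."""
        if y is None:
            raise ValueError("network membership mapping is required")
        networks = list(y)
        self.adjusted_alpha_ = adjusted_alpha(len(networks), self.alpha_family)
        rows = []
        for a, b in itertools.combinations(networks, 2):
            vals = participant_pair_mean(X, y[a], y[b])
            res = sign_test(vals)
            rows.append(
                {
                    "network_a": a,
                    "network_b": b,
                    "group_r": float(vals.mean()),
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "n_zero": res.n_zero,
                    "p_value": res.p_value,
                    "significant": res.p_value < self.adjusted_alpha_,
                }
            )
        self.results_ = pd.DataFrame(rows)
        return self
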