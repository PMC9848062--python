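"""Regression and virtual-screening metrics.

MSE and concordance index (CI) for affinity regression; enrichment factor
(EF) and BEDROC for ranked screens.  EF supports both the literature-standard
definition (active recall in the top fraction divided by the fraction) and a
decoy-referenced variant (fraction of actives retrieved at the score where
the given fraction of decoys has been retrieved).  BEDROC follows the
Truchon-Bailey formulation with the early-recognition parameter alpha
(alpha = 80.5 weights roughly the top 2% of the list).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def mse(pred, target) -> float:
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("prediction/target length mismatch")
    if pred.size == 0:
        raise ValueError("mse needs at least one observation")
    return float(np.mean((pred - target) ** 2))


def concordance_index(pred, target) -> float:
    """Fraction of label-discriminating pairs predicted in the right order.

    Pairs with tied targets are excluded; tied predictions earn half credit.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape or pred.size < 2:
        raise ValueError("need >= 2 paired observations")
    dt = target[:, None] - target[None, :]
    dp = pred[:, None] - pred[None, :]
    iu = np.triu_indices(pred.size, k=1)
    dt, dp = dt[iu], dp[iu]
    comparable = dt != 0
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("concordance index undefined: all targets equal")
    concordant = (np.sign(dp[comparable]) == np.sign(dt[comparable])).sum()
    tied = (dp[comparable] == 0).sum()
    return float((concordant + 0.5 * tied) / n_pairs)


@dataclass
class RankedScreen:
    """Scores and activity flags for a virtual screen."""

    scores: np.ndarray
    is_active: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.is_active = np.asarray(self.is_active).astype(bool)
        if self.scores.shape != self.is_active.shape:
            raise ValueError("scores and activity flags must align")

    @property
    def N(self) -> int:
        return int(self.scores.size)

    @property
    def n(self) -> int:
        return int(self.is_active.sum())

    def ranking(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Indices in descending score order; stable ties unless ``rng``."""
        if rng is not None:
            jitter = rng.permutation(self.N)
            order = np.lexsort((jitter, -self.scores))
        else:
            if np.unique(self.scores).size < self.N:
                warnings.warn(
                    "tied scores ranked by stable input order",
                    stacklevel=2,
                )
            order = np.argsort(-self.scores, kind="stable")
        return order


def _check_screen(screen: RankedScreen) -> None:
    if screen.n == 0 or screen.n == screen.N:
        raise ValueError(
            "enrichment metrics need both actives and inactives "
            f"(n={screen.n}, N={screen.N})"
        )


def enrichment_factor(
    screen: RankedScreen,
    fraction: float,
    definition: str = "standard",
    rng: np.random.Generator | None = None,
) -> float:
    """EF at the given list fraction.

    standard: (actives in top ceil(fraction*N) / n) / fraction.
    decoy-referenced: recall of actives at the rank where ``fraction`` of the
    decoys has been retrieved, divided by ``fraction``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    _check_screen(screen)
    order = screen.ranking(rng)
    active_sorted = screen.is_active[order]
    if definition == "standard":
        top = int(np.ceil(fraction * screen.N))
        recall = active_sorted[:top].sum() / screen.n
        return float(recall / fraction)
    if definition == "decoy-referenced":
        n_decoys = screen.N - screen.n
        decoy_cum = np.cumsum(~active_sorted)
        target_decoys = fraction * n_decoys
        reached = np.nonzero(decoy_cum >= target_decoys)[0]
        cut = int(reached[0]) + 1 if reached.size else screen.N
        recall = active_sorted[:cut].sum() / screen.n
        return float(recall / fraction)
    raise ValueError("definition must be 'standard' or 'decoy-referenced'")


def bedroc(
    screen: RankedScreen,
    alpha: float = 80.5,
    rng: np.random.Generator | None = None,
) -> float:
    """Boltzmann-enhanced discrimination of ROC (Truchon-Bailey).

    RIE = (sum over actives of exp(-alpha * r_i / N))
          / (n/N * (1 - exp(-alpha)) / (exp(alpha/N) - 1))
    BEDROC = RIE * Ra * sinh(alpha/2)
             / (cosh(alpha/2) - cosh(alpha/2 - alpha*Ra))
             + 1 / (1 - exp(alpha * (1 - Ra)))
    with Ra = n/N and r_i the 1-based rank of each active; bounded in [0, 1].
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    _check_screen(screen)
    order = screen.ranking(rng)
    ranks = np.nonzero(screen.is_active[order])[0] + 1  # 1-based
    N, n = screen.N, screen.n
    ra = n / N
    rie = np.sum(np.exp(-alpha * ranks / N)) / (
        ra * (1 - np.exp(-alpha)) / (np.exp(alpha / N) - 1)
    )
    val = rie * ra * np.sinh(alpha / 2) / (
        np.cosh(alpha / 2) - np.cosh(alpha / 2 - alpha * ra)
    ) + 1 / (1 - np.exp(alpha * (1 - ra)))
    return float(val)


def evaluate_regression(pred, target) -> dict[str, float]:
    return {"mse": mse(pred, target), "ci": concordance_index(pred, target)}


def evaluate_screening(
    scores, is_active, ef_fraction: float = 0.01, alpha: float = 80.5,
    ef_definition: str = "standard",
) -> dict[str, float]:
    screen = RankedScreen(scores, is_active)
    return {
        f"ef@{ef_fraction:g}": enrichment_factor(
            screen, ef_fraction, definition=ef_definition
        ),
        f"bedroc@{alpha:g}": bedroc(screen, alpha),
    }
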