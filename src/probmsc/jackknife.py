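"""Weighted delete-one-block jackknife over loci.

Loci contribute very different numbers of divergent sites, so a plain
delete-one jackknife over loci would mis-weight the variability.  The
unequal-block-size (delete-m_j) jackknife of Busing, Meijer & van der Leeden
(1999) is used instead: with n total sites over g loci, locus j carrying
m_j sites gets h_j = n / m_j, pseudo-values

    p_j = h_j * theta_hat - (h_j - 1) * theta_tilde_j,

the weighted-jackknife estimate theta_J = g*theta_hat - sum_j (1 - m_j/n) *
theta_tilde_j, and variance

    var = (1/g) * sum_j (p_j - theta_J)^2 / (h_j - 1).

With equal block sizes this reduces exactly to the classical delete-one
jackknife.  This is the sole uncertainty engine for every headline statistic
(divergence ratios, rate tests, ILS rates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .sites import DivergentSiteTable


@dataclass
class JackknifeResult:
    """A statistic with its weighted-jackknife uncertainty.

    ``p`` is the two-sided normal p-value from ``z = estimate / se`` unless
    computed by a caller that documents a one-sided use.
    """

    estimate: float
    se: float
    z: float
    p: float
    blocks: int
    weights: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover
        return (f"JackknifeResult(estimate={self.estimate:.6g}, se={self.se:.3g}, "
                f"z={self.z:.3g}, p={self.p:.3g}, blocks={self.blocks})")


def weighted_jackknife_values(
    estimate: float,
    leave_one_out: Sequence[float],
    weights: Sequence[float],
) -> tuple[float, float]:
    """Weighted-jackknife (estimate, se) from precomputed delete-one values.

    ``weights`` are the block sizes m_j (here: divergent sites per locus).
    """
    theta = float(estimate)
    loo = np.asarray(leave_one_out, dtype=float)
    m = np.asarray(weights, dtype=float)
    if len(loo) != len(m):
        raise ValueError("leave_one_out and weights length mismatch")
    if len(loo) < 2:
        raise ValueError("weighted jackknife needs >=2 blocks")
    if np.any(m <= 0):
        raise ValueError("block weights must be positive")
    n = m.sum()
    g = len(m)
    h = n / m
    theta_j = g * theta - float(((1.0 - m / n) * loo).sum())
    pseudo = h * theta - (h - 1.0) * loo
    var = float(((pseudo - theta_j) ** 2 / (h - 1.0)).sum()) / g
    return theta_j, math.sqrt(max(var, 0.0))


def weighted_jackknife(
    statistic: Callable[[DivergentSiteTable], float],
    table: DivergentSiteTable,
) -> JackknifeResult:
    """Delete each locus in turn, recompute ``statistic``, combine.

    Loci with zero divergent sites carry no weight and are skipped (they
    cannot change a site-count statistic).  A statistic that fails on some
    delete-one subtable raises, naming the locus.
    """
    theta = float(statistic(table))
    sizes = table.sites_per_locus()
    loci = [l for l in sizes.index if sizes[l] > 0]
    if len(loci) < 2:
        raise ValueError("weighted jackknife needs >=2 loci with divergent sites")
    loo = []
    for locus in loci:
        sub = table.drop_locus(locus)
        try:
            loo.append(float(statistic(sub)))
        except Exception as exc:
            raise ValueError(f"statistic undefined with locus {locus!r} removed: {exc}") from exc
    weights = sizes.loc[loci].to_numpy(dtype=float)
    _, se = weighted_jackknife_values(theta, loo, weights)
    if se > 0:
        z = theta / se
        p = 2.0 * float(norm.sf(abs(z)))
    else:
        z = math.inf if theta != 0 else 0.0
        p = 0.0 if theta != 0 else 1.0
    return JackknifeResult(estimate=theta, se=se, z=z, p=p,
                           blocks=len(loci), weights=weights)
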