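"""Genetic divergence, heterozygosity, relative-rate tests and calibration.

All quantities are expected-mismatch sums over polarized divergent sites with
complete data: for taxa x, y with per-site derived-allele frequencies f_x,
f_y in {0, 1/2, 1}, the divergence contribution of a site is

    f_x (1 - f_y) + f_y (1 - f_x),

the probability that one chromosome drawn from each taxon carries different
alleles.  Within-taxon "divergence" is heterozygosity: the count of
heterozygous genotypes in the designated individual (the expected mismatch
of its two chromosomes drawn without replacement, 2 f (1-f) * n/(n-1) with
n = 2).  Cross-taxon divergences are reported normalized by the
savanna-Asian divergence t_SA, which therefore carries no uncertainty.

The relative rate test compares lineage-specific derived-site counts
n_x = sum f_x (1 - f_y) and n_y = sum f_y (1 - f_x) since the x/y split via
the normalized difference (n_x - n_y) / (n_x + n_y), with a weighted-jackknife
z and two-sided normal p (a Tajima-style clock/data-quality check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .jackknife import JackknifeResult, weighted_jackknife
from .sites import DivergentSiteTable
from .taxa import ELEPHANTIDS, Taxon

#: Normalizer pair: savanna-Asian divergence.
NORMALIZER_PAIR: tuple[Taxon, Taxon] = (Taxon.SAVANNA, Taxon.ASIAN)


def _freqs(table: DivergentSiteTable, x: Taxon) -> np.ndarray:
    return table.frequencies(x)


def pairwise_divergence(table: DivergentSiteTable, x: Taxon | str, y: Taxon | str) -> float:
    """Expected-mismatch divergence between taxa (heterozygosity if x == y).

    Operates on the complete-site subset of a polarized table.  Sites fixed
    derived in both taxa contribute zero, so including elephantid-fixed
    sites does not change cross-taxon divergences.
    """
    x, y = Taxon(x), Taxon(y)
    sub = table.complete()
    if len(sub) == 0:
        raise ValueError("empty site table: divergence undefined")
    fx = _freqs(sub, x)
    if x == y:
        # count of heterozygous genotypes in the designated individual;
        # equals expected mismatch of its two chromosomes drawn without
        # replacement, 2 f (1-f) * n/(n-1) with n = 2
        return float(np.sum(fx == 0.5))
    fy = _freqs(sub, y)
    return float(np.sum(fx * (1.0 - fy) + fy * (1.0 - fx)))


@dataclass
class DivergenceMatrix:
    """All pairwise divergences and heterozygosities, with t_SA normalization.

    ``values[(x, y)]`` holds raw expected-mismatch sums (x == y entries are
    heterozygosities); ``normalized`` divides everything by the savanna-Asian
    entry; ``se`` holds weighted-jackknife standard errors of the normalized
    values (the normalizer itself has SE exactly 0 by construction).
    """

    values: dict[tuple[Taxon, Taxon], float]
    normalized: dict[tuple[Taxon, Taxon], float]
    se: dict[tuple[Taxon, Taxon], float] = field(default_factory=dict)
    rate_test_p: dict[tuple[Taxon, Taxon], float] = field(default_factory=dict)

    @property
    def t_sa(self) -> float:
        return self.values[NORMALIZER_PAIR]

    def get(self, x: Taxon | str, y: Taxon | str, normalized: bool = True) -> float:
        x, y = Taxon(x), Taxon(y)
        key = (x, y) if (x, y) in self.values else (y, x)
        return self.normalized[key] if normalized else self.values[key]

    def distance_frame(self, include_outgroup: bool = True) -> pd.DataFrame:
        """Symmetric normalized-distance matrix (mastodon distances are
        dominated by elephantid-mastodon fixed differences; used by NJ)."""
        taxa = [*ELEPHANTIDS, Taxon.MASTODON] if include_outgroup else list(ELEPHANTIDS)
        names = [t.value for t in taxa]
        mat = pd.DataFrame(0.0, index=names, columns=names)
        for x, y in combinations(taxa, 2):
            v = self.get(x, y)
            mat.loc[x.value, y.value] = mat.loc[y.value, x.value] = v
        return mat


def divergence_matrix(
    table: DivergentSiteTable,
    with_uncertainty: bool = True,
    with_rate_tests: bool = False,
) -> DivergenceMatrix:
    """Compute all 10 cross-taxon divergences (including mastodon pairs) and
    the 4 elephantid heterozygosities, normalized by t_SA.

    Jackknife SEs are for the normalized statistics; rate-test p-values are
    attached for elephantid pairs when requested.
    """
    taxa = [*ELEPHANTIDS, Taxon.MASTODON]
    values: dict[tuple[Taxon, Taxon], float] = {}
    for x, y in combinations(taxa, 2):
        values[(x, y)] = pairwise_divergence(table, x, y)
    for x in ELEPHANTIDS:
        values[(x, x)] = pairwise_divergence(table, x, x)
    t_sa = values[NORMALIZER_PAIR] if NORMALIZER_PAIR in values else values[NORMALIZER_PAIR[::-1]]
    if t_sa <= 0:
        raise ValueError("savanna-Asian divergence is zero: cannot normalize")
    normalized = {k: v / t_sa for k, v in values.items()}
    mat = DivergenceMatrix(values=values, normalized=normalized)
    if with_uncertainty:
        for key in values:
            x, y = key

            def stat(sub: DivergentSiteTable, x=x, y=y) -> float:
                return pairwise_divergence(sub, x, y) / pairwise_divergence(sub, *NORMALIZER_PAIR)

            mat.se[key] = weighted_jackknife(stat, table).se
    if with_rate_tests:
        for x, y in combinations(ELEPHANTIDS, 2):
            res = relative_rate_test(table, x, y)
            mat.rate_test_p[(x, y)] = res.p
    return mat


def relative_rate_test(table: DivergentSiteTable, x: Taxon | str, y: Taxon | str,
                       denominator: str = "pairwise") -> JackknifeResult:
    """Tajima-style relative rate test between two taxa.

    Statistic: (n_x - n_y) / D, the normalized difference of
    lineage-specific derived-site counts since the x/y split (polarized by
    the mastodon outgroup).  The default normalizer D is pairwise-restricted
    (n_x + n_y); ``denominator="global"`` divides by the total divergent-site
    count instead, an alternative reading of "normalized by the total number
    of divergent sites".  Undefined when n_x + n_y = 0.
    """
    x, y = Taxon(x), Taxon(y)
    if x == y:
        raise ValueError("relative rate test needs two distinct taxa")
    if not table.polarized:
        raise ValueError("relative rate test requires a polarized (mastodon-rooted) table")
    if denominator not in ("pairwise", "global"):
        raise ValueError("denominator must be 'pairwise' or 'global'")

    def stat(sub: DivergentSiteTable) -> float:
        s = sub.complete()
        fx, fy = _freqs(s, x), _freqs(s, y)
        nx = float(np.sum(fx * (1.0 - fy)))
        ny = float(np.sum(fy * (1.0 - fx)))
        if nx + ny == 0:
            raise ValueError(f"no lineage-specific sites between {x.value} and {y.value}")
        d = (nx + ny) if denominator == "pairwise" else float(len(s))
        return (nx - ny) / d

    return weighted_jackknife(stat, table)


def pooled_heterozygosity(table: DivergentSiteTable, taxon: Taxon | str,
                          extra_column: str = "A2") -> float:
    """Diversity pooled across two sequenced individuals of one taxon.

    For sites where a second individual's genotype column is present (the
    optional A2 column for the second Asian elephant), the four pooled
    chromosomes give an expected mismatch of 2 f (1-f) * n/(n-1) with
    n = 4 per site — the across-individuals counterpart of the within-
    individual heterozygosity count.  Sites lacking the extra column's call
    are skipped.
    """
    taxon = Taxon(taxon)
    if extra_column not in table.df.columns:
        raise ValueError(f"no {extra_column!r} column in the site table")
    sub = table.complete()
    extra = pd.to_numeric(sub.df[extra_column], errors="coerce").to_numpy(dtype=float)
    main = sub.df[taxon.value].to_numpy(dtype=float)
    ok = np.isfinite(extra)
    f = (main[ok] + extra[ok]) / 4.0
    return float(np.sum(2.0 * f * (1.0 - f) * (4.0 / 3.0)))


@dataclass
class CalibrationWindow:
    """Fossil calibration of the African-Eurasian split used to convert
    dimensionless split-time ratios to absolute ages."""

    t_lox_eur_mya: tuple[float, float] = (4.2, 9.0)
    generation_years: float = 31.0

    def __post_init__(self) -> None:
        lo, hi = self.t_lox_eur_mya
        if not (0 < lo <= hi):
            raise ValueError("calibration interval must be positive and ordered")
        if self.generation_years <= 0:
            raise ValueError("generation time must be positive")


def calibrate_absolute(
    ratio: float | tuple[float, float],
    calibration: CalibrationWindow = CalibrationWindow(),
) -> tuple[float, float]:
    """Convert a split-time ratio (or ratio interval) T_X / T_Lox-Eur into an
    absolute interval in Mya by multiplying through the fossil window.

    A ratio of 0.45 against the 4.2-9.0 Mya window yields a lower bound of
    1.89 Mya; an interval (0.45, 0.79) yields (1.89, 7.11) Mya.
    """
    if isinstance(ratio, (int, float)):
        lo = hi = float(ratio)
    else:
        lo, hi = map(float, ratio)
    if lo <= 0 or hi < lo:
        raise ValueError("ratio must be positive (and ordered if an interval)")
    cal_lo, cal_hi = calibration.t_lox_eur_mya
    return (lo * cal_lo, hi * cal_hi)


def theta_to_diploid_n(theta: float, mu_per_year: float, generation_years: float = 31.0) -> float:
    """Convert a scaled size theta = 4 N mu g to a diploid N given a per-year
    mutation rate mu (mutation rate is an external assumption, not estimated)."""
    if theta <= 0 or mu_per_year <= 0 or generation_years <= 0:
        raise ValueError("theta, mu and generation time must be positive")
    return theta / (4.0 * mu_per_year * generation_years)
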