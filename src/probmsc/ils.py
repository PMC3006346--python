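"""Incomplete-lineage-sorting site-class analysis.

For an ordered taxon triple (1, 2, 3) polarized against the mastodon — where
member 3 may be a merged sister clade ("Eurasian" = Asian+mammoth, or
"Loxodonta" = forest+savanna) — every polarized site is spread over seven
derived-allele-sharing classes by frequency products: the expected rate of a
"12" site, where 1 and 2 share the derived allele to the exclusion of 3, is
f1 * f2 * (1 - f3), and so on for classes 1, 2, 3, 12, 13, 23 and the
all-derived class (fixed elephantid-mastodon differences, the "Mastodon"
column).  Classes "13" and "23" cluster a non-sister pair and therefore
diagnose incomplete lineage sorting (or recurrent mutation, removed upstream).

The headline contrast is the ILS rate (13+23 classes divided by
savanna-Asian divergence) of the forest/savanna triple against that of the
Asian/mammoth triple: a ratio above 1 means more lineages survive, unsorted,
back past the African-Eurasian split on the African side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .divergence import NORMALIZER_PAIR, pairwise_divergence
from .jackknife import weighted_jackknife
from .sites import DivergentSiteTable
from .taxa import AFRICAN, EURASIAN, Taxon

#: A triple member: a single taxon or a merged sister clade.
TripleMember = Taxon | frozenset[Taxon]

#: Ordered taxon triples of the two four-taxon alignments.
SAVANNA_FOREST_EURASIAN: tuple[TripleMember, ...] = (Taxon.SAVANNA, Taxon.FOREST, EURASIAN)
ASIAN_MAMMOTH_LOXODONTA: tuple[TripleMember, ...] = (Taxon.ASIAN, Taxon.MAMMOTH, AFRICAN)

CLASS_NAMES = ("1", "2", "3", "12", "13", "23", "mastodon")

_CLASS_BITS = {
    "1": (1, 0, 0), "2": (0, 1, 0), "3": (0, 0, 1),
    "12": (1, 1, 0), "13": (1, 0, 1), "23": (0, 1, 1),
    "mastodon": (1, 1, 1),
}


def member_frequencies(table: DivergentSiteTable, member: TripleMember) -> np.ndarray:
    """Per-site derived frequency of a taxon or merged clade.

    A merged clade's frequency is the chromosome-weighted mean of its two
    members (four chromosomes per clade); sites missing either member are NaN
    and excluded from spectra.
    """
    if isinstance(member, Taxon):
        return table.frequencies(member)
    members = sorted(member, key=lambda t: t.value)
    freqs = np.stack([table.frequencies(t) for t in members])
    return freqs.mean(axis=0)


def merge_clade_frequency(freqs: dict[Taxon, float], clade: frozenset[Taxon]) -> float:
    """Merged derived frequency for one site (equal weight per chromosome)."""
    vals = [freqs[t] for t in clade]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        raise ValueError("missing member call: site must be excluded")
    return float(sum(vals)) / len(vals)


@dataclass
class SiteClassSpectrum:
    """Seven frequency-product class rates for one ordered triple."""

    triple: tuple[TripleMember, ...]
    rates: dict[str, float]
    n_sites: int

    def ils_classes(self) -> float:
        return self.rates["13"] + self.rates["23"]

    @property
    def total(self) -> float:
        return float(sum(self.rates.values()))


def site_class_spectrum(
    table: DivergentSiteTable,
    triple: tuple[TripleMember, ...],
) -> SiteClassSpectrum:
    """Accumulate the seven class rates over all complete polarized sites.

    Per site the seven contributions sum to 1 - prod(1 - f_i): the chance
    that at least one of three chromosomes drawn (one per triple member)
    carries the derived allele.
    """
    if not table.polarized:
        raise ValueError("site-class spectrum requires a polarized table")
    sub = table.complete()
    f = [member_frequencies(sub, m) for m in triple]
    rates: dict[str, float] = {}
    for name, bits in _CLASS_BITS.items():
        term = np.ones(len(sub.df))
        for fi, b in zip(f, bits):
            term = term * (fi if b else (1.0 - fi))
        rates[name] = float(np.nansum(term))
    return SiteClassSpectrum(triple=triple, rates=rates, n_sites=len(sub.df))


def ils_rate(spectrum: SiteClassSpectrum, t_sa: float) -> float:
    """Rate of 13+23 (ILS-suggesting) sites divided by savanna-Asian divergence."""
    if t_sa <= 0:
        raise ValueError("normalizer t_SA must be positive")
    return spectrum.ils_classes() / t_sa


@dataclass
class IlsResult:
    """Forest/savanna vs Asian/mammoth ILS-rate comparison."""

    rate_fs: float
    rate_fs_se: float
    rate_am: float
    rate_am_se: float
    ratio: float
    ratio_se: float
    p_two_sided: float
    p_exceed_unity: float
    blocks: int


def _rate_fs(sub: DivergentSiteTable) -> float:
    t_sa = pairwise_divergence(sub, *NORMALIZER_PAIR)
    return ils_rate(site_class_spectrum(sub, SAVANNA_FOREST_EURASIAN), t_sa)


def _rate_am(sub: DivergentSiteTable) -> float:
    t_sa = pairwise_divergence(sub, *NORMALIZER_PAIR)
    return ils_rate(site_class_spectrum(sub, ASIAN_MAMMOTH_LOXODONTA), t_sa)


def ils_ratio_test(table: DivergentSiteTable) -> IlsResult:
    """Ratio of the two ILS rates with weighted-jackknife inference.

    Two p-values are reported: a two-sided p for a difference between the
    rates (jackknife on rate_fs - rate_am) and a one-sided p for the ratio
    exceeding unity (jackknife on the log-ratio).
    """
    fs = weighted_jackknife(_rate_fs, table)
    am = weighted_jackknife(_rate_am, table)
    if am.estimate <= 0:
        raise ValueError("Asian-mammoth ILS rate is zero: ratio degenerate")
    ratio = fs.estimate / am.estimate

    def log_ratio(sub: DivergentSiteTable) -> float:
        r_am = _rate_am(sub)
        r_fs = _rate_fs(sub)
        if r_am <= 0 or r_fs <= 0:
            raise ValueError("degenerate ILS rate in delete-one subtable")
        return math.log(r_fs / r_am)

    def difference(sub: DivergentSiteTable) -> float:
        return _rate_fs(sub) - _rate_am(sub)

    diff = weighted_jackknife(difference, table)
    lr = weighted_jackknife(log_ratio, table)
    p_exceed = float(norm.sf(lr.estimate / lr.se)) if lr.se > 0 else (0.0 if lr.estimate > 0 else 1.0)
    ratio_se = ratio * lr.se  # delta method on the log scale
    return IlsResult(
        rate_fs=fs.estimate, rate_fs_se=fs.se,
        rate_am=am.estimate, rate_am_se=am.se,
        ratio=ratio, ratio_se=ratio_se,
        p_two_sided=diff.p, p_exceed_unity=p_exceed,
        blocks=fs.blocks,
    )
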