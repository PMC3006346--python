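"""Demographic-parameter estimation from the polarized site-pattern spectrum.

Estimates the species-tree split times (tau_FS, tau_AM, tau_LoxEur) and
interval sizes (theta for the four tip taxa and three ancestral intervals)
by maximizing a composite likelihood over the joint polarized site-pattern
spectrum.  A site's pattern is its derived-allele copy count in each
elephantid taxon, (n_F, n_S, n_A, n_M) with n in {0,1,2}; under infinite
sites the per-site probability of a pattern equals the expected genealogy
branch length subtending exactly that configuration, which is estimated by
Monte Carlo simulation of the structured coalescent.  The objective is the
multinomial log likelihood over all aligned bases, with the two
non-identifying configurations — monomorphic and fixed-derived across all
elephantids — collapsed into a complement class, so the poorly constrained
elephantid-mastodon root interval never enters the fit.

Monte Carlo pattern probabilities reuse a frozen random stream across
objective evaluations (common random numbers), making the objective a
deterministic function of the parameters, which bounded derivative-free
search (Powell by default) with seeded random restarts can optimize
reliably.  Interval estimates come
from a weighted jackknife over blocks of loci with warm-started refits;
they are frequentist standard-error intervals, not posteriors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .alignments import LocusAlignment
from .ils import TripleMember, CLASS_NAMES, _CLASS_BITS
from .jackknife import weighted_jackknife_values
from .sites import DivergentSiteTable, call_divergent_sites, polarize
from .simulate import SpeciesTreeModel, simulate_gene_tree
from .taxa import ELEPHANTIDS, Taxon

N_CLASSES = 81  # (n_F, n_S, n_A, n_M) each in {0,1,2}
_EXCLUDED = (0, 80)  # monomorphic and all-elephantids-derived

#: class index of every 8-bit leaf mask (bits: F1 F2 S1 S2 A1 A2 M1 M2)
_CLASS_OF_MASK = np.array([
    27 * (bin(m & 0b11).count("1"))
    + 9 * (bin(m >> 2 & 0b11).count("1"))
    + 3 * (bin(m >> 4 & 0b11).count("1"))
    + (bin(m >> 6 & 0b11).count("1"))
    for m in range(256)
], dtype=np.int64)

_PARAM_NAMES = ("tau_fs", "tau_am", "tau_loxeur",
                "theta_f", "theta_s", "theta_a", "theta_m",
                "theta_fs", "theta_am", "theta_loxeur")


@dataclass(frozen=True)
class PriorBounds:
    """Parameter search bounds, mirroring the study's prior ranges.

    Split-time priors are stated in Mya and mapped to mutation units through
    a reference per-year mutation rate (an explicit user assumption; the
    default corresponds to calibrating the African-Eurasian split at its
    fossil-window midpoint).  Theta bounds span the observed
    savanna-to-forest diversity range with a wide margin.
    """

    t_loxeur_mya: tuple[float, float] = (4.2, 9.0)
    t_am_mya: tuple[float, float] = (3.0, 8.5)
    t_fs_mya: tuple[float, float] = (0.5, 9.0)
    t_root_mya: tuple[float, float] = (24.0, 30.0)
    theta: tuple[float, float] = (0.0002, 0.008)
    mu_per_year: float = 3.33e-10

    def tau(self, which: str) -> tuple[float, float]:
        lo, hi = getattr(self, f"t_{which}_mya")
        return (lo * 1e6 * self.mu_per_year, hi * 1e6 * self.mu_per_year)


@dataclass
class FitConfig:
    """Optimizer and Monte-Carlo settings for :func:`fit_msc`."""

    mc_reps: int = 2000
    restarts: int = 3
    maxfev: int = 4000
    method: str = "Powell"         # bounded derivative-free search
    jackknife_blocks: int = 0      # 0 disables interval estimation
    jackknife_maxfev: int = 300
    jackknife_mc_reps: int | None = None


@dataclass
class FitResult:
    """Point estimates, optional jackknife 90% intervals, diagnostics."""

    params: dict[str, float]
    objective: float
    converged: bool
    n_restarts: int
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    jackknife_params: list[dict[str, float]] = field(default_factory=list)
    jackknife_weights: list[float] = field(default_factory=list)

    def ratio(self, num: str, den: str) -> float:
        return self.params[num] / self.params[den]


# -- fast structured-coalescent pattern-length accumulator ------------------


class _FastRand:
    """Buffered uniforms turned into exponentials and pair picks; cheap per
    draw, reproducible from a seed."""

    __slots__ = ("buf", "i", "rng")

    def __init__(self, seed) -> None:
        self.rng = np.random.default_rng(seed)
        self.buf = self.rng.random(65536)
        self.i = 0

    def u(self) -> float:
        i = self.i
        if i >= len(self.buf):
            self.buf = self.rng.random(65536)
            i = 0
        self.i = i + 1
        return self.buf[i]

    def exp(self, mean: float) -> float:
        return -mean * math.log(1.0 - self.u())

    def pick(self, k: int) -> int:
        return min(int(self.u() * k), k - 1)


def _run_interval(lineages: list, theta: float, t_start: float, t_end: float,
                  lengths: np.ndarray, rnd: _FastRand) -> list:
    """Coalesce [mask, birth] lineages over one interval, accruing per-class
    branch lengths when lineages terminate."""
    t = t_start
    while len(lineages) >= 2:
        k = len(lineages)
        t += rnd.exp(theta / (k * (k - 1)))
        if t >= t_end:
            break
        i = rnd.pick(k)
        j = rnd.pick(k - 1)
        if j >= i:
            j += 1
        a = lineages[i]
        b = lineages[j]
        lengths[_CLASS_OF_MASK[a[0]]] += t - a[1]
        lengths[_CLASS_OF_MASK[b[0]]] += t - b[1]
        merged = [a[0] | b[0], t]
        lineages = [l for n, l in enumerate(lineages) if n not in (i, j)]
        lineages.append(merged)
    return lineages


def expected_pattern_lengths(params: dict[str, float], mc_reps: int, seed) -> np.ndarray:
    """MC estimate of E[branch length subtending each derived pattern].

    Returns the 81-vector of expected per-site rates; entries 0 and 80 stay
    zero (nothing subtends no or all chromosomes below the elephantid MRCA).
    The elephantid-mastodon root interval is not simulated: patterns above
    the elephantid MRCA fall in the collapsed complement class.
    """
    rnd = _FastRand(seed)
    lengths = np.zeros(N_CLASSES)
    tau_fs, tau_am, tau_lox = params["tau_fs"], params["tau_am"], params["tau_loxeur"]
    inf = math.inf
    for _ in range(mc_reps):
        f = _run_interval([[0b1, 0.0], [0b10, 0.0]],
                          params["theta_f"], 0.0, tau_fs, lengths, rnd)
        s = _run_interval([[0b100, 0.0], [0b1000, 0.0]],
                          params["theta_s"], 0.0, tau_fs, lengths, rnd)
        a = _run_interval([[0b10000, 0.0], [0b100000, 0.0]],
                          params["theta_a"], 0.0, tau_am, lengths, rnd)
        m = _run_interval([[0b1000000, 0.0], [0b10000000, 0.0]],
                          params["theta_m"], 0.0, tau_am, lengths, rnd)
        fs = _run_interval(f + s, params["theta_fs"], tau_fs, tau_lox, lengths, rnd)
        am = _run_interval(a + m, params["theta_am"], tau_am, tau_lox, lengths, rnd)
        last = _run_interval(fs + am, params["theta_loxeur"], tau_lox, inf, lengths, rnd)
        # the MRCA lineage's branch lies above the elephantid root: complement
    out = lengths / mc_reps
    out[list(_EXCLUDED)] = 0.0
    return out


# -- observed spectrum -----------------------------------------------------


def observed_pattern_counts(table: DivergentSiteTable) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-class site counts (81-vector) and the per-locus count matrix.

    Uses complete polarized sites; the all-derived class (index 80) is
    zeroed (it belongs to the collapsed complement, along with monomorphic
    columns).  The recurrent-mutation filter must NOT have been applied:
    the model explicitly accommodates deep-coalescing configurations.
    """
    if not table.polarized:
        raise ValueError("pattern counts require a polarized table")
    sub = table.complete()
    counts = sub.df[[t.value for t in ELEPHANTIDS]].to_numpy(dtype=float).astype(int)
    idx = counts[:, 0] * 27 + counts[:, 1] * 9 + counts[:, 2] * 3 + counts[:, 3]
    per_locus = pd.crosstab(sub.df["locus_id"], idx)
    vec = np.zeros(N_CLASSES)
    for cls, n in zip(*np.unique(idx, return_counts=True)):
        vec[cls] = n
    vec[list(_EXCLUDED)] = 0.0
    return vec, per_locus


def _composite_nll(counts: np.ndarray, total_bp: float, p: np.ndarray,
                   eps: float = 1e-9) -> float:
    keep = np.ones(N_CLASSES, dtype=bool)
    keep[list(_EXCLUDED)] = False
    pc = np.clip(p[keep], eps, None)
    n_model = counts[keep]
    n_rest = total_bp - n_model.sum()
    p_rest = max(1.0 - pc.sum(), eps)
    return -(float(np.dot(n_model, np.log(pc))) + n_rest * math.log(p_rest))


# -- moment initialization -------------------------------------------------


def _moment_start(table: DivergentSiteTable, total_bp: float,
                  bounds: PriorBounds) -> dict[str, float]:
    from .divergence import pairwise_divergence  # deferred: avoids cycle

    sub = table.complete()
    rate = {}
    for x in ELEPHANTIDS:
        rate[f"theta_{x.value.lower()}"] = pairwise_divergence(sub, x, x) / total_bp
    t_sa = pairwise_divergence(sub, Taxon.SAVANNA, Taxon.ASIAN) / total_bp
    t_fs = pairwise_divergence(sub, Taxon.FOREST, Taxon.SAVANNA) / total_bp
    t_am = pairwise_divergence(sub, Taxon.ASIAN, Taxon.MAMMOTH) / total_bp
    theta_anc = 2.0 * float(np.mean(list(rate.values())))
    start = dict(rate)
    start["theta_fs"] = start["theta_am"] = start["theta_loxeur"] = theta_anc
    start["tau_loxeur"] = max((t_sa - theta_anc) / 2.0, bounds.tau("loxeur")[0])
    start["tau_fs"] = max((t_fs - theta_anc) / 2.0, bounds.tau("fs")[0])
    start["tau_am"] = max((t_am - theta_anc) / 2.0, bounds.tau("am")[0])
    lo, hi = bounds.theta
    for k in list(start):
        if k.startswith("theta"):
            start[k] = float(np.clip(start[k], lo, hi))
    return start


# -- the fit ----------------------------------------------------------------


def _pack(params: dict[str, float]) -> np.ndarray:
    """(tau_loxeur, r_fs, r_am, thetas...) optimizer vector."""
    return np.array([
        params["tau_loxeur"],
        params["tau_fs"] / params["tau_loxeur"],
        params["tau_am"] / params["tau_loxeur"],
        *(params[f"theta_{p}"] for p in ("f", "s", "a", "m", "fs", "am", "loxeur")),
    ])


def _unpack(x: np.ndarray) -> dict[str, float]:
    names = ("f", "s", "a", "m", "fs", "am", "loxeur")
    out = {"tau_loxeur": float(x[0]),
           "tau_fs": float(x[0] * x[1]),
           "tau_am": float(x[0] * x[2])}
    out.update({f"theta_{n}": float(v) for n, v in zip(names, x[3:])})
    return out


def _optimizer_bounds(bounds: PriorBounds) -> list[tuple[float, float]]:
    tl_lo, tl_hi = bounds.tau("loxeur")
    fs_lo, fs_hi = bounds.tau("fs")
    am_lo, am_hi = bounds.tau("am")
    r_fs = (max(fs_lo / tl_hi, 0.02), min(fs_hi / tl_lo, 0.98))
    r_am = (max(am_lo / tl_hi, 0.02), min(am_hi / tl_lo, 0.98))
    return [(tl_lo, tl_hi), r_fs, r_am] + [bounds.theta] * 7


def fit_msc(
    data: DivergentSiteTable | Iterable[LocusAlignment],
    bounds: PriorBounds | None = None,
    config: FitConfig | None = None,
    seed: int = 0,
    total_bp: float | None = None,
) -> FitResult:
    """Composite-likelihood fit of the ten demographic parameters.

    ``data`` is a polarized divergent-site table (unfiltered: recurrent-
    looking sites stay in, as the model accommodates them) or raw locus
    alignments, which are then called and polarized here.  ``total_bp``
    (total aligned bases) is taken from the table's accounting metadata if
    not given.  Fewer than ~50 loci make the spectrum noisy; a diagnostic
    warning is attached via ``FitResult.converged`` logic only.
    """
    bounds = bounds or PriorBounds()
    config = config or FitConfig()
    if not isinstance(data, DivergentSiteTable):
        data = polarize(call_divergent_sites(list(data)))
    if total_bp is None:
        total_bp = data.meta.get("total_bp")
    if not total_bp:
        raise ValueError("total_bp unknown: supply it or use a table from call_divergent_sites")
    counts, per_locus = observed_pattern_counts(data)
    mc_seed = np.random.SeedSequence(seed).spawn(1)[0]
    opt_bounds = _optimizer_bounds(bounds)

    def objective(x: np.ndarray) -> float:
        p = expected_pattern_lengths(_unpack(x), config.mc_reps, mc_seed)
        return _composite_nll(counts, total_bp, p)

    start = _moment_start(data, total_bp, bounds)
    x0 = np.clip(_pack(start), [b[0] for b in opt_bounds], [b[1] for b in opt_bounds])
    rng = np.random.default_rng(seed)
    best = None
    for r in range(config.restarts):
        if r == 0:
            xi = x0
        else:
            xi = np.clip(x0 * np.exp(rng.normal(0, 0.25, size=len(x0))),
                         [b[0] for b in opt_bounds], [b[1] for b in opt_bounds])
        res = minimize(objective, xi, method=config.method, bounds=opt_bounds,
                       options={"maxfev": config.maxfev})
        if best is None or res.fun < best.fun:
            best = res
    params = _unpack(best.x)
    fit = FitResult(params=params, objective=float(best.fun),
                    converged=bool(best.success), n_restarts=config.restarts)
    if config.jackknife_blocks and config.jackknife_blocks >= 2:
        _jackknife_intervals(fit, best.x, counts, per_locus, total_bp, data,
                             bounds, config, mc_seed)
    return fit


def _jackknife_intervals(fit: FitResult, x_hat: np.ndarray, counts: np.ndarray,
                         per_locus: pd.DataFrame, total_bp: float,
                         table: DivergentSiteTable, bounds: PriorBounds,
                         config: FitConfig, mc_seed) -> None:
    """Weighted delete-one-block jackknife over grouped loci (warm-started
    short refits); fills se and normal 90% intervals."""
    loci = list(per_locus.index)
    g = min(config.jackknife_blocks, len(loci))
    blocks = [loci[i::g] for i in range(g)]
    bp_per_locus = table.meta.get("bp_per_locus")
    mc = config.jackknife_mc_reps or config.mc_reps
    opt_bounds = _optimizer_bounds(bounds)
    loo_params: list[dict[str, float]] = []
    weights: list[float] = []
    for block in blocks:
        sub_counts = counts.copy()
        block_rows = per_locus.loc[per_locus.index.isin(block)]
        for cls in block_rows.columns:
            sub_counts[cls] -= block_rows[cls].sum()
        if bp_per_locus:
            sub_bp = total_bp - sum(bp_per_locus.get(l, 0) for l in block)
        else:
            sub_bp = total_bp * (1.0 - block_rows.to_numpy().sum() / max(counts.sum(), 1))

        def obj(x: np.ndarray) -> float:
            p = expected_pattern_lengths(_unpack(x), mc, mc_seed)
            return _composite_nll(sub_counts, sub_bp, p)

        res = minimize(obj, x_hat, method=config.method, bounds=opt_bounds,
                       options={"maxfev": config.jackknife_maxfev})
        loo_params.append(_unpack(res.x))
        weights.append(float(block_rows.to_numpy().sum()))
    fit.jackknife_params = loo_params
    fit.jackknife_weights = weights
    for name in _PARAM_NAMES:
        loo = [p[name] for p in loo_params]
        _, se = weighted_jackknife_values(fit.params[name], loo, weights)
        fit.se[name] = se
        fit.intervals[name] = (fit.params[name] - 1.645 * se, fit.params[name] + 1.645 * se)


# -- expected triple spectra (reporting / cross-checks) ---------------------


def pattern_probabilities(
    model: SpeciesTreeModel,
    triple: tuple[TripleMember, ...],
    mc_reps: int = 10000,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Expected per-site rates of the seven site classes for a taxon triple.

    Simulates full genealogies (including the mastodon) and accumulates, for
    each branch, length times the frequency product each class would receive
    from a mutation on that branch.  Returns (rates, mc standard errors).
    """
    rng = np.random.default_rng(seed)
    totals = {c: 0.0 for c in CLASS_NAMES}
    sq = {c: 0.0 for c in CLASS_NAMES}
    eleph_bits = {  # leaf-mask bit ranges per taxon: F, S, A, M
        Taxon.FOREST: (0, 2), Taxon.SAVANNA: (2, 4),
        Taxon.ASIAN: (4, 6), Taxon.MAMMOTH: (6, 8),
    }
    all_eleph_mask = (1 << 8) - 1

    def taxon_freq(mask: int, taxon: Taxon) -> float:
        lo, hi = eleph_bits[taxon]
        return bin(mask >> lo & ((1 << (hi - lo)) - 1)).count("1") / (hi - lo)

    def member_freq(mask: int, member: TripleMember) -> float:
        if isinstance(member, Taxon):
            return taxon_freq(mask, member)
        return sum(taxon_freq(mask, t) for t in member) / len(member)

    for _ in range(mc_reps):
        tree = simulate_gene_tree(model, rng)
        rep = {c: 0.0 for c in CLASS_NAMES}
        for node, bl in tree.branches():
            mask = tree.mask[node]
            if mask >> 8 & 1:  # branch carries the mastodon: polarized view flips
                mask = all_eleph_mask & ~mask
            if mask == 0:
                continue
            fs = [member_freq(mask, m) for m in triple]
            for name, bits in _CLASS_BITS.items():
                term = bl
                for f, b in zip(fs, bits):
                    term *= f if b else (1.0 - f)
                rep[name] += term
        for c in CLASS_NAMES:
            totals[c] += rep[c]
            sq[c] += rep[c] ** 2
    rates = {c: totals[c] / mc_reps for c in CLASS_NAMES}
    ses = {c: math.sqrt(max(sq[c] / mc_reps - rates[c] ** 2, 0.0) / mc_reps)
           for c in CLASS_NAMES}
    return rates, ses


# -- ratio reports ----------------------------------------------------------


def report_ratios(fit: FitResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-to-row ratio tables for split times and population sizes.

    Entry (row r, column c) is parameter_c / parameter_r, formatted with a
    jackknife 90% interval when delete-one-block refits are available.
    Diagonals are exactly 1 and r_ij * r_ji = 1.
    """
    taus = ["tau_fs", "tau_am", "tau_loxeur"]
    thetas = ["theta_f", "theta_s", "theta_a", "theta_m",
              "theta_fs", "theta_am", "theta_loxeur"]

    def table_for(names: list[str]) -> pd.DataFrame:
        cells = {}
        for r in names:
            row = {}
            for c in names:
                ratio = fit.params[c] / fit.params[r]
                if fit.jackknife_params and c != r:
                    loo = [p[c] / p[r] for p in fit.jackknife_params]
                    _, se = weighted_jackknife_values(ratio, loo, fit.jackknife_weights)
                    row[c] = f"{ratio:.2f} ({ratio - 1.645 * se:.2f}-{ratio + 1.645 * se:.2f})"
                else:
                    row[c] = f"{ratio:.2f}"
            cells[r] = row
        return pd.DataFrame(cells).T[names]

    return table_for(taus), table_for(thetas)
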