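"""Divergent-site tables: calling, polarization, QC filters and TSV I/O.

A *divergent site* is an alignment column at which exactly two alleles are
observed across all sampled chromosomes (eight elephantid chromosomes, two
per taxon, plus the haploid mastodon).  Sites are *polarized* by taking the
mastodon allele as ancestral; each elephantid taxon then carries 0, 1 or 2
copies of the derived allele, i.e. a derived-allele frequency f in {0, 1/2, 1}.

Two QC filters reproduce the study design:

* loci with more than ``max_poly_per_locus`` (default 3) columns polymorphic
  within the elephantids are dropped entirely — such loci are symptomatic of
  co-amplified paralogs producing false-positive divergent sites;
* polarized sites whose derived allele is seen on both sides of the
  African/Eurasian split in configurations that realistically require
  recurrent mutation or sequencing error are removed before the site-class
  analyses (rule configurable; see :func:`filter_recurrent`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .alignments import LocusAlignment, check_site_calling_ready
from .taxa import AFRICAN, ELEPHANTIDS, EURASIAN, OUTGROUP, PLOIDY, Taxon

logger = logging.getLogger(__name__)

#: Column order of the canonical tab-separated site table.
TABLE_COLUMNS = ["locus_id", "pos", "allele_anc", "allele_der", "F", "S", "A", "M", "O"]

GENOTYPE_COLUMNS = ["F", "S", "A", "M", "O"]

_PLOIDY_BY_COL = {c: PLOIDY[Taxon(c)] for c in GENOTYPE_COLUMNS}


class SiteTableError(ValueError):
    """Malformed site-table input; messages carry locus/position coordinates."""


@dataclass
class DivergentSiteTable:
    """Ordered collection of biallelic divergent sites grouped by locus.

    ``df`` columns: locus_id, pos, allele_anc, allele_der, F, S, A, M, O
    (+ optional A2).  Genotypes count copies of ``allele_der`` (mastodon is
    haploid, 0/1); NaN is a missing call.  Boolean flag columns ``complete``
    (all five taxa called) and ``recurrent`` (flagged by the recurrence
    filter) are maintained alongside.

    ``polarized`` records whether ``allele_anc`` is the mastodon allele.
    ``meta`` accumulates filter accounting (input/removed/retained counts).
    """

    df: pd.DataFrame
    polarized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SiteTableError(f"site table missing columns {missing}")
        df = self.df.reset_index(drop=True).copy()
        for col in GENOTYPE_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
            hi = _PLOIDY_BY_COL[col]
            bad = df[col].dropna()
            bad = bad[(bad < 0) | (bad > hi) | (bad != bad.round())]
            if len(bad):
                i = bad.index[0]
                raise SiteTableError(
                    f"locus {df.loc[i, 'locus_id']} pos {df.loc[i, 'pos']}: "
                    f"invalid {col} genotype {bad.iloc[0]} (allowed 0..{hi})"
                )
        same = df["allele_anc"] == df["allele_der"]
        if same.any():
            i = same.idxmax()
            raise SiteTableError(
                f"locus {df.loc[i, 'locus_id']} pos {df.loc[i, 'pos']}: "
                "ancestral and derived allele are identical"
            )
        if "complete" not in df.columns:
            df["complete"] = df[GENOTYPE_COLUMNS].notna().all(axis=1)
        if "recurrent" not in df.columns:
            df["recurrent"] = False
        self.df = df

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def locus_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["locus_id"]))

    def frequencies(self, taxon: Taxon | str) -> np.ndarray:
        """Derived-allele frequency per site for one taxon (NaN if missing)."""
        col = Taxon(taxon).value
        return self.df[col].to_numpy(dtype=float) / _PLOIDY_BY_COL[col]

    def derived_counts(self) -> np.ndarray:
        """Per-site derived-allele copy count over the 8 elephantid chromosomes."""
        return self.df[[t.value for t in ELEPHANTIDS]].to_numpy(dtype=float).sum(axis=1)

    def polymorphic_mask(self) -> np.ndarray:
        """Sites segregating among the elephantids (derived count in (0, 8)),
        restricted to sites with complete data in all five taxa."""
        counts = self.derived_counts()
        complete = self.df["complete"].to_numpy(dtype=bool)
        return complete & (counts > 0) & (counts < 8)

    @property
    def n_polymorphic(self) -> int:
        return int(self.polymorphic_mask().sum())

    def complete(self) -> "DivergentSiteTable":
        """Subtable of sites called in all five taxa."""
        return self.subset(self.df["complete"].to_numpy(dtype=bool))

    def subset(self, mask: np.ndarray) -> "DivergentSiteTable":
        return DivergentSiteTable(self.df.loc[mask].reset_index(drop=True),
                                  polarized=self.polarized, meta=dict(self.meta))

    def drop_locus(self, locus_id: str) -> "DivergentSiteTable":
        return self.subset((self.df["locus_id"] != locus_id).to_numpy())

    def sites_per_locus(self) -> pd.Series:
        """Divergent-site count per locus (the weighted-jackknife weights)."""
        return self.df.groupby("locus_id", sort=False).size()

    def copy(self) -> "DivergentSiteTable":
        return DivergentSiteTable(self.df.copy(), polarized=self.polarized, meta=dict(self.meta))


# -- TSV round trip --------------------------------------------------------


def read_site_table(path: str | Path) -> DivergentSiteTable:
    """Read the canonical tab-separated site table ('.' = missing call)."""
    path = Path(path)
    polarized = False
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            polarized = "polarized=1" in first
            header_line = None
        else:
            header_line = first
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."], dtype={"locus_id": str})
    del header_line
    unknown = [c for c in df.columns
               if c not in TABLE_COLUMNS + ["A2", "complete", "recurrent"]]
    if unknown:
        raise SiteTableError(f"{path}: unknown taxon/genotype columns {unknown}")
    for allele_col in ("allele_anc", "allele_der"):
        bad = ~df[allele_col].astype(str).str.fullmatch("[ACGT]")
        if bad.any():
            i = bad.idxmax()
            raise SiteTableError(
                f"{path}: locus {df.loc[i, 'locus_id']} pos {df.loc[i, 'pos']}: "
                f"{allele_col}={df.loc[i, allele_col]!r} is not a single A/C/G/T base "
                "(more than two alleles cannot be represented)"
            )
    return DivergentSiteTable(df, polarized=polarized)


def write_site_table(table: DivergentSiteTable, path: str | Path) -> None:
    """Write the canonical TSV; lossless round trip with :func:`read_site_table`."""
    df = table.df.copy()
    cols = TABLE_COLUMNS + [c for c in ("A2",) if c in df.columns]
    for col in GENOTYPE_COLUMNS + (["A2"] if "A2" in df.columns else []):
        df[col] = df[col].map(lambda v: "." if pd.isna(v) else str(int(v)))
    with open(path, "w") as fh:
        fh.write(f"# probmsc site table polarized={int(table.polarized)}\n")
        df[cols].to_csv(fh, sep="\t", index=False)


# -- site calling ----------------------------------------------------------


def _designated_samples(locus: LocusAlignment) -> dict[Taxon, list[str]]:
    """First `ploidy` samples per taxon, in label order (the designated
    diploid individual; extra samples such as a second Asian are ignored)."""
    out: dict[Taxon, list[str]] = {}
    for taxon in (*ELEPHANTIDS, OUTGROUP):
        out[taxon] = sorted(locus.samples_for(taxon))[: PLOIDY[taxon]]
    return out


def call_divergent_sites(
    loci: Iterable[LocusAlignment],
    max_poly_per_locus: int = 3,
) -> DivergentSiteTable:
    """Scan alignments for biallelic columns and emit an (unpolarized) table.

    Loci with more than ``max_poly_per_locus`` columns polymorphic within the
    elephantids are dropped entirely and logged (paralog filter).  Columns
    with three or more alleles are skipped.  Alleles of an emitted site are
    stored alphabetically (anc/der labels become meaningful after
    :func:`polarize`).
    """
    rows: list[dict] = []
    dropped: list[str] = []
    n_loci_kept = 0
    total_bp = 0
    bp_per_locus: dict[str, int] = {}
    for locus in loci:
        check_site_calling_ready(locus)
        designated = _designated_samples(locus)
        eleph_samples = [s for t in ELEPHANTIDS for s in designated[t]]
        mast_sample = designated[OUTGROUP][0]
        n_poly = 0
        candidate_rows = []
        for pos in range(1, locus.length + 1):
            col = locus.column(pos)
            eleph_bases = [col[s] for s in eleph_samples if col[s] != "N"]
            if len(set(eleph_bases)) >= 2:
                n_poly += 1
            all_bases = [col[s] for s in eleph_samples if col[s] != "N"]
            if col[mast_sample] != "N":
                all_bases.append(col[mast_sample])
            alleles = sorted(set(all_bases))
            if len(alleles) != 2:
                continue
            a, b = alleles
            row: dict = {"locus_id": locus.locus_id, "pos": pos,
                         "allele_anc": a, "allele_der": b}
            for taxon in ELEPHANTIDS:
                bases = [col[s] for s in designated[taxon]]
                row[taxon.value] = float(bases.count(b)) if "N" not in bases else np.nan
            mb = col[mast_sample]
            row["O"] = np.nan if mb == "N" else float(mb == b)
            candidate_rows.append(row)
        if n_poly > max_poly_per_locus:
            dropped.append(locus.locus_id)
            logger.info(
                "locus %s dropped: %d elephantid-polymorphic columns exceed "
                "max_poly_per_locus=%d", locus.locus_id, n_poly, max_poly_per_locus,
            )
            continue
        rows.extend(candidate_rows)
        n_loci_kept += 1
        total_bp += locus.length
        bp_per_locus[locus.locus_id] = locus.length
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS) if rows else pd.DataFrame(
        {c: pd.Series(dtype=(str if c in ("locus_id", "allele_anc", "allele_der") else float))
         for c in TABLE_COLUMNS}
    )
    table = DivergentSiteTable(df, polarized=False)
    table.meta.update(
        n_loci=n_loci_kept, n_loci_dropped=len(dropped), dropped_loci=dropped,
        total_bp=total_bp, bp_per_locus=bp_per_locus, n_biallelic=len(df),
    )
    return table


# -- polarization ----------------------------------------------------------


def polarize(table: DivergentSiteTable) -> DivergentSiteTable:
    """Polarize by the mastodon: ancestral allele := mastodon allele.

    Sites without a mastodon call (or with an impossible heterozygous
    mastodon genotype) cannot be polarized; they are excluded and counted in
    ``meta['n_unpolarizable']``.  Applying this twice equals applying it once.
    """
    df = table.df.copy()
    o = df["O"].to_numpy(dtype=float)
    unpolarizable = ~np.isfinite(o) | ((o != 0.0) & (o != 1.0))
    flip = np.isfinite(o) & (o == 1.0)
    for col in GENOTYPE_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        vals[flip] = _PLOIDY_BY_COL[col] - vals[flip]
        df[col] = vals
    anc = df["allele_anc"].to_numpy(dtype=object)
    der = df["allele_der"].to_numpy(dtype=object)
    anc2 = np.where(flip, der, anc)
    der2 = np.where(flip, anc, der)
    df["allele_anc"], df["allele_der"] = anc2, der2
    out = DivergentSiteTable(df.loc[~unpolarizable].reset_index(drop=True),
                             polarized=True, meta=dict(table.meta))
    out.meta["n_unpolarizable"] = int(unpolarizable.sum())
    out.meta["n_polymorphic"] = out.n_polymorphic
    return out


# -- recurrence filter -----------------------------------------------------


def _segregating_both_sides(df: pd.DataFrame) -> np.ndarray:
    """Derived allele heterozygous in >=1 African and >=1 Eurasian taxon."""
    afr = np.zeros(len(df), dtype=bool)
    eur = np.zeros(len(df), dtype=bool)
    for t in AFRICAN:
        afr |= df[t.value].to_numpy(dtype=float) == 1.0
    for t in EURASIAN:
        eur |= df[t.value].to_numpy(dtype=float) == 1.0
    return afr & eur


def _two_mutation(df: pd.DataFrame) -> np.ndarray:
    """Sites whose derived configuration requires >=2 mutations on the species
    tree even when a single discordantly-coalescing lineage is allowed.

    With at most one extra lineage surviving past the African/Eurasian split
    (a side entering the ancestral population as two lineages X and its
    complement instead of one), the branches available for a single mutation
    subtend either a within-side set or X plus the *entire* other side.
    Hence a site is one-mutation-explicable iff its derived alleles are
    confined to one side, or include all four chromosomes of at least one
    side; anything else is flagged.
    """
    counts = df[["F", "S", "A", "M"]].to_numpy(dtype=float)
    afr = counts[:, 0] + counts[:, 1]
    eur = counts[:, 2] + counts[:, 3]
    both_sides = (afr > 0) & (eur > 0)
    return both_sides & (afr < 4) & (eur < 4)


RECURRENCE_RULES: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {
    "segregating-both-sides": _segregating_both_sides,
    "two-mutation": _two_mutation,
}


def filter_recurrent(
    table: DivergentSiteTable,
    rule: str = "segregating-both-sides",
) -> DivergentSiteTable:
    """Flag and remove probable recurrent-mutation/error sites.

    Requires a polarized table.  Only complete sites can be judged; sites
    with missing calls are never flagged.  Accounting lands in ``meta``:
    ``n_recurrent_input``, ``n_recurrent_removed``, ``n_retained``.
    """
    if not table.polarized:
        raise ValueError("recurrence filtering requires a polarized table")
    try:
        rule_fn = RECURRENCE_RULES[rule]
    except KeyError:
        raise ValueError(f"unknown recurrence rule {rule!r}; "
                         f"choose from {sorted(RECURRENCE_RULES)}")
    df = table.df
    flags = rule_fn(df) & df["complete"].to_numpy(dtype=bool)
    out_df = df.copy()
    out_df["recurrent"] = flags
    out = DivergentSiteTable(out_df.loc[~flags].reset_index(drop=True),
                             polarized=True, meta=dict(table.meta))
    out.meta.update(
        n_recurrent_input=len(df),
        n_recurrent_removed=int(flags.sum()),
        n_retained=int((~flags).sum()),
        recurrence_rule=rule,
    )
    logger.info("recurrence filter (%s): removed %d of %d sites, retained %d",
                rule, int(flags.sum()), len(df), int((~flags).sum()))
    return out


def site_accounting(table: DivergentSiteTable) -> dict:
    """Roll up the count transitions a run must be able to report."""
    meta = table.meta
    return {
        "n_loci": meta.get("n_loci"),
        "n_loci_dropped": meta.get("n_loci_dropped"),
        "total_bp": meta.get("total_bp"),
        "n_biallelic": meta.get("n_biallelic"),
        "n_unpolarizable": meta.get("n_unpolarizable"),
        "n_recurrent_removed": meta.get("n_recurrent_removed"),
        "n_retained": meta.get("n_retained"),
        "n_polymorphic": table.n_polymorphic,
    }
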