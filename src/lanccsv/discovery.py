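"""Continent- and population-specific variant discovery.

A CSV is an allele observed (carrier count >= 1) in exactly one group at the
chosen level and absent (count 0) from every other group.  Both alleles at a
site may independently qualify (fixed differences).  The informative density
N_k — expected group-k CSVs carried per group-k haplotype per megabase —
drives the heterozygous-state emission ratios of the HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel


@dataclass
class CsvTable:
    """Per-allele CSV records with the source group and per-group frequencies.

    ``df`` columns: site (row in the harmonized site table), chrom, pos, ref,
    alt, csv_allele ('ref'|'alt'), group, and one ``freq_<group>`` column per
    group (frequency of the CSV allele; positive only for the source group).
    """

    df: pd.DataFrame
    groups: list
    level: str = "continental"

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    def counts_by_group(self) -> pd.Series:
        return self.df["group"].value_counts().reindex(self.groups, fill_value=0)

    def keys(self) -> set:
        """(site, csv_allele) identity of each record."""
        return set(zip(self.df["site"], self.df["csv_allele"]))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, level="continental") -> "CsvTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        groups = [c[len("freq_"):] for c in df.columns if c.startswith("freq_")]
        return cls(df, groups, level)


@dataclass
class DensityEstimate:
    """Observed CSV densities on held-out haplotypes.

    ``matrix``: rows = group of the evaluated haplotype, columns = source
    group of the CSVs counted; entries are mean carried CSVs per haplotype
    per megabase.  The diagonal is the informative density N_k; off-diagonal
    mass is the spurious rate.
    """

    matrix: pd.DataFrame
    n_haplotypes: pd.Series = field(default=None)

    @property
    def n_k(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix), index=self.matrix.index)

    @property
    def spurious_rate(self) -> pd.Series:
        return self.matrix.sum(axis=1) - self.n_k


@dataclass
class ObservationSequence:
    """Ordered CSV observations of one individual on one chromosome."""

    positions: np.ndarray  # bp, non-decreasing
    groups: np.ndarray     # index into group_names
    sites: np.ndarray      # row in the harmonized site table
    group_names: list
    chrom: str

    def __len__(self):
        return len(self.positions)

    @property
    def distances(self) -> np.ndarray:
        """Inter-observation distances d_j in bp (d_0 = 0)."""
        return np.diff(self.positions, prepend=self.positions[:1])


# ------------------------------------------------------------------- discovery

def _records_frame(sites: pd.DataFrame, sole: np.ndarray, freqs: np.ndarray,
                   groups: list, which_allele: str) -> pd.DataFrame:
    """Vectorized record table for alleles present in exactly one group.

    ``sole`` is (n_sites, K) boolean with at most one True per row; ``freqs``
    is the frequency of the allele per group.
    """
    idx = np.flatnonzero(sole.any(axis=1))
    k = np.argmax(sole[idx], axis=1)
    df = sites.iloc[idx].reset_index(drop=True).copy()
    df.insert(0, "site", idx)
    df["csv_allele"] = which_allele
    df["group"] = np.asarray(groups, dtype=object)[k]
    for j, g in enumerate(groups):
        df[f"freq_{g}"] = freqs[idx, j]
    return df


def _assemble(sites, alt_sole, ref_sole, freqs_alt, groups, level) -> CsvTable:
    parts = [_records_frame(sites, alt_sole, freqs_alt, groups, "alt"),
             _records_frame(sites, ref_sole, 1.0 - freqs_alt, groups, "ref")]
    df = pd.concat(parts, ignore_index=True)
    df = df.sort_values(["site", "csv_allele"], kind="stable").reset_index(drop=True)
    return CsvTable(df, list(groups), level)


def call_csvs(panel: HaplotypePanel, level: str = "continental",
              min_count: int = 1) -> CsvTable:
    """Call all (site, allele) pairs observed in exactly one group.

    ``min_count`` is the presence threshold for the source group (absence in
    the other groups always means count 0); the default of 1 is the plain
    presence/absence definition.
    """
    groups = panel.group_names(level)
    declared = panel.declared_group_names(level)
    if len(declared) < 2:
        raise ValueError("need >= 2 groups to call group-specific variants")
    missing = set(declared) - set(groups)
    if missing:
        raise ValueError(
            f"group(s) with zero haplotypes: {sorted(missing)} (cannot assert absence)")
    counts, sizes = panel.allele_counts(level)
    alt = counts.to_numpy()
    ref = sizes.to_numpy()[None, :] - alt
    freqs_alt = alt / sizes.to_numpy()[None, :]
    alt_sole = (alt >= min_count) & ((alt > 0).sum(axis=1, keepdims=True) == 1)
    ref_sole = (ref >= min_count) & ((ref > 0).sum(axis=1, keepdims=True) == 1)
    return _assemble(panel.sites, alt_sole, ref_sole, freqs_alt, groups, level)


def call_csvs_from_freqs(sites: pd.DataFrame, freqs_alt: pd.DataFrame,
                         level: str = "continental") -> CsvTable:
    """Call CSVs from per-group alt-allele frequencies (presence = freq > 0).

    Used after sample-aware frequency updates, where carrier counts are no
    longer available but presence/absence is what defines a CSV.
    """
    groups = list(freqs_alt.columns)
    fa = freqs_alt.to_numpy(dtype=float)
    alt_sole = (fa > 0) & ((fa > 0).sum(axis=1, keepdims=True) == 1)
    ref_sole = (fa < 1) & ((fa < 1).sum(axis=1, keepdims=True) == 1)
    return _assemble(sites, alt_sole, ref_sole, fa, groups, level)


# ------------------------------------------------------------------- densities

def loo_carried_counts(panel: HaplotypePanel, level: str = "continental",
                       min_count: int = 1):
    """Leave-one-out carried-CSV counts: (n_haplotypes, K) matrix.

    Entry (h, j) is the number of group-j CSV alleles — called with
    haplotype h held out — that h itself carries.  Fully vectorized: removing
    h from its group k only changes group k's allele counts, and only carried
    alleles can be counted, so the sole-group test is evaluated directly on
    the adjusted counts at h's carried sites.
    """
    groups = panel.group_names(level)
    K = len(groups)
    counts, sizes = panel.allele_counts(level)
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValueError(f"need >= 2 haplotypes per group for leave-one-out: {small}")
    alt = counts.to_numpy()
    ref = sizes.to_numpy()[None, :] - alt
    hap_groups = panel.hap_groups(level)
    gidx = {g: i for i, g in enumerate(groups)}
    out = np.zeros((panel.n_haplotypes, K), dtype=np.int64)

    for h in range(panel.n_haplotypes):
        k = gidx[hap_groups[h]]
        a = panel.haplotypes[:, h]
        for counts_mat, carrier in ((alt, a == 1), (ref, a == 0)):
            # adjusted counts at carried sites: column k loses one carrier
            c = counts_mat[carrier].copy()
            c[:, k] -= 1
            present = c > 0
            sole = (c >= min_count) & (present.sum(axis=1, keepdims=True) == 1) & present
            out[h] += sole.sum(axis=0)
    return out, hap_groups, groups


def estimate_density(panel: HaplotypePanel, level: str = "continental",
                     target_panel: HaplotypePanel | None = None,
                     min_count: int = 1) -> DensityEstimate:
    """Observed CSV densities per held-out haplotype per megabase.

    With a disjoint ``target_panel``, CSVs are called once on ``panel`` and
    counted on every target haplotype.  Without one, each panel haplotype is
    held out in turn, CSVs are re-called on the remainder and the CSV alleles
    the held-out haplotype carries are counted — the self-contained analogue
    of training and evaluating on disjoint populations of the same groups.
    """
    groups = panel.group_names(level)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to estimate specific-variant densities")
    span = panel.span_mb()

    if target_panel is not None:
        table = call_csvs(panel, level, min_count)
        t_sites = table.df["site"].to_numpy()
        t_alt = (table.df["csv_allele"] == "alt").to_numpy()
        t_group = table.df["group"].to_numpy()
        tgt_groups = target_panel.hap_groups(level)
        out = np.zeros((target_panel.n_haplotypes, len(groups)), dtype=np.int64)
        for j, g in enumerate(groups):
            sel = t_group == g
            s, is_alt = t_sites[sel], t_alt[sel]
            H = target_panel.haplotypes[s]  # (n_records_g, n_hap)
            carried = np.where(is_alt[:, None], H == 1, H == 0)
            out[:, j] = carried.sum(axis=0)
        eval_groups = tgt_groups
    else:
        out, eval_groups, groups = loo_carried_counts(panel, level, min_count)

    sums = pd.DataFrame(0.0, index=groups, columns=groups)
    n_eval = pd.Series(0, index=groups)
    for i, g in enumerate(eval_groups):
        sums.loc[g] += out[i]
        n_eval[g] += 1
    matrix = sums.div(n_eval.replace(0, np.nan), axis=0) / span
    return DensityEstimate(matrix, n_eval)


# ----------------------------------------------------------------- observation

def observe_csvs(genotype_or_hap: np.ndarray, table: CsvTable,
                 chrom: str | None = None) -> ObservationSequence:
    """CSV observations of one individual (or haplotype), in position order.

    A diploid individual carries an alt-allele CSV when its genotype is >= 1
    and a ref-allele CSV when <= 1; carriage yields *one* observation
    regardless of copy number.  A missing genotype yields no observation.
    Haploid 0/1 vectors follow the same rule.
    """
    g = np.asarray(genotype_or_hap)
    df = table.df
    if chrom is not None:
        df = df[df["chrom"].astype(str) == str(chrom)]
    s = df["site"].to_numpy()
    is_alt = (df["csv_allele"] == "alt").to_numpy()
    gi = g[s]
    carried = np.where(is_alt, gi >= 1, (gi >= 0) & (gi <= 1)) & (gi != MISSING)
    sel = np.flatnonzero(carried)
    group_names = list(table.groups)
    gmap = {name: i for i, name in enumerate(group_names)}
    pos = df["pos"].to_numpy()[sel]
    grp = np.array([gmap[x] for x in df["group"].to_numpy()[sel]], dtype=np.int64)
    site_idx = s[sel]
    order = np.argsort(pos, kind="stable")
    the_chrom = chrom if chrom is not None else (str(df["chrom"].iloc[0]) if len(df) else "")
    return ObservationSequence(pos[order], grp[order], site_idx[order],
                               group_names, the_chrom)
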