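"""Sub-continental population-specific variant (sCSV) analysis.

An sCSV is an allele observed in exactly one population among *all*
populations of all continents — the population-level refinement of a CSV.
Leave-one-out profiles, naive maximum-count segment assignment with a
continental roll-up, and enrichment counting inside called homozygous
ancestry regions.  Diploid sub-continental decoding needs no separate
engine: a population-level CsvTable feeds the same HMM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, GenotypeMatrix
from .tracks import AncestryTrack
from .discovery import CsvTable, call_csvs, loo_carried_counts


@dataclass
class SegmentAssignment:
    haplotype: int
    start: int
    end: int
    counts: pd.Series            # sCSVs carried per population on the segment
    assigned: str                # population or "unassigned"
    true_population: str | None = None


def loo_profile(panel: HaplotypePanel, level: str = "population",
                per_mb: bool = True):
    """Leave-one-out mean sCSV counts on held-out haplotypes.

    Returns ``(matrix, normalized)``: rows = population of the held-out
    haplotype, columns = source population of the carried sCSVs; entries are
    means over held-out haplotypes (per megabase when ``per_mb``).  The
    normalized variant divides each row by its maximum, so the strongest
    source population scores 1.
    """
    counts, hap_groups, groups = loo_carried_counts(panel, level)
    sums = pd.DataFrame(0.0, index=groups, columns=groups)
    n = pd.Series(0, index=groups)
    for i, g in enumerate(hap_groups):
        sums.loc[g] += counts[i]
        n[g] += 1
    matrix = sums.div(n, axis=0)
    if per_mb:
        matrix = matrix / panel.span_mb()
    row_max = matrix.max(axis=1).replace(0, np.nan)
    normalized = matrix.div(row_max, axis=0).fillna(0.0)
    return matrix, normalized


def _carried_positions(hap_alleles: np.ndarray, table: CsvTable) -> dict:
    """Positions (bp) of each population's sCSV alleles carried by a haplotype."""
    df = table.df
    s = df["site"].to_numpy()
    is_alt = (df["csv_allele"] == "alt").to_numpy()
    a = hap_alleles[s]
    carried = np.where(is_alt, a == 1, a == 0)
    out = {}
    for g in table.groups:
        sel = carried & (df["group"].to_numpy() == g)
        out[g] = np.sort(df["pos"].to_numpy()[sel])
    return out


def assign_segment(hap_alleles: np.ndarray, interval: tuple[int, int],
                   table: CsvTable, true_population: str | None = None,
                   haplotype: int = -1) -> SegmentAssignment:
    """Assign a haplotype segment to the population with the most carried
    sCSVs inside it; ties or zero counts yield "unassigned" (scored as
    incorrect downstream)."""
    start, end = interval
    pos_by_pop = _carried_positions(hap_alleles, table)
    counts = pd.Series({g: int(np.searchsorted(p, end, side="right")
                               - np.searchsorted(p, start, side="left"))
                        for g, p in pos_by_pop.items()})
    top = counts.max()
    if top == 0 or (counts == top).sum() > 1:
        assigned = "unassigned"
    else:
        assigned = counts.idxmax()
    return SegmentAssignment(haplotype, start, end, counts, assigned, true_population)


def segment_sweep(panel: HaplotypePanel, length_range=(0.05e6, 30e6),
                  n_per_hap: int = 5, seed: int = 0,
                  level: str = "population") -> pd.DataFrame:
    """Leave-one-out assignment accuracy over random segments.

    For every held-out haplotype, sCSVs are re-trained on the remainder and
    ``n_per_hap`` random segments with lengths uniform in ``length_range``
    (bp) are assigned by maximum sCSV count.  Returns a tidy table with the
    assignment, correctness at population level and after continental
    roll-up, and the segment length; deterministic given the seed.
    """
    lo, hi = length_range
    if not 0 < lo <= hi:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    pops = panel.group_names(level)
    labels = panel.hap_groups(level)
    chrom_start = int(panel.sites["pos"].min())
    chrom_end = int(panel.sites["pos"].max())
    rows = []
    for h in range(panel.n_haplotypes):
        loo = panel.drop_haplotypes([h])
        table = call_csvs(loo, level)
        pos_by_pop = _carried_positions(panel.haplotypes[:, h], table)
        for _ in range(n_per_hap):
            length = rng.uniform(lo, hi)
            length = min(length, chrom_end - chrom_start)
            start = int(rng.uniform(chrom_start, chrom_end - length))
            end = int(start + length)
            counts = {g: int(np.searchsorted(p, end, side="right")
                             - np.searchsorted(p, start, side="left"))
                      for g, p in pos_by_pop.items()}
            cs = pd.Series(counts)
            top = cs.max()
            assigned = ("unassigned" if top == 0 or (cs == top).sum() > 1
                        else cs.idxmax())
            true_pop = labels[h]
            correct_pop = assigned == true_pop
            if assigned == "unassigned":
                correct_cont = False
            elif level == "population":
                correct_cont = (panel.continent_of(assigned)
                                == panel.continent_of(true_pop))
            else:
                correct_cont = correct_pop
            rows.append({"haplotype": h, "population": true_pop,
                         "length_bp": end - start, "assigned": assigned,
                         "correct_population": correct_pop,
                         "correct_continental": correct_cont,
                         "unassigned": assigned == "unassigned"})
    return pd.DataFrame(rows)


def enrichment_counts(gm: GenotypeMatrix, tracks: AncestryTrack,
                      pair: tuple[str, str], table: CsvTable,
                      group_map: dict | None = None) -> pd.Series:
    """sCSVs per population per megabase per haplotype inside homozygous
    continental-ancestry regions.

    ``pair`` selects the diploid ancestry regions to scan, e.g. (AFR, AFR);
    track labels are compared after mapping through ``group_map`` when the
    tracks are continental and the table is population-level.  Counts of
    carried sCSV alleles inside the selected regions are normalized by the
    total selected length in megabases times two haplotypes per individual.
    """
    want = tuple(sorted(pair))
    df = table.df
    sites = df["site"].to_numpy()
    is_alt = (df["csv_allele"] == "alt").to_numpy()
    rec_pos = df["pos"].to_numpy()
    rec_chrom = df["chrom"].astype(str).to_numpy()
    rec_grp = df["group"].to_numpy()
    counts = pd.Series(0.0, index=table.groups)
    total_mb = 0.0
    gmap = group_map or {}
    tdf = tracks.df.copy()
    tdf["m1"] = tdf["a1"].map(lambda a: gmap.get(a, a))
    tdf["m2"] = tdf["a2"].map(lambda a: gmap.get(a, a))
    lo = tdf[["m1", "m2"]].min(axis=1)
    hi = tdf[["m1", "m2"]].max(axis=1)
    sel_tracks = tdf[(lo == want[0]) & (hi == want[1])]
    jidx = {str(s): j for j, s in enumerate(gm.samples)}
    for row in sel_tracks.itertuples(index=False):
        j = jidx.get(str(row.individual))
        if j is None:
            continue
        total_mb += (row.end - row.start + 1) / 1e6
        in_seg = ((rec_chrom == str(row.chrom))
                  & (rec_pos >= row.start) & (rec_pos <= row.end))
        gi = gm.genotypes[sites, j]
        carried = np.where(is_alt, gi >= 1, (gi >= 0) & (gi <= 1)) & (gi >= 0)
        hit = in_seg & carried
        if hit.any():
            counts = counts.add(pd.Series(rec_grp[hit]).value_counts(), fill_value=0)
    if total_mb == 0:
        raise ValueError("no regions with the requested homozygous ancestry pair")
    return counts / (total_mb * 2.0)
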