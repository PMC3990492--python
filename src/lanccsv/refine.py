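"""Sample-aware iterative refinement of the CSV set.

Confidently called homozygous-ancestry segments of the admixed cohort itself
are used to re-estimate per-group allele frequencies; the element-wise
maximum of reference and sample frequencies then re-defines CSV
presence/absence (frequencies act as presence indicators, so evidence only
accumulates), CSVs are re-called and the cohort re-decoded.  Sites within a
buffer of an inferred ancestry transition are excluded from the frequency
sums, as calls there are least confident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel, GenotypeMatrix
from .tracks import AncestryTrack
from .discovery import CsvTable, call_csvs_from_freqs, estimate_density
from .hmm import HmmSpec, infer_cohort


def sample_frequencies(gm: GenotypeMatrix, track: AncestryTrack,
                       groups, buffer: int = 10) -> pd.DataFrame:
    """Per-group alt-allele frequencies from homozygous-ancestry calls.

    For each site i and group k, p_ki = (sum of alt counts over individuals
    called homozygous-k at i) / (2 x number of such calls); individuals whose
    site lies within ``buffer`` analysis-set SNPs of one of their ancestry
    transitions are excluded, as are missing genotypes.  Sites with no
    eligible call are NaN (undefined).
    """
    groups = list(groups)
    num = {g: np.zeros(gm.n_sites) for g in groups}
    den = {g: np.zeros(gm.n_sites) for g in groups}
    for chrom, sub in gm.sites.groupby("chrom", sort=False):
        rows = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        idx = np.arange(len(rows))
        for j, ind in enumerate(gm.samples):
            a1, a2 = track.states_at(str(ind), str(chrom), pos, missing_ok=True)
            # distance (in analysis SNPs) to the nearest call transition
            change = np.flatnonzero(a1[1:] != a1[:-1]) + 1
            change2 = np.flatnonzero(a2[1:] != a2[:-1]) + 1
            bnds = np.union1d(change, change2)
            if len(bnds):
                # site at index b is adjacent to the transition (distance 1)
                d_right = idx[:, None] - bnds[None, :] + 1   # >= 1 after bnd
                d_left = bnds[None, :] - idx[:, None]        # >= 1 before bnd
                dist = np.where(idx[:, None] >= bnds[None, :], d_right, d_left)
                near = dist.min(axis=1) <= buffer
            else:
                near = np.zeros(len(idx), dtype=bool)
            g = gm.genotypes[rows, j]
            ok = (~near) & (g != MISSING)
            for k in groups:
                hom = (a1 == k) & (a2 == k) & ok
                num[k][rows[hom]] += g[hom]
                den[k][rows[hom]] += 2
    out = {}
    for k in groups:
        with np.errstate(invalid="ignore", divide="ignore"):
            out[k] = np.where(den[k] > 0, num[k] / np.maximum(den[k], 1), np.nan)
    return pd.DataFrame(out, columns=groups)


def max_update(ref_freqs: pd.DataFrame, sample_freqs: pd.DataFrame) -> pd.DataFrame:
    """Element-wise maximum, aligned by group name; undefined (NaN) sample
    entries pass the reference through.  Frequencies are presence indicators:
    absence in the sample never erases reference presence, while presence in
    the sample can both create new CSVs and kill spurious ones of other
    groups."""
    aligned = sample_freqs.reindex(columns=ref_freqs.columns)
    return pd.DataFrame(np.fmax(ref_freqs.to_numpy(float), aligned.to_numpy(float)),
                        columns=ref_freqs.columns, index=ref_freqs.index)


@dataclass
class IterationResult:
    """Final tracks plus per-iteration CSV-set diagnostics and history."""

    tracks: AncestryTrack
    csv_table: CsvTable
    diagnostics: pd.DataFrame          # iteration, n_csvs, added, removed
    history: list = field(default_factory=list)  # AncestryTrack per iteration
    tables: list = field(default_factory=list)   # CsvTable per iteration


def iterate(gm: GenotypeMatrix, panel: HaplotypePanel, spec: HmmSpec,
            n_iter: int = 4, buffer: int = 10, level: str = "continental",
            early_stop: bool = True, keep_history: bool = True) -> IterationResult:
    """Reference-panel decode followed by ``n_iter`` sample-aware refinements.

    Each refinement: estimate sample frequencies from homozygous segments of
    the current calls, take the element-wise max with the running
    frequencies, re-call CSVs, re-decode.  ``n_iter = 0`` reproduces the
    reference-panel-only pipeline.  Stops early when the CSV set no longer
    changes (the configured iteration count, not a frequency tolerance, is
    the only other stopping rule).
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    freqs = panel.allele_freqs(level)
    table = call_csvs_from_freqs(panel.sites, freqs, level)
    diags, history, tables = [], [], []
    tracks = infer_cohort(gm, table, spec)
    if keep_history:
        history.append(tracks)
        tables.append(table)
    diags.append({"iteration": 0, "n_csvs": len(table), "added": 0, "removed": 0})
    for it in range(1, n_iter + 1):
        sf = sample_frequencies(gm, tracks, spec.groups, buffer)
        freqs = max_update(freqs, sf)
        new_table = call_csvs_from_freqs(panel.sites, freqs, level)
        old_keys, new_keys = table.keys(), new_table.keys()
        added, removed = len(new_keys - old_keys), len(old_keys - new_keys)
        diags.append({"iteration": it, "n_csvs": len(new_table),
                      "added": added, "removed": removed})
        changed = added or removed
        table = new_table
        tracks = infer_cohort(gm, table, spec)
        if keep_history:
            history.append(tracks)
            tables.append(table)
        if early_stop and not changed:
            break
    return IterationResult(tracks, table, pd.DataFrame(diags), history, tables)


def update_from_provided_tracks(gm: GenotypeMatrix, tracks: AncestryTrack,
                                panel: HaplotypePanel, buffer: int = 10,
                                level: str = "continental") -> CsvTable:
    """One-shot CSV re-call from externally supplied ancestry tracks.

    Enables training on a held-in cohort with trusted (e.g. consensus) calls:
    sample frequencies from the provided tracks update the reference
    frequencies by element-wise max, then CSVs are re-called.  An empty track
    leaves the reference table unchanged.
    """
    groups = panel.group_names(level)
    freqs = panel.allele_freqs(level)
    if len(tracks.df):
        known = set(map(str, gm.samples))
        if not known & set(map(str, tracks.individuals)):
            raise ValueError("tracks reference none of the genotyped individuals")
        sf = sample_frequencies(gm, tracks, groups, buffer)
        freqs = max_update(freqs, sf)
    return call_csvs_from_freqs(panel.sites, freqs, level)
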