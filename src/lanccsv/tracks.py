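"""Piecewise-constant ancestry tracks (truth or calls).

Internally intervals are 1-based inclusive ``[start, end]``; on disk they are
written BED-like, 0-based half-open.  Diploid tracks carry an *unordered*
ancestry pair per segment (``a1 <= a2`` lexicographically); haploid tracks a
single ancestry (``a2`` empty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["individual", "chrom", "start", "end", "a1", "a2"]


def _normalize_pair(a1, a2):
    if a2 is None or a2 == "":
        return str(a1), ""
    a1, a2 = sorted((str(a1), str(a2)))
    return a1, a2


@dataclass
class AncestryTrack:
    """Ancestry intervals per individual; see module docstring for conventions."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        if "a2" not in df.columns:
            df["a2"] = ""
        df["a2"] = df["a2"].fillna("")
        pairs = [_normalize_pair(x, y) for x, y in zip(df["a1"], df["a2"])]
        df["a1"] = [p[0] for p in pairs]
        df["a2"] = [p[1] for p in pairs]
        df = df.sort_values(["individual", "chrom", "start"]).reset_index(drop=True)
        self.df = df[TRACK_COLUMNS]
        self._validate()
        self._index = {}
        for (ind, chrom), sub in self.df.groupby(["individual", "chrom"], sort=False):
            self._index[(ind, chrom)] = (
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                sub["a1"].to_numpy(), sub["a2"].to_numpy())

    def _validate(self):
        for (ind, chrom), sub in self.df.groupby(["individual", "chrom"], sort=False):
            start = sub["start"].to_numpy()
            end = sub["end"].to_numpy()
            if np.any(end < start):
                raise ValueError(f"empty interval for {ind} on {chrom}")
            if np.any(start[1:] <= end[:-1]):
                raise ValueError(f"overlapping intervals for {ind} on {chrom}")

    # ---------------------------------------------------------------- queries
    @property
    def individuals(self) -> list:
        return list(dict.fromkeys(self.df["individual"]))

    @property
    def ploidy(self) -> int:
        return 1 if (self.df["a2"] == "").all() else 2

    def states_at(self, individual, chrom, positions, missing_ok=False):
        """Ancestry (a1, a2) at each queried position for one individual.

        Positions outside any interval raise unless ``missing_ok``, in which
        case they return empty labels (no call).
        """
        if (individual, chrom) not in self._index:
            if missing_ok:
                n = len(np.asarray(positions))
                empty = np.full(n, "", dtype=object)
                return empty, empty.copy()
            raise KeyError(f"no track for {individual} on {chrom}")
        start, end, a1, a2 = self._index[(individual, chrom)]
        pos = np.asarray(positions)
        k = np.clip(np.searchsorted(start, pos, side="right") - 1, 0, None)
        outside = (pos < start[k]) | (pos > end[k])
        if outside.any() and not missing_ok:
            raise ValueError(f"position outside track coverage for {individual}")
        o1, o2 = a1[k].copy(), a2[k].copy()
        o1[outside] = ""
        o2[outside] = ""
        return o1, o2

    def pair_matrix(self, chrom, positions, individuals=None):
        """(n_sites, n_individuals) arrays of a1 and a2 labels."""
        individuals = self.individuals if individuals is None else individuals
        A1 = np.empty((len(positions), len(individuals)), dtype=object)
        A2 = np.empty_like(A1)
        for j, ind in enumerate(individuals):
            a1, a2 = self.states_at(ind, chrom, positions)
            A1[:, j], A2[:, j] = a1, a2
        return A1, A2

    def dosage_matrix(self, chrom, positions, group, individuals=None) -> np.ndarray:
        """Diploid dosage of ``group`` (0/1/2) at each site × individual."""
        A1, A2 = self.pair_matrix(chrom, positions, individuals)
        return (A1 == group).astype(np.int8) + (A2 == group).astype(np.int8)

    def switch_positions(self, individual, chrom) -> np.ndarray:
        """Positions (bp, start of the new segment) where the state changes."""
        start, end, a1, a2 = self._index[(individual, chrom)]
        if len(start) < 2:
            return np.array([], dtype=np.int64)
        changed = (a1[1:] != a1[:-1]) | (a2[1:] != a2[:-1])
        return start[1:][changed]

    def chroms(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    def map_labels(self, mapping: dict) -> "AncestryTrack":
        """Relabel ancestries (e.g. population -> continental group)."""
        df = self.df.copy()
        df["a1"] = df["a1"].map(lambda a: mapping.get(a, a))
        df["a2"] = df["a2"].map(lambda a: mapping.get(a, a) if a else "")
        return AncestryTrack(from_runs(df))

    def __eq__(self, other):
        return isinstance(other, AncestryTrack) and self.df.equals(other.df)


def from_segments(segments) -> AncestryTrack:
    """Build a track from (individual, chrom, start, end, a1, a2) tuples,
    merging adjacent segments with equal state."""
    df = pd.DataFrame(segments, columns=TRACK_COLUMNS)
    return AncestryTrack(from_runs(df))


def from_runs(df: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent same-state intervals per individual/chromosome."""
    out = []
    if "a2" not in df.columns:
        df = df.assign(a2="")
    df = df.sort_values(["individual", "chrom", "start"])
    for (ind, chrom), sub in df.groupby(["individual", "chrom"], sort=False):
        cur = None
        for row in sub.itertuples(index=False):
            a1, a2 = _normalize_pair(row.a1, row.a2)
            if cur is not None and (a1, a2) == (cur[4], cur[5]) and row.start == cur[3] + 1:
                cur[3] = row.end
            else:
                if cur is not None:
                    out.append(tuple(cur))
                cur = [ind, chrom, row.start, row.end, a1, a2]
        if cur is not None:
            out.append(tuple(cur))
    return pd.DataFrame(out, columns=TRACK_COLUMNS)


# ------------------------------------------------------------------------ I/O

def write_tracks(track: AncestryTrack, path) -> None:
    """BED-like TSV: chrom, start (0-based), end (half-open), individual, ancestry."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tindividual\tancestry\n")
        for row in track.df.itertuples(index=False):
            anc = f"{row.a1},{row.a2}" if row.a2 else row.a1
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.individual}\t{anc}\n")


def read_tracks(path) -> AncestryTrack:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, ind, anc = line.rstrip("\n").split("\t")
            parts = anc.split(",")
            a1 = parts[0]
            a2 = parts[1] if len(parts) > 1 else ""
            rows.append((ind, chrom, int(start) + 1, int(end), a1, a2))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return AncestryTrack(df)  # validation raises on overlap
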