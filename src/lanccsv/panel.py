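"""Reference-panel and genotype containers plus all on-disk formats.

Coordinate conventions: positions are 1-based internally (VCF convention);
interval outputs are 0-based half-open (BED convention, see :mod:`.tracks`).
Only biallelic SNVs are modeled; multiallelic and non-SNV records are skipped
on read with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype; never conflated with homozygous reference.
MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]

#: strand-ambiguous allele pairs (indistinguishable after a strand flip)
_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def _check_sites(sites: pd.DataFrame) -> pd.DataFrame:
    sites = sites.reset_index(drop=True)
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
    return sites


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix with population labels.

    Parameters
    ----------
    sites : DataFrame with columns chrom, pos (1-based), ref, alt.
    haplotypes : uint8 array (n_sites, n_haplotypes); 1 = alternate allele.
    labels : population name per haplotype column.
    group_map : population -> continental group.  Identity if omitted.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    labels: np.ndarray
    group_map: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sites = _check_sites(self.sites)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != len(self.sites):
            raise ValueError("haplotype matrix shape does not match sites")
        if self.haplotypes.shape[1] != len(self.labels):
            raise ValueError("one population label required per haplotype")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype entries must be 0/1")
        for pop in np.unique(self.labels):
            self.group_map.setdefault(pop, pop)

    # ------------------------------------------------------------------ views
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def hap_groups(self, level: str = "continental") -> np.ndarray:
        """Group label of each haplotype at the requested level."""
        if level == "population":
            return self.labels
        if level == "continental":
            return np.array([self.group_map[p] for p in self.labels], dtype=object)
        raise ValueError(f"unknown level {level!r}")

    def group_names(self, level: str = "continental") -> list[str]:
        return sorted(set(self.hap_groups(level)))

    def declared_group_names(self, level: str = "continental") -> list[str]:
        """Groups declared in the label map, whether or not any haplotype
        remains for them (absence claims need every declared group)."""
        if level == "population":
            return sorted(set(self.group_map))
        return sorted(set(self.group_map.values()))

    def continent_of(self, population: str) -> str:
        return self.group_map[population]

    def span_mb(self) -> float:
        """Total covered span over all chromosomes, in megabases."""
        total = 0
        for _, sub in self.sites.groupby("chrom", sort=False):
            span = int(sub["pos"].max() - sub["pos"].min())
            if span < 1:
                raise ValueError("chromosome span < 1 bp")
            total += span
        return total / 1e6

    def allele_counts(self, level: str = "continental"):
        """Alternate-allele count per site per group, plus group sizes."""
        groups = self.group_names(level)
        hap_g = self.hap_groups(level)
        onehot = np.stack([(hap_g == g) for g in groups], axis=1).astype(np.int64)
        counts = self.haplotypes.astype(np.int64) @ onehot
        sizes = onehot.sum(axis=0)
        return pd.DataFrame(counts, columns=groups), pd.Series(sizes, index=groups)

    def allele_freqs(self, level: str = "continental") -> pd.DataFrame:
        counts, sizes = self.allele_counts(level)
        return counts / sizes

    def drop_haplotypes(self, idx) -> "HaplotypePanel":
        keep = np.ones(self.n_haplotypes, dtype=bool)
        keep[idx] = False
        return HaplotypePanel(self.sites, self.haplotypes[:, keep],
                              self.labels[keep], dict(self.group_map))

    def subset_sites(self, mask) -> "HaplotypePanel":
        mask = np.asarray(mask)
        return HaplotypePanel(self.sites.loc[mask].reset_index(drop=True),
                              self.haplotypes[mask], self.labels, dict(self.group_map))


@dataclass
class GenotypeMatrix:
    """Unphased genotypes of admixed individuals: alt-allele counts 0/1/2, -1 missing."""

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list

    def __post_init__(self):
        self.sites = _check_sites(self.sites)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites × samples")
        vals = np.unique(self.genotypes)
        if not np.all(np.isin(vals, [MISSING, 0, 1, 2])):
            raise ValueError("genotypes must be in {0,1,2} or missing (-1)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)


# --------------------------------------------------------------------- filters

def filter_strand_ambiguous(panel: HaplotypePanel) -> HaplotypePanel:
    """Drop A/T and C/G sites, whose alleles are ambiguous under a strand flip."""
    pairs = [frozenset({r, a}) for r, a in zip(panel.sites["ref"], panel.sites["alt"])]
    keep = np.array([p not in _AMBIGUOUS for p in pairs])
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_strand_ambiguous: removed %d sites", removed)
    return panel.subset_sites(keep)


# ------------------------------------------------------------------- panel I/O

def _read_labels(labels_path) -> tuple[dict, dict]:
    """Label file: TSV of sample, population[, continental group]."""
    df = pd.read_csv(labels_path, sep=r"\s+", header=None, comment="#")
    pop_of = dict(zip(df[0].astype(str), df[1].astype(str)))
    group_map = {}
    if df.shape[1] > 2:
        group_map = dict(zip(df[1].astype(str), df[2].astype(str)))
    return pop_of, group_map


def _is_snv(ref: str, alts: list[str]) -> bool:
    return len(alts) == 1 and len(ref) == 1 and len(alts[0]) == 1 \
        and ref in "ACGT" and alts[0] in "ACGT"


def read_panel(path, labels_path, group_map: dict | None = None) -> HaplotypePanel:
    """Read a phased reference panel from VCF or the plain-matrix dialect.

    The plain-matrix dialect is a whitespace TSV: a header line of haplotype
    IDs, then one row per site ``chrom pos ref alt a1 a2 ...`` with alleles
    in {0,1}.  The labels file maps samples (VCF) or haplotype IDs (matrix)
    to populations and, optionally, populations to continental groups.
    """
    path = str(path)
    pop_of, file_gmap = _read_labels(labels_path)
    gmap = dict(file_gmap)
    if group_map:
        gmap.update(group_map)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        sites, hap, labels = _read_panel_vcf(path, pop_of)
    else:
        sites, hap, labels = _read_panel_matrix(path, pop_of)
    return HaplotypePanel(sites, hap, labels, gmap)


def _read_panel_vcf(path, pop_of):
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = vcf.samples
    for s in samples:
        if s not in pop_of:
            raise ValueError(f"sample {s!r} missing from labels file")
    rows, haps, skipped = [], [], 0
    for var in vcf:
        if not _is_snv(var.REF, var.ALT):
            skipped += 1
            continue
        alleles = []
        for s, gt in zip(samples, var.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {s} at {var.CHROM}:{var.POS}")
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype in reference panel at {var.CHROM}:{var.POS}")
            alleles.extend((a, b))
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        haps.append(alleles)
    if skipped:
        logger.info("read_panel: skipped %d multiallelic/non-SNV records", skipped)
    labels = np.repeat([pop_of[s] for s in samples], 2)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return sites, np.asarray(haps, dtype=np.uint8), labels


def _read_panel_matrix(path, pop_of):
    with open(path) as fh:
        hap_ids = fh.readline().split()
        rows, haps = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom, pos, ref, alt = parts[:4]
            if not _is_snv(ref, [alt]):
                continue
            rows.append((chrom, int(pos), ref, alt))
            haps.append([int(x) for x in parts[4:]])
    for h in hap_ids:
        if h not in pop_of:
            raise ValueError(f"haplotype {h!r} missing from labels file")
    labels = np.array([pop_of[h] for h in hap_ids], dtype=object)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return sites, np.asarray(haps, dtype=np.uint8), labels


def write_panel(panel: HaplotypePanel, path, labels_path=None) -> None:
    """Write the plain-matrix panel dialect (and optionally the labels file)."""
    hap_ids = [f"h{i}" for i in range(panel.n_haplotypes)]
    with open(path, "w") as fh:
        fh.write(" ".join(hap_ids) + "\n")
        for i, row in enumerate(panel.sites.itertuples(index=False)):
            alleles = " ".join(map(str, panel.haplotypes[i]))
            fh.write(f"{row.chrom} {row.pos} {row.ref} {row.alt} {alleles}\n")
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            for h, pop in zip(hap_ids, panel.labels):
                fh.write(f"{h}\t{pop}\t{panel.group_map[pop]}\n")


# ---------------------------------------------------------------- genotype I/O

def read_genotypes(path) -> GenotypeMatrix:
    """Read unphased genotypes from VCF (``./.`` becomes missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, geno, skipped = [], [], 0
    for var in vcf:
        if not _is_snv(var.REF, var.ALT):
            skipped += 1
            continue
        g = []
        for gt in var.genotypes:
            a, b = gt[0], gt[1]
            g.append(MISSING if (a < 0 or b < 0) else a + b)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        geno.append(g)
    if skipped:
        logger.info("read_genotypes: skipped %d multiallelic/non-SNV records", skipped)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return GenotypeMatrix(sites, np.asarray(geno, dtype=np.int8), samples)


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, sub in gm.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.samples)) + "\n")
        for i, row in enumerate(gm.sites.itertuples(index=False)):
            cells = "\t".join(gt_str[int(g)] for g in gm.genotypes[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{cells}\n")


# -------------------------------------------------------------- harmonization

def harmonize(panel: HaplotypePanel, gm: GenotypeMatrix,
              on_swap: str = "flip") -> GenotypeMatrix:
    """Align genotypes to the panel's site set by (chrom, pos, ref, alt).

    Sites present only in the genotypes are dropped (they cannot be CSVs
    under the panel); panel sites absent from the genotypes become missing.
    Allele-swapped records (ref/alt reversed) are flipped (g -> 2-g, logged)
    or dropped according to ``on_swap``.
    """
    if on_swap not in ("flip", "drop"):
        raise ValueError("on_swap must be 'flip' or 'drop'")
    key = lambda df: list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
    gidx = {k: i for i, k in enumerate(key(gm.sites))}
    out = np.full((panel.n_sites, gm.n_individuals), MISSING, dtype=np.int8)
    flipped = 0
    for i, (chrom, pos, ref, alt) in enumerate(key(panel.sites)):
        j = gidx.get((chrom, pos, ref, alt))
        if j is not None:
            out[i] = gm.genotypes[j]
            continue
        j = gidx.get((chrom, pos, alt, ref))
        if j is not None and on_swap == "flip":
            g = gm.genotypes[j]
            out[i] = np.where(g == MISSING, MISSING, 2 - g)
            flipped += 1
    if flipped:
        logger.info("harmonize: flipped %d allele-swapped records", flipped)
    return GenotypeMatrix(panel.sites, out, gm.samples)


# ----------------------------------------------------------------- read counts

def write_read_counts(sites: pd.DataFrame, samples, ref: np.ndarray,
                      alt: np.ndarray, path) -> None:
    """Long-format TSV: chrom, pos, individual, ref_count, alt_count."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tindividual\tref_count\talt_count\n")
        for j, s in enumerate(samples):
            for i, row in enumerate(sites.itertuples(index=False)):
                fh.write(f"{row.chrom}\t{row.pos}\t{s}\t{int(ref[i, j])}\t{int(alt[i, j])}\n")


def read_read_counts(path, sites: pd.DataFrame, samples):
    """Inverse of :func:`write_read_counts`, aligned to a site table."""
    df = pd.read_csv(path, sep="\t")
    sidx = {(c, p): i for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))}
    jidx = {s: j for j, s in enumerate(samples)}
    ref = np.zeros((len(sites), len(samples)), dtype=np.int64)
    alt = np.zeros_like(ref)
    for row in df.itertuples(index=False):
        i = sidx.get((row.chrom if isinstance(row.chrom, str) else str(row.chrom), row.pos))
        if i is None:
            i = sidx.get((str(row.chrom), row.pos))
        j = jidx[str(row.individual)]
        if i is not None:
            ref[i, j] = row.ref_count
            alt[i, j] = row.alt_count
    return ref, alt
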