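"""Admixture, panel and read simulation with known truth.

Admixed haploids are built by a random walk over reference haplotypes:
crossover distances are exponential with mean 1/(lambda * G) bp, and at each
crossover an ancestry is redrawn from the admixture proportions theta (so not
every crossover is an ancestry switch) and a source haplotype is drawn
uniformly from that group.  Two independent haploids form a diploid.

The synthetic-panel generator emulates K-population panels with
population-private rare variants at controlled densities plus shared
variants; ``generate_panel_pair`` additionally draws a disjoint reference /
simulation panel pair from the same truth, with an optional controlled rate
of *spurious* private variants: alleles the reference panel sees in only one
population although a second population truly carries them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel, GenotypeMatrix, SITE_COLUMNS
from .tracks import AncestryTrack, from_segments


@dataclass
class AdmixtureModel:
    """Admixture proportions, age and crossover rate of the simulated walk."""

    groups: list
    theta: np.ndarray
    generations: int
    crossover_rate: float = 1e-8  # per bp per generation

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if len(self.theta) != len(self.groups):
            raise ValueError("theta length must match groups")
        if np.any(self.theta < 0) or abs(self.theta.sum() - 1.0) > 1e-9:
            raise ValueError("theta must be a probability simplex")
        if self.generations <= 0:
            raise ValueError("generations must be a positive integer")
        if self.crossover_rate <= 0:
            raise ValueError("crossover rate must be positive")


#: simulation presets: theta over (EUR, NAM, AFR) and generations since admixture
PRESETS = {
    "AA": AdmixtureModel(["EUR", "NAM", "AFR"], (0.2, 0.0, 0.8), 6),
    "MEX": AdmixtureModel(["EUR", "NAM", "AFR"], (0.45, 0.5, 0.05), 15),
    "PUR": AdmixtureModel(["EUR", "NAM", "AFR"], (0.67, 0.13, 0.2), 15),
}


@dataclass
class PopulationSpec:
    """One synthetic population: panel size and private-variant regime."""

    name: str
    n_haplotypes: int
    private_density: float            # private sites per Mb
    private_freq: tuple = (0.02, 0.10)  # carrier frequency range (0, 1]
    continent: str | None = None      # defaults to the population name

    def __post_init__(self):
        if self.continent is None:
            self.continent = self.name
        lo, hi = self.private_freq
        if not (0 < lo <= hi <= 1):
            raise ValueError("private_freq range must lie in (0, 1]")
        if self.private_density < 0 or self.n_haplotypes < 1:
            raise ValueError("invalid population spec")


@dataclass
class SyntheticPanelSpec:
    """Synthetic ancestral-panel layout; densities are per megabase."""

    populations: list
    length_bp: int = 10_000_000
    chrom: str = "1"
    shared_density: float = 100.0
    shared_freq: tuple = (0.05, 0.95)
    spurious_density: float = 0.0   # per Mb per population (see module docstring)
    # true carrier frequency in the hidden population: low enough that a
    # ~60-haplotype reference panel plausibly misses it (P(miss) ~ 0.3)
    spurious_freq: float = 0.02
    ld_rho: float = 0.0             # first-order Markov copying knob in [0, 1)

    def __post_init__(self):
        if self.length_bp < 2:
            raise ValueError("length_bp too small")
        if self.shared_density < 0 or self.spurious_density < 0:
            raise ValueError("densities must be >= 0")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")

    @property
    def names(self):
        return [p.name for p in self.populations]

    @property
    def group_map(self):
        return {p.name: p.continent for p in self.populations}


@dataclass
class ReadCounts:
    """Per-site per-individual reference/alternate read counts."""

    ref: np.ndarray
    alt: np.ndarray
    sites: pd.DataFrame = None
    samples: list = None

    def __post_init__(self):
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref/alt count shapes differ")
        if np.any(self.ref < 0) or np.any(self.alt < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt


# ---------------------------------------------------------------- admixed walk

def _simulate_haploid(panel, model, chrom_sites, rng, crossover_log=None):
    """One mosaic haploid over one chromosome; returns (alleles, segments).

    ``crossover_log``, when a list, receives every exponential inter-crossover
    distance as drawn (before truncation at the chromosome end) — the raw
    generative quantity distributional checks should target.
    """
    pos = chrom_sites["pos"].to_numpy()
    start_bp, end_bp = int(pos[0]), int(pos[-1])
    idx_by_group = {}
    hap_groups = panel.hap_groups("continental")
    for g in model.groups:
        idx_by_group[g] = np.flatnonzero(hap_groups == g)
    mean_len = 1.0 / (model.crossover_rate * model.generations)

    alleles = np.zeros(len(pos), dtype=np.uint8)
    segments = []
    cur = start_bp
    while cur <= end_bp:
        k = rng.choice(len(model.groups), p=model.theta)
        group = model.groups[k]
        pool = idx_by_group[group]
        if len(pool) == 0:
            raise ValueError(f"no panel haplotypes for group {group!r} with theta > 0")
        src = int(rng.choice(pool))
        draw = rng.exponential(mean_len)
        if crossover_log is not None:
            crossover_log.append(draw)
        seg_len = max(1, int(np.ceil(draw)))
        seg_end = min(cur + seg_len - 1, end_bp)
        lo = np.searchsorted(pos, cur, side="left")
        hi = np.searchsorted(pos, seg_end, side="right")
        alleles[lo:hi] = panel.haplotypes[lo:hi, src]
        segments.append((cur, seg_end, group))
        cur = seg_end + 1
    return alleles, segments


def _overlay_diploid(segs1, segs2):
    """Intersect two haploid segment lists into diploid (start, end, pair) runs."""
    bounds = sorted({s for seg in segs1 + segs2 for s in (seg[0], seg[1] + 1)})
    out = []
    i1 = i2 = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        while segs1[i1][1] < lo:
            i1 += 1
        while segs2[i2][1] < lo:
            i2 += 1
        a, b = sorted((segs1[i1][2], segs2[i2][2]))
        out.append((lo, hi - 1, a, b))
    return out


def simulate_admixed(panel: HaplotypePanel, model: AdmixtureModel,
                     n_genotypes: int, seed: int, crossover_log=None):
    """Simulate admixed diploids with truth tracks.

    Returns ``(GenotypeMatrix, diploid truth AncestryTrack, haploid truth
    AncestryTrack)``.  2n haploids are built by the random walk and paired
    into n diploids; each simulated haploid is used in exactly one diploid.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    for g, t in zip(model.groups, model.theta):
        if t > 0 and not np.any(panel.hap_groups("continental") == g):
            raise ValueError(f"group {g!r} has theta > 0 but no panel haplotypes")
    samples = [f"ind{i:04d}" for i in range(n_genotypes)]
    geno = np.zeros((panel.n_sites, n_genotypes), dtype=np.int8)
    dip_segs, hap_segs = [], []
    for chrom, chrom_sites in panel.sites.groupby("chrom", sort=False):
        lo = chrom_sites.index[0]
        hi = chrom_sites.index[-1] + 1
        sub = chrom_sites.reset_index(drop=True)
        for j, ind in enumerate(samples):
            a1, s1 = _simulate_haploid(panel, model, sub, rng, crossover_log)
            a2, s2 = _simulate_haploid(panel, model, sub, rng, crossover_log)
            geno[lo:hi, j] = (a1 + a2).astype(np.int8)
            for hap_id, segs in ((f"{ind}.0", s1), (f"{ind}.1", s2)):
                hap_segs += [(hap_id, chrom, s, e, g, "") for s, e, g in segs]
            dip_segs += [(ind, chrom, s, e, a, b)
                         for s, e, a, b in _overlay_diploid(s1, s2)]
    gm = GenotypeMatrix(panel.sites, geno, samples)
    return gm, from_segments(dip_segs), from_segments(hap_segs)


# ------------------------------------------------------------- synthetic panel

def _unique_positions(rng, n, length_bp):
    pos = np.unique(rng.integers(1, length_bp + 1, size=int(n * 1.2) + 10))
    while len(pos) < n:
        extra = rng.integers(1, length_bp + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _draw_alleles(freqs, n_hap_per_pop, rng, ld_rho=0.0):
    """Sample haplotypes given per-site per-population frequencies.

    ``freqs`` is (n_sites, n_pops).  With ``ld_rho`` > 0 a first-order Markov
    copying scheme reuses the previous site's latent uniform with probability
    rho, inducing local allele correlation along each haplotype.
    """
    n_sites, n_pops = freqs.shape
    cols = []
    for p in range(n_pops):
        n_h = n_hap_per_pop[p]
        u = rng.random((n_sites, n_h))
        if ld_rho > 0 and n_sites > 1:
            keep = rng.random((n_sites, n_h)) < ld_rho
            keep[0] = False
            for i in range(1, n_sites):
                u[i] = np.where(keep[i], u[i - 1], u[i])
        cols.append((u < freqs[:, [p]]).astype(np.uint8))
    return np.concatenate(cols, axis=1)


def _spec_layout(spec: SyntheticPanelSpec, rng):
    """Draw the site layout and true per-population frequencies.

    Returns (sites, freq_matrix, truth) where truth records each site's kind
    ('shared' | 'private' | 'spurious'), owner population and — for spurious
    sites — the hidden second population that truly carries the allele.
    """
    mb = spec.length_bp / 1e6
    pops = spec.names
    counts = {"shared": rng.poisson(spec.shared_density * mb)}
    for p in spec.populations:
        counts[("private", p.name)] = rng.poisson(p.private_density * mb)
        if spec.spurious_density > 0 and len(pops) > 1:
            counts[("spurious", p.name)] = rng.poisson(spec.spurious_density * mb)
    n_total = sum(counts.values())
    positions = _unique_positions(rng, n_total, spec.length_bp)
    order = rng.permutation(n_total)

    kinds = np.empty(n_total, dtype=object)
    owner = np.empty(n_total, dtype=object)
    hidden = np.empty(n_total, dtype=object)
    freqs = np.zeros((n_total, len(pops)))
    pidx = {p: i for i, p in enumerate(pops)}

    at = 0
    for key, n in counts.items():
        sel = order[at:at + n]
        at += n
        if key == "shared":
            lo, hi = spec.shared_freq
            kinds[sel] = "shared"
            owner[sel] = ""
            hidden[sel] = ""
            freqs[sel] = rng.uniform(lo, hi, size=(n, len(pops)))
        else:
            kind, name = key
            k = pidx[name]
            kinds[sel] = kind
            owner[sel] = name
            hidden[sel] = ""
            if kind == "private":
                pspec = next(p for p in spec.populations if p.name == name)
                lo, hi = pspec.private_freq
                freqs[sel, k] = rng.uniform(lo, hi, size=n)
            else:  # spurious: truly present in a second, hidden population
                freqs[sel, k] = rng.uniform(*spec.populations[k].private_freq, size=n)
                others = [p for p in pops if p != name]
                hid = rng.choice(len(others), size=n)
                for i, s in enumerate(sel):
                    hidden[s] = others[hid[i]]
                    freqs[s, pidx[others[hid[i]]]] = spec.spurious_freq

    alt = np.array(["A"] * n_total, dtype=object)
    refs = rng.choice(list("ACGT"), size=n_total)
    # avoid strand-ambiguous and identical pairs deterministically
    comp = {"A": "G", "C": "T", "G": "A", "T": "C"}
    alt = np.array([comp[r] for r in refs], dtype=object)
    sites = pd.DataFrame({"chrom": spec.chrom, "pos": positions,
                          "ref": refs, "alt": alt})[SITE_COLUMNS]
    truth = pd.DataFrame({"site": np.arange(n_total), "pos": positions,
                          "kind": kinds, "population": owner,
                          "hidden_population": hidden})
    for i, p in enumerate(pops):
        truth[f"freq_{p}"] = freqs[:, i]
    return sites, freqs, truth


def _panel_from_freqs(spec, sites, freqs, rng, suppress_hidden, truth):
    sizes = [p.n_haplotypes for p in spec.populations]
    hap = _draw_alleles(freqs, sizes, rng, spec.ld_rho)
    labels = np.repeat(spec.names, sizes)
    if suppress_hidden:
        # the reference panel by construction missed the hidden population's
        # carriers: zero them so the site is called private to the owner
        pidx = {p: i for i, p in enumerate(spec.names)}
        starts = np.cumsum([0] + sizes)
        for row in truth[truth["kind"] == "spurious"].itertuples(index=False):
            k = pidx[row.hidden_population]
            hap[row.site, starts[k]:starts[k + 1]] = 0
    else:
        # make every spurious allele observable in its hidden population
        pidx = {p: i for i, p in enumerate(spec.names)}
        starts = np.cumsum([0] + sizes)
        for row in truth[truth["kind"] == "spurious"].itertuples(index=False):
            k = pidx[row.hidden_population]
            seg = hap[row.site, starts[k]:starts[k + 1]]
            if seg.sum() == 0:
                seg[rng.integers(0, len(seg))] = 1
    return HaplotypePanel(sites, hap, labels, spec.group_map)


def generate_synthetic_panel(spec: SyntheticPanelSpec, seed: int):
    """Generate one labeled panel; returns ``(HaplotypePanel, truth)``.

    ``truth`` records each site's kind, owner population and true
    frequencies, enabling parameter-recovery and spurious-CSV bookkeeping.
    """
    rng = np.random.default_rng(seed)
    sites, freqs, truth = _spec_layout(spec, rng)
    panel = _panel_from_freqs(spec, sites, freqs, rng, suppress_hidden=True, truth=truth)
    return panel, truth


def generate_panel_pair(spec: SyntheticPanelSpec, seed: int):
    """Disjoint (reference, simulation) panels from one truth.

    Both panels share sites and true frequencies but are independent draws.
    Spurious sites are suppressed in the reference panel's hidden population
    (so the reference mislabels them as private) yet segregate in the
    simulation panel — the finite-panel artifact the sample-aware iteration
    is designed to remove.
    """
    rng = np.random.default_rng(seed)
    sites, freqs, truth = _spec_layout(spec, rng)
    ref_panel = _panel_from_freqs(spec, sites, freqs, rng, True, truth)
    sim_panel = _panel_from_freqs(spec, sites, freqs, rng, False, truth)
    return ref_panel, sim_panel, truth


# ----------------------------------------------------------------------- reads

def simulate_reads(gm: GenotypeMatrix | np.ndarray, coverage: float,
                   eps_s: float = 0.01, seed: int = 0) -> ReadCounts:
    """Poisson depth, binomial alternate reads.

    Depth ~ Poisson(coverage) per site per individual; alternate count ~
    Binomial(depth, q(g)) with q = (eps_s, 0.5, 1 - eps_s) for g = 0, 1, 2.
    Missing genotypes yield no reads.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if not 0 < eps_s < 0.5:
        raise ValueError("eps_s must be in (0, 0.5)")
    if isinstance(gm, GenotypeMatrix):
        g, sites, samples = gm.genotypes, gm.sites, gm.samples
    else:
        g, sites, samples = np.asarray(gm), None, None
    rng = np.random.default_rng(seed)
    depth = rng.poisson(coverage, size=g.shape)
    depth[g == MISSING] = 0
    q = np.array([eps_s, 0.5, 1.0 - eps_s])
    qg = q[np.clip(g, 0, 2)]
    alt = rng.binomial(depth, qg)
    return ReadCounts(depth - alt, alt, sites, samples)
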