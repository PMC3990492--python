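"""Accuracy metrics for local ancestry calls.

The headline metric is the mean squared Pearson correlation (r^2) between
true and inferred per-ancestry diploid dosages, computed across individuals
at each evaluation SNP, averaged over ancestries with positive admixture
proportion and then over SNPs.  Haploid accuracy scores each (SNP,
individual) cell by the best pairing of inferred to true labels (0, 0.5 or
1); diploid accuracy requires the exact unordered pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import AncestryTrack


@dataclass
class AccuracyReport:
    r2: float
    haploid: float
    diploid: float
    per_ancestry_r2: dict
    n_zero_variance: int


def _common_setup(truth: AncestryTrack, calls: AncestryTrack, chrom,
                  positions, individuals):
    individuals = list(individuals)
    A1t, A2t = truth.pair_matrix(chrom, positions, individuals)
    A1c, A2c = calls.pair_matrix(chrom, positions, individuals)
    return A1t, A2t, A1c, A2c


def r2_metric(truth: AncestryTrack, calls: AncestryTrack, chrom,
              positions, individuals, groups, theta=None, mask=None):
    """Mean squared truth/call dosage correlation; see module docstring.

    Zero-variance (SNP, ancestry) cells — truth or calls constant across
    individuals — are excluded and counted.  ``mask`` restricts the
    evaluation SNPs.  Returns ``(mean_r2, per_ancestry, n_excluded)``.
    """
    positions = np.asarray(positions)
    if mask is not None:
        positions = positions[np.asarray(mask)]
    if len(positions) == 0:
        raise ValueError("no evaluation sites")
    use = list(groups)
    if theta is not None:
        use = [g for g, t in zip(groups, theta) if t > 0]
    per_anc_cells = {g: [] for g in use}
    excluded = 0
    site_means = []
    D = {}
    for g in use:
        D[g] = (truth.dosage_matrix(chrom, positions, g, individuals).astype(float),
                calls.dosage_matrix(chrom, positions, g, individuals).astype(float))
    for i in range(len(positions)):
        vals = []
        for g in use:
            t_row, c_row = D[g][0][i], D[g][1][i]
            if t_row.std() == 0 or c_row.std() == 0:
                excluded += 1
                continue
            r = np.corrcoef(t_row, c_row)[0, 1]
            vals.append(r * r)
            per_anc_cells[g].append(r * r)
        if vals:
            site_means.append(np.mean(vals))
    mean_r2 = float(np.mean(site_means)) if site_means else float("nan")
    per_anc = {g: (float(np.mean(v)) if v else float("nan"))
               for g, v in per_anc_cells.items()}
    return mean_r2, per_anc, excluded


def haploid_diploid_accuracy(truth: AncestryTrack, calls: AncestryTrack,
                             chrom, positions, individuals, mask=None):
    """(haploid, diploid) exact-match rates over (SNP, individual) cells.

    Diploid: the unordered inferred pair equals the unordered true pair.
    Haploid: matched allele slots under the best pairing (0, 0.5 or 1 per
    cell) — always at least the diploid score.
    """
    positions = np.asarray(positions)
    if mask is not None:
        positions = positions[np.asarray(mask)]
    A1t, A2t, A1c, A2c = _common_setup(truth, calls, chrom, positions, individuals)
    dip = (A1t == A1c) & (A2t == A2c)
    # best-pairing slot matches for unordered pairs (labels pre-sorted)
    m11, m12 = A1t == A1c, A1t == A2c
    m21, m22 = A2t == A1c, A2t == A2c
    both = dip
    one = (~both) & (m11 | m12 | m21 | m22)
    hap = (2 * both + one) / 2.0
    return float(hap.mean()), float(dip.mean())


def switch_resolution(truth: AncestryTrack, calls: AncestryTrack,
                      window: int = 500_000):
    """Distance from each true diploid switch to the nearest inferred switch.

    True switches with no inferred switch within ``window`` bp are excluded
    and counted.  Returns ``(distances, mean, sd, n_excluded)``; the mean is
    NaN when every switch is excluded.
    """
    dists = []
    excluded = 0
    for ind in truth.individuals:
        for chrom in truth.chroms():
            try:
                true_sw = truth.switch_positions(ind, chrom)
            except KeyError:
                continue
            call_sw = calls.switch_positions(ind, chrom)
            for p in true_sw:
                if len(call_sw) == 0:
                    excluded += 1
                    continue
                d = int(np.min(np.abs(call_sw - p)))
                if d <= window:
                    dists.append(d)
                else:
                    excluded += 1
    dists = np.asarray(dists, dtype=float)
    mean = float(dists.mean()) if len(dists) else float("nan")
    sd = float(dists.std()) if len(dists) else float("nan")
    return dists, mean, sd, excluded


def report(truth: AncestryTrack, calls: AncestryTrack, chrom, positions,
           individuals, groups, theta=None, mask=None) -> AccuracyReport:
    r2, per_anc, excl = r2_metric(truth, calls, chrom, positions, individuals,
                                  groups, theta, mask)
    hap, dip = haploid_diploid_accuracy(truth, calls, chrom, positions,
                                        individuals, mask)
    return AccuracyReport(r2, hap, dip, per_anc, excl)


# ----------------------------------------------------------------------- sweep

def sweep(kind: str, grid, base: dict, seeds=(0,)) -> pd.DataFrame:
    """Full-pipeline accuracy sweeps over coverage, cohort size or iterations.

    ``base`` holds the scenario: a SyntheticPanelSpec under 'panel_spec', an
    AdmixtureModel under 'model', cohort size 'n', HMM settings, and
    optionally 'coverage'.  Each grid point re-simulates with the given seed
    and reports (grid value, replicate, r2, haploid, diploid).
    """
    from .simulate import generate_panel_pair, simulate_admixed, simulate_reads
    from .discovery import estimate_density
    from .hmm import HmmSpec
    from .refine import iterate
    from .lowcov import weighted_freq, presence_genotypes
    from .panel import GenotypeMatrix

    if kind not in ("coverage", "cohort_size", "iterations"):
        raise ValueError(f"unknown sweep kind {kind!r}")
    rows = []
    for value in grid:
        for rep, seed in enumerate(seeds):
            cfg = dict(base)
            if kind == "coverage":
                cfg["coverage"] = value
            elif kind == "cohort_size":
                cfg["n"] = value
            else:
                cfg["n_iter"] = value
            ref_panel, sim_panel, _ = generate_panel_pair(cfg["panel_spec"], seed)
            model = cfg["model"]
            gm, truth_dip, _ = simulate_admixed(sim_panel, model, cfg["n"], seed + 1)
            dens = estimate_density(ref_panel).n_k
            spec = HmmSpec(model.groups, model.theta, model.generations,
                           dens.reindex(model.groups).to_numpy(),
                           lam=cfg.get("lam", 1e-15),
                           eps_csv=cfg.get("eps_csv", 1e-5))
            if cfg.get("coverage") is not None:
                reads = simulate_reads(gm, cfg["coverage"],
                                       cfg.get("eps_s", 0.01), seed + 2)
                freqs = ref_panel.allele_freqs()
                pbar = weighted_freq(freqs[model.groups].to_numpy(), model.theta)
                pg = presence_genotypes(reads, pbar, cfg.get("eps_s", 0.01),
                                        cfg.get("tau", 0.6))
                gm_obs = GenotypeMatrix(gm.sites, pg, gm.samples)
            else:
                gm_obs = gm
            res = iterate(gm_obs, ref_panel, spec,
                          n_iter=cfg.get("n_iter", 0), keep_history=False)
            chrom = str(gm.sites["chrom"].iloc[0])
            pos = gm.sites["pos"].to_numpy()
            step = max(1, len(pos) // cfg.get("eval_sites", 400))
            pos = pos[::step]
            r2, _, _ = r2_metric(truth_dip, res.tracks, chrom, pos, gm.samples,
                                 model.groups, model.theta)
            hap, dip = haploid_diploid_accuracy(truth_dip, res.tracks, chrom,
                                                pos, gm.samples)
            rows.append({"kind": kind, "value": value, "replicate": rep,
                         "r2": r2, "haploid": hap, "diploid": dip})
    return pd.DataFrame(rows)
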