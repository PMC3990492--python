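"""Scikit-learn-style estimator façade over the toolkit.

``CsvAncestryHMM`` is the central fit/predict surface: ``fit`` learns the
CSV table and informative densities from a labeled reference panel;
``predict`` decodes diploid local ancestry tracks for admixed genotypes,
optionally with sample-aware refinement.  The estimators follow sklearn
conventions (``get_params``/``set_params``, trailing-underscore fitted
attributes, ``clone``-compatibility) so they compose with sklearn tooling;
the module-level functions they wrap remain the scripting interface.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import HaplotypePanel, GenotypeMatrix
from .discovery import call_csvs_from_freqs, estimate_density
from .hmm import HmmSpec
from .refine import iterate
from .lowcov import weighted_freq, presence_genotypes
from .simulate import ReadCounts
from .tracks import AncestryTrack


class CsvAncestryHMM(BaseEstimator):
    """Local ancestry inference from continent-specific variants.

    Parameters
    ----------
    theta : admixture proportions; either a mapping {group: proportion} or a
        sequence aligned with ``groups`` (or with the panel's sorted group
        names when ``groups`` is None).  Required at fit.
    groups : explicit group order for ``theta`` and ``densities``; must match
        the panel's groups as a set.
    generations : generations since admixture (default 6, two-way settings).
    lam : HMM crossover rate per bp per generation; default 1e-15,
        deliberately far below the biological 1e-8 to damp linked CSVs.
    eps_csv : spurious-CSV emission floor per incompatible group.
    level : 'continental' or 'population' grouping of the panel labels.
    n_iter : sample-aware refinement rounds (0 = reference panel only).
    buffer : SNPs excluded around call transitions during refinement.
    densities : informative densities N_k; estimated leave-one-out from the
        panel when None.

    Attributes (after ``fit``)
    ----------
    groups_ : group names in model order.
    csv_table_ : the reference CsvTable.
    densities_ : N_k per group (per haplotype per megabase).
    spec_ : the assembled HmmSpec.
    """

    def __init__(self, theta=None, groups=None, generations=6, lam=1e-15,
                 eps_csv=1e-5, level="continental", n_iter=0, buffer=10,
                 densities=None):
        self.theta = theta
        self.groups = groups
        self.generations = generations
        self.lam = lam
        self.eps_csv = eps_csv
        self.level = level
        self.n_iter = n_iter
        self.buffer = buffer
        self.densities = densities

    def fit(self, X: HaplotypePanel, y=None):
        if not isinstance(X, HaplotypePanel):
            raise TypeError("fit expects a HaplotypePanel")
        if self.theta is None:
            raise ValueError("theta is required")
        panel_groups = X.group_names(self.level)
        if isinstance(self.theta, dict):
            groups = list(self.groups) if self.groups is not None \
                else sorted(self.theta)
            theta = np.array([self.theta[g] for g in groups], dtype=float)
        else:
            groups = list(self.groups) if self.groups is not None else panel_groups
            theta = np.asarray(self.theta, dtype=float)
        if set(groups) != set(panel_groups):
            raise ValueError(
                f"model groups {groups} do not match panel groups {panel_groups}")
        if len(theta) != len(groups):
            raise ValueError(
                f"theta has {len(theta)} entries for {len(groups)} groups")
        self.groups_ = groups
        if self.densities is not None:
            dens = np.asarray(self.densities, dtype=float)
        else:
            dens = (estimate_density(X, self.level)
                    .n_k.reindex(self.groups_).to_numpy())
        self.densities_ = dens
        self.ref_freqs_ = X.allele_freqs(self.level)
        self.csv_table_ = call_csvs_from_freqs(X.sites, self.ref_freqs_, self.level)
        self.spec_ = HmmSpec(self.groups_, theta, self.generations, dens,
                             lam=self.lam, eps_csv=self.eps_csv)
        self.panel_ = X
        return self

    def predict(self, X: GenotypeMatrix) -> AncestryTrack:
        """Diploid ancestry tracks for an admixed cohort (with ``n_iter``
        rounds of sample-aware refinement when configured)."""
        self._check_fitted()
        res = iterate(X, self.panel_, self.spec_, n_iter=self.n_iter,
                      buffer=self.buffer, level=self.level, keep_history=False)
        self.last_result_ = res
        return res.tracks

    def _check_fitted(self):
        if not hasattr(self, "spec_"):
            raise RuntimeError("estimator is not fitted")


class DosagePresenceCaller(BaseEstimator, TransformerMixin):
    """Read counts -> pseudo-genotypes via posterior-mean dosage thresholding.

    ``fit`` takes per-group alternate-allele frequencies (DataFrame, one
    column per group) and stores the admixture-weighted frequency;
    ``transform`` converts a ReadCounts batch into presence pseudo-genotypes
    consumable by the observation step.
    """

    def __init__(self, theta=None, eps_seq=0.01, tau=0.6):
        self.theta = theta
        self.eps_seq = eps_seq
        self.tau = tau

    def fit(self, X, y=None):
        if self.theta is None:
            raise ValueError("theta is required")
        self.p_bar_ = weighted_freq(np.asarray(X, dtype=float),
                                    np.asarray(self.theta, dtype=float))
        return self

    def transform(self, X: ReadCounts) -> np.ndarray:
        if not hasattr(self, "p_bar_"):
            raise RuntimeError("estimator is not fitted")
        return presence_genotypes(X, self.p_bar_, self.eps_seq, self.tau)


class SegmentPopulationAssigner(BaseEstimator):
    """Naive sub-continental assignment by maximum sCSV count.

    ``fit`` learns the population-specific variant table from a
    population-labeled panel; ``predict`` assigns haplotype segments to the
    population with the strictly largest carried-sCSV count ("unassigned"
    on ties or zero counts).
    """

    def __init__(self, level="population"):
        self.level = level

    def fit(self, X: HaplotypePanel, y=None):
        from .discovery import call_csvs

        self.scsv_table_ = call_csvs(X, self.level)
        self.populations_ = X.group_names(self.level)
        return self

    def predict(self, haplotypes: np.ndarray, intervals) -> list:
        """Assign each (haplotype column, interval) pair; ``haplotypes`` is a
        (n_sites, n) allele matrix aligned to the fitted panel's sites."""
        from .scsv import assign_segment

        if not hasattr(self, "scsv_table_"):
            raise RuntimeError("estimator is not fitted")
        H = np.atleast_2d(np.asarray(haplotypes).T).T
        out = []
        for h, interval in enumerate(intervals):
            out.append(assign_segment(H[:, h % H.shape[1]], interval,
                                      self.scsv_table_, haplotype=h))
        return [a.assigned for a in out]
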