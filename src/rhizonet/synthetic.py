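"""Synthetic compositional communities with known ground truth.

Generates ASV count tables that emulate a denoised rhizosphere amplicon
survey — a few hundred taxa, a handful of replicates per genotype ×
phosphorus condition — while recording exactly which correlation structure,
modules, hubs and differentially abundant taxa were planted. Every
downstream stage (compositional correlation, network topology, stability,
biomarkers) can then be tested against this ground truth without any
sequencing data.

Generation follows the logistic-normal / multinomial route: latent
log-basis abundances are multivariate normal with a user-specified
correlation structure, exponentiated and closed to fractions, and counts
are drawn multinomially at a gamma-mixed-Poisson library size. This is
precisely the data-generating model SparCC assumes, so parameter-recovery
tests are well-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

__all__ = ["CommunityDesign", "GroundTruth", "build_basis_covariance",
           "simulate_counts", "simulate", "default_design",
           "write_ground_truth"]

#: genotype × phosphorus groups of the emulated experiment
DEFAULT_GROUPS = [(g, c)
                  for g in ("Col-0", "d14-1", "max3-11", "bulk")
                  for c in ("LP", "HP")]

_EIG_FLOOR = 1e-8


class DesignError(ValueError):
    """Invalid community design."""


@dataclass
class CommunityDesign:
    """Parameters of one synthetic community experiment.

    Defaults emulate the emulated survey: ~500 taxa (essentially all of
    which pass the 0.01% mean-relative-abundance filter), 6 replicates per
    genotype × condition group, library sizes around 5×10⁴ reads with
    moderate overdispersion, planted correlation modules, hub taxa and
    condition-specific biomarkers.
    """

    n_taxa: int = 500
    n_samples_per_group: int = 6
    groups: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_GROUPS))
    depth_mean: float = 50_000.0
    depth_dispersion: float = 0.3
    #: (module size, within-module basis correlation); modules occupy
    #: consecutive taxon indices from 0
    module_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(20, 0.7), (15, 0.6), (10, 0.8)])
    #: (hub taxon index, spoke count, hub–spoke correlation); spokes are the
    #: indices immediately following the hub
    hub_spec: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(60, 8, 0.6)])
    #: (taxon index, (genotype, condition), log2 fold change)
    biomarker_spec: list[tuple[int, tuple[str, str], float]] = field(
        default_factory=lambda: [(80, ("Col-0", "LP"), 3.0),
                                 (90, ("d14-1", "HP"), 2.0)])
    base_logmean_range: tuple[float, float] = (0.0, 3.0)
    base_logsd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        # normalise sequence fields (YAML/JSON configs deliver lists)
        self.groups = [tuple(g) for g in self.groups]
        self.module_spec = [(int(s), float(r)) for s, r in self.module_spec]
        self.hub_spec = [(int(h), int(k), float(r))
                         for h, k, r in self.hub_spec]
        self.biomarker_spec = [(int(i), tuple(g), float(f))
                               for i, g, f in self.biomarker_spec]
        self.base_logmean_range = tuple(self.base_logmean_range)
        if self.n_taxa < 2 or self.n_samples_per_group < 1:
            raise DesignError("need n_taxa >= 2 and n_samples_per_group >= 1")
        if self.depth_dispersion < 0:
            raise DesignError("depth_dispersion must be nonnegative")
        if self.base_logsd <= 0:
            raise DesignError("base_logsd must be positive")
        if sum(s for s, _ in self.module_spec) > self.n_taxa:
            raise DesignError("sum of module sizes exceeds n_taxa")
        for _, r in self.module_spec:
            if not -1.0 <= r <= 1.0:
                raise DesignError(f"module correlation {r} outside [-1, 1]")
        for hub, k, r in self.hub_spec:
            if not -1.0 <= r <= 1.0:
                raise DesignError(f"spoke correlation {r} outside [-1, 1]")
            if hub < 0 or hub + k >= self.n_taxa:
                raise DesignError(
                    f"hub {hub} with {k} spokes out of range for "
                    f"{self.n_taxa} taxa")
        group_set = set(self.groups)
        for idx, grp, _ in self.biomarker_spec:
            if not 0 <= idx < self.n_taxa:
                raise DesignError(f"biomarker index {idx} out of range")
            if tuple(grp) not in group_set:
                raise DesignError(f"biomarker group {grp} not in design groups")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * len(self.groups)

    def taxon_ids(self) -> list[str]:
        width = len(str(self.n_taxa))
        return [f"ASV_{i:0{width}d}" for i in range(self.n_taxa)]


@dataclass
class GroundTruth:
    """What was actually planted (post PSD repair)."""

    basis_correlation: np.ndarray
    module_assignment: dict[str, int]
    hub_taxa: set[str]
    biomarker_taxa: dict[str, tuple[tuple[str, str], float]]
    taxon_ids: list[str]
    psd_repaired: bool = False


def _nearest_unit_diag_psd(C: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale back to unit diagonal."""
    w, V = np.linalg.eigh(C)
    w = np.clip(w, _EIG_FLOOR, None)
    C = (V * w) @ V.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    return (C + C.T) / 2


def build_basis_covariance(design: CommunityDesign) -> GroundTruth:
    """Assemble the basis correlation matrix from modules and hub spokes.

    Module blocks sit on consecutive diagonal positions starting at index 0;
    each hub contributes off-diagonal hub–spoke entries (spoke–spoke stays
    at whatever the modules left there, usually 0). If the assembled matrix
    is not positive semi-definite it is repaired by eigenvalue clipping and
    re-normalisation, and the repaired matrix becomes the recorded truth.
    """
    D = design.n_taxa
    C = np.eye(D)
    module_assignment: dict[str, int] = {}
    ids = design.taxon_ids()
    pos = 0
    for m, (size, r) in enumerate(design.module_spec):
        block = slice(pos, pos + size)
        C[block, block] = r
        for i in range(pos, pos + size):
            C[i, i] = 1.0
            module_assignment[ids[i]] = m
        pos += size
    hub_taxa: set[str] = set()
    for hub, k, r in design.hub_spec:
        hub_taxa.add(ids[hub])
        for s in range(hub + 1, hub + 1 + k):
            C[hub, s] = C[s, hub] = r
    repaired = False
    eigmin = np.linalg.eigvalsh(C)[0]
    if eigmin < 0:
        C = _nearest_unit_diag_psd(C)
        repaired = True
    biomarkers = {ids[i]: (tuple(grp), float(lfc))
                  for i, grp, lfc in design.biomarker_spec}
    return GroundTruth(basis_correlation=C,
                       module_assignment=module_assignment,
                       hub_taxa=hub_taxa,
                       biomarker_taxa=biomarkers,
                       taxon_ids=ids,
                       psd_repaired=repaired)


def _draw_depths(rng: np.random.Generator, n: int, mean: float,
                 dispersion: float) -> np.ndarray:
    """Gamma-mixed Poisson library sizes; dispersion 0 → constant depth."""
    if dispersion == 0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion, size=n)
    depths = rng.poisson(lam)
    return np.maximum(depths, 1).astype(np.int64)


def simulate_counts(design: CommunityDesign,
                    truth: GroundTruth) -> AbundanceTable:
    """Draw a count table under the recorded ground truth.

    Per sample: log-basis abundances ~ MVN(mu_group, s²·C), exponentiated
    and closed to fractions; library size from a gamma-mixed Poisson; counts
    multinomial. Deterministic given ``design.seed``.
    """
    D, C = design.n_taxa, truth.basis_correlation
    ss = np.random.SeedSequence(design.seed)
    rng_mu, rng_z, rng_depth, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4))

    lo, hi = design.base_logmean_range
    base_mu = rng_mu.uniform(lo, hi, size=D)

    # factor of the correlation matrix (PSD by construction)
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))

    ids = truth.taxon_ids
    idx_of = {t: i for i, t in enumerate(ids)}
    ln2 = np.log(2.0)

    samples, genotypes, conditions, replicates = [], [], [], []
    columns = []
    for genotype, condition in design.groups:
        mu = base_mu.copy()
        for taxon, (grp, lfc) in truth.biomarker_taxa.items():
            if tuple(grp) == (genotype, condition):
                mu[idx_of[taxon]] += lfc * ln2
        n = design.n_samples_per_group
        z = rng_z.standard_normal((n, D))
        logs = mu + design.base_logsd * (z @ L.T)
        basis = np.exp(logs)
        fracs = basis / basis.sum(axis=1, keepdims=True)
        depths = _draw_depths(rng_depth, n, design.depth_mean,
                              design.depth_dispersion)
        for r in range(n):
            counts = rng_counts.multinomial(depths[r], fracs[r])
            columns.append(counts)
            samples.append(f"{genotype}.{condition}.r{r + 1}")
            genotypes.append(genotype)
            conditions.append(condition)
            replicates.append(r + 1)

    counts = pd.DataFrame(np.column_stack(columns), index=ids,
                          columns=samples).astype(np.int64)
    metadata = pd.DataFrame({"genotype": genotypes, "condition": conditions,
                             "replicate": replicates},
                            index=pd.Index(samples, name="sample_id"))
    return AbundanceTable(counts, metadata)


def simulate(design: CommunityDesign) -> tuple[AbundanceTable, GroundTruth]:
    """Convenience wrapper: build the truth, then sample a table from it."""
    truth = build_basis_covariance(design)
    return simulate_counts(design, truth), truth


def default_design(**overrides) -> CommunityDesign:
    return CommunityDesign(**overrides)


def write_ground_truth(truth: GroundTruth, json_path: str | Path,
                       corr_path: str | Path | None = None) -> None:
    """Persist the truth bundle (JSON summary + TSV correlation matrix)."""
    payload = {
        "module_assignment": truth.module_assignment,
        "hub_taxa": sorted(truth.hub_taxa),
        "biomarker_taxa": {t: {"group": list(g), "log2_fold_change": f}
                           for t, (g, f) in truth.biomarker_taxa.items()},
        "psd_repaired": truth.psd_repaired,
    }
    Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    if corr_path is not None:
        pd.DataFrame(truth.basis_correlation, index=truth.taxon_ids,
                     columns=truth.taxon_ids).to_csv(corr_path, sep="\t",
                                                     float_format="%.10g")
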