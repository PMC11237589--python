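"""Alpha diversity, Bray–Curtis ordination and permutation tests.

Shannon (natural log), Chao1, Bray–Curtis dissimilarity, classical PCoA and
the three non-parametric community-dissimilarity tests (PERMANOVA, ANOSIM,
MRPP). Shannon/Chao1/PCoA/PERMANOVA/ANOSIM are delegated to scikit-bio;
MRPP, which no installed package provides, is implemented here with the
same plus-one permutation p-value convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as _alpha
from skbio.stats import distance as _skdist
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .abundance import AbundanceTable

__all__ = ["shannon", "chao1", "alpha_diversity", "bray_curtis", "pcoa",
           "permanova", "anosim", "mrpp", "DissimilarityTestResult",
           "dissimilarity_tests"]


@dataclass
class DissimilarityTestResult:
    method: str            # MRPP | ANOSIM | PERMANOVA
    statistic: float       # delta | R | pseudo-F
    p_value: float
    n_permutations: int

    def as_dict(self) -> dict:
        return {"method": self.method, "statistic": float(self.statistic),
                "p_value": float(self.p_value),
                "n_permutations": int(self.n_permutations)}


def shannon(counts, base: float | None = None) -> float:
    """Shannon index H = −Σ p ln p (nats by default; *base* switches)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    if (counts < 0).any():
        raise ValueError("negative counts")
    return float(_alpha.shannon(counts, base=base))


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1−1)/(2(F2+1))."""
    counts = np.asarray(counts)
    return float(_alpha.chao1(counts, bias_corrected=True))


def alpha_diversity(table: AbundanceTable,
                    base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon, Chao1 and observed richness on raw counts."""
    rows = {}
    for s in table.sample_ids:
        c = table.counts[s].to_numpy()
        rows[s] = {"shannon": shannon(c, base=base), "chao1": chao1(c),
                   "observed_richness": int((c > 0).sum())}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples."""
    X = table.counts.to_numpy(dtype=float).T  # samples × taxa
    if (X.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")),
                          ids=table.sample_ids)


def pcoa(dm: DistanceMatrix, k: int = 2):
    """Classical scaling of a distance matrix.

    Returns ``(coordinates, eigenvalues, proportion_explained, warnings)``
    where coordinates is a samples × k DataFrame. Axes are ordered by
    eigenvalue and proportions are relative to the sum of positive
    eigenvalues; if fewer than *k* positive eigenvalues exist the result is
    truncated and a warning recorded.
    """
    res = _skbio_pcoa(dm, method="eigh", dimensions=dm.shape[0],
                      warn_neg_eigval=False)
    eigvals = res.eigvals.to_numpy()
    n_pos = int((eigvals > 1e-12).sum())
    warnings: list[str] = []
    if k > n_pos:
        warnings.append(
            f"requested {k} axes but only {n_pos} positive eigenvalues; "
            f"truncated")
        k = n_pos
    coords = res.samples.iloc[:, :k].copy()
    coords.index = list(dm.ids)
    coords.columns = [f"PCo{i + 1}" for i in range(k)]
    pos_sum = eigvals[eigvals > 0].sum()
    prop = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return coords, eigvals, prop, warnings


def _check_groups(labels: np.ndarray) -> None:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"groups with fewer than 2 samples: {list(small)}")


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999,
              seed: int | None = None) -> DissimilarityTestResult:
    """Permutational MANOVA (pseudo-F on squared distances)."""
    labels = np.asarray(labels)
    _check_groups(labels)
    res = _skdist.permanova(dm, labels, permutations=n_perm, seed=seed)
    return DissimilarityTestResult("PERMANOVA", float(res["test statistic"]),
                                   float(res["p-value"]), n_perm)


def anosim(dm: DistanceMatrix, labels, n_perm: int = 999,
           seed: int | None = None) -> DissimilarityTestResult:
    """Analysis of similarities (rank-based R statistic, mid-rank ties)."""
    labels = np.asarray(labels)
    _check_groups(labels)
    res = _skdist.anosim(dm, labels, permutations=n_perm, seed=seed)
    return DissimilarityTestResult("ANOSIM", float(res["test statistic"]),
                                   float(res["p-value"]), n_perm)


def _mrpp_deltas(condensed: np.ndarray, pair_i: np.ndarray,
                 pair_j: np.ndarray, codes: np.ndarray,
                 n_groups: int) -> np.ndarray:
    """delta for each row of *codes* (permutations × samples), vectorised."""
    n = codes.shape[1]
    deltas = np.zeros(codes.shape[0])
    for g in range(n_groups):
        members = codes == g
        n_g = members[0].sum()  # group sizes are permutation-invariant
        mask = members[:, pair_i] & members[:, pair_j]
        deltas += (n_g / n) * (mask @ condensed) / mask.sum(axis=1)
    return deltas


def mrpp(dm: DistanceMatrix, labels, n_perm: int = 999,
         seed: int | None = None) -> DissimilarityTestResult:
    """Multiple-response permutation procedure.

    The statistic is the weighted mean within-group distance
    delta = Σ_g (n_g/n)·mean within-group distance; significance is the
    plus-one-corrected fraction of label permutations with delta at or
    below the observed value (small delta = tight groups).
    """
    labels = np.asarray(labels)
    _check_groups(labels)
    n = labels.size
    condensed = dm.condensed_form()
    pair_i, pair_j = np.triu_indices(n, k=1)
    _, codes = np.unique(labels, return_inverse=True)
    n_groups = codes.max() + 1
    observed = float(_mrpp_deltas(condensed, pair_i, pair_j,
                                  codes[None, :], n_groups)[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=codes.dtype)
    for k in range(n_perm):
        perms[k] = codes[rng.permutation(n)]
    deltas = _mrpp_deltas(condensed, pair_i, pair_j, perms, n_groups)
    p = (1 + int((deltas <= observed).sum())) / (1 + n_perm)
    return DissimilarityTestResult("MRPP", observed, p, n_perm)


def dissimilarity_tests(dm: DistanceMatrix, labels, n_perm: int = 999,
                        seed: int | None = None
                        ) -> list[DissimilarityTestResult]:
    """Run MRPP, ANOSIM and PERMANOVA on the same grouping."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    return [mrpp(dm, labels, n_perm, seeds[0]),
            anosim(dm, labels, n_perm, seeds[1]),
            permanova(dm, labels, n_perm, seeds[2])]
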