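"""Biomarker discovery: Kruskal–Wallis screen + bootstrap LDA effect size.

The two-stage procedure flags condition-indicator taxa: a nonparametric
Kruskal–Wallis test per taxon selects candidates, then a bootstrapped
linear discriminant analysis on 10⁶-scaled relative abundances converts
each candidate's between-group separation into an effect size whose log10
is the reported score (taxa with score ≥ 2 pass by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .abundance import RelativeAbundanceTable

__all__ = ["kruskal_wallis_screen", "lda_effect_size", "BiomarkerResult"]


@dataclass
class BiomarkerResult:
    """Per-taxon screen p-values, enriched group and LDA scores."""

    table: pd.DataFrame     # kw_p, enriched_group, lda_score, passes
    alpha: float
    lda_cut: float
    n_boot: int

    @property
    def passing(self) -> list[str]:
        return list(self.table.index[self.table["passes"].fillna(False)])


def kruskal_wallis_screen(table: RelativeAbundanceTable, labels,
                          alpha: float = 0.05,
                          fdr: bool = False) -> pd.Series:
    """Kruskal–Wallis p-value per taxon (mid-rank ties, χ² approximation).

    Returns the per-taxon p-value series; taxa constant across all samples
    get p = 1. ``fdr=True`` applies Benjamini–Hochberg before thresholding
    downstream (off by default, matching the standard workflow). Requires
    ≥2 groups with ≥3 samples each.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 groups with >= 3 samples each")
    X = table.fractions.to_numpy(dtype=float)
    pvals = np.ones(X.shape[0])
    for t in range(X.shape[0]):
        groups = [X[t, labels == g] for g in uniq]
        if np.ptp(X[t]) == 0:
            continue
        try:
            pvals[t] = stats.kruskal(*groups).pvalue
        except ValueError:   # all values identical within the test
            pvals[t] = 1.0
    out = pd.Series(pvals, index=table.taxon_ids, name="kw_p")
    if fdr:
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
        out = pd.Series(np.empty_like(adj), index=out.index, name="kw_p")
        out.iloc[order] = adj
    return out


def _one_round_effect(X: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Effect size per feature for one bootstrap round (two classes).

    The per-feature effect is the mean of two magnitudes: the raw
    class-mean difference, and the feature's share (via the unit-norm
    discriminant direction) of the projected class-mean difference.
    """
    classes = np.unique(y)
    if len(classes) < 2:
        return None
    lda = LinearDiscriminantAnalysis(solver="svd", store_covariance=False)
    try:
        lda.fit(X, y)
    except (np.linalg.LinAlgError, ValueError):
        return None
    w = lda.coef_[0]
    norm = np.linalg.norm(w)
    if norm == 0 or not np.isfinite(norm):
        return None
    w = w / norm
    d = X[y == classes[1]].mean(axis=0) - X[y == classes[0]].mean(axis=0)
    proj_diff = float(w @ d)   # class-mean difference along the discriminant
    return (np.abs(d) + np.abs(w * proj_diff)) / 2.0


def lda_effect_size(table: RelativeAbundanceTable, labels,
                    selected=None, alpha: float = 0.05,
                    n_boot: int = 30, subsample_frac: float = 2 / 3,
                    lda_cut: float = 2.0, scale: float = 1e6,
                    seed: int | None = None) -> BiomarkerResult:
    """Bootstrap LDA effect size for screened taxa.

    *selected* may be an explicit taxon list; otherwise the Kruskal–Wallis
    screen at *alpha* decides. Per bootstrap round, samples are subsampled
    within groups (fraction ``subsample_frac``, at least 2 per group), a
    two-class linear discriminant is fitted on the ``scale``-normalised
    abundances of the selected taxa, and per-taxon effect sizes are
    averaged over rounds; the score is their log10. For >2 groups the
    discriminant contrasts the taxon-wise enriched group against the rest.
    Rounds that degenerate to a single class are skipped with a diagnostic
    count. Deterministic given *seed*.
    """
    labels = np.asarray(labels)
    kw_p = kruskal_wallis_screen(table, labels, alpha=alpha)
    if selected is None:
        selected = list(kw_p.index[kw_p < alpha])
    else:
        selected = list(selected)

    uniq = np.unique(labels)
    F = table.fractions.loc[:, :].to_numpy(dtype=float) * scale  # taxa×samples
    idx = {t: i for i, t in enumerate(table.taxon_ids)}
    group_means = {g: F[:, labels == g].mean(axis=1) for g in uniq}
    enriched = pd.Series(
        [max(uniq, key=lambda g: group_means[g][idx[t]])
         for t in table.taxon_ids], index=table.taxon_ids,
        name="enriched_group")

    out = pd.DataFrame({"kw_p": kw_p, "enriched_group": enriched})
    out["lda_score"] = np.nan
    out["passes"] = pd.array([None] * len(out), dtype="boolean")
    n_skipped = 0

    if selected:
        sel_idx = [idx[t] for t in selected]
        Xsel = F[sel_idx].T                       # samples × taxa
        rng = np.random.default_rng(seed)
        if len(uniq) == 2:
            contrasts = {None: labels}
        else:
            # one-vs-rest per enriched group actually present among selected
            contrasts = {g: np.where(labels == g, str(g), "__rest__")
                         for g in sorted({enriched[t] for t in selected})}
        acc = np.zeros(len(selected))
        rounds_used = 0
        for _ in range(n_boot):
            take = []
            for g in uniq:
                members = np.flatnonzero(labels == g)
                k = max(2, int(round(subsample_frac * members.size)))
                k = min(k, members.size)
                take.extend(rng.choice(members, size=k, replace=False))
            take = np.array(sorted(take))
            round_eff = np.full(len(selected), np.nan)
            ok = False
            for g, contrast in contrasts.items():
                eff = _one_round_effect(Xsel[take], contrast[take])
                if eff is None:
                    continue
                ok = True
                if g is None:
                    round_eff = eff
                else:
                    for p, t in enumerate(selected):
                        if enriched[t] == g:
                            round_eff[p] = eff[p]
            if ok and np.isfinite(round_eff).all():
                acc += round_eff
                rounds_used += 1
            else:
                n_skipped += 1
        if rounds_used == 0:
            raise ValueError("all bootstrap rounds degenerate; cannot score")
        eff_mean = acc / rounds_used
        scores = np.log10(np.maximum(eff_mean, 1e-30))
        out.loc[selected, "lda_score"] = scores
        out.loc[selected, "passes"] = scores >= lda_cut

    res = BiomarkerResult(out, alpha=alpha, lda_cut=lda_cut, n_boot=n_boot)
    res.table.attrs["n_skipped_rounds"] = n_skipped
    return res
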