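"""Relatedness filtering, LD pruning and PCA on the merged dataset.

Population stratification inflates identity-by-descent estimates, so
relatedness is estimated with the KING-robust between-family kinship
estimator, which is immune to that inflation:

    φ̂(i,j) = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa(i) + N_Aa(j))

computed over markers non-missing in both samples, where N_Aa,Aa
counts markers at which both samples are heterozygous, N_AA,aa counts
opposite homozygotes, and N_Aa(·) counts heterozygous markers per
sample.  Duplicates score ≈ 0.5, parent–offspring ≈ 0.25, second-degree
relatives ≈ 0.125.  Clusters of relatives at φ̂ > 0.125 are reduced to
one representative each.

PCA runs on the unrelated samples over LD-pruned common markers
(MAF > 10%, pairwise r² below a bound within 100-marker windows),
with genotypes standardized per marker by the binomial scaling
(center 2p̂, scale √(2p̂(1−p̂))) and missing cells mean-imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class PopStructError(ValueError):
    pass


@dataclass(frozen=True)
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi: float
    n_markers: int


def king_kinship(
    genotypes: np.ndarray,
    sample_ids: list[str] | None = None,
    include_self: bool = False,
) -> list[KinshipEstimate]:
    """KING-robust kinship for every sample pair.

    ``genotypes`` has shape (n_markers, n_samples) with hard calls in
    {0, 1, 2} and -1 for missing.  Pairs with no marker informative for
    the denominator are omitted.
    """
    g = np.asarray(genotypes)
    n_samples = g.shape[1]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_samples)]
    valid = g != -1
    het = (g == 1) & valid
    hom_a = (g == 0) & valid
    hom_b = (g == 2) & valid

    v = valid.astype(np.float64)
    h = het.astype(np.float64)
    a = hom_a.astype(np.float64)
    b = hom_b.astype(np.float64)

    n_het_het = h.T @ h
    n_opp_hom = a.T @ b + b.T @ a
    # heterozygote counts restricted to markers valid in both samples
    het_i = h.T @ v  # [i, j] = #markers het in i and valid in j
    denom = het_i + het_i.T

    estimates = []
    pairs = (
        ((i, j) for i in range(n_samples) for j in range(i, n_samples))
        if include_self
        else ((i, j) for i in range(n_samples) for j in range(i + 1, n_samples))
    )
    n_both = v.T @ v
    for i, j in pairs:
        if denom[i, j] == 0:
            continue
        phi = (n_het_het[i, j] - 2.0 * n_opp_hom[i, j]) / denom[i, j]
        estimates.append(
            KinshipEstimate(sample_ids[i], sample_ids[j], float(phi),
                            int(n_both[i, j]))
        )
    return estimates


def select_unrelated(
    estimates: list[KinshipEstimate],
    sample_ids: list[str],
    threshold: float = 0.125,
    call_rates: dict[str, float] | None = None,
) -> list[str]:
    """One representative per cluster of relatives (φ̂ > threshold).

    Clusters are connected components of the relatedness graph; the
    kept representative is the sample with the highest call rate
    (ties, or absent call rates, go to the lexicographically smallest
    id).  Unclustered samples are all retained.
    """
    parent = {s: s for s in sample_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in estimates:
        if e.phi > threshold and e.sample_i in parent and e.sample_j in parent:
            ri, rj = find(e.sample_i), find(e.sample_j)
            if ri != rj:
                parent[ri] = rj

    clusters: dict[str, list[str]] = {}
    for s in sample_ids:
        clusters.setdefault(find(s), []).append(s)

    def rank(s: str) -> tuple:
        rate = call_rates.get(s) if call_rates else None
        return (-(rate if rate is not None else -1.0), s)

    kept = [min(members, key=rank) for members in clusters.values()]
    return sorted(kept, key=sample_ids.index)


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared correlation between marker dosage rows (NaN-safe)."""
    x = dosages.copy()
    for row in x:
        nan = np.isnan(row)
        if nan.any():
            row[nan] = np.nanmean(row) if (~nan).any() else 0.0
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    sd[sd == 0] = np.inf  # constant markers correlate with nothing
    x = x / sd[:, None]
    r = (x @ x.T) / x.shape[1]
    return r**2


def ld_prune(
    genotypes: np.ndarray,
    window: int = 100,
    r2_threshold: float = 0.1,
    maf_floor: float = 0.10,
    step: int = 5,
) -> list[int]:
    """Indices of markers surviving MAF and windowed-r² pruning.

    Markers below ``maf_floor`` go first; then a window of ``window``
    consecutive markers slides by ``step``, and within each window one
    member of every pair with dosage r² ≥ ``r2_threshold`` is greedily
    removed (the later marker).  Every retained pair closer than
    ``window`` positions ends with r² below the threshold.
    """
    g = np.asarray(genotypes, dtype=float)
    g[g == -1] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    candidates = [i for i in range(g.shape[0])
                  if not np.isnan(maf[i]) and maf[i] > maf_floor]

    removed: set[int] = set()
    for w_start in range(0, max(1, len(candidates) - window + 1), step):
        members = [i for i in candidates[w_start : w_start + window]
                   if i not in removed]
        if len(members) < 2:
            continue
        r2 = _pairwise_r2(g[members])
        for a in range(len(members)):
            if members[a] in removed:
                continue
            for b in range(a + 1, len(members)):
                if members[b] in removed:
                    continue
                if r2[a, b] >= r2_threshold:
                    removed.add(members[b])
    return [i for i in candidates if i not in removed]


def pca(
    genotypes: np.ndarray,
    n_components: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of a standardized genotype matrix.

    ``genotypes`` is (n_markers, n_samples) hard calls with -1 missing.
    Markers are centered by 2p̂ and scaled by √(2p̂(1−p̂)); missing
    cells are mean-imputed per marker; monomorphic markers drop out.
    Returns (sample components (n_samples, k), variance-explained
    fractions, non-increasing, summing to ≤ 1).  When fewer samples
    than components exist the result is truncated.
    """
    g = np.asarray(genotypes, dtype=float)
    g[g == -1] = np.nan
    n_samples = g.shape[1]
    rows = []
    for row in g:
        ok = ~np.isnan(row)
        if not ok.any():
            continue
        p = row[ok].mean() / 2.0
        if p <= 0.0 or p >= 1.0:
            continue
        filled = np.where(ok, row, 2.0 * p)
        rows.append((filled - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p)))
    if not rows:
        return np.zeros((n_samples, 0)), np.zeros(0)
    x = np.vstack(rows)  # (m, n)
    cov = (x.T @ x) / x.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    k = min(n_components, n_samples)
    total = eigvals.sum()
    explained = eigvals[:k] / total if total > 0 else np.zeros(k)
    components = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    return components, explained
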