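"""Marker quality control and genomic relationship matrices.

Pipeline order is fixed: subset individuals, then minor-allele-frequency
filtering, then linkage-disequilibrium pruning (PLINK indep-pairwise
semantics), then numericalized dosages feed the VanRaden additive and
Vitezica dominance relationship matrices:

    A = Z Z' / (2 * sum_m p_m (1 - p_m)),      Z_im = dosage_im - 2 p_m
    D = W W' / sum_m (2 p_m q_m)^2,            W coded -2q^2 / 2pq / -2p^2
                                               for dosages 0 / 1 / 2

with allele frequencies computed on the filtered individual set and missing
dosages mean-imputed per marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import (
    MarkerOrderError,
    MissingSampleError,
    MonomorphicMarkerError,
)


@dataclass
class MarkerMatrix:
    """Hybrid x marker additive dosage codes {0, 1, 2, NaN}."""

    hybrids: list[str]
    markers: pd.DataFrame  # columns Marker, Chrom, Pos
    dosage: np.ndarray  # float array, NaN = missing

    def __post_init__(self):
        if len(set(self.hybrids)) != len(self.hybrids):
            raise ValueError("duplicate hybrid ids")
        if self.markers["Marker"].duplicated().any():
            raise ValueError("duplicate marker ids")
        if self.dosage.shape != (len(self.hybrids), len(self.markers)):
            raise ValueError("dosage shape does not match ids")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class GenomicRelationship:
    kind: str  # "additive" | "dominance"
    matrix: pd.DataFrame  # hybrid x hybrid, symmetric

    def __post_init__(self):
        m = self.matrix.to_numpy()
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def hybrids(self) -> list[str]:
        return list(self.matrix.index)


def from_population(pop) -> MarkerMatrix:
    """Adapt a synthetic :class:`~metboost.synthetic.Population` to a MarkerMatrix."""
    return MarkerMatrix(
        hybrids=list(pop.hybrids),
        markers=pop.markers[["Marker", "Chrom", "Pos"]].copy(),
        dosage=pop.dosage.astype(float),
    )


def load_vcf(path) -> MarkerMatrix:
    """Read a biallelic VCF (v4.2, GT field) into dosages via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    hybrids = list(vcf.samples)
    rows, meta = [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        rows.append(code[v.gt_types])
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS))
    vcf.close()
    markers = pd.DataFrame(meta, columns=["Marker", "Chrom", "Pos"])
    return MarkerMatrix(hybrids, markers, np.array(rows).T)


def filter_individuals(m: MarkerMatrix, keep_ids) -> MarkerMatrix:
    """Retain the listed hybrids, in the requested order."""
    keep_ids = list(keep_ids)
    index = {h: i for i, h in enumerate(m.hybrids)}
    missing = [h for h in keep_ids if h not in index]
    if missing:
        raise MissingSampleError(f"samples absent from genotypes: {missing}")
    idx = [index[h] for h in keep_ids]
    return MarkerMatrix(keep_ids, m.markers.copy(), m.dosage[idx])


def filter_maf(m: MarkerMatrix, threshold: float = 0.01) -> MarkerMatrix:
    """Drop markers with minor allele frequency below ``threshold``."""
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    keep = m.maf() >= threshold
    return MarkerMatrix(
        list(m.hybrids),
        m.markers.loc[keep].reset_index(drop=True),
        m.dosage[:, keep],
    )


def _imputed(dosage: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per marker."""
    if not np.isnan(dosage).any():
        return dosage.astype(float)
    out = dosage.astype(float).copy()
    with np.errstate(invalid="ignore"):
        means = np.nanmean(out, axis=0)
    nan_r, nan_c = np.where(np.isnan(out))
    out[nan_r, nan_c] = means[nan_c]
    return out


def ld_prune(
    m: MarkerMatrix, window: int = 100, step: int = 20, r2: float = 0.9
) -> MarkerMatrix:
    """Sliding-window pairwise LD pruning (indep-pairwise semantics).

    Within each window of ``window`` markers on a chromosome, pairs with a
    squared Pearson correlation of dosages above ``r2`` are broken greedily by
    removing, from the currently worst pair, the member with the higher mean
    r^2 to the other surviving markers in the window (ties: the later marker
    by position).  The window then slides by ``step`` markers.
    """
    order = m.markers[["Chrom", "Pos"]].reset_index(drop=True)
    if not order.sort_values(["Chrom", "Pos"]).index.equals(order.index):
        raise MarkerOrderError("markers must be sorted by chromosome and position")

    X = _imputed(m.dosage)
    keep = np.ones(m.n_markers, dtype=bool)
    for chrom in pd.unique(m.markers["Chrom"]):
        idx = np.flatnonzero((m.markers["Chrom"] == chrom).to_numpy())
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            alive = [j for j in win if keep[j]]
            while True:
                if len(alive) < 2:
                    break
                sub = X[:, alive]
                sd = sub.std(axis=0)
                ok = sd > 0
                with np.errstate(invalid="ignore", divide="ignore"):
                    corr = np.corrcoef(sub, rowvar=False)
                r2_mat = np.square(np.nan_to_num(corr))
                np.fill_diagonal(r2_mat, 0.0)
                r2_mat[~ok, :] = 0.0
                r2_mat[:, ~ok] = 0.0
                i, j = np.unravel_index(np.argmax(r2_mat), r2_mat.shape)
                if r2_mat[i, j] <= r2:
                    break
                mean_i = r2_mat[i].sum() / (len(alive) - 1)
                mean_j = r2_mat[j].sum() / (len(alive) - 1)
                if mean_i > mean_j:
                    drop = i
                elif mean_j > mean_i:
                    drop = j
                else:
                    drop = max(i, j)  # tie: remove the later marker
                keep[alive[drop]] = False
                alive.pop(drop)
            if start + window >= len(idx):
                break
            start += step
    return MarkerMatrix(
        list(m.hybrids),
        m.markers.loc[keep].reset_index(drop=True),
        m.dosage[:, keep],
    )


def _check_polymorphic(p: np.ndarray) -> None:
    bad = np.flatnonzero((p <= 0) | (p >= 1))
    if len(bad):
        raise MonomorphicMarkerError(
            f"monomorphic markers present (zero GRM denominator): indices {bad[:5].tolist()}..."
        )


def grm_additive(m: MarkerMatrix) -> GenomicRelationship:
    """VanRaden additive relationship matrix A = ZZ' / (2 sum p(1-p))."""
    X = _imputed(m.dosage)
    p = X.mean(axis=0) / 2.0
    _check_polymorphic(p)
    Z = X - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    A = Z @ Z.T / denom
    A = (A + A.T) / 2.0
    return GenomicRelationship(
        "additive", pd.DataFrame(A, index=m.hybrids, columns=m.hybrids)
    )


def grm_dominance(m: MarkerMatrix) -> GenomicRelationship:
    """Vitezica dominance relationship matrix D = WW' / sum (2pq)^2."""
    X = _imputed(m.dosage)
    p = X.mean(axis=0) / 2.0
    _check_polymorphic(p)
    q = 1.0 - p
    # zero-mean under Hardy-Weinberg: dosage 0 -> -2p^2, 1 -> 2pq, 2 -> -2q^2
    # (p = frequency of the dosage-counted allele)
    W = np.select(
        [X < 0.5, X < 1.5],
        [np.broadcast_to(-2.0 * p**2, X.shape), np.broadcast_to(2.0 * p * q, X.shape)],
        default=np.broadcast_to(-2.0 * q**2, X.shape),
    )
    # mean-imputed fractional dosages are bucketed to the nearest code
    denom = float(np.sum((2.0 * p * q) ** 2))
    D = W @ W.T / denom
    D = (D + D.T) / 2.0
    return GenomicRelationship(
        "dominance", pd.DataFrame(D, index=m.hybrids, columns=m.hybrids)
    )


def pca_population(m: MarkerMatrix, n_components: int = 10):
    """Centered PCA of dosages for population-structure inspection.

    Returns (scores DataFrame with columns PC1..PCk, explained-variance ratios).
    """
    X = _imputed(m.dosage)
    n_components = int(min(n_components, X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1]))
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=m.hybrids, columns=cols),
        pca.explained_variance_ratio_,
    )


def write_grm(grm: GenomicRelationship, path) -> None:
    grm.matrix.to_csv(path, index_label="Hybrid")


def load_grm(path, kind: str) -> GenomicRelationship:
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return GenomicRelationship(kind, df)
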