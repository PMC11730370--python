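"""Alpha diversity, dissimilarity matrices, ordination and permutation tests.

Implements Shannon diversity, Bray-Curtis, unweighted/weighted (normalized)
UniFrac, principal coordinates analysis, PERMANOVA with pairwise
comparisons, and the multivariate-dispersion homogeneity test. Permutation
p-values use the (1 + hits) / (1 + n_perm) convention throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from skbio import TreeNode

from gutdyn.tables_io import CountTable, relative_abundance


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.sample_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.abs(np.diag(self.D)).max() > 1e-12:
            raise ValueError("distance matrix diagonal not zero")
        np.fill_diagonal(self.D, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.sample_ids,
                            columns=self.sample_ids)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    pairwise: list[tuple] | None = None


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray      # n x n_pos_axes
    eigenvalues: np.ndarray      # all eigenvalues, descending
    proportion_explained: np.ndarray  # relative to sum of positive eigs


def shannon(table: CountTable) -> pd.Series:
    """Per-sample Shannon H in nats over nonzero relative abundances."""
    rel = relative_abundance(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, rel * np.log(rel), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.sample_ids,
                     name="shannon")


def bray_curtis(rel: np.ndarray, sample_ids: list[str]) -> DistanceMatrix:
    """D_ij = 1 - sum(min(x_i, x_j)) for rows closed to 1."""
    rel = np.asarray(rel, dtype=float)
    if not np.allclose(rel.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows must sum to 1 (use relative_abundance)")
    n = rel.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(rel[i], rel[i + 1:]).sum(axis=1)
        D[i, i + 1:] = 1.0 - shared
        D[i + 1:, i] = D[i, i + 1:]
    return DistanceMatrix(sample_ids, np.clip(D, 0.0, 1.0))


def _branch_structure(tree: TreeNode, taxon_ids: list[str]):
    """Per-branch (length, leaf-indicator row) arrays for UniFrac."""
    tree = tree.copy()
    pos = {t: i for i, t in enumerate(taxon_ids)}
    missing = set(taxon_ids) - {tip.name for tip in tree.tips()}
    if missing:
        raise ValueError(f"taxa missing from tree: {sorted(missing)[:5]}")
    lengths, indicators = [], []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._leafset = np.zeros(len(taxon_ids), dtype=bool)
            if node.name in pos:
                node._leafset[pos[node.name]] = True
        else:
            node._leafset = np.any(
                [c._leafset for c in node.children], axis=0)
        if node.length and node._leafset.any():
            lengths.append(float(node.length))
            indicators.append(node._leafset)
    return np.array(lengths), np.array(indicators)


def unifrac(table: CountTable, tree, weighted: bool = False
            ) -> DistanceMatrix:
    """Unweighted or normalized weighted UniFrac.

    ``tree`` is a newick string or an ``skbio.TreeNode`` whose tips cover
    the table's taxa. Unweighted: unique branch length over total branch
    length covered by either sample. Weighted (normalized): branch-length
    weighted absolute abundance differences over summed abundances; both
    variants are bounded in [0, 1].
    """
    if isinstance(tree, str):
        # taxon labels contain underscores; keep them verbatim
        tree = TreeNode.read(io.StringIO(tree),
                             convert_underscores=False)
    lengths, indic = _branch_structure(tree, table.taxon_ids)
    rel = relative_abundance(table)
    # branch x sample matrix of subtree abundance / presence
    sub_abund = indic.astype(float) @ rel.T
    sub_pres = sub_abund > 0
    n = len(table.sample_ids)
    D = np.zeros((n, n))
    for i in range(n):
        if weighted:
            diff = np.abs(sub_abund[:, [i]] - sub_abund[:, i + 1:])
            tot = sub_abund[:, [i]] + sub_abund[:, i + 1:]
            num = lengths @ diff
            den = lengths @ tot
        else:
            xor = sub_pres[:, [i]] ^ sub_pres[:, i + 1:]
            either = sub_pres[:, [i]] | sub_pres[:, i + 1:]
            num = lengths @ xor
            den = lengths @ either
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, num / den, 0.0)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return DistanceMatrix(list(table.sample_ids), np.clip(D, 0.0, 1.0))


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling of -0.5 * J D^2 J.

    Negative eigenvalues are reported, not dropped; coordinates span the
    positive eigenspace, and proportion explained is relative to the sum
    of positive eigenvalues.
    """
    D2 = dm.D ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[pos].sum()
    proportion = np.where(pos, eigval / pos_sum if pos_sum > 0 else 0.0, 0.0)
    return OrdinationResult(list(dm.sample_ids), coords, eigval, proportion)


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, n_groups: int):
    """PERMANOVA pseudo-F from squared distances and integer group codes."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    F = (ss_among / df_among) / (ss_within / df_within)
    R2 = ss_among / ss_total
    return F, R2


def _check_groups(groups: np.ndarray):
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [labels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"groups with < 2 samples: {small}")
    return labels, codes


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA; p = (1 + #{perm F >= obs F}) / (1 + n_perm)."""
    groups = np.asarray(groups)
    labels, codes = _check_groups(groups)
    D2 = dm.D ** 2
    F_obs, R2 = _pseudo_f(D2, codes, len(labels))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        F_perm, _ = _pseudo_f(D2, perm, len(labels))
        if F_perm >= F_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(F_obs), float(R2), float(p), n_perm)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def permanova_pairwise(dm: DistanceMatrix, groups, n_perm: int = 999,
                       seed: int = 0, adjust: str = "bh"
                       ) -> PermanovaResult:
    """Overall PERMANOVA plus all pairwise tests with BH adjustment."""
    groups = np.asarray(groups)
    overall = permanova(dm, groups, n_perm=n_perm, seed=seed)
    labels = np.unique(groups)
    pairs, stats, pvals = [], [], []
    rng = np.random.default_rng(seed)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            mask = np.isin(groups, [labels[i], labels[j]])
            sub = DistanceMatrix(
                [s for s, m in zip(dm.sample_ids, mask) if m],
                dm.D[np.ix_(mask, mask)])
            res = permanova(sub, groups[mask], n_perm=n_perm,
                            seed=int(rng.integers(2 ** 31)))
            pairs.append((labels[i], labels[j]))
            stats.append(res.pseudo_F)
            pvals.append(res.p)
    if adjust == "bh":
        adj = _bh_adjust(np.array(pvals))
    elif adjust == "none":
        adj = np.array(pvals)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    overall.pairwise = [
        (pair, float(f), float(p), float(q))
        for pair, f, p, q in zip(pairs, stats, pvals, adj)]
    return overall


@dataclass
class DispersionResult:
    group_means: dict[str, float]
    F: float
    p: float
    n_perm: int
    distances: pd.Series = field(repr=False, default=None)


def dispersion_test(dm: DistanceMatrix, groups, n_perm: int = 999,
                    seed: int = 0) -> DispersionResult:
    """Homogeneity of multivariate dispersion (betadisper-style).

    Distances to group centroids are computed in PCoA space; negative
    eigenvalue axes contribute negatively to squared distances (Anderson's
    correction). The spread statistic is the one-way ANOVA F on those
    distances, tested by permuting group assignments.
    """
    groups = np.asarray(groups)
    labels, codes = _check_groups(groups)
    ord_res = pcoa(dm)
    eig = ord_res.eigenvalues
    pos = eig > 1e-10
    neg = eig < -1e-10
    D2 = dm.D ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    real_axes = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag_axes = (eigvec[:, neg] * np.sqrt(-eigval[neg])
                 if neg.any() else np.zeros((n, 0)))
    z = np.empty(n)
    for g in range(len(labels)):
        idx = codes == g
        c_real = real_axes[idx].mean(axis=0)
        c_imag = imag_axes[idx].mean(axis=0)
        d2 = (((real_axes[idx] - c_real) ** 2).sum(axis=1)
              - ((imag_axes[idx] - c_imag) ** 2).sum(axis=1))
        z[idx] = np.sqrt(np.maximum(d2, 0.0))

    def anova_f(vals, cds):
        grand = vals.mean()
        ss_among = sum(
            (cds == g).sum() * (vals[cds == g].mean() - grand) ** 2
            for g in range(len(labels)))
        ss_within = sum(
            ((vals[cds == g] - vals[cds == g].mean()) ** 2).sum()
            for g in range(len(labels)))
        df_a, df_w = len(labels) - 1, len(vals) - len(labels)
        if ss_within <= 0:
            return np.inf if ss_among > 0 else 0.0
        return (ss_among / df_a) / (ss_within / df_w)

    F_obs = anova_f(z, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        F_perm = anova_f(z, rng.permutation(codes))
        if F_perm >= F_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return DispersionResult(
        group_means={str(lab): float(z[codes == g].mean())
                     for g, lab in enumerate(labels)},
        F=float(F_obs), p=float(p), n_perm=n_perm,
        distances=pd.Series(z, index=dm.sample_ids),
    )
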