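"""Correlation and partial-correlation baselines for predicted network edges.

(Partial) correlation on the expression matrix is the standard first-pass
approach to inferring gene-gene links from single-cell data; comparing the
synthesized directed, signed edges against the top-k correlating pairs
shows which predicted interactions carry no marginal correlation signal.

Partial correlations come from the precision matrix of the rank-based
correlation matrix: rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj).  When
the correlation matrix is ill-conditioned (or there are more genes than
cells) a Ledoit-Wolf shrinkage estimate is used instead of the plain
inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expression_io import ExpressionDataset


@dataclass(frozen=True)
class ScoredPair:
    gene_a: str  # gene_a precedes gene_b in gene-set order
    gene_b: str
    score: float


@dataclass
class ScoredPairList:
    """All unordered gene pairs ranked by |score| descending, ties broken by
    gene-set index order."""

    pairs: list

    def top(self, k: int) -> list:
        return self.pairs[:k]

    def __len__(self) -> int:
        return len(self.pairs)


def _rank_pairs(names, score_matrix) -> ScoredPairList:
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append(ScoredPair(names[i], names[j], float(score_matrix[i, j])))
    order = {g: i for i, g in enumerate(names)}
    pairs.sort(key=lambda p: (-abs(p.score), order[p.gene_a], order[p.gene_b]))
    return ScoredPairList(pairs=pairs)


def correlation_pairs(ds: ExpressionDataset, method: str = "spearman") -> ScoredPairList:
    """Pairwise Spearman (default) or Pearson correlation on the binary
    matrix.  Constant genes have undefined correlation; they score 0."""
    mat = ds.matrix().astype(float)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 cells for a correlation baseline")
    constant = mat.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            "constant gene(s) score 0: "
            + ", ".join(np.array(ds.genes.names)[constant]),
            stacklevel=2,
        )
    if method == "spearman":
        # Pearson on ranks == Spearman, and stays well-defined per pair
        # when other columns are constant
        values = np.apply_along_axis(stats.rankdata, 0, mat)
    elif method == "pearson":
        values = mat
    else:
        raise ValueError(f"unknown method {method!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    return _rank_pairs(ds.genes.names, corr)


def partial_correlation_pairs(ds: ExpressionDataset, shrinkage: str = "auto") -> ScoredPairList:
    """Partial correlations from the inverse rank-correlation matrix.

    ``shrinkage='auto'`` inverts directly when the matrix is well-conditioned
    and there are more cells than genes, falling back to Ledoit-Wolf
    otherwise; 'never' forces direct inversion (raises if singular);
    'always' forces the shrinkage estimate.
    """
    mat = ds.matrix().astype(float)
    n, p = mat.shape
    names = ds.genes.names
    constant = mat.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            "constant gene(s) excluded from conditioning, scored 0: "
            + ", ".join(np.array(names)[constant]),
            stacklevel=2,
        )
    active = ~constant
    ranks = np.apply_along_axis(stats.rankdata, 0, mat[:, active])
    if ranks.shape[1] < 2:
        raise ValueError("need at least 2 non-constant genes")

    corr = np.corrcoef(ranks, rowvar=False)
    use_shrinkage = shrinkage == "always" or (
        shrinkage == "auto" and (n <= ranks.shape[1] or np.linalg.cond(corr) > 1e8)
    )
    if use_shrinkage:
        from sklearn.covariance import LedoitWolf

        std = ranks.std(axis=0, ddof=0)
        lw = LedoitWolf().fit((ranks - ranks.mean(axis=0)) / std)
        omega = lw.precision_
    else:
        try:
            omega = np.linalg.inv(corr)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular correlation matrix; re-run with shrinkage='always'"
            ) from None
    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)

    full = np.zeros((p, p))
    idx = np.flatnonzero(active)
    full[np.ix_(idx, idx)] = partial
    np.fill_diagonal(full, 0.0)
    return _rank_pairs(names, full)


@dataclass
class OverlapReport:
    k: int
    n_predicted_pairs: int
    n_covered: int
    missing: list  # directed (source, target, sign) edges absent from top-k

    @property
    def n_missing(self) -> int:
        return len(self.missing)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_predicted_pairs": self.n_predicted_pairs,
            "n_covered": self.n_covered,
            "n_missing": self.n_missing,
            "missing": [list(e) for e in self.missing],
        }


def compare_edges(predicted, baseline: ScoredPairList, k: int) -> OverlapReport:
    """How many predicted directed edges land in the baseline's top-k
    undirected pairs?  ``predicted`` holds (source, target, sign) triples;
    both directions of one pair are covered by the one undirected pair.
    Self-loops have no undirected counterpart and are ignored.
    """
    if k > len(baseline):
        raise ValueError(f"k={k} exceeds the {len(baseline)} available pairs")
    topk = {frozenset((p.gene_a, p.gene_b)) for p in baseline.top(k)}
    seen_pairs = set()
    missing = []
    for edge in predicted:
        src, tgt = edge[0], edge[1]
        if src == tgt:
            continue
        pair = frozenset((src, tgt))
        seen_pairs.add(pair)
        if pair not in topk:
            missing.append(tuple(edge))
    return OverlapReport(
        k=k,
        n_predicted_pairs=len(seen_pairs),
        n_covered=len(seen_pairs & topk),
        missing=missing,
    )


def write_ranked_pairs_tsv(pl: ScoredPairList, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for p in pl.pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.score:.6g}\n")
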