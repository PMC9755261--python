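"""Cis and trans target inference for lncRNAs.

Cis: protein-coding genes within a 100 kb window either side of a lncRNA,
paired with Pearson correlation of expression across samples.  Trans: a
simplified weighted co-expression network — adjacency |r|^beta, average-
linkage clustering on 1 - adjacency with a static cut — whose modules are
summarised by a principal-axis profile (an "eigengene" analog), associated
with a lncRNA by a permutation test, and annotated by hypergeometric
(Fisher) term enrichment with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotation_io import ExpressionMatrix, GenomicInterval

__all__ = [
    "CisPair",
    "ModuleAssignment",
    "EnrichmentResult",
    "find_cis_neighbors",
    "pearson",
    "attach_correlations",
    "call_cis_targets",
    "detect_modules",
    "lncrna_module_association",
    "fisher_enrichment",
]

DEFAULT_CIS_WINDOW = 100_000
DEFAULT_MIN_ABS_R = 0.8


@dataclass(frozen=True)
class CisPair:
    lncrna_id: str
    gene_id: str
    distance: int  # bp between nearest edges; 0 if overlapping
    orientation: str  # upstream | downstream | overlapping
    correlation: float | None = None


@dataclass
class ModuleAssignment:
    module_id: int
    members: list[str]
    correlation: float | None = None  # lncRNA vs module summary profile
    r_squared: float | None = None
    pvalue: float | None = None


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # members annotated with the term
    module_size: int
    term_size: int
    universe_size: int
    pvalue: float
    qvalue: float


def find_cis_neighbors(
    lncrna: GenomicInterval,
    lncrna_id: str,
    genes: Mapping[str, GenomicInterval],
    window: int = DEFAULT_CIS_WINDOW,
) -> list[CisPair]:
    """Genes within ``window`` bp (edge-to-edge, inclusive) of the lncRNA.

    Orientation is reported from the lncRNA's perspective on its own strand
    (unstranded lncRNAs use the + frame): a gene entirely left of the lncRNA
    is upstream on + / downstream on -.
    """
    out = []
    flip = lncrna.strand == "-"
    for gene_id, gene in genes.items():
        if gene.chrom != lncrna.chrom:
            continue
        d = lncrna.distance_to(gene)
        if gene.overlaps(lncrna):
            orientation = "overlapping"
        elif d > window:
            continue
        elif gene.end <= lncrna.start:
            orientation = "downstream" if flip else "upstream"
        else:
            orientation = "upstream" if flip else "downstream"
        out.append(CisPair(lncrna_id, gene_id, d, orientation))
    return sorted(out, key=lambda p: (p.distance, p.gene_id))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def attach_correlations(
    pairs: Sequence[CisPair],
    matrix: ExpressionMatrix,
    on_undefined: str = "raise",
) -> list[CisPair]:
    """Fill the ``correlation`` field of cis pairs from the expression matrix.

    ``on_undefined="drop"`` silently removes pairs whose correlation is
    undefined (a constant expression profile on either side).
    """
    if on_undefined not in ("raise", "drop"):
        raise ValueError(f"invalid on_undefined {on_undefined!r}")
    out = []
    for p in pairs:
        try:
            r = pearson(matrix.get(p.lncrna_id), matrix.get(p.gene_id))
        except ValueError:
            if on_undefined == "drop":
                continue
            raise
        out.append(replace(p, correlation=r))
    return out


def call_cis_targets(
    pairs: Sequence[CisPair], min_abs_r: float = DEFAULT_MIN_ABS_R
) -> list[CisPair]:
    """Keep pairs with |r| >= ``min_abs_r`` (correlations must be attached)."""
    for p in pairs:
        if p.correlation is None:
            raise ValueError(f"pair {p.lncrna_id}/{p.gene_id} has no correlation")
    return [p for p in pairs if abs(p.correlation) >= min_abs_r]


def _module_summary_profile(block: np.ndarray) -> np.ndarray:
    """First principal-axis projection of members' standardized expression.

    ``block`` is members x samples.  The profile is the leading right singular
    vector of the row-standardized block, sign-fixed to correlate positively
    with the mean member profile.
    """
    z = (block - block.mean(axis=1, keepdims=True)) / block.std(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    profile = vt[0]
    if np.dot(profile, z.mean(axis=0)) < 0:
        profile = -profile
    return profile


def detect_modules(
    matrix: ExpressionMatrix,
    beta: float = 6.0,
    min_module_size: int = 10,
    cut_height: float = 0.8,
    log_transform: bool = True,
    pseudocount: float = 0.01,
) -> list[ModuleAssignment]:
    """Simplified co-expression module detection.

    Unsigned adjacency a_ij = |pearson(i, j)|^beta on (log2-transformed)
    expression; average-linkage hierarchical clustering of dissimilarity
    1 - a; static cut at ``cut_height``; clusters below ``min_module_size``
    are left unassigned.  Constant rows are dropped with a warning.
    """
    X = matrix.values.to_numpy(dtype=float)
    ids = np.array(matrix.transcript_ids)
    if log_transform:
        X = np.log2(X + pseudocount)
    # tolerance guards rows that are constant up to float round-off
    keep = X.std(axis=1) > 1e-8 * np.maximum(1.0, np.abs(X).max(axis=1))
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant expression rows")
        X, ids = X[keep], ids[keep]
    if X.shape[0] < 2:
        return []
    corr = np.clip(np.corrcoef(X), -1.0, 1.0)
    adjacency = np.abs(corr) ** beta
    dissim = 1.0 - adjacency
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    tree = linkage(squareform(dissim, checks=False), method="average")
    labels = fcluster(tree, t=cut_height, criterion="distance")
    modules = []
    for mid in np.unique(labels):
        members = ids[labels == mid]
        if members.size >= min_module_size:
            modules.append(ModuleAssignment(module_id=len(modules) + 1, members=sorted(members)))
    return modules


def module_summary_profile(
    matrix: ExpressionMatrix,
    module: ModuleAssignment,
    log_transform: bool = True,
    pseudocount: float = 0.01,
) -> np.ndarray:
    if not module.members:
        raise ValueError("empty module")
    block = np.vstack([matrix.get(m) for m in module.members])
    if log_transform:
        block = np.log2(block + pseudocount)
    return _module_summary_profile(block)


def lncrna_module_association(
    lncrna_expression: Sequence[float],
    matrix: ExpressionMatrix,
    module: ModuleAssignment,
    n_permutations: int = 10_000,
    seed: int = 0,
    log_transform: bool = True,
) -> ModuleAssignment:
    """Correlate a lncRNA with a module summary profile; permutation p-value.

    p = (1 + #{|r_perm| >= |r_obs|}) / (n_permutations + 1) over random
    shufflings of the lncRNA's sample labels.  Returns a copy of the module
    with correlation, r^2 and p filled in.
    """
    x = np.asarray(lncrna_expression, dtype=float)
    if log_transform:
        x = np.log2(x + 0.01)
    profile = module_summary_profile(matrix, module, log_transform=log_transform)
    r_obs = pearson(x, profile)
    rng = np.random.default_rng(seed)
    n = x.size
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    xs = (x[perms] - x.mean()) / x.std()
    ps = (profile - profile.mean()) / profile.std()
    r_perm = xs @ ps / n
    p = float((1 + np.sum(np.abs(r_perm) >= abs(r_obs))) / (n_permutations + 1))
    return ModuleAssignment(
        module_id=module.module_id,
        members=list(module.members),
        correlation=r_obs,
        r_squared=r_obs**2,
        pvalue=p,
    )


def fisher_enrichment(
    member_set: Sequence[str],
    term_annotation: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric (Fisher) term enrichment with BH correction.

    For each term with gene set size K in a universe of size N, the p-value
    is the upper-tail probability of drawing >= k annotated genes in a module
    of size n.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    members = set(member_set) & universe_set
    if set(member_set) - universe_set:
        raise ValueError("member_set must be a subset of the universe")
    N, n = len(universe_set), len(members)
    rows = []
    for term, genes in term_annotation.items():
        term_genes = set(genes) & universe_set
        K = len(term_genes)
        k = len(members & term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        return []
    pvals = np.array([r[3] for r in rows])
    qvals = stats.false_discovery_control(pvals, method="bh")
    return [
        EnrichmentResult(term, k, n, K, N, p, float(q))
        for (term, k, K, p), q in zip(rows, qvals)
    ]
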