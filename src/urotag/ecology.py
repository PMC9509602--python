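"""Community ecology: alpha diversity, beta diversity, ordination, PERMANOVA, Venn.

Alpha diversity follows the usual conventions: bias-corrected Chao1 on
integer read counts (it needs singletons and doubletons), Shannon with
natural log and Gini-Simpson (1 - sum p^2) on relative abundances.  Beta
diversity offers Bray-Curtis, binary Jaccard and Euclidean distances;
ordination is classical PCoA (Gower double-centering of -D^2/2 followed by
eigendecomposition, negative eigenvalues reported but not corrected).
Group differences in composition are tested with PERMANOVA, optionally
restricted to within-subject permutations for paired designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as _alpha
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "chao1",
    "shannon",
    "simpson",
    "alpha_diversity_table",
    "distance_matrix",
    "OrdinationResult",
    "pcoa",
    "permanova",
    "VennSummary",
    "venn_summary",
]


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    return x


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)).

    Requires integer read counts; undefined on an all-zero vector.
    """
    x = _as_counts(counts)
    if not np.allclose(x, np.round(x)):
        raise ValueError("Chao1 requires integer counts")
    if x.sum() == 0:
        raise ValueError("Chao1 undefined for an empty sample")
    return float(_alpha.chao1(x.astype(int), bias_corrected=True))


def shannon(props) -> float:
    """Shannon diversity -sum p ln p (natural log), zero entries skipped."""
    p = _as_counts(props)
    return float(_alpha.shannon(p)) if p.sum() > 0 else 0.0


def simpson(props) -> float:
    """Gini-Simpson diversity 1 - sum p^2."""
    p = _as_counts(props)
    return float(_alpha.simpson(p)) if p.sum() > 0 else 0.0


def alpha_diversity_table(
    read_counts: pd.DataFrame, abundances: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample Chao1 (from counts) and Shannon/Simpson (from abundances)."""
    samples = list(abundances.columns)
    rows = {
        s: {
            "chao1": chao1(read_counts[s].to_numpy()),
            "shannon": shannon(abundances[s].to_numpy()),
            "simpson": simpson(abundances[s].to_numpy()),
        }
        for s in samples
    }
    return pd.DataFrame(rows).T.rename_axis("sample_id")


_METRICS = {"bray_curtis": "braycurtis", "jaccard_binary": "jaccard", "euclidean": "euclidean"}


def distance_matrix(profiles: pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise sample distances from a taxa x samples abundance matrix.

    ``bray_curtis`` acts on abundances, ``jaccard_binary`` on
    presence/absence, ``euclidean`` on abundance vectors.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    if profiles.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = profiles.T.to_numpy(dtype=float)
    if metric == "jaccard_binary":
        x = x > 0
    d = pdist(x, metric=_METRICS[metric])
    return DistanceMatrix(squareform(d), ids=list(profiles.columns))


@dataclass
class OrdinationResult:
    """PCoA output: sample coordinates on positive-eigenvalue axes."""

    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, decreasing (negatives included)
    proportion_explained: np.ndarray  # lambda / sum(positive lambdas)


def pcoa(d: DistanceMatrix, n_axes: int = 3) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix."""
    D = np.asarray(d.data, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    positive = evals > tol
    k = min(n_axes, int(positive.sum()))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    pos_sum = evals[positive].sum()
    prop = np.where(positive, evals / pos_sum if pos_sum > 0 else 0.0, 0.0)
    cols = [f"PCo{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


def _pseudo_f(d2: np.ndarray, group_masks: np.ndarray, n: int) -> np.ndarray:
    """Vectorised pseudo-F for a stack of group-indicator mask matrices.

    ``group_masks`` has shape (n_perm, n_groups, n); within-group sums of
    squared distances come from the quadratic form m D2 m / 2.
    """
    ss_total = d2.sum() / (2 * n)
    n_groups = group_masks.shape[1]
    sizes = group_masks.sum(axis=2)  # (n_perm, n_groups)
    quad = np.einsum("pgi,ij,pgj->pg", group_masks, d2, group_masks) / 2
    ss_within = (quad / sizes).sum(axis=1)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: DistanceMatrix,
    labels,
    n_perm: int = 999,
    strata=None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns (pseudo-F, p).  The p-value uses the (1 + exceedances) /
    (1 + n_perm) convention.  When ``strata`` (e.g. subject ids) are given,
    labels permute only within each stratum, respecting a paired design;
    the default permutes freely.
    """
    ids = list(d.ids)
    labels = pd.Series(np.asarray(labels), index=ids)
    groups = sorted(labels.unique())
    counts = labels.value_counts()
    if len(groups) < 2 or (counts < 2).any():
        raise ValueError("PERMANOVA needs >= 2 groups with >= 2 samples each")
    n = len(ids)
    d2 = np.asarray(d.data, dtype=float) ** 2
    codes = labels.map({g: i for i, g in enumerate(groups)}).to_numpy()

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, n), dtype=int)
    perms[0] = codes
    if strata is None:
        for p in range(1, n_perm + 1):
            perms[p] = codes[rng.permutation(n)]
    else:
        strata = pd.Series(np.asarray(strata), index=ids)
        blocks = [np.flatnonzero((strata == s).to_numpy()) for s in strata.unique()]
        for p in range(1, n_perm + 1):
            perm = codes.copy()
            for idx in blocks:
                perm[idx] = perm[idx[rng.permutation(len(idx))]]
            perms[p] = perm
    masks = np.stack(
        [(perms == g).astype(float) for g in range(len(groups))], axis=1
    )  # (n_perm+1, n_groups, n)
    f = _pseudo_f(d2, masks, n)
    f_obs = f[0]
    p_value = (1 + int((f[1:] >= f_obs).sum())) / (1 + n_perm)
    return float(f_obs), float(p_value)


@dataclass
class VennSummary:
    """Shared/unique species partition between two groups."""

    n_shared: int
    n_only_a: int
    n_only_b: int

    @property
    def n_union(self) -> int:
        return self.n_shared + self.n_only_a + self.n_only_b

    @property
    def pct_shared(self) -> float:
        return round(100 * self.n_shared / self.n_union, 2) if self.n_union else 0.0

    @property
    def pct_only_a(self) -> float:
        return round(100 * self.n_only_a / self.n_union, 2) if self.n_union else 0.0

    @property
    def pct_only_b(self) -> float:
        return round(100 * self.n_only_b / self.n_union, 2) if self.n_union else 0.0


def venn_summary(detected_a: set, detected_b: set) -> VennSummary:
    """Counts and union percentages of shared and group-unique species."""
    a, b = set(detected_a), set(detected_b)
    return VennSummary(
        n_shared=len(a & b), n_only_a=len(a - b), n_only_b=len(b - a)
    )
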