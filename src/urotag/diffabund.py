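"""Paired differential abundance, LDA effect sizes and Spearman networks.

Taxon-level group comparisons use the paired Wilcoxon signed-rank test on
within-subject (stone minus non-stone) differences, reporting raw
two-sided p-values exactly as a Table-2-style summary does.  A LEfSe-style
two-stage procedure scores discriminative features: a Kruskal-Wallis
screen, then a linear-discriminant effect size on per-sample abundances
rescaled to sum to one million, reported on a log10 scale with the usual
2.0 threshold.  Co-occurrence structure among the most abundant taxa is
summarised with tie-corrected Spearman correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "UndefinedTestError",
    "paired_wilcoxon",
    "differential_table",
    "lda_effect_size",
    "CorrelationMatrix",
    "spearman_matrix",
]

LDA_RESCALE = 1e6


class UndefinedTestError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (the classic Wilcoxon convention).  The
    null distribution is exact for untied small samples and a tie- and
    continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.all(x - y == 0):
        raise UndefinedTestError("all paired differences are zero")
    w, p = stats.wilcoxon(
        x, y, zero_method="wilcox", correction=True, method="auto",
        alternative="two-sided",
    )
    return float(w), float(p)


def differential_table(
    rank_profiles: dict[str, pd.DataFrame],
    design,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired Wilcoxon comparison of every taxon at every supplied rank.

    ``rank_profiles`` maps rank name to a taxa x samples abundance matrix;
    ``design`` is a PairedDesign (or anything with a ``samples`` frame of
    sample_id/subject_id/side).  Mean relative abundances are reported in
    percent per group; direction is the group with the higher mean.  Taxa
    whose paired differences are all zero get p = NaN and are never
    flagged.
    """
    samples = design.samples
    pivot = samples.pivot(index="subject_id", columns="side", values="sample_id")
    if pivot.isna().any().any() or set(pivot.columns) != {"stone", "non_stone"}:
        bad = pivot[pivot.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete pairs for subjects: {bad}")
    stone_ids = pivot["stone"].tolist()
    non_stone_ids = pivot["non_stone"].tolist()
    rows = []
    for rank, mat in rank_profiles.items():
        for taxon in mat.index:
            xs = mat.loc[taxon, stone_ids].to_numpy(dtype=float)
            ys = mat.loc[taxon, non_stone_ids].to_numpy(dtype=float)
            try:
                w, p = paired_wilcoxon(xs, ys)
            except UndefinedTestError:
                w, p = np.nan, np.nan
            mean_stone, mean_non = 100 * xs.mean(), 100 * ys.mean()
            rows.append(
                {
                    "taxon": taxon,
                    "rank": rank,
                    "mean_stone_pct": mean_stone,
                    "mean_non_stone_pct": mean_non,
                    "statistic": w,
                    "p_value": p,
                    "direction": "stone" if mean_stone >= mean_non else "non_stone",
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


def _kruskal_p(values: np.ndarray, masks: list[np.ndarray]) -> float:
    groups = [values[m] for m in masks]
    if np.ptp(values) == 0:
        return 1.0
    try:
        return float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all values identical
        return 1.0


def lda_effect_size(
    profiles: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
    include_all: bool = False,
) -> pd.DataFrame:
    """LEfSe-style discriminative-feature scores for a two-class design.

    Stage 1 keeps features with Kruskal-Wallis p < ``alpha``.  Stage 2
    rescales every sample to total one million, then repeats ``n_boot``
    times: draw a class-balanced two-thirds subsample, fit a single linear
    discriminant, and score each surviving feature as the average of its
    raw between-class mean difference and its share of the
    discriminant-projected class separation.  The reported LDA score is the
    signed log10 of (1 + |mean effect|); features reach the output when
    |score| >= ``lda_threshold`` (set ``include_all`` to get every stage-1
    survivor with its score).
    """
    labels = pd.Series(np.asarray(labels), index=profiles.columns)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    masks = [(labels == c).to_numpy() for c in classes]
    if any(m.sum() < 3 for m in masks):
        raise ValueError("each class needs at least 3 samples")

    x = profiles.to_numpy(dtype=float)
    kw_p = np.array([_kruskal_p(row, masks) for row in x])
    survivors = np.flatnonzero(kw_p < alpha)
    out_cols = ["taxon", "enriched_group", "lda_score", "kw_p"]
    if survivors.size == 0:
        return pd.DataFrame(columns=out_cols)

    # Per-sample rescale to the conventional one-million total.
    totals = x.sum(axis=0)
    totals[totals == 0] = 1.0
    xs = (x / totals * LDA_RESCALE)[survivors]  # features x samples
    rng = np.random.default_rng(seed)
    idx_a, idx_b = (np.flatnonzero(m) for m in masks)
    n_a = max(3, int(np.ceil(2 / 3 * len(idx_a))))
    n_b = max(3, int(np.ceil(2 / 3 * len(idx_b))))
    effects = np.zeros((n_boot, survivors.size))
    for b in range(n_boot):
        sub = np.concatenate(
            [rng.choice(idx_a, n_a, replace=False), rng.choice(idx_b, n_b, replace=False)]
        )
        xb = xs[:, sub].T  # samples x features
        yb = labels.to_numpy()[sub]
        mean_a = xb[yb == classes[0]].mean(axis=0)
        mean_b = xb[yb == classes[1]].mean(axis=0)
        raw = np.abs(mean_a - mean_b)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lda = LinearDiscriminantAnalysis(n_components=1).fit(xb, yb)
            w = lda.scalings_[:, 0]
            w_unit = np.abs(w) / max(np.linalg.norm(w), 1e-300)
            proj = xb @ w
            sep = abs(proj[yb == classes[0]].mean() - proj[yb == classes[1]].mean())
            effects[b] = (raw + w_unit * sep) / 2
        except np.linalg.LinAlgError:  # degenerate subsample; raw effect only
            effects[b] = raw
    mean_effect = effects.mean(axis=0)
    overall_a = x[survivors][:, masks[0]].mean(axis=1)
    overall_b = x[survivors][:, masks[1]].mean(axis=1)
    sign = np.where(overall_a >= overall_b, 1.0, -1.0)
    scores = sign * np.log10(1 + np.abs(mean_effect))
    result = pd.DataFrame(
        {
            "taxon": profiles.index[survivors],
            "enriched_group": np.where(sign > 0, classes[0], classes[1]),
            "lda_score": scores,
            "kw_p": kw_p[survivors],
        }
    )
    if include_all:
        return result.reset_index(drop=True)
    keep = result["lda_score"].abs() >= lda_threshold
    return result[keep].reset_index(drop=True)


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations among selected taxa."""

    taxa: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame


def spearman_matrix(profiles: pd.DataFrame, top_n: int = 30) -> CorrelationMatrix:
    """Tie-corrected Spearman correlations among the ``top_n`` most abundant taxa.

    Pairs involving a constant taxon are undefined and emitted as NaN.
    """
    if profiles.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    top = (
        profiles.mean(axis=1).sort_values(ascending=False).head(top_n).index.tolist()
    )
    sub = profiles.loc[top]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(sub.T.to_numpy())
    if np.isscalar(rho):  # two taxa: spearmanr returns scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    rho = np.asarray(rho, dtype=float).copy()
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(
        taxa=top,
        rho=pd.DataFrame(rho, index=top, columns=top),
        p=pd.DataFrame(np.asarray(p, dtype=float), index=top, columns=top),
    )
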