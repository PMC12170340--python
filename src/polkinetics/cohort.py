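"""Cohort-level analyses of kinetic trajectories.

Genes are grouped by the temporal pattern of their RNA synthesis across the
transdifferentiation time course (downregulated "pre-B", "bending",
"peaking", upregulated "iMac"), the upregulated set is subclustered on its
I and d trajectories with a bootstrapped consensus k-means (k = 2), and
groups are compared by quantile summaries, scaled metagene profiles and
two-sided Kolmogorov–Smirnov tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .annotation import GeneModel
from .errors import InputError

TERMINAL_TIMES = (72, 96)


# --------------------------------------------------------------------------
# differential expression gate
# --------------------------------------------------------------------------

def de_gate(
    tt_means: pd.DataFrame,
    fc_threshold: float = 1.5,
    padj_threshold: float = 0.05,
    external_calls: pd.DataFrame | None = None,
) -> pd.Index:
    """Differentially expressed genes.

    With ``external_calls`` (columns ``gene_id``, ``log2fc``, ``padj`` from
    any DE tool), apply |FC| > ``fc_threshold`` and padj < ``padj_threshold``.
    Otherwise fall back to a fold-change-only surrogate: max-vs-min
    time-point mean fold change > ``fc_threshold`` on normalized means (no
    p-value — documented as a self-contained stand-in for a count-model test).
    """
    if external_calls is not None:
        calls = external_calls.set_index("gene_id")
        keep = (2.0 ** calls["log2fc"].abs() > fc_threshold) & (
            calls["padj"] < padj_threshold
        )
        return calls.index[keep].intersection(tt_means.index)
    mx = tt_means.max(axis=1)
    mn = tt_means.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mn > 0, mx / mn, np.inf)
    return tt_means.index[(fc > fc_threshold) & (mx > 0)]


# --------------------------------------------------------------------------
# temporal classification
# --------------------------------------------------------------------------

def classify_temporal(means: np.ndarray, time_points: tuple[int, ...] = (0, 12, 24, 72, 96)) -> str:
    """Temporal class of one gene's synthesis trajectory.

    pre-B (down): maximum at 0 h, minimum at 72 or 96 h.
    iMac (up):    minimum at 0 h, maximum at 72 or 96 h.
    peaking:      interior maximum; bending: interior minimum.  When both an
    interior maximum and minimum exist, the larger relative excursion from
    the terminal baseline decides; exact ties are "unclassified".
    The rule is scale-invariant.
    """
    v = np.asarray(means, dtype=float)
    if v.size != len(time_points):
        raise InputError("one mean per time point required")
    terminal = {i for i, t in enumerate(time_points) if t in TERMINAL_TIMES}
    amax, amin = int(np.argmax(v)), int(np.argmin(v))
    if amax == 0 and amin in terminal:
        return "pre-B"
    if amin == 0 and amax in terminal:
        return "iMac"
    interior = set(range(1, len(time_points) - 1))
    peak_ok = amax in interior
    bend_ok = amin in interior
    if peak_ok and not bend_ok:
        return "peaking"
    if bend_ok and not peak_ok:
        return "bending"
    if peak_ok and bend_ok:
        baseline = (v[0] + v[-1]) / 2.0
        if baseline <= 0:
            return "unclassified"
        up = (v[amax] - baseline) / baseline
        down = (baseline - v[amin]) / baseline
        if up > down:
            return "peaking"
        if down > up:
            return "bending"
    return "unclassified"


# --------------------------------------------------------------------------
# bootstrapped consensus k-means
# --------------------------------------------------------------------------

def bootstrap_kmeans(
    features: pd.DataFrame,
    k: int = 2,
    n_boot: int = 100,
    seed: int = 0,
    final_d_columns: list[str] | None = None,
) -> tuple[pd.Series, pd.Series, np.ndarray]:
    """Consensus k-means over bootstrap resamples of the gene set.

    ``features`` holds per-gene I and d trajectories (positive values); each
    column is log2-transformed and z-scored so I's dynamic range cannot
    dominate d's.  Each bootstrap resample is clustered with k-means and all
    genes are assigned to the nearest centroid; the co-assignment frequencies
    form a consensus matrix, which is itself clustered for the final labels.
    Per-gene stability is the mean consensus with the gene's final co-members.

    With ``k = 2`` and ``final_d_columns`` given, labels are ordered so that
    cluster 1 has the lower mean final-time d ("iMac I" semantics); label 2
    is the other cluster.

    Returns (labels 1..k, stability in [0, 1], consensus matrix).
    """
    if (features <= 0).any().any():
        raise InputError(
            "features must be positive for the log transform; exclude genes "
            "with nonpositive I or d"
        )
    X = np.log2(features.to_numpy(dtype=float))
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
        km.fit(X[idx])
        labels_b = km.predict(X)
        same = labels_b[:, None] == labels_b[None, :]
        co += same
    co /= n_boot
    final_km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
    labels = final_km.fit_predict(co)

    # order labels deterministically by mean final-time d (ascending)
    if final_d_columns:
        d_final = features[final_d_columns].mean(axis=1).to_numpy()
        order = np.argsort(
            [d_final[labels == c].mean() if (labels == c).any() else np.inf
             for c in range(k)]
        )
        remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    else:
        remap = {c: c + 1 for c in range(k)}
    final = np.array([remap[int(c)] for c in labels])

    stability = np.empty(n)
    for i in range(n):
        members = np.flatnonzero((final == final[i]) & (np.arange(n) != i))
        stability[i] = co[i, members].mean() if members.size else 1.0
    return (
        pd.Series(final, index=features.index, name="subcluster"),
        pd.Series(stability, index=features.index, name="stability"),
        co,
    )


# --------------------------------------------------------------------------
# quantiles, metagenes, group tests
# --------------------------------------------------------------------------

def quantile_bins(values, q: int = 4) -> pd.Series:
    """Rank-based quantile bins 1..q (stable tie order).

    Degenerate input (all values equal) collapses to bin 1 with a warning.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < q:
        raise InputError(f"need at least {q} values for {q} quantiles")
    if s.nunique() == 1:
        warnings.warn("all values equal; assigning every gene to bin 1")
        return pd.Series(1, index=s.index, name="quantile")
    ranks = stats.rankdata(s.to_numpy(), method="ordinal")
    bins = np.ceil(ranks * q / len(s)).astype(int)
    return pd.Series(bins, index=s.index, name="quantile")


def metagene_profile(
    signals_by_gene: dict[str, np.ndarray], n_bins: int = 100
) -> pd.DataFrame:
    """Mean scaled profile TSS→pA with the 95% CI of the mean.

    Each gene's strand-oriented signal is pooled into ``n_bins`` equal
    genomic intervals by interval means; genes shorter than ``n_bins`` are
    excluded with a warning.  Requires >= 2 contributing genes for the CI.
    """
    pooled = []
    for gid, arr in signals_by_gene.items():
        arr = np.asarray(arr, dtype=float)
        if arr.size < n_bins:
            warnings.warn(f"{gid}: gene shorter than {n_bins} bins; excluded")
            continue
        edges = np.linspace(0, arr.size, n_bins + 1).astype(int)
        sums = np.add.reduceat(arr, edges[:-1])
        pooled.append(sums / np.diff(edges))
    if len(pooled) < 2:
        raise InputError("metagene profile requires >= 2 usable genes")
    mat = np.vstack(pooled)
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "mean": mean,
            "ci_lo": mean - 1.96 * sem,
            "ci_hi": mean + 1.96 * sem,
            "n_genes": mat.shape[0],
        }
    )


def oriented_gene_signal(signal, model: GeneModel) -> np.ndarray:
    """Dense sense-strand signal over the transcription unit, TSS→pA."""
    s, e = model.span
    dense = signal.dense(model.chrom, model.strand, s, e)
    return dense if model.strand == "+" else dense[::-1]


def ks_compare(group_a, group_b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov test (D statistic, p value)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
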