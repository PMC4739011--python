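"""Feature-table preparation: discretization, scaling, rebalancing, selection.

Four stages sit between raw per-lesion descriptors and classifier
training:

* entropy-based discretization (Fayyad-Irani MDLP) — used only to compute
  the information-theoretic quantities feature selection needs; the
  classifiers consume the continuous scaled values;
* scaling to roughly [-1, 1] — features that pass a chi-square
  goodness-of-fit test for normality are z-scored (divided by three
  standard deviations), the rest are min-max rescaled;
* SMOTE oversampling — the class counts in a dermoscopy atlas are skewed
  (Clark nevi outnumber melanomas), so minority classes are topped up with
  synthetic samples interpolated between same-class nearest neighbors;
* correlation-based feature selection (CFS) — greedy forward search on a
  subset merit that rewards feature-class relevance (symmetric
  uncertainty) and penalizes feature-feature redundancy, capped at 20
  features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LABEL_COLUMN = "class"
CLASS_ORDER = ("BN", "CN", "MM", "SN")
DEFAULT_K_MAX = 20


# ---------------------------------------------------------------- MDLP

def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mdlp_discretize(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Fayyad-Irani recursive entropy discretization; returns sorted cuts.

    Candidate cut points lie midway between adjacent sorted values whose
    label sets differ; a binary split is accepted only when its
    information gain clears the MDL threshold
    ``(log2(N-1) + log2(3^c - 2) - (c H(S) - c1 H(S1) - c2 H(S2))) / N``.
    An empty cut list means the feature carries no MDL-significant class
    information.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = pd.factorize(labels[order])[0]
    n_classes = y.max() + 1
    onehot = np.zeros((len(y), n_classes))
    onehot[np.arange(len(y)), y] = 1.0
    cuts: list[float] = []

    def seg_entropy(counts: np.ndarray) -> np.ndarray:
        total = counts.sum(axis=-1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / total
            t = np.where(p > 0, p * np.log2(p), 0.0)
        return -t.sum(axis=-1)

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        seg_v = v[lo:hi]
        prefix = onehot[lo:hi].cumsum(axis=0)  # counts for splits after i+1 samples
        total = prefix[-1]
        ent_s = float(seg_entropy(total))
        if ent_s == 0:
            return
        valid = seg_v[1:] != seg_v[:-1]  # cut must fall between distinct values
        if not valid.any():
            return
        left = prefix[:-1]
        right = total[None, :] - left
        e1 = seg_entropy(left)
        e2 = seg_entropy(right)
        sizes = np.arange(1, n)
        weighted = (sizes * e1 + (n - sizes) * e2) / n
        weighted = np.where(valid, weighted, np.inf)
        i = int(weighted.argmin()) + 1
        gain = ent_s - float(weighted[i - 1])
        c = int((total > 0).sum())
        c1 = int((left[i - 1] > 0).sum())
        c2 = int((right[i - 1] > 0).sum())
        delta = np.log2(3**c - 2) - (c * ent_s - c1 * float(e1[i - 1]) - c2 * float(e2[i - 1]))
        if gain <= (np.log2(n - 1) + delta) / n:
            return
        cuts.append((seg_v[i - 1] + seg_v[i]) / 2.0)
        recurse(lo, lo + i)
        recurse(lo + i, hi)

    recurse(0, len(v))
    return sorted(cuts)


def apply_cuts(values: np.ndarray, cuts: list[float]) -> np.ndarray:
    """Bin continuous values by the cut points (0..len(cuts) integer codes)."""
    return np.searchsorted(np.asarray(cuts, dtype=float), np.asarray(values, dtype=float))


# ---------------------------------------------------------------- scaling

def normality_route(values: np.ndarray, alpha: float = 0.05) -> str:
    """Choose the scaling route by a chi-square normality test.

    Bins follow Sturges' rule; adjacent bins are merged until every
    expected count is at least 5. Small samples (< 20) and degenerate
    features go min-max. Returns ``"zscore"`` or ``"minmax"``.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 20 or np.std(values, ddof=1) == 0:
        return "minmax"
    mu, sd = values.mean(), values.std(ddof=1)
    n_bins = int(np.ceil(np.log2(n) + 1))
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return "minmax"
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(values, bins=edges)
    cdf = stats.norm.cdf(edges, mu, sd)
    expected = n * np.diff(cdf)
    # merge bins with small expected counts
    obs, exp = [], []
    acc_o, acc_e = 0.0, 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o, acc_e = 0.0, 0.0
    if acc_e > 0 and exp:
        obs[-1] += acc_o
        exp[-1] += acc_e
    if len(exp) < 4:  # need dof >= 1 after estimating mu, sd
        return "minmax"
    obs = np.asarray(obs)
    exp = np.asarray(exp) * (sum(obs) / sum(exp))
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    dof = len(exp) - 1 - 2
    p = float(stats.chi2.sf(chi2, dof))
    return "zscore" if p > alpha else "minmax"


def scale_zscore(values: np.ndarray, mean: float | None = None, std: float | None = None
                 ) -> np.ndarray:
    """Z-score scaling over three standard deviations: (x - mean) / (3 s)."""
    values = np.asarray(values, dtype=float)
    if mean is None:
        mean = float(values.mean())
    if std is None:
        std = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    if std == 0:
        return np.zeros_like(values)
    return (values - mean) / (3.0 * std)


def scale_minmax(values: np.ndarray, lo: float | None = None, hi: float | None = None
                 ) -> np.ndarray:
    """Linear rescale to [-1, 1]: 2 (x - min) / (max - min) - 1."""
    values = np.asarray(values, dtype=float)
    if lo is None:
        lo = float(values.min())
    if hi is None:
        hi = float(values.max())
    if hi == lo:
        return np.zeros_like(values)
    return 2.0 * (values - lo) / (hi - lo) - 1.0


@dataclass
class FeatureScaler:
    """Per-feature scaling fitted on training data, applied to any table.

    Routing and the statistics (mean/std or min/max) come from the
    training rows only, so test folds never leak into the fit.
    """

    routes: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def fit(self, table: pd.DataFrame) -> "FeatureScaler":
        for col in table.columns:
            if col == LABEL_COLUMN:
                continue
            v = table[col].to_numpy(dtype=float)
            route = normality_route(v)
            self.routes[col] = route
            if route == "zscore":
                self.stats[col] = (float(v.mean()), float(v.std(ddof=1)))
            else:
                self.stats[col] = (float(v.min()), float(v.max()))
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, route in self.routes.items():
            v = out[col].to_numpy(dtype=float)
            a, b = self.stats[col]
            out[col] = scale_zscore(v, a, b) if route == "zscore" else scale_minmax(v, a, b)
        return out

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


# ---------------------------------------------------------------- SMOTE

def smote(
    table: pd.DataFrame,
    target_counts: dict[str, int] | None = None,
    k_neighbors: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic minority oversampling on a labeled feature table.

    Each synthetic row is ``x + u (x_n - x)`` for a random minority sample
    x, one of its k nearest same-class neighbors x_n, and u ~ U(0, 1) — a
    convex combination, so synthetics never leave the per-class convex
    hull. Originals are preserved; by default every class is raised to the
    majority count.
    """
    labels = table[LABEL_COLUMN]
    counts = labels.value_counts().to_dict()
    if target_counts is None:
        majority = max(counts.values())
        target_counts = {c: majority for c in counts}
    rng = np.random.default_rng(seed)
    feat_cols = [c for c in table.columns if c != LABEL_COLUMN]
    pieces = [table]
    for cls in sorted(counts):
        need = target_counts.get(cls, counts[cls]) - counts[cls]
        if need <= 0:
            continue
        X = table.loc[labels == cls, feat_cols].to_numpy(dtype=float)
        if len(X) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples; cannot SMOTE")
        k = min(k_neighbors, len(X) - 1)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn_idx = np.argsort(d2, axis=1)[:, :k]
        base = rng.integers(0, len(X), size=need)
        pick = rng.integers(0, k, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        synth = X[base] + u[:, None] * (X[nn_idx[base, pick]] - X[base])
        df = pd.DataFrame(synth, columns=feat_cols)
        df[LABEL_COLUMN] = cls
        pieces.append(df)
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------- CFS

def symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric uncertainty of two discrete vectors, in [0, 1].

    ``SU = 2 (H(X) + H(Y) - H(X, Y)) / (H(X) + H(Y))``; entropies in bits.
    Two constant vectors give 0 by convention.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    hx = _entropy(x)
    hy = _entropy(y)
    if hx + hy == 0:
        return 0.0
    xy = np.stack([pd.factorize(x)[0], pd.factorize(y)[0]], axis=1)
    hxy = _entropy(xy[:, 0] * (xy[:, 1].max() + 1) + xy[:, 1])
    return float(2.0 * (hx + hy - hxy) / (hx + hy))


def cfs_merit(subset: list[str], su_class: dict[str, float],
              su_pair) -> float:
    """CFS merit of a subset: ``k rcf / sqrt(k + k (k-1) rff)``.

    ``su_class`` maps feature -> feature-class SU; ``su_pair(f, g)``
    returns the feature-feature SU.
    """
    k = len(subset)
    if k == 0:
        return 0.0
    rcf = float(np.mean([su_class[f] for f in subset]))
    if k == 1:
        rff = 0.0
    else:
        pairs = [(subset[i], subset[j]) for i in range(k) for j in range(i + 1, k)]
        rff = float(np.mean([su_pair(a, b) for a, b in pairs]))
    denom = np.sqrt(k + k * (k - 1) * rff)
    if denom == 0:
        return 0.0
    return k * rcf / denom


@dataclass
class FeatureSubset:
    features: list[str]
    merit: float


def cfs_select(table: pd.DataFrame, k_max: int = DEFAULT_K_MAX) -> FeatureSubset:
    """Greedy forward CFS over MDLP-discretized features.

    Each feature is discretized against the class labels; features MDLP
    leaves uncut carry SU 0 and can never improve merit. The search adds
    the merit-maximizing feature (name as tie-break) until ``k_max``
    features are selected or no addition improves the merit.
    """
    y = table[LABEL_COLUMN].to_numpy()
    feat_cols = [c for c in table.columns if c != LABEL_COLUMN]
    disc: dict[str, np.ndarray] = {}
    su_class: dict[str, float] = {}
    for col in feat_cols:
        v = table[col].to_numpy(dtype=float)
        cuts = mdlp_discretize(v, y)
        codes = apply_cuts(v, cuts)
        disc[col] = codes
        su_class[col] = symmetric_uncertainty(codes, y) if cuts else 0.0

    pair_cache: dict[tuple[str, str], float] = {}

    def su_pair(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = symmetric_uncertainty(disc[key[0]], disc[key[1]])
        return pair_cache[key]

    selected: list[str] = []
    best_merit = 0.0
    remaining = sorted(feat_cols)
    while len(selected) < k_max and remaining:
        best = None
        for f in remaining:
            merit = cfs_merit(selected + [f], su_class, su_pair)
            if best is None or merit > best[0] + 1e-12:
                best = (merit, f)
        if best is None or best[0] <= best_merit + 1e-12:
            break
        best_merit, chosen = best
        selected.append(chosen)
        remaining.remove(chosen)
    return FeatureSubset(selected, best_merit)
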