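"""Evaluation metrics: entropy, MI, NMI, AMI, RI/ARI, Pearson, weighted PRF.

All partition metrics are implemented from their contingency-table
definitions with natural-log entropy (the ratio-form metrics are base
invariant) and the conventions 0*log(0) := 0 and NMI/AMI := 1 for two
identical single-class partitions.  The AMI expectation uses the exact
hypergeometric (permutation) null.  These implementations are cross-checked
against the scikit-learn/scipy equivalents in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


class MetricError(ValueError):
    pass


def _contingency(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Joint count table |U_i ∩ V_j| for two label vectors."""
    U = np.asarray(U)
    V = np.asarray(V)
    if U.shape != V.shape:
        raise MetricError(f"label length mismatch: {U.shape} vs {V.shape}")
    if U.size == 0:
        raise MetricError("labels must be non-empty")
    _, ui = np.unique(U, return_inverse=True)
    _, vi = np.unique(V, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def entropy(U: np.ndarray) -> float:
    """Shannon entropy of a partition, natural log."""
    counts = _contingency(U, U).sum(axis=1)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(U: np.ndarray, V: np.ndarray) -> float:
    nij = _contingency(U, V).astype(float)
    n = nij.sum()
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    mi = 0.0
    for i in range(nij.shape[0]):
        for j in range(nij.shape[1]):
            if nij[i, j] > 0:
                mi += (nij[i, j] / n) * np.log(
                    n * nij[i, j] / (ai[i] * bj[j])
                )
    return float(max(mi, 0.0))


def nmi(U: np.ndarray, V: np.ndarray) -> float:
    """Normalized mutual information, 2*MI / (H(U) + H(V)) in [0, 1]."""
    hu, hv = entropy(U), entropy(V)
    if hu == 0.0 and hv == 0.0:
        # both single-class: identical by definition
        return 1.0
    if hu == 0.0 or hv == 0.0:
        return 0.0
    return float(2.0 * mutual_information(U, V) / (hu + hv))


def batch_mixing(pred: np.ndarray, batch: np.ndarray) -> float:
    """1 - NMI(pred, batch): higher means better-mixed batches."""
    return 1.0 - nmi(pred, batch)


def expected_mutual_information(U: np.ndarray, V: np.ndarray) -> float:
    """E[MI] under the exact hypergeometric permutation null."""
    nij = _contingency(U, V)
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)
    n = int(nij.sum())
    emi = 0.0
    for a in ai:
        for b in bj:
            lo = max(1, a + b - n)
            hi = min(a, b)
            for k in range(lo, hi + 1):
                # P(n_ij = k) under fixed margins
                logp = (
                    gammaln(a + 1)
                    + gammaln(b + 1)
                    + gammaln(n - a + 1)
                    + gammaln(n - b + 1)
                    - gammaln(n + 1)
                    - gammaln(k + 1)
                    - gammaln(a - k + 1)
                    - gammaln(b - k + 1)
                    - gammaln(n - a - b + k + 1)
                )
                emi += np.exp(logp) * (k / n) * np.log(n * k / (a * b))
    return float(emi)


def ami(U: np.ndarray, V: np.ndarray) -> float:
    """Adjusted mutual information with the mean-entropy normalizer."""
    hu, hv = entropy(U), entropy(V)
    mi = mutual_information(U, V)
    emi = expected_mutual_information(U, V)
    denom = 0.5 * (hu + hv) - emi
    if abs(denom) < 1e-15:
        return 1.0 if nmi(U, V) == 1.0 else 0.0
    return float((mi - emi) / denom)


def rand_indices(U: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """(RI, ARI) by pair counting over all unordered cell pairs."""
    nij = _contingency(U, V)
    n = int(nij.sum())
    if n < 2:
        raise MetricError("need at least two observations for pair counting")
    ai = nij.sum(axis=1)
    bj = nij.sum(axis=0)

    def comb2(x: np.ndarray | int) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0

    sum_ij = comb2(nij).sum()  # tp: same cluster in both
    sum_a = comb2(ai).sum()
    sum_b = comb2(bj).sum()
    total = float(comb2(n))
    tp = sum_ij
    fp = sum_a - sum_ij
    fn = sum_b - sum_ij
    tn = total - tp - fp - fn
    ri = (tp + tn) / total
    exp_index = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == exp_index:
        ari = 1.0  # both partitions trivially identical structure
    else:
        ari = (sum_ij - exp_index) / (max_index - exp_index)
    return float(ri), float(ari)


def pair_confusion(U: np.ndarray, V: np.ndarray) -> tuple[float, float, float, float]:
    """(tp, fp, tn, fn) over unordered pairs; tp+fp+tn+fn = n(n-1)/2."""
    nij = _contingency(U, V)
    n = int(nij.sum())
    ai = nij.sum(axis=1).astype(float)
    bj = nij.sum(axis=0).astype(float)
    c2 = lambda x: (x * (x - 1) / 2.0)  # noqa: E731
    tp = c2(nij.astype(float)).sum()
    fp = c2(ai).sum() - tp
    fn = c2(bj).sum() - tp
    tn = c2(float(n)) - tp - fp - fn
    return float(tp), float(fp), float(tn), float(fn)


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Product-moment correlation of two equal-length real vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.size < 2:
        raise MetricError("vectors must share a length of at least 2")
    du = u - u.mean()
    dv = v - v.mean()
    denom = np.sqrt((du**2).sum() * (dv**2).sum())
    if denom == 0:
        raise MetricError("Pearson correlation undefined for constant vectors")
    return float((du * dv).sum() / denom)


def precision_recall_f1(
    pred: np.ndarray, truth: np.ndarray
) -> tuple[float, float, float]:
    """Support-weighted precision, recall and F1 across classes.

    Per class: precision = tp/(tp+fp), recall = tp/(tp+fn),
    f1 = 2PR/(P+R); classes are weighted by their count in ``truth``.
    Zero denominators score 0 for that class.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise MetricError("pred and truth must have equal length")
    classes = np.unique(truth)
    n = truth.size
    p_sum = r_sum = f_sum = 0.0
    for c in classes:
        tp = float(np.sum((pred == c) & (truth == c)))
        fp = float(np.sum((pred == c) & (truth != c)))
        fn = float(np.sum((pred != c) & (truth == c)))
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        w = float(np.sum(truth == c)) / n
        p_sum += w * prec
        r_sum += w * rec
        f_sum += w * f1
    return p_sum, r_sum, f_sum


def evaluate_clustering(
    pred: np.ndarray,
    truth: np.ndarray,
    batch: np.ndarray | None = None,
) -> dict[str, float]:
    """The standard report: NMI/AMI/ARI vs truth, plus batch mixing."""
    ri, ari_v = rand_indices(pred, truth)
    out = {
        "nmi_cluster": nmi(pred, truth),
        "ami_cluster": ami(pred, truth),
        "ri_cluster": ri,
        "ari_cluster": ari_v,
    }
    if batch is not None:
        out["one_minus_nmi_batch"] = batch_mixing(pred, batch)
    return out
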