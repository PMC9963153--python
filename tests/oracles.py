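"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive — dense linear algebra, explicit
loops, direct counting — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import numpy as np


def asls_dense(y: np.ndarray, lam: float, p: float, iters: int) -> np.ndarray:
    """Asymmetric least-squares baseline via dense normal equations."""
    n = y.size
    D = np.diff(np.eye(n), 2, axis=0)
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y
    for _ in range(iters):
        z = np.linalg.solve(np.diag(w) + penalty, w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def savgol_windowfits(y: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay by explicit per-window polynomial fits.

    Interior points take the centre value of a local fit; the first and last
    half-windows take the edge fits evaluated at their own positions
    (polynomial extrapolation, matching 'interp' edge handling).
    """
    half = window // 2
    n = y.size
    out = np.empty(n)
    x = np.arange(window, dtype=float)
    for i in range(half, n - half):
        coeffs = np.polyfit(x, y[i - half : i + half + 1], order)
        out[i] = np.polyval(coeffs, half)
    head = np.polyfit(x, y[:window], order)
    for i in range(half):
        out[i] = np.polyval(head, i)
    tail = np.polyfit(x, y[n - window :], order)
    for i in range(n - half, n):
        out[i] = np.polyval(tail, i - (n - window))
    return out


def pca_eig(X: np.ndarray, k: int):
    """PCA by dense eigendecomposition of the sample covariance."""
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    comps = vecs[:, order].T
    for row in comps:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    evr = vals[order] / vals[vals > -1e-12].sum()
    return mean, comps, evr


def confusion_metrics(counts: np.ndarray):
    """One-vs-rest sensitivity/specificity/accuracy by explicit counting."""
    k = counts.shape[0]
    n = counts.sum()
    out = []
    for c in range(k):
        tp = counts[c, c]
        fn = counts[c].sum() - tp
        fp = counts[:, c].sum() - tp
        tn = n - tp - fn - fp
        out.append(
            (
                tp / (tp + fn) if tp + fn else np.nan,
                tn / (tn + fp) if tn + fp else np.nan,
                (tp + tn) / n,
            )
        )
    return np.array(out)


def lod_rule_bruteforce(counts: np.ndarray, concentrations, threshold=0.02,
                        symmetric=True):
    """Direct evaluation of the classification LOD rule, class by class."""
    n_classes = counts.shape[0]
    conc = sorted(concentrations)
    ok = []
    for i in range(1, n_classes):
        f_cls = counts[i, 0] / counts[i].sum()
        f_ctl = counts[0, i] / counts[0].sum()
        good = f_cls < threshold and (f_ctl < threshold if symmetric else True)
        ok.append(good)
    for j in range(len(ok)):
        if all(ok[j:]):
            return conc[j]
    return None


def limits_bruteforce(preds_by_class: dict, concentrations, alpha=0.005):
    """LOB/LOD/LOQ by explicit percentile intervals and counting."""

    def interval(p):
        return tuple(np.percentile(p, [100 * alpha, 100 * (1 - alpha)]))

    def frac_in(p, iv):
        return np.mean((np.asarray(p) >= iv[0]) & (np.asarray(p) <= iv[1]))

    classes = sorted(preds_by_class)
    nonzero = classes[1:]
    conc = sorted(concentrations)
    ivs = {c: interval(preds_by_class[c]) for c in classes}
    lob = ivs[0]
    detect = [frac_in(preds_by_class[c], lob) < alpha for c in nonzero]
    lod_idx = next((j for j in range(len(nonzero)) if all(detect[j:])), None)
    lod = conc[lod_idx] if lod_idx is not None else None

    def qok(j):
        c = nonzero[j]
        below_iv = ivs[nonzero[j - 1]] if j > 0 else lob
        if frac_in(preds_by_class[c], below_iv) >= alpha:
            return False
        if j + 1 < len(nonzero) and frac_in(
            preds_by_class[c], ivs[nonzero[j + 1]]
        ) >= alpha:
            return False
        return True

    loq = None
    if lod_idx is not None:
        for j in range(lod_idx, len(nonzero)):
            if all(qok(i) for i in range(j, len(nonzero))):
                loq = conc[j]
                break
    return lob, lod, loq
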