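"""PLS discriminant analysis via SIMPLS regression onto a dummy response.

Class coding follows the study convention: class 0 -> (0,0,1),
class 1 -> (0,1,0), class 2 -> (1,0,0).  Prediction takes the argmax over
the three regressed dummy columns and maps the winning column back to its
class code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import RankError

#: row c is the dummy vector of class c
CLASS_CODING = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])

_RANK_TOL = 1e-10


def _simpls_coefficient_path(Xc: np.ndarray, Yc: np.ndarray, n_components: int) -> np.ndarray:
    """SIMPLS coefficient matrices for 1..n_components latent variables.

    Returns an array shaped ``(n_components, p, q)``; entry ``a-1`` maps
    centered X to centered Y using ``a`` latent variables.
    """
    n, p = Xc.shape
    q = Yc.shape[1]
    S = Xc.T @ Yc
    R = np.zeros((p, n_components))
    Q = np.zeros((q, n_components))
    V = np.zeros((p, n_components))
    path = np.zeros((n_components, p, q))
    for a in range(n_components):
        u, s, _ = np.linalg.svd(S, full_matrices=False)
        if s[0] < _RANK_TOL:
            raise RankError(
                f"X exhausted after {a} latent variables (effective rank {a})"
            )
        r = u[:, 0]
        t = Xc @ r
        norm_t = np.linalg.norm(t)
        if norm_t < _RANK_TOL:
            raise RankError(
                f"X exhausted after {a} latent variables (effective rank {a})"
            )
        t /= norm_t
        r /= norm_t
        p_load = Xc.T @ t
        q_load = Yc.T @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        v /= np.linalg.norm(v)
        S = S - np.outer(v, v @ S)
        R[:, a], Q[:, a], V[:, a] = r, q_load, v
        path[a] = R[:, : a + 1] @ Q[:, : a + 1].T
    return path


@dataclass
class PLSDAModel:
    n_latent_variables: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    coef: np.ndarray  # p x 3, for the chosen number of LVs
    coef_path: np.ndarray  # n_lv x p x 3

    def decision_scores(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        B = self.coef if n_lv is None else self.coef_path[n_lv - 1]
        return (np.asarray(X, float) - self.x_mean) @ B + self.y_mean


def plsda_fit(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSDAModel:
    """Fit PLS2 regression of spectra onto the 3-column dummy response."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1, 2}:
        raise ValueError("fitting requires samples from all three classes")
    Y = CLASS_CODING[y]
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    rank = int(np.linalg.matrix_rank(Xc))
    max_lv = min(rank, X.shape[0] - 1, X.shape[1])
    if not (1 <= n_lv <= max_lv):
        raise RankError(
            f"n_lv={n_lv} outside [1, {max_lv}] (data rank {rank})"
        )
    path = _simpls_coefficient_path(Xc, Y - y_mean, n_lv)
    return PLSDAModel(
        n_latent_variables=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=path[-1],
        coef_path=path,
    )


def _scores_to_classes(scores: np.ndarray) -> np.ndarray:
    # winning dummy column j carries a 1 for class 2 - j under CLASS_CODING
    return 2 - np.argmax(scores, axis=1)


def plsda_predict(model: PLSDAModel, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
    """Predicted origin codes (argmax decision rule)."""
    return _scores_to_classes(model.decision_scores(X, n_lv=n_lv))


def plsda_select_lv(X: np.ndarray, y: np.ndarray, max_lv: int) -> tuple[int, float]:
    """Choose the LV count by leave-one-out accuracy; ties favor fewer LVs.

    Returns ``(n_lv, loo_accuracy)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    max_lv = min(max_lv, rank - 1 if rank >= 2 else 1, n - 2)
    correct = np.zeros(max_lv, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = plsda_fit(X[keep], y[keep], max_lv)
        for a in range(1, max_lv + 1):
            pred = plsda_predict(model, X[i : i + 1], n_lv=a)[0]
            correct[a - 1] += int(pred == y[i])
    acc = correct / n
    best = int(np.argmax(acc))  # argmax returns the first (smallest) maximizer
    return best + 1, float(acc[best])
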