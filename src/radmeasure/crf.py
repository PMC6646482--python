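"""Linear-chain conditional random field for token sequence labeling.

The model scores a label sequence y for an observation sequence x as

    s(x, y) = b[y_1] + sum_t  w[., y_t] . f(x, t)  +  sum_t  T[y_{t-1}, y_t]  +  e[y_T]

with per-label weights ``w`` over sparse binary/real token features, a dense
label-to-label transition table ``T``, and begin/end potentials ``b``/``e``.
Training maximizes the conditional log-likelihood with an L2 penalty via
L-BFGS (the standard default setup of CRF toolkits); inference is Viterbi.
Forward-backward runs in log space, so the objective and its gradient are
exact. Everything is deterministic: identical data and settings give
identical weights, and models serialize to JSON and reload bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.sparse as sp

FeatureDict = dict  # feature name -> float (absent means 0)


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


class CRFError(ValueError):
    pass


class LinearChainCRF:
    def __init__(self, c2: float = 1.0, max_iterations: int = 100,
                 template_version: str = "v1"):
        self.c2 = float(c2)
        self.max_iterations = int(max_iterations)
        self.template_version = template_version
        self.labels: list[str] = []
        self.feature_index: dict[str, int] = {}
        self.w_state: np.ndarray | None = None
        self.w_trans: np.ndarray | None = None
        self.w_start: np.ndarray | None = None
        self.w_end: np.ndarray | None = None

    # -- data packing --------------------------------------------------------

    def _build_index(self, x_seqs: Sequence[Sequence[FeatureDict]]) -> None:
        index: dict[str, int] = {}
        for seq in x_seqs:
            for feats in seq:
                for name in feats:
                    if name not in index:
                        index[name] = len(index)
        self.feature_index = index

    def _pack(self, x_seqs: Sequence[Sequence[FeatureDict]]) -> tuple[sp.csr_matrix, list[int]]:
        rows, cols, vals = [], [], []
        lengths = []
        r = 0
        for seq in x_seqs:
            lengths.append(len(seq))
            for feats in seq:
                for name, value in feats.items():
                    j = self.feature_index.get(name)
                    if j is not None:
                        rows.append(r)
                        cols.append(j)
                        vals.append(float(value))
                r += 1
        X = sp.csr_matrix(
            (vals, (rows, cols)), shape=(r, len(self.feature_index)), dtype=np.float64
        )
        return X, lengths

    # -- training ------------------------------------------------------------

    def fit(
        self,
        x_seqs: Sequence[Sequence[FeatureDict]],
        y_seqs: Sequence[Sequence[str]],
        label_set: Sequence[str] | None = None,
    ) -> "LinearChainCRF":
        if not x_seqs:
            raise CRFError("empty training corpus")
        if len(x_seqs) != len(y_seqs):
            raise CRFError("feature and label sequence counts differ")
        seen = {lab for seq in y_seqs for lab in seq}
        if label_set is None:
            self.labels = sorted(seen)
        else:
            extra = seen - set(label_set)
            if extra:
                raise CRFError(f"labels outside declared label set: {sorted(extra)}")
            self.labels = list(label_set)
        lab_idx = {lab: i for i, lab in enumerate(self.labels)}
        L = len(self.labels)
        self._build_index(x_seqs)
        F = len(self.feature_index)
        X, lengths = self._pack(x_seqs)
        y_flat = np.array([lab_idx[lab] for seq in y_seqs for lab in seq], dtype=np.intp)
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        n_tokens = X.shape[0]

        # empirical transition / boundary counts
        emp_trans = np.zeros((L, L))
        emp_start = np.zeros(L)
        emp_end = np.zeros(L)
        for s, seq in enumerate(y_seqs):
            if not seq:
                continue
            idx = [lab_idx[lab] for lab in seq]
            emp_start[idx[0]] += 1
            emp_end[idx[-1]] += 1
            for a, b in zip(idx, idx[1:]):
                emp_trans[a, b] += 1
        Y_onehot = sp.csr_matrix(
            (np.ones(n_tokens), (np.arange(n_tokens), y_flat)), shape=(n_tokens, L)
        )
        emp_state = (X.T @ Y_onehot).toarray()

        n_params = F * L + L * L + 2 * L

        def unpack(w):
            ws = w[: F * L].reshape(F, L)
            wt = w[F * L: F * L + L * L].reshape(L, L)
            wb = w[F * L + L * L: F * L + L * L + L]
            we = w[F * L + L * L + L:]
            return ws, wt, wb, we

        def objective(w):
            ws, wt, wb, we = unpack(w)
            emissions = X @ ws  # (n_tokens, L)
            loglik = 0.0
            exp_state = np.zeros((n_tokens, L))
            exp_trans = np.zeros((L, L))
            exp_start = np.zeros(L)
            exp_end = np.zeros(L)
            for s in range(len(lengths)):
                T = lengths[s]
                if T == 0:
                    continue
                o = offsets[s]
                e = emissions[o: o + T]
                y = y_flat[o: o + T]
                alpha = np.empty((T, L))
                alpha[0] = wb + e[0]
                for t in range(1, T):
                    alpha[t] = _logsumexp(alpha[t - 1][:, None] + wt, axis=0) + e[t]
                logZ = _logsumexp(alpha[T - 1] + we, axis=0)
                beta = np.empty((T, L))
                beta[T - 1] = we
                for t in range(T - 2, -1, -1):
                    beta[t] = _logsumexp(wt + (e[t + 1] + beta[t + 1])[None, :], axis=1)
                post = np.exp(alpha + beta - logZ)
                exp_state[o: o + T] = post
                exp_start += post[0]
                exp_end += post[T - 1]
                for t in range(1, T):
                    M = alpha[t - 1][:, None] + wt + (e[t] + beta[t])[None, :] - logZ
                    exp_trans += np.exp(M)
                gold = wb[y[0]] + e[np.arange(T), y].sum() + we[y[T - 1]]
                gold += wt[y[:-1], y[1:]].sum() if T > 1 else 0.0
                loglik += gold - logZ
            grad_state = (X.T @ sp.csr_matrix(exp_state)).toarray() - emp_state
            grad = np.concatenate([
                grad_state.ravel(),
                (exp_trans - emp_trans).ravel(),
                exp_start - emp_start,
                exp_end - emp_end,
            ])
            penalty = self.c2 * np.dot(w, w)
            return -loglik + penalty, grad + 2.0 * self.c2 * w

        w0 = np.zeros(n_params)
        result = scipy.optimize.minimize(
            objective, w0, jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iterations, "ftol": 1e-8},
        )
        ws, wt, wb, we = unpack(result.x)
        self.w_state, self.w_trans, self.w_start, self.w_end = ws, wt, wb, we
        return self

    # -- inference -----------------------------------------------------------

    def _check_trained(self) -> None:
        if self.w_state is None:
            raise CRFError("model is not trained")

    def predict(self, x_seq: Sequence[FeatureDict]) -> list[str]:
        """Viterbi decode one sequence of feature dicts."""
        self._check_trained()
        T = len(x_seq)
        if T == 0:
            return []
        L = len(self.labels)
        e = np.zeros((T, L))
        for t, feats in enumerate(x_seq):
            for name, value in feats.items():
                j = self.feature_index.get(name)
                if j is not None:
                    e[t] += self.w_state[j] * float(value)
        delta = self.w_start + e[0]
        back = np.zeros((T, L), dtype=np.intp)
        for t in range(1, T):
            scores = delta[:, None] + self.w_trans
            back[t] = np.argmax(scores, axis=0)
            delta = scores[back[t], np.arange(L)] + e[t]
        delta = delta + self.w_end
        path = [int(np.argmax(delta))]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t][path[-1]]))
        path.reverse()
        return [self.labels[i] for i in path]

    def transition_matrix(self) -> np.ndarray:
        """Learned label-to-label transition scores (raw, unnormalized)."""
        self._check_trained()
        return self.w_trans.copy()

    # -- persistence ---------------------------------------------------------

    def save(self, path: "str | Path") -> None:
        self._check_trained()
        payload = {
            "format": "radmeasure-crf",
            "template_version": self.template_version,
            "c2": self.c2,
            "max_iterations": self.max_iterations,
            "labels": self.labels,
            "features": sorted(self.feature_index, key=self.feature_index.get),
            "w_state": self.w_state.tolist(),
            "w_trans": self.w_trans.tolist(),
            "w_start": self.w_start.tolist(),
            "w_end": self.w_end.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: "str | Path") -> "LinearChainCRF":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "radmeasure-crf":
            raise CRFError(f"{path}: not a radmeasure CRF model file")
        model = cls(
            c2=payload["c2"],
            max_iterations=payload["max_iterations"],
            template_version=payload["template_version"],
        )
        model.labels = list(payload["labels"])
        model.feature_index = {name: i for i, name in enumerate(payload["features"])}
        model.w_state = np.array(payload["w_state"], dtype=np.float64)
        model.w_trans = np.array(payload["w_trans"], dtype=np.float64)
        model.w_start = np.array(payload["w_start"], dtype=np.float64)
        model.w_end = np.array(payload["w_end"], dtype=np.float64)
        return model
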