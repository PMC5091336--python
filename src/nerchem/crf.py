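"""A linear-chain conditional random field for sequence labelling.

Emission features are label-independent observation strings ("w=aspirin",
"suf3=rin", ...); the model learns one weight per (feature, label) pair
plus a label-transition matrix and start/end potentials. Training
maximizes the L2-penalized conditional log-likelihood with L-BFGS; the
forward-backward recursions run vectorized across all sequences at once
(padded to the longest sequence, with per-sequence masking), which keeps
one training iteration at a few sparse-matrix products.

Everything is deterministic: the objective has no stochastic component and
the feature vocabulary is built in first-seen order.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import minimize

log = logging.getLogger(__name__)

def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    out = m.squeeze(axis) + np.log(np.sum(np.exp(a - m), axis=axis))
    return out


class LinearChainCRF:
    """L2-regularized linear-chain CRF trained with L-BFGS."""

    def __init__(self, c2: float = 1.0, max_iterations: int = 200):
        if c2 < 0 or max_iterations < 1:
            raise ValueError("c2 must be >= 0 and max_iterations >= 1")
        self.c2 = float(c2)
        self.max_iterations = int(max_iterations)
        self.labels: list[str] = []
        self.feature_index: dict[str, int] = {}
        self.W: Optional[np.ndarray] = None  # (F, L) emission weights
        self.T: Optional[np.ndarray] = None  # (L, L) transitions
        self.b_start: Optional[np.ndarray] = None
        self.b_end: Optional[np.ndarray] = None

    # -- data preparation ---------------------------------------------------

    def _build_vocab(self, X: Sequence[Sequence[Sequence[str]]],
                     y: Sequence[Sequence[str]],
                     labels: Optional[Sequence[str]]) -> None:
        if labels is not None:
            self.labels = list(labels)
        else:
            seen: dict[str, None] = {}
            for seq in y:
                for lab in seq:
                    seen.setdefault(lab, None)
            self.labels = list(seen)
        label_set = set(self.labels)
        for seq in y:
            for lab in seq:
                if lab not in label_set:
                    raise ValueError(f"label {lab!r} outside the model alphabet")
        for seq in X:
            for feats in seq:
                for f in feats:
                    self.feature_index.setdefault(f, len(self.feature_index))

    def _design_matrix(self, X: Sequence[Sequence[Sequence[str]]]) -> sparse.csr_matrix:
        """Rows = tokens over all sequences (in order); binary indicators."""
        indptr = [0]
        indices: list[int] = []
        fi = self.feature_index
        for seq in X:
            for feats in seq:
                cols = sorted({fi[f] for f in feats if f in fi})
                indices.extend(cols)
                indptr.append(len(indices))
        data = np.ones(len(indices), dtype=np.float64)
        return sparse.csr_matrix(
            (data, np.asarray(indices, dtype=np.int32), np.asarray(indptr, dtype=np.int64)),
            shape=(len(indptr) - 1, len(fi)),
        )

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: Sequence[Sequence[Sequence[str]]],
        y: Sequence[Sequence[str]],
        labels: Optional[Sequence[str]] = None,
    ) -> "LinearChainCRF":
        pairs = [(xs, ys) for xs, ys in zip(X, y) if len(xs) > 0]
        if not pairs:
            raise ValueError("training corpus contains no non-empty sequences")
        for xs, ys in pairs:
            if len(xs) != len(ys):
                raise ValueError("feature/label sequence length mismatch")
        X = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        self._build_vocab(X, y, labels)
        L = len(self.labels)
        F = len(self.feature_index)
        lab_idx = {lab: i for i, lab in enumerate(self.labels)}

        Xmat = self._design_matrix(X)
        lens = np.array([len(seq) for seq in X], dtype=np.int64)
        N, Tmax = len(X), int(lens.max())
        n_tok = int(lens.sum())
        y_flat = np.array([lab_idx[lab] for seq in y for lab in seq], dtype=np.int64)

        # process sequences longest-first so each time step touches only a
        # prefix of still-active sequences
        order = np.argsort(-lens, kind="stable")
        inv_order = np.empty(N, dtype=np.int64)
        inv_order[order] = np.arange(N)
        lens_s = lens[order]
        n_act = np.array([(lens_s > t).sum() for t in range(Tmax)], dtype=np.int64)

        # token -> (sorted sequence, position) scatter for padding
        seq_of = np.repeat(np.arange(N), lens)
        pos_of = np.concatenate([np.arange(n) for n in lens])
        pad_pos = inv_order[seq_of] * Tmax + pos_of
        starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
        last_tok = np.cumsum(lens) - 1
        y_first = y_flat[starts]
        y_last = y_flat[last_tok]
        # gold transition counts and emission indicator matrix
        intra = np.ones(n_tok, dtype=bool)
        intra[starts] = False  # positions that have a predecessor in-sequence
        trans_counts = np.zeros((L, L))
        np.add.at(trans_counts, (y_flat[np.flatnonzero(intra) - 1], y_flat[intra]), 1.0)
        Y_onehot = sparse.csr_matrix(
            (np.ones(n_tok), (np.arange(n_tok), y_flat)), shape=(n_tok, L)
        )
        gold_emit = Xmat.T @ Y_onehot  # (F, L) feature-label cooccurrence
        gold_emit = np.asarray(gold_emit.todense())
        start_counts = np.bincount(y_first, minlength=L).astype(np.float64)
        end_counts = np.bincount(y_last, minlength=L).astype(np.float64)

        n_params = F * L + L * L + 2 * L

        def unpack(theta: np.ndarray):
            o = 0
            W = theta[o : o + F * L].reshape(F, L); o += F * L
            Tm = theta[o : o + L * L].reshape(L, L); o += L * L
            bs = theta[o : o + L]; o += L
            be = theta[o : o + L]
            return W, Tm, bs, be

        def objective(theta: np.ndarray):
            W, Tm, bs, be = unpack(theta)
            E = Xmat @ W  # (n_tok, L)
            Ep = np.zeros((N * Tmax, L))
            Ep[pad_pos] = E
            Ep = Ep.reshape(N, Tmax, L)

            # forward (rows sorted longest-first; only active prefixes move)
            alpha = np.zeros((N, Tmax, L))
            alpha[:, 0] = bs[None, :] + Ep[:, 0]
            for t in range(1, Tmax):
                n = n_act[t]
                alpha[:n, t] = (
                    _logsumexp(alpha[:n, t - 1][:, :, None] + Tm[None], axis=1)
                    + Ep[:n, t]
                )
            alpha_last = alpha[np.arange(N), lens_s - 1]
            logZ = _logsumexp(alpha_last + be[None, :], axis=1)

            # gold path score
            gold = (
                float(E[np.arange(n_tok), y_flat].sum())
                + float((Tm * trans_counts).sum())
                + float(bs @ start_counts)
                + float(be @ end_counts)
            )
            nll = float(logZ.sum()) - gold

            # backward, fused with pairwise-marginal accumulation: the
            # tensor Tm + E[t+1] + beta[t+1] serves both recursions
            beta = np.zeros((N, Tmax, L))
            grad_T = -trans_counts.copy()
            beta[:, Tmax - 1] = be[None, :]
            for t in range(Tmax - 2, -1, -1):
                n = n_act[t + 1]  # rows still running at t+1
                beta[n : n_act[t], t] = be[None, :]  # rows ending exactly at t
                nxt = Tm[None] + Ep[:n, t + 1][:, None, :] + beta[:n, t + 1][:, None, :]
                beta[:n, t] = _logsumexp(nxt, axis=2)
                M = alpha[:n, t][:, :, None] + nxt - logZ[:n, None, None]
                grad_T += np.exp(M).sum(axis=0)

            # node marginals
            logP = alpha + beta - logZ[:, None, None]
            P_pad = np.exp(logP.reshape(N * Tmax, L))
            P = P_pad[pad_pos]  # (n_tok, L)
            grad_W = (Xmat.T @ P) - gold_emit

            P_first = P[starts]
            P_last = P[last_tok]
            grad_bs = P_first.sum(axis=0) - start_counts
            grad_be = P_last.sum(axis=0) - end_counts

            loss = nll + self.c2 * float(theta @ theta)
            grad = np.concatenate(
                [grad_W.ravel(), grad_T.ravel(), grad_bs, grad_be]
            ) + 2.0 * self.c2 * theta
            return loss, grad

        it = {"n": 0}

        def callback(theta: np.ndarray) -> None:
            it["n"] += 1
            if log.isEnabledFor(logging.INFO):
                loss, _ = objective(theta)
                log.info("iteration %d  loss %.4f", it["n"], loss)

        theta0 = np.zeros(n_params)
        cb = callback if log.isEnabledFor(logging.INFO) else None
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": self.max_iterations, "maxfun": 4 * self.max_iterations},
        )
        self.W, self.T, self.b_start, self.b_end = unpack(res.x)
        self.W = np.ascontiguousarray(self.W)
        self.T = np.ascontiguousarray(self.T)
        log.info("training finished: %d iterations, final loss %.4f", res.nit, res.fun)
        return self

    # -- inference ----------------------------------------------------------

    def _emissions(self, xseq: Sequence[Sequence[str]]) -> np.ndarray:
        E = np.zeros((len(xseq), len(self.labels)))
        fi = self.feature_index
        for t, feats in enumerate(xseq):
            rows = [fi[f] for f in feats if f in fi]
            if rows:
                E[t] = self.W[rows].sum(axis=0)
        return E

    def predict(self, xseq: Sequence[Sequence[str]]) -> list[str]:
        """Viterbi decoding: the maximum-probability label path."""
        if self.W is None:
            raise ValueError("model is not trained")
        n = len(xseq)
        if n == 0:
            return []
        E = self._emissions(xseq)
        L = len(self.labels)
        delta = self.b_start + E[0]
        back = np.zeros((n, L), dtype=np.int64)
        for t in range(1, n):
            scores = delta[:, None] + self.T
            back[t] = np.argmax(scores, axis=0)
            delta = scores[back[t], np.arange(L)] + E[t]
        delta = delta + self.b_end
        path = [int(np.argmax(delta))]
        for t in range(n - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [self.labels[i] for i in path]

    def marginal_path_confidence(self, xseq: Sequence[Sequence[str]], path: Sequence[str]) -> float:
        """Mean posterior marginal of the path labels (a [0,1] confidence)."""
        if len(xseq) == 0:
            return 1.0
        E = self._emissions(xseq)
        n, L = E.shape
        alpha = np.empty((n, L)); beta = np.empty((n, L))
        alpha[0] = self.b_start + E[0]
        for t in range(1, n):
            alpha[t] = _logsumexp(alpha[t - 1][:, None] + self.T, axis=0) + E[t]
        beta[n - 1] = self.b_end
        for t in range(n - 2, -1, -1):
            beta[t] = _logsumexp(self.T + E[t + 1][None] + beta[t + 1][None], axis=1)
        logZ = _logsumexp(alpha[n - 1] + self.b_end, axis=0)
        idx = [self.labels.index(lab) for lab in path]
        marg = np.exp(alpha[np.arange(n), idx] + beta[np.arange(n), idx] - logZ)
        return float(np.clip(marg.mean(), 0.0, 1.0))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        if self.W is None:
            raise ValueError("model is not trained")
        return {
            "c2": self.c2,
            "max_iterations": self.max_iterations,
            "labels": self.labels,
            "features": list(self.feature_index),
            "W": self.W.ravel().tolist(),
            "T": self.T.ravel().tolist(),
            "b_start": self.b_start.tolist(),
            "b_end": self.b_end.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearChainCRF":
        crf = cls(c2=d["c2"], max_iterations=d["max_iterations"])
        crf.labels = list(d["labels"])
        crf.feature_index = {f: i for i, f in enumerate(d["features"])}
        F, L = len(crf.feature_index), len(crf.labels)
        crf.W = np.asarray(d["W"]).reshape(F, L)
        crf.T = np.asarray(d["T"]).reshape(L, L)
        crf.b_start = np.asarray(d["b_start"])
        crf.b_end = np.asarray(d["b_end"])
        return crf
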