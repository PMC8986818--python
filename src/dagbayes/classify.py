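"""Per-node posterior probability models.

The decoding machinery only needs a model satisfying the probability
contract: ``fit(X, Y)`` on binary node-label matrices, then
``predict_proba(X)`` returning an (instances × nodes) matrix in [0, 1] whose
column order matches the hierarchy and whose root column is forced to 1.

Two implementations are provided: a dependency-light regularised logistic
baseline (one estimator per node), and a bidirectional-LSTM reference
network (dense expansion → layer norm → BiLSTM → dropout → sigmoid head)
available when a torch backend is installed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

__all__ = [
    "SplitSpec",
    "split_dataset",
    "LogisticNodeClassifier",
    "BiLSTMClassifier",
    "build_logistic_baseline",
    "build_reference_network",
]


@dataclass(frozen=True)
class SplitSpec:
    """Fractions for the train/validation/test partition.

    Two thirds of the data train the model (of which one third validates),
    one third is held out for testing.
    """

    train_fraction: float = 2 / 3
    fit_fraction: float = 2 / 3  # share of the training split used for fitting
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1 and 0 < self.fit_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")


def split_dataset(X, Y, spec: SplitSpec = None):
    """Disjoint, exhaustive, seeded (fit, validation, test) index partition.

    Sizes are floor-based: n_train = floor(n·train_fraction), of which
    n_fit = floor(n_train·fit_fraction); the remainder is the test split.
    Returns a dict of index arrays {"fit", "val", "test"}.
    """
    spec = spec or SplitSpec()
    X = np.asarray(X)
    Y = np.asarray(Y)
    if len(X) != len(Y):
        raise ValueError("features and labels have different row counts")
    n = len(X)
    n_train = int(n * spec.train_fraction)
    n_fit = int(n_train * spec.fit_fraction)
    n_val = n_train - n_fit
    if min(n_fit, n_val, n - n_train) < 1:
        raise ValueError(f"{n} rows are too few for three nonempty splits")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    return {
        "fit": np.sort(perm[:n_fit]),
        "val": np.sort(perm[n_fit:n_train]),
        "test": np.sort(perm[n_train:]),
    }


class LogisticNodeClassifier(BaseEstimator):
    """Independent L2-regularised logistic estimator per hierarchy node.

    Nodes whose training column is single-class fall back to predicting that
    class's empirical rate; an all-constant feature matrix triggers a warning
    and intercept-only fits.
    """

    def __init__(self, C=1.0, max_iter=1000, random_state=0):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        if X.ndim != 2 or Y.ndim != 2 or len(X) != len(Y):
            raise ValueError("X must be (n, d) and Y (n, nodes) with equal n")
        if np.allclose(X, X[0]):
            warnings.warn("all-constant features; fitting intercept-only models")
        self.n_nodes_ = Y.shape[1]
        self.models_ = []
        self.constant_ = np.full(self.n_nodes_, np.nan)
        for j in range(self.n_nodes_):
            col = Y[:, j]
            if len(np.unique(col)) < 2:
                self.constant_[j] = float(np.mean(col))
                self.models_.append(None)
                continue
            m = LogisticRegression(C=self.C, max_iter=self.max_iter,
                                   random_state=self.random_state)
            m.fit(X, col)
            self.models_.append(m)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        P = np.zeros((len(X), self.n_nodes_))
        for j, m in enumerate(self.models_):
            if m is None:
                P[:, j] = self.constant_[j]
            else:
                P[:, j] = m.predict_proba(X)[:, list(m.classes_).index(1)]
        P[:, 0] = 1.0  # root holds for every instance
        return P

    def predict(self, X):
        return (self.predict_proba(X) >= 0.5).astype(np.int8)


def build_logistic_baseline(n_features: int, n_nodes: int,
                            regularization: float = 1.0) -> LogisticNodeClassifier:
    """Baseline probability model (regularization = inverse of sklearn's C)."""
    if n_features < 1 or n_nodes < 1:
        raise ValueError("counts must be positive")
    return LogisticNodeClassifier(C=1.0 / regularization)


class BiLSTMClassifier(BaseEstimator):
    """Reference recurrent multi-label network.

    Architecture: dense expansion (sigmoid) → layer normalisation →
    bidirectional LSTM (tanh; forward/backward outputs concatenated) →
    dropout → dense sigmoid head of width n_nodes, trained with binary
    cross-entropy at learning rate 8e-4.  Each expanded feature is one
    recurrent time step.  Requires a torch backend.
    """

    def __init__(self, n_features=None, n_nodes=None, expansion=128,
                 recurrent=64, dropout=0.3, lr=8e-4, batch_size=32,
                 max_epochs=200, patience=10, random_state=0):
        self.n_features = n_features
        self.n_nodes = n_nodes
        self.expansion = expansion
        self.recurrent = recurrent
        self.dropout = dropout
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    def _torch(self):
        try:
            import torch  # noqa: F401
            return torch
        except ImportError as err:
            raise RuntimeError(
                "the BiLSTM reference network needs the optional torch backend; "
                "use LogisticNodeClassifier (build_logistic_baseline) instead"
            ) from err

    def _build(self, torch, n_features, n_nodes):
        nn = torch.nn

        class Net(nn.Module):
            def __init__(self, expansion, recurrent, dropout):
                super().__init__()
                self.expand = nn.Linear(n_features, expansion)
                self.norm = nn.LayerNorm(expansion)
                self.lstm = nn.LSTM(1, recurrent, batch_first=True,
                                    bidirectional=True)
                self.drop = nn.Dropout(dropout)
                self.head = nn.Linear(2 * recurrent, n_nodes)

            def forward(self, x):
                z = torch.sigmoid(self.expand(x))
                z = self.norm(z)
                seq = z.unsqueeze(-1)  # each expanded feature = one time step
                out, _ = self.lstm(seq)
                z = self.drop(out[:, -1, :])
                return torch.sigmoid(self.head(z))

        return Net(self.expansion, self.recurrent, self.dropout)

    def fit(self, X, Y):
        torch = self._torch()
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(Y, dtype=np.float32)
        torch.manual_seed(self.random_state)
        self.n_nodes_ = Y.shape[1]
        net = self._build(torch, X.shape[1], Y.shape[1])
        opt = torch.optim.Adam(net.parameters(), lr=self.lr)
        loss_fn = torch.nn.BCELoss()
        n_val = max(1, len(X) // 5)
        Xt, Yt = torch.tensor(X[:-n_val]), torch.tensor(Y[:-n_val])
        Xv, Yv = torch.tensor(X[-n_val:]), torch.tensor(Y[-n_val:])
        best, best_state, bad = np.inf, None, 0
        for _ in range(self.max_epochs):
            net.train()
            perm = torch.randperm(len(Xt))
            for k in range(0, len(Xt), self.batch_size):
                idx = perm[k:k + self.batch_size]
                opt.zero_grad()
                loss = loss_fn(net(Xt[idx]), Yt[idx])
                loss.backward()
                opt.step()
            net.eval()
            with torch.no_grad():
                vl = float(loss_fn(net(Xv), Yv))
            if vl < best - 1e-6:
                best, bad = vl, 0
                best_state = {k: v.clone() for k, v in net.state_dict().items()}
            else:
                bad += 1
                if bad >= self.patience:
                    break
        if best_state is not None:
            net.load_state_dict(best_state)
        self.net_ = net
        return self

    def predict_proba(self, X):
        torch = self._torch()
        self.net_.eval()
        with torch.no_grad():
            P = self.net_(torch.tensor(np.asarray(X, dtype=np.float32))).numpy()
        P[:, 0] = 1.0
        return P


def build_reference_network(n_features: int, n_nodes: int, expansion: int = 128,
                            recurrent: int = 64, dropout: float = 0.3,
                            **kwargs) -> BiLSTMClassifier:
    """Reference BiLSTM model; raises a capability error without torch."""
    if n_features < 1 or n_nodes < 1:
        raise ValueError("counts must be positive")
    model = BiLSTMClassifier(n_features=n_features, n_nodes=n_nodes,
                             expansion=expansion, recurrent=recurrent,
                             dropout=dropout, **kwargs)
    model._torch()  # fail fast with a clear message when the backend is absent
    return model
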