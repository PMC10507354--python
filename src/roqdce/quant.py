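"""Direct pharmacokinetic quantification network.

A simulation-pretrained multilayer perceptron mapping a concatenated
(Ct, AIF) curve pair to (Ktrans, kep); ve is derived as the ratio.
Trained with the mixed loss L = lambda * MAE + (1 - lambda) * MAPE
(lambda = 0.998) averaged over the three parameters, Adam, initial
learning rate 1e-3 held for 10 epochs then decayed by e^-0.1 per epoch.

Inputs are standardized per pair by the AIF peak before the network:
the Tofts parameters are invariant to a joint scaling of Ct and Cp, and
the random AIF amplitude augmentation would otherwise confound
amplitude with Ktrans.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._autograd import Adam, Tensor
from ._nn import MLP, lr_at_epoch
from .core import DynamicCurve, PKParams
from .protocol import SimulationSet

__all__ = ["mixed_loss", "QuantNetRegressor", "pretrain", "quantify"]

LR_DECAY_PER_EPOCH = float(np.exp(-0.1))


def mixed_loss(pred: np.ndarray, truth: np.ndarray, loss_lambda: float = 0.998) -> float:
    """Mixed MAE/MAPE loss averaged over the parameter triple.

    ``pred`` and ``truth`` are (n, 3) arrays of (ktrans, kep, ve).
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape:
        raise ValueError("pred and truth batches must have the same shape")
    if np.any(truth == 0):
        raise ValueError("MAPE undefined: truth contains zero components")
    err = np.abs(pred - truth)
    mae = float(err.mean())
    mape = float((err / np.abs(truth)).mean())
    return loss_lambda * mae + (1.0 - loss_lambda) * mape


class QuantNetRegressor(BaseEstimator, RegressorMixin):
    """Simulation-pretrained direct Tofts-parameter estimator.

    Parameters
    ----------
    hidden : tuple of int
        Hidden-layer widths of the MLP.
    loss_lambda : float
        Mixing weight between MAE and MAPE in the training loss.
    lr0, lr_decay_factor, warmup_epochs : float, float, int
        Adam schedule: ``lr0`` for the first ``warmup_epochs`` epochs,
        then multiplied by ``lr_decay_factor`` per epoch.
    batch_size, epochs : int
    random_state : int
        Seeds weight initialization and batch shuffling.

    Fitted attributes
    -----------------
    net_ : MLP
    n_steps_ : int
        Grid length; inputs are (n, 2 * n_steps_) concatenated (Ct, AIF).
    training_log_ : pandas.DataFrame with epoch, lr, loss columns.
    """

    def __init__(
        self,
        hidden: tuple[int, ...] = (256, 256, 256),
        loss_lambda: float = 0.998,
        lr0: float = 1e-3,
        lr_decay_factor: float = LR_DECAY_PER_EPOCH,
        warmup_epochs: int = 10,
        batch_size: int = 64,
        epochs: int = 100,
        random_state: int = 0,
    ):
        self.hidden = hidden
        self.loss_lambda = loss_lambda
        self.lr0 = lr0
        self.lr_decay_factor = lr_decay_factor
        self.warmup_epochs = warmup_epochs
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    # -- internal ----------------------------------------------------------

    @staticmethod
    def _normalize(X: np.ndarray) -> np.ndarray:
        """Scale each row by its AIF peak (second half of the feature vector)."""
        half = X.shape[1] // 2
        peak = np.maximum(X[:, half:].max(axis=1, keepdims=True), 1e-12)
        return X / peak

    def _forward_tensor(self, x: Tensor) -> Tensor:
        """Positive (ktrans, kep) batch from normalized input (autograd path)."""
        return self.net_.forward(x).softplus()

    def _loss_tensor(self, pred: Tensor, truth: np.ndarray) -> Tensor:
        """Mixed MAE/MAPE over (ktrans, kep, derived ve)."""
        kt, kep = pred[:, 0], pred[:, 1]
        ve = kt / kep
        lam = self.loss_lambda
        total = None
        for p, t in ((kt, truth[:, 0]), (kep, truth[:, 1]), (ve, truth[:, 2])):
            err = (p - Tensor(t)).abs()
            term = lam * err.mean() + (1.0 - lam) * (err / Tensor(np.abs(t))).mean()
            total = term if total is None else total + term
        return total * (1.0 / 3.0)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "QuantNetRegressor":
        """Train on simulated pairs.

        ``X``: (n, 2T) concatenated (Ct, AIF) rows; ``y``: (n, 2) or
        (n, 3) ground-truth (ktrans, kep[, ve]).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] % 2:
            raise ValueError("X must be (n, 2*n_steps)")
        if len(X) == 0:
            raise ValueError("empty training set")
        if y.shape[1] == 2:
            y = np.column_stack([y, y[:, 0] / y[:, 1]])
        self.n_steps_ = X.shape[1] // 2
        rng = np.random.default_rng(self.random_state)
        self.net_ = MLP((X.shape[1], *self.hidden, 2), rng)
        opt = Adam(self.net_.params, lr=self.lr0)
        Xn = self._normalize(X)
        n = len(Xn)
        log = []
        for epoch in range(1, self.epochs + 1):
            opt.lr = lr_at_epoch(epoch, self.lr0, self.warmup_epochs, self.lr_decay_factor)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                opt.zero_grad()
                pred = self._forward_tensor(Tensor(Xn[sel]))
                loss = self._loss_tensor(pred, y[sel])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate or check the inputs"
                    )
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(sel)
            log.append({"epoch": epoch, "lr": opt.lr, "loss": epoch_loss / n})
        self.training_log_ = pd.DataFrame(log)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """(n, 3) array of (ktrans, kep, ve) estimates."""
        check_is_fitted(self, "net_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 2 * self.n_steps_:
            raise ValueError(
                f"expected {2 * self.n_steps_} features (Ct and AIF of length "
                f"{self.n_steps_}), got {X.shape[1]}"
            )
        out = self._forward_tensor(Tensor(self._normalize(X))).data
        kt, kep = out[:, 0], out[:, 1]
        return np.column_stack([kt, kep, kt / kep])

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "net_")
        np.savez(
            path,
            sizes=np.array(self.net_.sizes),
            n_steps=self.n_steps_,
            **self.net_.state(),
        )

    @classmethod
    def load(cls, path, **kwargs) -> "QuantNetRegressor":
        data = np.load(path)
        est = cls(**kwargs)
        sizes = tuple(int(s) for s in data["sizes"])
        est.hidden = sizes[1:-1]
        est.net_ = MLP(sizes, np.random.default_rng(0))
        est.net_.load_state({k: data[k] for k in data.files if k[0] in "wb" and k[1:].isdigit()})
        est.n_steps_ = int(data["n_steps"])
        est.training_log_ = pd.DataFrame()
        return est


def pairs_to_xy(dataset: SimulationSet) -> tuple[np.ndarray, np.ndarray]:
    """Stack a simulated set into the (X, y) arrays the estimator consumes."""
    X = np.hstack([dataset.ct, dataset.aif])
    return X, dataset.truth_matrix()


def pretrain(dataset: SimulationSet, **config) -> QuantNetRegressor:
    """Pre-train a quantification network on a simulated set."""
    if len(dataset) == 0:
        raise ValueError("empty training set")
    X, y = pairs_to_xy(dataset)
    return QuantNetRegressor(**config).fit(X, y)


def quantify(net: QuantNetRegressor, ct: DynamicCurve, aif: DynamicCurve) -> PKParams:
    """Estimate the Tofts parameters for one (Ct, AIF) curve pair."""
    if ct.grid != aif.grid:
        raise ValueError("ct and aif are on different grids")
    kt, kep, _ = net.predict(np.concatenate([ct.values, aif.values])[None, :])[0]
    return PKParams(ktrans=float(kt), kep=float(kep))
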