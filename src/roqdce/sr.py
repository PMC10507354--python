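"""Pharmacokinetics-informed temporal super-resolution.

The upsampling block maps the four clinical phase values of a voxel (or
of the arterial input) to the full high-temporal-resolution curve. It
is trained with the three-term cost

    L = ||Sout - Sref||^2
        + lambda1 ||Sin - Omega(Sout)||^2
        + lambda2 ||Sout - fTofts(AIFout, kep_out, Ktrans_out)||^2

where Omega restricts a curve to the clinical phase times,
(Ktrans_out, kep_out) come from the frozen pre-trained quantification
network applied to (Sout, AIFout), and lambda1 = lambda2 = 0.1.
Disabling the pharmacokinetic constraint (lambda2 term) gives the
ablation variant. All curves live in normalized-enhancement space,
treated as a linear concentration surrogate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._autograd import Adam, Tensor, tofts_conv
from ._nn import MLP, lr_at_epoch
from .core import DynamicCurve, PKParams, TimeGrid
from .protocol import MultiPhasicSample
from .quant import LR_DECAY_PER_EPOCH, QuantNetRegressor

__all__ = ["sr_loss", "TemporalSuperResolver", "train_sr", "roq_infer"]


def _phase_indices(grid: TimeGrid, phase_times_s: np.ndarray) -> np.ndarray:
    return np.array([grid.nearest_index(t) for t in phase_times_s])


def sr_loss(
    s_out: DynamicCurve,
    s_ref: DynamicCurve,
    s_in: MultiPhasicSample,
    aif_out: DynamicCurve,
    pk: PKParams,
    lambda1: float = 0.1,
    lambda2: float = 0.1,
    pk_constraint_enabled: bool = True,
) -> float:
    """Three-term super-resolution cost for a single voxel.

    With ``pk_constraint_enabled=False`` the lambda2 term is omitted
    (the ablation cost).
    """
    if s_out.grid != s_ref.grid or s_out.grid != aif_out.grid:
        raise ValueError("curves are on different grids")
    grid = s_out.grid
    idx = _phase_indices(grid, s_in.phase_times_s)
    fidelity = float(np.sum((s_out.values - s_ref.values) ** 2))
    data_consistency = float(np.sum((s_in.phase_values - s_out.values[idx]) ** 2))
    total = fidelity + lambda1 * data_consistency
    if pk_constraint_enabled:
        from .pk import tofts_forward

        ct_fit = tofts_forward(aif_out, pk.ktrans, pk.kep)
        total += lambda2 * float(np.sum((s_out.values - ct_fit.values) ** 2))
    return total


class TemporalSuperResolver(BaseEstimator, TransformerMixin):
    """Upsampling block: 4 clinical phases -> full dynamic curve.

    Parameters
    ----------
    qnet : fitted QuantNetRegressor
        Frozen quantification network providing the pharmacokinetic
        constraint during training and the parameter read-out at
        inference.
    grid : TimeGrid
        Output time axis (defaults to the 130-step, 2-s axis).
    lambda1, lambda2 : float
        Data-consistency and pharmacokinetic-constraint weights.
    pk_constraint : bool
        ``False`` trains the ablation variant (lambda2 term omitted).
    batch_size : int
        1 reproduces voxel-wise training; larger values give the
        mini-batched scaled profile.

    Fitted attributes
    -----------------
    net_ : MLP mapping 4 phase values to ``grid.n_steps`` samples.
    training_log_ : per-epoch DataFrame with the loss decomposition.
    """

    def __init__(
        self,
        qnet: QuantNetRegressor | None = None,
        grid: TimeGrid | None = None,
        hidden: tuple[int, ...] = (128, 128),
        lambda1: float = 0.1,
        lambda2: float = 0.1,
        pk_constraint: bool = True,
        lr0: float = 1e-3,
        lr_decay_factor: float = LR_DECAY_PER_EPOCH,
        warmup_epochs: int = 10,
        batch_size: int = 1,
        epochs: int = 100,
        random_state: int = 0,
    ):
        self.qnet = qnet
        self.grid = grid
        self.hidden = hidden
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.pk_constraint = pk_constraint
        self.lr0 = lr0
        self.lr_decay_factor = lr_decay_factor
        self.warmup_epochs = warmup_epochs
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def _batch_loss(
        self,
        phases: np.ndarray,
        aif_phases: np.ndarray,
        refs: np.ndarray,
        idx: np.ndarray,
        tissue: np.ndarray,
    ) -> tuple[Tensor, dict[str, float]]:
        """Three-term loss over one mini-batch (mean of per-sample costs)."""
        B = len(phases)
        rows = np.arange(B)[:, None]
        s_out = self.net_.forward(Tensor(phases))
        rdiff = s_out - Tensor(refs)
        fidelity = (rdiff * rdiff).sum() * (1.0 / B)
        omega_diff = Tensor(phases) - s_out[(rows, idx)]
        dc = (omega_diff * omega_diff).sum() * (1.0 / B)
        loss = fidelity + self.lambda1 * dc
        parts = {"fidelity": float(fidelity.data), "data_consistency": float(self.lambda1 * dc.data), "pk": 0.0}
        if self.pk_constraint and np.any(tissue):
            tt = np.flatnonzero(tissue)
            s_t = s_out[tt]
            aif_out = self.net_.forward(Tensor(aif_phases[tt]))
            from ._autograd import concat

            # standardize by the (detached) AIF peak, as in pre-training
            scale = 1.0 / np.maximum(aif_out.data.max(axis=1, keepdims=True), 1e-12)
            x = concat([s_t * Tensor(scale), aif_out * Tensor(scale)], axis=1)
            params = self.qnet._forward_tensor(x)
            ct_fit = tofts_conv(aif_out, params[:, 0], params[:, 1], self._dt_min)
            diff = s_t - ct_fit
            pk_term = (diff * diff).sum() * (1.0 / B)
            loss = loss + self.lambda2 * pk_term
            parts["pk"] = float(self.lambda2 * pk_term.data)
        parts["total"] = float(loss.data)
        return loss, parts

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        phase_idx: np.ndarray | None = None,
        sample_kind: np.ndarray | None = None,
    ) -> "TemporalSuperResolver":
        """Train the upsampling block.

        ``X``: (n, 8) rows of [4 own phase values, 4 subject-AIF phase
        values]; ``y``: (n, n_steps) reference curves; ``phase_idx``:
        (n, 4) grid indices of each row's phase centers (required — the
        arterial timing differs between subjects); ``sample_kind``:
        'tissue'/'aif' per row (the pharmacokinetic constraint applies
        to tissue rows).
        """
        if self.qnet is None:
            raise ValueError("a fitted quantification network is required")
        grid = self.grid or TimeGrid()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 8:
            raise ValueError("X must be (n, 8): own phases + subject AIF phases")
        if y.shape != (len(X), grid.n_steps):
            raise ValueError("y must be (n, n_steps) reference curves")
        if phase_idx is None:
            raise ValueError("phase_idx (grid indices of the phase centers) is required")
        phase_idx = np.asarray(phase_idx, dtype=int)
        tissue = (
            np.full(len(X), True)
            if sample_kind is None
            else np.asarray(sample_kind) == "tissue"
        )
        self.grid_ = grid
        self._dt_min = grid.dt / 60.0
        rng = np.random.default_rng(self.random_state)
        self.net_ = MLP((4, *self.hidden, grid.n_steps), rng)
        self.qnet.net_.freeze()
        opt = Adam(self.net_.params, lr=self.lr0)
        n = len(X)
        log = []
        for epoch in range(1, self.epochs + 1):
            opt.lr = lr_at_epoch(epoch, self.lr0, self.warmup_epochs, self.lr_decay_factor)
            order = rng.permutation(n)
            sums = {"fidelity": 0.0, "data_consistency": 0.0, "pk": 0.0, "total": 0.0}
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                opt.zero_grad()
                loss, parts = self._batch_loss(
                    X[sel, :4], X[sel, 4:], y[sel], phase_idx[sel], tissue[sel]
                )
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite SR loss at epoch {epoch}")
                loss.backward()
                opt.step()
                for k in sums:
                    sums[k] += parts[k] * len(sel)
            log.append({"epoch": epoch, "lr": opt.lr, **{k: v / n for k, v in sums.items()}})
        self.training_log_ = pd.DataFrame(log)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Upsample (n, 4) phase rows to (n, n_steps) curves."""
        check_is_fitted(self, "net_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == 8:
            X = X[:, :4]
        if X.shape[1] != 4:
            raise ValueError("expected 4 phase values per row")
        return self.net_.forward(Tensor(X)).data

    def save(self, path) -> None:
        check_is_fitted(self, "net_")
        np.savez(path, sizes=np.array(self.net_.sizes), **self.net_.state())

    def load_weights(self, path, grid: TimeGrid | None = None) -> "TemporalSuperResolver":
        data = np.load(path)
        sizes = tuple(int(s) for s in data["sizes"])
        self.net_ = MLP(sizes, np.random.default_rng(0))
        self.net_.load_state({k: data[k] for k in data.files if k[0] in "wb" and k[1:].isdigit()})
        self.grid_ = grid or self.grid or TimeGrid()
        self.training_log_ = pd.DataFrame()
        return self


def train_sr(
    subjects,
    qnet: QuantNetRegressor,
    screened: dict[str, np.ndarray] | None = None,
    aif_replication: int = 1,
    **config,
) -> TemporalSuperResolver:
    """Train a super-resolver on a set of phantom subjects.

    ``screened`` maps subject_id -> boolean keep mask from voxel
    screening; passing subjects without masks raises, since unscreened
    voxels must not enter training. Each subject's AIF sample enters the
    training stream ``aif_replication`` times per epoch (once by
    default, mirroring its natural frequency in voxel-wise training) so
    the shared upsampling block also learns the arterial curve family.
    """
    if screened is None:
        raise ValueError(
            "voxels must be screened before SR training; pass screened="
            "{subject_id: keep_mask} from the screening stage"
        )
    grid = config.pop("grid", None) or TimeGrid()
    Xs, ys, idxs, kinds = [], [], [], []
    for s in subjects:
        keep = screened[s.subject_id]
        idx = _phase_indices(grid, s.phase_times_s)
        tis = s.samples[keep]
        Xs.append(np.hstack([tis, np.tile(s.aif_sample.phase_values, (len(tis), 1))]))
        ys.append(s.ref_curves[keep])
        idxs.append(np.tile(idx, (len(tis), 1)))
        kinds.extend(["tissue"] * len(tis))
        rep = np.tile(np.concatenate([s.aif_sample.phase_values] * 2), (aif_replication, 1))
        Xs.append(rep)
        ys.append(np.tile(s.aif_values, (aif_replication, 1)))
        idxs.append(np.tile(idx, (aif_replication, 1)))
        kinds.extend(["aif"] * aif_replication)
    est = TemporalSuperResolver(qnet=qnet, grid=grid, **config)
    return est.fit(
        np.concatenate(Xs),
        np.concatenate(ys),
        phase_idx=np.concatenate(idxs),
        sample_kind=np.array(kinds),
    )


def roq_infer(
    srnet: TemporalSuperResolver,
    qnet: QuantNetRegressor,
    tissue_sample: MultiPhasicSample,
    aif_sample: MultiPhasicSample,
    aif_mode: str = "upsampled",
    aif_ref: DynamicCurve | None = None,
) -> dict:
    """Retrospective quantification of one voxel.

    Upsamples the tissue sample, pairs it with either the upsampled AIF
    (``aif_mode='upsampled'``, the clinical scenario) or a supplied
    reference AIF (``aif_mode='reference'``, the validation scenario),
    and reads the parameters off the frozen quantification network.
    """
    if aif_mode not in ("upsampled", "reference"):
        raise ValueError(f"unknown aif_mode {aif_mode!r}")
    if aif_mode == "reference" and aif_ref is None:
        raise ValueError("aif_mode='reference' requires aif_ref")
    grid = srnet.grid_
    s_out = srnet.transform(tissue_sample.phase_values[None, :])[0]
    if aif_mode == "upsampled":
        aif_values = srnet.transform(aif_sample.phase_values[None, :])[0]
    else:
        aif_values = aif_ref.values
    kt, kep, _ = qnet.predict(np.concatenate([s_out, aif_values])[None, :])[0]
    return {
        "s_out": DynamicCurve(grid, s_out, kind="normalized_signal"),
        "params": PKParams(ktrans=float(kt), kep=float(kep)),
    }
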