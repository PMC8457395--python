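"""Message-passing network with edge updates for per-atom shift prediction.

The model follows the 3D message-passing lineage of SchNet-style networks
augmented with explicit edge updates.  Atoms are embedded by element into
feature vectors of size 256; each atom pair within the distance cutoff is
an edge carrying an RBF-expanded distance.  The network then iterates
three blocks of

* edge update   e' = e + MLP([h_i ‖ h_j ‖ e])
* message       m_i = Σ_j  h_j ⊙ filter(e'_ij)
* node update   h' = h + MLP(m_i)

and finally maps each node of the target element through a fully
connected readout (256→128→64→1) to a scalar chemical shift in ppm.
Separate models are trained per nucleus (1H, 13C).  Because the input is
a function of interatomic distances only, predictions are invariant to
rigid motions and equivariant to atom relabeling by construction.

Training minimizes mean absolute error with Adam on z-score-normalized
targets; the normalization constants are fitted once on the first
training set and stored with the parameters, so later transfer-learning
stages see a fixed scale.  Every parameter tensor carries a group label
(embedding / edge_update / message / node_update / readout) which the
transfer module uses to build freeze masks.

A thin statsmodels-flavored surface is provided on top of the functional
API: :class:`ChemicalShiftModel` holds the data and configuration and its
``fit`` returns a :class:`ShiftModelResults` with the trained parameters,
the training report, prediction/evaluation methods and ``summary()``.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from .featurize import ELEMENT_INDEX, EnvironmentGraph, GraphBatch, batch_graphs
from .molio import NUCLEI, ShiftRecord

PARAM_GROUPS = ("embedding", "edge_update", "message", "node_update", "readout")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training-target configuration of one model."""

    feature_dim: int = 256
    n_basis: int = 256
    n_update_blocks: int = 3
    edge_update_hidden_layers: int = 2
    readout_layer_widths: tuple = (256, 128, 64, 1)
    activation: str = "ssp"
    loss: str = "mae"
    nucleus: str = "C13"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.feature_dim < 1 or self.n_basis < 1:
            raise ValueError("feature_dim and n_basis must be >= 1")
        if self.n_update_blocks < 1:
            raise ValueError("n_update_blocks must be >= 1")
        if self.edge_update_hidden_layers < 1:
            raise ValueError("edge_update_hidden_layers must be >= 1")
        if self.readout_layer_widths[-1] != 1:
            raise ValueError("last readout width must be 1")
        if self.readout_layer_widths[0] != self.feature_dim:
            raise ValueError("first readout width must equal feature_dim")
        if self.activation != "ssp":
            raise ValueError("only the shifted-softplus activation is supported")
        if self.loss not in ("mae", "mse"):
            raise ValueError("loss must be mae or mse")
        if self.nucleus not in NUCLEI:
            raise ValueError(f"nucleus must be one of {NUCLEI}")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class ModelParams:
    """Parameter tensors plus their group labels and target scaling."""

    config: ModelConfig
    tensors: dict[str, np.ndarray]
    groups: dict[str, str]
    target_mean: float = 0.0
    target_std: float = 1.0
    lineage: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return int(sum(t.size for t in self.tensors.values()))

    def count_by_group(self) -> dict[str, int]:
        out = dict.fromkeys(PARAM_GROUPS, 0)
        for name, t in self.tensors.items():
            out[self.groups[name]] += t.size
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            config=self.config,
            tensors={k: v.copy() for k, v in self.tensors.items()},
            groups=dict(self.groups),
            target_mean=self.target_mean,
            target_std=self.target_std,
            lineage=copy.deepcopy(self.lineage),
        )

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tensors):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.tensors[name]).tobytes())
        return h.hexdigest()


@dataclass
class TrainReport:
    """Per-epoch losses and final held-out metrics (ppm)."""

    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    final_train_mae: float
    final_val_mae: float | None
    final_val_rmse: float | None
    frozen_fraction: float = 0.0
    n_train: int = 0
    n_val: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class LabelledGraph:
    """An environment graph with shift labels on a subset of target atoms."""

    graph: EnvironmentGraph
    atom_indices: np.ndarray
    shifts: np.ndarray  # ppm, aligned with atom_indices

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=np.int64)
        self.shifts = np.asarray(self.shifts, dtype=np.float64)
        if self.atom_indices.shape != self.shifts.shape:
            raise ValueError("atom_indices and shifts must align")
        if not np.all(self.graph.target_mask[self.atom_indices]):
            raise ValueError("every labelled atom must be masked for the nucleus")


def make_labelled(graph: EnvironmentGraph, records: list[ShiftRecord]) -> LabelledGraph:
    """Attach matching shift records to a graph as training labels."""
    recs = [r for r in records if r.nucleus == graph.nucleus]
    if not recs:
        raise ValueError(f"no {graph.nucleus} records for {graph.molecule_id}")
    idx = np.array([r.atom_index for r in recs], dtype=np.int64)
    y = np.array([r.shift for r in recs])
    return LabelledGraph(graph, idx, y)


# ---------------------------------------------------------------------------
# initialization


def _glorot(rng, fan_in, fan_out, dtype, scale=1.0):
    lim = scale * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, (fan_in, fan_out)).astype(dtype)


def init_model(config: ModelConfig) -> ModelParams:
    """Deterministically initialize parameters from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    dt = config.np_dtype
    F, B = config.feature_dim, config.n_basis
    tensors: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}

    def add(name, group, arr):
        tensors[name] = arr
        groups[name] = group

    add("embedding", "embedding", rng.normal(0.0, 1.0, (len(ELEMENT_INDEX), F)).astype(dt))
    # output layers of the residual branches start small so that node and
    # edge features stay near the embedding scale at initialization (the
    # neighbor sum would otherwise amplify activations block after block)
    for t in range(config.n_update_blocks):
        widths = [2 * F + B] + [B] * config.edge_update_hidden_layers
        last = config.edge_update_hidden_layers - 1
        for L in range(config.edge_update_hidden_layers):
            s = 0.1 if L == last else 1.0
            add(f"block{t}.edge.W{L}", "edge_update", _glorot(rng, widths[L], widths[L + 1], dt, s))
            add(f"block{t}.edge.b{L}", "edge_update", np.zeros(widths[L + 1], dtype=dt))
        add(f"block{t}.msg.W0", "message", _glorot(rng, B, F, dt))
        add(f"block{t}.msg.b0", "message", np.zeros(F, dtype=dt))
        add(f"block{t}.msg.W1", "message", _glorot(rng, F, F, dt, 0.1))
        add(f"block{t}.msg.b1", "message", np.zeros(F, dtype=dt))
        add(f"block{t}.node.W0", "node_update", _glorot(rng, F, F, dt))
        add(f"block{t}.node.b0", "node_update", np.zeros(F, dtype=dt))
        add(f"block{t}.node.W1", "node_update", _glorot(rng, F, F, dt, 0.1))
        add(f"block{t}.node.b1", "node_update", np.zeros(F, dtype=dt))
    w = config.readout_layer_widths
    for L in range(len(w) - 1):
        add(f"readout.W{L}", "readout", _glorot(rng, w[L], w[L + 1], dt))
        add(f"readout.b{L}", "readout", np.zeros(w[L + 1], dtype=dt))
    return ModelParams(config=config, tensors=tensors, groups=groups)


# ---------------------------------------------------------------------------
# forward pass


def _mlp(x, leaves, prefix, n_layers):
    for L in range(n_layers):
        x = ad.add(ad.matmul(x, leaves[f"{prefix}.W{L}"]), leaves[f"{prefix}.b{L}"])
        if L < n_layers - 1:
            x = ad.ssp(x)
    return x


def _tape_forward(params: ModelParams, graph: EnvironmentGraph, dtype) -> tuple:
    """Build the forward tape; returns (per-atom output Var, leaf dict)."""
    cfg = params.config
    if graph.edge_rbf.shape[1] != cfg.n_basis:
        raise ValueError(
            f"graph has {graph.edge_rbf.shape[1]} RBF components, "
            f"model expects {cfg.n_basis}"
        )
    if graph.nucleus != cfg.nucleus:
        raise ValueError(f"graph nucleus {graph.nucleus} != model nucleus {cfg.nucleus}")
    leaves = {k: ad.Var(v.astype(dtype, copy=False)) for k, v in params.tensors.items()}
    h = ad.take_rows(leaves["embedding"], graph.node_elements)
    e = ad.Var(graph.edge_rbf.astype(dtype))
    src, dst = graph.edge_src, graph.edge_dst
    n_ro = len(cfg.readout_layer_widths) - 1
    for t in range(cfg.n_update_blocks):
        hi = ad.take_rows(h, src)
        hj = ad.take_rows(h, dst)
        z = ad.add(
            ad.matmul_concat([hi, hj, e], leaves[f"block{t}.edge.W0"]),
            leaves[f"block{t}.edge.b0"],
        )
        for L in range(1, cfg.edge_update_hidden_layers):
            z = ad.add(
                ad.matmul(ad.ssp(z), leaves[f"block{t}.edge.W{L}"]),
                leaves[f"block{t}.edge.b{L}"],
            )
        e = ad.add(e, z)
        filt = _mlp(e, leaves, f"block{t}.msg", 2)
        msg = ad.segment_sum(ad.mul(hj, filt), src, graph.n_atoms)
        h = ad.add(h, _mlp(msg, leaves, f"block{t}.node", 2))
    out = _mlp(h, leaves, "readout", n_ro)
    return out, leaves


def forward(
    params: ModelParams,
    graph: EnvironmentGraph,
    compute_dtype=np.float64,
) -> np.ndarray:
    """Predicted shifts (ppm) for the graph's masked atoms, in mask order.

    All masked atoms are predicted in one pass.  Inference defaults to
    float64 regardless of the training dtype.
    """
    if not graph.target_mask.any():
        return np.zeros(0)
    out, _ = _tape_forward(params, graph, compute_dtype)
    raw = out.value[:, 0][graph.target_indices]
    return raw * params.target_std + params.target_mean


def predict_records(params: ModelParams, graph: EnvironmentGraph) -> list[ShiftRecord]:
    preds = forward(params, graph)
    return [
        ShiftRecord(graph.molecule_id, int(i), graph.nucleus, float(p), "predicted")
        for i, p in zip(graph.target_indices, preds)
    ]


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, names, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {n: 0.0 for n in names}
        self.v = {n: 0.0 for n in names}
        self.t = 0

    def step(self, tensors, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for n, g in grads.items():
            self.m[n] = b1 * self.m[n] + (1 - b1) * g
            self.v[n] = b2 * self.v[n] + (1 - b2) * g * g
            mhat = self.m[n] / (1 - b1**self.t)
            vhat = self.v[n] / (1 - b2**self.t)
            tensors[n] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                tensors[n].dtype
            )


def _epoch_batches(data, batch_size, rng):
    order = rng.permutation(len(data)) if rng is not None else np.arange(len(data))
    for start in range(0, len(data), batch_size):
        chunk = [data[i] for i in order[start : start + batch_size]]
        yield batch_graphs(
            [lg.graph for lg in chunk],
            labels=[(lg.atom_indices, lg.shifts) for lg in chunk],
        )


def _batch_loss_and_grads(params, batch: GraphBatch, dtype, loss_kind, freeze):
    out, leaves = _tape_forward(params, batch.graph, dtype)
    pred = ad.take_rows(out, batch.label_atoms)
    target = (
        (batch.label_values - params.target_mean) / params.target_std
    ).astype(dtype)[:, None]
    loss = (ad.mean_abs if loss_kind == "mae" else ad.mean_sq)(pred, target)
    ad.backward(loss)
    grads = {
        n: v.grad for n, v in leaves.items() if n not in freeze and v.grad is not None
    }
    return float(loss.value), grads


def train(
    params: ModelParams,
    train_data: list[LabelledGraph],
    val_data: list[LabelledGraph] | None = None,
    *,
    n_epochs: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
    lr_patience: int = 10,
    min_lr: float = 1e-6,
    freeze: set[str] | None = None,
    seed: int | None = None,
) -> tuple[ModelParams, TrainReport]:
    """Train (or fine-tune) a model; returns best-validation parameters.

    Parameters listed in ``freeze`` are never touched by the optimizer and
    come back bitwise identical.  Minibatches are whole molecules; the
    learning rate is halved when the validation loss has not improved for
    ``lr_patience`` epochs.  With a fixed ``seed`` the run is reproducible.
    Losses in the report are in ppm (denormalized).
    """
    if not train_data:
        raise ValueError("empty training set")
    freeze = set(freeze or ())
    unknown = freeze - set(params.tensors)
    if unknown:
        raise ValueError(f"freeze names not in model: {sorted(unknown)[:3]}")
    params = params.copy()
    cfg = params.config
    dt = cfg.np_dtype

    if "target_scale_set" not in params.lineage:
        all_y = np.concatenate([lg.shifts for lg in train_data])
        params.target_mean = float(all_y.mean())
        params.target_std = float(max(all_y.std(), 1e-8))
        params.lineage["target_scale_set"] = True

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    trainable = [n for n in params.tensors if n not in freeze]
    opt = _Adam(trainable, lr)
    n_frozen = sum(params.tensors[n].size for n in freeze)
    frozen_fraction = n_frozen / max(params.n_params, 1)

    val_batch = None
    if val_data:
        val_batch = batch_graphs(
            [lg.graph for lg in val_data],
            labels=[(lg.atom_indices, lg.shifts) for lg in val_data],
        )

    train_curve: list[float] = []
    val_curve: list[float] = []
    best = (np.inf, 0, {n: t.copy() for n, t in params.tensors.items()})
    stale = 0
    for epoch in range(n_epochs):
        losses, sizes = [], []
        for batch in _epoch_batches(train_data, batch_size, rng):
            loss, grads = _batch_loss_and_grads(params, batch, dt, cfg.loss, freeze)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={opt.lr:g}, batch of {len(batch.graph_slices)} graphs)"
                )
            if trainable:
                opt.step(params.tensors, grads)
            losses.append(loss)
            sizes.append(batch.label_atoms.size)
        scale = params.target_std if cfg.loss == "mae" else params.target_std**2
        train_curve.append(float(np.average(losses, weights=sizes)) * scale)

        if val_batch is not None:
            monitor = _eval_batch(params, val_batch)[0]
            val_curve.append(monitor)
        else:
            monitor = train_curve[-1]
        if monitor < best[0]:
            best = (monitor, epoch, {n: t.copy() for n, t in params.tensors.items()})
            stale = 0
        else:
            stale += 1
            if stale >= lr_patience:
                opt.lr = max(opt.lr / 2.0, min_lr)
                stale = 0

    params.tensors = best[2]
    final_val = _eval_batch(params, val_batch) if val_batch is not None else (None, None)
    report = TrainReport(
        train_loss=train_curve,
        val_loss=val_curve,
        best_epoch=best[1],
        final_train_mae=train_curve[-1],
        final_val_mae=final_val[0],
        final_val_rmse=final_val[1],
        frozen_fraction=frozen_fraction,
        n_train=len(train_data),
        n_val=len(val_data or ()),
    )
    return params, report


def _eval_batch(params: ModelParams, batch: GraphBatch) -> tuple[float, float]:
    out, _ = _tape_forward(params, batch.graph, np.float64)
    pred = out.value[:, 0][batch.label_atoms] * params.target_std + params.target_mean
    err = pred - batch.label_values
    return float(np.abs(err).mean()), float(np.sqrt((err**2).mean()))


def evaluate(params: ModelParams, data: list[LabelledGraph]) -> tuple[float, float]:
    """Pooled (MAE, RMSE) in ppm over all labelled atoms."""
    if not data:
        raise ValueError("empty evaluation set")
    batch = batch_graphs(
        [lg.graph for lg in data], labels=[(lg.atom_indices, lg.shifts) for lg in data]
    )
    return _eval_batch(params, batch)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(params: ModelParams, path: str | Path) -> None:
    """Versioned single-file archive; load/save round-trips bitwise."""
    meta = {
        "format": "shiftgnn-checkpoint-1",
        "config": dataclasses.asdict(params.config),
        "groups": params.groups,
        "target_mean": params.target_mean,
        "target_std": params.target_std,
        "lineage": params.lineage,
    }
    arrays = {f"tensor::{k}": v for k, v in params.tensors.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> ModelParams:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("format") != "shiftgnn-checkpoint-1":
            raise ValueError(f"{path}: not a shiftgnn checkpoint")
        cfg_d = meta["config"]
        cfg_d["readout_layer_widths"] = tuple(cfg_d["readout_layer_widths"])
        config = ModelConfig(**cfg_d)
        tensors = {
            k.removeprefix("tensor::"): npz[k] for k in npz.files if k.startswith("tensor::")
        }
    return ModelParams(
        config=config,
        tensors=tensors,
        groups=meta["groups"],
        target_mean=meta["target_mean"],
        target_std=meta["target_std"],
        lineage=meta["lineage"],
    )


# ---------------------------------------------------------------------------
# model / results surface


class ChemicalShiftModel:
    """Chemical-shift GNN bound to a training (and validation) dataset.

    Parameters
    ----------
    train_data, val_data : lists of LabelledGraph
        Environment graphs with per-atom shift labels; validation data
        drives best-epoch selection and the plateau schedule.
    config : ModelConfig, optional
    """

    def __init__(
        self,
        train_data: list[LabelledGraph],
        val_data: list[LabelledGraph] | None = None,
        config: ModelConfig | None = None,
    ):
        self.train_data = list(train_data)
        self.val_data = list(val_data) if val_data else None
        self.config = config or ModelConfig()
        for lg in self.train_data + (self.val_data or []):
            if lg.graph.nucleus != self.config.nucleus:
                raise ValueError("dataset nucleus differs from model nucleus")

    @classmethod
    def from_records(
        cls,
        structures,
        records,
        config: ModelConfig | None = None,
        rbf_params=None,
        val_fraction: float = 0.2,
        seed: int = 0,
    ) -> "ChemicalShiftModel":
        """Build from (Molecule, Conformer) pairs plus shift records.

        Splits at molecule-conformer level; records are matched by
        molecule id.
        """
        from .featurize import RBFParams, build_graph

        config = config or ModelConfig()
        rbf_params = rbf_params or RBFParams()
        by_mol: dict[str, list[ShiftRecord]] = {}
        for r in records:
            by_mol.setdefault(r.molecule_id, []).append(r)
        data = []
        for mol, conf in structures:
            graph = build_graph(conf, mol, rbf_params, config.nucleus)
            data.append(make_labelled(graph, by_mol[mol.id]))
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(data))
        n_val = int(round(len(data) * val_fraction))
        val = [data[i] for i in order[:n_val]]
        tr = [data[i] for i in order[n_val:]]
        return cls(tr, val or None, config)

    def fit(
        self,
        start_params: ModelParams | None = None,
        freeze: set[str] | None = None,
        **train_kwargs,
    ) -> "ShiftModelResults":
        params = start_params if start_params is not None else init_model(self.config)
        fitted, report = train(
            params, self.train_data, self.val_data, freeze=freeze, **train_kwargs
        )
        return ShiftModelResults(self, fitted, report)


class ShiftModelResults:
    """Trained parameters, training diagnostics and prediction methods."""

    def __init__(self, model: ChemicalShiftModel, params: ModelParams, report: TrainReport):
        self.model = model
        self.params = params
        self.report = report

    @property
    def config(self) -> ModelConfig:
        return self.params.config

    def predict(self, graph: EnvironmentGraph) -> np.ndarray:
        return forward(self.params, graph)

    def predict_conformer(self, mol, conf, rbf_params=None) -> list[ShiftRecord]:
        from .featurize import RBFParams, build_graph

        graph = build_graph(conf, mol, rbf_params or RBFParams(), self.config.nucleus)
        return predict_records(self.params, graph)

    def evaluate(self, data: list[LabelledGraph]) -> tuple[float, float]:
        return evaluate(self.params, data)

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.params, path)

    def summary(self) -> str:
        p, r = self.params, self.report
        counts = p.count_by_group()
        lines = [
            "Chemical shift GNN results",
            "=" * 44,
            f"nucleus:            {p.config.nucleus}",
            f"update blocks:      {p.config.n_update_blocks}",
            f"feature dim:        {p.config.feature_dim}",
            f"parameters:         {p.n_params:,}",
        ]
        lines += [f"  {g:<17} {n:,}" for g, n in counts.items()]
        lines += [
            f"frozen fraction:    {r.frozen_fraction:.1%}",
            f"epochs:             {r.n_epochs} (best {r.best_epoch})",
            f"train MAE (ppm):    {r.final_train_mae:.4f}",
        ]
        if r.final_val_mae is not None:
            lines.append(f"val MAE (ppm):      {r.final_val_mae:.4f}")
            lines.append(f"val RMSE (ppm):     {r.final_val_rmse:.4f}")
        lines.append(f"target scale:       {p.target_mean:.2f} ± {p.target_std:.2f} ppm")
        return "\n".join(lines)
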