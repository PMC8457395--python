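"""Transfer learning as freeze schemes over parameter groups.

The staged training regime mirrors the three-model regime used for shift
prediction: a base model is trained on computed labels with exact
geometries; a first transfer stage retrains only the readout layers on
experimental-quality labels (scheme ``readout_only``); a second stage
adapts to cheap force-field geometries by optimizing only the edge-update
layers — the part of the network that interprets raw interatomic
distances — while everything else stays fixed (scheme
``edge_update_only``).

Freezing operates at tensor granularity via the group labels attached to
every parameter tensor; frozen tensors are never touched by the optimizer
and come back bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gnn import (
    PARAM_GROUPS,
    LabelledGraph,
    ModelParams,
    ShiftModelResults,
    TrainReport,
    train,
)


@dataclass(frozen=True)
class FreezeScheme:
    """Named set of parameter groups to hold fixed during retraining."""

    name: str
    frozen_groups: frozenset

    def __post_init__(self):
        unknown = self.frozen_groups - set(PARAM_GROUPS)
        if unknown:
            raise ValueError(f"unknown parameter groups {sorted(unknown)}")


SCHEMES = {
    "none": FreezeScheme("none", frozenset()),
    "readout_only": FreezeScheme(
        "readout_only", frozenset({"embedding", "edge_update", "message", "node_update"})
    ),
    "edge_update_only": FreezeScheme(
        "edge_update_only", frozenset({"embedding", "message", "node_update", "readout"})
    ),
}


def get_scheme(name: str) -> FreezeScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(SCHEMES)}") from None


def make_freeze_mask(params: ModelParams, scheme: FreezeScheme) -> tuple[set[str], float]:
    """Tensor names covered by the scheme and the frozen scalar fraction."""
    unknown = set(params.groups.values()) - set(PARAM_GROUPS)
    if unknown:
        raise ValueError(f"model has unknown group labels {sorted(unknown)}")
    mask = {n for n, g in params.groups.items() if g in scheme.frozen_groups}
    n_frozen = sum(params.tensors[n].size for n in mask)
    return mask, n_frozen / max(params.n_params, 1)


def retrain(
    parent: ModelParams | ShiftModelResults,
    train_data: list[LabelledGraph],
    scheme: FreezeScheme | str,
    val_data: list[LabelledGraph] | None = None,
    *,
    lr: float = 1e-4,
    **train_kwargs,
) -> tuple[ModelParams, TrainReport]:
    """Fine-tune a previously trained model under a freeze scheme.

    The optimizer restarts from scratch (no momentum carry-over) and the
    default learning rate is ten times smaller than for initial training.
    Lineage metadata (parent checksum, scheme, data fingerprint) is
    recorded on the returned parameters.
    """
    if isinstance(parent, ShiftModelResults):
        parent = parent.params
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    mask, frac = make_freeze_mask(parent, scheme)
    fitted, report = train(
        parent, train_data, val_data, freeze=mask, lr=lr, **train_kwargs
    )
    fitted.lineage = dict(
        fitted.lineage,
        parent_checksum=parent.checksum(),
        scheme=scheme.name,
        data_fingerprint=_data_fingerprint(train_data),
        frozen_fraction=frac,
    )
    return fitted, report


def _data_fingerprint(data: list[LabelledGraph]) -> str:
    import hashlib

    h = hashlib.sha256()
    for lg in data:
        h.update(lg.graph.molecule_id.encode())
        h.update(lg.atom_indices.tobytes())
        h.update(lg.shifts.tobytes())
    return h.hexdigest()[:16]
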