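"""Conformer ensembles and Boltzmann-weighted shift predictions.

Observed NMR shifts are fast-exchange averages over the thermally
populated conformers of a molecule.  This module generates force-field
conformer ensembles (MMFF94 energies), weights per-conformer predictions
by exp(−E/RT), and combines them into final per-atom shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit.Chem import AllChem

from .featurize import RBFParams, build_graph
from .gnn import ModelParams, ShiftModelResults, forward
from .molio import Conformer, Molecule, ShiftRecord, to_rdkit

#: gas constant, kcal/(mol·K)
R_KCAL = 1.98720425864083e-3


@dataclass
class EnsemblePrediction:
    """Per-conformer and Boltzmann-averaged shifts for one molecule."""

    molecule_id: str
    nucleus: str
    atom_indices: np.ndarray  # (A,) target atoms
    per_conformer: np.ndarray  # (C, A) ppm
    weights: np.ndarray  # (C,)
    temperature: float  # K

    @property
    def final_shifts(self) -> np.ndarray:
        return self.weights @ self.per_conformer

    def to_records(self) -> list[ShiftRecord]:
        return [
            ShiftRecord(self.molecule_id, int(i), self.nucleus, float(s), "predicted")
            for i, s in zip(self.atom_indices, self.final_shifts)
        ]


def boltzmann_weights(rel_energies, temperature: float = 298.15) -> np.ndarray:
    """Normalized Boltzmann weights from relative energies (kcal/mol).

    Energies are shifted by their minimum before exponentiation for
    numerical stability, which leaves the weights unchanged.
    """
    e = np.asarray(rel_energies, dtype=np.float64)
    if e.size == 0:
        raise ValueError("empty energy list")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    w = np.exp(-(e - e.min()) / (R_KCAL * temperature))
    return w / w.sum()


def generate_conformers(
    mol: Molecule,
    max_confs: int = 200,
    seed: int = 1,
    dedup_rmsd: float = 0.5,
) -> list[Conformer]:
    """Embed and MMFF94-optimize up to ``max_confs`` conformers.

    Distance-geometry embedding is seeded and deterministic; energies are
    returned relative to the ensemble minimum (kcal/mol).  Near-duplicate
    conformers (heavy-atom RMSD below ``dedup_rmsd`` after optimal
    superposition) are pruned, keeping the lower-energy member.
    """
    if max_confs < 1:
        raise ValueError("max_confs must be >= 1")
    rdmol = to_rdkit(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_ids = AllChem.EmbedMultipleConfs(rdmol, numConfs=int(max_confs), params=params)
    if not conf_ids:
        raise RuntimeError(
            f"conformer embedding failed for molecule {mol.id} "
            "(force-field geometry generation can fail for unusual bonding)"
        )
    res = AllChem.MMFFOptimizeMoleculeConfs(rdmol, maxIters=2000)
    energies = np.array([e for _converged, e in res], dtype=np.float64)
    keep = _dedup(rdmol, energies, dedup_rmsd)
    energies = energies - energies[keep].min()
    return [
        Conformer(
            mol.id,
            np.array(rdmol.GetConformer(int(conf_ids[i])).GetPositions()),
            rel_energy=float(energies[i]),
            source="mmff",
        )
        for i in keep
    ]


def _dedup(rdmol, energies, rmsd_thresh: float) -> list[int]:
    from rdkit.Chem import RemoveHs, rdMolAlign

    heavy = RemoveHs(rdmol)
    order = np.argsort(energies, kind="stable")
    kept: list[int] = []
    for i in order:
        dup = any(
            rdMolAlign.GetBestRMS(heavy, heavy, prbId=int(i), refId=int(j)) < rmsd_thresh
            for j in kept
        )
        if not dup:
            kept.append(int(i))
    return sorted(kept)


def predict_ensemble(
    model: ModelParams | ShiftModelResults,
    mol: Molecule,
    conformers: list[Conformer],
    rbf_params: RBFParams | None = None,
    temperature: float = 298.15,
) -> EnsemblePrediction:
    """Boltzmann-weighted ensemble prediction over ``conformers``.

    Every conformer must belong to ``mol``; relative energies are required
    whenever more than one conformer is supplied.  A single conformer gets
    weight 1 exactly.
    """
    if isinstance(model, ShiftModelResults):
        model = model.params
    if not conformers:
        raise ValueError("empty conformer list")
    for c in conformers:
        if c.molecule_id != mol.id:
            raise ValueError(f"conformer of {c.molecule_id} does not belong to {mol.id}")
    if len(conformers) == 1:
        weights = np.array([1.0])
    else:
        if any(c.rel_energy is None for c in conformers):
            raise ValueError("relative energies required for multi-conformer ensembles")
        weights = boltzmann_weights([c.rel_energy for c in conformers], temperature)
    rbf_params = rbf_params or RBFParams()
    shifts = []
    atom_idx = None
    for c in conformers:
        graph = build_graph(c, mol, rbf_params, model.config.nucleus)
        atom_idx = graph.target_indices
        shifts.append(forward(model, graph))
    return EnsemblePrediction(
        molecule_id=mol.id,
        nucleus=model.config.nucleus,
        atom_indices=atom_idx,
        per_conformer=np.array(shifts),
        weights=weights,
        temperature=temperature,
    )
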