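"""Dataset construction and cleaning.

Covers the steps that turn a raw structure/shift collection into training
data: structure filters (neutral, MW < 500, supported elements, optional
defined stereochemistry), greedy farthest-neighbor diversity sampling over
molecular fingerprints, the empirical shielding-to-shift scaling
relations, interquartile-range (IQR) outlier removal of paired
computed/experimental shifts, and deterministic molecule-level splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molio import NUCLEI, SUPPORTED_ELEMENTS, Molecule, ShiftRecord


@dataclass(frozen=True)
class ScalingRelation:
    """Affine map from isotropic shielding σ to chemical shift δ = a − s·σ."""

    intercept: float  # a, ppm
    slope: float  # s, dimensionless
    nucleus: str

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.nucleus not in NUCLEI:
            raise ValueError(f"nucleus must be one of {NUCLEI}")

    def __call__(self, sigma):
        return self.intercept - self.slope * np.asarray(sigma, dtype=np.float64)


#: empirical scaling constants for mPW1PW91/6-311+G(d,p) GIAO shieldings
C13_SCALING = ScalingRelation(181.40, 0.97, "C13")
H1_SCALING = ScalingRelation(29.30, 0.91, "H1")


def scale_shielding(sigma, rel: ScalingRelation):
    """Convert shielding value(s) σ (ppm) to shift(s) δ (ppm)."""
    return rel(sigma)


# ---------------------------------------------------------------------------
# structure filtering


@dataclass
class FilterReport:
    kept: list[Molecule] = field(default_factory=list)
    rejected: dict[str, list[str]] = field(default_factory=dict)  # reason -> ids

    def counts(self) -> dict[str, int]:
        out = {"kept": len(self.kept)}
        out.update({reason: len(ids) for reason, ids in self.rejected.items()})
        return out


def filter_structures(
    mols: list[Molecule], require_stereo_defined: bool = False
) -> FilterReport:
    """Keep neutral molecules, MW < 500, elements within the supported set.

    With ``require_stereo_defined`` molecules containing any unassigned
    stereocenter are also rejected (ambiguous stereochemistry makes
    experimental assignments untrustworthy for 3D models).  Each rejection
    is recorded under its first failing reason.
    """
    report = FilterReport()
    for mol in mols:
        if mol.total_charge != 0:
            reason = "charge"
        elif mol.mol_weight >= 500.0:
            reason = "mol_weight"
        elif any(e not in SUPPORTED_ELEMENTS for e in mol.elements):
            reason = "element"
        elif require_stereo_defined and not all(mol.stereo_defined):
            reason = "stereo"
        else:
            report.kept.append(mol)
            continue
        report.rejected.setdefault(reason, []).append(mol.id)
    return report


# ---------------------------------------------------------------------------
# farthest-neighbor sampling


def morgan_fingerprints(mols: list[Molecule], n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Circular substructure fingerprints as a (n, n_bits) boolean array."""
    from rdkit.Chem import rdFingerprintGenerator

    from .molio import to_rdkit

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(mols), n_bits), dtype=bool)
    for i, mol in enumerate(mols):
        fp = gen.GetFingerprint(to_rdkit(mol))
        out[i, list(fp.GetOnBits())] = True
    return out


def farthest_neighbor_sample(fps: np.ndarray, k: int, seed: int = 0) -> list[int]:
    """Greedy max-min diversity selection over bit fingerprints.

    Starting from a seeded pick, repeatedly adds the item whose minimum
    Jaccard distance (1 − Tanimoto) to the already-selected set is
    largest.  Ties break to the lowest index; deterministic given seed.
    """
    fps = np.asarray(fps, dtype=bool)
    n = fps.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    first = int(rng.permutation(n)[0])
    selected = [first]
    popcount = fps.sum(axis=1)
    min_dist = _jaccard_distances(fps, fps[first], popcount)
    min_dist[first] = -1.0
    for _ in range(k - 1):
        nxt = int(np.argmax(min_dist))  # argmax takes the lowest index on ties
        selected.append(nxt)
        d = _jaccard_distances(fps, fps[nxt], popcount)
        min_dist = np.minimum(min_dist, d)
        min_dist[nxt] = -1.0
    return selected


def _jaccard_distances(fps: np.ndarray, probe: np.ndarray, popcount: np.ndarray) -> np.ndarray:
    inter = (fps & probe).sum(axis=1)
    union = popcount + probe.sum() - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return 1.0 - sim


# ---------------------------------------------------------------------------
# IQR cleaning


@dataclass
class CleaningReport:
    """Outcome of IQR-based cleaning of computed-vs-experimental pairs."""

    differences: np.ndarray  # computed − experimental, ppm
    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    kept: np.ndarray  # bool per pair
    mae_before: float
    rmse_before: float
    mae_after: float
    rmse_after: float
    quartile_method: str = "linear"

    @property
    def removed_fraction(self) -> float:
        return float(1.0 - self.kept.mean())

    def to_dict(self) -> dict:
        return {
            "n_pairs": int(self.differences.size),
            "q1": self.q1,
            "q3": self.q3,
            "iqr": self.iqr,
            "lower": self.lower,
            "upper": self.upper,
            "n_removed": int((~self.kept).sum()),
            "removed_fraction": self.removed_fraction,
            "mae_before": self.mae_before,
            "rmse_before": self.rmse_before,
            "mae_after": self.mae_after,
            "rmse_after": self.rmse_after,
            "quartile_method": self.quartile_method,
        }


def clean_by_iqr(
    pairs: list[tuple[ShiftRecord, ShiftRecord]],
) -> CleaningReport:
    """Flag pairs whose computed−experimental difference is an IQR outlier.

    Quartiles are taken over the pooled differences with the linear
    interpolation convention; a pair is kept iff its difference lies
    within [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (inclusive, so an all-equal set is
    fully kept).  Requires pairs matched by (molecule, atom, nucleus) and
    a single nucleus per call.
    """
    if len(pairs) < 4:
        raise ValueError("need at least 4 pairs for quartile estimation")
    nuclei = {c.nucleus for c, e in pairs} | {e.nucleus for c, e in pairs}
    if len(nuclei) != 1:
        raise ValueError(f"pairs mix nuclei {sorted(nuclei)}")
    for comp, exp in pairs:
        if (comp.molecule_id, comp.atom_index) != (exp.molecule_id, exp.atom_index):
            raise ValueError(
                f"mismatched pair {comp.molecule_id}/{comp.atom_index} vs "
                f"{exp.molecule_id}/{exp.atom_index}"
            )
    diffs = np.array([c.shift - e.shift for c, e in pairs])
    q1, q3 = np.percentile(diffs, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = (diffs >= lower) & (diffs <= upper)
    return CleaningReport(
        differences=diffs,
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower=float(lower),
        upper=float(upper),
        kept=kept,
        mae_before=float(np.abs(diffs).mean()),
        rmse_before=float(np.sqrt((diffs**2).mean())),
        mae_after=float(np.abs(diffs[kept]).mean()),
        rmse_after=float(np.sqrt((diffs[kept] ** 2).mean())),
    )


def match_pairs(
    computed: list[ShiftRecord], experimental: list[ShiftRecord]
) -> list[tuple[ShiftRecord, ShiftRecord]]:
    """Pair computed and experimental records by (molecule, atom, nucleus)."""
    by_key = {(r.molecule_id, r.atom_index, r.nucleus): r for r in experimental}
    out = []
    for c in computed:
        e = by_key.get((c.molecule_id, c.atom_index, c.nucleus))
        if e is not None:
            out.append((c, e))
    return out


# ---------------------------------------------------------------------------
# splits


def split_dataset(
    ids: list[str], n_val: int = 500, n_test: int = 500, seed: int = 0
) -> tuple[list[str], list[str], list[str]]:
    """Disjoint, exhaustive (train, val, test) split at molecule level."""
    unique = list(dict.fromkeys(ids))
    if len(unique) != len(ids):
        raise ValueError("ids must be unique (split at molecule level)")
    if n_val + n_test >= len(ids):
        raise ValueError(
            f"need n_val + n_test < n ({n_val}+{n_test} vs {len(ids)})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    val = [ids[i] for i in order[:n_val]]
    test = [ids[i] for i in order[n_val : n_val + n_test]]
    train = [ids[i] for i in order[n_val + n_test :]]
    return train, val, test
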