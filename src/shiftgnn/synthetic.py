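"""Deterministic fixtures and label oracles for desk-scale experiments.

Real training data for shift models comes from quantum-chemical shielding
calculations on thousands of conformers — far beyond a test suite.  This
module supplies the desk-scale stand-ins that make the rest of the package
testable end to end:

* hard-coded idealized 3D fixtures, including pairs that share a 2D graph
  but differ only in 3D (chair/boat, cis/trans, anti/gauche) and a
  valine-like molecule with diastereotopic methyl groups;
* a smooth geometry-sensitive oracle shift function standing in for
  computed labels, δ_i = b_Z(i) + Σ_j c_Z(j)·exp(−d_ij/λ) over neighbors
  within a cutoff — rigid-motion invariant and learnable by construction;
* contaminated computed/experimental shift pairs with planted outliers for
  scoring the IQR cleaner.

Fixture coordinates are fixed constants (idealized bond lengths/angles or
force-field-quality snapshots frozen into source), so tests never depend
on an embedding library's version or RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molio import Conformer, Molecule, ShiftRecord

FIXTURE_NAMES = (
    "methane",
    "butane_anti_gauche",
    "cyclohexane_chair_boat",
    "cis_trans_disub_cyclohexane",
    "valine_like",
)

# geometry constants (angstroms / degrees) used by the analytic builders
_CC = 1.526
_CH = 1.096
_CF = 1.39
_CHAIR_A, _CHAIR_C = 1.4521705233374256, 0.2344550975934174
_BOAT_X1, _BOAT_Z1, _BOAT_Y2 = 1.3098694922, 0.6693357436, 1.2576165576


# ---------------------------------------------------------------------------
# geometry helpers


def _unit(v):
    return v / np.linalg.norm(v)


def _tetra_pair(center, n1, n2, half_angle_deg=53.5):
    """Directions of the two remaining tetrahedral substituents.

    Given a center with two known neighbors, returns two unit vectors in
    the plane bisecting the known bonds, separated by twice
    ``half_angle_deg``.
    """
    u1 = _unit(n1 - center)
    u2 = _unit(n2 - center)
    bis = -_unit(u1 + u2)
    perp = _unit(np.cross(u1, u2))
    h = np.deg2rad(half_angle_deg)
    return bis * np.cos(h) + perp * np.sin(h), bis * np.cos(h) - perp * np.sin(h)


def _ring_with_hydrogens(ring):
    """Append two H per ring carbon; returns (coords, elements, bonds)."""
    coords = [r for r in ring]
    elements = ["C"] * 6
    bonds = [(k, (k + 1) % 6, 1.0) for k in range(6)]
    for k in range(6):
        d1, d2 = _tetra_pair(ring[k], ring[(k - 1) % 6], ring[(k + 1) % 6])
        # order the pair as (axial, equatorial): axial is more parallel to z
        if abs(d1[2]) < abs(d2[2]):
            d1, d2 = d2, d1
        for d in (d1, d2):
            coords.append(ring[k] + _CH * d)
            bonds.append((k, len(coords) - 1, 1.0))
            elements.append("H")
    return np.array(coords), elements, bonds


def _chair_ring():
    ang = np.deg2rad(60.0 * np.arange(6))
    z = _CHAIR_C * (-1.0) ** np.arange(6)
    return np.stack([_CHAIR_A * np.cos(ang), _CHAIR_A * np.sin(ang), z], axis=1)


def _boat_ring():
    x2 = _CC / 2.0
    return np.array(
        [
            [_BOAT_X1, 0.0, _BOAT_Z1],
            [x2, _BOAT_Y2, 0.0],
            [-x2, _BOAT_Y2, 0.0],
            [-_BOAT_X1, 0.0, _BOAT_Z1],
            [-x2, -_BOAT_Y2, 0.0],
            [x2, -_BOAT_Y2, 0.0],
        ]
    )


def _methane():
    s = 1.09 / np.sqrt(3.0)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [s, s, s],
            [s, -s, -s],
            [-s, s, -s],
            [-s, -s, s],
        ]
    )
    mol = Molecule(
        id="methane",
        elements=["C", "H", "H", "H", "H"],
        bonds=[(0, k, 1.0) for k in range(1, 5)],
        formal_charges=[0] * 5,
    )
    return mol, [Conformer("methane", coords)]


# force-field-quality butane snapshots (C-C-C-C torsion 180deg / ~65deg)
_BUTANE_ELEMENTS = ["C", "C", "C", "C"] + ["H"] * 10
_BUTANE_BONDS = [
    (0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0),
    (0, 4, 1.0), (0, 5, 1.0), (0, 6, 1.0),
    (1, 7, 1.0), (1, 8, 1.0), (2, 9, 1.0), (2, 10, 1.0),
    (3, 11, 1.0), (3, 12, 1.0), (3, 13, 1.0),
]
_BUTANE_ANTI = np.array(
    [
        [1.9083, 0.2944, -0.1315], [0.6021, -0.4695, 0.0159],
        [-0.6021, 0.4695, -0.0162], [-1.9083, -0.2944, 0.1312],
        [2.0341, 1.0169, 0.6811], [2.7566, -0.3968, -0.1059],
        [1.9405, 0.8367, -1.0819], [0.6155, -1.0261, 0.9602],
        [0.5225, -1.2053, -0.7929], [-0.6155, 1.0260, -0.9606],
        [-0.5225, 1.2052, 0.7925], [-2.0341, -1.0170, -0.6815],
        [-1.9405, -0.8367, 1.0815], [-2.7566, 0.3967, 0.1055],
    ]
)
_BUTANE_GAUCHE = np.array(
    [
        [1.9173, 0.5059, 0.1467], [0.6791, -0.3772, 0.1391],
        [-0.6076, 0.3816, -0.1868], [-0.6382, 0.9428, -1.6000],
        [1.7943, 1.3494, 0.8333], [2.7884, -0.0716, 0.4725],
        [2.1353, 0.8996, -0.8504], [0.5715, -0.8354, 1.1295],
        [0.8204, -1.1965, -0.5754], [-0.7525, 1.1966, 0.5320],
        [-1.4556, -0.3029, -0.0650], [0.1211, 1.7177, -1.7403],
        [-0.4694, 0.1540, -2.3399], [-1.6143, 1.3947, -1.8036],
    ]
)

# force-field-quality 2-amino-3-methylbutanoic acid snapshot: a stereocenter
# (atom 3) flanked by two diastereotopic methyl carbons (atoms 0 and 2)
_VALINE_ELEMENTS = ["C", "C", "C", "C", "N", "C", "O", "O"] + ["H"] * 11
_VALINE_BONDS = [
    (0, 1, 1.0), (1, 2, 1.0), (1, 3, 1.0), (3, 4, 1.0), (3, 5, 1.0),
    (5, 6, 2.0), (5, 7, 1.0), (0, 8, 1.0), (0, 9, 1.0), (0, 10, 1.0),
    (1, 11, 1.0), (2, 12, 1.0), (2, 13, 1.0), (2, 14, 1.0), (3, 15, 1.0),
    (4, 16, 1.0), (4, 17, 1.0), (7, 18, 1.0),
]
_VALINE_COORDS = np.array(
    [
        [-1.1159, -0.7622, -1.0057], [-0.5169, 0.4946, -0.3639],
        [-1.6168, 1.2827, 0.3556], [0.6709, 0.1971, 0.5806],
        [0.2923, -0.6930, 1.7044], [1.8654, -0.3992, -0.1794],
        [2.3858, -1.4856, 0.0283], [2.3557, 0.4186, -1.1311],
        [-0.3549, -1.3346, -1.5452], [-1.8928, -0.4880, -1.7280],
        [-1.5768, -1.4202, -0.2619], [-0.1508, 1.1287, -1.1823],
        [-2.4063, 1.5712, -0.3469], [-2.0805, 0.6959, 1.1553],
        [-1.2127, 2.2005, 0.7956], [1.0263, 1.1349, 1.0256],
        [1.1213, -0.8377, 2.2852], [0.0978, -1.6221, 1.3245],
        [3.1088, -0.0813, -1.5107],
    ]
)


def _cyclohexane():
    chair, elements, bonds = _ring_with_hydrogens(_chair_ring())
    boat, _, _ = _ring_with_hydrogens(_boat_ring())
    mol = Molecule(
        id="cyclohexane",
        elements=elements,
        bonds=bonds,
        formal_charges=[0] * len(elements),
    )
    return mol, [Conformer("cyclohexane", chair), Conformer("cyclohexane", boat)]


def _grow_methyl(coords, elements, bonds, ring_carbon, h_slot):
    """Replace the H in ``h_slot`` by a methyl group (in place).

    The methyl carbon takes over the H slot at C-C bond length; its three
    hydrogens are appended, staggered against the ring C-C bonds via a
    deterministic azimuth reference.
    """
    u = _unit(coords[h_slot] - coords[ring_carbon])
    c_me = coords[ring_carbon] + _CC * u
    coords[h_slot] = c_me
    elements[h_slot] = "C"
    ref = _unit(coords[(ring_carbon + 1) % 6] - coords[ring_carbon])
    v = _unit(ref - (ref @ u) * u)
    w = np.cross(u, v)
    theta = np.deg2rad(109.47)
    for phi in np.deg2rad([60.0, 180.0, 300.0]):
        d = u * np.cos(theta) + (v * np.cos(phi) + w * np.sin(phi)) * np.sin(theta)
        coords = np.vstack([coords, c_me + _CH * d])
        elements.append("H")
        bonds.append((h_slot, len(elements) - 1, 1.0))
    return coords, elements, bonds


def _dimethyl_cyclohexane():
    """cis and trans 1,3-dimethylcyclohexane on the analytic chair.

    _ring_with_hydrogens appends (axial, equatorial) H pairs per ring
    carbon: atom 6+2k is the axial and 7+2k the equatorial substituent of
    carbon k.  Methyls replace the substituent at carbons 0 and 2:
    cis = both equatorial (same face), trans = equatorial/axial.  An axial
    methyl sits in 1,3-diaxial contact with ring atoms, so the isomers
    differ strongly in their distance multisets (the gamma-gauche motif)
    while sharing one bond list.
    """

    def build(second_slot):
        coords, elements, bonds = _ring_with_hydrogens(_chair_ring())
        elements = list(elements)
        if second_slot == 10:  # axial: swap so the methyl lands in slot 11
            coords[[10, 11]] = coords[[11, 10]]
        coords, elements, bonds = _grow_methyl(coords, elements, bonds, 0, 7)
        coords, elements, bonds = _grow_methyl(coords, elements, bonds, 2, 11)
        return coords, elements, bonds

    cis, els, bonds = build(second_slot=11)  # eq, eq
    trans, _, _ = build(second_slot=10)  # eq, ax
    mol = Molecule(
        id="dimethyl_cyclohexane",
        elements=els,
        bonds=bonds,
        formal_charges=[0] * len(els),
        stereo_defined=[True, True],
    )
    return mol, [
        Conformer("dimethyl_cyclohexane", cis),
        Conformer("dimethyl_cyclohexane", trans),
    ]


def make_fixture(name: str) -> tuple[Molecule, list[Conformer]]:
    """Return one named fixture molecule with its conformer set.

    Pairs (anti/gauche, chair/boat, cis/trans) are returned as two
    conformers of a single molecule: identical elements and bond lists,
    different interatomic-distance multisets.
    """
    if name == "methane":
        return _methane()
    if name == "butane_anti_gauche":
        mol = Molecule(
            id="butane",
            elements=list(_BUTANE_ELEMENTS),
            bonds=list(_BUTANE_BONDS),
            formal_charges=[0] * 14,
        )
        return mol, [Conformer("butane", _BUTANE_ANTI), Conformer("butane", _BUTANE_GAUCHE)]
    if name == "cyclohexane_chair_boat":
        return _cyclohexane()
    if name == "cis_trans_disub_cyclohexane":
        return _dimethyl_cyclohexane()
    if name == "valine_like":
        mol = Molecule(
            id="valine_like",
            elements=list(_VALINE_ELEMENTS),
            bonds=list(_VALINE_BONDS),
            formal_charges=[0] * 19,
            stereo_defined=[True],
        )
        return mol, [Conformer("valine_like", _VALINE_COORDS)]
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def all_fixtures() -> list[tuple[Molecule, list[Conformer]]]:
    return [make_fixture(n) for n in FIXTURE_NAMES]


# ---------------------------------------------------------------------------
# oracle labels


@dataclass(frozen=True)
class OracleParams:
    """Parameters of the geometry-sensitive oracle shift function.

    ``base`` is the isolated-atom shift b_Z per element (ppm); ``coeff``
    the per-element neighbor contribution c_Z (ppm); ``decay`` the
    exponential decay length λ (angstroms); ``cutoff`` the neighbor cutoff,
    which should match the model's graph cutoff so the labels are exactly
    representable from the graph.
    """

    base: dict = field(
        default_factory=lambda: {
            "C": 100.0, "H": 5.0, "N": 150.0, "O": 250.0,
            "F": 180.0, "Cl": 50.0, "P": 120.0, "S": 90.0,
        }
    )
    coeff: dict = field(default_factory=lambda: dict.fromkeys("CHNOFPS", 10.0) | {"Cl": 10.0})
    decay: float = 1.5
    cutoff: float = 5.0

    def __post_init__(self):
        if self.decay <= 0 or self.cutoff <= 0:
            raise ValueError("decay and cutoff must be positive")


def oracle_shifts(
    conf: Conformer,
    mol: Molecule,
    params: OracleParams = OracleParams(),
    nucleus: str | None = None,
) -> list[ShiftRecord]:
    """Geometry-dependent stand-in labels, provenance ``computed``.

    δ_i = b_Z(i) + Σ_{j≠i, d_ij<cutoff} c_Z(j)·exp(−d_ij/λ).  Depends on
    the geometry only through distances, hence rigid-motion invariant.
    If ``nucleus`` is given, only atoms of that nucleus are labelled.
    """
    conf.validate(mol)
    d = np.linalg.norm(conf.coords[:, None] - conf.coords[None, :], axis=-1)
    c = np.array([params.coeff[e] for e in mol.elements])
    contrib = np.where(
        (d > 0) & (d < params.cutoff), c[None, :] * np.exp(-d / params.decay), 0.0
    )
    shifts = np.array([params.base[e] for e in mol.elements]) + contrib.sum(axis=1)
    want = {"H1": "H", "C13": "C"}.get(nucleus) if nucleus else None
    out = []
    for i, (elem, delta) in enumerate(zip(mol.elements, shifts)):
        if elem not in ("H", "C"):
            continue
        if want is not None and elem != want:
            continue
        nuc = "H1" if elem == "H" else "C13"
        out.append(ShiftRecord(mol.id, i, nuc, float(delta), "computed"))
    return out


def perturbed_conformer_set(
    n: int,
    seed: int,
    jitter: float = 0.1,
    fixture_names: tuple = FIXTURE_NAMES,
) -> list[tuple[Molecule, Conformer]]:
    """Geometry-diverse training pool built from the fixtures.

    Cycles round-robin over every fixture conformer; each sample gets
    isotropic Gaussian coordinate jitter (std ``jitter`` angstroms) plus a
    random rigid motion, emulating the conformational spread of a real
    dataset while staying label-consistent via the oracle.
    """
    rng = np.random.default_rng(seed)
    pool = []
    for name in fixture_names:
        mol, confs = make_fixture(name)
        pool.extend((mol, c) for c in confs)
    out = []
    for k in range(n):
        mol, conf = pool[k % len(pool)]
        coords = conf.coords + rng.normal(0.0, jitter, conf.coords.shape)
        coords = coords @ _random_rotation(rng).T + rng.normal(0.0, 5.0, 3)
        out.append((mol, Conformer(mol.id, coords, source="user")))
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


# ---------------------------------------------------------------------------
# contaminated paired datasets


@dataclass
class ContaminatedPairs:
    """Paired computed/experimental records with known planted outliers."""

    computed: list[ShiftRecord]
    experimental: list[ShiftRecord]
    planted_outliers: np.ndarray  # indices into the pair list

    def __len__(self):
        return len(self.computed)


def make_contaminated_pairs(
    n: int,
    sigma: float = 2.0,
    outlier_frac: float = 0.05,
    outlier_mag: float = 15.0,
    seed: int = 0,
    nucleus: str = "C13",
) -> ContaminatedPairs:
    """Computed-vs-experimental pairs whose differences are Normal(0, sigma)
    except for a planted fraction displaced by ±outlier_mag."""
    if not 0 <= outlier_frac < 0.5:
        raise ValueError("outlier_frac must be in [0, 0.5)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.0, 200.0 if nucleus == "C13" else 10.0, n)
    diffs = rng.normal(0.0, sigma, n)
    n_out = int(round(n * outlier_frac))
    planted = rng.choice(n, size=n_out, replace=False)
    diffs[planted] += rng.choice([-1.0, 1.0], size=n_out) * outlier_mag
    computed, experimental = [], []
    for i in range(n):
        mid = f"syn{i:06d}"
        experimental.append(ShiftRecord(mid, 0, nucleus, float(base[i]), "experimental"))
        computed.append(ShiftRecord(mid, 0, nucleus, float(base[i] + diffs[i]), "computed"))
    return ContaminatedPairs(computed, experimental, np.sort(planted))
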