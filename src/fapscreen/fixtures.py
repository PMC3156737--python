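"""Synthetic data: toy molecules, simulated conformer ensembles, screening sets.

Everything downstream of conformer generation can be exercised without a
conformer generator: ensembles are simulated either at the coordinate level
(torsion-sampled alkane chains, a rigid benzene) or directly at the
distance-profile level, where each flexible pair's distances are drawn from a
*planted* Gaussian mixture.  Planted structure gives parameter-recovery tests
a known ground truth, and synthetic screening sets give the metric pipeline a
known-direction answer (actives are perturbed copies of chemotype
prototypes, decoys are unrelated random molecules).

All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemgraph import AtomLabel, MoleculeGraph, classify_all_pairs, parse_molecule
from .encoder import EncodedMolecule, PairPayload, build_encoded
from .ensemble import (
    BoltzmannConfig,
    ConformerEnsemble,
    DistanceProfile,
    boltzmann_weights,
)
from .gmmfit import GaussianComponent, Gmm1D

#: mixture spec for one flexible pair: [(weight, mean A, variance A^2), ...]
PlantedMixture = List[Tuple[float, float, float]]

TEMPLATES = {
    "benzene": "c1ccccc1",
    # heterocycle-amide-acid toy scaffold (furan carboxamide propanoic acid)
    "heteroamide": "c1ccoc1C(=O)NCCC(=O)O",
}


def template_graph(template: str, name: Optional[str] = None) -> MoleculeGraph:
    """Topology of a built-in template ('chain:K', 'benzene', 'heteroamide') or SMILES."""
    if template.startswith("chain:"):
        k = int(template.split(":", 1)[1])
        if k < 1:
            raise ValueError("chain length must be >= 1")
        smiles = "C" * k
    else:
        smiles = TEMPLATES.get(template, template)
    return parse_molecule(smiles, name=name or template)


@dataclass
class EnsembleSpec:
    """Recipe for one simulated conformer ensemble.

    ``planted`` maps flexible pairs (i, j) to generating mixtures; pairs left
    unspecified get a deterministic default (one component per internal
    rotatable bond, means spread 2.5 A apart from 3 A, variance 0.09 A^2,
    equal weights).  The conformer energy is a stated function of the sampled
    distances: E_n = energy_coupling * sum of pair distances + seeded Gaussian
    noise of scale ``energy_noise`` (defaults zero: an equal-energy ensemble).
    """

    template: str = "chain:5"
    n_conformers: int = 200
    planted: Dict[Tuple[int, int], PlantedMixture] = field(default_factory=dict)
    energy_coupling: float = 0.0
    energy_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("need at least one conformer")


def default_planted(n_internal_rotatable: int) -> PlantedMixture:
    c = n_internal_rotatable
    return [(1.0 / c, 3.0 + 2.5 * k, 0.09) for k in range(c)]


def planted_to_gmm(mixture: PlantedMixture) -> Gmm1D:
    return Gmm1D([GaussianComponent(w, m, v) for w, m, v in mixture])


def _sample_mixture(rng: np.random.Generator, mixture: PlantedMixture, n: int) -> np.ndarray:
    weights = np.array([w for w, _, _ in mixture])
    weights = weights / weights.sum()
    comp = rng.choice(len(mixture), size=n, p=weights)
    means = np.array([m for _, m, _ in mixture])
    sds = np.sqrt([v for _, _, v in mixture])
    x = rng.normal(means[comp], sds[comp])
    return np.abs(x) + 1e-9  # distances must stay positive


def simulate_profiles(
    spec: EnsembleSpec, config: BoltzmannConfig = BoltzmannConfig()
) -> Tuple[MoleculeGraph, List[DistanceProfile]]:
    """Direct mode: distance profiles drawn exactly from the planted mixtures.

    Returns the template topology and one profile per flexible pair; all
    profiles share the per-conformer energies (and hence Boltzmann weights)
    computed from the spec's energy model.
    """
    rng = np.random.default_rng(spec.seed)
    graph = template_graph(spec.template)
    pair_classes = classify_all_pairs(graph)
    flexible = {p: c for p, c in pair_classes.items() if c.kind == "flexible"}
    samples = {
        pair: _sample_mixture(
            rng,
            spec.planted.get(pair, default_planted(cls.n_internal_rotatable)),
            spec.n_conformers,
        )
        for pair, cls in flexible.items()
    }
    energies = np.zeros(spec.n_conformers)
    if samples and spec.energy_coupling != 0.0:
        energies = spec.energy_coupling * np.sum(list(samples.values()), axis=0)
    if spec.energy_noise > 0.0:
        energies = energies + spec.energy_noise * rng.standard_normal(spec.n_conformers)
    weights = boltzmann_weights(energies, config)
    profiles = [
        DistanceProfile(
            pair=pair,
            samples=samples[pair],
            weights=weights,
            n_internal_rotatable=flexible[pair].n_internal_rotatable,
        )
        for pair in sorted(samples)
    ]
    return graph, profiles


# -- coordinate mode ---------------------------------------------------------

_BOND_LENGTH = 1.54  # A, sp3 C-C
_BOND_ANGLE = math.radians(112.0)
_ROTAMERS = (math.pi, math.pi / 3.0, -math.pi / 3.0)  # trans, gauche+, gauche-


def _chain_coordinates(rng: np.random.Generator, k: int) -> np.ndarray:
    """One alkane-chain conformer with torsions drawn from noisy rotamer states."""
    coords = np.zeros((k, 3))
    if k > 1:
        coords[1] = (_BOND_LENGTH, 0.0, 0.0)
    if k > 2:
        coords[2] = coords[1] + _BOND_LENGTH * np.array(
            (math.cos(math.pi - _BOND_ANGLE), math.sin(math.pi - _BOND_ANGLE), 0.0)
        )
    for a in range(3, k):
        phi = rng.choice(_ROTAMERS) + rng.normal(0.0, math.radians(10.0))
        # natural extension reference frame from the previous three atoms
        b1 = coords[a - 2] - coords[a - 3]
        b2 = coords[a - 1] - coords[a - 2]
        n1 = np.cross(b1, b2)
        n1 /= np.linalg.norm(n1)
        u2 = b2 / np.linalg.norm(b2)
        m1 = np.cross(n1, u2)
        d = np.array(
            (
                -math.cos(_BOND_ANGLE),
                math.sin(_BOND_ANGLE) * math.cos(phi),
                math.sin(_BOND_ANGLE) * math.sin(phi),
            )
        )
        coords[a] = coords[a - 1] + _BOND_LENGTH * (d[0] * u2 + d[1] * m1 + d[2] * n1)
    return coords


def _benzene_coordinates(k: int = 6) -> np.ndarray:
    radius = 1.39
    angles = 2.0 * math.pi * np.arange(k) / k
    return np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(k)], axis=1
    )


def simulate_ensemble(spec: EnsembleSpec) -> ConformerEnsemble:
    """Coordinate mode: a seeded conformer ensemble for a geometric template.

    Chain templates get torsion-sampled conformers (fixed bond lengths and
    angles, noisy rotamer torsions); benzene gets identical planar conformers.
    Energies follow the spec's energy model on the summed flexible-pair
    distances.  Templates without a geometry builder fall back to the
    distance-profile path (:func:`simulate_profiles`) with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    graph = template_graph(spec.template)
    if spec.template.startswith("chain:"):
        k = graph.n_atoms
        coords = np.stack([_chain_coordinates(rng, k) for _ in range(spec.n_conformers)])
    elif spec.template == "benzene":
        coords = np.repeat(_benzene_coordinates()[None, :, :], spec.n_conformers, axis=0)
    else:
        warnings.warn(
            f"no geometry builder for template {spec.template!r}; "
            "use simulate_profiles (direct mode) for this topology",
            stacklevel=2,
        )
        raise ValueError(f"coordinate mode unsupported for template {spec.template!r}")
    flexible = [
        p for p, c in classify_all_pairs(graph).items() if c.kind == "flexible"
    ]
    energies = np.zeros(spec.n_conformers)
    if flexible and spec.energy_coupling != 0.0:
        dsum = np.zeros(spec.n_conformers)
        for (i, j) in flexible:
            dsum += np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=1)
        energies = spec.energy_coupling * dsum
    if spec.energy_noise > 0.0:
        energies = energies + spec.energy_noise * rng.standard_normal(spec.n_conformers)
    return ConformerEnsemble(molecule=graph, coordinates=coords, energies=energies)


# -- random encoded molecules and screening sets -----------------------------

_ELEMENTS = ("C", "N", "O", "S")


def _random_label(rng: np.random.Generator) -> AtomLabel:
    return AtomLabel(
        element=str(rng.choice(_ELEMENTS)),
        ring_flag=bool(rng.integers(2)),
        neighbor_score=int(rng.integers(-2, 4)),
    )


def _random_gmm(rng: np.random.Generator, max_components: int = 3) -> Gmm1D:
    c = int(rng.integers(1, max_components + 1))
    w = rng.dirichlet(np.ones(c))
    means = np.sort(rng.uniform(2.0, 12.0, size=c))
    variances = rng.uniform(0.05, 1.0, size=c)
    return Gmm1D(
        [GaussianComponent(float(wi), float(mi), float(vi)) for wi, mi, vi in zip(w, means, variances)]
    )


@dataclass
class SyntheticMolecule:
    """Pair-level intermediate form of a random molecule; perturbable, encodable."""

    name: str
    labels: List[AtomLabel]
    payloads: Dict[Tuple[int, int], PairPayload]

    def encode(self) -> EncodedMolecule:
        return build_encoded(self.name, list(self.labels), dict(self.payloads))


def random_synthetic_molecule(
    rng: np.random.Generator,
    n_atoms: Optional[int] = None,
    atoms_range: Tuple[int, int] = (3, 12),
    flexible_fraction: float = 0.4,
    name: str = "random",
) -> SyntheticMolecule:
    """A random label/payload molecule for similarity property tests.

    Adjacent-like pairs are kept rigid with small topological distances;
    remaining pairs turn flexible with probability ``flexible_fraction`` and
    get a random planted mixture.
    """
    if n_atoms is None:
        n_atoms = int(rng.integers(atoms_range[0], atoms_range[1] + 1))
    labels = [_random_label(rng) for _ in range(n_atoms)]
    payloads: Dict[Tuple[int, int], PairPayload] = {}
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            if j == i + 1 or rng.random() >= flexible_fraction:
                payloads[(i, j)] = ("rigid", int(rng.integers(1, 7)))
            else:
                payloads[(i, j)] = ("flexible", _random_gmm(rng))
    return SyntheticMolecule(name=name, labels=labels, payloads=payloads)


def random_encoded_molecule(
    rng: np.random.Generator,
    n_atoms: Optional[int] = None,
    atoms_range: Tuple[int, int] = (3, 12),
    flexible_fraction: float = 0.4,
    name: str = "random",
) -> EncodedMolecule:
    return random_synthetic_molecule(rng, n_atoms, atoms_range, flexible_fraction, name).encode()


def perturb_synthetic_molecule(
    mol: SyntheticMolecule,
    rng: np.random.Generator,
    mean_jitter: float = 0.25,
    label_edit_prob: float = 0.0,
    name: Optional[str] = None,
) -> SyntheticMolecule:
    """Perturbed copy: Gaussian jitter on mixture means, optional label edits."""
    labels = list(mol.labels)
    for k in range(len(labels)):
        if rng.random() < label_edit_prob:
            labels[k] = _random_label(rng)
    payloads: Dict[Tuple[int, int], PairPayload] = {}
    for pair, (kind, payload) in mol.payloads.items():
        if kind == "flexible" and mean_jitter > 0.0:
            shifted = Gmm1D(
                [
                    GaussianComponent(c.weight, c.mean + rng.normal(0.0, mean_jitter), c.variance)
                    for c in payload.components
                ]
            )
            payloads[pair] = ("flexible", shifted)
        else:
            payloads[pair] = (kind, payload)
    return SyntheticMolecule(name=name or mol.name, labels=labels, payloads=payloads)


def shift_family(
    rng: np.random.Generator,
    n_atoms: int = 6,
    deltas: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 4.0),
) -> List[EncodedMolecule]:
    """Copies of one molecule with every flexible-pair mean shifted by delta.

    Built so the similarity to the delta=0 reference is provably non-increasing
    in delta: all atom labels are distinct (no cross-leaf label matches) and
    every flexible model has a single component, making each leaf correlation
    exp(-delta^2 / (4 sigma^2)).
    """
    pool = [
        AtomLabel(e, r, s)
        for e in _ELEMENTS
        for r in (False, True)
        for s in range(-2, 4)
    ]
    idx = rng.choice(len(pool), size=n_atoms, replace=False)
    labels = [pool[int(k)] for k in idx]
    base: Dict[Tuple[int, int], Tuple[float, float]] = {}
    payloads: Dict[Tuple[int, int], PairPayload] = {}
    for i in range(n_atoms):
        for j in range(i + 1, n_atoms):
            if j == i + 1 or rng.random() < 0.3:
                payloads[(i, j)] = ("rigid", int(rng.integers(1, 7)))
            else:
                base[(i, j)] = (float(rng.uniform(3.0, 10.0)), float(rng.uniform(0.1, 0.6)))
    family = []
    for delta in deltas:
        shifted = dict(payloads)
        for pair, (mean, var) in base.items():
            shifted[pair] = ("flexible", Gmm1D([GaussianComponent(1.0, mean + delta, var)]))
        family.append(build_encoded(f"shift_{delta:g}", list(labels), shifted))
    return family


@dataclass
class ScreeningSpec:
    """Recipe for a synthetic screening benchmark with a planted ordering signal.

    One base molecule (the query ligand) spawns ``n_clusters`` chemotype
    prototypes (strong perturbations), each prototype spawns its share of
    actives (mild perturbations); decoys are unrelated random molecules.
    """

    n_actives: int = 30
    n_decoys: int = 300
    n_clusters: int = 5
    n_atoms: Tuple[int, int] = (5, 10)
    proto_jitter: float = 0.8
    proto_label_edit_prob: float = 0.1
    active_jitter: float = 0.25
    active_label_edit_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_clusters <= self.n_actives:
            raise ValueError("need 1 <= n_clusters <= n_actives")


@dataclass
class SyntheticScreen:
    """A generated benchmark: query, encoded library, activity and cluster tables."""

    query: EncodedMolecule
    library: List[EncodedMolecule]
    activity: pd.DataFrame  # columns: id, active
    clusters: pd.DataFrame  # columns: id, cluster


def make_screening_set(spec: ScreeningSpec) -> SyntheticScreen:
    """Generate a screening benchmark with known-direction signal.

    Actives inherit the query's labels and (jittered) mixtures, so they score
    high against the query; decoys have independent random labels, which the
    Dirac label comparison mostly scores zero.
    """
    rng = np.random.default_rng(spec.seed)
    base = random_synthetic_molecule(rng, atoms_range=spec.n_atoms, name="query")
    prototypes = [
        perturb_synthetic_molecule(
            base, rng, spec.proto_jitter, spec.proto_label_edit_prob, name=f"proto_{c}"
        )
        for c in range(spec.n_clusters)
    ]
    library: List[EncodedMolecule] = []
    activity_rows = []
    cluster_rows = []
    for k in range(spec.n_actives):
        c = k % spec.n_clusters
        active = perturb_synthetic_molecule(
            prototypes[c],
            rng,
            spec.active_jitter,
            spec.active_label_edit_prob,
            name=f"active_{k:04d}",
        )
        library.append(active.encode())
        activity_rows.append((active.name, 1))
        cluster_rows.append((active.name, f"chemotype_{c}"))
    for k in range(spec.n_decoys):
        decoy = random_synthetic_molecule(
            rng, atoms_range=spec.n_atoms, name=f"decoy_{k:04d}"
        )
        library.append(decoy.encode())
        activity_rows.append((decoy.name, 0))
    return SyntheticScreen(
        query=base.encode(),
        library=library,
        activity=pd.DataFrame(activity_rows, columns=["id", "active"]),
        clusters=pd.DataFrame(cluster_rows, columns=["id", "cluster"]),
    )
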