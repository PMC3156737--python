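"""Encoded molecules: per-atom atom-pair prefix trees over rigid and flexible leaves.

Encoding a conformer ensemble is the preprocessing step of the 4D flexible
atom-pair method: classify every heavy-atom pair as rigid or flexible, model
each flexible pair's distance profile as a Boltzmann-weighted Gaussian
mixture, and assemble per-root-atom prefix trees.  Afterwards the ensemble
itself is no longer needed — similarity calculations use only the molecular
graph labels, the rigid pairs' topological distances, and the mixture
parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chemgraph import AtomLabel, classify_all_pairs, molecule_labels
from .ensemble import BoltzmannConfig, ConformerEnsemble, DistanceProfile, extract_profiles
from .gmmfit import BoltzmannGMM, EmConfig, GaussianComponent, Gmm1D, n_components_heuristic

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RigidLeaf:
    """A rigid pair seen from one root atom: partner label + topological distance."""

    leaf_label: AtomLabel
    topo_distance: int


@dataclass(frozen=True)
class FlexibleLeaf:
    """A flexible pair seen from one root atom: partner label + distance mixture."""

    leaf_label: AtomLabel
    model: Gmm1D


@dataclass
class AtomPairTree:
    """Prefix tree rooted at one heavy atom.

    Holds one leaf per remaining atom of the molecule, split into the rigid
    sub-tree R (labels + topological distances) and the flexible sub-tree F
    (labels + Gaussian mixtures).
    """

    root_index: int
    root_label: AtomLabel
    rigid: List[RigidLeaf] = field(default_factory=list)
    flexible: List[FlexibleLeaf] = field(default_factory=list)


@dataclass
class EncodedMolecule:
    """A fully preprocessed molecule: labels, one tree per atom, and metadata."""

    name: str
    labels: List[AtomLabel]
    trees: List[AtomPairTree]
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.labels)


def config_digest(em_config: EmConfig, boltzmann_config: BoltzmannConfig) -> str:
    """Short stable digest of every configuration value that affects an encoding."""
    payload = json.dumps(
        {
            "em": [
                em_config.max_iterations,
                em_config.tolerance,
                em_config.restarts,
                em_config.seed,
                em_config.variance_floor,
                em_config.c_max,
            ],
            "boltzmann": [
                boltzmann_config.temperature,
                boltzmann_config.gas_constant,
                boltzmann_config.uniform_weights,
            ],
            "schema": SCHEMA_VERSION,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _pair_seed(base_seed: int, i: int, j: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, i, j])


def _fit_pair_model(profile: DistanceProfile, em_config: EmConfig) -> Gmm1D:
    # canonical order: sort samples (weights paired) so conformer file order
    # cannot change the fit
    order = np.lexsort((profile.weights, profile.samples))
    samples = profile.samples[order]
    weights = profile.weights[order]
    n_comp = n_components_heuristic(
        profile.n_internal_rotatable, samples.size, em_config.c_max
    )
    i, j = profile.pair
    est = BoltzmannGMM(
        n_components=n_comp,
        max_iter=em_config.max_iterations,
        tol=em_config.tolerance,
        n_init=em_config.restarts,
        random_state=_pair_seed(em_config.seed, i, j),
        variance_floor=em_config.variance_floor,
    )
    est.fit(samples, sample_weight=weights)
    return est.to_mixture()


PairPayload = Tuple[str, object]  # ("rigid", topo_distance) or ("flexible", Gmm1D)


def build_encoded(
    name: str,
    labels: List[AtomLabel],
    pair_payloads: Dict[Tuple[int, int], PairPayload],
    metadata: Optional[Dict[str, object]] = None,
) -> EncodedMolecule:
    """Assemble an EncodedMolecule from per-pair payloads.

    ``pair_payloads`` maps every unordered pair (i < j) to either
    ``("rigid", topological_distance)`` or ``("flexible", Gmm1D)``.  Each pair
    becomes a leaf in the trees of both endpoints, the flexible model being
    shared.  Used by the encoding pipeline and by synthetic-molecule builders.
    """
    n = len(labels)
    expected = n * (n - 1) // 2
    if len(pair_payloads) != expected:
        raise ValueError(f"expected {expected} pair payloads, got {len(pair_payloads)}")
    trees = [AtomPairTree(root_index=i, root_label=labels[i]) for i in range(n)]
    for (i, j), (kind, payload) in pair_payloads.items():
        if kind == "rigid":
            trees[i].rigid.append(RigidLeaf(labels[j], int(payload)))
            trees[j].rigid.append(RigidLeaf(labels[i], int(payload)))
        elif kind == "flexible":
            trees[i].flexible.append(FlexibleLeaf(labels[j], payload))
            trees[j].flexible.append(FlexibleLeaf(labels[i], payload))
        else:
            raise ValueError(f"unknown payload kind {kind!r}")
    return EncodedMolecule(name=name, labels=labels, trees=trees, metadata=metadata or {})


def encode_molecule(
    ensemble: ConformerEnsemble,
    em_config: EmConfig = EmConfig(),
    boltzmann_config: BoltzmannConfig = BoltzmannConfig(),
) -> EncodedMolecule:
    """Encode one conformer ensemble into atom-pair prefix trees.

    Pipeline: classify all pairs, extract flexible-pair distance profiles with
    Boltzmann weights, fit one mixture per unordered flexible pair (shared by
    the trees of both endpoints), and assemble one tree per heavy atom.
    """
    graph = ensemble.molecule
    labels = molecule_labels(graph)
    pair_classes = classify_all_pairs(graph)
    profiles = {p.pair: p for p in extract_profiles(ensemble, pair_classes, boltzmann_config)}

    payloads: Dict[Tuple[int, int], PairPayload] = {}
    for pair, cls in pair_classes.items():
        if cls.kind == "rigid":
            payloads[pair] = ("rigid", cls.topo_distance)
        else:
            payloads[pair] = ("flexible", _fit_pair_model(profiles[pair], em_config))

    return build_encoded(
        name=graph.name,
        labels=labels,
        pair_payloads=payloads,
        metadata={
            "temperature": boltzmann_config.temperature,
            "config_digest": config_digest(em_config, boltzmann_config),
            "schema_version": SCHEMA_VERSION,
        },
    )


class MoleculeEncoder(BaseEstimator, TransformerMixin):
    """Transformer from conformer ensembles to encoded molecules.

    Stateless apart from its configuration; ``fit`` records the configuration
    digest, ``transform`` maps a sequence of :class:`ConformerEnsemble` to a
    list of :class:`EncodedMolecule`.
    """

    def __init__(
        self,
        temperature: float = 300.0,
        gas_constant: float = 1.9872041e-3,
        uniform_weights: bool = False,
        max_iterations: int = 200,
        tolerance: float = 1e-6,
        restarts: int = 3,
        seed: int = 0,
        variance_floor: float = 1e-4,
        c_max: Optional[int] = None,
    ):
        self.temperature = temperature
        self.gas_constant = gas_constant
        self.uniform_weights = uniform_weights
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.restarts = restarts
        self.seed = seed
        self.variance_floor = variance_floor
        self.c_max = c_max

    def _configs(self) -> Tuple[EmConfig, BoltzmannConfig]:
        em = EmConfig(
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            restarts=self.restarts,
            seed=self.seed,
            variance_floor=self.variance_floor,
            c_max=self.c_max,
        )
        boltz = BoltzmannConfig(
            temperature=self.temperature,
            gas_constant=self.gas_constant,
            uniform_weights=self.uniform_weights,
        )
        return em, boltz

    def fit(self, X=None, y=None) -> "MoleculeEncoder":
        em, boltz = self._configs()
        self.config_digest_ = config_digest(em, boltz)
        return self

    def transform(self, X: Iterable[ConformerEnsemble]) -> List[EncodedMolecule]:
        em, boltz = self._configs()
        return [encode_molecule(ens, em, boltz) for ens in X]


# ---------------------------------------------------------------------------
# JSON-lines serialization


class EncodedFileError(ValueError):
    pass


def _label_to_json(l: AtomLabel) -> list:
    return [l.element, l.ring_flag, l.neighbor_score]


def _label_from_json(v: list) -> AtomLabel:
    return AtomLabel(v[0], bool(v[1]), int(v[2]))


def _molecule_to_json(mol: EncodedMolecule) -> dict:
    return {
        "schema": "molecule",
        "name": mol.name,
        "labels": [_label_to_json(l) for l in mol.labels],
        "trees": [
            {
                "root": t.root_index,
                "rigid": [[_label_to_json(l.leaf_label), l.topo_distance] for l in t.rigid],
                "flexible": [
                    [
                        _label_to_json(l.leaf_label),
                        [[c.weight, c.mean, c.variance] for c in l.model.components],
                    ]
                    for l in t.flexible
                ],
            }
            for t in mol.trees
        ],
        "metadata": mol.metadata,
    }


def _molecule_from_json(obj: dict) -> EncodedMolecule:
    labels = [_label_from_json(v) for v in obj["labels"]]
    trees = []
    for t in obj["trees"]:
        root = int(t["root"])
        tree = AtomPairTree(root_index=root, root_label=labels[root])
        for lab, dist in t["rigid"]:
            tree.rigid.append(RigidLeaf(_label_from_json(lab), int(dist)))
        for lab, comps in t["flexible"]:
            model = Gmm1D([GaussianComponent(w, m, v) for w, m, v in comps])
            tree.flexible.append(FlexibleLeaf(_label_from_json(lab), model))
        trees.append(tree)
    return EncodedMolecule(
        name=obj["name"], labels=labels, trees=trees, metadata=obj.get("metadata", {})
    )


def save_encoded(molecules: Iterable[EncodedMolecule], path: str) -> None:
    """Write encoded molecules as JSON lines (schema header + one molecule per line).

    Floats are serialized at full precision (repr round-trip), so a save/load
    cycle reproduces similarity scores bit-for-bit and a second save is
    byte-identical.
    """
    with open(path, "w") as fh:
        fh.write(json.dumps({"schema": "fap-encoded", "version": SCHEMA_VERSION}) + "\n")
        for mol in molecules:
            fh.write(json.dumps(_molecule_to_json(mol), sort_keys=True) + "\n")


def load_encoded(path: str) -> List[EncodedMolecule]:
    """Read a JSON-lines file written by :func:`save_encoded`."""
    molecules: List[EncodedMolecule] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return []
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise EncodedFileError(f"line 1: not valid JSON ({exc})") from exc
    if header.get("schema") != "fap-encoded":
        raise EncodedFileError("missing fap-encoded schema header")
    if header.get("version") != SCHEMA_VERSION:
        raise EncodedFileError(
            f"schema version {header.get('version')} unsupported (expected {SCHEMA_VERSION})"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise EncodedFileError(f"line {lineno}: truncated or invalid JSON") from exc
        molecules.append(_molecule_from_json(obj))
    return molecules
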