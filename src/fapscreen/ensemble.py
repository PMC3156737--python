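"""Conformer ensembles, Boltzmann conformer weighting, and distance profiles.

A conformer ensemble holds the sampled 3D structures of one molecule together
with a per-conformer energy.  Each flexible atom pair contributes a *distance
profile*: its Euclidean distance in every conformer, paired with normalized
Boltzmann probabilities p(E_n) = exp(-dE_n/RT) / sum_m exp(-dE_m/RT), where
dE_n is the energy offset of conformer n from the ensemble minimum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from rdkit import Chem

from .chemgraph import MoleculeGraph, PairClass, mol_to_graph

#: gas constant in kcal / (mol K)
R_KCAL = 1.9872041e-3


@dataclass(frozen=True)
class BoltzmannConfig:
    """Canonical-ensemble weighting parameters.

    ``gas_constant`` must be expressed in the same energy unit per (mol K) as
    the conformer energies; the default pairs kcal/mol energies with
    R = 1.9872041e-3 kcal/(mol K).  ``uniform_weights=True`` disables the
    weighting entirely (every conformer gets 1/N).
    """

    temperature: float = 300.0
    gas_constant: float = R_KCAL
    uniform_weights: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.gas_constant <= 0:
            raise ValueError("temperature and gas_constant must be positive")


@dataclass
class ConformerEnsemble:
    """One molecule plus >= 1 conformers (coordinates in A, energies)."""

    molecule: MoleculeGraph
    coordinates: np.ndarray  # (n_conformers, n_atoms, 3)
    energies: np.ndarray  # (n_conformers,)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_conf, n_atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("an ensemble needs at least one conformer")
        if self.coordinates.shape[1] != self.molecule.n_atoms:
            raise ValueError(
                f"conformers have {self.coordinates.shape[1]} atoms, "
                f"molecule has {self.molecule.n_atoms}"
            )
        if self.energies.shape != (self.coordinates.shape[0],):
            raise ValueError("one energy per conformer required")

    @property
    def n_conformers(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class DistanceProfile:
    """Distance samples of one flexible atom pair across an ensemble."""

    pair: Tuple[int, int]
    samples: np.ndarray  # (n_conformers,), A
    weights: np.ndarray  # (n_conformers,), sum to 1
    n_internal_rotatable: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.samples.shape != self.weights.shape or self.samples.ndim != 1:
            raise ValueError("samples and weights must be 1-D and equally long")
        if self.samples.size == 0:
            raise ValueError("empty profile")
        if np.any(self.samples <= 0):
            raise ValueError("distances must be positive")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")


def boltzmann_weights(
    energies: Sequence[float], config: BoltzmannConfig = BoltzmannConfig()
) -> np.ndarray:
    """Normalized Boltzmann probabilities of a set of conformer energies.

    p_n = exp(-dE_n / RT) / sum_m exp(-dE_m / RT), dE_n = E_n - min(E).
    Subtracting the minimum first makes the exponentials overflow-safe and
    leaves the result invariant to any constant energy shift.
    """
    e = np.asarray(energies, dtype=float)
    if e.size < 1:
        raise ValueError("need at least one energy")
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite energy value")
    if config.uniform_weights:
        return np.full(e.shape, 1.0 / e.size)
    beta = 1.0 / (config.gas_constant * config.temperature)
    shifted = np.exp(-beta * (e - e.min()))
    return shifted / shifted.sum()


def extract_profiles(
    ensemble: ConformerEnsemble,
    pair_classes: Dict[Tuple[int, int], PairClass],
    config: BoltzmannConfig = BoltzmannConfig(),
) -> List[DistanceProfile]:
    """Distance profiles of every flexible pair of an ensemble.

    Rigid pairs get no profile: only flexible pairs are modeled, the rigid
    class keeps its topological distance instead.
    """
    weights = boltzmann_weights(ensemble.energies, config)
    profiles = []
    for (i, j), cls in pair_classes.items():
        if cls.kind != "flexible":
            continue
        d = np.linalg.norm(
            ensemble.coordinates[:, i, :] - ensemble.coordinates[:, j, :], axis=1
        )
        profiles.append(
            DistanceProfile(
                pair=(i, j),
                samples=d,
                weights=weights,
                n_internal_rotatable=cls.n_internal_rotatable,
            )
        )
    return profiles


def profile_histogram(
    profile: DistanceProfile, bin_width: float, weighted: bool = True
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of a distance profile (visualization aid).

    Returns (bin_edges, relative_frequencies) with frequencies summing to 1.
    The weighted variant uses the Boltzmann probabilities as masses, the
    unweighted one gives each conformer 1/N.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(profile.samples.min() / bin_width) * bin_width
    hi = np.ceil(profile.samples.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    w = profile.weights if weighted else np.full(profile.samples.size, 1.0 / profile.samples.size)
    counts, edges = np.histogram(profile.samples, bins=edges, weights=w)
    return edges, counts / counts.sum()


class SdfFormatError(ValueError):
    """Raised on malformed multi-conformer SDF input."""


def _topology_key(graph: MoleculeGraph) -> tuple:
    return (
        tuple((a.element, a.n_heavy_neighbors, a.n_hydrogens, a.in_ring) for a in graph.atoms),
        tuple((b.i, b.j, b.order) for b in graph.bonds),
    )


def read_ensembles(
    source: Union[str, io.IOBase],
    energy_tag: str = "energy",
    grouping: str = "title",
) -> List[ConformerEnsemble]:
    """Read multi-conformer ensembles from an SDF V2000 file or stream.

    One SDF record per conformer; the conformer energy is read from the named
    property tag.  Records are grouped into ensembles either by identical
    title (``grouping="title"``) or by consecutive runs of identical heavy-atom
    topology (``grouping="consecutive"``).  All records of a group must share
    the same heavy-atom graph.
    """
    if grouping not in ("title", "consecutive"):
        raise ValueError("grouping must be 'title' or 'consecutive'")
    if isinstance(source, str):
        supplier = Chem.SDMolSupplier(source, removeHs=True)
    else:
        data = source.read()
        if isinstance(data, str):
            data = data.encode()
        supplier = Chem.ForwardSDMolSupplier(io.BytesIO(data), removeHs=True)

    records: List[Tuple[str, MoleculeGraph, np.ndarray, float]] = []
    for idx, mol in enumerate(supplier, start=1):
        if mol is None:
            raise SdfFormatError(f"record {idx} failed to parse")
        if not mol.HasProp(energy_tag):
            raise SdfFormatError(f"energy tag {energy_tag!r} absent in record {idx}")
        try:
            energy = float(mol.GetProp(energy_tag))
        except ValueError as exc:
            raise SdfFormatError(f"energy tag in record {idx} is not numeric") from exc
        graph = mol_to_graph(mol)
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(k)) for k in range(mol.GetNumAtoms())], dtype=float
        )
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{idx}"
        records.append((title, graph, coords, energy))

    groups: List[List[Tuple[str, MoleculeGraph, np.ndarray, float]]] = []
    if grouping == "title":
        by_title: Dict[str, List] = {}
        order: List[str] = []
        for rec in records:
            if rec[0] not in by_title:
                by_title[rec[0]] = []
                order.append(rec[0])
            by_title[rec[0]].append(rec)
        groups = [by_title[t] for t in order]
    else:
        for rec in records:
            if groups and _topology_key(groups[-1][0][1]) == _topology_key(rec[1]):
                groups[-1].append(rec)
            else:
                groups.append([rec])

    ensembles = []
    for group in groups:
        key0 = _topology_key(group[0][1])
        for title, graph, _, _ in group[1:]:
            if _topology_key(graph) != key0:
                raise SdfFormatError(
                    f"topology mismatch within ensemble {group[0][0]!r} (record titled {title!r})"
                )
        graph = group[0][1]
        if not graph.name:
            graph.name = group[0][0]
        ensembles.append(
            ConformerEnsemble(
                molecule=graph,
                coordinates=np.stack([c for _, _, c, _ in group]),
                energies=np.array([e for _, _, _, e in group]),
            )
        )
    return ensembles


def write_ensembles(
    ensembles: Iterable[ConformerEnsemble], path: str, energy_tag: str = "energy"
) -> None:
    """Write ensembles as a multi-record SDF (one record per conformer)."""
    with open(path, "w") as fh:
        writer = Chem.SDWriter(fh)
        writer.SetKekulize(False)
        for ens in ensembles:
            mol = _graph_to_rwmol(ens.molecule)
            for k in range(ens.n_conformers):
                conf = Chem.Conformer(mol.GetNumAtoms())
                for a in range(mol.GetNumAtoms()):
                    conf.SetAtomPosition(a, ens.coordinates[k, a, :].tolist())
                m = Chem.Mol(mol)
                m.RemoveAllConformers()
                m.AddConformer(conf)
                m.SetProp("_Name", ens.molecule.name or "mol")
                m.SetProp(energy_tag, repr(float(ens.energies[k])))
                writer.write(m)
        writer.close()


_ORDER_TO_RDKIT = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}


def _graph_to_rwmol(graph: MoleculeGraph) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in graph.atoms:
        atom = Chem.Atom(a.element)
        atom.SetNumExplicitHs(a.n_hydrogens)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for b in graph.bonds:
        rw.AddBond(b.i, b.j, _ORDER_TO_RDKIT[b.order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS, catchErrors=True)
    mol.UpdatePropertyCache(strict=False)
    return mol
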