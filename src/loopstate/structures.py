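"""Atomic structure containers and PDB/mmCIF I/O.

Parsing and writing are delegated to gemmi; this module flattens structures
into per-atom numpy arrays, which is the shape every geometry statistic in
:mod:`loopstate.geometry` consumes.  Multi-model files (MODEL/ENDMDL or
multi-block ensembles) become :class:`Ensemble` objects whose conformations
share one topology.

Conventions: coordinates in angstroms; author residue numbering as
deposited (1-based); alternate locations resolved to the highest-occupancy
conformer, ties broken alphabetically by altloc id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "StructureModel",
    "Ensemble",
    "AtomSelection",
    "read_structure",
    "write_structure",
]

_HYDROGEN = ("H", "D")


class StructureError(ValueError):
    """Raised for invalid structures or selections."""


@dataclass
class StructureModel:
    """One conformation: parallel per-atom arrays.

    All arrays have length ``n_atoms``; ``coords`` is (n_atoms, 3) in A.
    """

    chain: np.ndarray  # str
    resid: np.ndarray  # int, author numbering
    resname: np.ndarray  # str
    atom_name: np.ndarray  # str
    element: np.ndarray  # str
    coords: np.ndarray  # float (N, 3)
    occupancy: np.ndarray  # float
    name: str = "model"

    def __post_init__(self) -> None:
        n = len(self.chain)
        for arr in (self.resid, self.resname, self.atom_name, self.element,
                    self.occupancy):
            if len(arr) != n:
                raise StructureError("per-atom arrays must have equal length")
        self.coords = np.asarray(self.coords, float)
        if self.coords.shape != (n, 3) or not np.isfinite(self.coords).all():
            raise StructureError("coords must be finite with shape (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(str(c), None)
        return list(seen)

    def topology_key(self) -> tuple:
        return (
            tuple(self.chain.tolist()),
            tuple(int(r) for r in self.resid),
            tuple(self.atom_name.tolist()),
        )

    def mask(
        self,
        chains=None,
        residues=None,
        atom_names=None,
        exclude_hydrogens: bool = False,
    ) -> np.ndarray:
        """Boolean mask over atoms; ``residues`` accepts ints, iterables or
        (first, last) ranges."""
        m = np.ones(self.n_atoms, bool)
        if chains is not None:
            if isinstance(chains, str):
                chains = [chains]
            m &= np.isin(self.chain, list(chains))
        if residues is not None:
            m &= np.isin(self.resid, _residue_list(residues))
        if atom_names is not None:
            if isinstance(atom_names, str):
                atom_names = [atom_names]
            m &= np.isin(self.atom_name, list(atom_names))
        if exclude_hydrogens:
            m &= ~np.isin(self.element, _HYDROGEN)
        return m

    def with_coords(self, coords: np.ndarray, name: str | None = None
                    ) -> "StructureModel":
        return StructureModel(
            chain=self.chain,
            resid=self.resid,
            resname=self.resname,
            atom_name=self.atom_name,
            element=self.element,
            coords=np.asarray(coords, float),
            occupancy=self.occupancy,
            name=name or self.name,
        )


def _residue_list(residues) -> list[int]:
    if isinstance(residues, (int, np.integer)):
        return [int(residues)]
    residues = list(residues)
    if (
        len(residues) == 2
        and all(isinstance(r, (int, np.integer)) for r in residues)
        and isinstance(residues, tuple)
    ):
        pass  # a 2-list is a list of ids; only explicit range objects expand
    return [int(r) for r in residues]


@dataclass
class Ensemble:
    """Ordered conformations sharing chain/residue/atom topology."""

    topology: StructureModel
    coords: np.ndarray  # (n_models, n_atoms, 3)
    label: str = "ensemble"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 2:
            raise StructureError("ensemble needs >= 2 conformations")
        if self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise StructureError("coords do not match topology atom count")

    @property
    def n_conformations(self) -> int:
        return self.coords.shape[0]

    def conformation(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.coords[i], name=f"model_{i + 1}")

    def __iter__(self):
        return (self.conformation(i) for i in range(self.n_conformations))


@dataclass(frozen=True)
class AtomSelection:
    """Set of (chain, residues, atom-name filter) triples.

    ``spec`` strings use the mini-language ``chain:first-last[:atom]``, e.g.
    ``"A:1-20:CA"`` or ``"G:289-312"``; several comma-separated terms may be
    given.  Resolution against a topology is deterministic (file atom order).
    """

    terms: tuple = ()

    @classmethod
    def parse(cls, spec: str) -> "AtomSelection":
        terms = []
        for part in spec.split(","):
            bits = part.strip().split(":")
            if len(bits) not in (2, 3) or not bits[0]:
                raise StructureError(f"bad selection term {part!r}")
            chain = bits[0]
            lo, _, hi = bits[1].partition("-")
            residues = tuple(range(int(lo), int(hi or lo) + 1))
            atom = bits[2] if len(bits) == 3 else None
            terms.append((chain, residues, atom))
        return cls(terms=tuple(terms))

    @classmethod
    def of(cls, chain, residues=None, atom=None) -> "AtomSelection":
        if isinstance(residues, (int, np.integer)):
            residues = (int(residues),)
        return cls(terms=((chain, None if residues is None else tuple(residues),
                           atom),))

    def resolve(self, model: StructureModel) -> np.ndarray:
        """Sorted atom indices matched by any term; non-empty or error."""
        mask = np.zeros(model.n_atoms, bool)
        for chain, residues, atom in self.terms:
            mask |= model.mask(
                chains=chain,
                residues=residues,
                atom_names=atom,
            )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise StructureError(f"selection resolves to no atoms: {self.terms}")
        return idx


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _flatten_model(model: gemmi.Model, name: str) -> StructureModel:
    chain_l, resid_l, resname_l, aname_l, elem_l, occ_l = [], [], [], [], [], []
    xyz = []
    for chain in model:
        for res in chain:
            # altloc resolution: highest occupancy, ties alphabetical
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                elif (atom.occ, -ord(atom.altloc or "~")) > (
                    prev.occ, -ord(prev.altloc or "~")
                ):
                    by_name[atom.name] = atom
            for atom in res:
                if by_name.get(atom.name) is not atom:
                    continue
                chain_l.append(chain.name)
                resid_l.append(res.seqid.num)
                resname_l.append(res.name)
                aname_l.append(atom.name)
                elem_l.append(atom.element.name)
                occ_l.append(atom.occ)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return StructureModel(
        chain=np.array(chain_l),
        resid=np.array(resid_l, int),
        resname=np.array(resname_l),
        atom_name=np.array(aname_l),
        element=np.array(elem_l),
        coords=np.array(xyz, float),
        occupancy=np.array(occ_l, float),
        name=name,
    )


def read_structure(path, format: str | None = None):
    """Read a PDB or mmCIF file.

    Returns a :class:`StructureModel` for single-model files, an
    :class:`Ensemble` when several MODEL blocks with identical topology are
    present.  Mismatched topology across models raises an error naming the
    first offending atom.
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    fmt = gemmi.CoorFormat.Mmcif if format == "mmcif" else gemmi.CoorFormat.Pdb
    st = gemmi.read_structure(str(path), format=fmt)
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    models = [_flatten_model(m, name=f"model_{i + 1}") for i, m in enumerate(st)]
    if len(models) == 1:
        models[0].name = path.stem
        return models[0]
    ref_key = models[0].topology_key()
    for i, m in enumerate(models[1:], start=2):
        key = m.topology_key()
        if key != ref_key:
            for a, b in zip(zip(*ref_key), zip(*key)):
                if a != b:
                    raise StructureError(
                        f"model {i} topology differs from model 1 at atom "
                        f"{a} vs {b}"
                    )
            raise StructureError(
                f"model {i} has {m.n_atoms} atoms, model 1 has "
                f"{models[0].n_atoms}"
            )
    coords = np.stack([m.coords for m in models])
    return Ensemble(topology=models[0], coords=coords, label=path.stem)


def _to_gemmi(models: list[StructureModel], name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for k, sm in enumerate(models, start=1):
        model = gemmi.Model(k)
        cur_chain = None
        cur_res = None
        for i in range(sm.n_atoms):
            cname = str(sm.chain[i])
            if cur_chain is None or cur_chain.name != cname:
                cur_chain = gemmi.Chain(cname)
                model.add_chain(cur_chain)
                cur_chain = model[-1]
                cur_res = None
            rid = int(sm.resid[i])
            if cur_res is None or cur_res.seqid.num != rid:
                res = gemmi.Residue()
                res.name = str(sm.resname[i])
                res.seqid = gemmi.SeqId(rid, " ")
                cur_chain.add_residue(res)
                cur_res = cur_chain[-1]
            atom = gemmi.Atom()
            atom.name = str(sm.atom_name[i])
            atom.element = gemmi.Element(str(sm.element[i]))
            atom.occ = float(sm.occupancy[i])
            atom.pos = gemmi.Position(*sm.coords[i])
            cur_res.add_atom(atom)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(obj, path) -> None:
    """Write a model or ensemble as a (multi-model) PDB file."""
    path = Path(path)
    if isinstance(obj, Ensemble):
        models = list(obj)
        name = obj.label
    else:
        models = [obj]
        name = obj.name
    st = _to_gemmi(models, name)
    st.write_pdb(str(path))
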