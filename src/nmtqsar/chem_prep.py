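"""Dataset ingestion and 3D structure preparation.

Reads molecule tables (CSV / SMI / SDF), converts IC50 (µM) to pIC50, and
produces a single MMFF94-optimized, MMFF94-charged 3D conformer per molecule.
Hydrogens are always made explicit before embedding because the downstream
atom-environment descriptors count hydrogen atoms.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

log = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "PrepConfig",
    "load_dataset",
    "pic50_from_ic50",
    "prepare_3d",
    "mmff_energy",
    "write_sdf",
]


@dataclass
class MoleculeRecord:
    """One compound: identity, activity, and (after preparation) geometry.

    ``symbols``, ``coords``, ``charges``, ``formal_charges`` and ``in_ring``
    are parallel per-atom arrays; ``bonds`` is a list of
    ``(atom_i, atom_j, order)`` tuples. Atom-level fields are ``None`` until
    :func:`prepare_3d` has run (or the record was hand-built for testing).
    """

    id: str
    smiles: str
    ic50: float | None = None          # µM
    pic50: float | None = None         # -log10(molar IC50)
    symbols: list[str] | None = None
    coords: np.ndarray | None = None   # (n_atoms, 3), Å
    charges: np.ndarray | None = None  # MMFF94 partial charges, e
    formal_charges: np.ndarray | None = None
    in_ring: np.ndarray | None = None  # bool, SSSR membership
    bonds: list[tuple[int, int, float]] | None = None
    failed: str | None = None          # reason string if preparation failed
    mol: Chem.Mol | None = None        # underlying RDKit molecule (with Hs)

    @property
    def n_atoms(self) -> int:
        return 0 if self.symbols is None else len(self.symbols)

    @property
    def prepared(self) -> bool:
        return self.coords is not None and self.charges is not None

    def validate(self) -> None:
        """Check the structural invariants of a prepared record."""
        if self.ic50 is not None and self.pic50 is not None:
            if abs(self.pic50 - pic50_from_ic50(self.ic50)) > 5e-4:
                raise ValueError(f"{self.id}: pic50 inconsistent with ic50")
        if self.bonds is not None:
            n = self.n_atoms
            for i, j, _ in self.bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"{self.id}: bond ({i},{j}) out of range")
        if self.charges is not None and self.formal_charges is not None:
            if abs(self.charges.sum() - self.formal_charges.sum()) > 1e-3:
                raise ValueError(f"{self.id}: partial charges do not sum to net charge")


@dataclass
class PrepConfig:
    force_field: str = "MMFF94"
    optimizer: str = "steepest_descent"
    max_steps: int = 1000
    embed_seed: int = 42

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.force_field != "MMFF94":
            raise ValueError("only the MMFF94 force field is supported")


def pic50_from_ic50(ic50_um: float) -> float:
    """Convert an IC50 in µM to pIC50 = -log10(molar IC50).

    1 µM maps to 6.0; a 2 nM inhibitor (0.002 µM) maps to ~8.699.
    """
    if ic50_um <= 0 or not math.isfinite(ic50_um):
        raise ValueError(f"IC50 must be positive and finite, got {ic50_um!r}")
    return -math.log10(ic50_um * 1e-6)


def _records_from_rows(rows: list[tuple[str, str, float | None]]) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for row_no, (mid, smiles, ic50) in enumerate(rows, start=1):
        if mid in seen:
            raise ValueError(f"duplicate id {mid!r}")
        seen.add(mid)
        if Chem.MolFromSmiles(smiles) is None:
            warnings.warn(f"row {row_no}: unparsable SMILES {smiles!r} for id {mid!r}; skipped")
            continue
        pic50 = pic50_from_ic50(ic50) if ic50 is not None else None
        records.append(MoleculeRecord(id=mid, smiles=smiles, ic50=ic50, pic50=pic50))
    if not records:
        raise ValueError("empty dataset")
    return records


def load_dataset(path: str | Path, format: str | None = None) -> list[MoleculeRecord]:
    """Load a molecule table into records.

    CSV needs columns ``id,smiles`` and optionally ``ic50_um`` (µM); SMI rows
    are ``id <whitespace> SMILES``; SDF molecules carry an optional
    ``IC50_uM`` property. Rows without an IC50 yield prediction-only records
    (no pIC50). Unparsable SMILES are skipped with a warning naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        import pandas as pd

        df = pd.read_csv(path, dtype={"id": str})
        if df.empty:
            raise ValueError("empty dataset")
        cols = {c.lower(): c for c in df.columns}
        if "id" not in cols or "smiles" not in cols:
            raise ValueError("CSV must have 'id' and 'smiles' columns")
        ic_col = cols.get("ic50_um") or cols.get("ic50")
        rows = []
        for _, r in df.iterrows():
            ic50 = None
            if ic_col is not None and not pd.isna(r[ic_col]):
                ic50 = float(r[ic_col])
            rows.append((str(r[cols["id"]]), str(r[cols["smiles"]]), ic50))
        return _records_from_rows(rows)
    if fmt == "smi":
        rows = []
        for line in path.read_text().splitlines():
            parts = line.split()
            if len(parts) >= 2:
                rows.append((parts[0], parts[1], None))
        if not rows:
            raise ValueError("empty dataset")
        return _records_from_rows(rows)
    if fmt == "sdf":
        return _load_sdf(path)
    raise ValueError(f"unsupported format {fmt!r}")


def _load_sdf(path: Path) -> list[MoleculeRecord]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for row_no, mol in enumerate(supplier, start=1):
        if mol is None:
            warnings.warn(f"molecule {row_no}: unparsable SDF entry; skipped")
            continue
        mid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else str(row_no)
        if mid in seen:
            raise ValueError(f"duplicate id {mid!r}")
        seen.add(mid)
        ic50 = float(mol.GetProp("IC50_uM")) if mol.HasProp("IC50_uM") else None
        rec = MoleculeRecord(
            id=mid,
            smiles=Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol))),
            ic50=ic50,
            pic50=pic50_from_ic50(ic50) if ic50 is not None else None,
        )
        if mol.GetNumConformers() > 0:
            _populate_from_mol(rec, mol)
            if mol.HasProp("PARTIAL_CHARGES"):
                rec.charges = np.array([float(x) for x in mol.GetProp("PARTIAL_CHARGES").split()])
        records.append(rec)
    if not records:
        raise ValueError("empty dataset")
    return records


def _largest_fragment(mol: Chem.Mol, mol_id: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        log.info("%s: multi-fragment input; keeping largest fragment (salt stripping)", mol_id)
        frags = sorted(frags, key=lambda m: (m.GetNumHeavyAtoms(), m.GetNumAtoms()))
        return frags[-1]
    return mol


def _populate_from_mol(record: MoleculeRecord, mol: Chem.Mol) -> None:
    record.mol = mol
    record.symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    record.coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    record.formal_charges = np.array([a.GetFormalCharge() for a in mol.GetAtoms()], dtype=float)
    record.in_ring = np.array([a.IsInRing() for a in mol.GetAtoms()], dtype=bool)
    record.bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble()) for b in mol.GetBonds()
    ]


def prepare_3d(record: MoleculeRecord, config: PrepConfig | None = None) -> MoleculeRecord:
    """Embed one 3D conformer, minimize it with MMFF94 and assign MMFF94 charges.

    A single conformer is generated with a fixed embedding seed, so repeated
    runs on the same input give identical coordinates. Records whose graph
    cannot be embedded or typed by MMFF94 come back with ``failed`` set and
    are meant to be excluded downstream.
    """
    config = config or PrepConfig()
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        record.failed = "unparsable SMILES"
        log.warning("%s: %s", record.id, record.failed)
        return record
    mol = _largest_fragment(mol, record.id)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(config.embed_seed)
    cid = AllChem.EmbedMolecule(mol, params)
    if cid < 0:
        params.useRandomCoords = True
        cid = AllChem.EmbedMolecule(mol, params)
    if cid < 0:
        record.failed = "3D embedding failed"
        log.warning("%s: %s", record.id, record.failed)
        return record
    props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94")
    if props is None:
        record.failed = "MMFF94 typing failed"
        log.warning("%s: %s", record.id, record.failed)
        return record
    AllChem.MMFFOptimizeMolecule(mol, mmffVariant="MMFF94", maxIters=int(config.max_steps))
    _populate_from_mol(record, mol)
    record.charges = np.array(
        [props.GetMMFFPartialCharge(i) for i in range(mol.GetNumAtoms())], dtype=float
    )
    record.failed = None
    return record


def mmff_energy(record: MoleculeRecord) -> float:
    """MMFF94 energy (kcal/mol) of the record's current conformer."""
    if record.mol is None or record.mol.GetNumConformers() == 0:
        raise ValueError("record has no 3D conformer")
    props = AllChem.MMFFGetMoleculeProperties(record.mol, mmffVariant="MMFF94")
    ff = AllChem.MMFFGetMoleculeForceField(record.mol, props)
    return ff.CalcEnergy()


def write_sdf(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write prepared records as an SDF with charges in a PARTIAL_CHARGES property."""
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            if not rec.prepared or rec.mol is None:
                continue
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.id)
            mol.SetProp("PARTIAL_CHARGES", " ".join(f"{q:.6f}" for q in rec.charges))
            if rec.ic50 is not None:
                mol.SetProp("IC50_uM", repr(rec.ic50))
            if rec.pic50 is not None:
                mol.SetProp("pIC50", f"{rec.pic50:.6f}")
            writer.write(mol)
    finally:
        writer.close()
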