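"""Synthetic inputs for exercising the pipeline end to end.

Two kinds of fixtures: (a) descriptor matrices with a planted sparse linear
response plus the degeneracies the objective filter must catch (constant,
near-constant and collinear columns), and (b) small molecules whose
descriptor values are enumerable by hand, together with the ten published
example compounds (the five most and five least active nitrogen heterocycles
with their IC50/pIC50 values).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_prep import MoleculeRecord, pic50_from_ic50
from .descriptors import DescriptorMatrix

__all__ = [
    "SyntheticSpec", "SyntheticDataset", "SyntheticTruth", "ToyMolecule",
    "gen_descriptor_dataset", "toy_molecules", "TABLE1", "write_table1_csv",
]


# ---------------------------------------------------------------------------
# planted-signal descriptor matrices
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for a planted-signal descriptor dataset.

    Informative columns are iid standard normal; the response is a sparse
    linear combination of ``planted_subset`` with N(0, noise_sigma²) noise
    (defaults: 100 molecules, a 20-column pool, a 3-descriptor signal at
    σ = 0.1 — a high signal-to-noise regime where subset search has a unique
    right answer). Degenerate columns are appended after the informative
    block, so the planted subset is disjoint from them by construction.
    ``collinear_jitter`` > 0 softens the duplicates below |R| = 1 so the
    correlation cutoff can be probed from both sides.
    """

    n_molecules: int = 100
    n_descriptors: int = 20
    n_constant: int = 2
    n_near_constant: int = 2
    n_collinear_pairs: int = 2
    planted_subset: tuple[int, ...] = (3, 7, 11)
    beta: tuple[float, ...] = (1.0, -1.5, 2.0)
    noise_sigma: float = 0.1
    collinear_jitter: float = 0.0
    near_constant_frac: float = 0.96
    seed: int = 0

    @property
    def n_informative(self) -> int:
        return (self.n_descriptors - self.n_constant - self.n_near_constant
                - self.n_collinear_pairs)

    def validate(self) -> None:
        if self.n_informative < 1:
            raise ValueError("degenerate columns leave no informative columns")
        if len(self.planted_subset) != len(self.beta):
            raise ValueError("planted_subset and beta lengths differ")
        if any(i >= self.n_informative or i < 0 for i in self.planted_subset):
            raise ValueError("planted subset must index informative columns "
                             "(disjoint from degenerate ones)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_molecules < 4:
            raise ValueError("need at least 4 molecules")


@dataclass
class SyntheticTruth:
    planted_names: list[str]
    beta: dict[str, float]
    noise_sigma: float
    constant_names: list[str]
    near_constant_names: list[str]
    collinear_map: dict[str, str]  # duplicate -> source column


@dataclass
class SyntheticDataset:
    X: DescriptorMatrix
    y: np.ndarray
    truth: SyntheticTruth


def gen_descriptor_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Generate a descriptor matrix with known degeneracies and a planted response."""
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, n_info = spec.n_molecules, spec.n_informative

    info = rng.standard_normal((n, n_info))
    y = info[:, list(spec.planted_subset)] @ np.asarray(spec.beta, dtype=float)
    if spec.noise_sigma > 0:
        y = y + rng.normal(0.0, spec.noise_sigma, size=n)

    cols = [info]
    names = [f"d{i:03d}" for i in range(n_info)]
    prov = {nm: {"family": "informative"} for nm in names}

    const_names = []
    for i in range(spec.n_constant):
        cols.append(np.full((n, 1), float(i + 1)))
        nm = f"const{i}"
        names.append(nm)
        const_names.append(nm)
        prov[nm] = {"family": "constant"}

    nc_names = []
    n_mode = int(np.ceil(spec.near_constant_frac * n))
    for i in range(spec.n_near_constant):
        col = np.zeros(n)
        off = rng.choice(n, size=n - n_mode, replace=False)
        col[off] = 1.0 + i
        cols.append(col[:, None])
        nm = f"nearconst{i}"
        names.append(nm)
        nc_names.append(nm)
        prov[nm] = {"family": "near_constant"}

    col_map = {}
    for i in range(spec.n_collinear_pairs):
        src = int(rng.integers(n_info))
        dup = 2.0 * info[:, src]
        if spec.collinear_jitter > 0:
            dup = dup + rng.normal(0.0, spec.collinear_jitter, size=n)
        cols.append(dup[:, None])
        nm = f"dup{i}_of_d{src:03d}"
        names.append(nm)
        col_map[nm] = f"d{src:03d}"
        prov[nm] = {"family": "collinear", "source": f"d{src:03d}"}

    X = DescriptorMatrix(
        ids=[f"mol{i:03d}" for i in range(n)],
        names=names,
        values=np.hstack(cols),
        provenance=prov,
    )
    truth = SyntheticTruth(
        planted_names=[f"d{i:03d}" for i in spec.planted_subset],
        beta={f"d{i:03d}": b for i, b in zip(spec.planted_subset, spec.beta)},
        noise_sigma=spec.noise_sigma,
        constant_names=const_names,
        near_constant_names=nc_names,
        collinear_map=col_map,
    )
    return SyntheticDataset(X=X, y=y, truth=truth)


# ---------------------------------------------------------------------------
# hand-enumerable molecules and the published example table
# ---------------------------------------------------------------------------

# (id, SMILES, IC50 µM, printed pIC50, printed decimal places)
TABLE1: list[tuple[str, str, float, float, int]] = [
    ("20", "Cn(n1)c(C)c(c1C)N(C(F)F)S(=O)(=O)c(c(Cl)c2)c(Cl)cc2CCCO[C@H](C3)C[C@@H](N4C)CC[C@H]34", 0.002, 8.699, 3),
    ("73", "Cn(n1)c(C)c(c1C)NS(=O)(=O)c(c(Cl)c2)c(Cl)cc2-c3cc(ncc3)N4CCNCC4", 0.003, 8.523, 3),
    ("2", "Cn(n1)c(C)c(c1C)NS(=O)(=O)c(cc2)c(Cl)cc2-c3cc(ncc3)N4CCNCC4", 0.004, 8.398, 3),
    ("78", "CC(C)Cc1c(c(C)n(n1)C)NS(=O)(=O)c(c(Cl)c2)c(Cl)cc2-c3cc(ncc3)N4CCNCC4", 0.004, 8.398, 3),
    ("95", "C1CN(C)CCC1CCCCc2cc(Cl)c(c(Cl)c2)S(=O)(=O)Nc(c3C)c(C)n(n3)C", 0.004, 8.398, 3),
    ("293", "CC(C)Cc1ccc2ncccc2c1NS(=O)(=O)c1ccc(CCCO[C@H]2C[C@@H]3CC[C@H](C2)N3C)cc1", 27000.0, 1.569, 3),
    ("82", "Cc1c(C)c(OC)cc(C)c1S(=O)(=O)Nc(c2C)cccn2", 70000.0, 1.155, 3),
    ("83", "Cn1ncc(c1C)NS(=O)(=O)c2c(Cl)cc(Br)cc2Cl", 70800.0, 1.15, 2),
    ("84", "Cn(n1)c(C)c(c1C)NS(=O)(=O)c(c2F)ccc(Br)c2", 87000.0, 1.06, 2),
    ("111", "Cn(n1)c(C)c(c1C)NS(=O)(=O)c(c2C)ccc(Br)c2", 107000.0, 0.971, 3),
]


@dataclass
class ToyMolecule:
    """A fixture molecule together with its hand-derived expected values."""

    record: MoleculeRecord
    expected: dict = field(default_factory=dict)


def toy_molecules() -> list[ToyMolecule]:
    """Hand-enumerable micro-molecules plus the ten published examples.

    Expected values were derived by hand: topological frequencies by path
    enumeration on the molecular graph, ``fringNH2A`` from covalent N–H
    geometry (an N–H bond is ~1.01 Å, inside the [1, 2) Å shell, while every
    C–H hydrogen of a five-membered azole sits beyond 2 Å from the ring N).
    """
    toys = [
        ToyMolecule(MoleculeRecord(id="methane", smiles="C"),
                    {"fNH4B": 0, "flipoH3B": 0, "fringNH2A": 0, "n_atoms": 5}),
        ToyMolecule(MoleculeRecord(id="water", smiles="O"),
                    {"fNH4B": 0, "C_AbSA": 0.0}),
        ToyMolecule(MoleculeRecord(id="ammonia", smiles="N"),
                    {"fNH4B": 0, "fringNH2A": 0}),
        ToyMolecule(MoleculeRecord(id="cyclohexane", smiles="C1CCCCC1"),
                    {"fringNH2A": 0, "fNH4B": 0}),
        ToyMolecule(MoleculeRecord(id="pyrrole", smiles="c1cc[nH]c1"),
                    {"fringNH2A": 1}),
        # n-propylamine: the three methyl H are 4 bonds from the single N
        ToyMolecule(MoleculeRecord(id="n-propylamine", smiles="NCCC"),
                    {"fNH4B": 3}),
        # chloromethanol: only the hydroxyl H is exactly 3 bonds from Cl
        # (H-O-C-Cl); the two methylene H are 2 bonds away, hence excluded
        ToyMolecule(MoleculeRecord(id="chloromethanol", smiles="OCCl"),
                    {"flipoH3B": 1}),
    ]
    for mid, smiles, ic50, pic50_printed, decimals in TABLE1:
        toys.append(ToyMolecule(
            MoleculeRecord(id=mid, smiles=smiles, ic50=ic50,
                           pic50=pic50_from_ic50(ic50)),
            {"pic50_printed": pic50_printed, "pic50_decimals": decimals},
        ))
    return toys


def write_table1_csv(path: str | Path) -> Path:
    """Write the ten published example compounds as a loadable CSV fixture."""
    path = Path(path)
    lines = ["id,smiles,ic50_um"]
    lines += [f"{mid},{smiles},{ic50}" for mid, smiles, ic50, _, _ in TABLE1]
    path.write_text("\n".join(lines) + "\n")
    return path
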