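"""Non-dynamic comparison descriptors: residue scales on an MSA, and ECFP6.

Residue-scale descriptors assign each amino acid a fixed numeric vector of
width ``d`` and lay those vectors out position-major over the columns of a
reference alignment, zero-filling gap columns — the same layout rs3DDPDs use,
so the two are directly exchangeable in a model matrix.

Numeric tables shipped:

* ``zscale_hellberg`` (d=5): the five-component extended z-scale set
  (Sandberg et al., J Med Chem 1998), transcribed from the standard reprints.
* ``zscale_vanwesten`` (d=3): the original three-component z-scales
  (Hellberg et al., J Med Chem 1987).
* ``physchem`` (d=3): Kyte-Doolittle hydropathy (J Mol Biol 1982), average
  residue mass, and a conventional side-chain charge at pH 7 (+1 K/R, +0.1 H,
  -1 D/E, 0 otherwise).
* ``mswhim`` (d=3) and ``stscale`` (d=8): SYNTHETIC stand-ins.  The published
  MS-WHIM and ST-scale value tables were not available when this package was
  assembled; these tables are deterministic orthogonal recombinations of the
  embedded z-scale + physicochemical property matrix with the published
  dimensionalities.  They behave like real scales structurally (fixed width,
  20 amino acids) but their values are not the literature values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .msa import MSA

__all__ = [
    "ResidueScaleTable",
    "SCALE_NAMES",
    "get_scale",
    "scale_descriptor",
    "ecfp6",
    "featurize_compounds",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ResidueScaleTable:
    """A named per-amino-acid numeric table of fixed width."""

    name: str
    width: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = sorted(set(STANDARD_AA) - set(self.values))
        if missing:
            raise ValueError(f"scale {self.name!r} lacks amino acids {missing}")
        for aa, vec in self.values.items():
            if vec.shape != (self.width,):
                raise ValueError(
                    f"scale {self.name!r}: {aa} row has width {vec.shape}, "
                    f"expected {self.width}"
                )

    def row(self, aa: str) -> np.ndarray:
        if aa not in self.values:
            raise ValueError(f"non-standard residue code {aa!r}")
        return self.values[aa]


def _load_csv(filename: str) -> pd.DataFrame:
    with resources.files("ddpd.data").joinpath(filename).open() as fh:
        return pd.read_csv(fh)


def _table_from_df(name: str, df: pd.DataFrame) -> ResidueScaleTable:
    cols = [c for c in df.columns if c != "aa"]
    values = {
        str(row["aa"]): row[cols].to_numpy(dtype=float) for _, row in df.iterrows()
    }
    return ResidueScaleTable(name=name, width=len(cols), values=values)


def _synthetic_scale(name: str, width: int, seed: int) -> ResidueScaleTable:
    """SYNTHETIC scale: a seeded orthogonal recombination of real properties.

    Stand-in for a published table that could not be shipped; see the module
    docstring.  Deterministic under the fixed seed baked into the registry.
    """
    z5 = _table_from_df("z", _load_csv("zscale5.csv"))
    pc = _table_from_df("p", _load_csv("physchem.csv"))
    aas = sorted(STANDARD_AA)
    base = np.array([np.concatenate([z5.values[a], pc.values[a]]) for a in aas])
    base = (base - base.mean(0)) / base.std(0)
    rng = np.random.default_rng(seed)
    # random orthonormal mixing columns
    q, _ = np.linalg.qr(rng.normal(size=(base.shape[1], base.shape[1])))
    mixed = np.round(base @ q[:, :width], 2)
    return ResidueScaleTable(
        name=name, width=width, values={a: mixed[i] for i, a in enumerate(aas)}
    )


_REGISTRY: dict[str, ResidueScaleTable] = {}


def get_scale(name: str) -> ResidueScaleTable:
    """Look up a scale table by registry name (see :data:`SCALE_NAMES`)."""
    if not _REGISTRY:
        _REGISTRY["zscale_hellberg"] = _table_from_df(
            "zscale_hellberg", _load_csv("zscale5.csv")
        )
        _REGISTRY["zscale_vanwesten"] = _table_from_df(
            "zscale_vanwesten", _load_csv("zscale3.csv")
        )
        _REGISTRY["physchem"] = _table_from_df("physchem", _load_csv("physchem.csv"))
        _REGISTRY["mswhim"] = _synthetic_scale("mswhim", 3, seed=20990101)
        _REGISTRY["stscale"] = _synthetic_scale("stscale", 8, seed=20990102)
    if name not in _REGISTRY:
        raise KeyError(f"unknown scale {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name]


SCALE_NAMES = ("zscale_hellberg", "zscale_vanwesten", "mswhim", "stscale", "physchem")


def scale_descriptor(msa: MSA, target_id: str, table: ResidueScaleTable):
    """Position-major scale descriptor of length ``d * L``; gaps are zero blocks."""
    from .descriptor import DescriptorVector  # local import to avoid a cycle

    seq = msa.sequence(target_id)
    cmap = msa.map_for(target_id)
    d, L = table.width, msa.n_columns
    values = np.zeros(d * L)
    for res_idx, col in enumerate(cmap):
        values[(col - 1) * d : col * d] = table.row(seq[res_idx])
    names = [
        f"AA{col}_{table.name}{j}"
        for col in range(1, L + 1)
        for j in range(1, d + 1)
    ]
    return DescriptorVector(
        kind="scale",
        values=values,
        feature_names=names,
        target_id=target_id,
        config_fingerprint=f"scale={table.name}",
    )


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=1024)


def ecfp6(smiles: str) -> np.ndarray:
    """Folded Morgan fingerprint of radius 3 (ECFP6), 1024 bits.

    Deterministic per canonical molecule, so SMILES rewritings of the same
    structure hash to the same bit vector.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    return _MORGAN.GetFingerprintAsNumPy(mol).astype(np.uint8)


def featurize_compounds(smiles_list) -> dict[str, np.ndarray]:
    """ECFP6 fingerprints for a collection of SMILES, keyed by the input string."""
    return {s: ecfp6(s) for s in dict.fromkeys(smiles_list)}
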